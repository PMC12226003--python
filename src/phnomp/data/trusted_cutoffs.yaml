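# Per-family trusted bit-score cutoffs for the 14 phn profile HMMs.
#
# A hit is accepted when its full-sequence bit score is >= the model's
# trusted cutoff. These defaults are the thresholds used by the synthetic
# survey generator and the examples; for a real screen, replace them with
# the TC line of each curated profile actually searched (every published
# phn model family carries its own curated threshold).
phnC: 112.6
phnD: 135.0
phnE: 118.4
phnF: 71.2
phnG: 55.0
phnH: 64.8
phnI: 160.3
phnJ: 188.9
phnK: 130.5
phnL: 88.7
phnM: 142.1
phnN: 60.9
phnO: 47.3
phnP: 93.6
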