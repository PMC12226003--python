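# Methods

## Cluster screening

### Rule

A *phn* cluster call on one contig is valid when three clauses hold
simultaneously:

1. **Count** — at least `k = 5` *distinct* families among the 14 screened
   (*phnC…phnP*). Distinct families, not hits: tandem paralogs of one gene
   cannot fake a cluster. All 14 families count toward `k`, including the
   regulator *phnF* and the accessories *phnN–P*.
2. **Window** — the members' joint span, leftmost start to rightmost end
   (1-based inclusive), is ≤ `W = 16,000` nt. The span metric is applied
   identically in the scanner and the brute-force oracle, so the choice is
   self-consistent; it is configurable.
3. **Core** — *phnK*, *phnL* and *phnM* (the named essentials of the C–P
   lyase complex) are all present. The core set is configurable.

Strand is ignored (operons can be re-arranged across genomes and the rule
names no strand condition). Gene-to-family assignment keeps hits whose
full-sequence bit score meets the per-model trusted cutoff, then takes the
highest-scoring hit per gene, breaking exact ties by the lexicographically
smallest family name so results are order-independent.

### Algorithm

Phn-assigned genes are sorted by start. For each index *i* the run *i..j*
is extended while the joint span fits in `W`; runs contained in a previous
maximal run are skipped. This is correct for the verdict because any gene
subset with span ≤ W lies inside such a maximal run, whose family set is a
superset — so a contig has a valid subset iff it has a valid maximal run.
Candidates sharing genes are merged when the merged span still fits
(with the two-pointer construction this is rare by construction, but the
rule keeps one biological cluster to one call). Invalid candidates are kept
and flagged, never dropped, so a screen is auditable.

`brute_force_scan` re-derives calls definitionally: depth-first enumeration
of *every* subset of phn genes, pruning only on the span bound (span is
monotone under adding genes, so pruning loses no subset that could ever
fit) and refusing contigs with more than 25 phn genes. It exists only as a
test oracle and is exercised against the scanner on hundreds of random
contigs.

### Trusted cutoffs

The packaged table (`data/trusted_cutoffs.yaml`) provides one bit-score
threshold per family. Published curated profiles each carry their own
trusted cutoff; those numbers are part of the external profile data, so the
packaged values are documented synthetic defaults used by the simulator and
examples. A real screen passes its own table (`--cutoffs`, YAML or TSV).

### Survey rollups

Prevalence is reported overall, per habitat (closed vocabulary:
freshwater, aquatic, soil, sediment, unknown) and per taxonomic rank
(GTDB-prefixed phylum and order by default). Percentages are rounded
half-up to one decimal — under this convention the count pair
(1445, 16671) reports 8.7% (≈9% at zero decimals) and (127, 1153) reports
11.0%. Report rendering may collapse taxa below a share threshold into
"other", but stored counts are never collapsed.

## Headspace quantitation

### Chain and assumptions

GC-FID peak areas map to mixing ratios through an OLS standard curve
(default standards 2.02, 4.99, 10.1, 100, 1000 ppm; intercept free, a
through-origin flag exists). The curve must have a positive slope; a flat
response is rejected as non-physical.

The bottle inventory assumes full liquid/headspace equilibrium at every
sampling (bottles shaken at 120 rpm; no kinetic transfer model) and a
fixed headspace pressure of 1 atm — biogenic overpressure at μM scale is
negligible. Defaults: 20 mL medium, 105 mL headspace, 125 mL bottle,
303.15 K, salinity 0. Reported concentrations are totals
(headspace + dissolved) per liquid volume, which makes volumetric rates
and the dissolved-phosphorus mass balance directly comparable.

The Bunsen coefficient uses the standard CH₄ seawater-solubility
polynomial in T and S; coefficients, units and source are recorded in
`data/bunsen_ch4.yaml` rather than hard-coded, with a tabulated spot value
(β = 0.0315 at 298.15 K, S = 0) kept alongside as a cross-check. Valid
range 273–313 K, 0–40 ‰; outside it the function raises rather than
extrapolates.

### Rates, stoichiometry, regulation

The default rate estimator is the OLS slope of concentration vs time
within a window, pooling replicates by simple concatenation (repeated time
values are expected); an endpoint estimator (ΔC/Δt of the window-edge
means) is retained for comparison. Which estimator and window a study
means by "average rate" is genuinely open; both are exposed and the
regression default is stated in every report.

DOP is computed pointwise as TDP − DIP. Stoichiometry is cumulative:
ΔCH₄(t) = CH₄(t) − CH₄(0) against ΔDOP(t) = DOP(0) − DOP(t). Ratios are
undefined (NaN, never an exception) when |ΔDOP| is below a floor (default
10⁻³ μM — well under the drawdown at the first sampled timepoint of a
typical series, but guarding true zero-drawdown division). Negative
apparent DOP (DIP > TDP, an analytical artifact) sets a flag; values are
never clamped.

Dose–response uses the Spearman rank correlation of treatment-mean final
CH₄ vs initial Pi (≥ 3 levels), with a monotone-decreasing flag requiring
both ρ < 0 and non-increasing consecutive means within a noise tolerance.
The repression test is a two-sample t-test, Welch (unequal-variance)
two-sided by default with α = 0.05, with one-sided and pooled options. The
pooled form is the exact-level choice under an equal-variance null (Welch
is conservative at n = 3 + 3), which is why the type-I calibration uses
it; Welch remains the safer default for real treatment comparisons.

## Synthetic data

### Survey generator

Each genome gets 1–2 contigs of 120 kb, background genes at ~1 per 10 kb
(a few carry non-phn model hits or sub-cutoff phn hits, exercising the
reader's drop counter and the cutoff filter), a habitat drawn from a mix
echoing a large multi-habitat genome corpus (freshwater ≈ 7%), and a
GTDB-style lineage; positives are drawn Pseudomonadota with probability
0.96, matching the taxonomic skew real surveys report. Planted positives
lay all 14 families head-to-tail with realistic per-family gene lengths
and 20–200 nt gaps; the realized span is asserted against the window, with
a minimal-gap retry (the spec of gene lengths guarantees feasibility, else
the generator refuses the spec).

Each decoy class violates exactly one clause: `four_gene` (4 families,
core present, compact), `missing_core` (13 families, no *phnK*),
`overspread` (8 families incl. core at 5–6 kb gaps: no 16-kb window holds
5 of them), `split_contig` (families split 4/3 over two contigs, neither
side valid), `subthreshold_scores` (full architecture, all scores at
0.3–0.9× cutoff). Planted counts are exact (`round(n × rate)`), outputs
are byte-identical given a seed, and the truth table lists every genome's
role.

What passing screens on this generator shows: the calling rule and its
negative controls are implemented correctly. What it does not show:
performance on real annotation (fragmented assemblies, overlapping or
mis-called ORFs, profile cross-hits between phn families), since no
sequence is simulated and hits are planted, not searched.

### Incubation generator

CH₄ accumulates piecewise linearly: slope `lag_rate` (default 4.0
nmol L⁻¹ h⁻¹) through a 24 h lag, then `planted_rate` (default 92) — the
two slopes are independent parameters, reflecting that lag-phase
metabolism and exponential-phase production are distinct quantities. The
cumulative CH₄:DOP ratio is planted *directly* as a trajectory (0.4 during
the lag, linear ramp to 1.0 by 216 h) and DOP is derived as
`dop0 − ΔCH₄/ratio`; no mechanistic uptake kinetics are claimed — the
generator's job is to make the reported statistic recoverable, nothing
more. The initial MPn-phosphorus pool is 200 μM. Pi treatments scale both
slopes by `1/(1 + Pi/Km)` with Km = 10 μM, a monotone inhibition
consistent with near-complete suppression a few tens of μM Pi. Sampling
follows the bench schedule: every 3–6 h for the first day, then every
48 h to 288 h. Headspace ppm is back-computed through the same equilibrium
partition the quantitation arm inverts, so noise-free data round-trip to
machine precision. Gaussian relative noise (2% ppm, 5% TDP/DIP, 10% cells)
is resampled, never clamped, when a draw goes negative.

## Numerical and reporting choices

* Coordinates 1-based inclusive everywhere; span = end − start + 1.
* Percentages: decimal half-up rounding (8.65 → 8.7), not banker's.
* G+C%: (G+C)/(A+C+G+T) × 100, ambiguity codes excluded from the
  denominator, one decimal; documented because the convention changes the
  last digit on real genomes.
* Gas constants: R = 0.082057 L atm mol⁻¹ K⁻¹, molar volume 22.414 L mol⁻¹
  at STP (consistent with the Bunsen definition).
* Problem sizes in tests and the acceptance script (500 oracle contigs of
  ≤ 20 genes, 200-genome surveys, 100 noisy incubations, 10,000-rep t-test
  null) are desk-scale choices that keep the full suite under a minute
  while leaving Monte-Carlo errors far smaller than the effects checked.

## Known limitations

* The screener consumes hit tables; it does not run HMM searches, so
  results inherit whatever profiles and cutoffs the user searched with.
* Habitat vocabulary is closed; corpora with other biomes must map or
  accept "unknown".
* The equilibrium headspace model has no mass-transfer kinetics and no
  CO₂/pH chemistry; it is correct for vigorously shaken bottles only.
* The incubation generator is phenomenological (piecewise-linear CH₄,
  planted ratio trajectory); it cannot test growth-kinetics inference,
  which the package deliberately does not offer.
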