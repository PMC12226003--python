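"""Cluster calling rule, the brute-force oracle, and survey rollups."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phnomp.io_model import DomainHit, GeneFeature, GenomeRecord, ValidationError
from phnomp.cluster_screen import (
    assign_families,
    brute_force_scan,
    brute_force_verdict,
    calls_to_frame,
    round_pct,
    scan_contig,
    screen_genome,
    summarize_survey,
)

from conftest import build_contig, operon_layout, random_contig


# ---------------------------------------------------------------------------
# Family assignment
# ---------------------------------------------------------------------------

def test_assignment_cutoff_and_max_score_rules():
    hits = [
        DomainHit("g1", "phnJ", 120.0, 1e-30, 100.0),   # above cutoff -> kept
        DomainHit("g2", "phnJ", 80.0, 1e-10, 100.0),    # below cutoff -> dropped
        DomainHit("g3", "phnC", 150.0, 1e-40, 90.0),    # highest for g3
        DomainHit("g3", "phnD", 140.0, 1e-38, 90.0),
    ]
    out = {a.gene_id: a.family for a in assign_families(hits)}
    assert out == {"g1": "phnJ", "g3": "phnC"}


def test_assignment_tie_breaks_lexicographically():
    hits = [
        DomainHit("g", "phnM", 150.0, 1e-40, 90.0),
        DomainHit("g", "phnD", 150.0, 1e-40, 90.0),
    ]
    (a,) = assign_families(hits)
    assert a.family == "phnD"
    assert assign_families([]) == []


# ---------------------------------------------------------------------------
# Contig scanning
# ---------------------------------------------------------------------------

def test_full_operon_within_window_is_valid(cutoffs):
    families = ["phnC", "phnD", "phnE", "phnF", "phnG", "phnH", "phnI",
                "phnJ", "phnK", "phnL", "phnM"]
    feats, hits = build_contig(operon_layout(families, gene_len=1000, gap=90),
                               cutoffs)
    calls = scan_contig(feats, assign_families(hits))
    assert len(calls) == 1
    call = calls[0]
    assert call.valid and call.window_ok and call.core_ok
    assert call.span_nt <= 12_000


def test_missing_core_gene_invalidates(cutoffs):
    """Six families in 10 kb, but no phnK anywhere: core check fails."""
    feats, hits = build_contig(
        operon_layout(["phnG", "phnH", "phnI", "phnJ", "phnL", "phnM"]),
        cutoffs)
    (call,) = scan_contig(feats, assign_families(hits))
    assert call.window_ok and not call.core_ok and not call.valid


def test_four_families_with_core_still_invalid(cutoffs):
    feats, hits = build_contig(
        operon_layout(["phnK", "phnL", "phnM", "phnJ"]), cutoffs)
    (call,) = scan_contig(feats, assign_families(hits))
    assert call.core_ok and call.window_ok
    assert len(call.families_present) == 4 < 5
    assert not call.valid


def test_overspread_genes_yield_no_valid_call(cutoffs):
    """7 phn genes over 40 kb: no 16-kb window covers 5 of them.

    Verdict cross-checked against exhaustive subset enumeration.
    """
    families = ["phnC", "phnJ", "phnK", "phnL", "phnM", "phnN", "phnP"]
    layout = [(fam, 1 + 6000 * i, 1 + 6000 * i + 899)
              for i, fam in enumerate(families)]  # starts 6 kb apart
    feats, hits = build_contig(layout, cutoffs)
    ass = assign_families(hits)
    assert not any(c.valid for c in scan_contig(feats, ass))
    assert brute_force_verdict(feats, ass) is False


def test_duplicate_paralogs_count_once(cutoffs):
    """Five genes but only 4 distinct families (two phnJ copies): invalid."""
    layout = operon_layout(["phnJ", "phnJ", "phnK", "phnL", "phnM"])
    feats, hits = build_contig(layout, cutoffs)
    (call,) = scan_contig(feats, assign_families(hits))
    assert len(call.member_gene_ids) == 5
    assert len(call.families_present) == 4
    assert not call.valid


def test_unknown_gene_id_in_assignment_rejected(cutoffs):
    feats, hits = build_contig(operon_layout(["phnJ"]), cutoffs)
    ass = assign_families(hits + [DomainHit("ghost", "phnK", 500.0, 1e-50, 130.5)])
    with pytest.raises(ValidationError, match="ghost"):
        scan_contig(feats, ass)


# ---------------------------------------------------------------------------
# Genome-level screening
# ---------------------------------------------------------------------------

def _genome(contig_layouts, cutoffs):
    features_by_contig = {}
    all_hits = []
    contigs = []
    for i, (layout, factor) in enumerate(contig_layouts, start=1):
        cid = f"c{i}"
        feats, hits = build_contig(layout, cutoffs, contig_id=cid,
                                   score_factor=factor)
        features_by_contig[cid] = feats
        all_hits += hits
        contigs.append((cid, 200_000))
    rec = GenomeRecord("G1", "soil", ("d__Bacteria",), tuple(contigs))
    return rec, features_by_contig, assign_families(all_hits)


def test_screen_genome_positive_on_any_contig(cutoffs):
    valid = operon_layout(["phnC", "phnD", "phnK", "phnL", "phnM", "phnJ"])
    empty = [(None, 100, 900)]
    rec, feats, ass = _genome([(empty, 2.0), (valid, 2.0)], cutoffs)
    positive, calls = screen_genome(rec, feats, ass)
    assert positive
    assert any(c.valid for c in calls)


def test_screen_genome_invalid_candidates_reported(cutoffs):
    bad = operon_layout(["phnG", "phnH", "phnI", "phnJ", "phnL"])  # no K/M
    rec, feats, ass = _genome([(bad, 2.0)], cutoffs)
    positive, calls = screen_genome(rec, feats, ass)
    assert not positive
    assert len(calls) == 1 and not calls[0].valid


def test_screen_genome_no_assignments(cutoffs):
    rec, feats, ass = _genome([([(None, 100, 900)], 2.0)], cutoffs)
    positive, calls = screen_genome(rec, feats, ass)
    assert not positive and calls == []


def test_screen_genome_unknown_contig_rejected(cutoffs):
    feats, hits = build_contig(operon_layout(["phnJ"]), cutoffs, contig_id="cX")
    rec = GenomeRecord("G1", "soil", (), (("c1", 1000),))
    with pytest.raises(ValidationError, match="cX"):
        screen_genome(rec, {"cX": feats}, assign_families(hits))


def test_subthreshold_scores_are_invisible(cutoffs):
    feats, hits = build_contig(
        operon_layout(["phnC", "phnD", "phnK", "phnL", "phnM"]),
        cutoffs, score_factor=0.5)
    assert assign_families(hits) == []


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def test_brute_force_guard(cutoffs):
    layout = [("phnJ", 1 + 2000 * i, 900 + 2000 * i) for i in range(26)]
    feats, hits = build_contig(layout, cutoffs)
    with pytest.raises(ValueError, match="25"):
        brute_force_scan(feats, assign_families(hits))


def test_brute_force_trivial_cases(cutoffs):
    assert brute_force_scan([], []) == []
    feats, hits = build_contig(operon_layout(["phnJ"]), cutoffs)
    calls = brute_force_scan(feats, assign_families(hits))
    assert not any(c.valid for c in calls)


def test_brute_force_maximal_subset_matches_scanner(cutoffs):
    families = ["phnC", "phnD", "phnK", "phnL", "phnM", "phnJ"]
    feats, hits = build_contig(operon_layout(families), cutoffs)
    ass = assign_families(hits)
    bf = [c for c in brute_force_scan(feats, ass) if c.valid]
    sc = [c for c in scan_contig(feats, ass) if c.valid]
    assert len(bf) == len(sc) == 1
    assert set(bf[0].member_gene_ids) == set(sc[0].member_gene_ids)


def test_oracle_equivalence_random_contigs(cutoffs):
    """Scanner and exhaustive-subset oracle agree on 500 random contigs."""
    rng = np.random.default_rng(20_240_901)
    for _ in range(500):
        feats, hits = random_contig(rng, cutoffs)
        ass = assign_families(hits)
        fast = any(c.valid for c in scan_contig(feats, ass))
        assert fast == brute_force_verdict(feats, ass)


# ---------------------------------------------------------------------------
# Properties (seeded via hypothesis derandomization)
# ---------------------------------------------------------------------------

@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_permutation_invariance(seed):
    """Verdicts do not depend on input ordering of features or hits."""
    from phnomp.io_model import default_trusted_cutoffs
    cut = default_trusted_cutoffs()
    rng = np.random.default_rng(seed)
    feats, hits = random_contig(rng, cut, max_genes=12)
    ass = assign_families(hits)
    base = any(c.valid for c in scan_contig(feats, ass))
    perm = rng.permutation(len(feats))
    feats2 = [feats[i] for i in perm]
    hits2 = [hits[i] for i in rng.permutation(len(hits))]
    assert any(c.valid for c in scan_contig(feats2, assign_families(hits2))) == base


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_window_monotonicity(seed):
    """Enlarging W never loses a positive; shrinking never creates one."""
    from phnomp.io_model import default_trusted_cutoffs
    cut = default_trusted_cutoffs()
    rng = np.random.default_rng(seed)
    feats, hits = random_contig(rng, cut, max_genes=12)
    ass = assign_families(hits)
    verdicts = [any(c.valid for c in scan_contig(feats, ass, W=w))
                for w in (8_000, 16_000, 32_000)]
    assert verdicts == sorted(verdicts)  # monotone non-decreasing in W


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_evidence_monotonicity(seed):
    """Adding one more phn-assigned gene never turns a positive negative."""
    from phnomp.io_model import default_trusted_cutoffs
    cut = default_trusted_cutoffs()
    rng = np.random.default_rng(seed)
    feats, hits = random_contig(rng, cut, max_genes=12)
    ass = assign_families(hits)
    before = any(c.valid for c in scan_contig(feats, ass))
    extra_f, extra_h = random_contig(rng, cut, max_genes=1)
    if not extra_f:
        return
    f, h = extra_f[0], extra_h[0]
    gid = "extra_gene"
    feats2 = feats + [GeneFeature("c1", gid, f.start, f.end)]
    hits2 = hits + [DomainHit(gid, h.family, h.bit_score, h.e_value,
                              h.trusted_cutoff)]
    after = any(c.valid for c in scan_contig(feats2, assign_families(hits2)))
    assert after or not before


# ---------------------------------------------------------------------------
# Survey rollups
# ---------------------------------------------------------------------------

def test_reported_prevalence_fractions():
    """The printed survey fractions reproduce from the raw counts."""
    assert round_pct(1445, 16671) == 8.7
    assert round_pct(1445, 16671, digits=0) == 9.0   # rendered "~9%"
    assert round_pct(127, 1153) == 11.0


def test_round_pct_half_up():
    assert round_pct(865, 10000) == 8.7   # 8.65 rounds up, not to even
    assert round_pct(0, 10) == 0.0
    with pytest.raises(ValidationError):
        round_pct(1, 0)


def _records(n, habitat="soil", phylum="p__Pseudomonadota"):
    return [GenomeRecord(f"G{i}", habitat,
                         ("d__Bacteria", phylum, "o__Burkholderiales"))
            for i in range(n)]


def test_summary_counts_and_conservation():
    records = _records(6, "soil") + _records(4, "freshwater")
    # relabel the freshwater ones uniquely
    records = records[:6] + [
        GenomeRecord(f"F{i}", "freshwater", ("d__Bacteria", "p__Bacteroidota"))
        for i in range(4)]
    verdicts = {r.genome_id: i % 2 == 0 for i, r in enumerate(records)}
    s = summarize_survey(records, verdicts)
    assert s.total_genomes == 10
    assert s.positive_genomes == sum(verdicts.values())
    assert sum(t for t, _, _ in s.by_habitat.values()) == s.total_genomes
    assert sum(p for _, p, _ in s.by_habitat.values()) == s.positive_genomes
    phylum_counts = {k: v for k, v in s.by_rank.items() if k[0] == "phylum"}
    assert sum(t for t, _, _ in phylum_counts.values()) == s.total_genomes


def test_summary_rejects_empty_and_stray_verdicts():
    with pytest.raises(ValidationError, match="no genomes"):
        summarize_survey([], {})
    records = _records(2)
    with pytest.raises(ValidationError, match="GX"):
        summarize_survey(records, {"GX": True})


def test_summary_json_collapses_rare_taxa_in_report_only():
    records = _records(249) + [
        GenomeRecord("R1", "soil", ("d__Bacteria", "p__Rare", "o__Rareales"))]
    verdicts = {r.genome_id: False for r in records}
    s = summarize_survey(records, verdicts)
    text = s.to_json(collapse_below_pct=1.0)
    assert "p__Rare" not in text and "other" in text
    # counts themselves are never collapsed
    assert ("phylum", "p__Rare") in s.by_rank


def test_calls_to_frame_columns(cutoffs):
    feats, hits = build_contig(
        operon_layout(["phnC", "phnD", "phnK", "phnL", "phnM"]), cutoffs)
    df = calls_to_frame(scan_contig(feats, assign_families(hits)))
    assert list(df["valid"]) == [True]
    assert df.loc[0, "n_families"] == 5
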