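"""phn gene-cluster calling and the habitat/taxonomy prevalence survey.

A valid phn cluster on a contig requires

* at least ``k`` (default 5) *distinct* phn families among co-localized
  genes (paralogous copies of one family count once),
* a joint span (leftmost start to rightmost end, 1-based inclusive) of at
  most ``W`` (default 16,000 nt) on a single contig, and
* all of the C-P lyase core genes phnK, phnL and phnM present.

Genes are first assigned to families from profile-HMM hits filtered at each
model's trusted cutoff; the highest-scoring surviving hit wins per gene,
with ties broken by the lexicographically smallest family name so results
are deterministic.

``brute_force_scan``/``brute_force_verdict`` re-derive cluster calls by
exhaustive subset enumeration and exist only as test oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from phnomp.io_model import (
    PHN_FAMILIES,
    HABITATS,
    DomainHit,
    GeneFeature,
    GenomeRecord,
    ValidationError,
)

__all__ = [
    "DEFAULT_WINDOW_NT",
    "DEFAULT_MIN_FAMILIES",
    "DEFAULT_CORE",
    "FamilyAssignment",
    "ClusterCall",
    "SurveySummary",
    "assign_families",
    "scan_contig",
    "screen_genome",
    "brute_force_scan",
    "brute_force_verdict",
    "summarize_survey",
    "round_pct",
    "calls_to_frame",
]

DEFAULT_WINDOW_NT = 16_000
DEFAULT_MIN_FAMILIES = 5
DEFAULT_CORE = frozenset({"phnK", "phnL", "phnM"})


@dataclass(frozen=True)
class FamilyAssignment:
    """The single winning family for one gene (bit score >= trusted cutoff)."""

    gene_id: str
    family: str
    bit_score: float


@dataclass(frozen=True)
class ClusterCall:
    """A candidate phn cluster on one contig, valid or not.

    ``valid`` is equivalent to ``len(families_present) >= k`` and
    ``window_ok`` and ``core_ok``; invalid candidates are kept for
    auditability.
    """

    genome_id: str
    contig_id: str
    member_gene_ids: tuple[str, ...]
    families_present: frozenset[str]
    span_nt: int
    window_ok: bool
    core_ok: bool
    valid: bool


def assign_families(hits: Iterable[DomainHit]) -> list[FamilyAssignment]:
    """Filter hits at trusted cutoffs and pick one family per gene.

    Hits scoring below their model's trusted cutoff are discarded. Among the
    survivors for a gene the highest bit score wins; exact ties go to the
    lexicographically smallest family name.
    """
    best: dict[str, tuple[float, str]] = {}
    for hit in hits:
        if not hit.above_cutoff:
            continue
        # key orders by score descending then family ascending
        cand = (hit.bit_score, hit.family)
        prev = best.get(hit.gene_id)
        if prev is None or cand[0] > prev[0] or (cand[0] == prev[0] and cand[1] < prev[1]):
            best[hit.gene_id] = cand
    return [
        FamilyAssignment(gene_id=g, family=fam, bit_score=score)
        for g, (score, fam) in sorted(best.items())
    ]


def _phn_genes_sorted(
    features: Sequence[GeneFeature],
    assignments: Sequence[FamilyAssignment],
) -> list[tuple[GeneFeature, str]]:
    """Pair phn-assigned genes with their family, sorted by (start, end, id)."""
    contigs = {f.contig_id for f in features}
    if len(contigs) > 1:
        raise ValidationError(f"features span multiple contigs: {sorted(contigs)}")
    by_id = {f.gene_id: f for f in features}
    out = []
    for a in assignments:
        feat = by_id.get(a.gene_id)
        if feat is None:
            raise ValidationError(
                f"assignment references unknown gene_id {a.gene_id!r}")
        out.append((feat, a.family))
    out.sort(key=lambda pair: (pair[0].start, pair[0].end, pair[0].gene_id))
    return out


def _make_call(
    genome_id: str,
    contig_id: str,
    members: Sequence[tuple[GeneFeature, str]],
    W: int,
    k: int,
    core: frozenset[str],
) -> ClusterCall:
    span = max(f.end for f, _ in members) - min(f.start for f, _ in members) + 1
    fams = frozenset(fam for _, fam in members)
    window_ok = span <= W
    core_ok = core <= fams
    return ClusterCall(
        genome_id=genome_id,
        contig_id=contig_id,
        member_gene_ids=tuple(f.gene_id for f, _ in members),
        families_present=fams,
        span_nt=span,
        window_ok=window_ok,
        core_ok=core_ok,
        valid=(len(fams) >= k) and window_ok and core_ok,
    )


def scan_contig(
    features: Sequence[GeneFeature],
    assignments: Sequence[FamilyAssignment],
    W: int = DEFAULT_WINDOW_NT,
    k: int = DEFAULT_MIN_FAMILIES,
    core: frozenset[str] = DEFAULT_CORE,
    genome_id: str = "",
) -> list[ClusterCall]:
    """Call candidate phn clusters on one contig.

    Candidates are the maximal runs of phn-assigned genes (in start order)
    whose joint span fits in the ``W``-nt window; each maximal run yields
    one :class:`ClusterCall` with the validity flags computed per the rule.
    Because any gene subset with span <= W is contained in such a maximal
    run, and the family set of the run contains the subset's, the contig
    verdict (any valid call?) equals exhaustive subset enumeration.

    A lone phn gene run is still reported (with ``window_ok`` reflecting
    its own extent) so every piece of phn evidence is auditable.
    """
    genes = _phn_genes_sorted(features, assignments)
    if not genes:
        return []
    n = len(genes)
    starts = [f.start for f, _ in genes]
    ends = [f.end for f, _ in genes]

    calls: list[ClusterCall] = []
    prev_j = -1
    contig_id = genes[0][0].contig_id
    for i in range(n):
        # extend run i..j while joint span stays within W
        j = i
        max_end = ends[i]
        while j + 1 < n:
            nxt_end = max(max_end, ends[j + 1])
            if nxt_end - starts[i] + 1 <= W:
                j += 1
                max_end = nxt_end
            else:
                break
        if j <= prev_j:
            continue  # contained in the previous maximal run
        prev_j = j
        calls.append(_make_call(genome_id, contig_id, genes[i:j + 1], W, k, core))
    return _merge_overlapping(calls, genes, W, k, core, genome_id, contig_id)


def _merge_overlapping(
    calls: list[ClusterCall],
    genes: Sequence[tuple[GeneFeature, str]],
    W: int,
    k: int,
    core: frozenset[str],
    genome_id: str,
    contig_id: str,
) -> list[ClusterCall]:
    """Merge candidate calls sharing genes when the merged span still fits W."""
    if len(calls) < 2:
        return calls
    by_id = {f.gene_id: (f, fam) for f, fam in genes}
    merged: list[ClusterCall] = [calls[0]]
    for call in calls[1:]:
        prev = merged[-1]
        if set(prev.member_gene_ids) & set(call.member_gene_ids):
            union_ids = list(dict.fromkeys(prev.member_gene_ids + call.member_gene_ids))
            members = sorted((by_id[g] for g in union_ids),
                             key=lambda pair: (pair[0].start, pair[0].end))
            span = max(f.end for f, _ in members) - min(f.start for f, _ in members) + 1
            if span <= W:
                merged[-1] = _make_call(genome_id, contig_id, members, W, k, core)
                continue
        merged.append(call)
    return merged


def screen_genome(
    genome: GenomeRecord,
    features_by_contig: Mapping[str, Sequence[GeneFeature]],
    assignments: Sequence[FamilyAssignment],
    W: int = DEFAULT_WINDOW_NT,
    k: int = DEFAULT_MIN_FAMILIES,
    core: frozenset[str] = DEFAULT_CORE,
) -> tuple[bool, list[ClusterCall]]:
    """Screen one genome: positive iff any contig carries a valid cluster.

    All candidate calls, valid and invalid, are returned for auditability.
    """
    known_contigs = {cid for cid, _ in genome.contigs}
    if known_contigs:
        unknown = set(features_by_contig) - known_contigs
        if unknown:
            raise ValidationError(
                f"genome {genome.genome_id!r}: features on contigs absent from "
                f"the genome record: {sorted(unknown)}")
    assigned_ids = {a.gene_id: a for a in assignments}
    calls: list[ClusterCall] = []
    for contig_id in sorted(features_by_contig):
        feats = features_by_contig[contig_id]
        local = [assigned_ids[f.gene_id] for f in feats if f.gene_id in assigned_ids]
        calls.extend(scan_contig(feats, local, W=W, k=k, core=core,
                                 genome_id=genome.genome_id))
    return any(c.valid for c in calls), calls


# ---------------------------------------------------------------------------
# Brute-force oracle (tests only)
# ---------------------------------------------------------------------------

_BRUTE_FORCE_MAX_GENES = 25


def _subset_dfs(genes, W, k, core, collect, stop_at_first):
    """DFS over subsets of start-sorted genes; prunes on span > W.

    Span is monotone under adding genes, so once a partial subset exceeds W
    no superset built by appending later-starting genes can fit.
    """
    n = len(genes)
    found: list[tuple[int, ...]] = []

    def recurse(idx: int, chosen: list[int], min_start: int, max_end: int) -> bool:
        if chosen:
            span = max_end - min_start + 1
            if span > W:
                return False
            fams = {genes[i][1] for i in chosen}
            if len(fams) >= k and core <= fams:
                found.append(tuple(chosen))
                if stop_at_first:
                    return True
        for nxt in range(idx, n):
            f = genes[nxt][0]
            new_min = min(min_start, f.start) if chosen else f.start
            new_max = max(max_end, f.end) if chosen else f.end
            if new_max - new_min + 1 > W:
                continue  # this gene alone breaks the window; a later one may not
            chosen.append(nxt)
            if recurse(nxt + 1, chosen, new_min, new_max):
                return True
            chosen.pop()
        return False

    recurse(0, [], 0, 0)
    collect.extend(found)
    return bool(found)


def brute_force_verdict(
    features: Sequence[GeneFeature],
    assignments: Sequence[FamilyAssignment],
    W: int = DEFAULT_WINDOW_NT,
    k: int = DEFAULT_MIN_FAMILIES,
    core: frozenset[str] = DEFAULT_CORE,
) -> bool:
    """True iff some subset of phn genes satisfies the cluster rule.

    Definitional oracle: exhaustive subset search (with span pruning and
    early exit), independent of the windowed scanner.
    """
    genes = _phn_genes_sorted(features, assignments)
    if len(genes) > _BRUTE_FORCE_MAX_GENES:
        raise ValueError(
            f"brute-force oracle refuses contigs with more than "
            f"{_BRUTE_FORCE_MAX_GENES} phn genes (got {len(genes)})")
    sink: list[tuple[int, ...]] = []
    return _subset_dfs(genes, W, k, core, sink, stop_at_first=True)


def brute_force_scan(
    features: Sequence[GeneFeature],
    assignments: Sequence[FamilyAssignment],
    W: int = DEFAULT_WINDOW_NT,
    k: int = DEFAULT_MIN_FAMILIES,
    core: frozenset[str] = DEFAULT_CORE,
    genome_id: str = "",
) -> list[ClusterCall]:
    """Enumerate every valid gene subset and return the maximal ones.

    Test oracle only; refuses contigs with more than 25 phn genes.
    """
    genes = _phn_genes_sorted(features, assignments)
    if len(genes) > _BRUTE_FORCE_MAX_GENES:
        raise ValueError(
            f"brute-force oracle refuses contigs with more than "
            f"{_BRUTE_FORCE_MAX_GENES} phn genes (got {len(genes)})")
    if not genes:
        return []
    subsets: list[tuple[int, ...]] = []
    _subset_dfs(genes, W, k, core, subsets, stop_at_first=False)
    as_sets = {frozenset(s) for s in subsets}
    maximal = [s for s in as_sets
               if not any(s < other for other in as_sets)]
    contig_id = genes[0][0].contig_id
    calls = []
    for s in sorted(maximal, key=lambda s: min(s)):
        members = [genes[i] for i in sorted(s)]
        calls.append(_make_call(genome_id, contig_id, members, W, k, core))
    return calls


# ---------------------------------------------------------------------------
# Survey rollups
# ---------------------------------------------------------------------------

def round_pct(positive: int, total: int, digits: int = 1) -> float:
    """Percentage positive/total rounded half-up to ``digits`` decimals.

    Half-up (not banker's) rounding so 8.65 -> 8.7, matching conventional
    survey reporting.
    """
    if total <= 0:
        raise ValidationError("percentage of an empty denominator")
    pct = Decimal(positive) * Decimal(100) / Decimal(total)
    q = Decimal(1).scaleb(-digits)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


_RANK_NAMES = {"d__": "domain", "p__": "phylum", "c__": "class", "o__": "order",
               "f__": "family", "g__": "genus", "s__": "species"}


@dataclass
class SurveySummary:
    """Prevalence counts and percentages, overall and stratified."""

    total_genomes: int
    positive_genomes: int
    prevalence_pct: float
    by_habitat: dict[str, tuple[int, int, float]]          # habitat -> (total, pos, pct)
    by_rank: dict[tuple[str, str], tuple[int, int, float]]  # (rank, taxon) -> ...

    def to_json(self, path: str | Path | None = None, collapse_below_pct: float | None = None) -> str:
        """Serialize to JSON. ``collapse_below_pct`` folds taxa contributing
        less than that share of positives into ``other`` in the report
        (counts are never collapsed)."""
        by_rank: dict[str, dict[str, list]] = {}
        other: dict[str, list[int]] = {}
        for (rank, taxon), (tot, pos, pct) in sorted(self.by_rank.items()):
            share = 100.0 * tot / self.total_genomes if self.total_genomes else 0.0
            if collapse_below_pct is not None and share < collapse_below_pct:
                acc = other.setdefault(rank, [0, 0])
                acc[0] += tot
                acc[1] += pos
                continue
            by_rank.setdefault(rank, {})[taxon] = [tot, pos, pct]
        for rank, (tot, pos) in other.items():
            by_rank.setdefault(rank, {})["other"] = [tot, pos, round_pct(pos, tot) if tot else 0.0]
        doc = {
            "total_genomes": self.total_genomes,
            "positive_genomes": self.positive_genomes,
            "prevalence_pct": self.prevalence_pct,
            "prevalence_display": f"≈{round_pct(self.positive_genomes, self.total_genomes, 0):.0f}%",
            "by_habitat": {h: list(v) for h, v in sorted(self.by_habitat.items())},
            "by_rank": by_rank,
        }
        text = json.dumps(doc, indent=2, ensure_ascii=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def summarize_survey(
    records: Sequence[GenomeRecord],
    verdicts: Mapping[str, bool],
    ranks: Sequence[str] = ("p__", "o__"),
) -> SurveySummary:
    """Roll prevalence up overall, per habitat, and per taxonomic rank.

    ``verdicts`` maps genome_id -> positive; genomes absent from it count
    as unscreened negatives only if absent, which is rejected: every
    verdict key must exist in ``records`` and vice versa totals use all
    records. Percentages are rounded half-up to one decimal.
    """
    if not records:
        raise ValidationError("no genomes to summarize")
    ids = {r.genome_id for r in records}
    stray = set(verdicts) - ids
    if stray:
        raise ValidationError(f"verdicts for unknown genomes: {sorted(stray)}")

    total = len(records)
    positive = sum(bool(verdicts.get(r.genome_id, False)) for r in records)
    by_habitat: dict[str, list[int]] = {}
    by_rank: dict[tuple[str, str], list[int]] = {}
    for rec in records:
        pos = bool(verdicts.get(rec.genome_id, False))
        acc = by_habitat.setdefault(rec.habitat, [0, 0])
        acc[0] += 1
        acc[1] += pos
        for prefix in ranks:
            taxon = rec.rank(prefix)
            rank_name = _RANK_NAMES.get(prefix, prefix.rstrip("_"))
            acc = by_rank.setdefault((rank_name, taxon), [0, 0])
            acc[0] += 1
            acc[1] += pos
    return SurveySummary(
        total_genomes=total,
        positive_genomes=positive,
        prevalence_pct=round_pct(positive, total),
        by_habitat={h: (t, p, round_pct(p, t)) for h, (t, p) in by_habitat.items()},
        by_rank={key: (t, p, round_pct(p, t)) for key, (t, p) in by_rank.items()},
    )


def calls_to_frame(calls: Iterable[ClusterCall]) -> pd.DataFrame:
    """Tabulate cluster calls (one row per candidate) for TSV output."""
    rows = [{
        "genome_id": c.genome_id,
        "contig_id": c.contig_id,
        "n_genes": len(c.member_gene_ids),
        "n_families": len(c.families_present),
        "members": ",".join(c.member_gene_ids),
        "families": ",".join(sorted(c.families_present)),
        "span_nt": c.span_nt,
        "window_ok": c.window_ok,
        "core_ok": c.core_ok,
        "valid": c.valid,
    } for c in calls]
    cols = ["genome_id", "contig_id", "n_genes", "n_families", "members",
            "families", "span_nt", "window_ok", "core_ok", "valid"]
    return pd.DataFrame(rows, columns=cols)
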