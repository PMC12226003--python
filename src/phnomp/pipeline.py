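"""End-to-end runners: survey screening, incubation quantitation, sequence stats.

These functions are the library surface behind the command-line interface:
each takes parsed inputs plus a :class:`RunConfig` and returns/writes tidy
tables, logging the counts at every filter stage so a screen is auditable
(hits read -> hits above cutoff -> candidate clusters -> valid clusters ->
positive genomes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from phnomp.io_model import (
    GenomeRecord,
    ValidationError,
    default_trusted_cutoffs,
    load_trusted_cutoffs,
    read_domain_hits,
    read_gene_features,
    read_genome_metadata,
    read_measurements,
    validate_measurements,
)
from phnomp.cluster_screen import (
    DEFAULT_CORE,
    DEFAULT_MIN_FAMILIES,
    DEFAULT_WINDOW_NT,
    SurveySummary,
    assign_families,
    calls_to_frame,
    screen_genome,
    summarize_survey,
)
from phnomp.methane_quant import (
    BottleGeometry,
    dose_response_trend,
    fit_calibration,
    headspace_partition,
    production_rate,
    repression_test,
    stoichiometric_series,
)

__all__ = [
    "RunConfig",
    "run_survey_pipeline",
    "run_incubation_pipeline",
    "sequence_stats",
]

logger = logging.getLogger("phnomp")


@dataclass
class RunConfig:
    """Tunable knobs shared by the pipelines (YAML-loadable)."""

    window_nt: int = DEFAULT_WINDOW_NT
    min_families: int = DEFAULT_MIN_FAMILIES
    core: frozenset[str] = DEFAULT_CORE
    cutoffs_path: str | None = None       # None -> packaged defaults
    geometry: BottleGeometry = field(default_factory=BottleGeometry)
    calibration_standards_ppm: tuple[float, ...] | None = None
    calibration_areas: tuple[float, ...] | None = None
    alpha: float = 0.05
    rate_window: tuple[float, float] | None = None
    lag_window: tuple[float, float] | None = (0.0, 24.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_nt <= 0:
            raise ValidationError("window_nt must be > 0")
        if self.min_families < 1:
            raise ValidationError("min_families must be >= 1")
        self.core = frozenset(self.core)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config keys {sorted(bad)}")
        if "geometry" in raw and isinstance(raw["geometry"], Mapping):
            raw["geometry"] = BottleGeometry(**raw["geometry"])
        if "core" in raw:
            raw["core"] = frozenset(raw["core"])
        return cls(**raw)

    def cutoffs(self) -> dict[str, float]:
        if self.cutoffs_path is None:
            return default_trusted_cutoffs()
        return load_trusted_cutoffs(self.cutoffs_path)


# ---------------------------------------------------------------------------
# Survey arm
# ---------------------------------------------------------------------------

def run_survey_pipeline(
    config: RunConfig,
    gff_path: str | Path,
    hits_path: str | Path,
    metadata_path: str | Path,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, SurveySummary]:
    """Screen every genome in a metadata table and roll up prevalence.

    Contigs are attributed to genomes through the metadata contig
    inventory; a contig carrying features but absent from every genome
    record is a consistency error naming the contig. Writes
    ``cluster_calls.tsv`` and ``survey_summary.json`` when ``outdir`` is
    given.
    """
    records = read_genome_metadata(metadata_path)
    features_by_contig = read_gene_features(gff_path)
    hits, n_dropped = read_domain_hits(hits_path, cutoffs=config.cutoffs())
    logger.info("hits read: %d (non-phn models dropped: %d)",
                len(hits) + n_dropped, n_dropped)

    contig_to_genome: dict[str, str] = {}
    for rec in records:
        for cid, _ in rec.contigs:
            contig_to_genome[cid] = rec.genome_id
    orphans = sorted(set(features_by_contig) - set(contig_to_genome))
    if orphans:
        raise ValidationError(
            f"features on contigs not claimed by any genome in the metadata: "
            f"{orphans[:5]}{'...' if len(orphans) > 5 else ''}")

    gene_to_genome = {
        f.gene_id: contig_to_genome[cid]
        for cid, feats in features_by_contig.items() for f in feats
    }
    unknown_genes = {h.gene_id for h in hits} - set(gene_to_genome)
    if unknown_genes:
        raise ValidationError(
            f"hits reference gene_ids absent from the GFF3: "
            f"{sorted(unknown_genes)[:5]}")

    assignments = assign_families(hits)
    logger.info("hits above trusted cutoff -> %d gene-family assignments",
                len(assignments))
    assign_by_genome: dict[str, list] = {}
    for a in assignments:
        assign_by_genome.setdefault(gene_to_genome[a.gene_id], []).append(a)

    all_calls = []
    verdicts: dict[str, bool] = {}
    for rec in records:
        feats = {cid: features_by_contig[cid]
                 for cid, _ in rec.contigs if cid in features_by_contig}
        positive, calls = screen_genome(
            rec, feats, assign_by_genome.get(rec.genome_id, []),
            W=config.window_nt, k=config.min_families, core=config.core)
        verdicts[rec.genome_id] = positive
        all_calls.extend(calls)
    n_valid = sum(c.valid for c in all_calls)
    logger.info("candidate clusters: %d; valid: %d; positive genomes: %d",
                len(all_calls), n_valid, sum(verdicts.values()))

    calls_df = calls_to_frame(all_calls)
    summary = summarize_survey(records, verdicts)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        calls_df.to_csv(outdir / "cluster_calls.tsv", sep="\t", index=False)
        summary.to_json(outdir / "survey_summary.json", collapse_below_pct=1.0)
    return calls_df, summary


# ---------------------------------------------------------------------------
# Incubation arm
# ---------------------------------------------------------------------------

def run_incubation_pipeline(
    config: RunConfig,
    measurements: pd.DataFrame | str | Path,
    outdir: str | Path | None = None,
) -> dict:
    """Quantify CH4 for every treatment in a measurement table.

    If the table carries ``headspace_ppm`` the calibration stage is
    skipped (and logged); if it carries only ``peak_area`` a calibration
    curve must be configured. Per treatment the report holds the partitioned
    gas samples, regression/lag production rates, and (when TDP and DIP are
    present) the CH4/DOP stoichiometry. Across treatments it adds the Pi
    dose-response trend (>= 3 Pi levels) and a repression t-test (exactly
    two treatments).
    """
    if not isinstance(measurements, pd.DataFrame):
        measurements = read_measurements(measurements)
    df = validate_measurements(measurements)

    if "headspace_ppm" in df.columns and df["headspace_ppm"].notna().any():
        logger.info("mixing ratios supplied directly; calibration stage skipped")
    elif "peak_area" in df.columns:
        if config.calibration_standards_ppm is None or config.calibration_areas is None:
            raise ValidationError(
                "peak areas supplied but no calibration curve configured")
        curve = fit_calibration(config.calibration_standards_ppm,
                                config.calibration_areas)
        logger.info("calibration: slope %.4g, intercept %.4g, r^2 %.5f",
                    curve.slope, curve.intercept, curve.r_squared)
        df = df.copy()
        df["headspace_ppm"] = curve.ppm(df["peak_area"].to_numpy())
    else:
        raise ValidationError("measurement table has neither headspace_ppm nor peak_area")

    geom = config.geometry
    samples = df.apply(
        lambda row: headspace_partition(row["headspace_ppm"], geom), axis=1)
    df = df.assign(
        headspace_nmol=[s.headspace_amount_nmol for s in samples],
        dissolved_umol_l=[s.dissolved_umol_per_l for s in samples],
        total_nmol=[s.total_amount_nmol for s in samples],
        conc_umol_l=[s.conc_umol_per_l_liquid for s in samples],
    )

    report: dict = {"treatments": {}}
    final_by_pi: dict[float, list[float]] = {}
    for treatment, grp in df.groupby("treatment"):
        t = grp["time_h"].to_numpy()
        conc_nmol_l = grp["conc_umol_l"].to_numpy() * 1000.0
        entry: dict = {}
        entry["rate"] = production_rate(t, conc_nmol_l, window=config.rate_window)
        if config.lag_window is not None and \
                (t <= config.lag_window[1]).sum() >= 2:
            entry["lag_rate"] = production_rate(t, conc_nmol_l,
                                                window=config.lag_window)
        if {"tdp_um", "dip_um"} <= set(grp.columns) and grp["tdp_um"].notna().any():
            mean = (grp.groupby("time_h")[["conc_umol_l", "tdp_um", "dip_um"]]
                    .mean().reset_index())
            entry["stoichiometry"] = stoichiometric_series(
                mean["time_h"], mean["conc_umol_l"], mean["tdp_um"], mean["dip_um"])
        report["treatments"][treatment] = entry
        if "pi_initial_um" in grp.columns and grp["pi_initial_um"].notna().any():
            pi0 = float(grp["pi_initial_um"].iloc[0])
            t_max = grp["time_h"].max()
            finals = grp.loc[grp["time_h"] == t_max, "conc_umol_l"]
            final_by_pi.setdefault(pi0, []).extend(map(float, finals))

    if len(final_by_pi) >= 3:
        rho, monotone = dose_response_trend(final_by_pi)
        report["dose_response"] = {"spearman_rho": rho,
                                   "monotone_decreasing": monotone}
    treatments = sorted(report["treatments"])
    if len(treatments) == 2:
        t_max = df["time_h"].max()
        groups = [
            df.loc[(df["treatment"] == tr) & (df["time_h"] == t_max),
                   "conc_umol_l"].to_numpy()
            for tr in treatments
        ]
        if all(len(g) >= 2 for g in groups):
            stat, p, sig = repression_test(groups[0], groups[1],
                                           alpha=config.alpha)
            report["repression_test"] = {
                "groups": treatments, "statistic": stat, "p_value": p,
                "significant": sig, "alpha": config.alpha,
            }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "gas_samples.tsv", sep="\t", index=False)
    report["samples"] = df
    return report


# ---------------------------------------------------------------------------
# Sequence utilities
# ---------------------------------------------------------------------------

def sequence_stats(path: str | Path) -> tuple[int, float]:
    """Total length (bp) and G+C percentage of a FASTA file.

    G+C% = (G+C)/(A+C+G+T) * 100 over all records, case-insensitive;
    ambiguity codes are excluded from the denominator. Rounded half-up to
    one decimal. Empty files are an error; non-nucleotide letters trigger a
    warning-level log but are tolerated.
    """
    total = 0
    gc = 0
    acgt = 0
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        seq = str(rec.seq).upper()
        total += len(seq)
        gc += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in "ACGT")
    if n_records == 0:
        raise ValidationError(f"no FASTA records in {path}")
    if acgt < total:
        non_acgt = total - acgt
        logger.warning("%d non-ACGT residues excluded from the G+C denominator",
                       non_acgt)
    if acgt == 0:
        raise ValidationError("no unambiguous nucleotides; cannot compute G+C%")
    pct = Decimal(gc) * Decimal(100) / Decimal(acgt)
    gc_pct = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return total, gc_pct
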