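"""Synthetic surveys and incubations with planted ground truth.

The survey generator emits genomes whose phn evidence is planted by
construction: positives carry a complete, compact phn operon; decoys each
violate exactly one clause of the cluster rule (too few families, missing
C-P lyase core, genes too spread out, cluster split across contigs, or
scores below the trusted cutoffs). No nucleotide sequence is simulated -
only coordinates, hit tables and metadata, in the same dialects the
readers consume.

The incubation generator plants the kinetics the quantitation arm must
recover: a lag-phase CH4 slope, a faster post-lag slope, a cumulative
CH4/DOP ratio trajectory ramping from the lag value to its asymptote,
logistic growth, and a monotone phosphate inhibition of the production
rate. Headspace mixing ratios are back-computed through the same
equilibrium partition model the quantitation arm inverts, so noise-free
simulations round-trip to machine precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from phnomp.io_model import (
    PHN_FAMILIES,
    DomainHit,
    GeneFeature,
    GenomeRecord,
    default_trusted_cutoffs,
    write_genome_metadata,
)
from phnomp.methane_quant import BottleGeometry, mixing_ratio_for_total

__all__ = [
    "GenomeSimSpec",
    "SurveySim",
    "simulate_survey",
    "IncubationSimSpec",
    "IncubationSim",
    "simulate_incubation",
    "DECOY_TYPES",
]

DECOY_TYPES = ("four_gene", "missing_core", "overspread", "split_contig",
               "subthreshold_scores")

# Typical phn gene lengths (nt), roughly 3x the subunit protein sizes.
_GENE_LEN = {
    "phnC": 780, "phnD": 1010, "phnE": 790, "phnF": 720, "phnG": 450,
    "phnH": 580, "phnI": 1060, "phnJ": 840, "phnK": 760, "phnL": 680,
    "phnM": 1140, "phnN": 560, "phnO": 440, "phnP": 760,
}

_PHYLA = {
    "p__Pseudomonadota": ("o__Burkholderiales", "o__Pseudomonadales",
                          "o__Enterobacterales", "o__Rhizobiales"),
    "p__Actinomycetota": ("o__Mycobacteriales", "o__Streptomycetales"),
    "p__Bacteroidota": ("o__Flavobacteriales", "o__Cytophagales"),
    "p__Bacillota": ("o__Bacillales", "o__Lactobacillales"),
    "p__Cyanobacteriota": ("o__Synechococcales",),
}
_PHYLUM_WEIGHTS = (0.45, 0.2, 0.15, 0.15, 0.05)
# phn-positive genomes are overwhelmingly Pseudomonadota in real surveys
_POSITIVE_PSEUDOMONADOTA_PROB = 0.96


@dataclass(frozen=True)
class GenomeSimSpec:
    """Design of a synthetic genome survey.

    ``prevalence`` is the planted fraction of positive genomes;
    ``decoy_rates`` gives the fraction of genomes (of the whole survey)
    planted as each decoy class. ``prevalence + sum(decoy_rates) <= 1``;
    the remainder are plain negatives with background genes only.
    """

    n_genomes: int = 200
    prevalence: float = 0.1
    habitat_mix: Mapping[str, float] = field(default_factory=lambda: {
        "freshwater": 0.07, "aquatic": 0.33, "soil": 0.40, "sediment": 0.20,
    })
    cluster_families: tuple[str, ...] = PHN_FAMILIES
    gap_range_nt: tuple[int, int] = (20, 200)
    decoy_rates: Mapping[str, float] = field(default_factory=lambda: {
        t: 0.08 for t in DECOY_TYPES})
    background_gene_density: float = 1.0   # genes per 10 kb
    contig_length: int = 120_000
    window_nt: int = 16_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        if abs(sum(self.habitat_mix.values()) - 1.0) > 1e-9:
            raise ValueError("habitat proportions must sum to 1")
        bad = set(self.decoy_rates) - set(DECOY_TYPES)
        if bad:
            raise ValueError(f"unknown decoy types {sorted(bad)}")
        if self.prevalence + sum(self.decoy_rates.values()) > 1 + 1e-9:
            raise ValueError("prevalence + decoy rates exceed 1")
        span = (sum(_GENE_LEN[f] for f in self.cluster_families)
                + (len(self.cluster_families) - 1) * self.gap_range_nt[0])
        if span > self.window_nt:
            raise ValueError(
                f"impossible spec: minimal cluster span {span} nt exceeds the "
                f"{self.window_nt} nt window")


@dataclass
class SurveySim:
    """A realized synthetic survey."""

    records: list[GenomeRecord]
    features: dict[str, dict[str, list[GeneFeature]]]   # genome -> contig -> genes
    hits: dict[str, list[DomainHit]]                     # genome -> phn hits
    raw_hit_rows: list[tuple[str, str, float, float]]    # incl. non-phn models
    truth: pd.DataFrame                                  # genome_id, positive, decoy_type

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit GFF3, 4-column hit table, metadata TSV and truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gff": outdir / "genes.gff3",
            "hits": outdir / "hits.tsv",
            "metadata": outdir / "metadata.tsv",
            "truth": outdir / "truth.tsv",
        }
        with open(paths["gff"], "w") as fh:
            fh.write("##gff-version 3\n")
            for genome_id in sorted(self.features):
                for contig_id in sorted(self.features[genome_id]):
                    for f in self.features[genome_id][contig_id]:
                        fh.write(
                            f"{f.contig_id}\tphnomp_sim\tCDS\t{f.start}\t{f.end}"
                            f"\t.\t{f.strand if f.strand != 'unknown' else '.'}\t0"
                            f"\tID={f.gene_id}\n")
        with open(paths["hits"], "w") as fh:
            fh.write("# gene_id\tmodel\tbit_score\te_value\n")
            for gene_id, model, score, evalue in self.raw_hit_rows:
                fh.write(f"{gene_id}\t{model}\t{score:.1f}\t{evalue:.3g}\n")
        write_genome_metadata(self.records, paths["metadata"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _lineage(rng: np.random.Generator, force_pseudomonadota: bool) -> tuple[str, ...]:
    phyla = list(_PHYLA)
    if force_pseudomonadota:
        phylum = "p__Pseudomonadota"
    else:
        phylum = phyla[rng.choice(len(phyla), p=_PHYLUM_WEIGHTS)]
    order = _PHYLA[phylum][rng.integers(len(_PHYLA[phylum]))]
    return ("d__Bacteria", phylum, order)


def _place_cluster(
    rng: np.random.Generator,
    families: Sequence[str],
    anchor: int,
    gaps: Sequence[int],
) -> list[tuple[str, int, int]]:
    """Lay genes head-to-tail from ``anchor``: (family, start, end) triples."""
    out = []
    pos = anchor
    for i, fam in enumerate(families):
        length = _GENE_LEN[fam] + int(rng.integers(-30, 31))
        out.append((fam, pos, pos + length - 1))
        pos += length + (gaps[i] if i < len(gaps) else 0)
    return out


def simulate_survey(spec: GenomeSimSpec) -> SurveySim:
    """Generate a survey with planted positives and per-rule decoys.

    Reproducible given ``spec.seed``. Every planted positive satisfies the
    cluster rule by construction (the realized span is asserted against the
    window); every decoy violates exactly its designated clause. The truth
    table lists genome_id, positive and decoy_type.
    """
    rng = np.random.default_rng(spec.seed)
    cutoffs = default_trusted_cutoffs()

    n_pos = round(spec.n_genomes * spec.prevalence)
    roles = ["positive"] * n_pos
    for decoy, rate in sorted(spec.decoy_rates.items()):
        roles += [decoy] * round(spec.n_genomes * rate)
    roles += ["background"] * (spec.n_genomes - len(roles))
    roles = roles[:spec.n_genomes]
    rng.shuffle(roles)  # habitat/lineage assignment independent of role order

    habitats = list(spec.habitat_mix)
    hab_p = np.array([spec.habitat_mix[h] for h in habitats], dtype=float)

    records: list[GenomeRecord] = []
    features: dict[str, dict[str, list[GeneFeature]]] = {}
    hits: dict[str, list[DomainHit]] = {}
    raw_rows: list[tuple[str, str, float, float]] = []
    truth_rows = []

    for g_idx, role in enumerate(roles):
        genome_id = f"G{g_idx:05d}"
        n_contigs = 2 if role == "split_contig" else int(rng.integers(1, 3))
        contigs = tuple((f"{genome_id}_c{c}", spec.contig_length)
                        for c in range(1, n_contigs + 1))
        habitat = habitats[rng.choice(len(habitats), p=hab_p)]
        lineage = _lineage(
            rng, role == "positive" and rng.random() < _POSITIVE_PSEUDOMONADOTA_PROB)
        rec = GenomeRecord(genome_id, habitat, lineage, contigs)
        records.append(rec)
        per_contig: dict[str, list[GeneFeature]] = {cid: [] for cid, _ in contigs}
        genome_hits: list[DomainHit] = []
        gene_counter = 0

        def add_gene(contig_id: str, start: int, end: int) -> str:
            nonlocal gene_counter
            gene_counter += 1
            gid = f"{genome_id}_g{gene_counter:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            per_contig[contig_id].append(GeneFeature(contig_id, gid, start, end, strand))
            return gid

        def add_hit(gid: str, fam: str, above: bool) -> None:
            cut = cutoffs[fam]
            factor = rng.uniform(1.2, 3.0) if above else rng.uniform(0.3, 0.9)
            score = cut * factor
            evalue = float(10.0 ** -rng.uniform(10, 60))
            genome_hits.append(DomainHit(gid, fam, score, evalue, cut))
            raw_rows.append((gid, fam, score, evalue))

        # background genes on every contig
        for cid, clen in contigs:
            n_bg = rng.poisson(spec.background_gene_density * clen / 10_000)
            for _ in range(n_bg):
                start = int(rng.integers(1, clen - 2000))
                gid = add_gene(cid, start, start + int(rng.integers(300, 1800)))
                r = rng.random()
                if r < 0.05:   # non-phn model hit: dropped by the reader
                    model = str(rng.choice(["phoB", "pstS", "phoA", "ppk1"]))
                    raw_rows.append((gid, model, float(rng.uniform(20, 200)),
                                     float(10.0 ** -rng.uniform(5, 40))))
                elif r < 0.10:  # stray sub-cutoff phn hit
                    add_hit(gid, str(rng.choice(PHN_FAMILIES)), above=False)

        def plant(contig_id: str, families: Sequence[str], gap_lo: int, gap_hi: int,
                  above: bool = True, max_span: int | None = None) -> int:
            gaps = [int(rng.integers(gap_lo, gap_hi + 1)) for _ in families]
            anchor = int(rng.integers(1, spec.contig_length // 2))
            laid = _place_cluster(rng, families, anchor, gaps)
            span = laid[-1][2] - laid[0][1] + 1
            if max_span is not None and span > max_span:
                # retry with minimal gaps; spec __post_init__ guarantees this fits
                gaps = [gap_lo] * len(families)
                laid = _place_cluster(rng, families, anchor, gaps)
                span = laid[-1][2] - laid[0][1] + 1
                assert span <= max_span
            for fam, start, end in laid:
                gid = add_gene(contig_id, start, end)
                add_hit(gid, fam, above=above)
            return span

        first_contig = contigs[0][0]
        lo, hi = spec.gap_range_nt
        if role == "positive":
            plant(first_contig, spec.cluster_families, lo, hi,
                  max_span=spec.window_nt)
        elif role == "four_gene":
            plant(first_contig, ("phnK", "phnL", "phnM", "phnJ"), lo, hi)
        elif role == "missing_core":
            fams = tuple(f for f in spec.cluster_families if f != "phnK")
            plant(first_contig, fams, lo, hi, max_span=spec.window_nt)
        elif role == "overspread":
            # 5-kb gaps: no 16-kb window can hold 5 of these genes
            plant(first_contig, ("phnC", "phnD", "phnJ", "phnK", "phnL",
                                 "phnM", "phnN", "phnP"), 5_000, 6_000)
        elif role == "split_contig":
            plant(contigs[0][0], ("phnC", "phnD", "phnE", "phnK"), lo, hi)
            plant(contigs[1][0], ("phnL", "phnM", "phnJ"), lo, hi)
        elif role == "subthreshold_scores":
            plant(first_contig, spec.cluster_families, lo, hi,
                  above=False, max_span=spec.window_nt)

        features[genome_id] = per_contig
        hits[genome_id] = genome_hits
        truth_rows.append({
            "genome_id": genome_id,
            "positive": role == "positive",
            "decoy_type": role if role in DECOY_TYPES else "",
        })

    truth = pd.DataFrame(truth_rows)
    return SurveySim(records=records, features=features, hits=hits,
                     raw_hit_rows=raw_rows, truth=truth)


# ---------------------------------------------------------------------------
# Incubations
# ---------------------------------------------------------------------------

def _default_sampling(duration: float) -> tuple[float, ...]:
    """Dense sampling every 3-6 h in the first 24 h, then every 48 h."""
    times = [0.0, 3.0, 6.0, 9.0, 12.0, 18.0, 24.0]
    t = 24.0 + 48.0
    while t < duration:
        times.append(t)
        t += 48.0
    if times[-1] < duration:
        times.append(float(duration))
    return tuple(times)


@dataclass(frozen=True)
class IncubationSimSpec:
    """Design of a synthetic serum-bottle incubation.

    Rates are volumetric CH4 production per liquid volume. The cumulative
    CH4/DOP ratio is planted directly: it equals ``lag_ratio`` through the
    lag, ramps linearly, and reaches ``asymptotic_ratio`` at
    ``ramp_end_hours``. ``pi_inhibition_km`` is the Pi concentration (uM)
    halving the production rate via rate * 1/(1 + Pi/Km).
    """

    duration_h: float = 288.0
    sampling_times_h: tuple[float, ...] | None = None
    planted_rate: float = 92.0        # nmol L^-1 h^-1, post-lag
    lag_rate: float = 4.0             # nmol L^-1 h^-1 during the lag
    lag_hours: float = 24.0
    lag_ratio: float = 0.4            # cumulative CH4/DOP during the lag
    asymptotic_ratio: float = 1.0
    ramp_end_hours: float = 216.0
    dop0_um: float = 200.0            # initial MPn-P pool, uM
    pi_levels_um: tuple[float, ...] = (0.0,)
    pi_inhibition_km: float = 10.0    # uM
    dip_decay_tau_h: float = 48.0     # first-order uptake of added Pi
    cells0_per_ml: float = 1e5
    cells_K_per_ml: float = 1e8
    growth_rate_per_h: float = 0.08
    noise_sd: Mapping[str, float] = field(default_factory=lambda: {
        "ppm_rel": 0.02, "tdp_rel": 0.05, "dip_rel": 0.05, "cells_rel": 0.10})
    n_replicates: int = 3
    geometry: BottleGeometry = BottleGeometry()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag_ratio > self.asymptotic_ratio:
            raise ValueError("lag_ratio must be <= asymptotic_ratio")
        if min(self.planted_rate, self.lag_rate, self.lag_hours,
               self.dop0_um) < 0:
            raise ValueError("rates, times and concentrations must be non-negative")

    def noise_free(self) -> "IncubationSimSpec":
        return replace(self, noise_sd={k: 0.0 for k in self.noise_sd})

    @property
    def times(self) -> tuple[float, ...]:
        if self.sampling_times_h is not None:
            return self.sampling_times_h
        return _default_sampling(self.duration_h)


@dataclass
class IncubationSim:
    """A realized synthetic incubation: tidy measurements plus truth."""

    measurements: pd.DataFrame
    truth: dict

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.measurements.to_csv(path, index=False)
        return path


def _planted_ch4_nmol_l(spec: IncubationSimSpec, t: float, rate_scale: float) -> float:
    lag = min(t, spec.lag_hours)
    post = max(0.0, t - spec.lag_hours)
    return rate_scale * (spec.lag_rate * lag + spec.planted_rate * post)


def _planted_ratio(spec: IncubationSimSpec, t: float) -> float:
    if t <= spec.lag_hours:
        return spec.lag_ratio
    if t >= spec.ramp_end_hours:
        return spec.asymptotic_ratio
    frac = (t - spec.lag_hours) / (spec.ramp_end_hours - spec.lag_hours)
    return spec.lag_ratio + frac * (spec.asymptotic_ratio - spec.lag_ratio)


def _noisy(rng: np.random.Generator, value: float, rel_sd: float,
           what: str) -> float:
    """Gaussian relative noise; negatives are resampled, never clamped."""
    if rel_sd == 0 or value == 0:
        return value
    for _ in range(100):
        draw = value * (1.0 + rng.normal(0.0, rel_sd))
        if draw >= 0:
            return draw
    warnings.warn(f"resampling failed to produce a non-negative {what}; using 0")
    return 0.0


def simulate_incubation(spec: IncubationSimSpec) -> IncubationSim:
    """Simulate headspace time series for every Pi treatment.

    One treatment per entry of ``spec.pi_levels_um`` (labelled ``Pi_<x>``;
    the bare ``0`` level is the plain MPn treatment). CH4 accumulates
    piecewise linearly (lag slope then planted slope, both scaled by the
    Pi inhibition factor); DOP is derived from the planted cumulative
    ratio; DIP decays first-order from the added Pi; cells grow
    logistically. Headspace ppm is back-computed through the equilibrium
    partition model, so the quantitation arm round-trips noise-free data
    exactly.
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.times
    rows = []
    truth_rates = {}
    for pi0 in spec.pi_levels_um:
        treatment = f"Pi_{pi0:g}"
        scale = 1.0 / (1.0 + pi0 / spec.pi_inhibition_km)
        truth_rates[treatment] = {
            "rate_scale": scale,
            "post_rate_nmol_l_h": spec.planted_rate * scale,
            "lag_rate_nmol_l_h": spec.lag_rate * scale,
        }
        for rep in range(1, spec.n_replicates + 1):
            for t in times:
                ch4_nmol_l = _planted_ch4_nmol_l(spec, t, scale)
                ratio = _planted_ratio(spec, t)
                dop = spec.dop0_um - (ch4_nmol_l / 1000.0) / ratio
                if dop < 0:
                    raise ValueError(
                        "planted CH4 exceeds the DOP pool; increase dop0_um")
                dip = pi0 * math.exp(-t / spec.dip_decay_tau_h)
                tdp = dop + dip
                total_nmol = ch4_nmol_l * spec.geometry.V_liq
                ppm = mixing_ratio_for_total(total_nmol, spec.geometry)
                growth_t = max(0.0, t - spec.lag_hours)
                cells = (spec.cells_K_per_ml /
                         (1.0 + (spec.cells_K_per_ml / spec.cells0_per_ml - 1.0)
                          * math.exp(-spec.growth_rate_per_h * scale * growth_t)))
                rows.append({
                    "treatment": treatment,
                    "replicate": rep,
                    "time_h": t,
                    "headspace_ppm": _noisy(rng, ppm, spec.noise_sd.get("ppm_rel", 0.0), "ppm"),
                    "tdp_um": _noisy(rng, tdp, spec.noise_sd.get("tdp_rel", 0.0), "TDP"),
                    "dip_um": _noisy(rng, dip, spec.noise_sd.get("dip_rel", 0.0), "DIP"),
                    "cells_per_ml": _noisy(rng, cells, spec.noise_sd.get("cells_rel", 0.0), "cells"),
                    "pi_initial_um": pi0,
                })
    truth = {
        "planted_rate": spec.planted_rate,
        "lag_rate": spec.lag_rate,
        "lag_hours": spec.lag_hours,
        "lag_ratio": spec.lag_ratio,
        "asymptotic_ratio": spec.asymptotic_ratio,
        "dop0_um": spec.dop0_um,
        "per_treatment": truth_rates,
    }
    return IncubationSim(measurements=pd.DataFrame(rows), truth=truth)
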