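"""Data model and readers for the formats the suite touches.

Coordinates are 1-based inclusive throughout (GFF3 convention); nothing in
the package converts to half-open coordinates. Gene "position" downstream
always means the full interval [start, end].

The phn vocabulary is the 14 screened families phnC..phnP: the phnC-E
transporter, the phnF regulator, the phnG-M C-P lyase core and the phnN-P
accessories. Habitats form a closed vocabulary of the four survey classes
plus ``unknown`` so that prevalence denominators are unambiguous.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from gffutils.feature import feature_from_line

__all__ = [
    "PHN_FAMILIES",
    "HABITATS",
    "ParseError",
    "FormatError",
    "ValidationError",
    "GeneFeature",
    "DomainHit",
    "GenomeRecord",
    "read_gene_features",
    "read_domain_hits",
    "read_genome_metadata",
    "load_trusted_cutoffs",
    "default_trusted_cutoffs",
    "read_measurements",
    "validate_measurements",
]

#: The 14 phn families screened for, in operon order.
PHN_FAMILIES: tuple[str, ...] = (
    "phnC", "phnD", "phnE", "phnF", "phnG", "phnH", "phnI",
    "phnJ", "phnK", "phnL", "phnM", "phnN", "phnO", "phnP",
)

#: Closed habitat vocabulary: the four survey classes plus unknown.
HABITATS: tuple[str, ...] = ("freshwater", "aquatic", "soil", "sediment", "unknown")


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class FormatError(ValueError):
    """An input file has an unrecognized column layout."""


class ValidationError(ValueError):
    """Parsed content violates a data-model invariant."""


@dataclass(frozen=True)
class GeneFeature:
    """A gene/CDS interval on one contig, 1-based inclusive."""

    contig_id: str
    gene_id: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(
                f"gene {self.gene_id!r}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id!r}: end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-", "unknown"):
            object.__setattr__(self, "strand", "unknown")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainHit:
    """Profile-HMM evidence assigning a gene to a phn family.

    ``trusted_cutoff`` is the per-model bit-score threshold above which a
    hit is accepted without further filtering.
    """

    gene_id: str
    family: str
    bit_score: float
    e_value: float
    trusted_cutoff: float

    def __post_init__(self) -> None:
        if self.family not in PHN_FAMILIES:
            raise ValidationError(f"unknown phn family {self.family!r}")
        if not (self.bit_score == self.bit_score and abs(self.bit_score) < float("inf")):
            raise ValidationError(f"non-finite bit score for {self.gene_id!r}")
        if self.e_value < 0:
            raise ValidationError(
                f"negative E-value {self.e_value} for {self.gene_id!r}")

    @property
    def above_cutoff(self) -> bool:
        return self.bit_score >= self.trusted_cutoff


@dataclass(frozen=True)
class GenomeRecord:
    """One genome with habitat, GTDB-style lineage and contig inventory."""

    genome_id: str
    habitat: str = "unknown"
    lineage: tuple[str, ...] = ()
    contigs: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValidationError(f"habitat {self.habitat!r} not in {HABITATS}")
        for cid, length in self.contigs:
            if length < 1:
                raise ValidationError(
                    f"contig {cid!r} of {self.genome_id!r} has length {length} < 1")

    def rank(self, prefix: str) -> str:
        """Return the lineage entry with a GTDB prefix like ``p__`` or ``o__``."""
        for entry in self.lineage:
            if entry.startswith(prefix):
                return entry
        return prefix + "unclassified"


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff_gene_id(feature, line_no: int) -> str:
    attrs = feature.attributes
    for key in ("ID", "locus_tag", "Name", "gene_id"):
        if key in attrs and attrs[key]:
            return attrs[key][0]
    return f"{feature.seqid}:{feature.start}-{feature.end}:{line_no}"


def read_gene_features(
    path: str | Path,
    feature_types: Sequence[str] = ("gene", "CDS"),
) -> dict[str, list[GeneFeature]]:
    """Read gene/CDS records from a GFF3 file, grouped per contig.

    One :class:`GeneFeature` is emitted per record whose type is in
    ``feature_types``; coordinates are preserved exactly as written
    (1-based inclusive). Malformed lines raise :class:`ParseError` naming
    the line number; ``end < start`` raises :class:`ValidationError`.
    """
    path = Path(path)
    wanted = set(feature_types)
    per_contig: dict[str, list[GeneFeature]] = {}
    n_records = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            if len(line.split("\t")) < 8:
                raise ParseError(
                    f"{path.name}, line {line_no}: expected >= 8 tab-delimited "
                    f"GFF3 columns")
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path.name}, line {line_no}: {exc}") from exc
            if feat.featuretype not in wanted:
                continue
            start, end = int(feat.start), int(feat.end)
            if end < start:
                raise ValidationError(
                    f"{path.name}, line {line_no}: end ({end}) < start ({start})")
            strand = feat.strand if feat.strand in ("+", "-") else "unknown"
            gf = GeneFeature(
                contig_id=feat.seqid,
                gene_id=_gff_gene_id(feat, line_no),
                start=start,
                end=end,
                strand=strand,
            )
            per_contig.setdefault(gf.contig_id, []).append(gf)
            n_records += 1
    if n_records == 0:
        warnings.warn(f"no gene/CDS records found in {path}", stacklevel=2)
    return per_contig


# ---------------------------------------------------------------------------
# HMM hit tables
# ---------------------------------------------------------------------------

def load_trusted_cutoffs(path: str | Path) -> dict[str, float]:
    """Load a per-family trusted-cutoff table from YAML or TSV.

    YAML form: ``{family: cutoff, ...}``. TSV form: two columns
    ``family<TAB>trusted_cutoff`` with an optional header line.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise FormatError(f"{path}: expected a mapping family -> cutoff")
        table = {str(k): float(v) for k, v in raw.items()}
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        cols = [c.lower() for c in df.columns]
        if "family" in cols:
            df.columns = cols
        else:  # headerless two-column file
            df = pd.read_csv(path, sep="\t", comment="#", header=None,
                             names=["family", "trusted_cutoff"])
        table = dict(zip(df["family"].astype(str), df["trusted_cutoff"].astype(float)))
    bad = sorted(set(table) - set(PHN_FAMILIES))
    if bad:
        raise ValidationError(f"{path}: cutoffs for non-phn families {bad}")
    return table


def default_trusted_cutoffs() -> dict[str, float]:
    """The packaged per-family trusted-cutoff table (see data/trusted_cutoffs.yaml)."""
    here = Path(__file__).parent / "data" / "trusted_cutoffs.yaml"
    return load_trusted_cutoffs(here)


def read_domain_hits(
    path: str | Path,
    cutoffs: Mapping[str, float] | None = None,
) -> tuple[list[DomainHit], int]:
    """Read a whitespace-delimited per-domain HMM hit table.

    Accepts the HMMER3 ``--domtblout`` layout (>= 22 columns; the full-
    sequence E-value and bit score are used) or a minimal 4-column layout
    ``gene_id  family  bit_score  e_value``. Hits whose query model is not
    one of the 14 phn families are dropped; the second return value counts
    them. ``cutoffs`` maps each family to its trusted cutoff (defaults to
    the packaged table).
    """
    path = Path(path)
    if cutoffs is None:
        cutoffs = default_trusted_cutoffs()
    hits: list[DomainHit] = []
    dropped = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) >= 22:  # HMMER3 domtblout: tname .. qname .. E .. score
                gene_id, family = fields[0], fields[3]
                e_str, score_str = fields[6], fields[7]
            elif len(fields) == 4:
                gene_id, family, score_str, e_str = fields
            else:
                raise FormatError(
                    f"{path.name}, line {line_no}: unrecognized layout "
                    f"({len(fields)} columns; expected 4 or >=22)")
            if family not in PHN_FAMILIES:
                dropped += 1
                continue
            try:
                score = float(score_str)
                e_value = float(e_str)
            except ValueError as exc:
                raise ParseError(f"{path.name}, line {line_no}: {exc}") from exc
            if e_value < 0:
                raise ValidationError(
                    f"{path.name}, line {line_no}: negative E-value {e_value}")
            if family not in cutoffs:
                raise ValidationError(
                    f"{path.name}, line {line_no}: no trusted cutoff for {family}")
            hits.append(DomainHit(gene_id, family, score, e_value, float(cutoffs[family])))
    return hits, dropped


# ---------------------------------------------------------------------------
# Genome metadata
# ---------------------------------------------------------------------------

def _normalize_habitat(raw: object) -> str:
    text = str(raw).strip().lower()
    if text in HABITATS:
        return text
    warnings.warn(f"habitat {raw!r} not in vocabulary; mapped to 'unknown'",
                  stacklevel=3)
    return "unknown"


def read_genome_metadata(path: str | Path) -> list[GenomeRecord]:
    """Read a genome metadata TSV with columns genome_id, habitat, lineage.

    Habitat is normalized case-insensitively to the closed vocabulary;
    anything else becomes ``unknown`` with a warning. Duplicate genome ids
    raise :class:`ValidationError` listing the duplicates. An optional
    ``contigs`` column holds ``contig:length`` pairs separated by commas.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "habitat", "lineage"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    dups = df["genome_id"][df["genome_id"].duplicated()].unique().tolist()
    if dups:
        raise ValidationError(f"{path}: duplicate genome_id values: {dups}")
    records: list[GenomeRecord] = []
    for row in df.itertuples(index=False):
        lineage = tuple(
            s.strip() for s in str(row.lineage).split(";") if s.strip()
        ) if pd.notna(row.lineage) else ()
        contigs: tuple[tuple[str, int], ...] = ()
        if "contigs" in df.columns and pd.notna(getattr(row, "contigs", None)):
            contigs = tuple(
                (part.split(":")[0], int(part.split(":")[1]))
                for part in str(row.contigs).split(",") if part
            )
        records.append(GenomeRecord(
            genome_id=str(row.genome_id),
            habitat=_normalize_habitat(row.habitat),
            lineage=lineage,
            contigs=contigs,
        ))
    return records


def write_genome_metadata(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write genome metadata in the same TSV dialect :func:`read_genome_metadata` reads."""
    rows = []
    for rec in records:
        rows.append({
            "genome_id": rec.genome_id,
            "habitat": rec.habitat,
            "lineage": ";".join(rec.lineage),
            "contigs": ",".join(f"{cid}:{length}" for cid, length in rec.contigs),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

#: Column vocabulary for incubation measurement tables. All but the first
#: three are optional; units follow the field's bench conventions.
MEASUREMENT_COLUMNS = (
    "treatment",        # text label, e.g. "MPn", "Pi", "NoP", "MPn+Pi"
    "replicate",        # integer bottle index
    "time_h",           # hours since inoculation
    "headspace_ppm",    # CH4 mixing ratio in the headspace (ppm)
    "peak_area",        # raw GC-FID peak area (calibration required)
    "tdp_um",           # total dissolved phosphorus (umol/L)
    "dip_um",           # dissolved inorganic phosphorus (umol/L)
    "cells_per_ml",     # cell counts
    "pi_initial_um",    # initial added orthophosphate (umol/L)
)


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read an incubation measurement table (CSV or TSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    return validate_measurements(df)


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a measurement table against the data-model invariants.

    Requires treatment, replicate and time_h columns; coerces known numeric
    columns; checks time is non-negative and strictly increasing within each
    (treatment, replicate) series.
    """
    missing = {"treatment", "replicate", "time_h"} - set(df.columns)
    if missing:
        raise FormatError(f"measurement table missing columns {sorted(missing)}")
    df = df.copy()
    for col in MEASUREMENT_COLUMNS[1:]:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    if (df["time_h"] < 0).any():
        raise ValidationError("negative time_h in measurement table")
    for col in ("headspace_ppm", "peak_area"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValidationError(f"negative {col} in measurement table")
    for (treat, rep), grp in df.groupby(["treatment", "replicate"]):
        t = grp["time_h"].to_numpy()
        if len(t) > 1 and not (t[1:] > t[:-1]).all():
            raise ValidationError(
                f"time_h not strictly increasing for treatment={treat!r}, "
                f"replicate={rep}")
    return df


def roundtrip_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Write a measurement table to CSV text and read it back (test helper)."""
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return validate_measurements(pd.read_csv(buf))
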