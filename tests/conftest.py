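"""Shared fixtures and contig-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from phnomp.io_model import (
    PHN_FAMILIES,
    DomainHit,
    GeneFeature,
    default_trusted_cutoffs,
)
from phnomp.cluster_screen import assign_families


@pytest.fixture(scope="session")
def cutoffs() -> dict[str, float]:
    return default_trusted_cutoffs()


def build_contig(layout, cutoffs, contig_id="c1", score_factor=2.0):
    """Build (features, hits) from (family_or_None, start, end) triples.

    ``family=None`` makes a background gene without any hit. Scores are
    ``score_factor`` times the family cutoff (so < 1.0 plants sub-cutoff
    evidence).
    """
    features, hits = [], []
    for i, (family, start, end) in enumerate(layout):
        gid = f"{contig_id}_g{i}"
        features.append(GeneFeature(contig_id, gid, start, end))
        if family is not None:
            hits.append(DomainHit(gid, family, cutoffs[family] * score_factor,
                                  1e-30, cutoffs[family]))
    return features, hits


def operon_layout(families, start=1000, gene_len=900, gap=100):
    """Head-to-tail layout triples for a list of families."""
    layout = []
    pos = start
    for fam in families:
        layout.append((fam, pos, pos + gene_len - 1))
        pos += gene_len + gap
    return layout


def random_contig(rng: np.random.Generator, cutoffs, max_genes=20,
                  contig_extent=60_000):
    """A random contig of phn-assigned genes for oracle-equivalence checks."""
    n = int(rng.integers(0, max_genes + 1))
    layout = []
    for _ in range(n):
        start = int(rng.integers(1, contig_extent))
        length = int(rng.integers(300, 1500))
        fam = str(rng.choice(PHN_FAMILIES))
        layout.append((fam, start, start + length - 1))
    return build_contig(layout, cutoffs)


@pytest.fixture(scope="session")
def assigned():
    """Helper turning hits into assignments (shortcut used all over)."""
    return assign_families
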