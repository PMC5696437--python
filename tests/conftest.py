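"""Shared fixtures: small hand-built alignments and simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from codiverge.ortholog_io import CodonAlignment, GeneAlignment, concatenate
from codiverge.synthetic_data import preset_host_like, preset_wri_like


def make_alignment(sequences: dict[str, str], gene_lengths=None) -> CodonAlignment:
    """Build a CodonAlignment from raw strings (single gene by default)."""
    length = len(next(iter(sequences.values())))
    if gene_lengths is None:
        gene_lengths = [length]
    spans, offset = [], 0
    for i, glen in enumerate(gene_lengths):
        spans.append((f"g{i + 1}", offset, offset + glen))
        offset += glen
    return CodonAlignment(
        taxa=tuple(sorted(sequences)), matrix=dict(sequences), gene_spans=spans
    )


@pytest.fixture(scope="session")
def wri48_sim():
    """One simulated symbiont trio dataset at 48 kb (study-scale divergences)."""
    fx = preset_wri_like(total_bp=48_000)
    genes, truth = fx.simulate(seed=20240915)
    return fx, genes, truth, concatenate(genes)


@pytest.fixture(scope="session")
def host_sim():
    """One simulated five-taxon host nuclear dataset (18 loci, 27 kb)."""
    fx = preset_host_like()
    genes, truth = fx.simulate(seed=20240916)
    return fx, genes, truth, concatenate(genes)
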