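"""Pairwise divergence by codon position, with Jeffreys binomial intervals,
plus shared/private difference partitioning for an ingroup pair against an
outgroup.

Sites where either sequence of a comparison carries a gap, N or other
non-ACGT state are excluded from that comparison's denominator, so each
pair has its own usable-site count.  The chronogram operations of this
module live in :mod:`codiverge.chronogram` and are re-exported here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta

from ._util import render_percent
from .chronogram import (  # noqa: F401  (module surface)
    ChronogramEstimate,
    clock_log_likelihood,
    estimate_chronogram,
)
from .ortholog_io import CodonAlignment

__all__ = [
    "DifferenceCount",
    "DivergenceEstimate",
    "SNVPartition",
    "count_pairwise_differences",
    "pairwise_divergence",
    "partition_shared_private",
    "jeffreys_interval",
    "clock_log_likelihood",
    "estimate_chronogram",
    "ChronogramEstimate",
]


@dataclass
class DifferenceCount:
    """Usable sites and observed differences for one taxon pair."""

    taxon_pair: tuple[str, str]
    per_position: dict[int, tuple[int, int]]  # position -> (sites, differences)

    def __post_init__(self) -> None:
        for p, (n, k) in self.per_position.items():
            if k > n:
                raise ValueError(f"position {p}: more differences than sites")

    @property
    def sites_compared(self) -> int:
        return sum(n for n, _ in self.per_position.values())

    @property
    def differences(self) -> int:
        return sum(k for _, k in self.per_position.values())

    @classmethod
    def from_overall(
        cls, pair: tuple[str, str], differences: int, sites: int
    ) -> "DifferenceCount":
        """Build from an overall count only (e.g. a published SNV total)."""
        return cls(taxon_pair=pair, per_position={0: (sites, differences)})


@dataclass
class DivergenceEstimate:
    """Substitutions/site point estimates with 95% Jeffreys intervals."""

    taxon_pair: tuple[str, str]
    per_position: dict[int, tuple[float, float, float]]  # est, lo, hi
    overall: tuple[float, float, float]
    counts: DifferenceCount

    def rendered(self) -> str:
        """Overall divergence as a percentage string (published-value rounding)."""
        return render_percent(self.overall[0])


@dataclass
class SNVPartition:
    """Shared vs private derived differences for (a, b) against outgroup c."""

    ingroup: tuple[str, str]
    outgroup: str
    shared: int          # a == b != c
    private_a: int       # a != b, b == c
    private_b: int       # a != b, a == c
    all_different: int   # three distinct states; reported, not classified
    sites_compared: int


def jeffreys_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Jeffreys (Beta(1/2,1/2)-based) binomial interval for k successes of n."""
    if n <= 0:
        raise ValueError("no usable sites")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k + 0.5, n - k + 0.5))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 0.5, n - k + 0.5))
    return lo, hi


def count_pairwise_differences(
    aln: CodonAlignment, a: str, b: str
) -> DifferenceCount:
    """Differences between taxa a and b, per codon position.

    Sites with non-ACGT in either taxon are excluded from both the site and
    the difference counts.
    """
    codes = aln.to_codes([a, b])
    valid = (codes < 4).all(axis=0)
    diff = valid & (codes[0] != codes[1])
    pos = aln.position_index()
    per = {
        p: (int((valid & (pos == p)).sum()), int((diff & (pos == p)).sum()))
        for p in (1, 2, 3)
    }
    return DifferenceCount(taxon_pair=(a, b), per_position=per)


def pairwise_divergence(dc: DifferenceCount) -> DivergenceEstimate:
    """Point estimate (differences/sites) and Jeffreys 95% interval.

    Per-position estimates are produced for whatever positions the count
    carries; the overall estimate pools them.
    """
    if dc.sites_compared <= 0:
        raise ValueError("no usable sites for divergence estimation")
    per = {}
    for p, (n, k) in dc.per_position.items():
        if n == 0:
            continue
        lo, hi = jeffreys_interval(k, n)
        per[p] = (k / n, lo, hi)
    lo, hi = jeffreys_interval(dc.differences, dc.sites_compared)
    overall = (dc.differences / dc.sites_compared, lo, hi)
    return DivergenceEstimate(
        taxon_pair=dc.taxon_pair, per_position=per, overall=overall, counts=dc
    )


def partition_shared_private(
    aln: CodonAlignment, ingroup: tuple[str, str], outgroup: str
) -> SNVPartition:
    """Classify polymorphic sites of the trio as shared or private.

    Only sites where all three taxa carry A/C/G/T are considered.  A site is
    "shared" if the ingroup agrees and differs from the outgroup, private to
    one ingroup taxon if the other matches the outgroup.  Sites with three
    distinct states are counted separately and left unclassified.
    """
    a, b = ingroup
    codes = aln.to_codes([a, b, outgroup])
    valid = (codes < 4).all(axis=0)
    xa, xb, xc = (codes[i][valid] for i in range(3))
    shared = int(((xa == xb) & (xa != xc)).sum())
    private_a = int(((xa != xb) & (xb == xc)).sum())
    private_b = int(((xa != xb) & (xa == xc)).sum())
    all_diff = int(((xa != xb) & (xb != xc) & (xa != xc)).sum())
    return SNVPartition(
        ingroup=ingroup,
        outgroup=outgroup,
        shared=shared,
        private_a=private_a,
        private_b=private_b,
        all_different=all_diff,
        sites_compared=int(valid.sum()),
    )
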