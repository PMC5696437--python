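"""Strict-clock chronogram estimation with codon-position rate multipliers.

The model: every site evolves under HKY (empirical base frequencies, one
transition/transversion ratio per dataset), each codon position p with its
own clock rate r_p, so the expected substitutions on a branch at position p
equal r_p times the branch duration.  Ages are relative: the age of a
user-chosen reference node is fixed at 1, which removes the rate/time
scaling non-identifiability.  Point estimates are maximum likelihood;
intervals come from a parametric bootstrap (resimulate under the fitted
model, refit, percentile interval).

At the divergences this package targets (1e-5 .. 1e-1 substitutions/site)
chronogram age ratios are insensitive to substitution-model richness, which
is why HKY suffices here in place of heavier parameterizations.

A weak regularizer -- half a pseudo-substitution on the reference-pair
path in total, implemented as (1/6)*sum_p log P(reference-path site
differs at position p) added to the log-likelihood -- keeps ages finite when the reference
clade happens to show zero differences, which is a real possibility at
~1e-5 divergence on sub-100-kb alignments.  With any appreciable signal the
term is numerically negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from ._hky import (
    ClockLikelihood,
    PartitionedPatterns,
    compress_alignment,
    simulate_patterns,
)
from .ortholog_io import CodonAlignment
from .trees import Clade, ClockTree

__all__ = ["ChronogramEstimate", "clock_log_likelihood", "estimate_chronogram"]

_LOG_RATE_BOUNDS = (-30.0, 3.0)
_LOG_KAPPA_BOUNDS = (np.log(0.05), np.log(20.0))
_X_AGE_BOUNDS = (-23.0, 16.0)


@dataclass
class ChronogramEstimate:
    """Relative node ages (reference node = 1) plus per-position rates."""

    tree: ClockTree
    reference: Clade
    ages: dict[Clade, float]
    age_intervals: dict[Clade, tuple[float, float]]
    rates: tuple[float, float, float]
    rate_intervals: tuple[tuple[float, float], ...]
    kappa: float
    loglik: float
    converged: bool
    n_bootstrap: int
    pi: np.ndarray = field(repr=False, default=None)

    def age_of(self, clade: Sequence[str]) -> float:
        return self.ages[frozenset(clade)]

    def interval_of(self, clade: Sequence[str]) -> tuple[float, float]:
        return self.age_intervals[frozenset(clade)]


def _as_tree(topology: str | ClockTree) -> ClockTree:
    return topology if isinstance(topology, ClockTree) else ClockTree.from_newick(topology)


def _patterns_for(aln: CodonAlignment, tree: ClockTree) -> PartitionedPatterns:
    codes = aln.to_codes(tree.taxa)
    return compress_alignment(codes, aln.position_index(), tree.taxa)


def clock_log_likelihood(
    aln: CodonAlignment,
    topology: str | ClockTree,
    ages: Mapping[Clade, float],
    rates: Sequence[float],
    kappa: float = 2.0,
) -> float:
    """Log-likelihood of the partitioned strict clock at the given parameters.

    ``ages`` maps internal-node clades (frozensets of tip names) to ages;
    tips are at age 0.  Raises on negative or non-ultrametric ages.
    """
    tree = _as_tree(topology)
    vec = tree.ages_vector(ages)
    r = [float(x) for x in rates]
    if len(r) != 3 or any(x < 0 for x in r):
        raise ValueError("need three non-negative codon-position rates")
    lik = ClockLikelihood(tree, _patterns_for(aln, tree))
    return lik.loglik(vec, r, kappa)


class _ClockFit:
    """Parametrization + optimizer for the penalized clock likelihood.

    Free parameters: one unconstrained height increment per internal node
    other than the reference (age = oldest child age + exp(x), guaranteeing
    valid orderings), log rate multipliers, log kappa.
    """

    def __init__(self, tree: ClockTree, data: PartitionedPatterns, ref_node: int):
        self.tree = tree
        self.data = data
        self.ref = ref_node
        self.lik = ClockLikelihood(tree, data)
        self.free_nodes = [i for i in tree.internal_nodes if i != ref_node]
        self.n_free = len(self.free_nodes)

    def ages_from_x(self, x: np.ndarray) -> np.ndarray | None:
        ages = np.zeros(self.tree.n_nodes)
        slot = {n: k for k, n in enumerate(self.free_nodes)}
        for i in self.tree.internal_nodes:  # postorder: children done first
            oldest_child = max(ages[c] for c in self.tree.children[i])
            if i == self.ref:
                if oldest_child >= 1.0:
                    return None
                ages[i] = 1.0
            else:
                ages[i] = oldest_child + np.exp(x[slot[i]])
        return ages

    def unpack(self, theta: np.ndarray):
        ages = self.ages_from_x(theta[: self.n_free])
        rates = np.exp(theta[self.n_free : self.n_free + 3])
        kappa = float(np.exp(theta[self.n_free + 3]))
        return ages, rates, kappa

    # Jeffreys-style regularizer: half a pseudo-substitution on the
    # reference-pair path in total, spread over the three partitions.
    PENALTY_WEIGHT = 1.0 / 6.0

    def penalty(self, rates: np.ndarray) -> float:
        # reference node fixed at 1 => reference-pair path = 2 r_p
        q = -np.expm1(-2.0 * rates)
        return float(self.PENALTY_WEIGHT * np.log(np.maximum(q, 1e-300)).sum())

    def objective(self, theta: np.ndarray) -> float:
        ages, rates, kappa = self.unpack(theta)
        if ages is None:
            return 1e12
        ll = self.lik.loglik(ages, rates, kappa) + self.penalty(rates)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    def initial_theta(self, kappa0: float = 2.0) -> np.ndarray:
        tree, data = self.tree, self.data
        ntips = tree.n_tips
        # raw pairwise p-distances per partition, JC-corrected
        def pdist(p: int, a: int, b: int) -> float:
            pat, cnt = data.patterns[p], data.counts[p]
            if cnt.size == 0:
                return 0.0
            tot = cnt.sum()
            diff = cnt[pat[:, a] != pat[:, b]].sum()
            prop = min(diff / tot, 0.70)
            return -0.75 * np.log1p(-4.0 * prop / 3.0)

        ref_tips = sorted(
            t for t in range(ntips) if tree.taxa[t] in tree.clades[self.ref]
        )
        # partition rates from within-reference-clade divergence, floored
        rates0 = []
        for p in range(3):
            L = max(data.n_sites[p], 1)
            pairs = [
                pdist(p, a, b)
                for ai, a in enumerate(ref_tips)
                for b in ref_tips[ai + 1 :]
            ]
            d = float(np.mean(pairs)) if pairs else 0.0
            rates0.append(max(d / 2.0, 0.25 / L))
        weights = np.maximum(data.n_sites, 1)
        pooled_rate = float(np.average(rates0, weights=weights))

        def pooled_dist(a: int, b: int) -> float:
            num = sum(
                pdist(p, a, b) * data.n_sites[p] for p in range(3)
            )
            return num / max(sum(data.n_sites), 1)

        ages0 = np.zeros(tree.n_nodes)
        for i in tree.internal_nodes:
            kids = tree.children[i]
            cross = [
                pooled_dist(a, b)
                for ka in range(len(kids))
                for kb in range(ka + 1, len(kids))
                for a in range(ntips)
                if tree.taxa[a] in tree.clades[kids[ka]]
                for b in range(ntips)
                if tree.taxa[b] in tree.clades[kids[kb]]
            ]
            ages0[i] = float(np.mean(cross)) / (2.0 * pooled_rate)
        scale = ages0[self.ref] if ages0[self.ref] > 0 else 1.0
        ages0 /= scale
        # enforce strict ordering before inverting the parametrization
        x0 = np.empty(self.n_free)
        slot = {n: k for k, n in enumerate(self.free_nodes)}
        adjusted = np.zeros(tree.n_nodes)
        for i in tree.internal_nodes:
            oldest = max(adjusted[c] for c in tree.children[i])
            if i == self.ref:
                adjusted[i] = 1.0
            else:
                target = max(ages0[i], oldest * 1.05 + 1e-6)
                adjusted[i] = target
                x0[slot[i]] = np.log(max(target - oldest, 1e-6))
        return np.concatenate([x0, np.log(rates0), [np.log(kappa0)]])

    def fit(self, theta0: np.ndarray | None = None):
        if theta0 is None:
            theta0 = self.initial_theta()
        bounds = (
            [_X_AGE_BOUNDS] * self.n_free
            + [_LOG_RATE_BOUNDS] * 3
            + [_LOG_KAPPA_BOUNDS]
        )
        res = minimize(self.objective, theta0, method="L-BFGS-B", bounds=bounds)
        if not res.success or not np.isfinite(res.fun):
            res2 = minimize(
                self.objective, res.x, method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8},
            )
            if res2.fun <= res.fun:
                res = res2
        return res


def estimate_chronogram(
    aln: CodonAlignment,
    topology: str | ClockTree,
    reference_node: Sequence[str] | Clade,
    n_bootstrap: int = 100,
    seed: int | None = None,
    kappa0: float = 2.0,
) -> ChronogramEstimate:
    """Fit relative node ages and per-position rates; bootstrap the intervals.

    ``reference_node`` names the tips of the internal node whose age is
    fixed at 1 (it must be internal).  Bootstrap intervals are percentile
    intervals over ``n_bootstrap`` parametric resimulations; pass
    ``n_bootstrap=0`` to skip them.
    """
    tree = _as_tree(topology)
    if tree.n_tips < 3:
        raise ValueError("chronogram estimation needs at least three taxa")
    ref = tree.node_for_clade(reference_node)
    if not tree.children[ref]:
        raise ValueError("reference node must be internal")
    data = _patterns_for(aln, tree)
    fitter = _ClockFit(tree, data, ref)
    res = fitter.fit()
    ages_vec, rates, kappa = fitter.unpack(res.x)
    converged = bool(np.isfinite(res.fun) and ages_vec is not None)
    if not converged:
        raise RuntimeError("chronogram optimizer failed to converge")

    internal = tree.internal_nodes
    boot_ages = {i: [] for i in internal}
    boot_rates: list[list[float]] = []
    rng = np.random.default_rng(seed)
    for _ in range(n_bootstrap):
        sim = simulate_patterns(
            tree, ages_vec, rates, kappa, data.pi, data.n_sites, rng
        )
        bfit = _ClockFit(tree, sim, ref)
        bres = bfit.fit(theta0=res.x.copy())
        b_ages, b_rates, _ = bfit.unpack(bres.x)
        if b_ages is None or not np.isfinite(bres.fun):
            continue
        for i in internal:
            boot_ages[i].append(b_ages[i])
        boot_rates.append(list(b_rates))

    def pct(vals: list[float]) -> tuple[float, float]:
        if not vals:
            return (np.nan, np.nan)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return float(lo), float(hi)

    ages = {tree.clades[i]: float(ages_vec[i]) for i in internal}
    intervals = {tree.clades[i]: pct(boot_ages[i]) for i in internal}
    if boot_rates:
        arr = np.array(boot_rates)
        rate_ints = tuple(pct(list(arr[:, p])) for p in range(3))
    else:
        rate_ints = ((np.nan, np.nan),) * 3
    return ChronogramEstimate(
        tree=tree,
        reference=tree.clades[ref],
        ages=ages,
        age_intervals=intervals,
        rates=tuple(float(r) for r in rates),
        rate_intervals=rate_ints,
        kappa=kappa,
        loglik=float(-res.fun),
        converged=converged,
        n_bootstrap=len(boot_rates),
        pi=data.pi,
    )
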