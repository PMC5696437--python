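"""HKY substitution model: closed-form transition probabilities, pruning
likelihood over compressed site patterns, and pattern simulation.

The rate matrix is normalized so one unit of branch length equals one
expected substitution per site; per-codon-position branch lengths are then
rate multiplier x branch duration.  States are coded A=0, C=1, G=2, T=3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trees import ClockTree

PURINE = np.array([True, False, True, False])  # A, G


def stationary_scale(kappa: float, pi: np.ndarray) -> float:
    """Mean substitution rate of the unnormalized HKY generator (b=1)."""
    pa, pc, pg, pt = pi
    return 2.0 * kappa * (pa * pg + pc * pt) + 2.0 * (pa + pg) * (pc + pt)


def hky_p_batch(ts: np.ndarray, kappa: float, pi: np.ndarray) -> np.ndarray:
    """Transition matrices for a vector of branch lengths, shape (len(ts), 4, 4)."""
    pi = np.asarray(pi, dtype=float)
    ts = np.asarray(ts, dtype=float)[:, None, None]
    mu = stationary_scale(kappa, pi)
    b = 1.0 / mu
    a = kappa / mu
    pr = pi[0] + pi[2]
    py = pi[1] + pi[3]
    group_freq = np.where(PURINE, pr, py)
    e2 = np.exp(-b * ts)
    lam3 = np.where(PURINE, pr * a + py * b, py * a + pr * b)
    e3 = np.exp(-ts * lam3[None, None, :])
    pj = pi[None, None, :]
    gj = group_freq[None, None, :]
    same_group = (PURINE[:, None] == PURINE[None, :])[None, :, :]
    base = pj + pj * (1.0 / gj - 1.0) * e2
    P = np.where(same_group, base - (pj / gj) * e3, pj * (1.0 - e2))
    diag = base + ((gj - pj) / gj) * e3
    idx = np.arange(4)
    P[:, idx, idx] = diag[:, 0, :]
    return np.clip(P, 0.0, 1.0)


def hky_p_matrix(t: float, kappa: float, pi: np.ndarray) -> np.ndarray:
    """Transition-probability matrix after branch length ``t`` (subs/site)."""
    pi = np.asarray(pi, dtype=float)
    mu = stationary_scale(kappa, pi)
    b = 1.0 / mu  # transversion rate
    a = kappa / mu  # transition rate
    pr = pi[0] + pi[2]
    py = pi[1] + pi[3]
    group_freq = np.where(PURINE, pr, py)
    e2 = np.exp(-b * t)
    # group-specific eigenvalue: transitions inside purines / pyrimidines
    e3 = np.where(
        PURINE,
        np.exp(-t * (pr * a + py * b)),
        np.exp(-t * (py * a + pr * b)),
    )
    pj = pi[None, :]
    gj = group_freq[None, :]
    e3j = e3[None, :]
    same_group = PURINE[:, None] == PURINE[None, :]
    base = pj + pj * (1.0 / gj - 1.0) * e2
    P = np.where(same_group, base - (pj / gj) * e3j, pj * (1.0 - e2))
    diag = (base + ((gj - pj) / gj) * e3j)[0]
    np.fill_diagonal(P, diag)
    return np.clip(P, 0.0, 1.0)


def _unique_columns(tips: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique rows + counts for an (L, ntaxa) state matrix (states < 4),
    via integer packing (much faster than row-wise sorting)."""
    ntaxa = tips.shape[1]
    weights = 4 ** np.arange(ntaxa, dtype=np.int64)
    keys = tips.astype(np.int64) @ weights
    uniq, cnt = np.unique(keys, return_counts=True)
    pats = ((uniq[:, None] // weights[None, :]) % 4).astype(np.uint8)
    return pats, cnt.astype(float)


@dataclass
class PartitionedPatterns:
    """Compressed alignment: per codon position, unique columns + counts."""

    taxa: tuple[str, ...]
    patterns: list[np.ndarray]  # per partition, (npat, ntaxa) uint8
    counts: list[np.ndarray]    # per partition, (npat,) float
    pi: np.ndarray              # empirical base frequencies, pooled
    n_excluded: int = 0

    @property
    def n_sites(self) -> list[int]:
        return [int(c.sum()) for c in self.counts]


def compress_alignment(
    codes: np.ndarray,
    position: np.ndarray,
    taxa: Sequence[str],
) -> PartitionedPatterns:
    """Drop columns with any non-ACGT state, split by codon position, compress.

    ``codes`` is (ntaxa, nsites) uint8 from CodonAlignment.to_codes;
    ``position`` the per-site codon-position index.
    """
    valid = (codes < 4).all(axis=0)
    n_excluded = int((~valid).sum())
    base_counts = np.bincount(codes[:, valid].ravel(), minlength=4)[:4]
    total = base_counts.sum()
    pi = base_counts / total if total else np.full(4, 0.25)
    patterns, counts = [], []
    for p in (1, 2, 3):
        cols = codes[:, valid & (position == p)]
        if cols.size == 0:
            patterns.append(np.empty((0, codes.shape[0]), dtype=np.uint8))
            counts.append(np.empty(0))
            continue
        uniq, cnt = _unique_columns(cols.T)
        patterns.append(uniq)
        counts.append(cnt)
    return PartitionedPatterns(
        taxa=tuple(taxa), patterns=patterns, counts=counts, pi=pi,
        n_excluded=n_excluded,
    )


class ClockLikelihood:
    """Felsenstein pruning for a clock tree over partitioned patterns."""

    def __init__(self, tree: ClockTree, data: PartitionedPatterns):
        if tuple(data.taxa) != tuple(tree.taxa):
            raise ValueError("pattern taxa must match tree tip order")
        self.tree = tree
        self.data = data
        eye = np.eye(4)
        # per partition, per tip: (npat, 4) one-hot partials
        self._tip_partials = [
            [eye[pat[:, tip]] for tip in range(tree.n_tips)] if pat.size else None
            for pat in data.patterns
        ]

    def loglik(
        self,
        ages: Sequence[float],
        rates: Sequence[float],
        kappa: float,
    ) -> float:
        tree = self.tree
        ages = np.asarray(ages, dtype=float)
        # one batched transition-matrix computation for every (partition, branch)
        branch_nodes = [
            c for node in tree.internal_nodes for c in tree.children[node]
        ]
        durations = np.array(
            [
                ages[node] - ages[c]
                for node in tree.internal_nodes
                for c in tree.children[node]
            ]
        )
        ts = np.concatenate([r * durations for r in rates])
        Ps = hky_p_batch(ts, kappa, self.data.pi)
        nb = len(branch_nodes)
        total = 0.0
        for p in range(3):
            pat = self.data.patterns[p]
            if pat.shape[0] == 0:
                continue
            partials: list[np.ndarray | None] = [None] * tree.n_nodes
            for tip in range(tree.n_tips):
                partials[tip] = self._tip_partials[p][tip]
            bi = p * nb
            for node in tree.internal_nodes:
                acc = None
                for child in tree.children[node]:
                    contrib = partials[child] @ Ps[bi].T
                    bi += 1
                    acc = contrib if acc is None else acc * contrib
                partials[node] = acc
            site_l = partials[tree.root] @ self.data.pi
            if np.any(site_l <= 0):
                return -np.inf
            total += float(self.data.counts[p] @ np.log(site_l))
        return total


def simulate_patterns(
    tree: ClockTree,
    ages: Sequence[float],
    rates: Sequence[float],
    kappa: float,
    pi: np.ndarray,
    n_sites: Sequence[int],
    rng: np.random.Generator,
) -> PartitionedPatterns:
    """Simulate tip states under the fitted clock model (parametric bootstrap)."""
    patterns, counts = [], []
    parent = [-1] * tree.n_nodes
    for i in tree.internal_nodes:
        for c in tree.children[i]:
            parent[c] = i
    preorder = [tree.root] + [
        n for n in reversed(range(tree.n_nodes)) if n != tree.root
    ]
    for p in range(3):
        L = int(n_sites[p])
        if L == 0:
            patterns.append(np.empty((0, tree.n_tips), dtype=np.uint8))
            counts.append(np.empty(0))
            continue
        states = np.empty((tree.n_nodes, L), dtype=np.uint8)
        states[tree.root] = rng.choice(4, size=L, p=pi)
        for node in preorder:
            if node == tree.root:
                continue
            t_branch = rates[p] * (ages[parent[node]] - ages[node])
            P = hky_p_matrix(t_branch, kappa, pi)
            cum = P.cumsum(axis=1)
            u = rng.random(L)
            states[node] = (u[:, None] > cum[states[parent[node]]]).sum(axis=1)
        tips = states[: tree.n_tips].T  # (L, ntips)
        uniq, cnt = _unique_columns(tips)
        patterns.append(uniq)
        counts.append(cnt)
    return PartitionedPatterns(
        taxa=tree.taxa, patterns=patterns, counts=counts, pi=np.asarray(pi, float)
    )
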