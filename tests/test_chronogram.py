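"""The partitioned strict-clock likelihood and chronogram estimation:
closed-form checks at small divergence and recovery of simulated ages."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from codiverge._hky import hky_p_matrix, stationary_scale
from codiverge.chronogram import clock_log_likelihood, estimate_chronogram
from codiverge.divergence import count_pairwise_differences
from codiverge.ortholog_io import concatenate
from codiverge.synthetic_data import simulate_codon_alignment
from codiverge.trees import ClockTree

from conftest import make_alignment


def jc_distance(p: float) -> float:
    return -0.75 * np.log1p(-4.0 * p / 3.0)


class TestHKYMatrix:
    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 8.0])
    @pytest.mark.parametrize("t", [1e-5, 0.01, 0.3, 2.0])
    def test_matches_matrix_exponential(self, kappa, t):
        pi = np.array([0.3, 0.2, 0.25, 0.25])
        mu = stationary_scale(kappa, pi)
        Q = np.zeros((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
        for i in range(4):
            for j in range(4):
                if i != j:
                    Q[i, j] = (kappa if (i, j) in transitions else 1.0) * pi[j] / mu
            Q[i, i] = -Q[i].sum()
        assert np.allclose(hky_p_matrix(t, kappa, pi), expm(Q * t), atol=1e-10)

    def test_rows_sum_to_one_and_stationarity(self):
        pi = np.array([0.4, 0.1, 0.2, 0.3])
        P = hky_p_matrix(0.15, 3.0, pi)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.allclose(pi @ P, pi)


class TestClockLogLikelihood:
    def _trio(self):
        seqs = {
            "A": "ATGGGATTTCAT" * 25,
            "B": "ATGGGATTTCAT" * 25,
            "C": "ATGGGATTTCAT" * 25,
        }
        return make_alignment(seqs)

    def test_zero_rates_identical_sequences_finite(self):
        aln = self._trio()
        ages = {frozenset("AB"): 1.0, frozenset("ABC"): 2.0}
        ll = clock_log_likelihood(aln, "((A,B),C);", ages, (0.0, 0.0, 0.0))
        assert np.isfinite(ll)

    def test_zero_rates_any_difference_is_impossible(self):
        seqs = {"A": "ATG" * 100, "B": "ATG" * 99 + "ATC", "C": "ATG" * 100}
        aln = make_alignment(seqs)
        ages = {frozenset("AB"): 1.0, frozenset("ABC"): 2.0}
        ll = clock_log_likelihood(aln, "((A,B),C);", ages, (0.0, 0.0, 0.0))
        assert ll == -np.inf

    def test_scale_invariance_of_ages_and_rates(self, wri48_sim):
        fx, genes, truth, aln = wri48_sim
        ages = {frozenset({"wSuz", "wSpc"}): 1.0, frozenset(fx.tree.taxa): 3.51}
        rates = (2e-5, 2e-5, 2e-5)
        ll1 = clock_log_likelihood(aln, fx.tree, ages, rates)
        ll2 = clock_log_likelihood(
            aln,
            fx.tree,
            {k: 2 * v for k, v in ages.items()},
            tuple(r / 2 for r in rates),
        )
        assert ll1 == pytest.approx(ll2, abs=1e-6)

    def test_non_ultrametric_ages_rejected(self, wri48_sim):
        fx, *_, aln = wri48_sim
        ages = {frozenset({"wSuz", "wSpc"}): 2.0, frozenset(fx.tree.taxa): 1.0}
        with pytest.raises(ValueError, match="ultrametric|child"):
            clock_log_likelihood(aln, fx.tree, ages, (1e-5, 1e-5, 1e-5))

    def test_two_taxon_ml_equals_corrected_distance(self):
        """On a two-taxon clock the ML of r (ref age fixed at 1) satisfies
        2r = corrected pairwise distance; checked against the closed form."""
        tree = ClockTree.from_newick("(A,B);")
        genes, _ = simulate_codon_alignment(
            tree, {frozenset("AB"): 1.0}, (0.01, 0.01, 0.01), n_codons=30_000, seed=5
        )
        aln = concatenate(genes)
        dc = count_pairwise_differences(aln, "A", "B")
        p = dc.differences / dc.sites_compared

        def nll(log_r):
            r = np.exp(log_r)
            return -clock_log_likelihood(
                aln, tree, {frozenset("AB"): 1.0}, (r, r, r), kappa=1.0
            )

        res = minimize_scalar(nll, bounds=(-8, -2), method="bounded")
        fitted = 2 * np.exp(res.x)
        assert fitted == pytest.approx(jc_distance(p), rel=0.02)


class TestEstimateChronogram:
    def test_symmetric_trio_small_divergence_closed_form(self):
        """With d(A,B)=x and d(A,C)=d(B,C)=y the root age is y/x at small
        divergence."""
        tree = ClockTree.from_newick("((A,B),C);")
        ages = {frozenset("AB"): 1.0, frozenset("ABC"): 2.5}
        genes, _ = simulate_codon_alignment(
            tree, ages, (0.01, 0.01, 0.01), n_codons=60_000, seed=17
        )
        aln = concatenate(genes)
        est = estimate_chronogram(aln, tree, ("A", "B"), n_bootstrap=0)
        dc_ab = count_pairwise_differences(aln, "A", "B")
        x = jc_distance(dc_ab.differences / dc_ab.sites_compared)
        ys = []
        for t in "AB":
            dc = count_pairwise_differences(aln, t, "C")
            ys.append(jc_distance(dc.differences / dc.sites_compared))
        oracle = np.mean(ys) / x
        assert est.ages[frozenset("ABC")] == pytest.approx(oracle, rel=0.03)

    def test_reference_age_exactly_one(self, host_sim):
        fx, genes, truth, aln = host_sim
        est = estimate_chronogram(
            aln, fx.tree, ("D_suzukii", "D_subpulchrella"), n_bootstrap=5, seed=1
        )
        assert est.ages[frozenset({"D_suzukii", "D_subpulchrella"})] == 1.0
        # intervals bracket their point estimates
        for clade, (lo, hi) in est.age_intervals.items():
            if clade != est.reference:
                assert lo <= hi

    def test_child_ages_below_parent_ages(self, host_sim):
        fx, genes, truth, aln = host_sim
        est = estimate_chronogram(
            aln, fx.tree, ("D_suzukii", "D_subpulchrella"), n_bootstrap=0
        )
        for clade, age in est.ages.items():
            for other, other_age in est.ages.items():
                if clade < other:
                    assert age < other_age
        assert all(r > 0 for r in est.rates)

    def test_host_fixture_age_recovery(self, host_sim):
        """Point estimates land near the generating relative ages (1.96 and
        0.72) on a single 27-kb replicate."""
        fx, genes, truth, aln = host_sim
        est = estimate_chronogram(
            aln, fx.tree, ("D_suzukii", "D_subpulchrella"), n_bootstrap=0
        )
        bia = frozenset({"D_suzukii", "D_subpulchrella", "D_biarmipes"})
        ms = frozenset({"D_melanogaster", "D_simulans"})
        assert est.ages[bia] == pytest.approx(1.96, rel=0.10)
        assert est.ages[ms] == pytest.approx(0.72, rel=0.12)

    def test_reference_must_be_internal(self, wri48_sim):
        fx, *_, aln = wri48_sim
        with pytest.raises((KeyError, ValueError)):
            estimate_chronogram(aln, fx.tree, ("wSuz",), n_bootstrap=0)
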