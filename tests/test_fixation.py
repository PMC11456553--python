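"""Fixation analytics: ratio products, dynamics, weak selection, equilibria."""

import math

import numpy as np
import pytest

from coopmove.fitness import FitnessPair
from coopmove.fixation import (
    DoveNeutrality,
    FitnessValidityError,
    FixationResult,
    TransitionRatios,
    bdb_ratios,
    bdd_ratios,
    dove_neutral_ratio,
    equilibrium_ratio,
    fixation_closed,
    fixation_from_ratios,
    markov_fixation_oracle,
    state_fitnesses,
    weak_selection_pgg,
)
from coopmove.games import GameSpec
from coopmove.group_stats import pair_statistics_exact
from coopmove.movement import MovementSpec, ParameterError

from conftest import mechanism_specs


class TestRatioFormula:
    def test_neutral_chain(self):
        for N in (2, 5, 20):
            rho = fixation_from_ratios(TransitionRatios((1.0,) * (N - 1)))
            assert rho == pytest.approx(1.0 / N, abs=1e-14)

    def test_constant_ratio_geometric(self):
        # r = 10/9, N = 3: rho = (1 - r)/(1 - r^3) = 81/271
        rho = fixation_from_ratios(TransitionRatios((10 / 9, 10 / 9)))
        assert rho == pytest.approx(81 / 271, abs=1e-14)
        # brute-force solve of the 4-state chain as an independent check
        r = 10 / 9
        beta, delta = 0.3, 0.3 * r
        A = np.array([[beta + delta, -beta], [-delta, beta + delta]])
        p = np.linalg.solve(A, np.array([0.0, beta]))
        assert rho == pytest.approx(p[0], abs=1e-12)

    def test_extreme_ratios(self):
        assert fixation_from_ratios(TransitionRatios((1e12,) * 4)) < 1e-11
        assert fixation_from_ratios(TransitionRatios((1e-12,) * 4)) == pytest.approx(
            1.0, abs=1e-11
        )

    def test_log_space_handles_many_states(self):
        # strong selection at N = 500 would overflow naive products
        rho = fixation_from_ratios(TransitionRatios((2.0,) * 499))
        assert 0.0 <= rho < 1e-100

    def test_invalid_ratios(self):
        with pytest.raises(ParameterError):
            TransitionRatios((1.0, -0.5))
        with pytest.raises(ParameterError):
            TransitionRatios(())


class TestDynamicsRatios:
    def test_neutral_fitness_gives_1_over_N(self):
        fits = tuple(FitnessPair(3.0, 3.0, k) for k in range(1, 6))
        assert fixation_from_ratios(bdb_ratios(fits)) == pytest.approx(1 / 6)
        for w_star in (0.0, 1.7, 10.0):
            assert fixation_from_ratios(bdd_ratios(fits, w_star)) == pytest.approx(
                1 / 6, abs=1e-12
            )

    def test_constant_fitness_ratio_reproduces_geometric(self, pgg):
        # V = 0 cooperator invasion: every ratio is R/(R-C) = 10/9
        game = GameSpec("public_goods", 10.0, 0.0, 1.0)
        fits = tuple(FitnessPair(9.0, 10.0, k) for k in (1, 2))
        assert fixation_from_ratios(bdb_ratios(fits)) == pytest.approx(
            81 / 271, abs=1e-12
        )

    def test_nonpositive_fitness_rejected(self):
        fits = (FitnessPair(1.0, 2.0, 1), FitnessPair(-0.5, 2.0, 2))
        with pytest.raises(FitnessValidityError, match="k=2"):
            bdb_ratios(fits)

    def test_bdd_approaches_bdb_at_wstar0_weak_selection(self):
        game = GameSpec("public_goods", 1e4, 2.0, 1.0)
        fits = tuple(
            FitnessPair(game.R - game.C + (k - 1) * 0.2, game.R + k * 0.2, k)
            for k in range(1, 10)
        )
        bdb = fixation_from_ratios(bdb_ratios(fits))
        bdd = fixation_from_ratios(bdd_ratios(fits, 0.0))
        assert bdd == pytest.approx(bdb, rel=1e-4)


class TestMarkovOracle:
    @pytest.mark.parametrize("h", [0.5, 1.0, 2.0, 10.0])
    @pytest.mark.parametrize("mech_idx", range(4))
    @pytest.mark.parametrize("dynamics", ["BDB", "BDD"])
    def test_closed_forms_agree_small_N(self, pgg, hd, h, mech_idx, dynamics):
        spec = mechanism_specs(5, h)[mech_idx]
        for game in (pgg, hd):
            closed = fixation_closed(spec, game, dynamics).probability
            oracle = markov_fixation_oracle(spec, game, dynamics)
            assert closed == pytest.approx(oracle, rel=1e-10)

    def test_neutral_martingale(self):
        # neutral game: p_k = k/N for every starting count
        spec = MovementSpec("independent", 1.0, 6)
        game = GameSpec("public_goods", 10.0, 0.0, 0.0)
        for dynamics in ("BDB", "BDD"):
            for k in range(1, 6):
                p = markov_fixation_oracle(spec, game, dynamics, start=k)
                assert p == pytest.approx(k / 6, abs=1e-12)

    def test_hd_large_h_near_neutral(self, hd):
        """Always-alone limit: both types earn R + V, so fixation tends to
        1/N under both dynamics."""
        spec = MovementSpec("independent", 1e6, 5)
        for dynamics in ("BDB", "BDD"):
            rho = fixation_closed(spec, hd, dynamics).probability
            assert rho == pytest.approx(1 / 5, abs=1e-5)


class TestWeakSelection:
    def test_printed_first_order_value(self):
        game = GameSpec("public_goods", 1000.0, 2.0, 1.0)
        approx = weak_selection_pgg(game, 10, 0.1, dynamics="BDB")
        assert approx == pytest.approx(0.1 * (1 - 0.0045 * 1.2), abs=1e-12)

    def test_wstar_zero_collapses_dynamics(self):
        game = GameSpec("public_goods", 1000.0, 2.0, 1.0)
        a = weak_selection_pgg(game, 10, 0.1, 0.0, "BDB")
        b = weak_selection_pgg(game, 10, 0.1, 0.0, "BDD")
        assert a == b

    def test_error_decays_quadratically_in_R(self):
        spec = MovementSpec("independent", 2.0, 10)
        d = pair_statistics_exact(spec).d_N
        errs = []
        for R in (1e3, 1e4):
            game = GameSpec("public_goods", R, 2.0, 1.0)
            exact = fixation_closed(spec, game, "BDB").probability
            errs.append(abs(exact - weak_selection_pgg(game, 10, d)))
        ratio = errs[0] / errs[1]
        assert 50 < ratio < 200


class TestEquilibriumAndNeutrality:
    def test_equilibrium_ratio_printed_values(self):
        vc = equilibrium_ratio(0.5)
        assert round(vc, 3) == 0.688
        assert round(1 / vc, 3) == 1.453

    def test_equilibrium_matches_fitness_equality(self):
        from coopmove.fitness import infinite_population_fitness

        for p in (0.25, 0.5, 0.8):
            vc = equilibrium_ratio(p)
            game = GameSpec("hawk_dove", R=5.0, V=vc, C=1.0)
            dove, hawk = infinite_population_fitness(game, p)
            assert dove == pytest.approx(hawk, abs=1e-10)

    def test_equilibrium_root_finding_oracle(self):
        """Independent root solve of dove = hawk fitness at p = 0.25."""
        from scipy.optimize import brentq

        from coopmove.fitness import infinite_population_fitness

        def gap(vc):
            game = GameSpec("hawk_dove", R=5.0, V=vc, C=1.0)
            dove, hawk = infinite_population_fitness(game, 0.25)
            return dove - hawk

        root = brentq(gap, 0.1, 10.0)
        assert equilibrium_ratio(0.25) == pytest.approx(root, rel=1e-10)

    def test_domain(self):
        with pytest.raises(ParameterError):
            equilibrium_ratio(0.0)

    def test_dove_neutrality_root(self):
        res = dove_neutral_ratio(h=1.0, N=10, R=1e4)
        # residual at the root
        from coopmove.fixation import _dove_fixation_given_cost

        rho = _dove_fixation_given_cost(1.0, 10, 1e4, 1.0, res.numeric_ratio,
                                        "BDB", 0.0)
        assert abs(rho - 0.1) < 1e-10
        # hawks are worse off than in pairwise classics: C/V above 1 yet
        # below the classical 1.5-2 range
        assert 1.0 < res.numeric_ratio < 1.5

    def test_dove_neutrality_dynamics_invariant_under_weak_selection(self):
        bdb = dove_neutral_ratio(h=2.0, N=8, R=1e5).numeric_ratio
        bdd = dove_neutral_ratio(h=2.0, N=8, R=1e5, dynamics="BDD").numeric_ratio
        assert bdb == pytest.approx(bdd, rel=1e-3)

    def test_series_value_reported_with_discrepancy(self):
        res = dove_neutral_ratio(h=1.0, N=10, R=1e4)
        assert res.series_ratio == pytest.approx(res.numeric_ratio - res.discrepancy)
        assert res.series_ratio > 0


def test_fixation_result_validation():
    with pytest.raises(ParameterError):
        FixationResult(probability=1.5, method="closed_form")
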