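"""Group-formation laws: enumeration, estimation, and pair statistics."""

import math

import numpy as np
import pytest

from coopmove.group_stats import (
    CapacityError,
    chi_independent,
    enumerate_distribution,
    estimate_distribution,
    exact_marginals,
    group_size_distribution,
    pair_statistics,
    pair_statistics_exact,
)
from coopmove.movement import MovementSpec, ParameterError, territorial_apriori

from conftest import mechanism_specs


class TestChiIndependent:
    def test_two_coins(self):
        p = np.full((2, 2), 0.5)
        assert chi_independent(p, 0, [0, 1]) == pytest.approx(0.25)

    def test_normalization_over_groups(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(3), size=4)
        import itertools

        for m in range(3):
            total = 0.0
            for r in range(0, 5):
                for G in itertools.combinations(range(4), r):
                    if G:
                        total += chi_independent(p, m, G)
                    else:
                        total += math.prod(1 - p[j, m] for j in range(4))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_all_three_together_uniform(self):
        p = np.full((3, 3), 1 / 3)
        total = sum(chi_independent(p, m, [0, 1, 2]) for m in range(3))
        assert total == pytest.approx(1 / 9, abs=1e-15)

    def test_bad_rows_rejected(self):
        with pytest.raises(ParameterError):
            chi_independent(np.full((2, 2), 0.4), 0, [0])


class TestEnumerateDistribution:
    def test_cap(self):
        with pytest.raises(CapacityError):
            enumerate_distribution(MovementSpec("independent", 1.0, 8))

    @pytest.mark.parametrize("spec", mechanism_specs(3, 2.0))
    def test_normalized(self, spec):
        dist = enumerate_distribution(spec)
        assert sum(dist.entries.values()) == pytest.approx(1.0, abs=1e-12)

    def test_independent_matches_product_form(self):
        """The enumerated independent-mechanism law agrees with the product
        formula applied to the territorial marginals."""
        spec = MovementSpec("independent", 2.0, 3)
        dist = enumerate_distribution(spec)
        p = np.vstack(
            [territorial_apriori(2.0, 3, home=i).as_array() for i in range(3)]
        )
        # P(all three on one place) both ways
        direct = sum(chi_independent(p, m, [0, 1, 2]) for m in range(3))
        together = dist.prob_partition(frozenset([frozenset({0, 1, 2})]))
        assert together == pytest.approx(direct, abs=1e-12)

    def test_estimate_converges_to_enumeration(self, rng):
        spec = MovementSpec("follow_majority", 2.0, 3)
        exact = enumerate_distribution(spec)
        emp = estimate_distribution(spec, 20_000, rng)
        for key, p in exact.unlabelled().items():
            se = math.sqrt(p * (1 - p) / 20_000)
            assert abs(emp.unlabelled().get(key, 0.0) - p) < 4 * se + 1e-9

    def test_estimate_seed_reproducible(self):
        spec = MovementSpec("wheel", 1.0, 3, theta=0.7)
        a = estimate_distribution(spec, 200, np.random.default_rng(5)).entries
        b = estimate_distribution(spec, 200, np.random.default_rng(5)).entries
        assert a == b

    def test_wheel_theta0_h1_all_together(self, rng):
        spec = MovementSpec("wheel", 1.0, 3, theta=0.0)
        emp = estimate_distribution(spec, 500, rng)
        assert emp.prob_partition(frozenset([frozenset({0, 1, 2})])) == 1.0


class TestSizeLawAgainstEnumeration:
    """The analytic focal group-size law is exact for every mechanism."""

    @pytest.mark.parametrize("h", [0.5, 1.0, 2.0, 10.0])
    @pytest.mark.parametrize(
        "mech_kwargs",
        [
            ("independent", {}),
            ("follow_majority", {}),
            ("polya_urn", {"B": 2.0}),
            ("polya_urn", {"B": 0.0}),
            ("wheel", {"theta": 2 * math.pi / 4}),
            ("wheel", {"theta": 1.234}),
        ],
    )
    def test_matches_full_enumeration(self, h, mech_kwargs):
        mech, kwargs = mech_kwargs
        spec = MovementSpec(mech, h, 4, **kwargs)
        enum_pmf = enumerate_distribution(spec).group_size_pmf()
        fast_pmf = np.array(group_size_distribution(spec))
        assert np.abs(enum_pmf - fast_pmf).max() < 1e-12


class TestPairStatistics:
    def test_two_individual_independent_h1(self):
        # d_2 = 2h/(h+1)^2 at h = 1 gives exactly 1/2
        spec = MovementSpec("independent", 1.0, 2)
        stats = pair_statistics(enumerate_distribution(spec))
        assert stats.d_N == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("h", [0.25, 1.0, 3.0])
    def test_two_individual_independent_formula(self, h):
        spec = MovementSpec("independent", h, 2)
        stats = pair_statistics_exact(spec)
        assert stats.d_N == pytest.approx(2 * h / (h + 1) ** 2, abs=1e-12)

    def test_follow_majority_h1_single_group(self):
        # all together => d_N = 1/(N-1)
        for N in (3, 5):
            spec = MovementSpec("follow_majority", 1.0, N)
            stats = pair_statistics_exact(spec)
            assert stats.d_N == pytest.approx(1 / (N - 1), abs=1e-12)

    def test_always_alone_raises(self):
        spec = MovementSpec("wheel", 1.0, 4, theta=2 * math.pi / 4,
                            theta_precision=None)
        with pytest.raises(ParameterError):
            pair_statistics_exact(spec)

    @pytest.mark.parametrize("h", [0.5, 1.0, 2.0, 10.0])
    @pytest.mark.parametrize("spec_idx", range(4))
    def test_conservation_and_identity(self, h, spec_idx):
        """w_s + (N-1) w = 1 and d_N = w for every mechanism and h."""
        spec = mechanism_specs(4, h)[spec_idx]
        stats = pair_statistics(enumerate_distribution(spec))
        assert stats.w_s + 3 * stats.w == pytest.approx(1.0, abs=1e-10)
        assert stats.d_N == pytest.approx(stats.w, abs=1e-10)

    def test_exchangeability_check_runs(self):
        # pair_statistics validates per-pair agreement on exact laws
        spec = MovementSpec("wheel", 2.0, 4, theta=1.0)
        stats = pair_statistics(enumerate_distribution(spec))
        assert 0 < stats.d_N < 1

    def test_d_monotone_in_urn_scale(self):
        """Herding raises pair co-occurrence: d_N non-increasing in B."""
        ds = [
            pair_statistics_exact(
                MovementSpec("polya_urn", 1.0, 10, B=B)
            ).d_N
            for B in (0.0, 2.0, 6.0, 100.0, 10_000.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(ds, ds[1:]))
        # limits: B=0 is the single-group value, B->inf the independent one
        assert ds[0] == pytest.approx(1 / 9, abs=1e-12)
        indep = pair_statistics_exact(MovementSpec("independent", 1.0, 10)).d_N
        assert ds[-1] == pytest.approx(indep, rel=1e-2)


class TestFaithfulness:
    @pytest.mark.parametrize("h", [0.5, 1.0, 2.0, 10.0])
    @pytest.mark.parametrize("N", [2, 3, 4])
    @pytest.mark.parametrize("mech_idx", range(4))
    def test_exact_marginals_small_N(self, h, N, mech_idx):
        spec = mechanism_specs(N, h)[mech_idx]
        marg = exact_marginals(spec)
        for i in range(N):
            target = territorial_apriori(h, N, home=i).as_array()
            assert np.abs(marg[i] - target).max() < 1e-12

    def test_mechanism_equivalences_exact(self):
        """urn(B=0) == follow-the-majority == wheel(theta=0), as laws."""
        h = 2.0
        ftm = enumerate_distribution(MovementSpec("follow_majority", h, 3))
        urn0 = enumerate_distribution(MovementSpec("polya_urn", h, 3, B=0.0))
        wheel0 = enumerate_distribution(MovementSpec("wheel", h, 3, theta=0.0))
        for key, p in ftm.entries.items():
            assert urn0.entries.get(key, 0.0) == pytest.approx(p, abs=1e-12)
            assert wheel0.entries.get(key, 0.0) == pytest.approx(p, abs=1e-12)

    def test_urn_large_B_approaches_independent(self):
        """Total-variation distance to the independent law decreases in B."""
        indep = enumerate_distribution(MovementSpec("independent", 1.0, 3))

        def tv(B):
            urn = enumerate_distribution(MovementSpec("polya_urn", 1.0, 3, B=B))
            keys = set(indep.entries) | set(urn.entries)
            return 0.5 * sum(
                abs(indep.entries.get(k, 0.0) - urn.entries.get(k, 0.0))
                for k in keys
            )

        tvs = [tv(B) for B in (1.0, 10.0, 100.0, 10_000.0)]
        assert all(a > b for a, b in zip(tvs, tvs[1:]))
        assert tvs[-1] < 1e-3
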