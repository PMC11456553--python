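"""Group-formation distributions and replacement-weight statistics.

Co-located individuals form groups; everything evolutionary in this package
is driven by the probability law of that random partition.  Three routes to
it are provided:

* :func:`enumerate_distribution` — exact sum over participation sets,
  mechanism outcomes and mover orderings (small ``N``; the reference
  implementation that everything else is validated against);
* :func:`estimate_distribution` — Monte-Carlo frequencies from the samplers;
* :func:`group_size_distribution` — an exact, closed computation of the
  *focal* group-size law for any ``N``, exploiting exchangeability of
  individuals on the complete graph (used by the fitness and fixation
  modules where the full partition law is not needed).

Derived quantities: the pair-meeting weight ``d_N`` (probability-weighted
chance that two fixed individuals share a group, each co-member weighted by
``1/(|G|-1)``), the self replacement weight ``w_s`` (probability of being
alone) and ``w* = (w_s - w)/w`` which governs the BDB/BDD difference.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, FrozenSet, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .movement import (
    AprioriDistribution,
    MovementSpec,
    ParameterError,
    PlacementConfiguration,
    sample_configuration,
    uniform_apriori,
)

__all__ = [
    "GroupDistribution",
    "PairStatistics",
    "chi_independent",
    "enumerate_distribution",
    "estimate_distribution",
    "pair_statistics",
    "pair_statistics_exact",
    "group_size_distribution",
    "exact_marginals",
]

LabelledPartition = FrozenSet[Tuple[int, FrozenSet[int]]]

DEFAULT_ENUMERATION_CAP = 6


class CapacityError(ValueError):
    """Problem size exceeds the exact-enumeration cap; use Monte Carlo."""


@dataclass
class GroupDistribution:
    """Probability mass over place-labelled co-location partitions.

    ``entries`` maps ``frozenset({(place, members), ...})`` over occupied
    places to probability.  ``exact`` distinguishes enumerated laws from
    empirical frequencies; empirical ones record ``n_samples`` and raw
    counts so standard errors are recoverable.
    """

    entries: Dict[LabelledPartition, float]
    N: int
    M: int
    exact: bool = True
    n_samples: Optional[int] = None
    counts: Optional[Dict[LabelledPartition, int]] = None

    def __post_init__(self) -> None:
        total = sum(self.entries.values())
        tol = 1e-10 if self.exact else 1e-3 / math.sqrt(max(self.n_samples or 1, 1))
        if any(p < -1e-15 for p in self.entries.values()):
            raise ParameterError("negative probability in group distribution")
        if abs(total - 1.0) > max(tol, 1e-10):
            raise ParameterError(f"group distribution sums to {total!r}")

    def unlabelled(self) -> Dict[FrozenSet[FrozenSet[int]], float]:
        """Aggregate out the place labels, keeping the set partition."""
        out: Dict[FrozenSet[FrozenSet[int]], float] = {}
        for key, p in self.entries.items():
            part = frozenset(members for _, members in key)
            out[part] = out.get(part, 0.0) + p
        return out

    def prob_partition(self, partition: FrozenSet[FrozenSet[int]]) -> float:
        return self.unlabelled().get(frozenset(frozenset(g) for g in partition), 0.0)

    def prob_all_together(self) -> float:
        return self.prob_partition(frozenset([frozenset(range(self.N))]))

    def group_size_pmf(self) -> np.ndarray:
        """Law of a uniformly chosen focal individual's group size."""
        pmf = np.zeros(self.N)
        for key, p in self.entries.items():
            for _, members in key:
                pmf[len(members) - 1] += p * len(members) / self.N
        return pmf

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, p in sorted(self.entries.items(), key=lambda kv: -kv[1]):
            label = ";".join(
                f"{place}:" + ",".join(map(str, sorted(members)))
                for place, members in sorted(key)
            )
            rows.append({"partition": label, "probability": p})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class PairStatistics:
    """Replacement weights of the exchangeable complete-graph process.

    ``d_N`` is the pair-meeting weight, ``w`` the off-diagonal replacement
    weight (they coincide), ``w_s`` the self weight (probability of being
    alone) and ``w_star = (w_s - w)/w``.  Row conservation holds exactly:
    ``w_s + (N-1) w = 1``.
    """

    d_N: float
    w: float
    w_s: float
    w_star: float
    N: int


def chi_independent(placement_probs: np.ndarray, m: int, G: Sequence[int]) -> float:
    """Probability that exactly the group ``G`` forms at place ``m`` under
    independent movement with per-individual place probabilities ``p[i, m]``."""
    p = np.asarray(placement_probs, dtype=float)
    if p.ndim != 2:
        raise ParameterError("placement_probs must be an N x M matrix")
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-10):
        raise ParameterError("placement probability rows must sum to 1")
    members = set(G)
    if not members:
        raise ParameterError("group must be non-empty")
    out = 1.0
    for i in range(p.shape[0]):
        out *= p[i, m] if i in members else 1.0 - p[i, m]
    return out


# ---------------------------------------------------------------------------
# Exact enumeration of the full partition law (small N).
# ---------------------------------------------------------------------------


def _exact_ftm_placements(parts: Tuple[int, ...], apriori: AprioriDistribution):
    """Follow-the-majority: all movers herd at a single apriori-distributed
    place.  (After the first mover there is always a unique most-occupied
    place, so the tie rule only matters for the first mover, where both tie
    rules reduce to sampling the apriori.)"""
    if not parts:
        yield {}, 1.0
        return
    for m, a in enumerate(apriori.weights):
        if a > 0:
            yield {i: m for i in parts}, a


def _exact_urn_placements(
    parts: Tuple[int, ...], apriori: AprioriDistribution, B: float
):
    """Polya urn: the mover-order average is a Dirichlet-multinomial, so the
    probability of a placement vector depends only on its occupancy counts:
    ``prod_m prod_{t<c_m}(B a_m + t) / prod_{t<n}(B + t)``."""
    if B == 0:
        yield from _exact_ftm_placements(parts, apriori)
        return
    n = len(parts)
    if n == 0:
        yield {}, 1.0
        return
    denom = 1.0
    for t in range(n):
        denom *= B + t
    for vec in itertools.product(range(apriori.M), repeat=n):
        counts = [0] * apriori.M
        num = 1.0
        for m in vec:
            num *= B * apriori.weights[m] + counts[m]
            counts[m] += 1
        if num > 0:
            yield dict(zip(parts, vec)), num / denom


def _wheel_spike_patterns(n: int, apriori: AprioriDistribution, theta_frac: float):
    """Exact rotation integration: yields ``(arc_of_spike tuple, measure)``
    for spikes at positions ``(j*theta_frac + phi) mod 1`` with ``phi``
    uniform on [0, 1).  The arc vector is piecewise constant in ``phi`` with
    breakpoints where a spike crosses an arc boundary."""
    if n == 0:
        yield (), 1.0
        return
    cuts = np.cumsum(apriori.as_array())
    cuts[-1] = 1.0
    bounds = np.concatenate(([0.0], cuts))
    breaks = sorted(
        {(b - j * theta_frac) % 1.0 for j in range(n) for b in bounds[:-1]}
    )
    breaks.append(breaks[0] + 1.0)
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        if hi - lo < 1e-15:
            continue
        phi = (lo + hi) / 2.0
        arcs = tuple(
            min(int(np.searchsorted(cuts, (j * theta_frac + phi) % 1.0, side="right")),
                apriori.M - 1)
            for j in range(n)
        )
        yield arcs, hi - lo


def _exact_wheel_placements(
    parts: Tuple[int, ...], apriori: AprioriDistribution, theta_frac: float
):
    """Wheel: integrate the rotation exactly, then average over the ``n!``
    uniformly random assignments of spikes to movers."""
    n = len(parts)
    if n == 0:
        yield {}, 1.0
        return
    fact = math.factorial(n)
    for arcs, measure in _wheel_spike_patterns(n, apriori, theta_frac):
        w = measure / fact
        for perm in itertools.permutations(range(n)):
            yield {parts[i]: arcs[perm[i]] for i in range(n)}, w


def _exact_independent_placements(parts: Tuple[int, ...], apriori: AprioriDistribution):
    n = len(parts)
    if n == 0:
        yield {}, 1.0
        return
    for vec in itertools.product(range(apriori.M), repeat=n):
        p = 1.0
        for m in vec:
            p *= apriori.weights[m]
        if p > 0:
            yield dict(zip(parts, vec)), p


def _mechanism_placements(spec: MovementSpec, parts: Tuple[int, ...], apriori):
    if spec.mechanism == "independent":
        return _exact_independent_placements(parts, apriori)
    if spec.mechanism == "follow_majority":
        return _exact_ftm_placements(parts, apriori)
    if spec.mechanism == "polya_urn":
        return _exact_urn_placements(parts, apriori, spec.B)
    return _exact_wheel_placements(parts, apriori, spec.theta_frac)


@lru_cache(maxsize=64)
def enumerate_distribution(
    spec: MovementSpec, cap: int = DEFAULT_ENUMERATION_CAP
) -> GroupDistribution:
    """Exact place-labelled partition law of one movement round.

    Sums over every participation pattern, every non-home choice of the
    random movers and every mechanism outcome (with mover orderings averaged
    exactly).  Feasible for ``N`` up to about ``cap``.  Results are cached
    per spec; treat the returned distribution as read-only.
    """
    if spec.N != spec.M:
        raise ParameterError("evolutionary setting requires N = M")
    if spec.N > cap:
        raise CapacityError(
            f"N = {spec.N} exceeds the enumeration cap {cap}; "
            "use estimate_distribution"
        )
    N = spec.N
    split = spec.split
    apriori = uniform_apriori(spec.M)
    actions = []  # (prob, placer) per individual action
    entries: Dict[LabelledPartition, float] = {}

    options = []
    if split.p_direct_home > 0:
        options.append(("home", split.p_direct_home))
    if split.p_mechanism > 0:
        options.append(("mech", split.p_mechanism))
    if split.p_random_nonhome > 0:
        options.append(("rand", split.p_random_nonhome))

    for assignment in itertools.product(options, repeat=N):
        base_prob = 1.0
        for _, p in assignment:
            base_prob *= p
        parts = tuple(i for i in range(N) if assignment[i][0] == "mech")
        randos = [i for i in range(N) if assignment[i][0] == "rand"]
        fixed = {i: i for i in range(N) if assignment[i][0] == "home"}
        rand_choices = [
            [(m, 1.0 / (spec.M - 1)) for m in range(spec.M) if m != i] for i in randos
        ]
        for rand_combo in itertools.product(*rand_choices):
            rp = base_prob
            placement = dict(fixed)
            for i, (m, q) in zip(randos, rand_combo):
                placement[i] = m
                rp *= q
            for mech_placement, mp in _mechanism_placements(spec, parts, apriori):
                full = dict(placement)
                full.update(mech_placement)
                key = PlacementConfiguration(
                    tuple(full[i] for i in range(N)), spec.M
                ).labelled_partition()
                entries[key] = entries.get(key, 0.0) + rp * mp
    return GroupDistribution(entries, N=N, M=spec.M, exact=True)


def estimate_distribution(
    spec: MovementSpec, samples: int, rng: np.random.Generator
) -> GroupDistribution:
    """Empirical partition frequencies from repeated sampling."""
    if samples < 1:
        raise ParameterError("samples must be at least 1")
    counts: Dict[LabelledPartition, int] = {}
    for _ in range(samples):
        key = sample_configuration(spec, rng).labelled_partition()
        counts[key] = counts.get(key, 0) + 1
    entries = {k: c / samples for k, c in counts.items()}
    return GroupDistribution(
        entries, N=spec.N, M=spec.M, exact=False, n_samples=samples, counts=counts
    )


# ---------------------------------------------------------------------------
# Pair statistics from a partition law.
# ---------------------------------------------------------------------------


def pair_statistics(
    dist: GroupDistribution, N: Optional[int] = None, check_tol: float = 1e-9
) -> PairStatistics:
    """Replacement weights from a partition law.

    ``d_N`` is computed per ordered pair as the expectation of
    ``1/(|G|-1)`` over realizations in which the pair shares a group, then
    averaged; ``w_s`` is the probability of a fixed individual being alone,
    averaged over individuals.  Per-pair/per-individual deviations from the
    average are checked when the law is exact (exchangeability).
    """
    N = N or dist.N
    pair_d = np.zeros((N, N))
    alone = np.zeros(N)
    for key, p in dist.entries.items():
        for _, members in key:
            size = len(members)
            if size == 1:
                (i,) = members
                alone[i] += p
            else:
                for i in members:
                    for j in members:
                        if i != j:
                            pair_d[i, j] += p / (size - 1)
    offdiag = pair_d[~np.eye(N, dtype=bool)]
    d = float(offdiag.mean())
    w_s = float(alone.mean())
    if dist.exact and check_tol is not None:
        if offdiag.size and np.max(np.abs(offdiag - d)) > check_tol:
            raise ParameterError("per-pair meeting weights are not exchangeable")
        if np.max(np.abs(alone - w_s)) > check_tol:
            raise ParameterError("per-individual self weights are not exchangeable")
    if d == 0:
        raise ParameterError(
            "pair weight w is zero (always-alone process); w_star undefined"
        )
    return PairStatistics(d_N=d, w=d, w_s=w_s, w_star=(w_s - d) / d, N=N)


# ---------------------------------------------------------------------------
# Exact focal group-size law for any N (analytic route).
#
# On the complete graph with the uniform mechanism apriori the partition law
# is exchangeable over individuals, so state-level quantities only need the
# law of the focal individual's group size plus hypergeometric sampling of
# the co-members.  The mechanism enters through two occupancy laws:
#   psi_n(y): participants on one fixed place out of n movers,
#   phi_n(s): size of a focal mover's mechanism group out of n movers.
# ---------------------------------------------------------------------------


def _rising(x: float, k: int) -> float:
    out = 1.0
    for t in range(k):
        out *= x + t
    return out


def _psi_phi_independent(n: int, M: int):
    p = 1.0 / M
    psi = np.array([math.comb(n, y) * p**y * (1 - p) ** (n - y) for y in range(n + 1)])
    phi = np.zeros(n + 1)
    for s in range(1, n + 1):
        phi[s] = math.comb(n - 1, s - 1) * p ** (s - 1) * (1 - p) ** (n - s)
    return psi, phi


def _psi_phi_ftm(n: int, M: int):
    psi = np.zeros(n + 1)
    phi = np.zeros(n + 1)
    if n == 0:
        psi[0] = 1.0
        return psi, phi
    psi[0] = 1.0 - 1.0 / M
    psi[n] += 1.0 / M
    phi[n] = 1.0
    return psi, phi


def _psi_phi_urn(n: int, M: int, B: float):
    if B == 0:
        return _psi_phi_ftm(n, M)
    a = B / M
    rest = B - a
    psi = np.zeros(n + 1)
    denom = _rising(B, n)
    for y in range(n + 1):
        psi[y] = math.comb(n, y) * _rising(a, y) * _rising(rest, n - y) / denom
    phi = np.zeros(n + 1)
    if n >= 1:
        denom1 = _rising(B + 1, n - 1)
        for s in range(1, n + 1):
            phi[s] = (
                math.comb(n - 1, s - 1)
                * _rising(a + 1, s - 1)
                * _rising(rest, n - s)
                / denom1
            )
    return psi, phi


def _psi_phi_wheel(n: int, M: int, theta_frac: float):
    psi = np.zeros(n + 1)
    phi = np.zeros(n + 1)
    if n == 0:
        psi[0] = 1.0
        return psi, phi
    # Breakpoints where any spike crosses any arc boundary (equal arcs 1/M).
    breaks = sorted(
        {(m / M - j * theta_frac) % 1.0 for j in range(n) for m in range(M)}
    )
    breaks.append(breaks[0] + 1.0)
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        if hi - lo < 1e-15:
            continue
        phi_mid = (lo + hi) / 2.0
        arcs = [int(((j * theta_frac + phi_mid) % 1.0) * M) % M for j in range(n)]
        measure = hi - lo
        y = sum(1 for a in arcs if a == 0)
        psi[y] += measure
        sizes = np.bincount(arcs, minlength=M)
        for j in range(n):
            phi[sizes[arcs[j]]] += measure / n
    return psi, phi


def _mechanism_psi_phi(spec: MovementSpec, n: int):
    if spec.mechanism == "independent":
        return _psi_phi_independent(n, spec.M)
    if spec.mechanism == "follow_majority":
        return _psi_phi_ftm(n, spec.M)
    if spec.mechanism == "polya_urn":
        return _psi_phi_urn(n, spec.M, spec.B)
    return _psi_phi_wheel(n, spec.M, spec.theta_frac)


def _binom_pmf(n: int, p: float) -> np.ndarray:
    if n < 0:
        raise ValueError("negative count")
    return np.array(
        [math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(n + 1)]
    )


def _shift_add(target: np.ndarray, pmf: np.ndarray, offset: int, weight: float):
    for j, q in enumerate(pmf):
        if q:
            target[offset + j] += weight * q


@lru_cache(maxsize=512)
def group_size_distribution(spec: MovementSpec) -> Tuple[float, ...]:
    """Exact law of the focal individual's group size, ``s = 1..N``.

    Valid for the evolutionary setting (``N = M``, uniform mechanism
    apriori).  Scales to any ``N`` for which the mechanism occupancy laws
    are computable (polynomial work), unlike the full partition enumeration.
    """
    if spec.N != spec.M:
        raise ParameterError("evolutionary setting requires N = M")
    N, M = spec.N, spec.M
    split = spec.split
    alpha, gamma, beta = split.p_direct_home, split.p_mechanism, split.p_random_nonhome
    nonpart = alpha + beta
    # chance that a given non-participant non-owner individual sits on a
    # given non-home place
    pnp = (beta / nonpart) / (M - 1) if nonpart > 0 else 0.0
    psi_cache = {}
    phi_cache = {}

    def psi(n):
        if n not in psi_cache:
            psi_cache[n] = _mechanism_psi_phi(spec, n)[0]
        return psi_cache[n]

    def phi(n):
        if n not in phi_cache:
            phi_cache[n] = _mechanism_psi_phi(spec, n)[1]
        return phi_cache[n]

    pi = np.zeros(N + 1)  # index = group size

    # Case 1: focal sits directly at home (weight alpha).
    if alpha > 0:
        part_counts = _binom_pmf(N - 1, gamma)
        for n, pn in enumerate(part_counts):
            if pn == 0:
                continue
            occ = psi(n)
            z = _binom_pmf(N - 1 - n, pnp)
            for y, py in enumerate(occ):
                if py:
                    _shift_add(pi, z, 1 + y, alpha * pn * py)

    # Case 2: focal moves to a random non-home place (weight beta).
    if beta > 0:
        owner_cases = [(alpha, 0, 1), (beta, 0, 0), (gamma, 1, 0)]
        part_counts = _binom_pmf(N - 2, gamma)
        for ow, omech, ohome in owner_cases:
            if ow == 0:
                continue
            for n3, pn in enumerate(part_counts):
                if pn == 0:
                    continue
                n = n3 + omech
                occ = psi(n)
                z = _binom_pmf(N - 2 - n3, pnp)
                for y, py in enumerate(occ):
                    if py:
                        _shift_add(pi, z, 1 + y + ohome, beta * ow * pn * py)

    # Case 3: focal joins the mechanism (weight gamma).  Its place is
    # uniform over M and independent of its mechanism group size.
    if gamma > 0:
        # 3a: focal lands on its own home (probability 1/M): no owner issue.
        part_counts = _binom_pmf(N - 1, gamma)
        for n_o, pn in enumerate(part_counts):
            if pn == 0:
                continue
            grp = phi(n_o + 1)
            z = _binom_pmf(N - 1 - n_o, pnp)
            for s_p, ps in enumerate(grp):
                if ps:
                    _shift_add(pi, z, s_p, gamma * (1.0 / M) * pn * ps)
        # 3b: focal lands on another individual's home place.
        owner_cases = [(alpha, 0, 1), (beta, 0, 0), (gamma, 1, 0)]
        part_counts = _binom_pmf(N - 2, gamma)
        w_there = gamma * (M - 1) / M
        for ow, omech, ohome in owner_cases:
            if ow == 0:
                continue
            for n3, pn in enumerate(part_counts):
                if pn == 0:
                    continue
                n_o = n3 + omech
                grp = phi(n_o + 1)
                z = _binom_pmf(N - 2 - n3, pnp)
                for s_p, ps in enumerate(grp):
                    if ps:
                        _shift_add(pi, z, s_p + ohome, w_there * ow * pn * ps)

    total = pi.sum()
    if abs(total - 1.0) > 1e-9:
        raise ParameterError(f"focal size law sums to {total!r}")
    return tuple(pi[1:] / total)


def pair_statistics_exact(spec: MovementSpec) -> PairStatistics:
    """Replacement weights from the analytic focal-size law.

    By exchangeability ``w_s`` is the probability of being alone and
    ``d_N = (1 - w_s)/(N - 1)``, so row conservation holds identically.
    """
    pi = group_size_distribution(spec)
    w_s = pi[0]
    d = (1.0 - w_s) / (spec.N - 1)
    if d == 0:
        raise ParameterError(
            "pair weight w is zero (always-alone process); w_star undefined"
        )
    return PairStatistics(d_N=d, w=d, w_s=w_s, w_star=(w_s - d) / d, N=spec.N)


def exact_marginals(spec: MovementSpec, cap: int = DEFAULT_ENUMERATION_CAP) -> np.ndarray:
    """Exact per-individual place marginals from the full enumeration.

    Returns the ``N x M`` matrix of ``P(individual i at place m)``; used to
    check faithfulness against :func:`territorial_apriori`.
    """
    if spec.N != spec.M:
        raise ParameterError("evolutionary setting requires N = M")
    if spec.N > cap:
        raise CapacityError("N exceeds the enumeration cap")
    dist = enumerate_distribution(spec, cap=cap)
    marg = np.zeros((spec.N, spec.M))
    for key, p in dist.entries.items():
        for place, members in key:
            for i in members:
                marg[i, place] += p
    return marg
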