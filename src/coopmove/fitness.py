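"""State-dependent mean fitnesses of mutants and residents.

The evolutionary state is the mutant count ``k``.  An individual's fitness
at state ``k`` is its expected one-round payoff, averaged over the movement
mechanism's group-formation law.  Exchangeability on the complete graph
makes the assignment of the ``k`` mutants to homes irrelevant, and reduces
the average to the focal group-size law combined with hypergeometric
sampling of the co-members' types.

Fast closed forms are provided where they exist: the Public Goods fitness
for *any* mechanism through the pair-meeting weight ``d_N``,

    ``F_C = R - C + (k-1) V d_N``,   ``F_D = R + k V d_N``,

the Hawk-Dove fitness under independent movement through the coefficient
functions ``tau`` (dove) and ``omega``/``nu`` (hawk), and the
infinite-population Hawk-Dove fitnesses at dove frequency ``p``.  The
enumeration-based average is the reference; the closed forms are fast paths
guarded by equivalence tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Tuple

import numpy as np

from .games import GameSpec, GroupComposition, payoff
from .group_stats import enumerate_distribution, group_size_distribution
from .movement import MovementSpec, ParameterError

__all__ = [
    "FitnessPair",
    "mean_fitness_general",
    "pgg_fitness_closed",
    "hd_fitness_closed",
    "hd_tau",
    "hd_omega",
    "hd_nu",
    "infinite_population_fitness",
]

Role = Literal["A", "B"]


@dataclass(frozen=True)
class FitnessPair:
    """Mean fitness of the mutant and resident types at mutant count ``k``."""

    F_mutant: float
    F_resident: float
    k: int


def _hypergeom_pmf(Npop: int, K: int, n: int) -> np.ndarray:
    """P(j successes drawing n without replacement from Npop with K marked)."""
    out = np.zeros(n + 1)
    denom = math.comb(Npop, n)
    for j in range(max(0, n - (Npop - K)), min(K, n) + 1):
        out[j] = math.comb(K, j) * math.comb(Npop - K, n - j) / denom
    return out


def _mean_payoff_from_sizes(
    pi, game: GameSpec, N: int, n_A: int, focal: Role
) -> float:
    """Expected payoff of a focal individual of type ``focal`` when the
    population holds ``n_A`` type-A individuals, given the focal group-size
    law ``pi`` (over sizes 1..N) and uniform co-member sampling."""
    others_A = n_A - 1 if focal == "A" else n_A
    total = 0.0
    for s, ps in enumerate(pi, start=1):
        if ps == 0:
            continue
        hyp = _hypergeom_pmf(N - 1, others_A, s - 1)
        inner = 0.0
        for j, pj in enumerate(hyp):
            if pj == 0:
                continue
            if focal == "A":
                comp = GroupComposition(a=j + 1, b=s - 1 - j)
            else:
                comp = GroupComposition(a=j, b=s - j)
            inner += pj * payoff(game, comp, focal)
        total += ps * inner
    return total


def _mean_payoff_enumerated(
    spec: MovementSpec, game: GameSpec, n_A: int, focal_role: Role
) -> float:
    """Reference route: average the focal payoff over the full exact
    partition law, with type A assigned to individuals ``0..n_A-1``."""
    dist = enumerate_distribution(spec)
    N = spec.N
    focal = 0 if focal_role == "A" else N - 1
    total = 0.0
    for key, p in dist.entries.items():
        for _, members in key:
            if focal in members:
                a = sum(1 for i in members if i < n_A)
                comp = GroupComposition(a=a, b=len(members) - a)
                total += p * payoff(game, comp, focal_role)
                break
    return total


def mean_fitness_general(
    spec: MovementSpec,
    game: GameSpec,
    k: int,
    mutant_role: Role = "A",
    method: str = "auto",
) -> FitnessPair:
    """Mean fitness of mutant and resident at mutant count ``k``.

    ``mutant_role`` names the game role of the mutant type ("A" =
    cooperator / hawk, "B" = defector / dove).  ``method="auto"`` uses the
    exact exchangeability reduction (any ``N``); ``method="enumerate"``
    averages over the full partition law (small ``N``; the oracle).
    """
    N = spec.N
    if not (1 <= k <= N - 1):
        raise ParameterError("mutant count k must satisfy 1 <= k <= N-1")
    resident_role: Role = "B" if mutant_role == "A" else "A"
    n_A = k if mutant_role == "A" else N - k
    if method == "auto":
        pi = group_size_distribution(spec)
        F_m = _mean_payoff_from_sizes(pi, game, N, n_A, mutant_role)
        F_r = _mean_payoff_from_sizes(pi, game, N, n_A, resident_role)
    elif method == "enumerate":
        F_m = _mean_payoff_enumerated(spec, game, n_A, mutant_role)
        F_r = _mean_payoff_enumerated(spec, game, n_A, resident_role)
    else:
        raise ParameterError(f"unknown method {method!r}")
    return FitnessPair(F_mutant=F_m, F_resident=F_r, k=k)


def pgg_fitness_closed(game: GameSpec, k: int, N: int, d_N: float) -> FitnessPair:
    """Public Goods closed form for any mechanism, via ``d_N``.

    The mutant is the cooperator: ``F_C = R - C + (k-1) V d_N`` and
    ``F_D = R + k V d_N``.
    """
    if game.kind != "public_goods":
        raise ParameterError("pgg_fitness_closed needs a public_goods game")
    if not (0.0 <= d_N <= 1.0):
        raise ParameterError("d_N must lie in [0, 1]")
    F_C = game.R - game.C + (k - 1) * game.V * d_N
    F_D = game.R + k * game.V * d_N
    return FitnessPair(F_mutant=F_C, F_resident=F_D, k=k)


def _power_ratio(r: float, a: int, q: float, b: int) -> float:
    """``r**a / q**b`` computed in log space (large exponents occur for the
    infinite-population limit checks)."""
    return math.exp(a * math.log(r) - b * math.log(q))


def hd_tau(h: float, N: int, k: int) -> float:
    """Dove reward coefficient under independent movement (``k`` doves)."""
    if k < 1:
        raise ParameterError("tau needs at least one dove (k >= 1)")
    q = h + N - 1
    r = h + N - 2
    return (
        _power_ratio(r, N - k, q, N - k)
        - _power_ratio(r, N - 1, q, N) * ((k * (N - 1) + (N - k) * (N - 1)) / k)
        + (N - k) * (N - 1) / k * _power_ratio(r, N - k - 1, q, N - k)
    )


def hd_omega(h: float, N: int, k: int) -> float:
    """Hawk reward coefficient under independent movement (``N - k`` hawks)."""
    if k > N - 1:
        raise ParameterError("omega needs at least one hawk (k <= N-1)")
    q = h + N - 1
    r = h + N - 2
    return (
        1.0
        + k / (N - k)
        - (N - 1) * _power_ratio(r, N - k - 1, q, N - k)
        - k / (N - k) * _power_ratio(r, N - k, q, N - k)
    )


def hd_nu(h: float, N: int, k: int) -> float:
    """Hawk cost coefficient under independent movement (``N - k`` hawks)."""
    if k > N - 1:
        raise ParameterError("nu needs at least one hawk (k <= N-1)")
    q = h + N - 1
    r = h + N - 2
    return (
        (k - N + 1) / q
        - k / (N - k)
        + (h * (N - k - 1) + (N - k - 1) * (N - 1)) / q**2
        + k / (N - k) * _power_ratio(r, N - k, q, N - k)
        + (N - 1) * _power_ratio(r, N - k - 1, q, N - k)
    )


def hd_fitness_closed(game: GameSpec, h: float, N: int, k: int) -> FitnessPair:
    """Hawk-Dove closed-form fitness under *independent* movement.

    The mutant is the dove: dove fitness ``R + tau V``, hawk fitness
    ``R + omega V - nu C``, with ``k`` doves and ``N - k`` hawks.
    """
    if game.kind != "hawk_dove":
        raise ParameterError("hd_fitness_closed needs a hawk_dove game")
    if not (1 <= k <= N - 1):
        raise ParameterError("need both types present: 1 <= k <= N-1")
    F_dove = game.R + hd_tau(h, N, k) * game.V
    F_hawk = game.R + hd_omega(h, N, k) * game.V - hd_nu(h, N, k) * game.C
    return FitnessPair(F_mutant=F_dove, F_resident=F_hawk, k=k)


def infinite_population_fitness(game: GameSpec, p: float) -> Tuple[float, float]:
    """Hawk-Dove fitnesses in the infinite well-mixed limit.

    At dove proportion ``p`` (with ``h = 1`` dynamics of group formation
    absorbed into the limit): dove ``R + ((e^p - 1)/(e p)) V``, hawk
    ``R + ((1 - e^{p-1})/(1-p)) V - ((e^{p-1} - p)/(1-p)) C``.
    Returns ``(dove_fitness, hawk_fitness)``.
    """
    if game.kind != "hawk_dove":
        raise ParameterError("infinite_population_fitness needs a hawk_dove game")
    if not (0.0 < p < 1.0):
        raise ParameterError("dove proportion p must lie strictly in (0, 1)")
    e = math.e
    dove = game.R + ((math.exp(p) - 1.0) / (e * p)) * game.V
    hawk = (
        game.R
        + ((1.0 - math.exp(p - 1.0)) / (1.0 - p)) * game.V
        - ((math.exp(p - 1.0) - p) / (1.0 - p)) * game.C
    )
    return dove, hawk
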