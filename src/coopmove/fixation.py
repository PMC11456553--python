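"""Fixation probabilities on the complete territorial-raider graph.

The mutant count performs a birth-death chain on ``{0..N}``.  Its fixation
probability from a single mutant is

    ``rho = 1 / (1 + sum_{j=1}^{N-1} prod_{k=1}^{j} delta_k / beta_k)``,

where ``delta_k / beta_k`` is the ratio of down- to up-transition rates at
state ``k``.  Under BDB dynamics (selection on birth) the ratio is simply
``F_R(k) / F_M(k)``; under BDD (uniform birth, death proportional to
inverse fitness through the replacement weights) it also involves
``w* = (w_s - w)/w``.

A full Markov solver built directly from the event probabilities (birth
choice, replacement weights) serves as the independent oracle for the
ratio-product closed forms.  Weak-selection approximations, the dove
neutrality condition and the infinite-population Hawk-Dove equilibrium
ratio complete the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .fitness import FitnessPair, hd_fitness_closed, mean_fitness_general
from .games import GameSpec
from .group_stats import pair_statistics_exact
from .movement import MovementSpec, ParameterError

__all__ = [
    "TransitionRatios",
    "FixationResult",
    "fixation_from_ratios",
    "bdb_ratios",
    "bdd_ratios",
    "state_fitnesses",
    "fixation_closed",
    "markov_fixation_oracle",
    "weak_selection_pgg",
    "dove_neutral_ratio",
    "DoveNeutrality",
    "equilibrium_ratio",
]

Dynamics = Literal["BDB", "BDD"]


class FitnessValidityError(ValueError):
    """A state-dependent mean fitness is non-positive."""


@dataclass(frozen=True)
class TransitionRatios:
    """Down/up transition-rate ratios ``delta_k / beta_k`` for ``k = 1..N-1``."""

    ratios: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ratios:
            raise ParameterError("need at least one ratio (N >= 2)")
        for r in self.ratios:
            if not (r > 0 and math.isfinite(r)):
                raise ParameterError(f"transition ratio {r!r} must be positive finite")

    @property
    def N(self) -> int:
        return len(self.ratios) + 1


@dataclass(frozen=True)
class FixationResult:
    """A fixation probability with provenance."""

    probability: float
    method: Literal["closed_form", "markov_solve", "weak_selection", "simulation"]
    metadata: Dict = field(default_factory=dict)
    ci: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ParameterError("fixation probability must lie in [0, 1]")


def fixation_from_ratios(ratios: TransitionRatios) -> float:
    """Evaluate the ratio-product formula in log space.

    ``rho = 1/(1 + sum_j prod_{k<=j} r_k)`` with the partial products
    accumulated as log sums to avoid under/overflow at large ``N`` or strong
    selection.
    """
    logs = np.log(np.asarray(ratios.ratios, dtype=float))
    cum = np.cumsum(logs)
    total = logsumexp(np.concatenate(([0.0], cum)))
    return float(math.exp(-total))


def _check_positive(fitnesses: Sequence[FitnessPair]) -> None:
    for fp in fitnesses:
        if not (fp.F_mutant > 0 and fp.F_resident > 0):
            raise FitnessValidityError(
                f"non-positive mean fitness at state k={fp.k}: "
                f"F_M={fp.F_mutant!r}, F_R={fp.F_resident!r}"
            )


def bdb_ratios(fitness_by_state: Sequence[FitnessPair]) -> TransitionRatios:
    """BDB: selection on birth gives ``delta_k/beta_k = F_R(k)/F_M(k)``."""
    _check_positive(fitness_by_state)
    return TransitionRatios(
        tuple(fp.F_resident / fp.F_mutant for fp in fitness_by_state)
    )


def bdd_ratios(
    fitness_by_state: Sequence[FitnessPair], w_star: float
) -> TransitionRatios:
    """BDD: uniform birth, death by inverse fitness through the weights.

    At state ``k`` (with ``N`` inferred from the number of states)::

        delta_k/beta_k = (N-k + (k+w*) F_R/F_M) / (k + (N-k+w*) F_M/F_R)
    """
    _check_positive(fitness_by_state)
    if not math.isfinite(w_star):
        raise ParameterError("w_star must be finite")
    N = len(fitness_by_state) + 1
    out = []
    for fp in fitness_by_state:
        k = fp.k
        rho_rm = fp.F_resident / fp.F_mutant
        out.append(
            (N - k + (k + w_star) * rho_rm) / (k + (N - k + w_star) / rho_rm)
        )
    return TransitionRatios(tuple(out))


def state_fitnesses(
    spec: MovementSpec,
    game: GameSpec,
    mutant_role: Literal["A", "B"],
    method: str = "auto",
) -> Tuple[FitnessPair, ...]:
    """Mean fitness pairs for every transient state ``k = 1..N-1``."""
    return tuple(
        mean_fitness_general(spec, game, k, mutant_role, method=method)
        for k in range(1, spec.N)
    )


def _default_mutant_role(game: GameSpec) -> Literal["A", "B"]:
    # cooperator invades defectors; dove invades hawks
    return "A" if game.kind == "public_goods" else "B"


def fixation_closed(
    spec: MovementSpec,
    game: GameSpec,
    dynamics: Dynamics,
    mutant_role: Optional[Literal["A", "B"]] = None,
) -> FixationResult:
    """Closed-form fixation of a single mutant via the ratio product.

    Fitnesses come from the exact mechanism-averaged group law; for BDD the
    self-weight ratio ``w*`` comes from the same law.
    """
    role = mutant_role or _default_mutant_role(game)
    fits = state_fitnesses(spec, game, role)
    if dynamics == "BDB":
        ratios = bdb_ratios(fits)
    elif dynamics == "BDD":
        ratios = bdd_ratios(fits, pair_statistics_exact(spec).w_star)
    else:
        raise ParameterError(f"unknown dynamics {dynamics!r}")
    return FixationResult(
        probability=fixation_from_ratios(ratios),
        method="closed_form",
        metadata={
            "N": spec.N,
            "mechanism": spec.mechanism,
            "h": spec.h,
            "game": game.kind,
            "dynamics": dynamics,
            "mutant_role": role,
        },
    )


def markov_fixation_oracle(
    spec: MovementSpec,
    game: GameSpec,
    dynamics: Dynamics,
    mutant_role: Optional[Literal["A", "B"]] = None,
    start: int = 1,
) -> float:
    """Fixation probability by solving the full birth-death chain.

    Transition probabilities are assembled from first principles: the birth
    event (fitness-proportional under BDB, uniform under BDD) composed with
    the replacement event through the averaged weights ``w`` (off-diagonal)
    and ``w_s`` (self).  The resulting linear system over the transient
    states is solved directly.  This is the independent oracle for the
    ratio-product closed forms.
    """
    role = mutant_role or _default_mutant_role(game)
    N = spec.N
    stats = pair_statistics_exact(spec)
    w, w_s = stats.w, stats.w_s
    fits = state_fitnesses(spec, game, role)
    _check_positive(fits)
    beta = np.zeros(N + 1)
    delta = np.zeros(N + 1)
    for fp in fits:
        k = fp.k
        FM, FR = fp.F_mutant, fp.F_resident
        if dynamics == "BDB":
            tot = k * FM + (N - k) * FR
            beta[k] = (k * FM / tot) * (N - k) * w
            delta[k] = ((N - k) * FR / tot) * k * w
        elif dynamics == "BDD":
            D_M = w_s / FM + (k - 1) * w / FM + (N - k) * w / FR
            D_R = w_s / FR + (N - k - 1) * w / FR + k * w / FM
            beta[k] = k * (1.0 / N) * (N - k) * (w / FR) / D_M
            delta[k] = (N - k) * (1.0 / N) * k * (w / FM) / D_R
        else:
            raise ParameterError(f"unknown dynamics {dynamics!r}")
    # Solve p_k = beta_k p_{k+1} + delta_k p_{k-1} + (1-beta_k-delta_k) p_k
    A = np.zeros((N - 1, N - 1))
    rhs = np.zeros(N - 1)
    for k in range(1, N):
        i = k - 1
        A[i, i] = beta[k] + delta[k]
        if A[i, i] == 0:
            raise ParameterError(
                "chain cannot leave state "
                f"{k}: absorption unreachable (always-alone process?)"
            )
        if k + 1 <= N - 1:
            A[i, i + 1] = -beta[k]
        else:
            rhs[i] += beta[k]  # p_N = 1
        if k - 1 >= 1:
            A[i, i - 1] = -delta[k]
    p = np.linalg.solve(A, rhs)
    if not (1 <= start <= N - 1):
        raise ParameterError("start count must lie in 1..N-1")
    return float(p[start - 1])


def weak_selection_pgg(
    game: GameSpec, N: int, d_N: float, w_star: float = 0.0,
    dynamics: Dynamics = "BDB",
) -> float:
    """First-order (large ``R``) cooperator fixation approximation.

    BDB: ``(1/N) (1 - (N-1)(V d_N + C)/(2R))``; BDD additionally carries
    the factor ``(N + 2w*)/(N + w*)`` on the selection term.  The two agree
    exactly when ``w* = 0``.
    """
    if game.kind != "public_goods":
        raise ParameterError("weak_selection_pgg needs a public_goods game")
    sel = (N - 1) * (game.V * d_N + game.C) / (2 * game.R)
    if dynamics == "BDB":
        return (1.0 / N) * (1.0 - sel)
    if dynamics == "BDD":
        return (1.0 / N) * (1.0 - sel * (N + 2 * w_star) / (N + w_star))
    raise ParameterError(f"unknown dynamics {dynamics!r}")


def _dove_fixation_given_cost(
    h: float, N: int, R: float, V: float, cost: float, dynamics: Dynamics,
    w_star: float,
) -> float:
    game = GameSpec(kind="hawk_dove", R=R, V=V, C=cost)
    fits = tuple(
        hd_fitness_closed(game, h, N, k) for k in range(1, N)
    )
    if dynamics == "BDB":
        ratios = bdb_ratios(fits)
    else:
        ratios = bdd_ratios(fits, w_star)
    return fixation_from_ratios(ratios)


@dataclass(frozen=True)
class DoveNeutrality:
    """Cost-to-reward ratio at which a lone dove's fixation equals ``1/N``.

    ``numeric_ratio`` is the root of the closed-form dove fixation (the
    authoritative value); ``series_ratio`` evaluates the printed
    weak-selection series under the documented reading (``gamma`` the
    Euler-Mascheroni constant, ``H[n, a] = sum_{k=1}^{n} a^k / k``).
    """

    numeric_ratio: float
    series_ratio: float
    h: float
    N: int
    R: float
    dynamics: Dynamics

    @property
    def discrepancy(self) -> float:
        return self.numeric_ratio - self.series_ratio


def _dove_neutral_series(h: float, N: int) -> float:
    """The printed weak-selection neutrality condition, as C/V."""
    a = (h + N - 1) / (h + N - 2)
    H = sum(a**k / k for k in range(1, N))
    f_h = H - math.log(N - 1)
    euler_gamma = 0.5772156649015329
    e = math.e
    # V = (1/2 - 1/e) / ((1/e)(gamma - 1 - f(h)) + 1) * C  =>  C/V below
    return ((1.0 / e) * (euler_gamma - 1.0 - f_h) + 1.0) / (0.5 - 1.0 / e)


def dove_neutral_ratio(
    h: float,
    N: int,
    R: float = 1e4,
    V: float = 1.0,
    dynamics: Dynamics = "BDB",
    bracket: Tuple[float, float] = (0.5, 4.0),
    tol: float = 1e-12,
) -> DoveNeutrality:
    """Solve ``rho_dove(C/V) = 1/N`` for the cost-to-reward ratio.

    Uses the closed-form dove fixation under independent movement at large
    background payoff ``R`` (weak selection) and bisects ``C/V`` on a
    bracket expanded geometrically from ``bracket`` until the residual
    changes sign.  The printed series value is reported alongside.
    """
    if N < 2:
        raise ParameterError("need N >= 2")
    w_star = 0.0
    if dynamics == "BDD":
        w_star = pair_statistics_exact(
            MovementSpec(mechanism="independent", h=h, N=N)
        ).w_star

    def resid(cost: float) -> float:
        return _dove_fixation_given_cost(h, N, R, V, cost, dynamics, w_star) - 1.0 / N

    lo, hi = bracket
    for _ in range(60):
        if resid(lo) * resid(hi) <= 0:
            break
        lo /= 2.0
        hi *= 2.0
    else:
        raise ParameterError("no sign change found for the neutrality root")
    root = brentq(resid, lo, hi, xtol=tol)
    return DoveNeutrality(
        numeric_ratio=float(root),
        series_ratio=_dove_neutral_series(h, N),
        h=h,
        N=N,
        R=R,
        dynamics=dynamics,
    )


def equilibrium_ratio(p: float) -> float:
    """Infinite-population Hawk-Dove equilibrium reward-to-cost ratio.

    The ``V/C`` at which dove and hawk fitnesses coincide at dove
    proportion ``p``::

        V/C = e p (e^{p-1} - p) / ((1 - e^{p-1}) e p - (e^p - 1)(1 - p))
    """
    if not (0.0 < p < 1.0):
        raise ParameterError("p must lie strictly in (0, 1)")
    e = math.e
    num = e * p * (math.exp(p - 1.0) - p)
    den = (1.0 - math.exp(p - 1.0)) * e * p - (math.exp(p) - 1.0) * (1.0 - p)
    if abs(den) < 1e-14:
        raise ParameterError("equilibrium ratio is singular at this p")
    return num / den
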