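"""Agent-based evolutionary simulation of mutant invasion.

The stochastic process the analytics idealize: per generation, one movement
realization assigns every individual its *realized* one-round payoff as
fitness, everyone returns home, a second movement realization (without
games) forms the groups for the replacement event, and exactly one
birth-death replacement occurs.  Under BDB the reproducer is chosen with
probability proportional to fitness over the whole population and the
victim uniformly among the reproducer's current co-group members; under
BDD the reproducer is uniform and the victim is chosen among co-group
members with probability proportional to inverse fitness.  A reproducer
that is alone replaces itself.  The run ends at fixation or extinction.

An optional *idealized* mode substitutes the state-dependent mean
fitnesses for the realized payoffs, which makes the mutant count an exact
realization of the analytic birth-death chain under BDB and enables direct
statistical comparison with the closed forms.  (Under BDD the idealized
simulation still averages the inverse-fitness weighting per realized
group, so small systematic differences from the averaged-weight chain
remain; they vanish under weak selection.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Tuple

import numpy as np

from . import _kernels
from .fitness import mean_fitness_general
from .games import GameSpec
from .movement import MovementSpec, ParameterError

__all__ = ["SimulationConfig", "SimulationResult", "run_single", "estimate_fixation"]

_MECH_CODE = {
    "independent": _kernels.MECH_INDEPENDENT,
    "follow_majority": _kernels.MECH_FTM,
    "polya_urn": _kernels.MECH_URN,
    "wheel": _kernels.MECH_WHEEL,
}
_GAME_CODE = {"public_goods": _kernels.GAME_PGG, "hawk_dove": _kernels.GAME_HD}
_DYN_CODE = {"BDB": _kernels.DYN_BDB, "BDD": _kernels.DYN_BDD}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce a batch of invasion trials."""

    movement: MovementSpec
    game: GameSpec
    dynamics: Literal["BDB", "BDD"]
    mutant_role: Optional[Literal["A", "B"]] = None
    replicates: int = 10_000
    seed: int = 0
    max_steps: int = 10_000_000
    idealized: bool = False
    exclude_parent: bool = True

    def __post_init__(self) -> None:
        if self.movement.N != self.movement.M:
            raise ParameterError("simulation requires the N = M evolutionary setting")
        if self.replicates < 1 or self.max_steps < 1:
            raise ParameterError("replicates and max_steps must be positive")
        if self.dynamics not in _DYN_CODE:
            raise ParameterError(f"unknown dynamics {self.dynamics!r}")
        if self.mutant_role is None:
            role = "A" if self.game.kind == "public_goods" else "B"
            object.__setattr__(self, "mutant_role", role)
        _validate_payoffs(self.game, self.movement.N)


def _validate_payoffs(game: GameSpec, N: int) -> None:
    """All realizable one-round payoffs must be strictly positive."""
    if game.kind == "public_goods":
        worst = min(game.R - game.C, game.R)
    else:
        worst = min(
            [game.R]
            + [game.R + (game.V - (a - 1) * game.C) / a for a in range(1, N + 1)]
        )
    if not worst > 0:
        raise ParameterError(
            f"realizable payoff {worst!r} is not positive; "
            "both dynamics need positive fitness"
        )


@dataclass(frozen=True)
class SimulationResult:
    """Fixation frequency with a Wilson 95% interval and run bookkeeping."""

    fixation_estimate: float
    ci_low: float
    ci_high: float
    replicates: int
    absorbed: int
    non_absorbed: int
    mean_steps: float
    seed: int
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def ci(self) -> Tuple[float, float]:
        return (self.ci_low, self.ci_high)


def wilson_interval(successes: int, trials: int, z: float = 1.959963984540054):
    """Wilson score 95% interval for a binomial proportion."""
    if trials == 0:
        return (0.0, 1.0)
    p = successes / trials
    denom = 1.0 + z * z / trials
    center = (p + z * z / (2 * trials)) / denom
    half = (
        z * math.sqrt(p * (1 - p) / trials + z * z / (4 * trials * trials)) / denom
    )
    return (max(0.0, center - half), min(1.0, center + half))


def _substream_seeds(master: int, n: int) -> np.ndarray:
    # 31-bit per-replicate seeds by counter: replicate i always gets the
    # same stream regardless of batch size ordering.
    ss = np.random.SeedSequence(master)
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


def _kernel_args(config: SimulationConfig):
    mv = config.movement
    split = mv.split
    mech = _MECH_CODE[mv.mechanism]
    B = float(mv.B) if mv.B is not None else 0.0
    theta_frac = float(mv.theta_frac) if mv.theta_frac is not None else 0.0
    mutant_is_A = config.mutant_role == "A"
    return (
        mv.N,
        mv.M,
        mech,
        split.p_direct_home,
        split.p_random_nonhome,
        B,
        theta_frac,
        _GAME_CODE[config.game.kind],
        mutant_is_A,
        config.game.R,
        config.game.V,
        config.game.C,
        _DYN_CODE[config.dynamics],
        config.exclude_parent,
        config.max_steps,
    )


def run_single(config: SimulationConfig, replicate: int = 0):
    """One invasion trial; returns ``(mutant_fixed, steps)``.

    ``replicate`` selects the per-replicate substream of the master seed,
    so ``run_single(cfg, i)`` reproduces trial ``i`` of
    :func:`estimate_fixation` exactly.
    """
    seeds = _substream_seeds(config.seed, replicate + 1)[replicate : replicate + 1]
    args = _kernel_args(config)
    (
        N, M, mech, p_home, p_rand, B, theta_frac,
        game, mutant_is_A, R, V, C, dyn, excl, max_steps,
    ) = args
    FM, FR = _idealized_tables(config)
    out, steps = _kernels.run_batch(
        1, N, M, mech, p_home, p_rand, B, theta_frac, game, mutant_is_A,
        R, V, C, dyn, excl, max_steps, seeds, config.idealized, FM, FR,
    )
    if out[0] < 0:
        raise RuntimeError(
            f"run not absorbed within max_steps={config.max_steps} "
            f"(mutant count still mixed)"
        )
    return bool(out[0]), int(steps[0])


def _idealized_tables(config: SimulationConfig):
    mv = config.movement
    N = mv.N
    FM = np.zeros(N + 1)
    FR = np.zeros(N + 1)
    if config.idealized:
        for k in range(1, N):
            fp = mean_fitness_general(mv, config.game, k, config.mutant_role)
            if not (fp.F_mutant > 0 and fp.F_resident > 0):
                raise ParameterError(f"non-positive mean fitness at k={k}")
            FM[k] = fp.F_mutant
            FR[k] = fp.F_resident
    return FM, FR


def estimate_fixation(config: SimulationConfig) -> SimulationResult:
    """Batch fixation-frequency estimate over independent replicates.

    Replicates use per-replicate substreams of the master seed.  Runs that
    fail to absorb within ``max_steps`` are excluded from the estimate and
    counted in ``non_absorbed``.
    """
    seeds = _substream_seeds(config.seed, config.replicates)
    (
        N, M, mech, p_home, p_rand, B, theta_frac,
        game, mutant_is_A, R, V, C, dyn, excl, max_steps,
    ) = _kernel_args(config)
    FM, FR = _idealized_tables(config)
    out, steps = _kernels.run_batch(
        config.replicates, N, M, mech, p_home, p_rand, B, theta_frac, game,
        mutant_is_A, R, V, C, dyn, excl, max_steps, seeds, config.idealized,
        FM, FR,
    )
    absorbed = int((out >= 0).sum())
    fixed = int((out == 1).sum())
    est = fixed / absorbed if absorbed else float("nan")
    lo, hi = wilson_interval(fixed, absorbed)
    return SimulationResult(
        fixation_estimate=est,
        ci_low=lo,
        ci_high=hi,
        replicates=config.replicates,
        absorbed=absorbed,
        non_absorbed=config.replicates - absorbed,
        mean_steps=float(steps[out >= 0].mean()) if absorbed else float("nan"),
        seed=config.seed,
        config=config,
    )
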