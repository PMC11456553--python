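"""Movement mechanisms on the complete territorial-raider graph.

A population of ``N`` individuals lives on ``M`` places (in the evolutionary
setting ``N = M`` and individual ``i`` owns place ``i``).  Each round every
individual ends up on exactly one place; co-located individuals form groups.
The *target* marginal distribution of any single individual is set by the
home-fidelity parameter ``h``: an individual is at its home place with
probability ``h/(h+M-1)`` and at each other place with probability
``1/(h+M-1)``.

Coordinated (row-dependent) mechanisms place the individuals jointly while
preserving that per-individual marginal ("faithfulness").  Four mechanisms
are provided:

``independent``
    every mover picks a place independently.
``follow_majority``
    movers are placed sequentially in a uniformly random order; the first
    samples the apriori distribution, later movers join the most occupied
    place (maximal herding).
``polya_urn``
    sequential placement with probability proportional to ``B*a_m + Y_m``
    where ``Y_m`` is the current occupancy; ``B`` interpolates between
    follow-the-majority (``B = 0``) and independence (``B -> inf``).
``wheel``
    simultaneous placement: spikes separated by an angle ``theta`` are spun
    over arcs whose lengths are the apriori weights; ``theta`` tunes herding
    (``theta = 0``) through dispersal (``theta = 2*pi/N``).

Embedding into the territorial raider model for general ``h`` uses a
three-way participation split: some individuals sit directly at home
(``h > 1``) or move to a uniformly random non-home place (``h < 1``), the
rest "play the process" with a *uniform* mechanism-internal apriori, which
reproduces the territorial target exactly.  Individuals that do not play the
process are invisible to the mechanism.

All indices (individuals and places) are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Literal, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "AprioriDistribution",
    "MovementSpec",
    "ParticipationSplit",
    "PlacementConfiguration",
    "MECHANISMS",
    "territorial_apriori",
    "uniform_apriori",
    "participation_split",
    "sample_follow_majority",
    "sample_polya_urn",
    "sample_wheel",
    "sample_configuration",
]

MECHANISMS = ("independent", "follow_majority", "polya_urn", "wheel")

_SUM_TOL = 1e-12


class ParameterError(ValueError):
    """Invalid model parameter."""


@dataclass(frozen=True)
class AprioriDistribution:
    """Target probability of a mover ending up at each place."""

    weights: Tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ParameterError("apriori must be a non-empty vector")
        if np.any(w < 0):
            raise ParameterError("apriori weights must be non-negative")
        if abs(w.sum() - 1.0) > _SUM_TOL:
            raise ParameterError(f"apriori weights sum to {w.sum()!r}, not 1")
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    @property
    def M(self) -> int:
        return len(self.weights)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def uniform_apriori(M: int) -> AprioriDistribution:
    """Uniform apriori over ``M`` places (the mechanism-internal target)."""
    if M < 1:
        raise ParameterError("M must be at least 1")
    return AprioriDistribution(tuple([1.0 / M] * M))


def territorial_apriori(h: float, M: int, home: int = 0) -> AprioriDistribution:
    """Per-individual marginal of the territorial raider on a complete graph.

    The individual's home place (index ``home``) carries weight
    ``h/(h+M-1)``; each of the ``M-1`` other places carries ``1/(h+M-1)``.
    """
    if not (h > 0):
        raise ParameterError("home fidelity h must be positive")
    if M < 2:
        raise ParameterError("a complete territorial raider graph needs M >= 2")
    if not (0 <= home < M):
        raise ParameterError("home index out of range")
    denom = h + M - 1
    w = [1.0 / denom] * M
    w[home] = h / denom
    return AprioriDistribution(tuple(w))


@dataclass(frozen=True)
class ParticipationSplit:
    """Three-way action split embedding a mechanism at home fidelity ``h``.

    Each individual independently sits directly at home
    (``p_direct_home``), joins the movement mechanism (``p_mechanism``), or
    moves to a uniformly random non-home place (``p_random_nonhome``).
    """

    p_direct_home: float
    p_mechanism: float
    p_random_nonhome: float

    def __post_init__(self) -> None:
        probs = (self.p_direct_home, self.p_mechanism, self.p_random_nonhome)
        if any(p < 0 for p in probs):
            raise ParameterError("split probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > _SUM_TOL:
            raise ParameterError("split probabilities must sum to 1")


def participation_split(h: float, M: int) -> ParticipationSplit:
    """Participation probabilities reproducing the territorial marginal.

    For ``h > 1`` an individual stays home with probability
    ``(h-1)/(h+M-1)`` and otherwise plays the mechanism; for ``h = 1``
    everyone plays; for ``h < 1`` an individual plays with probability
    ``M*h/(h+M-1)`` and otherwise moves to a random non-home place.
    Composed with the uniform mechanism apriori this yields the marginal
    ``territorial_apriori(h, M)`` exactly.
    """
    if not (h > 0):
        raise ParameterError("home fidelity h must be positive")
    if M < 2:
        raise ParameterError("a complete territorial raider graph needs M >= 2")
    denom = h + M - 1
    if h > 1:
        return ParticipationSplit((h - 1) / denom, M / denom, 0.0)
    if h == 1:
        return ParticipationSplit(0.0, 1.0, 0.0)
    return ParticipationSplit(0.0, M * h / denom, (M - 1) * (1 - h) / denom)


@dataclass(frozen=True)
class MovementSpec:
    """Mechanism identity plus all parameters fixing the placement law.

    Parameters
    ----------
    mechanism
        One of ``independent``, ``follow_majority``, ``polya_urn``,
        ``wheel``.
    h
        Home fidelity, positive.
    N
        Number of individuals.  In the evolutionary setting ``N = M`` and
        individual ``i`` is home at place ``i``.
    M
        Number of places; defaults to ``N``.
    B
        Urn scale (``polya_urn`` only), non-negative.  ``B = 0`` is defined
        as the follow-the-majority limit.
    theta
        Spike separation in radians (``wheel`` only), in ``[0, 2*pi)``.
    theta_precision
        Decimal places to which ``theta`` is rounded before use (``None``
        disables quantization).  The default of 3 keeps near-dispersal
        angles slightly incommensurate with the arcs so that occasional
        meetings occur.
    ftm_tie_break
        Tie rule among equally occupied places for follow-the-majority:
        ``"apriori"`` (probability proportional to the apriori weights of
        the tied places) or ``"uniform"``.
    """

    mechanism: str
    h: float
    N: int
    M: Optional[int] = None
    B: Optional[float] = None
    theta: Optional[float] = None
    theta_precision: Optional[int] = 3
    ftm_tie_break: Literal["apriori", "uniform"] = "apriori"

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ParameterError(f"unknown mechanism {self.mechanism!r}")
        if not (self.h > 0):
            raise ParameterError("home fidelity h must be positive")
        if self.N < 1:
            raise ParameterError("N must be positive")
        if self.M is None:
            object.__setattr__(self, "M", self.N)
        if self.M < 2:
            raise ParameterError("M must be at least 2")
        if self.mechanism == "polya_urn":
            if self.B is None or self.B < 0:
                raise ParameterError("polya_urn needs urn scale B >= 0")
        elif self.B is not None:
            raise ParameterError("B is only meaningful for polya_urn")
        if self.mechanism == "wheel":
            if self.theta is None or not (0 <= self.theta < 2 * math.pi):
                raise ParameterError("wheel needs theta in [0, 2*pi)")
        elif self.theta is not None:
            raise ParameterError("theta is only meaningful for wheel")
        if self.ftm_tie_break not in ("apriori", "uniform"):
            raise ParameterError("ftm_tie_break must be 'apriori' or 'uniform'")

    @property
    def split(self) -> ParticipationSplit:
        return participation_split(self.h, self.M)

    @property
    def theta_effective(self) -> Optional[float]:
        """Theta after quantization (radians), or None for non-wheel specs."""
        if self.theta is None:
            return None
        if self.theta_precision is None:
            return self.theta
        return round(self.theta, self.theta_precision)

    @property
    def theta_frac(self) -> Optional[float]:
        """Spike separation as a fraction of the circumference."""
        t = self.theta_effective
        return None if t is None else t / (2 * math.pi)

    def with_(self, **kwargs) -> "MovementSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PlacementConfiguration:
    """One realized assignment of all ``N`` individuals to places."""

    place_of: Tuple[int, ...]
    M: int

    def __post_init__(self) -> None:
        if any(not (0 <= p < self.M) for p in self.place_of):
            raise ParameterError("place index out of range")

    @property
    def N(self) -> int:
        return len(self.place_of)

    def groups(self) -> Dict[int, frozenset]:
        """Map occupied place -> frozenset of co-located individuals."""
        out: Dict[int, set] = {}
        for i, p in enumerate(self.place_of):
            out.setdefault(p, set()).add(i)
        return {p: frozenset(s) for p, s in out.items()}

    def partition(self) -> frozenset:
        """The induced set partition of individuals (place labels dropped)."""
        return frozenset(self.groups().values())

    def labelled_partition(self) -> frozenset:
        """Frozenset of ``(place, members)`` pairs for occupied places."""
        return frozenset((p, g) for p, g in self.groups().items())


# ---------------------------------------------------------------------------
# Raw mechanism samplers (operate on an arbitrary subset of movers and an
# arbitrary apriori; used by the embedding with the uniform apriori).
# ---------------------------------------------------------------------------


def _check_participants(participants: Sequence[int]) -> list:
    parts = list(participants)
    if len(set(parts)) != len(parts):
        raise ParameterError("participants must be distinct")
    return parts


def sample_follow_majority(
    participants: Sequence[int],
    apriori: AprioriDistribution,
    rng: np.random.Generator,
    tie_break: str = "apriori",
) -> Dict[int, int]:
    """Place ``participants`` by the follow-the-majority rule.

    Movers are taken in a uniformly random order; the first samples the
    apriori, each later mover joins the place with maximal current
    participant occupancy.  Ties are broken proportionally to the apriori
    weights of the tied places (or uniformly with ``tie_break="uniform"``).
    """
    parts = _check_participants(participants)
    w = apriori.as_array()
    placement: Dict[int, int] = {}
    if not parts:
        return placement
    order = rng.permutation(len(parts))
    occupancy = np.zeros(apriori.M, dtype=np.int64)
    for idx in order:
        top = occupancy.max()
        tied = np.flatnonzero(occupancy == top)
        if len(tied) == 1:
            m = int(tied[0])
        else:
            if tie_break == "apriori":
                tw = w[tied]
                tot = tw.sum()
                if tot <= 0:  # apriori vanishes on all tied places
                    m = int(rng.choice(tied))
                else:
                    m = int(rng.choice(tied, p=tw / tot))
            else:
                m = int(rng.choice(tied))
        placement[parts[idx]] = m
        occupancy[m] += 1
    return placement


def sample_polya_urn(
    participants: Sequence[int],
    apriori: AprioriDistribution,
    B: float,
    rng: np.random.Generator,
) -> Dict[int, int]:
    """Place ``participants`` by the Polya-urn rule.

    Movers are taken in a uniformly random order; a mover picks place ``m``
    with probability proportional to ``B*a_m + Y_m`` where ``Y_m`` counts
    previously placed participants.  ``B = 0`` is the follow-the-majority
    limit (the urn starts empty, so the first draw uses the apriori and all
    later movers join it deterministically).
    """
    if B < 0:
        raise ParameterError("urn scale B must be non-negative")
    if B == 0:
        return sample_follow_majority(participants, apriori, rng)
    parts = _check_participants(participants)
    placement: Dict[int, int] = {}
    if not parts:
        return placement
    order = rng.permutation(len(parts))
    weights = B * apriori.as_array()
    for idx in order:
        p = weights / weights.sum()
        m = int(rng.choice(apriori.M, p=p))
        placement[parts[idx]] = m
        weights[m] += 1.0
    return placement


def sample_wheel(
    participants: Sequence[int],
    apriori: AprioriDistribution,
    theta: float,
    rng: np.random.Generator,
) -> Dict[int, int]:
    """Place ``participants`` by spinning the wheel-and-base.

    The circle of circumference 1 carries consecutive half-open arcs of
    lengths ``a_1..a_M`` starting at position 0.  Spikes sit at fractional
    positions ``(j*theta/(2*pi) + phi) mod 1`` with a single uniform
    rotation ``phi``; spikes are assigned to participants in a uniformly
    random order.  Every participant's marginal equals the apriori for any
    ``theta``.  ``theta`` is used as given; quantization is the caller's
    responsibility (see :class:`MovementSpec`).
    """
    if not (0 <= theta < 2 * math.pi):
        raise ParameterError("theta must lie in [0, 2*pi)")
    parts = _check_participants(participants)
    placement: Dict[int, int] = {}
    if not parts:
        return placement
    frac = theta / (2 * math.pi)
    phi = rng.random()
    order = rng.permutation(len(parts))
    cuts = np.cumsum(apriori.as_array())
    cuts[-1] = 1.0  # guard against rounding
    for j, idx in enumerate(order):
        pos = (j * frac + phi) % 1.0
        m = int(np.searchsorted(cuts, pos, side="right"))
        placement[parts[idx]] = min(m, apriori.M - 1)
    return placement


def sample_mechanism(
    spec: MovementSpec,
    participants: Sequence[int],
    apriori: AprioriDistribution,
    rng: np.random.Generator,
) -> Dict[int, int]:
    """Dispatch to the raw sampler selected by ``spec.mechanism``."""
    if spec.mechanism == "independent":
        parts = _check_participants(participants)
        draws = rng.choice(apriori.M, size=len(parts), p=apriori.as_array())
        return {i: int(m) for i, m in zip(parts, draws)}
    if spec.mechanism == "follow_majority":
        return sample_follow_majority(participants, apriori, rng, spec.ftm_tie_break)
    if spec.mechanism == "polya_urn":
        return sample_polya_urn(participants, apriori, spec.B, rng)
    return sample_wheel(participants, apriori, spec.theta_effective, rng)


def sample_configuration(
    spec: MovementSpec, rng: np.random.Generator
) -> PlacementConfiguration:
    """Draw one full placement of the evolutionary population.

    Requires ``N = M`` with individual ``i`` home at place ``i``.  Each
    individual independently takes an action from the participation split;
    direct-home individuals sit at their home place, random movers pick a
    uniform non-home place, and mechanism participants are placed jointly
    with the uniform mechanism apriori.  The per-individual marginal equals
    :func:`territorial_apriori`.
    """
    if spec.N != spec.M:
        raise ParameterError(
            "the evolutionary setting requires one home per place (N = M)"
        )
    N = spec.N
    split = spec.split
    u = rng.random(N)
    place = np.empty(N, dtype=np.int64)
    participants = []
    for i in range(N):
        if u[i] < split.p_direct_home:
            place[i] = i
        elif u[i] < split.p_direct_home + split.p_random_nonhome:
            j = int(rng.integers(spec.M - 1))
            place[i] = j if j < i else j + 1
        else:
            participants.append(i)
            place[i] = -1
    placed = sample_mechanism(spec, participants, uniform_apriori(spec.M), rng)
    for i, m in placed.items():
        place[i] = m
    return PlacementConfiguration(tuple(int(p) for p in place), spec.M)
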