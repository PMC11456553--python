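"""Multiplayer Public Goods and Hawk-Dove payoffs on group compositions.

Both games are played once per round by each co-location group.  A group
holds ``a`` type-A individuals (cooperators / hawks) and ``b`` type-B
individuals (defectors / doves); payoffs depend on the composition only.

Public Goods: a cooperator pays a cost ``C`` which is shared as a reward
``V`` among the *other* group members (cooperators pay the cost even when
alone and get no share of their own contribution).  Hawk-Dove: the group
competes for a reward ``V``; if hawks are present the doves concede and the
hawks fight, the winner takes ``V`` and each losing hawk pays ``C``; an
all-dove group splits ``V`` equally.  Everyone receives the background
payoff ``R``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .movement import ParameterError

__all__ = ["GameSpec", "GroupComposition", "pgg_payoff", "hd_payoff", "payoff"]

Role = Literal["A", "B"]


@dataclass(frozen=True)
class GameSpec:
    """Game identity and parameters (background ``R``, reward ``V``, cost ``C``)."""

    kind: Literal["public_goods", "hawk_dove"]
    R: float
    V: float
    C: float

    def __post_init__(self) -> None:
        if self.kind not in ("public_goods", "hawk_dove"):
            raise ParameterError(f"unknown game kind {self.kind!r}")
        for name in ("R", "V", "C"):
            v = getattr(self, name)
            if not (v == v and abs(v) < float("inf")):
                raise ParameterError(f"{name} must be finite")
        if self.V < 0 or self.C < 0:
            raise ParameterError("V and C must be non-negative")


@dataclass(frozen=True)
class GroupComposition:
    """Counts of the two types in one group (``a`` of type A, ``b`` of B)."""

    a: int
    b: int

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.a + self.b < 1:
            raise ParameterError("composition needs non-negative counts, size >= 1")

    @property
    def size(self) -> int:
        return self.a + self.b


def pgg_payoff(spec: GameSpec, comp: GroupComposition, role: Role) -> float:
    """Public Goods payoff for one individual of ``role`` in ``comp``.

    Cooperator: ``R - C`` when it is the only cooperator, otherwise
    ``R - C + V (a-1)/(a+b-1)``.  Defector: ``R`` with no cooperators,
    otherwise ``R + V a/(a+b-1)``.
    """
    a, b = comp.a, comp.b
    if role == "A":
        if a < 1:
            raise ParameterError("no cooperator present in the composition")
        if a == 1:
            return spec.R - spec.C
        return spec.R - spec.C + ((a - 1) / (a + b - 1)) * spec.V
    if b < 1:
        raise ParameterError("no defector present in the composition")
    if a == 0:
        return spec.R
    return spec.R + (a / (a + b - 1)) * spec.V


def hd_payoff(spec: GameSpec, comp: GroupComposition, role: Role) -> float:
    """Hawk-Dove expected payoff for one individual of ``role`` in ``comp``.

    Hawk: ``R + (V - (a-1) C)/a`` (win/lose split over the ``a`` fighting
    hawks).  Dove: ``R`` whenever hawks are present, ``R + V/b`` in an
    all-dove group.
    """
    a, b = comp.a, comp.b
    if role == "A":
        if a < 1:
            raise ParameterError("no hawk present in the composition")
        return spec.R + (spec.V - (a - 1) * spec.C) / a
    if b < 1:
        raise ParameterError("no dove present in the composition")
    if a > 0:
        return spec.R
    return spec.R + spec.V / b


def payoff(spec: GameSpec, comp: GroupComposition, role: Role) -> float:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "public_goods":
        return pgg_payoff(spec, comp, role)
    return hd_payoff(spec, comp, role)
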