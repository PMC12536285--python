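"""Base-10 taxonomy of serial-addition steps.

In serial addition, a mentally maintained running total (the *augend* ``Au``,
with decade part ``A`` and unit digit ``u``) is incremented by externally
displayed single-digit *addends*.  The relation of the augend and sum to the
nearest decade boundary defines qualitatively distinct addition types:

* post-complement ``[-]`` — the augend is a round number (``u == 0``);
* subcomplement ``[<]`` — non-round augend, the sum stays below the next decade;
* complement ``[=]`` — the sum lands exactly on the next decade (``u + a == 10``);
* supercomplement ``[>]`` — the sum crosses the decade (a carry is required).

When two addends are displayed at once, the two arithmetic laws of
associativity and commutativity allow three evaluation orders, and the
step's type depends on which pairwise sums reach a decade.  This module
classifies both the single- and dual-addend cases and enumerates the
candidate evaluation plans, ranked by the difficulty of the single
additions they induce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

BASE = 10

__all__ = [
    "BASE",
    "AdditionType",
    "SingleAddition",
    "DualAddition",
    "DualAdditionType",
    "EvaluationPlan",
    "PlanStep",
    "classify_single",
    "classify_dual",
    "category_of",
    "optimal_sequences",
    "DIFFICULTY_WEIGHT",
]


class AdditionType(str, Enum):
    """The four basic addition types, valued by their bracket notation."""

    POST = "[-]"
    SUB = "[<]"
    COMP = "[=]"
    SUPER = "[>]"

    def __str__(self) -> str:  # serialize as notation
        return self.value


#: Ranking weights for evaluation plans, mirroring the empirical mean
#: latencies (ms) of the four types in the single-addend task.  Only the
#: induced ordering POST < COMP < SUB < SUPER matters for plan ranking.
DIFFICULTY_WEIGHT: dict[AdditionType, float] = {
    AdditionType.POST: 638.0,
    AdditionType.COMP: 823.0,
    AdditionType.SUB: 935.0,
    AdditionType.SUPER: 1298.0,
}


def _check_addend(a: int, name: str = "addend") -> None:
    if not (1 <= a <= 9):
        raise ValueError(f"{name} must be a digit in 1..9, got {a!r}")


@dataclass(frozen=True)
class SingleAddition:
    """One serial-addition step ``Au + a``."""

    augend: int
    addend: int

    def __post_init__(self) -> None:
        if self.augend < 0:
            raise ValueError(f"augend must be non-negative, got {self.augend}")
        _check_addend(self.addend)

    @property
    def unit(self) -> int:
        """Unit digit ``u`` of the augend."""
        return self.augend % BASE

    @property
    def sum(self) -> int:
        return self.augend + self.addend

    @property
    def addition_type(self) -> AdditionType:
        return classify_single(self.augend, self.addend)


@dataclass(frozen=True)
class DualAddition:
    """One paired serial-addition step ``Au + a1 + a2``."""

    augend: int
    a1: int
    a2: int

    def __post_init__(self) -> None:
        if self.augend < 0:
            raise ValueError(f"augend must be non-negative, got {self.augend}")
        _check_addend(self.a1, "a1")
        _check_addend(self.a2, "a2")

    @property
    def unit(self) -> int:
        return self.augend % BASE


def classify_single(augend: int, addend: int) -> AdditionType:
    """Classify the addition ``augend + addend`` into one of the four types.

    Only the unit digit of the augend matters: the taxonomy is defined by
    the relation of augend and sum to the base of the place-value notation.
    """
    if augend < 0:
        raise ValueError(f"augend must be non-negative, got {augend}")
    _check_addend(addend)
    u = augend % BASE
    if u == 0:
        return AdditionType.POST
    s = u + addend
    if s < BASE:
        return AdditionType.SUB
    if s == BASE:
        return AdditionType.COMP
    return AdditionType.SUPER


_DUAL_NOTATION = {
    1: "[-<]",
    2: "[-=]",
    3: "[->]",
    4: "[<<]",
    5: "[<=]",
    6: "[=-]",
    7: "[<>]",
    8: "[>=]",
    9: "[>>]",
}

_DUAL_NAME = {
    1: "decade-subcomplement",
    2: "decade-complement",
    3: "decade-supercomplement",
    4: "subcomplement",
    5: "covert complement",
    (6, "a"): "direct complement",
    (6, "b"): "indirect complement",
    (6, "c"): "pair",
    (6, "d"): "direct complement-pair",
    (6, "e"): "indirect complement-pair",
    7: "supercomplement",
    8: "covert complement 2",
    9: "supercomplement 2",
}

_CATEGORY = {
    1: AdditionType.POST,
    2: AdditionType.POST,
    3: AdditionType.POST,
    4: AdditionType.SUB,
    5: AdditionType.SUB,
    6: AdditionType.COMP,
    7: AdditionType.SUPER,
    8: AdditionType.SUPER,
    9: AdditionType.SUPER,
}


@dataclass(frozen=True)
class DualAdditionType:
    """One of the nine dual-addend types (type 6 carries subtypes a–e)."""

    type_index: int
    subtype: str = ""  # "" except for type 6: one of "a".."e"

    def __post_init__(self) -> None:
        if self.type_index not in range(1, 10):
            raise ValueError(f"type_index must be 1..9, got {self.type_index}")
        if (self.type_index == 6) != bool(self.subtype):
            raise ValueError("subtype is required exactly for type 6")
        if self.subtype and self.subtype not in "abcde":
            raise ValueError(f"subtype must be one of a..e, got {self.subtype!r}")

    @property
    def label(self) -> str:
        """Compact label such as ``"2"`` or ``"6b"``."""
        return f"{self.type_index}{self.subtype}"

    @property
    def notation(self) -> str:
        return _DUAL_NOTATION[self.type_index]

    @property
    def name(self) -> str:
        key = (6, self.subtype) if self.type_index == 6 else self.type_index
        return _DUAL_NAME[key]

    @property
    def category(self) -> AdditionType:
        return category_of(self)


def classify_dual(augend: int, a1: int, a2: int) -> DualAdditionType:
    """Classify the paired addition ``augend + a1 + a2``.

    The decision cascade follows the decade relations of the three pairwise
    sums ``u+a1``, ``u+a2``, ``a1+a2`` and the total ``u+a1+a2``:

    * round augend (``u == 0``): types 1/2/3 by ``a1+a2`` below / at / above 10;
    * any pairwise sum equal to 10: type 6, with subtype a/b/c/d/e recording
      whether the first addend, the second addend, the addend pair, or a
      combination complements to 10;
    * otherwise types 4/5/7/8/9 by the total below 10 / at 10 / crossing one
      decade / at 20 / above 20.
    """
    if augend < 0:
        raise ValueError(f"augend must be non-negative, got {augend}")
    _check_addend(a1, "a1")
    _check_addend(a2, "a2")
    u = augend % BASE
    pair = a1 + a2
    if u == 0:
        if pair < BASE:
            return DualAdditionType(1)
        if pair == BASE:
            return DualAdditionType(2)
        return DualAdditionType(3)
    s1, s2 = u + a1, u + a2
    if s1 == BASE or s2 == BASE or pair == BASE:
        # subtype precedence: complement-pairs (both relations) before plain
        # complements, direct before indirect; degenerate a1 == a2 inputs
        # collapse onto the direct subtypes.
        if s1 == BASE and pair == BASE and a1 != a2:
            return DualAdditionType(6, "d")
        if s2 == BASE and pair == BASE and a1 != a2:
            return DualAdditionType(6, "e")
        if s1 == BASE:
            return DualAdditionType(6, "a")
        if s2 == BASE:
            return DualAdditionType(6, "b")
        return DualAdditionType(6, "c")
    total = u + pair
    if total < BASE:
        return DualAdditionType(4)
    if total == BASE:
        return DualAdditionType(5)
    if total < 2 * BASE:
        return DualAdditionType(7)
    if total == 2 * BASE:
        return DualAdditionType(8)
    return DualAdditionType(9)


def category_of(dual_type: DualAdditionType) -> AdditionType:
    """Map a dual-addend type onto the four single-addend categories.

    Types 1–3 (round augend) group with post-complements, 4–5 with
    subcomplements, 6 with complements, 7–9 with supercomplements.
    """
    return _CATEGORY[dual_type.type_index]


@dataclass(frozen=True)
class PlanStep:
    """A single executed addition within an evaluation plan.

    ``running_unit`` is the unit digit of the mentally maintained running
    total at the moment the step is taken.  For the pair-combination step of
    an associative plan the operands are the two addends themselves, but the
    running total (and hence ``running_unit``) is still the untouched augend.
    """

    augend: int
    addend: int
    step_type: AdditionType
    running_unit: int


@dataclass(frozen=True)
class EvaluationPlan:
    """One of the three legal orders for evaluating ``Au + a1 + a2``."""

    name: str  # "linear" | "commuted" | "associative"
    steps: tuple[PlanStep, ...]
    facilitative_steps: int = field(init=False)
    cost: float = field(init=False)

    def __post_init__(self) -> None:
        fac = sum(
            s.step_type in (AdditionType.POST, AdditionType.COMP) for s in self.steps
        )
        cost = sum(DIFFICULTY_WEIGHT[s.step_type] for s in self.steps)
        object.__setattr__(self, "facilitative_steps", fac)
        object.__setattr__(self, "cost", cost)


def _classify_wide(augend: int, addend: int) -> AdditionType:
    """Classify adding a combined addend (2..18) to the augend.

    Adding an exact multiple of the base is a pure decade increment and
    behaves like a post-complement; landing exactly on a decade is a
    complement; otherwise the sub/super distinction applies as usual.
    """
    u = augend % BASE
    if u == 0 or addend % BASE == 0:
        return AdditionType.POST
    s = u + addend
    if s < BASE:
        return AdditionType.SUB
    if s % BASE == 0:
        return AdditionType.COMP
    return AdditionType.SUPER


_PLAN_ORDER = {"linear": 0, "commuted": 1, "associative": 2}


def optimal_sequences(augend: int, a1: int, a2: int) -> list[EvaluationPlan]:
    """Enumerate the three evaluation plans for ``Au + a1 + a2``, best first.

    Plans are ranked by the number of facilitative steps (post-complements
    and complements) they induce, then by the summed difficulty weight of
    their steps, with deterministic tie-breaking: linear before commuted
    before associative.
    """
    if augend < 0:
        raise ValueError(f"augend must be non-negative, got {augend}")
    _check_addend(a1, "a1")
    _check_addend(a2, "a2")
    u = augend % BASE

    def two_step(name: str, first: int, second: int) -> EvaluationPlan:
        mid = augend + first
        return EvaluationPlan(
            name,
            (
                PlanStep(augend, first, classify_single(augend, first), u),
                PlanStep(mid, second, classify_single(mid, second), mid % BASE),
            ),
        )

    pair = a1 + a2
    associative = EvaluationPlan(
        "associative",
        (
            PlanStep(a1, a2, classify_single(a1, a2), u),
            PlanStep(augend, pair, _classify_wide(augend, pair), u),
        ),
    )
    plans = [two_step("linear", a1, a2), two_step("commuted", a2, a1), associative]
    plans.sort(key=lambda p: (-p.facilitative_steps, p.cost, _PLAN_ORDER[p.name]))
    return plans
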