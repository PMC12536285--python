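"""Constrained random stimulus lists for the serial-addition paradigm.

Study 1 presents lists of four to six digits (1–9, no adjacent repetitions)
added one at a time; the first element seeds the running total.  Lists are
controlled by the number of complement steps along the running total: none,
exactly one, or exactly two.

Study 2 presents lists of 8, 10 or 12 digits consumed two at a time, with
an initial running total of zero.  Lists are controlled by the number of
facilitative opportunities at the paired steps: *overt complements* (one of
the displayed addends complements a non-round running total to the next
decade) and *pairs* (the two displayed addends sum to 10).  List types allow
for no such opportunities, some (exactly one of each), or many (three or
more in total).  Covert complements — steps whose grand total reaches a
decade only after combining both addends — are counted but never forbidden.

Generation is by rejection sampling of uniform adjacent-distinct digit
sequences, which keeps the conditional distribution uniform over the valid
lists of each type.  Per-type length weights and sum windows are chosen so
that element counts and list sums increase slightly with the number of
facilitators, so a facilitation effect cannot be mimicked by problem size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .taxonomy import AdditionType, classify_single, classify_dual

__all__ = [
    "ListSpec",
    "StimulusList",
    "ValidationReport",
    "Opportunities",
    "GenerationError",
    "STUDY1_TYPES",
    "STUDY2_TYPES",
    "get_spec",
    "count_complements",
    "count_opportunities",
    "generate_list",
    "generate_set",
    "validate_list",
]

STUDY1_TYPES = ("none", "one", "two")
STUDY2_TYPES = ("no", "some", "many")


class GenerationError(RuntimeError):
    """Raised when rejection sampling exhausts its attempt budget."""


class Opportunities(NamedTuple):
    """Facilitation counts over the paired steps of a study-2 list."""

    complements: int  # overt: u + a1 == 10 or u + a2 == 10 with u > 0
    pairs: int  # a1 + a2 == 10
    covert: int  # steps of dual types 2, 5 or 8


@dataclass(frozen=True)
class ListSpec:
    """Constraint set that a stimulus list of a given type must satisfy."""

    study: int
    list_type: str
    lengths: tuple[int, ...]
    length_weights: tuple[float, ...]
    sum_range: tuple[int, int]
    n_complements: int | None = None  # study 1: exact complement count
    n_overt_complements: int | None = None  # study 2: exact count
    n_pairs: int | None = None  # study 2: exact count
    min_opportunities: int | None = None  # study 2: complements + pairs >= this
    max_attempts: int = 200_000


# Nominal length weights are calibrated so that the *realized* per-type
# means (after rejection against the count and sum constraints, which tilts
# the conditional length distribution) sit close to the study conditions:
# study 1 elements 4.92/5.06/5.23 and sums 24.5/25.1/25.7; study 2 elements
# 9.79/10.03/10.26 and sums 49.5/50.2/51.3 — slightly increasing in the
# number of facilitators.
_STUDY1_SPECS = {
    "none": ListSpec(1, "none", (4, 5, 6), (0.33, 0.33, 0.34), (20, 28), n_complements=0),
    "one": ListSpec(1, "one", (4, 5, 6), (0.37, 0.33, 0.30), (21, 29), n_complements=1),
    "two": ListSpec(1, "two", (4, 5, 6), (0.58, 0.31, 0.11), (22, 29), n_complements=2),
}

_STUDY2_SPECS = {
    "no": ListSpec(
        2, "no", (8, 10, 12), (0.27, 0.34, 0.39), (45, 55),
        n_overt_complements=0, n_pairs=0,
    ),
    "some": ListSpec(
        2, "some", (8, 10, 12), (0.36, 0.33, 0.31), (45, 55),
        n_overt_complements=1, n_pairs=1,
    ),
    "many": ListSpec(
        2, "many", (8, 10, 12), (0.50, 0.32, 0.18), (47, 56),
        min_opportunities=3,
    ),
}


def get_spec(study: int, list_type: str) -> ListSpec:
    """Return the default constraint spec for a study / list-type pair."""
    specs = {1: _STUDY1_SPECS, 2: _STUDY2_SPECS}.get(study)
    if specs is None:
        raise ValueError(f"study must be 1 or 2, got {study}")
    try:
        return specs[list_type]
    except KeyError:
        raise ValueError(
            f"unknown list type {list_type!r} for study {study}; "
            f"expected one of {tuple(specs)}"
        ) from None


@dataclass(frozen=True)
class StimulusList:
    """A generated (or loaded) digit list with its derived counts."""

    study: int
    list_type: str
    elements: tuple[int, ...]
    list_id: int = 0

    @property
    def total(self) -> int:
        return int(sum(self.elements))

    @property
    def running_totals(self) -> tuple[int, ...]:
        """Running totals after each serial step.

        Study 1 steps one element at a time starting from the first element;
        study 2 steps one displayed *pair* at a time starting from zero.
        """
        if self.study == 1:
            acc = self.elements[0]
            out = [acc]
            for e in self.elements[1:]:
                acc += e
                out.append(acc)
        else:
            acc = 0
            out = []
            for a1, a2 in zip(self.elements[::2], self.elements[1::2]):
                acc += a1 + a2
                out.append(acc)
        return tuple(out)

    @property
    def n_complements(self) -> int:
        return count_complements(self.elements)

    @property
    def opportunities(self) -> Opportunities:
        return count_opportunities(self.elements)


def _check_elements(elements: Sequence[int], min_len: int = 2) -> None:
    if len(elements) < min_len:
        raise ValueError(f"list too short: need >= {min_len} elements")
    for e in elements:
        if not (1 <= int(e) <= 9):
            raise ValueError(f"elements must be digits 1..9, got {e!r}")


def count_complements(elements: Sequence[int]) -> int:
    """Number of complement steps when adding the list one digit at a time.

    The first element provides the initial augend; each later element is an
    addend onto the running total.
    """
    _check_elements(elements)
    total = int(elements[0])
    n = 0
    for a in elements[1:]:
        if classify_single(total, int(a)) is AdditionType.COMP:
            n += 1
        total += int(a)
    return n


def count_opportunities(elements: Sequence[int]) -> Opportunities:
    """Facilitation counts over the paired steps of a study-2 list.

    The running total starts at zero; elements are consumed two at a time in
    presentation order.
    """
    _check_elements(elements)
    if len(elements) % 2:
        raise ValueError("study-2 lists must have an even number of elements")
    total, comp, pairs, covert = 0, 0, 0, 0
    for a1, a2 in zip(elements[::2], elements[1::2]):
        a1, a2 = int(a1), int(a2)
        u = total % 10
        if u > 0 and (u + a1 == 10 or u + a2 == 10):
            comp += 1
        if a1 + a2 == 10:
            pairs += 1
        if classify_dual(total, a1, a2).type_index in (2, 5, 8):
            covert += 1
        total += a1 + a2
    return Opportunities(comp, pairs, covert)


@dataclass(frozen=True)
class ValidationReport:
    """Per-constraint outcome of validating a list against a spec."""

    checks: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())

    @property
    def violations(self) -> list[str]:
        return [name for name, ok in self.checks.items() if not ok]


def validate_list(elements: Sequence[int], spec: ListSpec) -> ValidationReport:
    """Check a digit sequence against every constraint of a spec."""
    checks: dict[str, bool] = {}
    elems = [int(e) for e in elements]
    checks["digits_1_9"] = all(1 <= e <= 9 for e in elems)
    checks["length"] = len(elems) in spec.lengths
    checks["no_adjacent_repeats"] = all(a != b for a, b in zip(elems, elems[1:]))
    lo, hi = spec.sum_range
    checks["sum_in_range"] = lo <= sum(elems) <= hi
    if not checks["digits_1_9"] or len(elems) < 2:
        return ValidationReport(checks)
    if spec.study == 1:
        if spec.n_complements is not None:
            checks["complement_count"] = count_complements(elems) == spec.n_complements
    else:
        if len(elems) % 2:
            checks["even_length"] = False
            return ValidationReport(checks)
        opp = count_opportunities(elems)
        if spec.n_overt_complements is not None:
            checks["overt_complement_count"] = opp.complements == spec.n_overt_complements
        if spec.n_pairs is not None:
            checks["pair_count"] = opp.pairs == spec.n_pairs
        if spec.min_opportunities is not None:
            checks["min_opportunities"] = (
                opp.complements + opp.pairs >= spec.min_opportunities
            )
    return ValidationReport(checks)


def _sample_sequence(length: int, rng: np.random.Generator) -> list[int]:
    # uniform over digit sequences 1..9 without adjacent repeats
    first = int(rng.integers(1, 10))
    out = [first]
    offsets = rng.integers(1, 9, size=length - 1)
    for d in offsets:
        d = int(d)
        prev = out[-1]
        out.append(d + 1 if d >= prev else d)
    return out


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_list(spec: ListSpec, rng_seed) -> StimulusList:
    """Draw one list satisfying ``spec`` by rejection sampling.

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``.
    Raises :class:`GenerationError` if ``spec.max_attempts`` uniform draws
    produce no valid list, which signals an over-tight spec.
    """
    rng = _as_rng(rng_seed)
    weights = np.asarray(spec.length_weights, dtype=float)
    weights = weights / weights.sum()
    lo, hi = spec.sum_range
    for _ in range(spec.max_attempts):
        length = int(rng.choice(spec.lengths, p=weights))
        elems = _sample_sequence(length, rng)
        if not lo <= sum(elems) <= hi:
            continue
        if spec.study == 1:
            if count_complements(elems) != spec.n_complements:
                continue
        else:
            opp = count_opportunities(elems)
            if (
                spec.n_overt_complements is not None
                and opp.complements != spec.n_overt_complements
            ):
                continue
            if spec.n_pairs is not None and opp.pairs != spec.n_pairs:
                continue
            if (
                spec.min_opportunities is not None
                and opp.complements + opp.pairs < spec.min_opportunities
            ):
                continue
        return StimulusList(spec.study, spec.list_type, tuple(elems))
    raise GenerationError(
        f"no valid list for spec {spec.list_type!r} (study {spec.study}) "
        f"after {spec.max_attempts} attempts"
    )


def generate_set(
    study: int,
    rng_seed,
    n_per_type: int = 10,
    specs: Iterable[ListSpec] | None = None,
) -> list[StimulusList]:
    """Generate one participant's stimulus set (10 lists per list type).

    Reproducible from the seed; two calls with the same seed yield the same
    set.
    """
    rng = _as_rng(rng_seed)
    if specs is None:
        types = STUDY1_TYPES if study == 1 else STUDY2_TYPES
        specs = [get_spec(study, t) for t in types]
    out: list[StimulusList] = []
    list_id = 0
    for spec in specs:
        for _ in range(n_per_type):
            lst = generate_list(spec, rng)
            out.append(
                StimulusList(lst.study, lst.list_type, lst.elements, list_id=list_id)
            )
            list_id += 1
    return out
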