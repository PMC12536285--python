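"""Generative model of a participant performing serial addition.

Each addition step draws a latency from a lognormal distribution whose mean
is an additive combination of a per-type base latency, a linear problem-size
term and a participant-level random intercept.  Default base latencies
(post-complement 638 ms < complement 823 ms < subcomplement 935 ms <
supercomplement 1298 ms) encode the empirical difficulty gradient of the
single-addend task.  Miscalculations occur independently per addition with a
per-type hazard and are observed only at the list level; erroneous or late
lists are re-presented after all remaining lists, as in the experimental
procedure.  In the dual-addend task the simulated adder chooses, with
probability ``strategy_prob``, the easiest of the three evaluation orders
(paying ``search_cost`` when it departs from the linear order), which
produces the diagnostic latency signature of strategic addend reversal.
"""

from __future__ import annotations

from collections import deque
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import stimuli
from .taxonomy import (
    AdditionType,
    EvaluationPlan,
    classify_dual,
    classify_single,
    optimal_sequences,
)

__all__ = [
    "SimParams",
    "TRIAL_COLUMNS",
    "step_latency",
    "choose_plan",
    "simulate_participant",
    "simulate_experiment",
]

#: Canonical trial-log column order.
TRIAL_COLUMNS = [
    "participant_id",
    "study",
    "list_id",
    "list_type",
    "presentation_index",
    "step_index",
    "augend",
    "addend1",
    "addend2",
    "chosen_plan",
    "step_type",
    "category",
    "latency_ms",
    "entry_ms",
    "list_correct",
    "late_entry",
]


class SimParams(BaseModel):
    """Parameters of the generative behaviour model.

    Latencies are in milliseconds.  ``base_latency`` and ``error_hazard``
    are keyed by the four addition-type names.  ``addend_slope`` is the
    latency increase per unit of the centred size covariate (addend − 5 in
    the single-addend task, (addend sum − 10)/2 per executed sub-step in the
    dual-addend task, so that the pair-level slope is per unit addend sum).
    """

    base_latency: dict[str, float] = Field(
        default_factory=lambda: {"POST": 638.0, "SUB": 935.0, "COMP": 823.0, "SUPER": 1298.0}
    )
    addend_slope: float = 40.0
    participant_sd: float = 150.0
    residual_cv: float = 0.25
    error_hazard: dict[str, float] = Field(
        default_factory=lambda: {"POST": 0.005, "SUB": 0.04, "COMP": 0.01, "SUPER": 0.08}
    )
    late_prob: float = 0.02
    strategy_prob: float = 0.9
    search_cost: float = 100.0
    entry_latency: float = 900.0
    entry_limit: float = 2000.0
    seed: int | None = None

    @field_validator("base_latency")
    @classmethod
    def _latencies_positive(cls, v: dict[str, float]) -> dict[str, float]:
        missing = {t.name for t in AdditionType} - set(v)
        if missing:
            raise ValueError(f"base_latency missing types: {sorted(missing)}")
        if any(x <= 0 for x in v.values()):
            raise ValueError("base latencies must be positive")
        return v

    @field_validator("error_hazard")
    @classmethod
    def _hazards_valid(cls, v: dict[str, float]) -> dict[str, float]:
        missing = {t.name for t in AdditionType} - set(v)
        if missing:
            raise ValueError(f"error_hazard missing types: {sorted(missing)}")
        if any(not 0.0 <= x < 1.0 for x in v.values()):
            raise ValueError("error hazards must be in [0, 1)")
        return v

    @field_validator("late_prob", "strategy_prob")
    @classmethod
    def _probabilities(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
        return v

    @field_validator("residual_cv", "participant_sd", "search_cost")
    @classmethod
    def _non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("must be non-negative")
        return v


def step_latency(
    step_type: AdditionType,
    size_covariate: float,
    participant_effect: float,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> float:
    """Draw one step latency (ms).

    The noise-free mean is ``base_latency[type] + addend_slope * size +
    participant_effect``; multiplicative lognormal noise with coefficient of
    variation ``residual_cv`` preserves that mean and gives the right-skewed
    positive distribution typical of response times.
    """
    mean = (
        params.base_latency[step_type.name]
        + params.addend_slope * size_covariate
        + participant_effect
    )
    mean = max(mean, 1.0)
    if params.residual_cv == 0 or rng is None:
        return mean
    sigma2 = np.log1p(params.residual_cv**2)
    return float(mean * np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2))))


def choose_plan(
    augend: int,
    a1: int,
    a2: int,
    params: SimParams,
    rng: np.random.Generator,
) -> EvaluationPlan:
    """Pick the evaluation order for a dual-addend step.

    With probability ``strategy_prob`` the adder detects and executes the
    top-ranked plan; otherwise it falls back to the linear left-to-right
    order.
    """
    plans = optimal_sequences(augend, a1, a2)
    if rng.random() < params.strategy_prob:
        return plans[0]
    return next(p for p in plans if p.name == "linear")


def _present_study1(
    lst: stimuli.StimulusList,
    pres_idx: int,
    participant_id: int,
    participant_effect: float,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[list[dict], bool, bool]:
    rows: list[dict] = []
    total = lst.elements[0]
    any_error = False
    for i, addend in enumerate(lst.elements[1:], start=1):
        t = classify_single(total, addend)
        lat = step_latency(t, addend - 5.0, participant_effect, params, rng)
        if rng.random() < params.error_hazard[t.name]:
            any_error = True
        rows.append(
            {
                "participant_id": participant_id,
                "study": 1,
                "list_id": lst.list_id,
                "list_type": lst.list_type,
                "presentation_index": pres_idx,
                "step_index": i,
                "augend": total,
                "addend1": addend,
                "addend2": np.nan,
                "chosen_plan": "linear",
                "step_type": t.value,
                "category": t.value,
                "latency_ms": lat,
                "entry_ms": np.nan,
            }
        )
        total += addend
    return rows, any_error, _entry(rows, participant_effect, params, rng)


def _present_study2(
    lst: stimuli.StimulusList,
    pres_idx: int,
    participant_id: int,
    participant_effect: float,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[list[dict], bool, bool]:
    rows: list[dict] = []
    total = 0
    any_error = False
    elems = lst.elements
    for i, (a1, a2) in enumerate(zip(elems[::2], elems[1::2]), start=1):
        dual = classify_dual(total, a1, a2)
        plan = choose_plan(total, a1, a2, params, rng)
        size = (a1 + a2 - 10.0) / 2.0
        lat = 0.0
        for s in plan.steps:
            lat += step_latency(s.step_type, size, participant_effect, params, rng)
            if rng.random() < params.error_hazard[s.step_type.name]:
                any_error = True
        if plan.name != "linear":
            lat += params.search_cost
        rows.append(
            {
                "participant_id": participant_id,
                "study": 2,
                "list_id": lst.list_id,
                "list_type": lst.list_type,
                "presentation_index": pres_idx,
                "step_index": i,
                "augend": total,
                "addend1": a1,
                "addend2": a2,
                "chosen_plan": plan.name,
                "step_type": dual.label,
                "category": dual.category.value,
                "latency_ms": lat,
                "entry_ms": np.nan,
            }
        )
        total += a1 + a2
    return rows, any_error, _entry(rows, participant_effect, params, rng)


def _entry(
    rows: list[dict],
    participant_effect: float,
    params: SimParams,
    rng: np.random.Generator,
) -> bool:
    """Draw the result-entry interval onto the last step row; return lateness.

    The entry interval is recorded separately from the addition latencies so
    that list latency can be computed under either convention.  Lateness is
    its own hazard: a late entry exceeds the entry time limit.
    """
    mean = max(params.entry_latency + participant_effect, 1.0)
    if params.residual_cv > 0:
        sigma2 = np.log1p(params.residual_cv**2)
        entry = float(mean * np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2))))
    else:
        entry = mean
    late = bool(rng.random() < params.late_prob)
    if late:
        entry = max(entry, params.entry_limit + 1.0)
    else:
        entry = min(entry, params.entry_limit - 1.0)
    rows[-1]["entry_ms"] = entry
    return late


def simulate_participant(
    stimulus_set: Sequence[stimuli.StimulusList],
    params: SimParams,
    participant_id: int = 0,
    participant_effect: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one participant adding a 30-list stimulus set.

    The initial presentation order is a random permutation; lists with a
    miscalculation or a late entry are appended to the end of the queue with
    an incremented presentation index, until every list has been added
    correctly within the entry limit.
    """
    rng = np.random.default_rng() if rng is None else rng
    studies = {lst.study for lst in stimulus_set}
    if len(studies) != 1:
        raise ValueError("stimulus set mixes studies")
    study = studies.pop()
    present = _present_study1 if study == 1 else _present_study2
    order = rng.permutation(len(stimulus_set))
    queue: deque[tuple[stimuli.StimulusList, int]] = deque(
        (stimulus_set[i], 1) for i in order
    )
    all_rows: list[dict] = []
    while queue:
        lst, pres_idx = queue.popleft()
        rows, any_error, late = present(
            lst, pres_idx, participant_id, participant_effect, params, rng
        )
        for r in rows:
            r["list_correct"] = not any_error
            r["late_entry"] = late
        all_rows.extend(rows)
        if any_error or late:
            queue.append((lst, pres_idx + 1))
    return pd.DataFrame(all_rows, columns=TRIAL_COLUMNS)


def simulate_experiment(
    n_participants: int = 21,
    params: SimParams | None = None,
    study: int = 1,
    stimulus_sets: Sequence[Sequence[stimuli.StimulusList]] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the full experiment (default: 21 participants).

    Each participant receives a unique stimulus set (generated from a
    participant-specific stream derived from the master seed) and a random
    intercept drawn once from ``N(0, participant_sd)``.  Passing
    ``stimulus_sets`` reuses pre-generated sets instead.
    """
    params = SimParams() if params is None else params
    if seed is None:
        seed = params.seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants + 1)
    master = np.random.default_rng(children[-1])
    effects = master.normal(0.0, params.participant_sd, size=n_participants)
    logs = []
    for pid in range(n_participants):
        rng = np.random.default_rng(children[pid])
        if stimulus_sets is None:
            sset = stimuli.generate_set(study, rng)
        else:
            sset = stimulus_sets[pid]
        logs.append(
            simulate_participant(
                sset, params, participant_id=pid, participant_effect=effects[pid], rng=rng
            )
        )
    return pd.concat(logs, ignore_index=True)
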