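"""Conservative accuracy and latency measures from a trial log.

Accuracy is measured only on each list's first presentation (erroneous
lists reappear later in the sequence, so later presentations are neither
independent nor comparable), and late entries are excluded from both the
numerator and denominator since they are neither correct additions nor
genuine miscalculations.  Latency is measured only on correctly added
lists, after a one-pass screening that excludes values exceeding the
overall mean by more than ``outlier_k`` standard deviations (upper-sided by
default: slow outliers reflect lapses, implausibly fast responses are
impossible in this paradigm).  List latency is the sum of the step
latencies; the result-entry interval is reported separately so either
convention can be computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementConfig",
    "screen_outliers",
    "list_table",
    "first_presentation_accuracy",
    "addition_latency_table",
    "list_latency_table",
    "screened_list_data",
    "screened_addition_data",
]


@dataclass(frozen=True)
class MeasurementConfig:
    outlier_k: float = 3.0
    upper_only: bool = True
    correct_lists_only: bool = True
    first_presentation_only: bool = True
    include_entry_in_list_latency: bool = False
    min_cell_n: int = 10

    def __post_init__(self) -> None:
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")


def screen_outliers(values, config: MeasurementConfig | None = None) -> np.ndarray:
    """Inclusion mask: True for values to keep.

    The mean and standard deviation are computed once on the full vector
    (not iteratively); a value is excluded iff it exceeds
    ``mean + k * sd`` (and, if two-sided, iff it falls below ``mean - k * sd``).
    """
    config = config or MeasurementConfig()
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return np.ones_like(x, dtype=bool)
    mean = x.mean()
    sd = x.std(ddof=1)
    keep = x <= mean + config.outlier_k * sd
    if not config.upper_only:
        keep &= x >= mean - config.outlier_k * sd
    return keep


def list_table(log: pd.DataFrame) -> pd.DataFrame:
    """Collapse a step-level trial log to one row per list presentation.

    Derives element count, list sum, summed addition latency (s) and the
    entry interval (s) for each (participant, list, presentation).
    """
    keys = ["participant_id", "list_id", "presentation_index"]
    study = int(log["study"].iloc[0])
    g = log.sort_values(keys + ["step_index"]).groupby(keys, sort=False)
    out = g.agg(
        list_type=("list_type", "last"),
        n_steps=("step_index", "size"),
        latency_ms=("latency_ms", "sum"),
        _augend=("augend", "last"),
        _a1=("addend1", "last"),
        _a2=("addend2", "last"),
        entry_ms=("entry_ms", "last"),
        list_correct=("list_correct", "last"),
        late_entry=("late_entry", "last"),
    ).reset_index()
    if study == 1:
        out["n_elements"] = out["n_steps"] + 1
        out["list_sum"] = (out["_augend"] + out["_a1"]).astype(int)
    else:
        out["n_elements"] = 2 * out["n_steps"]
        out["list_sum"] = (out["_augend"] + out["_a1"] + out["_a2"]).astype(int)
    out["study"] = study
    out["latency_s"] = out["latency_ms"] / 1000.0
    out["entry_s"] = out["entry_ms"] / 1000.0
    out["list_correct"] = out["list_correct"].astype(bool)
    out["late_entry"] = out["late_entry"].astype(bool)
    return out.drop(columns=["_augend", "_a1", "_a2", "latency_ms", "entry_ms"])


def _order_types(log_or_table: pd.DataFrame, column: str) -> list:
    vals = list(pd.unique(log_or_table[column]))
    for known in (["none", "one", "two"], ["no", "some", "many"],
                  ["[-]", "[<]", "[=]", "[>]"]):
        if set(vals) <= set(known):
            return [v for v in known if v in vals]
    return sorted(vals, key=str)


def first_presentation_accuracy(
    log: pd.DataFrame, config: MeasurementConfig | None = None
) -> pd.DataFrame:
    """Per-list-type proportion of genuine errors on first presentations.

    Late entries are removed from both numerator and denominator.  Empty
    cells are reported as missing (NaN), never as zero.
    """
    config = config or MeasurementConfig()
    lists = list_table(log)
    if config.first_presentation_only:
        lists = lists[lists["presentation_index"] == 1]
    lists = lists[~lists["late_entry"]]
    rows = []
    for lt in _order_types(log, "list_type"):
        cell = lists[lists["list_type"] == lt]
        n = len(cell)
        if n == 0:
            rows.append({"list_type": lt, "error_rate": np.nan, "se": np.nan, "n": 0})
            continue
        p = float((~cell["list_correct"]).mean())
        rows.append(
            {
                "list_type": lt,
                "error_rate": p,
                "se": float(np.sqrt(p * (1 - p) / n)),
                "n": n,
            }
        )
    return pd.DataFrame(rows).set_index("list_type")


def _correct_lists(log: pd.DataFrame, config: MeasurementConfig) -> pd.DataFrame:
    lists = list_table(log)
    if config.correct_lists_only:
        lists = lists[lists["list_correct"] & ~lists["late_entry"]]
    return lists


def addition_latency_table(
    log: pd.DataFrame,
    config: MeasurementConfig | None = None,
    by: str = "category",
) -> pd.DataFrame:
    """Per-type latency and problem-size summary of individual additions.

    Restricted to correctly added lists; latencies exceeding the overall
    mean by more than ``outlier_k`` SD are excluded.  ``by`` selects the
    grouping column (``"category"`` for the four-way grouping,
    ``"step_type"`` for the fine dual-addend types).  The number of
    excluded outliers is recorded in ``DataFrame.attrs["n_outliers"]``.
    """
    config = config or MeasurementConfig()
    df = log
    if config.correct_lists_only:
        df = df[df["list_correct"] & ~df["late_entry"]]
    keep = screen_outliers(df["latency_ms"].to_numpy(), config)
    n_outliers = int((~keep).sum())
    df = df[keep]
    study = int(log["study"].iloc[0])
    rows = []
    for t in _order_types(df, by):
        cell = df[df[by] == t]
        n = len(cell)
        addend = cell["addend1"] if study == 1 else cell["addend1"] + cell["addend2"]
        rows.append(
            {
                by: t,
                "mean_augend": float(cell["augend"].mean()),
                "mean_addend": float(addend.mean()),
                "mean_sum": float((cell["augend"] + addend).mean()),
                "latency_ms": float(cell["latency_ms"].mean()),
                "se": float(cell["latency_ms"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "n": n,
                "low_n": n < config.min_cell_n,
            }
        )
    out = pd.DataFrame(rows).set_index(by)
    out.attrs["n_outliers"] = n_outliers
    out.attrs["n_before_screening"] = n_outliers + int(len(df))
    return out


def list_latency_table(
    log: pd.DataFrame, config: MeasurementConfig | None = None
) -> pd.DataFrame:
    """Per-list-type summary of correctly added lists.

    Reports mean element count, list sum and addition latency in seconds
    (optionally including the entry interval), after outlier screening at
    the list level.  Outlier counts are in ``attrs["n_outliers"]``.
    """
    config = config or MeasurementConfig()
    lists = _correct_lists(log, config)
    lat = lists["latency_s"].to_numpy(copy=True)
    if config.include_entry_in_list_latency:
        lat = lat + lists["entry_s"].to_numpy()
    keep = screen_outliers(lat, config)
    n_outliers = int((~keep).sum())
    lists = lists[keep]
    lat = lat[keep]
    lists = lists.assign(_lat=lat)
    rows = []
    for lt in _order_types(lists, "list_type"):
        cell = lists[lists["list_type"] == lt]
        n = len(cell)
        rows.append(
            {
                "list_type": lt,
                "mean_elements": float(cell["n_elements"].mean()),
                "mean_sum": float(cell["list_sum"].mean()),
                "latency_s": float(cell["_lat"].mean()),
                "se": float(cell["_lat"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "n": n,
            }
        )
    out = pd.DataFrame(rows).set_index("list_type")
    out.attrs["n_outliers"] = n_outliers
    out.attrs["n_before_screening"] = n_outliers + int(len(lists))
    return out


def screened_list_data(
    log: pd.DataFrame, config: MeasurementConfig | None = None
) -> pd.DataFrame:
    """Row-level correct lists after outlier screening, for model fitting.

    Adds a ``latency`` column in seconds (including the entry interval when
    the config says so).
    """
    config = config or MeasurementConfig()
    lists = _correct_lists(log, config)
    lat = lists["latency_s"].to_numpy(copy=True)
    if config.include_entry_in_list_latency:
        lat = lat + lists["entry_s"].to_numpy()
    keep = screen_outliers(lat, config)
    return lists[keep].assign(latency=lat[keep])


def screened_addition_data(
    log: pd.DataFrame, config: MeasurementConfig | None = None
) -> pd.DataFrame:
    """Addition-level rows from correct lists after outlier screening.

    Adds the problem-size columns used by the latency models: ``addend``
    (the single addend, or the addend sum in the dual-addend task),
    ``addend_sum`` and ``problem_sum``.
    """
    config = config or MeasurementConfig()
    df = log
    if config.correct_lists_only:
        df = df[df["list_correct"] & ~df["late_entry"]]
    keep = screen_outliers(df["latency_ms"].to_numpy(), config)
    df = df[keep].copy()
    study = int(log["study"].iloc[0])
    if study == 1:
        addend = df["addend1"].astype(float)
    else:
        addend = (df["addend1"] + df["addend2"]).astype(float)
    df["addend"] = addend
    df["addend_sum"] = addend
    df["problem_sum"] = df["augend"].astype(float) + addend
    return df
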