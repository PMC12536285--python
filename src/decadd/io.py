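"""Trial-log and stimulus-list serialization with provenance.

Trial logs round-trip through a plain CSV schema (one row per addition
step).  Files written by this package start with ``#``-prefixed metadata
lines recording the schema version, the RNG seed and the parameter set, so
every artifact carries its provenance; readers skip those lines.  External
data sets with different column names are adapted through a schema map (a
JSON dictionary of column renames, constant defaults and a latency unit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import TRIAL_COLUMNS, SimParams
from .stimuli import StimulusList

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "SchemaMap",
    "read_trial_csv",
    "write_trial_csv",
    "write_lists_csv",
    "read_lists_csv",
    "to_jsonable",
]

SCHEMA_VERSION = "1"

_REQUIRED = [c for c in TRIAL_COLUMNS if c not in ("addend2", "chosen_plan",
                                                   "category", "entry_ms")]


class SchemaError(ValueError):
    """Raised when a trial CSV fails validation; carries per-row messages."""

    def __init__(self, message: str, row_errors: list[str] | None = None):
        self.row_errors = row_errors or []
        detail = "".join(f"\n  - {e}" for e in self.row_errors[:20])
        super().__init__(message + detail)


@dataclass(frozen=True)
class SchemaMap:
    """Adapter from an external column layout to the canonical schema."""

    columns: dict[str, str] = field(default_factory=dict)  # external -> canonical
    defaults: dict[str, object] = field(default_factory=dict)
    latency_unit: str = "ms"  # "ms" or "s"

    @classmethod
    def from_json(cls, path: str | Path) -> "SchemaMap":
        raw = json.loads(Path(path).read_text())
        return cls(
            columns=raw.get("columns", {}),
            defaults=raw.get("defaults", {}),
            latency_unit=raw.get("latency_unit", "ms"),
        )


def _provenance_header(seed=None, params: SimParams | None = None) -> str:
    lines = [f"# decadd trial log v{SCHEMA_VERSION}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if params is not None:
        lines.append(f"# params={params.model_dump_json()}")
    return "\n".join(lines) + "\n"


def write_trial_csv(
    log: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    params: SimParams | None = None,
) -> None:
    """Write a trial log with provenance metadata lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance_header(seed, params))
        log.to_csv(fh, index=False, columns=TRIAL_COLUMNS)


def read_trial_csv(path: str | Path, schema_map: SchemaMap | None = None) -> pd.DataFrame:
    """Read and validate a trial log, optionally adapting an external schema.

    Raises :class:`SchemaError` with a per-row report on malformed data
    (missing columns, addends outside 1..9, non-positive latencies).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    if schema_map is not None:
        df = df.rename(columns=schema_map.columns)
        for col, value in schema_map.defaults.items():
            if col not in df.columns:
                df[col] = value
        if schema_map.latency_unit == "s" and "latency_ms" in df.columns:
            df["latency_ms"] = df["latency_ms"] * 1000.0
            if "entry_ms" in df.columns:
                df["entry_ms"] = df["entry_ms"] * 1000.0
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    for col in ("addend2", "chosen_plan", "category", "entry_ms"):
        if col not in df.columns:
            df[col] = np.nan
    errors: list[str] = []
    a1 = pd.to_numeric(df["addend1"], errors="coerce")
    bad = df.index[~a1.between(1, 9) | a1.isna()]
    errors += [f"row {i}: addend1={df.loc[i, 'addend1']!r} not a digit 1..9" for i in bad]
    a2 = pd.to_numeric(df["addend2"], errors="coerce")
    bad = df.index[a2.notna() & ~a2.between(1, 9)]
    errors += [f"row {i}: addend2={df.loc[i, 'addend2']!r} not a digit 1..9" for i in bad]
    lat = pd.to_numeric(df["latency_ms"], errors="coerce")
    bad = df.index[lat.isna() | (lat <= 0)]
    errors += [f"row {i}: latency_ms={df.loc[i, 'latency_ms']!r} must be > 0" for i in bad]
    pres = pd.to_numeric(df["presentation_index"], errors="coerce")
    bad = df.index[pres.isna() | (pres < 1)]
    errors += [f"row {i}: presentation_index={df.loc[i, 'presentation_index']!r} must be >= 1"
               for i in bad]
    if errors:
        raise SchemaError(f"{len(errors)} invalid rows in {path.name}", errors)
    df["list_correct"] = df["list_correct"].astype(bool)
    df["late_entry"] = df["late_entry"].astype(bool)
    return df[TRIAL_COLUMNS]


def write_lists_csv(
    lists: list[StimulusList], path: str | Path, seed: int | None = None
) -> None:
    """Serialize stimulus lists (one row per list, digits comma-joined)."""
    rows = []
    for lst in lists:
        row = {
            "study": lst.study,
            "list_id": lst.list_id,
            "list_type": lst.list_type,
            "elements": " ".join(str(e) for e in lst.elements),
            "n_elements": len(lst.elements),
            "list_sum": lst.total,
        }
        if lst.study == 1:
            row["n_complements"] = lst.n_complements
        else:
            opp = lst.opportunities
            row["n_overt_complements"] = opp.complements
            row["n_pairs"] = opp.pairs
            row["n_covert"] = opp.covert
        rows.append(row)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# decadd stimulus lists v{SCHEMA_VERSION}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_lists_csv(path: str | Path) -> list[StimulusList]:
    df = pd.read_csv(path, comment="#")
    return [
        StimulusList(
            int(r["study"]),
            str(r["list_type"]),
            tuple(int(x) for x in str(r["elements"]).split()),
            list_id=int(r["list_id"]),
        )
        for _, r in df.iterrows()
    ]


def to_jsonable(obj):
    """Recursively convert numpy/pandas scalars so json.dumps accepts them."""
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
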