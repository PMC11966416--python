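"""Daily linac machine-performance-check (MPC) series handling.

Parses timestamped MPC exports into date-ordered records of 141 named metrics
(21 scalar geometry/output metrics plus 120 per-leaf MLC offsets), builds
fixed-length windows ending at a QA delivery date, and provides train-fitted
z-score standardization.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources

import numpy as np
import pandas as pd

DEFAULT_WINDOW_DAYS = 30


def load_registry() -> list[str]:
    """Ordered metric names of the shipped 141-metric registry."""
    with resources.files("vmatqa.data").joinpath("mpc_registry.json").open() as f:
        reg = json.load(f)
    names = [m["name"] for m in reg["metrics"]]
    assert len(names) == 141
    return names


REGISTRY: list[str] = load_registry()
N_METRICS = len(REGISTRY)


@dataclass
class MPCRecord:
    day: date
    metrics: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(REGISTRY) - set(self.metrics)
        extra = set(self.metrics) - set(REGISTRY)
        if missing or extra:
            raise ValueError(
                f"MPC record must carry exactly the {N_METRICS} registry metrics; "
                f"missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}"
            )

    def as_vector(self) -> np.ndarray:
        return np.array([self.metrics[n] for n in REGISTRY], dtype=float)


@dataclass
class MPCSeries:
    records: list[MPCRecord]
    machine_id: str = "TB1"

    def __post_init__(self) -> None:
        days = [r.day for r in self.records]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("MPC record dates must be strictly increasing")


@dataclass
class SequenceWindow:
    matrix: np.ndarray            # (W, 141)
    qa_date: date
    imputed: np.ndarray           # (W,) bool, True where forward-filled
    dates: list[date] = field(default_factory=list)


def parse_mpc(path) -> MPCSeries:
    """Parse a wide or long MPC CSV export into a date-sorted series.

    Wide dialect: one row per machine-day, columns ``date`` [, ``machine_id``]
    plus the 141 registry metric names.  Long dialect: columns ``date``,
    ``metric``, ``value`` [, ``machine_id``].  Duplicate machine-days keep the
    last row with a warning.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"metric", "value"} <= cols:
        unknown = set(df["metric"]) - set(REGISTRY)
        if unknown:
            raise ValueError(
                f"unknown MPC metrics {sorted(unknown)[:5]}; registry has "
                f"{N_METRICS} names (see vmatqa/data/mpc_registry.json)"
            )
        wide = df.pivot_table(index="date", columns="metric", values="value",
                              aggfunc="last").reset_index()
    else:
        unknown = cols - set(REGISTRY) - {"date", "machine_id"}
        if unknown:
            raise ValueError(
                f"unknown MPC columns {sorted(unknown)[:5]}; registry has "
                f"{N_METRICS} names"
            )
        wide = df
    machine = str(wide["machine_id"].iloc[0]) if "machine_id" in wide else "TB1"
    wide = wide.copy()
    wide["date"] = pd.to_datetime(wide["date"]).dt.date
    if wide["date"].duplicated().any():
        warnings.warn("duplicate machine-days in MPC export; keeping last")
        wide = wide.drop_duplicates("date", keep="last")
    wide = wide.sort_values("date")
    records = [
        MPCRecord(day=row["date"], metrics={n: float(row[n]) for n in REGISTRY})
        for _, row in wide.iterrows()
    ]
    return MPCSeries(records=records, machine_id=machine)


def serialize_mpc(series: MPCSeries, path) -> None:
    """Write the canonical wide-dialect CSV (inverse of :func:`parse_mpc`)."""
    rows = []
    for r in series.records:
        row = {"date": r.day.isoformat(), "machine_id": series.machine_id}
        row.update({n: r.metrics[n] for n in REGISTRY})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def build_window(series: MPCSeries, qa_date: date,
                 window_days: int = DEFAULT_WINDOW_DAYS) -> SequenceWindow:
    """Last ``window_days`` calendar days of machine state ending at the most
    recent record on/before ``qa_date``; missing days are forward-filled and
    flagged imputed.  Uses only records <= qa_date (no future leakage)."""
    past = [r for r in series.records if r.day <= qa_date]
    if not past:
        raise ValueError(f"no MPC record on or before {qa_date}")
    end = past[-1].day
    days = [end - timedelta(days=window_days - 1 - k) for k in range(window_days)]
    by_day = {r.day: r for r in past}
    matrix = np.zeros((window_days, N_METRICS))
    imputed = np.zeros(window_days, dtype=bool)
    last_vec = None
    earliest = past[0]
    warned = False
    for k, d in enumerate(days):
        if d in by_day:
            last_vec = by_day[d].as_vector()
        else:
            imputed[k] = True
            if last_vec is None:
                # window starts before the series: back-fill from earliest
                last_vec = earliest.as_vector()
                if not warned:
                    warnings.warn("window precedes series start; leading rows "
                                  "imputed from the earliest record")
                    warned = True
            else:
                prev = [r for r in past if r.day < d]
                if prev:
                    last_vec = prev[-1].as_vector()
        matrix[k] = last_vec
    return SequenceWindow(matrix=matrix, qa_date=qa_date, imputed=imputed, dates=days)


@dataclass
class ZScoreStats:
    mean: np.ndarray
    std: np.ndarray
    constant: np.ndarray  # bool flags for sigma == 0 columns
    columns: list[str] | None = None

    @property
    def hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.mean.tobytes())
        h.update(self.std.tobytes())
        return h.hexdigest()[:16]


def zscore_fit_transform(
    table: np.ndarray, stats: ZScoreStats | None = None,
    columns: list[str] | None = None,
) -> tuple[np.ndarray, ZScoreStats]:
    """Column-wise (x - mu) / sigma with population sigma.

    When ``stats`` is given (fitted on the training split) it is reused
    verbatim; constant columns map to 0.
    """
    x = np.asarray(table, dtype=float)
    flat = x.reshape(-1, x.shape[-1])
    if stats is None:
        mu = flat.mean(axis=0)
        sd = flat.std(axis=0)
        const = sd == 0
        stats = ZScoreStats(mean=mu, std=np.where(const, 1.0, sd),
                            constant=const, columns=columns)
    elif stats.columns is not None and columns is not None and stats.columns != columns:
        raise ValueError("z-score stats column names do not match")
    out = (x - stats.mean) / stats.std
    out[..., stats.constant] = 0.0
    return out, stats
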