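"""Read and write trajectory tables as plain TSV/CSV.

Two dialects are supported:

* ``wide`` — one row per individual with columns ``individual_id,
  brood_id, host, sex, time_to_instar5, initial_mass, day1..dayN,
  final_larval_mass, pupal_mass[, censored]``.  Individuals with shorter
  instars leave trailing day columns empty; an empty or ``NA`` cell
  inside an individual's instar is an explicit missing weighing and is
  preserved as NaN, never imputed.
* ``long`` — one row per (individual, day) with columns
  ``individual_id, day, mass``, accompanied by a per-individual metadata
  table ``<stem>_meta.<ext>`` carrying the remaining columns.

Masses are mg, times days.  Sex codes are ``F``/``M`` (case-insensitive
on read).  The delimiter is taken from the file extension (``.csv`` →
comma, otherwise tab) unless forced with ``sep``.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import Trajectory, TrajectoryTable

_WIDE_META = ["individual_id", "brood_id", "host", "sex",
              "time_to_instar5", "initial_mass"]
_WIDE_TAIL = ["final_larval_mass", "pupal_mass", "censored"]
_FLOAT_FMT = "%.8g"  # >= 6 significant digits for lossless round trips


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + "_meta" + path.suffix)


def _norm_sex(value, row_label) -> str:
    s = str(value).strip().upper()
    if s not in ("F", "M"):
        raise ValueError(f"row {row_label}: unknown sex code {value!r}")
    return s


def _to_mass(value, row_label, column) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    if isinstance(value, str):
        if value.strip() in ("", "NA", "NaN", "nan"):
            return math.nan
        try:
            return float(value)
        except ValueError:
            raise ValueError(
                f"row {row_label}: non-numeric mass {value!r} in {column}") from None
    return float(value)


def write_trajectories(table: TrajectoryTable, path: str | Path,
                       dialect: str = "wide", sep: str | None = None) -> Path:
    """Serialize a trajectory table; returns the (main) written path.

    The ``long`` dialect additionally writes ``<stem>_meta.<ext>``.
    """
    path = Path(path)
    sep = _infer_sep(path, sep)
    if dialect not in ("wide", "long"):
        raise ValueError(f"unknown dialect {dialect!r}")

    n_days = max((t.instar_duration for t in table), default=0)
    meta_rows = []
    for t in table:
        row = {
            "individual_id": t.individual_id, "brood_id": t.brood_id,
            "host": t.host, "sex": t.sex,
            "time_to_instar5": t.time_to_instar5,
            "initial_mass": t.initial_mass,
            "final_larval_mass": t.final_larval_mass,
            "pupal_mass": t.pupal_mass,
            "censored": int(t.censored),
        }
        meta_rows.append(row)

    if dialect == "wide":
        rows = []
        for t, meta in zip(table, meta_rows):
            row = {k: meta[k] for k in _WIDE_META}
            for d in range(1, n_days + 1):
                row[f"day{d}"] = t.mass_on_day(d) if d <= t.instar_duration else math.nan
            row.update({k: meta[k] for k in _WIDE_TAIL})
            rows.append(row)
        cols = (_WIDE_META + [f"day{d}" for d in range(1, n_days + 1)] + _WIDE_TAIL)
        df = pd.DataFrame(rows, columns=cols)
        df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT, na_rep="")
        return path

    mass_rows = []
    for t in table:
        for d in range(1, t.instar_duration + 1):
            mass_rows.append({"individual_id": t.individual_id, "day": d,
                              "mass": t.mass_on_day(d)})
    pd.DataFrame(mass_rows, columns=["individual_id", "day", "mass"]).to_csv(
        path, sep=sep, index=False, float_format=_FLOAT_FMT, na_rep="NA")
    meta_cols = _WIDE_META + ["instar_duration"] + _WIDE_TAIL
    for t, meta in zip(table, meta_rows):
        meta["instar_duration"] = t.instar_duration
    pd.DataFrame(meta_rows, columns=meta_cols).to_csv(
        _meta_path(path), sep=sep, index=False, float_format=_FLOAT_FMT)
    return path


def read_trajectories(path: str | Path, dialect: str = "wide",
                      sep: str | None = None) -> TrajectoryTable:
    """Read and validate a trajectory table written by this package."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _infer_sep(path, sep)
    if dialect == "wide":
        return _read_wide(path, sep)
    if dialect == "long":
        return _read_long(path, sep)
    raise ValueError(f"unknown dialect {dialect!r}")


def _trajectory_from_parts(meta: dict, daily: list[float], label) -> Trajectory:
    return Trajectory(
        individual_id=str(meta["individual_id"]),
        brood_id=str(meta["brood_id"]),
        host=str(meta["host"]),
        sex=_norm_sex(meta["sex"], label),
        time_to_instar5=float(meta["time_to_instar5"]),
        initial_mass=_to_mass(meta["initial_mass"], label, "initial_mass"),
        daily_masses=daily,
        final_larval_mass=_to_mass(meta["final_larval_mass"], label,
                                   "final_larval_mass"),
        pupal_mass=_to_mass(meta["pupal_mass"], label, "pupal_mass"),
        censored=bool(int(meta.get("censored", 0) or 0)),
    )


def _read_wide(path: Path, sep: str) -> TrajectoryTable:
    df = pd.read_csv(path, sep=sep, dtype={"individual_id": str, "brood_id": str})
    day_cols = sorted((c for c in df.columns if c.startswith("day")),
                      key=lambda c: int(c[3:]))
    trajectories = []
    for idx, rec in df.iterrows():
        label = rec.get("individual_id", idx)
        masses = [_to_mass(rec[c], label, c) for c in day_cols]
        while masses and math.isnan(masses[-1]):  # trailing blanks = shorter instar
            masses.pop()
        trajectories.append(_trajectory_from_parts(rec, masses, label))
    return TrajectoryTable(trajectories,
                           metadata={"source": str(path), "dialect": "wide"})


def _read_long(path: Path, sep: str) -> TrajectoryTable:
    mass_df = pd.read_csv(path, sep=sep, dtype={"individual_id": str},
                          na_values=["NA"])
    meta_df = pd.read_csv(_meta_path(path), sep=sep,
                          dtype={"individual_id": str, "brood_id": str})
    grouped = {ind: g for ind, g in mass_df.groupby("individual_id", sort=False)}
    trajectories = []
    for idx, rec in meta_df.iterrows():
        ind = rec["individual_id"]
        dur = int(rec["instar_duration"])
        daily = [math.nan] * dur
        if ind in grouped:
            for _, r in grouped[ind].iterrows():
                d = int(r["day"])
                if not 1 <= d <= dur:
                    raise ValueError(f"row for {ind}: day {d} outside 1..{dur}")
                daily[d - 1] = _to_mass(r["mass"], ind, "mass")
        trajectories.append(_trajectory_from_parts(rec, daily, ind))
    return TrajectoryTable(trajectories,
                           metadata={"source": str(path), "dialect": "long"})
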