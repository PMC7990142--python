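"""Delimited-text I/O for cohorts, observations, centerlines and scan logs.

All tables are plain CSV with a fixed column order so that re-runs are
byte-identical.  Malformed rows are reported with their 1-based line
number in the file (header = line 1).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MouseRecord, ObservationRecord
from .geometry import ScanLog, SpineCenterline

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_observations",
    "read_observations",
    "write_centerline",
    "read_centerline",
    "read_scan_log",
]

COHORT_COLUMNS = ["mouse_id", "sex", "treatment", "enroll_age_days",
                  "death_age_days", "censored"]
OBS_COLUMNS = ["mouse_id", "phenotype", "age_days", "value"]


class MalformedRowError(ValueError):
    """A row failed validation; the message names the offending line."""


def write_cohort(mice: list[MouseRecord], path: str | Path) -> None:
    """Write a cohort table; a missing death age is an empty field."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(",".join(COHORT_COLUMNS) + "\n")
        for m in mice:
            death = "" if m.death_age_days is None else repr(float(m.death_age_days))
            fh.write(
                f"{m.mouse_id},{m.sex},{m.treatment},{float(m.enroll_age_days)!r},"
                f"{death},{int(m.censored)}\n"
            )


def read_cohort(path: str | Path) -> list[MouseRecord]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"mouse_id": str, "sex": str, "treatment": str},
                     float_precision="round_trip")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise MalformedRowError(f"{path}: missing columns {sorted(missing)}")
    mice: list[MouseRecord] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header on line 1
        death = row["death_age_days"]
        death = None if pd.isna(death) else float(death)
        try:
            mice.append(
                MouseRecord(
                    mouse_id=str(row["mouse_id"]),
                    sex=str(row["sex"]),
                    treatment=str(row["treatment"]),
                    enroll_age_days=float(row["enroll_age_days"]),
                    death_age_days=death,
                    censored=bool(int(row["censored"])),
                )
            )
        except (ValueError, TypeError) as exc:
            raise MalformedRowError(f"{path}, line {line}: {exc}") from exc
    return mice


def write_observations(obs: list[ObservationRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(",".join(OBS_COLUMNS) + "\n")
        for o in obs:
            fh.write(f"{o.mouse_id},{o.phenotype},{float(o.age_days)!r},"
                     f"{float(o.value)!r}\n")


def read_observations(path: str | Path) -> list[ObservationRecord]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"mouse_id": str, "phenotype": str},
                     float_precision="round_trip")
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise MalformedRowError(f"{path}: missing columns {sorted(missing)}")
    obs: list[ObservationRecord] = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            value = float(row["value"])
            age = float(row["age_days"])
            if not math.isfinite(value) or not math.isfinite(age):
                raise ValueError("non-finite value or age")
            obs.append(
                ObservationRecord(str(row["mouse_id"]), str(row["phenotype"]),
                                  age, value)
            )
        except (ValueError, TypeError) as exc:
            raise MalformedRowError(f"{path}, line {line}: {exc}") from exc
    return obs


def write_centerline(spine: SpineCenterline, path: str | Path) -> None:
    """Write x,y,z (mm) rows, or JSON when the suffix is .json."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {"voxel_size_mm": spine.voxel_size_mm,
                   "points_mm": spine.points.tolist()}
        path.write_text(json.dumps(payload))
        return
    with path.open("w", newline="") as fh:
        fh.write("x_mm,y_mm,z_mm\n")
        for x, y, z in spine.points:
            fh.write(f"{float(x)!r},{float(y)!r},{float(z)!r}\n")


def read_centerline(path: str | Path, voxel_size_mm: float = 0.035) -> SpineCenterline:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return SpineCenterline(
            points=np.asarray(payload["points_mm"], dtype=float),
            voxel_size_mm=float(payload.get("voxel_size_mm", voxel_size_mm)),
        )
    df = pd.read_csv(path)
    if list(df.columns[:3]) != ["x_mm", "y_mm", "z_mm"]:
        raise MalformedRowError(f"{path}: expected columns x_mm,y_mm,z_mm")
    return SpineCenterline(points=df.to_numpy(dtype=float),
                           voxel_size_mm=voxel_size_mm)


def read_scan_log(path: str | Path, scan_id: str | None = None) -> ScanLog:
    """Parse an INI-like key=value log file; '#' starts a comment."""
    path = Path(path)
    values: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise MalformedRowError(f"{path}, line {lineno}: expected key=value")
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    return ScanLog(values=values, scan_id=scan_id or path.stem)
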