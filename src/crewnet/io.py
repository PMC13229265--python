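"""Readers, writers and validation for contact streams, rosters and windows.

Canonical on-disk formats (all UTF-8 delimited text):

* ``contacts.tsv`` — columns ``t i j``: one active-contact row per 10-s slot,
  SocioPatterns convention. A row asserts contact during ``[t, t+resolution)``.
* ``roster.csv`` — ``sensor_id,kind,group,room_category,first_day,last_day``.
* ``windows.csv`` — ``label,start_day,end_day`` (half-open day spans).
* ``responses.csv`` — long format ``person_id,wave,scale_id,item_index,response``.

Times are integer seconds since the study epoch; days are integer day indices
since the same epoch. Intervals are half-open ``[t, t+duration)`` and deployment
windows are half-open ``[start_day, end_day)`` so that boundary contacts are
never double counted. Presence windows on the roster are inclusive day spans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sensor temporal resolution in seconds
RESOLUTION = 10
SECONDS_PER_DAY = 86_400
#: deployment labels, mission months 1, 3, 6 and 9
WAVES = ("M1", "M3", "M6", "M9")

CONTACT_COLUMNS = ("t", "i", "j")
ROSTER_COLUMNS = ("sensor_id", "kind", "group", "room_category", "first_day", "last_day")


class ContactParseError(ValueError):
    """Malformed row in a contact file; the message names the line."""


@dataclass(frozen=True, order=True)
class DeploymentWindow:
    """A sensor-wearing period: half-open span ``[start_day, end_day)``."""

    label: str
    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.end_day <= self.start_day:
            raise ValueError(f"window {self.label}: end_day must exceed start_day")

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day

    @property
    def days(self) -> range:
        return range(self.start_day, self.end_day)


def canonicalize_contacts(df: pd.DataFrame, resolution: int = RESOLUTION) -> pd.DataFrame:
    """Order each pair (i < j), attach durations and sort by time."""
    df = df.copy()
    i = df["i"].astype(str)
    j = df["j"].astype(str)
    swap = i > j
    df["i"] = i.where(~swap, j)
    df["j"] = j.where(~swap, i)
    if "duration" not in df.columns:
        df["duration"] = resolution
    df = df.sort_values(["t", "i", "j"], kind="mergesort").reset_index(drop=True)
    return df


def read_contacts(
    path: str | Path,
    resolution: int = RESOLUTION,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a contact stream into a canonical frame ``(t, i, j, duration)``.

    ``column_map`` maps the file's column names onto ``t``/``i``/``j`` for
    deposits whose headers differ from the SocioPatterns convention.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        logger.warning("contact file %s is empty", path)
        return pd.DataFrame(columns=[*CONTACT_COLUMNS, "duration"])
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in CONTACT_COLUMNS if c not in df.columns]
    if missing:
        raise ContactParseError(f"{path}: missing columns {missing}")
    if df.empty:
        logger.warning("contact file %s has a header but no rows", path)
        return pd.DataFrame(columns=[*CONTACT_COLUMNS, "duration"])

    t = pd.to_numeric(df["t"], errors="coerce")
    bad = t.isna()
    if bad.any():
        # +2: header line and 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ContactParseError(f"{path}: non-numeric timestamp at line {line}")
    if (t < 0).any():
        line = int(np.flatnonzero((t < 0).to_numpy())[0]) + 2
        raise ValueError(f"{path}: negative timestamp at line {line}")
    df["t"] = t.astype(np.int64)
    if (df["i"].astype(str) == df["j"].astype(str)).any():
        raise ValueError(f"{path}: self-contact rows (i == j) are invalid")
    return canonicalize_contacts(df[list(CONTACT_COLUMNS)], resolution=resolution)


def write_contacts(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df[list(CONTACT_COLUMNS)].to_csv(path, sep=sep, index=False)


def read_roster(path: str | Path) -> pd.DataFrame:
    """Read and validate a sensor roster; index is ``sensor_id``."""
    df = pd.read_csv(path, dtype={"sensor_id": str})
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: roster missing columns {missing}")
    return validate_roster(df)


def validate_roster(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["sensor_id"] = df["sensor_id"].astype(str)
    if df["sensor_id"].duplicated().any():
        dupes = df.loc[df["sensor_id"].duplicated(), "sensor_id"].tolist()
        raise ValueError(f"duplicate sensor ids in roster: {dupes}")
    kinds = set(df["kind"].unique())
    if not kinds <= {"person", "room"}:
        raise ValueError(f"unknown sensor kinds: {sorted(kinds - {'person', 'room'})}")
    person = df["kind"] == "person"
    if df.loc[person, "room_category"].notna().any():
        raise ValueError("person sensors must not carry a room_category")
    if df.loc[person, "group"].isna().any():
        raise ValueError("person sensors require a group label")
    if df.loc[~person, "group"].notna().any():
        raise ValueError("room sensors must not carry a group label")
    if df.loc[~person, "room_category"].isna().any():
        raise ValueError("room sensors require a room_category")
    bad_cat = set(df.loc[~person, "room_category"].unique()) - {"shared", "accommodation"}
    if bad_cat:
        raise ValueError(f"unknown room categories: {sorted(bad_cat)}")
    df["first_day"] = df["first_day"].astype(int)
    df["last_day"] = df["last_day"].astype(int)
    if (df["last_day"] < df["first_day"]).any():
        raise ValueError("roster presence windows must be non-empty")
    out = df.set_index("sensor_id")
    logger.info("roster: %s", roster_counts(out))
    return out


def roster_counts(roster: pd.DataFrame) -> dict:
    by_kind = roster["kind"].value_counts().to_dict()
    by_group = roster.loc[roster["kind"] == "person", "group"].value_counts().to_dict()
    return {"by_kind": by_kind, "by_group": by_group}


def write_roster(roster: pd.DataFrame, path: str | Path) -> None:
    roster.reset_index()[list(ROSTER_COLUMNS)].to_csv(path, index=False)


def read_windows(path: str | Path) -> list[DeploymentWindow]:
    df = pd.read_csv(path)
    windows = [
        DeploymentWindow(str(r.label), int(r.start_day), int(r.end_day))
        for r in df.itertuples()
    ]
    return validate_windows(windows)


def validate_windows(windows: Sequence[DeploymentWindow]) -> list[DeploymentWindow]:
    ordered = sorted(windows, key=lambda w: w.start_day)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_day < a.end_day:
            raise ValueError(f"windows {a.label} and {b.label} overlap")
    return list(ordered)


def write_windows(windows: Iterable[DeploymentWindow], path: str | Path) -> None:
    pd.DataFrame(
        [(w.label, w.start_day, w.end_day) for w in windows],
        columns=["label", "start_day", "end_day"],
    ).to_csv(path, index=False)


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read long-format questionnaire responses.

    Item-level files carry ``item_index`` + ``response``; scale-level files
    (already-scored deposits) may instead carry a ``score`` column and bypass
    item scoring downstream.
    """
    df = pd.read_csv(path, dtype={"person_id": str, "wave": str, "scale_id": str})
    required = {"person_id", "wave", "scale_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: responses need columns {sorted(required)}")
    if "response" in df.columns and "item_index" in df.columns:
        key = ["person_id", "wave", "scale_id", "item_index"]
        if df.duplicated(subset=key).any():
            raise ValueError(f"{path}: duplicate (person, wave, scale, item) rows")
    return df


def write_responses(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def day_of(t: np.ndarray | int, day_start_hour: int = 0) -> np.ndarray | int:
    """Map epoch seconds to station-local day indices.

    The day boundary is configurable because per-day summaries depend on it;
    the default is midnight station time.
    """
    return (np.asarray(t) - day_start_hour * 3600) // SECONDS_PER_DAY


def present_mask(roster: pd.DataFrame, sensor: pd.Series, day: np.ndarray) -> np.ndarray:
    first = roster["first_day"].reindex(sensor).to_numpy()
    last = roster["last_day"].reindex(sensor).to_numpy()
    return (day >= first) & (day <= last)


def filter_window(
    contacts: pd.DataFrame,
    window: DeploymentWindow,
    roster: pd.DataFrame,
    day_start_hour: int = 0,
) -> pd.DataFrame:
    """Restrict contacts to a deployment window and to sensors present that day.

    A contact is kept when its start time falls inside the half-open window and
    both sensors' roster presence spans cover the contact's calendar day (so
    evacuated or not-yet-arrived members contribute nothing).
    """
    day = day_of(contacts["t"].to_numpy(), day_start_hour)
    in_window = (day >= window.start_day) & (day < window.end_day)
    if not in_window.any():
        logger.warning("window %s contains no contacts", window.label)
    known = contacts["i"].isin(roster.index) & contacts["j"].isin(roster.index)
    if not known.all():
        unknown = sorted(
            (set(contacts.loc[~known, "i"]) | set(contacts.loc[~known, "j"]))
            - set(roster.index)
        )
        logger.warning("dropping contacts with sensors missing from roster: %s", unknown)
    keep = in_window & known.to_numpy()
    sub = contacts.loc[keep]
    day = day[keep]
    ok = present_mask(roster, sub["i"], day) & present_mask(roster, sub["j"], day)
    return sub.loc[ok].reset_index(drop=True)


def validate_dataset(
    contacts: pd.DataFrame,
    roster: pd.DataFrame,
    windows: Sequence[DeploymentWindow],
) -> dict:
    """Cross-check the three inputs; returns a summary report."""
    validate_windows(windows)
    sensors = set(contacts["i"]) | set(contacts["j"])
    unknown = sorted(sensors - set(roster.index))
    if unknown:
        logger.warning("contacts reference sensors missing from roster: %s", unknown)
    in_any = np.zeros(len(contacts), dtype=bool)
    day = day_of(contacts["t"].to_numpy())
    for w in windows:
        in_any |= (day >= w.start_day) & (day < w.end_day)
    return {
        "n_contacts": int(len(contacts)),
        "n_sensors_seen": len(sensors),
        "unknown_sensors": unknown,
        "n_contacts_outside_windows": int((~in_any).sum()),
        "roster": roster_counts(roster),
        "windows": [w.label for w in windows],
    }
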