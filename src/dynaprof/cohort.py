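"""Cohort containers and CSV I/O for clinical and CSF-mediator data.

A cohort couples one clinical/demographic record per patient (age, sex,
injury characteristics, initial Glasgow Coma Scale score, 6/12-month
Glasgow Outcome Scale scores) with per-patient time series of 13 CSF
inflammatory mediators sampled at irregular times post-injury.

Two plain-CSV dialects are supported:

* clinical table — one row per patient, columns ``id, age, sex, infection,
  bleeding, surgical_decompression, subarachnoid_hemorrhage, gcs, gos6,
  gos12`` plus free extra covariate columns; boolean columns accept 0/1.
* mediator table (long format) — columns ``patient_id, mediator,
  time_hours, concentration_pg_ml``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

#: The fixed 13-mediator CSF panel (ASCII spellings; "a"/"b" stand for α/β).
MEDIATOR_PANEL: tuple[str, ...] = (
    "IL1a", "IL1b", "IL2", "IL4", "IL5", "IL6", "IL8",
    "IL10", "IL13", "MIP1a", "MIP1b", "TNFa", "VEGF",
)

CLINICAL_FLAGS: tuple[str, ...] = (
    "infection", "bleeding", "surgical_decompression", "subarachnoid_hemorrhage",
)

_REQUIRED_CLINICAL_COLUMNS = (
    "id", "age", "sex", *CLINICAL_FLAGS, "gcs", "gos6", "gos12",
)
_MEDIATOR_COLUMNS = ("patient_id", "mediator", "time_hours", "concentration_pg_ml")


@dataclass
class ClinicalProfile:
    """One-dimensional clinical/demographic variables for a patient.

    ``gcs`` is the initial Glasgow Coma Scale score (3 = deep coma,
    15 = fully alert); severe TBI cohorts cluster at the low end.
    """

    age: float
    sex: str  # "male" | "female"
    infection: bool
    bleeding: bool
    surgical_decompression: bool
    subarachnoid_hemorrhage: bool
    gcs: int
    extra_covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not 3 <= int(self.gcs) <= 15:
            raise ValueError(f"GCS must lie in [3, 15], got {self.gcs}")
        self.gcs = int(self.gcs)


@dataclass
class MediatorSeries:
    """Concentration time series (pg/mL) of one mediator for one patient.

    ``rounds`` carries the reading-round index of each sample once
    :func:`assign_rounds` has run; until then it is ``None``.
    """

    mediator: str
    times: np.ndarray
    values: np.ndarray
    rounds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"times for {self.mediator} must be strictly increasing"
            )
        if np.any(self.values < 0):
            raise ValueError(f"negative concentration in {self.mediator} series")
        if self.rounds is not None:
            self.rounds = np.asarray(self.rounds, dtype=int)

    def __len__(self) -> int:
        return int(self.times.size)

    def values_up_to_round(self, up_to: int | None) -> np.ndarray:
        """Values with round index <= ``up_to`` (all values when ``None``)."""
        if up_to is None or self.rounds is None:
            return self.values
        return self.values[self.rounds <= up_to]

    def value_at_round(self, i: int) -> float | None:
        """Concentration recorded in round ``i``, or ``None`` if missing."""
        if self.rounds is None:
            return None
        hit = np.flatnonzero(self.rounds == i)
        return float(self.values[hit[0]]) if hit.size else None


@dataclass
class Patient:
    id: str
    clinical: ClinicalProfile
    series: dict[str, MediatorSeries] = field(default_factory=dict)
    gos6: int | None = None
    gos12: int | None = None

    def __post_init__(self) -> None:
        for name, score in (("gos6", self.gos6), ("gos12", self.gos12)):
            if score is not None and not 1 <= int(score) <= 5:
                raise ValueError(f"{name} must lie in [1, 5], got {score}")

    @property
    def gos(self) -> int | None:
        """Final outcome score: the 12-month GOS, else the 6-month one."""
        return self.gos12 if self.gos12 is not None else self.gos6

    @property
    def survived(self) -> bool | None:
        return None if self.gos is None else self.gos > 1

    @property
    def n_rounds(self) -> int:
        """Highest reading-round index over all mediator series (0 if none)."""
        best = 0
        for s in self.series.values():
            if s.rounds is not None and len(s):
                best = max(best, int(s.rounds.max()))
            elif s.rounds is None:
                best = max(best, len(s))
        return best

    def has_round(self, i: int) -> bool:
        return any(
            s.rounds is not None and np.any(s.rounds == i)
            for s in self.series.values()
        )


@dataclass
class Cohort:
    patients: list[Patient] = field(default_factory=list)
    mediator_panel: tuple[str, ...] = MEDIATOR_PANEL

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dupes}")
        for p in self.patients:
            for m in self.mediator_panel:
                p.series.setdefault(m, MediatorSeries(m, [], []))

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[Patient]:
        return iter(self.patients)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.patients]

    def get(self, pid: str) -> Patient:
        for p in self.patients:
            if p.id == pid:
                return p
        raise KeyError(f"unknown patient id {pid!r}")

    def without(self, pid: str) -> "Cohort":
        """A shallow copy of the cohort with one patient removed."""
        kept = [p for p in self.patients if p.id != pid]
        if len(kept) == len(self.patients):
            raise KeyError(f"unknown patient id {pid!r}")
        return Cohort(kept, self.mediator_panel)

    @property
    def max_round(self) -> int:
        return max((p.n_rounds for p in self.patients), default=0)


# ---------------------------------------------------------------------------
# CSV readers / writers


def _parse_flag(x) -> bool:
    s = str(x).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise ValueError(f"cannot parse boolean flag from {x!r}")


def _parse_gos(x) -> int | None:
    if x is None or (isinstance(x, float) and np.isnan(x)) or str(x).strip() == "":
        return None
    try:
        return int(float(x))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"unparsable GOS value {x!r}") from exc


def read_clinical(path: str | Path, mediator_panel: tuple[str, ...] = MEDIATOR_PANEL) -> Cohort:
    """Read the clinical table into a cohort skeleton (empty mediator series)."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in _REQUIRED_CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical CSV missing required columns: {missing}")
    extra_cols = [c for c in df.columns if c not in _REQUIRED_CLINICAL_COLUMNS]
    patients = []
    for _, row in df.iterrows():
        sex = str(row["sex"]).strip().lower()
        sex = {"m": "male", "f": "female"}.get(sex, sex)
        clinical = ClinicalProfile(
            age=float(row["age"]),
            sex=sex,
            infection=_parse_flag(row["infection"]),
            bleeding=_parse_flag(row["bleeding"]),
            surgical_decompression=_parse_flag(row["surgical_decompression"]),
            subarachnoid_hemorrhage=_parse_flag(row["subarachnoid_hemorrhage"]),
            gcs=int(float(row["gcs"])),
            extra_covariates={c: float(row[c]) for c in extra_cols},
        )
        patients.append(
            Patient(
                id=str(row["id"]),
                clinical=clinical,
                gos6=_parse_gos(row["gos6"]),
                gos12=_parse_gos(row["gos12"]),
            )
        )
    return Cohort(patients, mediator_panel)


def read_mediators(path: str | Path, cohort: Cohort) -> Cohort:
    """Append long-format mediator readings to an existing cohort.

    Rows are grouped by (patient, mediator) and sorted by time before the
    series invariants (strictly increasing times, non-negative values) are
    enforced, so input row order is immaterial.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _MEDIATOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mediator CSV missing required columns: {missing}")
    known = set(cohort.ids)
    unknown = sorted(set(df["patient_id"]) - known)
    if unknown:
        raise ValueError(f"mediator readings for unknown patient ids: {unknown}")
    bad = sorted(set(df["mediator"]) - set(cohort.mediator_panel))
    if bad:
        raise ValueError(f"mediators outside the panel: {bad}")
    if (df["concentration_pg_ml"] < 0).any():
        raise ValueError("negative concentration in mediator CSV")
    for (pid, mediator), grp in df.groupby(["patient_id", "mediator"], sort=False):
        grp = grp.sort_values("time_hours")
        times = grp["time_hours"].to_numpy(dtype=float)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError(
                f"duplicate or non-increasing timestamps for ({pid}, {mediator})"
            )
        cohort.get(pid).series[mediator] = MediatorSeries(
            mediator, times, grp["concentration_pg_ml"].to_numpy(dtype=float)
        )
    return cohort


def write_clinical(cohort: Cohort, path: str | Path) -> None:
    rows = []
    for p in cohort:
        row = {
            "id": p.id,
            "age": p.clinical.age,
            "sex": p.clinical.sex,
            **{f: int(getattr(p.clinical, f)) for f in CLINICAL_FLAGS},
            "gcs": p.clinical.gcs,
            "gos6": "" if p.gos6 is None else p.gos6,
            "gos12": "" if p.gos12 is None else p.gos12,
            **p.clinical.extra_covariates,
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_mediators(cohort: Cohort, path: str | Path) -> None:
    rows = []
    for p in cohort:
        for m in cohort.mediator_panel:
            s = p.series[m]
            for t, v in zip(s.times, s.values):
                rows.append(
                    {"patient_id": p.id, "mediator": m,
                     "time_hours": t, "concentration_pg_ml": v}
                )
    pd.DataFrame(rows, columns=list(_MEDIATOR_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Reading rounds


def assign_rounds(
    cohort: Cohort, scheme: str = "ordinal", bin_width: float = 24.0
) -> Cohort:
    """Attach a reading-round index (1-based) to every mediator sample.

    ``ordinal``
        a patient's j-th available reading of each mediator is round j —
        the default, matching per-patient stage counting.
    ``time_binned``
        round = floor(time / bin_width) + 1, aligning rounds on a shared
        post-injury clock.

    Idempotent, and independent of original input row order (series are
    stored time-sorted).
    """
    if scheme not in ("ordinal", "time_binned"):
        raise ValueError(f"unknown round scheme {scheme!r}")
    if scheme == "time_binned" and bin_width <= 0:
        raise ValueError("bin_width must be positive under time_binned")
    for p in cohort:
        for s in p.series.values():
            if scheme == "ordinal":
                s.rounds = np.arange(1, len(s) + 1)
            else:
                s.rounds = np.floor(s.times / bin_width).astype(int) + 1
    return cohort
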