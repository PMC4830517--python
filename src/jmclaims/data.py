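"""Cohort data model, long-format CSV I/O and descriptive summaries.

A cohort is a list of subjects, each carrying baseline survival
covariates (sex coded man:0 / woman:1, age at study entry in years),
the observed follow-up time ``t_obs = min(T*, C)`` since entry, the
death indicator ``delta``, and an ordered series of yearly measurement
occasions.  Each occasion records the count of hospital / emergency /
ambulance claims in the preceding year together with its log1p
transform ``y = log(1 + count)``, which is the response the
longitudinal sub-model treats as Gaussian.

The on-disk representation is a single long-format CSV with columns
``id, sex, age0, T_obs, delta, t, count[, y]``; baseline columns are
repeated on every occasion row, and a subject without occasions is
stored as one row with empty ``t``/``count``.  A ``y`` column, when
present, takes precedence over the log1p of ``count`` — simulated
cohorts carry the continuous model-scale response, of which the integer
count is only a rounded view.
"""

from __future__ import annotations

import decimal
import io
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASE_COLUMNS = ("id", "sex", "age0", "T_obs", "delta")
OCCASION_COLUMNS = ("t", "count")


class CohortValidationError(ValueError):
    """Base class for all cohort validation failures."""


class MissingColumnError(CohortValidationError):
    """A required baseline or occasion column is absent."""


class NegativeCountError(CohortValidationError):
    """A claim count is negative."""


class DuplicateOccasionError(CohortValidationError):
    """Two occasion rows share the same (id, t)."""


class RecordTimeError(CohortValidationError):
    """An occasion time is negative or exceeds the follow-up time."""


class BaselineFieldError(CohortValidationError):
    """A baseline field is missing, inconsistent across rows, or invalid."""


@dataclass
class LongitudinalRecord:
    """One measurement occasion: time since entry, claim count, log1p response."""

    t: float
    count: int | None
    y: float

    @classmethod
    def from_count(cls, t: float, count: int) -> "LongitudinalRecord":
        return cls(t=float(t), count=int(count), y=float(np.log1p(count)))


@dataclass
class Subject:
    id: str
    sex: int
    age0: float
    t_obs: float
    delta: int
    records: list[LongitudinalRecord] = field(default_factory=list)

    def validate(self) -> None:
        if self.sex not in (0, 1):
            raise BaselineFieldError(f"subject {self.id}: sex must be 0 or 1")
        if not np.isfinite(self.age0) or self.age0 < 65:
            raise BaselineFieldError(
                f"subject {self.id}: age0 must be finite and >= 65, got {self.age0}"
            )
        if not np.isfinite(self.t_obs) or self.t_obs < 0:
            raise BaselineFieldError(f"subject {self.id}: T_obs must be >= 0")
        if self.delta not in (0, 1):
            raise BaselineFieldError(f"subject {self.id}: delta must be 0 or 1")
        times = np.array([r.t for r in self.records])
        if times.size > 1:
            d = np.diff(times)
            if np.any(d == 0):
                raise DuplicateOccasionError(
                    f"subject {self.id}: duplicate occasion times"
                )
            if np.any(d < 0):
                raise RecordTimeError(
                    f"subject {self.id}: occasion times must be strictly increasing"
                )
        for r in self.records:
            if r.t < 0 or r.t > self.t_obs + 1e-12:
                raise RecordTimeError(
                    f"subject {self.id}: occasion time {r.t} outside [0, T_obs={self.t_obs}]"
                )
            if r.count is not None and r.count < 0:
                raise NegativeCountError(
                    f"subject {self.id}: negative claim count {r.count}"
                )


@dataclass
class Cohort:
    subjects: list[Subject]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subjects)

    def validate(self) -> None:
        if not self.subjects:
            raise CohortValidationError("cohort is empty")
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise DuplicateOccasionError("duplicate subject ids in cohort")
        for s in self.subjects:
            s.validate()

    @property
    def n_events(self) -> int:
        return sum(s.delta for s in self.subjects)


def read_cohort(path, layout: dict[str, str] | None = None) -> Cohort:
    """Read a long-format panel CSV into a validated :class:`Cohort`.

    ``layout`` optionally maps canonical column names (``id``, ``sex``,
    ``age0``, ``T_obs``, ``delta``, ``t``, ``count``, ``y``) to the
    actual names used in the file.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if layout:
        df = df.rename(columns={v: k for k, v in layout.items()})
    missing = [c for c in BASE_COLUMNS + OCCASION_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"missing required columns: {missing}")
    has_y = "y" in df.columns
    if df[list(BASE_COLUMNS)].isna().any().any():
        bad = df.index[df[list(BASE_COLUMNS)].isna().any(axis=1)][0]
        raise BaselineFieldError(f"missing baseline field in row {bad}")

    subjects: list[Subject] = []
    for sid, grp in df.groupby("id", sort=False):
        base = grp.iloc[0]
        for col in ("sex", "age0", "T_obs", "delta"):
            if grp[col].nunique() > 1:
                raise BaselineFieldError(
                    f"subject {sid}: baseline column {col!r} varies across rows"
                )
        occ = grp.dropna(subset=["t"]).sort_values("t")
        if occ["t"].duplicated().any():
            t_dup = occ.loc[occ["t"].duplicated(), "t"].iloc[0]
            raise DuplicateOccasionError(f"subject {sid}: duplicate occasion t={t_dup}")
        records = []
        for idx, row in occ.iterrows():
            cnt = row["count"]
            if pd.isna(cnt):
                cnt = None
            else:
                if cnt < 0:
                    raise NegativeCountError(
                        f"row {idx} (subject {sid}): negative count {cnt}"
                    )
                cnt = int(cnt)
            if has_y and not pd.isna(row["y"]):
                y = float(row["y"])
            elif cnt is not None:
                y = float(np.log1p(cnt))
            else:
                raise MissingColumnError(
                    f"row {idx} (subject {sid}): neither count nor y present"
                )
            records.append(LongitudinalRecord(t=float(row["t"]), count=cnt, y=y))
        subjects.append(
            Subject(
                id=str(sid),
                sex=int(base["sex"]),
                age0=float(base["age0"]),
                t_obs=float(base["T_obs"]),
                delta=int(base["delta"]),
                records=records,
            )
        )
    cohort = Cohort(subjects=subjects, meta={"source": str(path)})
    cohort.validate()
    logger.info("read cohort: %d subjects, %d events", len(cohort), cohort.n_events)
    return cohort


def cohort_frame(cohort: Cohort) -> pd.DataFrame:
    """Long-format DataFrame view (one row per occasion, baseline repeated)."""
    rows = []
    for s in cohort.subjects:
        base = dict(id=s.id, sex=s.sex, age0=s.age0, T_obs=s.t_obs, delta=s.delta)
        if not s.records:
            rows.append({**base, "t": np.nan, "count": np.nan, "y": np.nan})
        for r in s.records:
            rows.append(
                {**base, "t": r.t, "count": np.nan if r.count is None else r.count, "y": r.y}
            )
    df = pd.DataFrame(rows)
    df["count"] = df["count"].astype("Int64")
    return df


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as long-format CSV, re-readable bit-compatibly.

    Floats are written with shortest round-trip representation, so a
    ``write_cohort`` -> :func:`read_cohort` cycle is the identity on
    valid cohorts.
    """
    cohort.validate()
    df = cohort_frame(cohort)
    # shortest round-trip decimal representation for every float column
    for col in ("age0", "T_obs", "t", "y"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, as used in printed summary tables."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def cohort_summary(
    cohort: Cohort, age_breaks: Sequence[float] = (65.0, 75.0, 85.0, np.inf)
) -> pd.DataFrame:
    """Stratified counts, row percentages and percent death rates.

    One output row per (gender group x age-at-entry stratum), with
    gender groups ``all`` / ``man`` / ``woman`` and an ``overall``
    stratum per group.  ``death_rate`` is 100 * deaths / subjects, NaN
    for an empty stratum.  Values are exact; apply
    :func:`round_half_up` for table-style presentation.
    """
    breaks = list(age_breaks)
    if any(np.diff(breaks) <= 0):
        raise ValueError("age_breaks must be strictly increasing")
    df = pd.DataFrame(
        {
            "sex": [s.sex for s in cohort.subjects],
            "age0": [s.age0 for s in cohort.subjects],
            "delta": [s.delta for s in cohort.subjects],
        }
    )
    labels = []
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        labels.append(f">={lo:g}" if np.isinf(hi) else f"[{lo:g},{hi:g})")
    df["stratum"] = pd.cut(df["age0"], bins=breaks, labels=labels, right=False)

    rows = []
    groups = {"all": df, "man": df[df.sex == 0], "woman": df[df.sex == 1]}
    for gname, g in groups.items():
        n_tot = len(g)
        d_tot = int(g["delta"].sum())
        for strat in labels + ["overall"]:
            sub = g if strat == "overall" else g[g.stratum == strat]
            n = len(sub)
            d = int(sub["delta"].sum())
            rows.append(
                {
                    "gender": gname,
                    "stratum": strat,
                    "subjects": n,
                    "pct_subjects": 100.0 * n / n_tot if n_tot else np.nan,
                    "deaths": d,
                    "pct_deaths": 100.0 * d / d_tot if d_tot else np.nan,
                    "death_rate": 100.0 * d / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)
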