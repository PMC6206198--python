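"""Containers, validation and delimited-text I/O for age-structured banding data.

The data model mirrors standard band-recovery bookkeeping: each banded cohort
(birds newly marked in year ``t`` at a known age class) is followed through
subsequent hunting/recovery occasions, and dead recoveries are tabulated into
an m-array whose rows are cohorts and whose columns are recovery occasions.
Live recaptures during the *initial* banding season are kept separate from the
recovery matrix: they inform capture probability (and hence the relative
vulnerability of juveniles to capture), not survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

AgeClass = Literal["juvenile", "adult"]
EventType = Literal["banding", "same-season-recapture", "dead-recovery"]

AGE_CLASSES = ("juvenile", "adult")
EVENTS = ("banding", "same-season-recapture", "dead-recovery")


class DataError(ValueError):
    """Raised for structurally invalid banding data."""


@dataclass(frozen=True)
class Finding:
    """A machine-readable validation finding (non-fatal)."""

    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


@dataclass(frozen=True)
class EncounterRecord:
    """One capture/recovery event for one marked individual."""

    individual_id: str
    banding_year: int
    age_at_banding: AgeClass
    event: EventType
    event_year: int

    def __post_init__(self) -> None:
        if self.age_at_banding not in AGE_CLASSES:
            raise DataError(f"unknown age class {self.age_at_banding!r}")
        if self.event not in EVENTS:
            raise DataError(f"unknown event type {self.event!r}")
        if self.event_year < self.banding_year:
            raise DataError(
                f"individual {self.individual_id}: event year {self.event_year} "
                f"precedes banding year {self.banding_year}"
            )
        if self.event == "banding" and self.event_year != self.banding_year:
            raise DataError(
                f"individual {self.individual_id}: banding event year must equal banding year"
            )


@dataclass
class MArray:
    """Cohort-by-occasion dead-recovery table for one age class.

    Rows are banding cohorts (years ``cohort_years``), columns are recovery
    occasions labelled by the calendar year in which the recovery season
    begins.  ``recoveries[t, k]`` counts members of cohort ``t`` first (and
    only) reported dead in occasion ``k``; the never-recovered birds form the
    implicit final multinomial cell.
    """

    age_class: AgeClass
    cohort_years: np.ndarray
    releases: np.ndarray
    recoveries: np.ndarray
    occasion_years: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cohort_years = np.asarray(self.cohort_years, dtype=int)
        self.releases = np.asarray(self.releases, dtype=int)
        self.recoveries = np.asarray(self.recoveries, dtype=int)
        if self.occasion_years is None:
            self.occasion_years = self.cohort_years.copy()
        else:
            self.occasion_years = np.asarray(self.occasion_years, dtype=int)
        self.validate()

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_years)

    @property
    def n_occasions(self) -> int:
        return self.recoveries.shape[1]

    @property
    def never_recovered(self) -> np.ndarray:
        return self.releases - self.recoveries.sum(axis=1)

    def validate(self) -> None:
        if self.age_class not in AGE_CLASSES:
            raise DataError(f"unknown age class {self.age_class!r}")
        if self.recoveries.shape != (len(self.cohort_years), len(self.occasion_years)):
            raise DataError(
                f"recovery matrix shape {self.recoveries.shape} does not match "
                f"{len(self.cohort_years)} cohorts x {len(self.occasion_years)} occasions"
            )
        if len(self.releases) != len(self.cohort_years):
            raise DataError("releases length does not match number of cohorts")
        if (self.releases < 0).any() or (self.recoveries < 0).any():
            raise DataError("negative counts in m-array")
        row_sums = self.recoveries.sum(axis=1)
        bad = np.nonzero(row_sums > self.releases)[0]
        if bad.size:
            t = bad[0]
            raise DataError(
                f"cohort {self.cohort_years[t]}: {row_sums[t]} recoveries exceed "
                f"{self.releases[t]} releases"
            )
        # recoveries cannot precede banding
        for t, yr in enumerate(self.cohort_years):
            pre = self.occasion_years < yr
            if self.recoveries[t, pre].any():
                raise DataError(
                    f"cohort {yr}: recovery recorded before banding occasion"
                )

    def total_recoveries(self) -> int:
        return int(self.recoveries.sum())


@dataclass
class CollapsedMArray:
    """Dead recoveries indexed by years since banding (lag 1 = banding season).

    ``lag_recoveries[d-1]`` pools recoveries at lag ``d`` over all cohorts.
    When built by :func:`collapse_marray` the per-cohort lag rows are retained
    in ``lag_matrix`` so the likelihood can use exact per-cohort horizons;
    files carry only the pooled counts.
    """

    age_class: AgeClass
    cohort_years: np.ndarray
    releases: np.ndarray
    lag_recoveries: np.ndarray
    lag_matrix: np.ndarray | None = None
    horizons: np.ndarray | None = None  # max observable lag per cohort

    def __post_init__(self) -> None:
        self.cohort_years = np.asarray(self.cohort_years, dtype=int)
        self.releases = np.asarray(self.releases, dtype=int)
        self.lag_recoveries = np.asarray(self.lag_recoveries, dtype=int)
        if self.lag_matrix is not None:
            self.lag_matrix = np.asarray(self.lag_matrix, dtype=int)
        if self.horizons is None:
            # assume a square study: cohort t of T observes lags 1..T-t
            T = len(self.cohort_years)
            self.horizons = np.arange(T, 0, -1)
        else:
            self.horizons = np.asarray(self.horizons, dtype=int)
        self.validate()

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_years)

    @property
    def max_lag(self) -> int:
        return len(self.lag_recoveries)

    def validate(self) -> None:
        if self.age_class not in AGE_CLASSES:
            raise DataError(f"unknown age class {self.age_class!r}")
        if (self.releases < 0).any() or (self.lag_recoveries < 0).any():
            raise DataError("negative counts in collapsed m-array")
        if len(self.horizons) != self.n_cohorts:
            raise DataError("horizons length does not match number of cohorts")
        if self.max_lag > int(self.horizons.max()):
            raise DataError(
                f"max lag {self.max_lag} exceeds longest cohort horizon "
                f"{int(self.horizons.max())}"
            )
        if self.lag_recoveries.sum() > self.releases.sum():
            raise DataError("total recoveries exceed total releases")
        if self.lag_matrix is not None:
            if self.lag_matrix.shape != (self.n_cohorts, self.max_lag):
                raise DataError("lag matrix shape mismatch")
            if (self.lag_matrix < 0).any():
                raise DataError("negative counts in lag matrix")
            if not np.array_equal(self.lag_matrix.sum(axis=0), self.lag_recoveries):
                raise DataError("lag matrix does not sum to pooled lag counts")
            if (self.lag_matrix.sum(axis=1) > self.releases).any():
                raise DataError("per-cohort recoveries exceed releases")

    def total_recoveries(self) -> int:
        return int(self.lag_recoveries.sum())


@dataclass
class RecaptureSummary:
    """Within-season recapture counts per age class.

    ``M`` birds newly banded, of which ``f1`` were handled exactly once and
    ``f2`` at least twice during the initial season (``M = f1 + f2``).
    """

    M_j: int
    f1_j: int
    f2_j: int
    M_a: int
    f1_a: int
    f2_a: int

    def __post_init__(self) -> None:
        for name in ("M_j", "f1_j", "f2_j", "M_a", "f1_a", "f2_a"):
            if getattr(self, name) < 0:
                raise DataError(f"negative recapture count {name}")
        if self.M_j != self.f1_j + self.f2_j or self.M_a != self.f1_a + self.f2_a:
            raise DataError("recapture identity M = f1 + f2 violated")

    @classmethod
    def from_counts(cls, M_j: int, f2_j: int, M_a: int, f2_a: int) -> "RecaptureSummary":
        """Build from banding totals and twice-captured counts (f1 = M - f2)."""
        return cls(M_j, M_j - f2_j, f2_j, M_a, M_a - f2_a, f2_a)


@dataclass
class BandingDataset:
    """Joint container for the model's three data streams.

    Any component may be absent: a fit uses whichever likelihood components
    its data support (dead-recovery multinomials, within-season recapture
    binomials, age-composition binomial).
    """

    juvenile: MArray | CollapsedMArray | None = None
    adult: MArray | CollapsedMArray | None = None
    recaptures: RecaptureSummary | None = None
    label: str = ""

    @property
    def banding_totals(self) -> tuple[int, int] | None:
        """(juveniles banded, adults banded) for the age-composition binomial."""
        if self.juvenile is not None and self.adult is not None:
            return int(self.juvenile.releases.sum()), int(self.adult.releases.sum())
        if self.recaptures is not None:
            return self.recaptures.M_j, self.recaptures.M_a
        return None

    @property
    def n_occasions(self) -> int:
        for arr in (self.juvenile, self.adult):
            if isinstance(arr, MArray):
                return arr.n_occasions
            if isinstance(arr, CollapsedMArray):
                return arr.n_cohorts
        return 1


# ---------------------------------------------------------------------------
# construction from encounter records


def _check_records(records: Sequence[EncounterRecord]) -> dict[str, EncounterRecord]:
    bandings: dict[str, EncounterRecord] = {}
    for rec in records:
        if rec.event == "banding":
            if rec.individual_id in bandings:
                raise DataError(f"duplicate banding for individual {rec.individual_id}")
            bandings[rec.individual_id] = rec
    for rec in records:
        if rec.event != "banding":
            band = bandings.get(rec.individual_id)
            if band is None:
                raise DataError(
                    f"{rec.event} for unbanded individual {rec.individual_id}"
                )
            if rec.event_year < band.banding_year:
                raise DataError(
                    f"individual {rec.individual_id}: recovery in {rec.event_year} "
                    f"precedes banding in {band.banding_year}"
                )
    return bandings


def build_marray(
    records: Sequence[EncounterRecord],
    age_class: AgeClass,
    year_range: tuple[int, int],
) -> MArray:
    """Tabulate encounter records into a cohort-by-occasion m-array.

    Same-season live recaptures are deliberately excluded here; use
    :func:`build_recapture_summary` for those.  Dead recoveries outside
    ``year_range`` are rejected.
    """
    bandings = _check_records(records)
    y0, y1 = year_range
    years = np.arange(y0, y1 + 1)
    T = len(years)
    releases = np.zeros(T, dtype=int)
    m = np.zeros((T, T), dtype=int)
    for rec in bandings.values():
        if rec.age_at_banding != age_class:
            continue
        if not (y0 <= rec.banding_year <= y1):
            raise DataError(
                f"individual {rec.individual_id} banded in {rec.banding_year}, "
                f"outside year range {year_range}"
            )
        releases[rec.banding_year - y0] += 1
    for rec in records:
        if rec.event != "dead-recovery":
            continue
        band = bandings[rec.individual_id]
        if band.age_at_banding != age_class:
            continue
        if not (y0 <= rec.event_year <= y1):
            raise DataError(
                f"dead recovery of {rec.individual_id} in {rec.event_year} "
                f"outside year range {year_range}"
            )
        m[band.banding_year - y0, rec.event_year - y0] += 1
    return MArray(age_class, years, releases, m)


def build_recapture_summary(
    records: Sequence[EncounterRecord],
) -> tuple[RecaptureSummary, list[Finding]]:
    """Tally banded individuals by number of same-season captures.

    An individual handled three or more times within the season is folded
    into the twice-captured class (the estimator conditions on 1 vs 2
    captures only) and flagged with a ``triple-capture`` finding.
    """
    bandings = _check_records(records)
    n_caps = {iid: 1 for iid in bandings}
    findings: list[Finding] = []
    for rec in records:
        if rec.event == "same-season-recapture":
            if rec.event_year != bandings[rec.individual_id].banding_year:
                findings.append(
                    Finding(
                        "closure-violated",
                        f"individual {rec.individual_id} recaptured in "
                        f"{rec.event_year}, banded in "
                        f"{bandings[rec.individual_id].banding_year}",
                    )
                )
                continue
            n_caps[rec.individual_id] += 1
    counts = {"juvenile": [0, 0], "adult": [0, 0]}  # [f1, f2]
    for iid, n in n_caps.items():
        age = bandings[iid].age_at_banding
        if n >= 3:
            findings.append(
                Finding("triple-capture", f"individual {iid} captured {n} times; folded into f2")
            )
        counts[age][0 if n == 1 else 1] += 1
    f1j, f2j = counts["juvenile"]
    f1a, f2a = counts["adult"]
    rs = RecaptureSummary(f1j + f2j, f1j, f2j, f1a + f2a, f1a, f2a)
    return rs, findings


def build_dataset(
    records: Sequence[EncounterRecord],
    year_range: tuple[int, int],
    label: str = "",
) -> BandingDataset:
    """Build the full joint dataset (two m-arrays + recapture summary)."""
    rs, _ = build_recapture_summary(records)
    return BandingDataset(
        juvenile=build_marray(records, "juvenile", year_range),
        adult=build_marray(records, "adult", year_range),
        recaptures=rs,
        label=label,
    )


def collapse_marray(m: MArray) -> CollapsedMArray:
    """Re-index an m-array by years since banding (lag 1 = banding-year season).

    Preserves releases per cohort and total recoveries; retains the per-cohort
    lag rows so the collapsed likelihood can respect each cohort's own horizon.
    """
    T, K = m.recoveries.shape
    # map occasion years to lag relative to each cohort year; keep all lags
    # up to the longest observable one (trailing zeros included)
    D = int(m.occasion_years.max() - m.cohort_years.min()) + 1
    lag_rows = np.zeros((T, D), dtype=int)
    for t in range(T):
        for k in range(K):
            if m.recoveries[t, k] == 0:
                continue
            lag = int(m.occasion_years[k] - m.cohort_years[t]) + 1
            lag_rows[t, lag - 1] += m.recoveries[t, k]
    horizons = m.occasion_years.max() - m.cohort_years + 1
    return CollapsedMArray(
        age_class=m.age_class,
        cohort_years=m.cohort_years,
        releases=m.releases,
        lag_recoveries=lag_rows.sum(axis=0),
        lag_matrix=lag_rows,
        horizons=horizons,
    )


# ---------------------------------------------------------------------------
# file I/O (delimited text)


def write_marray(m: MArray | CollapsedMArray, path) -> None:
    """Write an m-array as CSV (occasion columns ``rec_<year>``, or ``lag_<d>``)."""
    if isinstance(m, MArray):
        cols = {"cohort_year": m.cohort_years, "releases": m.releases}
        for k, yr in enumerate(m.occasion_years):
            cols[f"rec_{yr}"] = m.recoveries[:, k]
    else:
        cols = {"cohort_year": m.cohort_years, "releases": m.releases}
        if m.lag_matrix is not None:
            for d in range(m.max_lag):
                cols[f"lag_{d + 1}"] = m.lag_matrix[:, d]
        else:
            pooled = np.zeros((m.n_cohorts, m.max_lag), dtype=int)
            pooled[0] = m.lag_recoveries
            for d in range(m.max_lag):
                cols[f"lag_{d + 1}"] = pooled[:, d]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_marray(path, age_class: AgeClass, dialect: str = "occasion") -> MArray | CollapsedMArray:
    """Read an m-array CSV.

    ``dialect="occasion"`` expects ``cohort_year,releases,rec_<y>...`` columns;
    ``dialect="lag"`` expects ``cohort_year,releases,lag_<d>...`` and returns a
    :class:`CollapsedMArray`.  Parse errors name the offending cohort row.
    """
    df = pd.read_csv(path)
    for col in ("cohort_year", "releases"):
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    if df.isna().any().any():
        bad = int(df.index[df.isna().any(axis=1)][0]) + 2  # 1-based incl header
        raise DataError(f"{path}: ragged or missing values at line {bad}")
    prefix = "rec_" if dialect == "occasion" else "lag_"
    val_cols = [c for c in df.columns if c.startswith(prefix)]
    if not val_cols:
        raise DataError(f"{path}: no {prefix}* recovery columns found")
    counts = df[val_cols].to_numpy()
    releases = df["releases"].to_numpy()
    if (counts < 0).any() or (releases < 0).any():
        raise DataError(f"{path}: negative counts")
    row_sums = counts.sum(axis=1)
    if dialect == "occasion":
        bad = np.nonzero(row_sums > releases)[0]
        if bad.size:
            t = bad[0]
            raise DataError(
                f"{path}: cohort {df['cohort_year'].iloc[t]} (row {t + 2}): "
                f"{row_sums[t]} recoveries exceed {releases[t]} releases"
            )
        occ_years = np.array([int(c[len(prefix):]) for c in val_cols])
        return MArray(
            age_class,
            df["cohort_year"].to_numpy(),
            releases,
            counts,
            occasion_years=occ_years,
        )
    lags = [int(c[len(prefix):]) for c in val_cols]
    if lags != list(range(1, len(lags) + 1)):
        raise DataError(f"{path}: lag columns must be lag_1..lag_D contiguous")
    return CollapsedMArray(
        age_class,
        df["cohort_year"].to_numpy(),
        releases,
        counts.sum(axis=0),
        lag_matrix=counts,
    )


def write_recaptures(rs: RecaptureSummary, path) -> None:
    pd.DataFrame(
        {
            "age_class": ["juvenile", "adult"],
            "M": [rs.M_j, rs.M_a],
            "f1": [rs.f1_j, rs.f1_a],
            "f2": [rs.f2_j, rs.f2_a],
        }
    ).to_csv(path, index=False)


def read_recaptures(path) -> RecaptureSummary:
    df = pd.read_csv(path)
    for col in ("age_class", "M", "f1", "f2"):
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    rows = {r["age_class"]: r for _, r in df.iterrows()}
    try:
        j, a = rows["juvenile"], rows["adult"]
    except KeyError as exc:
        raise DataError(f"{path}: need one juvenile and one adult row") from exc
    return RecaptureSummary(
        int(j["M"]), int(j["f1"]), int(j["f2"]), int(a["M"]), int(a["f1"]), int(a["f2"])
    )


def read_encounters(path) -> list[EncounterRecord]:
    """Read individual encounter records (columns id,banding_year,age,event,event_year)."""
    df = pd.read_csv(path)
    for col in ("id", "banding_year", "age", "event", "event_year"):
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    return [
        EncounterRecord(
            str(r["id"]), int(r["banding_year"]), r["age"], r["event"], int(r["event_year"])
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# dataset-level validation


def validate_dataset(
    d: BandingDataset, records: Sequence[EncounterRecord] | None = None
) -> list[Finding]:
    """Check cross-component invariants; returns findings instead of raising."""
    findings: list[Finding] = []
    if d.recaptures is not None:
        rs = d.recaptures
        if rs.M_j != rs.f1_j + rs.f2_j or rs.M_a != rs.f1_a + rs.f2_a:  # defensive
            findings.append(Finding("recapture-identity-violated", "M != f1 + f2"))
    for arr, name in ((d.juvenile, "juvenile"), (d.adult, "adult")):
        if arr is None:
            continue
        if isinstance(arr, MArray):
            if (arr.recoveries.sum(axis=1) > arr.releases).any():
                findings.append(
                    Finding("recoveries-exceed-releases", f"{name} m-array overdrawn")
                )
        if (arr.releases < 0).any():
            findings.append(Finding("negative-count", f"{name} releases negative"))
    if d.juvenile is not None and d.adult is not None:
        if not np.array_equal(d.juvenile.cohort_years, d.adult.cohort_years):
            findings.append(
                Finding("cohort-range-mismatch", "juvenile/adult cohort years differ")
            )
    if d.recaptures is not None and d.juvenile is not None and d.adult is not None:
        mj = int(d.juvenile.releases.sum())
        ma = int(d.adult.releases.sum())
        if mj != d.recaptures.M_j or ma != d.recaptures.M_a:
            findings.append(
                Finding(
                    "releases-mismatch",
                    f"m-array totals ({mj}, {ma}) differ from recapture summary "
                    f"({d.recaptures.M_j}, {d.recaptures.M_a})",
                )
            )
    if records is not None:
        try:
            bandings = _check_records(records)
        except DataError as exc:
            findings.append(Finding("invalid-records", str(exc)))
        else:
            for rec in records:
                if (
                    rec.event == "same-season-recapture"
                    and rec.event_year != bandings[rec.individual_id].banding_year
                ):
                    findings.append(
                        Finding(
                            "closure-violated",
                            f"individual {rec.individual_id} recaptured outside "
                            "the banding season",
                        )
                    )
    return findings
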