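"""Domain types and tabular readers/writers for camera-trap SCR data.

Three delimited text formats are handled, all comma-separated UTF-8 with a
header row:

* trap file        -- ``id,x,y`` (planar metres in a projected CRS)
* capture file     -- ``individual,sex,detector,day`` (or ``date`` ISO-8601,
                      converted with a survey start date)
* track file       -- ``animal,day,x,y`` (GPS fixes)

Coordinates are planar metres throughout: the estimator needs Euclidean
distances, so reprojection from geographic coordinates is the caller's
responsibility.  Occasions are 1-based calendar days; a ``date`` column maps
to ``day = (date - survey_start).days + 1``.

On ingest, repeat detections of the same individual at the same detector on
the same day are collapsed to a single record — the standard independence
rule for camera-trap capture histories — and the number of collapsed rows is
reported.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

__all__ = [
    "Detector",
    "TrapArray",
    "DetectionRecord",
    "DetectionRecordSet",
    "Track",
    "read_traps",
    "write_traps",
    "read_captures",
    "write_captures",
    "read_tracks",
    "write_tracks",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]

_SEXES = {"male", "female", "unknown"}


def normalize_sex(value) -> str:
    """Map free-form sex labels onto {male, female, unknown}."""
    s = str(value).strip().lower()
    if s in ("m", "male"):
        return "male"
    if s in ("f", "female"):
        return "female"
    return "unknown"


@dataclass(frozen=True)
class Detector:
    """A camera station with a stable id and planar coordinates in metres."""

    id: str
    x: float
    y: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise FormatError(f"detector {self.id!r}: non-finite coordinate")


@dataclass
class TrapArray:
    """Ordered collection of detectors; order fixes history column order."""

    detectors: list[Detector]

    def __post_init__(self):
        if len(self.detectors) < 1:
            raise ParameterError("a trap array needs at least one detector")
        ids = [d.id for d in self.detectors]
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise FormatError(f"duplicate detector id {i!r}")
            seen.add(i)
        self._index = {d.id: k for k, d in enumerate(self.detectors)}

    @property
    def K(self) -> int:
        return len(self.detectors)

    @property
    def ids(self) -> list[str]:
        return [d.id for d in self.detectors]

    def coords(self) -> np.ndarray:
        """(K, 2) array of detector coordinates in metres."""
        return np.array([(d.x, d.y) for d in self.detectors], dtype=float)

    def index(self, detector_id: str) -> int:
        try:
            return self._index[detector_id]
        except KeyError:
            raise FormatError(f"unknown detector id {detector_id!r}") from None

    def __contains__(self, detector_id: str) -> bool:
        return detector_id in self._index

    def bounding_box(self) -> tuple[float, float, float, float]:
        c = self.coords()
        return (c[:, 0].min(), c[:, 1].min(), c[:, 0].max(), c[:, 1].max())


@dataclass(frozen=True)
class DetectionRecord:
    """One deduplicated individual-by-detector-by-day camera detection."""

    individual: str
    sex: str
    detector: str
    day: int

    def __post_init__(self):
        if self.sex not in _SEXES:
            object.__setattr__(self, "sex", normalize_sex(self.sex))
        if self.day < 1:
            raise ParameterError(f"day must be >= 1, got {self.day}")


@dataclass
class DetectionRecordSet:
    """Deduplicated detection records tied to a trap array and survey span.

    No two records share (individual, detector, day); duplicates are dropped
    on construction and counted in ``duplicates_removed``.
    """

    records: list[DetectionRecord]
    total_days: int
    traps: TrapArray
    duplicates_removed: int = 0

    @classmethod
    def from_records(
        cls,
        records: list[DetectionRecord],
        traps: TrapArray,
        total_days: int,
    ) -> "DetectionRecordSet":
        if total_days < 1:
            raise ParameterError("total_days must be >= 1")
        kept: list[DetectionRecord] = []
        seen: set[tuple[str, str, int]] = set()
        dropped = 0
        for r in records:
            if r.detector not in traps:
                raise FormatError(f"unknown detector id {r.detector!r}")
            if not (1 <= r.day <= total_days):
                raise ParameterError(
                    f"day {r.day} outside [1, {total_days}] for {r.individual!r}"
                )
            key = (r.individual, r.detector, r.day)
            if key in seen:
                dropped += 1
                continue
            seen.add(key)
            kept.append(r)
        return cls(kept, total_days, traps, dropped)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.individual, r.sex, r.detector, r.day) for r in self.records],
            columns=["individual", "sex", "detector", "day"],
        )


@dataclass
class Track:
    """GPS fixes for one animal, ordered by day (ties keep file order)."""

    animal: str
    fixes: list[tuple[int, float, float]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.fixes) < 1:
            raise ParameterError(f"track {self.animal!r} has no fixes")
        days = [f[0] for f in self.fixes]
        if any(b < a for a, b in zip(days, days[1:])):
            self.fixes = sorted(self.fixes, key=lambda f: f[0])

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def span_days(self) -> int:
        return self.fixes[-1][0] - self.fixes[0][0] + 1

    def xy(self) -> np.ndarray:
        return np.array([(x, y) for _, x, y in self.fixes], dtype=float)

    def days(self) -> np.ndarray:
        return np.array([d for d, _, _ in self.fixes], dtype=int)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path, required: tuple[str, ...], optional=()) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns and c not in optional]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def _as_float(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    for c in cols:
        try:
            df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
        except (ValueError, TypeError):
            raise FormatError(f"{path}: non-numeric value in column {c!r}") from None
    return df


def read_traps(path) -> TrapArray:
    """Read a trap layout file (``id,x,y``; metres) preserving row order."""
    df = _as_float(_read_table(path, ("id", "x", "y")), ["x", "y"], path)
    dets = [Detector(str(r.id), r.x, r.y) for r in df.itertuples(index=False)]
    return TrapArray(dets)


def write_traps(traps: TrapArray, path) -> None:
    pd.DataFrame(
        [(d.id, d.x, d.y) for d in traps.detectors], columns=["id", "x", "y"]
    ).to_csv(path, index=False, float_format="%.12g")


def read_captures(
    path,
    traps: TrapArray,
    total_days: int,
    start_date: str | _dt.date | None = None,
) -> DetectionRecordSet:
    """Read a capture file and apply the daily per-station dedup rule.

    Accepts either a ``day`` column (1-based integer occasions) or a ``date``
    column (ISO-8601) together with ``start_date``.
    """
    df = _read_table(path, ("individual", "sex", "detector"), optional=())
    if "day" not in df.columns:
        if "date" not in df.columns:
            raise FormatError(f"{path}: need a 'day' or 'date' column")
        if start_date is None:
            raise ParameterError("a 'date' column requires start_date")
        start = pd.Timestamp(start_date)
        df["day"] = (pd.to_datetime(df["date"]) - start).dt.days + 1
    try:
        days = pd.to_numeric(df["day"], errors="raise").astype(int)
    except (ValueError, TypeError):
        raise FormatError(f"{path}: non-integer day") from None
    records = [
        DetectionRecord(str(ind), normalize_sex(sex), str(det), int(day))
        for ind, sex, det, day in zip(
            df["individual"], df["sex"], df["detector"], days
        )
    ]
    return DetectionRecordSet.from_records(records, traps, total_days)


def write_captures(recset: DetectionRecordSet, path) -> None:
    recset.to_frame().to_csv(path, index=False)


def read_tracks(path) -> list[Track]:
    """Read GPS fixes (``animal,day,x,y``); one day-sorted Track per animal."""
    df = _read_table(path, ("animal", "day", "x", "y"))
    if df.empty:
        return []
    df = _as_float(df, ["x", "y"], path)
    df["day"] = pd.to_numeric(df["day"], errors="raise").astype(int)
    tracks = []
    for animal, grp in df.groupby("animal", sort=True):
        fixes = [(int(d), float(x), float(y)) for d, x, y in
                 zip(grp["day"], grp["x"], grp["y"])]
        tracks.append(Track(str(animal), fixes))
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    rows = [(t.animal, d, x, y) for t in tracks for d, x, y in t.fixes]
    pd.DataFrame(rows, columns=["animal", "day", "x", "y"]).to_csv(
        path, index=False, float_format="%.12g"
    )


RESULT_COLUMNS = [
    "start_day", "end_day",
    "D", "D_lo", "D_hi",
    "g0", "g0_lo", "g0_hi",
    "sigma", "sigma_lo", "sigma_hi",
    "logLik", "converged",
    "n_individuals", "n_detections", "n_spatial_recaptures",
]

# covariate columns appended after the core results for downstream analysis
RESULT_EXTRA_COLUMNS = [
    "n_male", "n_female", "det_male", "det_female",
    "mean_spatial_recaptures_per_male",
]


def write_results(obj, path) -> None:
    """Write fitted results as delimited text, one row per session.

    ``obj`` may be a ``sessions.SessionSeries``, a ``scr.ScrFit`` (single
    row), or a DataFrame already holding the result columns.  Floats are
    written with 12 significant digits so a write/read round trip preserves
    values beyond 10 significant digits.  Density units are individuals per
    km^2; sigma is in metres.
    """
    df = _results_frame(obj)
    df.to_csv(path, index=False, float_format="%.12g")


def _results_frame(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj
    if hasattr(obj, "to_frame"):  # SessionSeries
        return obj.to_frame()
    # single ScrFit
    from .scr import ScrFit  # local import to avoid a cycle

    if isinstance(obj, ScrFit):
        ci = obj.ci95
        row = {
            "start_day": 1,
            "end_day": obj.T,
            "D": obj.params.D, "D_lo": ci["D"][0], "D_hi": ci["D"][1],
            "g0": obj.params.g0, "g0_lo": ci["g0"][0], "g0_hi": ci["g0"][1],
            "sigma": obj.params.sigma,
            "sigma_lo": ci["sigma"][0], "sigma_hi": ci["sigma"][1],
            "logLik": obj.logLik, "converged": obj.converged,
            "n_individuals": obj.n, "n_detections": np.nan,
            "n_spatial_recaptures": np.nan,
        }
        return pd.DataFrame([row], columns=RESULT_COLUMNS)
    raise TypeError(f"cannot write results for {type(obj).__name__}")


def read_results(path) -> pd.DataFrame:
    """Read a results file back into a DataFrame."""
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing result column(s) {missing}")
    return df
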