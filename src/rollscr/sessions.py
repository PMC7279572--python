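"""Rolling-window sessions: summaries and batch SCR fits over a year.

A year-long (or any ``total_days``-long) record is subsampled into every
contiguous L-day window ("session"): with step 1 a 365-day record yields
365 - L + 1 sessions (276 for L = 90, 186 for L = 180).  Each session is
treated as an independent closed-population sample and fitted with identical
mask settings, producing the time series of density, g0 and sigma estimates
that reveals how stable — or not — snapshot density estimates are.

Spatial recaptures are counted as (number of distinct detectors with a
detection - 1) per individual, summed over individuals: the extra stations
beyond each animal's first, which is the information content sigma is
estimated from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError, ParameterError, PipelineError
from .io import RESULT_COLUMNS, RESULT_EXTRA_COLUMNS, DetectionRecordSet, TrapArray
from .scr import HabitatMask, ScrFit, ScrParams, build_mask, collapse_histories, fit_scr

__all__ = [
    "SessionWindow",
    "SessionSummary",
    "SessionSeries",
    "make_windows",
    "spatial_recaptures",
    "summarize_session",
    "batch_fit",
]


@dataclass(frozen=True)
class SessionWindow:
    """Inclusive 1-based day range [start_day, end_day]."""

    start_day: int
    end_day: int

    def __post_init__(self):
        if self.end_day < self.start_day or self.start_day < 1:
            raise ParameterError(f"invalid window {self}")

    @property
    def L(self) -> int:
        return self.end_day - self.start_day + 1

    def as_tuple(self) -> tuple[int, int]:
        return (self.start_day, self.end_day)


@dataclass
class SessionSummary:
    """Demographic summary of one window, counted after daily dedup."""

    window: SessionWindow
    n_male: int = 0
    n_female: int = 0
    det_male: int = 0
    det_female: int = 0
    spatial_recaptures_male: int = 0
    mean_spatial_recaptures_per_male: float = 0.0


def make_windows(total_days: int, L: int, step: int = 1) -> list[SessionWindow]:
    """All windows (d, d + L - 1) with d = 1, 1+step, ... inside total_days."""
    if not (1 <= L <= total_days):
        raise ParameterError(f"window length {L} outside [1, {total_days}]")
    if step < 1:
        raise ParameterError("step must be >= 1")
    return [
        SessionWindow(d, d + L - 1)
        for d in range(1, total_days - L + 2, step)
    ]


def _window_tuple(window) -> tuple[int, int]:
    if isinstance(window, SessionWindow):
        return window.as_tuple()
    return (int(window[0]), int(window[1]))


def spatial_recaptures(
    records: DetectionRecordSet,
    window,
    sex_filter: str = "male",
) -> tuple[int, dict[str, int]]:
    """Per-individual (distinct detectors - 1) and the session total."""
    start, end = _window_tuple(window)
    stations: dict[str, set[str]] = {}
    for r in records.records:
        if start <= r.day <= end and (sex_filter == "all" or r.sex == sex_filter):
            stations.setdefault(r.individual, set()).add(r.detector)
    per_ind = {ind: max(len(s) - 1, 0) for ind, s in stations.items()}
    return sum(per_ind.values()), per_ind


def summarize_session(records: DetectionRecordSet, window) -> SessionSummary:
    """Count individuals and detections per sex plus male spatial recaptures.

    Individuals of unknown sex are excluded from the sex-specific counts.
    """
    start, end = _window_tuple(window)
    win = SessionWindow(start, end)
    inds: dict[str, set[str]] = {"male": set(), "female": set()}
    dets = {"male": 0, "female": 0}
    for r in records.records:
        if start <= r.day <= end and r.sex in dets:
            inds[r.sex].add(r.individual)
            dets[r.sex] += 1
    total_sr, per_ind = spatial_recaptures(records, window, "male")
    n_male = len(inds["male"])
    return SessionSummary(
        window=win,
        n_male=n_male,
        n_female=len(inds["female"]),
        det_male=dets["male"],
        det_female=dets["female"],
        spatial_recaptures_male=total_sr,
        mean_spatial_recaptures_per_male=(total_sr / n_male) if n_male else 0.0,
    )


@dataclass
class SessionSeries:
    """Aligned per-session summaries and fits (None where a fit failed)."""

    windows: list[SessionWindow]
    summaries: list[SessionSummary]
    fits: list[ScrFit | None]
    failure_reasons: list[str | None]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_failed(self) -> int:
        return sum(f is None for f in self.fits)

    def density_series(self, per_100km2: bool = True) -> np.ndarray:
        """D-hat per session (NaN where the fit failed)."""
        scale = 100.0 if per_100km2 else 1.0
        return np.array(
            [f.params.D * scale if f else np.nan for f in self.fits]
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per session with results and demographic covariates."""
        rows = []
        for w, s, f, reason in zip(
            self.windows, self.summaries, self.fits, self.failure_reasons
        ):
            row = dict.fromkeys(RESULT_COLUMNS, np.nan)
            row["start_day"], row["end_day"] = w.start_day, w.end_day
            if f is not None:
                row.update(
                    D=f.params.D, D_lo=f.ci95["D"][0], D_hi=f.ci95["D"][1],
                    g0=f.params.g0, g0_lo=f.ci95["g0"][0], g0_hi=f.ci95["g0"][1],
                    sigma=f.params.sigma,
                    sigma_lo=f.ci95["sigma"][0], sigma_hi=f.ci95["sigma"][1],
                    logLik=f.logLik, converged=f.converged,
                )
            else:
                row["converged"] = False
            row["n_individuals"] = s.n_male
            row["n_detections"] = s.det_male
            row["n_spatial_recaptures"] = s.spatial_recaptures_male
            row["n_male"] = s.n_male
            row["n_female"] = s.n_female
            row["det_male"] = s.det_male
            row["det_female"] = s.det_female
            row["mean_spatial_recaptures_per_male"] = (
                s.mean_spatial_recaptures_per_male
            )
            row["failure"] = reason if reason else ""
            rows.append(row)
        cols = RESULT_COLUMNS + RESULT_EXTRA_COLUMNS + ["failure"]
        return pd.DataFrame(rows, columns=cols)


def batch_fit(
    records: DetectionRecordSet,
    traps: TrapArray,
    L: int,
    sex_filter: str = "male",
    step: int = 1,
    buffer: float = 30_000.0,
    spacing: float = 300.0,
    mask: HabitatMask | None = None,
    compute_ci: bool = True,
    warm_start: bool = True,
) -> SessionSeries:
    """Fit the SCR model independently to every rolling window.

    The habitat mask is built once from the (fixed) trap array and reused.
    Windows whose fit raises (e.g. no spatial recaptures) appear as missing
    entries carrying the error message rather than aborting the batch; with
    ``warm_start`` each fit starts from the previous window's optimum, which
    is both faster and numerically stabler for heavily overlapping windows.
    """
    if mask is None:
        mask = build_mask(traps, buffer=buffer, spacing=spacing)
    windows = make_windows(records.total_days, L, step)
    summaries, fits, reasons = [], [], []
    prev: ScrParams | None = None
    for w in windows:
        summaries.append(summarize_session(records, w))
        hist = collapse_histories(records, w.as_tuple(), sex_filter)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_scr(
                    hist, traps, mask,
                    start=prev if warm_start else None,
                    compute_ci=compute_ci,
                )
            fits.append(fit)
            reasons.append(None)
            if warm_start:
                prev = fit.params
        except EstimationError as exc:
            fits.append(None)
            reasons.append(str(exc))
    if all(f is None for f in fits):
        raise PipelineError("every session failed to fit")
    return SessionSeries(
        windows=windows,
        summaries=summaries,
        fits=fits,
        failure_reasons=reasons,
        metadata={
            "L": L,
            "step": step,
            "total_days": records.total_days,
            "sex_filter": sex_filter,
            "buffer": mask.buffer,
            "spacing": mask.spacing,
        },
    )
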