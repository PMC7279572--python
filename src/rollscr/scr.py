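"""Maximum-likelihood spatially explicit capture-recapture (SCR) core.

Closed-population SCR for proximity detectors (camera traps) with a
half-normal detection function,

    p(d) = g0 * exp(-d^2 / (2 sigma^2)),

a discretized habitat mask as the quadrature over latent activity centres,
and the full (unconditional) likelihood in which the number of detected
individuals n is Poisson:

    log L = sum_i log( D a sum_m Pr(omega_i | s_m) )
            - D a sum_m pdot(s_m)                      (log n! dropped)

with Pr(omega_i | s) = prod_k p_k(s)^{n_ik} (1 - p_k(s))^{T - n_ik} and
pdot(s) = 1 - prod_k (1 - p_k(s))^T the probability of at least one
detection during the session.  Because detection probability is constant
over occasions within a session, per-occasion binary histories collapse to
binomial counts n_ik, giving O(n K M) likelihood cost.

Estimation is on link scale (log D, logit g0, log sigma) with a Nelder-Mead
start polished by BFGS; standard errors come from a central-difference
Hessian at the optimum and 95% Wald intervals are back-transformed from the
link scale, so they respect the parameters' natural ranges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, logit, logsumexp

from .errors import EstimationError, ParameterError
from .io import DetectionRecordSet, TrapArray

__all__ = [
    "HabitatMask",
    "SessionHistories",
    "ScrParams",
    "ScrFit",
    "build_mask",
    "halfnormal_p",
    "pdot",
    "collapse_histories",
    "negloglik",
    "fit_scr",
    "density_per_100km2",
]

_LOG_TINY = -745.0  # log of the smallest positive double; floor for log p


@dataclass
class HabitatMask:
    """Regular grid of candidate activity-centre locations.

    ``points`` are cell centres of a spacing x spacing tiling of the trap
    bounding box expanded by ``buffer`` metres on every side; ``cell_area``
    is in km^2 so that D (per km^2) times cell area is a per-cell intensity.
    """

    points: np.ndarray  # (M, 2) metres
    spacing: float  # metres
    buffer: float  # metres

    @property
    def M(self) -> int:
        return len(self.points)

    @property
    def cell_area(self) -> float:
        """Cell area a in km^2 (spacing^2 / 1e6)."""
        return self.spacing**2 / 1e6


def build_mask(
    traps: TrapArray, buffer: float = 30_000.0, spacing: float = 300.0
) -> HabitatMask:
    """Tile the buffered trap bounding box with a regular point grid.

    Defaults follow common practice for wide-ranging felids: a 30 km buffer
    (several home-range radii) and 300 m spacing.
    """
    if buffer <= 0 or spacing <= 0:
        raise ParameterError("buffer and spacing must be positive")
    if spacing > buffer:
        warnings.warn(
            f"mask spacing {spacing} m exceeds buffer {buffer} m; "
            "the mask will be very coarse",
            stacklevel=2,
        )
    xmin, ymin, xmax, ymax = traps.bounding_box()
    x0, y0 = xmin - buffer, ymin - buffer
    width, height = (xmax + buffer) - x0, (ymax + buffer) - y0
    nx = math.ceil(width / spacing)
    ny = math.ceil(height / spacing)
    xs = x0 + (np.arange(nx) + 0.5) * spacing
    ys = y0 + (np.arange(ny) + 0.5) * spacing
    gx, gy = np.meshgrid(xs, ys)
    points = np.column_stack([gx.ravel(), gy.ravel()])
    return HabitatMask(points=points, spacing=float(spacing), buffer=float(buffer))


@dataclass
class SessionHistories:
    """Collapsed capture counts for one session.

    ``counts[i, k]`` is the number of distinct occasions on which individual
    ``individuals[i]`` was recorded at detector k within the session of T
    occasions.  Every row has at least one detection.
    """

    individuals: list[str]
    counts: np.ndarray  # (n, K) int
    T: int
    K: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.individuals), self.K):
            raise ParameterError("counts shape does not match individuals/K")
        if self.counts.size and (
            self.counts.min() < 0 or self.counts.max() > self.T
        ):
            raise ParameterError("counts must lie in [0, T]")
        if self.counts.size and (self.counts.sum(axis=1) < 1).any():
            raise ParameterError("every individual needs >= 1 detection")

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def n_detections(self) -> int:
        return int(self.counts.sum())

    def spatial_recaptures(self) -> int:
        """Total (distinct detectors - 1) over individuals."""
        if self.n == 0:
            return 0
        return int(((self.counts > 0).sum(axis=1) - 1).sum())


@dataclass(frozen=True)
class ScrParams:
    """Natural-scale SCR parameters: density (per km^2), g0, sigma (m)."""

    D: float
    g0: float
    sigma: float

    def __post_init__(self):
        if not (self.D > 0 and 0 < self.g0 < 1 and self.sigma > 0):
            raise ParameterError(
                f"invalid parameters D={self.D}, g0={self.g0}, sigma={self.sigma}"
            )

    def to_link(self) -> np.ndarray:
        return np.array([math.log(self.D), logit(self.g0), math.log(self.sigma)])

    @staticmethod
    def from_link(theta) -> "ScrParams":
        return ScrParams(
            D=float(np.exp(theta[0])),
            g0=float(expit(theta[1])),
            sigma=float(np.exp(theta[2])),
        )


@dataclass
class ScrFit:
    """A fitted SCR model with link-scale uncertainty.

    ``logLik`` omits the constant -log(n!) term of the Poisson-n likelihood
    (recorded in ``loglik_convention``).  ``ci95`` maps parameter name to a
    natural-scale (lo, hi) pair back-transformed from link-scale Wald
    intervals; entries are (nan, nan) when the Hessian was not positive
    definite.
    """

    params: ScrParams
    link_estimates: np.ndarray  # (log D, logit g0, log sigma)
    link_se: np.ndarray | None
    ci95: dict[str, tuple[float, float]]
    logLik: float
    converged: bool
    n: int
    K: int
    T: int
    mask: HabitatMask
    loglik_convention: str = "log(n!) dropped"
    message: str = ""


def halfnormal_p(d, g0: float, sigma: float):
    """Half-normal detection probability g0*exp(-d^2/(2 sigma^2)).

    ``d`` is a distance (or array of distances) in the same units as sigma.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    out = g0 * np.exp(-(d**2) / (2.0 * sigma**2))
    return out if out.ndim else float(out)


def pdot(points, traps: TrapArray, g0: float, sigma: float, T: int):
    """P(detected at least once in T occasions) for centres at ``points``.

    Vectorised over mask points: 1 - prod_k (1 - p_k(s))^T.
    """
    if T < 1:
        raise ParameterError("T must be >= 1")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d2 = _sq_distances(pts, traps.coords())
    p = g0 * np.exp(-d2 / (2.0 * sigma**2))
    log_surv = T * np.log1p(-p).sum(axis=1)
    out = -np.expm1(log_surv)
    return float(out[0]) if np.ndim(points) == 1 else out


def _sq_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between row sets a (n,2) and b (m,2)."""
    diff = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def collapse_histories(
    records: DetectionRecordSet,
    window: tuple[int, int],
    sex_filter: str = "male",
) -> SessionHistories:
    """Collapse daily records in [start, end] to per-individual counts n_ik.

    ``sex_filter`` is "male", "female" or "all"; individuals with no
    detection inside the window are excluded.
    """
    start, end = int(window[0]), int(window[1])
    if not (1 <= start <= end <= records.total_days):
        raise ParameterError(
            f"window ({start}, {end}) outside [1, {records.total_days}]"
        )
    if sex_filter not in ("male", "female", "all"):
        raise ParameterError(f"unknown sex filter {sex_filter!r}")
    traps = records.traps
    counts: dict[str, np.ndarray] = {}
    for r in records.records:
        if r.day < start or r.day > end:
            continue
        if sex_filter != "all" and r.sex != sex_filter:
            continue
        row = counts.setdefault(r.individual, np.zeros(traps.K))
        row[traps.index(r.detector)] += 1
    individuals = sorted(counts)
    mat = (
        np.array([counts[i] for i in individuals])
        if individuals
        else np.zeros((0, traps.K))
    )
    return SessionHistories(
        individuals=individuals, counts=mat, T=end - start + 1, K=traps.K
    )


class _LikelihoodCache:
    """Precomputed geometry for repeated likelihood evaluations of one fit."""

    def __init__(self, hist: SessionHistories, traps: TrapArray, mask: HabitatMask):
        if mask.M == 0:
            raise EstimationError("habitat mask is empty")
        self.hist = hist
        self.d2 = _sq_distances(mask.points, traps.coords())  # (M, K)
        self.counts = hist.counts  # (n, K)
        self.rest = hist.T - hist.counts  # (n, K)
        self.log_a = math.log(mask.cell_area)
        self.T = hist.T

    def neg_loglik(self, theta: np.ndarray) -> float:
        logD, lg0, lsig = float(theta[0]), float(theta[1]), float(theta[2])
        if not np.all(np.isfinite(theta)):
            return np.inf
        g0 = expit(lg0)
        inv2s2 = 0.5 * math.exp(-2.0 * lsig)
        # p: (M, K) detection probability per occasion
        p = g0 * np.exp(-self.d2 * inv2s2)
        log_q = np.log1p(-p)  # log(1 - p)
        log_p = np.log(np.maximum(p, 1e-323))
        # Poisson rate of detected individuals: D a sum_m pdot(s_m)
        pdot_m = -np.expm1(self.T * log_q.sum(axis=1))
        Lambda = math.exp(logD + self.log_a) * pdot_m.sum()
        # per-individual mask-summed detection-history probabilities
        # log Pr(omega_i | s_m): (n, M)
        ll_im = self.counts @ log_p.T + self.rest @ log_q.T
        li = logsumexp(ll_im, axis=1)  # log sum_m Pr(omega_i|s_m)
        if not np.all(np.isfinite(li)):
            return np.inf
        loglik = float(np.sum(logD + self.log_a + li) - Lambda)
        return -loglik


def negloglik(
    link_params,
    hist: SessionHistories,
    traps: TrapArray,
    mask: HabitatMask,
) -> float:
    """Negative log likelihood at link parameters (log D, logit g0, log sigma).

    The additive -log(n!) constant is omitted.
    """
    if hist.n < 1:
        raise EstimationError("no detections: likelihood undefined")
    cache = _LikelihoodCache(hist, traps, mask)
    return cache.neg_loglik(np.asarray(link_params, dtype=float))


def _default_start(
    hist: SessionHistories, traps: TrapArray, mask: HabitatMask
) -> ScrParams:
    """Cheap method-of-moments starting values."""
    coords = trap_xy = traps.coords()
    # sigma0: half the mean per-individual maximum recapture distance,
    # floored at half the mean nearest-trap spacing
    max_d = []
    for row in hist.counts:
        used = trap_xy[row > 0]
        if len(used) >= 2:
            d = np.sqrt(_sq_distances(used, used))
            max_d.append(d.max())
    if traps.K >= 2:
        dd = np.sqrt(_sq_distances(coords, coords))
        np.fill_diagonal(dd, np.inf)
        nn = dd.min(axis=1).mean()
    else:
        nn = mask.spacing
    sigma0 = max(
        0.5 * float(np.mean(max_d)) if max_d else 0.0, 0.5 * float(nn)
    )
    # g0: detections over exposure discounted by mean distance decay
    d2_bar = _sq_distances(mask.points, coords).mean()
    decay = math.exp(-d2_bar / (2 * sigma0**2))
    exposure = hist.n * hist.K * hist.T * max(decay, 1e-6)
    g00 = min(max(hist.n_detections / exposure, 0.001), 0.5)
    pd = pdot(mask.points, traps, g00, sigma0, hist.T)
    denom = mask.cell_area * float(np.sum(pd))
    D0 = hist.n / max(denom, 1e-12)
    return ScrParams(D=max(D0, 1e-8), g0=g00, sigma=sigma0)


def _numeric_gradient(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    g = np.zeros_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h**2)
    return H


def fit_scr(
    hist: SessionHistories,
    traps: TrapArray,
    mask: HabitatMask,
    start: ScrParams | None = None,
    compute_ci: bool = True,
) -> ScrFit:
    """Maximise the full SCR likelihood and return estimates with Wald CIs.

    Requires at least two detected individuals and at least one individual
    detected at two or more detectors (otherwise sigma is unidentifiable).
    A warm ``start`` (e.g. the previous rolling window's estimate) shortens
    the simplex stage considerably.
    """
    if hist.n == 0:
        raise EstimationError("no detections")
    if hist.spatial_recaptures() == 0:
        raise EstimationError("sigma unidentifiable: no spatial recaptures")
    if hist.n < 2:
        raise EstimationError("need >= 2 detected individuals")

    cache = _LikelihoodCache(hist, traps, mask)
    theta0 = (start or _default_start(hist, traps, mask)).to_link()

    # A warm start (e.g. from an overlapping window) is near the optimum, so
    # quasi-Newton alone suffices; a cold start gets a derivative-free
    # simplex exploration first, then the BFGS polish.
    best = None
    if start is not None:
        direct = optimize.minimize(cache.neg_loglik, theta0, method="BFGS")
        if np.isfinite(direct.fun):
            best = direct
    if best is None:
        nm = optimize.minimize(
            cache.neg_loglik,
            theta0,
            method="Nelder-Mead",
            options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": 400},
        )
        polish = optimize.minimize(cache.neg_loglik, nm.x, method="BFGS")
        best = polish if polish.fun <= nm.fun else nm
    theta = np.asarray(best.x, dtype=float)

    grad = _numeric_gradient(cache.neg_loglik, theta)
    converged = bool(np.isfinite(best.fun) and np.abs(grad).max() < 0.1)

    link_se = None
    ci: dict[str, tuple[float, float]] = {
        k: (float("nan"), float("nan")) for k in ("D", "g0", "sigma")
    }
    if compute_ci:
        H = _numeric_hessian(cache.neg_loglik, theta)
        try:
            cov = np.linalg.inv(H)
            diag = np.diag(cov)
            if np.all(np.isfinite(diag)) and np.all(diag > 0):
                link_se = np.sqrt(diag)
        except np.linalg.LinAlgError:
            link_se = None
        if link_se is None:
            warnings.warn(
                "Hessian not positive definite; SEs/CIs unavailable",
                stacklevel=2,
            )
        else:
            z = 1.959963984540054  # Phi^{-1}(0.975)
            lo, hi = theta - z * link_se, theta + z * link_se
            ci = {
                "D": (math.exp(lo[0]), math.exp(hi[0])),
                "g0": (float(expit(lo[1])), float(expit(hi[1]))),
                "sigma": (math.exp(lo[2]), math.exp(hi[2])),
            }

    return ScrFit(
        params=ScrParams.from_link(theta),
        link_estimates=theta,
        link_se=link_se,
        ci95=ci,
        logLik=-float(best.fun),
        converged=converged,
        n=hist.n,
        K=hist.K,
        T=hist.T,
        mask=mask,
        message=best.message if isinstance(best.message, str) else "",
    )


def density_per_100km2(fit: ScrFit) -> tuple[float, float, float]:
    """Density estimate and 95% CI rescaled to individuals per 100 km^2."""
    lo, hi = fit.ci95["D"]
    return (fit.params.D * 100.0, lo * 100.0, hi * 100.0)
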