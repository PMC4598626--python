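"""Frame-by-frame 2D Gaussian fitting of dF images and FWHM² trace metrics.

The spatial spread of newly exocytosed protein is read out by fitting each
background-subtracted frame of a responding synapse with a rotated elliptical
Gaussian

    I(x, y) = I0 + A·exp(-(a·(x-x0)² + 2b·(x-x0)(y-y0) + c·(y-y0)²))

with a, b, c the usual functions of (sigma_major, sigma_minor, theta), and
tracking the squared full width at half maximum of the major axis,
FWHM = 2·sqrt(2·ln 2)·sigma, over time.  Summary metrics (maximal spread,
final FWHM², reclustering half-time) are taken from median-filtered traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.optimize import least_squares

from .preproc import SynapseROI
from .simcore import ImageSequence

__all__ = [
    "FWHM_FACTOR",
    "GaussFit2D",
    "FWHMTrace",
    "TraceMetrics",
    "fwhm_from_sigma",
    "fit_gaussian2d",
    "extract_fwhm_trace",
    "trace_metrics",
    "pool_hierarchical",
]

#: FWHM = FWHM_FACTOR * sigma for a Gaussian profile
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fwhm_from_sigma(sigma: float | np.ndarray) -> float | np.ndarray:
    """Full width at half maximum of a Gaussian with standard deviation ``sigma``."""
    if np.any(np.asarray(sigma) < 0):
        raise ValueError("sigma must be >= 0")
    return FWHM_FACTOR * sigma


@dataclass(frozen=True)
class GaussFit2D:
    """Rotated elliptical Gaussian fit of one dF frame (lengths in um)."""

    I0: float
    A: float
    x0: float
    y0: float
    sigma_major: float
    sigma_minor: float
    theta: float  # rad, in [0, pi); 0 when isotropic
    residual_rms: float
    converged: bool

    @property
    def fwhm_major(self) -> float:
        return FWHM_FACTOR * self.sigma_major

    @property
    def fwhm_minor(self) -> float:
        return FWHM_FACTOR * self.sigma_minor

    @property
    def fwhm2(self) -> float:
        """Squared major-axis FWHM — the per-frame spread readout."""
        return self.fwhm_major**2


def _gauss2d(coords, I0, A, x0, y0, sx, sy, th):
    x, y = coords
    ct, st = np.cos(th), np.sin(th)
    a = ct**2 / (2 * sx**2) + st**2 / (2 * sy**2)
    b = st * ct * (1 / (2 * sx**2) - 1 / (2 * sy**2))
    c = st**2 / (2 * sx**2) + ct**2 / (2 * sy**2)
    dx, dy = x - x0, y - y0
    return I0 + A * np.exp(-(a * dx**2 + 2 * b * dx * dy + c * dy**2))


def _normalise(sx: float, sy: float, th: float) -> tuple[float, float, float]:
    """Order axes (major >= minor) and wrap the angle into [0, pi)."""
    if sy > sx:
        sx, sy = sy, sx
        th = th + math.pi / 2
    th = th % math.pi
    if math.isclose(sx, sy, rel_tol=1e-12, abs_tol=0.0):
        th = 0.0  # angle unidentifiable at isotropy
    return sx, sy, th


def fit_gaussian2d(
    patch: np.ndarray,
    pixel_size: float,
    min_amplitude_snr: float = 3.0,
) -> GaussFit2D:
    """Least-squares fit of a rotated elliptical Gaussian with offset to a patch.

    Coordinates are physical (um), pixel-centre convention, origin at the
    patch corner.  Initialisation uses image moments of the
    background-subtracted patch.  ``converged`` is False for degenerate
    patches, optimiser failure, or amplitude below
    ``min_amplitude_snr``·residual_rms.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or min(patch.shape) < 7:
        raise ValueError("patch must be 2D with at least 7x7 pixels")
    H, W = patch.shape
    xs = (np.arange(W) + 0.5) * pixel_size
    ys = (np.arange(H) + 0.5) * pixel_size
    X, Y = np.meshgrid(xs, ys)

    failed = GaussFit2D(
        I0=float(patch.mean()), A=0.0, x0=float(xs.mean()), y0=float(ys.mean()),
        sigma_major=np.nan, sigma_minor=np.nan, theta=0.0,
        residual_rms=float(patch.std()), converged=False,
    )
    if np.ptp(patch) == 0:
        return failed

    # moment-based initialisation
    I0_0 = float(np.percentile(patch, 10))
    w = np.clip(patch - I0_0, 0, None)
    wsum = w.sum()
    if wsum <= 0:
        return failed
    x0_0 = float((w * X).sum() / wsum)
    y0_0 = float((w * Y).sum() / wsum)
    vx = float((w * (X - x0_0) ** 2).sum() / wsum)
    vy = float((w * (Y - y0_0) ** 2).sum() / wsum)
    s0 = math.sqrt(max(min(vx, vy), (0.5 * pixel_size) ** 2))
    s1 = math.sqrt(max(max(vx, vy), (0.5 * pixel_size) ** 2))
    A0 = float(patch.max() - I0_0)

    p0 = np.array([I0_0, A0, x0_0, y0_0, s1, s0, 0.0])
    smin = 0.25 * pixel_size
    smax = 2.0 * max(W, H) * pixel_size
    lo = [-np.inf, 0.0, xs[0] - pixel_size, ys[0] - pixel_size, smin, smin, -math.pi]
    hi = [np.inf, np.inf, xs[-1] + pixel_size, ys[-1] + pixel_size, smax, smax, 2 * math.pi]

    def resid(p):
        return (_gauss2d((X, Y), *p) - patch).ravel()

    try:
        sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000)
    except Exception:
        return failed
    I0, A, x0, y0, sx, sy, th = sol.x
    sx, sy, th = _normalise(float(sx), float(sy), float(th))
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    converged = bool(sol.success) and A > min_amplitude_snr * rms and np.isfinite([sx, sy]).all()
    return GaussFit2D(
        I0=float(I0), A=float(A), x0=float(x0), y0=float(y0),
        sigma_major=sx, sigma_minor=sy, theta=th,
        residual_rms=rms, converged=converged,
    )


@dataclass
class FWHMTrace:
    """FWHM²(t) of one synapse: per-frame major-axis squared FWHM (um²)."""

    times: np.ndarray  # s
    fwhm2: np.ndarray  # um²; NaN where invalid
    amplitude: np.ndarray
    valid: np.ndarray  # bool

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "fwhm2_um2": self.fwhm2, "amplitude": self.amplitude, "valid": self.valid}
        )


def extract_fwhm_trace(
    seq: ImageSequence,
    roi: SynapseROI,
    margin_px: int = 6,
    min_amplitude_snr: float = 3.0,
) -> FWHMTrace:
    """Fit every frame of a dF sequence on the ROI patch and collect FWHM²(t).

    The fit patch is the ROI bounding box expanded by ``margin_px`` (clipped to
    the image).  Frames whose fit does not converge are marked invalid.
    """
    if not roi.responding:
        raise ValueError("ROI is not a responding synapse")
    H, W = seq.frames.shape[1:]
    x0 = max(0, roi.x0 - margin_px)
    y0 = max(0, roi.y0 - margin_px)
    x1 = min(W, roi.x1 + margin_px)
    y1 = min(H, roi.y1 + margin_px)
    T = seq.frames.shape[0]
    fwhm2 = np.full(T, np.nan)
    amp = np.full(T, np.nan)
    valid = np.zeros(T, dtype=bool)
    for m in range(T):
        fit = fit_gaussian2d(seq.frames[m, y0:y1, x0:x1], seq.pixel_size, min_amplitude_snr)
        if fit.converged:
            fwhm2[m] = fit.fwhm2
            amp[m] = fit.A
            valid[m] = True
    if not valid.any():
        raise ValueError("no frame produced a valid Gaussian fit")
    return FWHMTrace(times=seq.times, fwhm2=fwhm2, amplitude=amp, valid=valid)


@dataclass(frozen=True)
class TraceMetrics:
    """Summary of a median-filtered FWHM² trace."""

    max_spread: float  # um²
    last_fwhm2: float  # um²
    t_half: float  # s from the filtered maximum; NaN when undefined
    filter_window: int

    @property
    def t_half_defined(self) -> bool:
        return bool(np.isfinite(self.t_half))


def trace_metrics(trace: FWHMTrace, filter_window: int = 5) -> TraceMetrics:
    """Maximal spread, final FWHM² and reclustering half-time of a trace.

    The valid samples are median-filtered (window ``filter_window``, odd).
    t_half is the time after the filtered maximum at which the filtered trace
    first falls to (max + last)/2, linearly interpolated between frames; NaN
    (flagged) when the trace never crosses that level.
    """
    if filter_window % 2 == 0 or filter_window < 1:
        raise ValueError("filter_window must be odd and >= 1")
    t = trace.times[trace.valid]
    y = trace.fwhm2[trace.valid]
    if len(y) == 0:
        raise ValueError("trace has no valid samples")
    # 'nearest' edge handling keeps the endpoints unbiased on short traces
    f = median_filter(y, size=min(filter_window, len(y)), mode="nearest")
    imax = int(np.argmax(f))
    max_spread = float(f[imax])
    last = float(f[-1])
    half = 0.5 * (max_spread + last)

    t_half = np.nan
    for j in range(imax + 1, len(f)):
        if f[j] <= half:
            # linear interpolation between samples j-1 and j
            if f[j - 1] == f[j]:
                tc = t[j]
            else:
                frac = (f[j - 1] - half) / (f[j - 1] - f[j])
                tc = t[j - 1] + frac * (t[j] - t[j - 1])
            t_half = float(tc - t[imax])
            break
    return TraceMetrics(max_spread=max_spread, last_fwhm2=last, t_half=t_half, filter_window=filter_window)


def pool_hierarchical(
    values: pd.DataFrame,
    value_col: str = "value",
    neuron_col: str = "neuron",
    experiment_col: str = "experiment",
) -> dict:
    """Two-step hierarchical pooling of per-synapse metrics.

    Median over synapses within each neuron, then median over neurons within
    each experiment, then mean ± s.e.m. across experiments — so every neuron
    and every experiment carries equal weight regardless of synapse count.
    """
    if values.empty:
        raise ValueError("no values to pool")
    if values[value_col].isna().any():
        values = values.dropna(subset=[value_col])
        if values.empty:
            raise ValueError("no finite values to pool")
    neuron_medians = values.groupby([experiment_col, neuron_col])[value_col].median()
    experiment_values = neuron_medians.groupby(level=0).median()
    n = len(experiment_values)
    mean = float(experiment_values.mean())
    sem = float(experiment_values.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return {
        "neuron_medians": neuron_medians,
        "experiment_values": experiment_values,
        "mean": mean,
        "sem": sem,
        "n_experiments": n,
    }
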