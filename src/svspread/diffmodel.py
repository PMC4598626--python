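"""Successive-fusion free-diffusion model and diffusion-coefficient estimation.

Each fusion event deposits protein that subsequently spreads by free 2D
Brownian motion, so at time t_m a vesicle fused at frame n contributes an
isotropic Gaussian intensity distribution of variance

    sigma_n²(t_m) = psf_sigma0² + 2·D·(t_m - t_n),

weighted by the measured frame-to-frame intensity increase (the relative
number of vesicles fusing in that frame) and mass-normalised, i.e. the radial
profile is

    I(r, t_m) = sum_n  w_n / (2·pi·sigma_n²) · exp(-r² / (2·sigma_n²)).

The summed profile is re-fit with a single Gaussian, I(r) = I0 + A·exp(-r²/2σ²),
on a dense radial grid, and FWHM² = 8·ln2·σ² is reported per frame.  The
diffusion coefficient is estimated by matching the mean slope of the measured
FWHM²(t) to the model's over a fit window during stimulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .spreadfit import FWHMTrace

__all__ = [
    "DiffusionModelFit",
    "model_fwhm2",
    "estimate_D",
    "characteristic_displacement",
    "ols_slope",
]

EIGHT_LN2 = 8.0 * math.log(2.0)


def ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    """Ordinary least-squares slope of y on t."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two samples for a slope")
    tc = t - t.mean()
    return float((tc * (y - y.mean())).sum() / (tc * tc).sum())


def _fit_radial_gaussian(
    weights: np.ndarray,
    variances: np.ndarray,
    weighting: str = "area",
    rmax_factor: float = 3.0,
    n_radial: int = 200,
) -> float:
    """Least-squares single-Gaussian fit of a Gaussian mixture's radial profile.

    The profile I(r) = sum_n w_n/(2·pi·v_n)·exp(-r²/2v_n) is sampled on a
    uniform radial grid from 0 to ``rmax_factor``x the widest component sd and
    fit with I0 + A·exp(-r²/2σ²).  ``weighting='area'`` weights each sample by
    r — the continuum limit of fitting the 2D image over a disk, matching how
    the measured frames are fit pixel-by-pixel; ``'uniform'`` weights samples
    equally (a plain 1D radial fit).  Returns the fitted variance σ².
    """
    sig_max = math.sqrt(float(variances.max()))
    r = np.linspace(0.0, rmax_factor * sig_max, n_radial)
    prof = np.zeros_like(r)
    for w, v in zip(weights, variances):
        prof += w / (2.0 * math.pi * v) * np.exp(-(r**2) / (2.0 * v))
    if weighting == "area":
        sw = np.sqrt(r)
    elif weighting == "uniform":
        sw = np.ones_like(r)
    else:
        raise ValueError("weighting must be 'area' or 'uniform'")

    prof = prof / prof.max()  # scale-free: the fitted width is weight-scale invariant

    def gauss_w(r, I0, A, sig):
        return (I0 + A * np.exp(-(r**2) / (2.0 * sig**2))) * sw

    v_eff = float((weights * variances).sum() / weights.sum())
    p0 = (0.0, 1.0, math.sqrt(v_eff))
    popt, _ = curve_fit(gauss_w, r, prof * sw, p0=p0, maxfev=20000, xtol=1e-14, ftol=1e-14)
    return float(popt[2]) ** 2


def model_fwhm2(
    increments: np.ndarray,
    D: float,
    frame_duration: float,
    psf_sigma0: float = 0.0,
    age_offset: float = 0.5,
    weighting: str = "area",
) -> np.ndarray:
    """Model FWHM²(t) of the increment-weighted sum of spreading Gaussians.

    ``increments[n]`` is the intensity increase attributed to frame n (at time
    n·frame_duration, time measured from stimulus onset); negative increments
    are clipped to zero.  Because the vesicles behind frame n's increment
    actually fused throughout that frame, their mean age at any later frame
    exceeds the frame-grid difference by about half a frame; ``age_offset``
    (frames, default 0.5) adds that correction, so
    sigma_n²(t_m) = psf_sigma0² + 2·D·(t_m - t_n + age_offset·f).
    Set ``age_offset=0`` for the pure frame-grid model.  ``weighting`` selects
    how the summed profile is re-fit (see :func:`_fit_radial_gaussian`).

    Returns FWHM² (same length as ``increments``) at the frame times.  Units
    follow psf_sigma0 and D (um, um²/s).
    """
    w = np.asarray(increments, dtype=float)
    if D <= 0:
        raise ValueError("D must be positive")
    if frame_duration <= 0:
        raise ValueError("frame_duration must be positive")
    w = np.clip(w, 0.0, None)
    if not np.any(w > 0):
        raise ValueError("all intensity increments are zero")
    n_frames = len(w)
    t = np.arange(n_frames) * frame_duration
    out = np.full(n_frames, np.nan)
    for m in range(n_frames):
        wk = w[: m + 1]
        active = wk > 0
        if not active.any():
            continue
        var = psf_sigma0**2 + 2.0 * D * (t[m] - t[: m + 1] + age_offset * frame_duration)
        wk, var = wk[active], var[active]
        zero = var <= 0
        if zero.all():
            out[m] = 0.0
            continue
        if len(wk) == 1 or np.allclose(var, var[0]):
            # single component: the fit is exact
            out[m] = EIGHT_LN2 * float(var[0])
        else:
            # drop zero-width singular components (psf_sigma0=0, age_offset=0, same frame)
            out[m] = EIGHT_LN2 * _fit_radial_gaussian(wk[~zero], var[~zero], weighting=weighting)
    return out


@dataclass(frozen=True)
class DiffusionModelFit:
    """Result of slope-matched diffusion-coefficient estimation."""

    D_est: float  # um²/s; NaN when the experimental slope is not positive
    model_fwhm2: np.ndarray  # um² at the frame grid
    times: np.ndarray  # s, from stimulus onset
    fit_window: tuple[float, float]  # s
    intensity_increments: np.ndarray  # clipped weights actually used
    psf_sigma0: float
    exp_slope: float  # um²/s
    valid: bool


def estimate_D(
    exp_trace: FWHMTrace,
    increments: np.ndarray,
    frame_duration: float,
    fit_window: tuple[float, float] = (0.8, 2.0),
    psf_sigma0: float = 0.0,
    bracket: tuple[float, float] = (0.01, 2.0),
    tol: float = 1e-4,
    age_offset: float = 0.5,
    weighting: str = "area",
) -> DiffusionModelFit:
    """Estimate D by matching measured and modelled mean FWHM² slopes.

    ``exp_trace`` times and the increment frame grid are both measured from
    stimulus onset.  The slope is the OLS slope of FWHM² vs t over
    ``fit_window`` (inclusive); D minimises the squared slope difference via a
    bounded 1D search.  A non-positive experimental slope yields
    ``valid=False`` with ``D_est=NaN``.
    """
    w = np.clip(np.asarray(increments, dtype=float), 0.0, None)
    t_model = np.arange(len(w)) * frame_duration
    lo, hi = fit_window
    sel_exp = exp_trace.valid & (exp_trace.times >= lo) & (exp_trace.times <= hi)
    if sel_exp.sum() < 2:
        raise ValueError("experimental trace has fewer than 2 valid samples in the fit window")
    exp_slope = ols_slope(exp_trace.times[sel_exp], exp_trace.fwhm2[sel_exp])
    sel_mod = (t_model >= lo) & (t_model <= hi)
    if sel_mod.sum() < 2:
        raise ValueError("fit window spans fewer than 2 model frames")

    if exp_slope <= 0:
        return DiffusionModelFit(
            D_est=float("nan"),
            model_fwhm2=np.full(len(w), np.nan),
            times=t_model,
            fit_window=fit_window,
            intensity_increments=w,
            psf_sigma0=psf_sigma0,
            exp_slope=exp_slope,
            valid=False,
        )

    def model_slope(D: float) -> float:
        f2 = model_fwhm2(w, D, frame_duration, psf_sigma0, age_offset=age_offset, weighting=weighting)
        return ols_slope(t_model[sel_mod], f2[sel_mod])

    res = minimize_scalar(
        lambda D: (model_slope(D) - exp_slope) ** 2,
        bounds=bracket,
        method="bounded",
        options={"xatol": tol},
    )
    D_est = float(res.x)
    return DiffusionModelFit(
        D_est=D_est,
        model_fwhm2=model_fwhm2(w, D_est, frame_duration, psf_sigma0, age_offset=age_offset, weighting=weighting),
        times=t_model,
        fit_window=fit_window,
        intensity_increments=w,
        psf_sigma0=psf_sigma0,
        exp_slope=exp_slope,
        valid=True,
    )


def characteristic_displacement(D: float, t: float) -> float:
    """Root-mean-square 1D displacement sqrt(2·D·t) of a freely diffusing molecule.

    With D = 0.25 um²/s this is 1 um in 2 s — the scale of protein movement
    away from a release site during one stimulus train.
    """
    if D < 0 or t < 0:
        raise ValueError("D and t must be >= 0")
    return math.sqrt(2.0 * D * t)
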