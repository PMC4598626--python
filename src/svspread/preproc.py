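"""Pre-processing of pHluorin time-lapse stacks.

Steps, in the order an analysis runs them:

1. per-pixel photobleaching fit on the pre-stimulus segment,
   I(t) = bg + a·exp(-t/tau), bleach rate lambda = 1/tau;
2. bleach correction of the whole sequence,
   I_bc(t) = bg + (I(t) - bg)·exp(lambda·t), which exactly inverts the decay
   and leaves the background stationary;
3. baseline subtraction: dF(t) = I_bc(t) - median of the last pre-stimulus
   frames;
4. identification of responding synapses from the differential image
   (F_after - F_before) by a histogram threshold;
5. quantification of signal escaping into the axon from a small region placed
   at a fixed distance from a responding synapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .simcore import ImageSequence

__all__ = [
    "BleachFit",
    "BleachModel",
    "SynapseROI",
    "fit_pixel_bleach",
    "fit_bleach_model",
    "bleach_correct",
    "compute_deltaF",
    "detect_responding_synapses",
    "measure_axonal_escape",
]


@dataclass(frozen=True)
class BleachFit:
    """Single-pixel exponential-decay fit: I(t) = bg + a·exp(-t/tau)."""

    bg: float
    a: float
    tau: float  # s; inf for a flat (non-bleaching) trace
    lam: float  # bleach rate, 1/tau; 0 for a flat trace
    fit_ok: bool


@dataclass
class BleachModel:
    """Per-pixel bleach parameters for a whole field of view."""

    bg: np.ndarray  # (H, W)
    a: np.ndarray
    tau: np.ndarray
    lam: np.ndarray
    fit_ok: np.ndarray  # bool (H, W)


def _exp_decay(t, bg, a, tau):
    return bg + a * np.exp(-t / tau)


def fit_pixel_bleach(
    trace: np.ndarray,
    times: np.ndarray,
    t_stim: float,
    noise_floor: float | None = None,
) -> BleachFit:
    """Fit an exponential photobleaching decay to one pixel's pre-stimulus trace.

    Only samples with ``times < t_stim`` enter the fit; at least 5 are
    required.  A trace whose decaying amplitude is at or below the noise floor
    (default: 3x the fit residual sd) is flagged ``fit_ok=False`` with
    ``lam=0`` so that the correction step leaves it untouched.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    pre = times < t_stim
    t, y = times[pre], trace[pre]
    if len(t) < 5:
        raise ValueError(f"need >= 5 pre-stimulus samples, got {len(t)}")

    span = float(y.max() - y.min())
    flat = BleachFit(bg=float(y.mean()), a=0.0, tau=np.inf, lam=0.0, fit_ok=False)
    if span == 0.0:
        return flat

    # variable projection: (bg, a) are linear given tau, so search only over
    # log(tau) — robust and accurate to machine precision on noiseless decays
    t0 = t - t[0]
    ones = np.ones_like(t0)

    def linfit(tau: float) -> tuple[float, float, float]:
        g = np.exp(-t0 / tau)
        M = np.column_stack([ones, g])
        coef, *_ = np.linalg.lstsq(M, y, rcond=None)
        r = y - M @ coef
        return float(coef[0]), float(coef[1]), float(r @ r)

    span_t = float(t0[-1]) if t0[-1] > 0 else 1.0
    grid = np.log(span_t) + np.linspace(-5, 7, 25)
    sses = [linfit(math.exp(u))[2] for u in grid]
    i = int(np.argmin(sses))
    lo, hi = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
    try:
        res = minimize_scalar(
            lambda u: linfit(math.exp(u))[2], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        tau = math.exp(float(res.x))
        bg, a, _ = linfit(tau)
    except (ValueError, FloatingPointError):
        return flat
    if not np.isfinite(tau) or tau <= 0 or not np.isfinite(a) or a <= 0:
        return flat
    resid = y - (bg + a * np.exp(-t0 / tau))
    # tau is referenced to t[0]=0; rescale a to absolute time 0
    a_abs = a * math.exp(t[0] / tau)
    floor = 3.0 * float(np.std(resid)) if noise_floor is None else noise_floor
    # both the initial amplitude and the amplitude still left at the end of
    # the baseline must clear the noise floor: a decay that vanishes within
    # the fit window leaves lam unconstrained and e^(lam·t) would amplify
    # noise without bound over the rest of the sequence
    ok = a > floor and a * math.exp(-span_t / tau) > floor
    return BleachFit(bg=bg, a=a_abs, tau=tau, lam=1.0 / tau, fit_ok=ok)


def fit_bleach_model(seq: ImageSequence, noise_floor: float | None = None) -> BleachModel:
    """Fit the pre-stimulus bleach decay independently for every pixel."""
    T, H, W = seq.frames.shape
    times = seq.times
    if int(np.sum(times < seq.stim_start)) < 5:
        raise ValueError("need >= 5 pre-stimulus frames for the bleach fit")
    bg = np.zeros((H, W))
    a = np.zeros((H, W))
    tau = np.full((H, W), np.inf)
    lam = np.zeros((H, W))
    ok = np.zeros((H, W), dtype=bool)
    for i in range(H):
        for j in range(W):
            f = fit_pixel_bleach(seq.frames[:, i, j], times, seq.stim_start, noise_floor)
            bg[i, j], a[i, j], tau[i, j], lam[i, j], ok[i, j] = f.bg, f.a, f.tau, f.lam, f.fit_ok
    return BleachModel(bg=bg, a=a, tau=tau, lam=lam, fit_ok=ok)


def bleach_correct(seq: ImageSequence, model: BleachModel) -> ImageSequence:
    """Undo per-pixel photobleaching over the entire sequence.

    I_bc(t) = bg + (I(t) - bg)·exp(lambda·t).  Pixels whose bleach fit failed
    (``fit_ok=False``) pass through unchanged (their lambda is 0).
    """
    if model.bg.shape != seq.frames.shape[1:]:
        raise ValueError("bleach model geometry does not match the sequence")
    t = seq.times[:, None, None]
    lam = np.where(model.fit_ok, model.lam, 0.0)[None, :, :]
    bg = model.bg[None, :, :]
    corrected = np.where(
        model.fit_ok[None, :, :],
        bg + (seq.frames - bg) * np.exp(lam * t),
        seq.frames,
    )
    return ImageSequence(
        frames=corrected,
        pixel_size=seq.pixel_size,
        frame_interval=seq.frame_interval,
        stim_start=seq.stim_start,
        stim_end=seq.stim_end,
    )


def compute_deltaF(seq: ImageSequence, n_pre: int = 5) -> ImageSequence:
    """Subtract the per-pixel median of the last ``n_pre`` pre-stimulus frames."""
    pre_idx = np.flatnonzero(seq.times < seq.stim_start)
    if len(pre_idx) < n_pre:
        raise ValueError(f"need >= {n_pre} pre-stimulus frames, have {len(pre_idx)}")
    baseline = np.median(seq.frames[pre_idx[-n_pre:]], axis=0)
    return ImageSequence(
        frames=seq.frames - baseline,
        pixel_size=seq.pixel_size,
        frame_interval=seq.frame_interval,
        stim_start=seq.stim_start,
        stim_end=seq.stim_end,
    )


@dataclass(frozen=True)
class SynapseROI:
    """A responding synaptic region: half-open pixel box [y0:y1, x0:x1]."""

    x0: int
    y0: int
    x1: int
    y1: int
    centre_um: tuple[float, float]  # (x, y), pixel-centre convention, um from image corner
    area_um2: float
    responding: bool = True
    roi_id: int = 0

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)


def detect_responding_synapses(
    seq: ImageSequence,
    n_avg: int = 5,
    min_area_um2: float = 0.3,
    significance: float = 3.0,
) -> list[SynapseROI]:
    """Find synapses responding to the stimulus.

    The differential image (mean of the ``n_avg`` frames after stimulus end
    minus the mean of the ``n_avg`` frames before stimulus start) is
    thresholded with Otsu's histogram criterion; connected components larger
    than ``min_area_um2`` become ROIs.  The threshold is accepted only if the
    foreground mean exceeds the background mean by ``significance`` background
    standard deviations — a flat stack yields no ROIs rather than noise ROIs.
    """
    times = seq.times
    pre_idx = np.flatnonzero(times < seq.stim_start)[-n_avg:]
    post_idx = np.flatnonzero(times >= seq.stim_end)[:n_avg]
    if len(pre_idx) == 0 or len(post_idx) == 0:
        raise ValueError("stimulus window leaves no pre or post frames")
    diff = seq.frames[post_idx].mean(axis=0) - seq.frames[pre_idx].mean(axis=0)

    if np.ptp(diff) == 0:
        return []
    thr = threshold_otsu(diff)
    fg = diff > thr
    if not fg.any() or fg.all():
        return []
    bg_sd = float(diff[~fg].std())
    if float(diff[fg].mean() - diff[~fg].mean()) <= significance * max(bg_sd, 1e-12):
        return []

    min_px = min_area_um2 / seq.pixel_size**2
    rois: list[SynapseROI] = []
    for k, prop in enumerate(regionprops(label(fg))):
        if prop.area < min_px:
            continue
        y0, x0, y1, x1 = prop.bbox
        cy, cx = prop.centroid  # weighted by mask only; pixel units
        rois.append(
            SynapseROI(
                x0=int(x0),
                y0=int(y0),
                x1=int(x1),
                y1=int(y1),
                centre_um=((cx + 0.5) * seq.pixel_size, (cy + 0.5) * seq.pixel_size),
                area_um2=float(prop.area) * seq.pixel_size**2,
                responding=True,
                roi_id=len(rois),
            )
        )
    return rois


def measure_axonal_escape(
    seq: ImageSequence,
    roi: SynapseROI,
    axon_area_um2: float = 0.9,
    axon_distance_um: float = 1.2,
    direction: tuple[float, float] = (1.0, 0.0),
) -> np.ndarray:
    """Mean dF over an axonal region near a responding synapse, per frame.

    A square region of ``axon_area_um2`` is centred ``axon_distance_um`` away
    from the ROI centre along ``direction`` (unit-normalised); the returned
    trace is the spatial mean of each frame over that square.
    """
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("direction must be non-zero")
    d = d / n
    side_um = float(np.sqrt(axon_area_um2))
    cx_um = roi.centre_um[0] + axon_distance_um * d[0]
    cy_um = roi.centre_um[1] + axon_distance_um * d[1]
    px = seq.pixel_size
    half = max(1, int(round(side_um / px / 2)))
    cx = int(round(cx_um / px - 0.5))
    cy = int(round(cy_um / px - 0.5))
    H, W = seq.frames.shape[1:]
    x0, x1 = cx - half, cx + half + 1
    y0, y1 = cy - half, cy + half + 1
    if x0 < 0 or y0 < 0 or x1 > W or y1 > H:
        raise ValueError("axonal region falls outside the image")
    return seq.frames[:, y0:y1, x0:x1].mean(axis=(1, 2))
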