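"""Spatial statistics for dual-channel localization data.

Implements the second-order and nearest-neighbour statistics used to
characterise sub-synaptic clustering and co-clustering of localization
patterns:

* edge-corrected Ripley's K,
      K(r) = (A/N²) · sum_i sum_{j≠i} 1(d_ij < r) / w(l_i, l_j),
  with Ripley's isotropic correction — w is the fraction of the circle of
  radius d_ij centred on point i that lies inside the rectangular window;
* the variance-stabilised L(r) - r = sqrt(K(r)/pi) - r, zero in expectation
  under complete spatial randomness (CSR), positive for clustering;
* pointwise upper envelopes of L(r) - r from CSR simulations;
* cross-channel k-nearest-neighbour distance distributions with a
  toroidal-shift negative control;
* radial intensity profiles around reference-channel maxima;
* diffraction-limited rendering of localization tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .simcore import LocalizationTable
from .spreadfit import FWHM_FACTOR

__all__ = [
    "RipleyResult",
    "KNNResult",
    "ripley_K",
    "L_minus_r",
    "csr_envelope",
    "knn_cross",
    "toroidal_shift",
    "radial_profile",
    "widefield_sigma",
    "render_sigma",
    "render_diffraction_limited",
]

Window = tuple[float, float, float, float]  # (x0, y0, x1, y1)


def _isotropic_weights(points: np.ndarray, d: np.ndarray, window: Window) -> np.ndarray:
    """Ripley isotropic edge-correction weights for circles centred on ``points``.

    ``d`` is an (N, M) array of circle radii (one row per centre).  Valid for
    radii up to half the shorter window side, where a circle can cross at most
    one vertical and one horizontal edge; the blocked arc is the union of the
    two edge arcs minus their overlap at the nearest corner.
    """
    x0, y0, x1, y1 = window
    dx = np.minimum(points[:, 0] - x0, x1 - points[:, 0])[:, None]
    dy = np.minimum(points[:, 1] - y0, y1 - points[:, 1])[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.arccos(np.clip(np.where(d > 0, dx / d, 1.0), -1.0, 1.0))
        t2 = np.arccos(np.clip(np.where(d > 0, dy / d, 1.0), -1.0, 1.0))
    t1 = np.where(dx < d, t1, 0.0)
    t2 = np.where(dy < d, t2, 0.0)
    overlap = np.maximum(0.0, t1 + t2 - math.pi / 2)
    blocked = 2 * t1 + 2 * t2 - overlap
    return 1.0 - blocked / (2 * math.pi)


@dataclass
class RipleyResult:
    """Edge-corrected Ripley statistics of one point pattern."""

    radii: np.ndarray  # nm
    K: np.ndarray  # nm²
    L_minus_r: np.ndarray | None  # nm
    envelope_upper: np.ndarray | None  # nm
    N: int
    window_area: float  # nm²


def ripley_K(points: np.ndarray, window: Window, radii: np.ndarray) -> RipleyResult:
    """Edge-corrected Ripley's K of a single-channel point pattern.

    ``points`` is an (N, 2) array in the same units as ``window`` and
    ``radii``.  Radii exceeding half the shorter window side (the validity
    limit of the isotropic correction) are truncated with a warning.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    radii = np.asarray(radii, dtype=float)
    N = len(points)
    if N < 2:
        raise ValueError("Ripley's K needs at least 2 points")
    x0, y0, x1, y1 = window
    area = (x1 - x0) * (y1 - y0)
    r_max = 0.5 * min(x1 - x0, y1 - y0)
    if np.any(radii > r_max):
        warnings.warn(f"radii truncated at half the shorter window side ({r_max:g})")
        radii = radii[radii <= r_max]

    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))  # (N, N)
    np.fill_diagonal(d, np.inf)  # exclude i == j
    w = _isotropic_weights(points, np.where(np.isfinite(d), d, 1.0), window)
    with np.errstate(divide="ignore"):
        inv_w = np.where(np.isfinite(d), 1.0 / w, 0.0)

    K = np.empty(len(radii))
    for i, r in enumerate(radii):
        K[i] = (inv_w * (d < r)).sum() * area / N**2
    return RipleyResult(radii=radii, K=K, L_minus_r=None, envelope_upper=None, N=N, window_area=area)


def L_minus_r(result: RipleyResult) -> RipleyResult:
    """Attach the normalised statistic L(r) - r = sqrt(K/pi) - r."""
    result.L_minus_r = np.sqrt(result.K / math.pi) - result.radii
    return result


def csr_envelope(
    window: Window,
    N: int,
    radii: np.ndarray,
    n_sim: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Pointwise upper envelope of L(r)-r over ``n_sim`` CSR simulations."""
    if N < 2:
        raise ValueError("need N >= 2")
    if n_sim < 1:
        raise ValueError("need n_sim >= 1")
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = window
    env = np.full(len(np.atleast_1d(radii)), -np.inf)
    for _ in range(n_sim):
        pts = np.column_stack(
            [rng.uniform(x0, x1, size=N), rng.uniform(y0, y1, size=N)]
        )
        res = L_minus_r(ripley_K(pts, window, radii))
        env = np.maximum(env, res.L_minus_r)
    return env


@dataclass
class KNNResult:
    """k-th nearest-neighbour distances of a query channel against a reference."""

    k: int
    distances: np.ndarray  # nm, one per query point
    bin_edges: np.ndarray
    histogram: np.ndarray
    null_distances: np.ndarray | None = None
    null_histogram: np.ndarray | None = None


def knn_cross(
    query: np.ndarray,
    reference: np.ndarray,
    k: int = 10,
    bin_width: float = 10.0,
    r_max: float | None = None,
) -> KNNResult:
    """Distance from each query point to its k-th nearest reference point.

    k = 10 damps the influence of isolated noise localizations: a query point
    only scores a short distance when a whole cluster of reference points
    surrounds it.  Distances are histogrammed with ``bin_width`` (nm).
    """
    query = np.asarray(query, dtype=float).reshape(-1, 2)
    reference = np.asarray(reference, dtype=float).reshape(-1, 2)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(reference) < k:
        raise ValueError(f"reference has {len(reference)} points, fewer than k={k}")
    tree = cKDTree(reference)
    dist, _ = tree.query(query, k=k)
    dist = np.atleast_2d(dist)
    dk = dist[:, -1] if k > 1 else dist.ravel()
    top = float(r_max) if r_max is not None else (float(dk.max()) + bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    hist, edges = np.histogram(dk, bins=edges)
    return KNNResult(k=k, distances=dk, bin_edges=edges, histogram=hist)


def toroidal_shift(points: np.ndarray, window: Window) -> np.ndarray:
    """Shift a channel by half the window width along x, wrapping around.

    x -> (x - x0 + width/2) mod width + x0, y unchanged — the negative control
    for colocalization: real cross-channel structure is destroyed while each
    channel's internal clustering is preserved.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    x0, _, x1, _ = window
    width = x1 - x0
    out = points.copy()
    out[:, 0] = np.mod(points[:, 0] - x0 + width / 2.0, width) + x0
    return out


def radial_profile(
    images: dict[str, np.ndarray],
    reference_channel: str,
    pixel_size: float = 105.0,
    bin_width: float = 105.0,
    r_max: float | None = None,
    min_distance: int = 1,
    threshold_rel: float = 0.5,
    maxima: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean intensity versus radial distance to the nearest reference maximum.

    Local maxima are detected in ``images[reference_channel]`` over a
    (2·min_distance+1)² neighbourhood with a relative intensity threshold,
    unless ``maxima`` ((n, 2) row/col pixel coordinates) is given.  Every
    pixel of every channel is assigned to a distance bin (units of
    ``pixel_size``); bins with no pixels are absent from the output rather
    than reported as zero.
    """
    ref = np.asarray(images[reference_channel], dtype=float)
    if maxima is None:
        maxima = peak_local_max(ref, min_distance=min_distance, threshold_rel=threshold_rel)
    maxima = np.asarray(maxima, dtype=float).reshape(-1, 2)
    if len(maxima) == 0:
        raise ValueError("no reference maxima found")
    H, W = ref.shape
    rows, cols = np.mgrid[0:H, 0:W]
    pix = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    tree = cKDTree(maxima)
    dist_px, _ = tree.query(pix)
    dist = dist_px * pixel_size
    if r_max is None:
        r_max = float(dist.max()) + bin_width
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    which = np.digitize(dist, edges) - 1

    records = []
    for ch, img in images.items():
        vals = np.asarray(img, dtype=float).ravel()
        for b in range(len(edges) - 1):
            m = which == b
            if not m.any():
                continue  # empty bin: missing, not zero
            records.append(
                {
                    "channel": ch,
                    "r_nm": 0.5 * (edges[b] + edges[b + 1]),
                    "mean_intensity": float(vals[m].mean()),
                    "n_pixels": int(m.sum()),
                }
            )
    return pd.DataFrame.from_records(records)


def widefield_sigma(emission_wavelength: float, na: float) -> float:
    """Gaussian sd of the diffraction-limited wide-field PSF.

    The wide-field resolution FWHM = wavelength / (2·NA) (Abbe), converted to
    a Gaussian sd via FWHM = 2·sqrt(2·ln2)·sigma.
    """
    if emission_wavelength <= 0 or na <= 0:
        raise ValueError("wavelength and NA must be positive")
    return (emission_wavelength / (2.0 * na)) / FWHM_FACTOR


def render_sigma(sigma_widefield: float, localization_sigma: float) -> float:
    """Blur sd that degrades a localization image to wide-field resolution.

    Localization uncertainty already blurs the data by ``localization_sigma``,
    so only the quadrature complement is applied:
    sigma_render = sqrt(sigma_widefield² - sigma_localization²).
    """
    if sigma_widefield <= localization_sigma:
        raise ValueError("wide-field sigma must exceed the localization sigma")
    return math.sqrt(sigma_widefield**2 - localization_sigma**2)


def render_diffraction_limited(
    table: LocalizationTable,
    channel,
    emission_wavelength: float = 680.0,
    na: float = 1.49,
    localization_sigma: float = 10.0,
    pixel_size: float = 105.0,
) -> np.ndarray:
    """Render one channel of a localization table at wide-field resolution.

    Points are binned at the camera pixel size and blurred with the quadrature
    blur from :func:`render_sigma`.  Total intensity equals the number of
    points (the blur conserves mass).
    """
    sw = widefield_sigma(emission_wavelength, na)
    sr = render_sigma(sw, localization_sigma)
    pts = table.channel(channel)
    x0, y0, x1, y1 = table.window
    sig_px = sr / pixel_size
    margin = int(math.ceil(6.0 * sig_px)) + 1
    W = int(math.ceil((x1 - x0) / pixel_size)) + 2 * margin
    H = int(math.ceil((y1 - y0) / pixel_size)) + 2 * margin
    img = np.zeros((H, W))
    if len(pts):
        cols = np.clip(((pts[:, 0] - x0) / pixel_size).astype(int) + margin, 0, W - 1)
        rows = np.clip(((pts[:, 1] - y0) / pixel_size).astype(int) + margin, 0, H - 1)
        np.add.at(img, (rows, cols), 1.0)
    return gaussian_filter(img, sigma=sig_px, mode="constant", truncate=6.0)
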