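"""Forward simulation of newly exocytosed protein dynamics and localization patterns.

Two generators live here:

* :func:`simulate_fusion_sequence` renders a pHluorin-style time-lapse of a
  single presynaptic bouton in which successive vesicle fusion events deposit
  molecules that spread by free 2D Brownian motion, are optionally confined by
  a reflecting boundary, recluster toward capture sites after stimulation, and
  photobleach — together with the underlying molecule trajectories as ground
  truth.
* :func:`simulate_point_pattern` draws complete-spatial-randomness (CSR) or
  parent–offspring clustered localization tables, optionally dual-channel with
  a shared-parent fraction, emulating single-molecule localization data.

All randomness flows through a single integer seed; identical parameters and
seed give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "AxonGeometry",
    "FusionGroundTruth",
    "ImageSequence",
    "LocalizationTable",
    "MoleculeTrajectories",
    "default_event_times",
    "recluster_rate_for_halftime",
    "simulate_fusion_sequence",
    "simulate_point_pattern",
]

#: number of Brownian sub-steps integrated per rendered frame
SUBSTEPS_PER_FRAME = 10


def default_event_times(stim_start: float, n_events: int = 40, rate_hz: float = 20.0) -> tuple[float, ...]:
    """Fusion-event train for an action-potential burst.

    Events are spaced 1/rate_hz apart starting at ``stim_start`` — the layout
    of a 40-AP, 20-Hz, 2-s field stimulus.
    """
    return tuple(stim_start + i / rate_hz for i in range(n_events))


def recluster_rate_for_halftime(t_half: float) -> float:
    """Drift rate ``k`` such that the ensemble FWHM² decays with half-time ``t_half``.

    A deterministic exponential approach of positions, x(t) = s + (x0-s)·e^(-kt),
    makes the ensemble position *variance* — and with it the fitted FWHM² —
    decay as e^(-2kt).  The half-time of the FWHM² trace is therefore
    ln2/(2k); inverting gives k = ln2 / (2·t_half).
    """
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    return math.log(2.0) / (2.0 * t_half)


@dataclass(frozen=True)
class AxonGeometry:
    """A transmitting gap in the bouton boundary feeding a rectangular axon strip.

    The strip runs along +x from the bouton edge; molecules whose |y| is below
    ``gap_halfwidth`` may cross the circular boundary and diffuse in the strip.
    """

    gap_halfwidth: float  # um, half-width of the opening around y=0
    strip_length: float  # um, extent of the strip beyond the bouton edge
    strip_halfwidth: float | None = None  # um; defaults to gap_halfwidth

    def __post_init__(self):
        if self.gap_halfwidth <= 0 or self.strip_length <= 0:
            raise ValueError("axon gap and strip length must be positive")
        if self.strip_halfwidth is None:
            object.__setattr__(self, "strip_halfwidth", self.gap_halfwidth)


@dataclass(frozen=True)
class FusionGroundTruth:
    """Complete parameter set (and thus ground truth) of a fusion-diffusion simulation.

    Units: um, seconds, camera counts.  ``bleach_lifetime=inf`` disables
    bleaching; ``bouton_radius=None`` disables confinement; ``recluster_rate=0``
    disables reclustering (which otherwise switches on after ``stim_end``).
    """

    D: float = 0.30  # um^2/s, free diffusion coefficient
    event_times: tuple[float, ...] = ()  # s, fusion times within [stim_start, stim_end]
    molecules_per_event: int = 50
    bouton_radius: float | None = 1.15  # um (~2 um² confinement area); None = unbounded
    recluster_rate: float = 0.0  # 1/s drift rate toward nearest recluster site
    recluster_sites: tuple[tuple[float, float], ...] = ((0.0, 0.0),)
    recluster_D: float = 0.004  # um^2/s residual mobility while reclustering
    bleach_lifetime: float = math.inf  # s (tau); inf = no bleaching
    background: float = 100.0  # camera counts
    noise_sd: float = 0.0  # additive Gaussian noise, counts
    psf_sigma: float = 0.15  # um
    pixel_size: float = 0.105  # um
    frame_interval: float = 0.4  # s
    stim_start: float = 2.0  # s
    stim_end: float = 4.0  # s
    n_frames: int = 30
    image_shape: tuple[int, int] = (48, 48)  # (H, W) pixels
    fusion_scatter: float = 0.0  # um, sd of fusion-site scatter around centre
    resting_molecules: int = 0  # pre-existing (un-eclipsed) surface molecules
    axon_geometry: AxonGeometry | None = None
    seed: int = 0

    def __post_init__(self):
        if not np.isfinite(self.D) or self.D < 0:
            raise ValueError("D must be finite and >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.bouton_radius is not None and self.bouton_radius <= 0:
            raise ValueError("bouton_radius must be positive when set")
        if self.stim_start >= self.stim_end:
            raise ValueError("stim_start must precede stim_end")
        if self.stim_end > (self.n_frames - 1) * self.frame_interval:
            raise ValueError("stimulus window must end within the acquisition")
        for t in self.event_times:
            if not (self.stim_start <= t <= self.stim_end):
                raise ValueError("all event_times must lie in [stim_start, stim_end]")
        if self.recluster_rate < 0 or self.recluster_D < 0:
            raise ValueError("recluster parameters must be >= 0")
        if self.recluster_rate > 0 and not self.event_times and self.resting_molecules == 0:
            raise ValueError("reclustering requested but no molecules will ever exist")
        if self.psf_sigma <= 0 or self.pixel_size <= 0:
            raise ValueError("psf_sigma and pixel_size must be positive")
        if self.noise_sd < 0 or self.bleach_lifetime <= 0:
            raise ValueError("noise_sd >= 0 and bleach_lifetime > 0 required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bleach_lifetime"] = None if math.isinf(self.bleach_lifetime) else self.bleach_lifetime
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FusionGroundTruth":
        d = dict(d)
        if d.get("bleach_lifetime") is None:
            d["bleach_lifetime"] = math.inf
        if d.get("axon_geometry") is not None:
            d["axon_geometry"] = AxonGeometry(**d["axon_geometry"])
        d["event_times"] = tuple(d.get("event_times", ()))
        d["recluster_sites"] = tuple(tuple(s) for s in d.get("recluster_sites", ((0.0, 0.0),)))
        d["image_shape"] = tuple(d.get("image_shape", (48, 48)))
        return cls(**d)


@dataclass
class ImageSequence:
    """Time-ordered stack of 2D intensity frames with acquisition metadata."""

    frames: np.ndarray  # (T, H, W) float
    pixel_size: float = 0.105  # um
    frame_interval: float = 0.4  # s
    stim_start: float = 2.0  # s
    stim_end: float = 4.0  # s

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if not (self.stim_start < self.stim_end <= self.times[-1]):
            raise ValueError("need stim_start < stim_end <= last frame time")

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame 0 at t=0)."""
        return np.arange(self.frames.shape[0]) * self.frame_interval

    @property
    def n_pre_stim(self) -> int:
        """Number of frames acquired strictly before stimulus onset."""
        return int(np.sum(self.times < self.stim_start))

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of pixel centres, origin at image centre, um."""
        H, W = self.frames.shape[1:]
        x = (np.arange(W) + 0.5 - W / 2) * self.pixel_size
        y = (np.arange(H) + 0.5 - H / 2) * self.pixel_size
        return x, y

    # --- I/O: multi-page TIFF + JSON sidecar -------------------------------
    def save(self, path: str | Path, ground_truth: FusionGroundTruth | None = None) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.frames.astype(np.float32))
        meta = {
            "pixel_size": self.pixel_size,
            "frame_interval": self.frame_interval,
            "stim_start": self.stim_start,
            "stim_end": self.stim_end,
        }
        if ground_truth is not None:
            meta["ground_truth"] = ground_truth.to_dict()
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ImageSequence":
        path = Path(path)
        frames = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            frames=np.asarray(frames, dtype=float),
            pixel_size=meta["pixel_size"],
            frame_interval=meta["frame_interval"],
            stim_start=meta["stim_start"],
            stim_end=meta["stim_end"],
        )


@dataclass
class MoleculeTrajectories:
    """Ground-truth molecule positions at frame times.

    ``positions[t, i]`` is (x, y) in um of molecule i at frame t, NaN before the
    molecule's fusion event.  ``birth_times`` records when each molecule appeared
    (0 for resting-pool molecules).
    """

    positions: np.ndarray  # (T, N, 2)
    birth_times: np.ndarray  # (N,)

    def alive(self, frame: int, frame_interval: float) -> np.ndarray:
        return self.birth_times <= frame * frame_interval + 1e-12


@dataclass
class LocalizationTable:
    """Point localizations (nm) with a per-point channel label and ROI window."""

    points: pd.DataFrame  # columns x_nm, y_nm, channel
    window: tuple[float, float, float, float]  # (x0, y0, x1, y1) nm

    def __post_init__(self):
        x0, y0, x1, y1 = self.window
        if x1 <= x0 or y1 <= y0:
            raise ValueError("window must have positive area")
        p = self.points
        if len(p) and not (
            (p.x_nm >= x0).all() and (p.x_nm <= x1).all() and (p.y_nm >= y0).all() and (p.y_nm <= y1).all()
        ):
            raise ValueError("all points must lie inside the window")

    def channel(self, label) -> np.ndarray:
        """(n, 2) coordinate array of one channel."""
        sel = self.points[self.points.channel == label]
        return sel[["x_nm", "y_nm"]].to_numpy(dtype=float)

    @property
    def channels(self) -> list:
        return sorted(self.points.channel.unique().tolist())

    def to_csv(self, path: str | Path) -> None:
        self.points.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, window: tuple[float, float, float, float] | None = None) -> "LocalizationTable":
        pts = pd.read_csv(path)
        if window is None:
            window = (pts.x_nm.min(), pts.y_nm.min(), pts.x_nm.max(), pts.y_nm.max())
        return cls(points=pts, window=window)


# ---------------------------------------------------------------------------
# fusion-diffusion simulation
# ---------------------------------------------------------------------------


def _inside(params: FusionGroundTruth, pos: np.ndarray) -> np.ndarray:
    """Boolean mask of positions inside the allowed domain (disk + optional strip)."""
    R = params.bouton_radius
    if R is None:
        return np.ones(len(pos), dtype=bool)
    r2 = pos[:, 0] ** 2 + pos[:, 1] ** 2
    ok = r2 <= R * R
    ax = params.axon_geometry
    if ax is not None:
        in_strip = (
            (pos[:, 0] >= 0)
            & (pos[:, 0] <= R + ax.strip_length)
            & (np.abs(pos[:, 1]) <= ax.strip_halfwidth)
        )
        ok = ok | in_strip
    return ok


def _reflect(params: FusionGroundTruth, pos: np.ndarray) -> None:
    """Reflect positions back into the domain, in place.

    Sub-frame steps are short relative to the geometry, so a single radial
    (disk) or mirror (strip walls) reflection suffices; a final clip guards
    pathological multi-reflection cases.
    """
    R = params.bouton_radius
    if R is None:
        return
    ax = params.axon_geometry
    out = ~_inside(params, pos)
    if not out.any():
        return
    idx = np.flatnonzero(out)
    p = pos[idx]
    if ax is not None:
        # molecules just outside the strip walls/end: mirror back into the strip
        strip_like = (p[:, 0] >= 0) & (p[:, 0] ** 2 + p[:, 1] ** 2 > R * R)
        sl = strip_like & (np.abs(p[:, 1]) <= 3 * ax.strip_halfwidth)
        if sl.any():
            q = p[sl]
            w = ax.strip_halfwidth
            q[:, 1] = np.where(q[:, 1] > w, 2 * w - q[:, 1], q[:, 1])
            q[:, 1] = np.where(q[:, 1] < -w, -2 * w - q[:, 1], q[:, 1])
            xmax = R + ax.strip_length
            q[:, 0] = np.where(q[:, 0] > xmax, 2 * xmax - q[:, 0], q[:, 0])
            np.clip(q[:, 1], -w, w, out=q[:, 1])
            np.clip(q[:, 0], 0.0, xmax, out=q[:, 0])
            p[sl] = q
        rad = ~sl
    else:
        rad = np.ones(len(p), dtype=bool)
    if rad.any():
        q = p[rad]
        r = np.sqrt(q[:, 0] ** 2 + q[:, 1] ** 2)
        rr = np.where(r > R, 2 * R - r, r)  # radial mirror at the boundary
        rr = np.clip(rr, 0.0, R)
        scale = np.where(r > 0, rr / np.maximum(r, 1e-300), 0.0)
        p[rad] = q * scale[:, None]
    pos[idx] = p


def _render_frame(
    pos: np.ndarray,
    shape: tuple[int, int],
    pixel_size: float,
    psf_sigma: float,
) -> np.ndarray:
    """Sum unit-peak Gaussian PSFs at molecule positions onto the pixel grid."""
    H, W = shape
    img = np.zeros((H, W), dtype=float)
    if len(pos) == 0:
        return img
    # pixel-centre coordinates in um, origin at image centre
    half = max(3, int(math.ceil(4 * psf_sigma / pixel_size)))
    # molecule position in fractional pixel units
    px = pos[:, 0] / pixel_size + W / 2 - 0.5
    py = pos[:, 1] / pixel_size + H / 2 - 0.5
    cx = np.round(px).astype(int)
    cy = np.round(py).astype(int)
    off = np.arange(-half, half + 1)
    ox, oy = np.meshgrid(off, off)  # (k, k)
    ix = cx[:, None, None] + ox[None]  # (N, k, k)
    iy = cy[:, None, None] + oy[None]
    dx = (ix - px[:, None, None]) * pixel_size
    dy = (iy - py[:, None, None]) * pixel_size
    vals = np.exp(-(dx * dx + dy * dy) / (2.0 * psf_sigma**2))
    ok = (ix >= 0) & (ix < W) & (iy >= 0) & (iy < H)
    np.add.at(img, (iy[ok], ix[ok]), vals[ok])
    return img


def simulate_fusion_sequence(
    params: FusionGroundTruth,
) -> tuple[ImageSequence, MoleculeTrajectories]:
    """Simulate a bouton time-lapse of successively fusing vesicles.

    Molecules are deposited at the fusion site at each event time and move by
    2D Brownian steps (per-axis step variance 2·D·Δt, Δt = frame_interval/10)
    with a reflecting boundary at ``bouton_radius``.  After ``stim_end``, if
    ``recluster_rate`` k > 0, each molecule instead drifts toward its nearest
    recluster site by the deterministic exponential map
    x → s + (x−s)·e^(−kΔt), superposed with diffusion at ``recluster_D``.
    Frames are rendered by summing unit-peak Gaussian PSFs, scaled by the
    photobleaching factor e^(−t/τ), plus background and Gaussian noise.

    Returns the rendered :class:`ImageSequence` and ground-truth
    :class:`MoleculeTrajectories`.
    """
    rng = np.random.default_rng(params.seed)
    T = params.n_frames
    dt = params.frame_interval / SUBSTEPS_PER_FRAME
    sites = np.asarray(params.recluster_sites, dtype=float).reshape(-1, 2)

    # birth schedule: resting pool first (t=0), then event molecules
    births: list[float] = [0.0] * params.resting_molecules
    for et in params.event_times:
        births.extend([et] * params.molecules_per_event)
    birth_times = np.asarray(births, dtype=float)
    N = len(birth_times)

    pos = np.full((N, 2), np.nan)
    if params.resting_molecules:
        # residual surface pool, uniform on the bouton disk (or near centre if unbounded)
        R0 = params.bouton_radius if params.bouton_radius is not None else 0.5
        rr = R0 * np.sqrt(rng.random(params.resting_molecules))
        th = rng.random(params.resting_molecules) * 2 * np.pi
        pos[: params.resting_molecules, 0] = rr * np.cos(th)
        pos[: params.resting_molecules, 1] = rr * np.sin(th)

    traj = np.full((T, N, 2), np.nan)
    frames = np.empty((T,) + tuple(params.image_shape), dtype=float)

    sigma_free = math.sqrt(2.0 * params.D * dt)
    sigma_rec = math.sqrt(2.0 * params.recluster_D * dt)
    decay = math.exp(-params.recluster_rate * dt)

    def render_at(t: float) -> np.ndarray:
        alive = birth_times <= t + 1e-12
        img = _render_frame(pos[alive], params.image_shape, params.pixel_size, params.psf_sigma)
        if math.isfinite(params.bleach_lifetime):
            img *= math.exp(-t / params.bleach_lifetime)
        img += params.background
        if params.noise_sd > 0:
            img += rng.normal(0.0, params.noise_sd, size=img.shape)
        return img

    # frame 0 rendered before any dynamics
    traj[0] = pos
    frames[0] = render_at(0.0)

    for m in range(1, T):
        t0 = (m - 1) * params.frame_interval
        for s in range(SUBSTEPS_PER_FRAME):
            ta, tb = t0 + s * dt, t0 + (s + 1) * dt
            # deposit molecules whose event time falls in (ta, tb]
            newborn = (birth_times > ta + 1e-12) & (birth_times <= tb + 1e-12)
            if newborn.any():
                k = int(newborn.sum())
                xy = np.zeros((k, 2))
                if params.fusion_scatter > 0:
                    xy = rng.normal(0.0, params.fusion_scatter, size=(k, 2))
                pos[newborn] = xy
            alive = birth_times <= tb + 1e-12
            na = int(alive.sum())
            if na == 0:
                continue
            reclustering = params.recluster_rate > 0 and tb > params.stim_end
            if reclustering:
                p = pos[alive]
                # drift toward the nearest recluster site
                d2 = ((p[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
                s_near = sites[np.argmin(d2, axis=1)]
                p = s_near + (p - s_near) * decay
                if sigma_rec > 0:
                    p = p + rng.normal(0.0, sigma_rec, size=p.shape)
                pos[alive] = p
            elif sigma_free > 0:
                pos[alive] += rng.normal(0.0, sigma_free, size=(na, 2))
            p = pos[alive]  # fancy indexing copies; reflect then write back
            _reflect(params, p)
            pos[alive] = p
        tm = m * params.frame_interval
        traj[m] = pos
        frames[m] = render_at(tm)

    seq = ImageSequence(
        frames=frames,
        pixel_size=params.pixel_size,
        frame_interval=params.frame_interval,
        stim_start=params.stim_start,
        stim_end=params.stim_end,
    )
    return seq, MoleculeTrajectories(positions=traj, birth_times=birth_times)


# ---------------------------------------------------------------------------
# point patterns
# ---------------------------------------------------------------------------


def simulate_point_pattern(
    kind: Literal["CSR", "clustered"],
    window: tuple[float, float, float, float],
    *,
    n_points: int | None = 200,
    poisson: bool = False,
    n_parents: int = 10,
    mean_offspring: float = 20.0,
    cluster_sigma: float = 50.0,
    channels: Sequence[str] = ("A",),
    shared_parent_fraction: float = 0.0,
    seed: int = 0,
) -> LocalizationTable:
    """Draw a CSR or parent–offspring clustered localization table.

    CSR: ``n_points`` uniform points (or Poisson(n_points) when ``poisson``).
    Clustered: ``n_parents`` uniform parents each spawning Poisson
    (``mean_offspring``) offspring displaced by an isotropic Gaussian of sd
    ``cluster_sigma`` (nm); offspring falling outside the window are redrawn.
    With two channels, a ``shared_parent_fraction`` of parents is common to
    both (offspring counts shared, displacements independent), the remainder
    drawn independently per channel — a controllable co-clustering pattern.
    """
    x0, y0, x1, y1 = window
    if x1 <= x0 or y1 <= y0:
        raise ValueError("window must have positive area")
    if kind not in ("CSR", "clustered"):
        raise ValueError(f"unknown pattern kind: {kind!r}")
    if kind == "CSR" and (n_points is None or n_points < 0):
        raise ValueError("CSR requires n_points >= 0")
    if kind == "clustered" and (n_parents < 0 or mean_offspring < 0 or cluster_sigma < 0):
        raise ValueError("clustered pattern requires non-negative counts and radius")
    if not 0.0 <= shared_parent_fraction <= 1.0:
        raise ValueError("shared_parent_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []

    def uniform(n):
        return np.column_stack(
            [rng.uniform(x0, x1, size=n), rng.uniform(y0, y1, size=n)]
        )

    if kind == "CSR":
        for ch in channels:
            n = int(rng.poisson(n_points)) if poisson else int(n_points)
            pts = uniform(n)
            rows.append(pd.DataFrame({"x_nm": pts[:, 0], "y_nm": pts[:, 1], "channel": ch}))
    else:
        n_shared = int(round(shared_parent_fraction * n_parents)) if len(channels) > 1 else 0
        shared_parents = uniform(n_shared)
        shared_counts = rng.poisson(mean_offspring, size=n_shared)
        for ch in channels:
            own = uniform(n_parents - n_shared)
            parents = np.vstack([shared_parents, own]) if len(own) else shared_parents
            counts = np.concatenate([shared_counts, rng.poisson(mean_offspring, size=len(own))])
            pts = []
            for (px, py), c in zip(parents, counts):
                for _ in range(int(c)):
                    while True:  # redraw offspring that leave the window
                        ox, oy = px, py
                        if cluster_sigma > 0:
                            ox, oy = rng.normal((px, py), cluster_sigma)
                        if x0 <= ox <= x1 and y0 <= oy <= y1:
                            pts.append((ox, oy))
                            break
            arr = np.asarray(pts, dtype=float).reshape(-1, 2)
            rows.append(pd.DataFrame({"x_nm": arr[:, 0], "y_nm": arr[:, 1], "channel": ch}))

    points = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["x_nm", "y_nm", "channel"])
    return LocalizationTable(points=points, window=window)
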