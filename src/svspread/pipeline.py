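"""Batch orchestration: simulate -> preprocess -> fit -> model -> report.

A :class:`RunConfig` (JSON-serialisable) fully determines a run; identical
configs and seeds give identical reports (timestamps excluded).  Every stage
writes its artifacts (TIFF/CSV/JSON) into the output directory so any stage
can be re-run and audited from its persisted inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffmodel import estimate_D
from .pointstats import L_minus_r, csr_envelope, knn_cross, ripley_K, toroidal_shift
from .preproc import (
    bleach_correct,
    compute_deltaF,
    detect_responding_synapses,
    fit_bleach_model,
    measure_axonal_escape,
)
from .simcore import (
    FusionGroundTruth,
    ImageSequence,
    LocalizationTable,
    simulate_fusion_sequence,
    simulate_point_pattern,
)
from .spreadfit import FWHMTrace, extract_fwhm_trace, trace_metrics

log = logging.getLogger("svspread.pipeline")

__all__ = ["RunConfig", "run_pipeline", "validate_config"]


@dataclass
class RunConfig:
    """Declarative description of a full analysis run."""

    outdir: str = "svspread_run"
    seed: int | None = 0
    # input: either a simulation block or a TIFF (+ JSON sidecar) path
    simulation: FusionGroundTruth | None = None
    input_tiff: str | None = None
    # stage toggles
    run_imaging: bool = True
    run_pointstats: bool = False
    # preprocessing
    n_pre: int = 5
    bleach_correction: bool = True
    measure_escape: bool = False
    # spread fitting
    filter_window: int = 5
    # diffusion model
    fit_window: tuple[float, float] = (0.8, 2.0)
    psf_sigma0: float | None = None  # None: use the simulation PSF sigma
    d_bracket: tuple[float, float] = (0.01, 2.0)
    # point statistics
    localization_csv: str | None = None
    pattern: dict | None = None  # kwargs for simulate_point_pattern
    ripley_radii: tuple[float, ...] = tuple(float(r) for r in range(10, 260, 10))
    n_sim_envelope: int = 10
    knn_k: int = 10
    knn_bin_width: float = 10.0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if d.get("simulation") is not None:
            d["simulation"] = FusionGroundTruth.from_dict(d["simulation"])
        if d.get("fit_window") is not None:
            d["fit_window"] = tuple(d["fit_window"])
        if d.get("d_bracket") is not None:
            d["d_bracket"] = tuple(d["d_bracket"])
        if d.get("ripley_radii") is not None:
            d["ripley_radii"] = tuple(d["ripley_radii"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        """Hash of the analysis-relevant config (output location excluded)."""
        d = json.loads(self.to_json())
        d.pop("outdir", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Return every violated invariant without executing any stage."""
    problems: list[str] = []
    if config.seed is None and (config.simulation is not None or config.pattern is not None):
        problems.append("stochastic stages enabled but no seed set")
    if config.run_imaging and config.simulation is None and config.input_tiff is None:
        problems.append("imaging stages enabled but neither simulation block nor input_tiff given")
    if config.simulation is not None:
        sim = config.simulation
        if sim.pixel_size <= 0:
            problems.append("pixel_size must be positive")
        lo, hi = config.fit_window
        if not (0 <= lo < hi):
            problems.append("fit_window must satisfy 0 <= start < end")
        elif hi > sim.stim_end - sim.stim_start:
            problems.append("fit_window extends beyond the stimulation period")
    if config.filter_window < 1 or config.filter_window % 2 == 0:
        problems.append("filter_window must be odd and >= 1")
    if config.n_pre < 1:
        problems.append("n_pre must be >= 1")
    if config.knn_k < 1:
        problems.append("knn_k must be >= 1")
    if config.n_sim_envelope < 1:
        problems.append("n_sim_envelope must be >= 1")
    if config.run_pointstats and config.localization_csv is None and config.pattern is None:
        problems.append("pointstats enabled but neither localization_csv nor pattern given")
    if config.pattern is not None:
        if config.pattern.get("n_parents", 1) < 0 or config.pattern.get("cluster_sigma", 0) < 0:
            problems.append("pattern counts and radii must be non-negative")
    return problems


def _imaging_stages(config: RunConfig, outdir: Path, report: dict) -> None:
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed if config.seed is not None else config.simulation.seed)
        seq, traj = simulate_fusion_sequence(sim)
        seq.save(outdir / "sequence.tif", ground_truth=sim)
        log.info("simulated %d frames, %d molecules", seq.frames.shape[0], traj.positions.shape[1])
    else:
        seq = ImageSequence.load(Path(config.input_tiff))
        sim = None

    if config.bleach_correction:
        model = fit_bleach_model(seq)
        report["bleach"] = {
            "n_pixels_fit": int(model.fit_ok.sum()),
            "median_lifetime_s": float(np.median(model.tau[model.fit_ok])) if model.fit_ok.any() else None,
        }
        seq = bleach_correct(seq, model)

    dF = compute_deltaF(seq, n_pre=config.n_pre)
    rois = detect_responding_synapses(dF)
    pd.DataFrame(
        [
            {
                "roi_id": r.roi_id, "x0": r.x0, "y0": r.y0, "x1": r.x1, "y1": r.y1,
                "area_um2": r.area_um2, "responding": r.responding,
            }
            for r in rois
        ]
    ).to_csv(outdir / "rois.csv", index=False)
    report["rois"] = []
    log.info("detected %d responding ROI(s)", len(rois))

    psf0 = config.psf_sigma0
    if psf0 is None and sim is not None:
        psf0 = sim.psf_sigma
    if psf0 is None:
        psf0 = 0.0

    for roi in rois:
        entry: dict = {"roi_id": roi.roi_id, "area_um2": roi.area_um2}
        trace = extract_fwhm_trace(dF, roi)
        trace.to_frame().to_csv(outdir / f"fwhm_trace_roi{roi.roi_id}.csv", index=False)
        tm = trace_metrics(trace, filter_window=config.filter_window)
        entry["metrics"] = {
            "max_spread_um2": tm.max_spread,
            "last_fwhm2_um2": tm.last_fwhm2,
            "t_half_s": tm.t_half if tm.t_half_defined else None,
        }
        # intensity increments: frame-to-frame increase of summed dF over the patch
        total = dF.frames[:, roi.y0 : roi.y1, roi.x0 : roi.x1].sum(axis=(1, 2))
        onset = int(np.searchsorted(dF.times, dF.stim_start))
        if onset == 0:
            raise RuntimeError("no pre-stimulus frame before onset")
        inc = np.diff(total)[onset - 1 :]
        shifted = FWHMTrace(
            times=trace.times[onset:] - dF.stim_start,
            fwhm2=trace.fwhm2[onset:],
            amplitude=trace.amplitude[onset:],
            valid=trace.valid[onset:],
        )
        fit = estimate_D(
            shifted,
            inc[: len(shifted.times)],
            dF.frame_interval,
            fit_window=config.fit_window,
            psf_sigma0=psf0,
            bracket=config.d_bracket,
        )
        entry["diffusion"] = {
            "D_est_um2_per_s": fit.D_est if fit.valid else None,
            "exp_slope_um2_per_s": fit.exp_slope,
            "valid": fit.valid,
        }
        pd.DataFrame({"time_s": fit.times, "model_fwhm2_um2": fit.model_fwhm2}).to_csv(
            outdir / f"model_trace_roi{roi.roi_id}.csv", index=False
        )
        if config.measure_escape:
            try:
                axon = measure_axonal_escape(dF, roi)
                entry["axon_escape_final_dF"] = float(axon[-1])
                pd.DataFrame({"time_s": dF.times, "axon_dF": axon}).to_csv(
                    outdir / f"axon_trace_roi{roi.roi_id}.csv", index=False
                )
            except ValueError as e:
                entry["axon_escape_error"] = str(e)
        report["rois"].append(entry)


def _pointstats_stage(config: RunConfig, outdir: Path, report: dict) -> None:
    if config.pattern is not None:
        kwargs = dict(config.pattern)
        kind = kwargs.pop("kind", "clustered")
        window = tuple(kwargs.pop("window", (0.0, 0.0, 1000.0, 1000.0)))
        kwargs.setdefault("seed", config.seed if config.seed is not None else 0)
        table = simulate_point_pattern(kind, window, **kwargs)
        table.to_csv(outdir / "localizations.csv")
    else:
        table = LocalizationTable.from_csv(Path(config.localization_csv))
    radii = np.asarray(config.ripley_radii, dtype=float)
    stats: dict = {"channels": {}}
    for ch in table.channels:
        pts = table.channel(ch)
        if len(pts) < 2:
            continue
        res = L_minus_r(ripley_K(pts, table.window, radii))
        env = csr_envelope(
            table.window, res.N, res.radii,
            n_sim=config.n_sim_envelope,
            seed=(config.seed or 0) + 1,
        )
        pd.DataFrame(
            {"r_nm": res.radii, "K_nm2": res.K, "L_minus_r_nm": res.L_minus_r, "envelope_upper_nm": env}
        ).to_csv(outdir / f"ripley_{ch}.csv", index=False)
        stats["channels"][str(ch)] = {
            "N": res.N,
            "max_L_minus_r_nm": float(np.max(res.L_minus_r)),
            "r_at_max_nm": float(res.radii[int(np.argmax(res.L_minus_r))]),
            "exceeds_csr_envelope": bool(np.any(res.L_minus_r > env)),
        }
    chs = table.channels
    if len(chs) >= 2:
        q, ref = table.channel(chs[0]), table.channel(chs[1])
        if len(ref) >= config.knn_k:
            res = knn_cross(q, ref, k=config.knn_k, bin_width=config.knn_bin_width)
            null = knn_cross(
                q, toroidal_shift(ref, table.window),
                k=config.knn_k, bin_width=config.knn_bin_width,
            )
            stats["knn"] = {
                "k": config.knn_k,
                "query": str(chs[0]),
                "reference": str(chs[1]),
                "median_distance_nm": float(np.median(res.distances)),
                "null_median_distance_nm": float(np.median(null.distances)),
            }
            pd.DataFrame({"knn_nm": res.distances, "null_knn_nm": null.distances}).to_csv(
                outdir / "knn_distances.csv", index=False
            )
    report["pointstats"] = stats


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages and return (and persist) the run report."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json())

    report: dict = {
        "provenance": {
            "package": "svspread",
            "version": __version__,
            "config_hash": config.config_hash,
            "seed": config.seed,
        }
    }
    if config.run_imaging and (config.simulation is not None or config.input_tiff is not None):
        _imaging_stages(config, outdir, report)
    if config.run_pointstats:
        _pointstats_stage(config, outdir, report)

    payload = json.dumps(report, indent=1, sort_keys=True)
    report["timestamp"] = datetime.now(timezone.utc).isoformat()
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    report["_payload"] = payload  # deterministic part, for byte-identity checks
    return report
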