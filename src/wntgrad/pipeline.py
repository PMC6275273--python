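"""End-to-end orchestration of the synthetic gradient-orientation study.

``run_pipeline`` executes the stages in dependency order, each writing its
outputs into its own subdirectory of the run directory:

1. ``calibration`` — bead z-stack, decay fit, correction round-trip;
2. ``gradient``   — gradient + reference images, flat-field normalization,
   per-ROI erfc fits, per-ROI dC1/dC2 medians and the valid-region mask;
3. ``cells``      — synthetic mitotic cohort over the valid region,
   toward-gradient / toward-upstream exact binomial tests, rose histograms;
4. ``bins``       — equal-count exposure bins per phase and the derived
   sensitivity threshold;
5. ``stability``  — image time series, measured dC1 fluctuation sigma
   against the planted truth.

Every run writes a serialized copy of its configuration and a report whose
numbers are all traceable to stage output files.  Reruns with the same
config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import axisstats, calibration, gradientfit, io, synthdata
from .models import ChannelGeometry, FlowParams, ResponseModel

__all__ = ["RunConfig", "run_pipeline", "export_figure_data", "load_config"]


class GeometryConfig(BaseModel):
    width_um: float = 1000.0
    length_um: float = 10_000.0
    height_um: float = 160.0
    microgroove_width_um: float = 250.0
    n_grooves: int = 20
    pixel_size_um: float = 2.7

    def build(self) -> ChannelGeometry:
        return ChannelGeometry(**self.model_dump())


class FlowConfig(BaseModel):
    flow_rate_ul_min: float = 2.0
    diffusivity_um2_s: float = 50.0
    source_conc_ng_ml: float = 30.0
    mw_kda: float = 38.0

    def build(self, geometry: ChannelGeometry) -> FlowParams:
        return FlowParams.from_flow_rate(
            self.flow_rate_ul_min, geometry,
            diffusivity_um2_s=self.diffusivity_um2_s,
            source_conc_ng_ml=self.source_conc_ng_ml, mw_kda=self.mw_kda)


class ResponseConfig(BaseModel):
    threshold_nM_per_um: float = Field(default=1.0e-3, ge=0.0)
    p_toward: float = Field(default=0.7, ge=0.5, le=1.0)
    kappa: float = Field(default=2.0, ge=0.0)
    logistic_width_nM_per_um: float = 0.0

    def build(self) -> ResponseModel:
        return ResponseModel(**self.model_dump())


class FitConfig(BaseModel):
    mode: str = "free"              # or "constrained"
    halved_dc1: bool = False        # alternative reading of the dC1 formula
    halved_dc2: bool = True
    wall_margin_um: float = 50.0
    x_interface_um: float = 450.0


class AnalysisConfig(BaseModel):
    k_bins: int = 4
    alpha: float = 0.05
    cell_diameter_um: float = 30.0
    window_px: int = 11
    ratio_threshold: float = 0.5
    # default mirrors the original analysis area (groove channels 1-15);
    # set to null in the config to apply the data-driven dC2/dC1 ratio rule
    roi_override: list[int] | None = Field(
        default_factory=lambda: list(range(1, 16)))
    phases: list[str] = Field(
        default_factory=lambda: ["metaphase", "postmetaphase"])


class SimulateConfig(BaseModel):
    n_cells: int = 400
    noise_sd: float = 0.01
    downstream_disturbance: float = 0.6
    disturbance_from_roi: int = 16
    inlet_offset_um: float = 5000.0
    bead_noise_sd: float = 0.01
    n_beads: int = 12
    n_planes: int = 21
    z_range_um: tuple[float, float] = (0.0, 20.0)
    decay: tuple[float, float, float] = (0.645, -0.200, 0.352)
    intervals_s: list[float] = Field(default_factory=lambda: [1.0, 10.0, 100.0, 1000.0])
    n_frames: int = 10
    drift_sd: float = 0.0
    sigma_positions_um: list[float] = Field(
        default_factory=lambda: [200.0, 400.0, 600.0])


class RunConfig(BaseModel):
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "runs/demo"
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    flow: FlowConfig = Field(default_factory=FlowConfig)
    response: ResponseConfig = Field(default_factory=ResponseConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def _stage_calibration(cfg: RunConfig, out: Path) -> dict:
    import pandas as pd

    sim = cfg.simulate
    stack, truth = synthdata.generate_bead_stack(
        decay=sim.decay, n_beads=sim.n_beads, z_range_um=sim.z_range_um,
        noise_sd=sim.bead_noise_sd, seed=cfg.seed, n_planes=sim.n_planes)
    positions, _ = calibration.detect_bead_peaks(stack)
    readings = calibration.measure_bead_intensities(stack, positions)
    ref = readings[0].mean()
    rel = readings.mean(axis=1) / ref
    model = calibration.fit_decay((truth.z_positions_um, rel))
    corrected = calibration.correct_stack(stack, model, truth.z_positions_um)
    cv = float(np.std(calibration.measure_bead_intensities(
        corrected, positions).mean(axis=1), ddof=1)
        / np.mean(calibration.measure_bead_intensities(corrected, positions)))
    io.write_tiff16(out / "bead_stack.tif", np.clip(stack, 0, None) / 2)
    pd.DataFrame({"delta_z_um": truth.z_positions_um,
                  "relative_intensity": rel}).to_csv(
        out / "bead_measurements.csv", index=False)
    (out / "decay_model.json").write_text(model.to_json())
    return {"n_beads_detected": int(len(positions)),
            "decay": {"a": model.a, "b": model.b, "c": model.c},
            "true_decay": list(truth.decay),
            "corrected_cv": cv}


def _stage_gradient(cfg: RunConfig, out: Path) -> dict:
    import pandas as pd

    geometry = cfg.geometry.build()
    flow = cfg.flow.build(geometry)
    pair = synthdata.render_device_image(
        geometry, flow, noise_sd=cfg.simulate.noise_sd, seed=cfg.seed,
        x_interface_um=cfg.fit.x_interface_um,
        downstream_disturbance=cfg.simulate.downstream_disturbance,
        disturbance_from_roi=cfg.simulate.disturbance_from_roi,
        inlet_offset_um=cfg.simulate.inlet_offset_um)
    norm = gradientfit.flatfield_normalize(pair.image, pair.reference)
    io.write_tiff16(out / "gradient.tif", np.clip(pair.image, 0, None))
    io.write_tiff16(out / "reference.tif", np.clip(pair.reference, 0, None))

    fits = {}
    rows = []
    for roi in range(1, geometry.n_grooves + 1):
        prof = gradientfit.extract_profile(
            norm, geometry, roi, wall_margin_um=cfg.fit.wall_margin_um)
        fit = gradientfit.fit_erfc(prof, mode=cfg.fit.mode)
        fits[roi] = fit
        rows.append({"roi_id": roi, "c_max": fit.c_max, "c_min": fit.c_min,
                     "alpha_um": fit.alpha_um, "beta_um": fit.beta_um,
                     "rss": fit.rss, "converged": fit.converged})
    pd.DataFrame(rows).to_csv(out / "erfc_fits.csv", index=False)

    # per-ROI dC1/dC2 medians over a grid of candidate cell positions
    d = cfg.analysis.cell_diameter_um
    xs = np.linspace(cfg.fit.wall_margin_um + d / 2,
                     geometry.width_um - cfg.fit.wall_margin_um - d / 2, 61)
    dc1_per_roi, dc2_per_roi = {}, {}
    for roi in fits:
        up = fits[max(roi - 1, 1)]
        down = fits[min(roi + 1, geometry.n_grooves)]
        dc1_per_roi[roi] = gradientfit.delta_c1(
            fits[roi], xs, d, halved=cfg.fit.halved_dc1)
        dc2_per_roi[roi] = gradientfit.delta_c2(
            up, down, xs, d, geometry.microgroove_width_um,
            halved=cfg.fit.halved_dc2)
    included = gradientfit.valid_region_mask(
        dc1_per_roi, dc2_per_roi, cfg.analysis.ratio_threshold,
        override=cfg.analysis.roi_override)
    pd.DataFrame({
        "roi_id": list(fits),
        "median_abs_dc1": [float(np.median(np.abs(dc1_per_roi[r]))) for r in fits],
        "median_abs_dc2": [float(np.median(np.abs(dc2_per_roi[r]))) for r in fits],
        "included": [r in included for r in fits],
    }).to_csv(out / "valid_region.csv", index=False)
    return {"fits": fits, "included_rois": sorted(included),
            "true_fits": pair.per_roi_fits}


def _stage_cells(cfg: RunConfig, out: Path, fits: dict,
                 included: list[int]) -> dict:
    import pandas as pd

    geometry = cfg.geometry.build()
    flow = cfg.flow.build(geometry)
    cells = synthdata.generate_cell_population(
        cfg.simulate.n_cells, geometry,
        {r: fits[r] for r in included}, cfg.response.build(),
        seed=cfg.seed, flow=flow, d_um=cfg.analysis.cell_diameter_um,
        roi_ids=included)
    cells.to_csv(out / "cells.csv", index=False)

    rows = []
    for phase in ["all"] + cfg.analysis.phases:
        sub = cells if phase == "all" else cells[cells["phase"] == phase]
        for reference in ("gradient", "upstream"):
            t = axisstats.orientation_test(sub["theta_rad"].to_numpy(),
                                           reference=reference)
            rows.append({"phase": phase, "reference": reference,
                         "a": t.a, "b": t.b,
                         "fraction": t.fraction_toward, "p_value": t.p_value})
    tests = pd.DataFrame(rows)
    tests.to_csv(out / "orientation_tests.csv", index=False)

    rose = {phase: axisstats.rose_histogram(
        (cells if phase == "all" else cells[cells["phase"] == phase])
        ["theta_rad"].to_numpy())
        for phase in ["all"] + cfg.analysis.phases}
    pd.DataFrame({"sector": np.arange(12), **rose}).to_csv(
        out / "rose_histogram.csv", index=False)
    return {"cells": cells, "tests": tests}


def _stage_bins(cfg: RunConfig, out: Path, cells) -> dict:
    import pandas as pd

    rows = []
    thresholds = {}
    for phase in cfg.analysis.phases:
        sub = cells[cells["phase"] == phase]
        if len(sub) < cfg.analysis.k_bins:
            continue
        bins = axisstats.bin_orientation_tests(
            np.abs(sub["delta_c_nM_per_um"].to_numpy()),
            sub["theta_rad"].to_numpy(), k=cfg.analysis.k_bins)
        bins = axisstats.sensitivity_threshold(bins, cfg.analysis.alpha)
        thresholds[phase] = bins.threshold_nM_per_um
        for i, t in enumerate(bins.tests):
            rows.append({"phase": phase, "bin": i,
                         "bin_lo": bins.edges[i], "bin_hi": bins.edges[i + 1],
                         "a": t.a, "b": t.b, "fraction": t.fraction_toward,
                         "p_value": t.p_value})
    pd.DataFrame(rows).to_csv(out / "bins.csv", index=False)
    (out / "threshold.json").write_text(json.dumps(thresholds, indent=2))
    return {"thresholds": thresholds}


def _stage_stability(cfg: RunConfig, out: Path) -> dict:
    import pandas as pd

    geometry = cfg.geometry.build()
    rows = []
    for interval in cfg.simulate.intervals_s:
        frames, reference, truth = synthdata.generate_timeseries(
            geometry, interval_s=interval, n_frames=cfg.simulate.n_frames,
            drift_sd=cfg.simulate.drift_sd, noise_sd=cfg.simulate.noise_sd,
            seed=cfg.seed + int(interval),
            positions_um=tuple(cfg.simulate.sigma_positions_um))
        for pos in cfg.simulate.sigma_positions_um:
            series = gradientfit.delta_c1_series(
                frames, reference, geometry, roi_id=1, position_um=pos,
                d_um=cfg.analysis.cell_diameter_um)
            res = gradientfit.sigma_fluctuation(series, position_um=pos,
                                                interval_s=interval)
            dc1_est = float(np.median(series))
            rows.append({"interval_s": interval, "position_um": pos,
                         "sigma": res.sigma, "dc1_median": dc1_est,
                         "sigma_true": truth.true_sigma[pos],
                         "stable": res.sigma < abs(dc1_est) / 10})
    df = pd.DataFrame(rows)
    df.to_csv(out / "sigma.csv", index=False)
    return {"all_stable": bool(df["stable"].all()),
            "max_sigma_over_dc1": float((df["sigma"] / df["dc1_median"].abs()).max())}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written to disk)."""
    from . import __version__

    run_dir = io.ensure_dir(config.out_dir)
    (run_dir / "config.yaml").write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True))
    report: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                    "version": __version__, "stages": {}}

    out = io.ensure_dir(run_dir / "calibration")
    report["stages"]["calibration"] = _stage_calibration(config, out)

    out = io.ensure_dir(run_dir / "gradient")
    grad = _stage_gradient(config, out)
    report["stages"]["gradient"] = {
        "included_rois": grad["included_rois"],
        "n_fits": len(grad["fits"]),
        "all_converged": all(f.converged for f in grad["fits"].values())}

    out = io.ensure_dir(run_dir / "cells")
    cells_res = _stage_cells(config, out, grad["fits"], grad["included_rois"])
    report["stages"]["cells"] = {
        "n_cells": int(len(cells_res["cells"])),
        "tests": cells_res["tests"].to_dict(orient="records")}

    out = io.ensure_dir(run_dir / "bins")
    bins_res = _stage_bins(config, out, cells_res["cells"])
    report["stages"]["bins"] = bins_res

    out = io.ensure_dir(run_dir / "stability")
    report["stages"]["stability"] = _stage_stability(config, out)

    (run_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def export_figure_data(run_dir) -> dict:
    """Emit plot-ready tables from a completed run directory.

    Writes profile-vs-fit, rose-histogram, theta-vs-exposure scatter and
    bin-ratio CSVs under ``<run_dir>/figures`` and returns their paths.
    """
    import pandas as pd

    run_dir = Path(run_dir)
    cfg = load_config(run_dir / "config.yaml")
    geometry = cfg.geometry.build()
    out = io.ensure_dir(run_dir / "figures")
    paths = {}

    fits = pd.read_csv(run_dir / "gradient" / "erfc_fits.csv")
    norm = io.read_tiff16(run_dir / "gradient" / "gradient.tif")
    ref = io.read_tiff16(run_dir / "gradient" / "reference.tif")
    normalized = gradientfit.flatfield_normalize(norm, ref)
    rows = []
    for _, fr in fits.iterrows():
        prof = gradientfit.extract_profile(
            normalized, geometry, int(fr.roi_id),
            wall_margin_um=cfg.fit.wall_margin_um)
        from .models import ErfcFitResult
        fit = ErfcFitResult(c_max=fr.c_max, c_min=fr.c_min,
                            alpha_um=fr.alpha_um, beta_um=fr.beta_um,
                            rss=fr.rss, converged=bool(fr.converged))
        pred = gradientfit.predict_concentration(fit, prof.x_um)
        for x, c, p in zip(prof.x_um, prof.c_norm, pred):
            rows.append({"roi_id": int(fr.roi_id), "x_um": x,
                         "c_norm": c, "c_fit": p})
    p = out / "profile_vs_fit.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    paths["profile_vs_fit"] = p

    cells = pd.read_csv(run_dir / "cells" / "cells.csv")
    p = out / "scatter_theta_vs_gradient.csv"
    cells[["theta_rad", "delta_c_nM_per_um", "phase"]].to_csv(p, index=False)
    paths["scatter"] = p

    p = out / "rose.csv"
    pd.read_csv(run_dir / "cells" / "rose_histogram.csv").to_csv(p, index=False)
    paths["rose"] = p

    bins = pd.read_csv(run_dir / "bins" / "bins.csv")
    bins["ratio"] = bins["a"] / (bins["a"] + bins["b"])
    p = out / "bin_ratio.csv"
    bins.to_csv(p, index=False)
    paths["bin_ratio"] = p
    return paths
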