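"""Seeded synthetic-data generators with stored ground truth.

Every input the analysis pipeline consumes can be produced here with known
truth: steady-state cross-channel concentration fields (closed-form erfc
and a finite-difference plug-flow cross-check), noisy flat-field-structured
fluorescence images of the gradient, bead z-stacks with exponential
intensity decay, image time series for stability analysis, mitotic cell
populations with a planted orientation response, and two-channel
chromosome/LRP6 images with a known activation side.

All generators are pure functions of (parameters, seed).  Child random
streams are derived from the master seed via ``numpy.random.SeedSequence``
spawn keys (one fixed key per generator, see ``STREAMS``) so each dataset
is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from .models import ChannelGeometry, ErfcFitResult, FlowParams, ResponseModel
from . import gradientfit

__all__ = [
    "STREAMS", "child_rng", "physical_erfc_params", "simulate_gradient_field",
    "plug_flow_steady_state", "GradientImagePair", "render_gradient_image",
    "BeadStackTruth", "generate_bead_stack", "generate_cell_population",
    "Lrp6ImageTruth", "generate_lrp6_image", "TimeSeriesTruth",
    "generate_timeseries", "default_device_fit",
]

#: Fixed spawn keys: dataset type -> child-stream index under the master seed.
STREAMS = {
    "gradient": 0,
    "beads": 1,
    "cells": 2,
    "lrp6": 3,
    "timeseries": 4,
}


def child_rng(seed: int, stream: str | int) -> np.random.Generator:
    """Derive an independent child generator from the master seed."""
    key = STREAMS[stream] if isinstance(stream, str) else int(stream)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def default_device_fit() -> ErfcFitResult:
    """Normalized profile parameters of the default synthetic device.

    (c_max, c_min, alpha, beta) = (1, 0, 450, 90): with a 30 ng/mL Wnt3a
    source this puts the maximum per-cell exposure (cell diameter 30 um)
    at ~4.9e-3 nM/um, matching the exposure range observed in the original
    device.
    """
    return ErfcFitResult(c_max=1.0, c_min=0.0, alpha_um=450.0, beta_um=90.0)


# ---------------------------------------------------------------------------
# Concentration fields
# ---------------------------------------------------------------------------

def physical_erfc_params(flow: FlowParams, y_um: float,
                         x_interface_um: float = 450.0) -> ErfcFitResult:
    """Closed-form profile parameters at along-flow position y.

    One-dimensional diffusion from a step source carried by plug flow
    gives C(x) = 1/2 C0 erfc((x - xi) / (2 sqrt(D y / v))), i.e. the erfc
    model with alpha = xi and beta = 2 sqrt(D y / v) (normalized units:
    c_max = 1, c_min = 0).
    """
    if y_um <= 0:
        raise ValueError("y_um must be > 0")
    beta = 2.0 * np.sqrt(flow.diffusivity_um2_s * y_um / flow.mean_speed_um_s)
    return ErfcFitResult(c_max=1.0, c_min=0.0, alpha_um=x_interface_um,
                         beta_um=float(beta))


def simulate_gradient_field(geometry: ChannelGeometry, flow: FlowParams,
                            y_um: float, x_um: np.ndarray | None = None,
                            x_interface_um: float = 450.0,
                            normalized: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state cross-channel concentration profile at position y.

    Returns ``(x_um, c)`` where c is the closed-form erfc profile; with
    ``normalized=False`` the profile is scaled by the source mass
    concentration (ng/mL) instead of lying in [0, 1].
    """
    if y_um <= 0:
        raise ValueError("y_um must be > 0")
    if x_um is None:
        x_um = (np.arange(geometry.shape_px[1]) + 0.5) * geometry.pixel_size_um
    x_um = np.asarray(x_um, dtype=float)
    p = physical_erfc_params(flow, y_um, x_interface_um)
    c = 0.5 * erfc((x_um - p.alpha_um) / p.beta_um)
    if not normalized:
        c = c * flow.source_conc_ng_ml
    return x_um, c


def plug_flow_steady_state(geometry: ChannelGeometry, flow: FlowParams,
                           y_um: float, dx_um: float = 2.0,
                           x_interface_um: float = 450.0,
                           courant: float = 1.0 / 6.0) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference plug-flow solution of the same transport problem.

    Solves v dC/dy = D d2C/dx2 by marching downstream from a sharp step at
    the inlet (forward Euler in y, central differences in x, Dirichlet
    walls pinned to the step plateaus).  The default diffusion number
    r = 1/6 cancels the leading spatial truncation error.  Serves as the
    independent numerical cross-check of the closed form.
    """
    if y_um <= 0:
        raise ValueError("y_um must be > 0")
    if dx_um <= 0:
        raise ValueError("dx_um must be > 0")
    x = np.arange(0.0, geometry.width_um + dx_um / 2, dx_um)
    c = np.where(x < x_interface_um, 1.0,
                 np.where(x > x_interface_um, 0.0, 0.5))
    kappa = flow.diffusivity_um2_s / flow.mean_speed_um_s  # effective "time" D
    dy = courant * dx_um ** 2 / kappa
    n_steps = max(int(np.ceil(y_um / dy)), 1)
    dy = y_um / n_steps
    r = kappa * dy / dx_um ** 2
    for _ in range(n_steps):
        c[1:-1] = c[1:-1] + r * (c[2:] - 2.0 * c[1:-1] + c[:-2])
        c[0], c[-1] = 1.0, 0.0
    return x, c


# ---------------------------------------------------------------------------
# Gradient images
# ---------------------------------------------------------------------------

@dataclass
class GradientImagePair:
    """A synthetic gradient image with its flat-filled reference and truth."""

    image: np.ndarray
    reference: np.ndarray
    c_norm: np.ndarray          # planted per-column normalized profile(s)
    flatfield: np.ndarray
    noise_sd: float
    true_fit: ErfcFitResult | None = None
    per_roi_fits: dict = field(default_factory=dict)


def default_flatfield(shape: tuple[int, int], rng: np.random.Generator,
                      amplitude: float = 0.1) -> np.ndarray:
    """Smooth multiplicative illumination field with mean 1."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    cy, cx = rng.uniform(0.3, 0.7) * rows, rng.uniform(0.3, 0.7) * cols
    r2 = ((yy - cy) / rows) ** 2 + ((xx - cx) / cols) ** 2
    f = 1.0 - amplitude * r2 / r2.max() if r2.max() > 0 else np.ones(shape)
    return f / f.mean()


def render_gradient_image(profile: np.ndarray, geometry: ChannelGeometry,
                          noise_sd: float = 0.01,
                          flatfield: np.ndarray | None = None,
                          seed: int = 0) -> GradientImagePair:
    """Render the normalized profile as a noisy image plus its reference.

    ``profile`` is either a 1-D per-column normalized concentration
    (broadcast down all rows) or a full 2-D field.  Pixel values are
    flatfield * c_norm + Gaussian noise; the paired reference is
    flatfield * 1 + independent noise of the same sd.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    profile = np.asarray(profile, dtype=float)
    shape = geometry.shape_px
    if profile.ndim == 1:
        if profile.size != shape[1]:
            raise ValueError("1-D profile length must equal image columns")
        field2d = np.broadcast_to(profile, shape).copy()
    elif profile.shape == shape:
        field2d = profile.copy()
    else:
        raise ValueError(f"profile shape {profile.shape} does not match {shape}")
    if flatfield is None:
        flatfield = np.ones(shape)
    flatfield = np.asarray(flatfield, dtype=float)
    if flatfield.shape != shape:
        raise ValueError("flatfield shape must match the image")
    if np.any(flatfield <= 0):
        raise ValueError("flatfield must be strictly positive")
    rng = child_rng(seed, "gradient")
    image = flatfield * field2d + rng.normal(0.0, noise_sd, shape)
    reference = flatfield + rng.normal(0.0, noise_sd, shape)
    return GradientImagePair(image=image, reference=reference,
                             c_norm=field2d, flatfield=flatfield,
                             noise_sd=noise_sd)


def render_device_image(geometry: ChannelGeometry, flow: FlowParams,
                        noise_sd: float = 0.01,
                        flatfield: np.ndarray | None = None,
                        seed: int = 0, x_interface_um: float = 450.0,
                        downstream_disturbance: float = 0.0,
                        disturbance_from_roi: int = 16,
                        inlet_offset_um: float = 5000.0) -> GradientImagePair:
    """Render a full-channel image whose profile develops along flow.

    Each row carries the plug-flow closed form at its own distance from
    the stream junction, so downstream ROIs have broader transitions.
    ``inlet_offset_um`` is the junction-to-imaged-region distance: the
    gradient is already developed when it enters the culturing area, so
    adjacent ROIs differ only mildly.  ``downstream_disturbance`` mixes
    rows at/after ``disturbance_from_roi`` toward the well-mixed level
    0.5 with a strength growing along flow — a stand-in for the along-flow
    inhomogeneity that disqualifies downstream channels.
    """
    rows, cols = geometry.shape_px
    x = (np.arange(cols) + 0.5) * geometry.pixel_size_um
    y_local = (np.arange(rows) + 0.5) * geometry.pixel_size_um
    y = y_local + inlet_offset_um
    beta = 2.0 * np.sqrt(flow.diffusivity_um2_s * np.maximum(y, 1e-6)
                         / flow.mean_speed_um_s)
    field2d = 0.5 * erfc((x[None, :] - x_interface_um) / beta[:, None])
    per_roi_fits = {}
    for roi in range(1, geometry.n_grooves + 1):
        per_roi_fits[roi] = physical_erfc_params(
            flow, geometry.groove_center_um(roi) + inlet_offset_um,
            x_interface_um)
    if downstream_disturbance > 0:
        y0 = (disturbance_from_roi - 1) * geometry.groove_pitch_um
        lam = downstream_disturbance * np.clip(
            (y_local - y0) / (geometry.length_um - y0), 0.0, 1.0)
        field2d = field2d * (1 - lam[:, None]) + 0.5 * lam[:, None]
    if flatfield is None:
        flatfield = default_flatfield((rows, cols), child_rng(seed, "gradient"))
    pair = render_gradient_image(field2d, geometry, noise_sd, flatfield, seed)
    pair.per_roi_fits = per_roi_fits
    return pair


# ---------------------------------------------------------------------------
# Bead z-stacks
# ---------------------------------------------------------------------------

@dataclass
class BeadStackTruth:
    """Planted bead positions/intensities and the decay parameters used."""

    positions: np.ndarray       # (n_beads, 2) row, col
    base_peaks: np.ndarray      # decay-free peak intensity per bead
    z_positions_um: np.ndarray
    decay: tuple                # (a, b, c)
    spot_sigma_px: float
    noise_sd: float


def generate_bead_stack(decay: tuple = (0.645, -0.200, 0.352),
                        n_beads: int = 12,
                        z_range_um: tuple = (0.0, 20.0),
                        noise_sd: float = 0.0, seed: int = 0,
                        n_planes: int = 21,
                        shape: tuple[int, int] = (128, 128),
                        spot_sigma_px: float = 2.0,
                        min_separation_px: float = 14.0
                        ) -> tuple[np.ndarray, BeadStackTruth]:
    """Render a calibration z-stack of fluorescent beads.

    Every plane images the same beads at an increasing objective offset
    dz; each bead is a 2-D Gaussian spot whose peak scales with the
    exponential attenuation a*exp(b*dz) + c (relative to 1.0 at the
    reference plane, where a + c is its predicted value).  Defocus blur
    is deliberately not modelled — only the intensity decay matters for
    the calibration it feeds.
    """
    a, b, c = decay
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    z = np.linspace(z_range_um[0], z_range_um[1], n_planes)
    att = a * np.exp(b * z) + c
    if np.any(att <= 0):
        raise ValueError("decay model predicts non-positive intensity in range")
    rng = child_rng(seed, "beads")
    margin = int(4 * spot_sigma_px) + 2
    positions = []
    attempts = 0
    while len(positions) < n_beads:
        cand = rng.uniform([margin, margin],
                           [shape[0] - margin, shape[1] - margin])
        if all(np.hypot(*(cand - p)) >= min_separation_px for p in positions):
            positions.append(cand)
        attempts += 1
        if attempts > 10_000:
            raise ValueError("could not place non-overlapping beads; "
                             "reduce n_beads or min_separation_px")
    positions = np.array(positions)
    base_peaks = rng.uniform(0.8, 1.2, n_beads)

    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    spot = np.zeros(shape)
    for (r, cc), amp in zip(positions, base_peaks):
        spot += amp * np.exp(-((yy - r) ** 2 + (xx - cc) ** 2)
                             / (2 * spot_sigma_px ** 2))
    stack = spot[None, :, :] * att[:, None, None]
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, stack.shape)
    truth = BeadStackTruth(positions=positions, base_peaks=base_peaks,
                           z_positions_um=z, decay=(a, b, c),
                           spot_sigma_px=spot_sigma_px, noise_sd=noise_sd)
    return stack, truth


# ---------------------------------------------------------------------------
# Cell populations
# ---------------------------------------------------------------------------

def generate_cell_population(n: int, geometry: ChannelGeometry,
                             fits: dict | ErfcFitResult,
                             response: ResponseModel,
                             phase_mix: dict | None = None,
                             seed: int = 0,
                             flow: FlowParams | None = None,
                             d_um: float = 30.0,
                             wall_margin_um: float = 50.0,
                             roi_ids: list | None = None):
    """Sample a mitotic-cell table with planted orientation response.

    Each cell receives a uniform across-channel position x, a groove
    channel, a mitotic phase, its true normalized and molar gradient
    exposure (from the supplied per-ROI profile fits), and a pole-to-pole
    angle theta: with probability p(exposure) the angle is von Mises
    around 0 (toward the high-concentration wall), otherwise around pi.

    Returns a pandas DataFrame carrying both the observable columns and
    the ground-truth columns (true_side, p_used).
    """
    import pandas as pd

    if n < 1:
        raise ValueError("n must be >= 1")
    if phase_mix is None:
        phase_mix = {"metaphase": 0.5, "postmetaphase": 0.5}
    if not phase_mix or sum(phase_mix.values()) <= 0:
        raise ValueError("phase_mix must contain at least one positive weight")
    if flow is None:
        flow = FlowParams()
    if isinstance(fits, ErfcFitResult):
        fits = {roi: fits for roi in range(1, geometry.n_grooves + 1)}
    if roi_ids is None:
        roi_ids = sorted(fits.keys())
    missing = [r for r in roi_ids if r not in fits]
    if missing:
        raise ValueError(f"no fit supplied for roi(s) {missing}")

    rng = child_rng(seed, "cells")
    x = rng.uniform(wall_margin_um + d_um / 2,
                    geometry.width_um - wall_margin_um - d_um / 2, n)
    rois = rng.choice(np.asarray(roi_ids), size=n)
    phases = rng.choice(list(phase_mix.keys()), size=n,
                        p=np.asarray(list(phase_mix.values()), dtype=float)
                        / sum(phase_mix.values()))
    dc1 = np.array([gradientfit.delta_c1(fits[r], xi, d_um)
                    for r, xi in zip(rois, x)])
    grad = gradientfit.to_molar_gradient(dc1, d_um, flow.source_conc_ng_ml,
                                         flow.mw_kda)
    p = np.asarray(response.p_of_gradient(grad), dtype=float)
    toward = rng.random(n) < p
    # Sample within the chosen half-plane: p_toward is defined as the
    # probability of landing in the toward half, so the von Mises draw is
    # conditioned on that half (rejection sampling; ~90% acceptance at
    # kappa = 2).
    mu = np.where(toward, 0.0, np.pi)
    if response.kappa > 0:
        theta = rng.vonmises(mu, response.kappa)
        theta = np.where(theta <= -np.pi, theta + 2 * np.pi, theta)
        in_toward_half = (-np.pi / 2 <= theta) & (theta < np.pi / 2)
        bad = in_toward_half != toward
        while np.any(bad):
            redraw = rng.vonmises(mu[bad], response.kappa)
            redraw = np.where(redraw <= -np.pi, redraw + 2 * np.pi, redraw)
            theta[bad] = redraw
            in_toward_half = (-np.pi / 2 <= theta) & (theta < np.pi / 2)
            bad = in_toward_half != toward
    else:
        half = rng.uniform(-np.pi / 2, np.pi / 2, n)
        theta = np.where(toward, half, half + np.pi)
        theta = np.where(theta > np.pi, theta - 2 * np.pi, theta)
    df = pd.DataFrame({
        "cell_id": np.arange(n),
        "x_um": x,
        "channel_no": rois,
        "phase": phases,
        "theta_rad": theta,
        "delta_c_norm": dc1,
        "delta_c_nM_per_um": grad,
        "true_side": np.where(toward, "toward", "against"),
        "p_used": p,
    })
    return df


# ---------------------------------------------------------------------------
# LRP6 localization images
# ---------------------------------------------------------------------------

@dataclass
class Lrp6ImageTruth:
    center: np.ndarray          # (row, col)
    true_side: str              # "toward" (high side) or "against"
    offset_px: float
    phase: str
    snr: float


def generate_lrp6_image(center: tuple[float, float], true_side: str,
                        geometry: ChannelGeometry, seed: int = 0,
                        shape: tuple[int, int] = (96, 96),
                        phase: str = "metaphase", snr: float = 5.0,
                        offset_px: float = 20.0,
                        blob_sigma_px: float = 4.0,
                        patch_sigma_px: float = 4.0,
                        pole_sep_px: float = 30.0
                        ) -> tuple[np.ndarray, Lrp6ImageTruth]:
    """Two-channel (chromosomes, LRP6) image with a known activation side.

    The chromosome channel holds one blob (metaphase) or two separated
    blobs (postmetaphase) around the cell centre.  The LRP6 channel holds
    a bright patch displaced from the centre along the gradient axis:
    toward the high-concentration wall (smaller column) for
    ``true_side="toward"``, away from it for ``"against"``.  Gaussian
    noise is added at sd = patch amplitude / snr.
    """
    if true_side not in ("toward", "against"):
        raise ValueError("true_side must be 'toward' or 'against'")
    r0, c0 = float(center[0]), float(center[1])
    if not (0 <= r0 < shape[0] and 0 <= c0 < shape[1]):
        raise ValueError("center must lie inside the image")
    sign = -1.0 if true_side == "toward" else 1.0
    patch_c = c0 + sign * offset_px
    if not (0 <= patch_c < shape[1]):
        raise ValueError("LRP6 patch falls outside the image")
    rng = child_rng(seed, "lrp6")
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    chrom = np.zeros(shape)
    if phase == "metaphase":
        chrom += np.exp(-((yy - r0) ** 2 + (xx - c0) ** 2)
                        / (2 * blob_sigma_px ** 2))
    elif phase == "postmetaphase":
        for dr in (-pole_sep_px / 2, pole_sep_px / 2):
            chrom += np.exp(-((yy - (r0 + dr)) ** 2 + (xx - c0) ** 2)
                            / (2 * blob_sigma_px ** 2))
    else:
        raise ValueError(f"unknown phase {phase!r}")
    lrp6 = np.exp(-((yy - r0) ** 2 + (xx - patch_c) ** 2)
                  / (2 * patch_sigma_px ** 2))
    if snr > 0 and np.isfinite(snr):
        noise_sd = 1.0 / snr
        chrom = chrom + rng.normal(0.0, noise_sd, shape)
        lrp6 = lrp6 + rng.normal(0.0, noise_sd, shape)
    img = np.stack([chrom, lrp6])
    truth = Lrp6ImageTruth(center=np.array([r0, c0]), true_side=true_side,
                           offset_px=offset_px, phase=phase, snr=snr)
    return img, truth


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------

@dataclass
class TimeSeriesTruth:
    drift: np.ndarray               # multiplicative factor per frame
    true_dc1: dict                  # position_um -> planted dC1 series
    true_sigma: dict                # position_um -> sigma of that series
    interval_s: float
    fit: ErfcFitResult


def generate_timeseries(geometry: ChannelGeometry,
                        fit: ErfcFitResult | None = None,
                        interval_s: float = 1.0, n_frames: int = 10,
                        drift_sd: float = 0.0, noise_sd: float = 0.01,
                        seed: int = 0,
                        positions_um: tuple = (200.0, 400.0, 600.0),
                        d_um: float = 30.0
                        ) -> tuple[np.ndarray, np.ndarray, TimeSeriesTruth]:
    """Image sequence sharing one profile, with independent frame noise.

    ``drift_sd`` adds a slow multiplicative random-walk drift to the
    underlying field (step sd per frame).  Returns (frames, reference,
    truth); the truth stores the planted per-frame dC1 series at the
    standard evaluation positions and its fluctuation sigma.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if fit is None:
        # broad profile so all standard positions sit on the graded region
        fit = ErfcFitResult(c_max=1.0, c_min=0.0, alpha_um=400.0, beta_um=300.0)
    rng = child_rng(seed, "timeseries")
    rows, cols = geometry.shape_px
    x = (np.arange(cols) + 0.5) * geometry.pixel_size_um
    profile = gradientfit.predict_concentration(fit, x)
    drift = np.ones(n_frames)
    if drift_sd > 0:
        drift = 1.0 + np.cumsum(rng.normal(0.0, drift_sd, n_frames))
    frames = np.empty((n_frames, rows, cols))
    for i in range(n_frames):
        frames[i] = (np.broadcast_to(profile * drift[i], (rows, cols))
                     + rng.normal(0.0, noise_sd, (rows, cols)))
    reference = np.ones((rows, cols)) + rng.normal(0.0, noise_sd, (rows, cols))
    base = {p: gradientfit.delta_c1(fit, p, d_um) for p in positions_um}
    true_dc1 = {p: base[p] * drift for p in positions_um}
    true_sigma = {p: float(np.mean(np.abs(s - np.median(s))))
                  for p, s in true_dc1.items()}
    truth = TimeSeriesTruth(drift=drift, true_dc1=true_dc1,
                            true_sigma=true_sigma, interval_s=interval_s,
                            fit=fit)
    return frames, reference, truth
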