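"""Quantification of cross-channel concentration gradients.

Turns flat-field-normalized fluorescence images of the culturing channel
into fitted diffusion profiles and per-cell gradient exposures:

* ``flatfield_normalize`` removes illumination structure using a
  uniformly-filled reference image;
* ``extract_profile`` averages a 15-um ROI band across the channel;
* ``fit_erfc`` fits the one-dimensional diffusion profile
  C(x) = 1/2 (c_max - c_min) erfc((x - alpha)/beta) + c_min;
* ``delta_c1`` / ``delta_c2`` evaluate the normalized concentration
  difference across one mitotic cell along the gradient axis and the flow
  axis respectively;
* ``sigma_fluctuation`` is the temporal-stability statistic (mean absolute
  deviation from the median of a dC1 series);
* ``to_molar_gradient`` converts normalized differences into nM/um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.special import erfc

from .models import ChannelGeometry, ErfcFitResult, FluctuationResult

__all__ = [
    "IntensityProfile", "flatfield_normalize", "extract_profile",
    "fit_erfc", "predict_concentration", "delta_c1", "delta_c2",
    "valid_region_mask", "sigma_fluctuation", "to_molar_gradient",
    "delta_c1_series",
]


@dataclass
class IntensityProfile:
    """Mean normalized intensity across the channel in one ROI band."""

    roi_id: int
    x_um: np.ndarray
    c_norm: np.ndarray
    sd: np.ndarray | None = None
    roi_width_um: float = 15.0
    roi_length_um: float = 900.0

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.c_norm = np.asarray(self.c_norm, dtype=float)
        if self.x_um.ndim != 1 or self.x_um.shape != self.c_norm.shape:
            raise ValueError("x_um and c_norm must be 1-D and equally long")
        if np.any(np.diff(self.x_um) <= 0):
            raise ValueError("x_um must be strictly increasing")
        if self.roi_width_um <= 0 or self.roi_length_um <= 0:
            raise ValueError("ROI extents must be > 0")


def flatfield_normalize(image: np.ndarray, reference: np.ndarray,
                        smooth_sigma_px: float = 5.0) -> np.ndarray:
    """Divide an image by the (smoothed, mean-normalized) reference.

    The reference is an image of the channel uniformly filled with the
    fluorescent solution; dividing by it removes the multiplicative
    illumination/optical structure so the result is the normalized
    concentration field.  Values are NOT clipped here — clipping is an
    export-time concern only.
    """
    image = np.asarray(image, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if image.shape != reference.shape:
        raise ValueError(
            f"image {image.shape} and reference {reference.shape} differ")
    ref = ndimage.gaussian_filter(reference, smooth_sigma_px) \
        if smooth_sigma_px > 0 else reference
    if np.any(ref <= 0):
        raise ValueError("reference contains non-positive values after smoothing")
    return image / (ref / ref.mean())


def extract_profile(normalized: np.ndarray, geometry: ChannelGeometry,
                    roi_id: int, roi_width_um: float = 15.0,
                    wall_margin_um: float = 50.0) -> IntensityProfile:
    """Average an ROI band set across the channel at one groove position.

    The band is ``roi_width_um`` wide along flow (centred on the groove
    channel) and spans the channel width minus a wall margin on each side,
    giving the ~900 um profile length.  The band height in pixels is
    floor(width/pixel), at least 1.
    """
    normalized = np.asarray(normalized, dtype=float)
    if not 1 <= roi_id <= geometry.n_grooves:
        raise ValueError(f"roi_id must be in 1..{geometry.n_grooves}")
    px = geometry.pixel_size_um
    y_c = geometry.groove_center_um(roi_id)
    n_rows = max(int(roi_width_um / px), 1)
    r0 = int(round(y_c / px - n_rows / 2))
    r1 = r0 + n_rows
    if r0 < 0 or r1 > normalized.shape[0]:
        raise ValueError(f"ROI band for roi_id={roi_id} falls outside the image")
    c0 = int(np.ceil(wall_margin_um / px))
    c1 = normalized.shape[1] - c0
    if c1 - c0 < 2:
        raise ValueError("wall margin leaves no profile columns")
    band = normalized[r0:r1, c0:c1]
    x = (np.arange(c0, c1) + 0.5) * px
    return IntensityProfile(
        roi_id=roi_id, x_um=x, c_norm=band.mean(axis=0),
        sd=band.std(axis=0, ddof=1) if n_rows > 1 else np.zeros(c1 - c0),
        roi_width_um=n_rows * px, roi_length_um=(c1 - c0) * px)


def _erfc_model(x, c_max, c_min, alpha, beta):
    return 0.5 * (c_max - c_min) * erfc((x - alpha) / beta) + c_min


def fit_erfc(profile: IntensityProfile, mode: str = "free",
             max_nfev: int = 2000) -> ErfcFitResult:
    """Nonlinear least-squares fit of the erfc diffusion profile.

    ``mode="free"`` fits all four coefficients; ``mode="constrained"``
    pins c_max/c_min to the observed extremes of the ROI and fits only
    (alpha, beta).  Initialization: plateaus from the 95th/5th
    percentiles, alpha at the half-range crossing, beta as half the
    16%-84% span.  A non-converged solver still returns the best iterate,
    flagged ``converged=False``.
    """
    x, y = profile.x_um, profile.c_norm
    if x.size < 8:
        raise ValueError("need at least 8 profile points")
    if np.allclose(y, y[0]):
        raise ValueError("profile is constant; nothing to fit")

    c_max0, c_min0 = np.percentile(y, 95), np.percentile(y, 5)
    mid = 0.5 * (c_max0 + c_min0)
    alpha0 = x[np.argmin(np.abs(y - mid))]
    hi = c_min0 + 0.84 * (c_max0 - c_min0)
    lo = c_min0 + 0.16 * (c_max0 - c_min0)
    beta0 = max(abs(x[np.argmin(np.abs(y - lo))]
                    - x[np.argmin(np.abs(y - hi))]) / 2.0, x[1] - x[0])

    if mode == "constrained":
        c_max_fix, c_min_fix = float(y.max()), float(y.min())

        def resid(p):
            return _erfc_model(x, c_max_fix, c_min_fix, p[0], p[1]) - y

        p0 = [alpha0, beta0]
        lb, ub = [-np.inf, 1e-9], [np.inf, np.inf]
    elif mode == "free":
        def resid(p):
            return _erfc_model(x, p[0], p[1], p[2], p[3]) - y

        p0 = [c_max0, c_min0, alpha0, beta0]
        lb = [-np.inf, -np.inf, -np.inf, 1e-9]
        ub = [np.inf] * 4
    else:
        raise ValueError(f"unknown fit mode {mode!r}")

    sol = optimize.least_squares(resid, p0, bounds=(lb, ub), max_nfev=max_nfev)
    if mode == "constrained":
        alpha, beta = sol.x
        c_max, c_min = c_max_fix, c_min_fix
    else:
        c_max, c_min, alpha, beta = sol.x
        if c_max < c_min:  # relabel the plateaus; model is symmetric in them
            c_max, c_min = c_min, c_max
    return ErfcFitResult(
        c_max=float(c_max), c_min=float(c_min), alpha_um=float(alpha),
        beta_um=float(beta), rss=float(np.sum(sol.fun ** 2)),
        converged=bool(sol.success), n_points=int(x.size))


def predict_concentration(fit: ErfcFitResult, x_um) -> np.ndarray | float:
    """Evaluate the fitted erfc profile at across-channel position(s)."""
    out = _erfc_model(np.asarray(x_um, dtype=float),
                      fit.c_max, fit.c_min, fit.alpha_um, fit.beta_um)
    return out if out.ndim else float(out)


def delta_c1(fit: ErfcFitResult, x_um, d_um: float = 30.0,
             halved: bool = False) -> np.ndarray | float:
    """Normalized concentration difference across a cell, gradient axis.

    dC1 = C(x - d/2) - C(x + d/2), the end-to-end difference over the
    cell diameter d (default 30 um, ~11 px).  ``halved=True`` applies the
    alternative reading with an overall factor 1/2.
    """
    if d_um <= 0:
        raise ValueError("d_um must be > 0")
    x = np.asarray(x_um, dtype=float)
    out = (predict_concentration(fit, x - d_um / 2)
           - predict_concentration(fit, x + d_um / 2))
    if halved:
        out = out / 2.0
    return out if np.ndim(out) else float(out)


def delta_c2(fit_upstream: ErfcFitResult, fit_downstream: ErfcFitResult,
             x_um, d_um: float = 30.0, w_um: float = 250.0,
             halved: bool = True) -> np.ndarray | float:
    """Normalized concentration difference across a cell, flow axis.

    Estimated from the two fitted ROI profiles bracketing the cell's
    position: dC2 = (C_up(x) - C_down(x)) / 2 * d / w, where w is the
    microgroove width.  ``halved=False`` drops the factor 1/2 (the
    alternative reading of the formula).
    """
    if w_um <= 0 or d_um <= 0:
        raise ValueError("d_um and w_um must be > 0")
    diff = (predict_concentration(fit_upstream, x_um)
            - predict_concentration(fit_downstream, x_um))
    scale = (0.5 if halved else 1.0) * d_um / w_um
    out = diff * scale
    return out if np.ndim(out) else float(out)


def valid_region_mask(per_roi_dc1: dict, per_roi_dc2: dict,
                      ratio_threshold: float = 0.5,
                      override: list | None = None) -> set:
    """Select ROI channels where the along-flow difference is negligible.

    An ROI is included iff median|dC2| <= ratio_threshold * median|dC1|.
    ``override`` replaces the data-driven rule with an explicit channel
    list (e.g. 1..15, the analysed area of the original study).
    """
    if override is not None:
        return set(override)
    included = set()
    for roi in per_roi_dc1:
        m1 = float(np.median(np.abs(np.asarray(per_roi_dc1[roi], dtype=float))))
        m2 = float(np.median(np.abs(np.asarray(per_roi_dc2.get(roi, [0.0]),
                                               dtype=float))))
        if m2 <= ratio_threshold * m1:
            included.add(roi)
    return included


def sigma_fluctuation(delta_c1_series, position_um: float | None = None,
                      interval_s: float | None = None) -> FluctuationResult:
    """Mean absolute deviation from the median of a dC1 time series."""
    s = np.asarray(delta_c1_series, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 frames to measure fluctuation")
    sigma = float(np.mean(np.abs(s - np.median(s))))
    return FluctuationResult(sigma=sigma, n_frames=int(s.size),
                             position_um=position_um, interval_s=interval_s)


def to_molar_gradient(delta_c_norm, d_um: float, source_ng_ml: float,
                      mw_kda: float) -> np.ndarray | float:
    """Convert a normalized difference over diameter d into nM per um.

    The normalized field scales from 0 to the source concentration, so
    grad = dC_norm * C_source[nM] / d, with
    C_source[nM] = (source [ng/mL] * 1e-6 [g/L]) / (MW [kDa] * 1e3 [g/mol]) * 1e9.
    """
    if d_um <= 0 or source_ng_ml <= 0 or mw_kda <= 0:
        raise ValueError("d_um, source_ng_ml and mw_kda must be > 0")
    source_nM = source_ng_ml * 1e-6 / (mw_kda * 1e3) * 1e9
    out = np.asarray(delta_c_norm, dtype=float) * source_nM / d_um
    return out if out.ndim else float(out)


def delta_c1_series(frames: np.ndarray, reference: np.ndarray,
                    geometry: ChannelGeometry, roi_id: int,
                    position_um: float, d_um: float = 30.0,
                    halved: bool = False) -> np.ndarray:
    """Per-frame dC1 at one position from a time series of raw images.

    Each frame is flat-field normalized against the shared reference,
    profiled at the requested ROI, fitted, and evaluated at
    ``position_um``.  Returns the dC1 series (one value per frame).
    """
    out = []
    for frame in frames:
        norm = flatfield_normalize(frame, reference)
        prof = extract_profile(norm, geometry, roi_id)
        fit = fit_erfc(prof)
        out.append(delta_c1(fit, position_um, d_um, halved=halved))
    return np.asarray(out, dtype=float)
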