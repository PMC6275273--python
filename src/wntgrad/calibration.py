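"""Objective-height intensity-decay calibration.

Fluorescence collected deeper into the sample (larger objective offset dz)
is attenuated; on bead stacks the attenuation is well described by
I(dz) = a exp(b dz) + c relative to the reference plane.  This module
detects beads, fits the decay model, and divides stacks by the normalized
predicted attenuation so intensities become comparable across z before any
quantification.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, optimize
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from .models import BeadMeasurement, DecayModel

__all__ = [
    "detect_bead_peaks", "measure_bead_intensities", "fit_decay",
    "correct_stack", "max_project", "sum_project",
]


def detect_bead_peaks(stack: np.ndarray, min_separation_px: int = 7,
                      plane: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Locate bead spots in one plane of a stack.

    Local maxima above an Otsu-derived floor, at most one per
    ``min_separation_px`` (the brighter wins; ties go to the smaller
    row-major index), each refined to subpixel precision by an
    intensity-weighted centroid over a 5x5 patch.

    Returns ``(positions, peaks)`` where positions is (n, 2) float
    (row, col).  An empty result is returned with a warning when nothing
    is found.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        img = stack
    elif stack.ndim == 3:
        if stack.shape[0] < 1:
            raise ValueError("stack must have at least one plane")
        img = stack[plane]
    else:
        raise ValueError("stack must be 2-D or 3-D")
    try:
        floor = threshold_otsu(img)
    except ValueError:  # constant image
        floor = np.inf
    coords = peak_local_max(img, min_distance=int(min_separation_px),
                            threshold_abs=floor, exclude_border=False)
    if coords.size == 0:
        warnings.warn("no bead peaks found", stacklevel=2)
        return np.empty((0, 2)), np.empty(0)
    # peak_local_max sorts by intensity; re-sort by row-major for a stable,
    # documented ordering
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    coords = coords[order]
    refined = np.empty(coords.shape, dtype=float)
    peaks = np.empty(len(coords))
    for i, (r, c) in enumerate(coords):
        r0, r1 = max(r - 2, 0), min(r + 3, img.shape[0])
        c0, c1 = max(c - 2, 0), min(c + 3, img.shape[1])
        patch = img[r0:r1, c0:c1]
        w = patch - patch.min()
        if w.sum() > 0:
            rr, cc = np.mgrid[r0:r1, c0:c1]
            refined[i] = [(w * rr).sum() / w.sum(), (w * cc).sum() / w.sum()]
        else:
            refined[i] = [r, c]
        peaks[i] = img[r, c]
    return refined, peaks


def measure_bead_intensities(stack: np.ndarray, positions: np.ndarray,
                             patch_half: int = 1) -> np.ndarray:
    """Mean intensity in a (2h+1)^2 patch around each bead, per plane.

    Returns an array of shape (n_planes, n_beads).  A small patch mean is
    used rather than the single maximum pixel so the reading is unbiased
    under noise and consistent across planes.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    out = np.empty((stack.shape[0], len(positions)))
    for j, (r, c) in enumerate(np.round(np.asarray(positions)).astype(int)):
        r0, r1 = max(r - patch_half, 0), min(r + patch_half + 1, stack.shape[1])
        c0, c1 = max(c - patch_half, 0), min(c + patch_half + 1, stack.shape[2])
        out[:, j] = stack[:, r0:r1, c0:c1].mean(axis=(1, 2))
    return out


def _decay_model(z, a, b, c):
    return a * np.exp(b * z) + c


def fit_decay(measurements: list[BeadMeasurement] | tuple[np.ndarray, np.ndarray]
              ) -> DecayModel:
    """Least-squares fit of I(dz) = a exp(b dz) + c to bead readings.

    Initialization: c from the minimum intensity, a from I(0) - min(I),
    b from a log-linear regression of I - c against dz.  Constant data is
    returned as the degenerate (b = 0) solution, flagged rather than
    raised.  Requires readings at >= 4 distinct heights.
    """
    if isinstance(measurements, tuple):
        z, y = (np.asarray(v, dtype=float) for v in measurements)
    else:
        z = np.array([m.delta_z_um for m in measurements], dtype=float)
        y = np.array([m.relative_intensity for m in measurements], dtype=float)
    if len(np.unique(z)) < 4:
        raise ValueError("need measurements at >= 4 distinct heights")
    if np.ptp(y) < 1e-12:
        return DecayModel(a=0.0, b=0.0, c=float(y.mean()),
                          converged=True, degenerate=True)

    order = np.argsort(z)
    z_s, y_s = z[order], y[order]
    c0 = float(y.min())
    a0 = max(float(y_s[0] - c0), 1e-6)
    w = y_s - c0
    mask = w > max(1e-6, 1e-3 * np.ptp(y))
    if mask.sum() >= 2:
        b0 = float(np.polyfit(z_s[mask], np.log(w[mask]), 1)[0])
    else:
        b0 = -0.1
    b0 = min(b0, -1e-9)
    try:
        popt, pcov = optimize.curve_fit(_decay_model, z, y, p0=[a0, b0, c0],
                                        maxfev=10_000)
        converged = True
    except RuntimeError:
        popt, pcov = np.array([a0, b0, c0]), np.full((3, 3), np.nan)
        converged = False
    return DecayModel(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
                      cov=np.asarray(pcov).tolist(), converged=converged)


def correct_stack(stack: np.ndarray, model: DecayModel,
                  z_positions_um: np.ndarray) -> np.ndarray:
    """Divide each plane by its normalized predicted attenuation.

    Plane k is divided by I(dz_k)/I(0), so the reference plane is
    unchanged and deeper planes are boosted back to reference scale.
    """
    stack = np.asarray(stack, dtype=float)
    z = np.asarray(z_positions_um, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (planes, rows, cols)")
    if z.shape[0] != stack.shape[0]:
        raise ValueError("need one z position per plane")
    pred = model.predict(z)
    ref = model.predict(0.0)
    if ref <= 0:
        raise ValueError("decay model predicts non-positive reference intensity")
    bad = np.nonzero(pred <= 0)[0]
    if bad.size:
        raise ValueError(
            f"predicted attenuation <= 0 at plane {bad[0]} (dz={z[bad[0]]} um)")
    return stack / (pred / ref)[:, None, None]


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection along z."""
    return np.asarray(stack).max(axis=0)


def sum_project(stack: np.ndarray) -> np.ndarray:
    """Sum projection along z (alternative to the default max)."""
    return np.asarray(stack).sum(axis=0)
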