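"""Pole-to-pole axis statistics under a concentration gradient.

Angle convention (device frame): 0 points toward the Wnt-source wall
(direction of increasing concentration), -pi/2 points upstream; angles are
wrapped to (-pi, pi].  The pole-to-pole axis runs from the dimmer to the
brighter ODF2/cenexin centriole.

The bias statistics are two-sided exact binomial tests of the toward /
against counts at p0 = 0.5, applied to the whole cohort and within
equal-count gradient-exposure bins; the sensitivity threshold is the lower
edge of the weakest-exposure bin showing a significant toward bias.  No
multiple-testing correction is applied across bins (deliberately, matching
the original analysis design).
"""

from __future__ import annotations

from fractions import Fraction
import math

import numpy as np

from .models import OrientationTest, SensitivityBins

__all__ = [
    "pole_axis_angle", "classify_toward_gradient", "classify_toward_upstream",
    "exact_binomial_two_sided", "orientation_test", "equal_count_bins",
    "bin_orientation_tests", "sensitivity_threshold", "rose_histogram",
    "cell_center", "lrp6_activated_position", "classify_lrp6_side",
]


def _wrap_angle(theta: float) -> float:
    """Wrap to (-pi, pi]."""
    t = math.remainder(theta, 2 * math.pi)
    if t <= -math.pi:
        t += 2 * math.pi
    return t


def pole_axis_angle(pole_high, pole_low) -> float:
    """Angle of the vector from the dim to the bright centriole.

    Poles are (x_um, y_um) device coordinates (x from the Wnt-source
    wall, y downstream).  Returns theta in (-pi, pi] with 0 toward the
    source wall and -pi/2 upstream.
    """
    dx = float(pole_high[0]) - float(pole_low[0])
    dy = float(pole_high[1]) - float(pole_low[1])
    if dx == 0 and dy == 0:
        raise ValueError("pole coordinates coincide")
    # theta = 0 axis is -x (toward the wall), +pi/2 axis is +y (downstream)
    return _wrap_angle(math.atan2(dy, -dx))


def classify_toward_gradient(theta: float) -> bool:
    """True iff the axis points into the high-concentration half-plane.

    Half-open convention: toward iff -pi/2 <= theta < pi/2 (theta = -pi/2
    counts toward, theta = +pi/2 against).
    """
    t = _wrap_angle(theta)
    if t == math.pi:  # quoted intervals use the [-pi, pi) wrap
        t = -math.pi
    return -math.pi / 2 <= t < math.pi / 2


def classify_toward_upstream(theta: float) -> bool:
    """True iff the axis points into the upstream half-plane
    (-pi <= theta < 0)."""
    t = _wrap_angle(theta)
    if t == math.pi:
        t = -math.pi
    return -math.pi <= t < 0


def exact_binomial_two_sided(a: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value by the point-probability method.

    Sums the probabilities of all outcomes no more likely than the
    observed one.  For p0 = 1/2 this equals twice the smaller tail
    (capped at 1) and is computed in exact integer arithmetic; other p0
    use exact rational arithmetic.  Practical up to n ~ 1e4.
    """
    a, n = int(a), int(n)
    if n < 1 or not 0 <= a <= n:
        raise ValueError(f"invalid counts a={a}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if n > 10_000:
        raise ValueError("n too large for exact summation (max 10000)")
    if p0 == 0.5:
        obs = math.comb(n, a)
        total = sum(math.comb(n, k) for k in range(n + 1)
                    if math.comb(n, k) <= obs)
        return float(Fraction(total, 2 ** n))
    p = Fraction(p0)
    q = 1 - p
    pmf = [math.comb(n, k) * p ** k * q ** (n - k) for k in range(n + 1)]
    obs = pmf[a]
    return float(min(sum(v for v in pmf if v <= obs), Fraction(1)))


def orientation_test(thetas, reference: str = "gradient",
                     p0: float = 0.5) -> OrientationTest:
    """Count toward/against calls for a cohort and run the exact test."""
    if reference == "gradient":
        calls = [classify_toward_gradient(t) for t in np.asarray(thetas)]
    elif reference == "upstream":
        calls = [classify_toward_upstream(t) for t in np.asarray(thetas)]
    else:
        raise ValueError("reference must be 'gradient' or 'upstream'")
    a = int(sum(calls))
    b = len(calls) - a
    return OrientationTest(a=a, b=b, reference=reference,
                           p_value=exact_binomial_two_sided(a, a + b, p0))


def equal_count_bins(values, k: int = 4) -> SensitivityBins:
    """Split values into k contiguous near-equal-count bins.

    Values are stably sorted and cut into groups of floor(n/k) or
    ceil(n/k) cells, the remainder going to the lowest bins.  Edges are
    reported as [min, midpoints between adjacent sorted groups, max].
    Also records the bin assignment of every input value (``assignments``
    attribute on the returned object follows input order).
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if k < 1 or k > n:
        raise ValueError(f"k must be in 1..{n}")
    order = np.argsort(v, kind="stable")
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    bounds = np.cumsum([0] + sizes)
    sv = v[order]
    edges = [float(sv[0])]
    for b in bounds[1:-1]:
        edges.append(float(0.5 * (sv[b - 1] + sv[b])))
    edges.append(float(sv[-1]))
    assignments = np.empty(n, dtype=int)
    for i in range(k):
        assignments[order[bounds[i]:bounds[i + 1]]] = i
    bins = SensitivityBins(k=k, edges=edges, counts=sizes,
                           degenerate=bool(np.ptp(v) == 0))
    bins.assignments = assignments
    return bins


def bin_orientation_tests(grad_values, thetas, k: int = 4,
                          reference: str = "gradient") -> SensitivityBins:
    """Equal-count exposure bins with a per-bin orientation test."""
    grad_values = np.asarray(grad_values, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    if grad_values.shape != thetas.shape:
        raise ValueError("gradient values and angles must align")
    bins = equal_count_bins(grad_values, k)
    bins.tests = [orientation_test(thetas[bins.assignments == i],
                                   reference=reference)
                  for i in range(k)]
    return bins


def sensitivity_threshold(bins: SensitivityBins,
                          alpha: float = 0.05) -> SensitivityBins:
    """Derive the sensitivity threshold from per-bin tests.

    The threshold is the lower edge of the lowest-exposure bin whose
    toward fraction exceeds 0.5 with p < alpha; None when no bin
    qualifies.  The qualifying bin index is recorded alongside.
    """
    if not bins.tests:
        raise ValueError("bins carry no orientation tests")
    bins.threshold_nM_per_um = None
    bins.threshold_bin = None
    for i, test in enumerate(bins.tests):
        if test.p_value < alpha and test.fraction_toward > 0.5:
            bins.threshold_nM_per_um = bins.edges[i]
            bins.threshold_bin = i
            break
    return bins


def rose_histogram(thetas, n_sectors: int = 12) -> np.ndarray:
    """Counts over equal angular sectors of (-pi, pi].

    Sectors are left-closed right-open starting at -pi; theta = pi is
    counted in the first sector (equivalent to -pi).
    """
    if n_sectors < 2:
        raise ValueError("n_sectors must be >= 2")
    t = np.array([_wrap_angle(x) for x in np.asarray(thetas, dtype=float)])
    t[t == np.pi] = -np.pi
    idx = np.floor((t + np.pi) / (2 * np.pi / n_sectors)).astype(int)
    idx = np.clip(idx, 0, n_sectors - 1)
    return np.bincount(idx, minlength=n_sectors)


def segment_chromosomes(chrom_image: np.ndarray, phase: str,
                        smooth_sigma_px: float = 2.0) -> list[np.ndarray]:
    """Segment the chromosome channel into the phase's expected masks.

    Gaussian-smooths, thresholds with Otsu and keeps the largest one
    (metaphase) or two (postmetaphase) connected components.
    """
    from scipy.ndimage import gaussian_filter
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    n_expected = {"metaphase": 1, "postmetaphase": 2}.get(phase)
    if n_expected is None:
        raise ValueError(f"unknown phase {phase!r}")
    img = gaussian_filter(np.asarray(chrom_image, dtype=float),
                          smooth_sigma_px)
    lab = label(img > threshold_otsu(img))
    regions = sorted(regionprops(lab), key=lambda r: r.area, reverse=True)
    if len(regions) < n_expected:
        raise ValueError(
            f"found {len(regions)} chromosome masses, need {n_expected}")
    return [lab == r.label for r in regions[:n_expected]]


def cell_center(masks: list[np.ndarray], phase: str,
                intensity: np.ndarray | None = None) -> tuple[float, float]:
    """Cell centre from chromosome masks, by mitotic phase.

    Metaphase: the (intensity-weighted) centroid of the single chromosome
    mass.  Postmetaphase: the midpoint of the line across the two divided
    chromosome centroids.
    """
    def centroid(mask):
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty chromosome mask")
        rr, cc = np.nonzero(mask)
        if intensity is not None:
            w = np.asarray(intensity, dtype=float)[rr, cc]
            w = w - w.min() + 1e-12
            return float((rr * w).sum() / w.sum()), float((cc * w).sum() / w.sum())
        return float(rr.mean()), float(cc.mean())

    if phase == "metaphase":
        if len(masks) != 1:
            raise ValueError(f"metaphase expects 1 chromosome mask, got {len(masks)}")
        return centroid(masks[0])
    if phase == "postmetaphase":
        if len(masks) != 2:
            raise ValueError(f"postmetaphase expects 2 chromosome masks, got {len(masks)}")
        (r1, c1), (r2, c2) = centroid(masks[0]), centroid(masks[1])
        return (r1 + r2) / 2, (c1 + c2) / 2
    raise ValueError(f"unknown phase {phase!r}")


def lrp6_activated_position(image: np.ndarray,
                            window_px: int = 11) -> tuple[int, int]:
    """Centre of the window with the highest mean LRP6 signal.

    Scans every fully-contained ``window_px`` x ``window_px`` placement
    using an integral image; ties go to the smallest row-major index of
    the window centre.  The window must be odd and fit in the image.
    """
    arr = np.asarray(image)
    if window_px % 2 == 0:
        raise ValueError("window_px must be odd")
    if arr.ndim != 2:
        raise ValueError("image must be 2-D")
    if min(arr.shape) < window_px:
        raise ValueError("image smaller than the window")
    # integer input stays in exact int64 arithmetic
    work = (arr.astype(np.int64) if np.issubdtype(arr.dtype, np.integer)
            else arr.astype(np.float64))
    s = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=work.dtype)
    s[1:, 1:] = work.cumsum(axis=0).cumsum(axis=1)
    w = window_px
    sums = (s[w:, w:] - s[:-w, w:] - s[w:, :-w] + s[:-w, :-w])
    flat = int(np.argmax(sums))  # argmax returns the first (row-major) max
    r0, c0 = divmod(flat, sums.shape[1])
    half = w // 2
    return r0 + half, c0 + half


def classify_lrp6_side(activated, center, reference: str = "gradient") -> str:
    """Side of the activated LRP6 position relative to the cell centre.

    Coordinates are (row, col); the gradient reference calls 'toward'
    when the activated position lies at a smaller column (closer to the
    Wnt-source wall), the upstream reference when it lies at a smaller
    row.  An exactly zero displacement component along the reference axis
    is 'indeterminate' and should be excluded from the counts.
    """
    dr = float(activated[0]) - float(center[0])
    dc = float(activated[1]) - float(center[1])
    if dr == 0 and dc == 0:
        raise ValueError("activated position coincides with the cell centre")
    comp = -dc if reference == "gradient" else -dr
    if reference not in ("gradient", "upstream"):
        raise ValueError("reference must be 'gradient' or 'upstream'")
    if comp > 0:
        return "toward"
    if comp < 0:
        return "against"
    return "indeterminate"
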