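"""Shared domain types for the gradient-orientation pipeline.

Coordinate conventions used throughout the package
--------------------------------------------------
Image arrays are indexed ``(row, col)``.  Columns map to ``x``, the
across-channel position in micrometres measured from the wall bearing the
Wnt-source microgrooves (so concentration decreases with increasing ``x``).
Rows map to ``y``, the along-flow position, increasing downstream.

Pole-to-pole angles use the device frame: an angle of 0 points toward the
Wnt-source wall (direction of increasing concentration, i.e. -x) and an
angle of -pi/2 points upstream (-y).  Angles are wrapped to (-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import math


@dataclass(frozen=True)
class ChannelGeometry:
    """Physical layout of the cell-culturing channel and its imaging scale.

    The culturing channel is a straight rectangular channel (default
    1000 um across, 160 um deep) flanked by microgrooves 250 um wide
    through which the Wnt3a-conditioned medium diffuses in.  Grooves are
    numbered 1..n_grooves from upstream to downstream; each groove centre
    defines one ROI band for gradient profiling.
    """

    width_um: float = 1000.0
    length_um: float = 10_000.0
    height_um: float = 160.0
    microgroove_width_um: float = 250.0
    n_grooves: int = 20
    pixel_size_um: float = 2.7

    def __post_init__(self) -> None:
        for name in ("width_um", "length_um", "height_um",
                     "microgroove_width_um", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_grooves < 1:
            raise ValueError("n_grooves must be >= 1")

    @property
    def groove_pitch_um(self) -> float:
        return self.length_um / self.n_grooves

    def groove_center_um(self, roi_id: int) -> float:
        """Along-flow centre of groove channel ``roi_id`` (1-based)."""
        if not 1 <= roi_id <= self.n_grooves:
            raise ValueError(
                f"roi_id must be in 1..{self.n_grooves}, got {roi_id}")
        return (roi_id - 0.5) * self.groove_pitch_um

    @property
    def shape_px(self) -> tuple[int, int]:
        """(rows, cols) of a full-channel image at this pixel size."""
        return (int(round(self.length_um / self.pixel_size_um)),
                int(round(self.width_um / self.pixel_size_um)))


@dataclass(frozen=True)
class FlowParams:
    """Flow and solute parameters of one perfusion condition.

    ``mean_speed_um_s`` is the plug-flow speed v; it can be derived from
    the volumetric rate and the channel cross-section.  ``diffusivity``
    defaults to 50 um^2/s, an order-of-magnitude literature value for a
    ~40 kDa dextran tracer (the solute D is a free parameter of the model).
    """

    flow_rate_ul_min: float = 2.0
    mean_speed_um_s: float = 208.3
    diffusivity_um2_s: float = 50.0
    source_conc_ng_ml: float = 30.0
    mw_kda: float = 38.0

    def __post_init__(self) -> None:
        if self.mean_speed_um_s <= 0:
            raise ValueError("mean flow speed must be > 0")
        if self.diffusivity_um2_s <= 0:
            raise ValueError("diffusivity must be > 0")
        if self.source_conc_ng_ml < 0:
            raise ValueError("source concentration must be >= 0")
        if self.mw_kda <= 0:
            raise ValueError("molecular weight must be > 0")

    @classmethod
    def from_flow_rate(cls, flow_rate_ul_min: float,
                       geometry: ChannelGeometry,
                       diffusivity_um2_s: float = 50.0,
                       source_conc_ng_ml: float = 30.0,
                       mw_kda: float = 38.0) -> "FlowParams":
        """Derive the mean plug-flow speed from rate / cross-section."""
        if flow_rate_ul_min <= 0:
            raise ValueError("flow rate must be > 0")
        q_um3_s = flow_rate_ul_min * 1e9 / 60.0
        v = q_um3_s / (geometry.width_um * geometry.height_um)
        return cls(flow_rate_ul_min=flow_rate_ul_min, mean_speed_um_s=v,
                   diffusivity_um2_s=diffusivity_um2_s,
                   source_conc_ng_ml=source_conc_ng_ml, mw_kda=mw_kda)

    @property
    def source_conc_nM(self) -> float:
        """Source molar concentration in nM from mass conc and MW."""
        # ng/mL = 1e-6 g/L; MW in kDa = 1e3 g/mol; mol/L -> nM is 1e9
        return (self.source_conc_ng_ml * 1e-6) / (self.mw_kda * 1e3) * 1e9


@dataclass(frozen=True)
class ResponseModel:
    """Synthetic dose-response of mitotic axis orientation to the gradient.

    A cell whose local gradient exposure is at/above ``threshold_nM_per_um``
    orients toward the high-concentration side with probability
    ``p_toward``; below threshold the toward/against choice is fair.  Within
    the chosen half-plane the angle is von Mises distributed with
    concentration ``kappa`` around 0 (toward) or pi (against).

    ``logistic_width_nM_per_um`` switches the step response to a logistic
    ramp of that width when set to a positive value.

    The default threshold (1.0e-3 nM/um) sits near the upper-quartile
    exposure of the default synthetic device so that a four-bin equal-count
    analysis has power to localize it; see docs/methods.md.
    """

    threshold_nM_per_um: float = 1.0e-3
    p_toward: float = 0.7
    kappa: float = 2.0
    logistic_width_nM_per_um: float = 0.0

    def __post_init__(self) -> None:
        if not 0.5 <= self.p_toward <= 1.0:
            raise ValueError("p_toward must be in [0.5, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.threshold_nM_per_um < 0:
            raise ValueError("threshold must be >= 0")

    def p_of_gradient(self, grad_nM_per_um):
        """Probability of a toward-gradient axis at the given exposure."""
        import numpy as np
        g = np.asarray(grad_nM_per_um, dtype=float)
        if self.logistic_width_nM_per_um > 0:
            z = (g - self.threshold_nM_per_um) / self.logistic_width_nM_per_um
            out = 0.5 + (self.p_toward - 0.5) / (1.0 + np.exp(-z))
        else:
            out = np.where(g >= self.threshold_nM_per_um, self.p_toward, 0.5)
        return out if out.ndim else float(out)


@dataclass
class ErfcFitResult:
    """Fitted parameters of the cross-channel diffusion profile

        C(x) = 1/2 (c_max - c_min) erfc((x - alpha)/beta) + c_min

    alpha is the mid-concentration position, beta the diffusive spread
    (both in micrometres), and rss the residual sum of squares of the fit.
    """

    c_max: float
    c_min: float
    alpha_um: float
    beta_um: float
    rss: float = 0.0
    converged: bool = True
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.beta_um <= 0:
            raise ValueError("beta_um must be > 0")
        if self.c_max < self.c_min:
            raise ValueError("c_max must be >= c_min")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")


@dataclass
class DecayModel:
    """Exponential z-attenuation of fluorescence with objective height.

    Relative intensity at objective offset dz (um above the reference
    plane z0) is modelled as  I(dz) = a * exp(b * dz) + c,  with b <= 0
    expected; a + c is the predicted relative intensity at dz = 0 and c
    the residual intensity at maximal attenuation.
    """

    a: float
    b: float
    c: float
    cov: list | None = None
    converged: bool = True
    degenerate: bool = False

    def predict(self, dz_um):
        import numpy as np
        return self.a * np.exp(self.b * np.asarray(dz_um, dtype=float)) + self.c

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DecayModel":
        return cls(**json.loads(text))


@dataclass
class BeadMeasurement:
    """One bead intensity reading at objective offset ``delta_z_um``."""

    delta_z_um: float
    relative_intensity: float

    def __post_init__(self) -> None:
        if self.delta_z_um < 0:
            raise ValueError("delta_z_um must be >= 0")
        if self.relative_intensity <= 0:
            raise ValueError("relative_intensity must be > 0")


@dataclass
class OrientationTest:
    """Counts and exact binomial p-value for one directional classification.

    ``a`` counts cells oriented toward the reference direction, ``b``
    against; the reported probability is a/(a+b) and the p-value is the
    two-sided exact binomial test against p0 = 0.5.
    """

    a: int
    b: int
    p_value: float
    reference: str = "gradient"

    @property
    def n(self) -> int:
        return self.a + self.b

    @property
    def fraction_toward(self) -> float:
        return self.a / self.n if self.n else math.nan


@dataclass
class FluctuationResult:
    """Temporal-stability statistic of a normalized-difference series:
    sigma = mean |dC1_i - median(dC1)|."""

    sigma: float
    n_frames: int
    position_um: float | None = None
    interval_s: float | None = None


@dataclass
class SensitivityBins:
    """Equal-count gradient-exposure bins with per-bin orientation tests.

    ``edges`` has k+1 entries (data min, midpoints between adjacent bins,
    data max).  ``threshold_nM_per_um`` is the lower edge of the
    lowest-exposure bin with a significant toward-gradient bias, or None
    when no bin qualifies.
    """

    k: int
    edges: list
    counts: list
    tests: list = field(default_factory=list)
    threshold_nM_per_um: float | None = None
    threshold_bin: int | None = None
    degenerate: bool = False
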