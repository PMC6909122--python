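"""Planar dose containers and gamma-index comparison (3%/1 mm default).

The gamma index combines a dose-difference criterion with a
distance-to-agreement (DTA) search: a reference pixel passes when some
nearby evaluated dose lies within the combined ellipsoidal tolerance,

    gamma(p) = min_q sqrt( |p-q|^2 / dta^2
                           + (D_e(q) - D_r(p))^2 / (crit * D_norm)^2 ),

with global normalization D_norm. Film planes here are normalized to a
low-gradient plateau region inside the target before comparison, so the
default normalization mode is "plateau".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "DosePlane",
    "GammaParams",
    "GammaResult",
    "RegionSpec",
    "gamma_map",
    "normalize_to_plateau",
    "find_plateau_region",
]


@dataclass
class DosePlane:
    """2-D dose (or film-response) distribution on a regular lattice.

    Axes are (u, v) in mm in the measurement plane; ``origin`` is the
    center of pixel (0, 0).
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.spacing = np.asarray(self.spacing, float)
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("dose plane must be 2-D")
        if np.any(self.spacing <= 0):
            raise ValueError("plane spacing must be positive")

    def axes(self):
        return [
            self.origin[a] + np.arange(self.values.shape[a]) * self.spacing[a]
            for a in range(2)
        ]

    def interpolator(self, fill=np.nan):
        return RegularGridInterpolator(
            self.axes(), self.values, method="linear", bounds_error=False, fill_value=fill
        )

    def pixel_positions(self):
        u, v = self.axes()
        return np.meshgrid(u, v, indexing="ij")


@dataclass(frozen=True)
class RegionSpec:
    """Axis-aligned rectangular region: center (u, v) and half-widths, mm."""

    center: tuple[float, float]
    half_width: tuple[float, float]

    def mask(self, plane: DosePlane) -> np.ndarray:
        U, V = plane.pixel_positions()
        return (np.abs(U - self.center[0]) <= self.half_width[0]) & (
            np.abs(V - self.center[1]) <= self.half_width[1]
        )


@dataclass(frozen=True)
class GammaParams:
    """Gamma-comparison settings; defaults 3 % / 1 mm, plateau-normalized,
    10 % low-dose threshold, search radius 3*dta."""

    dose_criterion: float = 3.0  # % of the normalization dose
    dta: float = 1.0  # mm
    normalization: Union[str, float] = "plateau"  # "plateau" | "max" | explicit Gy
    plateau_region: Optional[RegionSpec] = None
    low_dose_threshold: float = 10.0  # % of normalization dose
    search_radius: Optional[float] = None  # mm; None -> 3*dta
    max_step: float = 0.1  # mm, evaluated-plane upsampling step

    def __post_init__(self):
        if min(self.dose_criterion, self.dta, self.low_dose_threshold, self.max_step) <= 0:
            raise ValueError("gamma parameters must be positive")

    @property
    def radius(self) -> float:
        return self.search_radius if self.search_radius is not None else 3.0 * self.dta


@dataclass
class GammaResult:
    """Gamma map on the reference lattice plus the headline pass rate."""

    gamma: np.ndarray
    evaluated_mask: np.ndarray  # pixels included in the pass rate
    pass_rate: float  # % of evaluated pixels with gamma <= 1
    d_norm: float
    params: GammaParams = field(repr=False, default_factory=GammaParams)


def _normalization_dose(ref: DosePlane, params: GammaParams) -> float:
    if isinstance(params.normalization, (int, float)):
        return float(params.normalization)
    if params.normalization == "max":
        return float(ref.values.max())
    if params.normalization == "plateau":
        if params.plateau_region is not None:
            m = params.plateau_region.mask(ref)
            if not m.any():
                raise ValueError("plateau region does not intersect the reference plane")
            return float(ref.values[m].mean())
        # no operator-supplied region: use the high-dose plateau proxy
        top = ref.values >= 0.95 * ref.values.max()
        return float(ref.values[top].mean())
    raise ValueError(f"unknown normalization {params.normalization!r}")


def gamma_map(reference: DosePlane, evaluated: DosePlane, params: GammaParams | None = None) -> GammaResult:
    """Global gamma comparison of an evaluated plane against a reference.

    The evaluated plane is resampled onto a fine lattice (steps <=
    ``params.max_step``) aligned with the reference pixels, and the DTA
    search scans every fine-lattice offset within the search radius.
    Reference pixels below the low-dose threshold are excluded from the
    pass rate (their gamma is still reported).
    """
    params = params or GammaParams()
    d_norm = _normalization_dose(reference, params)
    if d_norm <= 0:
        raise ValueError("normalization dose must be positive")
    dose_tol = params.dose_criterion / 100.0 * d_norm

    ru, rv = reference.axes()
    eu, ev = evaluated.axes()
    if ru[-1] < eu[0] or eu[-1] < ru[0] or rv[-1] < ev[0] or ev[-1] < rv[0]:
        raise ValueError("reference and evaluated planes do not overlap")

    # fine lattice aligned with reference pixels
    ku = max(1, int(math.ceil(reference.spacing[0] / params.max_step)))
    kv = max(1, int(math.ceil(reference.spacing[1] / params.max_step)))
    fu = reference.spacing[0] / ku
    fv = reference.spacing[1] / kv
    radius = params.radius
    nou = int(math.floor(radius / fu))
    nov = int(math.floor(radius / fv))

    nu, nv = reference.values.shape
    fine_u = reference.origin[0] + np.arange(-nou, (nu - 1) * ku + nou + 1) * fu
    fine_v = reference.origin[1] + np.arange(-nov, (nv - 1) * kv + nov + 1) * fv
    interp = evaluated.interpolator(fill=np.nan)
    FU, FV = np.meshgrid(fine_u, fine_v, indexing="ij")
    fine = interp(np.stack([FU.ravel(), FV.ravel()], axis=-1)).reshape(FU.shape)

    ref_vals = reference.values
    gamma_sq = np.full((nu, nv), np.inf)
    base_i = np.arange(nu) * ku + nou
    base_j = np.arange(nv) * kv + nov
    for a in range(-nou, nou + 1):
        du2 = (a * fu) ** 2
        if du2 > radius**2:
            continue
        for b in range(-nov, nov + 1):
            dist2 = du2 + (b * fv) ** 2
            if dist2 > radius**2:
                continue
            shifted = fine[np.ix_(base_i + a, base_j + b)]
            cand = dist2 / params.dta**2 + (shifted - ref_vals) ** 2 / dose_tol**2
            np.fmin(gamma_sq, cand, out=gamma_sq, where=~np.isnan(cand))
    gamma = np.sqrt(gamma_sq)

    eval_mask = ref_vals >= params.low_dose_threshold / 100.0 * d_norm
    eval_mask &= np.isfinite(gamma)
    if not eval_mask.any():
        raise ValueError("no reference pixels above the low-dose threshold")
    pass_rate = 100.0 * float(np.mean(gamma[eval_mask] <= 1.0))
    return GammaResult(gamma=gamma, evaluated_mask=eval_mask, pass_rate=pass_rate, d_norm=d_norm, params=params)


def normalize_to_plateau(
    plane: DosePlane,
    region: RegionSpec,
    reference_mean: float = 1.0,
    max_gradient: float = 0.005,
) -> tuple[DosePlane, float]:
    """Scale a plane so a low-gradient plateau region has a given mean.

    The region must be a genuine plateau: the relative dose change per mm
    (central differences) must stay below ``max_gradient`` everywhere
    inside it. Returns the scaled plane and the scale factor applied.
    """
    m = region.mask(plane)
    if not m.any():
        raise ValueError("plateau region does not intersect the plane")
    vals = plane.values
    gu, gv = np.gradient(vals, *plane.spacing)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(vals > 0, np.maximum(np.abs(gu), np.abs(gv)) / vals, np.inf)
    if np.any(rel[m] >= max_gradient):
        worst = float(np.max(rel[m]))
        raise ValueError(
            f"region is not a plateau: max relative gradient {worst:.4f}/mm >= {max_gradient}/mm"
        )
    mean = float(vals[m].mean())
    if mean <= 0:
        raise ValueError("plateau mean must be positive")
    scale = reference_mean / mean
    return replace(plane, values=vals * scale), scale


def find_plateau_region(
    plane: DosePlane,
    half_width: float = 3.0,
    max_gradient: float = 0.005,
) -> RegionSpec:
    """Locate a plateau (low-gradient, high-dose) region on a dose plane.

    Scans square regions of the given half-width (mm); a candidate center
    qualifies when every pixel of its region has a relative dose gradient
    below ``max_gradient`` per mm. Among qualifying centers the one with
    the highest dose wins. Raises when no region qualifies.
    """
    from scipy.ndimage import maximum_filter

    vals = plane.values
    gu, gv = np.gradient(vals, *plane.spacing)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(vals > 0, np.maximum(np.abs(gu), np.abs(gv)) / vals, np.inf)
    ku = max(1, int(round(half_width / plane.spacing[0])))
    kv = max(1, int(round(half_width / plane.spacing[1])))
    worst = maximum_filter(rel, size=(2 * ku + 1, 2 * kv + 1), mode="constant", cval=np.inf)
    ok = worst < max_gradient
    # region must fit inside the plane
    ok[:ku, :] = ok[-ku:, :] = False
    ok[:, :kv] = ok[:, -kv:] = False
    if not ok.any():
        raise ValueError(
            f"no {2*half_width:.0f} mm plateau with gradient < {max_gradient}/mm on the plane"
        )
    masked = np.where(ok, vals, -np.inf)
    i, j = np.unravel_index(int(np.argmax(masked)), vals.shape)
    u, v = plane.axes()
    return RegionSpec(center=(float(u[i]), float(v[j])), half_width=(ku * plane.spacing[0], kv * plane.spacing[1]))
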