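"""Plan model for cup-based breast stereotactic radiosurgery.

A treatment is described as an ordered list of *control points*: table
positions (x, y, z) at which the focal spot dwells for a given beam-on time
with a given collimator (15 or 25 mm). The breast is immobilized in a
vacuum-assisted dual-cup system that doubles as the stereotactic frame.

Coordinate convention (stereotactic frame): ``y`` runs along the cup axis
with the chest wall at y = 0 and the cup apex at positive y; ``x`` and ``z``
span the transverse plane. The machine radial coordinate is
``r = sqrt(x**2 + z**2)``.
"""

from __future__ import annotations

import json
import math
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "CupGeometry",
    "ControlPoint",
    "TargetStructure",
    "Plan",
    "ReferencePoint",
    "PlanGeneratorSpec",
    "read_plan",
    "write_plan",
    "make_qa_plan",
    "find_low_gradient_point",
    "to_jig_coordinates",
    "from_jig_coordinates",
    "generate_synthetic_plan",
    "sphere_mask",
]

#: Base diameter (mm) of each outer-cup size class.
BASE_DIAMETER_MM = {"small": 93.7, "medium": 121.7, "large": 153.7}

_SIZE_OFFSET_MM = {"small": 0.0, "medium": 6.0, "large": 12.0}


def default_apex_y(size_class: str, inner_index: int) -> float:
    """Chest-to-apex distance (mm) of the default cup model.

    Inner cups come in 10 depth classes per outer size; the model spaces
    them 8 mm apart with a modest offset between outer sizes.
    """
    return 40.0 + 8.0 * inner_index + _SIZE_OFFSET_MM[size_class]


class CupGeometry(BaseModel):
    """Immobilization cup: outer size class plus inner (depth) index.

    The cup interior is modeled as a half-ellipsoid of revolution about the
    cup axis: base radius ``base_diameter/2`` at the chest wall (y = 0)
    tapering to the apex at ``y = apex_y``.
    """

    model_config = {"frozen": True}

    size_class: Literal["small", "medium", "large"]
    inner_index: int = Field(ge=1, le=10)
    base_diameter: Optional[float] = None
    apex_y: Optional[float] = None

    @model_validator(mode="after")
    def _fill_derived(self) -> "CupGeometry":
        expected = BASE_DIAMETER_MM[self.size_class]
        if self.base_diameter is None:
            object.__setattr__(self, "base_diameter", expected)
        elif abs(self.base_diameter - expected) > 1e-9:
            raise ValueError(
                f"base_diameter {self.base_diameter} does not match "
                f"size_class {self.size_class!r} (expected {expected})"
            )
        if self.apex_y is None:
            object.__setattr__(
                self, "apex_y", default_apex_y(self.size_class, self.inner_index)
            )
        elif self.apex_y <= 0:
            raise ValueError("apex_y must be positive")
        return self

    @property
    def cup_id(self) -> str:
        return f"{self.size_class[0].upper()}{self.inner_index:02d}"

    @property
    def base_radius(self) -> float:
        return self.base_diameter / 2.0

    @property
    def center(self) -> tuple[float, float, float]:
        """Nominal cup center: on-axis at half the chest-to-apex depth."""
        return (0.0, self.apex_y / 2.0, 0.0)

    def contains(self, x: float, y: float, z: float, margin: float = 0.0) -> bool:
        """Whether a point lies inside the half-ellipsoid cup interior."""
        if y < -1e-9 or y > self.apex_y:
            return False
        rr = math.hypot(x, z)
        scale = 1.0 - (y / self.apex_y) ** 2
        if scale <= 0:
            return rr <= margin
        return rr <= self.base_radius * math.sqrt(scale) - margin

    def radius_at(self, y: float) -> float:
        """Transverse cup radius (mm) at axial position y."""
        scale = max(0.0, 1.0 - (y / self.apex_y) ** 2)
        return self.base_radius * math.sqrt(scale)


class ControlPoint(BaseModel):
    """One delivery state: table position, collimator and dwell time."""

    model_config = {"populate_by_name": True}

    x: float = Field(alias="x_mm")
    y: float = Field(alias="y_mm")
    z: float = Field(alias="z_mm")
    collimator: Literal[15, 25] = Field(alias="collimator_mm")
    dwell_time: float = Field(alias="time_s", ge=0.0)

    @property
    def r(self) -> float:
        """Distance from the machine central axis, sqrt(x^2 + z^2)."""
        return math.hypot(self.x, self.z)

    @property
    def position(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


class TargetStructure(BaseModel):
    """A contoured structure: label, volume and centroid.

    ``mask`` optionally carries the voxel-index set of the structure on a
    named dose grid (``{"grid": name, "voxels": [[i, j, k], ...]}``).
    """

    model_config = {"populate_by_name": True}

    label: Literal["GTV", "PTV", "normal_breast"]
    volume: float = Field(alias="volume_cc", gt=0.0)
    centroid: tuple[float, float, float] = Field(alias="centroid_mm")
    mask: Optional[dict] = None

    @property
    def equivalent_radius(self) -> float:
        """Radius (mm) of the volume-equivalent sphere."""
        return (3.0 * self.volume * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


class ReferencePoint(BaseModel):
    """Dose-verification point with its averaging convention.

    ``cube_5x5x5`` mirrors reading the mean of the 5x5x5-voxel block
    (0.125 cc at 1 mm voxels) around the point, which approximates a small
    thimble-chamber sensitive volume better than a single 0.001 cc voxel.
    """

    position: tuple[float, float, float]
    averaging: Literal["single_voxel", "cube_5x5x5"] = "cube_5x5x5"

    @property
    def y(self) -> float:
        return self.position[1]

    @property
    def r(self) -> float:
        return math.hypot(self.position[0], self.position[2])


class Plan(BaseModel):
    """A full delivery description for one patient or QA session."""

    model_config = {"populate_by_name": True}

    plan_id: str
    cup: CupGeometry
    control_points: list[ControlPoint] = Field(min_length=1)
    targets: list[TargetStructure] = Field(default_factory=list)
    prescription_dose: float = Field(alias="prescription_Gy", gt=0.0)
    qa_metadata: Optional[dict] = None

    @property
    def n_control_points(self) -> int:
        return len(self.control_points)

    @property
    def is_qa_plan(self) -> bool:
        return bool(self.qa_metadata and self.qa_metadata.get("is_qa_plan"))

    def target(self, label: str) -> TargetStructure:
        for t in self.targets:
            if t.label == label:
                return t
        raise KeyError(f"plan {self.plan_id!r} has no target labeled {label!r}")

    def total_beam_on_time(self) -> float:
        return sum(cp.dwell_time for cp in self.control_points)

    def validate_geometry(self) -> None:
        """Check that every control point lies inside the cup interior."""
        bad = [
            i
            for i, cp in enumerate(self.control_points)
            if not self.cup.contains(cp.x, cp.y, cp.z)
        ]
        if bad:
            raise ValueError(
                f"control points outside cup interior: indices {bad[:10]}"
                + ("..." if len(bad) > 10 else "")
            )


# ---------------------------------------------------------------------------
# Plan file format (JSON, explicit units)
# ---------------------------------------------------------------------------

_UNITS = {"length": "mm", "time": "s", "dose": "Gy"}


def _plan_to_dict(plan: Plan) -> dict:
    d = {
        "format": "gpqa-plan-v1",
        "units": dict(_UNITS),
        "plan_id": plan.plan_id,
        "cup": {
            "size_class": plan.cup.size_class,
            "inner_index": plan.cup.inner_index,
            "apex_y_mm": plan.cup.apex_y,
        },
        "prescription_Gy": plan.prescription_dose,
        "control_points": [
            cp.model_dump(by_alias=True) for cp in plan.control_points
        ],
        "targets": [
            t.model_dump(by_alias=True, exclude_none=True) for t in plan.targets
        ],
    }
    if plan.qa_metadata is not None:
        d["qa"] = plan.qa_metadata
    return d


def _plan_from_dict(d: dict) -> Plan:
    cup_d = dict(d["cup"])
    apex = cup_d.pop("apex_y_mm", None)
    cup = CupGeometry(apex_y=apex, **cup_d)
    return Plan(
        plan_id=d["plan_id"],
        cup=cup,
        control_points=d["control_points"],
        targets=d.get("targets", []),
        prescription_Gy=d["prescription_Gy"],
        qa_metadata=d.get("qa"),
    )


def write_plan(plan: Plan, path) -> None:
    """Write a plan to the JSON plan format (round-trip lossless)."""
    with open(path, "w") as fh:
        json.dump(_plan_to_dict(plan), fh, indent=1)
        fh.write("\n")


def read_plan(path) -> Plan:
    """Read a plan from the JSON plan format, validating the schema."""
    with open(path) as fh:
        d = json.load(fh)
    return _plan_from_dict(d)


# ---------------------------------------------------------------------------
# QA-plan generation
# ---------------------------------------------------------------------------


def make_qa_plan(
    plan: Plan,
    chamber_position: tuple[float, float, float],
    centroid_of: Literal["GTV", "PTV"] = "GTV",
) -> Plan:
    """Translate a clinical plan so a target centroid lands on the chamber.

    Only the table positions change: every control point (and each target
    centroid, so the shifted geometry stays self-consistent) is translated
    by ``chamber_position - centroid(centroid_of)``. Dwell times and
    collimators are untouched. Which centroid is moved (GTV or PTV) is an
    explicit choice recorded in the QA metadata. Structure masks do not
    survive the shift (they index the original grid) and are dropped.
    """
    target = plan.target(centroid_of)
    shift = tuple(c - t for c, t in zip(chamber_position, target.centroid))
    cps = [
        cp.model_copy(update={"x": cp.x + shift[0], "y": cp.y + shift[1], "z": cp.z + shift[2]})
        for cp in plan.control_points
    ]
    targets = [
        t.model_copy(
            update={
                "centroid": tuple(c + s for c, s in zip(t.centroid, shift)),
                "mask": None,
            }
        )
        for t in plan.targets
    ]
    return plan.model_copy(
        update={
            "plan_id": plan.plan_id + "-QA",
            "control_points": cps,
            "targets": targets,
            "qa_metadata": {
                "is_qa_plan": True,
                "centroid_of": centroid_of,
                "chamber_position_mm": list(chamber_position),
                "shift_mm": list(shift),
                "source_plan_id": plan.plan_id,
            },
        }
    )


# ---------------------------------------------------------------------------
# Reference-point selection and jig coordinates
# ---------------------------------------------------------------------------


def find_low_gradient_point(grid, structure: TargetStructure, max_gradient: float = 0.005) -> ReferencePoint:
    """Pick a verification point in a low-gradient region of a structure.

    A voxel qualifies when the relative dose change per mm (central
    differences along each axis, normalized by the local dose) stays below
    ``max_gradient`` on all three axes. Among qualifying voxels the one
    with the largest dose wins; remaining ties go to the voxel closest to
    the structure centroid.

    Parameters
    ----------
    grid : DoseGrid
        Dose grid carrying the structure mask's voxel indices.
    structure : TargetStructure
        Must have a ``mask`` on this grid.
    max_gradient : float
        Threshold as a fraction per mm (default 0.005, i.e. <0.5 % over 1 mm).
    """
    if structure.mask is None:
        raise ValueError(f"structure {structure.label} carries no voxel mask")
    idx = np.asarray(structure.mask["voxels"], dtype=int)
    if idx.size == 0:
        raise ValueError("empty structure mask")
    values = grid.values
    shape = np.asarray(values.shape)
    # central differences need both neighbors on-grid
    interior = np.all((idx >= 1) & (idx <= shape - 2), axis=1)
    idx = idx[interior]
    if idx.size == 0:
        raise ValueError("no low-gradient point: mask has no interior voxels")
    i, j, k = idx[:, 0], idx[:, 1], idx[:, 2]
    dose = values[i, j, k]
    ok = dose > 0
    rel = np.zeros((len(idx), 3))
    sp = grid.spacing
    rel[:, 0] = np.abs(values[i + 1, j, k] - values[i - 1, j, k]) / (2 * sp[0])
    rel[:, 1] = np.abs(values[i, j + 1, k] - values[i, j - 1, k]) / (2 * sp[1])
    rel[:, 2] = np.abs(values[i, j, k + 1] - values[i, j, k - 1]) / (2 * sp[2])
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(dose[:, None] > 0, rel / dose[:, None], np.inf)
    ok &= np.all(rel < max_gradient, axis=1)
    if not np.any(ok):
        raise ValueError(
            f"no low-gradient point: no voxel in {structure.label} has relative "
            f"gradient < {max_gradient:.4f}/mm on all axes"
        )
    idx, dose = idx[ok], dose[ok]
    pos = grid.origin + idx * grid.spacing
    dist = np.linalg.norm(pos - np.asarray(structure.centroid), axis=1)
    # lexicographic: max dose, then min distance to centroid
    order = np.lexsort((dist, -dose))
    best = pos[order[0]]
    return ReferencePoint(position=tuple(float(v) for v in best))


def to_jig_coordinates(point) -> tuple[float, float, float]:
    """Stereotactic (x, y, z) -> chamber-jig cylindrical (r, theta_deg, y).

    theta is measured in the transverse plane from +x toward +z, reported
    in [0, 360). On the axis (r = 0) theta is defined as 0.
    """
    x, y, z = point
    r = math.hypot(x, z)
    theta = 0.0 if r == 0.0 else math.degrees(math.atan2(z, x)) % 360.0
    if theta >= 360.0:  # guard the wrap-around rounding of tiny negatives
        theta = 0.0
    return (r, theta, y)


def from_jig_coordinates(jig) -> tuple[float, float, float]:
    """Inverse of :func:`to_jig_coordinates`."""
    r, theta, y = jig
    th = math.radians(theta)
    return (r * math.cos(th), y, r * math.sin(th))


# ---------------------------------------------------------------------------
# Synthetic plan generation
# ---------------------------------------------------------------------------


class PlanGeneratorSpec(BaseModel):
    """Sampling envelope for synthetic plans.

    Defaults reproduce the attribute ranges of a 15-patient single-fraction
    8 Gy boost cohort: GTV 2.9-29.1 cc (mean 11.1), PTV 21.7-153.9 cc
    (mean 66.9), breast 722-1994 cc (mean 1264) and 361-813 control points
    (mean 491). Each attribute is drawn from a Beta distribution rescaled
    to its [min, max] envelope with the mean pinned at the cohort average.
    """

    gtv_cc: tuple[float, float, float] = (2.9, 11.1, 29.1)  # (min, mean, max)
    ptv_cc: tuple[float, float, float] = (21.7, 66.9, 153.9)
    breast_cc: tuple[float, float, float] = (722.0, 1264.0, 1994.0)
    n_control_points: tuple[float, float, float] = (361.0, 491.0, 813.0)
    prescription_Gy: float = 8.0
    dwell_time_s: tuple[float, float] = (0.02, 20.0)  # optimizer bounds
    spread_divisor: float = 1.5  # cloud SD = PTV-equivalent radius / this
    collimator_25_fraction: float = 0.3  # of shots, interleaved through the sequence
    position_jitter: float = 0.5  # mm, SD of per-shot placement noise
    concentration: float = 6.0  # Beta pseudo-sample size

    @model_validator(mode="after")
    def _check(self) -> "PlanGeneratorSpec":
        for name in ("gtv_cc", "ptv_cc", "breast_cc", "n_control_points"):
            lo, mean, hi = getattr(self, name)
            if not (0 < lo < mean < hi):
                raise ValueError(f"{name}: need 0 < min < mean < max")
        return self


def _draw_pinned_beta(rng, lo_mean_hi, kappa):
    """Sample in [lo, hi] from a Beta with the requested mean."""
    lo, mean, hi = lo_mean_hi
    m = (mean - lo) / (hi - lo)
    a, b = kappa * m, kappa * (1.0 - m)
    return lo + (hi - lo) * rng.beta(a, b)


def _cup_for_breast_volume(breast_cc: float, spec: PlanGeneratorSpec) -> CupGeometry:
    lo, _, hi = spec.breast_cc
    frac = np.clip((breast_cc - lo) / (hi - lo), 0.0, 1.0)
    size = "small" if frac < 1 / 3 else ("medium" if frac < 2 / 3 else "large")
    inner = int(round(2 + 7 * frac))  # 2..9: extreme inner cups are rare
    return CupGeometry(size_class=size, inner_index=inner)


def _ball_points(n: int, rng) -> np.ndarray:
    """Low-discrepancy (Halton) points filling the unit ball."""
    from scipy.stats import qmc

    sampler = qmc.Halton(d=3, scramble=True, seed=rng)
    pts: list = []
    while len(pts) < n:
        cand = 2.0 * sampler.random(2 * (n - len(pts)) + 8) - 1.0
        keep = np.sum(cand * cand, axis=1) <= 1.0
        pts.extend(cand[keep])
    return np.asarray(pts[:n])


def _flatten_dwell_times(
    positions: np.ndarray,
    collimators: np.ndarray,
    centroid,
    r_target: float,
    prescription: float,
    apex_y: float,
    rng,
    bounds: tuple[float, float],
    n_sample: int = 128,
) -> np.ndarray:
    """Beam-on times that flatten the in-target dose at the prescription.

    Emulates the planning optimizer: bounded linear least squares on a
    nominal kernel model (erf top-hat profiles, exponential depth
    attenuation) over low-discrepancy sample points inside the target.
    """
    from scipy.optimize import lsq_linear

    from .profiles import NOMINAL_FWHM, NOMINAL_MU, NOMINAL_RATE, NOMINAL_SIGMA, erf_tophat

    pts = np.asarray(centroid) + 0.8 * r_target * _ball_points(n_sample, rng)
    dy = pts[:, 1][:, None] - positions[:, 1][None, :]
    dr = np.hypot(
        pts[:, 0][:, None] - positions[:, 0][None, :],
        pts[:, 2][:, None] - positions[:, 2][None, :],
    )
    A = np.empty_like(dy)
    for coll in (15, 25):
        m = collimators == coll
        if m.any():
            w, s = NOMINAL_FWHM[coll], NOMINAL_SIGMA
            A[:, m] = erf_tophat(dy[:, m], w, s) * erf_tophat(dr[:, m], w, s)
    rate = NOMINAL_RATE * np.exp(-NOMINAL_MU * (apex_y - positions[:, 1])) / 60.0  # Gy/s
    A *= rate[None, :]
    res = lsq_linear(A, np.full(len(pts), prescription), bounds=bounds, lsmr_tol="auto")
    return np.clip(res.x, *bounds)


def _gaussian_cloud(n: int, rng) -> np.ndarray:
    """Low-discrepancy (Halton) standard-normal cloud in 3-D.

    Quasi-random placement keeps the cloud's radial profile essentially
    deterministic at a given n, emulating an optimizer's reproducible
    shot pattern rather than an accidental scatter.
    """
    from scipy.stats import norm, qmc

    sampler = qmc.Halton(d=3, scramble=True, seed=rng)
    u = sampler.random(n)
    return norm.ppf(np.clip(u, 1e-9, 1 - 1e-9))


def generate_synthetic_plan(
    spec: PlanGeneratorSpec | None = None,
    seed: int = 0,
    plan_id: str | None = None,
) -> Plan:
    """Draw a synthetic plan emulating the clinical cohort envelope.

    Control points emulate an optimizer painting the target: a quasi-
    random Gaussian cloud around the target centroid (SD of two-thirds
    the PTV-equivalent sphere radius) with sub-millimetre per-shot
    jitter. The two collimators are interleaved evenly through the
    delivery sequence. Points falling outside the cup (or that would leave it
    after the lateral QA shift onto the axis) are re-drawn. Beam-on times
    are then set by a bounded least-squares flattening of the in-target
    dose at the prescription level, as a planning optimizer would.
    Deterministic for a fixed seed.
    """
    spec = spec or PlanGeneratorSpec()
    rng = np.random.default_rng(seed)
    kappa = spec.concentration
    gtv = _draw_pinned_beta(rng, spec.gtv_cc, kappa)
    ptv = max(gtv * 1.5, _draw_pinned_beta(rng, spec.ptv_cc, kappa))
    breast = _draw_pinned_beta(rng, spec.breast_cc, kappa)
    n_cp = int(round(_draw_pinned_beta(rng, spec.n_control_points, kappa)))

    cup = _cup_for_breast_volume(breast, spec)
    r_ptv = (3.0 * ptv * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)

    # centroid: mid-depth band on the axis, modest lateral offset
    y_c = cup.apex_y * rng.uniform(0.40, 0.60)
    max_lat = max(0.0, cup.radius_at(y_c) - r_ptv - 2.0)
    lat = rng.uniform(0.0, min(0.30 * cup.base_radius, max_lat))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    centroid = (lat * math.cos(phi), y_c, lat * math.sin(phi))

    sd = r_ptv / spec.spread_divisor
    positions, collimators = [], []
    raw = _gaussian_cloud(n_cp, rng) * sd
    i = 0
    while len(positions) < n_cp:
        if i >= len(raw):
            raw = np.vstack([raw, _gaussian_cloud(n_cp, rng) * sd])
        dev = raw[i] + rng.normal(0.0, spec.position_jitter, size=3)
        i += 1
        p = np.asarray(centroid) + dev
        if not cup.contains(p[0], p[1], p[2], margin=1.0):
            continue
        # keep the plan deliverable after the QA lateral shift onto the axis
        if math.hypot(dev[0], dev[2]) > cup.base_radius - 1.0:
            continue
        # deterministic interleave of the two collimators through the
        # delivery sequence at the configured 25 mm fraction
        frac = spec.collimator_25_fraction
        collimators.append(25 if (len(positions) % 10) < round(10 * frac) else 15)
        positions.append(p)
    positions = np.asarray(positions)
    collimators = np.asarray(collimators)
    times = _flatten_dwell_times(
        positions, collimators, centroid, r_ptv, spec.prescription_Gy,
        cup.apex_y, rng, spec.dwell_time_s,
    )
    cps = [
        ControlPoint(x=float(p[0]), y=float(p[1]), z=float(p[2]), collimator=int(c), dwell_time=float(t))
        for p, c, t in zip(positions, collimators, times)
    ]

    targets = [
        TargetStructure(label="GTV", volume=float(gtv), centroid=centroid),
        TargetStructure(label="PTV", volume=float(ptv), centroid=centroid),
        TargetStructure(
            label="normal_breast",
            volume=float(breast),
            centroid=(0.0, 0.45 * cup.apex_y, 0.0),
        ),
    ]
    return Plan(
        plan_id=plan_id or f"synth-{seed:05d}",
        cup=cup,
        control_points=cps,
        targets=targets,
        prescription_Gy=spec.prescription_Gy,
    )


def sphere_mask(grid, centroid, volume_cc: float, grid_name: str = "grid") -> dict:
    """Voxel-index mask of the volume-equivalent sphere on a dose grid."""
    r = (3.0 * volume_cc * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    axes = [grid.origin[a] + np.arange(grid.values.shape[a]) * grid.spacing[a] for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    inside = (X - centroid[0]) ** 2 + (Y - centroid[1]) ** 2 + (Z - centroid[2]) ** 2 <= r * r
    vox = np.argwhere(inside)
    return {"grid": grid_name, "voxels": vox.tolist()}
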