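"""Forward dose engine: kernel superposition over control points.

The dose at a point p from a plan is the sum over control points i of

    rate(C_i, cup, y_i, r_i) * t_i * K_i(p - p_i)

where the kernel ``K_i`` is the off-center-ratio table of collimator C_i
evaluated at the axial offset ``y_p - y_i`` and the transverse distance
``rho = hypot(x_p - x_i, z_p - z_i)`` — a cylindrically symmetric dose
blob around each focal spot. Away from the cup's central axis the kernel
widens according to the library's distortion model:
``K_i(dy, rho) = OCR(dy / b_i, rho / b_i) / b_i**3`` with
``b_i = 1 + alpha * r_i / R`` (the 1/b^3 factor conserves the kernel's
integral: a distorted beam redistributes dose without creating it).
With ``alpha = 0`` and shots on the cup
axis the engine reduces exactly to the position-invariant central kernel
the independent point-dose check assumes — the lever used to validate
that check.

The engine serves as the in-package stand-in for the planning system's
Monte-Carlo-derived dose: it is the ground truth the verification
analytics are exercised against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import DoseGrid, GridSpec
from .kernels import KernelLibrary
from .plan import Plan

__all__ = ["compute_dose_grid", "apply_medium_correction", "CorrectedDose"]


def _accumulate_shot(dose, X, Y, Z, lib, collimator, cup, pos, minutes, broadening):
    """Add one shot's contribution in place. ``minutes`` = dwell in min.

    The kernel acts on the displacement from the focal spot: axial offset
    ``y - y_i`` and transverse distance ``rho = hypot(x - x_i, z - z_i)``,
    looked up in the cylindrically symmetric OCR table. For a focal spot
    on the cup axis this coincides exactly with the point-dose check's
    ``(y - y_i, r - r_i)`` convention, which is the centered-geometry
    condition under which the first-order kernel sum is valid.
    """
    x0, y0, z0 = pos
    r0 = math.hypot(x0, z0)
    rate = lib.dose_rate_lookup(collimator, cup, y0, r0)
    tab = lib.ocr[(collimator, cup.cup_id)]
    ext_y = tab.dy[-1] * broadening
    ext_r = tab.dr[-1] * broadening
    dy = Y - y0
    sel = np.abs(dy) <= ext_y
    if not np.any(sel):
        return
    rho = np.hypot(X[sel] - x0, Z[sel] - z0)
    inner = rho <= ext_r
    if not np.any(inner):
        return
    idx = np.flatnonzero(sel.ravel())[inner]
    f = lib._ocr_interp(collimator, cup.cup_id)
    pts = np.stack([dy[sel][inner] / broadening, rho[inner] / broadening], axis=-1)
    # width scaling divided by b^3 conserves the kernel's volume integral:
    # distortion redistributes dose, it does not create it
    dose.ravel()[idx] += rate * minutes * f(pts) / broadening**3


def compute_dose_grid(
    plan: Plan,
    lib: KernelLibrary,
    grid_spec: GridSpec,
    transit: bool = False,
    table_speed: float = 5.0,
    transit_step: float = 0.5,
) -> DoseGrid:
    """Superpose all control-point contributions onto a dose grid.

    Parameters
    ----------
    transit : bool
        When True, the dose delivered while the table moves in a straight
        line between consecutive control points (sources unblocked) is
        integrated by trapezoidal subdivision at steps of at most
        ``transit_step`` mm, assuming constant ``table_speed`` (mm/s) and
        the departing control point's collimator. Default off, matching
        the point-dose check's static-shot assumption.
    """
    if not lib.covers(plan):
        raise KeyError(f"library does not cover plan {plan.plan_id} (cup {plan.cup.cup_id})")
    grid = DoseGrid.zeros(grid_spec)
    X, Y, Z = grid.meshgrid()
    cup = plan.cup
    dist = lib.distortion
    for cp in plan.control_points:
        b = dist.broadening(cup, cp.x, cp.y, cp.z)
        _accumulate_shot(
            grid.values, X, Y, Z, lib, cp.collimator, cup, cp.position, cp.dwell_time / 60.0, b
        )
    if transit and len(plan.control_points) > 1:
        if table_speed <= 0:
            raise ValueError("table_speed must be positive")
        for a, bcp in zip(plan.control_points[:-1], plan.control_points[1:]):
            p0 = np.asarray(a.position, float)
            p1 = np.asarray(bcp.position, float)
            seg = np.linalg.norm(p1 - p0)
            if seg == 0.0:
                continue
            seg_time_min = seg / table_speed / 60.0
            nseg = max(1, int(math.ceil(seg / transit_step)))
            # trapezoidal rule: endpoints half-weighted
            ts = np.linspace(0.0, 1.0, nseg + 1)
            weights = np.full(nseg + 1, 1.0 / nseg)
            weights[[0, -1]] *= 0.5
            for t, w in zip(ts, weights):
                p = p0 + t * (p1 - p0)
                bfac = dist.broadening(cup, *p)
                _accumulate_shot(
                    grid.values, X, Y, Z, lib, a.collimator, cup,
                    tuple(p), seg_time_min * w, bfac,
                )
    grid.meta = {
        "plan_id": plan.plan_id,
        "transit": bool(transit),
        "table_speed_mm_s": table_speed if transit else None,
    }
    return grid


@dataclass(frozen=True)
class CorrectedDose:
    """A dose value with the medium-density correction applied and recorded."""

    value: float
    factor: float
    sign: int

    def __float__(self) -> float:
        return float(self.value)


def apply_medium_correction(dose: float, factor: float = 0.016, sign: int = +1) -> CorrectedDose:
    """Apply the water-vs-breast-density correction, multiplying by
    ``1 + sign * factor`` (default 1.6 %).

    The direction of the correction (whether measurement or calculation is
    scaled up) is deployment-specific, so the sign is explicit
    configuration and is recorded in the result rather than applied
    silently.
    """
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    if factor < 0:
        raise ValueError("factor must be non-negative")
    base = float(dose)
    if base < 0:
        raise ValueError("dose must be non-negative")
    return CorrectedDose(value=base * (1.0 + sign * factor), factor=factor, sign=sign)
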