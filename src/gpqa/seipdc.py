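"""Semi-empirical independent point-dose calculation (SEIPDC).

The secondary check of the planning system's point dose. The first-order
estimate overlays every shot and sums its contribution at the reference
point using the *central* (position-invariant) kernel:

    D_ref,no-volume = sum_i  D_i(C_i, c, y_i, r_i) * t_i
                             * OCR(C_i, y_i - y_ref, r_i - r_ref)

This is exact only when the dose kernel does not change with isocenter
position; in reality it distorts away from the cup center, increasingly so
for larger targets whose control points spread further out. The residual
is absorbed by an empirical, dimensionless volume-dependence factor Vf,
fitted as a linear function of target volume v against ground truth
(measurement or forward engine):

    D_ref = D_ref,no-volume  (x)  Vf(v),        Vf(v) = slope * v + intercept

How Vf combines with the first-order dose is configurable (see
:func:`dose_ref`); the operative definition is the calibration pathway:
fitting ground-truth/first-order *ratios* against volume and multiplying.
A published preset (slope 0.028/cc, intercept 2.7) is shipped for
completeness, but its magnitude (~2.7-7) cannot be a direct multiplier of
a dose that already agrees with ground truth to a few percent, so it is
never used as the default correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .kernels import KernelLibrary
from .plan import Plan, ReferencePoint

__all__ = [
    "VfModel",
    "SeipdcResult",
    "dose_ref_no_volume",
    "dose_ref",
    "vf_eval",
    "calibrate_vf",
    "percent_difference",
]


@dataclass(frozen=True)
class VfModel:
    """Linear volume-dependence correction: Vf(v) = slope * v + intercept."""

    slope: float  # per cc
    intercept: float  # unitless
    provenance: Literal["identity", "calibrated", "paper_preset"]
    residual_sd: float | None = None

    @classmethod
    def identity(cls) -> "VfModel":
        return cls(slope=0.0, intercept=1.0, provenance="identity")

    @classmethod
    def paper_preset(cls) -> "VfModel":
        """The published linear coefficients (0.028 per cc, 2.7).

        Shipped as reported; note the caveat in the module docstring about
        their scale — prefer a freshly calibrated model.
        """
        return cls(slope=0.028, intercept=2.7, provenance="paper_preset")


def vf_eval(model: VfModel, v: float) -> float:
    """Evaluate the volume factor at a target volume v (cc)."""
    if v < 0:
        raise ValueError("target volume must be non-negative")
    return model.slope * v + model.intercept


@dataclass(frozen=True)
class SeipdcResult:
    """Output of the independent point-dose calculation."""

    dose_no_volume: float  # Gy, first-order kernel sum
    dose_corrected: float  # Gy, after the volume factor
    vf_used: float
    reference: ReferencePoint
    contributions: np.ndarray  # Gy per control point
    convention: str = "multiply"


def dose_ref_no_volume(plan: Plan, ref: ReferencePoint, lib: KernelLibrary) -> SeipdcResult:
    """First-order kernel-sum dose at the reference point (no volume factor).

    Uses only the central (undistorted) kernel for every shot, whatever the
    library's distortion model says — that is the approximation the volume
    factor exists to correct.
    """
    y_ref, r_ref = ref.y, ref.r
    n = len(plan.control_points)
    contrib = np.zeros(n)
    cup = plan.cup
    for i, cp in enumerate(plan.control_points):
        rate = lib.dose_rate_lookup(cp.collimator, cup, cp.y, cp.r)
        ocr = lib.ocr_lookup(cp.collimator, cup, cp.y - y_ref, cp.r - r_ref)
        contrib[i] = rate * (cp.dwell_time / 60.0) * ocr
    total = float(contrib.sum())
    return SeipdcResult(
        dose_no_volume=total,
        dose_corrected=total,
        vf_used=1.0,
        reference=ref,
        contributions=contrib,
        convention="none",
    )


def dose_ref(
    plan: Plan,
    ref: ReferencePoint,
    lib: KernelLibrary,
    model: VfModel | None = None,
    target_label: str = "PTV",
    convention: Literal["multiply", "divide", "percent"] = "multiply",
) -> SeipdcResult:
    """Volume-corrected independent point dose.

    Conventions for combining Vf(v) with the first-order dose D1:

    * ``multiply`` (default): D = D1 * Vf — the calibrated ratio-fit
      semantics, and the published formula read literally.
    * ``divide``: D = D1 / Vf.
    * ``percent``: D = D1 * (1 + Vf/100) — reads Vf as a percent-scale
      correction.
    """
    model = model or VfModel.identity()
    base = dose_ref_no_volume(plan, ref, lib)
    if model.provenance == "identity":
        vf = 1.0
    else:
        v = plan.target(target_label).volume
        vf = vf_eval(model, v)
    if convention == "multiply":
        corrected = base.dose_no_volume * vf
    elif convention == "divide":
        corrected = base.dose_no_volume / vf
    elif convention == "percent":
        corrected = base.dose_no_volume * (1.0 + vf / 100.0)
    else:
        raise ValueError(f"unknown Vf application convention {convention!r}")
    return SeipdcResult(
        dose_no_volume=base.dose_no_volume,
        dose_corrected=float(corrected),
        vf_used=vf,
        reference=ref,
        contributions=base.contributions,
        convention=convention,
    )


def calibrate_vf(pairs: Sequence[tuple[float, float]]) -> VfModel:
    """Fit the volume factor from (volume, ground-truth/first-order ratio)
    pairs by ordinary least squares.

    The ratio is ground truth (measurement, or the forward engine when
    calibrating in silico) divided by the first-order kernel-sum dose, so
    the fitted line is directly the multiplicative correction.
    """
    pairs = np.asarray(pairs, float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 3:
        raise ValueError("need at least 3 (volume, ratio) pairs")
    v, ratio = pairs[:, 0], pairs[:, 1]
    if np.ptp(v) == 0:
        raise ValueError("degenerate design: all volumes equal")
    A = np.stack([v, np.ones_like(v)], axis=1)
    coef, *_ = np.linalg.lstsq(A, ratio, rcond=None)
    resid = ratio - A @ coef
    dof = max(1, len(v) - 2)
    sd = float(np.sqrt((resid**2).sum() / dof))
    return VfModel(slope=float(coef[0]), intercept=float(coef[1]), provenance="calibrated", residual_sd=sd)


def percent_difference(calc: float, tps: float) -> float:
    """Signed percent difference, 100 * (calc - tps) / tps.

    Negative values mean the (measured or independently calculated) value
    sits below the planning-system dose.
    """
    if tps <= 0:
        raise ValueError("reference (TPS) dose must be positive")
    return 100.0 * (calc - tps) / tps
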