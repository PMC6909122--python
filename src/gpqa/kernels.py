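"""Precomputed dose kernels: isocenter dose rates and off-center ratios.

The independent point-dose check and the forward engine both consume two
families of lookup tables, normally exported from a Monte-Carlo beam model
for every (collimator, inner cup) combination:

* **OCR tables** — the dimensionless off-center ratio ``OCR(dy, dr)``: the
  relative dose at an axial offset ``dy`` and a radial-coordinate offset
  ``dr`` from a control point's focal spot, for the beam centered in the
  cup. ``OCR(0, 0) = 1`` by construction.
* **Dose-rate tables** — the isocenter dose rate (Gy/min) as a function of
  the focal spot's axial position ``y`` and off-axis distance ``r``: deep
  positions near the chest wall of a large cup see a lower rate than
  shallow positions near the apex of a small one.

A synthetic generator stands in for the vendor tables: OCR profiles are
error-function-smoothed top-hats and dose rates decay exponentially with
depth below the apex. The library also carries the *distortion model* the
forward engine uses to broaden kernels away from the cup center; the
point-dose check deliberately ignores it (it only ever uses the central
kernel).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .plan import CupGeometry
from .profiles import erf_tophat

__all__ = [
    "OCRTable",
    "DoseRateTable",
    "DistortionModel",
    "KernelLibrary",
    "LibraryParams",
    "make_synthetic_library",
    "fwhm_of_profile",
    "erf_tophat",
    "default_cup_set",
    "save_library",
    "load_library",
]


@dataclass(frozen=True)
class OCRTable:
    """Off-center-ratio lattice for one (collimator, cup) pair."""

    collimator: int
    cup_id: str
    dy: np.ndarray  # axial offsets, mm
    dr: np.ndarray  # radial-coordinate offsets, mm
    values: np.ndarray  # shape (len(dy), len(dr)), unitless

    def __post_init__(self):
        v = self.values
        iy = np.searchsorted(self.dy, 0.0)
        ir = np.searchsorted(self.dr, 0.0)
        has_origin = (
            iy < len(self.dy) and ir < len(self.dr)
            and self.dy[iy] == 0.0 and self.dr[ir] == 0.0
        )
        if has_origin and abs(v[iy, ir] - 1.0) > 1e-12:
            raise ValueError("OCR(0,0) must equal 1 exactly")
        if np.any(v < 0):
            raise ValueError("OCR values must be non-negative")

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.dy, self.dr), self.values, method="linear",
            bounds_error=False, fill_value=0.0,
        )


@dataclass(frozen=True)
class DoseRateTable:
    """Isocenter dose-rate lattice (Gy/min) over (y, r) for one pair."""

    collimator: int
    cup_id: str
    y: np.ndarray
    r: np.ndarray
    values: np.ndarray  # Gy/min

    def __post_init__(self):
        if np.any(self.values <= 0):
            raise ValueError("dose rates must be positive")

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.y, self.r), self.values, method="linear", bounds_error=True,
        )


@dataclass(frozen=True)
class DistortionModel:
    """Kernel broadening away from the cup's central axis (engine only).

    The beam profile is positionally invariant only for a focal spot at
    the center of the cup; elsewhere the delivered kernel widens. Off-
    center position is measured the way the device measures everything
    transverse: by the radial distance ``r = hypot(x, z)`` from the cup's
    central axis. Modeled as a width scale
    ``b = 1 + alpha * r / reference_radius``; ``alpha = 0`` switches the
    engine to the position-invariant kernel exactly.
    """

    alpha: float = 0.0
    reference_radius: float = 50.0  # mm

    def __post_init__(self):
        if self.alpha < 0 or self.reference_radius <= 0:
            raise ValueError("alpha must be >= 0 and reference_radius > 0")

    def broadening(self, cup: CupGeometry, x: float, y: float, z: float) -> float:
        return 1.0 + self.alpha * math.hypot(x, z) / self.reference_radius


@dataclass
class KernelLibrary:
    """The full kernel set plus the engine's distortion model."""

    ocr: dict = field(default_factory=dict)  # (collimator, cup_id) -> OCRTable
    rates: dict = field(default_factory=dict)  # (collimator, cup_id) -> DoseRateTable
    distortion: DistortionModel = field(default_factory=DistortionModel)
    meta: dict = field(default_factory=dict)
    _interp_cache: dict = field(default_factory=dict, repr=False)

    def _ocr_interp(self, collimator: int, cup_id: str):
        key = ("ocr", collimator, cup_id)
        if key not in self._interp_cache:
            tab = self.ocr.get((collimator, cup_id))
            if tab is None:
                raise KeyError(f"no OCR table for collimator {collimator}, cup {cup_id}")
            self._interp_cache[key] = tab.interpolator()
        return self._interp_cache[key]

    def _rate_interp(self, collimator: int, cup_id: str):
        key = ("rate", collimator, cup_id)
        if key not in self._interp_cache:
            tab = self.rates.get((collimator, cup_id))
            if tab is None:
                raise KeyError(f"no dose-rate table for collimator {collimator}, cup {cup_id}")
            self._interp_cache[key] = tab.interpolator()
        return self._interp_cache[key]

    def ocr_lookup(self, collimator: int, cup, dy, dr):
        """Bilinear OCR lookup; exact at lattice nodes, 0 outside the lattice."""
        cup_id = cup.cup_id if isinstance(cup, CupGeometry) else cup
        f = self._ocr_interp(collimator, cup_id)
        pts = np.stack(np.broadcast_arrays(np.asarray(dy, float), np.asarray(dr, float)), axis=-1)
        out = f(pts)
        return float(out[0]) if pts.ndim == 1 else out

    def dose_rate_lookup(self, collimator: int, cup, y, r):
        """Bilinear isocenter dose-rate lookup (Gy/min); errors off-lattice."""
        cup_id = cup.cup_id if isinstance(cup, CupGeometry) else cup
        f = self._rate_interp(collimator, cup_id)
        pts = np.stack(np.broadcast_arrays(np.asarray(y, float), np.asarray(r, float)), axis=-1)
        try:
            out = f(pts)
        except ValueError as exc:
            raise ValueError(
                f"dose-rate query (y={y}, r={r}) outside the table for "
                f"collimator {collimator}, cup {cup_id}: {exc}"
            ) from None
        return float(out[0]) if pts.ndim == 1 else out

    def covers(self, plan) -> bool:
        collimators = {cp.collimator for cp in plan.control_points}
        return all(
            (c, plan.cup.cup_id) in self.ocr and (c, plan.cup.cup_id) in self.rates
            for c in collimators
        )

    def cups(self) -> list[str]:
        return sorted({cup_id for (_, cup_id) in self.ocr})


# ---------------------------------------------------------------------------
# Synthetic library generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibraryParams:
    """Parameters of the synthetic kernel generator.

    fwhm_15 is the measured profile width of the small collimator
    (~22.0 mm); the large collimator's width and both penumbra sigmas are
    configurable stand-ins, not vendor-asserted values.
    """

    fwhm_15: float = 22.0  # mm
    fwhm_25: float = 35.0  # mm
    sigma: float = 3.0  # penumbra SD, mm (axial and radial)
    lattice_spacing: float = 1.0  # mm
    lattice_extent: float = 50.0  # mm, half-width of the (dy, dr) lattice
    rate_apex: float = 3.0  # Gy/min at the cup apex
    mu: float = 0.008  # per mm, exponential depth attenuation
    radial_beta: float = 0.05  # fractional rate drop at the cup wall
    alpha: float = 0.7  # distortion broadening coefficient
    reference_radius: float = 50.0  # mm

    def __post_init__(self):
        if min(self.fwhm_15, self.fwhm_25, self.sigma, self.lattice_spacing) <= 0:
            raise ValueError("profile parameters must be positive")
        if self.mu < 0 or self.alpha < 0:
            raise ValueError("mu and alpha must be non-negative")

    def fwhm(self, collimator: int) -> float:
        return {15: self.fwhm_15, 25: self.fwhm_25}[collimator]


def default_cup_set() -> list[CupGeometry]:
    """The 19 inner-cup geometries the default library covers."""
    cups = []
    for size, indices in (("small", range(1, 6)), ("medium", range(2, 9)), ("large", range(4, 11))):
        cups.extend(CupGeometry(size_class=size, inner_index=i) for i in indices)
    return cups


def make_synthetic_library(
    params: LibraryParams | None = None,
    seed: int = 0,
    cups: list[CupGeometry] | None = None,
) -> KernelLibrary:
    """Build a synthetic kernel library (deterministic per params/seed).

    OCR lattices sample the separable erf-top-hat profile, normalized so
    the (0, 0) node is exactly 1. Dose-rate lattices follow
    ``rate(y, r) = R0 * exp(-mu * (apex_y - y)) * (1 - beta * (r/R)^2)``:
    the rate falls with depth below the apex (hence larger cups read lower
    at a given (y, r)) and slightly off-axis.
    """
    params = params or LibraryParams()
    cups = cups if cups is not None else default_cup_set()
    ext, sp = params.lattice_extent, params.lattice_spacing
    n = int(round(ext / sp))
    offsets = np.arange(-n, n + 1) * sp

    lib = KernelLibrary(
        distortion=DistortionModel(alpha=params.alpha, reference_radius=params.reference_radius),
        meta={"generator": "erf-tophat", "seed": seed, "params": params.__dict__.copy()},
    )
    cup_index = {}
    for cup in cups:
        cup_index[cup.cup_id] = {"size_class": cup.size_class, "inner_index": cup.inner_index,
                                 "apex_y_mm": cup.apex_y, "base_diameter_mm": cup.base_diameter}
        y_grid = np.linspace(0.0, cup.apex_y, 41)
        r_grid = np.linspace(0.0, cup.base_radius, 33)
        depth = cup.apex_y - y_grid
        radial = 1.0 - params.radial_beta * (r_grid / cup.base_radius) ** 2
        rate = params.rate_apex * np.exp(-params.mu * depth)[:, None] * radial[None, :]
        for coll in (15, 25):
            w = params.fwhm(coll)
            ax = erf_tophat(offsets, w, params.sigma)
            rad = erf_tophat(offsets, w, params.sigma)
            vals = np.outer(ax / ax[n], rad / rad[n])
            vals[n, n] = 1.0  # exact by construction; pin against rounding
            lib.ocr[(coll, cup.cup_id)] = OCRTable(coll, cup.cup_id, offsets.copy(), offsets.copy(), vals)
            lib.rates[(coll, cup.cup_id)] = DoseRateTable(coll, cup.cup_id, y_grid, r_grid, rate.copy())
    lib.meta["cups"] = cup_index
    return lib


# ---------------------------------------------------------------------------
# Profile width measurement
# ---------------------------------------------------------------------------


def fwhm_of_profile(x, y) -> float:
    """Full width at half maximum by linear interpolation of the crossings.

    Requires a unimodal profile: a single contiguous run of samples at or
    above half-maximum. Raises ValueError otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim != 1 or x.shape != y.shape or len(x) < 3:
        raise ValueError("need matching 1-D sample arrays of length >= 3")
    half = y.max() / 2.0
    above = y >= half
    runs = np.flatnonzero(np.diff(above.astype(int)))
    if not np.any(above):
        raise ValueError("profile never reaches half-maximum")
    first, last = np.flatnonzero(above)[[0, -1]]
    if not np.all(above[first : last + 1]):
        raise ValueError("profile is not unimodal at half-maximum")

    def _cross(i0, i1):
        # linear interpolation of the half-max crossing between samples
        y0, y1 = y[i0], y[i1]
        if y1 == y0:
            return x[i1]
        return x[i0] + (half - y0) * (x[i1] - x[i0]) / (y1 - y0)

    left = x[first] if first == 0 else _cross(first - 1, first)
    right = x[last] if last == len(x) - 1 else _cross(last + 1, last)
    return float(abs(right - left))


# ---------------------------------------------------------------------------
# CSV persistence
# ---------------------------------------------------------------------------


def save_library(lib: KernelLibrary, directory) -> None:
    """Write one CSV per table plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "gpqa-kernels-v1",
        "distortion": {"alpha": lib.distortion.alpha, "reference_radius_mm": lib.distortion.reference_radius},
        "meta": {k: v for k, v in lib.meta.items() if k != "params"} | (
            {"params": lib.meta["params"]} if "params" in lib.meta else {}
        ),
        "ocr_tables": [],
        "rate_tables": [],
    }
    for (coll, cup_id), tab in sorted(lib.ocr.items()):
        name = f"ocr_c{coll}_{cup_id}.csv"
        with open(directory / name, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["delta_y_mm", "delta_r_mm", "ocr"])
            for i, dy in enumerate(tab.dy):
                for j, dr in enumerate(tab.dr):
                    w.writerow([repr(float(dy)), repr(float(dr)), repr(float(tab.values[i, j]))])
        manifest["ocr_tables"].append({"collimator": coll, "cup_id": cup_id, "file": name})
    for (coll, cup_id), tab in sorted(lib.rates.items()):
        name = f"rate_c{coll}_{cup_id}.csv"
        with open(directory / name, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["y_mm", "r_mm", "rate_gy_min"])
            for i, yv in enumerate(tab.y):
                for j, rv in enumerate(tab.r):
                    w.writerow([repr(float(yv)), repr(float(rv)), repr(float(tab.values[i, j]))])
        manifest["rate_tables"].append({"collimator": coll, "cup_id": cup_id, "file": name})
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _read_long_csv(path, cols):
    a_vals, b_vals, v_vals = [], [], []
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        if header != cols:
            raise ValueError(f"{path}: expected header {cols}, got {header}")
        for row in r:
            a_vals.append(float(row[0]))
            b_vals.append(float(row[1]))
            v_vals.append(float(row[2]))
    a = np.unique(a_vals)
    b = np.unique(b_vals)
    vals = np.full((len(a), len(b)), np.nan)
    ia = np.searchsorted(a, a_vals)
    ib = np.searchsorted(b, b_vals)
    vals[ia, ib] = v_vals
    if np.any(np.isnan(vals)):
        raise ValueError(f"{path}: lattice is not complete/regular")
    return a, b, vals


def load_library(directory) -> KernelLibrary:
    """Load a library saved by :func:`save_library`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    dist = manifest.get("distortion", {})
    lib = KernelLibrary(
        distortion=DistortionModel(
            alpha=dist.get("alpha", 0.0),
            reference_radius=dist.get("reference_radius_mm", 50.0),
        ),
        meta=manifest.get("meta", {}),
    )
    for entry in manifest["ocr_tables"]:
        dy, dr, vals = _read_long_csv(directory / entry["file"], ["delta_y_mm", "delta_r_mm", "ocr"])
        lib.ocr[(entry["collimator"], entry["cup_id"])] = OCRTable(
            entry["collimator"], entry["cup_id"], dy, dr, vals
        )
    for entry in manifest["rate_tables"]:
        y, r, vals = _read_long_csv(directory / entry["file"], ["y_mm", "r_mm", "rate_gy_min"])
        lib.rates[(entry["collimator"], entry["cup_id"])] = DoseRateTable(
            entry["collimator"], entry["cup_id"], y, r, vals
        )
    return lib
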