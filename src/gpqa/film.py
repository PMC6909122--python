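"""Radiochromic-film workflow: calibration, registration, synthesis.

Film enters the analysis as a response-valued plane (red-channel net
optical density). The workflow mirrors clinical practice: a 12-point
calibration curve over 0.01-10 Gy maps response to dose, four pin-pricked
marks register the scanned film rigidly to the planned dose plane, the
film dose is normalized to an in-target plateau, and the result is
compared to the plan by gamma analysis.

A synthetic film generator closes the loop for testing: it converts a
planned dose plane to response through the inverse calibration, adds
response noise and a known rigid misregistration, and burns the four
registration marks, so the full pipeline can be validated against ground
truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq, curve_fit

from .gamma import DosePlane, GammaParams, GammaResult, RegionSpec, gamma_map, normalize_to_plateau

__all__ = [
    "CalibrationCurve",
    "RegistrationTransform",
    "FilmImage",
    "fit_calibration",
    "response_to_dose",
    "register_marks",
    "synth_film",
    "default_calibration",
    "process_film",
    "save_plane_text",
    "load_plane_text",
]


def _netod_model(d, a, b, c):
    return a * d / (b + d) + c * d


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone dose->response map fitted to calibration points.

    Functional form: ``netOD(D) = a*D/(b + D) + c*D`` — a saturating
    rational term plus a linear tail; with a, c >= 0 and b > 0 it is
    strictly increasing, so the response->dose inverse is well defined on
    the calibrated range.
    """

    doses: np.ndarray
    responses: np.ndarray
    a: float
    b: float
    c: float
    residuals: np.ndarray

    def response(self, dose):
        return _netod_model(np.asarray(dose, float), self.a, self.b, self.c)

    @property
    def dose_range(self) -> tuple[float, float]:
        return float(self.doses.min()), float(self.doses.max())


def fit_calibration(doses, responses) -> CalibrationCurve:
    """Least-squares fit of the monotone calibration model.

    Requires >= 4 points and responses that increase with dose (after
    sorting by dose).
    """
    d = np.asarray(doses, float)
    r = np.asarray(responses, float)
    if d.size < 4 or d.shape != r.shape:
        raise ValueError("need at least 4 matching (dose, response) points")
    order = np.argsort(d)
    d, r = d[order], r[order]
    if np.any(np.diff(r) <= 0):
        raise ValueError("responses are not strictly monotone in dose")
    p0 = (max(r.max(), 1e-3), max(np.median(d), 1e-2), 1e-4)
    popt, _ = curve_fit(
        _netod_model, d, r, p0=p0,
        bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    resid = r - _netod_model(d, *popt)
    return CalibrationCurve(doses=d, responses=r, a=float(popt[0]), b=float(popt[1]), c=float(popt[2]), residuals=resid)


def response_to_dose(curve: CalibrationCurve, response):
    """Invert the calibration numerically (bracketed root find)."""
    resp = np.asarray(response, float)
    d_hi = curve.dose_range[1] * 1.5 + 1.0
    r_lo, r_hi = curve.response(0.0), curve.response(d_hi)

    def _invert_one(rv):
        if rv <= r_lo:
            return 0.0
        if rv >= r_hi:
            return d_hi
        return brentq(lambda dd: curve.response(dd) - rv, 0.0, d_hi, xtol=1e-10)

    if resp.ndim == 0:
        return float(_invert_one(float(resp)))
    # monotone map: interpolate a dense inverse table (fast for images)
    dd = np.linspace(0.0, d_hi, 4096)
    rr = curve.response(dd)
    return np.interp(resp, rr, dd)


def default_calibration(n_points: int = 12, dose_range: tuple[float, float] = (0.01, 10.0)) -> CalibrationCurve:
    """A nominal EBT3-like red-channel curve on 12 log-spaced points
    spanning 0.01-10 Gy, for synthetic-film work."""
    d = np.geomspace(dose_range[0], dose_range[1], n_points)
    truth = (0.55, 3.0, 0.012)
    r = _netod_model(d, *truth)
    return fit_calibration(d, r)


# ---------------------------------------------------------------------------
# Rigid registration from the four pin marks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegistrationTransform:
    """Rigid 2-D transform: rotation (deg, counter-clockwise) then
    translation (mm). No scaling or shear."""

    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    rms_residual: float = 0.0

    def matrix(self) -> np.ndarray:
        th = math.radians(self.rotation)
        return np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])

    def apply(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        return p @ self.matrix().T + np.asarray(self.translation)

    def inverse(self) -> "RegistrationTransform":
        R = self.matrix()
        t = np.asarray(self.translation)
        return RegistrationTransform(rotation=-self.rotation, translation=tuple(-(R.T @ t)), rms_residual=self.rms_residual)


def register_marks(film_marks, plan_marks) -> RegistrationTransform:
    """Least-squares rigid transform taking film marks onto plan marks.

    Orthogonal-Procrustes (Kabsch) restricted to rotation + translation —
    no scale. Requires four non-collinear point pairs (the four holder
    pins).
    """
    fm = np.asarray(film_marks, float)
    pm = np.asarray(plan_marks, float)
    if fm.shape != pm.shape or fm.shape[0] < 4 or fm.shape[1] != 2:
        raise ValueError("need four 2-D mark pairs")
    fc, pc = fm.mean(axis=0), pm.mean(axis=0)
    A = fm - fc
    B = pm - pc
    if np.linalg.matrix_rank(A, tol=1e-8 * max(1.0, np.abs(A).max())) < 2:
        raise ValueError("film marks are collinear; registration is degenerate")
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    rot = math.degrees(math.atan2(R[1, 0], R[0, 0]))
    t = pc - R @ fc
    resid = pm - (fm @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RegistrationTransform(rotation=rot, translation=(float(t[0]), float(t[1])), rms_residual=rms)


# ---------------------------------------------------------------------------
# Synthetic film
# ---------------------------------------------------------------------------


@dataclass
class FilmImage:
    """A response-valued film plane with its registration marks.

    ``film_marks`` are the pin positions in the film's own coordinate
    frame; ``plan_marks`` are the corresponding burned positions in the
    planned dose plane's frame.
    """

    plane: DosePlane  # values = response (netOD)
    film_marks: np.ndarray  # (4, 2) mm, film frame
    plan_marks: np.ndarray  # (4, 2) mm, plan frame
    meta: dict


def _default_marks(plane: DosePlane, inset: float = 5.0) -> np.ndarray:
    u, v = plane.axes()
    return np.array(
        [
            [u[0] + inset, v[0] + inset],
            [u[-1] - inset, v[0] + inset],
            [u[-1] - inset, v[-1] - inset],
            [u[0] + inset, v[-1] - inset],
        ]
    )


def synth_film(
    dose_plane: DosePlane,
    curve: CalibrationCurve,
    noise_sd: float = 0.0,
    misregistration: RegistrationTransform | None = None,
    seed: int = 0,
) -> FilmImage:
    """Generate a synthetic scanned film from a planned dose plane.

    The film frame relates to the plan frame by ``plan = T(film)`` where T
    is the injected misregistration. Each film pixel reads the planned
    dose at its mapped plan position, converted to response through the
    calibration curve, with additive Gaussian response noise. The four
    plan marks are burned at fixed inset positions; the film's pin marks
    are their pre-images under T. Deterministic per seed.
    """
    T = misregistration or RegistrationTransform()
    rng = np.random.default_rng(seed)
    U, V = dose_plane.pixel_positions()
    film_pts = np.stack([U.ravel(), V.ravel()], axis=-1)
    plan_pts = T.apply(film_pts)
    interp = dose_plane.interpolator(fill=0.0)
    dose = interp(plan_pts).reshape(U.shape)
    response = curve.response(dose)
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, size=response.shape)
    plan_marks = _default_marks(dose_plane)
    film_marks = T.inverse().apply(plan_marks)
    film_plane = replace(dose_plane, values=response)
    return FilmImage(
        plane=film_plane,
        film_marks=film_marks,
        plan_marks=plan_marks,
        meta={"seed": seed, "noise_sd": noise_sd,
              "true_transform": {"rotation_deg": T.rotation, "translation_mm": list(T.translation)}},
    )


def process_film(
    film: FilmImage,
    curve: CalibrationCurve,
    reference: DosePlane,
    plateau_region: RegionSpec,
    gamma_params: GammaParams | None = None,
) -> tuple[GammaResult, RegistrationTransform, DosePlane]:
    """Full measurement pipeline: register, convert, normalize, compare.

    1. recover the film->plan rigid transform from the four mark pairs;
    2. resample the film onto the reference lattice through that transform
       and convert response to dose via the calibration curve;
    3. normalize the film dose so the plateau region matches the
       reference plane's plateau mean;
    4. gamma-compare against the reference.

    Returns (gamma result, recovered transform, normalized film dose plane).
    """
    T = register_marks(film.film_marks, film.plan_marks)
    U, V = reference.pixel_positions()
    plan_pts = np.stack([U.ravel(), V.ravel()], axis=-1)
    film_pts = T.inverse().apply(plan_pts)
    interp = film.plane.interpolator(fill=np.nan)
    response = interp(film_pts).reshape(U.shape)
    response = np.nan_to_num(response, nan=0.0)
    dose = response_to_dose(curve, response)
    film_dose = DosePlane(origin=reference.origin.copy(), spacing=reference.spacing.copy(), values=dose)

    # the plateau is chosen on the planned dose: validate it there, then
    # scale the (possibly noisy) film to the reference plateau mean
    ref_mask = plateau_region.mask(reference)
    ref_plateau_mean = float(reference.values[ref_mask].mean())
    normalize_to_plateau(reference, plateau_region, reference_mean=ref_plateau_mean)
    film_mean = float(film_dose.values[plateau_region.mask(film_dose)].mean())
    if film_mean <= 0:
        raise ValueError("film plateau mean must be positive")
    film_dose = replace(film_dose, values=film_dose.values * (ref_plateau_mean / film_mean))
    result = gamma_map(reference, film_dose, gamma_params or GammaParams(plateau_region=plateau_region))
    return result, T, film_dose


# ---------------------------------------------------------------------------
# Plain-text film / plane I/O
# ---------------------------------------------------------------------------


def save_plane_text(plane: DosePlane, path, marks: np.ndarray | None = None) -> None:
    """Whitespace matrix plus a JSON sidecar with spacing/origin/marks."""
    path = Path(path)
    np.savetxt(path, plane.values)
    sidecar = {
        "origin_mm": plane.origin.tolist(),
        "spacing_mm": plane.spacing.tolist(),
        "shape": list(plane.values.shape),
    }
    if marks is not None:
        sidecar["marks_mm"] = np.asarray(marks, float).tolist()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_plane_text(path) -> tuple[DosePlane, np.ndarray | None]:
    path = Path(path)
    values = np.atleast_2d(np.loadtxt(path))
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    plane = DosePlane(origin=sidecar["origin_mm"], spacing=sidecar["spacing_mm"], values=values)
    marks = np.asarray(sidecar["marks_mm"], float) if "marks_mm" in sidecar else None
    return plane, marks
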