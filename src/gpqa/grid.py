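"""3-D dose grid container in stereotactic coordinates."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = ["DoseGrid", "GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned lattice definition: origin of the first voxel center,
    per-axis spacing (mm) and voxel counts."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    @classmethod
    def from_center(cls, center, half_extent: float, spacing: float = 1.0) -> "GridSpec":
        """Cube of half-width ``half_extent`` centered on ``center``.

        The center is always a voxel center, so trilinear interpolation
        there is exact.
        """
        n = int(round(half_extent / spacing))
        shape = (2 * n + 1,) * 3
        origin = tuple(c - n * spacing for c in center)
        return cls(origin=origin, spacing=(spacing,) * 3, shape=shape)

    def axes(self):
        return [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]


@dataclass
class DoseGrid:
    """Dose values (Gy) on a regular lattice.

    ``origin`` is the coordinate of voxel (0,0,0)'s center; axes follow the
    stereotactic frame (x, y, z). Default voxels of 1 mm correspond to the
    0.001 cc single-pixel readout of the planning system.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    frame: str = "stereotactic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.spacing = np.asarray(self.spacing, float)
        self.values = np.asarray(self.values, float)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if self.values.ndim != 3:
            raise ValueError("dose grid must be 3-D")

    @classmethod
    def zeros(cls, spec: GridSpec) -> "DoseGrid":
        return cls(origin=spec.origin, spacing=spec.spacing, values=np.zeros(spec.shape))

    @property
    def shape(self):
        return self.values.shape

    def axes(self):
        return [
            self.origin[a] + np.arange(self.values.shape[a]) * self.spacing[a]
            for a in range(3)
        ]

    def meshgrid(self):
        return np.meshgrid(*self.axes(), indexing="ij")

    def voxel_index(self, point) -> tuple[int, int, int]:
        """Index of the voxel whose center is nearest the point."""
        idx = np.round((np.asarray(point, float) - self.origin) / self.spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.values.shape)):
            raise ValueError(f"point {tuple(point)} outside grid")
        return tuple(int(i) for i in idx)

    def point_dose(self, point) -> float:
        """Trilinear dose at an arbitrary point (Gy)."""
        interp = RegularGridInterpolator(self.axes(), self.values, method="linear", bounds_error=True)
        try:
            return float(interp(np.asarray(point, float))[0])
        except ValueError:
            raise ValueError(f"point {tuple(point)} outside grid") from None

    def neighborhood_mean(self, point, half: int = 2) -> float:
        """Mean of the (2*half+1)^3 voxel block centered on the containing
        voxel — 5x5x5 (0.125 cc at 1 mm spacing) by default, emulating the
        chamber-volume averaging readout."""
        i, j, k = self.voxel_index(point)
        lo = np.array([i - half, j - half, k - half])
        hi = np.array([i + half, j + half, k + half])
        if np.any(lo < 0) or np.any(hi >= np.asarray(self.values.shape)):
            raise ValueError(f"{2*half+1}^3 block around {tuple(point)} extends outside grid")
        return float(
            self.values[i - half : i + half + 1, j - half : j + half + 1, k - half : k + half + 1].mean()
        )

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Portable container: NPZ with a JSON attribute blob."""
        attrs = {
            "origin_mm": self.origin.tolist(),
            "spacing_mm": self.spacing.tolist(),
            "frame": self.frame,
            "units": "Gy",
            "meta": self.meta,
        }
        np.savez_compressed(path, values=self.values, attrs=json.dumps(attrs))

    @classmethod
    def load(cls, path) -> "DoseGrid":
        with np.load(path, allow_pickle=False) as f:
            attrs = json.loads(str(f["attrs"]))
            return cls(
                origin=attrs["origin_mm"],
                spacing=attrs["spacing_mm"],
                values=f["values"],
                frame=attrs.get("frame", "stereotactic"),
                meta=attrs.get("meta", {}),
            )

    def save_text(self, path) -> None:
        """Plain-text export (JSON) for small grids."""
        doc = {
            "format": "gpqa-grid-v1",
            "origin_mm": self.origin.tolist(),
            "spacing_mm": self.spacing.tolist(),
            "shape": list(self.values.shape),
            "frame": self.frame,
            "units": "Gy",
            "values": self.values.ravel().tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load_text(cls, path) -> "DoseGrid":
        doc = json.loads(Path(path).read_text())
        values = np.asarray(doc["values"], float).reshape(doc["shape"])
        return cls(origin=doc["origin_mm"], spacing=doc["spacing_mm"], values=values, frame=doc["frame"])
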