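"""Observation windows for 3D point patterns.

A region mask describes the volume within which cells and Ki67-cluster (KC)
centroids live: an axis-aligned box, a spherical shell (emulating the band of
tissue along a lesion border), or an arbitrary voxelized label volume. All
coordinates are in micrometres.

Regions support three operations used throughout the package: volume
computation, point-membership tests, and uniform sampling (the engine behind
complete-spatial-randomness nulls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class RegionError(ValueError):
    """Raised for geometrically invalid region specifications."""


@dataclass(frozen=True)
class BoxRegion:
    """Axis-aligned box ``[lo, hi]`` per axis, in micrometres."""

    lo: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hi: tuple[float, float, float] = (1000.0, 1000.0, 1000.0)

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lo, float), np.asarray(self.hi, float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise RegionError("box bounds must be length-3")
        if not np.all(hi > lo):
            raise RegionError("box must have hi > lo on every axis")

    @property
    def volume(self) -> float:
        lo, hi = np.asarray(self.lo, float), np.asarray(self.hi, float)
        return float(np.prod(hi - lo))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        lo, hi = np.asarray(self.lo, float), np.asarray(self.hi, float)
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo, hi = np.asarray(self.lo, float), np.asarray(self.hi, float)
        return rng.uniform(lo, hi, size=(int(n), 3))

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.lo, float), np.asarray(self.hi, float)


@dataclass(frozen=True)
class SphericalShellRegion:
    """Shell ``r_inner <= |x - center| <= r_outer`` (micrometres).

    With ``r_inner = 0`` this degenerates to a ball. The shell emulates the
    geometry of a neurogenic area hugging a roughly spherical lesion border.
    """

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    r_inner: float = 0.0
    r_outer: float = 500.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_inner < self.r_outer):
            raise RegionError("need 0 <= r_inner < r_outer")

    @property
    def volume(self) -> float:
        return float(4.0 / 3.0 * np.pi * (self.r_outer**3 - self.r_inner**3))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        r = np.linalg.norm(pts - np.asarray(self.center, float), axis=1)
        return (r >= self.r_inner) & (r <= self.r_outer)

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        n = int(n)
        # Inverse-CDF in radius; isotropic direction.
        u = rng.random(n)
        r3 = self.r_inner**3 + u * (self.r_outer**3 - self.r_inner**3)
        r = np.cbrt(r3)
        v = rng.normal(size=(n, 3))
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return np.asarray(self.center, float) + r[:, None] * v / norms

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, float)
        return c - self.r_outer, c + self.r_outer


@dataclass(frozen=True)
class VoxelRegion:
    """Binary voxel label volume with anisotropic spacing (micrometres).

    ``labels[i, j, k]`` truthy marks an in-region voxel whose physical extent
    is ``origin + [i, j, k] * spacing`` to ``origin + [i+1, j+1, k+1] * spacing``.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (10.0, 10.0, 10.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    _inside_idx: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels).astype(bool)
        if lab.ndim != 3:
            raise RegionError("voxel labels must be a 3D array")
        sp = np.asarray(self.spacing, float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise RegionError("voxel spacing must be positive on all axes")
        if not lab.any():
            raise RegionError("voxel mask is empty (volume would be 0)")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "_inside_idx", np.argwhere(lab))

    @property
    def volume(self) -> float:
        return float(self.labels.sum() * np.prod(np.asarray(self.spacing, float)))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        sp = np.asarray(self.spacing, float)
        idx = np.floor((pts - np.asarray(self.origin, float)) / sp).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(self.labels.shape)), axis=1)
        out = np.zeros(len(pts), bool)
        if ok.any():
            ii = idx[ok]
            out[ok] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        n = int(n)
        # Uniform over in-mask voxels, then uniform within the voxel.
        pick = rng.integers(0, len(self._inside_idx), size=n)
        sp = np.asarray(self.spacing, float)
        frac = rng.random((n, 3))
        return np.asarray(self.origin, float) + (self._inside_idx[pick] + frac) * sp

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        o = np.asarray(self.origin, float)
        sp = np.asarray(self.spacing, float)
        return o, o + np.asarray(self.labels.shape) * sp


RegionMask = BoxRegion | SphericalShellRegion | VoxelRegion


def region_from_dict(spec: dict) -> RegionMask:
    """Build a region from a plain-dict spec (as parsed from YAML).

    ``kind`` selects ``box`` / ``spherical-shell`` / ``voxel-volume``.
    """
    kind = spec.get("kind", "box")
    if kind == "box":
        return BoxRegion(lo=tuple(spec.get("lo", (0, 0, 0))), hi=tuple(spec.get("hi", (1000, 1000, 1000))))
    if kind == "spherical-shell":
        return SphericalShellRegion(
            center=tuple(spec.get("center", (0, 0, 0))),
            r_inner=float(spec.get("r_inner", 0.0)),
            r_outer=float(spec.get("r_outer", 500.0)),
        )
    if kind == "voxel-volume":
        return VoxelRegion(
            labels=np.asarray(spec["labels"]),
            spacing=tuple(spec.get("spacing", (10.0, 10.0, 10.0))),
            origin=tuple(spec.get("origin", (0.0, 0.0, 0.0))),
        )
    raise RegionError(f"unknown region kind: {kind!r}")
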