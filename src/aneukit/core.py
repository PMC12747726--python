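"""Core containers for post-CFD aneurysm hemodynamics analysis.

The analysis operates on three substrates:

* :class:`Domain` — a voxelised saccular-aneurysm geometry (sac mask,
  ostium plane, surface wall nodes with outward normals and areas),
* :class:`FlowSeries` — time-resolved 3-D velocity fields sampled on the
  domain grid over one cardiac cycle,
* :class:`WallShearSeries` — per-wall-node shear-stress vector time series.

Units follow the conventions of the field: lengths in mm, velocities in
mm/s, stresses in Pa, time in s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


def periodic_trapezoid_weights(times: np.ndarray, period: float | None = None) -> np.ndarray:
    """Quadrature weights for a periodic trapezoidal rule.

    Frames sample one cycle; the segment from the last frame back to the
    first (wrapped by ``period``) is included, so for equispaced samples
    every frame receives the same weight ``period / n``.

    Parameters
    ----------
    times
        Strictly increasing frame timestamps, s.
    period
        Cycle length.  Defaults to ``n * median(dt)`` measured from the
        spacing of ``times``, which equals the true period for equispaced
        sampling of a full cycle.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least 2 timestamps")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if period is None:
        period = t.size * float(np.median(np.diff(t)))
    if period <= t[-1] - t[0]:
        raise ValueError("period must exceed the sampled span")
    dt = np.diff(t)
    wrap = period - (t[-1] - t[0])
    w = np.empty_like(t)
    w[0] = 0.5 * (dt[0] + wrap)
    w[-1] = 0.5 * (dt[-1] + wrap)
    if t.size > 2:
        w[1:-1] = 0.5 * (dt[:-1] + dt[1:])
    return w


@dataclass(frozen=True)
class Domain:
    """Voxelised isolated-aneurysm geometry.

    Attributes
    ----------
    sac_mask
        3-D boolean array marking sac voxels (6-connected, nonempty).
    spacing
        Isotropic voxel edge length, mm.
    ostium_point, ostium_normal
        A point on the ostium plane (grid coordinates, mm) and its unit
        normal, pointing into the sac.
    wall_points, wall_normals, wall_areas
        Surface tiling of the sac wall: point coordinates (mm), outward
        unit normals, and per-node areas (mm²).
    neck_radius
        Radius of the cylindrical neck stub, mm (metadata).
    """

    sac_mask: np.ndarray
    spacing: float
    ostium_point: np.ndarray
    ostium_normal: np.ndarray
    wall_points: np.ndarray
    wall_normals: np.ndarray
    wall_areas: np.ndarray
    neck_radius: float = 0.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        m = np.asarray(self.sac_mask, bool)
        if m.ndim != 3 or not m.any():
            raise ValueError("sac_mask must be a nonempty 3-D boolean array")
        n_comp = ndimage.label(m)[1]
        if n_comp != 1:
            raise ValueError(f"sac_mask must be 6-connected (found {n_comp} components)")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not np.isclose(np.linalg.norm(self.ostium_normal), 1.0, atol=1e-8):
            raise ValueError("ostium normal must have unit length")
        if np.any(np.asarray(self.wall_areas) <= 0):
            raise ValueError("wall node areas must be positive")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.sac_mask))

    @property
    def sac_volume(self) -> float:
        """Voxelised sac volume, mm³."""
        return self.n_voxels * self.spacing**3

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-centre coordinates, mm."""
        idx = np.indices(self.sac_mask.shape).astype(float)
        return np.moveaxis(idx, 0, -1) * self.spacing + self.origin


@dataclass(frozen=True)
class FlowSeries:
    """Time-resolved velocity fields (mm/s) on the domain grid.

    ``frames`` has shape (n_frames, nx, ny, nz, 3); velocities are zero
    outside the sac mask.  ``times`` are strictly increasing timestamps in
    s, by convention 20 equispaced samples over one cardiac cycle.
    """

    frames: np.ndarray
    times: np.ndarray
    domain: Domain
    period: float | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if f.ndim != 5 or f.shape[-1] != 3:
            raise ValueError("frames must have shape (n_frames, nx, ny, nz, 3)")
        if f.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if f.shape[1:4] != self.domain.sac_mask.shape:
            raise ValueError("frame grid does not match sac_mask")
        if t.shape != (f.shape[0],) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing, one per frame")
        if not np.all(np.isfinite(f)):
            raise ValueError("non-finite velocities")
        object.__setattr__(self, "frames", f)
        object.__setattr__(self, "times", t)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def time_weights(self) -> np.ndarray:
        return periodic_trapezoid_weights(self.times, self.period)

    def speed(self) -> np.ndarray:
        """(n_frames, nx, ny, nz) speed magnitude, mm/s."""
        return np.linalg.norm(self.frames, axis=-1)

    def peak_frame_index(self) -> int:
        """Frame with the highest mean speed inside the sac."""
        sp = self.speed()[:, self.domain.sac_mask]
        return int(np.argmax(sp.mean(axis=1)))


@dataclass(frozen=True)
class WallShearSeries:
    """Per-node wall shear-stress vector time series.

    ``tau`` has shape (n_frames, n_nodes, 3) in Pa; ``areas`` are per-node
    area weights in mm²; ``times`` as in :class:`FlowSeries`.
    """

    tau: np.ndarray
    areas: np.ndarray
    times: np.ndarray
    period: float | None = None

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        areas = np.asarray(self.areas, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if tau.ndim != 3 or tau.shape[-1] != 3:
            raise ValueError("tau must have shape (n_frames, n_nodes, 3)")
        if tau.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if areas.shape != (tau.shape[1],):
            raise ValueError("areas must be per-node")
        if t.shape != (tau.shape[0],) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing, one per frame")
        if not np.all(np.isfinite(tau)):
            raise ValueError("non-finite shear stresses")
        if areas.sum() <= 0:
            raise ValueError("total wall area must be positive")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "areas", areas)
        object.__setattr__(self, "times", t)

    @property
    def n_frames(self) -> int:
        return self.tau.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.tau.shape[1]

    def time_weights(self) -> np.ndarray:
        return periodic_trapezoid_weights(self.times, self.period)

    def magnitude(self) -> np.ndarray:
        """(n_frames, n_nodes) array of |τ|, Pa."""
        return np.linalg.norm(self.tau, axis=-1)
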