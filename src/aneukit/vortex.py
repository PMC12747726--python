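"""Swirling-flow extraction and vortex-stability metrics.

Vortex regions are identified per frame with the λ2 criterion: with
J = ∇v decomposed into its symmetric part S and antisymmetric part Ω, a
voxel belongs to a vortex where the middle eigenvalue of S² + Ω² is
negative.  The Q-criterion (Q = ½(‖Ω‖² − ‖S‖²) > 0) is available as an
alternative detector for sensitivity checks.

Two scalar summaries describe the temporal stability of the swirling
flow over the cardiac cycle:

* DVO — degree of vortex overlap: the mean Dice coefficient between
  vortex masks of consecutive frames (cyclic, last→first included).
  1 for a perfectly stable vortex, decreasing as the vortex moves.
* Vt/V — time-averaged fraction of the sac volume occupied by vortex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .core import Domain, FlowSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VortexSeries:
    """Per-frame vortex masks plus the λ2 (or Q) fields that produced them."""

    masks: np.ndarray        # (n_frames, nx, ny, nz) bool
    lambda2: np.ndarray      # (n_frames, nx, ny, nz), s^-2
    threshold: float
    criterion: str = "lambda2"

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


def _velocity_gradient(frame: np.ndarray, spacing: float) -> np.ndarray:
    """(nx, ny, nz, 3, 3) tensor J with J[..., i, j] = dv_i/dx_j."""
    v = np.asarray(frame, dtype=float)
    if v.ndim != 4 or v.shape[-1] != 3:
        raise ValueError("frame must have shape (nx, ny, nz, 3)")
    if min(v.shape[:3]) < 3:
        raise ValueError("need at least 3 voxels per axis")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite velocities")
    jac = np.empty(v.shape[:3] + (3, 3))
    for i in range(3):
        gi = np.gradient(v[..., i], spacing, axis=(0, 1, 2))
        for j in range(3):
            jac[..., i, j] = gi[j]
    return jac


def lambda2_field(frame: np.ndarray, spacing: float) -> np.ndarray:
    """λ2: middle eigenvalue of S² + Ω² per voxel, s⁻².

    Negative λ2 marks swirling flow.  Gradients use central differences
    with one-sided stencils at the array boundary; spacing in mm and
    velocity in mm/s give λ2 in s⁻².
    """
    jac = _velocity_gradient(frame, spacing)
    s = 0.5 * (jac + np.swapaxes(jac, -1, -2))
    om = 0.5 * (jac - np.swapaxes(jac, -1, -2))
    m = s @ s + om @ om
    eig = np.linalg.eigvalsh(m)  # ascending
    return eig[..., 1]


def q_criterion_field(frame: np.ndarray, spacing: float) -> np.ndarray:
    """Q = ½(‖Ω‖² − ‖S‖²) per voxel, s⁻²; positive Q marks a vortex."""
    jac = _velocity_gradient(frame, spacing)
    s = 0.5 * (jac + np.swapaxes(jac, -1, -2))
    om = 0.5 * (jac - np.swapaxes(jac, -1, -2))
    return 0.5 * ((om**2).sum(axis=(-1, -2)) - (s**2).sum(axis=(-1, -2)))


def extract_vortex_mask(
    series: FlowSeries,
    threshold: float = 0.0,
    min_voxels: int = 8,
    criterion: Literal["lambda2", "q"] = "lambda2",
) -> VortexSeries:
    """Per-frame vortex masks within the sac.

    A voxel is flagged where λ2 < ``threshold`` (or Q > −``threshold``
    with the Q-criterion) and lies in the sac interior; the one-voxel
    boundary layer is excluded because its difference stencils straddle
    the wall (velocity jumps to zero there, which would register as
    spurious swirl).  Connected components (26-connectivity) smaller
    than ``min_voxels`` are removed as noise.
    """
    sac = ndimage.binary_erosion(series.domain.sac_mask)
    spacing = series.domain.spacing
    fields = np.empty((series.n_frames,) + sac.shape)
    masks = np.empty((series.n_frames,) + sac.shape, dtype=bool)
    struct = np.ones((3, 3, 3), dtype=bool)
    for k in range(series.n_frames):
        if criterion == "lambda2":
            f = lambda2_field(series.frames[k], spacing)
            raw = (f < threshold) & sac
        elif criterion == "q":
            f = q_criterion_field(series.frames[k], spacing)
            raw = (f > -threshold) & sac
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        fields[k] = f
        if min_voxels > 1 and raw.any():
            lab, n = ndimage.label(raw, structure=struct)
            if n:
                sizes = np.bincount(lab.ravel())
                keep = sizes >= min_voxels
                keep[0] = False
                raw = keep[lab]
        masks[k] = raw
    return VortexSeries(masks=masks, lambda2=fields, threshold=threshold,
                        criterion=criterion)


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0   # no vortex in either frame: nothing moved
    if na == 0 or nb == 0:
        return 0.0   # vortex appeared/vanished: no overlap
    inter = int(np.count_nonzero(a & b))
    return 2.0 * inter / (na + nb)


def dvo(series: VortexSeries, mode: Literal["consecutive", "reference"] = "consecutive") -> float:
    """Temporally averaged degree of vortex overlap, in [0, 1].

    ``consecutive`` (default) averages the Dice coefficient over cyclic
    consecutive frame pairs; ``reference`` compares every frame against
    the temporal union of all masks.  Pairs where both masks are empty
    contribute 1, pairs where exactly one is empty contribute 0.
    """
    m = series.masks
    if m.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if np.any([not m[k].any() for k in range(m.shape[0])]):
        logger.info("empty vortex mask in at least one frame")
    if mode == "consecutive":
        vals = [_dice(m[k], m[(k + 1) % m.shape[0]]) for k in range(m.shape[0])]
    elif mode == "reference":
        union = m.any(axis=0)
        vals = [_dice(m[k], union) for k in range(m.shape[0])]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.mean(vals))


def vortex_volume_fraction(series: VortexSeries, domain: Domain) -> float:
    """Time-averaged |vortex mask| / |sac mask|, in [0, 1]."""
    n_sac = domain.n_voxels
    if n_sac == 0:
        raise ValueError("empty sac")
    outside = series.masks & ~domain.sac_mask
    if outside.any():
        raise ValueError("vortex masks extend outside the sac")
    return float(series.masks.sum(axis=(1, 2, 3)).mean() / n_sac)


def analyze(series: FlowSeries, threshold: float = 0.0, min_voxels: int = 8) -> tuple[float, float]:
    """Convenience wrapper: (DVO, Vt/V) for a flow series."""
    vs = extract_vortex_mask(series, threshold=threshold, min_voxels=min_voxels)
    return dvo(vs), vortex_volume_fraction(vs, series.domain)
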