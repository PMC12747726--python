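"""Wall-shear-stress derived hemodynamic metrics.

Computes the standard WSS summary parameters used in aneurysm-rupture
hemodynamics from a :class:`~aneukit.core.WallShearSeries`:

* STA-WSS — area-weighted spatial mean of the per-node time-averaged |τ|;
* WSS-max — spatiotemporal maximum of |τ|;
* WSS-min — time average of the per-frame spatial minimum of |τ|
  (a ``global_min`` strategy is also available);
* LSA — percent of wall area whose time-averaged |τ| falls below 2 Pa;
* OSI — He–Ku oscillatory shear index, 0.5·(1 − |∫τ dt| / ∫|τ| dt);
* RRT — Himburg relative residence time, 1 / ((1 − 2·OSI)·TAWSS).

All time integrals use a periodic trapezoidal rule (the segment wrapping
the last frame back to the first is included); spatial aggregates are
area-weighted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

from .core import WallShearSeries

logger = logging.getLogger(__name__)

#: Denominator clamp for RRT when OSI approaches 0.5 or TAWSS approaches 0.
RRT_EPS = 1e-6

#: Low-shear threshold, Pa.
LSA_THRESHOLD = 2.0


@dataclass(frozen=True)
class HemodynamicSummary:
    """Scalar hemodynamic parameters for one case.

    ``dvo`` and ``vtv`` come from the vortex analysis and may be NaN when
    only wall data are available.
    """

    sta_wss: float          # Pa
    wss_max: float          # Pa
    wss_min: float          # Pa
    lsa: float              # percent of wall area
    osi: float              # [0, 0.5]
    rrt: float              # 1/Pa
    dvo: float = float("nan")
    vtv: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def tawss_field(ws: WallShearSeries) -> np.ndarray:
    """Per-node time-averaged |τ| over the cycle, Pa."""
    w = ws.time_weights()
    return (ws.magnitude() * w[:, None]).sum(axis=0) / w.sum()


def osi_field(ws: WallShearSeries) -> np.ndarray:
    """Per-node oscillatory shear index, dimensionless in [0, 0.5].

    OSI = 0.5·(1 − |∫τ dt| / ∫|τ| dt).  A node with identically zero τ
    has no oscillation and is assigned OSI = 0.
    """
    w = ws.time_weights()
    num = np.linalg.norm((ws.tau * w[:, None, None]).sum(axis=0), axis=-1)
    den = (ws.magnitude() * w[:, None]).sum(axis=0)
    osi = np.zeros(ws.n_nodes)
    live = den > 0
    osi[live] = 0.5 * (1.0 - num[live] / den[live])
    # guard tiny negative values from roundoff
    return np.clip(osi, 0.0, 0.5)


def rrt_field(ws: WallShearSeries, eps: float = RRT_EPS) -> np.ndarray:
    """Per-node relative residence time 1/((1−2·OSI)·TAWSS), Pa⁻¹.

    The denominator is clamped at ``eps``; a warning is logged when the
    clamp triggers (fully oscillatory or zero-shear nodes).
    """
    den = (1.0 - 2.0 * osi_field(ws)) * tawss_field(ws)
    n_clamped = int(np.count_nonzero(den < eps))
    if n_clamped:
        logger.warning("RRT denominator clamped at %d node(s)", n_clamped)
    return 1.0 / np.maximum(den, eps)


def lsa(ws: WallShearSeries, threshold: float = LSA_THRESHOLD) -> float:
    """Low-shear area: percent of wall area with TAWSS strictly below ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    low = tawss_field(ws) < threshold
    return 100.0 * float(ws.areas[low].sum() / ws.areas.sum())


def scalar_osi(ws: WallShearSeries, area_weighted: bool = True) -> float:
    """Area-weighted (default) or plain spatial mean OSI."""
    f = osi_field(ws)
    if area_weighted:
        return float(np.average(f, weights=ws.areas))
    return float(f.mean())


def scalar_rrt(ws: WallShearSeries) -> float:
    """Area-weighted spatial mean RRT, Pa⁻¹."""
    return float(np.average(rrt_field(ws), weights=ws.areas))


def summarize(
    ws: WallShearSeries,
    lsa_threshold: float = LSA_THRESHOLD,
    min_mode: Literal["time_avg_of_spatial_min", "global_min"] = "time_avg_of_spatial_min",
) -> HemodynamicSummary:
    """All six WSS-derived scalar parameters for one case.

    ``min_mode`` selects the WSS-min convention: the time average of the
    per-frame spatial minimum of |τ| (default), or the global minimum over
    nodes and frames.
    """
    mag = ws.magnitude()
    w = ws.time_weights()
    sta = float(np.average(tawss_field(ws), weights=ws.areas))
    wss_max = float(mag.max())
    if min_mode == "time_avg_of_spatial_min":
        wss_min = float((mag.min(axis=1) * w).sum() / w.sum())
    elif min_mode == "global_min":
        wss_min = float(mag.min())
    else:
        raise ValueError(f"unknown min_mode {min_mode!r}")
    return HemodynamicSummary(
        sta_wss=sta,
        wss_max=wss_max,
        wss_min=wss_min,
        lsa=lsa(ws, lsa_threshold),
        osi=scalar_osi(ws),
        rrt=scalar_rrt(ws),
    )
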