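"""Directional velocity informatics: texture features of intra-sac flow.

The directional structure of the aneurysmal velocity field is encoded as a
gray-level volume: per voxel, the angle θ ∈ [0, π] between the local
velocity and the inflow-jet direction is mapped linearly to gray values
0–255 (gray 0 = aligned with the jet, 255 = opposed).  Radiomic-style
texture statistics of this volume then summarise how spatially organised
the flow directions are: 18 first-order statistics on the raw 0–255
grays, plus 24 gray-level co-occurrence (GLCM), 16 run-length (GLRLM) and
16 size-zone (GLSZM) features on a quantized volume (default 16 levels) —
74 features in total.  Matrix features follow the IBSI reference
definitions; GLCM/GLRLM aggregate over the 13 unique 3-D directions by
computing each feature per direction and averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .core import Domain, FlowSeries

_EPS = np.spacing(1.0)

#: The 13 unique direction offsets for distance-1 neighbours in 3-D.
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

FIRST_ORDER_NAMES = (
    "FirstOrder.Energy", "FirstOrder.TotalEnergy", "FirstOrder.Entropy",
    "FirstOrder.Minimum", "FirstOrder.10Percentile", "FirstOrder.90Percentile",
    "FirstOrder.Maximum", "FirstOrder.Mean", "FirstOrder.Median",
    "FirstOrder.InterquartileRange", "FirstOrder.Range",
    "FirstOrder.MeanAbsoluteDeviation", "FirstOrder.RobustMeanAbsoluteDeviation",
    "FirstOrder.RootMeanSquared", "FirstOrder.Skewness", "FirstOrder.Kurtosis",
    "FirstOrder.Variance", "FirstOrder.Uniformity",
)

GLCM_NAMES = (
    "GLCM.Autocorrelation", "GLCM.ClusterProminence", "GLCM.ClusterShade",
    "GLCM.ClusterTendency", "GLCM.Contrast", "GLCM.Correlation",
    "GLCM.DifferenceAverage", "GLCM.DifferenceEntropy", "GLCM.DifferenceVariance",
    "GLCM.Id", "GLCM.Idm", "GLCM.Idmn", "GLCM.Idn", "GLCM.IMC1", "GLCM.IMC2",
    "GLCM.InverseVariance", "GLCM.JointAverage", "GLCM.JointEnergy",
    "GLCM.JointEntropy", "GLCM.MCC", "GLCM.MaximumProbability",
    "GLCM.SumAverage", "GLCM.SumEntropy", "GLCM.SumSquares",
)

GLRLM_NAMES = (
    "GLRLM.ShortRunEmphasis", "GLRLM.LongRunEmphasis",
    "GLRLM.GrayLevelNonUniformity", "GLRLM.GrayLevelNonUniformityNormalized",
    "GLRLM.RunLengthNonUniformity", "GLRLM.RunLengthNonUniformityNormalized",
    "GLRLM.RunPercentage", "GLRLM.GrayLevelVariance", "GLRLM.RunVariance",
    "GLRLM.RunEntropy", "GLRLM.LowGrayLevelRunEmphasis",
    "GLRLM.HighGrayLevelRunEmphasis", "GLRLM.ShortRunLowGrayLevelEmphasis",
    "GLRLM.ShortRunHighGrayLevelEmphasis", "GLRLM.LongRunLowGrayLevelEmphasis",
    "GLRLM.LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "GLSZM.SmallAreaEmphasis", "GLSZM.LargeAreaEmphasis",
    "GLSZM.GrayLevelNonUniformity", "GLSZM.GrayLevelNonUniformityNormalized",
    "GLSZM.SizeZoneNonUniformity", "GLSZM.SizeZoneNonUniformityNormalized",
    "GLSZM.ZonePercentage", "GLSZM.GrayLevelVariance", "GLSZM.ZoneVariance",
    "GLSZM.ZoneEntropy", "GLSZM.LowGrayLevelZoneEmphasis",
    "GLSZM.HighGrayLevelZoneEmphasis", "GLSZM.SmallAreaLowGrayLevelEmphasis",
    "GLSZM.SmallAreaHighGrayLevelEmphasis", "GLSZM.LargeAreaLowGrayLevelEmphasis",
    "GLSZM.LargeAreaHighGrayLevelEmphasis",
)

#: Stable column order of the full 74-feature vector.
FEATURE_NAMES: tuple[str, ...] = FIRST_ORDER_NAMES + GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES


@dataclass(frozen=True)
class GrayVolume:
    """Gray-level encoding of a directional velocity volume.

    ``gray`` holds integers 0–255 (angle-to-jet encoding); ``levels``
    holds the quantized labels 1..n_levels once :func:`quantize` has run,
    else None.  ``voxel_volume`` (mm³) scales FirstOrder.TotalEnergy.
    """

    gray: np.ndarray
    mask: np.ndarray
    n_levels: int = 0
    levels: np.ndarray | None = None
    voxel_volume: float = 1.0

    def __post_init__(self) -> None:
        g = np.asarray(self.gray)
        m = np.asarray(self.mask, bool)
        if g.shape != m.shape or g.ndim != 3:
            raise ValueError("gray and mask must be matching 3-D arrays")
        gv = g[m]
        if gv.size and (gv.min() < 0 or gv.max() > 255):
            raise ValueError("gray values must lie in [0, 255]")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def estimate_jet_direction(series: FlowSeries, domain: Domain) -> np.ndarray:
    """Unit inflow-jet direction, estimated at the ostium.

    Averages the velocity over sac voxels within one voxel spacing of the
    ostium plane at the peak-speed frame; falls back to the sac-mean
    velocity direction when the near-ostium flux nearly cancels.
    """
    sac = domain.sac_mask
    frame = series.frames[series.peak_frame_index()]
    speeds = np.linalg.norm(frame[sac], axis=-1)
    if not speeds.size or speeds.max() <= 0:
        raise ValueError("zero-velocity series: jet direction undefined")
    centers = domain.voxel_centers()
    dist = (centers - domain.ostium_point) @ domain.ostium_normal
    near = sac & (np.abs(dist) <= domain.spacing * 1.5)
    mean_v = frame[near].mean(axis=0) if near.any() else np.zeros(3)
    nrm = np.linalg.norm(mean_v)
    if nrm < 1e-9 * speeds.mean():
        mean_v = frame[sac].mean(axis=0)
        nrm = np.linalg.norm(mean_v)
        if nrm == 0:
            raise ValueError("velocity directions cancel: jet direction undefined")
    return mean_v / nrm


def encode_direction(
    series: FlowSeries,
    jet: np.ndarray,
    frame_mode: Literal["peak", "per-frame"] = "peak",
    frame_index: int | None = None,
    v_floor: float = 1e-6,
) -> GrayVolume | list[GrayVolume]:
    """Encode the angle between voxel velocity and the jet as gray 0–255.

    gray = round-half-up(255·θ/π), θ = angle(v, jet) ∈ [0, π].  Voxels
    slower than ``v_floor`` (mm/s) are excluded from the mask.  With
    ``frame_mode='peak'`` only the peak-systole frame is encoded; with
    ``'per-frame'`` a list of per-frame volumes is returned.
    """
    jet = np.asarray(jet, dtype=float)
    if not np.isclose(np.linalg.norm(jet), 1.0, atol=1e-6):
        raise ValueError("jet direction must be a unit vector")

    def _one(frame: np.ndarray) -> GrayVolume:
        speed = np.linalg.norm(frame, axis=-1)
        mask = series.domain.sac_mask & (speed > v_floor)
        if not mask.any():
            raise ValueError("stagnant field: no voxel exceeds the velocity floor")
        cosang = np.zeros(speed.shape)
        cosang[mask] = (frame[mask] @ jet) / speed[mask]
        theta = np.arccos(np.clip(cosang, -1.0, 1.0))
        gray = _round_half_up(255.0 * theta / np.pi).astype(np.int64)
        return GrayVolume(gray=gray, mask=mask,
                          voxel_volume=series.domain.spacing**3)

    if frame_mode == "peak":
        k = series.peak_frame_index() if frame_index is None else frame_index
        return _one(series.frames[k])
    if frame_mode == "per-frame":
        return [_one(f) for f in series.frames]
    raise ValueError(f"unknown frame_mode {frame_mode!r}")


def quantize(gv: GrayVolume, n_levels: int = 16) -> GrayVolume:
    """Equal-width quantization of gray 0–255 into levels 1..n_levels.

    Bin width is 256/n_levels over [0, 256), so gray 0 maps to level 1,
    gray 255 to level n_levels, and n_levels=256 is the identity up to
    the +1 label shift.
    """
    if not 2 <= n_levels <= 256:
        raise ValueError("n_levels must lie in [2, 256]")
    levels = (gv.gray.astype(np.int64) * n_levels) // 256 + 1
    return GrayVolume(gray=gv.gray, mask=gv.mask, n_levels=n_levels,
                      levels=levels, voxel_volume=gv.voxel_volume)


# ---------------------------------------------------------------------------
# first-order statistics (raw 0-255 grays)

def first_order_features(gv: GrayVolume) -> dict[str, float]:
    """The 18 first-order statistics over masked gray values.

    Entropy and Uniformity use the discrete histogram of integer gray
    values.  For a constant volume, skewness and kurtosis are defined as
    0 (degenerate).
    """
    x = gv.gray[gv.mask].astype(float)
    if x.size < 10:
        raise ValueError("need at least 10 masked voxels")
    mean = x.mean()
    var = x.var()  # population
    dev = x - mean
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    counts = np.bincount(gv.gray[gv.mask].astype(np.int64), minlength=256)
    p = counts[counts > 0] / x.size
    if var > 0:
        skew = (dev**3).mean() / var**1.5
        kurt = (dev**4).mean() / var**2
    else:
        skew = kurt = 0.0
    return {
        "FirstOrder.Energy": float((x**2).sum()),
        "FirstOrder.TotalEnergy": float(gv.voxel_volume * (x**2).sum()),
        "FirstOrder.Entropy": float(-(p * np.log2(p)).sum()),
        "FirstOrder.Minimum": float(x.min()),
        "FirstOrder.10Percentile": float(p10),
        "FirstOrder.90Percentile": float(p90),
        "FirstOrder.Maximum": float(x.max()),
        "FirstOrder.Mean": float(mean),
        "FirstOrder.Median": float(np.median(x)),
        "FirstOrder.InterquartileRange": float(p75 - p25),
        "FirstOrder.Range": float(x.max() - x.min()),
        "FirstOrder.MeanAbsoluteDeviation": float(np.abs(dev).mean()),
        "FirstOrder.RobustMeanAbsoluteDeviation":
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "FirstOrder.RootMeanSquared": float(np.sqrt((x**2).mean())),
        "FirstOrder.Skewness": float(skew),
        "FirstOrder.Kurtosis": float(kurt),
        "FirstOrder.Variance": float(var),
        "FirstOrder.Uniformity": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# GLCM

def _require_levels(gv: GrayVolume) -> np.ndarray:
    if gv.levels is None or gv.n_levels < 2:
        raise ValueError("volume must be quantized first (see quantize())")
    if np.count_nonzero(gv.mask) < 2:
        raise ValueError("need at least 2 masked voxels")
    return gv.levels


def glcm_matrices(gv: GrayVolume) -> np.ndarray:
    """(13, Ng, Ng) symmetric, normalized co-occurrence matrices."""
    levels = _require_levels(gv)
    ng = gv.n_levels
    out = np.zeros((len(DIRECTIONS_3D), ng, ng))
    lab = np.where(gv.mask, levels, 0)
    for d_idx, d in enumerate(DIRECTIONS_3D):
        sl_a, sl_b = [], []
        for ax in range(3):
            n = lab.shape[ax]
            o = d[ax]
            if o >= 0:
                sl_a.append(slice(0, n - o))
                sl_b.append(slice(o, n))
            else:
                sl_a.append(slice(-o, n))
                sl_b.append(slice(0, n + o))
        a = lab[tuple(sl_a)].ravel()
        b = lab[tuple(sl_b)].ravel()
        valid = (a > 0) & (b > 0)
        a, b = a[valid] - 1, b[valid] - 1
        mat = np.zeros((ng, ng))
        np.add.at(mat, (a, b), 1.0)
        mat = mat + mat.T  # symmetric pairs
        s = mat.sum()
        if s > 0:
            mat /= s
        out[d_idx] = mat
    return out


def _glcm_features_one(p: np.ndarray, ng: int) -> dict[str, float]:
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)          # == py by symmetry
    mu = float((ii * p).sum())  # joint average
    sigma2 = float(((ii - mu) ** 2 * p).sum())

    # diagonal / cross-diagonal distributions
    k_diff = np.arange(ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    da = float((k_diff * p_diff).sum())
    autoc = float((ii * jj * p).sum())

    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hxy = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
    pxpy = np.outer(px, px)
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz] + _EPS)).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())

    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = math.sqrt(1.0 - math.exp(-2.0 * (hxy2 - hxy))) if hxy2 > hxy else 0.0

    corr = float(((ii * jj * p).sum() - mu * mu) / sigma2) if sigma2 > 0 else 1.0

    # maximal correlation coefficient
    if np.count_nonzero(px > 0) < 2:
        mcc = 1.0
    else:
        keep = px > 0
        psub = p[np.ix_(keep, keep)]
        pxs = px[keep]
        q = (psub[:, None, :] * psub[None, :, :] / (pxs[:, None, None] * pxs[None, None, :])).sum(axis=2)
        ev = np.sort(np.linalg.eigvals(q).real)
        mcc = math.sqrt(max(ev[-2], 0.0)) if ev.size >= 2 else 1.0

    off = np.abs(ii - jj)
    inv_var = float((p[off > 0] / off[off > 0] ** 2).sum())

    return {
        "GLCM.Autocorrelation": autoc,
        "GLCM.ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "GLCM.ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "GLCM.ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "GLCM.Contrast": float(((ii - jj) ** 2 * p).sum()),
        "GLCM.Correlation": corr,
        "GLCM.DifferenceAverage": da,
        "GLCM.DifferenceEntropy":
            float(-(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()),
        "GLCM.DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "GLCM.Id": float((p / (1.0 + off)).sum()),
        "GLCM.Idm": float((p / (1.0 + off**2)).sum()),
        "GLCM.Idmn": float((p / (1.0 + (off / ng) ** 2)).sum()),
        "GLCM.Idn": float((p / (1.0 + off / ng)).sum()),
        "GLCM.IMC1": imc1,
        "GLCM.IMC2": imc2,
        "GLCM.InverseVariance": inv_var,
        "GLCM.JointAverage": mu,
        "GLCM.JointEnergy": float((p**2).sum()),
        "GLCM.JointEntropy": hxy,
        "GLCM.MCC": mcc,
        "GLCM.MaximumProbability": float(p.max()),
        "GLCM.SumAverage": float((k_sum * p_sum).sum()),
        "GLCM.SumEntropy":
            float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()),
        "GLCM.SumSquares": sigma2,
    }


def glcm_features(gv: GrayVolume) -> dict[str, float]:
    """24 GLCM features: per-direction values averaged over 13 directions."""
    mats = glcm_matrices(gv)
    per_dir = [_glcm_features_one(m, gv.n_levels) for m in mats if m.sum() > 0]
    if not per_dir:
        raise ValueError("no voxel pairs: mask too small for GLCM")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM

def glrlm_matrix(gv: GrayVolume, direction: tuple[int, int, int]) -> np.ndarray:
    """(Ng, Lmax) run-length matrix along one direction (runs within mask)."""
    levels = _require_levels(gv)
    mask = gv.mask
    shape = mask.shape
    lab = np.where(mask, levels, 0)
    d = np.asarray(direction)
    # run starts: in-mask voxels whose predecessor is absent or differs
    prev = np.zeros(shape, dtype=lab.dtype)
    sl_dst, sl_src = [], []
    for ax in range(3):
        n, o = shape[ax], d[ax]
        if o >= 0:
            sl_dst.append(slice(o, n))
            sl_src.append(slice(0, n - o))
        else:
            sl_dst.append(slice(0, n + o))
            sl_src.append(slice(-o, n))
    prev[tuple(sl_dst)] = lab[tuple(sl_src)]
    starts = np.argwhere((lab > 0) & (prev != lab))
    counts: dict[tuple[int, int], int] = {}
    run_max = 1
    for pos in starts:
        lvl = lab[tuple(pos)]
        length = 1
        nxt = pos + d
        while (0 <= nxt[0] < shape[0] and 0 <= nxt[1] < shape[1]
               and 0 <= nxt[2] < shape[2] and lab[tuple(nxt)] == lvl):
            length += 1
            nxt = nxt + d
        counts[(lvl, length)] = counts.get((lvl, length), 0) + 1
        run_max = max(run_max, length)
    mat = np.zeros((gv.n_levels, run_max))
    for (lvl, length), c in counts.items():
        mat[lvl - 1, length - 1] = c
    return mat


def _rl_features_one(mat: np.ndarray, n_voxels: int, prefix: str,
                     names: tuple[str, ...]) -> dict[str, float]:
    """Shared feature formulas for run-length / size-zone matrices."""
    nr = mat.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=float)
    l = np.arange(1, mat.shape[1] + 1, dtype=float)
    ii, ll = np.meshgrid(i, l, indexing="ij")
    p = mat / nr
    mu_i = (ii * p).sum()
    mu_l = (ll * p).sum()
    pn = p[p > 0]
    short = "ShortRun" if prefix == "GLRLM" else "SmallArea"
    long_ = "LongRun" if prefix == "GLRLM" else "LargeArea"
    run = "Run" if prefix == "GLRLM" else "Zone"
    size = "RunLength" if prefix == "GLRLM" else "SizeZone"
    vals = {
        f"{prefix}.{short}Emphasis": (mat / ll**2).sum() / nr,
        f"{prefix}.{long_}Emphasis": (mat * ll**2).sum() / nr,
        f"{prefix}.GrayLevelNonUniformity": (mat.sum(axis=1) ** 2).sum() / nr,
        f"{prefix}.GrayLevelNonUniformityNormalized": (mat.sum(axis=1) ** 2).sum() / nr**2,
        f"{prefix}.{size}NonUniformity": (mat.sum(axis=0) ** 2).sum() / nr,
        f"{prefix}.{size}NonUniformityNormalized": (mat.sum(axis=0) ** 2).sum() / nr**2,
        f"{prefix}.{run}Percentage": nr / n_voxels,
        f"{prefix}.GrayLevelVariance": ((ii - mu_i) ** 2 * p).sum(),
        f"{prefix}.{run}Variance": ((ll - mu_l) ** 2 * p).sum(),
        f"{prefix}.{run}Entropy": -(pn * np.log2(pn)).sum(),
        f"{prefix}.LowGrayLevel{run}Emphasis": (mat / ii**2).sum() / nr,
        f"{prefix}.HighGrayLevel{run}Emphasis": (mat * ii**2).sum() / nr,
        f"{prefix}.{short}LowGrayLevelEmphasis": (mat / (ii**2 * ll**2)).sum() / nr,
        f"{prefix}.{short}HighGrayLevelEmphasis": (mat * ii**2 / ll**2).sum() / nr,
        f"{prefix}.{long_}LowGrayLevelEmphasis": (mat * ll**2 / ii**2).sum() / nr,
        f"{prefix}.{long_}HighGrayLevelEmphasis": (mat * ii**2 * ll**2).sum() / nr,
    }
    return {k: float(vals[k]) for k in names}


def glrlm_features(gv: GrayVolume) -> dict[str, float]:
    """16 GLRLM features averaged over the 13 directions."""
    n_vox = int(np.count_nonzero(gv.mask))
    per_dir = []
    for d in DIRECTIONS_3D:
        mat = glrlm_matrix(gv, d)
        if mat.sum() > 0:
            per_dir.append(_rl_features_one(mat, n_vox, "GLRLM", GLRLM_NAMES))
    if not per_dir:
        raise ValueError("mask too small for GLRLM")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM

def glszm_matrix(gv: GrayVolume) -> np.ndarray:
    """(Ng, Smax) size-zone matrix; zones are 26-connected equal-level regions."""
    levels = _require_levels(gv)
    struct = np.ones((3, 3, 3), dtype=bool)
    zone_sizes: list[tuple[int, int]] = []
    present = np.unique(levels[gv.mask])
    for lvl in present:
        lab, n = ndimage.label((levels == lvl) & gv.mask, structure=struct)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zone_sizes.extend((int(lvl), int(s)) for s in sizes)
    smax = max(s for _, s in zone_sizes)
    mat = np.zeros((gv.n_levels, smax))
    for lvl, s in zone_sizes:
        mat[lvl - 1, s - 1] += 1
    return mat


def glszm_features(gv: GrayVolume) -> dict[str, float]:
    """16 GLSZM features (single matrix; no directional averaging)."""
    mat = glszm_matrix(gv)
    return _rl_features_one(mat, int(np.count_nonzero(gv.mask)), "GLSZM", GLSZM_NAMES)


# ---------------------------------------------------------------------------

def extract_all(
    series: FlowSeries,
    domain: Domain,
    n_levels: int = 16,
    frame_mode: Literal["peak", "per-frame"] = "peak",
    jet: np.ndarray | None = None,
) -> dict[str, float]:
    """Full 74-feature velocity-informatics vector for one case.

    Pipeline: jet estimation → direction encoding → quantization → the
    four feature families.  With ``frame_mode='per-frame'``, features are
    extracted per frame and averaged.
    """
    if jet is None:
        jet = estimate_jet_direction(series, domain)

    def _features(gv: GrayVolume) -> dict[str, float]:
        q = quantize(gv, n_levels)
        out: dict[str, float] = {}
        out.update(first_order_features(gv))
        out.update(glcm_features(q))
        out.update(glrlm_features(q))
        out.update(glszm_features(q))
        return {k: out[k] for k in FEATURE_NAMES}

    if frame_mode == "peak":
        gv = encode_direction(series, jet, frame_mode="peak")
        return _features(gv)
    vols = encode_direction(series, jet, frame_mode="per-frame")
    per_frame = [_features(gv) for gv in vols]
    return {k: float(np.mean([f[k] for f in per_frame])) for k in FEATURE_NAMES}
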