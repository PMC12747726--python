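"""Independent brute-force oracles used to validate the library.

Everything here is written as plainly as possible — explicit Python
loops, flood fills and textbook formulas — and shares no code with the
package implementation it checks.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

OFFSETS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def strain_rate_loop(v: np.ndarray, spacing: float) -> np.ndarray:
    """Per-voxel γ̇ = sqrt(2 S:S) by explicit tensor assembly."""
    nx, ny, nz = v.shape[:3]
    out = np.zeros((nx, ny, nz))
    def deriv(comp, pos, axis):
        lo = list(pos); hi = list(pos)
        n = v.shape[axis]
        if pos[axis] == 0:
            hi[axis] += 1
            return (v[tuple(hi) + (comp,)] - v[tuple(pos) + (comp,)]) / spacing
        if pos[axis] == n - 1:
            lo[axis] -= 1
            return (v[tuple(pos) + (comp,)] - v[tuple(lo) + (comp,)]) / spacing
        lo[axis] -= 1; hi[axis] += 1
        return (v[tuple(hi) + (comp,)] - v[tuple(lo) + (comp,)]) / (2 * spacing)
    for pos in product(range(nx), range(ny), range(nz)):
        ss = 0.0
        for i in range(3):
            for j in range(3):
                s_ij = 0.5 * (deriv(i, pos, j) + deriv(j, pos, i))
                ss += s_ij * s_ij
        out[pos] = math.sqrt(2.0 * ss)
    return out


def trapezoid_periodic(values: np.ndarray, times: np.ndarray, period: float) -> float:
    """Periodic trapezoidal integral of a sampled scalar over one cycle."""
    total = 0.0
    n = len(times)
    for k in range(n):
        k2 = (k + 1) % n
        dt = (times[k2] - times[k]) % period
        total += 0.5 * (values[k] + values[k2]) * dt
    return total


# ---------------------------------------------------------------------------
# texture oracles

def first_order_loop(values: list[float], voxel_volume: float = 1.0) -> dict:
    x = sorted(float(v) for v in values)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    p10, p25, p75, p90 = (np.percentile(x, q) for q in (10, 25, 75, 90))
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    hist: dict[float, int] = {}
    for v in x:
        hist[v] = hist.get(v, 0) + 1
    probs = [c / n for c in hist.values()]
    energy = sum(v * v for v in x)
    skew = sum((v - mean) ** 3 for v in x) / n / var**1.5 if var > 0 else 0.0
    kurt = sum((v - mean) ** 4 for v in x) / n / var**2 if var > 0 else 0.0
    return {
        "FirstOrder.Energy": energy,
        "FirstOrder.TotalEnergy": voxel_volume * energy,
        "FirstOrder.Entropy": -sum(p * math.log2(p) for p in probs),
        "FirstOrder.Minimum": x[0],
        "FirstOrder.10Percentile": float(p10),
        "FirstOrder.90Percentile": float(p90),
        "FirstOrder.Maximum": x[-1],
        "FirstOrder.Mean": mean,
        "FirstOrder.Median": float(np.median(x)),
        "FirstOrder.InterquartileRange": float(p75 - p25),
        "FirstOrder.Range": x[-1] - x[0],
        "FirstOrder.MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "FirstOrder.RobustMeanAbsoluteDeviation":
            sum(abs(v - rmean) for v in robust) / len(robust),
        "FirstOrder.RootMeanSquared": math.sqrt(energy / n),
        "FirstOrder.Skewness": skew,
        "FirstOrder.Kurtosis": kurt,
        "FirstOrder.Variance": var,
        "FirstOrder.Uniformity": sum(p * p for p in probs),
    }


def glcm_matrix_loop(levels: np.ndarray, mask: np.ndarray, offset, ng: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by voxel-pair enumeration."""
    mat = np.zeros((ng, ng))
    nx, ny, nz = levels.shape
    dx, dy, dz = offset
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                x2, y2, z2 = x + dx, y + dy, z + dz
                if 0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz and mask[x2, y2, z2]:
                    i, j = levels[x, y, z] - 1, levels[x2, y2, z2] - 1
                    mat[i, j] += 1
                    mat[j, i] += 1
    s = mat.sum()
    return mat / s if s else mat


def glcm_features_loop(p: np.ndarray) -> dict:
    """GLCM features from a normalized symmetric matrix, scalar loops."""
    ng = p.shape[0]
    eps = np.spacing(1.0)
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    var = sum((i + 1 - mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    pdiff = [sum(p[i, j] for i in range(ng) for j in range(ng)
                 if abs(i - j) == k) for k in range(ng)]
    psum = [sum(p[i, j] for i in range(ng) for j in range(ng)
                if i + j + 2 == k) for k in range(2, 2 * ng + 1)]
    da = sum(k * pdiff[k] for k in range(ng))
    hx = -sum(v * math.log2(v) for v in px if v > 0)
    hxy = -sum(p[i, j] * math.log2(p[i, j])
               for i in range(ng) for j in range(ng) if p[i, j] > 0)
    hxy1 = -sum(p[i, j] * math.log2(px[i] * px[j] + eps)
                for i in range(ng) for j in range(ng) if p[i, j] > 0)
    hxy2 = -sum(px[i] * px[j] * math.log2(px[i] * px[j])
                for i in range(ng) for j in range(ng) if px[i] * px[j] > 0)
    corr = ((sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
             - mu * mu) / var) if var > 0 else 1.0
    live = [i for i in range(ng) if px[i] > 0]
    if len(live) < 2:
        mcc = 1.0
    else:
        q = np.zeros((len(live), len(live)))
        for a, i in enumerate(live):
            for b, j in enumerate(live):
                q[a, b] = sum(p[i, k] * p[j, k] / (px[i] * px[k])
                              for k in live)
        ev = sorted(np.linalg.eigvals(q).real)
        mcc = math.sqrt(max(ev[-2], 0.0))
    return {
        "GLCM.Autocorrelation":
            sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng)),
        "GLCM.ClusterProminence":
            sum((i + j + 2 - 2 * mu) ** 4 * p[i, j] for i in range(ng) for j in range(ng)),
        "GLCM.ClusterShade":
            sum((i + j + 2 - 2 * mu) ** 3 * p[i, j] for i in range(ng) for j in range(ng)),
        "GLCM.ClusterTendency":
            sum((i + j + 2 - 2 * mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng)),
        "GLCM.Contrast":
            sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)),
        "GLCM.Correlation": corr,
        "GLCM.DifferenceAverage": da,
        "GLCM.DifferenceEntropy":
            -sum(v * math.log2(v) for v in pdiff if v > 0),
        "GLCM.DifferenceVariance":
            sum((k - da) ** 2 * pdiff[k] for k in range(ng)),
        "GLCM.Id":
            sum(p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)),
        "GLCM.Idm":
            sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)),
        "GLCM.Idmn":
            sum(p[i, j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)),
        "GLCM.Idn":
            sum(p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)),
        "GLCM.IMC1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "GLCM.IMC2":
            math.sqrt(1 - math.exp(-2 * (hxy2 - hxy))) if hxy2 > hxy else 0.0,
        "GLCM.InverseVariance":
            sum(p[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j),
        "GLCM.JointAverage": mu,
        "GLCM.JointEnergy":
            sum(p[i, j] ** 2 for i in range(ng) for j in range(ng)),
        "GLCM.JointEntropy": hxy,
        "GLCM.MCC": mcc,
        "GLCM.MaximumProbability": p.max(),
        "GLCM.SumAverage": sum((k + 2) * psum[k] for k in range(len(psum))),
        "GLCM.SumEntropy": -sum(v * math.log2(v) for v in psum if v > 0),
        "GLCM.SumSquares": var,
    }


def glrlm_matrix_loop(levels: np.ndarray, mask: np.ndarray, offset, ng: int) -> np.ndarray:
    """Run-length matrix by explicit run walking."""
    nx, ny, nz = levels.shape
    dx, dy, dz = offset
    runs: list[tuple[int, int]] = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                px, py, pz = x - dx, y - dy, z - dz
                prev_same = (0 <= px < nx and 0 <= py < ny and 0 <= pz < nz
                             and mask[px, py, pz]
                             and levels[px, py, pz] == levels[x, y, z])
                if prev_same:
                    continue
                length = 1
                cx, cy, cz = x + dx, y + dy, z + dz
                while (0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz
                       and mask[cx, cy, cz]
                       and levels[cx, cy, cz] == levels[x, y, z]):
                    length += 1
                    cx, cy, cz = cx + dx, cy + dy, cz + dz
                runs.append((int(levels[x, y, z]), length))
    lmax = max(l for _, l in runs)
    mat = np.zeros((ng, lmax))
    for lvl, length in runs:
        mat[lvl - 1, length - 1] += 1
    return mat


def glszm_matrix_loop(levels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    """Size-zone matrix by breadth-first flood fill, 26-connectivity."""
    nx, ny, nz = levels.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones: list[tuple[int, int]] = []
    nbrs = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
            for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                lvl = levels[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in nbrs:
                        ax, ay, az = cx + dx, cy + dy, cz + dz
                        if (0 <= ax < nx and 0 <= ay < ny and 0 <= az < nz
                                and mask[ax, ay, az] and not seen[ax, ay, az]
                                and levels[ax, ay, az] == lvl):
                            seen[ax, ay, az] = True
                            stack.append((ax, ay, az))
                zones.append((int(lvl), size))
    smax = max(s for _, s in zones)
    mat = np.zeros((ng, smax))
    for lvl, s in zones:
        mat[lvl - 1, s - 1] += 1
    return mat


def rl_features_loop(mat: np.ndarray, n_voxels: int, prefix: str) -> dict:
    """Run-length / size-zone features by scalar loops."""
    ng, lm = mat.shape
    nr = mat.sum()
    p = mat / nr
    mu_i = sum((i + 1) * p[i, l] for i in range(ng) for l in range(lm))
    mu_l = sum((l + 1) * p[i, l] for i in range(ng) for l in range(lm))
    short = "ShortRun" if prefix == "GLRLM" else "SmallArea"
    long_ = "LongRun" if prefix == "GLRLM" else "LargeArea"
    run = "Run" if prefix == "GLRLM" else "Zone"
    size = "RunLength" if prefix == "GLRLM" else "SizeZone"
    def s(fn):
        return sum(fn(i + 1, l + 1) * mat[i, l] for i in range(ng) for l in range(lm))
    return {
        f"{prefix}.{short}Emphasis": s(lambda i, l: 1 / l**2) / nr,
        f"{prefix}.{long_}Emphasis": s(lambda i, l: l**2) / nr,
        f"{prefix}.GrayLevelNonUniformity":
            sum(mat[i, :].sum() ** 2 for i in range(ng)) / nr,
        f"{prefix}.GrayLevelNonUniformityNormalized":
            sum(mat[i, :].sum() ** 2 for i in range(ng)) / nr**2,
        f"{prefix}.{size}NonUniformity":
            sum(mat[:, l].sum() ** 2 for l in range(lm)) / nr,
        f"{prefix}.{size}NonUniformityNormalized":
            sum(mat[:, l].sum() ** 2 for l in range(lm)) / nr**2,
        f"{prefix}.{run}Percentage": nr / n_voxels,
        f"{prefix}.GrayLevelVariance":
            sum((i + 1 - mu_i) ** 2 * p[i, l] for i in range(ng) for l in range(lm)),
        f"{prefix}.{run}Variance":
            sum((l + 1 - mu_l) ** 2 * p[i, l] for i in range(ng) for l in range(lm)),
        f"{prefix}.{run}Entropy":
            -sum(p[i, l] * math.log2(p[i, l]) for i in range(ng) for l in range(lm)
                 if p[i, l] > 0),
        f"{prefix}.LowGrayLevel{run}Emphasis": s(lambda i, l: 1 / i**2) / nr,
        f"{prefix}.HighGrayLevel{run}Emphasis": s(lambda i, l: i**2) / nr,
        f"{prefix}.{short}LowGrayLevelEmphasis": s(lambda i, l: 1 / (i**2 * l**2)) / nr,
        f"{prefix}.{short}HighGrayLevelEmphasis": s(lambda i, l: i**2 / l**2) / nr,
        f"{prefix}.{long_}LowGrayLevelEmphasis": s(lambda i, l: l**2 / i**2) / nr,
        f"{prefix}.{long_}HighGrayLevelEmphasis": s(lambda i, l: i**2 * l**2) / nr,
    }


def texture_features_loop(gray: np.ndarray, mask: np.ndarray, n_levels: int,
                          voxel_volume: float = 1.0) -> dict:
    """All 74 features of a gray volume by brute force."""
    out = first_order_loop(list(gray[mask].astype(float)), voxel_volume)
    levels = (gray.astype(np.int64) * n_levels) // 256 + 1
    glcm_dicts = []
    for off in OFFSETS_13:
        m = glcm_matrix_loop(levels, mask, off, n_levels)
        if m.sum() > 0:
            glcm_dicts.append(glcm_features_loop(m))
    for k in glcm_dicts[0]:
        out[k] = float(np.mean([d[k] for d in glcm_dicts]))
    nvox = int(mask.sum())
    rl_dicts = []
    for off in OFFSETS_13:
        m = glrlm_matrix_loop(levels, mask, off, n_levels)
        if m.sum() > 0:
            rl_dicts.append(rl_features_loop(m, nvox, "GLRLM"))
    for k in rl_dicts[0]:
        out[k] = float(np.mean([d[k] for d in rl_dicts]))
    out.update(rl_features_loop(glszm_matrix_loop(levels, mask, n_levels),
                                nvox, "GLSZM"))
    return out
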