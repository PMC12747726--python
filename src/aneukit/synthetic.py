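"""Seeded synthetic aneurysm flow, wall-shear and cohort generators.

Patient-specific CFD data are not publicly available in this problem
domain, so every downstream analysis in this package is exercised on
synthetic inputs with controllable ground truth:

* :func:`make_domain` — a voxelised spherical sac truncated at an ostium
  plane, with a tiled wall-node surface;
* :func:`make_flow_series` — pulsatile velocity frames built from
  Lamb–Oseen rotational cores (optionally moving along a prescribed
  path, so vortex-overlap ground truth is controllable), a uniform
  inflow jet, a positive waveform and seeded Gaussian noise;
* :func:`make_wall_shear` — per-node shear-vector series constructed so
  that the recomputed spatial-mean TAWSS, OSI and low-shear area hit
  requested targets (closed loop with :mod:`aneukit.wss`);
* :func:`make_cohort` — a case table (default 112 cases, 44 ruptured /
  68 unruptured, locations 39 ICA / 52 MCA / 21 ACA) whose morphological
  and velocity-informatics feature distributions are shifted between
  rupture groups by configurable standardized effect sizes.

All outputs are bit-reproducible for identical seeds and arguments.
The synthetic flow is not divergence-free in general (cores are
individually solenoidal, the jet is uniform, noise is not); no
downstream metric assumes incompressibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Domain, FlowSeries, WallShearSeries
from .texture import FEATURE_NAMES

LOCATIONS = ("ICA", "MCA", "ACA")

#: Morphological feature columns emitted per case.
MORPHOLOGY_COLUMNS = ("parent_vessel_diameter_mm", "ostium_min_mm", "nrv2")

#: Baseline (unruptured-group) mean and SD for features whose scale
#: matters downstream; any feature not listed is drawn from N(0, 1).
DEFAULT_FEATURE_BASE: dict[str, tuple[float, float]] = {
    "FirstOrder.Mean": (176.5, 22.0),
    "FirstOrder.Range": (228.2, 24.4),
    "GLCM.JointAverage": (7.70, 0.99),
    "GLCM.SumAverage": (15.41, 1.97),
    "parent_vessel_diameter_mm": (3.3, 0.8),
    "ostium_min_mm": (3.0, 1.0),
    "nrv2": (0.45, 0.15),
}

#: Default standardized mean shifts (ruptured minus unruptured, in SD
#: units) reproducing moderate group separation on the features the
#: rupture-status models rely on.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "parent_vessel_diameter_mm": 0.6,
    "ostium_min_mm": 0.2,
    "nrv2": 0.8,
    "FirstOrder.Mean": 0.45,
    "FirstOrder.Range": 0.36,
    "GLCM.JointAverage": 0.48,
    "GLCM.SumAverage": 0.49,
    "GLCM.IMC2": 0.40,
    "GLCM.DifferenceEntropy": 0.45,
    "GLCM.DifferenceAverage": 0.45,
    "GLRLM.LongRunEmphasis": 0.50,
    "GLRLM.RunEntropy": 0.45,
}


def default_waveform(n_frames: int, peak_at: float = 0.3, base: float = 0.2) -> np.ndarray:
    """One-period raised-cosine pulse, systolic peak at ``peak_at`` of the cycle.

    Returns strictly positive amplitude samples with maximum 1.
    """
    t = np.arange(n_frames) / n_frames
    return base + (1.0 - base) * 0.5 * (1.0 + np.cos(2.0 * np.pi * (t - peak_at)))


def make_domain(sac_radius: float, neck_radius: float, spacing: float) -> Domain:
    """Voxelised spherical sac truncated at a circular ostium.

    The sac is the portion of a sphere of radius ``sac_radius`` (mm)
    above the plane where its cross-section narrows to ``neck_radius``;
    wall nodes tile the spherical cap with near-equal areas (Fibonacci
    sampling).  The ostium plane normal points into the sac (+z).

    Raises if geometry is degenerate (sac under 10 voxels across).
    """
    if not 0 < neck_radius < sac_radius:
        raise ValueError("need 0 < neck_radius < sac_radius")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if 2.0 * sac_radius / spacing < 10:
        raise ValueError("spacing too coarse: fewer than 10 voxels across the sac")

    r, rn = float(sac_radius), float(neck_radius)
    z0 = -np.sqrt(r * r - rn * rn)  # ostium plane height

    half = int(np.ceil(r / spacing)) + 2
    n = 2 * half + 1
    origin = -half * spacing * np.ones(3)
    ax = np.arange(n) * spacing - half * spacing
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    sac = (x * x + y * y + z * z <= r * r) & (z > z0)

    # wall nodes: Fibonacci points on the spherical cap z > z0
    cap_area = 2.0 * np.pi * r * (r - z0)
    n_nodes = max(64, int(round(cap_area / spacing**2)))
    # oversample the full sphere, keep the cap
    frac_cap = (r - z0) / (2.0 * r)
    n_sphere = int(np.ceil(n_nodes / frac_cap))
    k = np.arange(n_sphere)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    zs = 1.0 - (2.0 * k + 1.0) / n_sphere          # cos(polar) in (-1, 1)
    phi = 2.0 * np.pi * k / golden
    pts = np.stack([np.sqrt(1 - zs**2) * np.cos(phi),
                    np.sqrt(1 - zs**2) * np.sin(phi), zs], axis=1)
    keep = pts[:, 2] * r > z0
    normals = pts[keep]
    points = normals * r
    areas = np.full(points.shape[0], cap_area / points.shape[0])

    return Domain(
        sac_mask=sac,
        spacing=float(spacing),
        ostium_point=np.array([0.0, 0.0, z0]),
        ostium_normal=np.array([0.0, 0.0, 1.0]),
        wall_points=points,
        wall_normals=normals,
        wall_areas=areas,
        neck_radius=rn,
        origin=origin,
    )


@dataclass(frozen=True)
class VortexCoreSpec:
    """A Lamb–Oseen-style rotational core.

    ``center`` is either a single (3,) point (static core) or an
    (n_frames, 3) path in mm; ``radius`` is the core radius r_c in mm;
    ``circulation`` Γ in mm²/s; ``axis`` the unit swirl axis.  The
    tangential speed profile is v_θ(r) = (Γ / 2πr)(1 − exp(−r²/r_c²)).
    """

    center: np.ndarray
    radius: float
    circulation: float
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))


def _core_velocity(coords: np.ndarray, center: np.ndarray, radius: float,
                   circulation: float, axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    rel = coords - center
    rel_perp = rel - (rel @ axis)[..., None] * axis[None, None, None, :]
    dist = np.linalg.norm(rel_perp, axis=-1)
    tang = np.cross(np.broadcast_to(axis, rel.shape), rel_perp)
    tn = np.linalg.norm(tang, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vtheta = circulation / (2.0 * np.pi * dist) * (1.0 - np.exp(-(dist / radius) ** 2))
        unit = tang / tn[..., None]
    v = np.where((dist > 1e-12)[..., None], vtheta[..., None] * unit, 0.0)
    return np.nan_to_num(v)


def make_flow_series(
    domain: Domain,
    n_frames: int = 20,
    waveform: np.ndarray | None = None,
    vortex_spec: list[VortexCoreSpec] | None = None,
    jet_spec: tuple[np.ndarray, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    period: float = 1.0,
) -> FlowSeries:
    """Pulsatile synthetic velocity frames on the domain grid.

    Each frame is ``waveform(t) × [Σ rotational cores + uniform jet]``
    plus seeded Gaussian noise (mm/s), zeroed outside the sac mask.
    Core centres may follow per-frame paths so that the downstream
    degree-of-vortex-overlap has controllable ground truth.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if waveform is None:
        waveform = default_waveform(n_frames)
    waveform = np.asarray(waveform, float)
    if waveform.shape != (n_frames,) or np.any(waveform <= 0):
        raise ValueError("waveform must be n_frames positive samples")
    vortex_spec = vortex_spec or []
    for core in vortex_spec:
        if core.radius < 2.0 * domain.spacing:
            raise ValueError("vortex core radius below 2x spacing is unresolvable")

    coords = domain.voxel_centers()
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * period / n_frames
    frames = np.zeros((n_frames,) + domain.sac_mask.shape + (3,))
    for k in range(n_frames):
        base = np.zeros(domain.sac_mask.shape + (3,))
        for core in vortex_spec:
            c = np.asarray(core.center, float)
            center_k = c if c.ndim == 1 else c[k]
            base += _core_velocity(coords, center_k, core.radius,
                                   core.circulation, core.axis)
        if jet_spec is not None:
            direction, peak = jet_spec
            direction = np.asarray(direction, float)
            direction = direction / np.linalg.norm(direction)
            base += peak * direction
        frame = waveform[k] * base
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frame[~domain.sac_mask] = 0.0
        frames[k] = frame
    return FlowSeries(frames=frames, times=times, domain=domain, period=period)


def make_wall_shear(
    domain: Domain,
    target_tawss: float,
    target_osi: float,
    target_lsa: float,
    n_frames: int = 20,
    seed: int = 0,
    period: float = 1.0,
    lsa_threshold: float = 2.0,
) -> WallShearSeries:
    """Wall shear-vector series hitting requested summary targets.

    Per node the shear magnitude is constant over the cycle and the
    direction flips sign on a per-node subset of frames, so that the
    recomputed area-weighted spatial means satisfy: TAWSS within 5% of
    ``target_tawss``, OSI within 0.02 of ``target_osi`` and low-shear
    area fraction within 0.05 of ``target_lsa``.

    Raises for infeasible targets, e.g. ``target_lsa=1`` with
    ``target_tawss >= 2`` (every node below 2 Pa cannot average >= 2 Pa).
    """
    if not 0.0 <= target_osi <= 0.5:
        raise ValueError("target_osi must lie in [0, 0.5]")
    if not 0.0 <= target_lsa <= 1.0:
        raise ValueError("target_lsa must lie in [0, 1]")
    if target_tawss <= 0:
        raise ValueError("target_tawss must be positive")
    thr = lsa_threshold

    # group means: fraction target_lsa of wall area below thr at mean m_low,
    # the rest above thr at mean m_high, overall mean = target_tawss
    if target_lsa >= 1.0 - 1e-12:
        if target_tawss >= thr:
            raise ValueError("infeasible: all area below threshold but mean above it")
        m_low, m_high = target_tawss, None
    elif target_lsa <= 1e-12:
        if target_tawss <= thr:
            raise ValueError("infeasible: no low-shear area but mean below threshold")
        m_low, m_high = None, target_tawss
    else:
        m_low = min(1.0, target_tawss / 2.0)
        m_high = (target_tawss - target_lsa * m_low) / (1.0 - target_lsa)
        if m_high <= thr * 1.05:
            m_low = (target_tawss - (1.0 - target_lsa) * thr * 1.1) / target_lsa
            m_high = thr * 1.1
            if not 0.01 < m_low < thr * 0.95:
                raise ValueError("infeasible TAWSS / LSA combination")

    rng = np.random.default_rng(seed)
    areas = domain.wall_areas
    n = areas.size
    order = rng.permutation(n)
    frac = np.cumsum(areas[order]) / areas.sum()
    n_low = int(np.searchsorted(frac, target_lsa, side="left"))
    if target_lsa >= 1.0 - 1e-12:
        n_low = n
    low_nodes = order[:n_low]
    high_nodes = order[n_low:]

    mags = np.empty(n)
    if n_low and m_low is not None:
        delta = min(0.5, max(0.02, 0.95 * thr / m_low - 1.0))
        u = rng.uniform(1.0 - delta, 1.0 + delta, size=n_low)
        scale = m_low / np.average(u, weights=areas[low_nodes])
        mags[low_nodes] = np.minimum(scale * u, thr * 0.98)
    if high_nodes.size and m_high is not None:
        floor = thr * 1.05
        u = rng.uniform(0.0, 1.0, size=high_nodes.size)
        spread = (m_high - floor) / max(np.average(u, weights=areas[high_nodes]), 1e-12)
        mags[high_nodes] = floor + max(spread, 0.0) * u

    # per-node count of sign-flipped frames so OSI_node = k / n_frames;
    # mix counts floor/ceil of target_osi*n_frames to hit the spatial mean
    kf = target_osi * n_frames
    k_lo = int(np.floor(kf))
    n_hi = int(round((kf - k_lo) * n))
    flip_counts = np.full(n, k_lo)
    flip_counts[rng.permutation(n)[:n_hi]] = k_lo + 1
    flip_counts = np.minimum(flip_counts, n_frames // 2)

    # random unit direction per node
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)

    signs = np.ones((n_frames, n))
    for j in range(n):
        if flip_counts[j]:
            signs[rng.permutation(n_frames)[: flip_counts[j]], j] = -1.0
    tau = signs[:, :, None] * (mags * d.T).T[None, :, :]
    times = np.arange(n_frames) * period / n_frames
    return WallShearSeries(tau=tau, areas=areas, times=times, period=period)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic aneurysm cohort.

    ``locations`` maps location labels to case counts and must sum to
    ``n_cases``; ``effect_sizes`` maps feature names to standardized
    mean shifts between rupture groups (defaults reproduce moderate
    separation on the morphology and a dozen informatics features).
    """

    n_cases: int = 112
    n_ruptured: int = 44
    locations: dict[str, int] = field(
        default_factory=lambda: {"ICA": 39, "MCA": 52, "ACA": 21})
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ruptured > self.n_cases:
            raise ValueError("n_ruptured cannot exceed n_cases")
        if self.n_cases < 2:
            raise ValueError("need at least 2 cases")
        if sum(self.locations.values()) != self.n_cases:
            raise ValueError("location counts must sum to n_cases")
        if any(v < 0 for v in self.locations.values()):
            raise ValueError("negative location count")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Synthetic per-case feature table with rupture labels.

    Columns: ``case_id``, ``location``, ``label`` (ruptured/unruptured),
    the morphological features and the 74 velocity-informatics features
    (stable order).  Group-shifted Gaussians: for feature f with baseline
    (μ_f, σ_f) and effect size d_f, ruptured cases are drawn from
    N(μ_f + d_f·σ_f, σ_f).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases

    locations = np.concatenate(
        [np.repeat(loc, cnt) for loc, cnt in sorted(spec.locations.items())])
    rng.shuffle(locations)

    label = np.array(["unruptured"] * n, dtype=object)
    label[rng.permutation(n)[: spec.n_ruptured]] = "ruptured"
    ruptured = label == "ruptured"

    df = pd.DataFrame({
        "case_id": [f"case_{i:04d}" for i in range(n)],
        "location": locations,
        "label": label,
    })
    for name in MORPHOLOGY_COLUMNS + FEATURE_NAMES:
        mu, sd = DEFAULT_FEATURE_BASE.get(name, (0.0, 1.0))
        d = spec.effect_sizes.get(name, 0.0)
        vals = rng.normal(mu, sd, size=n)
        vals[ruptured] += d * sd
        df[name] = vals
    # vessel calibre depends on location (ICA largest), on top of any shift
    calibre = {"ICA": 0.9, "MCA": 0.0, "ACA": -0.6}
    df["parent_vessel_diameter_mm"] += df["location"].map(calibre).to_numpy()
    df["parent_vessel_diameter_mm"] = df["parent_vessel_diameter_mm"].clip(lower=0.8)
    df["ostium_min_mm"] = df["ostium_min_mm"].clip(lower=0.5)
    return df
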