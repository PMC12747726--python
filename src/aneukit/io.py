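"""Container formats: native compressed arrays, VTK export, CSV/JSON tables.

The native container is an ``.npz`` archive (compressed numpy arrays)
holding the field arrays plus a JSON metadata string (units, spacing,
provenance).  Velocity frames can additionally be exported as ASCII
legacy-VTK structured-points files for visual inspection in ParaView.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Domain, FlowSeries, WallShearSeries
from .synthetic import CohortSpec

FORMAT_VERSION = 1


def _domain_arrays(domain: Domain) -> dict:
    return {
        "sac_mask": domain.sac_mask,
        "wall_points": domain.wall_points,
        "wall_normals": domain.wall_normals,
        "wall_areas": domain.wall_areas,
        "ostium_point": domain.ostium_point,
        "ostium_normal": domain.ostium_normal,
        "origin": domain.origin,
    }


def _domain_from(arrs, meta) -> Domain:
    return Domain(
        sac_mask=arrs["sac_mask"].astype(bool),
        spacing=meta["spacing_mm"],
        ostium_point=arrs["ostium_point"],
        ostium_normal=arrs["ostium_normal"],
        wall_points=arrs["wall_points"],
        wall_normals=arrs["wall_normals"],
        wall_areas=arrs["wall_areas"],
        neck_radius=meta.get("neck_radius_mm", 0.0),
        origin=arrs["origin"],
    )


def save_flow_series(path, series: FlowSeries) -> None:
    """Write a FlowSeries to the native compressed container."""
    meta = {
        "kind": "flow_series",
        "version": FORMAT_VERSION,
        "units": {"velocity": "mm/s", "length": "mm", "time": "s"},
        "spacing_mm": series.domain.spacing,
        "neck_radius_mm": series.domain.neck_radius,
        "period_s": series.period,
    }
    np.savez_compressed(path, frames=series.frames, times=series.times,
                        meta=json.dumps(meta), **_domain_arrays(series.domain))


def load_flow_series(path) -> FlowSeries:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta.get("kind") != "flow_series":
            raise ValueError(f"{path} is not a flow-series container")
        domain = _domain_from(z, meta)
        return FlowSeries(frames=z["frames"], times=z["times"], domain=domain,
                          period=meta.get("period_s"))


def save_wall_shear(path, ws: WallShearSeries) -> None:
    """Write a WallShearSeries to the native compressed container."""
    meta = {
        "kind": "wall_shear_series",
        "version": FORMAT_VERSION,
        "units": {"stress": "Pa", "area": "mm^2", "time": "s"},
        "period_s": ws.period,
    }
    np.savez_compressed(path, tau=ws.tau, areas=ws.areas, times=ws.times,
                        meta=json.dumps(meta))


def load_wall_shear(path) -> WallShearSeries:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta.get("kind") != "wall_shear_series":
            raise ValueError(f"{path} is not a wall-shear container")
        return WallShearSeries(tau=z["tau"], areas=z["areas"], times=z["times"],
                               period=meta.get("period_s"))


# ---------------------------------------------------------------------------
# legacy-VTK structured points (ASCII)

def write_vtk_structured_points(path, field: np.ndarray, spacing: float,
                                origin=(0.0, 0.0, 0.0), name: str = "field") -> None:
    """Export a scalar or 3-vector voxel field as ASCII legacy VTK.

    ``field`` has shape (nx, ny, nz) or (nx, ny, nz, 3); VTK orders
    points with x varying fastest, so arrays are transposed accordingly.
    """
    f = np.asarray(field, float)
    vector = f.ndim == 4 and f.shape[-1] == 3
    if not vector and f.ndim != 3:
        raise ValueError("field must be (nx, ny, nz) or (nx, ny, nz, 3)")
    nx, ny, nz = f.shape[:3]
    lines = [
        "# vtk DataFile Version 3.0",
        name,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {origin[0]} {origin[1]} {origin[2]}",
        f"SPACING {spacing} {spacing} {spacing}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    if vector:
        lines.append(f"VECTORS {name} double")
        data = f.transpose(2, 1, 0, 3).reshape(-1, 3)
        lines += [" ".join(format(v, ".17g") for v in row) for row in data]
    else:
        lines += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
        lines += [format(v, ".17g") for v in f.transpose(2, 1, 0).ravel()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_structured_points(path) -> tuple[np.ndarray, float, np.ndarray]:
    """Read an ASCII legacy-VTK structured-points file written by this package.

    Returns (field, spacing, origin); field shape (nx, ny, nz) or
    (nx, ny, nz, 3).
    """
    text = Path(path).read_text().splitlines()
    dims = spacing = origin = None
    vector = None
    data_start = None
    for i, line in enumerate(text):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "DIMENSIONS":
            dims = tuple(int(v) for v in tok[1:4])
        elif tok[0] == "SPACING":
            spacing = float(tok[1])
        elif tok[0] == "ORIGIN":
            origin = np.array([float(v) for v in tok[1:4]])
        elif tok[0] == "VECTORS":
            vector, data_start = True, i + 1
        elif tok[0] == "LOOKUP_TABLE":
            vector, data_start = False, i + 1
    if dims is None or data_start is None:
        raise ValueError(f"{path}: not a structured-points file")
    nx, ny, nz = dims
    vals = np.array(" ".join(text[data_start:]).split(), dtype=float)
    if vector:
        field = vals.reshape(nz, ny, nx, 3).transpose(2, 1, 0, 3)
    else:
        field = vals.reshape(nz, ny, nx).transpose(2, 1, 0)
    return field, spacing, origin


def export_flow_vtk(directory, series: FlowSeries, prefix: str = "velocity") -> list[Path]:
    """One structured-points file per frame; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(series.n_frames):
        p = directory / f"{prefix}_{k:03d}.vtk"
        write_vtk_structured_points(p, series.frames[k], series.domain.spacing,
                                    origin=series.domain.origin, name=prefix)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# tables and specs

def write_table(path, df: pd.DataFrame, provenance: dict | None = None) -> None:
    """CSV with '#'-prefixed JSON provenance header."""
    with open(path, "w") as fh:
        if provenance:
            fh.write("# " + json.dumps(provenance) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def cohort_spec_from_json(path) -> CohortSpec:
    d = json.loads(Path(path).read_text())
    return CohortSpec(**d)


def cohort_spec_to_json(path, spec: CohortSpec) -> None:
    Path(path).write_text(json.dumps({
        "n_cases": spec.n_cases,
        "n_ruptured": spec.n_ruptured,
        "locations": spec.locations,
        "effect_sizes": spec.effect_sizes,
        "seed": spec.seed,
    }, indent=2))
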