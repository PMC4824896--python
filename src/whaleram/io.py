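"""Deterministic writers: legacy ASCII VTK, per-element stress CSV, config.

All numeric formatting uses repr-faithful ``%.17g`` so identical inputs
produce byte-identical files (the determinism contract of the pipeline).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .fem import StressField
from .geometry import Mesh, REGION_LABELS

#: stable integer id per region label for VTK cell data
MATERIAL_IDS = {lab: i for i, lab in enumerate(REGION_LABELS)}


def _fmt(values) -> str:
    return " ".join("%.17g" % v for v in values)


def write_vtk(
    path: str | Path,
    mesh: Mesh,
    cell_data: Mapping[str, np.ndarray] | None = None,
    point_data: Mapping[str, np.ndarray] | None = None,
    title: str = "whaleram",
) -> Path:
    """Write the mesh as a legacy ASCII VTK UNSTRUCTURED_GRID.

    Scalar per-element arrays go to CELL_DATA; per-node arrays of shape
    (N, 2) are written as 3-vectors (zero z) under POINT_DATA.  A
    ``material_id`` cell field (integer id per region label) is always
    included.
    """
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for x, y in mesh.nodes:
        lines.append(_fmt((x, y, 0.0)))
    E = mesh.n_elements
    lines.append(f"CELLS {E} {4 * E}")
    for tri in mesh.triangles:
        lines.append(f"3 {tri[0]} {tri[1]} {tri[2]}")
    lines.append(f"CELL_TYPES {E}")
    lines.extend(["5"] * E)

    lines.append(f"CELL_DATA {E}")
    lines.append("SCALARS material_id int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(
        str(MATERIAL_IDS.get(lab, -1)) for lab in mesh.element_material
    )
    for name, arr in (cell_data or {}).items():
        arr = np.asarray(arr)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend("%.17g" % v for v in arr)

    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2:
                lines.append(f"VECTORS {name} double")
                for row in arr:
                    lines.append(_fmt((row[0], row[1], 0.0)))
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend("%.17g" % v for v in arr)
    path.write_text("\n".join(lines) + "\n")
    return path


def stress_table(mesh: Mesh, stress: StressField) -> pd.DataFrame:
    """Per-element stress table: id, material, components, von Mises,
    principal values."""
    p_max, p_min = stress.principal()
    return pd.DataFrame(
        {
            "element": np.arange(mesh.n_elements),
            "material": mesh.element_material,
            "sxx": stress.sxx,
            "syy": stress.syy,
            "txy": stress.txy,
            "vm": stress.von_mises,
            "p_max": p_max,
            "p_min": p_min,
        }
    )


def write_stress_csv(path: str | Path, mesh: Mesh, stress: StressField) -> Path:
    path = Path(path)
    stress_table(mesh, stress).to_csv(path, index=False, float_format="%.17g")
    return path


def write_population(path_base: str | Path, pop) -> tuple[Path, Path]:
    """Persist a Monte Carlo stress population: the iterations-by-elements
    von Mises matrix as CSV plus a JSON sidecar recording the seed, sampled
    moduli and group order."""
    import json

    base = Path(path_base)
    csv_path = base.with_suffix(".csv")
    pd.DataFrame(pop.von_mises).to_csv(
        csv_path, index_label="iteration", float_format="%.17g"
    )
    meta = {
        "seed": pop.seed,
        "n_iter": pop.n_iter,
        "n_elements": pop.n_elements,
        "group_names": list(pop.group_names),
        "moduli": pop.moduli.tolist(),
        "n_resampled": pop.n_resampled,
    }
    json_path = base.with_suffix(".json")
    json_path.write_text(json.dumps(meta, indent=2))
    return csv_path, json_path


def load_config(path: str | Path) -> dict:
    """Read a run configuration from a YAML key-value file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(path: str | Path, cfg: dict) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True, default_flow_style=False))
    return path
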