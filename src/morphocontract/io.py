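"""Result serialization: CSV tables, legacy-VTK mesh snapshots, manifests.

CSV is the canonical tabular format; field snapshots go to ASCII legacy VTK
(readable by ParaView/VisIt and text-diffable).  Every run directory gets a
``manifest.yaml`` with the fully resolved configuration, so all numeric
tolerances are reproducible from the artifacts alone.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fem.mesh import TriangleMesh
from .fem.solver import FIELD_NAMES, FieldState, SimulationResult

__all__ = ["export_timeseries", "write_vtk", "write_manifest"]


def export_timeseries(result: SimulationResult, path: str | Path) -> pd.DataFrame:
    """Write per-step traces of the tracked material points.

    One row per recorded step per tracked point: time, point id, current
    coordinates, the nine model fields (plus the mirror strain component),
    and the global mesh quality.  An empty result yields a header-only file.
    """
    path = Path(path)
    rows = []
    for pid, trace in result.tracked_points.items():
        n_steps = result.times.size
        for s in range(n_steps):
            row = {"time": result.times[s], "point_id": pid,
                   "x": trace["x"][s], "y": trace["y"][s]}
            row.update({name: trace[name][s] for name in FIELD_NAMES})
            row["mesh_quality"] = result.quality_trace[s]
            rows.append(row)
    columns = ["time", "point_id", "x", "y", *FIELD_NAMES, "mesh_quality"]
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, index=False)
    return frame


def write_vtk(mesh: TriangleMesh, state: FieldState, path: str | Path) -> None:
    """ASCII legacy-VTK snapshot of the moving mesh with nodal fields."""
    path = Path(path)
    n, m = mesh.n_nodes, mesh.n_elements
    lines = [
        "# vtk DataFile Version 3.0",
        f"morphocontract snapshot t={state.t:.6g} day",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    for x, y in mesh.coords:
        lines.append(f"{x:.10g} {y:.10g} 0")
    lines.append(f"CELLS {m} {4 * m}")
    for tri in mesh.triangles:
        lines.append("3 " + " ".join(str(int(v)) for v in tri))
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["5"] * m)
    lines.append(f"POINT_DATA {n}")
    for name in FIELD_NAMES:
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.10g}" for v in state.get(name))
    lines.append("VECTORS displacement double")
    lines.extend(f"{u:.10g} {v:.10g} 0" for u, v in state.u)
    path.write_text("\n".join(lines) + "\n")


def write_manifest(config: dict, path: str | Path, **extra) -> None:
    """Resolved-configuration manifest for reproducibility."""
    payload = {"config": _plain(config), **{k: _plain(v) for k, v in extra.items()}}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
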