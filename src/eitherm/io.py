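"""Plain-text I/O: meshes (legacy VTK, Gmsh MSH v2) and measurement frames.

Writers emit ASCII files readable by ParaView/Gmsh; the MSH reader accepts
version 2.2 ASCII files with tetrahedral elements and uses the first
element tag as the tissue label.  Measurement frames round-trip through
CSV (one row per channel with the injection and measurement pairs).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .forward import MeasurementFrame, StimulationPattern
from .mesh import TetMesh

__all__ = [
    "write_vtk",
    "write_msh",
    "read_msh",
    "frame_to_dataframe",
    "write_frame_csv",
    "read_frame_csv",
    "write_frame_json",
]


def write_vtk(path, mesh: TetMesh, cell_data: Optional[dict] = None) -> None:
    """Write a legacy ASCII VTK unstructured grid with per-element data.

    ``cell_data`` maps field names to per-element arrays; the tissue label
    is always included.
    """
    cell_data = dict(cell_data or {})
    cell_data.setdefault("tissue_label", mesh.labels)
    lines = [
        "# vtk DataFile Version 3.0",
        "eitherm tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{x:.9g}" for x in p) for p in mesh.node_coords]
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 5}")
    lines += ["4 " + " ".join(map(str, t)) for t in mesh.tets]
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += ["10"] * mesh.n_elements
    lines.append(f"CELL_DATA {mesh.n_elements}")
    for name, values in cell_data.items():
        values = np.asarray(values)
        kind = "int" if np.issubdtype(values.dtype, np.integer) else "double"
        lines.append(f"SCALARS {name} {kind} 1")
        lines.append("LOOKUP_TABLE default")
        fmt = (lambda v: str(int(v))) if kind == "int" else (lambda v: f"{v:.9g}")
        lines += [fmt(v) for v in values]
    Path(path).write_text("\n".join(lines) + "\n")


def write_msh(path, mesh: TetMesh) -> None:
    """Write a Gmsh MSH v2.2 ASCII file (tissue label as physical tag)."""
    out = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    out += [f"{i + 1} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}"
            for i, p in enumerate(mesh.node_coords)]
    out += ["$EndNodes", "$Elements", str(mesh.n_elements)]
    for i, (t, lab) in enumerate(zip(mesh.tets, mesh.labels)):
        nodes = " ".join(str(n + 1) for n in t)
        out.append(f"{i + 1} 4 2 {lab} {lab} {nodes}")
    out.append("$EndElements")
    Path(path).write_text("\n".join(out) + "\n")


def read_msh(path) -> TetMesh:
    """Read a Gmsh MSH v2.2 ASCII file (tetrahedral elements only)."""
    text = Path(path).read_text().splitlines()
    it = iter(text)
    nodes: list = []
    tets: list = []
    labels: list = []
    node_ids: dict = {}
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                node_ids[int(parts[0])] = len(nodes)
                nodes.append([float(x) for x in parts[1:4]])
        elif line.strip() == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                if etype != 4:  # skip non-tet elements
                    continue
                ntags = int(parts[2])
                labels.append(int(parts[3]) if ntags else 0)
                tets.append([node_ids[int(x)] for x in parts[3 + ntags:7 + ntags]])
    if not tets:
        raise ValueError(f"no tetrahedral elements found in {path}")
    return TetMesh(np.array(nodes), np.array(tets), np.array(labels))


def frame_to_dataframe(frame: MeasurementFrame) -> pd.DataFrame:
    rows = []
    for m, (i, inj, pair) in enumerate(frame.pattern.flat()):
        rows.append({
            "injection_pos": inj[0], "injection_neg": inj[1],
            "measure_pos": pair[0], "measure_neg": pair[1],
            "voltage_V": frame.values[m],
        })
    return pd.DataFrame(rows)


def write_frame_csv(path, frame: MeasurementFrame) -> None:
    frame_to_dataframe(frame).to_csv(path, index=False)


def read_frame_csv(path, pattern: StimulationPattern,
                   frequency_tag: str = "lf") -> MeasurementFrame:
    """Read a frame CSV; channel order must match the given pattern."""
    df = pd.read_csv(path)
    expected = frame_to_dataframe(
        MeasurementFrame(np.zeros(pattern.n_measurements), pattern))
    cols = ["injection_pos", "injection_neg", "measure_pos", "measure_neg"]
    if not (df[cols].values == expected[cols].values).all():
        raise ValueError("CSV channel order does not match the pattern")
    return MeasurementFrame(df["voltage_V"].to_numpy(), pattern, frequency_tag)


def write_frame_json(path, frame: MeasurementFrame) -> None:
    payload = {
        "frequency_tag": frame.frequency_tag,
        "current_A": frame.pattern.current,
        "n_electrodes": frame.pattern.n_electrodes,
        "values_V": frame.values.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
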