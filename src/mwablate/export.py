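"""Plain-text exports: legacy-VTK meshes with fields, tables as CSV/JSON."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import TriMesh

__all__ = ["write_vtk"]


def write_vtk(path: str | Path, mesh: TriMesh,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the (r, z) triangle mesh as a legacy ASCII VTK file.

    Complex fields are split into ``<name>_re``/``<name>_im`` components.
    """
    def _split(data):
        out = {}
        for name, arr in (data or {}).items():
            arr = np.asarray(arr)
            if np.iscomplexobj(arr):
                out[f"{name}_re"] = arr.real
                out[f"{name}_im"] = arr.imag
            else:
                out[name] = arr.astype(float)
        return out

    point_data = _split(point_data)
    cell_data = _split(cell_data)
    lines = ["# vtk DataFile Version 3.0", "mwablate mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    for r, z in mesh.nodes:
        lines.append(f"{r:.9e} {z:.9e} 0.0")
    lines.append(f"CELLS {mesh.n_elements} {4 * mesh.n_elements}")
    for t in mesh.tris:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend(["5"] * mesh.n_elements)

    def _section(header, data, n):
        if not data:
            return
        lines.append(header)
        for name, arr in data.items():
            if len(arr) != n:
                raise ValueError(f"field {name!r} has wrong length")
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9e}" for v in arr)

    _section(f"POINT_DATA {mesh.n_nodes}", point_data, mesh.n_nodes)
    cdata = dict(cell_data)
    cdata.setdefault("region", mesh.regions.astype(float))
    _section(f"CELL_DATA {mesh.n_elements}", cdata, mesh.n_elements)
    Path(path).write_text("\n".join(lines) + "\n")
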