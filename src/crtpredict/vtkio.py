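"""Legacy-ASCII VTK unstructured-grid I/O and plain-text configs.

A deliberately small writer/reader pair for the named data arrays this
package uses (tissue_class, aha_segment, wall_label, layer_label, fiber,
element_volume, activation maps).  Only the legacy ASCII VTK format with
tetrahedral cells is supported — enough for ParaView inspection and for
lossless round-trips of the package's own meshes.

Shape parameters and lesion maps load from YAML config files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .anatomy import LesionSpec, ShapeParams, VentricularMesh

_VTK_TET = 10


def write_vtk(mesh: VentricularMesh, path: str | Path,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh (plus optional extra arrays) as legacy ASCII VTK."""
    path = Path(path)
    n, m = mesh.n_nodes, mesh.n_elements
    pd = {"wall_label_node": mesh.wall_label_node}
    pd.update(point_data or {})
    cd = {
        "wall_label": mesh.wall_label,
        "layer_label": mesh.layer_label,
        "aha_segment": mesh.aha_segment,
        "tissue_class": mesh.tissue_class,
        "element_volume": mesh.element_volume,
    }
    cd.update(cell_data or {})

    with path.open("w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("crtpredict ventricular mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {n} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.10g")
        f.write(f"CELLS {m} {5 * m}\n")
        cells = np.column_stack([np.full(m, 4), mesh.tets])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {m}\n")
        np.savetxt(f, np.full(m, _VTK_TET), fmt="%d")

        f.write(f"POINT_DATA {n}\n")
        for name, arr in pd.items():
            _write_array(f, name, np.asarray(arr))
        f.write(f"CELL_DATA {m}\n")
        for name, arr in cd.items():
            _write_array(f, name, np.asarray(arr))
        _write_vectors(f, "fiber", mesh.fiber)


def _write_array(f, name: str, arr: np.ndarray) -> None:
    kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
    fmt = "%d" if kind == "int" else "%.10g"
    f.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
    np.savetxt(f, arr.ravel(), fmt=fmt)


def _write_vectors(f, name: str, arr: np.ndarray) -> None:
    f.write(f"VECTORS {name} double\n")
    np.savetxt(f, arr, fmt="%.10g")


def read_vtk(path: str | Path):
    """Read a legacy ASCII VTK unstructured grid written by this package.

    Returns ``(nodes, tets, point_data, cell_data)``; the fiber vector
    array, if present, appears in ``cell_data['fiber']``.
    """
    tokens = Path(path).read_text().split()
    i = 0

    def expect(word: str) -> None:
        nonlocal i
        while tokens[i].upper() != word:
            i += 1
        i += 1

    expect("POINTS")
    n = int(tokens[i]); i += 2
    nodes = np.array(tokens[i:i + 3 * n], dtype=float).reshape(n, 3)
    i += 3 * n
    expect("CELLS")
    m = int(tokens[i]); size = int(tokens[i + 1]); i += 2
    raw = np.array(tokens[i:i + size], dtype=int).reshape(m, 5)
    if not np.all(raw[:, 0] == 4):
        raise ValueError("only tetrahedral cells are supported")
    tets = raw[:, 1:]
    i += size
    expect("CELL_TYPES")
    i += 1 + m

    point_data: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {}
    target, count = None, 0
    while i < len(tokens):
        word = tokens[i].upper()
        if word == "POINT_DATA":
            target, count = point_data, int(tokens[i + 1]); i += 2
        elif word == "CELL_DATA":
            target, count = cell_data, int(tokens[i + 1]); i += 2
        elif word == "SCALARS":
            name, kind = tokens[i + 1], tokens[i + 2]
            i += 4  # SCALARS name type 1
            i += 2  # LOOKUP_TABLE default
            dtype = int if kind == "int" else float
            target[name] = np.array(tokens[i:i + count], dtype=dtype)
            i += count
        elif word == "VECTORS":
            name = tokens[i + 1]
            i += 3
            target[name] = np.array(tokens[i:i + 3 * count],
                                    dtype=float).reshape(count, 3)
            i += 3 * count
        else:
            i += 1
    return nodes, tets, point_data, cell_data


def load_shape_params(path: str | Path) -> ShapeParams:
    """Shape parameters from a YAML config (keys match ShapeParams fields)."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key in ("lv_endo_radii", "rv_center", "rv_epi_radii"):
        if key in cfg:
            kwargs[key] = tuple(float(x) for x in cfg[key])
    for key in ("lv_wall", "rv_wall"):
        if key in cfg:
            kwargs[key] = float(cfg[key])
    return ShapeParams(**kwargs)


def load_lesion_spec(path: str | Path) -> LesionSpec:
    """Lesion map from YAML: a list of {segments, layers, class} blocks.

    Example::

        lesions:
          - segments: [2, 3, 8, 9]
            layers: [mid]
            class: fibrosis
    """
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    entries: dict[tuple[int, int], str] = {}
    for block in cfg.get("lesions", []):
        for seg in block["segments"]:
            for layer in block["layers"]:
                entries[(int(seg), layer)] = block["class"]
    return LesionSpec(entries)
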