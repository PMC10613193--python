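"""File formats: ASCII VTU, Abaqus INP, pose-profile CSV and YAML configs.

The VTU writer emits plain-text XML UnstructuredGrid files readable by
ParaView/VTK; the INP exporter writes node/element/set definitions for
cross-validation against commercial solvers.  Both are deliberately
minimal: single piece, point/cell data as named arrays.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .kinematics import (
    CONVENTIONS,
    FlexionPose,
    LungeProfile,
    recompose_6dof,
)
from .meshing import Mesh

VTK_CELL_TYPE = {"tet4": 10, "hex8": 12}
ABAQUS_ELEMENT = {"tet4": "C3D4", "hex8": "C3D8"}


def write_vtu(mesh: Mesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write a mesh with named per-point / per-cell arrays as ASCII VTU.

    Tensor-valued cell arrays (ne, 3, 3) are flattened to 9 components;
    vectors stay 3-component; scalars 1.
    """
    path = Path(path)
    pd = dict(mesh.point_data)
    pd.update(point_data or {})
    cd = dict(cell_data or {})
    ne, npts = mesh.n_elements, mesh.n_nodes
    k = mesh.elements.shape[1]
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" '
        'byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{npts}" NumberOfCells="{ne}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
    ]
    lines.append("\n".join(" ".join(f"{v:.9g}" for v in row)
                           for row in mesh.nodes))
    lines += ["</DataArray>", "</Points>", "<Cells>",
              '<DataArray type="Int64" Name="connectivity" format="ascii">']
    lines.append("\n".join(" ".join(str(i) for i in c)
                           for c in mesh.elements))
    lines += ["</DataArray>",
              '<DataArray type="Int64" Name="offsets" format="ascii">']
    lines.append(" ".join(str(k * (i + 1)) for i in range(ne)))
    lines += ["</DataArray>",
              '<DataArray type="UInt8" Name="types" format="ascii">']
    lines.append(" ".join(str(VTK_CELL_TYPE[mesh.element_type])
                          for _ in range(ne)))
    lines += ["</DataArray>", "</Cells>"]

    def emit(data: dict, n_expected: int, tag: str):
        out = [f"<{tag}>"]
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.dtype.kind in "US":
                continue  # skip string tags
            flat = arr.reshape(n_expected, -1)
            ncomp = flat.shape[1]
            out.append(
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            out.append("\n".join(" ".join(f"{v:.9g}" for v in row)
                                 for row in flat))
            out.append("</DataArray>")
        out.append(f"</{tag}>")
        return out

    lines += emit(pd, npts, "PointData")
    lines += emit(cd, ne, "CellData")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(lines) + "\n")


def write_inp(mesh: Mesh, path, part_name: str = "PART") -> None:
    """Export the mesh as an Abaqus input fragment with node/element sets
    named for the regions and tagged surfaces (1-based ids)."""
    path = Path(path)
    lines = [f"*NODE"]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}")
    lines.append(
        f"*ELEMENT, TYPE={ABAQUS_ELEMENT[mesh.element_type]}, "
        f"ELSET={part_name}"
    )
    for i, conn in enumerate(mesh.elements, start=1):
        lines.append(f"{i}, " + ", ".join(str(c + 1) for c in conn))
    for region in np.unique(mesh.region):
        ids = np.nonzero(mesh.region == region)[0] + 1
        lines.append(f"*ELSET, ELSET={str(region).upper()}")
        lines += _chunks(ids)
    for name, ids in mesh.element_sets.items():
        lines.append(f"*ELSET, ELSET={name.upper()}")
        lines += _chunks(np.asarray(ids) + 1)
    for name, facets in mesh.surfaces.items():
        ids = np.unique(facets) + 1
        lines.append(f"*NSET, NSET={name.upper()}")
        lines += _chunks(ids)
    path.write_text("\n".join(lines) + "\n")


def _chunks(ids, per_line: int = 12):
    ids = list(int(i) for i in ids)
    return [", ".join(str(i) for i in ids[j:j + per_line])
            for j in range(0, len(ids), per_line)]


def write_profile_csv(profile: LungeProfile, path) -> None:
    """Pose sequence as CSV: angle + six dof columns, convention in the
    header comment row."""
    path = Path(path)
    conv = profile.poses[0].convention
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([f"# convention={conv} provenance={profile.provenance} "
                    f"seed={profile.seed}"])
        w.writerow(["flexion_angle", "flexion_deg", "adduction_deg",
                    "internal_rotation_deg", "tx_mm", "ty_mm", "tz_mm"])
        for p in profile.poses:
            w.writerow([p.flexion_angle] + [f"{v:.12g}" for v in p.dof])


def read_profile_csv(path) -> LungeProfile:
    path = Path(path)
    with path.open() as fh:
        rows = list(csv.reader(fh))
    header = rows[0][0]
    conv = "knee-xzy-intrinsic"
    for tok in header.replace("#", "").split():
        if tok.startswith("convention="):
            conv = tok.split("=", 1)[1]
    if conv not in CONVENTIONS:
        raise ValidationError(f"unknown convention {conv!r} in {path}")
    poses = []
    for row in rows[2:]:
        if not row:
            continue
        ang = float(row[0])
        dof = [float(v) for v in row[1:7]]
        poses.append(FlexionPose(ang, recompose_6dof(dof, conv), conv))
    return LungeProfile(poses=tuple(poses), provenance="user-supplied")


def write_boundary_csv(polyline: np.ndarray, path) -> None:
    """Closed cross-section boundary polyline as x,y CSV."""
    np.savetxt(path, polyline, delimiter=",", header="x_mm,y_mm",
               comments="")


def load_config(path) -> dict:
    """YAML pipeline/geometry configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
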