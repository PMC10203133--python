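"""File formats: MRC volumes and stacks, STAR orientation tables, tilt files.

Conventions
-----------
* MRC volumes are written mode 2 (float32) with the voxel size in the cell
  header.  On disk, MRC columns/rows/sections map to (x, y, z) with z the
  beam axis; in memory volumes are indexed ``[z, y, x]``, so the gemmi grid
  (x fastest) is transposed on the way in and out.  Round trips are
  bit-exact for float32 data.
* Orientation tables use the STAR dialect with columns ``rlnAngleRot`` /
  ``rlnAngleTilt`` / ``rlnAnglePsi`` (intrinsic ZYZ, degrees),
  ``rlnCoordinateX/Y/Z`` (particle centre, voxels) and ``rlnOriginX/Y/Z``
  (shifts, voxels), plus ``rlnImageName`` for the particle id and
  ``rlnMicrographName`` for the source tomogram.
* Tilt angle files are IMOD-style ``.tlt``: one angle in degrees per line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .pair_factory import OrientationRecord, PairSetManifest
from .tomo_forward import DensityVolume, ProjectionStack, RigidTransform

__all__ = [
    "read_volume",
    "write_volume",
    "read_stack",
    "write_stack",
    "read_orientations",
    "write_orientations",
    "read_tlt",
    "write_tlt",
    "read_manifest",
    "write_manifest",
    "read_matches",
    "write_matches",
]


# ---------------------------------------------------------------------------
# MRC volumes


def write_volume(vol: DensityVolume, path) -> None:
    """Write a volume as MRC mode 2 (float32) with voxel size in the header."""
    values = np.asarray(vol.values, dtype=np.float32)
    nz, ny, nx = values.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    arr = np.array(grid, copy=False)
    arr[...] = values.T  # (x, y, z) <- (z, y, x)
    grid.set_unit_cell(
        gemmi.UnitCell(nx * vol.voxel_A, ny * vol.voxel_A, nz * vol.voxel_A, 90, 90, 90)
    )
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_volume(path) -> DensityVolume:
    """Read an MRC/CCP4 volume; returns values indexed ``[z, y, x]``."""
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse MRC header of {path}: {exc}") from exc
    arr = np.array(m.grid, copy=True)  # (x, y, z), x fastest
    nx = m.grid.nu
    voxel = m.grid.unit_cell.a / nx if nx else 1.0
    return DensityVolume(np.ascontiguousarray(arr.T), voxel_A=float(voxel))


def write_stack(stack: ProjectionStack, path, tlt_path=None) -> None:
    """Write a tilt series as an MRC stack (sections = tilts).

    The angle list is not representable in the plain MRC header; pass
    ``tlt_path`` to write the companion ``.tlt`` file alongside.
    """
    images = np.asarray(stack.images, dtype=np.float32)
    n, h, w = images.shape
    grid = gemmi.FloatGrid(w, h, n)
    arr = np.array(grid, copy=False)
    arr[...] = images.T
    grid.set_unit_cell(
        gemmi.UnitCell(w * stack.pixel_A, h * stack.pixel_A, n * stack.pixel_A, 90, 90, 90)
    )
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))
    if tlt_path is not None:
        write_tlt(stack.angles_deg, tlt_path)


def read_stack(path, tlt_path) -> ProjectionStack:
    """Read an MRC stack plus its ``.tlt`` angle file."""
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True).T  # (n, h, w)
    pixel = m.grid.unit_cell.a / m.grid.nu if m.grid.nu else 1.0
    angles = read_tlt(tlt_path)
    return ProjectionStack(np.ascontiguousarray(arr), angles, float(pixel))


# ---------------------------------------------------------------------------
# tilt files


def write_tlt(angles_deg: Sequence[float], path) -> None:
    with open(path, "w") as fh:
        for a in angles_deg:
            fh.write(f"{float(a):.2f}\n")


def read_tlt(path) -> np.ndarray:
    with open(path) as fh:
        return np.array([float(line) for line in fh if line.strip()])


# ---------------------------------------------------------------------------
# STAR orientation tables

_STAR_COLUMNS = [
    "rlnImageName",
    "rlnMicrographName",
    "rlnAngleRot",
    "rlnAngleTilt",
    "rlnAnglePsi",
    "rlnCoordinateX",
    "rlnCoordinateY",
    "rlnCoordinateZ",
    "rlnOriginX",
    "rlnOriginY",
    "rlnOriginZ",
]


def write_orientations(records: Sequence[OrientationRecord], path) -> None:
    """Write orientation records as a STAR table (columns documented above)."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    loop = block.init_loop("_", _STAR_COLUMNS)
    for rec in records:
        rot, tilt, psi = rec.transform.euler_deg
        sx, sy, sz = rec.transform.shift_vox
        cx, cy, cz = rec.center_vox
        loop.add_row(
            [
                gemmi.cif.quote(rec.particle_id),
                gemmi.cif.quote(rec.source_tomogram or "."),
                f"{rot:.6f}",
                f"{tilt:.6f}",
                f"{psi:.6f}",
                f"{cx:.6f}",
                f"{cy:.6f}",
                f"{cz:.6f}",
                f"{sx:.6f}",
                f"{sy:.6f}",
                f"{sz:.6f}",
            ]
        )
    doc.write_file(str(path))


def read_orientations(path) -> list[OrientationRecord]:
    """Read a STAR orientation table back into records."""
    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()
    cols = {}
    for name in _STAR_COLUMNS:
        col = block.find_loop(f"_{name}")
        vals = list(col)
        if not vals and name in (
            "rlnAngleRot",
            "rlnAngleTilt",
            "rlnAnglePsi",
            "rlnCoordinateX",
            "rlnCoordinateY",
            "rlnCoordinateZ",
        ):
            raise ValueError(f"STAR table {path} is missing required column _{name}")
        cols[name] = vals
    n = len(cols["rlnAngleRot"])

    def get(name, i, default="0"):
        vals = cols[name]
        return vals[i] if vals else default

    records = []
    for i in range(n):
        transform = RigidTransform(
            (
                float(get("rlnAngleRot", i)),
                float(get("rlnAngleTilt", i)),
                float(get("rlnAnglePsi", i)),
            ),
            (
                float(get("rlnOriginX", i)),
                float(get("rlnOriginY", i)),
                float(get("rlnOriginZ", i)),
            ),
        )
        pid = gemmi.cif.as_string(get("rlnImageName", i, str(i)))
        src = gemmi.cif.as_string(get("rlnMicrographName", i, "."))
        records.append(
            OrientationRecord(
                particle_id=pid,
                transform=transform,
                source_tomogram="" if src == "." else src,
                center_vox=(
                    int(float(get("rlnCoordinateX", i))),
                    int(float(get("rlnCoordinateY", i))),
                    int(float(get("rlnCoordinateZ", i))),
                ),
            )
        )
    return records


# ---------------------------------------------------------------------------
# template-matching tables

_MATCH_COLUMNS = [
    "rlnCoordinateX",
    "rlnCoordinateY",
    "rlnCoordinateZ",
    "rlnAngleRot",
    "rlnAngleTilt",
    "rlnAnglePsi",
    "rlnAutopickFigureOfMerit",
]


def write_matches(matches, path) -> None:
    """Write template-matching peaks as a STAR table (cc = figure of merit)."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block("picks")
    loop = block.init_loop("_", _MATCH_COLUMNS)
    for m in matches:
        x, y, z = m.peak_coord_vox
        rot, tilt, psi = m.euler_deg
        loop.add_row([f"{x:.1f}", f"{y:.1f}", f"{z:.1f}",
                      f"{rot:.3f}", f"{tilt:.3f}", f"{psi:.3f}", f"{m.cc:.6f}"])
    doc.write_file(str(path))


def read_matches(path) -> list:
    """Read a match table written by :func:`write_matches`."""
    from .metrics import MatchResult

    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()
    cols = [list(block.find_loop(f"_{c}")) for c in _MATCH_COLUMNS]
    out = []
    for x, y, z, rot, tilt, psi, cc in zip(*cols):
        out.append(
            MatchResult(
                (int(float(x)), int(float(y)), int(float(z))),
                (float(rot), float(tilt), float(psi)),
                float(cc),
            )
        )
    return out


# ---------------------------------------------------------------------------
# manifests


def write_manifest(manifest: PairSetManifest, path) -> None:
    Path(path).write_text(manifest.to_json())


def read_manifest(path) -> PairSetManifest:
    return PairSetManifest.from_json(Path(path).read_text())
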