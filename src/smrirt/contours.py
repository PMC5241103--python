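"""Planar-contour structure sets and their rasterization.

Structure sets mirror what an RT planning system exports: per structure,
closed planar polygons with world-mm vertices, grouped by axial slice
position. They are stored in a small JSON dialect (documented below)
rather than full DICOM-RT — the transport format is not part of the
method — and rasterized into a voxel grid with the voxel-center
even-odd rule: a voxel belongs to the structure iff its center lies
inside an odd number of that slice's polygons, so nested contours
subtract as holes.

JSON dialect::

    {"structures": [
        {"name": "GTV2",
         "slices": [
            {"z": 12.5, "polygons": [[[x0, y0], [x1, y1], ...], ...]},
            ...]}
    ]}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
from matplotlib.path import Path as MplPath
from skimage import measure

from .grids import Mask, VolumeGrid

__all__ = ["StructureSet", "rasterize_structure", "extract_contours"]

_SLICE_TOL = 1e-3  # fraction of slice spacing a contour may sit off-plane


@dataclass
class StructureSet:
    """Named planar polygon structures.

    structures maps name -> list of (z_world_mm, vertices) where vertices
    is an (N, 2) array of in-plane (x, y) world coordinates, N >= 3.
    """

    structures: Dict[str, List[tuple]] = field(default_factory=dict)

    def add_polygon(self, name: str, z: float, vertices) -> None:
        verts = np.asarray(vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError("a polygon needs >= 3 (x, y) vertices")
        self.structures.setdefault(name, []).append((float(z), verts))

    @property
    def names(self) -> List[str]:
        return list(self.structures)

    def to_json(self, path=None) -> str:
        payload = {"structures": []}
        for name, polys in self.structures.items():
            by_z: Dict[float, list] = {}
            for z, verts in polys:
                by_z.setdefault(round(z, 6), []).append(verts.tolist())
            payload["structures"].append({
                "name": name,
                "slices": [{"z": z, "polygons": ps} for z, ps in sorted(by_z.items())],
            })
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "StructureSet":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        ss = cls()
        for st in payload["structures"]:
            for sl in st["slices"]:
                for poly in sl["polygons"]:
                    ss.add_polygon(st["name"], sl["z"], poly)
        return ss


def _slice_index(z: float, grid: VolumeGrid) -> int:
    dz = grid.spacing[2]
    k = (z - grid.origin[2]) / dz
    k_round = int(round(k))
    if abs(k - k_round) > _SLICE_TOL or not (0 <= k_round < grid.shape[2]):
        raise ValueError(
            f"polygon plane z={z:g} mm is not coplanar with any grid slice "
            f"(spacing {dz:g} mm, origin {grid.origin[2]:g} mm)"
        )
    return k_round


def rasterize_structure(s: StructureSet, grid: VolumeGrid) -> Dict[str, Mask]:
    """Rasterize each structure onto ``grid`` by the voxel-center rule.

    Returns one Mask per structure name. A voxel is a member iff its
    center falls inside the structure's polygons on that slice under the
    even-odd rule (holes subtract). Polygons must lie on grid slice
    planes; an off-plane polygon raises ``ValueError``.
    """
    xs = grid.axis_coordinates(0)
    ys = grid.axis_coordinates(1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])

    out: Dict[str, Mask] = {}
    for name, polys in s.structures.items():
        vol = np.zeros(grid.shape, dtype=bool)
        for z, verts in polys:
            k = _slice_index(z, grid)
            # Path implicitly closes the polygon for containment tests
            inside = MplPath(verts).contains_points(centers)
            vol[:, :, k] ^= inside.reshape(grid.shape[0], grid.shape[1])
        out[name] = Mask(grid, vol, name)
    if not s.structures:
        return {}
    return out


def extract_contours(m: Mask, name: str | None = None) -> StructureSet:
    """Trace slice-wise iso-contours of a mask back into a StructureSet.

    Contours are traced at the 0.5 level of the binary slice (sub-voxel,
    halfway between member and non-member centers), so rasterizing the
    result reproduces the mask to Dice >= 0.99 whenever features span at
    least ~3 voxels. An empty mask yields an empty set.
    """
    ss = StructureSet()
    if m.is_empty:
        return ss
    label = name or m.label or "structure"
    dx, dy = m.grid.spacing[0], m.grid.spacing[1]
    ox, oy = m.grid.origin[0], m.grid.origin[1]
    for k in range(m.grid.shape[2]):
        sl = m.data[:, :, k]
        if not sl.any():
            continue
        z = m.grid.origin[2] + k * m.grid.spacing[2]
        padded = np.pad(sl.astype(float), 1)
        for contour in measure.find_contours(padded, 0.5):
            # padded (row=x index, col=y index) -> world mm
            pts = np.column_stack([
                ox + (contour[:, 0] - 1.0) * dx,
                oy + (contour[:, 1] - 1.0) * dy,
            ])
            # find_contours closes interior loops; drop duplicate end vertex
            if np.allclose(pts[0], pts[-1]):
                pts = pts[:-1]
            if pts.shape[0] >= 3:
                ss.add_polygon(label, z, pts)
    return ss
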