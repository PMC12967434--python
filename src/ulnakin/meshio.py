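"""Reading and writing bone surfaces and labelled volumes.

Surface meshes travel as STL (binary or ASCII) or PLY in millimetre
coordinates, via trimesh.  A labelled 3-D volume (NIfTI, one integer
label per bone) can be isosurfaced instead: each label is extracted with
marching cubes at the 0.5 level and mapped through the header affine so
voxel anisotropy (e.g. 0.59 × 0.59 × 0.50 mm dynamic voxels) is honoured.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from skimage.measure import marching_cubes

from .geometry import TriangleMesh

_SUPPORTED = {".stl", ".ply"}


def load_mesh(path: str | Path, bone_label: str) -> TriangleMesh:
    """Load an STL/PLY surface as a bone mesh (mm coordinates preserved)."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise ValueError(f"unsupported mesh format {path.suffix!r} (use STL or PLY)")
    tm = trimesh.load(str(path), force="mesh", process=False)
    # STL stores a triangle soup; merge coincident vertices so the surface
    # is connected (curvature and watertightness need shared edges)
    tm.merge_vertices()
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces), bone_label)


def save_mesh(mesh: TriangleMesh, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise ValueError(f"unsupported mesh format {path.suffix!r} (use STL or PLY)")
    mesh.to_trimesh().export(str(path))
    return path


def labeled_volume_to_meshes(
    path: str | Path, label_map: dict[int, str]
) -> dict[str, TriangleMesh]:
    """Isosurface each labelled bone of a NIfTI segmentation.

    ``label_map`` maps integer voxel labels to bone names.  Marching cubes
    runs at level 0.5 on each binary label mask; vertices are mapped into
    world (mm) coordinates through the NIfTI affine.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    affine = img.affine
    out: dict[str, TriangleMesh] = {}
    for label, bone in label_map.items():
        mask = (data == label).astype(np.float32)
        if mask.sum() == 0:
            raise ValueError(f"label {label} ({bone}) absent from volume")
        verts, faces, *_ = marching_cubes(mask, level=0.5)
        world = verts @ affine[:3, :3].T + affine[:3, 3]
        out[bone] = TriangleMesh(world, faces, bone)
    return out
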