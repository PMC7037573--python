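"""Label-volume and surface-mesh input/output and geometry.

Subcortical structures arrive as integer label maps (FreeSurfer
aseg-style NIfTI/MGZ) or as precomputed surface meshes. This module
extracts closed boundary surfaces per structure with marching cubes,
validates mesh topology, and measures surface area and enclosed volume
in world millimetres. Spectra downstream require a closed, edge-manifold,
single-component mesh; :func:`validate_mesh` is the gatekeeper.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.measure import marching_cubes

__all__ = [
    "LabelVolume",
    "TriangleMesh",
    "StructureSpec",
    "MeshValidation",
    "DEFAULT_STRUCTURES",
    "read_label_volume",
    "extract_surface",
    "validate_mesh",
    "repair_orientation",
    "mesh_area",
    "mesh_volume",
    "read_mesh",
    "write_mesh",
    "load_structure_specs",
]


class MeshError(ValueError):
    """Raised when mesh geometry or topology violates a contract."""


@dataclass
class LabelVolume:
    """Integer label map with a voxel-to-world affine.

    Attributes
    ----------
    voxels : ndarray of int
        3D array of non-negative structure labels.
    affine : ndarray, shape (4, 4)
        Maps voxel indices (i, j, k, 1) to world coordinates in mm.
    """

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"label volume must be 3D, got {self.voxels.ndim}D")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("label volume must hold integer labels")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("label values must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length of a voxel along each axis, in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def labels(self) -> np.ndarray:
        return np.unique(self.voxels)


@dataclass
class TriangleMesh:
    """Triangle surface mesh in world mm.

    vertices : (N, 3) float coordinates; faces : (M, 3) 0-based vertex
    indices, consistently wound with outward normals once validated.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (M, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise MeshError("face index out of range")
        if self.faces.size and self.faces.min() < 0:
            raise MeshError("negative face index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))


@dataclass(frozen=True)
class StructureSpec:
    """A lateralized structure and its left/right label IDs."""

    name: str
    left_label_id: int
    right_label_id: int

    def __post_init__(self) -> None:
        if self.left_label_id == self.right_label_id:
            raise ValueError("left and right label IDs must differ")


#: FreeSurfer aseg convention for the three structures of interest.
DEFAULT_STRUCTURES: tuple[StructureSpec, ...] = (
    StructureSpec("amygdala", 18, 54),
    StructureSpec("hippocampus", 17, 53),
    StructureSpec("lateral_ventricle", 4, 43),
)


def load_structure_specs(source: str | Path | dict) -> list[StructureSpec]:
    """Load a structure label map from JSON ``{name: {left: id, right: id}}``."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = json.load(fh)
    return [
        StructureSpec(name, int(ids["left"]), int(ids["right"]))
        for name, ids in source.items()
    ]


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI (.nii/.nii.gz) or MGZ integer label volume.

    Raises if the file does not exist, is not 3D, or holds non-integral
    values (a probabilistic map is not a segmentation).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D label volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError("volume holds non-integral values; not a label map")
        data = rounded.astype(np.int32)
    return LabelVolume(voxels=data.astype(np.int32), affine=np.asarray(img.affine))


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.int32), vol.affine), str(path))


def extract_surface(
    vol: LabelVolume,
    label_id: int,
    smooth: bool = False,
    min_component_fraction: float = 0.01,
) -> TriangleMesh:
    """Extract the closed boundary surface of one label via marching cubes.

    The binary mask ``voxels == label_id`` is zero-padded by one voxel and
    contoured at iso-level 0.5; vertices are mapped to world mm through the
    affine. No smoothing by default (deterministic geometry); ``smooth=True``
    applies 10 iterations of Taubin smoothing. If the surface splits into
    several components, specks below ``min_component_fraction`` of the total
    enclosed volume are dropped and the largest component is kept; larger
    secondary components raise.
    """
    mask = vol.voxels == label_id
    if not mask.any():
        raise MeshError(f"label {label_id} absent from volume")
    # A mask on the border would be clipped by the scan FOV; the surface we
    # could close there is not the structure's boundary.
    border = (
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )
    if border:
        raise MeshError(
            f"mask for label {label_id} touches the volume border; "
            "pad the volume with background voxels before extraction"
        )
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    verts = verts - 1.0  # undo padding offset, back to voxel index space
    verts = verts @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    mesh = TriangleMesh(verts, faces)
    mesh = _keep_main_component(mesh, min_component_fraction)
    if smooth:
        tm = mesh.to_trimesh()
        trimesh.smoothing.filter_taubin(tm, iterations=10)
        mesh = TriangleMesh.from_trimesh(tm)
    return repair_orientation(mesh)


def _keep_main_component(mesh: TriangleMesh, min_fraction: float) -> TriangleMesh:
    tm = mesh.to_trimesh()
    parts = tm.split(only_watertight=False)
    if len(parts) <= 1:
        return mesh
    vols = np.array([abs(p.volume) for p in parts])
    total = vols.sum()
    small = vols < min_fraction * total
    if (~small).sum() > 1:
        raise MeshError(
            f"surface has {int((~small).sum())} components above "
            f"{min_fraction:.0%} of total volume; segmentation is fragmented"
        )
    warnings.warn(
        f"discarding {int(small.sum())} speck component(s) "
        f"({vols[small].sum():.3g} of {total:.3g} mm³)",
        stacklevel=3,
    )
    return TriangleMesh.from_trimesh(parts[int(np.argmax(vols))])


@dataclass
class MeshValidation:
    """Topology/geometry report from exhaustive edge and face accounting."""

    closed: bool
    manifold: bool
    n_components: int
    euler_characteristic: int
    min_face_area: float
    oriented: bool

    @property
    def ok_for_spectra(self) -> bool:
        """Closed + edge-manifold + single component: required for spectra."""
        return self.closed and self.manifold and self.n_components == 1


def _edge_counts(faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    return uniq, counts


def validate_mesh(mesh: TriangleMesh) -> MeshValidation:
    """Report closedness, manifoldness, components, Euler characteristic.

    Always returns; downstream spectra refuse meshes failing
    ``ok_for_spectra``.
    """
    uniq, counts = _edge_counts(mesh.faces)
    closed = bool(np.all(counts == 2))
    manifold = bool(np.all(counts <= 2))
    # components over vertices referenced by faces
    used = np.unique(mesh.faces)
    if len(used) == 0:
        n_comp = 0
    else:
        row, col = uniq[:, 0], uniq[:, 1]
        n = mesh.n_vertices
        adj = coo_matrix(
            (np.ones(len(row)), (row, col)), shape=(n, n)
        )
        labels_all = connected_components(adj, directed=False)[1]
        n_comp = len(np.unique(labels_all[used]))
    # count only face-referenced vertices so stray isolated vertices do not
    # distort the characteristic
    euler = len(used) - len(uniq) + mesh.n_faces
    areas = mesh.face_areas()
    # oriented: every shared edge traversed once in each direction
    edges = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    _, dir_counts = np.unique(edges, axis=0, return_counts=True)
    oriented = bool(np.all(dir_counts == 1)) if closed else bool(np.all(dir_counts <= 1))
    return MeshValidation(
        closed=closed,
        manifold=manifold,
        n_components=n_comp,
        euler_characteristic=int(euler),
        min_face_area=float(areas.min()) if len(areas) else 0.0,
        oriented=oriented,
    )


def repair_orientation(mesh: TriangleMesh) -> TriangleMesh:
    """Return a copy with consistent outward-pointing face normals.

    Winding is unified across the surface and flipped globally if the
    signed enclosed volume comes out negative. Orientation problems are
    repaired rather than rejected.
    """
    tm = mesh.to_trimesh()
    trimesh.repair.fix_normals(tm)
    out = TriangleMesh.from_trimesh(tm)
    if _signed_volume(out) < 0:
        out = TriangleMesh(out.vertices, out.faces[:, [0, 2, 1]])
    return out


def mesh_area(mesh: TriangleMesh) -> float:
    """Total surface area in mm² (sum of triangle areas)."""
    areas = mesh.face_areas()
    total = float(areas.sum())
    if total <= 0:
        raise MeshError("mesh has zero total area (degenerate)")
    return total


def _signed_volume(mesh: TriangleMesh) -> float:
    v = mesh.vertices
    f = mesh.faces
    return float(
        np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0
    )


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume in mm³ via the divergence theorem (positive magnitude).

    Requires a closed mesh; inward-wound meshes yield the same magnitude
    with a warning.
    """
    report = validate_mesh(mesh)
    if not report.closed:
        raise MeshError("mesh is not closed; enclosed volume undefined")
    signed = _signed_volume(mesh)
    if signed < 0:
        warnings.warn("mesh wound inward; returning |volume|", stacklevel=2)
    return abs(signed)


def read_mesh(path: str | Path) -> TriangleMesh:
    """Read OFF, PLY (ascii or binary) or FreeSurfer binary surface."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".off", ".ply"}:
        tm = trimesh.load(path, process=False, force="mesh")
        return TriangleMesh.from_trimesh(tm)
    # FreeSurfer surfaces carry no extension convention (lh.hippo etc.)
    verts, faces = nib.freesurfer.read_geometry(str(path))
    return TriangleMesh(np.asarray(verts, dtype=float), np.asarray(faces))


def write_mesh(mesh: TriangleMesh, path: str | Path, binary: bool = False) -> None:
    """Write OFF or PLY; PLY may be binary little-endian."""
    path = Path(path)
    tm = mesh.to_trimesh()
    suffix = path.suffix.lower()
    if suffix == ".off":
        path.write_bytes(trimesh.exchange.off.export_off(tm).encode())
    elif suffix == ".ply":
        data = trimesh.exchange.ply.export_ply(
            tm, encoding="binary_little_endian" if binary else "ascii"
        )
        path.write_bytes(data)
    else:
        raise ValueError(f"unsupported mesh format: {suffix}")
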