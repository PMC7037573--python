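"""Synthetic inputs: mirrored mesh pairs, label volumes, simulated cohorts.

Everything the pipeline consumes can be generated here at desk scale with
known ground truth: genus-0 left/right mesh pairs where the right side is
a mirror image carrying a controlled smooth deformation (so the true
shape asymmetry is a single amplitude knob), digitized mirrored solids in
integer label volumes (to exercise the voxel→mesh path), and cohort
tables drawn from the same linear model the analysis fits (so regression
calibration can be checked against known coefficients). Every generator
is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy import stats as sps

from .mesh_io import LabelVolume, MeshError, TriangleMesh, mesh_volume
from .cohort_stats import OUTCOME_COLUMNS

__all__ = [
    "DeformationSpec",
    "CohortSimSpec",
    "make_sphere_mesh",
    "mirror_mesh",
    "make_asymmetric_pair",
    "make_label_volume",
    "simulate_cohort",
]


def make_sphere_mesh(radius: float = 1.0, subdivisions: int = 3) -> TriangleMesh:
    """Icosphere: icosahedron subdivided ``subdivisions`` times, projected
    to the sphere of given radius (V = 10·4^s + 2 vertices, genus 0)."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh.from_trimesh(tm)


def mirror_mesh(mesh: TriangleMesh, axis: int = 0) -> TriangleMesh:
    """Exact mirror image across the plane ``coordinate[axis] = 0``.

    Faces are rewound so outward orientation is preserved.
    """
    verts = mesh.vertices.copy()
    verts[:, axis] *= -1.0
    return TriangleMesh(verts, mesh.faces[:, [0, 2, 1]].copy())


@dataclass(frozen=True)
class DeformationSpec:
    """A seeded smooth deformation of controlled amplitude.

    ``amplitude`` is a fraction of the mesh's mean radius; ``amplitude=0``
    reproduces the base shape exactly. Modes:

    * ``bump``    — C¹ indentation of a compact random surface patch along
      its axis (cosine-squared kernel), emulating a focal shape change;
    * ``bend``    — a shear bending the shape along its z extent; volume
      preserving in the continuum (each z-slice translates rigidly);
    * ``stretch`` — anisotropic scaling along a seeded random axis.

    ``compensate_volume`` rescales the deformed mesh uniformly back to the
    base enclosed volume, producing the "shape change without volume
    change" scenario (the normalized spectrum is scale invariant, so the
    compensation does not mask the shape difference).
    """

    amplitude: float = 0.05
    mode: str = "bump"
    seed: int = 0
    compensate_volume: bool = False
    patch_radius: float = 0.9  # angular support of the bump kernel, radians

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.mode not in {"bump", "bend", "stretch"}:
            raise ValueError(f"unknown deformation mode: {self.mode}")


def _deform(mesh: TriangleMesh, spec: DeformationSpec) -> TriangleMesh:
    rng = np.random.default_rng(spec.seed)
    v = mesh.vertices.copy()
    centroid = v.mean(axis=0)
    p = v - centroid
    r = np.linalg.norm(p, axis=1)
    r_mean = r.mean()
    a = spec.amplitude

    if spec.mode == "bump":
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        with np.errstate(invalid="ignore"):
            cos_theta = np.clip((p / np.maximum(r[:, None], 1e-12)) @ direction, -1, 1)
        theta = np.arccos(cos_theta)
        w = np.where(
            theta < spec.patch_radius,
            np.cos(0.5 * np.pi * theta / spec.patch_radius) ** 2,
            0.0,
        )
        # indent along the patch axis: near the centre this is the inward
        # normal; an excessive amplitude pushes the patch through its own
        # rim and folds the surface (detected below)
        v = v - (a * r_mean * w)[:, None] * direction
    elif spec.mode == "bend":
        # draw a seeded bend direction in the x-y plane; shear proportional
        # to z² translates each z-slice rigidly (volume preserving)
        phi = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(phi), np.sin(phi), 0.0])
        v = v + (a * p[:, 2] ** 2 / r_mean)[:, None] * direction
    else:  # stretch
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        proj = p @ axis
        v = v + a * proj[:, None] * axis

    out = TriangleMesh(v, mesh.faces.copy())
    _check_fold_over(mesh, out, spec)
    if spec.compensate_volume and a > 0:
        target = mesh_volume(mesh)
        got = mesh_volume(out)
        scale = (target / got) ** (1.0 / 3.0)
        out = TriangleMesh(centroid + scale * (out.vertices - out.vertices.mean(axis=0)),
                           out.faces)
    return out


def _check_fold_over(before: TriangleMesh, after: TriangleMesh, spec: DeformationSpec) -> None:
    def normals(m: TriangleMesh) -> np.ndarray:
        v, f = m.vertices, m.faces
        return np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])

    n0, n1 = normals(before), normals(after)
    area1 = 0.5 * np.linalg.norm(n1, axis=1)
    flipped = np.einsum("ij,ij->i", n0, n1) <= 0
    if area1.min() < 1e-12 or flipped.any():
        raise MeshError(
            f"deformation amplitude {spec.amplitude} folds the surface "
            f"({int(flipped.sum())} inverted faces); reduce the amplitude"
        )


def make_asymmetric_pair(
    base: TriangleMesh, spec: DeformationSpec
) -> tuple[TriangleMesh, TriangleMesh]:
    """Left/right pair: left is the base, right its mirror plus deformation.

    With ``spec.amplitude == 0`` the right mesh is an exact mirror image,
    so any downstream shape-asymmetry measure should vanish (up to solver
    noise): the end-to-end reflection-invariance control.
    """
    left = base
    right = mirror_mesh(base)
    if spec.amplitude > 0:
        right = _deform(right, spec)
    return left, right


def make_label_volume(
    shape: str = "ball",
    grid_size: int = 48,
    seed: int = 0,
    radius: int | None = None,
    left_label: int = 17,
    right_label: int = 53,
    voxel_size: float = 1.0,
) -> LabelVolume:
    """Digitized mirrored left/right solids in one integer label volume.

    ``shape`` is ``ball`` or ``blob`` (a two-lobe union of balls, seeded).
    The right structure is the exact voxel mirror of the left across the
    mid-plane of axis 0, so voxel counts match exactly. Structures keep a
    ≥ 2-voxel margin from the border and from each other.
    """
    if shape not in {"ball", "blob"}:
        raise ValueError(f"unknown shape: {shape}")
    g = int(grid_size)
    if radius is None:
        radius = max(3, g // 6)
    half = g // 2
    cx = half // 2  # left structure centre along axis 0
    if radius + 2 > cx or radius + 2 > g // 2 - cx or radius + 2 > g // 2:
        raise MeshError(
            f"grid of size {g} cannot fit two radius-{radius} structures "
            "with a 2-voxel margin"
        )
    rng = np.random.default_rng(seed)
    ii, jj, kk = np.meshgrid(
        np.arange(g), np.arange(g), np.arange(g), indexing="ij"
    )
    centre = np.array([cx, (g - 1) / 2.0, (g - 1) / 2.0])

    def ball_mask(c, r):
        return (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2 <= r**2

    left = ball_mask(centre, radius)
    if shape == "blob":
        off = rng.integers(-radius // 2, radius // 2 + 1, size=3)
        lobe_r = max(2, int(radius * 0.6))
        left |= ball_mask(centre + off, lobe_r)
    right = left[::-1].copy()  # exact voxel mirror about the axis-0 mid-plane
    if (left & right).any():
        raise MeshError("left and right structures overlap; shrink radius")
    if left[:2].any() or left[-2:].any():
        raise MeshError("structure too close to the volume border")
    vox = np.zeros((g, g, g), dtype=np.int32)
    vox[left] = left_label
    vox[right] = right_label
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return LabelVolume(voxels=vox, affine=affine)


@dataclass(frozen=True)
class CohortSimSpec:
    """Parameters of a simulated cohort following the analysis model.

    Marginals default to a realistic multi-site developmental cohort
    (n = 948, ~85% male, age ≈ 16 ± 6 years in [6, 35], FSIQ ≈ 108 ± 13,
    ICV ≈ 1.33e6 ± 2.6e5 mm³, 17 sites). Outcomes are drawn as
    ``intercept + β·x + site offset + N(0, residual_sd)`` with diagnosis
    coded 1 = control and sex coded 1 = female (so a negative diagnosis β
    makes the ASD group mean larger). The true coefficients are stored in
    ``DataFrame.attrs['true_betas']``.
    """

    n: int = 948
    beta_diagnosis: float = 0.0
    beta_sex: float = 0.0
    beta_age: float = 0.0
    beta_icv: float = 0.0
    beta_fsiq: float = 0.0
    beta_age_sq: float = 0.0
    intercept: float = 2.0
    residual_sd: float = 1.0
    site_sd: float = 0.2
    n_sites: int = 17
    site_proportions: tuple[float, ...] | None = None
    prop_male: float = 0.85
    prop_asd: float = 0.46
    prop_poor_quality: float = 0.0
    age_mean: float = 16.0
    age_sd: float = 6.2
    age_range: tuple[float, float] = (6.0, 35.0)
    icv_mean: float = 1.33e6
    icv_sd: float = 2.6e5
    fsiq_mean: float = 108.0
    fsiq_sd: float = 13.0
    outcomes: tuple[str, ...] = OUTCOME_COLUMNS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.residual_sd <= 0:
            raise ValueError("residual SD must be positive")
        if self.site_proportions is not None:
            if len(self.site_proportions) != self.n_sites:
                raise ValueError("site_proportions length must equal n_sites")
            if abs(sum(self.site_proportions) - 1.0) > 1e-8:
                raise ValueError("site proportions must sum to 1")


def simulate_cohort(spec: CohortSimSpec = CohortSimSpec()) -> pd.DataFrame:
    """Draw a cohort table with outcomes from the spec's linear model."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    lo, hi = spec.age_range
    a_std = (lo - spec.age_mean) / spec.age_sd
    b_std = (hi - spec.age_mean) / spec.age_sd
    age = sps.truncnorm.rvs(
        a_std, b_std, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng
    )
    sex = np.where(rng.random(n) < spec.prop_male, "male", "female")
    diagnosis = np.where(rng.random(n) < spec.prop_asd, "ASD", "control")
    site_names = [f"site{i + 1:02d}" for i in range(spec.n_sites)]
    props = (
        np.asarray(spec.site_proportions)
        if spec.site_proportions is not None
        else np.full(spec.n_sites, 1.0 / spec.n_sites)
    )
    site = rng.choice(site_names, size=n, p=props)
    icv = np.maximum(rng.normal(spec.icv_mean, spec.icv_sd, size=n), 1e5)
    fsiq = rng.normal(spec.fsiq_mean, spec.fsiq_sd, size=n)
    quality = np.where(rng.random(n) < spec.prop_poor_quality, "poor", "ok")

    site_offsets = dict(zip(site_names, rng.normal(0.0, spec.site_sd, spec.n_sites)))
    dx_control = (diagnosis == "control").astype(float)
    female = (sex == "female").astype(float)
    age_c = age - age.mean()
    linpred = (
        spec.intercept
        + spec.beta_diagnosis * dx_control
        + spec.beta_sex * female
        + spec.beta_age * age
        + spec.beta_icv * icv
        + spec.beta_fsiq * fsiq
        + spec.beta_age_sq * age_c**2
        + np.vectorize(site_offsets.get)(site)
    )
    df = pd.DataFrame(
        {
            "subject_id": [f"sub{i + 1:05d}" for i in range(n)],
            "diagnosis": diagnosis,
            "sex": sex,
            "age": age,
            "site": site,
            "icv": icv,
            "fsiq": fsiq,
            "quality_flag": quality,
        }
    )
    for outcome in spec.outcomes:
        df[outcome] = linpred + rng.normal(0.0, spec.residual_sd, size=n)
    df.attrs["true_betas"] = {
        "diagnosis": spec.beta_diagnosis,
        "sex": spec.beta_sex,
        "age": spec.beta_age,
        "icv": spec.beta_icv,
        "fsiq": spec.beta_fsiq,
        "age_sq": spec.beta_age_sq,
        "intercept": spec.intercept,
    }
    df.attrs["sim_spec"] = asdict(spec)
    return df
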