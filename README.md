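# shapeasym

Spectral shape asymmetry of lateralized brain structures.

Hemispheric asymmetry of subcortical structures — amygdala, hippocampus,
lateral ventricles — is usually quantified by volume alone. `shapeasym`
additionally quantifies *shape* asymmetry with a registration-free
spectral descriptor, and runs the cohort-level statistics needed to
compare clinical groups (e.g. an autism cohort against controls across
many scanning sites). It is aimed at neuroimaging researchers who have
FreeSurfer-style subcortical segmentations (aseg label volumes) or
surface meshes per hemisphere and want a per-subject, within-subject
asymmetry measure plus a covariate-adjusted group analysis.

## Model

For each structure and hemisphere, the boundary surface is extracted from
the label volume by marching cubes and its **shapeDNA** descriptor is
computed: the first *l* non-zero eigenvalues of the Laplace-Beltrami
operator Δ on the surface, from the Helmholtz eigenproblem

    Δf = −λf,    0 = λ₀ < λ₁ ≤ λ₂ ≤ … ,    λ̄ = (λ₁, …, λ_l),  l = 30,

discretized with linear (P1) finite elements (cotangent stiffness A,
consistent mass B; generalized problem A f = λ B f). The spectrum is
isometry invariant — rigid motions *and reflections* leave it unchanged —
so left and right hemispheres can be compared directly, with no
registration and no lateral processing bias. Scale is removed by
normalizing λ′ = vol^(2/D)·λ with vol the surface area (D = 2).

Per subject and structure, two non-directional asymmetry measures:

* **shape asymmetry**  Y_s = ‖λ̄_left − λ̄_right‖_Σ with diagonal Σ,
  Σᵢᵢ = i², i.e. sqrt(Σᵢ (λ_L,i − λ_R,i)²/i²) — higher eigenvalues are
  down-weighted;
* **volumetric asymmetry**  |V_left − V_right| in mm³.

At the cohort level each outcome is regressed on diagnosis and sex with
age, scanning site, intracranial volume and FSIQ as covariates (OLS;
quadratic-age need checked by likelihood-ratio test; Bonferroni
correction across the six outcomes; Welch t-tests for subgroup
contrasts). A synthetic-data module generates mirrored mesh pairs with a
controlled asymmetry amplitude, digitized label volumes, and cohort
tables with known regression coefficients, so every stage is testable
with ground truth.

## Worked example

```python
import numpy as np
from shapeasym import (make_sphere_mesh, make_asymmetric_pair, DeformationSpec,
                       shape_dna, lateral_asymmetry, mesh_volume, volumetric_asymmetry)

base = make_sphere_mesh(radius=10.0, subdivisions=3)          # 10 mm "structure"
left, right = make_asymmetric_pair(
    base, DeformationSpec(amplitude=0.1, mode="bump", seed=7)) # focal indentation

dl, dr = shape_dna(left), shape_dna(right)                     # l = 30, normalized
print("first 5 normalized eigenvalues (left): ", np.round(dl.eigenvalues[:5], 3))
print("first 5 normalized eigenvalues (right):", np.round(dr.eigenvalues[:5], 3))
print("shape asymmetry Y_s:", round(lateral_asymmetry(dl, dr), 4))
vl, vr = mesh_volume(left), mesh_volume(right)
print("volumetric asymmetry (mm^3):", round(volumetric_asymmetry(vl, vr), 2))
```

prints

```
first 5 normalized eigenvalues (left):  [25.157 25.157 25.157 75.913 75.913]
first 5 normalized eigenvalues (right): [24.979 24.98  25.514 75.248 75.248]
shape asymmetry Y_s: 0.6362
volumetric asymmetry (mm^3): 66.15
```

The left surface is a sphere, so its normalized spectrum shows the exact
multiplicities of the analytic sphere spectrum (4π·k(k+1) with
multiplicity 2k+1: 25.13…, ×3, then 75.40…, ×5). The right surface
carries a focal indentation: the degenerate eigenvalues split, and the
weighted spectral distance Y_s = 0.64 quantifies the shape asymmetry. At
amplitude 0 the pair is an exact mirror and Y_s drops to ~1e-13. The
volume difference (66 mm³ of ~4113 mm³) is reported separately — a
volume-compensated deformation yields Y_s ≫ 0 with zero volumetric
asymmetry, which is exactly the dissociation the shape measure exists to
detect.

A command-line interface covers the same pipeline on files:
`shapeasym extract` (label volume → meshes), `spectrum`, `asymmetry`,
`analyze` (manifest batch), `simulate` (synthetic fixtures) and `report`
(cohort filtering + regression + Welch tests → CSV/Markdown).

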