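"""Per-subject hemispheric asymmetry from left/right descriptors and volumes.

Two non-directional measures per structure:

* **Shape asymmetry** Y_s — the Mahalanobis distance between the left and
  right shapeDNA vectors under the fixed diagonal covariance Σ with
  Σii = i², i.e. ``sqrt(Σ_i (λL_i − λR_i)² / i²)``. The 1/i² weights damp
  the higher eigenvalues, which carry fine-scale detail and discretization
  noise. Because the spectrum is reflection invariant, mirroring plays no
  role: the distance is computed directly, with no registration and no
  lateral processing bias.
* **Volumetric asymmetry** — the absolute left-right enclosed-volume
  difference |L − R| in mm³ (a normalized index |L−R|/(L+R) is available
  behind a flag; head size is handled as a regression covariate, not a
  denominator).

Both are symmetric in their arguments: swapping hemispheres changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import ShapeDescriptor

__all__ = [
    "AsymmetryRecord",
    "lateral_asymmetry",
    "volumetric_asymmetry",
    "records_to_frame",
]


@dataclass
class AsymmetryRecord:
    """Shape and volumetric asymmetry of one structure in one subject."""

    subject_id: str
    structure: str
    shape_asymmetry: float
    volumetric_asymmetry: float
    left_volume: float
    right_volume: float

    def __post_init__(self) -> None:
        if self.shape_asymmetry < 0 or self.volumetric_asymmetry < 0:
            raise ValueError("asymmetry measures are non-negative by definition")


def lateral_asymmetry(left: ShapeDescriptor, right: ShapeDescriptor) -> float:
    """Shape asymmetry Y_s = ‖λ̄_left − λ̄_right‖_Σ with Σii = i² (1-based)."""
    if left.l != right.l:
        raise ValueError(f"descriptor lengths differ: {left.l} vs {right.l}")
    if left.normalized != right.normalized:
        raise ValueError("descriptors differ in normalization; not comparable")
    diff = left.eigenvalues - right.eigenvalues
    i = np.arange(1, left.l + 1, dtype=float)
    return float(np.sqrt(np.sum((diff / i) ** 2)))


def volumetric_asymmetry(
    left_volume: float, right_volume: float, normalized: bool = False
) -> float:
    """Non-directional volume asymmetry: |L − R| mm³ (or |L−R|/(L+R) if normalized)."""
    if left_volume <= 0 or right_volume <= 0:
        raise ValueError("structure volumes must be positive")
    diff = abs(left_volume - right_volume)
    if normalized:
        return diff / (left_volume + right_volume)
    return diff


def records_to_frame(records: list[AsymmetryRecord]) -> pd.DataFrame:
    """Tidy table: one row per subject × structure, both measures + raw volumes."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "structure": r.structure,
                "shape_asymmetry": r.shape_asymmetry,
                "volumetric_asymmetry": r.volumetric_asymmetry,
                "left_volume": r.left_volume,
                "right_volume": r.right_volume,
            }
            for r in records
        ]
    )
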