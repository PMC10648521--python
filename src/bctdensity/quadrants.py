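"""Nipple localization and quadrant partition of the breast.

The four clinical quadrants — upper outer (UOQ), upper inner (UIQ), lower
outer (LOQ), lower inner (LIQ) — are separated by the two perpendicular
planes parallel to the image rows and columns that intersect the nipple.
The nipple is taken as the centre of mass of the skin voxels in the most
posterior (highest-index) skin-bearing slice, which in pendant prone
geometry is the nipple tip.

Tie rules (documented, affect at most one voxel sheet each): voxels exactly
on the row plane go to "upper", voxels on the column plane go to "outer".
The mapping of image columns to the anatomical outer/inner side depends on
laterality and on whether columns run patient-right to patient-left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import LabelMap, Tissue

UOQ, UIQ, LOQ, LIQ = 1, 2, 3, 4
QUADRANT_NAMES = {UOQ: "UOQ", UIQ: "UIQ", LOQ: "LOQ", LIQ: "LIQ"}
QUADRANT_CODES = {v: k for k, v in QUADRANT_NAMES.items()}


def outer_is_low_column(laterality: str, columns_run_right_to_left: bool = True) -> bool:
    """Whether the anatomical outer (lateral) side lies at low column index.

    For a right breast with columns running patient-right to patient-left the
    patient's right — the outer side — is at low column indices.
    """
    if laterality not in ("left", "right"):
        raise ValueError(f"laterality must be 'left' or 'right', got {laterality!r}")
    return (laterality == "right") == columns_run_right_to_left


def quadrant_codes_for(
    rows: np.ndarray,
    cols: np.ndarray,
    nipple_rc: tuple[float, float],
    laterality: str,
    columns_run_right_to_left: bool = True,
) -> np.ndarray:
    """Vectorized quadrant code (1-4) for row/column coordinates."""
    nip_r, nip_c = nipple_rc
    upper = rows <= nip_r
    low = outer_is_low_column(laterality, columns_run_right_to_left)
    outer = cols <= nip_c if low else cols >= nip_c
    codes = np.where(
        upper,
        np.where(outer, UOQ, UIQ),
        np.where(outer, LOQ, LIQ),
    )
    return codes.astype(np.uint8)


@dataclass
class QuadrantPartition:
    """Per-voxel quadrant assignment over the breast-tissue voxels.

    ``assignment`` is 0 outside breast tissue and 1-4 (UOQ/UIQ/LOQ/LIQ) on
    adipose and gland voxels.
    """

    nipple: tuple[int, int, int]
    assignment: np.ndarray
    laterality: str
    columns_run_right_to_left: bool = True

    def mask(self, quadrant: int | str) -> np.ndarray:
        code = QUADRANT_CODES[quadrant] if isinstance(quadrant, str) else int(quadrant)
        return self.assignment == code

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.assignment > 0


def locate_nipple(labels: LabelMap) -> tuple[int, int, int]:
    """Nipple voxel: centroid of skin in the most posterior skin-bearing slice.

    Raises ``ValueError`` when the label map carries no skin.
    """
    skin = labels.mask(Tissue.SKIN)
    slices_with_skin = np.flatnonzero(skin.any(axis=(1, 2)))
    if slices_with_skin.size == 0:
        raise ValueError("no skin voxels: cannot locate the nipple")
    z = int(slices_with_skin[-1])
    rr, cc = np.nonzero(skin[z])
    return (z, int(np.rint(rr.mean())), int(np.rint(cc.mean())))


def assign_quadrants(
    labels: LabelMap,
    nipple: tuple[int, int, int],
    laterality: str | None = None,
    columns_run_right_to_left: bool = True,
) -> QuadrantPartition:
    """Partition the breast-tissue voxels into the four quadrants.

    The two dividing planes are the row plane and the column plane through
    the nipple; every adipose/gland voxel receives exactly one quadrant.
    """
    laterality = laterality or labels.laterality
    tissue = labels.breast_tissue
    assignment = np.zeros(labels.shape, dtype=np.uint8)
    zz, rr, cc = np.nonzero(tissue)
    assignment[zz, rr, cc] = quadrant_codes_for(
        rr, cc, (nipple[1], nipple[2]), laterality, columns_run_right_to_left
    )
    return QuadrantPartition(
        nipple=tuple(int(v) for v in nipple),
        assignment=assignment,
        laterality=laterality,
        columns_run_right_to_left=columns_run_right_to_left,
    )
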