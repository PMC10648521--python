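"""Core in-memory containers for breast-CT grids.

Axis convention (fixed package-wide): axis 0 indexes slices running from the
chest wall (slice 0) toward the nipple (highest tissue-bearing slice, the
"most posterior" slice of a prone pendant-breast scan); axis 1 indexes image
rows (smaller row = upper breast); axis 2 indexes image columns. Columns run
patient-right to patient-left unless a volume says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class Tissue(IntEnum):
    """Integer label codes used in every label map this package writes."""

    AIR = 0
    ADIPOSE = 1
    GLAND = 2
    SKIN = 3
    PECTORALIS = 4
    RIB = 5
    SKINFOLD = 6


#: Tissue classes that count as breast tissue for BTV (adipose + gland).
BREAST_TISSUE = (Tissue.ADIPOSE, Tissue.GLAND)


@dataclass
class CTVolume:
    """A 3D CT volume in Hounsfield units with isotropic voxel spacing.

    Parameters
    ----------
    hu : ndarray
        3D array of HU values (finite).
    voxel_size : float
        Edge length of the cubic voxel in mm.
    laterality : str
        ``"left"`` or ``"right"`` breast.
    columns_run_right_to_left : bool
        Whether increasing column index moves from the patient's right side
        toward the left (the radiological default).
    """

    hu: np.ndarray
    voxel_size: float
    laterality: str = "right"
    columns_run_right_to_left: bool = True

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float32)
        if self.hu.ndim != 3:
            raise ValueError(f"HU grid must be 3D, got {self.hu.ndim}D")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU grid contains non-finite values")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.laterality not in ("left", "right"):
            raise ValueError(f"laterality must be 'left' or 'right', got {self.laterality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3 (mm^3 / 1000)."""
        return float(self.voxel_size) ** 3 / 1000.0


@dataclass
class LabelMap:
    """Per-voxel tissue classification aligned with a :class:`CTVolume`."""

    labels: np.ndarray
    voxel_size: float
    laterality: str = "right"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError(f"label grid must be 3D, got {self.labels.ndim}D")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.labels.max(initial=0) > max(Tissue):
            raise ValueError("label grid contains codes outside the Tissue enum")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, *tissues: Tissue) -> np.ndarray:
        """Boolean mask of voxels belonging to any of the given classes."""
        out = np.zeros(self.labels.shape, dtype=bool)
        for t in tissues:
            out |= self.labels == int(t)
        return out

    @property
    def breast_tissue(self) -> np.ndarray:
        """Mask of adipose + gland voxels (the BTV region)."""
        return self.mask(*BREAST_TISSUE)

    @property
    def voxel_volume_cm3(self) -> float:
        return float(self.voxel_size) ** 3 / 1000.0
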