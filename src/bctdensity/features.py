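"""Breast composition features: BTV, MGV and percent breast density.

BTV (breast tissue volume) sums the voxel volumes of adipose + gland; MGV
(mammary gland volume) those of gland alone. Percent breast density is
computed two ways, which differ under partial volume:

* ``pbd_hu`` (primary) — 100 × the mean per-voxel glandular fraction
  ``g = clamp((HU - mu_fat)/(mu_gland - mu_fat), 0, 1)`` over the region's
  tissue voxels, i.e. the HU-weighted glandular content;
* ``pbd_volumetric`` — 100 × MGV / BTV, the binary voxel-count ratio.

The two coincide exactly when every tissue voxel sits at one of the two
reference HU values. HU references default to the mean HU of the
morphologically eroded adipose and gland cores (2-voxel erosion), which
avoids partial-volume contamination without requiring scanner calibration
values; fixed references can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .quadrants import QUADRANT_NAMES, QuadrantPartition
from .volume import CTVolume, LabelMap, Tissue

REGIONS = ("whole", "UOQ", "UIQ", "LOQ", "LIQ")


@dataclass
class BreastComposition:
    """Composition of one breast, whole and per quadrant.

    ``shares`` are quadrant percentages of the whole-breast value; the PBD
    ratio is quadrant PBD as a percentage of whole-breast PBD. Shares of a
    zero whole-breast quantity are ``None`` (undefined, reported missing).
    """

    btv: dict = field(default_factory=dict)          # region -> cm^3
    mgv: dict = field(default_factory=dict)          # region -> cm^3
    pbd_hu: dict = field(default_factory=dict)       # region -> %
    pbd_volumetric: dict = field(default_factory=dict)
    share_btv: dict = field(default_factory=dict)    # quadrant -> % or None
    share_mgv: dict = field(default_factory=dict)
    pbd_ratio: dict = field(default_factory=dict)
    mu_fat: float | None = None
    mu_gland: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per region."""
        rows = []
        for region in REGIONS:
            rows.append(
                {
                    "region": region,
                    "btv_cm3": self.btv[region],
                    "mgv_cm3": self.mgv[region],
                    "pbd_hu_pct": self.pbd_hu[region],
                    "pbd_vol_pct": self.pbd_volumetric[region],
                    "share_btv_pct": self.share_btv.get(region),
                    "share_mgv_pct": self.share_mgv.get(region),
                    "pbd_ratio_pct": self.pbd_ratio.get(region),
                }
            )
        return pd.DataFrame(rows)


def _region_masks(labels: LabelMap, partition: QuadrantPartition) -> dict:
    if labels.shape != partition.assignment.shape:
        raise ValueError("label map and partition shapes differ")
    tissue = labels.breast_tissue
    masks = {"whole": tissue}
    for code, name in QUADRANT_NAMES.items():
        masks[name] = tissue & (partition.assignment == code)
    return masks


def compute_volumes(labels: LabelMap, partition: QuadrantPartition) -> dict:
    """BTV and MGV (cm^3) per region: voxel count × voxel volume."""
    masks = _region_masks(labels, partition)
    gland = labels.mask(Tissue.GLAND)
    vv = labels.voxel_volume_cm3
    return {
        region: {
            "btv": float(m.sum()) * vv,
            "mgv": float((m & gland).sum()) * vv,
        }
        for region, m in masks.items()
    }


def estimate_hu_references(
    volume: CTVolume, labels: LabelMap, erosion_voxels: int = 2
) -> tuple[float | None, float | None]:
    """Mean HU of the eroded adipose and gland cores.

    Falls back to the un-eroded class mean when erosion empties a class;
    returns ``None`` for an absent class.
    """

    def core_mean(mask: np.ndarray) -> float | None:
        if not mask.any():
            return None
        eroded = ndi.binary_erosion(mask, iterations=erosion_voxels)
        use = eroded if eroded.any() else mask
        return float(volume.hu[use].mean())

    return core_mean(labels.mask(Tissue.ADIPOSE)), core_mean(labels.mask(Tissue.GLAND))


def compute_pbd(
    volume: CTVolume,
    labels: LabelMap,
    partition: QuadrantPartition,
    mu_fat: float | None = None,
    mu_gland: float | None = None,
) -> dict:
    """HU-fraction and volumetric PBD (%) per region.

    References default to the eroded-core estimates. Explicit references
    with ``mu_gland <= mu_fat`` raise ``ValueError``.
    """
    if volume.shape != labels.shape:
        raise ValueError("volume and label map shapes differ")
    if mu_fat is None or mu_gland is None:
        est_fat, est_gland = estimate_hu_references(volume, labels)
        mu_fat = mu_fat if mu_fat is not None else est_fat
        mu_gland = mu_gland if mu_gland is not None else est_gland
    masks = _region_masks(labels, partition)
    gland = labels.mask(Tissue.GLAND)
    out = {}
    no_gland_refs = mu_gland is None or mu_fat is None
    if not no_gland_refs and not mu_gland > mu_fat:
        raise ValueError(
            f"degenerate HU references: mu_gland ({mu_gland}) must exceed mu_fat ({mu_fat})"
        )
    for region, m in masks.items():
        n = int(m.sum())
        if n == 0:
            out[region] = {"pbd_hu": 0.0, "pbd_volumetric": 0.0, "mu_fat": mu_fat, "mu_gland": mu_gland}
            continue
        pbd_vol = 100.0 * float((m & gland).sum()) / n
        if no_gland_refs:
            pbd_hu = 0.0  # no gland class present: density zero by definition
        else:
            g = np.clip((volume.hu[m] - mu_fat) / (mu_gland - mu_fat), 0.0, 1.0)
            pbd_hu = 100.0 * float(g.mean())
        out[region] = {
            "pbd_hu": pbd_hu,
            "pbd_volumetric": pbd_vol,
            "mu_fat": mu_fat,
            "mu_gland": mu_gland,
        }
    return out


def compose_features(
    volume: CTVolume,
    labels: LabelMap,
    partition: QuadrantPartition,
    mu_fat: float | None = None,
    mu_gland: float | None = None,
) -> BreastComposition:
    """Assemble volumes, densities and quadrant shares for one breast."""
    vols = compute_volumes(labels, partition)
    dens = compute_pbd(volume, labels, partition, mu_fat, mu_gland)
    comp = BreastComposition(
        mu_fat=dens["whole"]["mu_fat"], mu_gland=dens["whole"]["mu_gland"]
    )
    for region in REGIONS:
        comp.btv[region] = vols[region]["btv"]
        comp.mgv[region] = vols[region]["mgv"]
        comp.pbd_hu[region] = dens[region]["pbd_hu"]
        comp.pbd_volumetric[region] = dens[region]["pbd_volumetric"]
    whole_btv, whole_mgv = comp.btv["whole"], comp.mgv["whole"]
    whole_pbd = comp.pbd_hu["whole"]
    for q in QUADRANT_NAMES.values():
        comp.share_btv[q] = 100.0 * comp.btv[q] / whole_btv if whole_btv > 0 else None
        comp.share_mgv[q] = 100.0 * comp.mgv[q] / whole_mgv if whole_mgv > 0 else None
        comp.pbd_ratio[q] = 100.0 * comp.pbd_hu[q] / whole_pbd if whole_pbd > 0 else None
    return comp
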