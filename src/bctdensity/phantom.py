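"""Synthetic pendant-breast CT phantoms and tabular cohort simulation.

The image phantom emulates a prone-position breast CT acquisition at
isotropic ~(300 µm)^3 voxels: a half-ellipsoid breast of adipose tissue
hangs from a pectoral (chest-wall) slab at slice 0, wrapped in a skin shell
with a protruding nipple at the most posterior slice; glandular tissue is a
union of random ellipsoidal inclusions placed with configurable quadrant
weighting; optional ribs sit inside the chest slab and an optional skin-fold
flap of tissue hangs from the chest wall beside the breast. Every geometric
primitive carries an anti-aliased sub-voxel inside-fraction, so boundary
voxels receive partial-volume HU and the ground-truth glandular fraction —
hence the true percent breast density — is well defined per voxel.
Gaussian HU noise is added last. The same seed gives bit-identical output.

The cohort simulator draws integer patient ages and generates BTV/MGV/PBD
from configurable mean curves (by default the published age-regression
models: BTV = 290 ln(age) − 554 cm^3, MGV = 4885/age − 26 cm^3,
PBD = 1237/age − 8.4 %) plus independent Gaussian noise, truncated to the
physical ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .quadrants import QUADRANT_NAMES, quadrant_codes_for
from .reference import AGE_BINS, PUBLISHED_MODELS
from .volume import CTVolume, LabelMap, Tissue


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Geometry, composition and imaging parameters of one phantom.

    Lengths in mm; the grid is ``slices × rows × columns`` with slice 0 at
    the chest wall. HU reference means default to literature-typical CT
    values (fat −100, gland +40, skin +30, muscle +45, rib +700, air −1000).
    The default geometry is a scaled-down pendant breast that fits a
    ~6 cm field of view; ``gland_volume_target`` of 8 cm^3 inside a ~54 cm^3
    breast gives a phantom PBD around 15%, matching screening-cohort
    averages.
    """

    grid_shape: tuple[int, int, int] = (192, 200, 200)
    voxel_size: float = 0.3
    breast_semiaxes: tuple[float, float, float] = (45.0, 24.0, 24.0)
    skin_thickness: float = 1.5
    n_gland_components: int = 12
    gland_volume_target: float = 8.0
    # published quadrant MGV shares 34/21/26/18 (%), normalized (they print
    # to 99 from rounding)
    quadrant_weights: tuple[float, float, float, float] = (34 / 99, 21 / 99, 26 / 99, 18 / 99)
    pectoral_slab_depth: int = 16
    include_ribs: bool = True
    include_skinfold: bool = True
    nipple_radius: float = 4.0
    hu_fat: float = -100.0
    hu_gland: float = 40.0
    hu_skin: float = 30.0
    hu_muscle: float = 45.0
    hu_rib: float = 700.0
    hu_air: float = -1000.0
    noise_sd: float = 15.0
    seed: int = 0
    laterality: str = "right"

    def validate(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.skin_thickness < self.voxel_size:
            raise ValueError("skin_thickness must be at least one voxel")
        w = np.asarray(self.quadrant_weights, dtype=float)
        if w.size != 4 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("quadrant_weights must be 4 non-negative values summing to 1")
        if not (self.hu_air < self.hu_fat < self.hu_gland):
            raise ValueError("HU ordering must satisfy air < fat < gland")
        nz, nr, nc = self.grid_shape
        if min(nz, nr, nc) < 16:
            raise ValueError(f"degenerate grid {self.grid_shape}: each axis needs >= 16 voxels")
        a, b, c = self.breast_semiaxes
        if min(a, b, c) <= 0:
            raise ValueError("breast_semiaxes must be positive")
        vs = self.voxel_size
        need_z = self.pectoral_slab_depth + (a + self.nipple_radius) / vs + 2
        if need_z > nz:
            raise ValueError(
                f"grid too small along slices: need {need_z:.0f} voxels for slab + breast + nipple, have {nz}"
            )
        if 2 * b / vs + 4 > nr or 2 * c / vs + 4 > nc:
            raise ValueError("grid too small in rows/columns to contain the breast")
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying a generated phantom.

    Volumes in cm^3, PBD in percent. ``gland_fraction`` is the per-voxel
    true glandular fraction (0-1, non-zero only inside the breast interior);
    ``pbd_true`` is its mean over breast-interior voxels × 100, which with
    linear HU mixing coincides with the HU-fraction density of the noiseless
    phantom.
    """

    label_map: LabelMap
    btv_true: float
    mgv_true: float
    pbd_true: float
    per_quadrant: dict
    nipple_true: tuple[int, int, int]
    gland_fraction: np.ndarray | None = None

    def sidecar_dict(self) -> dict:
        return {
            "btv_true": self.btv_true,
            "mgv_true": self.mgv_true,
            "pbd_true": self.pbd_true,
            "per_quadrant": self.per_quadrant,
            "nipple_true": list(self.nipple_true),
        }


@dataclass
class CohortSimSpec:
    """Parameters of the tabular cohort simulator.

    ``bin_counts`` (optional, seven entries aligned with the 40-44 ... 70-74
    bins) pins the number of patients per five-year age bin; otherwise
    ``n_patients`` integer ages are drawn uniformly over ``age_range``.
    Noise SDs default to the published model RSEs (386 / 67 cm^3, 13%).
    """

    n_patients: int = 1033
    age_range: tuple[int, int] = (40, 74)
    bin_counts: tuple[int, ...] | None = None
    model_coefficients: dict = field(
        default_factory=lambda: {
            k: (v["family"], v["a"], v["b"]) for k, v in PUBLISHED_MODELS.items()
        }
    )
    noise_sd_btv: float = 386.0
    noise_sd_mgv: float = 67.0
    noise_sd_pbd: float = 13.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.age_range
        if not (0 < lo <= hi):
            raise ValueError("invalid age_range")
        if self.bin_counts is not None:
            if len(self.bin_counts) != len(AGE_BINS) or any(c < 0 for c in self.bin_counts):
                raise ValueError("bin_counts needs one non-negative count per five-year bin")
        elif self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if min(self.noise_sd_btv, self.noise_sd_mgv, self.noise_sd_pbd) < 0:
            raise ValueError("noise SDs must be non-negative")
        for feat, (family, _a, _b) in self.model_coefficients.items():
            if family not in ("log", "inverse"):
                raise ValueError(f"unknown family {family!r} for {feat}")


# --------------------------------------------------------------------------
# geometric primitives with sub-voxel fractions
# --------------------------------------------------------------------------


def _ellipsoid_fraction(shape, center, semiaxes, supersample: int = 4):
    """Anti-aliased inside-fraction of an axis-aligned ellipsoid.

    ``center``/``semiaxes`` are in voxel-index units. Returns
    ``(bbox_slices, frac)`` where ``frac`` covers only the bounding box;
    interior/exterior voxels are resolved analytically and only voxels in a
    thin band around the surface are super-sampled (``supersample``^3
    deterministic sub-voxel points).
    """
    center = np.asarray(center, dtype=float)
    semi = np.asarray(semiaxes, dtype=float)
    lo = np.maximum(0, np.floor(center - semi - 1).astype(int))
    hi = np.minimum(shape, np.ceil(center + semi + 2).astype(int))
    if np.any(lo >= hi):
        return tuple(slice(a, a) for a in lo), np.zeros((0, 0, 0), dtype=np.float32)
    ax = [np.arange(lo[i], hi[i], dtype=float) - center[i] for i in range(3)]
    rho2 = (
        (ax[0][:, None, None] / semi[0]) ** 2
        + (ax[1][None, :, None] / semi[1]) ** 2
        + (ax[2][None, None, :] / semi[2]) ** 2
    )
    rho = np.sqrt(rho2)
    frac = (rho <= 1.0).astype(np.float32)
    # Surface band half-width: a voxel's half-diagonal mapped through the
    # steepest normalized gradient (1/min semiaxis), padded for safety.
    margin = min(0.95, 1.8 / float(semi.min()))
    band = np.abs(rho - 1.0) <= margin
    if band.any():
        pts = np.argwhere(band).astype(float) + lo  # absolute voxel indices
        offs = (np.arange(supersample) + 0.5) / supersample - 0.5
        acc = np.zeros(len(pts))
        for dz in offs:
            for dr in offs:
                for dc in offs:
                    q = (
                        ((pts[:, 0] + dz - center[0]) / semi[0]) ** 2
                        + ((pts[:, 1] + dr - center[1]) / semi[1]) ** 2
                        + ((pts[:, 2] + dc - center[2]) / semi[2]) ** 2
                    )
                    acc += q <= 1.0
        frac[band] = (acc / supersample**3).astype(np.float32)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi)), frac


def _paint_max(target: np.ndarray, bbox, frac: np.ndarray) -> None:
    if frac.size:
        np.maximum(target[bbox], frac, out=target[bbox])


def _paint_union(target: np.ndarray, bbox, frac: np.ndarray) -> None:
    """Probabilistic union accumulate: t <- 1 - (1-t)(1-f)."""
    if frac.size:
        sub = target[bbox]
        sub += frac - sub * frac


# --------------------------------------------------------------------------
# phantom generation
# --------------------------------------------------------------------------


def _gland_union(shape, components, interior_mask) -> np.ndarray:
    g = np.zeros(shape, dtype=np.float32)
    for center, semi in components:
        bbox, frac = _ellipsoid_fraction(shape, center, semi)
        _paint_union(g, bbox, frac)
    g[~interior_mask] = 0.0
    return g


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Generate one pendant-breast CT phantom with exact ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nz, nr, nc = spec.grid_shape
    vs = spec.voxel_size
    voxvol_cm3 = vs**3 / 1000.0
    d = int(spec.pectoral_slab_depth)
    a, b, c = (s / vs for s in spec.breast_semiaxes)  # semiaxes in voxels
    r_c, c_c = (nr - 1) / 2.0, (nc - 1) / 2.0
    rn = spec.nipple_radius / vs

    # --- body occupancy (fractional union of tissue primitives) ----------
    body_frac = np.zeros(spec.grid_shape, dtype=np.float32)
    body_frac[:d] = 1.0  # pectoral slab, crisp faces on voxel planes
    bbox, frac = _ellipsoid_fraction(spec.grid_shape, (d, r_c, c_c), (a, b, c))
    _paint_max(body_frac, bbox, frac)
    tip_z = d + a
    bbox, frac = _ellipsoid_fraction(spec.grid_shape, (tip_z, r_c, c_c), (rn, rn, rn))
    _paint_max(body_frac, bbox, frac)

    fold_frac = np.zeros(spec.grid_shape, dtype=np.float32)
    if spec.include_skinfold:
        # Tissue flap attached to the chest wall, placed along the row/col
        # diagonal outside the breast surface with an air gap so it stays a
        # separate tissue component.
        r_diag = 1.0 / np.sqrt((0.5 / b**2) + (0.5 / c**2))  # breast radius on diagonal
        gap = 2.0 / vs  # air clearance, mm -> voxels
        # largest fold radius that fits between breast surface and grid edge
        fr_max = (min(r_c, c_c) - 2.0 - (r_diag + gap) / np.sqrt(2.0)) / (1.0 + 1.0 / np.sqrt(2.0))
        fr = min(6.0 / vs, fr_max)
        if fr < 1.0 / vs:
            raise ValueError(
                "grid too small to place a skin-fold clear of the breast; "
                "enlarge the grid or set include_skinfold=False"
            )
        t = (r_diag + gap + fr) / np.sqrt(2.0)
        fold_center = (d + 1.0, r_c - t, c_c - t)
        bbox, frac = _ellipsoid_fraction(spec.grid_shape, fold_center, (2.5 / vs, fr, fr))
        _paint_max(fold_frac, bbox, frac)
        _paint_max(body_frac, bbox, frac)

    rib_frac = np.zeros(spec.grid_shape, dtype=np.float32)
    if spec.include_ribs:
        rib_r = max(2.0, min(2.5 / vs, d / 2.0 - 2.0))
        for row_off in (-0.22 * nr, 0.22 * nr):
            center = (d / 2.0, r_c + row_off)
            col0, col1 = int(0.1 * nc), int(0.9 * nc)
            zz = np.arange(nz, dtype=float)
            rr = np.arange(nr, dtype=float)
            rho = np.sqrt(
                ((zz[:, None] - center[0]) / rib_r) ** 2
                + ((rr[None, :] - center[1]) / rib_r) ** 2
            )
            prof = np.clip((1.0 - rho) * rib_r + 0.5, 0.0, 1.0).astype(np.float32)
            rib_frac[:, :, col0:col1] = np.maximum(
                rib_frac[:, :, col0:col1], prof[:, :, None]
            )
        rib_frac[d:] = 0.0  # ribs are confined to the chest slab

    # --- truth regions ----------------------------------------------------
    body = body_frac >= 0.5
    dist_to_air = ndi.distance_transform_edt(body, sampling=vs)
    skin = body & (dist_to_air <= spec.skin_thickness)
    interior = body & ~skin
    zgrid = np.arange(nz)[:, None, None]
    pect = interior & (zgrid < d)
    rib = (rib_frac >= 0.5) & pect
    pect &= ~rib
    fold = interior & (fold_frac >= 0.5) & (zgrid >= d)
    breast_interior = interior & (zgrid >= d) & ~fold

    # --- glandular inclusions --------------------------------------------
    components: list[tuple[np.ndarray, np.ndarray]] = []
    gland = np.zeros(spec.grid_shape, dtype=np.float32)
    if spec.n_gland_components > 0 and spec.gland_volume_target > 0:
        interior_vol = breast_interior.sum() * voxvol_cm3
        if spec.gland_volume_target > 0.45 * interior_vol:
            raise ValueError(
                f"gland_volume_target {spec.gland_volume_target} cm^3 exceeds the "
                f"capacity of the breast interior ({interior_vol:.1f} cm^3)"
            )
        dist_in = ndi.distance_transform_edt(breast_interior, sampling=vs)
        zz, rr, cc = np.nonzero(breast_interior)
        qcodes = quadrant_codes_for(rr, cc, (r_c, c_c), spec.laterality)
        weights = np.asarray(spec.quadrant_weights, dtype=float)
        # Deterministic volume budget per quadrant (weights control volume,
        # not just placement counts), split over whole components; centers
        # are rejection-sampled inside the quadrant's interior.
        n_q = np.maximum((weights > 0).astype(int), np.rint(weights * spec.n_gland_components).astype(int))
        while n_q.sum() > spec.n_gland_components and n_q.max() > 1:
            n_q[n_q.argmax()] -= 1
        while n_q.sum() < spec.n_gland_components:
            n_q[(weights / np.maximum(n_q, 1)).argmax()] += 1
        for q0 in range(4):
            if weights[q0] == 0 or n_q[q0] == 0:
                continue
            v_each = spec.gland_volume_target * weights[q0] / n_q[q0]
            r_geo = (3.0 * v_each * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
            for _ in range(int(n_q[q0])):
                ratios = rng.uniform(0.7, 1.4, size=3)
                semi_mm = r_geo * ratios / np.prod(ratios) ** (1.0 / 3.0)
                clearance = semi_mm.max() + 2.0 * vs
                semi_vox = semi_mm / vs
                deep = dist_in[zz, rr, cc] >= clearance
                # keep the component clear of the dividing planes so its
                # volume stays inside its assigned quadrant
                off_planes = (np.abs(rr - r_c) >= semi_vox[1] + 1) & (
                    np.abs(cc - c_c) >= semi_vox[2] + 1
                )
                ok = (qcodes == q0 + 1) & deep & off_planes
                if not ok.any():
                    ok = (qcodes == q0 + 1) & deep
                if not ok.any():
                    ok = deep
                if not ok.any():
                    raise ValueError(
                        "breast interior too small to host a gland component of "
                        f"radius {semi_mm.max():.1f} mm"
                    )
                cand = np.flatnonzero(ok)
                # keep components apart to limit overlap (relaxed gradually
                # when the quadrant gets crowded)
                center = None
                for sep_factor in (0.9, 0.6, 0.3, 0.0):
                    for _try in range(40):
                        k = rng.choice(cand)
                        pt = np.array([zz[k], rr[k], cc[k]], dtype=float)
                        if all(
                            np.linalg.norm(pt - ctr)
                            >= sep_factor * (semi_mm.max() / vs + prev.max())
                            for ctr, prev in components
                        ):
                            center = pt
                            break
                    if center is not None:
                        break
                components.append([center, semi_mm / vs])

        # Rescale all components together until the true (fractional) gland
        # volume lands within 5% of the target.
        scale = 1.0
        for _ in range(8):
            scaled = [(ctr, semi * scale) for ctr, semi in components]
            gland = _gland_union(spec.grid_shape, scaled, breast_interior)
            vol = float(gland.sum()) * voxvol_cm3
            if abs(vol - spec.gland_volume_target) <= 0.05 * spec.gland_volume_target:
                break
            scale *= (spec.gland_volume_target / vol) ** (1.0 / 3.0)
        else:
            raise ValueError("could not rescale gland components to the volume target")
        components = [(ctr, semi * scale) for ctr, semi in components]

    # --- HU synthesis ------------------------------------------------------
    tissue_hu = np.full(spec.grid_shape, spec.hu_fat, dtype=np.float32)
    tissue_hu[:d] = spec.hu_muscle
    if spec.include_ribs:
        slab = slice(0, d)
        tissue_hu[slab] = (
            spec.hu_muscle * (1.0 - rib_frac[slab]) + spec.hu_rib * rib_frac[slab]
        )
    gm = gland > 0
    tissue_hu[gm] = spec.hu_fat + (spec.hu_gland - spec.hu_fat) * gland[gm]
    tissue_hu[skin] = spec.hu_skin
    hu = spec.hu_air + body_frac * (tissue_hu - spec.hu_air)
    if spec.noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape).astype(np.float32)

    # --- labels and truth quantities ---------------------------------------
    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[breast_interior] = Tissue.ADIPOSE
    labels[breast_interior & (gland >= 0.5)] = Tissue.GLAND
    labels[skin] = Tissue.SKIN
    labels[pect] = Tissue.PECTORALIS
    labels[rib] = Tissue.RIB
    labels[fold] = Tissue.SKINFOLD

    slices_with_skin = np.flatnonzero(skin.any(axis=(1, 2)))
    z_nip = int(slices_with_skin[-1])
    rr_n, cc_n = np.nonzero(skin[z_nip])
    nipple_true = (z_nip, int(np.rint(rr_n.mean())), int(np.rint(cc_n.mean())))

    btv_true = float(breast_interior.sum()) * voxvol_cm3
    mgv_true = float(gland.sum()) * voxvol_cm3
    pbd_true = 100.0 * mgv_true / btv_true if btv_true > 0 else 0.0

    zz, rr, cc = np.nonzero(breast_interior)
    qcodes = quadrant_codes_for(
        rr, cc, (nipple_true[1], nipple_true[2]), spec.laterality
    )
    gvals = gland[zz, rr, cc]
    per_quadrant = {}
    for code, name in QUADRANT_NAMES.items():
        sel = qcodes == code
        q_btv = float(sel.sum()) * voxvol_cm3
        q_mgv = float(gvals[sel].sum()) * voxvol_cm3
        per_quadrant[name] = {
            "btv": q_btv,
            "mgv": q_mgv,
            "pbd": 100.0 * q_mgv / q_btv if q_btv > 0 else 0.0,
        }

    volume = CTVolume(hu=hu, voxel_size=vs, laterality=spec.laterality)
    truth = PhantomTruth(
        label_map=LabelMap(labels=labels, voxel_size=vs, laterality=spec.laterality),
        btv_true=btv_true,
        mgv_true=mgv_true,
        pbd_true=pbd_true,
        per_quadrant=per_quadrant,
        nipple_true=nipple_true,
        gland_fraction=gland,
    )
    return volume, truth


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Simulate a tabular cohort of (age, BTV, MGV, PBD) records.

    Mean values follow the configured age curves at each patient's integer
    age; independent Gaussian noise is added per feature and the results are
    truncated to the physical ranges (volumes >= 0, MGV <= BTV,
    0 <= PBD <= 100).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.bin_counts is not None:
        ages = np.concatenate(
            [
                rng.integers(lo, hi + 1, size=n)
                for (lo, hi), n in zip(AGE_BINS, spec.bin_counts)
            ]
        )
    else:
        lo, hi = spec.age_range
        ages = rng.integers(lo, hi + 1, size=spec.n_patients)
    ages = ages.astype(int)

    def curve(feature: str) -> np.ndarray:
        family, a_, b_ = spec.model_coefficients[feature]
        x = np.log(ages) if family == "log" else 1.0 / ages
        return a_ * x + b_

    btv = curve("btv") + rng.normal(0.0, spec.noise_sd_btv, size=ages.size)
    mgv = curve("mgv") + rng.normal(0.0, spec.noise_sd_mgv, size=ages.size)
    pbd = curve("pbd") + rng.normal(0.0, spec.noise_sd_pbd, size=ages.size)
    btv = np.clip(btv, 0.0, None)
    mgv = np.clip(mgv, 0.0, btv)
    pbd = np.clip(pbd, 0.0, 100.0)
    return pd.DataFrame(
        {
            "patient_id": np.arange(ages.size),
            "age": ages,
            "btv": btv,
            "mgv": mgv,
            "pbd": pbd,
        }
    )


# --------------------------------------------------------------------------
# file output
# --------------------------------------------------------------------------


def write_phantom(volume: CTVolume, truth: PhantomTruth, out_dir) -> dict:
    """Write HU volume + label map as NIfTI and the truth as a JSON sidecar.

    Returns the paths written (keys: hu, labels, truth).
    """
    from . import fileio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "hu": out / "hu.nii.gz",
        "labels": out / "labels.nii.gz",
        "truth": out / "truth.json",
    }
    fileio.write_volume(volume, paths["hu"])
    fileio.write_labels(truth.label_map, paths["labels"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.sidecar_dict(), fh, indent=2)
    return paths


def read_truth_sidecar(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def spec_from_dict(d: dict) -> PhantomSpec:
    """Build a PhantomSpec from a plain mapping (e.g. parsed YAML)."""
    kwargs = dict(d)
    for key in ("grid_shape", "breast_semiaxes", "quadrant_weights"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return PhantomSpec(**kwargs)
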