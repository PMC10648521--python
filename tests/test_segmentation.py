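import numpy as np
import pytest

from bctdensity.phantom import generate_phantom
from bctdensity.segmentation import (
    SegmentationError,
    SegmentationParams,
    body_mask,
    segment_all,
    segment_chest_structures,
    segment_gland,
    segment_skin,
)
from bctdensity.volume import CTVolume, Tissue

from conftest import dice, flat_volume, tiny_spec
from oracles import grow_region_bruteforce


class TestBodyMask:
    def test_all_air_fails(self):
        with pytest.raises(SegmentationError, match="no tissue"):
            body_mask(flat_volume((20, 20, 20), -1000.0))

    def test_volume_close_to_truth_and_connected(self, medium_phantom, medium_segmentation):
        _, volume, truth = medium_phantom
        mask = body_mask(volume)
        truth_body = truth.label_map.labels != Tissue.AIR
        assert mask.sum() == pytest.approx(truth_body.sum(), rel=0.01)
        from scipy import ndimage as ndi

        _, n = ndi.label(mask, structure=np.ones((3, 3, 3), bool))
        assert n == 1


class TestSkin:
    def test_skin_dice_against_truth(self, medium_phantom, medium_segmentation):
        _, _, truth = medium_phantom
        seg_skin = medium_segmentation.label_map.mask(Tissue.SKIN)
        true_skin = truth.label_map.mask(Tissue.SKIN)
        assert dice(seg_skin, true_skin) >= 0.85

    def test_zero_thickness_gives_empty_skin(self, medium_phantom):
        _, volume, _ = medium_phantom
        body = body_mask(volume)
        skin, interior = segment_skin(
            volume, body, SegmentationParams(skin_thickness=0.0)
        )
        assert not skin.any()
        assert np.array_equal(interior, body)

    def test_excessive_thickness_fails(self, medium_phantom):
        _, volume, _ = medium_phantom
        body = body_mask(volume)
        with pytest.raises(SegmentationError, match="interior"):
            segment_skin(volume, body, SegmentationParams(skin_thickness=100.0))

    def test_last_tissue_slice_contains_skin(self, medium_segmentation):
        labels = medium_segmentation.label_map.labels
        tissue_slices = np.flatnonzero((labels != Tissue.AIR).any(axis=(1, 2)))
        last = tissue_slices[-1]
        assert (labels[last] == Tissue.SKIN).any()


class TestChestStructures:
    def test_absent_ribs_give_empty_mask(self):
        volume, _ = generate_phantom(tiny_spec(include_ribs=False))
        body = body_mask(volume)
        _, interior = segment_skin(volume, body)
        _, ribs, _ = segment_chest_structures(volume, interior)
        assert not ribs.any()

    def test_pectoralis_recovery(self, medium_phantom, medium_segmentation):
        _, _, truth = medium_phantom
        true_pect = truth.label_map.mask(Tissue.PECTORALIS)
        seg_pect = medium_segmentation.label_map.mask(Tissue.PECTORALIS)
        assert (true_pect & seg_pect).sum() / true_pect.sum() >= 0.90

    def test_skinfold_detected(self, medium_phantom, medium_segmentation):
        _, _, truth = medium_phantom
        true_fold = truth.label_map.mask(Tissue.SKINFOLD)
        seg_fold = medium_segmentation.label_map.mask(Tissue.SKINFOLD)
        assert true_fold.any()
        assert (true_fold & seg_fold).sum() / true_fold.sum() >= 0.5

    def test_no_rib_hu_left_in_breast(self, medium_phantom, medium_segmentation):
        _, volume, _ = medium_phantom
        params = SegmentationParams()
        nz = volume.shape[0]
        gate = np.zeros(volume.shape, bool)
        gate[: int(np.ceil(params.chest_extent * nz))] = True
        breast = medium_segmentation.label_map.breast_tissue
        assert not (breast & gate & (volume.hu >= params.rib_threshold)).any()


def _volume_from_fraction(g, hu_fat=-100.0, hu_gland=40.0):
    return CTVolume(hu=hu_fat + (hu_gland - hu_fat) * g, voxel_size=0.3)


def _random_bimodal_fraction(shape, rng):
    """Mostly two-mode field (fat/gland) with some partial-volume voxels."""
    g = np.zeros(shape, dtype=np.float32)
    kind = rng.uniform(size=shape)
    g[kind > 0.75] = 1.0
    mid = (kind > 0.6) & (kind <= 0.75)
    g[mid] = rng.uniform(0.1, 0.9, size=int(mid.sum())).astype(np.float32)
    return g


class TestGlandGrowing:
    def test_pure_fat_interior_is_unimodal(self):
        volume = flat_volume((24, 24, 24), -100.0)
        interior = np.zeros(volume.shape, bool)
        interior[4:20, 4:20, 4:20] = True
        with pytest.warns(UserWarning, match="unimodal"):
            result = segment_gland(volume, interior)
        assert result.unimodal
        assert not result.gland.any()
        assert np.array_equal(result.adipose, interior)

    def test_noiseless_gland_dice(self, medium_phantom, medium_segmentation):
        _, _, truth = medium_phantom
        true_gland = truth.label_map.mask(Tissue.GLAND)
        seg_gland = medium_segmentation.label_map.mask(Tissue.GLAND)
        assert dice(seg_gland, true_gland) >= 0.95

    def test_matches_threshold_component_oracle(self, medium_phantom, medium_segmentation):
        """On a noiseless two-tissue breast the adaptive rule reduces to
        thresholding at floor_fraction restricted to seeded components."""
        from scipy import ndimage as ndi

        _, volume, _ = medium_phantom
        res = medium_segmentation
        params = SegmentationParams()
        interior = res.label_map.breast_tissue
        g = np.where(
            interior,
            np.clip((volume.hu - res.mu_fat) / (res.mu_gland - res.mu_fat), 0, 1),
            0.0,
        )
        above = interior & (g >= params.floor_fraction)
        lab, _ = ndi.label(above, structure=np.ones((3, 3, 3), bool))
        seed_ids = np.unique(lab[interior & (g >= params.seed_fraction)])
        oracle = np.isin(lab, seed_ids[seed_ids > 0])
        assert np.array_equal(res.label_map.mask(Tissue.GLAND), oracle)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle_on_small_grids(self, seed):
        """Vectorized growing equals the set-based sweep oracle exactly."""
        rng = np.random.default_rng(seed)
        shape = (14, 14, 14)
        g = _random_bimodal_fraction(shape, rng)
        interior = np.ones(shape, bool)
        interior[0] = interior[-1] = False
        volume = _volume_from_fraction(g)
        params = SegmentationParams()
        result = segment_gland(volume, interior, params)
        assert result.mu_fat == pytest.approx(-100.0)
        assert result.mu_gland == pytest.approx(40.0)
        region, trace = grow_region_bruteforce(
            g,
            interior,
            params.seed_fraction,
            params.floor_fraction,
            params.alpha,
            params.convergence_tol,
            params.max_iterations,
        )
        expected = np.zeros(shape, bool)
        for p in region:
            expected[p] = True
        assert np.array_equal(result.gland, expected)
        assert np.allclose(result.density_trace, trace, atol=1e-12)

    def test_floor_monotonicity(self, medium_phantom):
        """Raising the acceptance floor never grows the gland region."""
        _, volume, _ = medium_phantom
        counts = []
        for floor in (0.15, 0.25, 0.35, 0.45):
            res = segment_all(volume, SegmentationParams(floor_fraction=floor))
            counts.append(int(res.label_map.mask(Tissue.GLAND).sum()))
        assert counts == sorted(counts, reverse=True)

    def test_density_trace_converges(self, medium_segmentation):
        trace = medium_segmentation.density_trace
        assert 0 < len(trace) <= SegmentationParams().max_iterations + 1
        tail = np.diff(trace[2:])
        # after the initial sweeps the running density changes monotonically
        assert (tail <= 1e-12).all() or (tail >= -1e-12).all()


class TestSegmentAll:
    def test_labels_partition_grid(self, medium_segmentation):
        labels = medium_segmentation.label_map.labels
        counts = np.bincount(labels.ravel(), minlength=7)
        assert counts.sum() == labels.size

    def test_gland_within_interior_and_disjoint_from_skin(self, medium_segmentation):
        lm = medium_segmentation.label_map
        assert not (lm.mask(Tissue.GLAND) & lm.mask(Tissue.SKIN)).any()

    def test_label_volumes_within_10pct(self, medium_phantom, medium_segmentation):
        _, _, truth = medium_phantom
        for tissue in (Tissue.ADIPOSE, Tissue.GLAND):
            t = truth.label_map.mask(tissue).sum()
            s = medium_segmentation.label_map.mask(tissue).sum()
            assert s == pytest.approx(t, rel=0.10)

    def test_deterministic(self, medium_phantom, medium_segmentation):
        _, volume, _ = medium_phantom
        again = segment_all(volume)
        assert np.array_equal(
            again.label_map.labels, medium_segmentation.label_map.labels
        )
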