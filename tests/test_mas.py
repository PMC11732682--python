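import numpy as np
import pytest

from morphcascade.mas import (AtlasSet, FusionConfig, local_weighted_vote,
                              majority_vote, rank_atlases, register_atlases,
                              segment)
from morphcascade.network import BackboneConfig, CascadeConfig, CascadeModel
from morphcascade.phantom import PhantomSpec, make_cohort
from morphcascade.volume_io import LabelMap, Volume

TINY = BackboneConfig(enc_channels=(4, 8, 8), dec_channels=(8, 4))


def identity_model(size=32):
    """Untrained model: zero-initialized emission => identity registration."""
    return CascadeModel(CascadeConfig(n_cascades=1, image_size=size,
                                      backbone=TINY), seed=0)


def label_cube(shape, value, lo, hi):
    data = np.zeros(shape, dtype=np.uint8)
    data[lo:hi, lo:hi, lo:hi] = value
    return LabelMap(data)


class TestRegisterAtlases:
    def test_count_and_identity_contract(self, phantom32):
        vol, lab = phantom32
        atlases = AtlasSet([(vol, lab, {})] * 3)
        out = register_atlases(vol, atlases, identity_model())
        assert len(out) == 3
        warped, prop, field = out[0]
        np.testing.assert_allclose(warped.data, vol.data, atol=1e-6)
        np.testing.assert_array_equal(prop.data, lab.data)
        assert not field.vectors.any()

    def test_empty_atlas_set_rejected(self):
        with pytest.raises(ValueError):
            AtlasSet([])


class TestRankAtlases:
    def test_exact_copy_ranked_first_any_metric(self, phantom32, rng):
        vol, _ = phantom32
        noisy = Volume(np.clip(vol.data + rng.normal(0, 0.1, vol.shape),
                               0, 1).astype(np.float32))
        for metric in ("ncc", "mse", "ssim"):
            order, scores = rank_atlases(vol, [noisy, vol], metric)
            assert order[0] == 1
        order, scores = rank_atlases(vol, [noisy, vol], "ncc")
        assert scores[0] == pytest.approx(1.0, abs=1e-6)
        order, scores = rank_atlases(vol, [noisy, vol], "mse")
        assert scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_mse_ranks_smaller_offset_first(self, phantom32):
        vol, _ = phantom32
        plus1 = Volume(vol.data + 0.1)
        plus2 = Volume(vol.data + 0.2)
        order, scores = rank_atlases(vol, [plus2, plus1], "mse")
        assert order == [1, 0]
        assert scores[0] == pytest.approx(0.01, abs=1e-6)

    def test_permutation_consistency(self, phantom32, rng):
        vol, _ = phantom32
        warped = [Volume(np.clip(vol.data + rng.normal(0, s, vol.shape),
                                 0, 1).astype(np.float32))
                  for s in (0.05, 0.15, 0.25)]
        order_a, _ = rank_atlases(vol, warped, "ncc")
        shuffled = [warped[2], warped[0], warped[1]]
        order_b, _ = rank_atlases(vol, shuffled, "ncc")
        remap = {0: 2, 1: 0, 2: 1}  # position in shuffled -> original index
        assert [remap[i] for i in order_b] == order_a

    def test_unknown_metric_rejected(self, phantom32):
        vol, _ = phantom32
        with pytest.raises(ValueError, match="metric"):
            rank_atlases(vol, [vol], "psnr")


class TestMajorityVote:
    def test_unanimity(self):
        m = label_cube((6, 6, 6), 3, 1, 4)
        fused = majority_vote([m, m, m])
        np.testing.assert_array_equal(fused.data, m.data)

    def test_strict_majority(self):
        a = label_cube((4, 4, 4), 1, 0, 4)
        b = label_cube((4, 4, 4), 2, 0, 4)
        fused = majority_vote([a, a, b])
        assert (fused.data == 1).all()

    def test_tie_breaks_to_lowest_class(self):
        a = label_cube((4, 4, 4), 1, 0, 4)
        b = label_cube((4, 4, 4), 2, 0, 4)
        fused = majority_vote([a, b])
        assert (fused.data == 1).all()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestLocalWeightedVote:
    def _target_and_atlases(self):
        rng = np.random.default_rng(0)
        base = rng.random((9, 9, 9)).astype(np.float32)
        target = Volume(base)
        match = Volume(base.copy())               # locally identical
        anti = Volume((1.0 - base))               # anti-correlated
        lab_match = label_cube((9, 9, 9), 1, 0, 9)
        lab_anti = label_cube((9, 9, 9), 2, 0, 9)
        return target, [match, anti], [lab_match, lab_anti]

    def test_gain_zero_equals_majority_vote(self, phantom32):
        vol, lab = phantom32
        shifted = LabelMap(np.roll(lab.data, 2, axis=0))
        maps = [lab, lab, shifted]
        warped = [vol, vol, vol]
        cfg = FusionConfig(gain=0.0)
        lwv = local_weighted_vote(vol, warped, maps, cfg)
        mv = majority_vote(maps)
        np.testing.assert_array_equal(lwv.data, mv.data)

    def test_locally_identical_atlas_wins(self):
        target, warped, props = self._target_and_atlases()
        for gain in (1.0, 2.0):
            fused = local_weighted_vote(target, warped, props,
                                        FusionConfig(gain=gain))
            assert (fused.data == 1).all()

    def test_single_atlas_passthrough(self, phantom32):
        vol, lab = phantom32
        fused = local_weighted_vote(vol, [vol], [lab], FusionConfig())
        np.testing.assert_array_equal(fused.data, lab.data)

    def test_idempotent_on_identical_maps(self, phantom32, rng):
        vol, lab = phantom32
        warped = [Volume(np.clip(vol.data + rng.normal(0, s, vol.shape),
                                 0, 1).astype(np.float32))
                  for s in (0.02, 0.3, 0.6)]
        fused = local_weighted_vote(vol, warped, [lab, lab, lab],
                                    FusionConfig())
        np.testing.assert_array_equal(fused.data, lab.data)

    def test_mismatched_lists_rejected(self, phantom32):
        vol, lab = phantom32
        with pytest.raises(ValueError):
            local_weighted_vote(vol, [vol, vol], [lab], FusionConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FusionConfig(window=8)
        with pytest.raises(ValueError):
            FusionConfig(gain=-1)
        with pytest.raises(ValueError):
            FusionConfig(fusion="average")
        with pytest.raises(ValueError):
            FusionConfig(selection_metric="psnr")


@pytest.fixture(scope="module")
def cohort_set():
    cohort = make_cohort(4, PhantomSpec(size=32, seed=5),
                         age_range=(0.4, 0.6))
    return AtlasSet.from_cohort(cohort)


class TestSegment:
    def test_full_selection_mv_equals_majority_vote(self, cohort_set,
                                                    phantom32):
        vol, _ = phantom32
        model = identity_model()
        cfg = FusionConfig(n_select=4, fusion="mv")
        fused, prov = segment(vol, cohort_set, model, cfg)
        registered = register_atlases(vol, cohort_set, model)
        mv = majority_vote([r[1] for r in registered])
        np.testing.assert_array_equal(fused.data, mv.data)
        assert sorted(prov["selected_indices"]) == [0, 1, 2, 3]

    def test_output_classes_subset_of_atlas_classes(self, cohort_set,
                                                    phantom32):
        vol, _ = phantom32
        fused, _ = segment(vol, cohort_set, identity_model(),
                           FusionConfig(n_select=2))
        atlas_classes = set()
        for _, lab, _ in cohort_set.entries:
            atlas_classes |= set(np.unique(lab.data))
        assert set(np.unique(fused.data)) <= atlas_classes

    def test_provenance_records_scores_and_config(self, cohort_set,
                                                  phantom32):
        vol, _ = phantom32
        fused, prov = segment(vol, cohort_set, identity_model(),
                              FusionConfig(n_select=3))
        assert len(prov["ranked_indices"]) == 4
        assert len(prov["selected_indices"]) == 3
        assert prov["selection_metric"] == "ncc"
        # scores are sorted best-first for NCC
        assert prov["ranked_scores"] == sorted(prov["ranked_scores"],
                                               reverse=True)

    def test_n_select_larger_than_atlas_count_rejected(self, cohort_set,
                                                       phantom32):
        vol, _ = phantom32
        with pytest.raises(ValueError):
            segment(vol, cohort_set, identity_model(),
                    FusionConfig(n_select=10))
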