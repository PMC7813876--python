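"""Generator properties: determinism, geometry, and planted-effect recovery."""
import numpy as np
import pytest

from trimodal.fmri import bandpass, degree_centrality, detrend_design, nuisance_regress, reho
from trimodal.microstates import backfit
from trimodal.pet import compute_bpnd, frame_average
from trimodal.synth import (
    default_bold_truth,
    default_pet_truth,
    disc_layout,
    make_atlas,
    make_templates,
    simulate_bold,
    simulate_eeg,
    simulate_pet,
    BoldGroundTruth,
    PetGroundTruth,
)
from trimodal.types import ValidationError, Volume


class TestTemplates:
    def test_maps_are_zero_mean_unit_norm_and_decorrelated(self):
        mset, _ = make_templates(32)
        assert np.abs(mset.maps.mean(axis=1)).max() < 1e-12
        assert np.allclose(np.linalg.norm(mset.maps, axis=1), 1.0)
        gram = mset.maps @ mset.maps.T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 0.3  # orthonormal by construction

    def test_mirrored_layout_swaps_a_and_b(self):
        mset, _ = make_templates(32)
        layout = disc_layout(32)
        mirrored = layout * np.array([-1.0, 1.0])
        mset_m, _ = make_templates(32, layout=mirrored)
        assert np.allclose(mset_m.maps[0], mset.maps[1], atol=1e-12)
        assert np.allclose(mset_m.maps[1], mset.maps[0], atol=1e-12)
        assert np.allclose(mset_m.maps[2], mset.maps[2], atol=1e-12)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValidationError):
            make_templates(7)


class TestSimulateEEG:
    def test_same_seed_is_identical(self, templates_truth):
        _, truth = templates_truth
        r1, s1 = simulate_eeg(truth, 5.0, 125.0, 4.0, seed=3)
        r2, s2 = simulate_eeg(truth, 5.0, 125.0, 4.0, seed=3)
        assert np.array_equal(r1.data, r2.data)
        assert np.array_equal(s1, s2)

    def test_noiseless_backfit_recovers_sequence(self, templates_truth):
        mset, truth = templates_truth
        rec, states = simulate_eeg(truth, 10.0, 125.0, np.inf, seed=5)
        labels, _ = backfit(rec, mset)
        assert np.array_equal(labels, states)

    def test_nonstochastic_transition_matrix_rejected(self, templates_truth):
        _, truth = templates_truth
        import copy

        bad = copy.deepcopy(truth)
        bad.transition_matrix = np.ones((4, 4))
        with pytest.raises(ValidationError):
            simulate_eeg(bad, 1.0, 125.0, 4.0, seed=0)


@pytest.fixture(scope="module")
def bold_and_truth():
    shape = (12, 12, 12)
    truth = default_bold_truth(shape)
    bold = simulate_bold(shape, 120, truth, seed=5)
    return bold, truth


class TestSimulateBold:
    def test_homogeneity_block_elevates_reho(self, bold_and_truth):
        bold, truth = bold_and_truth
        bp = bandpass(nuisance_regress(bold, detrend_design(bold.n_volumes)))
        w = reho(bp)
        planted = np.zeros(bold.grid_shape, bool)
        planted[tuple(truth.homo_blocks[0].T)] = True
        assert w.data[planted].mean() > w.data[~planted].mean()

    def test_hub_voxel_elevates_degree(self, bold_and_truth):
        bold, truth = bold_and_truth
        bp = bandpass(nuisance_regress(bold, detrend_design(bold.n_volumes)))
        dc = degree_centrality(bp)
        hub = tuple(truth.hub_voxels[0])
        assert dc.data[hub] > np.median(dc.data)

    def test_out_of_grid_indices_rejected(self):
        truth = BoldGroundTruth(hub_voxels=np.array([[99, 0, 0]]))
        with pytest.raises(ValidationError):
            simulate_bold((12, 12, 12), 64, truth, seed=0)

    def test_deterministic(self):
        shape = (10, 10, 10)
        truth = default_bold_truth(shape)
        b1 = simulate_bold(shape, 64, truth, seed=9)
        b2 = simulate_bold(shape, 64, truth, seed=9)
        assert np.array_equal(b1.data, b2.data)


class TestSimulatePet:
    def test_noiseless_bpnd_matches_definition(self):
        shape = (10, 10, 10)
        truth = default_pet_truth(shape)
        frames = simulate_pet(shape, truth, seed=0)
        avg = frame_average(frames)
        bp = compute_bpnd(avg, Volume(data=truth.reference_mask))
        c_t = np.average(truth.c_t, weights=frames.durations_min)
        c_ref = np.average(truth.c_ref, weights=frames.durations_min)
        expected = (c_t - c_ref) / c_ref
        assert np.allclose(bp.volume.data[truth.target_mask], expected, atol=1e-12)

    def test_equal_concentrations_give_zero_bpnd(self):
        shape = (8, 8, 8)
        truth = default_pet_truth(shape)
        truth.c_t = truth.c_ref.copy()
        frames = simulate_pet(shape, truth, seed=0)
        bp = compute_bpnd(frame_average(frames), Volume(data=truth.reference_mask))
        assert np.allclose(bp.volume.data, 0.0, atol=1e-12)

    def test_overlapping_masks_rejected(self):
        m = np.zeros((6, 6, 6), bool)
        m[0, 0, 0] = True
        with pytest.raises(ValidationError):
            PetGroundTruth(target_mask=m, reference_mask=m, c_t=[1.0], c_ref=[1.0])

    def test_deterministic_with_noise(self):
        shape = (8, 8, 8)
        truth = default_pet_truth(shape)
        f1 = simulate_pet(shape, truth, seed=4, noise_sd=0.5)
        f2 = simulate_pet(shape, truth, seed=4, noise_sd=0.5)
        for a, b in zip(f1.frames, f2.frames):
            assert np.array_equal(a.data, b.data)


class TestMakeAtlas:
    def test_masks_disjoint_gm_bounded_leadfield_consistent(self):
        atlas = make_atlas((12, 12, 12), seed=1)
        masks = list(atlas["masks"].values())
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                assert not (masks[i].data & masks[j].data).any()
        gm = atlas["gm_prob"].data
        assert gm.min() >= 0.0 and gm.max() <= 1.0
        lf = atlas["leadfield"]
        assert lf.gain.shape == (32, lf.n_sources)

    def test_gm_corrected_region_is_subset(self):
        from trimodal.stats import gm_correct

        atlas = make_atlas((12, 12, 12), seed=1)
        dmn = atlas["masks"]["DMN"]
        corrected = gm_correct(dmn, atlas["gm_prob"], 0.5)
        assert (corrected.data <= dmn.data).all()

    def test_deterministic(self):
        a1 = make_atlas((10, 10, 10), seed=2)
        a2 = make_atlas((10, 10, 10), seed=2)
        assert np.array_equal(a1["gm_prob"].data, a2["gm_prob"].data)
        assert np.array_equal(a1["leadfield"].gain, a2["leadfield"].gain)
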