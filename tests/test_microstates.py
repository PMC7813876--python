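"""Microstate segmentation: GFP, peak picking, AAHC, sorting, backfitting."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import best_assignment_oracle, gfp_oracle, local_maxima_oracle
from trimodal.microstates import (
    GfpSeries,
    aahc_cluster,
    backfit,
    extract_state_epochs,
    find_gfp_peaks,
    gfp,
    prepare_eeg,
    sort_to_templates,
    spatial_correlation,
)
from trimodal.synth import simulate_eeg
from trimodal.types import EEGRecording, MicrostateSet, ValidationError


class TestPrepare:
    def test_constant_offsets_removed(self):
        rec = EEGRecording(data=np.outer([1.0, -2.0, 3.0, 0.5], np.ones(500)),
                           fs=250.0)
        out = prepare_eeg(rec, (2.0, 20.0), fs_out=125.0)
        assert np.abs(out.data).max() < 1e-8

    def test_out_of_band_sinusoid_attenuated(self):
        fs = 250.0
        t = np.arange(2000) / fs
        sig = np.sin(2 * np.pi * 30.0 * t)
        rec = EEGRecording(data=np.vstack([sig, -sig]), fs=fs)
        out = prepare_eeg(rec, (2.0, 20.0), fs_out=125.0)
        core = out.data[0, 200:-200]  # avoid filter edge transients
        atten_db = 20 * np.log10(np.abs(core).max() / 1.0)
        assert atten_db < -20

    def test_output_is_average_referenced(self, sim_eeg):
        rec, _ = sim_eeg
        out = prepare_eeg(rec, (2.0, 20.0), fs_out=125.0)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_band_outside_nyquist_rejected(self):
        rec = EEGRecording(data=np.zeros((4, 100)), fs=100.0)
        with pytest.raises(ValidationError):
            prepare_eeg(rec, (2.0, 60.0), fs_out=100.0)


class TestGfp:
    def test_matches_spatial_sd_oracle(self, rng):
        for _ in range(100):
            data = rng.standard_normal((8, 20))
            g = gfp(EEGRecording(data=data, fs=100.0))
            assert np.abs(g.values - gfp_oracle(data)).max() < 1e-10

    def test_equal_channels_give_zero_and_pm1_gives_one(self):
        data = np.array([[3.0, 1.0], [3.0, -1.0]])
        g = gfp(EEGRecording(data=data, fs=10.0))
        assert g.values[0] == 0.0
        assert np.isclose(g.values[1], 1.0)

    def test_single_channel_rejected(self):
        with pytest.raises(ValidationError):
            gfp(EEGRecording(data=np.zeros((1, 10)), fs=10.0))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_nonnegative_and_offset_invariant(self, seed):
        data = np.random.default_rng(seed).standard_normal((6, 30))
        g1 = gfp(EEGRecording(data=data, fs=100.0)).values
        shifted = data + np.random.default_rng(seed + 1).standard_normal((1, 30))
        g2 = gfp(EEGRecording(data=shifted, fs=100.0)).values
        assert (g1 >= 0).all()
        assert np.allclose(g1, g2, atol=1e-10)  # common-mode shift invariant


class TestGfpPeaks:
    def test_monotone_series_has_no_peaks(self):
        g = GfpSeries(values=np.arange(50.0), fs=125.0)
        assert find_gfp_peaks(g).size == 0

    def test_triangle_pulse_has_single_apex(self):
        v = np.concatenate([np.arange(10.0), np.arange(10.0)[::-1]])
        g = GfpSeries(values=v, fs=125.0)
        assert list(find_gfp_peaks(g)) == [9]

    def test_matches_exhaustive_scan_on_synthetic_eeg(self, templates_truth):
        _, truth = templates_truth
        rec, _ = simulate_eeg(truth, 10.0, 125.0, 4.0, seed=7)
        g = gfp(rec)
        peaks = find_gfp_peaks(g, min_separation_ms=10.0)  # < 2 samples at 125 Hz
        assert list(peaks) == local_maxima_oracle(g.values)


class TestAahc:
    def test_noiseless_recovery_from_template_draws(self, templates_truth, rng):
        mset, _ = templates_truth
        draws = mset.maps[rng.integers(0, 4, size=200)] * \
            rng.uniform(0.5, 2.0, size=(200, 1))
        out = aahc_cluster(draws, 4)
        c = np.abs(spatial_correlation(out.maps, mset.maps))
        # every template matched by exactly one centroid with |corr| = 1
        assert np.allclose(np.sort(c.max(axis=0)), 1.0, atol=1e-9)

    def test_gev_not_lower_with_more_clusters(self, sim_eeg):
        rec, _ = sim_eeg
        g = gfp(rec)
        peaks = find_gfp_peaks(g)[:300]
        maps = rec.data[:, peaks].T
        gev3 = aahc_cluster(maps, 3).gev
        gev4 = aahc_cluster(maps, 4).gev
        assert gev4 >= gev3 - 1e-9

    def test_permutation_invariance_of_centroid_set(self, sim_eeg, rng):
        rec, _ = sim_eeg
        peaks = find_gfp_peaks(gfp(rec))[:150]
        maps = rec.data[:, peaks].T
        a = aahc_cluster(maps, 4).maps
        b = aahc_cluster(maps[rng.permutation(len(maps))], 4).maps
        c = np.abs(spatial_correlation(a, b))
        assert np.allclose(np.sort(c.max(axis=0)), 1.0, atol=1e-6)

    def test_more_clusters_than_maps_rejected(self, rng):
        with pytest.raises(ValidationError):
            aahc_cluster(rng.standard_normal((3, 8)), 4)


class TestSorting:
    def test_shuffled_and_flipped_templates_recovered(self, templates_truth):
        mset, _ = templates_truth
        perm = [2, 0, 3, 1]
        shuffled = MicrostateSet(maps=mset.maps[perm] * np.array([[1], [-1], [1], [-1]]))
        out = sort_to_templates(shuffled, mset)
        assert out.labels == ["A", "B", "C", "D"]
        assert np.allclose(out.maps, mset.maps, atol=1e-12)  # polarity corrected

    def test_matches_exhaustive_assignment_oracle(self, rng):
        for _ in range(50):
            maps = rng.standard_normal((4, 16))
            templ = rng.standard_normal((4, 16))
            out = sort_to_templates(MicrostateSet(maps=maps),
                                    MicrostateSet(maps=templ,
                                                  labels=list("ABCD")))
            corr = spatial_correlation(maps, templ)
            perm, best = best_assignment_oracle(corr)
            achieved = sum(
                abs(spatial_correlation(out.maps[[j]], templ[[j]])[0, 0])
                for j in range(4)
            )
            assert np.isclose(achieved, best, atol=1e-10)

    def test_channel_mismatch_rejected(self, templates_truth):
        mset, _ = templates_truth
        with pytest.raises(ValidationError):
            sort_to_templates(MicrostateSet(maps=np.zeros((4, 16))), mset)


class TestBackfit:
    def test_single_state_data_fully_covered(self, templates_truth):
        mset, _ = templates_truth
        data = np.outer(mset.maps[0], np.sin(np.arange(100) / 3.0) + 2.0)
        rec = EEGRecording(data=data, fs=125.0)
        labels, stats = backfit(rec, mset)
        assert (labels == 0).all()
        assert stats["A"]["coverage"] == 1.0

    def test_coverages_partition_assigned_samples(self, sim_eeg, templates_truth):
        mset, _ = templates_truth
        rec, _ = sim_eeg
        labels, stats = backfit(rec, mset)
        total = sum(stats[name]["coverage"] for name in "ABCD")
        assert np.isclose(total, 1.0)

    def test_polarity_flip_invariance(self, sim_eeg, templates_truth):
        mset, _ = templates_truth
        rec, _ = sim_eeg
        flipped = EEGRecording(data=-rec.data, fs=rec.fs)
        l1, _ = backfit(rec, mset)
        l2, _ = backfit(flipped, mset)
        assert np.array_equal(l1, l2)

    def test_accuracy_monotone_in_snr(self, templates_truth):
        _, truth = templates_truth
        mset = MicrostateSet(maps=truth.templates, labels=list("ABCD"))
        accs = []
        for snr in (0.5, 4.0, 64.0):
            rec, states = simulate_eeg(truth, 30.0, 125.0, snr, seed=21)
            labels, _ = backfit(rec, mset)
            accs.append((labels == states).mean())
        assert accs[0] <= accs[1] <= accs[2]

    def test_peaks_only_mode_close_to_full_mode(self, sim_eeg, templates_truth):
        mset, _ = templates_truth
        rec, states = sim_eeg
        labels, _ = backfit(rec, mset, peaks_only=True)
        assert (labels == states).mean() > 0.8


class TestEpochs:
    def test_identity_and_partition(self, sim_eeg, templates_truth):
        mset, _ = templates_truth
        rec, _ = sim_eeg
        labels, _ = backfit(rec, mset)
        lengths = [extract_state_epochs(rec, labels, k).n_samples for k in range(4)]
        assert sum(lengths) == (labels != -1).sum()

    def test_all_one_state_returns_input(self):
        rec = EEGRecording(data=np.arange(20.0).reshape(4, 5), fs=10.0)
        out = extract_state_epochs(rec, np.zeros(5, int), 0)
        assert np.array_equal(out.data, rec.data)

    def test_absent_state_warns_and_returns_empty(self):
        rec = EEGRecording(data=np.ones((4, 6)), fs=10.0)
        with pytest.warns(UserWarning):
            out = extract_state_epochs(rec, np.zeros(6, int), 3)
        assert out.n_samples == 0
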