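"""Voxel-wise fMRI measures vs brute-force oracles and spectral checks."""
import numpy as np
import pytest

from oracles import dc_oracle, hat_matrix_residual_oracle, kendall_w_oracle
from trimodal.fmri import (
    NuisanceSet,
    bandpass,
    degree_centrality,
    detrend_design,
    falff,
    kendall_w,
    nuisance_regress,
    reho,
)
from trimodal.types import BoldSeries, ValidationError, Volume

TR = 2.2


def _series(data):
    return BoldSeries(data=data, tr_s=TR)


class TestNuisance:
    def _nuisance(self, rng, t):
        return NuisanceSet(motion=0.1 * rng.standard_normal((t, 6)),
                           wm_mean=rng.standard_normal(t),
                           csf_mean=rng.standard_normal(t))

    def test_in_span_voxel_has_zero_residual(self, rng):
        t = 48
        nset = self._nuisance(rng, t)
        x, _ = nset.design()
        data = np.tile(x[:, 0], (2, 2, 2, 1)).reshape(2, 2, 2, t)
        out = nuisance_regress(_series(data), nset)
        assert np.abs(out.data).max() < 1e-8

    def test_residuals_orthogonal_to_design(self, rng):
        t = 64
        nset = self._nuisance(rng, t)
        data = rng.standard_normal((3, 3, 3, t))
        out = nuisance_regress(_series(data), nset)
        x, _ = nset.design()
        dots = out.data.reshape(-1, t) @ x
        assert np.abs(dots).max() < 1e-8

    def test_matches_hat_matrix_oracle(self, rng):
        t = 40
        nset = self._nuisance(rng, t)
        x, _ = nset.design()
        data = rng.standard_normal((2, 1, 1, t))
        out = nuisance_regress(_series(data), nset)
        for v in range(2):
            expected = hat_matrix_residual_oracle(data[v, 0, 0], x)
            assert np.abs(out.data[v, 0, 0] - expected).max() < 1e-8

    def test_rank_deficient_design_names_columns(self, rng):
        t = 40
        motion = rng.standard_normal((t, 6))
        motion[:, 5] = motion[:, 0]  # duplicate column
        nset = NuisanceSet(motion=motion, wm_mean=rng.standard_normal(t),
                           csf_mean=rng.standard_normal(t))
        with pytest.raises(ValidationError, match="motion"):
            nuisance_regress(_series(rng.standard_normal((2, 2, 2, t))), nset)


class TestBandpass:
    def _tone(self, freq, t=180):
        time = np.arange(t) * TR
        return np.sin(2 * np.pi * freq * time)

    def test_in_band_tone_preserved(self):
        sig = self._tone(0.04)
        out = bandpass(_series(np.tile(sig, (2, 1, 1, 1))))
        core = out.data[0, 0, 0, 30:-30]
        assert np.abs(core).max() > 0.9

    def test_out_of_band_tone_attenuated(self):
        sig = self._tone(0.2)
        out = bandpass(_series(np.tile(sig, (2, 1, 1, 1))))
        core = out.data[0, 0, 0, 30:-30]
        assert 20 * np.log10(np.abs(core).max()) < -20

    def test_constant_series_removed(self):
        out = bandpass(_series(np.full((2, 2, 1, 64), 5.0)))
        assert np.abs(out.data).max() < 1e-6

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            bandpass(_series(np.zeros((2, 2, 2, 64))), 0.01, 0.3)


class TestReho:
    def test_identical_series_give_w_one(self):
        base = np.random.default_rng(0).standard_normal(40)
        data = np.tile(base, (3, 3, 3, 1))
        w = reho(_series(data))
        assert np.allclose(w.data, 1.0, atol=1e-10)

    def test_two_reversed_rank_series_give_w_zero(self):
        w = kendall_w(np.array([[1.0, 2.0, 3.0, 4.0],
                                [4.0, 3.0, 2.0, 1.0]]))
        assert w == 0.0

    def test_matches_rank_sum_oracle_on_random_neighbourhoods(self, rng):
        for _ in range(100):
            data = rng.standard_normal((3, 3, 3, 34))
            if rng.random() < 0.3:
                data = np.round(data)  # force ties
            w = reho(_series(data))
            series = data.reshape(-1, 34)
            assert abs(w.data[1, 1, 1] - kendall_w_oracle(series)) < 1e-10

    def test_mask_edges_shrink_neighbourhood(self, rng):
        data = rng.standard_normal((3, 3, 3, 34))
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, :2] = True  # only two voxels in the mask
        b = BoldSeries(data=data, tr_s=TR, mask=Volume(data=mask))
        w = reho(b)
        pair = data[0, 0, :2]
        assert abs(w.data[0, 0, 0] - kendall_w_oracle(pair)) < 1e-10
        assert w.data[2, 2, 2] == 0.0

    def test_affine_rescaling_invariance(self, rng):
        data = rng.standard_normal((3, 3, 3, 34))
        gains = rng.uniform(0.5, 2.0, (3, 3, 3, 1))
        offs = rng.standard_normal((3, 3, 3, 1))
        w1 = reho(_series(data)).data
        w2 = reho(_series(gains * data + offs)).data
        assert np.abs(w1 - w2).max() < 1e-10

    def test_range_bounds(self, rng):
        w = reho(_series(rng.standard_normal((4, 4, 4, 40)))).data
        assert w.min() >= 0.0 and w.max() <= 1.0


class TestDegreeCentrality:
    def test_identical_voxels_form_complete_graph(self):
        base = np.random.default_rng(1).standard_normal(40)
        data = np.tile(base, (2, 2, 2, 1))
        dc = degree_centrality(_series(data), 0.25)
        assert np.allclose(dc.data, 7.0)

    def test_unattainable_threshold_gives_zero(self, rng):
        dc = degree_centrality(_series(rng.standard_normal((2, 2, 2, 40))), 1.0)
        assert np.allclose(dc.data, 0.0)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(20):
            data = rng.standard_normal((10, 1, 1, 36))
            dc = degree_centrality(_series(data), 0.25)
            expected = dc_oracle(data.reshape(10, 36), 0.25)
            assert np.array_equal(dc.data.ravel(), expected)

    def test_zero_variance_voxel_counts_nothing(self, rng):
        data = rng.standard_normal((4, 1, 1, 40))
        data[0] = 2.5
        dc = degree_centrality(_series(data), 0.25)
        assert dc.data[0, 0, 0] == 0.0


class TestFalff:
    def test_in_band_tone_near_one(self):
        # 0.05 Hz falls exactly on a frequency bin at n=200, TR 2.2 s,
        # so the amplitude spectrum is leakage-free
        t = np.arange(200) * TR
        sig = np.sin(2 * np.pi * 0.05 * t)
        out = falff(_series(np.tile(sig, (2, 1, 1, 1))))
        assert out.data[0, 0, 0] >= 0.95

    def test_out_of_band_tone_near_zero(self):
        t = np.arange(160) * TR
        sig = np.sin(2 * np.pi * 0.2 * t)
        out = falff(_series(np.tile(sig, (2, 1, 1, 1))))
        assert out.data[0, 0, 0] <= 0.05

    def test_white_noise_matches_band_fraction(self):
        n = 128
        freqs = np.fft.rfftfreq(n, d=TR)
        pos = freqs > 0
        frac = ((freqs >= 0.01) & (freqs <= 0.1) & pos).sum() / pos.sum()
        vals = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            out = falff(_series(r.standard_normal((4, 4, 1, n))))
            vals.append(out.data.mean())
        assert abs(np.mean(vals) - frac) < 0.02

    def test_affine_invariance_and_bounds(self, rng):
        data = rng.standard_normal((3, 3, 1, 64))
        gains = rng.uniform(0.5, 3.0, (3, 3, 1, 1))
        f1 = falff(_series(data)).data
        f2 = falff(_series(gains * data + 5.0)).data
        assert np.abs(f1 - f2).max() < 1e-10
        assert f1.min() >= 0.0 and f1.max() <= 1.0

    def test_all_zero_voxel_gets_zero(self):
        data = np.zeros((2, 1, 1, 64))
        data[1] = np.random.default_rng(0).standard_normal(64)
        out = falff(_series(data))
        assert out.data[0, 0, 0] == 0.0
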