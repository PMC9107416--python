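"""Spectral estimation: amplitude spectra, ALFF/fALFF, z-maps, differences."""

import numpy as np
import pytest

from falffmvpa.falff import (
    FALFFMap,
    VolumeSeries,
    amplitude_spectrum,
    falff,
    falff_map,
    session_difference,
    zscore_map,
)
from falffmvpa.synth import generate_timeseries

from conftest import centered_affine

DT = 1.5
N = 310  # 320 acquired minus 10 discarded


class TestAmplitudeSpectrum:
    def test_constant_series_has_dc_only(self):
        freqs, amps = amplitude_spectrum(np.full(64, 3.7), dt=DT)
        assert freqs[0] == 0.0
        assert amps[0] > 0
        assert np.allclose(amps[1:], 0.0, atol=1e-12)

    def test_bin_sinusoid_concentrates_at_its_frequency(self):
        k = 12
        t = np.arange(N) * DT
        f0 = k / (N * DT)
        ts = np.sin(2 * np.pi * f0 * t)
        freqs, amps = amplitude_spectrum(ts, dt=DT)
        assert freqs[np.argmax(amps)] == pytest.approx(f0)
        others = np.delete(amps, np.argmax(amps))
        assert others.max() < 1e-9 * amps.max()

    def test_parseval_energy_identity(self):
        # oracle: direct time-domain energy of the series
        rng = np.random.default_rng(0)
        ts = rng.normal(size=N)
        _, amps = amplitude_spectrum(ts, dt=DT)
        energy = np.sum(ts ** 2)
        assert np.sum(amps ** 2) == pytest.approx(energy, rel=1e-6)

    def test_frequency_resolution(self):
        freqs, _ = amplitude_spectrum(np.zeros(N), dt=DT)
        assert freqs[1] == pytest.approx(1.0 / (N * DT))

    @pytest.mark.parametrize("bad", [np.zeros(31), np.zeros((4, 64))])
    def test_rejects_short_or_nonvector_input(self, bad):
        with pytest.raises(ValueError):
            amplitude_spectrum(bad, dt=DT)

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            amplitude_spectrum(np.zeros(64), dt=0.0)


class TestFalff:
    def test_in_band_only_signal_gives_one(self):
        t = np.arange(N) * DT
        # bin frequencies k/(N*dt) for k=10,20,30 all lie inside the band
        ts = sum(np.sin(2 * np.pi * (k / (N * DT)) * t + p)
                 for k, p in [(10, 0.3), (20, 1.1), (30, 2.0)])
        _, f = falff(ts, dt=DT)
        assert f == pytest.approx(1.0, abs=1e-9)

    def test_out_of_band_sinusoid_gives_zero(self):
        t = np.arange(N) * DT
        ts = np.sin(2 * np.pi * 0.2 * t)  # 0.2 Hz = bin 93 of 465 s window
        _, f = falff(ts, dt=DT)
        assert f == pytest.approx(0.0, abs=1e-6)

    def test_white_noise_expectation_matches_bin_fraction(self):
        # oracle: fraction of nonzero-frequency bins inside the band
        freqs = np.fft.rfftfreq(N, d=DT)
        expected = np.sum((freqs >= 0.01) & (freqs <= 0.08)) / np.sum(freqs > 0)
        rng = np.random.default_rng(42)
        vals = np.array([falff(rng.normal(size=N), dt=DT)[1] for _ in range(100)])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expected) < 3 * se

    @pytest.mark.parametrize("scale", [0.1, 1.0, 250.0])
    def test_falff_invariant_and_alff_linear_under_scaling(self, scale):
        rng = np.random.default_rng(3)
        ts = generate_timeseries(N, DT, band_amplitude=1.0, broadband_sd=1.0,
                                 rng=rng)
        a1, f1 = falff(ts, dt=DT)
        a2, f2 = falff(scale * ts, dt=DT)
        assert f2 == pytest.approx(f1, rel=1e-12)
        assert a2 == pytest.approx(scale * a1, rel=1e-12)

    def test_falff_increases_with_in_band_amplitude(self):
        prev = -1.0
        for amp in (0.5, 1.0, 2.0, 4.0):
            rng = np.random.default_rng(11)  # same noise draw each time
            ts = generate_timeseries(N, DT, band_amplitude=amp,
                                     broadband_sd=1.0, rng=rng)
            _, f = falff(ts, dt=DT)
            assert f > prev
            prev = f

    def test_mean_ratio_mode_differs_by_bin_count_factor(self):
        rng = np.random.default_rng(5)
        ts = rng.normal(size=N)
        freqs = np.fft.rfftfreq(N, d=DT)
        n_band = np.sum((freqs >= 0.01) & (freqs <= 0.08))
        n_all = np.sum(freqs > 0)
        _, f_sum = falff(ts, dt=DT, ratio="sum")
        _, f_mean = falff(ts, dt=DT, ratio="mean")
        assert f_mean == pytest.approx(f_sum * n_all / n_band, rel=1e-12)

    def test_rejects_band_outside_nyquist(self):
        with pytest.raises(ValueError):
            falff(np.zeros(64), dt=DT, band=(0.01, 0.5))

    def test_rejects_empty_band(self):
        # resolution 1/(64*1.5) ~ 0.0104 Hz; a sliver below it holds no bin
        with pytest.raises(ValueError):
            falff(np.random.default_rng(0).normal(size=64), dt=DT,
                  band=(0.0301, 0.0302))


def _toy_map(values, affine=None, kind="falff"):
    values = np.asarray(values, dtype=float)
    return FALFFMap(values=values, mask=np.ones(values.shape, bool),
                    affine=affine if affine is not None else np.eye(4),
                    kind=kind)


class TestZScoreMap:
    def test_mean_zero_sd_one_inside_mask(self):
        rng = np.random.default_rng(1)
        z = zscore_map(_toy_map(rng.random((6, 6, 6))))
        vals = z.values[z.mask]
        assert vals.mean() == pytest.approx(0.0, abs=1e-12)
        assert vals.std() == pytest.approx(1.0, abs=1e-12)
        assert z.kind == "zfalff"

    def test_submask_changes_z_values(self):
        rng = np.random.default_rng(2)
        m = _toy_map(rng.random((6, 6, 6)))
        sub = np.zeros((6, 6, 6), bool)
        sub[:3] = True
        z_full = zscore_map(m)
        z_sub = zscore_map(m, mask=sub)
        assert not np.allclose(z_full.values[sub], z_sub.values[sub])

    def test_geometry_free(self):
        rng = np.random.default_rng(3)
        vals = rng.random((5, 5, 5))
        shifted = centered_affine((5, 5, 5))
        a = zscore_map(_toy_map(vals))
        b = zscore_map(_toy_map(vals, affine=shifted))
        assert np.allclose(a.values[a.mask], b.values[b.mask])

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(ValueError, match="variance"):
            zscore_map(_toy_map(np.full((4, 4, 4), 2.0)))


class TestSessionDifference:
    def _z(self, values):
        return zscore_map(_toy_map(values))

    def test_identity_linearity_antisymmetry(self):
        rng = np.random.default_rng(4)
        pre = self._z(rng.random((5, 5, 5)))
        post = self._z(rng.random((5, 5, 5)))
        zero = session_difference(pre, pre)
        assert np.allclose(zero.values[zero.mask], 0.0)
        d = session_difference(post, pre)
        neg = session_difference(pre, post)
        assert np.allclose(d.values[d.mask], -neg.values[neg.mask])
        assert d.kind == "delta_zfalff"

    def test_constant_offset_on_z_inputs(self):
        rng = np.random.default_rng(5)
        pre = self._z(rng.random((5, 5, 5)))
        post = FALFFMap(values=pre.values + 0.25, mask=pre.mask,
                        affine=pre.affine, kind="zfalff")
        d = session_difference(post, pre)
        assert np.allclose(d.values[d.mask], 0.25)

    def test_rejects_mismatched_inputs(self):
        rng = np.random.default_rng(6)
        a = self._z(rng.random((5, 5, 5)))
        b = self._z(rng.random((4, 4, 4)))
        with pytest.raises(ValueError):
            session_difference(a, b)
        raw = _toy_map(rng.random((5, 5, 5)))  # not z-scored
        with pytest.raises(ValueError):
            session_difference(a, raw)


class TestFalffMap:
    def test_voxelwise_matches_single_series(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(3, 2, 2, 64))
        series = VolumeSeries(data, dt=DT, affine=np.eye(4))
        fmap = falff_map(series)
        _, expected = falff(data[1, 0, 1], dt=DT)
        assert fmap.values[1, 0, 1] == pytest.approx(expected)
        assert np.all((fmap.values[fmap.mask] >= 0)
                      & (fmap.values[fmap.mask] <= 1))

    def test_series_validation(self):
        with pytest.raises(ValueError):
            VolumeSeries(np.zeros((2, 2, 2, 16)), dt=DT, affine=np.eye(4))
        with pytest.raises(ValueError):
            VolumeSeries(np.zeros((2, 2, 2, 64)), dt=-1.0, affine=np.eye(4))
        with pytest.raises(ValueError):
            VolumeSeries(np.zeros((2, 2, 2, 64)), dt=DT, affine=np.zeros((4, 4)))

    def test_nifti_round_trip_discards_initial_volumes(self, tmp_path):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(4, 4, 4, 74))
        series = VolumeSeries(data, dt=DT, affine=centered_affine((4, 4, 4)))
        path = tmp_path / "bold.nii.gz"
        series.to_nifti(path)
        back = VolumeSeries.from_nifti(path, discard=10)
        assert back.n_volumes == 64
        assert back.n_discarded == 10
        assert back.dt == pytest.approx(DT)
        assert np.allclose(back.data, data[..., 10:], atol=1e-6)
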