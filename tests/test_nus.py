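"""NUS schedules, masked acquisition, nuFT and the point spread function."""

import numpy as np
import pytest

import tropnmr as t
from conftest import dim_direct, dim_indirect


class TestGenerateSchedule:
    def test_full_fraction_keeps_whole_grid(self):
        s = t.generate_schedule((6, 5), 1.0, mode="uniform_random", seed=3)
        assert s.n_points == 30
        assert s.fraction == 1.0

    def test_quarter_schedule_is_deterministic_with_origin(self):
        s1 = t.generate_schedule((8, 8), 0.25, mode="uniform_random", seed=7)
        s2 = t.generate_schedule((8, 8), 0.25, mode="uniform_random", seed=7)
        assert s1.n_points == 16
        assert len(np.unique(s1.points, axis=0)) == 16
        assert np.all(s1.points[0] == 0)
        assert np.array_equal(s1.points, s2.points)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            t.generate_schedule((8,), 0.0)
        with pytest.raises(ValueError, match="fraction"):
            t.generate_schedule((8,), 1.2)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            t.generate_schedule((), 0.5)

    def test_exponential_bias_prefers_early_increments(self):
        """Strongly biased schedules have a smaller mean sampled index than
        uniform ones (Monte Carlo over 1000 schedule draws)."""
        means_u, means_b = [], []
        for seed in range(1000):
            u = t.generate_schedule((8, 8), 0.25, "uniform_random", seed=seed)
            b = t.generate_schedule(
                (8, 8), 0.25, "exponential_biased", seed=seed, bias_decay=(4.0, 4.0)
            )
            means_u.append(u.points.mean())
            means_b.append(b.points.mean())
        assert np.mean(means_b) < np.mean(means_u) - 0.5

    def test_schedule_file_round_trip(self, tmp_path):
        s = t.generate_schedule((8, 6), 0.3, "exponential_biased", seed=5)
        path = tmp_path / "schedule.txt"
        t.write_schedule(s, path)
        s2 = t.read_schedule(path)
        assert s2.shape == s.shape
        assert np.array_equal(s2.points, s.points)
        assert s2.mode == s.mode


class TestApplySchedule:
    def _grid(self):
        dims = [dim_indirect(quad="states", n=8), dim_direct(n=16)]
        scheme = t.TransferScheme({"N": t.TransferStep("cp_states")})
        res = [t.Resonance((300.0, -200.0), 1.0, (10.0, 20.0))]
        return t.simulate_experiment(res, dims, scheme)

    def test_full_schedule_leaves_grid_unchanged(self):
        g = self._grid()
        s = t.generate_schedule((8,), 1.0)
        assert np.array_equal(t.apply_schedule(g, s).data, g.data)

    def test_origin_only_schedule_keeps_first_increment(self):
        g = self._grid()
        s = t.SamplingSchedule((8,), np.array([[0]]))
        masked = t.apply_schedule(g, s)
        assert np.array_equal(masked.data[:, 0, :], g.data[:, 0, :])
        assert np.all(masked.data[:, 1:, :] == 0)

    def test_mask_counts_sampled_points(self):
        g = self._grid()
        s = t.generate_schedule((8,), 0.25, seed=1)
        masked = t.apply_schedule(g, s)
        assert masked.meta["nus_mask"].sum() == s.n_points

    def test_shape_mismatch_rejected(self):
        g = self._grid()
        s = t.generate_schedule((6,), 0.5)
        with pytest.raises(ValueError, match="does not match"):
            t.apply_schedule(g, s)

    def test_schedule_must_contain_origin(self):
        with pytest.raises(ValueError, match="origin"):
            t.SamplingSchedule((8,), np.array([[1], [2]]))


class TestNuft:
    def test_full_sampling_identical_to_plain_ft(self, sparse2d):
        g = t.convert_to_states(
            t.simulate_experiment(
                sparse2d["resonances"], sparse2d["dims"], sparse2d["scheme"]
            )
        )
        s = t.generate_schedule((64,), 1.0)
        assert np.array_equal(
            t.nuft(t.apply_schedule(g, s)).values, t.hypercomplex_ft(g).values
        )

    def test_zero_data_gives_zero_spectrum(self):
        dims = [dim_indirect(quad="states", n=8), dim_direct(n=16)]
        scheme = t.TransferScheme({"N": t.TransferStep("cp_states")})
        g = t.simulate_experiment([], dims, scheme)
        s = t.generate_schedule((8,), 0.5, seed=2)
        assert np.all(t.nuft(t.apply_schedule(g, s)).values == 0)

    def test_missing_mask_rejected(self):
        dims = [dim_indirect(quad="states", n=8), dim_direct(n=16)]
        scheme = t.TransferScheme({"N": t.TransferStep("cp_states")})
        g = t.simulate_experiment([], dims, scheme)
        with pytest.raises(ValueError, match="mask"):
            t.nuft(g)

    def test_matches_direct_dft_oracle_on_sampled_points(self):
        """nuFT of masked States data equals the brute-force discrete Fourier
        sum over only the sampled increments."""
        n_ind, sw = 16, 1600.0
        dims = [dim_indirect(quad="states", n=n_ind, sw=sw), dim_direct(n=8)]
        scheme = t.TransferScheme({"N": t.TransferStep("cp_states")})
        res = [
            t.Resonance((300.0, -200.0), 1.0, (25.0, 20.0)),
            t.Resonance((-450.0, 400.0), 0.7, (35.0, 20.0)),
        ]
        g = t.simulate_experiment(res, dims, scheme)
        sched = t.generate_schedule((n_ind,), 0.5, seed=9)
        spec = t.nuft(t.apply_schedule(g, sched), zero_fill=1)

        # oracle: transform the direct dimension of the cos/sin components,
        # keep the absorptive (real) parts, form the indirect interferogram
        # rc + i*rs and sum the discrete Fourier series over sampled points
        rc = np.fft.fftshift(np.fft.fft(g.data[0], axis=1), axes=1).real
        rs = np.fft.fftshift(np.fft.fft(g.data[1], axis=1), axes=1).real
        zi = rc + 1j * rs
        ks = sched.points[:, 0]
        dft = np.zeros((n_ind, zi.shape[1]), dtype=complex)
        for i, f in enumerate(np.fft.fftshift(np.fft.fftfreq(n_ind))):
            dft[i] = np.sum(zi[ks] * np.exp(-2j * np.pi * f * ks)[:, None], axis=0)
        np.testing.assert_allclose(
            spec.values, dft.real, atol=1e-8 * np.abs(dft.real).max()
        )


class TestPointSpreadFunction:
    def test_full_sampling_gives_delta(self):
        s = t.generate_schedule((16,), 1.0)
        psf = t.point_spread_function(s)
        center = np.argmin(np.abs(psf.axes[0]))
        assert psf.values[center] == pytest.approx(1.0)
        side = np.abs(np.delete(psf.values, center))
        assert side.max() <= 1e-12

    def test_origin_only_schedule_gives_flat_psf(self):
        s = t.SamplingSchedule((16,), np.array([[0]]))
        psf = t.point_spread_function(s)
        np.testing.assert_allclose(psf.values, 1.0, atol=1e-12)

    def test_nuft_of_unit_peak_equals_shifted_psf(self, sparse2d):
        """Convolution contract: the nuFT spectrum of a noiseless on-grid
        peak is the peak height times the PSF shifted to the peak position
        (checked to 1e-10 on the 50% random schedule)."""
        n_ind, sw = 64, 1600.0
        k = 9
        dims = [dim_indirect(quad="states", n=n_ind, sw=sw), dim_direct(n=8)]
        scheme = t.TransferScheme({"N": t.TransferStep("cp_states")})
        res = [t.Resonance((k * sw / n_ind, 0.0), 1.3, (0.0, 0.0))]
        g = t.simulate_experiment(res, dims, scheme)
        sched = t.generate_schedule((n_ind,), 0.5, seed=3)
        spec = t.nuft(t.apply_schedule(g, sched), zero_fill=1)
        psf = t.point_spread_function(sched)
        jd = np.argmin(np.abs(spec.axes[1] - 8.5))  # direct on-carrier column
        column = spec.values[:, jd]
        expected = 1.3 * sched.n_points * 8 * np.roll(psf.values, k).real
        np.testing.assert_allclose(
            column, expected, atol=1e-10 * np.abs(expected).max()
        )

    def test_sidelobe_rms_decreases_with_sampling_fraction(self):
        """Mean PSF side-lobe RMS is monotone decreasing over sampling
        fractions {0.1, 0.25, 0.5, 1.0}, averaged over 100 seeds."""
        fractions = (0.1, 0.25, 0.5, 1.0)
        rms = []
        for frac in fractions:
            vals = []
            for seed in range(100):
                s = t.generate_schedule((32,), frac, seed=seed)
                psf = t.point_spread_function(s)
                center = np.argmin(np.abs(psf.axes[0]))
                side = np.abs(np.delete(psf.values, center))
                vals.append(np.sqrt(np.mean(side**2)))
            rms.append(np.mean(vals))
        assert all(a > b for a, b in zip(rms, rms[1:]))
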