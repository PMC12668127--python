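"""Quadrature recombination and hypercomplex Fourier processing."""

import numpy as np
import pytest

import tropnmr as t
from tropnmr.processing import RANCE_KAY_NOISE_FACTOR
from conftest import dim_direct, dim_indirect, make_pair_2d


class TestRecombineEchoAntiecho:
    def test_zero_offset_gives_pure_cosine_component(self):
        """At zero offset echo and antiecho are identical, so the sine
        component of the recombined pair vanishes identically."""
        res, (dims, scheme), _ = make_pair_2d(
            offsets=((0.0, 200.0),), amps=(1.0,), decays=(20.0, 25.0)
        )
        g = t.recombine_echo_antiecho(t.simulate_experiment(res, dims, scheme), "N")
        cos = g.data[0]
        sin = g.data[1]
        envelope = np.exp(-20.0 * dims[0].times)
        np.testing.assert_allclose(cos[:, 0].real, envelope, atol=1e-12)
        np.testing.assert_allclose(sin, 0.0, atol=1e-12)

    def test_all_zero_grid_stays_zero(self):
        _, (dims, scheme), _ = make_pair_2d()
        g = t.recombine_echo_antiecho(t.simulate_experiment([], dims, scheme), "N")
        assert np.all(g.data == 0)

    def test_unknown_dimension_rejected(self):
        _, (dims, scheme), _ = make_pair_2d()
        g = t.simulate_experiment([], dims, scheme)
        with pytest.raises(ValueError, match="unknown dimension"):
            t.recombine_echo_antiecho(g, "Q")

    def test_non_echo_antiecho_dimension_rejected(self):
        _, _, (dims_st, scheme_st) = make_pair_2d()
        g = t.simulate_experiment([], dims_st, scheme_st)
        with pytest.raises(t.ProcessingOrderError):
            t.recombine_echo_antiecho(g, "N")

    def test_noise_contract_sigma_over_sqrt2(self):
        """Recombining components carrying iid noise sigma yields components
        at sigma/sqrt(2) under the (E +/- A)/2 convention (Monte Carlo)."""
        rng = np.random.default_rng(11)
        n = 10_000
        echo = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        anti = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        cos = 0.5 * (echo + anti)
        sin = (echo - anti) / 2j
        target = RANCE_KAY_NOISE_FACTOR
        for comp in (cos, sin):
            assert np.std(comp.real) == pytest.approx(target, rel=0.05)
            assert np.std(comp.imag) == pytest.approx(target, rel=0.05)

    def test_noise_scale_recorded_in_provenance(self):
        _, (dims, scheme), _ = make_pair_2d()
        g = t.recombine_echo_antiecho(t.simulate_experiment([], dims, scheme), "N")
        assert g.meta["noise_scale"] == pytest.approx(RANCE_KAY_NOISE_FACTOR)


class TestStatesTppi:
    def test_zero_offset_peak_lands_on_carrier(self):
        scheme = t.TransferScheme({"N": t.TransferStep("cp_states_tppi")})
        dims = [dim_indirect(quad="states_tppi"), dim_direct()]
        res = [t.Resonance((0.0, 0.0), 1.0, (15.0, 20.0))]
        g = t.states_tppi_to_states(t.simulate_experiment(res, dims, scheme), "N")
        spec = t.hypercomplex_ft(g)
        i, _ = np.unravel_index(np.argmax(spec.values), spec.values.shape)
        assert spec.axes[0][i] == pytest.approx(dims[0].carrier, abs=1e-9)

    def test_all_zero_grid_stays_zero(self):
        scheme = t.TransferScheme({"N": t.TransferStep("cp_states_tppi")})
        dims = [dim_indirect(quad="states_tppi"), dim_direct()]
        g = t.states_tppi_to_states(t.simulate_experiment([], dims, scheme), "N")
        assert np.all(g.data == 0)

    def test_quarter_spectral_width_matches_states_encoding(self):
        sw = 1600.0
        res = [t.Resonance((0.25 * sw, -300.0), 1.0, (15.0, 20.0))]
        scheme_tp = t.TransferScheme({"N": t.TransferStep("cp_states_tppi")})
        scheme_st = t.TransferScheme({"N": t.TransferStep("cp_states")})
        g_tp = t.simulate_experiment(
            res, [dim_indirect(quad="states_tppi", sw=sw), dim_direct()], scheme_tp
        )
        g_st = t.simulate_experiment(
            res, [dim_indirect(quad="states", sw=sw), dim_direct()], scheme_st
        )
        s_tp = t.hypercomplex_ft(t.states_tppi_to_states(g_tp, "N"))
        s_st = t.hypercomplex_ft(g_st)
        np.testing.assert_allclose(s_tp.values, s_st.values, atol=1e-10)

    def test_wrong_quadrature_rejected(self):
        _, (dims, scheme), _ = make_pair_2d()
        g = t.simulate_experiment([], dims, scheme)
        with pytest.raises(t.ProcessingOrderError):
            t.states_tppi_to_states(g, "N")


class TestHypercomplexFT:
    def test_single_resonance_peaks_at_its_ppm(self):
        res = [t.Resonance((400.0, -600.0), 2.5, (20.0, 25.0))]
        _, _, (dims, scheme) = make_pair_2d()
        spec = t.hypercomplex_ft(
            t.simulate_experiment(res, dims, scheme), zero_fill=2
        )
        idx = np.unravel_index(np.argmax(spec.values), spec.values.shape)
        expect = (118.0 + 400.0 / 81.1, 8.5 - 600.0 / 800.0)
        for i, (ax, p) in enumerate(zip(spec.axes, expect)):
            step = abs(ax[1] - ax[0])
            assert abs(ax[idx[i]] - p) <= step + 1e-12

    def test_peak_height_proportional_to_amplitude(self):
        _, _, (dims, scheme) = make_pair_2d()
        heights = []
        for a in (1.0, 2.0):
            res = [t.Resonance((400.0, -600.0), a, (20.0, 25.0))]
            spec = t.hypercomplex_ft(t.simulate_experiment(res, dims, scheme))
            heights.append(spec.values.max())
        assert heights[1] == pytest.approx(2 * heights[0], rel=1e-12)

    def test_linearity_on_random_grids(self):
        _, _, (dims, scheme) = make_pair_2d()
        rng = np.random.default_rng(5)
        shape = (2, dims[0].n_complex_points, dims[1].n_complex_points)
        base = t.simulate_experiment([], dims, scheme)
        x = base.with_data(rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
        y = base.with_data(rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
        xy = base.with_data(x.data + y.data)
        np.testing.assert_allclose(
            t.hypercomplex_ft(xy).values,
            t.hypercomplex_ft(x).values + t.hypercomplex_ft(y).values,
            atol=1e-9,
        )

    def test_unrecombined_echo_antiecho_fails_loudly(self):
        res, (dims, scheme), _ = make_pair_2d()
        g = t.simulate_experiment(res, dims, scheme)
        with pytest.raises(t.ProcessingOrderError, match="recombine"):
            t.hypercomplex_ft(g)

    def test_parseval_power_scales_quadratically(self):
        res, (dims, scheme), _ = make_pair_2d()
        g = t.simulate_experiment(res, dims, scheme)
        p1 = t.hypercomplex_ft(t.recombine_echo_antiecho(g, "N")).total_power()
        g2 = g.with_data(2.0 * g.data)
        p2 = t.hypercomplex_ft(t.recombine_echo_antiecho(g2, "N")).total_power()
        assert p2 == pytest.approx(4.0 * p1, rel=1e-10)


class TestEncodingEquivalence:
    def test_echo_antiecho_recombination_equals_states(self):
        """Noiseless E/A acquisition, recombined and transformed, equals the
        States acquisition of the same resonances to 1e-10 relative."""
        res, (dims_ea, scheme_ea), (dims_st, scheme_st) = make_pair_2d()
        s_ea = t.hypercomplex_ft(
            t.recombine_echo_antiecho(
                t.simulate_experiment(res, dims_ea, scheme_ea), "N"
            )
        )
        s_st = t.hypercomplex_ft(t.simulate_experiment(res, dims_st, scheme_st))
        scale = np.abs(s_st.values).max()
        np.testing.assert_allclose(s_ea.values / scale, s_st.values / scale, atol=1e-10)

    def test_mixed_encoding_order_independent(self):
        """States-TPPI conversion and E/A recombination commute: processing
        the two indirect dimensions in either order yields identical
        spectra."""
        b = t.fixture_library("toy5d_3enh_smallgrid", 3)
        g = t.simulate_experiment(b.resonances, list(b.dims), b.scheme)
        order_a = t.recombine_echo_antiecho(
            t.states_tppi_to_states(
                t.recombine_echo_antiecho(
                    t.recombine_echo_antiecho(g, "CO"), "CA"
                ),
                "N1",
            ),
            "N2",
        )
        order_b = t.states_tppi_to_states(
            t.recombine_echo_antiecho(
                t.recombine_echo_antiecho(
                    t.recombine_echo_antiecho(g, "N2"), "CA"
                ),
                "CO",
            ),
            "N1",
        )
        sa = t.hypercomplex_ft(order_a, zero_fill=1)
        sb = t.hypercomplex_ft(order_b, zero_fill=1)
        np.testing.assert_allclose(sa.values, sb.values, atol=1e-10)

    def test_mixed_3d_fixture_matches_all_states_reference(self):
        b = t.fixture_library("toy3d_mixed_encoding", 2)
        conv = b.conventional()
        s_mixed = t.hypercomplex_ft(
            t.convert_to_states(
                t.simulate_experiment(b.resonances, list(b.dims), b.scheme)
            )
        )
        s_states = t.hypercomplex_ft(
            t.simulate_experiment(conv.resonances, list(conv.dims), conv.scheme)
        )
        scale = np.abs(s_states.values).max()
        np.testing.assert_allclose(
            s_mixed.values / scale, s_states.values / scale, atol=1e-10
        )
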