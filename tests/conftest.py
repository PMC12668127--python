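"""Shared builders and measurement helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import tropnmr as t
from tropnmr.dimensions import SpectrumGrid


def dim_indirect(label="N", quad="states", n=16, sw=1600.0, obs=81.1, carrier=118.0):
    return t.DimensionSpec(label, "15N", "indirect", quad, n, sw, obs, carrier)


def dim_direct(n=64, sw=3200.0, obs=800.0, carrier=8.5):
    return t.DimensionSpec("H", "1H", "direct", "simple", n, sw, obs, carrier)


def make_pair_2d(offsets=((500.0, 300.0), (-200.0, -400.0)), amps=(1.0, 0.6),
                 decays=(20.0, 25.0), n_ind=16, bulk=1.0):
    """Matched echo/antiecho and States encodings of the same resonances."""
    res = [t.Resonance(o, a, decays) for o, a in zip(offsets, amps)]
    scheme_ea = t.TransferScheme({"N": t.TransferStep("trop_echo_antiecho", bulk)})
    scheme_st = scheme_ea.conventional()
    dims_ea = [dim_indirect(quad="echo_antiecho", n=n_ind), dim_direct()]
    dims_st = t.dims_for_scheme(dims_ea, scheme_st)
    return res, (dims_ea, scheme_ea), (dims_st, scheme_st)


@pytest.fixture(scope="session")
def sparse2d():
    """2D bundle with on-grid, non-decaying indirect resonances.

    The indirect spectrum is genuinely sparse, which makes the PSF
    convolution identity exact and gives the thresholding reconstruction a
    well-posed problem.
    """
    n_ind, sw = 64, 1600.0
    dims = [dim_indirect(quad="echo_antiecho", n=n_ind, sw=sw), dim_direct()]
    scheme = t.TransferScheme({"N": t.TransferStep("trop_echo_antiecho", 1.0)})
    ks = (-17, 5, 21)
    specs = [(ks[0], 300.0, 1.0), (ks[1], -650.0, 0.7), (ks[2], 950.0, 0.5)]
    res = [
        t.Resonance((k * sw / n_ind, od), a, (0.0, 35.0)) for k, od, a in specs
    ]
    positions = [
        (118.0 + k * sw / n_ind / 81.1, 8.5 + od / 800.0) for k, od, a in specs
    ]
    return {"resonances": res, "dims": dims, "scheme": scheme, "positions": positions}


def offpeak_mask(spectrum: SpectrumGrid, positions, frac_halfwidth=0.08):
    """Boolean mask of grid points away from every peak (per-axis boxes)."""
    keep = np.ones(spectrum.values.shape, dtype=bool)
    for pos in positions:
        box = np.ones(spectrum.values.shape, dtype=bool)
        for i, (ax, p) in enumerate(zip(spectrum.axes, pos)):
            sel = np.abs(ax - p) <= frac_halfwidth * abs(ax[-1] - ax[0])
            shape = [1] * spectrum.ndim
            shape[i] = ax.size
            box &= sel.reshape(shape)
        keep &= ~box
    return keep


def max_offpeak_deviation(spectrum, reference, positions):
    """Largest artifact: |spectrum - reference| away from all peaks."""
    keep = offpeak_mask(spectrum, positions)
    return float(np.abs(spectrum.values - reference.values)[keep].max())


def snr_ratio_study(bundle, n_real, sigma, seed, conventional=None):
    """Monte-Carlo peak-SNR ratio (enhanced over conventional).

    Noise is measured as the off-peak standard deviation of the difference
    between each noisy spectrum and its noiseless reference, an oracle-style
    measurement that isolates the thermal component; the ratio of per-peak
    mean SNRs is returned together with its propagated standard error.
    """
    conv = conventional or bundle.conventional()
    pos = bundle.peak_positions()
    ref_e = t.hypercomplex_ft(
        t.convert_to_states(
            t.simulate_experiment(bundle.resonances, list(bundle.dims), bundle.scheme)
        )
    )
    ref_c = t.hypercomplex_ft(
        t.convert_to_states(
            t.simulate_experiment(conv.resonances, list(conv.dims), conv.scheme)
        )
    )
    keep_e = offpeak_mask(ref_e, pos, 0.1)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2 * n_real)
    snr_e = np.zeros((n_real, len(pos)))
    snr_c = np.zeros((n_real, len(pos)))
    for k in range(n_real):
        ge = t.convert_to_states(
            t.simulate_experiment(
                bundle.resonances, list(bundle.dims), bundle.scheme,
                t.NoiseModel(sigma, int(seeds[2 * k])),
            )
        )
        gc = t.convert_to_states(
            t.simulate_experiment(
                conv.resonances, list(conv.dims), conv.scheme,
                t.NoiseModel(sigma, int(seeds[2 * k + 1])),
            )
        )
        se = t.hypercomplex_ft(ge)
        sc = t.hypercomplex_ft(gc)
        ne = float(np.std((se.values - ref_e.values)[keep_e], ddof=1))
        nc = float(np.std((sc.values - ref_c.values)[keep_e], ddof=1))
        snr_e[k] = [se.value_at(p) / ne for p in pos]
        snr_c[k] = [sc.value_at(p) / nc for p in pos]
    me, mc = snr_e.mean(0), snr_c.mean(0)
    see = snr_e.std(0, ddof=1) / np.sqrt(n_real)
    sec = snr_c.std(0, ddof=1) / np.sqrt(n_real)
    per_peak = me / mc
    per_peak_se = per_peak * np.sqrt((see / me) ** 2 + (sec / mc) ** 2)
    ratio = float(per_peak.mean())
    se_total = float(np.sqrt((per_peak_se**2).sum()) / len(pos))
    return ratio, se_total
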