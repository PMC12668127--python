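"""Deterministic synthetic experiment bundles sized for desk-scale runs.

Each fixture returns a :class:`SimulationBundle` of resonances, dimension
specs and a transfer scheme that runs end-to-end (simulation, recombination,
Fourier processing, NUS reconstruction) in seconds.  Peak positions are drawn
reproducibly from the fixture seed within +/- 0.35 of each spectral width so
that peaks stay clear of the spectrum edges; amplitudes and decays are fixed
per fixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dimensions import DimensionSpec
from .simulate import Resonance, TransferScheme, TransferStep, dims_for_scheme

__all__ = ["SimulationBundle", "fixture_library", "FIXTURE_NAMES"]


@dataclass(frozen=True)
class SimulationBundle:
    """A named, reproducible synthetic experiment definition."""

    name: str
    seed: int
    resonances: tuple
    dims: tuple
    scheme: TransferScheme

    @property
    def indirect_shape(self) -> tuple[int, ...]:
        return tuple(d.n_complex_points for d in self.dims[:-1])

    def conventional(self) -> "SimulationBundle":
        """Matched CP-based bundle (TROP dimensions re-encoded as States)."""
        scheme = self.scheme.conventional()
        return SimulationBundle(
            name=self.name + "_conventional",
            seed=self.seed,
            resonances=self.resonances,
            dims=tuple(dims_for_scheme(self.dims, scheme)),
            scheme=scheme,
        )

    def with_bulk(self, bulk: float) -> "SimulationBundle":
        """Same bundle with every TROP transfer set to bulk efficiency ``bulk``."""
        scheme = TransferScheme(
            {
                label: (
                    TransferStep(step.mode, bulk)
                    if step.mode == "trop_echo_antiecho"
                    else step
                )
                for label, step in self.scheme.entries.items()
            }
        )
        return SimulationBundle(
            name=self.name, seed=self.seed, resonances=self.resonances,
            dims=self.dims, scheme=scheme,
        )

    def with_amplitudes(self, scale: float) -> "SimulationBundle":
        """Same bundle with all resonance amplitudes multiplied by ``scale``."""
        res = tuple(
            Resonance(r.offsets, r.amplitude * scale, r.decays)
            for r in self.resonances
        )
        return SimulationBundle(
            name=self.name, seed=self.seed, resonances=res,
            dims=self.dims, scheme=self.scheme,
        )

    def peak_positions(self) -> list[tuple[float, ...]]:
        """Peak coordinates in ppm, one tuple per resonance (dims order)."""
        return [
            tuple(d.offset_to_ppm(o) for d, o in zip(self.dims, r.offsets))
            for r in self.resonances
        ]


def _draw_offsets(rng: np.random.Generator, dims, n_peaks: int) -> np.ndarray:
    """Peak offsets within +/- 0.35 * sw, separated by >= 2 grid steps per dim.

    Coarsely digitized dimensions (fewer than 16 complex points, as in the
    4D/5D toys) get offsets snapped onto grid frequencies: at such low
    resolution an off-grid peak loses most of its height to sinc leakage in
    every dimension, which would make the toy spectra unrepresentative.
    """
    offsets = np.empty((n_peaks, len(dims)))
    for j, d in enumerate(dims):
        df = d.spectral_width / d.n_complex_points
        while True:
            col = rng.uniform(-0.35, 0.35, size=n_peaks) * d.spectral_width
            if n_peaks == 1 or np.min(np.abs(np.subtract.outer(col, col)[~np.eye(n_peaks, dtype=bool)])) > 2 * df:
                break
        if d.n_complex_points < 16:
            col = np.round(col / df) * df
        offsets[:, j] = col
    return offsets


def _dim(label, nucleus, role, quad, n, sw, obs, carrier):
    return DimensionSpec(label, nucleus, role, quad, n, sw, obs, carrier)


def _bundle(name, seed, dims, scheme, amplitudes, decays_hz):
    rng = np.random.default_rng(seed)
    dims = tuple(dims_for_scheme(dims, scheme))
    offsets = _draw_offsets(rng, dims, len(amplitudes))
    resonances = tuple(
        Resonance(tuple(offsets[i]), amplitudes[i], decays_hz)
        for i in range(len(amplitudes))
    )
    return SimulationBundle(name, seed, resonances, dims, scheme)


def _toy2d(seed):
    dims = [
        _dim("N", "15N", "indirect", "echo_antiecho", 16, 1600.0, 81.1, 118.0),
        _dim("H", "1H", "direct", "simple", 64, 3200.0, 800.0, 8.5),
    ]
    scheme = TransferScheme({"N": TransferStep("trop_echo_antiecho", 1.0)})
    return _bundle("toy2d", seed, dims, scheme, (1.0, 0.75, 0.55), (22.0, 28.0))


def _toy3d_mixed(seed):
    dims = [
        _dim("CO", "13C", "indirect", "states", 10, 1500.0, 201.2, 175.0),
        _dim("N", "15N", "indirect", "echo_antiecho", 10, 1600.0, 81.1, 118.0),
        _dim("H", "1H", "direct", "simple", 48, 3200.0, 800.0, 8.5),
    ]
    scheme = TransferScheme(
        {"CO": TransferStep("cp_states"), "N": TransferStep("trop_echo_antiecho", 1.0)}
    )
    return _bundle(
        "toy3d_mixed_encoding", seed, dims, scheme, (1.0, 0.7, 0.5), (30.0, 25.0, 28.0)
    )


def _toy4d_3enh(seed):
    dims = [
        _dim("CO", "13C", "indirect", "echo_antiecho", 8, 1500.0, 201.2, 175.0),
        _dim("CA", "13C", "indirect", "echo_antiecho", 8, 1800.0, 201.2, 55.0),
        _dim("N", "15N", "indirect", "echo_antiecho", 8, 1600.0, 81.1, 118.0),
        _dim("H", "1H", "direct", "simple", 32, 3200.0, 800.0, 8.5),
    ]
    scheme = TransferScheme(
        {
            "CO": TransferStep("trop_echo_antiecho", 1.0),
            "CA": TransferStep("trop_echo_antiecho", 1.0),
            "N": TransferStep("trop_echo_antiecho", 1.0),
        }
    )
    return _bundle("toy4d_3enh", seed, dims, scheme, (1.0, 0.6), (35.0, 35.0, 30.0, 30.0))


def _toy5d_3enh(seed):
    # Amide-to-amide style pathway: first N encoded conventionally
    # (States-TPPI), the CO/CA/N dimensions preserved via TROPs.
    dims = [
        _dim("N1", "15N", "indirect", "states_tppi", 6, 1600.0, 81.1, 118.0),
        _dim("CO", "13C", "indirect", "echo_antiecho", 6, 1500.0, 201.2, 175.0),
        _dim("CA", "13C", "indirect", "echo_antiecho", 6, 1800.0, 201.2, 55.0),
        _dim("N2", "15N", "indirect", "echo_antiecho", 6, 1600.0, 81.1, 118.0),
        _dim("H", "1H", "direct", "simple", 32, 3200.0, 800.0, 8.5),
    ]
    scheme = TransferScheme(
        {
            "N1": TransferStep("cp_states_tppi"),
            "CO": TransferStep("trop_echo_antiecho", 1.0),
            "CA": TransferStep("trop_echo_antiecho", 1.0),
            "N2": TransferStep("trop_echo_antiecho", 1.0),
        }
    )
    return _bundle(
        "toy5d_3enh_smallgrid", seed, dims, scheme, (1.0, 0.65),
        (35.0, 35.0, 35.0, 30.0, 30.0),
    )


_FIXTURES = {
    "toy2d": _toy2d,
    "toy3d_mixed_encoding": _toy3d_mixed,
    "toy4d_3enh": _toy4d_3enh,
    "toy5d_3enh_smallgrid": _toy5d_3enh,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture_library(name: str, seed: int = 0) -> SimulationBundle:
    """Return the named deterministic fixture bundle.

    Parameters
    ----------
    name :
        One of ``toy2d``, ``toy3d_mixed_encoding``, ``toy4d_3enh``,
        ``toy5d_3enh_smallgrid``.
    seed :
        Seed for the reproducible peak-position draw; identical
        ``(name, seed)`` always returns the same bundle.
    """
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return factory(seed)
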