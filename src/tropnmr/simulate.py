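"""Synthetic hypercomplex acquisition under CP-like and TROP-like transfers.

The transfer physics is abstracted to amplitude bookkeeping: a conventional
cross-polarization (CP) transfer retains a single transverse component of the
evolving magnetization at unit relative amplitude, so a CP-based indirect
dimension records cosine- and sine-modulated FIDs of amplitude 1.  A
transverse-mixing optimal-control (TROP) transfer preserves both components
("preservation of equivalent pathways") at bulk efficiency ``b`` relative to
CP, so an enhanced indirect dimension records echo/antiecho FIDs
``b * exp(+/- i*Omega*t - R*t)``.  After Rance-Kay recombination the two
coherently added pathways give per-component amplitude ``b`` with thermal
noise reduced by sqrt(2), which is the sqrt(2)-per-dimension SNR gain at
``b = 1``.  Thermal noise is receiver-determined and therefore identical per
recorded FID for both experiment types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from functools import reduce

import numpy as np

from .dimensions import DimensionSpec, HypercomplexGrid

__all__ = [
    "Resonance",
    "TransferStep",
    "TransferScheme",
    "NoiseModel",
    "TRANSFER_MODES",
    "simulate_experiment",
    "first_fid",
    "dims_for_scheme",
]

TWO_PI = 2.0 * np.pi

TRANSFER_MODES = ("cp_states", "cp_states_tppi", "trop_echo_antiecho")

#: Quadrature a dimension must declare for each transfer mode.
MODE_QUADRATURE = {
    "cp_states": "states",
    "cp_states_tppi": "states_tppi",
    "trop_echo_antiecho": "echo_antiecho",
}


@dataclass(frozen=True)
class Resonance:
    """One peak of the signal model.

    ``offsets`` are frequency offsets from the carrier in Hz (one per
    dimension, direct last), ``amplitude`` is the signal amplitude in
    arbitrary units and ``decays`` are per-dimension decay rates R in 1/s.
    """

    offsets: tuple[float, ...]
    amplitude: float
    decays: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", tuple(float(o) for o in self.offsets))
        object.__setattr__(self, "decays", tuple(float(r) for r in self.decays))
        if len(self.offsets) != len(self.decays):
            raise ValueError("offsets and decays must have one entry per dimension")
        if any(r < 0 for r in self.decays):
            raise ValueError("decay rates must be >= 0")


@dataclass(frozen=True)
class TransferStep:
    """Transfer into one indirect dimension: mode plus bulk efficiency ``b``.

    ``bulk`` is the per-component signal amplitude relative to the CP-based
    experiment; it is meaningful only for TROP transfers and pinned to 1 for
    CP modes (CP defines the reference amplitude).
    """

    mode: str
    bulk: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in TRANSFER_MODES:
            raise ValueError(f"unknown transfer mode {self.mode!r}")
        if self.bulk <= 0:
            raise ValueError("bulk efficiency must be positive")
        if self.mode != "trop_echo_antiecho":
            object.__setattr__(self, "bulk", 1.0)


@dataclass(frozen=True)
class TransferScheme:
    """Per-indirect-dimension transfer modes, keyed by dimension label."""

    entries: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        for label, step in self.entries.items():
            if not isinstance(step, TransferStep):
                raise TypeError(f"entry for {label!r} must be a TransferStep")

    def step(self, label: str) -> TransferStep:
        return self.entries[label]

    @property
    def n_enhanced(self) -> int:
        return sum(1 for s in self.entries.values() if s.mode == "trop_echo_antiecho")

    @property
    def bulk(self) -> float:
        """Overall bulk signal relative to the all-CP experiment (product of b)."""
        return float(np.prod([s.bulk for s in self.entries.values()]))

    def conventional(self) -> "TransferScheme":
        """The matched CP-based scheme: every TROP transfer replaced by CP/States."""
        return TransferScheme(
            {
                label: (
                    TransferStep("cp_states")
                    if step.mode == "trop_echo_antiecho"
                    else step
                )
                for label, step in self.entries.items()
            }
        )

    def describe(self) -> dict:
        return {
            label: {"mode": s.mode, "bulk": s.bulk} for label, s in self.entries.items()
        }


@dataclass(frozen=True)
class NoiseModel:
    """Complex Gaussian thermal noise: per-point standard deviation ``sigma``
    on the real and imaginary parts of every recorded FID point, identically
    for every hypercomplex component (receiver noise is uncorrelated between
    separately recorded FIDs)."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def dims_for_scheme(dims, scheme: TransferScheme):
    """Dims with indirect quadratures set to match the scheme's transfer modes."""
    from dataclasses import replace

    out = []
    for d in dims:
        if d.role == "indirect":
            out.append(replace(d, quadrature=MODE_QUADRATURE[scheme.step(d.label).mode]))
        else:
            out.append(d)
    return out


def _indirect_factor(
    step: TransferStep, component: int, omega: float, decay: float, dim: DimensionSpec
) -> np.ndarray:
    """Modulation of one indirect dimension for one hypercomplex component."""
    t = dim.times
    envelope = np.exp(-decay * t)
    if step.mode == "trop_echo_antiecho":
        sign = +1.0 if component == 0 else -1.0  # echo = +Omega (p-type) pathway
        return step.bulk * np.exp(sign * 1j * TWO_PI * omega * t) * envelope
    trig = np.cos(TWO_PI * omega * t) if component == 0 else np.sin(TWO_PI * omega * t)
    base = trig * envelope
    if step.mode == "cp_states_tppi":
        base = base * (-1.0) ** np.arange(dim.n_complex_points)
    return base


def simulate_experiment(
    resonances,
    dims,
    scheme: TransferScheme,
    noise: NoiseModel | None = None,
) -> HypercomplexGrid:
    """Simulate a hypercomplex acquisition of a resonance list.

    For each hypercomplex component vector the FID is the sum over resonances
    of a separable product over dimensions: the direct dimension contributes
    ``a * exp(i*Omega*t - R*t)``; a CP dimension contributes
    ``cos(Omega*t) * exp(-R*t)`` or ``sin(Omega*t) * exp(-R*t)`` (component 0/1,
    single transferred component, unit amplitude; States-TPPI additionally
    alternates the sign per increment); a TROP dimension contributes
    ``b * exp(+/- i*Omega*t - R*t)`` (echo/antiecho component).  Independent
    complex Gaussian noise is then added to every recorded point of every
    component FID.  Identical inputs and seed give bit-identical output.
    """
    dims = list(dims)
    if not dims or dims[-1].role != "direct" or sum(d.role == "direct" for d in dims) != 1:
        raise ValueError("dims must contain exactly one direct dimension, listed last")
    indirect = dims[:-1]
    labels = {d.label for d in indirect}
    if set(scheme.entries) != labels:
        raise ValueError(
            f"scheme covers {sorted(scheme.entries)}, experiment has indirect "
            f"dimensions {sorted(labels)}"
        )
    for d in indirect:
        expected = MODE_QUADRATURE[scheme.step(d.label).mode]
        if d.quadrature != expected:
            raise ValueError(
                f"dimension {d.label!r} declares quadrature {d.quadrature!r} but "
                f"mode {scheme.step(d.label).mode!r} requires {expected!r}"
            )
    for res in resonances:
        if len(res.offsets) != len(dims):
            raise ValueError("resonance must provide one offset per dimension")
        for o, d in zip(res.offsets, dims):
            if abs(o) > d.spectral_width / 2:
                raise ValueError(
                    f"offset {o} Hz outside +/- sw/2 of dimension {d.label!r}"
                )

    n_ind = len(indirect)
    grid_shape = tuple(d.n_complex_points for d in dims)
    data = np.zeros((2,) * n_ind + grid_shape, dtype=complex)

    direct = dims[-1]
    for comp in product((0, 1), repeat=n_ind):
        acc = np.zeros(grid_shape, dtype=complex)
        for res in resonances:
            factors = [
                _indirect_factor(
                    scheme.step(d.label), comp[j], res.offsets[j], res.decays[j], d
                )
                for j, d in enumerate(indirect)
            ]
            t = direct.times
            factors.append(
                np.exp((1j * TWO_PI * res.offsets[-1] - res.decays[-1]) * t)
            )
            acc = acc + res.amplitude * reduce(np.multiply.outer, factors)
        data[comp] = acc

    meta = {
        "scheme": scheme.describe(),
        "n_enhanced": scheme.n_enhanced,
        "bulk": scheme.bulk,
        "noise_sigma": 0.0 if noise is None else noise.sigma,
        "noise_seed": None if noise is None else noise.seed,
        "noise_scale": 1.0,
    }
    if noise is not None and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        data = data + noise.sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    return HypercomplexGrid(dims=dims, data=data, meta=meta)


def first_fid(grid: HypercomplexGrid) -> np.ndarray:
    """Direct-dimension FID at all-zero indirect increments, first component.

    This is the "bulk signal" probe: for a noiseless on-carrier resonance it
    equals ``a * exp(-R*t)`` times the product of transfer amplitudes, so the
    first-FID amplitude ratio of a TROP experiment over its CP counterpart
    recovers the bulk efficiency ``b`` (per enhanced dimension).
    """
    n = grid.n_indirect
    index = (0,) * n + (0,) * n + (slice(None),)
    return grid.data[index].copy()
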