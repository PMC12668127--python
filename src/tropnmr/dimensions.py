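"""Dimension metadata and containers for hypercomplex multidimensional NMR data.

A multidimensional NMR acquisition records, for every combination of
indirect-dimension time increments, one complex FID along the directly
detected dimension.  Phase-sensitive frequency discrimination in an indirect
dimension requires two data sets per time increment -- cosine- and
sine-modulated FIDs for States-type quadrature, or echo- and
antiecho-modulated FIDs for Rance-Kay-type (preserved-pathway) quadrature.
An experiment with ``n`` indirect dimensions therefore stores ``2**n``
component FIDs per point of the indirect time grid ("hypercomplex" data).

:class:`HypercomplexGrid` holds that raw time-domain data;
:class:`SpectrumGrid` holds processed frequency-domain data with ppm axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "DimensionSpec",
    "HypercomplexGrid",
    "SpectrumGrid",
    "QUADRATURES",
]

QUADRATURES = ("simple", "states", "states_tppi", "echo_antiecho")


@dataclass(frozen=True)
class DimensionSpec:
    """Metadata for one spectral dimension.

    Parameters
    ----------
    label :
        Short identifier, unique within an experiment (e.g. ``"N"``, ``"Hdet"``).
    nucleus :
        Observed nucleus, e.g. ``"1H"``, ``"15N"``, ``"13C"``.
    role :
        ``"direct"`` for the acquisition dimension, ``"indirect"`` otherwise.
    quadrature :
        ``"simple"`` (plain complex sampling; direct dimension only),
        ``"states"``, ``"states_tppi"`` or ``"echo_antiecho"`` (indirect only).
    n_complex_points :
        Number of complex points (time increments) recorded.
    spectral_width :
        Sweep width in Hz; the complex dwell time is ``1 / spectral_width``.
    observe_frequency :
        Larmor frequency of the nucleus in MHz, used for Hz <-> ppm conversion.
    carrier :
        Carrier (transmitter) position in ppm; frequency offsets are relative
        to the carrier.
    """

    label: str
    nucleus: str
    role: str
    quadrature: str
    n_complex_points: int
    spectral_width: float
    observe_frequency: float
    carrier: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("direct", "indirect"):
            raise ValueError(f"role must be 'direct' or 'indirect', got {self.role!r}")
        if self.quadrature not in QUADRATURES:
            raise ValueError(f"unknown quadrature {self.quadrature!r}")
        if self.role == "direct" and self.quadrature != "simple":
            raise ValueError("a direct dimension must use simple quadrature")
        if self.role == "indirect" and self.quadrature == "simple":
            raise ValueError("an indirect dimension needs a phase-sensitive quadrature")
        if self.n_complex_points < 1:
            raise ValueError("n_complex_points must be >= 1")
        if self.spectral_width <= 0:
            raise ValueError("spectral_width must be positive")
        if self.observe_frequency <= 0:
            raise ValueError("observe_frequency must be positive")

    # -- time / frequency axes -------------------------------------------------

    @property
    def dwell(self) -> float:
        """Complex dwell time in seconds."""
        return 1.0 / self.spectral_width

    @property
    def times(self) -> np.ndarray:
        """Sampled evolution times ``t_k = k / spectral_width`` (seconds)."""
        return np.arange(self.n_complex_points) / self.spectral_width

    def ppm_axis(self, n_points: int | None = None) -> np.ndarray:
        """Strictly increasing ppm axis of the Fourier-transformed dimension.

        ``ppm = carrier + offset_Hz / observe_frequency`` with offsets covering
        ``[-spectral_width/2, +spectral_width/2)`` on an ``n_points`` grid.
        """
        n = self.n_complex_points if n_points is None else int(n_points)
        freqs = np.fft.fftshift(np.fft.fftfreq(n, d=self.dwell))
        return self.carrier + freqs / self.observe_frequency

    def offset_to_ppm(self, offset_hz: float) -> float:
        return self.carrier + offset_hz / self.observe_frequency

    def ppm_to_offset(self, ppm: float) -> float:
        return (ppm - self.carrier) * self.observe_frequency


def _validate_dims(dims: Sequence[DimensionSpec]) -> None:
    labels = [d.label for d in dims]
    if len(set(labels)) != len(labels):
        raise ValueError(f"dimension labels must be unique, got {labels}")
    direct = [d for d in dims if d.role == "direct"]
    if len(direct) != 1:
        raise ValueError("exactly one direct dimension is required")
    if dims[-1].role != "direct":
        raise ValueError("the direct dimension must be listed last (acquisition order)")


@dataclass
class HypercomplexGrid:
    """Raw hypercomplex time-domain data.

    ``data`` is a complex array of shape ``(2,)*n_indirect + grid_shape`` where
    ``grid_shape`` lists ``n_complex_points`` of every dimension in ``dims``
    order (indirect dimensions as acquired, direct dimension last).  Component
    axis ``j`` belongs to ``dims[j]`` and indexes its two quadrature data sets:
    ``0``/``1`` mean cos/sin for States-type dimensions and echo/antiecho for
    Rance-Kay-type dimensions.  The direct-dimension FID itself is stored as
    ordinary complex numbers.

    ``meta`` carries provenance (transfer scheme, noise sigma, seed, applied
    processing steps, NUS mask ...).
    """

    dims: list[DimensionSpec]
    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dims = list(self.dims)
        _validate_dims(self.dims)
        self.data = np.asarray(self.data)
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(complex)
        expected = (2,) * self.n_indirect + self.grid_shape
        if self.data.shape != expected:
            raise ValueError(
                f"data shape {self.data.shape} does not match expected {expected}"
            )

    # -- structure -------------------------------------------------------------

    @property
    def n_indirect(self) -> int:
        return len(self.dims) - 1

    @property
    def indirect_dims(self) -> list[DimensionSpec]:
        return self.dims[:-1]

    @property
    def direct_dim(self) -> DimensionSpec:
        return self.dims[-1]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return tuple(d.n_complex_points for d in self.dims)

    @property
    def indirect_shape(self) -> tuple[int, ...]:
        return tuple(d.n_complex_points for d in self.indirect_dims)

    def dim_index(self, label: str) -> int:
        for i, d in enumerate(self.dims):
            if d.label == label:
                return i
        raise ValueError(f"unknown dimension label {label!r}")

    def get_dim(self, label: str) -> DimensionSpec:
        return self.dims[self.dim_index(label)]

    def component_axis(self, label: str) -> int:
        """Axis of ``data`` indexing the quadrature components of ``label``."""
        i = self.dim_index(label)
        if self.dims[i].role != "indirect":
            raise ValueError(f"dimension {label!r} is not indirect")
        return i

    def time_axis(self, label: str) -> int:
        """Axis of ``data`` holding the time increments of ``label``."""
        return self.n_indirect + self.dim_index(label)

    def with_data(self, data: np.ndarray, **meta_updates) -> "HypercomplexGrid":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return HypercomplexGrid(dims=list(self.dims), data=data, meta=meta)

    def replace_dim(self, label: str, **changes) -> list[DimensionSpec]:
        """New dims list with ``label``'s spec updated via dataclass replace."""
        i = self.dim_index(label)
        dims = list(self.dims)
        dims[i] = replace(dims[i], **changes)
        return dims

    def first_component_vector(self) -> tuple[int, ...]:
        return (0,) * self.n_indirect

    def copy(self) -> "HypercomplexGrid":
        return HypercomplexGrid(
            dims=list(self.dims), data=self.data.copy(), meta=dict(self.meta)
        )


@dataclass
class SpectrumGrid:
    """Processed frequency-domain data.

    ``axes`` holds one strictly monotone ppm (or normalized-frequency)
    coordinate array per retained dimension, ordered like the ``values`` axes.
    ``values`` are real absorptive amplitudes for processed spectra; the point
    spread function is the one deliberately complex-valued instance.  ``meta``
    records processing provenance (zero-fill, apodization, recombination
    convention, NUS schedule, reconstruction settings ...).
    """

    axes: list[np.ndarray]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axes = [np.asarray(a, dtype=float) for a in self.axes]
        self.values = np.asarray(self.values)
        if self.values.ndim != len(self.axes):
            raise ValueError("one axis per dimension of values is required")
        for i, ax in enumerate(self.axes):
            if ax.ndim != 1 or ax.size != self.values.shape[i]:
                raise ValueError(f"axis {i} does not match values shape")
            if ax.size > 1:
                steps = np.diff(ax)
                if not (np.all(steps > 0) or np.all(steps < 0)):
                    raise ValueError(f"axis {i} must be strictly monotone")

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def index_of(self, axis: int, coordinate: float) -> int:
        """Grid index on ``axis`` closest to ``coordinate``."""
        return int(np.argmin(np.abs(self.axes[axis] - coordinate)))

    def value_at(self, position: Sequence[float]):
        """Value at the grid point nearest to ``position`` (one ppm per axis)."""
        idx = tuple(self.index_of(i, p) for i, p in enumerate(position))
        return self.values[idx]

    def plane(self, keep: tuple[int, int], at: Sequence[float]) -> "SpectrumGrid":
        """Extract the 2D plane spanned by axes ``keep``.

        The remaining axes are fixed at the grid points nearest to the
        corresponding entries of ``at`` (one coordinate per axis of the
        spectrum; entries for the kept axes are ignored).
        """
        if self.ndim == 2 and tuple(sorted(keep)) == (0, 1):
            return self
        if len(at) != self.ndim:
            raise ValueError("need one coordinate per spectrum axis")
        indexer: list = []
        for i in range(self.ndim):
            if i in keep:
                indexer.append(slice(None))
            else:
                indexer.append(self.index_of(i, at[i]))
        vals = self.values[tuple(indexer)]
        a, b = sorted(keep)
        plane_axes = [self.axes[a], self.axes[b]]
        if keep[0] > keep[1]:  # caller asked for transposed order
            vals = vals.T
            plane_axes = [self.axes[keep[0]], self.axes[keep[1]]]
        meta = dict(self.meta)
        meta["plane_of"] = {"keep": tuple(keep), "at": tuple(float(x) for x in at)}
        return SpectrumGrid(axes=plane_axes, values=vals, meta=meta)

    def total_power(self) -> float:
        return float(np.sum(np.abs(self.values) ** 2))
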