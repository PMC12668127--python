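"""Quadrature recombination and hypercomplex Fourier processing.

The processing model follows standard multidimensional phase-sensitive NMR:

* Rance-Kay (echo/antiecho) dimensions are first *recombined* into
  cos/sin (States) pairs by linear combination of the two recorded pathways.
* States-TPPI dimensions are converted to plain States by undoing the
  per-increment sign alternation.
* The resulting all-States hypercomplex data set is Fourier transformed one
  dimension at a time.  Internally every dimension -- including the direct
  one, whose complex FID supplies its own real/imaginary pair -- contributes
  one length-2 component axis to a purely real array; transforming dimension
  ``d`` pairs its two components into a complex interferogram, applies a
  complex FFT along ``d``'s time axis and splits the result back into
  real/imaginary components.  Because each step touches only its own
  component and time axes, the per-dimension transforms commute; the fully
  transformed array's all-real component is the absorptive spectrum.

Rance-Kay convention (fixed, recorded in provenance): with echo
``E(t) = a*exp(+i*Omega*t - R*t)`` and antiecho ``A(t) = a*exp(-i*Omega*t - R*t)``,

* cos component = (E + A) / 2
* sin component = (E - A) / (2i)   (the 90-degree zero-order phase correction)

which makes a noiseless echo/antiecho acquisition numerically identical to
the States acquisition of the same resonance.  Each output component's noise
variance is half the sum of the two input variances, i.e. iid noise sigma on
E and A becomes sigma/sqrt(2) per recombined component.
"""

from __future__ import annotations

import numpy as np

from .dimensions import DimensionSpec, HypercomplexGrid, SpectrumGrid

__all__ = [
    "ProcessingOrderError",
    "RANCE_KAY_NOISE_FACTOR",
    "recombine_echo_antiecho",
    "states_tppi_to_states",
    "convert_to_states",
    "hypercomplex_ft",
]


class ProcessingOrderError(ValueError):
    """Raised when the mandated processing order is violated.

    Echo/antiecho dimensions must be recombined (and States-TPPI dimensions
    converted) *before* Fourier processing or reconstruction.
    """


#: Factor by which the per-component thermal noise amplitude changes under the
#: (E +/- A)/2 recombination convention.
RANCE_KAY_NOISE_FACTOR = 2.0 ** -0.5


def recombine_echo_antiecho(grid: HypercomplexGrid, dim: str) -> HypercomplexGrid:
    """Rance-Kay recombination of an echo/antiecho dimension.

    Converts dimension ``dim`` from ``echo_antiecho`` to ``states``
    quadrature using the module-level convention ``cos = (E+A)/2``,
    ``sin = (E-A)/(2i)``.  The operation is linear and acts per time
    increment, so it commutes with masking and with processing of other
    dimensions.

    Raises
    ------
    ValueError
        If ``dim`` is unknown.
    ProcessingOrderError
        If ``dim`` is not echo/antiecho encoded.
    """
    spec = grid.get_dim(dim)  # raises ValueError for unknown labels
    if spec.quadrature != "echo_antiecho":
        raise ProcessingOrderError(
            f"dimension {dim!r} has quadrature {spec.quadrature!r}, "
            "not 'echo_antiecho'"
        )
    ax = grid.component_axis(dim)
    echo = np.take(grid.data, 0, axis=ax)
    anti = np.take(grid.data, 1, axis=ax)
    cos = 0.5 * (echo + anti)
    sin = (echo - anti) / 2j
    data = np.stack([cos, sin], axis=ax)
    out = HypercomplexGrid(
        dims=grid.replace_dim(dim, quadrature="states"),
        data=data,
        meta=dict(grid.meta),
    )
    out.meta.setdefault("recombined", []).append(dim)
    out.meta["rance_kay_convention"] = "cos=(E+A)/2, sin=(E-A)/(2i)"
    out.meta["noise_scale"] = grid.meta.get("noise_scale", 1.0) * RANCE_KAY_NOISE_FACTOR
    return out


def states_tppi_to_states(grid: HypercomplexGrid, dim: str) -> HypercomplexGrid:
    """Convert a States-TPPI dimension to plain States quadrature.

    Re-applies the per-increment sign alternation ``(-1)**k`` recorded during
    acquisition, after which a resonance appears at its true offset under the
    ordinary States Fourier transform.
    """
    spec = grid.get_dim(dim)
    if spec.quadrature != "states_tppi":
        raise ProcessingOrderError(
            f"dimension {dim!r} has quadrature {spec.quadrature!r}, not 'states_tppi'"
        )
    t_ax = grid.time_axis(dim)
    signs = (-1.0) ** np.arange(spec.n_complex_points)
    shape = [1] * grid.data.ndim
    shape[t_ax] = spec.n_complex_points
    data = grid.data * signs.reshape(shape)
    out = HypercomplexGrid(
        dims=grid.replace_dim(dim, quadrature="states"),
        data=data,
        meta=dict(grid.meta),
    )
    out.meta.setdefault("tppi_converted", []).append(dim)
    return out


def convert_to_states(grid: HypercomplexGrid) -> HypercomplexGrid:
    """Recombine / convert every indirect dimension to States quadrature."""
    for d in grid.indirect_dims:
        if d.quadrature == "echo_antiecho":
            grid = recombine_echo_antiecho(grid, d.label)
        elif d.quadrature == "states_tppi":
            grid = states_tppi_to_states(grid, d.label)
    return grid


# -- windows ------------------------------------------------------------------


def _window(spec, dim: DimensionSpec) -> np.ndarray:
    """Apodization window sampled on the dimension's acquisition times.

    Supported specs: ``("em", lb_hz)`` exponential line broadening and
    ``("cos",)`` half-cosine (shifted sine bell).
    """
    t = dim.times
    if spec is None:
        return np.ones_like(t)
    kind = spec[0]
    if kind == "em":
        return np.exp(-np.pi * float(spec[1]) * t)
    if kind == "cos":
        n = dim.n_complex_points
        return np.cos(0.5 * np.pi * np.arange(n) / n)
    raise ValueError(f"unknown apodization spec {spec!r}")


# -- hypercomplex transform ---------------------------------------------------


def _real_components(grid: HypercomplexGrid) -> np.ndarray:
    """Real array with one length-2 component axis per dimension.

    Component axes come first, ordered like ``grid.dims`` (the direct
    dimension's real/imaginary pair is axis ``n_indirect``), followed by the
    time axes in the same order.
    """
    return np.stack([grid.data.real, grid.data.imag], axis=grid.n_indirect)


def _transform_dim(
    arr: np.ndarray,
    j: int,
    n_dims: int,
    n_out: int,
    window: np.ndarray | None = None,
    inverse: bool = False,
) -> np.ndarray:
    """(Inverse) Fourier transform of dimension ``j`` on a real component array.

    ``arr`` has ``n_dims`` leading component axes and ``n_dims`` trailing grid
    axes.  Forward: window, zero-fill to ``n_out``, FFT, fftshift.  Inverse
    undoes the shifted FFT and crops back to ``n_out`` points.
    """
    comp_ax = j
    z = np.take(arr, 0, axis=comp_ax) + 1j * np.take(arr, 1, axis=comp_ax)
    t_ax = n_dims + j - 1  # component axis removed, grid axes shifted left
    if not inverse:
        if window is not None:
            shape = [1] * z.ndim
            shape[t_ax] = window.size
            z = z * window.reshape(shape)
        Z = np.fft.fftshift(np.fft.fft(z, n=n_out, axis=t_ax), axes=t_ax)
    else:
        Z = np.fft.ifft(np.fft.ifftshift(z, axes=t_ax), axis=t_ax)
        Z = Z[tuple(slice(None) if a != t_ax else slice(0, n_out) for a in range(z.ndim))]
    return np.stack([Z.real, Z.imag], axis=comp_ax)


def _normalize_per_dim(value, dims, default):
    """Expand a scalar or ``{label: value}`` mapping to one entry per dim."""
    if value is None:
        return [default] * len(dims)
    if isinstance(value, dict):
        return [value.get(d.label, default) for d in dims]
    return [value] * len(dims)


def hypercomplex_ft(
    grid: HypercomplexGrid,
    zero_fill: int | dict = 2,
    apodization: dict | None = None,
) -> SpectrumGrid:
    """Fourier transform an all-States hypercomplex grid to an absorptive spectrum.

    Every indirect dimension must already be in States quadrature
    (:func:`recombine_echo_antiecho` / :func:`states_tppi_to_states` first);
    violating this ordering raises :class:`ProcessingOrderError` because
    recombination does not commute with the Fourier transform.

    Parameters
    ----------
    grid :
        Time-domain data, direct dimension in simple complex quadrature.
    zero_fill :
        Per-dimension zero-filling factor (scalar or ``{label: factor}``);
        each dimension is transformed on ``factor * n_complex_points`` points.
    apodization :
        Optional ``{label: window_spec}`` mapping, see :func:`_window`.
        No window and no first-point scaling are applied by default.

    Returns
    -------
    SpectrumGrid
        Real absorptive spectrum with strictly increasing ppm axes and the
        processing parameters recorded in ``meta``.
    """
    for d in grid.indirect_dims:
        if d.quadrature == "echo_antiecho":
            raise ProcessingOrderError(
                f"dimension {d.label!r} is still echo/antiecho encoded; apply "
                "recombine_echo_antiecho before Fourier processing"
            )
        if d.quadrature == "states_tppi":
            raise ProcessingOrderError(
                f"dimension {d.label!r} is still States-TPPI encoded; apply "
                "states_tppi_to_states before Fourier processing"
            )
    n_dims = len(grid.dims)
    zf = _normalize_per_dim(zero_fill, grid.dims, 2)
    apod = _normalize_per_dim(apodization, grid.dims, None) if apodization else [None] * n_dims

    arr = _real_components(grid)
    n_out = [int(round(z * d.n_complex_points)) for z, d in zip(zf, grid.dims)]
    for j, d in enumerate(grid.dims):
        win = _window(apod[j], d) if apod[j] is not None else None
        arr = _transform_dim(arr, j, n_dims, n_out[j], window=win)
    values = arr[(0,) * n_dims]
    axes = [d.ppm_axis(n) for d, n in zip(grid.dims, n_out)]
    meta = dict(grid.meta)
    meta["processing"] = {
        "zero_fill": {d.label: z for d, z in zip(grid.dims, zf)},
        "apodization": {d.label: a for d, a in zip(grid.dims, apod)},
        "first_point_scaling": None,
        "dim_order": [d.label for d in grid.dims],
    }
    return SpectrumGrid(axes=axes, values=values, meta=meta)
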