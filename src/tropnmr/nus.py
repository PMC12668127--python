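"""Non-uniform sampling: schedules, masked acquisition, nuFT and the PSF.

A NUS schedule selects a subset of the indirect-dimension time grid; one
schedule "point" covers *all* hypercomplex components of that time increment
(they are recorded back-to-back on a spectrometer).  The direct dimension is
always fully sampled.

Direct Fourier transform of the zero-filled masked data (nuFT) convolves the
true spectrum with the schedule's point spread function (PSF): the spectrum
of the sampling indicator mask.  PSF side lobes appear as artifacts whose
amplitude is proportional to the peak intensities -- the "sampling noise"
that reconstruction algorithms remove.

Schedule interchange format: plain text, one 0-based multi-index per line,
space-separated, ``#`` comments (a ``# shape: ...`` header records the grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dimensions import HypercomplexGrid, SpectrumGrid
from .processing import hypercomplex_ft

__all__ = [
    "SamplingSchedule",
    "generate_schedule",
    "read_schedule",
    "write_schedule",
    "apply_schedule",
    "nuft",
    "point_spread_function",
]

SCHEDULE_MODES = ("uniform_random", "exponential_biased", "full")


@dataclass(frozen=True)
class SamplingSchedule:
    """A set of sampled multi-indices over the indirect time grid.

    ``points`` is an ``(m, n_indirect)`` integer array of unique 0-based
    indices, stored in lexicographic order; the origin ``(0, ..., 0)`` (the
    first FID) is always included.
    """

    shape: tuple[int, ...]
    points: np.ndarray
    mode: str = "uniform_random"
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        object.__setattr__(self, "shape", shape)
        pts = np.atleast_2d(np.asarray(self.points, dtype=np.intp))
        if pts.shape[1] != len(shape):
            raise ValueError("points must have one index per indirect dimension")
        if np.any(pts < 0) or np.any(pts >= np.asarray(shape)):
            raise ValueError("schedule points outside the grid")
        pts = pts[np.lexsort(pts.T[::-1])]
        if len(np.unique(pts, axis=0)) != len(pts):
            raise ValueError("schedule points must be unique")
        if not np.all(pts[0] == 0):
            raise ValueError("the origin (first FID) must be part of the schedule")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def grid_size(self) -> int:
        return int(np.prod(self.shape))

    @property
    def fraction(self) -> float:
        return self.n_points / self.grid_size

    @property
    def mask(self) -> np.ndarray:
        """Boolean indicator array over the indirect grid."""
        m = np.zeros(self.shape, dtype=bool)
        m[tuple(self.points.T)] = True
        return m


def generate_schedule(
    shape,
    fraction: float,
    mode: str = "uniform_random",
    seed: int = 0,
    bias_decay=None,
) -> SamplingSchedule:
    """Draw a deterministic NUS schedule.

    ``uniform_random`` samples grid points without replacement with equal
    probability; ``exponential_biased`` weights point ``(k_1 .. k_n)`` by
    ``exp(-sum_i bias_decay_i * k_i / N_i)`` before sampling, favouring early
    (high-signal) increments; ``full`` (or ``fraction == 1``) keeps the whole
    grid.  The origin is always forced into the schedule.
    """
    shape = tuple(int(n) for n in shape)
    if not shape or any(n < 1 for n in shape):
        raise ValueError("empty sampling grid")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if mode not in SCHEDULE_MODES:
        raise ValueError(f"unknown schedule mode {mode!r}")

    total = int(np.prod(shape))
    m = max(1, int(round(fraction * total)))
    all_points = np.indices(shape).reshape(len(shape), -1).T
    if mode == "full" or m >= total:
        return SamplingSchedule(shape, all_points, mode="full", seed=seed)

    rng = np.random.default_rng(seed)
    if mode == "uniform_random":
        weights = np.ones(total)
    else:
        rates = np.full(len(shape), 2.0) if bias_decay is None else np.asarray(
            bias_decay, dtype=float
        )
        if rates.shape != (len(shape),):
            raise ValueError("bias_decay needs one rate per indirect dimension")
        exponent = all_points / np.asarray(shape, dtype=float)
        weights = np.exp(-exponent @ rates)
    weights = weights.copy()
    weights[0] = 0.0  # origin joins unconditionally
    p = weights / weights.sum()
    chosen = rng.choice(total, size=m - 1, replace=False, p=p) if m > 1 else []
    idx = np.concatenate(([0], np.asarray(chosen, dtype=np.intp)))
    return SamplingSchedule(shape, all_points[idx], mode=mode, seed=seed)


def write_schedule(schedule: SamplingSchedule, path) -> None:
    """Write a schedule in the plain-text interchange format."""
    with open(path, "w") as fh:
        fh.write("# NUS schedule: one 0-based multi-index per line\n")
        fh.write(f"# shape: {' '.join(str(n) for n in schedule.shape)}\n")
        fh.write(f"# mode: {schedule.mode}  seed: {schedule.seed}\n")
        for pt in schedule.points:
            fh.write(" ".join(str(int(k)) for k in pt) + "\n")


def read_schedule(path, shape=None) -> SamplingSchedule:
    """Read a plain-text schedule; the grid shape comes from the ``# shape:``
    header unless given explicitly."""
    points = []
    mode, seed = "uniform_random", 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("shape:") and shape is None:
                    shape = tuple(int(x) for x in body.split(":", 1)[1].split())
                elif body.startswith("mode:"):
                    parts = body.replace("mode:", "").replace("seed:", "").split()
                    if parts:
                        mode = parts[0]
                    if len(parts) > 1:
                        seed = int(parts[1])
                continue
            points.append([int(x) for x in line.split()])
    if shape is None:
        raise ValueError("schedule file has no '# shape:' header and no shape given")
    if mode not in SCHEDULE_MODES:
        mode = "uniform_random"
    return SamplingSchedule(tuple(shape), np.asarray(points, dtype=np.intp), mode=mode, seed=seed)


def apply_schedule(grid: HypercomplexGrid, schedule: SamplingSchedule) -> HypercomplexGrid:
    """Zero every unsampled time increment of the grid.

    One schedule point covers all ``2**n`` hypercomplex components of that
    increment and the full direct-dimension FID.  The boolean mask and the
    schedule are stored in ``meta`` for downstream nuFT / reconstruction.
    """
    if schedule.shape != grid.indirect_shape:
        raise ValueError(
            f"schedule shape {schedule.shape} does not match indirect grid "
            f"{grid.indirect_shape}"
        )
    mask = schedule.mask
    shape = (1,) * grid.n_indirect + mask.shape + (1,)
    data = grid.data * mask.reshape(shape)
    return grid.with_data(
        data,
        nus_mask=mask,
        nus_schedule=schedule,
        nus_fraction=schedule.fraction,
    )


def nuft(
    grid: HypercomplexGrid,
    schedule: SamplingSchedule | None = None,
    zero_fill: int | dict = 2,
    apodization: dict | None = None,
) -> SpectrumGrid:
    """Direct Fourier transform of (zero-filled) non-uniformly sampled data.

    Echo/antiecho dimensions must be recombined first; recombination acts per
    time increment, so it commutes with the masking.  With a full schedule
    the result equals :func:`~tropnmr.processing.hypercomplex_ft` exactly.
    """
    if schedule is not None:
        grid = apply_schedule(grid, schedule)
    elif "nus_mask" not in grid.meta:
        raise ValueError(
            "nuft needs a schedule argument or a grid with an applied NUS mask"
        )
    spec = hypercomplex_ft(grid, zero_fill=zero_fill, apodization=apodization)
    spec.meta["transform"] = "nuft"
    return spec


def point_spread_function(
    schedule: SamplingSchedule,
    zero_fill: int = 1,
    dims=None,
) -> SpectrumGrid:
    """Spectrum of the sampling indicator mask, normalized to 1 at zero frequency.

    The returned values are complex (a random mask has no symmetry); their
    magnitude is the relative artifact level: the nuFT spectrum of a noiseless
    on-grid peak equals the peak height times the PSF circularly shifted to
    the peak position.  Axes are ppm when ``dims`` (the indirect
    :class:`DimensionSpec` list) is given, otherwise normalized frequency in
    cycles per increment.
    """
    mask = schedule.mask.astype(complex)
    out = mask
    axes = []
    for ax, n in enumerate(schedule.shape):
        n_out = int(round(zero_fill * n))
        out = np.fft.fftshift(np.fft.fft(out, n=n_out, axis=ax), axes=ax)
        if dims is not None:
            axes.append(dims[ax].ppm_axis(n_out))
        else:
            axes.append(np.fft.fftshift(np.fft.fftfreq(n_out)))
    out = out / schedule.n_points
    return SpectrumGrid(
        axes=axes,
        values=out,
        meta={
            "transform": "psf",
            "n_points": schedule.n_points,
            "fraction": schedule.fraction,
            "mode": schedule.mode,
            "seed": schedule.seed,
        },
    )
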