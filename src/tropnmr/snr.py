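"""Sensitivity metrics: plane-wise SNR, bulk-signal ratios, enhancement tables.

High-dimensional spectra are evaluated as stacks of 2D planes.  The noise
level of a plane is estimated from 100 random grid points drawn outside an
exclusion rectangle around the peak (default half-widths 1.0 ppm along a 1H
axis and 2.5 ppm along a 15N axis); the mean of the sampled points is
subtracted from the peak intensity (enforcing a zero mean noise level), the
noise level is their standard deviation, and SNR = corrected peak intensity
/ noise level.  With NUS data this "effective noise" deliberately mixes
thermal noise and sampling artifacts -- comparing it before and after
reconstruction quantifies how much sampling noise the reconstruction
removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dimensions import SpectrumGrid

__all__ = [
    "DegenerateNoiseError",
    "PeakRecord",
    "PlaneSNR",
    "SNRReport",
    "plane_snr",
    "snr_report",
    "bulk_signal_ratio",
    "per_peak_enhancement",
    "noise_ratio_report",
    "effective_noise",
    "read_peaks",
    "write_peaks",
]

DEFAULT_EXCLUSION = (1.0, 2.5)  # ppm half-widths: (1H-type axis, 15N-type axis)


class DegenerateNoiseError(ValueError):
    """Raised when the sampled noise points have zero variance."""


@dataclass(frozen=True)
class PeakRecord:
    """A confirmed peak: label, ppm coordinates, and whether it is also
    detectable in the conventional (CP-based) experiment."""

    label: str
    position: tuple[float, ...]
    detected_in_conventional: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", tuple(float(p) for p in self.position))


@dataclass(frozen=True)
class PlaneSNR:
    """Per-peak result of the random-point plane SNR estimator."""

    label: str
    peak_intensity: float
    mean_noise: float
    noise_level: float
    snr: float
    n_points: int
    seed: int


def plane_snr(
    plane: SpectrumGrid,
    peak,
    n_points: int = 100,
    exclusion: tuple[float, float] = DEFAULT_EXCLUSION,
    seed: int = 0,
) -> PlaneSNR:
    """Random-point SNR estimate of one peak in a 2D plane.

    Samples ``n_points`` grid points without replacement outside the
    exclusion rectangle ``peak +/- exclusion`` (per-axis ppm half-widths),
    subtracts their mean from the peak intensity and divides by their
    standard deviation.  Deterministic for a fixed ``seed`` and invariant
    under adding a constant to the whole plane.

    Raises
    ------
    ValueError
        If the exclusion region leaves fewer than ``n_points`` grid points.
    DegenerateNoiseError
        If the sampled points have zero variance (e.g. a constant plane).
    """
    if plane.ndim != 2:
        raise ValueError("plane_snr expects a 2D spectrum plane")
    if isinstance(peak, PeakRecord):
        label, position = peak.label, peak.position
    else:
        label, position = "peak", tuple(peak)
    if len(position) != 2:
        raise ValueError("peak position must have one ppm coordinate per plane axis")
    for p, ax in zip(position, plane.axes):
        lo, hi = min(ax[0], ax[-1]), max(ax[0], ax[-1])
        if not lo <= p <= hi:
            raise ValueError(f"peak position {p} outside axis range [{lo}, {hi}]")

    intensity = float(plane.value_at(position))
    in_excl = [
        np.abs(ax - p) <= half for ax, p, half in zip(plane.axes, position, exclusion)
    ]
    rect = np.logical_and.outer(in_excl[0], in_excl[1])
    candidates = np.flatnonzero(~rect.ravel())
    if candidates.size < n_points:
        raise ValueError(
            f"only {candidates.size} grid points outside the exclusion region, "
            f"need {n_points}; exclusion too large for this plane"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n_points, replace=False)
    samples = plane.values.ravel()[chosen].astype(float)
    mean = float(samples.mean())
    noise = float(samples.std(ddof=1))
    if noise == 0.0:
        raise DegenerateNoiseError("sampled noise points have zero variance")
    return PlaneSNR(
        label=label,
        peak_intensity=intensity,
        mean_noise=mean,
        noise_level=noise,
        snr=(intensity - mean) / noise,
        n_points=n_points,
        seed=seed,
    )


@dataclass
class SNRReport:
    """Per-peak SNR table for one spectrum plus the estimator settings."""

    entries: pd.DataFrame
    settings: dict = field(default_factory=dict)

    @property
    def mean_snr(self) -> float:
        return float(self.entries["snr"].mean())

    @property
    def median_snr(self) -> float:
        return float(self.entries["snr"].median())

    def __len__(self) -> int:
        return len(self.entries)


def snr_report(
    spectrum: SpectrumGrid,
    peaks,
    plane_axes: tuple[int, int] | None = None,
    n_points: int = 100,
    exclusion: tuple[float, float] | None = None,
    seed: int = 0,
) -> SNRReport:
    """Plane-wise SNR for a list of peaks in a spectrum of any dimensionality.

    For spectra with more than two dimensions, each peak is evaluated in the
    2D plane spanned by ``plane_axes`` (default: first indirect axis and the
    direct axis) sliced at the peak's coordinates in the remaining
    dimensions, mirroring how 4D/5D data are inspected as stacks of planes.
    ``exclusion`` defaults to 8% of each kept axis' span when not given.
    Per-peak sampling seeds derive deterministically from ``seed``.
    """
    nd = spectrum.ndim
    if plane_axes is None:
        plane_axes = (0, nd - 1) if nd > 2 else (0, 1)
    rows = []
    for k, peak in enumerate(peaks):
        plane = spectrum.plane(plane_axes, peak.position) if nd > 2 else spectrum
        pos2 = (peak.position[plane_axes[0]], peak.position[plane_axes[1]])
        excl = exclusion
        if excl is None:
            excl = tuple(0.08 * abs(ax[-1] - ax[0]) for ax in plane.axes)
        result = plane_snr(
            plane,
            PeakRecord(peak.label, pos2, peak.detected_in_conventional),
            n_points=n_points,
            exclusion=excl,
            seed=seed + 7919 * k,
        )
        rows.append(
            {
                "label": peak.label,
                "peak_intensity": result.peak_intensity,
                "mean_noise": result.mean_noise,
                "noise_level": result.noise_level,
                "snr": result.snr,
                "detected_in_conventional": peak.detected_in_conventional,
            }
        )
    entries = pd.DataFrame(rows)
    return SNRReport(
        entries=entries,
        settings={
            "n_points": n_points,
            "exclusion": None if exclusion is None else tuple(exclusion),
            "plane_axes": tuple(plane_axes),
            "seed": seed,
        },
    )


def bulk_signal_ratio(fid_enh, fid_conv, method: str = "sum") -> float:
    """Bulk-signal ratio of two first FIDs (enhanced over conventional).

    ``method="sum"`` compares the magnitudes of the summed FIDs (integral of
    the signal); ``method="max"`` compares maximum point magnitudes.  For a
    noiseless construction with bulk efficiency ``b`` both return ``b``.
    """
    fid_enh = np.asarray(fid_enh)
    fid_conv = np.asarray(fid_conv)
    if fid_enh.shape != fid_conv.shape:
        raise ValueError("FIDs must have the same length (and dwell)")
    if method == "sum":
        num, den = np.abs(fid_enh.sum()), np.abs(fid_conv.sum())
    elif method == "max":
        num, den = np.abs(fid_enh).max(), np.abs(fid_conv).max()
    else:
        raise ValueError(f"unknown method {method!r}")
    if den == 0:
        raise ValueError("zero conventional signal")
    return float(num / den)


def per_peak_enhancement(report_enh: SNRReport, report_conv: SNRReport) -> pd.DataFrame:
    """Per-peak SNR enhancement table (enhanced over conventional).

    Peaks flagged as undetected in the conventional experiment -- or absent
    from the conventional report altogether -- are kept in the table but
    excluded from the mean (their ratio would be meaningless).  The mean and
    median over shared peaks are stored in ``DataFrame.attrs``.
    """
    enh = report_enh.entries.set_index("label")
    conv = report_conv.entries.set_index("label")
    rows = []
    for label, row in enh.iterrows():
        shared = (
            label in conv.index
            and bool(row.get("detected_in_conventional", True))
        )
        rows.append(
            {
                "label": label,
                "snr_enhanced": row["snr"],
                "snr_conventional": conv.loc[label, "snr"] if label in conv.index else np.nan,
                "enhancement": (
                    row["snr"] / conv.loc[label, "snr"] if shared else np.nan
                ),
                "excluded": not shared,
            }
        )
    table = pd.DataFrame(rows)
    shared_mask = ~table["excluded"]
    if not shared_mask.any():
        raise ValueError("no peaks shared between the two reports")
    table.attrs["mean_enhancement"] = float(table.loc[shared_mask, "enhancement"].mean())
    table.attrs["median_enhancement"] = float(
        table.loc[shared_mask, "enhancement"].median()
    )
    table.attrs["n_excluded"] = int((~shared_mask).sum())
    return table


def noise_ratio_report(
    spec_nuft_enh: SpectrumGrid,
    spec_recon_enh: SpectrumGrid,
    spec_nuft_conv: SpectrumGrid,
    spec_recon_conv: SpectrumGrid,
    peaks,
    **snr_settings,
) -> pd.DataFrame:
    """Per-peak noise levels before (nuFT) and after reconstruction.

    For every peak the plane-wise noise level is measured in all four spectra
    and the enhanced/conventional noise ratios are formed before and after
    reconstruction.  Degenerate (zero-variance) planes are flagged and their
    ratios reported as NaN.  Mean ratios over valid peaks are stored in
    ``DataFrame.attrs`` as ``mean_ratio_pre`` / ``mean_ratio_post``.
    """
    spectra = {
        "nuft_enhanced": spec_nuft_enh,
        "recon_enhanced": spec_recon_enh,
        "nuft_conventional": spec_nuft_conv,
        "recon_conventional": spec_recon_conv,
    }
    ref_axes = spec_nuft_enh.axes
    for name, spec in spectra.items():
        if len(spec.axes) != len(ref_axes) or any(
            a.shape != b.shape or not np.allclose(a, b)
            for a, b in zip(spec.axes, ref_axes)
        ):
            raise ValueError(f"axis mismatch between spectra ({name})")

    tables = {}
    for name, spec in spectra.items():
        noise = []
        degenerate = []
        try:
            rep = snr_report(spec, peaks, **snr_settings)
            noise = list(rep.entries["noise_level"])
            degenerate = [False] * len(noise)
        except DegenerateNoiseError:
            # fall back to per-peak evaluation so one flat plane doesn't kill all
            for k, peak in enumerate(peaks):
                try:
                    rep = snr_report(spec, [peak], **snr_settings)
                    noise.append(float(rep.entries["noise_level"].iloc[0]))
                    degenerate.append(False)
                except DegenerateNoiseError:
                    noise.append(np.nan)
                    degenerate.append(True)
        tables[name] = (noise, degenerate)

    out = pd.DataFrame({"label": [p.label for p in peaks]})
    for name, (noise, degenerate) in tables.items():
        out[f"noise_{name}"] = noise
        out[f"degenerate_{name}"] = degenerate
    out["ratio_pre"] = out["noise_nuft_enhanced"] / out["noise_nuft_conventional"]
    out["ratio_post"] = out["noise_recon_enhanced"] / out["noise_recon_conventional"]
    for key, col in (("mean_ratio_pre", "ratio_pre"), ("mean_ratio_post", "ratio_post")):
        valid = out[col].dropna()
        out.attrs[key] = float(valid.mean()) if len(valid) else float("nan")
    return out


def effective_noise(spectrum: SpectrumGrid, peak_positions, half_widths) -> float:
    """Standard deviation of spectrum values outside all peak exclusion boxes.

    ``half_widths`` gives one ppm half-width per spectrum axis; the union of
    boxes around ``peak_positions`` is excluded.  This is the dense-grid
    companion of :func:`plane_snr`'s random-point estimator, used for
    Monte-Carlo comparisons where sampling error must be minimal.
    """
    keep = np.ones(spectrum.values.shape, dtype=bool)
    for pos in peak_positions:
        box = np.ones(spectrum.values.shape, dtype=bool)
        for i, (ax, p, half) in enumerate(zip(spectrum.axes, pos, half_widths)):
            sel = np.abs(ax - p) <= half
            shape = [1] * spectrum.ndim
            shape[i] = ax.size
            box &= sel.reshape(shape)
        keep &= ~box
    vals = spectrum.values[keep]
    if vals.size < 2:
        raise ValueError("exclusion boxes cover the whole spectrum")
    return float(np.std(vals.astype(float), ddof=1))


def read_peaks(path) -> list[PeakRecord]:
    """Read a peak list CSV: ``label, ppm_0, ppm_1, ..., detected_in_conventional``."""
    df = pd.read_csv(path)
    pos_cols = [c for c in df.columns if c.startswith("ppm_")]
    peaks = []
    for _, row in df.iterrows():
        peaks.append(
            PeakRecord(
                label=str(row["label"]),
                position=tuple(float(row[c]) for c in pos_cols),
                detected_in_conventional=bool(
                    row.get("detected_in_conventional", True)
                ),
            )
        )
    return peaks


def write_peaks(peaks, path) -> None:
    rows = []
    for p in peaks:
        row = {"label": p.label}
        row.update({f"ppm_{i}": x for i, x in enumerate(p.position)})
        row["detected_in_conventional"] = p.detected_in_conventional
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
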