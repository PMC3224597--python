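"""Pure-standard spectrum clean-up.

Even spectra of pure compounds carry baseline distortion, chemical and
electronic noise, and solvent-suppression residuals.  Before a standard
can contribute to a simulated mixture it is:

1. linearly interpolated onto the target ppm grid (``regrid``),
2. zeroed in the exclusion regions (internal reference, residual
   water/urea) (``apply_exclusion_regions``),
3. baseline-corrected with a moving-window median, applied only below an
   intensity threshold so peaks are untouched (``baseline_correct``),
4. floored at a limit l = M - 3*sigma_med derived from a binned noise
   estimate, removing negative artifacts (``remove_negative_artifacts``),
5. kernel-smoothed below a threshold to suppress residual noise without
   broadening large peaks (``kernel_smooth``), and finally
6. scaled to unit integrated intensity (``normalize_unit_integral``)
   so that concentration and proton count alone set its weight in the
   mixture.

Threshold comparisons are strict (<): a point exactly at a threshold is
never modified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .nssd_io import SimulationParameters, StandardSpectrum

KERNELS = ("normal", "box", "triangle", "epanechnikov")


@dataclass
class PreprocessReport:
    """Record of what preprocessing did to one standard spectrum."""

    metabolite_id: str = ""
    experiment_id: str = ""
    baseline_threshold: float = float("nan")
    baseline_window: float = float("nan")
    sigma_med: float = float("nan")
    intensity_median: float = float("nan")
    clip_limit: float = float("nan")
    n_points_clipped: int = 0
    exclusion_regions: list[tuple[float, float]] = field(default_factory=list)
    kernel: str = ""
    kernel_bandwidth: int = 0
    n_points_smoothed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def regrid(spectrum: StandardSpectrum, grid: np.ndarray) -> StandardSpectrum:
    """Linear interpolation onto ``grid``; points outside the source range get 0."""
    grid = np.asarray(grid, dtype=float)
    y = np.interp(grid, spectrum.ppm, spectrum.intensity, left=0.0, right=0.0)
    out = spectrum.copy()
    out.ppm, out.intensity = grid.copy(), y
    return out


def apply_exclusion_regions(
    spectrum: StandardSpectrum, regions: list[tuple[float, float]]
) -> StandardSpectrum:
    """Set intensity to exactly zero at every grid point inside a closed interval."""
    out = spectrum.copy()
    for lo, hi in regions:
        if hi < lo:
            lo, hi = hi, lo
        mask = (out.ppm >= lo) & (out.ppm <= hi)
        out.intensity[mask] = 0.0
    return out


def baseline_correct(
    spectrum: StandardSpectrum,
    window: float,
    threshold_divisor: float,
) -> StandardSpectrum:
    """Moving-window median baseline subtraction below an intensity threshold.

    The grid is split into consecutive disjoint windows of width
    ``window`` ppm; the median intensity of each window is taken as the
    baseline level at the window centre and linearly interpolated
    between centres (held constant beyond the outermost centres).  The
    baseline is subtracted only where intensity < max(intensity) /
    ``threshold_divisor``, so genuine peaks are preserved.
    """
    if window <= 0 or threshold_divisor <= 0:
        raise ValidationError("window and threshold_divisor must be > 0")
    x, y = spectrum.ppm, spectrum.intensity
    step = float(np.min(np.diff(x)))
    if window < step:
        raise ValidationError(
            f"baseline window {window} ppm is smaller than the grid spacing {step:.3g} ppm"
        )
    n_windows = max(1, int(np.ceil((x[-1] - x[0]) / window)))
    edges = x[0] + window * np.arange(n_windows + 1)
    centres, medians = [], []
    for i in range(n_windows):
        lo, hi = edges[i], edges[i + 1]
        # half-open windows; the last closes to include the final point
        mask = (x >= lo) & ((x < hi) if i < n_windows - 1 else (x <= hi))
        if mask.any():
            centres.append((lo + hi) / 2.0)
            medians.append(float(np.median(y[mask])))
    baseline = np.interp(x, centres, medians)
    threshold = float(y.max()) / threshold_divisor
    out = spectrum.copy()
    below = y < threshold
    out.intensity[below] = y[below] - baseline[below]
    return out


def binned_noise_sd(y: np.ndarray, n_bins: int) -> float:
    """Noise SD estimate: median of the sample SDs of contiguous bins."""
    if n_bins < 1 or n_bins > y.size:
        raise ValidationError("n_bins must be in [1, n_points]")
    bin_sds = [
        float(np.std(b, ddof=1)) if b.size > 1 else 0.0
        for b in np.array_split(np.asarray(y, dtype=float), n_bins)
    ]
    return float(np.median(bin_sds))


def remove_negative_artifacts(
    spectrum: StandardSpectrum, n_bins: int
) -> tuple[StandardSpectrum, float, float, float]:
    """Floor the spectrum at l = M - 3*sigma_med.

    ``sigma_med`` is the median of the standard deviations of ``n_bins``
    contiguous, (near-)equal-length bins of the intensity vector
    (sample SD, ddof=1); ``M`` is the median of all intensities.  Every
    intensity strictly below ``l`` is set equal to it.  Returns the
    floored spectrum together with ``(M, sigma_med, l)``.
    """
    y = spectrum.intensity
    sigma_med = binned_noise_sd(y, n_bins)
    M = float(np.median(y))
    limit = M - 3.0 * sigma_med
    out = spectrum.copy()
    out.intensity[y < limit] = limit
    return out, M, sigma_med, limit


def _kernel_weights(kernel: str, bandwidth: int) -> np.ndarray:
    """Kernel weights at integer point distances, widest support first.

    The normal kernel is truncated at +/- 3 bandwidths; compact kernels
    vanish beyond +/- 1 bandwidth.
    """
    if kernel not in KERNELS:
        raise ValidationError(f"unknown kernel {kernel!r}; choose from {KERNELS}")
    if bandwidth < 1:
        raise ValidationError("bandwidth must be >= 1 data point")
    if kernel == "normal":
        half = 3 * bandwidth
        u = np.arange(-half, half + 1) / bandwidth
        w = np.exp(-0.5 * u * u)
    else:
        half = bandwidth
        u = np.arange(-half, half + 1) / bandwidth
        if kernel == "box":
            w = np.ones_like(u)
        elif kernel == "triangle":
            w = 1.0 - np.abs(u)
        else:  # epanechnikov
            w = 1.0 - u * u
        w = np.maximum(w, 0.0)
    return w


def kernel_smooth(
    spectrum: StandardSpectrum,
    kernel: str,
    bandwidth: int,
    threshold_fraction: float,
) -> StandardSpectrum:
    """Replace sub-threshold points by a kernel-weighted mean of neighbours.

    The weighted mean at point i runs over all points within the kernel
    support centred on i (using original, un-smoothed intensities);
    weights are renormalised over the neighbours actually available, so
    edges are handled without padding.  Points at or above
    ``threshold_fraction * max(intensity)`` are untouched, keeping tall
    peaks at their native linewidth.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValidationError("threshold_fraction must be in (0, 1]")
    w = _kernel_weights(kernel, bandwidth)
    y = spectrum.intensity
    num = np.convolve(y, w, mode="same")
    den = np.convolve(np.ones_like(y), w, mode="same")
    smoothed = num / den
    threshold = threshold_fraction * float(y.max())
    out = spectrum.copy()
    below = y < threshold
    out.intensity[below] = smoothed[below]
    return out


def normalize_unit_integral(spectrum: StandardSpectrum) -> StandardSpectrum:
    """Scale to unit integrated (summed) intensity.

    Residual negative values (at most the Eq-style floor level, i.e.
    below the noise floor) are zeroed first so the result is a valid
    non-negative density; a spectrum with no positive signal is an
    error, since such a metabolite cannot contribute to a mixture.
    """
    y = np.maximum(spectrum.intensity, 0.0)
    total = float(y.sum())
    if total <= 0:
        raise ValidationError(
            f"spectrum {spectrum.metabolite_id!r} has no positive intensity to normalize"
        )
    out = spectrum.copy()
    out.intensity = y / total
    out.stage = "normalized"
    # re-validate the normalized-stage invariants
    return StandardSpectrum(
        out.metabolite_id, out.experiment_id, out.ppm, out.intensity,
        stage="normalized", ppm_descending_on_disk=out.ppm_descending_on_disk,
    )


def preprocess_standard(
    spectrum: StandardSpectrum, params: SimulationParameters
) -> tuple[StandardSpectrum, PreprocessReport]:
    """Full clean-up pipeline: regrid, exclusions, baseline, floor, smooth,
    then unit-integral normalization.

    Returns the normalized spectrum and a report of the thresholds
    actually used.  A spectrum left with no positive signal (e.g. all
    of its peaks fall inside exclusion regions) raises at the
    normalization step.
    """
    report = PreprocessReport(
        metabolite_id=spectrum.metabolite_id,
        experiment_id=spectrum.experiment_id,
        exclusion_regions=list(params.exclusion_regions),
        kernel=params.kernel,
        kernel_bandwidth=params.kernel_bandwidth,
        baseline_window=params.baseline_window,
    )
    out = regrid(spectrum, params.grid())
    out = apply_exclusion_regions(out, params.exclusion_regions)
    report.baseline_threshold = float(out.intensity.max()) / params.baseline_threshold_divisor
    out = baseline_correct(out, params.baseline_window, params.baseline_threshold_divisor)
    pre_floor = out.intensity
    out, M, sigma_med, limit = remove_negative_artifacts(out, params.n_noise_bins)
    report.intensity_median = M
    report.sigma_med = sigma_med
    report.clip_limit = limit
    report.n_points_clipped = int(np.count_nonzero(pre_floor < limit))
    pre_smooth = out.intensity
    out = kernel_smooth(
        out, params.kernel, params.kernel_bandwidth, params.smoothing_threshold_fraction
    )
    report.n_points_smoothed = int(
        np.count_nonzero(pre_smooth < params.smoothing_threshold_fraction * pre_smooth.max())
    )
    out = normalize_unit_integral(out)
    return out, report
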