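"""pH-driven peak positional variation.

In real biofluid spectra the position of a titratable resonance moves
between its acid-limit position *a* and base-limit position *b* as the
sample pH crosses the metabolite's pKa.  The shift applied to a peak at
tabulated position delta is the Henderson-Hasselbalch interpolation

    eta = [e^(pH - pKa) (a - delta) - delta + b] / [e^(pH - pKa) + 1]

so the shifted position delta + eta slides logistically from *b*
(pH << pKa) to *a* (pH >> pKa), with the midpoint (a + b)/2 at
pH == pKa.  Note the convention of this formula as adopted here: the
high-pH limit is the *acid*-limit position ``a`` (see the methods note).

Peaks are detected in the preprocessed standard, matched to tabulated
multiplets, and each multiplet is moved rigidly (one eta, evaluated at
the multiplet's mean position) by whole grid points; the vacated points
are filled with the pre-shift local baseline level and the spectrum is
re-smoothed to suppress translation artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .nssd_io import Multiplet, SimulationParameters, StandardSpectrum
from .preprocess import binned_noise_sd, kernel_smooth

logger = logging.getLogger(__name__)


@dataclass
class DetectedPeak:
    """A local maximum suitable for shifting."""

    index: int  # grid index of the apex
    apex_ppm: float
    apex_intensity: float
    metabolite_id: str = ""
    multiplet_index: int | None = None  # None = unassigned, not shifted


@dataclass
class MultipletShift:
    """Resolved titration parameters and shift for one multiplet."""

    multiplet_index: int
    delta: float  # mean tabulated position (ppm)
    acid_limit: float  # mean acid-limit position (ppm)
    base_limit: float  # mean base-limit position (ppm)
    pka: float
    eta: float  # shift in ppm
    peak_indices: list[int] = field(default_factory=list)  # detected apex grid indices


@dataclass
class ShiftAssignment:
    """Everything needed to reproduce one replicate's shifts for one metabolite."""

    metabolite_id: str
    ph: float
    shifts: list[MultipletShift] = field(default_factory=list)


def detect_peaks(
    spectrum: StandardSpectrum,
    min_height_fraction: float,
    noise_multiple: float,
    n_noise_bins: int = 32,
) -> list[DetectedPeak]:
    """Local maxima above both a relative-height and a noise threshold.

    A peak apex is strictly greater than both neighbours; a flat-topped
    run higher than its flanks counts once, at its centre point (ties
    broken toward lower ppm).  The detection threshold is
    ``max(min_height_fraction * max(y), noise_multiple * sigma_med)``
    with ``sigma_med`` the binned noise-SD estimate.
    """
    y = spectrum.intensity
    n = y.size
    if float(y.max()) <= 0:
        return []
    sigma_med = binned_noise_sd(y, min(n_noise_bins, n))
    threshold = max(min_height_fraction * float(y.max()), noise_multiple * sigma_med)
    peaks: list[DetectedPeak] = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[i] > y[j + 1]:
                apex = (i + j) // 2  # centre; lower index (= lower ppm) on ties
                if y[apex] > threshold:
                    peaks.append(
                        DetectedPeak(
                            index=int(apex),
                            apex_ppm=float(spectrum.ppm[apex]),
                            apex_intensity=float(y[apex]),
                            metabolite_id=spectrum.metabolite_id,
                        )
                    )
            i = j + 1
        else:
            i += 1
    return peaks


def group_multiplets(
    peaks: list[DetectedPeak],
    multiplets: list[Multiplet],
    tolerance: float,
) -> list[DetectedPeak]:
    """Assign each detected peak to the multiplet of its nearest tabulated peak.

    A peak with no tabulated position within ``tolerance`` ppm stays
    unassigned (and will not be shifted).  When two tabulated peaks are
    exactly equidistant, the lower-ppm entry wins and a warning is
    logged.  Peaks of one multiplet therefore always move together.
    """
    entries: list[tuple[float, int]] = []  # (tabulated ppm, multiplet index)
    for mi, m in enumerate(multiplets):
        entries.extend((p, mi) for p in m.peaks)
    entries.sort()
    for peak in peaks:
        best: tuple[float, float, int] | None = None  # (distance, ppm, multiplet)
        tied = False
        for ppm, mi in entries:
            d = abs(peak.apex_ppm - ppm)
            if d > tolerance:
                continue
            if best is None or d < best[0] - 1e-15:
                best = (d, ppm, mi)
                tied = False
            elif abs(d - best[0]) <= 1e-15 and mi != best[2]:
                tied = True  # entries sorted by ppm: first (lower-ppm) entry kept
        if best is not None:
            if tied:
                logger.warning(
                    "peak at %.4f ppm equidistant between multiplets; "
                    "assigned to the lower-ppm entry", peak.apex_ppm,
                )
            peak.multiplet_index = best[2]
    return peaks


def sample_ph(
    params: SimulationParameters, n_replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-replicate sample pH: fixed user value, or i.i.d. normal draws."""
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if params.ph_fixed is not None:
        return np.full(n_replicates, float(params.ph_fixed))
    if params.ph_sd < 0:
        raise ValidationError("pH sd must be >= 0")
    return params.ph_mean + params.ph_sd * rng.standard_normal(n_replicates)


def henderson_hasselbalch_shift(
    delta: float, a: float, b: float, pka: float, ph: float
) -> float:
    """Shift eta (ppm) of a peak at ``delta`` for the given pH.

    Computed in the logistic form ``eta = s*(a - delta) + (1 - s)*(b -
    delta)`` with ``s = 1 / (1 + e^-(pH - pKa))``, which is
    algebraically identical to the exponential ratio form but immune to
    overflow for large |pH - pKa|.
    """
    for v in (delta, a, b, pka, ph):
        if not np.isfinite(v):
            raise ValidationError("all shift-model inputs must be finite")
    x = ph - pka
    if x >= 0:
        s = 1.0 / (1.0 + np.exp(-x))
    else:
        e = np.exp(x)
        s = e / (1.0 + e)
    return float(s * (a - delta) + (1.0 - s) * (b - delta))


def resolve_titration(
    multiplet: Multiplet,
    params: SimulationParameters,
    rng: np.random.Generator,
    pka_override: float | None = None,
) -> tuple[float, float, float, float]:
    """Mean (delta, a, b) of a multiplet plus its pKa, sampling fallbacks.

    Missing pKa values are drawn from the configured normal fallback
    (``pka_override`` shares one draw across a metabolite's multiplets,
    since pKa is a per-metabolite quantity).  Missing acid/base limits
    are drawn as a symmetric offset around the tabulated position —
    acid limit above, base limit below — keeping the ordering sane.
    """
    delta = float(np.mean(multiplet.peaks))
    pka = multiplet.pka if multiplet.pka is not None else pka_override
    if pka is None:
        pka = float(params.pka_fallback_mean + params.pka_fallback_sd * rng.standard_normal())
    if multiplet.acid_limits is not None and multiplet.base_limits is not None:
        a = float(np.mean(multiplet.acid_limits))
        b = float(np.mean(multiplet.base_limits))
    else:
        offset = abs(params.limit_offset_mean + params.limit_offset_sd * rng.standard_normal())
        a, b = delta + offset, delta - offset
    return delta, a, b, float(pka)


def make_shift_assignment(
    spectrum: StandardSpectrum,
    multiplets: list[Multiplet],
    params: SimulationParameters,
    ph: float,
    rng: np.random.Generator,
) -> ShiftAssignment:
    """Detect, group and compute one eta per multiplet for one replicate."""
    peaks = detect_peaks(
        spectrum, params.peak_min_height_fraction, params.peak_noise_multiple,
        n_noise_bins=params.n_noise_bins,
    )
    peaks = group_multiplets(peaks, multiplets, params.multiplet_match_tolerance)
    assignment = ShiftAssignment(metabolite_id=spectrum.metabolite_id, ph=float(ph))
    if not multiplets:
        return assignment
    pka_fallback_draw: float | None = None
    if any(m.pka is None for m in multiplets):
        pka_fallback_draw = float(
            params.pka_fallback_mean + params.pka_fallback_sd * rng.standard_normal()
        )
    by_multiplet: dict[int, list[int]] = {}
    for p in peaks:
        if p.multiplet_index is not None:
            by_multiplet.setdefault(p.multiplet_index, []).append(p.index)
    for mi, m in enumerate(multiplets):
        if mi not in by_multiplet:
            continue
        delta, a, b, pka = resolve_titration(m, params, rng, pka_override=pka_fallback_draw)
        eta = henderson_hasselbalch_shift(delta, a, b, pka, ph)
        assignment.shifts.append(
            MultipletShift(
                multiplet_index=mi, delta=delta, acid_limit=a, base_limit=b,
                pka=pka, eta=eta, peak_indices=sorted(by_multiplet[mi]),
            )
        )
    return assignment


def _walk_to_minimum(y: np.ndarray, start: int, direction: int) -> int:
    """Follow the slope downhill from ``start`` to the nearest local minimum."""
    i = start
    while 0 < i < y.size - 1 and y[i + direction] < y[i]:
        i += direction
    return i


def shift_spectrum(
    spectrum: StandardSpectrum,
    assignment: ShiftAssignment,
    params: SimulationParameters,
) -> StandardSpectrum:
    """Translate each assigned multiplet's segment by its rounded eta.

    The segment spans from the nearest local minimum left of the
    multiplet's leftmost apex to the nearest local minimum right of its
    rightmost apex; it moves rigidly by ``round(eta / grid_step)``
    points, vacated points are filled with the pre-shift intensity at
    the segment edge on the vacated side, and a shift that would leave
    the grid is clipped at the edge with a warning.  A final kernel
    smoothing pass (below the configured threshold) suppresses
    translation artifacts.
    """
    out = spectrum.copy()
    # translation breaks the unit-integral property; re-normalization
    # happens downstream, so the result is merely "preprocessed"
    out.stage = "preprocessed"
    y = out.intensity
    step = float(out.ppm[1] - out.ppm[0])
    for shift in assignment.shifts:
        n_shift = int(round(shift.eta / step))
        if n_shift == 0 or not shift.peak_indices:
            continue
        i0 = _walk_to_minimum(y, shift.peak_indices[0], -1)
        i1 = _walk_to_minimum(y, shift.peak_indices[-1], +1)
        seg = y[i0 : i1 + 1].copy()
        j0 = i0 + n_shift
        j1 = i1 + n_shift
        if j0 < 0:
            logger.warning(
                "shift of %s multiplet %d clipped at the low-ppm grid edge",
                assignment.metabolite_id, shift.multiplet_index,
            )
            seg = seg[-j0:]
            j0 = 0
        if j1 > y.size - 1:
            logger.warning(
                "shift of %s multiplet %d clipped at the high-ppm grid edge",
                assignment.metabolite_id, shift.multiplet_index,
            )
            seg = seg[: y.size - j0]
            j1 = y.size - 1
        fill = y[i0] if n_shift > 0 else y[i1]
        y[i0 : i1 + 1] = fill
        y[j0 : j1 + 1] = seg
    if params.final_smoothing:
        out = kernel_smooth(
            out, params.kernel, params.kernel_bandwidth, params.smoothing_threshold_fraction
        )
    return out


def shift_replicate(
    spectrum: StandardSpectrum,
    multiplets: list[Multiplet],
    params: SimulationParameters,
    ph: float,
    rng: np.random.Generator,
) -> tuple[StandardSpectrum, ShiftAssignment]:
    """Convenience wrapper: build the assignment and apply it."""
    assignment = make_shift_assignment(spectrum, multiplets, params, ph, rng)
    return shift_spectrum(spectrum, assignment, params), assignment
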