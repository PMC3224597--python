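"""Synthetic standard-spectra database with known ground truth.

Real standard libraries are acquired on a spectrometer and cannot ship
with a test suite, so this module manufactures a complete, synthetic
NSSD — Lorentzian multiplets on a polynomial baseline with optional
noise and negative dips — together with every metadata table the
simulator needs (concentration template, proton counts, multiplet
definitions with and without titration data, experiment selection,
synonyms).  Because peak positions and analytic areas are recorded as
truth, the full pipeline can be verified end to end: simulate a
mixture, integrate known peaks, and recover the c_k * p_k weights.

Fixtures support asymmetric lines (different half-widths left and right
of the apex) because real resonances are rarely ideal Lorentzians; a
test that only ever sees perfect symmetric lines proves less.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .nssd_io import (
    ConcentrationEntry,
    ConcentrationTemplate,
    Multiplet,
    MultipletTable,
    ProtonTable,
    StandardSpectrum,
    write_concentration_template,
    write_experiment_selection,
    write_multiplet_table,
    write_proton_table,
    write_standard_spectrum,
    write_synonyms,
)

#: multiplet intensity patterns (binomial splitting): singlet, doublet, triplet
PATTERNS: tuple[tuple[float, ...], ...] = ((1.0,), (1.0, 1.0), (1.0, 2.0, 1.0))


@dataclass
class MultipletShape:
    """One synthetic multiplet: Lorentzian lines split by a J-spacing."""

    centre: float  # ppm
    j_spacing: float = 0.0  # ppm between adjacent lines (0 for a singlet)
    weights: tuple[float, ...] = (1.0,)  # relative line areas, e.g. (1, 2, 1)
    half_width: float = 0.002  # Lorentzian gamma (HWHM), ppm
    area_weight: float = 1.0  # total multiplet area relative to others
    asymmetry: float = 1.0  # right-side gamma = asymmetry * left-side gamma

    def __post_init__(self) -> None:
        if self.half_width <= 0 or self.asymmetry <= 0:
            raise ValidationError("half_width and asymmetry must be > 0")
        if any(w <= 0 for w in self.weights) or self.area_weight <= 0:
            raise ValidationError("weights must be positive")

    def line_positions(self) -> list[float]:
        k = len(self.weights)
        return [self.centre + (i - (k - 1) / 2.0) * self.j_spacing for i in range(k)]


@dataclass
class LorentzianSpec:
    """Full recipe for one synthetic standard spectrum."""

    multiplets: list[MultipletShape]
    baseline: tuple[float, ...] = ()  # polynomial coefficients, low order first
    noise_sd: float = 0.0
    dips: list[tuple[float, float, float]] = field(default_factory=list)  # (ppm, depth, width)


def _lorentzian(x: np.ndarray, x0: float, area: float, gamma_l: float, gamma_r: float) -> np.ndarray:
    """Unit-area (before asymmetry) Lorentzian with side-dependent width.

    Height is area / (pi * gamma_mean) so the analytic integral of the
    two half-lines equals ``area`` exactly:
    integral = h * pi * (gamma_l + gamma_r) / 2.
    """
    gamma_mean = (gamma_l + gamma_r) / 2.0
    h = area / (math.pi * gamma_mean)
    left = x < x0
    y = np.empty_like(x)
    y[left] = h * gamma_l**2 / ((x[left] - x0) ** 2 + gamma_l**2)
    y[~left] = h * gamma_r**2 / ((x[~left] - x0) ** 2 + gamma_r**2)
    return y


def make_lorentzian_standard(
    spec: LorentzianSpec,
    grid: np.ndarray,
    metabolite_id: str = "synthetic",
    experiment_id: str = "expt1",
    rng: np.random.Generator | None = None,
    scale: float = 1e6,
) -> tuple[StandardSpectrum, dict]:
    """Render a spectrum from its recipe; return it with a truth record.

    ``scale`` sets the total signal area in intensity units (large by
    default so integer quantization in the bruker dialect is
    negligible).  The truth record stores every line's exact position
    and analytic area plus the per-multiplet area fractions.
    """
    grid = np.asarray(grid, dtype=float)
    y = np.zeros_like(grid)
    total_weight = sum(m.area_weight for m in spec.multiplets)
    truth: dict = {"metabolite_id": metabolite_id, "multiplets": []}
    for m in spec.multiplets:
        wsum = sum(m.weights)
        lines = []
        for pos, w in zip(m.line_positions(), m.weights):
            area = scale * (m.area_weight / total_weight) * (w / wsum)
            y += _lorentzian(grid, pos, area, m.half_width, m.half_width * m.asymmetry)
            lines.append({"ppm": pos, "area": area})
        truth["multiplets"].append(
            {
                "centre": m.centre,
                "area_fraction": m.area_weight / total_weight,
                "lines": lines,
            }
        )
    if spec.baseline:
        y += np.polyval(list(reversed(spec.baseline)), grid)
    for ppm0, depth, width in spec.dips:
        y -= _lorentzian(grid, ppm0, depth * math.pi * width, width, width)
    if spec.noise_sd > 0:
        if rng is None:
            raise ValidationError("noise requested but no rng supplied")
        y += spec.noise_sd * rng.standard_normal(y.size)
    spectrum = StandardSpectrum(metabolite_id, experiment_id, grid, y, stage="raw")
    return spectrum, truth


# signal bands that avoid the default exclusion regions (<0.2, 4.5-6.0 ppm)
_BANDS = [(0.8, 4.2), (6.3, 9.5)]


def _random_spec(rng: np.random.Generator, n_multiplets: int) -> LorentzianSpec:
    multiplets = []
    for _ in range(n_multiplets):
        band = _BANDS[rng.integers(len(_BANDS))]
        centre = float(rng.uniform(band[0] + 0.1, band[1] - 0.1))
        pattern = PATTERNS[rng.integers(len(PATTERNS))]
        multiplets.append(
            MultipletShape(
                centre=centre,
                j_spacing=0.0 if len(pattern) == 1 else float(rng.uniform(0.01, 0.02)),
                weights=pattern,
                half_width=float(rng.uniform(0.0015, 0.003)),
                area_weight=float(rng.uniform(0.5, 2.0)),
                asymmetry=float(rng.uniform(0.8, 1.25)),
            )
        )
    baseline = (float(rng.uniform(0.0, 30.0)), float(rng.uniform(-2.0, 2.0)))
    return LorentzianSpec(multiplets=multiplets, baseline=baseline, noise_sd=5.0)


def make_synthetic_nssd(
    n_metabolites: int,
    rng: np.random.Generator | int,
    out_dir: str | Path,
    names: list[str] | None = None,
    grid: np.ndarray | None = None,
    means: list[float] | None = None,
) -> dict:
    """Write a complete, self-consistent synthetic NSSD to ``out_dir``.

    Each metabolite gets one experiment written in *both* dialects (a
    bruker-style directory and a two-column text file), a concentration
    template row (mean 100-1000 uM-like units, SD = mean/5), a proton
    count, multiplet records (with pKa and acid/base limits for even-
    indexed metabolites, omitted for odd ones so fallback sampling is
    exercised), an experiment-selection row, and a synonym alias.
    Returns the truth records keyed by metabolite id.
    """
    if n_metabolites < 1:
        raise ValidationError("n_metabolites must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if names is None:
        names = [f"met{i:02d}" for i in range(n_metabolites)]
    if len(names) != n_metabolites:
        raise ValidationError("names length must equal n_metabolites")
    if grid is None:
        grid = np.linspace(-0.5, 10.0, 8192)

    entries, protons, experiments, synonyms = [], {}, {}, {}
    multiplet_table: dict[str, list[Multiplet]] = {}
    truths: dict[str, dict] = {}
    for i, name in enumerate(names):
        spec = _random_spec(rng, n_multiplets=int(rng.integers(1, 4)))
        spectrum, truth = make_lorentzian_standard(
            spec, grid, metabolite_id=name, experiment_id="expt1", rng=rng
        )
        truths[name] = truth
        write_standard_spectrum(spectrum, out_dir / name / "expt1", "bruker")
        write_standard_spectrum(spectrum, out_dir / name / "expt1.txt", "text")

        mults = []
        pka = float(rng.uniform(5.5, 8.0))  # one pKa per metabolite
        for m in spec.multiplets:
            positions = sorted(m.line_positions())
            if i % 2 == 0:
                offset = float(rng.uniform(0.03, 0.08))
                mults.append(
                    Multiplet(
                        peaks=positions,
                        pka=pka,
                        acid_limits=[p + offset for p in positions],
                        base_limits=[p - offset for p in positions],
                    )
                )
            else:
                mults.append(Multiplet(peaks=positions))
        multiplet_table[name] = mults

        mean = means[i] if means is not None else float(rng.uniform(100.0, 1000.0))
        entries.append(ConcentrationEntry(name, mean, mean / 5.0))
        protons[name] = int(rng.integers(1, 10))
        experiments[name] = "expt1"
        synonyms[f"{name}_alias"] = name

    write_concentration_template(
        ConcentrationTemplate(entries, group_label="control"),
        out_dir / "template_control.csv",
    )
    write_proton_table(ProtonTable(protons), out_dir / "protons.csv")
    write_multiplet_table(MultipletTable(multiplet_table), out_dir / "multiplets.txt")
    write_experiment_selection(experiments, out_dir / "experiments.csv")
    write_synonyms(synonyms, out_dir / "synonyms.csv")
    (out_dir / "truth.json").write_text(json.dumps(truths, indent=2) + "\n")
    return truths
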