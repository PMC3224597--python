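"""Mixture assembly and two-group experiment orchestration.

A replicate spectrum is the proton-weighted linear combination of the
normalized standards,

    y(delta) = sum_k y_k(delta) * c_k * p_k + eps(delta),

where c_k is the replicate's simulated concentration of metabolite k,
p_k its observed proton count and eps white Gaussian noise with
standard deviation sigma_n = max(y) / SNR.  A final kernel-smoothing
pass over the composite reproduces the autocorrelated noise texture
that exponential apodization gives real spectra; the smoothing
threshold keeps tall peaks from being broadened twice.

``simulate_experiment`` wires the whole pipeline: load the required
standards from an NSSD, preprocess each once, draw per-group
concentrations (correlated if requested), sample one pH per replicate,
apply peak shifts when enabled, and assemble both groups
deterministically from a single root seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .concentration_model import ConcentrationDraws, draw_group_concentrations
from .errors import ValidationError
from .nssd_io import (
    ConcentrationTemplate,
    CorrelationSpec,
    MultipletTable,
    ProtonTable,
    SimulationParameters,
    StandardSpectrum,
    read_experiment_selection,
    read_multiplet_table,
    read_proton_table,
    read_standard_spectrum,
    read_synonyms,
)
from .peak_shift import ShiftAssignment, sample_ph, shift_replicate
from .preprocess import PreprocessReport, kernel_smooth, normalize_unit_integral, preprocess_standard

logger = logging.getLogger(__name__)


@dataclass
class MixtureSpectrum:
    """One simulated replicate with its ground truth."""

    ppm: np.ndarray
    intensity: np.ndarray
    group_label: str
    replicate_index: int
    concentrations: dict[str, float]
    ph: float | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.size != self.intensity.size:
            raise ValidationError("grid and intensity lengths differ")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")


@dataclass
class ExperimentResult:
    """Both groups of replicates plus everything needed to audit the run."""

    control: list[MixtureSpectrum]
    case: list[MixtureSpectrum]
    control_draws: ConcentrationDraws
    case_draws: ConcentrationDraws
    parameters: SimulationParameters
    preprocess_reports: list[PreprocessReport] = field(default_factory=list)
    shift_assignments: dict[str, list[list[ShiftAssignment]]] = field(default_factory=dict)

    def group(self, label: str) -> list[MixtureSpectrum]:
        return {"control": self.control, "case": self.case}[label]

    def intensity_matrix(self, label: str) -> np.ndarray:
        """Replicates x points matrix for one group."""
        return np.vstack([m.intensity for m in self.group(label)])


def noise_sigma(max_intensity: float, snr: float) -> float:
    """Noise SD: maximum peak intensity divided by the target SNR."""
    if max_intensity < 0:
        raise ValidationError("max_intensity must be >= 0")
    if not snr > 0:
        raise ValidationError("SNR must be > 0 (use inf for noise-free)")
    if math.isinf(snr):
        return 0.0
    return max_intensity / snr


def assemble_mixture(
    standards: list[StandardSpectrum],
    concentrations: np.ndarray,
    protons: np.ndarray,
    params: SimulationParameters,
    rng: np.random.Generator,
    group_label: str = "",
    replicate_index: int = 0,
    ph: float | None = None,
    add_noise: bool = True,
    final_smoothing: bool | None = None,
) -> MixtureSpectrum:
    """Build one replicate: weighted sum + noise + apodization-like smoothing.

    All standards must be normalized and share one grid.  ``add_noise``
    and ``final_smoothing`` can be forced off for exact-arithmetic
    testing; by default the smoothing switch follows the parameters.
    """
    if not standards:
        raise ValidationError("at least one standard is required")
    grid = standards[0].ppm
    c = np.asarray(concentrations, dtype=float)
    p = np.asarray(protons, dtype=float)
    if not (len(standards) == c.size == p.size):
        raise ValidationError("standards, concentrations and proton counts must align")
    if np.any(c <= 0):
        raise ValidationError("concentrations must be > 0")
    if np.any(p < 1):
        raise ValidationError("proton counts must be >= 1")
    y = np.zeros_like(grid)
    for spec, ck, pk in zip(standards, c, p):
        if spec.stage != "normalized":
            raise ValidationError(f"standard {spec.metabolite_id!r} is not normalized")
        if spec.ppm.size != grid.size or not np.array_equal(spec.ppm, grid):
            raise ValidationError(f"standard {spec.metabolite_id!r} is not on the common grid")
        y = y + spec.intensity * (ck * pk)
    sigma_n = noise_sigma(float(y.max()), params.snr) if add_noise else 0.0
    if sigma_n > 0:
        y = y + sigma_n * rng.standard_normal(y.size)
    do_smooth = params.final_smoothing if final_smoothing is None else final_smoothing
    if do_smooth:
        tmp = StandardSpectrum("mixture", "mixture", grid, y, stage="raw")
        y = kernel_smooth(
            tmp, params.kernel, params.kernel_bandwidth, params.smoothing_threshold_fraction
        ).intensity
    return MixtureSpectrum(
        ppm=grid, intensity=y, group_label=group_label,
        replicate_index=replicate_index,
        concentrations={s.metabolite_id: float(ck) for s, ck in zip(standards, c)},
        ph=ph, noise_sd=sigma_n,
    )


# ---------------------------------------------------------------------------
# Experiment orchestration
# ---------------------------------------------------------------------------


def _load_standard(nssd_dir: Path, metabolite: str, experiment: str) -> StandardSpectrum:
    bruker_dir = nssd_dir / metabolite / experiment
    text_file = nssd_dir / metabolite / f"{experiment}.txt"
    if bruker_dir.is_dir():
        return read_standard_spectrum(
            bruker_dir, "bruker", metabolite_id=metabolite, experiment_id=experiment
        )
    if text_file.exists():
        return read_standard_spectrum(
            text_file, "text", metabolite_id=metabolite, experiment_id=experiment
        )
    raise ValidationError(
        f"no spectrum for metabolite {metabolite!r} experiment {experiment!r} in {nssd_dir}"
    )


def load_nssd_metadata(
    nssd_dir: str | Path,
) -> tuple[dict[str, str], ProtonTable, MultipletTable, dict[str, str]]:
    """Load experiment selection, proton counts, multiplets and synonyms."""
    nssd_dir = Path(nssd_dir)
    experiments = read_experiment_selection(nssd_dir / "experiments.csv")
    protons = read_proton_table(nssd_dir / "protons.csv")
    mpath = nssd_dir / "multiplets.txt"
    multiplets = read_multiplet_table(mpath) if mpath.exists() else MultipletTable({})
    spath = nssd_dir / "synonyms.csv"
    synonyms = read_synonyms(spath) if spath.exists() else {}
    return experiments, protons, multiplets, synonyms


def simulate_experiment(
    nssd_dir: str | Path,
    control_template: ConcentrationTemplate,
    case_template: ConcentrationTemplate,
    params: SimulationParameters,
    correlation: CorrelationSpec | None = None,
) -> ExperimentResult:
    """Simulate a two-group (control/case) experiment from an NSSD on disk.

    Both templates must list the same metabolites (a case template is
    typically the control template with fold changes applied).  The run
    is fully determined by ``params.rng_seed``.
    """
    nssd_dir = Path(nssd_dir)
    experiments, protons, multiplet_table, synonyms = load_nssd_metadata(nssd_dir)

    def resolve(name: str) -> str:
        return synonyms.get(name, name)

    mets_control = [resolve(m) for m in control_template.metabolites]
    mets_case = [resolve(m) for m in case_template.metabolites]
    if mets_control != mets_case:
        raise ValidationError(
            "control and case templates must list the same metabolites in the same order"
        )
    missing = [m for m in mets_control if m not in experiments or m not in protons.counts]
    if missing:
        raise ValidationError(
            f"metabolite(s) {missing} have no NSSD spectrum or proton count"
        )

    # preprocess each required standard once (shared by both groups)
    standards: dict[str, StandardSpectrum] = {}
    reports: list[PreprocessReport] = []
    for met in mets_control:
        raw = _load_standard(nssd_dir, met, experiments[met])
        clean, report = preprocess_standard(raw, params)
        standards[met] = clean
        reports.append(report)
    p_vec = np.array([protons[m] for m in mets_control], dtype=float)

    R = correlation.to_matrix(mets_control) if correlation is not None else None

    groups: dict[str, list[MixtureSpectrum]] = {}
    draws_by_group: dict[str, ConcentrationDraws] = {}
    shift_log: dict[str, list[list[ShiftAssignment]]] = {}
    for label, template in (
        ("control", control_template),
        ("case", case_template),
    ):
        # both groups restart from the same derived substreams (common
        # random numbers): between-group differences then reflect the
        # templates, not sampling noise, and identical templates give
        # bit-identical groups
        conc_seed, ph_seed, rep_root = np.random.SeedSequence(params.rng_seed).spawn(3)
        draws = draw_group_concentrations(
            template, params.n_replicates, np.random.default_rng(conc_seed),
            correlation=R,
        )
        draws.group_label = label
        draws.metabolites = mets_control
        ph_values = sample_ph(params, params.n_replicates, np.random.default_rng(ph_seed))
        rep_seeds = rep_root.spawn(params.n_replicates)
        replicates: list[MixtureSpectrum] = []
        rep_assignments: list[list[ShiftAssignment]] = []
        for r in range(params.n_replicates):
            shift_seed, noise_seed = rep_seeds[r].spawn(2)
            ph_r = float(ph_values[r])
            if params.shift_enabled:
                shift_rng = np.random.default_rng(shift_seed)
                rep_standards = []
                assignments = []
                for met in mets_control:
                    shifted, assignment = shift_replicate(
                        standards[met], multiplet_table.get(met), params, ph_r, shift_rng
                    )
                    rep_standards.append(normalize_unit_integral(shifted))
                    assignments.append(assignment)
                rep_assignments.append(assignments)
            else:
                rep_standards = [standards[m] for m in mets_control]
            mix = assemble_mixture(
                rep_standards, draws.values[r], p_vec, params,
                np.random.default_rng(noise_seed),
                group_label=label, replicate_index=r,
                ph=ph_r if params.shift_enabled else None,
            )
            replicates.append(mix)
        groups[label] = replicates
        draws_by_group[label] = draws
        shift_log[label] = rep_assignments

    return ExperimentResult(
        control=groups["control"], case=groups["case"],
        control_draws=draws_by_group["control"], case_draws=draws_by_group["case"],
        parameters=params, preprocess_reports=reports,
        shift_assignments=shift_log,
    )


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------


def _write_matrix_csv(path: Path, matrix: np.ndarray, header: list[str]) -> None:
    with path.open("w") as fh:
        fh.write(",".join(header) + "\n")
        for row in np.atleast_2d(matrix):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def write_experiment_result(result: ExperimentResult, out_dir: str | Path) -> None:
    """Write all run artifacts to a directory.

    Per group: a TSV spectra matrix (first column ppm, one column per
    replicate), a concentrations CSV and a pH CSV; plus the adjusted
    correlation/covariance matrices, a parameter snapshot and the
    preprocessing reports.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for label in ("control", "case"):
        reps = result.group(label)
        grid = reps[0].ppm
        with (out_dir / f"spectra_{label}.tsv").open("w") as fh:
            fh.write("ppm\t" + "\t".join(f"rep{m.replicate_index}" for m in reps) + "\n")
            mat = np.column_stack([grid] + [m.intensity for m in reps])
            for row in mat:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")
        draws = {"control": result.control_draws, "case": result.case_draws}[label]
        _write_matrix_csv(
            out_dir / f"concentrations_{label}.csv", draws.values, draws.metabolites
        )
        with (out_dir / f"ph_{label}.csv").open("w") as fh:
            fh.write("replicate,ph\n")
            for m in reps:
                fh.write(f"{m.replicate_index},{'' if m.ph is None else repr(m.ph)}\n")
        for name, mat in (
            ("requested_correlation", draws.requested_correlation),
            ("repaired_correlation", draws.repaired_correlation),
            ("covariance", draws.covariance),
            ("inflated_covariance", draws.inflated_covariance),
        ):
            if mat is not None:
                _write_matrix_csv(out_dir / f"{name}_{label}.csv", mat, draws.metabolites)
    snapshot = {
        k: (None if isinstance(v, float) and math.isnan(v) else v)
        for k, v in vars(result.parameters).items()
    }
    snapshot["snr"] = "inf" if math.isinf(result.parameters.snr) else result.parameters.snr
    (out_dir / "parameters.json").write_text(json.dumps(snapshot, indent=2) + "\n")
    for report in result.preprocess_reports:
        report.to_json(out_dir / f"preprocess_{report.metabolite_id}.json")
    with (out_dir / "run.log").open("w") as fh:
        fh.write(f"seed {result.parameters.rng_seed}\n")
        for label in ("control", "case"):
            reps = result.group(label)
            draws = {"control": result.control_draws, "case": result.case_draws}[label]
            fh.write(
                f"{label}: {len(reps)} replicates, {len(draws.metabolites)} metabolites, "
                f"noise sd {reps[0].noise_sd:.6g}, "
                f"rejection attempts {draws.attempts}, "
                f"diagonal inflation {draws.diagonal_inflation:.6g}\n"
            )
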