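"""Reading and writing the NMR standard-spectra database (NSSD) and its metadata.

An NSSD is a directory of pure-compound 1D 1H spectra, one per
(metabolite, experiment) pair, plus plain-text metadata tables:
concentration templates, proton counts, multiplet definitions,
experiment selection, synonyms and pairwise inter-metabolite
correlations.  Two spectrum dialects are supported:

``bruker``
    A processed-data directory holding a binary real spectrum ``1r``
    (32-bit signed integers) and a text parameter file ``procs``.  The
    ppm axis is reconstructed from the offset (ppm of the first stored
    point), the spectral width (ppm) and the number of points: stored
    point *i* sits at ``offset - i * sw / size`` (descending, as the
    instrument software writes it).  Intensities are scaled by
    ``2**NC_proc``.  Internally every spectrum is re-sorted to an
    ascending ppm axis and the original direction recorded.

``text``
    Two whitespace- or comma-separated columns (ppm, intensity);
    ``#`` starts a comment.

All metadata tables are small delimited text files; the exact dialects
are documented with each reader below and emitted by the matching
writers, so a database written by :mod:`nmrmixsim.synthetic_standards`
round-trips exactly.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

STAGES = ("raw", "preprocessed", "normalized")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class StandardSpectrum:
    """One metabolite's pure-compound spectrum on a ppm grid.

    ``ppm`` is strictly monotone (ascending after ingest); ``intensity``
    has the same length.  ``stage`` tracks where the spectrum sits in
    the preprocessing pipeline; a ``normalized`` spectrum integrates
    (sums) to one and is non-negative.
    """

    metabolite_id: str
    experiment_id: str
    ppm: np.ndarray
    intensity: np.ndarray
    stage: str = "raw"
    ppm_descending_on_disk: bool = False

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValidationError("ppm and intensity must be 1-D vectors")
        if self.ppm.size != self.intensity.size or self.ppm.size < 2:
            raise ValidationError(
                "ppm and intensity must have equal length >= 2 "
                f"(got {self.ppm.size} and {self.intensity.size})"
            )
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("ppm axis must be strictly monotone")
        if np.all(d < 0):
            # ascending convention everywhere after ingest
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
            self.ppm_descending_on_disk = True
        if self.stage == "normalized":
            if abs(float(self.intensity.sum()) - 1.0) > 1e-9:
                raise ValidationError("normalized spectrum must sum to 1 within 1e-9")
            if float(self.intensity.min()) < 0:
                raise ValidationError("normalized spectrum must be non-negative")

    @property
    def n_points(self) -> int:
        return int(self.ppm.size)

    def copy(self, **changes) -> "StandardSpectrum":
        out = replace(self, ppm=self.ppm.copy(), intensity=self.intensity.copy())
        for k, v in changes.items():
            setattr(out, k, v)
        return out


@dataclass(frozen=True)
class ConcentrationEntry:
    metabolite_id: str
    mean: float
    sd: float
    units: str = "uM"


@dataclass
class ConcentrationTemplate:
    """Per-metabolite concentration mean/SD for one group."""

    entries: list[ConcentrationEntry]
    group_label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.metabolite_id in seen:
                raise ValidationError(f"duplicate metabolite {e.metabolite_id!r}")
            seen.add(e.metabolite_id)
            if not (math.isfinite(e.mean) and math.isfinite(e.sd)):
                raise ValidationError(f"non-finite mean/sd for {e.metabolite_id!r}")
            if e.mean < 0 or e.sd < 0:
                raise ValidationError(f"negative mean/sd for {e.metabolite_id!r}")

    @property
    def metabolites(self) -> list[str]:
        return [e.metabolite_id for e in self.entries]

    @property
    def means(self) -> np.ndarray:
        return np.array([e.mean for e in self.entries], dtype=float)

    @property
    def sds(self) -> np.ndarray:
        return np.array([e.sd for e in self.entries], dtype=float)


@dataclass
class ProtonTable:
    """Observed 1H count per metabolite (peak area scales with it)."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for met, p in self.counts.items():
            if int(p) != p or p < 1:
                raise ValidationError(f"proton count for {met!r} must be a positive integer")
            self.counts[met] = int(p)

    def __getitem__(self, metabolite_id: str) -> int:
        try:
            return self.counts[metabolite_id]
        except KeyError:
            raise ValidationError(f"no proton count for metabolite {metabolite_id!r}") from None


@dataclass
class Multiplet:
    """One multiplet: tabulated peak positions plus optional titration data.

    ``acid_limits``/``base_limits`` give each peak's position in the
    fully protonated / deprotonated limit; ``pka`` the acid dissociation
    constant governing the titration midpoint.  Absent values are
    sampled downstream from configured fallbacks.
    """

    peaks: list[float]
    pka: float | None = None
    acid_limits: list[float] | None = None
    base_limits: list[float] | None = None

    def __post_init__(self) -> None:
        order = np.argsort(self.peaks, kind="stable")
        self.peaks = [float(self.peaks[i]) for i in order]
        for name in ("acid_limits", "base_limits"):
            lim = getattr(self, name)
            if lim is not None:
                if len(lim) != len(self.peaks):
                    raise ValidationError(
                        f"{name} length {len(lim)} != peak count {len(self.peaks)}"
                    )
                if not all(math.isfinite(v) for v in lim):
                    raise ValidationError(f"{name} must be finite")
                setattr(self, name, [float(lim[i]) for i in order])


@dataclass
class MultipletTable:
    """Multiplet definitions per metabolite (one pKa per metabolite)."""

    multiplets: dict[str, list[Multiplet]]

    def __post_init__(self) -> None:
        for met, mlist in self.multiplets.items():
            pkas = {m.pka for m in mlist if m.pka is not None}
            if len(pkas) > 1:
                raise ValidationError(
                    f"metabolite {met!r} has conflicting pKa values {sorted(pkas)}; "
                    "one pKa per metabolite is assumed"
                )

    def get(self, metabolite_id: str) -> list[Multiplet]:
        return self.multiplets.get(metabolite_id, [])


@dataclass
class CorrelationSpec:
    """User-specified pairwise Pearson correlations between metabolites."""

    pairs: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        seen: set[frozenset[str]] = set()
        for a, b, r in self.pairs:
            if a == b:
                raise ValidationError(f"self-correlation for {a!r}")
            if abs(r) > 1:
                raise ValidationError(f"|r| > 1 for pair ({a!r}, {b!r})")
            key = frozenset((a, b))
            if key in seen:
                raise ValidationError(f"duplicate pair ({a!r}, {b!r})")
            seen.add(key)

    def to_matrix(self, metabolites: list[str]) -> np.ndarray:
        """Dense correlation matrix in the given metabolite order."""
        idx = {m: i for i, m in enumerate(metabolites)}
        R = np.eye(len(metabolites))
        for a, b, r in self.pairs:
            if a not in idx or b not in idx:
                missing = [m for m in (a, b) if m not in idx]
                raise ValidationError(f"correlation references unknown metabolite(s) {missing}")
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
        return R


@dataclass
class SimulationParameters:
    """All tunables of a simulation run.

    Defaults follow the conventions of urine profiling: the internal
    chemical-shift standard (TSP) region below 0.2 ppm and the residual
    water/urea region 4.5-6.0 ppm are zeroed; the baseline window is
    0.3125 ppm with threshold divisor 10; negative-artifact removal uses
    32 bins; kernel smoothing uses a normal kernel below 0.8 of the
    maximum intensity.
    """

    n_replicates: int = 50
    ppm_min: float = -0.5
    ppm_max: float = 10.0
    n_points: int = 16384
    snr: float = 200.0  # may be math.inf for noise-free runs
    exclusion_regions: list[tuple[float, float]] = field(
        default_factory=lambda: [(-math.inf, 0.2), (4.5, 6.0)]
    )
    baseline_window: float = 0.3125  # ppm
    baseline_threshold_divisor: float = 10.0
    n_noise_bins: int = 32
    kernel: str = "normal"
    kernel_bandwidth: int = 2  # data points
    smoothing_threshold_fraction: float = 0.8
    peak_min_height_fraction: float = 0.05
    peak_noise_multiple: float = 5.0
    multiplet_match_tolerance: float = 0.03  # ppm
    shift_enabled: bool = True
    ph_fixed: float | None = None
    ph_mean: float = 7.0
    ph_sd: float = 0.5
    pka_fallback_mean: float = 7.0
    pka_fallback_sd: float = 0.5
    limit_offset_mean: float = 0.05  # ppm offset of acid/base limits around delta
    limit_offset_sd: float = 0.01
    rng_seed: int = 0
    case_mode: str = "explicit_template"  # or "fold_change"
    final_smoothing: bool = True

    def __post_init__(self) -> None:
        if not self.ppm_min < self.ppm_max:
            raise ValidationError("ppm_min must be < ppm_max")
        if self.n_points < 2:
            raise ValidationError("n_points must be >= 2")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if not self.snr > 0:
            raise ValidationError("SNR must be > 0 (use inf for noise-free)")
        if self.baseline_threshold_divisor <= 0:
            raise ValidationError("baseline_threshold_divisor must be > 0")
        if not 0 < self.smoothing_threshold_fraction <= 1:
            raise ValidationError("smoothing_threshold_fraction must be in (0, 1]")
        if self.baseline_window <= 0:
            raise ValidationError("baseline_window must be > 0")
        if self.n_noise_bins < 1:
            raise ValidationError("n_noise_bins must be >= 1")
        if self.kernel_bandwidth < 1:
            raise ValidationError("kernel_bandwidth must be >= 1")
        if self.ph_sd < 0 or self.pka_fallback_sd < 0 or self.limit_offset_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.case_mode not in ("explicit_template", "fold_change"):
            raise ValidationError(f"unknown case_mode {self.case_mode!r}")
        # clip exclusion regions to the grid
        clipped = []
        for lo, hi in self.exclusion_regions:
            if hi < lo:
                lo, hi = hi, lo
            lo = max(lo, self.ppm_min)
            hi = min(hi, self.ppm_max)
            if lo <= hi:
                clipped.append((lo, hi))
        self.exclusion_regions = clipped

    def grid(self) -> np.ndarray:
        return np.linspace(self.ppm_min, self.ppm_max, self.n_points)


# ---------------------------------------------------------------------------
# Spectrum readers/writers
# ---------------------------------------------------------------------------

_PROCS_KEYS = {"OFFSET", "SW_p", "SI", "BYTORDP", "NC_proc"}


def _read_procs(path: Path) -> dict[str, float]:
    params: dict[str, float] = {}
    for line in path.read_text().splitlines():
        m = re.match(r"##\$(\w+)=\s*(\S+)", line)
        if m and m.group(1) in _PROCS_KEYS:
            params[m.group(1)] = float(m.group(2))
    missing = _PROCS_KEYS - params.keys()
    if missing:
        raise FormatError(f"{path}: missing parameter(s) {sorted(missing)}")
    return params


def read_standard_spectrum(
    path: str | Path,
    dialect: str,
    metabolite_id: str | None = None,
    experiment_id: str | None = None,
) -> StandardSpectrum:
    """Read one standard spectrum in the ``bruker`` or ``text`` dialect.

    For ``bruker``, *path* is the processed-data directory containing
    ``1r`` and ``procs``; for ``text`` it is the two-column file.
    Metabolite/experiment ids default to the enclosing directory / file
    stem.
    """
    path = Path(path)
    if dialect == "bruker":
        procs = path / "procs"
        oner = path / "1r"
        for p in (procs, oner):
            if not p.exists():
                raise FormatError(f"missing file {p}")
        params = _read_procs(procs)
        size = int(params["SI"])
        byt = int(params["BYTORDP"])
        if byt == 0:
            dtype = "<i4"
        elif byt == 1:
            dtype = ">i4"
        else:
            raise FormatError(f"{procs}: unknown byte order BYTORDP={byt}")
        raw = np.fromfile(oner, dtype=dtype)
        if raw.size < size:
            raise FormatError(
                f"{oner}: expected {size} points, file holds {raw.size}"
            )
        intensity = raw[:size].astype(float) * 2.0 ** params["NC_proc"]
        sw, offset = params["SW_p"], params["OFFSET"]
        ppm = offset - np.arange(size) * (sw / size)
        met = metabolite_id or path.parent.name
        exp = experiment_id or path.name
        return StandardSpectrum(met, exp, ppm, intensity, stage="raw")
    if dialect == "text":
        rows = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = re.split(r"[,\s]+", line)
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from None
        if len(rows) < 2:
            raise FormatError(f"{path}: fewer than two data points")
        arr = np.asarray(rows)
        met = metabolite_id or path.stem
        exp = experiment_id or path.stem
        return StandardSpectrum(met, exp, arr[:, 0], arr[:, 1], stage="raw")
    raise ValidationError(f"unknown dialect {dialect!r}")


def write_standard_spectrum(spectrum: StandardSpectrum, path: str | Path, dialect: str) -> None:
    """Write a spectrum in the given dialect (inverse of the reader).

    The bruker writer stores intensities as 32-bit integers (``NC_proc``
    = 0), little-endian, with the ppm axis descending as on the
    instrument; it requires a uniform grid.
    """
    path = Path(path)
    if dialect == "text":
        with path.open("w") as fh:
            fh.write("# ppm intensity\n")
            for x, y in zip(spectrum.ppm, spectrum.intensity):
                fh.write(f"{float(x)!r} {float(y)!r}\n")
        return
    if dialect == "bruker":
        steps = np.diff(spectrum.ppm)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0):
            raise ValidationError("bruker dialect requires a uniform ppm grid")
        n = spectrum.n_points
        step = float(steps[0])
        sw = step * n
        offset = float(spectrum.ppm[-1])  # highest ppm = first stored point
        path.mkdir(parents=True, exist_ok=True)
        vals = np.round(spectrum.intensity[::-1]).astype("<i4")
        vals.tofile(path / "1r")
        (path / "procs").write_text(
            "##TITLE= processed spectrum parameters\n"
            f"##$SI= {n}\n"
            f"##$OFFSET= {offset!r}\n"
            f"##$SW_p= {sw!r}\n"
            "##$BYTORDP= 0\n"
            "##$NC_proc= 0\n"
        )
        return
    raise ValidationError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------


def _data_lines(path: Path) -> list[tuple[int, str]]:
    out = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if line:
            out.append((lineno, line))
    return out


def read_concentration_template(
    path: str | Path,
    group_label: str = "",
    synonyms: dict[str, str] | None = None,
) -> ConcentrationTemplate:
    """Read a CSV of ``metabolite,mean,sd[,units]`` with a header row.

    A blank SD is filled with mean/1.95 (the half-range convention for
    database entries that report only a mean or a range).  If a synonym
    map is given, metabolite names are translated through it; names
    absent from the map are kept as-is.
    """
    from .concentration_model import estimate_sd_from_mean

    path = Path(path)
    lines = _data_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty template")
    entries = []
    for lineno, line in lines[1:]:  # skip header
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected metabolite,mean,sd[,units]")
        name = parts[0]
        if synonyms and name in synonyms:
            name = synonyms[name]
        try:
            mean = float(parts[1])
        except ValueError:
            raise ValidationError(f"{path}:{lineno}: non-numeric mean {parts[1]!r}") from None
        if mean < 0:
            raise ValidationError(f"{path}:{lineno}: negative mean for {name!r}")
        if parts[2] == "":
            sd = estimate_sd_from_mean(mean)
        else:
            try:
                sd = float(parts[2])
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-numeric sd {parts[2]!r}") from None
        units = parts[3] if len(parts) > 3 and parts[3] else "uM"
        entries.append(ConcentrationEntry(name, mean, sd, units))
    return ConcentrationTemplate(entries, group_label=group_label or path.stem)


def write_concentration_template(template: ConcentrationTemplate, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("metabolite,mean,sd,units\n")
        for e in template.entries:
            fh.write(f"{e.metabolite_id},{e.mean!r},{e.sd!r},{e.units}\n")


def read_proton_table(path: str | Path) -> ProtonTable:
    """Read a CSV of ``metabolite,protons`` with a header row."""
    path = Path(path)
    counts: dict[str, int] = {}
    for lineno, line in _data_lines(path)[1:]:
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected metabolite,protons")
        name = parts[0]
        if name in counts:
            raise ValidationError(f"{path}:{lineno}: duplicate metabolite {name!r}")
        try:
            counts[name] = int(parts[1])
        except ValueError:
            raise ValidationError(f"{path}:{lineno}: non-integer proton count") from None
    return ProtonTable(counts)


def write_proton_table(table: ProtonTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("metabolite,protons\n")
        for met, p in table.counts.items():
            fh.write(f"{met},{p}\n")


def _parse_float_list(text: str) -> list[float]:
    return [float(v) for v in text.split(",") if v.strip() != ""]


def read_multiplet_table(path: str | Path) -> MultipletTable:
    """Read multiplet records, one per line, pipe-separated::

        metabolite | 7.05,7.06 | pKa=6.0 | acid=7.30,7.31 | base=6.90,6.91

    The pKa and acid/base limit fields are optional; limit lists must
    match the peak count.
    """
    path = Path(path)
    table: dict[str, list[Multiplet]] = {}
    for lineno, line in _data_lines(path):
        parts = [p.strip() for p in line.split("|")]
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'metabolite | peaks | ...'")
        name = parts[0]
        try:
            peaks = _parse_float_list(parts[1])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: bad peak list {parts[1]!r}") from None
        if not peaks:
            raise FormatError(f"{path}:{lineno}: empty peak list")
        kw: dict[str, object] = {}
        for extra in parts[2:]:
            if not extra:
                continue
            if "=" not in extra:
                raise FormatError(f"{path}:{lineno}: expected key=value, got {extra!r}")
            key, val = (s.strip() for s in extra.split("=", 1))
            try:
                if key == "pKa":
                    kw["pka"] = float(val)
                elif key == "acid":
                    kw["acid_limits"] = _parse_float_list(val)
                elif key == "base":
                    kw["base_limits"] = _parse_float_list(val)
                else:
                    raise FormatError(f"{path}:{lineno}: unknown field {key!r}")
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad value for {key!r}") from None
        try:
            mult = Multiplet(peaks, **kw)  # type: ignore[arg-type]
        except ValidationError as err:
            raise ValidationError(f"{path}:{lineno}: {err}") from None
        table.setdefault(name, []).append(mult)
    return MultipletTable(table)


def write_multiplet_table(table: MultipletTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# metabolite | peaks (ppm) | pKa=... | acid=... | base=...\n")
        for met, mlist in table.multiplets.items():
            for m in mlist:
                line = f"{met} | " + ",".join(repr(p) for p in m.peaks)
                if m.pka is not None:
                    line += f" | pKa={m.pka!r}"
                if m.acid_limits is not None:
                    line += " | acid=" + ",".join(repr(v) for v in m.acid_limits)
                if m.base_limits is not None:
                    line += " | base=" + ",".join(repr(v) for v in m.base_limits)
                fh.write(line + "\n")


def read_experiment_selection(path: str | Path) -> dict[str, str]:
    """Read a CSV of ``metabolite,experiment`` (which spectrum to use)."""
    path = Path(path)
    out: dict[str, str] = {}
    for lineno, line in _data_lines(path)[1:]:
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected metabolite,experiment")
        if parts[0] in out:
            raise ValidationError(f"{path}:{lineno}: duplicate metabolite {parts[0]!r}")
        out[parts[0]] = parts[1]
    return out


def write_experiment_selection(selection: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("metabolite,experiment\n")
        for met, exp in selection.items():
            fh.write(f"{met},{exp}\n")


def read_synonyms(path: str | Path) -> dict[str, str]:
    """Read a CSV of ``external_name,nssd_id``."""
    path = Path(path)
    out: dict[str, str] = {}
    for lineno, line in _data_lines(path)[1:]:
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected external_name,nssd_id")
        out[parts[0]] = parts[1]
    return out


def write_synonyms(synonyms: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("external_name,nssd_id\n")
        for ext, nssd in synonyms.items():
            fh.write(f"{ext},{nssd}\n")


def read_correlation_spec(path: str | Path) -> CorrelationSpec:
    """Read a CSV of ``metabolite_a,metabolite_b,r``."""
    path = Path(path)
    pairs = []
    for lineno, line in _data_lines(path)[1:]:
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected metabolite_a,metabolite_b,r")
        try:
            pairs.append((parts[0], parts[1], float(parts[2])))
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric correlation") from None
    return CorrelationSpec(pairs)


def write_correlation_spec(spec: CorrelationSpec, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("metabolite_a,metabolite_b,r\n")
        for a, b, r in spec.pairs:
            fh.write(f"{a},{b},{r!r}\n")


# ---------------------------------------------------------------------------
# Parameter/config file
# ---------------------------------------------------------------------------

_BOOL_KEYS = {"shift_enabled", "final_smoothing"}
_INT_KEYS = {
    "n_replicates", "n_points", "n_noise_bins", "kernel_bandwidth", "rng_seed",
}
_FLOAT_KEYS = {
    "ppm_min", "ppm_max", "snr", "baseline_window", "baseline_threshold_divisor",
    "smoothing_threshold_fraction", "peak_min_height_fraction", "peak_noise_multiple",
    "multiplet_match_tolerance", "ph_fixed", "ph_mean", "ph_sd",
    "pka_fallback_mean", "pka_fallback_sd", "limit_offset_mean", "limit_offset_sd",
}
_STR_KEYS = {"kernel", "case_mode"}

# keys interpreted by the run driver (paths etc.), tolerated here
RUN_CONFIG_KEYS = {
    "nssd", "control_template", "case_template", "fold_changes",
    "correlations", "synonyms", "experiments", "protons",
}


def read_config_dict(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file with ``#`` comments."""
    path = Path(path)
    out: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected key = value")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = val
    return out


def _parse_regions(text: str) -> list[tuple[float, float]]:
    regions = []
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        lo, hi = (float(v) for v in chunk.split(":"))
        regions.append((lo, hi))
    return regions


def parameters_from_dict(
    config: dict[str, str], source: str = "<config>"
) -> SimulationParameters:
    """Build :class:`SimulationParameters` from a flat key/value mapping.

    Unknown keys produce a warning, never an error, so run-driver keys
    and forward-compatible extensions pass through harmlessly.
    """
    known = {f.name for f in fields(SimulationParameters)}
    kwargs: dict[str, object] = {}
    for key, val in config.items():
        try:
            if key == "exclusion_regions":
                kwargs[key] = _parse_regions(val)
            elif key in _BOOL_KEYS:
                low = val.lower()
                if low in ("true", "1", "yes", "on"):
                    kwargs[key] = True
                elif low in ("false", "0", "no", "off"):
                    kwargs[key] = False
                else:
                    raise ValueError(val)
            elif key in _INT_KEYS:
                kwargs[key] = int(val)
            elif key in _FLOAT_KEYS:
                kwargs[key] = None if val.lower() == "none" else float(val)
            elif key in _STR_KEYS:
                kwargs[key] = val
            elif key in known:
                kwargs[key] = val
            elif key in RUN_CONFIG_KEYS:
                continue
            else:
                warnings.warn(f"{source}: ignoring unknown parameter {key!r}", stacklevel=2)
        except (ValueError, TypeError):
            raise ValidationError(
                f"{source}: cannot parse value {val!r} for key {key!r}"
            ) from None
    return SimulationParameters(**kwargs)  # type: ignore[arg-type]


def load_parameters(path: str | Path | None = None) -> SimulationParameters:
    """Load parameters from a config file; ``None`` gives all defaults."""
    if path is None:
        return SimulationParameters()
    return parameters_from_dict(read_config_dict(path), source=str(path))
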