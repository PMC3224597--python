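"""Simulation of per-replicate metabolite concentrations.

Concentrations are physically non-negative, so independent metabolites
are drawn from a normal distribution truncated at zero,

    c_k ~ N(mu, sigma^2) I(c_k > 0),

sampled by the inverse-CDF method.  When the user specifies pairwise
inter-metabolite correlations, the requested correlation matrix is
first repaired to the nearest positive-semidefinite correlation matrix
(Higham's alternating-projections method), a covariance matrix is built
from it and the per-metabolite standard deviations, its diagonal is
inflated if needed to restore strict positive definiteness, and
replicate vectors are drawn from the multivariate normal with rejection
of any vector containing a non-positive component.  Every matrix
actually used (requested, repaired, inflated) is retained for
inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError
from .nssd_io import ConcentrationEntry, ConcentrationTemplate

logger = logging.getLogger(__name__)

#: half-range divisor: a database entry reporting only a mean (or a
#: "half-range") is assigned SD = mean / 1.95, i.e. the stated value is
#: read as roughly a 95% half-width.
SD_FALLBACK_DIVISOR = 1.95


@dataclass
class ConcentrationDraws:
    """Concentration matrix for one group plus the matrices used to draw it."""

    values: np.ndarray  # (n_replicates, K), all entries > 0
    metabolites: list[str]
    group_label: str = ""
    requested_correlation: np.ndarray | None = None
    repaired_correlation: np.ndarray | None = None
    covariance: np.ndarray | None = None
    inflated_covariance: np.ndarray | None = None
    diagonal_inflation: float = 0.0
    attempts: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.metabolites):
            raise ValidationError("draw matrix shape does not match metabolite list")
        if not np.all(self.values > 0):
            raise ValidationError("all concentration draws must be strictly positive")

    def column(self, metabolite_id: str) -> np.ndarray:
        return self.values[:, self.metabolites.index(metabolite_id)]


def estimate_sd_from_mean(mean_or_half_range: float) -> float:
    """SD fallback for entries reporting only a mean or half-range."""
    if not np.isfinite(mean_or_half_range) or mean_or_half_range < 0:
        raise ValidationError("mean/half-range must be finite and >= 0")
    return mean_or_half_range / SD_FALLBACK_DIVISOR


def apply_fold_changes(
    control: ConcentrationTemplate, folds: dict[str, float]
) -> ConcentrationTemplate:
    """Derive a case template by scaling control means (and SDs) by fold changes.

    SDs scale by the same fold, keeping each metabolite's coefficient of
    variation constant between groups.  Metabolites without a fold are
    copied unchanged.
    """
    known = set(control.metabolites)
    unknown = sorted(set(folds) - known)
    if unknown:
        raise ValidationError(f"fold changes reference unknown metabolite(s) {unknown}")
    for met, f in folds.items():
        if not (np.isfinite(f) and f > 0):
            raise ValidationError(f"fold change for {met!r} must be > 0")
    entries = []
    for e in control.entries:
        f = folds.get(e.metabolite_id, 1.0)
        entries.append(ConcentrationEntry(e.metabolite_id, e.mean * f, e.sd * f, e.units))
    return ConcentrationTemplate(entries, group_label=control.group_label + "_case")


def sample_truncated_normal(
    mu: float, sigma: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF draws from N(mu, sigma^2) truncated to (0, inf).

    With alpha = -mu/sigma, each draw is
    ``mu + sigma * Q(Phi(alpha) + u * (1 - Phi(alpha)))`` for u uniform
    on (0, 1), where Phi and Q are the standard normal CDF and quantile.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma == 0:
        if mu <= 0:
            raise ValidationError(
                "sigma = 0 with mu <= 0: the truncated distribution has no positive mass"
            )
        return np.full(n, float(mu))
    alpha = -mu / sigma
    phi_alpha = stats.norm.cdf(alpha)
    u = rng.uniform(size=n)
    draws = mu + sigma * stats.norm.ppf(phi_alpha + u * (1.0 - phi_alpha))
    # the inverse CDF can only land in the open interval, but guard the
    # float boundary anyway
    return np.maximum(draws, np.nextafter(0.0, 1.0))


def _project_psd(A: np.ndarray, floor: float = 0.0) -> np.ndarray:
    w, V = np.linalg.eigh(A)
    w = np.maximum(w, floor)
    return (V * w) @ V.T


def nearest_psd_correlation(
    R: np.ndarray, tol: float = 1e-8, max_iter: int = 200
) -> np.ndarray:
    """Nearest (Frobenius) correlation matrix to ``R`` that is PSD.

    Alternating projections with Dykstra's correction between the PSD
    cone and the unit-diagonal affine set.  If ``R`` is already PSD
    (minimum eigenvalue >= -1e-10) it is returned unchanged; any repair
    is logged.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-12):
        raise ValidationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-12):
        raise ValidationError("correlation matrix must have a unit diagonal")
    if np.any(np.abs(R) > 1 + 1e-12):
        raise ValidationError("correlation entries must lie in [-1, 1]")

    if float(np.linalg.eigvalsh(R).min()) >= -1e-10:
        return R

    Y = R.copy()
    dS = np.zeros_like(R)
    for _ in range(max_iter):
        Rk = Y - dS
        X = _project_psd(Rk)
        X = (X + X.T) / 2.0
        dS = X - Rk
        Y_new = X.copy()
        np.fill_diagonal(Y_new, 1.0)
        delta = float(np.max(np.abs(Y_new - Y)))
        Y = Y_new
        if delta < tol:
            break
    # final clean-up: symmetric, unit diagonal, eigenvalues >= -1e-10
    Y = (Y + Y.T) / 2.0
    if float(np.linalg.eigvalsh(Y).min()) < -1e-10:
        Y = _project_psd(Y)
        d = np.sqrt(np.clip(np.diag(Y), 1e-300, None))
        Y = Y / np.outer(d, d)
        np.fill_diagonal(Y, 1.0)
    logger.warning(
        "requested correlation matrix was not PSD; repaired "
        "(max |change| = %.3g)", float(np.max(np.abs(Y - R)))
    )
    return Y


def build_covariance(
    R_psd: np.ndarray, sds: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Covariance Sigma = diag(sd) R diag(sd), inflated to positive definite.

    Returns ``(sigma, sigma_inflated, inflation)``; if the minimum
    eigenvalue of Sigma is <= 0 every diagonal entry is increased by
    ``|lambda_min| + 1e-8 * trace(Sigma) / K`` so downstream Cholesky
    factorisation succeeds.  Both matrices are returned for inspection.
    """
    R_psd = np.asarray(R_psd, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if R_psd.shape[0] != sds.size:
        raise ValidationError("correlation matrix and SD vector sizes differ")
    if np.any(sds < 0):
        raise ValidationError("standard deviations must be >= 0")
    sigma = np.outer(sds, sds) * R_psd
    lam_min = float(np.linalg.eigvalsh(sigma).min())
    inflation = 0.0
    inflated = sigma
    if lam_min <= 0:
        k = sigma.shape[0]
        inflation = abs(lam_min) + 1e-8 * float(np.trace(sigma)) / k
        inflated = sigma + inflation * np.eye(k)
        logger.warning("covariance diagonal inflated by %.3g to restore PD", inflation)
    return sigma, inflated, inflation


def sample_correlated_concentrations(
    mu: np.ndarray,
    cov: np.ndarray,
    n: int,
    rng: np.random.Generator,
    max_attempts: int = 1000,
    metabolites: list[str] | None = None,
    group_label: str = "",
) -> ConcentrationDraws:
    """Draw ``n`` strictly positive vectors from N(mu, cov) by rejection.

    Any vector with a non-positive component is redrawn.  If the
    acceptance rate (estimated online) falls below ``1/max_attempts``
    the sampler aborts with advice rather than silently looping.
    """
    mu = np.asarray(mu, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if n < 1:
        raise ValidationError("n must be >= 1")
    k = mu.size
    if cov.shape != (k, k):
        raise ValidationError("mean vector and covariance sizes differ")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValidationError("covariance must be positive definite") from None
    if metabolites is None:
        metabolites = [f"met{i}" for i in range(k)]

    accepted: list[np.ndarray] = []
    attempts = 0
    n_accepted = 0
    while n_accepted < n:
        batch = max(n - n_accepted, 64)
        z = rng.standard_normal(size=(batch, k))
        draws = mu + z @ chol.T
        ok = np.all(draws > 0, axis=1)
        attempts += batch
        if ok.any():
            accepted.append(draws[ok])
            n_accepted += int(ok.sum())
        if attempts >= max(1000, max_attempts) and n_accepted < attempts / max_attempts:
            raise ValidationError(
                f"rejection sampling acceptance rate {n_accepted / attempts:.2e} "
                f"below 1/{max_attempts}; the requested means/SDs place most of "
                "the distribution's mass at negative concentrations — increase "
                "the means or decrease the SDs"
            )
    values = np.concatenate(accepted, axis=0)[:n]
    return ConcentrationDraws(
        values=values,
        metabolites=list(metabolites),
        group_label=group_label,
        covariance=cov,
        inflated_covariance=cov,
        attempts=attempts,
    )


def draw_group_concentrations(
    template: ConcentrationTemplate,
    n: int,
    rng: np.random.Generator,
    correlation: np.ndarray | None = None,
    max_attempts: int = 1000,
) -> ConcentrationDraws:
    """Draw a group's concentration matrix from its template.

    Without a correlation matrix each metabolite is sampled
    independently from its truncated normal; with one, the matrix is
    repaired to the nearest PSD correlation matrix, converted to a
    covariance with inflation if needed, and sampled by rejection.
    """
    mets = template.metabolites
    if correlation is None:
        cols = [
            sample_truncated_normal(e.mean, e.sd, n, rng) for e in template.entries
        ]
        return ConcentrationDraws(
            values=np.column_stack(cols), metabolites=mets,
            group_label=template.group_label,
        )
    R = np.asarray(correlation, dtype=float)
    R_psd = nearest_psd_correlation(R)
    sigma, inflated, inflation = build_covariance(R_psd, template.sds)
    draws = sample_correlated_concentrations(
        template.means, inflated, n, rng, max_attempts=max_attempts,
        metabolites=mets, group_label=template.group_label,
    )
    draws.requested_correlation = R
    draws.repaired_correlation = R_psd
    draws.covariance = sigma
    draws.inflated_covariance = inflated
    draws.diagonal_inflation = inflation
    return draws
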