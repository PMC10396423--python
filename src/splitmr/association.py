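"""Per-variant association testing: linear (exposure) and logistic (outcome).

Conventions match a standard GWAS pipeline: Wald tests with two-sided
p-values from the normal approximation (not the t distribution), hard-call
dosages coded 0/1/2, and covariate adjustment recomputed within whatever
sample subset is analysed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .cohort import Cohort, empirical_maf
from .exceptions import DegenerateDesignError, SeparationError

__all__ = [
    "AssociationEstimate",
    "linear_association",
    "linear_gwas",
    "logistic_association",
    "maf_filter",
    "f_statistic",
    "SUMMARY_COLUMNS",
    "write_summary_stats",
    "read_summary_stats",
]

_RANK_TOL = 1e-9
_LOGISTIC_TOL = 1e-10
_LOGISTIC_MAX_ITER = 25
_SEPARATION_BOUND = 50.0


@dataclass(frozen=True)
class AssociationEstimate:
    """One variant's association with one trait in one sample group.

    ``beta`` is in exposure units per allele for the exposure trait, or
    log-odds per allele for the outcome trait.  ``pvalue`` is the two-sided
    normal tail of ``z = beta / se``.
    """

    variant_id: str
    trait: str  # "exposure" | "outcome"
    group: str  # "A" | "B" | "C" | "pooled"
    beta: float
    se: float
    z: float
    pvalue: float
    n_used: int


def _two_sided_p(z: float | np.ndarray) -> float | np.ndarray:
    # sf underflows to 0 below ~z=39; clip into (0, 1] per the estimate contract
    p = 2.0 * norm.sf(np.abs(z))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _check_design(x: np.ndarray) -> None:
    n, p = x.shape
    if n < p + 1:
        raise DegenerateDesignError(
            f"need at least {p + 1} observations for {p} parameters, got {n}"
        )
    if np.linalg.matrix_rank(x) < p:
        raise DegenerateDesignError("design matrix is rank deficient")


def _design(genotype: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    g = np.asarray(genotype, dtype=float)
    cols = [np.ones_like(g), g]
    if covariates is not None and np.size(covariates):
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != g.shape[0]:
            raise ValueError("genotype and covariates have different lengths")
        cols.append(c)
    return np.column_stack(cols)


def linear_association(
    genotype: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    variant_id: str = "",
    group: str = "pooled",
    trait: str = "exposure",
) -> AssociationEstimate:
    """OLS coefficient and Wald statistics for the genotype column.

    The model is ``phenotype ~ intercept + genotype + covariates``; ``beta``
    and ``se`` are the ordinary-least-squares estimate and standard error for
    the genotype term, with the residual variance estimated on ``n - p``
    degrees of freedom.
    """
    y = np.asarray(phenotype, dtype=float)
    x = _design(genotype, covariates)
    if y.shape[0] != x.shape[0]:
        raise ValueError("genotype and phenotype have different lengths")
    _check_design(x)
    n, p = x.shape
    xtx = x.T @ x
    coef = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ coef
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(xtx)
    beta = float(coef[1])
    se = float(np.sqrt(cov[1, 1]))
    z = beta / se
    return AssociationEstimate(
        variant_id=variant_id,
        trait=trait,
        group=group,
        beta=beta,
        se=se,
        z=z,
        pvalue=float(_two_sided_p(z)),
        n_used=n,
    )


def linear_gwas(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    variant_ids: list[str] | None = None,
    group: str = "pooled",
    trait: str = "exposure",
) -> pd.DataFrame:
    """Vectorized covariate-adjusted linear scan over a genotype matrix.

    Numerically identical to calling :func:`linear_association` per column:
    phenotype and genotypes are residualized on the covariates (plus
    intercept) via a QR projection, after which each variant reduces to a
    simple regression whose residual variance is assessed on the full-model
    degrees of freedom.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n, m = g.shape
    if covariates is not None and np.size(covariates):
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        base = np.column_stack([np.ones(n), c])
    else:
        base = np.ones((n, 1))
    k = base.shape[1]
    q, _ = np.linalg.qr(base)
    y_res = y - q @ (q.T @ y)
    g_res = g - q @ (q.T @ g)
    gss = np.einsum("ij,ij->j", g_res, g_res)
    degenerate = gss <= _RANK_TOL * n
    if degenerate.any():
        which = np.flatnonzero(degenerate)
        names = (
            [variant_ids[j] for j in which[:5]] if variant_ids else list(which[:5])
        )
        raise DegenerateDesignError(
            f"variant(s) collinear with covariates or monomorphic: {names}"
        )
    beta = (g_res.T @ y_res) / gss
    rss = float(y_res @ y_res) - beta**2 * gss
    dof = n - (k + 1)
    if dof < 1:
        raise DegenerateDesignError("not enough observations for the model")
    se = np.sqrt(rss / dof / gss)
    z = beta / se
    ids = variant_ids if variant_ids is not None else [f"v{j}" for j in range(m)]
    return pd.DataFrame(
        {
            "variant_id": ids,
            "trait": trait,
            "group": group,
            "beta": beta,
            "se": se,
            "z": z,
            "pvalue": _two_sided_p(z),
            "n": n,
        }
    )


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # stable: log(1+exp(eta)) via logaddexp
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def logistic_association(
    genotype: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    variant_id: str = "",
    group: str = "pooled",
) -> AssociationEstimate:
    """Maximum-likelihood logistic coefficient and Wald SE for the genotype.

    The binomial log-likelihood is maximized by Newton's method with
    step-halving; convergence is declared when the relative log-likelihood
    change falls below 1e-10 (at most 25 steps).  Any coefficient escaping
    ``|beta| > 50`` is treated as quasi-complete separation.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError(
            f"outcome is constant (all {int(y[0])}) -- logistic model undefined"
        )
    x = _design(genotype, covariates)
    if y.shape[0] != x.shape[0]:
        raise ValueError("genotype and outcome have different lengths")
    _check_design(x)
    n, p = x.shape

    coef = np.zeros(p)
    coef[0] = np.log(y.mean() / (1.0 - y.mean()))
    eta = x @ coef
    ll = _log_likelihood(y, eta)
    converged = False
    for _ in range(_LOGISTIC_MAX_ITER):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = x.T @ (y - mu)
        hess = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as err:
            raise SeparationError(
                f"singular information matrix for variant {variant_id!r}"
            ) from err
        # step-halving keeps the likelihood monotone
        scale = 1.0
        for _half in range(30):
            trial = coef + scale * step
            ll_new = _log_likelihood(y, x @ trial)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        coef = coef + scale * step
        eta = x @ coef
        if np.abs(coef).max() > _SEPARATION_BOUND:
            raise SeparationError(
                f"logistic fit diverged for variant {variant_id!r} "
                "(possible separation)"
            )
        if abs(ll_new - ll) < _LOGISTIC_TOL * (abs(ll) + _LOGISTIC_TOL):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        raise SeparationError(
            f"logistic fit did not converge in {_LOGISTIC_MAX_ITER} steps "
            f"for variant {variant_id!r}"
        )
    mu = expit(eta)
    w = mu * (1.0 - mu)
    hess = (x * w[:, None]).T @ x
    cov = np.linalg.inv(hess)
    beta = float(coef[1])
    se = float(np.sqrt(cov[1, 1]))
    z = beta / se
    return AssociationEstimate(
        variant_id=variant_id,
        trait="outcome",
        group=group,
        beta=beta,
        se=se,
        z=z,
        pvalue=float(_two_sided_p(z)),
        n_used=n,
    )


def maf_filter(cohort: Cohort, threshold: float) -> list[str]:
    """Variant ids whose empirical minor allele frequency exceeds ``threshold``.

    The comparison is strict (``maf > threshold``), matching the conventional
    "MAF > 0.01%" phrasing of GWAS quality control.
    """
    if not (0.0 <= threshold < 0.5):
        raise ValueError("threshold must be in [0, 0.5)")
    ids = cohort.variant_ids
    return [
        vid
        for j, vid in enumerate(ids)
        if empirical_maf(cohort.genotypes[:, j]) > threshold
    ]


def f_statistic(estimate: AssociationEstimate) -> float:
    """Single-variant instrument-strength F approximation, ``(beta/se)^2``."""
    if estimate.trait != "exposure":
        raise ValueError("F-statistic is defined for exposure associations")
    if estimate.se == 0:
        raise ValueError("standard error is zero")
    return (estimate.beta / estimate.se) ** 2


# -- tab-delimited interchange format ------------------------------------------

SUMMARY_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "z",
    "pvalue",
    "n",
    "trait",
    "group",
]


def write_summary_stats(table: pd.DataFrame, path: str | Path) -> None:
    """Write summary statistics in the tab-delimited interchange format."""
    missing = [c for c in SUMMARY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"summary-statistics table missing columns: {missing}")
    table[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics table, validating its header."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return table
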