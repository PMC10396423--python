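"""Summary-statistic Mendelian randomization estimators and curse corrections.

Implements the ratio estimate, the random-effects inverse-variance weighted
(IVW) estimator, the debiased IVW (DIVW) estimator that subtracts the
exposure-beta sampling variance from the IVW denominator, and the
false-discovery-rate inverse-quantile-transformation (FIQT) shrinkage of
discovery Z-scores with the associated beta rescaling.

Estimates are log odds ratios of the outcome per one-unit increase in
genetically predicted exposure.  Standard errors follow the multiplicative
random-effects convention: the fixed-effect SE is inflated by
``max(1, sqrt(Q / (J - 1)))`` where Q is Cochran's heterogeneity statistic
over the per-variant ratio estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .exceptions import EstimationError

__all__ = [
    "MREstimate",
    "ratio_estimate",
    "ivw_random_effects",
    "divw",
    "fiqt_correct",
    "apply_fiqt_scaling",
    "FIQT_SCALED_TRAITS",
]

_CI_Z = 1.96

#: Which association set carries winner's curse -- and is therefore rescaled
#: by the FIQT factor -- in each overlap scenario: the exposure associations
#: are estimated in the discovery group in scenario 2, the outcome
#: associations in scenario 3, and both in scenario 5.
FIQT_SCALED_TRAITS = {2: ("exposure",), 3: ("outcome",), 5: ("exposure", "outcome")}


@dataclass(frozen=True)
class MREstimate:
    """A causal log-odds-ratio estimate from one scenario and method."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    method: str  # "IVW" | "DIVW" | "FIQT"
    n_variants: int
    heterogeneity_q: float
    scenario_id: int

    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))


def ratio_estimate(bx: float, by: float) -> float:
    """Single-variant Wald ratio: outcome association over exposure association."""
    if bx == 0:
        raise EstimationError("ratio estimate undefined for zero exposure association")
    return by / bx


def _validate_inputs(
    bx: np.ndarray, sx: np.ndarray | None, by: np.ndarray, sy: np.ndarray
) -> None:
    lengths = {len(bx), len(by), len(sy)} | ({len(sx)} if sx is not None else set())
    if len(lengths) != 1:
        raise EstimationError("association lists have mismatched lengths")
    if len(bx) < 1:
        raise EstimationError("at least one variant is required")
    if (sy <= 0).any() or (sx is not None and (sx < 0).any()):
        raise EstimationError("standard errors must be positive")
    if (bx == 0).all():
        raise EstimationError("all exposure associations are zero")


def _finish(
    estimate: float,
    denominator: float,
    weights: np.ndarray,
    ratios: np.ndarray,
    method: str,
    scenario_id: int,
) -> MREstimate:
    j = len(ratios)
    fixed_se = denominator ** -0.5
    q = float(np.sum(weights * (ratios - estimate) ** 2))
    q = max(q, 0.0)  # debiased weights can be negative for very weak variants
    inflation = max(1.0, np.sqrt(q / (j - 1))) if j >= 2 else 1.0
    se = fixed_se * inflation
    return MREstimate(
        estimate=float(estimate),
        se=float(se),
        ci_low=float(estimate - _CI_Z * se),
        ci_high=float(estimate + _CI_Z * se),
        method=method,
        n_variants=j,
        heterogeneity_q=q,
        scenario_id=scenario_id,
    )


def ivw_random_effects(
    beta_x: np.ndarray,
    beta_y: np.ndarray,
    se_y: np.ndarray,
    *,
    scenario_id: int = 0,
) -> MREstimate:
    """Random-effects inverse-variance weighted estimate.

    estimate = sum_j bY_j bX_j / se(bY_j)^2  /  sum_j bX_j^2 / se(bY_j)^2,
    equivalently the weighted mean of per-variant ratios with weights
    ``w_j = bX_j^2 / se(bY_j)^2`` (a weighted least-squares fit of bY on bX
    through the origin).
    """
    bx = np.asarray(beta_x, dtype=float)
    by = np.asarray(beta_y, dtype=float)
    sy = np.asarray(se_y, dtype=float)
    _validate_inputs(bx, None, by, sy)
    inv_vy = sy**-2.0
    numerator = float(np.sum(by * bx * inv_vy))
    denominator = float(np.sum(bx**2 * inv_vy))
    estimate = numerator / denominator
    weights = bx**2 * inv_vy
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(bx != 0, by / np.where(bx != 0, bx, 1.0), 0.0)
    return _finish(estimate, denominator, weights, ratios, "IVW", scenario_id)


def divw(
    beta_x: np.ndarray,
    se_x: np.ndarray,
    beta_y: np.ndarray,
    se_y: np.ndarray,
    *,
    scenario_id: int = 0,
) -> MREstimate:
    """Debiased IVW: the IVW denominator with ``se(bX_j)^2`` subtracted.

    estimate = sum_j bY_j bX_j / se(bY_j)^2
             / sum_j (bX_j^2 - se(bX_j)^2) / se(bY_j)^2.

    Subtracting the sampling variance of the exposure associations removes
    the first-order weak-instrument/selection bias of IVW; with error-free
    exposure associations (se(bX) = 0) it reduces to IVW exactly.
    """
    bx = np.asarray(beta_x, dtype=float)
    sx = np.asarray(se_x, dtype=float)
    by = np.asarray(beta_y, dtype=float)
    sy = np.asarray(se_y, dtype=float)
    _validate_inputs(bx, sx, by, sy)
    inv_vy = sy**-2.0
    numerator = float(np.sum(by * bx * inv_vy))
    weights = (bx**2 - sx**2) * inv_vy
    denominator = float(np.sum(weights))
    if denominator <= 0:
        raise EstimationError(
            "debiased denominator is non-positive; instruments are too weak "
            "for the DIVW correction"
        )
    estimate = numerator / denominator
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(bx != 0, by / np.where(bx != 0, bx, 1.0), 0.0)
    return _finish(estimate, denominator, weights, ratios, "DIVW", scenario_id)


def fiqt_correct(z_scores: np.ndarray, m_tests: int | None = None) -> np.ndarray:
    """FIQT shrinkage of GWAS Z-scores.

    Two-sided p-values of the input Z-scores are Benjamini-Hochberg adjusted
    over ``m_tests`` hypotheses (default: the length of the input, i.e. the
    scan itself); each corrected Z is the upper-tail normal quantile of half
    the adjusted p-value, carrying the original sign.  Because
    ``m_tests >= rank`` for every element, ``|corrected| <= |original|``.

    Pass the *whole* discovery scan so that ranks reflect the full
    multiplicity structure, then take the entries for the selected variants.
    """
    z = np.asarray(z_scores, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("Z-scores must be finite")
    j = len(z)
    if m_tests is None:
        m_tests = j
    if m_tests < j:
        raise ValueError(f"m_tests ({m_tests}) must be >= number of Z-scores ({j})")
    p = 2.0 * norm.sf(np.abs(z))
    p = np.clip(p, 1e-300, 1.0)  # guard against underflow for extreme scores
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, j + 1)
    # BH over m_tests hypotheses: adj_(i) = min_{k >= i} m * p_(k) / k, capped at 1
    stepped = p[order] * m_tests / ranks
    adjusted_sorted = np.minimum.accumulate(stepped[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(j)
    adjusted[order] = adjusted_sorted
    corrected = norm.isf(adjusted / 2.0) * np.sign(z)
    # adjusted p can reach 1, whose quantile is 0 in the correct (shrunk) limit
    return np.where(np.sign(z) == 0, 0.0, corrected)


def apply_fiqt_scaling(
    beta_x: np.ndarray,
    beta_y: np.ndarray,
    original_z: np.ndarray,
    corrected_z: np.ndarray,
    scenario_id: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale the curse-affected beta-coefficients by ``corrected_z / original_z``.

    The factor derives from the discovery-group exposure Z-scores and is
    applied to whichever associations were estimated in the discovery group:
    the exposure betas in scenario 2, the outcome betas in scenario 3, both
    in scenario 5 (see :data:`FIQT_SCALED_TRAITS`).  Standard errors are left
    unchanged, and instrument selection still uses the original p-values.
    """
    if scenario_id not in FIQT_SCALED_TRAITS:
        raise ValueError(
            f"FIQT rescaling applies to overlap scenarios {sorted(FIQT_SCALED_TRAITS)}, "
            f"got scenario {scenario_id}"
        )
    zo = np.asarray(original_z, dtype=float)
    zc = np.asarray(corrected_z, dtype=float)
    if (zo == 0).any():
        raise ValueError("original Z-scores must be non-zero")
    factor = zc / zo
    bx = np.asarray(beta_x, dtype=float).copy()
    by = np.asarray(beta_y, dtype=float).copy()
    traits = FIQT_SCALED_TRAITS[scenario_id]
    if "exposure" in traits:
        bx = bx * factor
    if "outcome" in traits:
        by = by * factor
    return bx, by
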