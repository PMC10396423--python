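"""Per-variant winner's-curse statistics across study iterations.

For each cross-iteration locus (one representative variant per locus), the
discovery-group beta is averaged over all iterations and over the subset of
iterations in which the variant was genome-wide significant for the
*exposure*; winner's curse shows up as the significant-iteration mean
exceeding the all-iteration mean.  Both the relative (%) and absolute
differences are computed for the exposure and outcome associations --
significance is always judged on the exposure, mirroring how instruments are
selected in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .engine import StudyResult

__all__ = [
    "VariantCurseSummary",
    "percent_difference",
    "absolute_difference",
    "summarize_variant_curse",
    "bias_maf_correlation",
    "to_odds_ratio",
]

BIAS_MEASURES = {
    "abs_x": "abs_diff_x",
    "abs_y": "abs_diff_y",
    "pct_x": "pct_diff_x",
    "pct_y": "pct_diff_y",
}


@dataclass(frozen=True)
class VariantCurseSummary:
    """Winner's-curse statistics for one locus, aggregated over iterations."""

    locus_id: str
    representative_variant: str
    min_p_exposure: float
    n_iter_selected: int
    mean_beta_all_x: float
    mean_beta_sig_x: float
    mean_beta_all_y: float
    mean_beta_sig_y: float
    pct_diff_x: float
    pct_diff_y: float
    abs_diff_x: float
    abs_diff_y: float
    maf: float


def percent_difference(mean_sig: float, mean_all: float) -> float:
    """Relative inflation: ``100 * (mean_sig - mean_all) / mean_all``.

    Returns NaN (an undefined-value marker, not an exception) when the
    all-iteration mean is zero; near-zero denominators legitimately produce
    very large percentages, as they do for outcome associations.
    """
    if mean_all == 0:
        return float("nan")
    return 100.0 * (mean_sig - mean_all) / mean_all


def absolute_difference(mean_sig: float, mean_all: float) -> float:
    """Signed absolute inflation: ``mean_sig - mean_all``."""
    return mean_sig - mean_all


def summarize_variant_curse(
    study: StudyResult, threshold: float | None = None
) -> pd.DataFrame:
    """Per-locus curse summaries for a completed study.

    For each registry locus's representative variant, the discovery-group
    (group A) exposure beta is taken from every iteration's discovery scan
    and the group-A outcome beta from the study's second association pass;
    iterations are weighted equally.  Loci never significant for the exposure
    are excluded (the significant-iteration mean is undefined there).
    """
    if threshold is None:
        threshold = study.config.pvalue_threshold
    disc = study.discovery_long()
    outcome = study.group_a_outcome
    rows = []
    for rep in study.representatives.itertuples():
        dx = disc.loc[disc["variant_id"] == rep.variant_id]
        if dx.empty:
            continue
        sig_iters = set(dx.loc[dx["pvalue"] < threshold, "iteration"])
        if not sig_iters:
            continue
        beta_x = dx["beta"].to_numpy()
        sig_x = dx.loc[dx["iteration"].isin(sig_iters), "beta"].to_numpy()
        dy = outcome.loc[outcome["variant_id"] == rep.variant_id]
        beta_y = dy["beta"].to_numpy()
        sig_y = dy.loc[dy["iteration"].isin(sig_iters), "beta"].to_numpy()
        mean_all_x, mean_sig_x = float(beta_x.mean()), float(sig_x.mean())
        mean_all_y = float(beta_y.mean()) if beta_y.size else float("nan")
        mean_sig_y = float(sig_y.mean()) if sig_y.size else float("nan")
        rows.append(
            {
                "locus_id": rep.locus_id,
                "representative_variant": rep.variant_id,
                "min_p_exposure": rep.min_p_exposure,
                "n_iter_selected": rep.n_iter_selected,
                "mean_beta_all_x": mean_all_x,
                "mean_beta_sig_x": mean_sig_x,
                "mean_beta_all_y": mean_all_y,
                "mean_beta_sig_y": mean_sig_y,
                "pct_diff_x": percent_difference(mean_sig_x, mean_all_x),
                "pct_diff_y": percent_difference(mean_sig_y, mean_all_y),
                "abs_diff_x": absolute_difference(mean_sig_x, mean_all_x),
                "abs_diff_y": absolute_difference(mean_sig_y, mean_all_y),
                "maf": rep.maf,
            }
        )
    return pd.DataFrame(rows)


def bias_maf_correlation(
    summaries: pd.DataFrame,
    which: str = "abs_x",
    n_permutations: int = 9_999,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation between MAF and a chosen bias measure.

    The coefficient is the Pearson correlation of mid-ranks; the p-value is
    a two-sided permutation p over at least ``n_permutations`` seeded
    shuffles.  Rows with undefined (NaN) bias values are excluded.
    """
    if which not in BIAS_MEASURES:
        raise ValueError(f"unknown bias measure {which!r}; expected {sorted(BIAS_MEASURES)}")
    col = BIAS_MEASURES[which]
    data = summaries[["maf", col]].dropna()
    if len(data) < 3:
        raise ValueError(f"need at least 3 defined points, got {len(data)}")
    maf_ranks = rankdata(data["maf"].to_numpy())
    bias_ranks = rankdata(data[col].to_numpy())
    if np.std(maf_ranks) == 0 or np.std(bias_ranks) == 0:
        rho = 0.0
    else:
        rho = float(np.corrcoef(maf_ranks, bias_ranks)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(bias_ranks)
        if np.std(perm) == 0:
            r = 0.0
        else:
            r = np.corrcoef(maf_ranks, perm)[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    pvalue = (1 + count) / (1 + n_permutations)
    return rho, float(pvalue)


def to_odds_ratio(log_or: float) -> float:
    """Convert a log odds ratio to the odds-ratio scale."""
    return float(np.exp(log_or))
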