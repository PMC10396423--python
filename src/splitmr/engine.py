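"""Repeated three-way splitting and the five sample-overlap scenarios.

Each iteration randomly splits the cohort into three equally sized groups
(A, B, C), runs a discovery GWAS for the exposure in group A, selects and
clumps genome-wide significant instruments, estimates per-group exposure and
outcome associations for the lead variants, and computes MR estimates under
five scenarios that differ in which groups supply the exposure and outcome
associations:

====  ========  =======  ===============================  ==========
scn   exposure  outcome  winner's curse affects           one-sample
====  ========  =======  ===============================  ==========
1     B         C        --                               no
2     A         B        exposure associations            no
3     B         A        outcome associations             no
4     B         B        --                               yes
5     A         A        exposure and outcome             yes
====  ========  =======  ===============================  ==========

Scenario 1 (three distinct data sets) is the reference: no winner's curse,
weak-instrument bias toward the null.  One-sample scenarios (4, 5) have
weak-instrument bias toward the confounded observational association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import linear_gwas, logistic_association
from .cohort import Cohort
from .exceptions import EstimationError, SeparationError, StudyError
from .mr import MREstimate, apply_fiqt_scaling, divw, fiqt_correct, ivw_random_effects
from .selection import (
    InstrumentSet,
    LocusRegistry,
    apply_strategy,
    clump,
    match_loci_across_iterations,
    select_significant,
)

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "SplitAssignment",
    "split_three_way",
    "StudyConfig",
    "IterationResult",
    "StudyResult",
    "run_iteration",
    "run_study",
    "scenario_table",
    "write_study",
]

logger = logging.getLogger(__name__)

GROUPS = ("A", "B", "C")

#: scenarios with sample overlap, for which DIVW and FIQT are also computed
CORRECTION_SCENARIOS = (2, 3, 5)


@dataclass(frozen=True)
class ScenarioSpec:
    scenario_id: int
    exposure_group: str
    outcome_group: str
    label: str
    wc_exposure: bool
    wc_outcome: bool
    one_sample: bool


SCENARIOS: dict[int, ScenarioSpec] = {
    1: ScenarioSpec(1, "B", "C", "no overlap, two-sample", False, False, False),
    2: ScenarioSpec(2, "A", "B", "overlap with exposure, two-sample", True, False, False),
    3: ScenarioSpec(3, "B", "A", "overlap with outcome, two-sample", False, True, False),
    4: ScenarioSpec(4, "B", "B", "no overlap, one-sample", False, False, True),
    5: ScenarioSpec(
        5, "A", "A", "overlap with exposure and outcome, one-sample", True, True, True
    ),
}


@dataclass
class SplitAssignment:
    """A three-way random partition of individuals into groups A, B, C."""

    iteration: int
    group_of: np.ndarray  # length-n array of "A"/"B"/"C"
    seed_used: int

    def indices(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.group_of == group)


def split_three_way(n: int, seed: int, iteration: int = 0) -> SplitAssignment:
    """Uniformly random partition into three groups whose sizes differ by <= 1."""
    if n < 3:
        raise ValueError(f"need at least 3 individuals to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, remainder = divmod(n, 3)
    sizes = [base + (1 if k < remainder else 0) for k in range(3)]
    group_of = np.empty(n, dtype="<U1")
    start = 0
    for label, size in zip(GROUPS, sizes):
        group_of[perm[start : start + size]] = label
        start += size
    return SplitAssignment(iteration=iteration, group_of=group_of, seed_used=seed)


@dataclass
class StudyConfig:
    """Analysis settings for a repeated split-sample study."""

    n_iterations: int = 100
    pvalue_threshold: float = 5e-8
    strict_threshold: float = 5e-11
    maf_threshold: float = 1e-4  # "MAF > 0.01%"
    clump_distance_bp: int = 1_000_000
    clump_r2_max: float = 0.01
    strategies: tuple[str, ...] = ("primary",)
    fiqt_m_tests: int | None = None  # default: scan size after the MAF filter
    seed: int = 0


@dataclass
class IterationResult:
    iteration: int
    split: SplitAssignment
    usable: bool
    discovery: pd.DataFrame  # genome-wide exposure GWAS in group A (post filter)
    instrument_set: InstrumentSet | None = None
    assoc_store: pd.DataFrame = field(default_factory=pd.DataFrame)
    mr_estimates: dict[tuple[str, int, str], MREstimate] = field(default_factory=dict)


def _group_data(cohort: Cohort, split: SplitAssignment, group: str):
    idx = split.indices(group)
    return (
        cohort.genotypes[idx],
        cohort.covariates[idx] if cohort.covariates.size else None,
        cohort.exposure[idx],
        cohort.outcome[idx],
    )


def _scan_filter(cohort: Cohort, split: SplitAssignment, maf_threshold: float):
    """Columns passing the discovery MAF filter and polymorphic in every group.

    The MAF filter is applied to the discovery group (group A), as in a real
    discovery GWAS; variants monomorphic in any group are dropped so that
    per-group lead associations remain estimable.
    """
    keep = None
    for group in GROUPS:
        idx = split.indices(group)
        g = cohort.genotypes[idx]
        freq = g.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        ok = maf > (maf_threshold if group == "A" else 0.0)
        keep = ok if keep is None else keep & ok
    return np.flatnonzero(keep)


def _mr_for_instruments(
    instrument_set: InstrumentSet,
    assoc_store: pd.DataFrame,
    discovery: pd.DataFrame,
    strategy: str,
) -> dict[tuple[str, int, str], MREstimate]:
    """All (scenario, method) MR estimates for one iteration's instrument set."""
    leads = instrument_set.lead_variants
    if not leads:
        return {}
    store = assoc_store.set_index(["trait", "group", "variant_id"]).sort_index()
    disc = discovery.set_index("variant_id").loc[leads]
    z_orig = disc["z"].to_numpy()
    z_corr = disc["z_fiqt"].to_numpy()
    out: dict[tuple[str, int, str], MREstimate] = {}
    for spec in SCENARIOS.values():
        ex = store.loc[("exposure", spec.exposure_group)].loc[leads]
        oy = store.loc[("outcome", spec.outcome_group)].loc[leads]
        bx, sx = ex["beta"].to_numpy(), ex["se"].to_numpy()
        by, sy = oy["beta"].to_numpy(), oy["se"].to_numpy()
        out[(strategy, spec.scenario_id, "IVW")] = ivw_random_effects(
            bx, by, sy, scenario_id=spec.scenario_id
        )
        if spec.scenario_id in CORRECTION_SCENARIOS:
            try:
                out[(strategy, spec.scenario_id, "DIVW")] = divw(
                    bx, sx, by, sy, scenario_id=spec.scenario_id
                )
            except EstimationError:
                logger.warning(
                    "DIVW denominator non-positive (iteration %s, scenario %s, %s)",
                    instrument_set.iteration,
                    spec.scenario_id,
                    strategy,
                )
            bx_f, by_f = apply_fiqt_scaling(bx, by, z_orig, z_corr, spec.scenario_id)
            fiqt = ivw_random_effects(bx_f, by_f, sy, scenario_id=spec.scenario_id)
            out[(strategy, spec.scenario_id, "FIQT")] = MREstimate(
                estimate=fiqt.estimate,
                se=fiqt.se,
                ci_low=fiqt.ci_low,
                ci_high=fiqt.ci_high,
                method="FIQT",
                n_variants=fiqt.n_variants,
                heterogeneity_q=fiqt.heterogeneity_q,
                scenario_id=spec.scenario_id,
            )
    return out


def run_iteration(
    cohort: Cohort,
    iteration: int,
    config: StudyConfig,
    split_seed: int | None = None,
) -> IterationResult:
    """One full split -> discovery -> selection -> estimation pass.

    Returns a flagged (``usable=False``) result when no variant reaches the
    selection threshold; the discovery scan is retained either way so that
    per-variant curse statistics can average over all iterations.
    """
    if split_seed is None:
        split_seed = int(
            np.random.SeedSequence((config.seed, iteration)).generate_state(1)[0]
            & 0x7FFFFFFF
        )
    split = split_three_way(cohort.n_individuals, split_seed, iteration)
    meta = cohort.meta_frame()

    keep = _scan_filter(cohort, split, config.maf_threshold)
    scan_ids = [cohort.variant_ids[j] for j in keep]

    ga, cov_a, exp_a, _ = _group_data(cohort, split, "A")
    discovery = linear_gwas(
        ga[:, keep], exp_a, cov_a, variant_ids=scan_ids, group="A", trait="exposure"
    )
    discovery = discovery.merge(
        meta[["variant_id", "chromosome", "position"]], on="variant_id"
    )
    m_tests = config.fiqt_m_tests if config.fiqt_m_tests is not None else len(discovery)
    discovery["z_fiqt"] = fiqt_correct(discovery["z"].to_numpy(), m_tests)

    candidates = select_significant(discovery, config.pvalue_threshold)
    if not candidates:
        logger.warning("iteration %s: empty instrument set, flagged", iteration)
        return IterationResult(iteration, split, usable=False, discovery=discovery)

    cand_df = discovery[discovery["variant_id"].isin(candidates)]
    loci = clump(
        cand_df,
        ga[:, keep],
        scan_ids,
        distance_bp=config.clump_distance_bp,
        r2_max=config.clump_r2_max,
    )
    leads = [locus.lead_variant for locus in loci]
    lead_stats = (
        discovery.set_index("variant_id")
        .loc[leads]
        .reset_index()[["variant_id", "chromosome", "position", "beta", "se", "z", "pvalue"]]
    )
    instrument_set = InstrumentSet(
        iteration=iteration,
        strategy="primary",
        threshold=config.pvalue_threshold,
        loci=loci,
        lead_variants=leads,
        lead_stats=lead_stats,
    )

    # per-group associations for the lead variants
    lead_cols = np.array([cohort.variant_index(v) for v in leads])
    frames = []
    disc_by_id = discovery.set_index("variant_id")
    for group in GROUPS:
        gg, cov_g, exp_g, out_g = _group_data(cohort, split, group)
        if group == "A":
            # identity: discovery rows ARE the group-A exposure associations
            rows = disc_by_id.loc[leads].reset_index()
            frames.append(
                rows[["variant_id", "trait", "group", "beta", "se", "z", "pvalue", "n"]]
            )
        else:
            frames.append(
                linear_gwas(
                    gg[:, lead_cols],
                    exp_g,
                    cov_g,
                    variant_ids=leads,
                    group=group,
                    trait="exposure",
                )
            )
        logi = []
        for vid, col in zip(leads, lead_cols):
            est = logistic_association(
                gg[:, col], out_g, cov_g, variant_id=vid, group=group
            )
            logi.append(
                {
                    "variant_id": vid,
                    "trait": "outcome",
                    "group": group,
                    "beta": est.beta,
                    "se": est.se,
                    "z": est.z,
                    "pvalue": est.pvalue,
                    "n": est.n_used,
                }
            )
        frames.append(pd.DataFrame(logi))
    assoc_store = pd.concat(frames, ignore_index=True)

    result = IterationResult(
        iteration=iteration,
        split=split,
        usable=True,
        discovery=discovery,
        instrument_set=instrument_set,
        assoc_store=assoc_store,
    )
    result.mr_estimates = _mr_for_instruments(
        instrument_set, assoc_store, discovery, "primary"
    )
    return result


@dataclass
class StudyResult:
    """Everything produced by a repeated split-sample study."""

    iterations: list[IterationResult]
    registry: LocusRegistry
    config: StudyConfig
    representatives: pd.DataFrame  # one row per cross-iteration locus
    group_a_outcome: pd.DataFrame  # per-iteration group-A outcome assoc, reps only

    @property
    def usable_iterations(self) -> list[IterationResult]:
        return [r for r in self.iterations if r.usable]

    def discovery_long(self) -> pd.DataFrame:
        frames = []
        for r in self.iterations:
            d = r.discovery.copy()
            d.insert(0, "iteration", r.iteration)
            frames.append(d)
        return pd.concat(frames, ignore_index=True)

    def mr_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.iterations:
            for (strategy, scenario, method), est in r.mr_estimates.items():
                rows.append(
                    {
                        "iteration": r.iteration,
                        "scenario": scenario,
                        "method": method,
                        "strategy": strategy,
                        "estimate": est.estimate,
                        "se": est.se,
                        "n_variants": est.n_variants,
                        "Q": est.heterogeneity_q,
                    }
                )
        return pd.DataFrame(rows)

    def instruments_frame(self) -> pd.DataFrame:
        frames = [
            r.instrument_set.to_frame() for r in self.usable_iterations
        ]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _representatives(
    registry: LocusRegistry, discovery_long: pd.DataFrame, cohort: Cohort
) -> pd.DataFrame:
    """One representative variant per cross-iteration locus.

    The representative is the member with the smallest discovery p-value
    across all iterations (ties broken by position); its full-cohort
    empirical MAF is recorded for stratified summaries.
    """
    from .cohort import empirical_maf

    stats = (
        discovery_long.groupby("variant_id")
        .agg(min_p=("pvalue", "min"), position=("position", "first"))
    )
    rows = []
    for locus in registry.loci:
        members = sorted(locus.members)
        present = [m for m in members if m in stats.index]
        if not present:
            continue
        best = min(present, key=lambda v: (stats.loc[v, "min_p"], stats.loc[v, "position"]))
        rows.append(
            {
                "locus_id": locus.locus_id,
                "variant_id": best,
                "chromosome": locus.chromosome,
                "position": int(stats.loc[best, "position"]),
                "min_p_exposure": float(stats.loc[best, "min_p"]),
                "n_iter_selected": locus.n_iterations_selected,
                "maf": empirical_maf(cohort.genotypes[:, cohort.variant_index(best)]),
            }
        )
    return pd.DataFrame(rows)


def run_study(
    cohort: Cohort, n_iterations: int | None = None, config: StudyConfig | None = None
) -> StudyResult:
    """Run the full repeated-splitting study.

    Per-iteration split seeds are derived from the master ``config.seed`` via
    a seed sequence, so the whole study is reproducible while splits remain
    independent across iterations.  After the primary pass, the
    cross-iteration locus registry is built and any secondary strategies
    (``strict``, ``no_full_replication``) are evaluated on the *same* splits
    and association estimates -- no re-randomization.
    """
    config = config or StudyConfig()
    if n_iterations is None:
        n_iterations = config.n_iterations
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")

    seeds = (
        np.random.SeedSequence(config.seed).generate_state(n_iterations) & 0x7FFFFFFF
    )
    results = [
        run_iteration(cohort, k, config, int(seeds[k])) for k in range(n_iterations)
    ]
    usable = [r for r in results if r.usable]
    if not usable:
        raise StudyError("every iteration produced an empty instrument set")

    positions = {
        m.variant_id: (m.chromosome, m.position_bp) for m in cohort.variant_meta
    }
    registry = match_loci_across_iterations(
        [r.instrument_set for r in usable], positions, config.clump_distance_bp
    )

    for strategy in config.strategies:
        if strategy == "primary":
            continue
        for r in usable:
            derived = apply_strategy(
                strategy,
                registry,
                r.instrument_set,
                strict_threshold=config.strict_threshold,
            )
            if not derived.lead_variants:
                logger.warning(
                    "iteration %s: strategy %s left no instruments", r.iteration, strategy
                )
                continue
            r.mr_estimates.update(
                _mr_for_instruments(derived, r.assoc_store, r.discovery, strategy)
            )

    # second pass: group-A outcome associations for locus representatives in
    # every iteration (needed to average outcome betas over ALL iterations)
    study_partial = StudyResult(results, registry, config, pd.DataFrame(), pd.DataFrame())
    discovery_long = study_partial.discovery_long()
    reps = _representatives(registry, discovery_long, cohort)
    rows = []
    for r in results:
        ga, cov_a, _, out_a = _group_data(cohort, r.split, "A")
        for rep in reps.itertuples():
            col = cohort.variant_index(rep.variant_id)
            try:
                est = logistic_association(
                    ga[:, col], out_a, cov_a, variant_id=rep.variant_id, group="A"
                )
            except SeparationError:
                logger.warning(
                    "iteration %s: outcome association for %s did not converge",
                    r.iteration,
                    rep.variant_id,
                )
                continue
            rows.append(
                {
                    "iteration": r.iteration,
                    "variant_id": rep.variant_id,
                    "beta": est.beta,
                    "se": est.se,
                    "z": est.z,
                    "pvalue": est.pvalue,
                }
            )
    group_a_outcome = pd.DataFrame(rows)

    return StudyResult(results, registry, config, reps, group_a_outcome)


def scenario_table(study: StudyResult) -> pd.DataFrame:
    """Scenario summaries: median and mean estimate, mean SE, SD of estimates.

    Computed across usable iterations only; ``n_usable`` reports how many
    contributed.  The SD is not available (NaN) with a single iteration.
    """
    mr = study.mr_frame()
    if mr.empty:
        raise StudyError("no MR estimates available")
    grouped = (
        mr.groupby(["scenario", "method", "strategy"])
        .agg(
            n_usable=("estimate", "size"),
            median_estimate=("estimate", "median"),
            mean_estimate=("estimate", "mean"),
            mean_se=("se", "mean"),
            sd_estimates=("estimate", lambda s: s.std(ddof=1) if len(s) > 1 else np.nan),
        )
        .reset_index()
    )
    return grouped


def write_study(study: StudyResult, directory: str | Path) -> None:
    """Persist a study as tab-delimited tables under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study.mr_frame().to_csv(directory / "mr_long.tsv", sep="\t", index=False)
    scenario_table(study).to_csv(directory / "scenario_table.tsv", sep="\t", index=False)
    study.instruments_frame().to_csv(directory / "instruments.tsv", sep="\t", index=False)
    study.registry.to_frame().to_csv(directory / "registry.tsv", sep="\t", index=False)
    study.discovery_long().to_csv(directory / "discovery_long.tsv", sep="\t", index=False)
    study.representatives.to_csv(directory / "representatives.tsv", sep="\t", index=False)
    study.group_a_outcome.to_csv(directory / "group_a_outcome.tsv", sep="\t", index=False)
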