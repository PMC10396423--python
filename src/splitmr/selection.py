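"""Instrument selection: significance filtering, LD clumping, strategies.

Clumping follows the greedy convention used by standard GWAS tooling:
candidates are visited in order of ascending p-value; a candidate founds a
new locus unless it is within the distance window of an existing lead on the
same chromosome or is correlated (r^2 above the cutoff, estimated from the
discovery-group dosages) with any existing lead, in which case it is absorbed
into the nearest offending lead's locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ClumpingError

__all__ = [
    "Locus",
    "InstrumentSet",
    "RegistryLocus",
    "LocusRegistry",
    "select_significant",
    "clump",
    "match_loci_across_iterations",
    "apply_strategy",
]

DEFAULT_DISTANCE_BP = 1_000_000
DEFAULT_R2_MAX = 0.01
STRATEGIES = ("primary", "strict", "no_full_replication")


@dataclass
class Locus:
    locus_id: str
    lead_variant: str
    member_variants: set[str]
    chromosome: str
    window: tuple[int, int]

    def __post_init__(self) -> None:
        if self.lead_variant not in self.member_variants:
            raise ValueError("lead variant must be a member of its locus")


@dataclass
class InstrumentSet:
    """Clumped lead variants selected in one discovery iteration."""

    iteration: int
    strategy: str
    threshold: float
    loci: list[Locus]
    lead_variants: list[str]
    lead_stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    # lead_stats columns: variant_id, chromosome, position, beta, se, z, pvalue

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def to_frame(self) -> pd.DataFrame:
        """Export as the tab-delimited instrument table."""
        rows = []
        stats = self.lead_stats.set_index("variant_id") if len(self.lead_stats) else None
        for locus in self.loci:
            row = {
                "iteration": self.iteration,
                "strategy": self.strategy,
                "locus_id": locus.locus_id,
                "lead_variant": locus.lead_variant,
                "chromosome": locus.chromosome,
            }
            if stats is not None and locus.lead_variant in stats.index:
                s = stats.loc[locus.lead_variant]
                row.update(
                    position=int(s["position"]),
                    discovery_beta=s["beta"],
                    discovery_se=s["se"],
                    discovery_p=s["pvalue"],
                )
            rows.append(row)
        return pd.DataFrame(rows)


def _ordered_candidates(assocs: pd.DataFrame) -> pd.DataFrame:
    """Ascending p-value, ties broken by (chromosome, position, variant_id)."""
    by = ["pvalue"]
    for col in ("chromosome", "position", "variant_id"):
        if col in assocs.columns:
            by.append(col)
    return assocs.sort_values(by, kind="mergesort").reset_index(drop=True)


def select_significant(assocs: pd.DataFrame, threshold: float) -> list[str]:
    """Variant ids with discovery p-value strictly below ``threshold``.

    Returned in ascending p-value order (deterministic tie-break by
    chromosome, position, variant id).  An empty list is a valid result.
    """
    hits = assocs.loc[assocs["pvalue"] < threshold]
    return _ordered_candidates(hits)["variant_id"].tolist()


def clump(
    candidates: pd.DataFrame,
    genotype_reference: np.ndarray,
    reference_ids: list[str],
    distance_bp: int = DEFAULT_DISTANCE_BP,
    r2_max: float = DEFAULT_R2_MAX,
) -> list[Locus]:
    """Greedy p-value clumping of significant candidates into loci.

    Parameters
    ----------
    candidates
        Table with ``variant_id``, ``chromosome``, ``position``, ``pvalue``.
    genotype_reference, reference_ids
        Dosage matrix (individuals x variants) of the discovery group and
        the variant ids labelling its columns; used to estimate r^2 as the
        squared Pearson correlation of dosages.
    """
    if len(candidates) == 0:
        raise ClumpingError("no candidates to clump")
    for col in ("variant_id", "chromosome", "position", "pvalue"):
        if col not in candidates.columns:
            raise ClumpingError(f"candidate table lacks required column {col!r}")
    col_of = {vid: j for j, vid in enumerate(reference_ids)}
    missing = [v for v in candidates["variant_id"] if v not in col_of]
    if missing:
        raise ClumpingError(f"no reference genotypes for candidate(s) {missing[:5]}")

    ordered = _ordered_candidates(candidates)
    dosages = {
        v: np.asarray(genotype_reference[:, col_of[v]], dtype=float)
        for v in ordered["variant_id"]
    }

    loci: list[Locus] = []
    lead_info: list[tuple[str, str, int]] = []  # (variant_id, chrom, pos)
    for row in ordered.itertuples():
        vid, chrom, pos = row.variant_id, str(row.chromosome), int(row.position)
        offenders: list[tuple[tuple, int]] = []  # (sort key, locus index)
        for idx, (lead, lead_chrom, lead_pos) in enumerate(lead_info):
            same_chrom = lead_chrom == chrom
            too_close = same_chrom and abs(lead_pos - pos) < distance_bp
            g1, g2 = dosages[vid], dosages[lead]
            r = np.corrcoef(g1, g2)[0, 1]
            too_correlated = np.isfinite(r) and r * r >= r2_max
            if too_close or too_correlated:
                distance = abs(lead_pos - pos) if same_chrom else np.inf
                offenders.append(((0 if same_chrom else 1, distance, -(r * r)), idx))
        if offenders:
            _, idx = min(offenders)
            locus = loci[idx]
            locus.member_variants.add(vid)
            locus.window = (
                min(locus.window[0], pos),
                max(locus.window[1], pos),
            )
        else:
            loci.append(
                Locus(
                    locus_id=f"locus_{vid}",
                    lead_variant=vid,
                    member_variants={vid},
                    chromosome=chrom,
                    window=(pos, pos),
                )
            )
            lead_info.append((vid, chrom, pos))
    return loci


@dataclass
class RegistryLocus:
    """A cross-iteration locus in the study-wide registry."""

    locus_id: str
    chromosome: str
    members: set[str]
    n_iterations_selected: int
    min_p_selected: float  # smallest discovery p among selection events
    iterations_selected: set[int] = field(default_factory=set)


@dataclass
class LocusRegistry:
    """Stable cross-iteration locus identities with selection counts."""

    loci: list[RegistryLocus]
    distance_bp: int
    n_iterations: int

    def locus_of(self, variant_id: str) -> RegistryLocus | None:
        for locus in self.loci:
            if variant_id in locus.members:
                return locus
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": [l.locus_id for l in self.loci],
                "chromosome": [l.chromosome for l in self.loci],
                "n_members": [len(l.members) for l in self.loci],
                "n_iterations_selected": [l.n_iterations_selected for l in self.loci],
                "min_p_across_iterations": [l.min_p_selected for l in self.loci],
            }
        )


def match_loci_across_iterations(
    instrument_sets: list[InstrumentSet],
    positions: dict[str, tuple[str, int]],
    distance_bp: int = DEFAULT_DISTANCE_BP,
) -> LocusRegistry:
    """Group variants selected in any iteration into cross-iteration loci.

    Single-linkage merging: two selected variants belong to the same registry
    locus if they are on the same chromosome within ``distance_bp`` of each
    other, directly or through a chain of selected variants.  The per-locus
    count is the number of iterations in which *any* member was selected.

    ``positions`` maps variant_id -> (chromosome, position_bp).
    """
    if not instrument_sets:
        raise ValueError("at least one iteration is required")
    selected_in: dict[str, set[int]] = {}
    min_p: dict[str, float] = {}
    for iset in instrument_sets:
        stats = iset.lead_stats.set_index("variant_id") if len(iset.lead_stats) else None
        for vid in iset.lead_variants:
            selected_in.setdefault(vid, set()).add(iset.iteration)
            if stats is not None and vid in stats.index:
                p = float(stats.loc[vid, "pvalue"])
                min_p[vid] = min(min_p.get(vid, np.inf), p)

    variants = sorted(
        selected_in, key=lambda v: (positions[v][0], positions[v][1], v)
    )
    loci: list[RegistryLocus] = []
    current: list[str] = []

    def _flush(group: list[str]) -> None:
        if not group:
            return
        chrom = positions[group[0]][0]
        iters = set().union(*(selected_in[v] for v in group))
        loci.append(
            RegistryLocus(
                locus_id=f"cl_{len(loci):04d}",
                chromosome=chrom,
                members=set(group),
                n_iterations_selected=len(iters),
                min_p_selected=min(min_p.get(v, np.inf) for v in group),
                iterations_selected=iters,
            )
        )

    for vid in variants:
        chrom, pos = positions[vid]
        if current:
            prev_chrom, prev_pos = positions[current[-1]]
            if chrom != prev_chrom or pos - prev_pos >= distance_bp:
                _flush(current)
                current = []
        current.append(vid)
    _flush(current)

    n_iterations = len({s.iteration for s in instrument_sets})
    return LocusRegistry(loci=loci, distance_bp=distance_bp, n_iterations=n_iterations)


def apply_strategy(
    strategy: str,
    registry: LocusRegistry | None,
    instrument_set: InstrumentSet,
    *,
    strict_threshold: float = 5e-11,
    n_iterations: int | None = None,
) -> InstrumentSet:
    """Derive a secondary-analysis instrument set from the primary one.

    ``primary`` returns the input unchanged.  ``strict`` keeps only leads
    whose discovery p-value beats the stricter threshold (the selected
    variants are filtered, so the strict set nests inside the primary set).
    ``no_full_replication`` removes loci whose cross-iteration registry locus
    was selected in every iteration of the study.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if strategy == "primary":
        return instrument_set

    if strategy == "strict":
        stats = instrument_set.lead_stats.set_index("variant_id")
        keep = [
            l for l in instrument_set.loci
            if float(stats.loc[l.lead_variant, "pvalue"]) < strict_threshold
        ]
        threshold = strict_threshold
    else:  # no_full_replication
        if registry is None:
            raise ValueError(
                "no_full_replication requires a completed cross-iteration registry"
            )
        total = n_iterations if n_iterations is not None else registry.n_iterations
        always = {
            v
            for locus in registry.loci
            if locus.n_iterations_selected == total
            for v in locus.members
        }
        keep = [l for l in instrument_set.loci if l.lead_variant not in always]
        threshold = instrument_set.threshold

    leads = [l.lead_variant for l in keep]
    stats = instrument_set.lead_stats
    return InstrumentSet(
        iteration=instrument_set.iteration,
        strategy=strategy,
        threshold=threshold,
        loci=keep,
        lead_variants=leads,
        lead_stats=stats[stats["variant_id"].isin(leads)].reset_index(drop=True),
    )
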