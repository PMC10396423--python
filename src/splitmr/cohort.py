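"""Seeded simulation of individual-level cohorts for split-sample MR studies.

The generator emulates a biobank-style data set: ``n`` unrelated individuals
typed at ``M`` biallelic variants, a continuous polygenic exposure (BMI-like),
a latent standard-normal confounder, age/sex-like covariates, and a binary
outcome (CAD-like) produced by a logistic model with a positive causal effect
of the exposure.

True per-variant exposure effects are parameterized on the *non-centrality*
scale: each causal variant is assigned a target non-centrality for its
single-variant association chi-square at one-third of the cohort size (the
size of one discovery group after a three-way split).  The default range
(5-80) straddles the genome-wide significance boundary -- a chi-square of
about 29.7 corresponds to P = 5e-8 -- so that instrument selection is
genuinely stochastic across random splits, with some variants selected in
almost every split, some in roughly half, and some only when sampling noise
pushes them over the line.  That mixture is the regime in which winner's
curse is visible, and it reproduces the empirical pattern of minimum
p-values spreading continuously downward from the selection threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, ndtri
from scipy.stats import norm

from .exceptions import ConfigurationError

__all__ = [
    "EffectSpec",
    "CovariateSpec",
    "LDBlock",
    "SimulationConfig",
    "VariantMeta",
    "Cohort",
    "simulate_cohort",
    "empirical_maf",
    "write_cohort",
    "read_cohort",
]

#: chi-square(1 df) quantile at the genome-wide significance threshold 5e-8
GENOME_WIDE_CHI2 = float(norm.isf(5e-8 / 2.0) ** 2)


@dataclass(frozen=True)
class EffectSpec:
    """Distribution of true exposure effects for causal variants.

    ``ncp_min``/``ncp_max`` bound the per-variant non-centrality of the
    expected association chi-square at one-third of the cohort size.
    Targets are drawn *log-uniformly* within the range: complex-trait effect
    spectra are bottom-heavy, and the excess of marginal instruments is what
    makes the median iteration select only a fraction of the loci that are
    ever selected -- the regime in which winner's curse dominates.
    """

    ncp_min: float = 5.0
    ncp_max: float = 80.0

    def validate(self) -> None:
        if not (0.0 < self.ncp_min <= self.ncp_max):
            raise ConfigurationError(
                f"invalid non-centrality range ({self.ncp_min}, {self.ncp_max})"
            )


@dataclass(frozen=True)
class CovariateSpec:
    """Effects of an age-like continuous and a sex-like binary covariate.

    Exposure effects are in exposure units; outcome effects in log-odds.
    """

    age_effect_exposure: float = 0.5
    sex_effect_exposure: float = 1.0
    age_effect_outcome: float = 0.3
    sex_effect_outcome: float = 0.4


@dataclass(frozen=True)
class LDBlock:
    """A block of adjacent variants sharing exchangeable correlation."""

    size: int
    correlation: float

    def validate(self) -> None:
        if self.size < 1:
            raise ConfigurationError(f"LD block size must be >= 1, got {self.size}")
        if not (0.0 <= self.correlation < 1.0):
            raise ConfigurationError(
                f"within-block correlation must be in [0, 1), got {self.correlation}"
            )


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic cohort.

    Parameters
    ----------
    n_individuals, n_variants
        Cohort dimensions.
    maf_range
        Minor allele frequencies are drawn uniformly from this interval;
        both endpoints must lie in (0, 0.5].
    effect_spec
        Non-centrality range for causal-variant effects (see :class:`EffectSpec`).
    n_null_variants
        Number of variants with exactly zero effect on the exposure.
    exposure_noise_sd
        SD of the independent Gaussian noise on the exposure, in exposure units.
    confounder_effect_exposure
        Exposure units per SD of the latent confounder.
    confounder_effect_outcome
        Log-odds per SD of the latent confounder.
    causal_log_or
        True causal effect of the exposure on the outcome (log odds ratio per
        exposure unit).
    baseline_log_odds
        Intercept of the outcome logistic model; the default corresponds to a
        CAD-like 8% prevalence at average exposure.
    ld_block_spec
        Optional list of :class:`LDBlock`; block members are placed at adjacent
        positions and correlated via a latent-Gaussian copula.
    covariate_spec
        Age/sex-like covariate effects, or ``None`` for no covariates.
    position_stride_bp
        Base-pair stride between independent variants on the single synthetic
        chromosome (default 200 kb, so a 1 Mb clumping window is meaningful).
    seed
        Master seed; identical config + seed gives a bit-identical cohort.
    """

    n_individuals: int = 30_000
    n_variants: int = 400
    maf_range: tuple[float, float] = (0.01, 0.5)
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    n_null_variants: int = 240
    exposure_noise_sd: float = 3.6
    confounder_effect_exposure: float = 2.0
    confounder_effect_outcome: float = 0.8
    causal_log_or: float = 0.08
    baseline_log_odds: float = math.log(0.08 / 0.92)
    ld_block_spec: list[LDBlock] | None = None
    covariate_spec: CovariateSpec | None = field(default_factory=CovariateSpec)
    position_stride_bp: int = 200_000
    within_block_stride_bp: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 3:
            raise ConfigurationError("n_individuals must be >= 3")
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0 <= self.n_null_variants <= self.n_variants):
            raise ConfigurationError("n_null_variants must be in [0, n_variants]")
        if self.exposure_noise_sd <= 0:
            raise ConfigurationError("exposure_noise_sd must be positive")
        self.effect_spec.validate()
        if self.ld_block_spec is not None:
            for block in self.ld_block_spec:
                block.validate()
            if sum(b.size for b in self.ld_block_spec) > self.n_variants:
                raise ConfigurationError("LD blocks cover more variants than n_variants")

    # -- plain-text round trip -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        """Write the configuration as a YAML key-value file."""
        data = asdict(self)
        data["maf_range"] = list(self.maf_range)
        if self.ld_block_spec is not None:
            data["ld_block_spec"] = [asdict(b) for b in self.ld_block_spec]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        """Load a configuration from a YAML key-value file."""
        data = yaml.safe_load(Path(path).read_text())
        if data.get("effect_spec") is not None:
            data["effect_spec"] = EffectSpec(**data["effect_spec"])
        if data.get("covariate_spec") is not None:
            data["covariate_spec"] = CovariateSpec(**data["covariate_spec"])
        if data.get("ld_block_spec") is not None:
            data["ld_block_spec"] = [LDBlock(**b) for b in data["ld_block_spec"]]
        if data.get("maf_range") is not None:
            data["maf_range"] = tuple(data["maf_range"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class VariantMeta:
    variant_id: str
    chromosome: str
    position_bp: int
    maf_true: float
    beta_true_exposure: float


@dataclass
class Cohort:
    """Individual-level synthetic data plus per-variant truth metadata."""

    genotypes: np.ndarray  # (n, M) int8 dosages in {0,1,2}
    covariates: np.ndarray  # (n, k)
    covariate_names: list[str]
    confounder: np.ndarray  # (n,) latent, diagnostics only
    exposure: np.ndarray  # (n,)
    outcome: np.ndarray  # (n,) in {0,1}
    variant_meta: list[VariantMeta]
    config: SimulationConfig | None = None

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return [m.variant_id for m in self.variant_meta]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant {variant_id!r}") from None

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [m.variant_id for m in self.variant_meta],
                "chromosome": [m.chromosome for m in self.variant_meta],
                "position": [m.position_bp for m in self.variant_meta],
                "maf_true": [m.maf_true for m in self.variant_meta],
                "beta_true_exposure": [m.beta_true_exposure for m in self.variant_meta],
            }
        )


def empirical_maf(genotypes: np.ndarray) -> float:
    """Minor allele frequency of one variant's dosage vector.

    Returns ``min(p, 1-p)`` with ``p`` the allele count over ``2n`` alleles.
    """
    g = np.asarray(genotypes)
    if g.size == 0:
        raise ValueError("empty genotype vector")
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("dosages must be in {0, 1, 2}")
    p = float(g.sum()) / (2.0 * g.size)
    return min(p, 1.0 - p)


def _solve_effect_sizes(
    config: SimulationConfig, mafs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Translate target non-centralities into per-allele effect sizes.

    For variant j with per-allele effect b_j and MAF p_j, the expected
    association chi-square at sample size m is approximately
    1 + m * h2_j / sigma_resid^2 with h2_j = 2 p_j (1 - p_j) b_j^2 and
    sigma_resid^2 the exposure variance not explained by variant j
    (confounder + noise + remaining polygenic background).  Given targets
    t_j the total polygenic variance g solves g = sigma0^2 * S / (m - S)
    with S = sum(t_j) and sigma0^2 the non-genetic variance, which requires
    S < m (an infeasible-heritability check).
    """
    n_causal = config.n_variants - config.n_null_variants
    betas = np.zeros(config.n_variants)
    if n_causal == 0:
        return betas
    m = config.n_individuals / 3.0
    spec = config.effect_spec
    targets = np.exp(
        rng.uniform(math.log(spec.ncp_min), math.log(spec.ncp_max), size=n_causal)
    )
    s_total = float(targets.sum())
    if s_total >= m:
        raise ConfigurationError(
            "summed non-centrality targets exceed one-third sample size; "
            "implied heritability is >= 100% -- reduce the number of causal "
            "variants or the non-centrality range, or increase n_individuals"
        )
    sigma0_sq = config.exposure_noise_sd**2 + config.confounder_effect_exposure**2
    poly_var = sigma0_sq * s_total / (m - s_total)
    h2 = targets * (sigma0_sq + poly_var) / m
    causal_idx = rng.choice(config.n_variants, size=n_causal, replace=False)
    p = mafs[causal_idx]
    magnitude = np.sqrt(h2 / (2.0 * p * (1.0 - p)))
    signs = rng.choice((-1.0, 1.0), size=n_causal)
    betas[causal_idx] = signs * magnitude
    return betas


def _draw_genotypes(
    config: SimulationConfig, mafs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Hard-call dosages; optional exchangeable within-block correlation.

    Correlated blocks are generated haplotype-wise through a latent-Gaussian
    threshold scheme: each haplotype's latent value is sqrt(rho) * shared
    factor + sqrt(1-rho) * idiosyncratic noise, and the allele is carried when
    the latent value falls below the normal quantile of the allele frequency.
    """
    n, m_var = config.n_individuals, config.n_variants
    genotypes = rng.binomial(2, mafs[None, :], size=(n, m_var)).astype(np.int8)
    if not config.ld_block_spec:
        return genotypes
    start = 0
    for block in config.ld_block_spec:
        stop = start + block.size
        rho = block.correlation
        thresholds = ndtri(mafs[start:stop])  # (size,)
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            noise = rng.standard_normal((n, block.size))
            latent = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * noise
            alleles = (latent < thresholds[None, :]).astype(np.int8)
            if _hap == 0:
                genotypes[:, start:stop] = alleles
            else:
                genotypes[:, start:stop] += alleles
        start = stop
    return genotypes


def _assign_positions(config: SimulationConfig) -> np.ndarray:
    """Positions on one synthetic chromosome; LD-block members adjacent."""
    positions = np.empty(config.n_variants, dtype=np.int64)
    in_block_stride = config.within_block_stride_bp
    block_bounds: list[int] = []
    if config.ld_block_spec:
        start = 0
        for block in config.ld_block_spec:
            block_bounds.extend(range(start + 1, start + block.size))
            start += block.size
    tight = set(block_bounds)  # indices that continue a block
    pos = 1
    for j in range(config.n_variants):
        if j == 0:
            pos = 1
        elif j in tight:
            pos += in_block_stride
        else:
            pos += config.position_stride_bp
        positions[j] = pos
    return positions


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a cohort under ``config``; fully determined by ``config.seed``.

    The exposure is the sum of a mean-centred polygenic score, confounder and
    covariate contributions, and Gaussian noise.  The outcome is Bernoulli
    with logit ``alpha0 + theta * exposure + gamma * confounder`` plus
    covariate terms.  Genotypes are independent of the confounder by
    construction.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_variants)
    betas = _solve_effect_sizes(config, mafs, rng)
    genotypes = _draw_genotypes(config, mafs, rng)
    positions = _assign_positions(config)

    confounder = rng.standard_normal(config.n_individuals)
    if config.covariate_spec is not None:
        age = rng.standard_normal(config.n_individuals)
        sex = rng.binomial(1, 0.5, size=config.n_individuals).astype(float)
        covariates = np.column_stack([age, sex])
        covariate_names = ["age", "sex"]
        cs = config.covariate_spec
        cov_exposure = cs.age_effect_exposure * age + cs.sex_effect_exposure * sex
        cov_outcome = cs.age_effect_outcome * age + cs.sex_effect_outcome * sex
    else:
        covariates = np.empty((config.n_individuals, 0))
        covariate_names = []
        cov_exposure = cov_outcome = 0.0

    centred = genotypes - 2.0 * mafs[None, :]  # centring shifts only the intercept
    genetic = centred @ betas
    noise = config.exposure_noise_sd * rng.standard_normal(config.n_individuals)
    exposure = (
        genetic + config.confounder_effect_exposure * confounder + cov_exposure + noise
    )

    logit = (
        config.baseline_log_odds
        + config.causal_log_or * exposure
        + config.confounder_effect_outcome * confounder
        + cov_outcome
    )
    outcome = rng.binomial(1, expit(logit)).astype(np.int8)

    meta = [
        VariantMeta(
            variant_id=f"v{j:04d}",
            chromosome="1",
            position_bp=int(positions[j]),
            maf_true=float(mafs[j]),
            beta_true_exposure=float(betas[j]),
        )
        for j in range(config.n_variants)
    ]
    return Cohort(
        genotypes=genotypes,
        covariates=covariates,
        covariate_names=covariate_names,
        confounder=confounder,
        exposure=exposure,
        outcome=outcome,
        variant_meta=meta,
        config=config,
    )


# -- persistence (dense delimited tables) --------------------------------------


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Persist a cohort as tab-delimited text tables.

    Writes ``genotypes.tsv`` (individuals x variants dosage matrix),
    ``samples.tsv`` (phenotypes/covariates with header) and ``variants.tsv``
    (per-variant metadata).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    geno = pd.DataFrame(cohort.genotypes, columns=cohort.variant_ids)
    geno.to_csv(directory / "genotypes.tsv", sep="\t", index=False)
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(cohort.n_individuals)],
            **{name: cohort.covariates[:, k] for k, name in enumerate(cohort.covariate_names)},
            "confounder": cohort.confounder,
            "exposure": cohort.exposure,
            "outcome": cohort.outcome,
        }
    )
    samples.to_csv(directory / "samples.tsv", sep="\t", index=False)
    cohort.meta_frame().to_csv(directory / "variants.tsv", sep="\t", index=False)


def read_cohort(directory: str | Path) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    geno = pd.read_csv(directory / "genotypes.tsv", sep="\t")
    samples = pd.read_csv(directory / "samples.tsv", sep="\t")
    meta = pd.read_csv(directory / "variants.tsv", sep="\t")
    covariate_names = [
        c for c in samples.columns if c not in ("sample_id", "confounder", "exposure", "outcome")
    ]
    variant_meta = [
        VariantMeta(
            variant_id=str(row.variant_id),
            chromosome=str(row.chromosome),
            position_bp=int(row.position),
            maf_true=float(row.maf_true),
            beta_true_exposure=float(row.beta_true_exposure),
        )
        for row in meta.itertuples()
    ]
    return Cohort(
        genotypes=geno.to_numpy(dtype=np.int8),
        covariates=samples[covariate_names].to_numpy(dtype=float),
        covariate_names=covariate_names,
        confounder=samples["confounder"].to_numpy(dtype=float),
        exposure=samples["exposure"].to_numpy(dtype=float),
        outcome=samples["outcome"].to_numpy(dtype=np.int8),
        variant_meta=variant_meta,
    )
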