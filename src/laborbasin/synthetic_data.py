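"""Synthetic myometrial-cohort generator.

Emulates the statistical structure the analysis assumes: two transcriptome
platforms with distinct affine scales (a microarray-like cohort of 3 NIL,
3 term-IL and 3 preterm-IL samples, one term-IL sample excluded as ambiguous;
an RNA-seq-like cohort of 5 NIL and 5 IL samples), group-dependent expression
shifts (inflammatory surrogates elevated in laboring samples, PR-B-responsive
surrogates elevated in quiescent samples), Gaussian measurement noise, and a
null mode with no group effect.  The default configuration reproduces the
pooled 18-sample (10 IL, 8 NIL) cohort shape.

Raw expression for gene g in a sample of group G on platform P is drawn as

    raw = offset_P + scale_P * mu_g(G) + Normal(0, noise_sd_P * scale_P)

with group means on a dimensionless [0, 1] signal scale.  Because the
downstream pipeline min-max normalizes within platform, it is invariant to
the affine platform factors, which the generator deliberately varies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression import Cohort, INFLAMMATORY_GENES, PRB_GENES, SURROGATE_GENES
from .ode_model import LaborBasinError

__all__ = [
    "PlatformSpec",
    "GeneMeans",
    "GeneratorConfig",
    "GeneratorConfigError",
    "default_config",
    "generate_cohort",
    "generate_parameter_truth",
]


class GeneratorConfigError(LaborBasinError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class PlatformSpec:
    """Cohort structure and affine measurement model of one platform."""

    name: str
    n_nil: int
    n_il_term: int
    n_il_preterm: int
    offset: float
    scale: float
    noise_sd: float  # on the dimensionless signal scale, multiplied by `scale`

    def __post_init__(self):
        if min(self.n_nil, self.n_il_term, self.n_il_preterm) < 0:
            raise GeneratorConfigError("sample counts must be nonnegative")
        if self.noise_sd <= 0:
            raise GeneratorConfigError("noise_sd must be positive")
        if self.scale == 0:
            raise GeneratorConfigError("scale must be nonzero")


@dataclass(frozen=True)
class GeneMeans:
    """Group means of one gene on the dimensionless signal scale."""

    mu_nil: float
    mu_il: float


# Defaults: inflammatory surrogates elevated in IL, PR-B surrogates in NIL,
# with a between-group separation of 0.5 signal units (5x the default noise
# sd, a strong but realistic bulk-transcriptome marker effect).
_DEFAULT_MEANS = {
    **{g: GeneMeans(mu_nil=0.25, mu_il=0.75) for g in INFLAMMATORY_GENES},
    **{g: GeneMeans(mu_nil=0.75, mu_il=0.25) for g in PRB_GENES},
}

_DEFAULT_PLATFORMS = (
    # fluorescence-intensity-like scale
    PlatformSpec(name="microarray", n_nil=3, n_il_term=3, n_il_preterm=3,
                 offset=120.0, scale=900.0, noise_sd=0.1),
    # normalized-abundance-like scale (e.g. TPM)
    PlatformSpec(name="rnaseq", n_nil=5, n_il_term=5, n_il_preterm=0,
                 offset=0.0, scale=60.0, noise_sd=0.1),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort draw.

    ``effect_size`` multiplies each gene's deviation from its grand midpoint,
    so 1.0 reproduces the default group separation, 0 removes it; ``null_mode``
    forces both groups onto the midpoint regardless.  ``exclude_one_term_il``
    drops the first term-IL microarray sample (by id), mirroring the curation
    of an ambiguous laboring sample.
    """

    platforms: tuple[PlatformSpec, ...] = _DEFAULT_PLATFORMS
    gene_means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    effect_size: float = 1.0
    null_mode: bool = False
    exclude_one_term_il: bool = True
    seed: int = 0

    def __post_init__(self):
        missing = [g for g in SURROGATE_GENES if g not in self.gene_means]
        if missing:
            raise GeneratorConfigError(f"gene_means missing genes: {missing}")


def default_config(**overrides) -> GeneratorConfig:
    """The default 18-sample two-platform configuration, with overrides."""
    return replace(GeneratorConfig(), **overrides)


def _effective_mean(means: GeneMeans, group: str, config: GeneratorConfig) -> float:
    mid = 0.5 * (means.mu_nil + means.mu_il)
    if config.null_mode:
        return mid
    mu = means.mu_il if group == "IL" else means.mu_nil
    return mid + config.effect_size * (mu - mid)


def _sample_plan(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for spec in config.platforms:
        prefix = spec.name[:2].upper()
        for j in range(spec.n_nil):
            rows.append((f"{prefix}_NIL_{j + 1}", spec.name, "NIL", "term"))
        for j in range(spec.n_il_term):
            rows.append((f"{prefix}_ILT_{j + 1}", spec.name, "IL", "term"))
        for j in range(spec.n_il_preterm):
            rows.append((f"{prefix}_ILP_{j + 1}", spec.name, "IL", "preterm"))
    plan = pd.DataFrame(rows, columns=["sample_id", "platform", "group", "timing"])
    if config.exclude_one_term_il:
        mask = (plan["platform"] == "microarray") & (plan["group"] == "IL") & (
            plan["timing"] == "term"
        )
        if mask.any():
            drop_id = plan.loc[mask, "sample_id"].min()  # deterministically the first
            plan = plan[plan["sample_id"] != drop_id]
    return plan.reset_index(drop=True)


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Draw an unnormalized synthetic cohort.

    Deterministic under ``config.seed``.  With the default configuration the
    result has 18 samples (10 IL, 8 NIL) across the two platforms.  Raises
    :class:`GeneratorConfigError` when any (platform, group) stratum that
    survives exclusion has fewer than 2 samples, since within-platform
    normalization would be undefined downstream.
    """
    config = config or GeneratorConfig()
    plan = _sample_plan(config)
    stratum_sizes = plan.groupby(["platform", "group"]).size()
    if (stratum_sizes < 2).any():
        small = stratum_sizes[stratum_sizes < 2].index.tolist()
        raise GeneratorConfigError(
            f"strata with fewer than 2 samples would break normalization: {small}"
        )
    rng = np.random.default_rng(config.seed)
    specs = {s.name: s for s in config.platforms}
    data = {g: np.empty(len(plan)) for g in SURROGATE_GENES}
    for r, row in plan.iterrows():
        spec = specs[row["platform"]]
        for gene in SURROGATE_GENES:
            mu = _effective_mean(config.gene_means[gene], row["group"], config)
            signal = mu + rng.normal(0.0, spec.noise_sd)
            data[gene][r] = spec.offset + spec.scale * signal
    df = plan.drop(columns="timing").assign(**data)
    return Cohort(data=df, normalized=False)


def generate_parameter_truth(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Noise-free normalized group signal per sample and gene.

    Returns a sample x gene table of the expression each sample would show
    with zero noise, min-max normalized within platform.  With two distinct
    group means the truth is binary per stratum, giving the ground-truth
    (b, i) of every predictor for parameter-recovery tests.
    """
    config = config or GeneratorConfig()
    plan = _sample_plan(config)
    out = pd.DataFrame(index=plan["sample_id"], columns=list(SURROGATE_GENES), dtype=float)
    for platform in plan["platform"].unique():
        idx = plan["platform"] == platform
        groups = plan.loc[idx, "group"]
        for gene in SURROGATE_GENES:
            mus = groups.map(
                lambda g: _effective_mean(config.gene_means[gene], g, config)
            ).astype(float)
            lo, hi = mus.min(), mus.max()
            normalized = (mus - lo) / (hi - lo) if hi > lo else mus * 0.0
            out.loc[plan.loc[idx, "sample_id"], gene] = normalized.to_numpy()
    return out
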