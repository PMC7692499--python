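"""Synthetic glioma-like cohorts with known subtype ground truth.

The generator emulates the structure a bulk-transcriptome subtyping pipeline
has to cope with: a centered/scaled expression matrix with latent subtypes of
unequal prevalence, one subtype whose tumor profile duplicates another's and
is distinguishable only through low tumor purity (the bulk signal drifts
toward a shared "normal tissue" profile as purity drops), a binary mutation
matrix with subtype-enriched genes, and survival times with subtype-dependent
hazards.

Expression for sample i with subtype k and purity p_i is

    x_i = p_i * (mu_k + eps_tumor) + (1 - p_i) * (nu + eps_normal)

followed by per-gene standardization.  Tumor profile shifts are calibrated so
that each subtype's informative genes show a standardized mean difference
(Cohen's d: subtype vs rest, pooled within-subtype sd) of ``effect_size`` on
the generated matrix — "effect size" therefore means what it says in sd
units.  For the subtype that the diluted twin copies, the twin is excluded
from the reference group, since it expresses the same program.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_preprocess import ExpressionMatrix, standardize

__all__ = ["CohortConfig", "PlatformDistortion", "SyntheticCohort", "generate_cohort", "degrade_to_platform"]


@dataclass
class CohortConfig:
    """Parameters of a simulated cohort.

    Defaults mirror a desk-scale glioma cohort: four subtypes of unequal
    prevalence, the last subtype a low-purity twin of the second (distinct
    only through dilution with the normal profile), hazards spanning an
    aggressive and an indolent group.
    """

    n_samples: int = 400
    n_genes: int = 2000
    n_subtypes: int = 4
    subtype_prevalence: tuple[float, ...] = (0.40, 0.25, 0.20, 0.15)
    n_informative_genes: int = 200
    effect_size: float = 2.0
    #: per-subtype Beta(a, b) purity parameters; means 0.77 for pure tumor
    #: subtypes and 0.60 for the diluted one
    purity_distribution: tuple[tuple[float, float], ...] = (
        (77.0, 23.0),
        (77.0, 23.0),
        (77.0, 23.0),
        (60.0, 40.0),
    )
    #: sd of the fixed per-gene normal-tissue profile (z units before mixing)
    normal_profile_shift: float = 3.0
    #: index of the subtype whose tumor profile copies ``twin_subtype`` and
    #: which differs only by its purity distribution; None disables dilution
    diluted_subtype: int | None = 3
    twin_subtype: int = 1
    mutation_genes_per_subtype: int = 3
    mutation_background_genes: int = 10
    mutation_baseline_rate: float = 0.10
    mutation_enrichment_odds: float = 8.0
    baseline_hazard: float = 0.0087  # events per month; median ~80 months
    subtype_log_hazard: tuple[float, ...] = (2.4, 0.0, 0.35, 0.0)
    censoring_rate: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subtypes < 2:
            raise ValueError("need at least 2 subtypes")
        if len(self.subtype_prevalence) != self.n_subtypes:
            raise ValueError("subtype_prevalence length != n_subtypes")
        if abs(sum(self.subtype_prevalence) - 1.0) > 1e-9:
            raise ValueError("subtype_prevalence must sum to 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_informative_genes > self.n_genes:
            raise ValueError("n_informative_genes > n_genes")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        if len(self.purity_distribution) != self.n_subtypes:
            raise ValueError("purity_distribution length != n_subtypes")
        if len(self.subtype_log_hazard) != self.n_subtypes:
            raise ValueError("subtype_log_hazard length != n_subtypes")
        if self.diluted_subtype is not None and self.diluted_subtype == self.twin_subtype:
            raise ValueError("diluted_subtype must differ from twin_subtype")


@dataclass
class PlatformDistortion:
    """Monotone per-gene distortion emulating a platform change.

    Each gene g is passed through ``exp(a_g) * x + b_g + nonlinearity * tanh(x)``
    plus Gaussian noise; a_g ~ N(0, gain_sd^2), b_g ~ N(0, offset_sd^2).  The
    transform is strictly increasing for nonlinearity > -1.
    """

    gain_sd: float = 0.2
    offset_sd: float = 0.5
    nonlinearity: float = 0.3
    noise_sd: float = 0.3

    @classmethod
    def identity(cls) -> "PlatformDistortion":
        return cls(gain_sd=0.0, offset_sd=0.0, nonlinearity=0.0, noise_sd=0.0)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: pd.DataFrame
    mutations: pd.DataFrame
    purity: pd.Series
    true_subtype: pd.Series
    informative_gene_ids: list[str]
    config: CohortConfig

    def __post_init__(self) -> None:
        sids = self.expression.sample_ids
        for part in (self.clinical.index, self.mutations.columns, self.purity.index, self.true_subtype.index):
            if list(part) != sids:
                raise ValueError("cohort components disagree on sample_ids")
        if ((self.purity < 0) | (self.purity > 1)).any():
            raise ValueError("purity out of [0, 1]")


def _subtype_blocks(rng: np.random.Generator, cfg: CohortConfig) -> tuple[np.ndarray, list[np.ndarray]]:
    """Pick informative gene indices and split them among distinct profiles."""
    informative = rng.choice(cfg.n_genes, size=cfg.n_informative_genes, replace=False)
    informative.sort()
    distinct = [k for k in range(cfg.n_subtypes) if k != cfg.diluted_subtype]
    blocks = np.array_split(informative, len(distinct))
    block_of: list[np.ndarray] = [np.array([], dtype=int)] * cfg.n_subtypes
    for k, blk in zip(distinct, blocks):
        block_of[k] = blk
    if cfg.diluted_subtype is not None:
        block_of[cfg.diluted_subtype] = block_of[cfg.twin_subtype]
    return informative, block_of


def _mix_and_standardize(
    shifts: np.ndarray,
    block_of: list[np.ndarray],
    z: np.ndarray,
    purity: np.ndarray,
    nu: np.ndarray,
    eps_t: np.ndarray,
    eps_n: np.ndarray,
    cfg: CohortConfig,
) -> np.ndarray:
    profiles = np.zeros((cfg.n_genes, cfg.n_subtypes))
    for k in range(cfg.n_subtypes):
        profiles[block_of[k], k] = shifts[k if k != cfg.diluted_subtype else cfg.twin_subtype]
    tumor = profiles[:, z] + eps_t
    normal = nu[:, None] + eps_n
    x = purity[None, :] * tumor + (1.0 - purity[None, :]) * normal
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mean) / sd


def _pooled_within_sd(xg: np.ndarray, z: np.ndarray, n_subtypes: int) -> np.ndarray:
    """Per-gene pooled within-subtype sd for a genes x samples block."""
    ss = np.zeros(xg.shape[0])
    dof = 0
    for k in range(n_subtypes):
        in_k = z == k
        n_k = int(in_k.sum())
        if n_k < 2:
            continue
        ss += xg[:, in_k].var(axis=1, ddof=1) * (n_k - 1)
        dof += n_k - 1
    return np.sqrt(ss / max(dof, 1))


def _realized_shifts(x: np.ndarray, block_of: list[np.ndarray], z: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    """Per-subtype realized Cohen's d on its informative block (NaN for diluted)."""
    out = np.full(cfg.n_subtypes, np.nan)
    for k in range(cfg.n_subtypes):
        if k == cfg.diluted_subtype or len(block_of[k]) == 0:
            continue
        in_k = z == k
        rest = ~in_k
        if cfg.diluted_subtype is not None and k == cfg.twin_subtype:
            rest = rest & (z != cfg.diluted_subtype)
        xg = x[block_of[k]]
        delta = xg[:, in_k].mean(axis=1) - xg[:, rest].mean(axis=1)
        sd = _pooled_within_sd(xg, z, cfg.n_subtypes)
        out[k] = float(np.mean(delta / sd))
    return out


def _calibrate_shifts(
    block_of, z, purity, nu, eps_t, eps_n, cfg: CohortConfig
) -> np.ndarray:
    """Solve for raw profile shifts that realize ``effect_size`` post-scaling.

    The realized within-sd-standardized shift r for a block obeys
    r(s)^2 = A s^2 / (C + B s^2) (purity jitter puts a small s-dependent term
    in the within-group variance), so 1/r^2 is linear in 1/s^2; two probe
    evaluations identify the coefficients and the target is solved in closed
    form, followed by one multiplicative refinement.
    """
    if cfg.effect_size == 0:
        return np.zeros(cfg.n_subtypes)
    e = cfg.effect_size
    s1 = np.full(cfg.n_subtypes, e)
    s2 = 2.0 * s1
    r1 = _realized_shifts(_mix_and_standardize(s1, block_of, z, purity, nu, eps_t, eps_n, cfg), block_of, z, cfg)
    r2 = _realized_shifts(_mix_and_standardize(s2, block_of, z, purity, nu, eps_t, eps_n, cfg), block_of, z, cfg)
    shifts = np.zeros(cfg.n_subtypes)
    for k in range(cfg.n_subtypes):
        if np.isnan(r1[k]):
            continue
        # 1/r^2 = alpha / s^2 + beta
        y1, y2 = 1.0 / r1[k] ** 2, 1.0 / r2[k] ** 2
        x1, x2 = 1.0 / s1[k] ** 2, 1.0 / s2[k] ** 2
        alpha = (y1 - y2) / (x1 - x2)
        beta = y1 - alpha * x1
        denom = 1.0 / e**2 - beta
        if denom <= 0:
            raise ValueError(
                f"effect_size {e} is not attainable for subtype {k}: "
                "within-group variance grows too fast with the profile shift "
                "(reduce effect_size or tighten the purity distributions)"
            )
        shifts[k] = np.sqrt(alpha / denom)
    if cfg.diluted_subtype is not None:
        shifts[cfg.diluted_subtype] = shifts[cfg.twin_subtype]
    # one multiplicative touch-up against residual model misfit
    r = _realized_shifts(_mix_and_standardize(shifts, block_of, z, purity, nu, eps_t, eps_n, cfg), block_of, z, cfg)
    adj = np.where(np.isnan(r) | (r <= 0), 1.0, e / np.where(np.isnan(r) | (r <= 0), 1.0, r))
    return shifts * adj


def _censoring_bound(rates: np.ndarray, weights: np.ndarray, target: float) -> float:
    """Administrative-censoring horizon u with C ~ U(0, u) achieving the target rate."""

    def frac_censored(u: float) -> float:
        # P(C < T) with C ~ U(0, u), T ~ Exp(rate): (1 - exp(-rate*u)) / (rate*u)
        lu = rates * u
        return float(np.sum(weights * (np.expm1(-lu) / -lu)))

    lo, hi = 1e-6, 1e8
    return brentq(lambda u: frac_censored(u) - target, lo, hi, xtol=1e-8)


def generate_cohort(config: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate a fully reproducible cohort from the configuration seed."""
    cfg = replace(config, **overrides) if config is not None else CohortConfig(**overrides)
    rng = np.random.default_rng(cfg.seed)

    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]

    z = rng.choice(cfg.n_subtypes, size=cfg.n_samples, p=np.asarray(cfg.subtype_prevalence))
    informative, block_of = _subtype_blocks(rng, cfg)
    ab = np.asarray(cfg.purity_distribution)
    purity = rng.beta(ab[z, 0], ab[z, 1])
    nu = rng.normal(0.0, cfg.normal_profile_shift, size=cfg.n_genes)
    eps_t = rng.normal(size=(cfg.n_genes, cfg.n_samples))
    eps_n = rng.normal(size=(cfg.n_genes, cfg.n_samples))

    shifts = _calibrate_shifts(block_of, z, purity, nu, eps_t, eps_n, cfg)
    x = _mix_and_standardize(shifts, block_of, z, purity, nu, eps_t, eps_n, cfg)
    expr = ExpressionMatrix(pd.DataFrame(x, index=gene_ids, columns=sample_ids), standardized=True)

    # mutations: a disjoint gene namespace; per-subtype enriched genes plus background
    r = cfg.mutation_baseline_rate
    odds = cfg.mutation_enrichment_odds
    enriched_rate = odds * r / (1.0 - r + odds * r)
    mut_genes = [
        f"MUT_S{k}_{j}" for k in range(cfg.n_subtypes) for j in range(cfg.mutation_genes_per_subtype)
    ] + [f"MUT_BG_{j}" for j in range(cfg.mutation_background_genes)]
    rates = np.full((len(mut_genes), cfg.n_samples), r)
    for k in range(cfg.n_subtypes):
        rows = slice(k * cfg.mutation_genes_per_subtype, (k + 1) * cfg.mutation_genes_per_subtype)
        rates[rows, z == k] = enriched_rate
    mutations = pd.DataFrame(
        (rng.random(rates.shape) < rates).astype(int), index=mut_genes, columns=sample_ids
    )

    # survival: exponential hazards per subtype, uniform administrative censoring
    log_hr = np.asarray(cfg.subtype_log_hazard)
    lam = cfg.baseline_hazard * np.exp(log_hr[z])
    event_time = rng.exponential(1.0 / lam)
    if cfg.censoring_rate > 0:
        prev = np.bincount(z, minlength=cfg.n_subtypes) / cfg.n_samples
        u = _censoring_bound(cfg.baseline_hazard * np.exp(log_hr), prev, cfg.censoring_rate)
        censor_time = rng.uniform(0.0, u, size=cfg.n_samples)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(cfg.n_samples, dtype=int)

    true_subtype = pd.Series([f"S{k + 1}" for k in z], index=sample_ids, name="true_subtype")
    clinical = pd.DataFrame(
        {"survival_time": time, "event": event, "true_subtype": true_subtype},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SyntheticCohort(
        expression=expr,
        clinical=clinical,
        mutations=mutations,
        purity=pd.Series(purity, index=sample_ids, name="purity"),
        true_subtype=true_subtype,
        informative_gene_ids=[gene_ids[i] for i in informative],
        config=cfg,
    )


def degrade_to_platform(
    cohort: SyntheticCohort | ExpressionMatrix,
    gene_retention: float = 161 / 168,
    distortion: PlatformDistortion | None = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Emulate measuring the cohort on a different expression platform.

    A random fraction of genes is retained (platforms rarely share complete
    gene sets), every surviving gene is passed through a monotone per-gene
    transform plus noise, and the result is re-standardized within itself.
    """
    if not (0 < gene_retention <= 1):
        raise ValueError("gene_retention must be in (0, 1]")
    expr = cohort.expression if isinstance(cohort, SyntheticCohort) else cohort
    dist = distortion if distortion is not None else PlatformDistortion()
    rng = np.random.default_rng(seed)

    n_keep = int(round(gene_retention * expr.n_genes))
    keep = np.sort(rng.choice(expr.n_genes, size=n_keep, replace=False))
    x = expr.values[keep].astype(float)

    gain = np.exp(rng.normal(0.0, dist.gain_sd, size=n_keep))[:, None]
    offset = rng.normal(0.0, dist.offset_sd, size=n_keep)[:, None]
    y = gain * x + offset + dist.nonlinearity * np.tanh(x)
    if dist.noise_sd > 0:
        y = y + rng.normal(0.0, dist.noise_sd, size=y.shape)

    out = ExpressionMatrix(
        pd.DataFrame(y, index=[expr.gene_ids[i] for i in keep], columns=expr.sample_ids),
        standardized=False,
    )
    return standardize(out)
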