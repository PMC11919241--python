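"""Prevalence estimation for an autosomal recessive disease from allele counts.

Under Hardy–Weinberg equilibrium the frequency of disease genotypes for a
set of pathogenic alleles with total frequency ``q = Σ_i q_i`` is ``q²``,
which expands over ordered allele pairs as ``Σ_i Σ_j q_i q_j``.  Three
estimators of this quantity are provided:

* ``ml`` — each ``q_i`` is the maximum-likelihood ratio AC/AN;
* ``bayes_mean`` — each ``q_i`` is replaced by its posterior expectation
  under a conjugate beta-binomial model, giving ``(Σ_i E[q_i])²``;
* ``bayes_var`` — the posterior expectation of ``q²`` itself,
  ``E[q²] = Var(q) + E[q]² = Σ_i Var(q_i) + (Σ_i E[q_i])²`` (posteriors
  independent across variants).

A severity-aware refinement multiplies each ordered pair by a symmetric
0/1 compatibility matrix ``A``: pairs of two null (loss-of-function)
alleles are excluded as embryonically lethal, and designated mild founder
alleles and synonymous alleles are excluded in homozygosity as
non-penetrant.  Confidence intervals come from a parametric bootstrap that
resamples allele counts binomially at the estimated frequencies.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .records import (
    GLOBAL_POPULATION,
    Consequence,
    PopulationCounts,
    ValidationError,
    VariantRecord,
)
from .variant_io import DEFAULT_TRANSCRIPT


class Method(str, enum.Enum):
    ML = "ml"
    BAYES_MEAN = "bayes_mean"
    BAYES_VAR = "bayes_var"


class Severity(str, enum.Enum):
    NULL = "null"
    MILD_HOM_EXCLUDED = "mild_hom_excluded"
    SYNONYMOUS = "synonymous"
    STANDARD = "standard"


#: loss-of-function consequence classes treated as null alleles
DEFAULT_NULL_CONSEQUENCES = frozenset(
    {
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.SPLICE_CANONICAL,
        Consequence.START_LOSS,
    }
)

#: founder/common alleles excluded in homozygosity by default:
#: p.Asp207Val, p.Asp239Glu, p.Val727Met
DEFAULT_MILD_VARIANTS = (
    f"{DEFAULT_TRANSCRIPT}:c.620A>T",
    f"{DEFAULT_TRANSCRIPT}:c.717T>G",
    f"{DEFAULT_TRANSCRIPT}:c.2179G>A",
)


class UndefinedFrequencyError(ValueError):
    """AN is zero, so no frequency can be estimated for this population."""


# --------------------------------------------------------------------------
# per-variant frequency summaries
# --------------------------------------------------------------------------

def ml_allele_freq(counts: PopulationCounts) -> float:
    """Maximum-likelihood allele frequency AC/AN."""
    if counts.an == 0:
        raise UndefinedFrequencyError("an = 0")
    return counts.ac / counts.an


def bayes_posterior(
    counts: PopulationCounts, prior: tuple[float, float] = (1.0, 1.0)
) -> tuple[float, float]:
    """Posterior mean and variance of the allele frequency.

    Conjugate update of a Beta(alpha, beta) prior with a Binomial(AN, q)
    observation of AC alternate alleles: the posterior is
    Beta(alpha + AC, beta + AN − AC).
    """
    alpha, beta = prior
    if alpha <= 0 or beta <= 0:
        raise ValueError("prior hyperparameters must be positive")
    a = alpha + counts.ac
    b = beta + counts.an - counts.ac
    s = a + b
    mean = a / s
    var = a * b / (s * s * (s + 1.0))
    return mean, var


@dataclass
class AlleleFrequencySummary:
    """Frequency estimates for one variant in one population."""

    key: str
    q_ml: float
    post_mean: float
    post_var: float
    prior: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_ml <= 1.0):
            raise ValidationError(f"q_ml {self.q_ml} outside [0, 1]")
        if self.post_var < 0 or self.post_var > self.post_mean * (1 - self.post_mean):
            raise ValidationError("posterior variance out of admissible range")


def summarize_catalog(
    catalog: Iterable[VariantRecord],
    population: str = GLOBAL_POPULATION,
    prior: tuple[float, float] = (1.0, 1.0),
) -> list[AlleleFrequencySummary]:
    """Frequency summaries for every record with usable counts in a population.

    Records lacking counts (or with AN = 0) for the population are skipped
    with a warning rather than imputed at zero frequency.
    """
    out: list[AlleleFrequencySummary] = []
    skipped = 0
    for rec in catalog:
        c = rec.counts_for(population)
        if c is None or c.an == 0:
            skipped += 1
            continue
        mean, var = bayes_posterior(c, prior)
        out.append(
            AlleleFrequencySummary(
                key=rec.key, q_ml=ml_allele_freq(c), post_mean=mean,
                post_var=var, prior=prior,
            )
        )
    if skipped:
        warnings.warn(
            f"{skipped} record(s) without counts for population "
            f"{population!r} skipped"
        )
    return out


# --------------------------------------------------------------------------
# severity policy
# --------------------------------------------------------------------------

@dataclass
class CompatibilityPolicy:
    """Severity classes and the allowed-genotype matrix they induce.

    The symmetric 0/1 matrix ``A`` over variant pairs has ``A[i][j] = 0``
    exactly when both alleles are null (embryonic lethality) or when
    ``i = j`` and the allele is mild-homozygote-excluded or synonymous
    (non-penetrant homozygotes).  Compound heterozygotes of two distinct
    mild or synonymous alleles remain allowed.
    """

    class_of: dict[str, Severity] = field(default_factory=dict)

    def severity(self, key: str) -> Severity:
        try:
            return self.class_of[key]
        except KeyError:
            raise KeyError(f"key {key!r} not covered by policy") from None

    def allowed(self, i: str, j: str) -> bool:
        si, sj = self.severity(i), self.severity(j)
        if si is Severity.NULL and sj is Severity.NULL:
            return False
        if i == j and si in (Severity.MILD_HOM_EXCLUDED, Severity.SYNONYMOUS):
            return False
        return True

    def matrix(self, keys: Sequence[str]) -> np.ndarray:
        sev = [self.severity(k) for k in keys]
        null = np.array([s is Severity.NULL for s in sev])
        A = np.ones((len(keys), len(keys)))
        A[np.outer(null, null)] = 0.0
        for idx, s in enumerate(sev):
            if s in (Severity.MILD_HOM_EXCLUDED, Severity.SYNONYMOUS):
                A[idx, idx] = 0.0
        return A


@dataclass
class PolicyConfig:
    null_consequences: frozenset[Consequence] = DEFAULT_NULL_CONSEQUENCES
    mild_list: tuple[str, ...] = DEFAULT_MILD_VARIANTS


def build_policy(
    catalog: Iterable[VariantRecord], config: PolicyConfig | None = None
) -> CompatibilityPolicy:
    """Assign a severity class to every catalog key.

    Mild-list membership takes precedence (the designated founder alleles
    are missense), then loss-of-function consequences map to null, then
    synonymous; everything else is standard.  Mild-list keys absent from
    the catalog only produce a warning.
    """
    config = config or PolicyConfig()
    catalog = list(catalog)
    present = {r.key for r in catalog}
    for missing in sorted(set(config.mild_list) - present):
        warnings.warn(f"mild-list key {missing} not in catalog")
    class_of: dict[str, Severity] = {}
    for rec in catalog:
        if rec.key in config.mild_list:
            class_of[rec.key] = Severity.MILD_HOM_EXCLUDED
        elif rec.consequence in config.null_consequences:
            class_of[rec.key] = Severity.NULL
        elif rec.consequence is Consequence.SYNONYMOUS:
            class_of[rec.key] = Severity.SYNONYMOUS
        else:
            class_of[rec.key] = Severity.STANDARD
    return CompatibilityPolicy(class_of=class_of)


# --------------------------------------------------------------------------
# the quadratic-form estimate
# --------------------------------------------------------------------------

@dataclass
class PrevalenceEstimate:
    method: Method
    set_label: str | None
    population: str
    value_per_million: float
    ci95: tuple[float, float] | None = None
    severity_adjusted: bool = False


def _genotype_frequency(
    q: np.ndarray,
    post_mean: np.ndarray,
    post_var: np.ndarray,
    method: Method,
    A: np.ndarray | None,
) -> float:
    """Σ_ij A_ij m_ij over ordered pairs for the requested method."""
    if method is Method.ML:
        v = q
    else:
        v = post_mean
    if A is None:
        value = float(np.sum(v)) ** 2
        if method is Method.BAYES_VAR:
            value += float(np.sum(post_var))
        return value
    value = float(v @ A @ v)
    if method is Method.BAYES_VAR:
        value += float(np.diag(A) @ post_var)
    return value


def prevalence_estimate(
    summaries: Sequence[AlleleFrequencySummary],
    method: Method | str = Method.ML,
    policy: CompatibilityPolicy | None = None,
    population: str = GLOBAL_POPULATION,
    set_label: str | None = None,
) -> PrevalenceEstimate:
    """Genotype-frequency estimate (per million) from frequency summaries.

    With ``policy=None`` every genotype combination counts and the ml value
    reduces exactly to ``(Σ_i q_i)²``.  An empty summary list yields zero.
    """
    method = Method(method)
    keys = [s.key for s in summaries]
    q = np.array([s.q_ml for s in summaries])
    mean = np.array([s.post_mean for s in summaries])
    var = np.array([s.post_var for s in summaries])
    A = policy.matrix(keys) if policy is not None else None
    value = _genotype_frequency(q, mean, var, method, A) if keys else 0.0
    return PrevalenceEstimate(
        method=method,
        set_label=set_label,
        population=population,
        value_per_million=1e6 * value,
        severity_adjusted=policy is not None,
    )


class PrevalenceEstimator(BaseEstimator):
    """Recessive-disease prevalence from a variant catalog.

    Scikit-learn-style estimator: ``fit`` takes a catalog (list of
    :class:`~gnemprev.records.VariantRecord`), converts each record's
    counts in ``population`` into frequency summaries, and stores the
    genotype-frequency estimate (per million) plus an optional parametric
    bootstrap 95% CI in trailing-underscore attributes.

    Parameters
    ----------
    method : {"ml", "bayes_mean", "bayes_var"}
    policy : CompatibilityPolicy or None
        None means every genotype combination is allowed.
    prior : (alpha, beta) of the beta prior for the Bayesian methods.
    population : population label; "all" uses global counts.
    n_bootstrap : int or None
        Number of parametric-bootstrap replicates; None disables the CI.
    seed : int or None
        Seed for the bootstrap generator.

    Attributes
    ----------
    summaries_ : list of AlleleFrequencySummary
    value_per_million_ : float
    ci95_ : (lo, hi) per million, or None
    estimate_ : PrevalenceEstimate
    """

    def __init__(
        self,
        method: str = "ml",
        policy: CompatibilityPolicy | None = None,
        prior: tuple[float, float] = (1.0, 1.0),
        population: str = GLOBAL_POPULATION,
        n_bootstrap: int | None = None,
        seed: int | None = None,
        set_label: str | None = None,
    ):
        self.method = method
        self.policy = policy
        self.prior = prior
        self.population = population
        self.n_bootstrap = n_bootstrap
        self.seed = seed
        self.set_label = set_label

    def fit(self, X: Sequence[VariantRecord], y=None):
        catalog = list(X)
        self.summaries_ = summarize_catalog(
            catalog, population=self.population, prior=self.prior
        )
        est = prevalence_estimate(
            self.summaries_,
            method=self.method,
            policy=self.policy,
            population=self.population,
            set_label=self.set_label,
        )
        self.ci95_ = None
        if self.n_bootstrap is not None:
            self.ci95_ = bootstrap_ci(
                catalog,
                method=self.method,
                policy=self.policy,
                replicates=self.n_bootstrap,
                seed=self.seed if self.seed is not None else 0,
                population=self.population,
                prior=self.prior,
            )
            est.ci95 = self.ci95_
        self.value_per_million_ = est.value_per_million
        self.estimate_ = est
        return self

    def score(self, X=None, y=None):  # pragma: no cover - sklearn API glue
        check_is_fitted(self, "value_per_million_")
        return self.value_per_million_


def per_population_estimates(
    catalog: Sequence[VariantRecord],
    method: Method | str = Method.ML,
    policy: CompatibilityPolicy | None = None,
    populations: Sequence[str] | None = None,
    prior: tuple[float, float] = (1.0, 1.0),
    set_label: str | None = None,
) -> pd.DataFrame:
    """One prevalence row per population plus the global "all" estimate.

    Variants lacking counts for a population are skipped for that
    population (logged via warnings), not imputed at zero.
    """
    if populations is None:
        populations = sorted({p for r in catalog for p in r.populations()})
    else:
        known = {p for r in catalog for p in r.populations()}
        unknown = [p for p in populations if p != GLOBAL_POPULATION and p not in known]
        if unknown:
            raise ValidationError(f"unknown population label(s): {unknown}")
    rows = []
    for pop in [GLOBAL_POPULATION, *populations]:
        summaries = summarize_catalog(catalog, population=pop, prior=prior)
        est = prevalence_estimate(
            summaries, method=method, policy=policy, population=pop,
            set_label=set_label,
        )
        rows.append(
            {
                "set_label": set_label,
                "population": pop,
                "method": Method(method).value,
                "severity_adjusted": policy is not None,
                "value_per_million": est.value_per_million,
                "n_variants": len(summaries),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# parametric bootstrap and burden arithmetic
# --------------------------------------------------------------------------

def bootstrap_ci(
    catalog: Sequence[VariantRecord],
    method: Method | str = Method.ML,
    policy: CompatibilityPolicy | None = None,
    replicates: int = 1000,
    seed: int = 0,
    population: str = GLOBAL_POPULATION,
    prior: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, float]:
    """Parametric-bootstrap 95% CI (per million) for the prevalence estimate.

    Each replicate redraws every variant's allele count as
    ``AC* ~ Binomial(AN, AC/AN)`` at its observed frequency, recomputes the
    estimate, and the 2.5th/97.5th percentiles of the replicate values form
    the interval.  Identical seeds give identical intervals.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    method = Method(method)
    usable = []
    for rec in catalog:
        c = rec.counts_for(population)
        if c is None or c.an == 0:
            raise UndefinedFrequencyError(
                f"{rec.key}: no counts with an > 0 for population {population!r}"
            )
        usable.append((rec.key, c.ac, c.an))
    if not usable:
        return (0.0, 0.0)
    keys = [k for k, _, _ in usable]
    ac = np.array([a for _, a, _ in usable], dtype=float)
    an = np.array([n for _, _, n in usable], dtype=float)
    q_hat = ac / an
    rng = np.random.default_rng(seed)
    ac_star = rng.binomial(an.astype(np.int64), q_hat, size=(replicates, len(keys)))
    A = policy.matrix(keys) if policy is not None else None
    alpha, beta = prior
    Q = ac_star / an
    if method is Method.ML:
        V = Q
        var = None
    else:
        a_post = alpha + ac_star
        b_post = beta + an - ac_star
        s = a_post + b_post
        V = a_post / s
        var = a_post * b_post / (s * s * (s + 1.0))
    if A is None:
        values = V.sum(axis=1) ** 2
        if method is Method.BAYES_VAR:
            values = values + var.sum(axis=1)
    else:
        values = np.einsum("ri,ij,rj->r", V, A, V)
        if method is Method.BAYES_VAR:
            values = values + var @ np.diag(A)
    lo, hi = np.percentile(1e6 * values, [2.5, 97.5])
    return float(lo), float(hi)


def burden(
    prevalence_per_million: float,
    population_size: float,
    affected_fraction: float = 1.0,
    precision: int = 0,
) -> float:
    """Number of affected individuals implied by a per-million prevalence.

    ``prevalence_per_million × population_size / 1e6 × affected_fraction``,
    rounded to ``precision`` decimals.  The affected fraction discounts for
    pre-symptomatic carriers of disease genotypes (adult-onset disease).
    """
    if prevalence_per_million < 0 or population_size < 0:
        raise ValueError("inputs must be non-negative")
    if not (0.0 <= affected_fraction <= 1.0):
        raise ValueError("affected_fraction must lie in [0, 1]")
    value = prevalence_per_million * population_size / 1e6 * affected_fraction
    return round(value, precision) if precision > 0 else float(round(value))
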