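"""Allele-frequency summaries, severity policy, quadratic-form estimates,
parametric bootstrap, and burden arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from gnemprev.prevalence import (
    AlleleFrequencySummary,
    CompatibilityPolicy,
    Method,
    PolicyConfig,
    PrevalenceEstimator,
    Severity,
    UndefinedFrequencyError,
    bayes_posterior,
    bootstrap_ci,
    build_policy,
    burden,
    ml_allele_freq,
    per_population_estimates,
    prevalence_estimate,
    summarize_catalog,
)
from gnemprev.records import Consequence, PopulationCounts
from gnemprev.variant_io import DEFAULT_TRANSCRIPT

T = DEFAULT_TRANSCRIPT


def summary(key: str, q: float) -> AlleleFrequencySummary:
    return AlleleFrequencySummary(key=key, q_ml=q, post_mean=q, post_var=0.0)


def beta_moments_by_integration(alpha, beta, ac, an):
    """Independent oracle: numerical integration of the posterior density."""
    post = stats.beta(alpha + ac, beta + an - ac)
    pts = [post.ppf(1e-12), post.mean(), post.ppf(1 - 1e-12)]
    mean, _ = integrate.quad(lambda q: q * post.pdf(q), 0, 1, points=pts)
    second, _ = integrate.quad(lambda q: q * q * post.pdf(q), 0, 1, points=pts)
    return mean, second - mean**2


class TestFrequencySummaries:
    def test_ml_ratio(self):
        assert ml_allele_freq(PopulationCounts(3, 1000)) == pytest.approx(0.003)
        assert ml_allele_freq(PopulationCounts(0, 10)) == 0.0

    def test_ml_undefined_at_zero_an(self):
        with pytest.raises(UndefinedFrequencyError):
            ml_allele_freq(PopulationCounts(0, 0))

    def test_uniform_prior_unchanged_by_no_data(self):
        mean, var = bayes_posterior(PopulationCounts(0, 0), (1, 1))
        assert mean == pytest.approx(0.5)
        assert var == pytest.approx(1 / 12)

    @pytest.mark.parametrize(
        "prior, ac, an",
        [((1, 1), 2, 1000), ((0.5, 0.5), 0, 100), ((2, 50), 7, 300)],
    )
    def test_posterior_matches_numerical_integration(self, prior, ac, an):
        mean, var = bayes_posterior(PopulationCounts(ac, an), prior)
        omean, ovar = beta_moments_by_integration(*prior, ac, an)
        assert mean == pytest.approx(omean, abs=1e-10)
        assert var == pytest.approx(ovar, abs=1e-10)

    def test_known_posterior_values(self):
        mean, var = bayes_posterior(PopulationCounts(2, 1000), (1, 1))
        assert mean == pytest.approx(3 / 1002)
        assert var == pytest.approx(2.976e-6, rel=1e-3)
        mean, _ = bayes_posterior(PopulationCounts(0, 100), (0.5, 0.5))
        assert mean == pytest.approx(0.5 / 101)

    def test_posterior_converges_to_ml(self):
        an = 10**6
        q = 2.4e-4
        c = PopulationCounts(int(q * an), an)
        mean, _ = bayes_posterior(c, (1, 1))
        assert abs(mean - ml_allele_freq(c)) < 1e-4

    def test_summaries_skip_missing_populations_with_warning(self, record_factory):
        recs = [
            record_factory("c.1A>G", pops={"afr": (1, 100)}),
            record_factory("c.2T>C", pops={"eas": (2, 200)}),
        ]
        with pytest.warns(UserWarning, match="skipped"):
            out = summarize_catalog(recs, population="afr")
        assert [s.key for s in out] == [f"{T}:c.1A>G"]


class TestCompatibilityPolicy:
    def policy(self, **classes):
        return CompatibilityPolicy(class_of={k: v for k, v in classes.items()})

    def test_two_nulls_are_lethal(self):
        p = self.policy(n1=Severity.NULL, n2=Severity.NULL, s=Severity.STANDARD)
        assert not p.allowed("n1", "n2")
        assert not p.allowed("n1", "n1")
        assert p.allowed("n1", "s")

    def test_mild_variant_excluded_only_in_homozygosity(self):
        p = self.policy(m=Severity.MILD_HOM_EXCLUDED, s=Severity.STANDARD,
                        m2=Severity.MILD_HOM_EXCLUDED)
        assert not p.allowed("m", "m")
        assert p.allowed("m", "s")
        assert p.allowed("m", "m2")  # distinct mild alleles in trans allowed

    def test_synonymous_excluded_only_in_homozygosity(self):
        p = self.policy(y=Severity.SYNONYMOUS, s=Severity.STANDARD)
        assert not p.allowed("y", "y")
        assert p.allowed("y", "s")

    def test_all_standard_gives_all_ones_matrix(self):
        p = self.policy(a=Severity.STANDARD, b=Severity.STANDARD)
        assert np.array_equal(p.matrix(["a", "b"]), np.ones((2, 2)))

    def test_matrix_is_symmetric_binary(self):
        p = self.policy(
            a=Severity.NULL, b=Severity.MILD_HOM_EXCLUDED,
            c=Severity.SYNONYMOUS, d=Severity.STANDARD, e=Severity.NULL,
        )
        A = p.matrix(list("abcde"))
        assert np.array_equal(A, A.T)
        assert set(np.unique(A)) <= {0.0, 1.0}

    def test_build_policy_from_consequences(self, record_factory):
        catalog = [
            record_factory("c.1A>G", Consequence.NONSENSE),
            record_factory("c.2T>C", Consequence.SYNONYMOUS),
            record_factory("c.3G>A", Consequence.MISSENSE),
            record_factory("c.2179G>A", Consequence.MISSENSE),  # mild founder
        ]
        with pytest.warns(UserWarning, match="mild-list"):
            policy = build_policy(catalog)
        assert policy.severity(f"{T}:c.1A>G") is Severity.NULL
        assert policy.severity(f"{T}:c.2T>C") is Severity.SYNONYMOUS
        assert policy.severity(f"{T}:c.3G>A") is Severity.STANDARD
        assert policy.severity(f"{T}:c.2179G>A") is Severity.MILD_HOM_EXCLUDED

    def test_missing_key_raises(self):
        p = self.policy(a=Severity.STANDARD)
        with pytest.raises(KeyError):
            p.matrix(["a", "zzz"])


class TestPrevalenceEstimate:
    def test_empty_input_is_zero(self):
        assert prevalence_estimate([]).value_per_million == 0.0

    def test_single_standard_variant(self):
        est = prevalence_estimate([summary("a", 0.01)])
        assert est.value_per_million == pytest.approx(100.0)

    def test_null_plus_standard_pair_excludes_null_homozygotes(self):
        policy = CompatibilityPolicy(
            class_of={"n": Severity.NULL, "s": Severity.STANDARD}
        )
        est = prevalence_estimate(
            [summary("n", 1e-3), summary("s", 2e-3)], policy=policy
        )
        # full (3e-3)^2 = 9e-6 minus the null x null cell 1e-6
        assert est.value_per_million == pytest.approx(8.0)
        assert est.severity_adjusted

    def test_all_allowed_ml_equals_squared_sum(self):
        rng = np.random.default_rng(7)
        qs = rng.uniform(0, 1e-3, size=40)
        est = prevalence_estimate([summary(f"v{i}", q) for i, q in enumerate(qs)])
        assert est.value_per_million == pytest.approx(
            1e6 * qs.sum() ** 2, rel=1e-12
        )

    def test_severity_adjusted_never_exceeds_unadjusted(self):
        rng = np.random.default_rng(11)
        sevs = list(Severity)
        summaries = [summary(f"v{i}", q) for i, q in enumerate(rng.uniform(0, 1e-3, 25))]
        policy = CompatibilityPolicy(
            class_of={s.key: sevs[i % 4] for i, s in enumerate(summaries)}
        )
        adj = prevalence_estimate(summaries, policy=policy).value_per_million
        unadj = prevalence_estimate(summaries).value_per_million
        assert adj <= unadj

    def test_adding_a_variant_never_decreases_the_estimate(self):
        base = [summary("a", 1e-3), summary("b", 2e-4)]
        bigger = base + [summary("c", 5e-4)]
        for method in Method:
            assert (
                prevalence_estimate(bigger, method).value_per_million
                >= prevalence_estimate(base, method).value_per_million
            )

    def test_bayes_var_adds_posterior_variance(self, record_factory):
        recs = [record_factory(f"c.{i}A>G", ac=i, an=10000) for i in (1, 2, 3)]
        s = summarize_catalog(recs)
        v_mean = prevalence_estimate(s, Method.BAYES_MEAN).value_per_million
        v_var = prevalence_estimate(s, Method.BAYES_VAR).value_per_million
        assert v_var == pytest.approx(v_mean + 1e6 * sum(x.post_var for x in s))
        assert v_var >= v_mean >= 0

    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(0, 5000), st.integers(0, 3)),
            min_size=1, max_size=12,
        )
    )
    @settings(deadline=None)
    def test_bayes_var_dominates_bayes_mean(self, raw):
        summaries = []
        for i, (ac, extra, sev) in enumerate(raw):
            c = PopulationCounts(ac, ac + extra)
            mean, var = bayes_posterior(c, (1, 1))
            summaries.append(
                AlleleFrequencySummary(f"v{i}", ac / max(c.an, 1) if c.an else 0.0,
                                       mean, var)
            )
        policy = CompatibilityPolicy(
            class_of={s.key: list(Severity)[sev_idx % 4]
                      for (s, (_, _, sev_idx)) in zip(summaries, raw)}
        )
        v_mean = prevalence_estimate(summaries, Method.BAYES_MEAN, policy)
        v_var = prevalence_estimate(summaries, Method.BAYES_VAR, policy)
        assert v_var.value_per_million >= v_mean.value_per_million >= 0.0

    def test_exhaustive_pair_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        n = 15
        qs = rng.uniform(0, 2e-3, n)
        sevs = [list(Severity)[i % 4] for i in range(n)]
        keys = [f"v{i}" for i in range(n)]
        policy = CompatibilityPolicy(class_of=dict(zip(keys, sevs)))
        est = prevalence_estimate(
            [summary(k, q) for k, q in zip(keys, qs)], policy=policy
        )
        brute = sum(
            qs[i] * qs[j]
            for i in range(n)
            for j in range(n)
            if policy.allowed(keys[i], keys[j])
        )
        assert est.value_per_million == pytest.approx(1e6 * brute, rel=1e-12)


class TestEstimatorAndPopulations:
    def test_estimator_fit_attributes_and_params(self, record_factory):
        recs = [record_factory(f"c.{i}A>G", ac=2, an=10000) for i in (1, 2)]
        est = PrevalenceEstimator(method="ml", n_bootstrap=100, seed=5).fit(recs)
        assert est.value_per_million_ == pytest.approx(1e6 * (4 / 10000) ** 2)
        lo, hi = est.ci95_
        assert lo <= est.value_per_million_ <= hi
        assert est.get_params()["seed"] == 5

    def test_single_population_equals_worldwide(self, record_factory):
        recs = [record_factory(f"c.{i}A>G", pops={"eas": (i, 5000)}) for i in (1, 3)]
        table = per_population_estimates(recs)
        by_pop = table.set_index("population")["value_per_million"]
        assert by_pop["eas"] == pytest.approx(by_pop["all"])

    def test_all_zero_ac_population_gives_zero(self, record_factory):
        recs = [record_factory("c.1A>G", pops={"fin": (0, 8000)})]
        table = per_population_estimates(recs)
        assert (table["value_per_million"] == 0).all()

    def test_unknown_population_label_is_error(self, record_factory):
        recs = [record_factory("c.1A>G", pops={"fin": (1, 100)})]
        with pytest.raises(Exception, match="unknown population"):
            per_population_estimates(recs, populations=["mars"])

    def test_variants_missing_a_population_are_skipped(self, record_factory):
        recs = [
            record_factory("c.1A>G", pops={"afr": (2, 1000)}),
            record_factory("c.2T>C", pops={"afr": (1, 1000), "eas": (4, 1000)}),
        ]
        with pytest.warns(UserWarning):
            table = per_population_estimates(recs)
        eas = table.set_index("population").loc["eas"]
        assert eas["n_variants"] == 1
        assert eas["value_per_million"] == pytest.approx(1e6 * (4 / 1000) ** 2)


class TestBootstrap:
    def test_identical_seed_identical_interval(self, record_factory):
        recs = [record_factory(f"c.{i}A>G", ac=3 * i, an=50000) for i in (1, 2, 3)]
        a = bootstrap_ci(recs, replicates=300, seed=42)
        b = bootstrap_ci(recs, replicates=300, seed=42)
        assert a == b

    def test_all_zero_counts_degenerate_interval(self, record_factory):
        recs = [record_factory("c.1A>G", ac=0, an=1000)]
        assert bootstrap_ci(recs, replicates=100, seed=0) == (0.0, 0.0)

    def test_zero_an_is_an_error(self, record_factory):
        recs = [record_factory("c.1A>G", ac=0, an=0)]
        with pytest.raises(UndefinedFrequencyError):
            bootstrap_ci(recs, replicates=10, seed=0)

    def test_interval_brackets_the_point_estimate(self, record_factory):
        recs = [record_factory(f"c.{i}A>G", ac=20, an=100000) for i in range(1, 6)]
        value = PrevalenceEstimator().fit(recs).value_per_million_
        lo, hi = bootstrap_ci(recs, replicates=500, seed=9)
        assert lo <= value <= hi


class TestBurden:
    def test_worldwide_burden_from_per_million(self):
        assert burden(11.00, 8e9) == 88000
        assert burden(11.00, 8e9, affected_fraction=0.5) == 44000
        assert burden(0, 8e9, 0.3) == 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            burden(-1, 8e9)
        with pytest.raises(ValueError):
            burden(1, 8e9, affected_fraction=1.5)
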