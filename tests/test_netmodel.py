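"""Dyad table assembly, mixed-model fitting, adaptive FDR, reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import false_discovery_control, kstest

from vagalnet.connectome import (
    clean_timeseries,
    compute_nodal_metrics,
    correlation_network,
)
from vagalnet.netmodel import (
    FIXED_EFFECT_TERMS,
    adaptive_fdr,
    build_dyad_table,
    fit_strength_model,
    report_results,
    standardize_covariates,
)
from vagalnet.synthetic import (
    CohortSpec,
    GeneratorModelSpec,
    default_beta,
    simulate_dyad_dataset,
    simulate_region_timeseries,
)

I3 = FIXED_EFFECT_TERMS.index("clustering_state_rsa")


def small_cohort_inputs(n_subjects=3, n_nodes=8, n_timepoints=120, seed=0):
    spec = CohortSpec(
        n_subjects=n_subjects, n_nodes=n_nodes, n_timepoints=n_timepoints,
        n_blocks=2, seed=seed,
    )
    data, _ = simulate_region_timeseries(spec)
    networks, metrics = {}, {}
    for key, m in data.items():
        net = correlation_network(clean_timeseries(m))
        networks[key] = net
        metrics[key] = compute_nodal_metrics(net, seed=0)
    rng = np.random.default_rng(seed + 1)
    cov = pd.DataFrame(
        {
            "subject": np.arange(n_subjects),
            "rsa": rng.normal(5.8, 1.7, n_subjects),
            "age": rng.normal(38.8, 10.9, n_subjects),
            "sex": rng.integers(0, 2, n_subjects),
            "bmi": rng.normal(24.8, 3.8, n_subjects),
        }
    )
    return networks, metrics, cov


class TestBuildDyadTable:
    def test_row_count_and_standardization(self):
        networks, metrics, cov = small_cohort_inputs()
        table = build_dyad_table(networks, metrics, cov)
        assert len(table) == 3 * 2 * (8 * 7 // 2)
        for col in ("clust_avg", "eff_avg", "degree_diff", "rsa", "age", "bmi"):
            assert table[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert table[col].std(ddof=0) == pytest.approx(1.0, abs=1e-10)
        assert set(table["state"]) == {0, 1}

    def test_endpoint_average_definition(self):
        networks, metrics, cov = small_cohort_inputs()
        table = build_dyad_table(networks, metrics, cov, standardize=False)
        key = (0, 0)
        m = metrics[key]
        sub = table[(table["subject"] == 0) & (table["state"] == 0)]
        row = sub.iloc[0]
        i, j = int(row["node_i"]), int(row["node_j"])
        assert row["clust_avg"] == pytest.approx((m.clustering[i] + m.clustering[j]) / 2)
        assert row["degree_diff"] == pytest.approx(abs(m.degree[i] - m.degree[j]))
        assert row["strength"] == pytest.approx(networks[key].weights[i, j])

    def test_missing_state_or_covariate_names_subject(self):
        networks, metrics, cov = small_cohort_inputs()
        broken = {k: v for k, v in networks.items() if k != (1, 1)}
        with pytest.raises(ValueError, match="subject 1"):
            build_dyad_table(broken, metrics, cov)
        cov2 = cov.copy()
        cov2.loc[cov2["subject"] == 2, "bmi"] = np.nan
        with pytest.raises(ValueError, match="subject 2"):
            build_dyad_table(networks, metrics, cov2)

    def test_standardization_equivariance_to_raw_rescaling(self):
        networks, metrics, cov = small_cohort_inputs()
        cov2 = cov.copy()
        cov2["age"] = cov2["age"] * 12.0 + 5.0  # months-ish
        t1 = build_dyad_table(networks, metrics, cov)
        t2 = build_dyad_table(networks, metrics, cov2)
        np.testing.assert_allclose(t1["age"], t2["age"], atol=1e-10)


class TestFitStrengthModel:
    def test_noiseless_recovery_is_exact(self):
        beta = default_beta(
            intercept=0.234, state=-0.015, clustering=0.068, efficiency=0.029,
            clustering_state_rsa=0.012, efficiency_state_rsa=-0.005, bmi=-0.003,
        )
        spec = GeneratorModelSpec(
            beta=beta, sigma_subject=0, sigma_subject_state=0, sigma_resid=0,
            n_subjects=5, n_nodes=8, seed=0,
        )
        table, _ = simulate_dyad_dataset(spec)
        fit = fit_strength_model(table)
        truth = np.array([beta[t] for t in FIXED_EFFECT_TERMS])
        np.testing.assert_allclose(fit.estimates, truth, atol=1e-8)

    def test_single_replicate_recovery_and_variance_components(self):
        spec = GeneratorModelSpec(
            beta=default_beta(intercept=0.234, clustering_state_rsa=0.012),
            sigma_subject=0.05, sigma_subject_state=0.03, sigma_resid=0.10,
            n_subjects=30, n_nodes=30, seed=4,
        )
        table, _ = simulate_dyad_dataset(spec)
        fit = fit_strength_model(table)
        assert fit.estimates[I3] == pytest.approx(0.012, abs=3 * fit.std_errors[I3])
        assert fit.variance_components["residual"] == pytest.approx(0.10, rel=0.05)
        assert fit.method in ("reml", "ml")

    def test_random_state_component_can_be_disabled(self):
        spec = GeneratorModelSpec(
            beta=default_beta(), sigma_subject=0.05, sigma_subject_state=0.0,
            sigma_resid=0.10, n_subjects=10, n_nodes=10, seed=5,
        )
        table, _ = simulate_dyad_dataset(spec)
        fit = fit_strength_model(table, include_random_state=False)
        assert fit.variance_components["subject_state"] == 0.0
        assert len(fit.estimates) == len(FIXED_EFFECT_TERMS)

    def test_requires_two_subjects(self):
        spec = GeneratorModelSpec(beta=default_beta(), n_subjects=2, n_nodes=5, seed=0)
        table, _ = simulate_dyad_dataset(spec)
        with pytest.raises(ValueError, match="subjects"):
            fit_strength_model(table[table["subject"] == 0])


class TestAdaptiveFDR:
    def test_hand_computed_step_up(self):
        adj, rej = adaptive_fdr([0.001, 0.8], q=0.05)
        np.testing.assert_allclose(adj, [0.002, 0.8])
        assert rej.tolist() == [True, False]

    def test_all_ones_no_rejections(self):
        adj, rej = adaptive_fdr(np.ones(10))
        assert np.all(adj == 1.0) and not rej.any()

    def test_forced_m0_reproduces_classical_bh(self, rng):
        for _ in range(5):
            p = rng.uniform(size=50)
            adj, _ = adaptive_fdr(p, m0=p.size)
            np.testing.assert_allclose(adj, false_discovery_control(p, method="bh"))

    def test_rejections_superset_of_bh(self, rng):
        for _ in range(20):
            p = np.concatenate([rng.uniform(0, 0.01, 10), rng.uniform(size=40)])
            adj_a, rej_a = adaptive_fdr(p)
            adj_bh, rej_bh = adaptive_fdr(p, m0=p.size)
            assert np.all(rej_a >= rej_bh)

    def test_adaptive_gains_power_with_strong_signal(self):
        p = np.concatenate([np.full(50, 1e-6), np.linspace(0.02, 0.9, 50)])
        _, rej_a = adaptive_fdr(p, q=0.05)
        _, rej_bh = adaptive_fdr(p, q=0.05, m0=p.size)
        assert rej_a.sum() > rej_bh.sum()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            adaptive_fdr([])
        with pytest.raises(ValueError):
            adaptive_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            adaptive_fdr([0.5], m0=3)


class TestReport:
    def _fit(self, **beta_overrides):
        spec = GeneratorModelSpec(
            beta=default_beta(**beta_overrides), sigma_subject=0, sigma_subject_state=0,
            sigma_resid=0.0, n_subjects=4, n_nodes=6, seed=1,
        )
        table, _ = simulate_dyad_dataset(spec)
        return fit_strength_model(table)

    def test_no_interactions_means_constant_slope(self):
        fit = self._fit(clustering=0.07)
        table, slopes = report_results(fit)
        cl = slopes[slopes["metric"] == "clustering"]
        np.testing.assert_allclose(cl["slope"], 0.07, atol=1e-8)

    def test_positive_three_way_maximizes_abstinent_high_rsa_slope(self):
        fit = self._fit(clustering=0.07, clustering_state_rsa=0.012)
        _, slopes = report_results(fit)
        cl = slopes[slopes["metric"] == "clustering"].set_index(["state", "rsa_level"])
        assert cl.loc[(1, 1.0), "slope"] == cl["slope"].max()

    def test_report_row_count_matches_terms(self):
        fit = self._fit()
        table, slopes = report_results(fit)
        assert len(table) == len(FIXED_EFFECT_TERMS)
        assert len(slopes) == 8  # 2 metrics x 2 states x 2 RSA levels
        assert list(table.columns) == [
            "Effect", "Estimate", "Standard Error", "p-Value", "Adaptive FDR p-Value",
        ]


def test_null_three_way_p_uniform_under_generating_model():
    """When the mixed model is the generating process and the 3-way effect is
    zero, its Wald p-value is uniform (KS test over replicates)."""
    pvals = []
    for rep in range(60):
        spec = GeneratorModelSpec(
            beta=default_beta(intercept=0.234), sigma_subject=0.05,
            sigma_subject_state=0.03, sigma_resid=0.10,
            n_subjects=15, n_nodes=20, seed=7000 + rep,
        )
        table, _ = simulate_dyad_dataset(spec)
        fit = fit_strength_model(table)
        pvals.append(fit.p_values[I3])
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_full_pipeline_null_is_not_anticonservative():
    """Exchangeable drinking states through the full synthetic pipeline
    (region series -> networks -> metrics -> dyads -> fit): the 3-way test
    must not reject above its nominal level. Dyads sharing a node are
    positively dependent in ways the subject-level random effects do not
    capture, which makes the Wald test conservative in this regime — the
    safe direction — so only type-I inflation is ruled out here."""
    pvals = []
    for rep in range(50):
        networks, metrics, cov = small_cohort_inputs(
            n_subjects=8, n_nodes=12, n_timepoints=100, seed=1000 + rep
        )
        table = build_dyad_table(networks, metrics, cov)
        fit = fit_strength_model(table)
        pvals.append(fit.p_values[I3])
    assert float(np.mean(np.asarray(pvals) < 0.05)) <= 0.08
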