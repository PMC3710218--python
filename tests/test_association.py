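"""Regression scans, BH FDR, thresholds, effect-size summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mireqtl import (
    SimulationConfig,
    ValidationError,
    bh_fdr,
    bonferroni_threshold,
    effect_size_summary,
    eqtl_scan,
    linear_assoc,
    mirna_mrna_scan,
    significant_negative,
    simulate_cohort,
    simulate_genotypes,
    simulate_mirnas,
    truncated_negative_normal_sampler,
)
from mireqtl.association import screen_covariates

from conftest import make_expression, make_genotypes


def closed_form_simple_ols(x, y):
    """Textbook simple-regression formulas; the oracle for linear_assoc."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    beta = (xc @ yc) / (xc @ xc)
    resid = yc - beta * xc
    se = np.sqrt(resid @ resid / (n - 2) / (xc @ xc))
    t = beta / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return beta, se, t, p


def bh_double_loop(p):
    """Brute-force BH: q_i = min over j with p_j >= p_i of m p_j / rank_j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    rank = np.empty(m, int)
    rank[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        q[i] = min(min(m * p[j] / rank[j] for j in range(m) if p[j] >= p[i]), 1.0)
    return q


class TestLinearAssoc:
    def test_hand_worked_example(self):
        rec = linear_assoc([0, 0, 1, 1, 2, 2], [0.0, 0.2, 1.0, 1.2, 2.0, 2.2])
        assert rec["beta"] == pytest.approx(1.0, abs=1e-12)
        assert rec["se"] == pytest.approx(np.sqrt(0.00375), abs=1e-12)
        assert rec["n"] == 6

    def test_matches_closed_form_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(5, 30)
            x = rng.integers(0, 3, n).astype(float)
            if np.ptp(x) == 0:
                continue
            y = rng.normal(size=n)
            rec = linear_assoc(x, y)
            beta, se, t, p = closed_form_simple_ols(x, y)
            assert rec["beta"] == pytest.approx(beta, abs=1e-10)
            assert rec["se"] == pytest.approx(se, abs=1e-10)
            assert rec["p"] == pytest.approx(p, rel=1e-8)

    def test_matches_statsmodels_with_covariates(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 40
            x = rng.integers(0, 3, n).astype(float)
            C = rng.normal(size=(n, 2))
            y = 0.5 * x + C @ [1.0, -0.5] + rng.normal(size=n)
            rec = linear_assoc(x, y, covariates=C)
            X = sm.add_constant(np.column_stack([x, C]))
            fit = sm.OLS(y, X).fit()
            assert rec["beta"] == pytest.approx(fit.params[1], abs=1e-10)
            assert rec["se"] == pytest.approx(fit.bse[1], abs=1e-10)
            assert rec["p"] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_perfect_fit_p_clamped(self):
        x = np.array([0.0, 1.0, 2.0, 0.0, 1.0])
        rec = linear_assoc(x, x)
        assert rec["beta"] == pytest.approx(1.0)
        assert 0 < rec["p"] <= np.nextafter(0, 1)

    def test_constant_x_skipped(self):
        rec = linear_assoc([1, 1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0, 5.0])
        assert np.isnan(rec["p"]) and np.isnan(rec["beta"])

    def test_missing_values_complete_case(self):
        x = [0, 1, 2, np.nan, 1, 0, 2, 1]
        y = [0.1, 1.1, 2.0, 5.0, np.nan, -0.1, 2.2, 0.9]
        rec = linear_assoc(x, y)
        assert rec["n"] == 6
        keep = [0, 1, 2, 5, 6, 7]
        beta, _, _, _ = closed_form_simple_ols(np.array(x)[keep], np.array(y)[keep])
        assert rec["beta"] == pytest.approx(beta, abs=1e-12)


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.3], [0.3]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_hand_examples(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-15)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(1e-8, 1.0, rng.integers(1, 60))
            np.testing.assert_allclose(bh_fdr(p), bh_double_loop(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 500)
        q_ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_fdr(p), q_ref, atol=1e-12)

    def test_empty_and_invalid(self):
        assert len(bh_fdr([])) == 0
        with pytest.raises(ValidationError):
            bh_fdr([0.0, 0.5])


class TestMirnaMrnaScan:
    def test_planted_pair_detected(self):
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_samples=79, n_snps=10, n_mirnas=10, n_low_quality_mirnas=0,
                n_mrnas=50, n_planted_eqtls=0, n_planted_regulations=1,
                regulation_beta_sampler=lambda rng, k: np.full(k, -2.0),
                n_hidden_factors=0, noise_sd=0.5, missingness_rate=0.0,
                catalog_size=0, seed=200 + seed,
            )
            c = simulate_cohort(cfg)
            tab = mirna_mrna_scan(c.mirna, c.mrna)
            sig = significant_negative(tab)
            reg = c.truth.planted_regulations.iloc[0]
            hits += ((sig.x_id == reg.mirna_id) & (sig.y_id == reg.mrna_id)).any()
        assert hits == 20

    def test_positive_pair_never_in_negative_set(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(1, 79))
        y = 3.0 * x + rng.normal(0, 0.1, (1, 79))
        tab = mirna_mrna_scan(make_expression(x, "miRNA", "m"),
                              make_expression(y, "mRNA", "g"))
        assert len(significant_negative(tab)) == 0
        assert (tab["beta"] > 0).all()

    def test_family_wide_fdr_flag(self):
        rng = np.random.default_rng(5)
        mirna = make_expression(rng.normal(size=(3, 40)), "miRNA", "m")
        mrna = make_expression(rng.normal(size=(10, 40)), "mRNA", "g")
        tab = mirna_mrna_scan(mirna, mrna, fdr_scope="all")
        assert tab["q"].notna().all()

    def test_matches_linear_assoc_pairwise(self):
        rng = np.random.default_rng(6)
        vals_x = rng.normal(size=(3, 30))
        vals_y = rng.normal(size=(4, 30))
        vals_x[0, :4] = np.nan
        vals_y[2, 5:8] = np.nan
        mirna = make_expression(vals_x, "miRNA", "m")
        mrna = make_expression(vals_y, "mRNA", "g")
        tab = mirna_mrna_scan(mirna, mrna).set_index(["x_id", "y_id"])
        for i, mid in enumerate(mirna.feature_ids):
            for j, gid in enumerate(mrna.feature_ids):
                rec = linear_assoc(vals_x[i], vals_y[j])
                row = tab.loc[(mid, gid)]
                assert row["beta"] == pytest.approx(rec["beta"], abs=1e-10)
                assert row["p"] == pytest.approx(rec["p"], rel=1e-8)
                assert row["n"] == rec["n"]


class TestEqtlScan:
    def test_equals_pairwise_linear_assoc_without_covariates(self):
        cfg = SimulationConfig(n_samples=40, n_snps=15, n_mirnas=4,
                               n_low_quality_mirnas=0, n_planted_eqtls=2,
                               n_hidden_factors=0, missingness_rate=0.1, seed=7)
        g = simulate_genotypes(cfg)
        mirna, _ = simulate_mirnas(g, cfg)
        tab = eqtl_scan(mirna, g).set_index(["x_id", "y_id"])
        E = mirna.values.to_numpy()
        D = g.dosage.to_numpy()
        for i, mid in enumerate(mirna.feature_ids):
            for j, sid in enumerate(g.snp_ids):
                rec = linear_assoc(D[:, j], E[i])
                if np.isnan(rec["p"]):
                    assert (sid, mid) not in tab.index
                    continue
                row = tab.loc[(sid, mid)]
                assert row["beta"] == pytest.approx(rec["beta"], abs=1e-10)
                assert row["p"] == pytest.approx(rec["p"], rel=1e-8)

    def test_planted_eqtl_is_top_hit(self):
        top = 0
        for seed in range(10):
            cfg = SimulationConfig(n_samples=200, n_snps=500, n_mirnas=1,
                                   n_low_quality_mirnas=0, n_planted_eqtls=1,
                                   eqtl_beta_sampler=lambda rng, k: np.ones(k),
                                   n_hidden_factors=0, missingness_rate=0.0,
                                   maf_low=0.3, seed=300 + seed)
            g = simulate_genotypes(cfg)
            mirna, truth = simulate_mirnas(g, cfg)
            tab = eqtl_scan(mirna, g)
            best = tab.loc[tab["p"].idxmin()]
            top += best.x_id == truth.planted_eqtls.iloc[0].snp_id
        assert top >= 9

    def test_null_covariate_screen_rate(self):
        """A covariate with no effect is included for about 5% of traits."""
        rng = np.random.default_rng(8)
        cov = pd.DataFrame({"age": rng.normal(size=79)},
                           index=[f"S{i + 1:03d}" for i in range(79)])
        included = 0
        n_traits = 400
        for _ in range(n_traits):
            y = rng.normal(size=79)
            included += len(screen_covariates(y, cov, 0.05))
        # binomial(400, 0.05): 3.3 sigma band
        assert abs(included / n_traits - 0.05) < 3.3 * np.sqrt(0.05 * 0.95 / n_traits)

    def test_informative_covariate_selected_and_effective(self):
        rng = np.random.default_rng(9)
        n = 100
        sample_ids = [f"S{i + 1:03d}" for i in range(n)]
        age = rng.normal(size=n)
        d = rng.binomial(2, 0.4, (n, 5)).astype(float)
        y = 1.0 * d[:, 0] + 2.0 * age + rng.normal(size=n)
        g = make_genotypes(d)
        g.dosage.index = pd.Index(sample_ids)
        mirna = make_expression(y[None, :], "miRNA", "m")
        mirna.values.columns = pd.Index(sample_ids)
        cov = pd.DataFrame({"age": age}, index=sample_ids)
        tab = eqtl_scan(mirna, g, covariates=cov)
        assert (tab["covariates_used"] == "age").all()
        rec = tab[tab.x_id == "rs1"].iloc[0]
        assert rec["beta"] == pytest.approx(1.0, abs=0.35)

    def test_permuting_phenotype_destroys_signal(self):
        cfg = SimulationConfig(n_samples=150, n_snps=100, n_mirnas=3,
                               n_low_quality_mirnas=0, n_planted_eqtls=3,
                               eqtl_beta_sampler=lambda rng, k: np.full(k, 1.5),
                               n_hidden_factors=0, missingness_rate=0.0,
                               maf_low=0.25, seed=10)
        g = simulate_genotypes(cfg)
        mirna, truth = simulate_mirnas(g, cfg)
        tab = eqtl_scan(mirna, g).set_index(["x_id", "y_id"])
        planted = list(zip(truth.planted_eqtls.snp_id, truth.planted_eqtls.mirna_id))
        assert max(-np.log10(tab.loc[pair, "p"]) for pair in planted) > 10
        rng = np.random.default_rng(0)
        perm = mirna.values.sample(frac=1, axis=1, random_state=1)
        perm.columns = mirna.values.columns
        from mireqtl import ExpressionMatrix
        tab_perm = eqtl_scan(ExpressionMatrix(perm, "miRNA"), g).set_index(["x_id", "y_id"])
        assert max(-np.log10(tab_perm.loc[pair, "p"]) for pair in planted) < 5


class TestThresholdsAndSummaries:
    @pytest.mark.parametrize("alpha, n_snps, n_traits, expected",
                             [(0.05, 1000, 10, 5e-6), (0.05, 1, 1, 0.05)])
    def test_bonferroni(self, alpha, n_snps, n_traits, expected):
        assert bonferroni_threshold(alpha, n_snps, n_traits) == pytest.approx(expected)

    def test_bonferroni_zero_counts(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.05, 0, 10)

    def test_effect_size_summary_basic(self):
        tab = pd.DataFrame({"x_id": "m", "y_id": list("abc"),
                            "beta": [-1.0, -2.0, -3.0], "q": [0.01] * 3})
        s = effect_size_summary(tab)
        assert s.mean == pytest.approx(-2.0)
        assert s.sd == pytest.approx(1.0)
        assert s.n == 3

    def test_effect_size_summary_empty(self):
        tab = pd.DataFrame({"x_id": [], "y_id": [], "beta": [], "q": []})
        s = effect_size_summary(tab)
        assert s.n == 0 and np.isnan(s.mean)

    def test_recovers_truncated_normal_mean(self):
        """Planted regulation betas ~ truncated N(-1.21, 1.05^2): the
        significant-set mean tracks the truncated-normal mean."""
        tn_mean = stats.truncnorm.mean(-np.inf, (0 - (-1.21)) / 1.05,
                                       loc=-1.21, scale=1.05)
        means = []
        for seed in range(10):
            cfg = SimulationConfig(
                n_samples=79, n_snps=10, n_mirnas=20, n_low_quality_mirnas=0,
                n_mrnas=100, n_planted_eqtls=0, n_planted_regulations=60,
                regulation_beta_sampler=truncated_negative_normal_sampler(),
                n_hidden_factors=0, noise_sd=0.2, missingness_rate=0.0,
                catalog_size=0, seed=400 + seed,
            )
            c = simulate_cohort(cfg)
            tab = mirna_mrna_scan(c.mirna, c.mrna)
            s = effect_size_summary(tab)
            if s.n:
                means.append(s.mean)
        assert abs(np.mean(means) - tn_mean) < 0.15
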