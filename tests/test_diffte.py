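"""Normalization, dispersion, NB GLM interaction fit, Wald test, FDR, calls."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from riboprof.diffte import (
    LN2,
    DISPERSION_FLOOR,
    adjust_fdr,
    blunted_induction,
    build_design,
    call_significant,
    estimate_dispersion,
    fit_nbglm,
    run_te_test,
    size_factors,
    wald_test,
)
from riboprof.quantify import CountMatrix
from riboprof.synthetic import SimulationConfig, simulate_counts

from conftest import factorial_count_matrix


def brute_force_bh(p):
    """Textbook step-up, computed directly from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def _simple_cm(counts_dict, assay="FP"):
    genes = list(next(iter(counts_dict.values())).keys()) if False else None
    counts = pd.DataFrame(counts_dict, dtype=float)
    counts.index = [f"g{i}" for i in range(len(counts))]
    counts.index.name = "gene_id"
    samples = pd.DataFrame({"assay": assay}, index=counts.columns)
    return CountMatrix(counts, samples)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        cm = _simple_cm({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(cm), [1.0, 1.0])

    def test_doubled_sample_closed_form(self):
        cm = _simple_cm({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = size_factors(cm)
        assert f["a"] == pytest.approx(0.7071, abs=5e-5)
        assert f["b"] == pytest.approx(1.4142, abs=5e-5)

    def test_single_sample_is_one(self):
        cm = _simple_cm({"a": [10, 20, 30]})
        assert size_factors(cm).tolist() == [1.0]

    def test_no_all_nonzero_gene_is_error(self):
        cm = _simple_cm({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pre-filter"):
            size_factors(cm)

    def test_stratified_by_assay(self):
        counts = pd.DataFrame(
            {"fp1": [10, 20], "fp2": [20, 40], "rna1": [100, 200], "rna2": [100, 200]},
            index=pd.Index(["g0", "g1"], name="gene_id"), dtype=float)
        samples = pd.DataFrame({"assay": ["FP", "FP", "RNA", "RNA"]}, index=counts.columns)
        f = size_factors(CountMatrix(counts, samples), stratify_by="assay")
        assert f["rna1"] == pytest.approx(1.0)
        assert f["fp2"] == pytest.approx(np.sqrt(2), abs=1e-6)


class TestDispersion:
    def _sim(self, alpha, seed=3, n_genes=2000):
        cfg = SimulationConfig(n_genes=n_genes, n_reps=3, dispersion=alpha,
                               include_tm_arm=False, seed=seed)
        cm, _ = simulate_counts(cfg)
        design = build_design(cm.samples, "genotype", "control")
        factors = size_factors(cm)
        return estimate_dispersion(cm, design, factors)

    def test_poisson_data_estimates_near_zero(self):
        assert self._sim(0.0).median() <= 0.01

    def test_alpha_point_one_recovered(self):
        assert 0.07 <= self._sim(0.1).median() <= 0.13

    def test_constant_counts_hit_floor(self):
        cm = factorial_count_matrix(
            {("RNA", "control"): 50, ("RNA", "KO"): 50, ("FP", "control"): 50, ("FP", "KO"): 50},
            n_genes=5)
        design = build_design(cm.samples, "genotype", "control")
        alpha = estimate_dispersion(cm, design, size_factors(cm))
        assert (alpha == DISPERSION_FLOOR).all()


class TestGLM:
    def _fit(self, cm, factors=None):
        design = build_design(cm.samples, "genotype", "control")
        if factors is None:
            factors = size_factors(cm)
        alpha = estimate_dispersion(cm, design, factors)
        return fit_nbglm(cm.counts, design, factors, alpha), design, factors

    def test_saturated_closed_form(self):
        # normalized group means FP/ctrl=100, RNA/ctrl=100, FP/KO=50, RNA/KO=100
        cm = factorial_count_matrix(
            {("RNA", "control"): 100, ("RNA", "KO"): 100,
             ("FP", "control"): 100, ("FP", "KO"): 50},
            n_genes=2, n_background=20)
        fit, design, _ = self._fit(cm)
        j = fit.coef_names.index("interaction")
        assert np.allclose(fit.beta_log2[:2, j], -1.0, atol=1e-6)

    def test_null_identity(self):
        cm = factorial_count_matrix(
            {("RNA", "control"): 80, ("RNA", "KO"): 160,
             ("FP", "control"): 40, ("FP", "KO"): 80},
            n_genes=2, n_background=20, background_mean=80)
        design = build_design(cm.samples, "genotype", "control")
        factors = pd.Series(1.0, index=cm.sample_ids)
        alpha = estimate_dispersion(cm, design, factors)
        fit = fit_nbglm(cm.counts, design, factors, alpha)
        j = fit.coef_names.index("interaction")
        assert np.allclose(fit.beta_log2[:2, j], 0.0, atol=1e-8)

    def test_offset_invariance_on_noise_free_counts(self):
        # depth rescaling of one sample leaves every per-sample residual at
        # zero for noise-free counts, so the MLE is unchanged exactly
        cm = factorial_count_matrix(
            {("RNA", "control"): 100, ("RNA", "KO"): 100,
             ("FP", "control"): 100, ("FP", "KO"): 50},
            n_genes=3, n_background=12)
        design = build_design(cm.samples, "genotype", "control")
        factors = pd.Series(1.0, index=cm.sample_ids)
        alpha = pd.Series(0.05, index=cm.gene_ids)
        fit1 = fit_nbglm(cm.counts, design, factors, alpha)

        c = 3.0
        scaled = cm.counts.copy()
        target = cm.sample_ids[0]
        scaled[target] = scaled[target] * c
        factors2 = factors.copy()
        factors2[target] *= c
        fit2 = fit_nbglm(scaled, design, factors2, alpha)
        assert np.allclose(fit1.beta_log2, fit2.beta_log2, atol=1e-6)

    def test_matches_statsmodels_mle(self):
        """Independent oracle: statsmodels NB GLM with fixed alpha and offsets."""
        rng = np.random.default_rng(17)
        cfg = SimulationConfig(n_genes=20, n_reps=3, dispersion=0.05,
                               include_tm_arm=False, seed=17)
        cm, _ = simulate_counts(cfg)
        design = build_design(cm.samples, "genotype", "control")
        factors = size_factors(cm)
        alpha = pd.Series(0.05, index=cm.gene_ids)
        fit = fit_nbglm(cm.counts, design, factors, alpha)
        X = design.to_numpy()
        offset = np.log(factors[design.index].to_numpy())
        for i, gene in enumerate(cm.gene_ids[:10]):
            y = cm.counts.loc[gene, design.index].to_numpy()
            ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=0.05),
                         offset=offset).fit()
            assert np.allclose(fit.beta_log2[i] * LN2, ref.params, atol=1e-4)
            assert np.allclose(fit.se_log2[i] * LN2, ref.bse, rtol=1e-3)


class TestWald:
    def test_zero_coefficient_gives_p_one(self):
        cm = factorial_count_matrix(
            {("RNA", "control"): 80, ("RNA", "KO"): 80,
             ("FP", "control"): 80, ("FP", "KO"): 80},
            n_genes=3, n_background=10)
        design = build_design(cm.samples, "genotype", "control")
        factors = size_factors(cm)
        alpha = estimate_dispersion(cm, design, factors)
        res = wald_test(fit_nbglm(cm.counts, design, factors, alpha))
        assert np.allclose(res["pvalue"], 1.0)

    def test_w_196_quantile(self):
        from scipy import stats
        assert round(2 * stats.norm.sf(1.96), 4) == 0.0500

    def test_null_calibration_single_run(self):
        cfg = SimulationConfig(n_genes=2000, n_reps=3, dispersion=0.1,
                               include_tm_arm=False, seed=23)
        cm, _ = simulate_counts(cfg)
        res = run_te_test(cm, "ko")
        p = res["pvalue"].dropna()
        assert 0.03 <= (p < 0.05).mean() <= 0.07


class TestFDR:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.04], [0.04]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.1, 0.9], [0.015, 0.15, 0.9]),
        ],
    )
    def test_hand_examples(self, p, expected):
        assert np.allclose(adjust_fdr(np.array(p)), expected)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 60)))
            got = adjust_fdr(p)
            assert np.allclose(got, brute_force_bh(p), atol=1e-12)
            order = np.argsort(p)
            assert (np.diff(got[order]) >= -1e-12).all()

    def test_missing_p_excluded_from_m(self):
        p = np.array([0.01, np.nan, 0.02])
        got = adjust_fdr(p)
        assert np.isnan(got[1])
        assert np.allclose(got[[0, 2]], brute_force_bh([0.01, 0.02]))


class TestCalls:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["log2FC_TE", "padj"],
                            index=[f"g{i}" for i in range(len(rows))])

    def test_down_call_rules(self):
        res = self._results([(-1.2, 0.04), (-0.9, 0.001), (-1.5, 0.2), (1.4, 0.01)])
        assert list(call_significant(res, "down")) == ["g0"]

    def test_up_call_inclusive_boundary(self):
        res = self._results([(1.0, 0.01), (0.99, 0.01), (-1.0, 0.01)])
        assert list(call_significant(res, "up")) == ["g0"]

    def test_empty_input(self):
        res = self._results([])
        assert len(call_significant(res, "down")) == 0

    def test_blunted_induction(self):
        ctrl = self._results([(1.5, 0.01), (1.5, 0.01), (0.3, 0.4), (1.2, 0.04)])
        ko = self._results([(1.4, 0.02), (0.3, 0.4), (1.5, 0.01), (0.9, 0.01)])
        got = blunted_induction(ctrl, ko)
        # g0 induced in both -> excluded; g1 blunted -> in; g2 not induced in ctrl
        # -> excluded; g3 induced in ctrl, below cut in KO -> in
        assert set(got) == {"g1", "g3"}

    def test_gene_set_mismatch_is_error(self):
        ctrl = self._results([(1.5, 0.01)])
        ko = self._results([(1.5, 0.01), (0.0, 0.9)])
        with pytest.raises(ValueError, match="different gene sets"):
            blunted_induction(ctrl, ko)
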