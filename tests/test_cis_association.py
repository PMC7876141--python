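import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svgex.breakpoint_matrices import (
    WindowSpec,
    build_distance_matrix,
    build_presence_matrix,
)
from svgex.cis_association import (
    ModelSpec,
    fit_gene_model,
    permutation_fdr,
    run_association,
    sd_from_median,
    storey_fdr,
    subgroup_breakpoint_enrichment,
)
from svgex.io_formats import TumorMeta

from conftest import make_gene, make_ssv


def ols_oracle(y, X):
    """Independent normal-equations OLS with t-test on the last column."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = (resid @ resid) / df
    cov = s2 * np.linalg.inv(XtX)
    t = beta[-1] / np.sqrt(cov[-1, -1])
    return beta[-1], 2 * stats.t.sf(abs(t), df)


class TestFitGeneModel:
    def test_separated_groups_zero_noise(self):
        y = np.array([6.0] * 5 + [4.0] * 5)
        p = np.array([1.0] * 5 + [0.0] * 5)
        fit = fit_gene_model(y, p, spec=ModelSpec(covariates=()))
        assert np.isclose(fit.coefficient, 2.0)
        assert fit.p_value == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictor_gives_reason(self):
        rng = np.random.default_rng(0)
        fit = fit_gene_model(rng.normal(size=10), np.ones(10), spec=ModelSpec(covariates=()))
        assert not fit.ok
        assert fit.reason == "constant_predictor"

    def test_predictor_confounded_with_type_level(self):
        types = ["A"] * 5 + ["B"] * 5
        p = np.array([1.0] * 5 + [0.0] * 5)  # identical to the A indicator
        rng = np.random.default_rng(1)
        fit = fit_gene_model(rng.normal(size=10), p, types=types,
                             spec=ModelSpec(covariates=("tumor_type",)))
        assert fit.reason == "collinear_predictor"

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(7)
        n, reps = 200, 1000
        pvals = np.empty(reps)
        for i in range(reps):
            y = rng.normal(size=n)
            p = rng.normal(size=n)
            pvals[i] = fit_gene_model(y, p, spec=ModelSpec(covariates=())).p_value
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = 40
        types = list(rng.choice(["A", "B", "C"], size=n))
        cna = rng.integers(-2, 3, size=n).astype(float)
        p = rng.normal(size=n) if seed % 2 else (rng.random(n) < 0.3).astype(float)
        if np.allclose(p, p[0]):
            p[0] += 1.0
        y = rng.normal(size=n) + 0.5 * p
        fit = fit_gene_model(y, p, types=types, cna_row=cna, spec=ModelSpec())
        levels = sorted(set(types))
        dummies = np.column_stack(
            [[1.0 if t == lev else 0.0 for t in types] for lev in levels[1:]]
        )
        X = np.column_stack([np.ones(n), dummies, cna, p])
        beta, pv = ols_oracle(y, X)
        assert np.isclose(fit.coefficient, beta, atol=1e-8)
        assert np.isclose(fit.p_value, pv, atol=1e-8)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 50
        p = rng.normal(size=n)
        cna = rng.integers(-2, 3, size=n).astype(float)
        y = rng.normal(size=n) + 0.3 * p + 0.2 * cna
        fit = fit_gene_model(y, p, cna_row=cna, spec=ModelSpec(covariates=("cna",)))
        X = sm.add_constant(np.column_stack([cna, p]))
        res = sm.OLS(y, X).fit()
        assert np.isclose(fit.coefficient, res.params[-1], atol=1e-10)
        assert np.isclose(fit.p_value, res.pvalues[-1], atol=1e-10)


class TestStoreyFdr:
    def test_printed_formula_example(self):
        # 1000 genes; 50 have p <= 0.01 -> q(0.01) = 0.01 * 1000 / 50 = 0.2
        p = np.concatenate([np.full(50, 0.01), np.linspace(0.5, 1.0, 950)])
        q = storey_fdr(p)
        assert np.allclose(q[:50], 0.2)

    def test_all_ones(self):
        assert np.allclose(storey_fdr(np.ones(10)), 1.0)

    def test_single_p(self):
        assert storey_fdr([0.5])[0] == pytest.approx(0.5)

    def test_empty(self):
        assert storey_fdr([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            storey_fdr([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(200)
        q = storey_fdr(p)
        for i in rng.integers(0, 200, size=20):
            expected = min(1.0, p[i] * len(p) / np.sum(p <= p[i]))
            assert np.isclose(q[i], expected)


def _toy_cohort(seed=0, n_tumors=40, n_genes=12, planted_gene=0, carriers=10, shift=1.5):
    """Expression cohort with one planted breakpoint-linked gene."""
    rng = np.random.default_rng(seed)
    tumors = [f"T{i}" for i in range(n_tumors)]
    meta = [
        TumorMeta(t, f"P{i}", "typeA" if i % 2 else "typeB", "initial")
        for i, t in enumerate(tumors)
    ]
    genes = [make_gene(f"G{i}", start=2_000_000 * (i + 1), end=2_000_000 * (i + 1) + 50_000)
             for i in range(n_genes)]
    ssvs = []
    carrier_ids = tumors[:carriers]
    for j, t in enumerate(carrier_ids):
        g = genes[planted_gene]
        ssvs.append(make_ssv(f"S{j}", pos1=g.start + 10, pos2=g.start + 5_000, tumor_id=t))
    z = rng.normal(8.0, 1.0, size=(n_genes, n_tumors))
    for t in carrier_ids:
        z[planted_gene, tumors.index(t)] += shift
    expr = pd.DataFrame(np.power(2.0, z) - 1, index=[g.gene_id for g in genes], columns=tumors)
    cna = pd.DataFrame(0, index=expr.index, columns=tumors)
    return expr, genes, ssvs, meta, cna, tumors


class TestRunAssociation:
    def test_planted_gene_ranks_first_with_positive_direction(self):
        expr, genes, ssvs, meta, cna, tumors = _toy_cohort()
        dm = build_distance_matrix(ssvs, genes, tumors)
        table = run_association(expr, dm, meta, cna, ModelSpec())
        assert table.iloc[0]["gene_id"] == "G0"
        assert table.iloc[0]["direction"] == "positive"
        assert table.iloc[0]["n_ssv_tumors"] >= 10

    def test_no_ssvs_gives_empty_table_with_warning(self):
        expr, genes, _, meta, cna, tumors = _toy_cohort()
        dm = build_distance_matrix([], genes, tumors)
        with pytest.warns(UserWarning, match="no genes pass"):
            table = run_association(expr, dm, meta, cna, ModelSpec())
        assert table.empty

    def test_min_tumors_filter_excludes_sparse_genes(self):
        expr, genes, ssvs, meta, cna, tumors = _toy_cohort(carriers=2)
        dm = build_distance_matrix(ssvs, genes, tumors)
        with pytest.warns(UserWarning):
            table = run_association(expr, dm, meta, cna, ModelSpec(min_tumors=3))
        assert "G0" not in set(table.get("gene_id", []))

    def test_permuting_carrier_labels_destroys_significance(self):
        expr, genes, ssvs, meta, cna, tumors = _toy_cohort(shift=2.5)
        dm = build_distance_matrix(ssvs, genes, tumors)
        obs = run_association(expr, dm, meta, cna, ModelSpec())
        obs_p = obs.set_index("gene_id").loc["G0", "p_value"]
        assert obs_p < 1e-4
        rng = np.random.default_rng(11)
        worse = 0
        n_shuffle = 40
        for _ in range(n_shuffle):
            perm = rng.permutation(len(tumors))
            shuffled = expr.copy()
            shuffled.columns = [tumors[i] for i in perm]
            shuffled = shuffled[tumors]
            tab = run_association(shuffled, dm, meta, cna, ModelSpec())
            worse += tab.set_index("gene_id").loc["G0", "p_value"] > 0.05
        assert worse >= int(0.95 * n_shuffle)


class TestPermutationFdr:
    def test_zero_permutations_rejected(self):
        expr, genes, ssvs, meta, cna, tumors = _toy_cohort()
        dm = build_distance_matrix(ssvs, genes, tumors)
        with pytest.raises(ValueError):
            permutation_fdr(expr, dm, meta, cna, ModelSpec(), 0.05, n_perm=0, seed=1)

    def test_planted_effect_low_estimated_fdr(self):
        expr, genes, ssvs, meta, cna, tumors = _toy_cohort(shift=3.0)
        dm = build_distance_matrix(ssvs, genes, tumors)
        result = permutation_fdr(
            expr, dm, meta, cna, ModelSpec(), threshold=1e-4, n_perm=100, seed=2
        )
        assert result.observed_count >= 1
        assert result.estimated_fdr < 0.5


class TestSubgroupEnrichment:
    def _presence(self, data, tumors):
        df = pd.DataFrame(data, index=["G1"], columns=tumors)
        from svgex.breakpoint_matrices import BreakpointPresenceMatrix

        return BreakpointPresenceMatrix(df, WindowSpec("upstream", 100_000))

    def test_strong_enrichment(self):
        a = [f"A{i}" for i in range(10)]
        b = [f"B{i}" for i in range(90)]
        presence = self._presence([[1] * 5 + [0] * 5 + [0] * 90], a + b)
        table = subgroup_breakpoint_enrichment(presence, a, b)
        assert table.iloc[0]["p_value"] < 1e-4
        # exact hypergeometric oracle
        expected = stats.hypergeom.sf(4, 100, 5, 10)
        assert np.isclose(table.iloc[0]["p_value"], expected)

    def test_equal_frequencies_not_significant(self):
        a = [f"A{i}" for i in range(10)]
        b = [f"B{i}" for i in range(10)]
        presence = self._presence([[1] * 5 + [0] * 5 + [1] * 5 + [0] * 5], a + b)
        table = subgroup_breakpoint_enrichment(presence, a, b)
        assert table.iloc[0]["p_value"] >= 0.5

    def test_zero_breakpoints_p_one(self):
        a, b = ["A1", "A2"], ["B1", "B2"]
        presence = self._presence([[0, 0, 0, 0]], a + b)
        table = subgroup_breakpoint_enrichment(presence, a, b)
        assert table.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        presence = self._presence([[1, 0]], ["A1", "B1"])
        with pytest.raises(ValueError):
            subgroup_breakpoint_enrichment(presence, [], ["A1", "B1"])


class TestSdFromMedian:
    def test_centering_and_scaling(self):
        expr = pd.DataFrame(
            {"T1": [1.0, 5.0], "T2": [2.0, 5.0], "T3": [3.0, 5.0]}, index=["G1", "G2"]
        )
        scores = sd_from_median(expr)
        assert scores.loc["G1", "T2"] == pytest.approx(0.0)
        assert scores.loc["G1", "T3"] == pytest.approx(1.0)
        assert scores.loc["G2"].isna().all()  # zero-SD gene flagged as NaN
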