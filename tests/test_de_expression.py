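"""Differential expression: fold change, shrinkage, moderated t, BH, selection."""

import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from varfunnel.de_expression import (
    ShrinkageParams,
    benjamini_hochberg,
    fit_shrinkage,
    fold_change,
    moderated_t,
    select_de,
)
from varfunnel.io_formats import ExpressionMatrix, ValidationError
from varfunnel.synthetic_data import SimulationConfig, simulate_expression

# published microarray group means (log2) and the fold changes they imply,
# restricted to rows where the printed means reconcile with the printed FC
PRINTED_ROWS = [
    ("NR1D1", 8.31, 6.45, 3.63, "up"),
    ("SMARCA4", 14.07, 12.12, 3.86, "up"),
    ("CAMK2G", 6.80, 8.01, 2.31, "down"),
    ("LEF1", 7.64, 6.29, 2.55, "up"),
    ("ARL11", 3.11, 2.07, 2.06, "up"),
]


def two_group_matrix(case: np.ndarray, ctrl: np.ndarray, genes=None) -> ExpressionMatrix:
    case, ctrl = np.atleast_2d(case), np.atleast_2d(ctrl)
    n = case.shape[0]
    return ExpressionMatrix(
        gene_ids=genes or [f"G{i}" for i in range(n)],
        sample_ids=[f"S{i}" for i in range(case.shape[1] + ctrl.shape[1])],
        group_labels=["case"] * case.shape[1] + ["control"] * ctrl.shape[1],
        values=np.hstack([case, ctrl]),
    )


class TestFoldChange:
    @pytest.mark.parametrize("gene, m_case, m_ctrl, fc, direction", PRINTED_ROWS)
    def test_printed_group_means_reproduce_fc(self, gene, m_case, m_ctrl, fc, direction):
        got_fc, got_dir = fold_change(m_case, m_ctrl)
        assert round(got_fc, 2) == fc
        assert got_dir == direction

    def test_tie_is_up(self):
        assert fold_change(5.0, 5.0) == (1.0, "up")

    @given(
        a=st.floats(-20, 20, allow_nan=False),
        b=st.floats(-20, 20, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=50)
    def test_antisymmetry(self, a, b):
        fc_ab, dir_ab = fold_change(a, b)
        fc_ba, dir_ba = fold_change(b, a)
        assert fc_ab == pytest.approx(fc_ba)
        if a != b:
            assert {dir_ab, dir_ba} == {"up", "down"}


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_step_up_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_direct_step_up_formula(self, rng):
        """Cross-check against the textbook cumulative-minimum step-up."""
        p = rng.uniform(1e-6, 1, size=200)
        order = np.argsort(p)
        n = len(p)
        stepped = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(benjamini_hochberg(list(p)), expected, rtol=1e-12)

    def test_monotone_in_rank(self, rng):
        p = rng.uniform(1e-9, 1, size=100)
        adj = benjamini_hochberg(list(p))
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-15)

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            benjamini_hochberg(bad)


class TestModeratedT:
    def test_identical_groups_give_null(self):
        x = np.array([[1.0, 2.0, 3.0]])
        recs = moderated_t(two_group_matrix(x, x))
        assert recs[0].t_stat == 0.0
        assert recs[0].p_raw == 1.0

    def test_unshrunk_equals_textbook_pooled_t(self, rng):
        """With shrinkage off, reduces to the ordinary pooled two-sample t."""
        n1, n0, g = 3, 4, 50
        case = rng.normal(size=(g, n1))
        ctrl = rng.normal(size=(g, n0))
        recs = moderated_t(two_group_matrix(case, ctrl), shrink=None)
        for i, rec in enumerate(recs):
            t_ref, p_ref = stats.ttest_ind(case[i], ctrl[i], equal_var=True)
            assert rec.t_stat == pytest.approx(t_ref, abs=1e-12)
            assert rec.p_raw == pytest.approx(p_ref, abs=1e-12)

    def test_hand_computed_pooled_t(self):
        case = np.array([[4.0, 5.0, 6.0]])
        ctrl = np.array([[1.0, 2.0, 3.0]])
        # delta 3, pooled var 1, se = sqrt(1*(1/3+1/3))
        recs = moderated_t(two_group_matrix(case, ctrl), shrink=None)
        assert recs[0].t_stat == pytest.approx(3.0 / math.sqrt(2.0 / 3.0), abs=1e-12)

    def test_large_prior_df_limit(self, rng):
        s0_sq = 0.5
        case = rng.normal(size=(20, 5))
        ctrl = rng.normal(size=(20, 5))
        m = two_group_matrix(case, ctrl)
        recs = moderated_t(m, ShrinkageParams(d0=1e12, s0_sq=s0_sq))
        for i, rec in enumerate(recs):
            expected = (case[i].mean() - ctrl[i].mean()) / math.sqrt(s0_sq * (2 / 5))
            assert rec.t_stat == pytest.approx(expected, rel=1e-6)

    def test_zero_variance_limit_convention(self):
        case = np.array([[2.0, 2.0, 2.0]])
        ctrl = np.array([[1.0, 1.0, 1.0]])
        rec = moderated_t(two_group_matrix(case, ctrl), shrink=None)[0]
        assert rec.degenerate
        assert math.isinf(rec.t_stat) and rec.p_raw == 0.0
        same = moderated_t(two_group_matrix(case, case), shrink=None)[0]
        assert same.degenerate and same.p_raw == 1.0


class TestFitShrinkage:
    def test_parameter_recovery(self):
        """Recover (d0, s0^2) from 5,000 scaled inverse-chi-square variances."""
        rng = np.random.default_rng(42)
        d0_true, s0_true, dg, n = 6.0, 0.09, 18, 5000
        true_var = d0_true * s0_true / rng.chisquare(d0_true, n)
        sample_var = true_var * rng.chisquare(dg, n) / dg
        fit = fit_shrinkage(sample_var, dg)
        assert fit.d0 == pytest.approx(d0_true, rel=0.20)
        assert fit.s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_identical_variances_give_infinite_prior_df(self):
        fit = fit_shrinkage(np.full(100, 0.25), 10)
        assert math.isinf(fit.d0)
        assert fit.s0_sq > 0

    def test_too_few_genes(self):
        with pytest.raises(ValidationError, match="10"):
            fit_shrinkage(np.array([0.1] * 5), 4)

    def test_all_zero_variances(self):
        with pytest.raises(ValidationError, match="zero"):
            fit_shrinkage(np.zeros(100), 4)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_moderated_t_matches_limma(tmp_path, rng):
    """Cross-check the empirical-Bayes machinery against limma's eBayes."""
    g, n1, n0 = 80, 5, 5
    sigma = np.sqrt(4 * 0.05 / rng.chisquare(4, g))
    values = rng.normal(size=(g, n1 + n0)) * sigma[:, None]
    values[: g // 4, :n1] += 1.0
    np.savetxt(tmp_path / "m.tsv", values, delimiter="\t")
    rcode = f"""
    suppressMessages(library(limma))
    x <- as.matrix(read.delim("{tmp_path}/m.tsv", header=FALSE))
    design <- cbind(1, c(rep(1, {n1}), rep(0, {n0})))
    fit <- eBayes(lmFit(x, design))
    out <- cbind(fit$df.prior, fit$s2.prior, fit$t[,2], fit$p.value[,2])
    write.table(out, "{tmp_path}/limma.tsv", sep="\t", row.names=FALSE, col.names=FALSE)
    """
    subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True, timeout=300)
    ref = np.loadtxt(tmp_path / "limma.tsv")
    d0_ref, s0_ref = ref[0, 0], ref[0, 1]

    matrix = two_group_matrix(values[:, :n1], values[:, n1:])
    pooled = (
        (n1 - 1) * values[:, :n1].var(axis=1, ddof=1)
        + (n0 - 1) * values[:, n1:].var(axis=1, ddof=1)
    ) / (n1 + n0 - 2)
    fit = fit_shrinkage(pooled, n1 + n0 - 2)
    assert fit.d0 == pytest.approx(d0_ref, rel=0.02)
    assert fit.s0_sq == pytest.approx(s0_ref, rel=0.02)

    # with limma's own prior plugged in, the statistics must agree exactly
    recs = moderated_t(matrix, ShrinkageParams(d0=float(d0_ref), s0_sq=float(s0_ref)))
    np.testing.assert_allclose([r.t_stat for r in recs], ref[:, 2], rtol=1e-8)
    np.testing.assert_allclose([r.p_raw for r in recs], ref[:, 3], rtol=1e-8)


class TestSelectDe:
    def _rec(self, fc, p):
        from varfunnel.de_expression import DERecord

        return DERecord("g", 0, 0, 0, 0, 0, 1, p, p, fc, "up")

    def test_boundaries_inclusive(self):
        assert select_de([self._rec(2.0, 0.05)]) == ["g"]
        assert select_de([self._rec(1.99, 0.001)]) == []

    def test_monotone_in_thresholds(self, rng):
        recs = [self._rec(fc, p) for fc, p in zip(rng.uniform(1, 4, 50), rng.uniform(0.001, 1, 50))]
        base = set(select_de(recs))
        assert set(select_de(recs, fc_min=2.5)) <= base
        assert set(select_de(recs, p_max=0.01)) <= base

    def test_planted_de_genes_recovered_exactly(self):
        """Study-scale fixture: the 923 planted genes of 20,000, no extras."""
        cfg = SimulationConfig(seed=3)
        matrix, truth = simulate_expression(cfg)
        n1 = cfg.n_case_samples
        pooled = (
            (n1 - 1) * matrix.values[:, :n1].var(axis=1, ddof=1)
            + (cfg.n_control_samples - 1) * matrix.values[:, n1:].var(axis=1, ddof=1)
        ) / (n1 + cfg.n_control_samples - 2)
        shrink = fit_shrinkage(pooled, n1 + cfg.n_control_samples - 2)
        selected = set(select_de(moderated_t(matrix, shrink)))
        planted = set(truth.loc[truth.is_de, "gene_id"])
        assert len(planted) == 923
        assert selected == planted


def test_printed_de_table_emits_all_rows():
    """A matrix built from the 18 printed group means yields 18 selected genes."""
    genes, case_cols, ctrl_cols = [], [], []
    printed = PRINTED_ROWS + [
        ("AFF1", 9.95, 8.84, 2.17, "up"),
        ("ALDH1L1", 6.03, 7.23, 2.29, "down"),
        ("BATF", 10.52, 8.94, 2.99, "up"),
        ("CD86", 14.38, 11.30, 8.48, "up"),
        ("DOCK10", 8.71, 10.01, 2.47, "down"),
        ("IL20RA", 7.57, 5.97, 3.00, "up"),
        ("KCNIP1", 3.84, 2.65, 2.28, "up"),
        ("LINC01108", 2.09, 3.17, 2.12, "down"),
        ("LOC100130476", 3.33, 2.16, 2.24, "up"),
        ("TEF", 9.02, 7.76, 2.40, "up"),
        ("TMEM130", 6.73, 7.94, 2.32, "down"),
        ("TMEM47", 9.60, 10.70, 2.21, "down"),
        ("TTC28", 8.72, 7.52, 2.30, "up"),
    ]
    d = 0.05  # small symmetric spread keeps group means exact
    for gene, m1, m0, _fc, _dir in printed:
        genes.append(gene)
        case_cols.append([m1 - d, m1 + d, m1 - d, m1 + d])
        ctrl_cols.append([m0 - d, m0 + d, m0 - d, m0 + d])
    matrix = two_group_matrix(np.array(case_cols), np.array(ctrl_cols), genes=genes)
    recs = moderated_t(matrix, shrink=None)
    assert len(select_de(recs)) == 18
    by_gene = {r.gene_id: r for r in recs}
    for gene, m1, m0, fc, direction in printed:
        assert by_gene[gene].mean_case == pytest.approx(m1, abs=1e-12)
        assert by_gene[gene].direction == direction
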