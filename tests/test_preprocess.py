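"""Normalization, moderated t, BH correction, DEG selection, discretization."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from congems import preprocess as pp


def two_group(values, n_case):
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(len(values))],
        columns=[f"s{j}" for j in range(len(values[0]))],
    )
    groups = pd.Series(
        ["case"] * n_case + ["control"] * (df.shape[1] - n_case), index=df.columns
    )
    return df, groups


class TestZeroMeanNormalize:
    def test_hand_example(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        out = pp.zero_mean_normalize(df)
        assert np.allclose(out.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_idempotent_on_standardized_row(self):
        df = pd.DataFrame([[-1.0, 0.0, 1.0]], index=["g"], columns=list("abc"))
        pd.testing.assert_frame_equal(pp.zero_mean_normalize(df), df)

    def test_constant_row_raises_with_gene_name(self):
        df = pd.DataFrame([[5.0, 5.0, 5.0]], index=["flat"], columns=list("abc"))
        with pytest.raises(ValueError, match="flat"):
            pp.zero_mean_normalize(df)


class TestModeratedT:
    def test_equal_group_means_give_zero_t_unit_p(self):
        df, groups = two_group([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], n_case=3)
        rec = pp.moderated_t_test(df, groups)[0]
        assert rec.t_moderated == pytest.approx(0.0)
        assert rec.p == pytest.approx(1.0)

    def test_shrinkage_disabled_equals_pooled_t(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 9))
        df, groups = two_group(x, n_case=4)
        records = pp.moderated_t_test(df, groups, shrink=False)
        ref = stats.ttest_ind(x[:, :4], x[:, 4:], axis=1, equal_var=True)
        assert np.allclose(
            [r.t_moderated for r in records], ref.statistic, atol=1e-10
        )
        assert np.allclose([r.p for r in records], ref.pvalue, atol=1e-10)

    def test_hand_pooled_example(self):
        df, groups = two_group([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], n_case=3)
        rec = pp.moderated_t_test(df, groups, shrink=False)[0]
        assert rec.t_moderated == pytest.approx(-3.674234614, abs=1e-6)

    def test_identical_variances_trigger_full_shrinkage(self):
        # Every gene is a permutation of the same values: identical s_g^2.
        base = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        x = np.stack([np.roll(base, i % 3) for i in range(12)])
        df, groups = two_group(x, n_case=3)
        records = pp.moderated_t_test(df, groups)
        assert all(np.isfinite(r.p) for r in records)

    def test_small_group_rejected(self):
        df, groups = two_group([[1.0, 2.0, 3.0]], n_case=1)
        with pytest.raises(ValueError, match="at least 2"):
            pp.moderated_t_test(df, groups)

    def test_matches_limma_reference(self, tmp_path):
        """Cross-check the empirical-Bayes fit against Bioconductor limma."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; cannot run the limma cross-check")
        rng = np.random.default_rng(11)
        n_genes, n1, n2 = 120, 5, 6
        sd = np.exp(rng.normal(0, 0.8, n_genes))
        x = rng.normal(0, 1, (n_genes, n1 + n2)) * sd[:, None]
        x[:15, :n1] += 2.0 * sd[:15, None]
        df, groups = two_group(x, n_case=n1)
        df.to_csv(tmp_path / "expr.tsv", sep="\t")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{tmp_path}/expr.tsv", row.names=1))
            design <- cbind(Intercept=1, case=c(rep(1,{n1}), rep(0,{n2})))
            fit <- eBayes(lmFit(x, design))
            write.csv(data.frame(t=fit$t[,"case"], p=fit$p.value[,"case"]),
                      "{tmp_path}/ref.csv")
            """
        )
        (tmp_path / "ref.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "ref.R")], check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "ref.csv", index_col=0)
        records = pp.moderated_t_test(df, groups)
        assert np.allclose(
            [r.t_moderated for r in records], ref["t"].to_numpy(), atol=1e-8
        )
        assert np.allclose([r.p for r in records], ref["p"].to_numpy(), atol=1e-8)


class TestBhFdr:
    def test_hand_example(self):
        assert np.allclose(
            pp.bh_fdr([0.01, 0.02, 0.04, 0.05]), [0.04, 0.04, 0.05, 0.05]
        )

    def test_single_p_unchanged(self):
        assert pp.bh_fdr([0.3]) == pytest.approx([0.3])

    def test_all_equal_unchanged(self):
        assert np.allclose(pp.bh_fdr([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pp.bh_fdr([0.1, 1.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(max_examples=50, derandomize=True)
    def test_correction_never_decreases_p(self, pvals):
        q = pp.bh_fdr(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(pvals)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestSelectDegs:
    @staticmethod
    def rec(gene, p=0.001, fdr=0.01, fc=1.5):
        return pp.DEStatRecord(
            gene_id=gene, t_moderated=0.0, p=p, fdr=fdr, fold_change=fc,
            direction="up" if fc >= 1 else "down",
        )

    def test_fold_change_gate(self):
        kept = pp.select_degs([self.rec("a", fc=1.5), self.rec("b", fc=1.0)])
        assert [r.gene_id for r in kept] == ["a"]
        assert kept[0].direction == "up"

    def test_down_regulated_kept(self):
        kept = pp.select_degs([self.rec("a", fc=0.5)])
        assert kept[0].direction == "down"

    def test_probe_collapse_prefers_lowest_raw_p(self):
        records = [
            self.rec("probe1", p=0.01, fc=1.5),
            self.rec("probe2", p=0.001, fc=0.5),
        ]
        kept = pp.select_degs(
            records, probe_to_gene={"probe1": "G", "probe2": "G"}
        )
        assert len(kept) == 1
        assert kept[0].gene_id == "G"
        assert kept[0].fold_change == 0.5

    def test_empty_result_raises(self):
        with pytest.raises(ValueError, match="no DEGs"):
            pp.select_degs([self.rec("a", fdr=0.9)])


class TestRankAndWeight:
    def test_weights_for_four_genes(self):
        degs = [
            pp.DEStatRecord(f"g{i}", 0.0, p=0.01 * (i + 1), fdr=0.01 * (i + 1))
            for i in range(4)
        ]
        table = pp.rank_and_weight(degs).table
        assert list(table["rank"]) == [1, 2, 3, 4]
        assert np.allclose(table["weight"], [1.0, 0.75, 0.5, 0.25])

    def test_endpoint_weights(self):
        degs = [
            pp.DEStatRecord(f"g{i}", 0.0, p=0.001 * (i + 1), fdr=0.001 * (i + 1))
            for i in range(7)
        ]
        table = pp.rank_and_weight(degs)
        weights = table.table["weight"].to_numpy()
        assert weights[0] == 1.0
        assert weights[-1] == pytest.approx(1 / 7)
        assert np.allclose(np.diff(weights), -1 / 7)

    def test_fdr_ties_broken_by_raw_p(self):
        degs = [
            pp.DEStatRecord("late", 0.0, p=0.02, fdr=0.05),
            pp.DEStatRecord("early", 0.0, p=0.01, fdr=0.05),
        ]
        table = pp.rank_and_weight(degs).table
        assert list(table["gene"]) == ["early", "late"]


class TestDiscretization:
    def test_sign_rule_with_zero_mapped_up(self):
        df = pd.DataFrame(
            [[0.5, -0.3, 0.0]], index=["s1"], columns=["g1", "g2", "g3"]
        )
        di = pp.discretize(df)
        assert di.to_numpy().tolist() == [[True, False, True]]

    def test_non_finite_rejected(self):
        df = pd.DataFrame([[np.nan]], index=["s"], columns=["g"])
        with pytest.raises(ValueError, match="non-finite"):
            pp.discretize(df)

    def test_post_discretize_rows(self):
        di = pd.DataFrame(
            [[True, False], [True, True]], index=["s1", "s2"], columns=["g1", "g2"]
        )
        pdi = pp.post_discretize(di)
        assert list(pdi.columns) == ["g1+", "g2+", "g1-", "g2-"]
        assert pdi.loc["s1"].tolist() == [True, False, False, True]
        assert pdi.loc["s2"].tolist() == [True, True, False, False]

    def test_shape_doubles(self):
        di = pd.DataFrame(np.ones((5, 3), dtype=bool))
        assert pp.post_discretize(di).shape == (5, 6)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, derandomize=True)
    def test_signed_columns_are_complementary(self, seed):
        rng = np.random.default_rng(seed)
        di = pd.DataFrame(
            rng.random((6, 4)) < 0.5, columns=[f"g{i}" for i in range(4)]
        )
        pdi = pp.post_discretize(di)
        up = pdi.iloc[:, :4].to_numpy()
        down = pdi.iloc[:, 4:].to_numpy()
        assert np.all(up ^ down)
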