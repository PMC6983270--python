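import numpy as np
import pandas as pd
import pytest
from scipy import stats

from decondoublet.calls import (
    DoubletCalls,
    chunked_anova,
    recluster_step,
    remove_step,
    rescue_step,
    unique_genes,
)
from decondoublet.io_formats import AnnotatedExpression


def _dcp_frame(rows, refs):
    return pd.DataFrame(rows).T.set_axis(refs, axis=1)


def _setup_n2(cell_rows):
    cells = [f"c{i}" for i in range(len(cell_rows))]
    cell_dcps = pd.DataFrame(cell_rows, index=cells, columns=[1, 2])
    ref_dcps = pd.DataFrame(
        [[0.95, 0.05], [0.05, 0.95]], index=[1, 2], columns=[1, 2]
    )
    synth = pd.DataFrame(
        [[0.5, 0.5], [0.7, 0.3], [0.3, 0.7]],
        index=["1|2.even", "1|2.one", "1|2.two"], columns=[1, 2],
    )
    clusters = pd.Series([1] * len(cells), index=cells)
    return cell_dcps, ref_dcps, synth, clusters


class TestRemoveStep:
    def test_cell_matching_reference_centroid_is_singlet(self):
        cell_dcps, ref_dcps, synth, clusters = _setup_n2([[0.95, 0.05]])
        calls = remove_step(cell_dcps, ref_dcps, synth, clusters)
        row = calls.table.iloc[0]
        assert row["state"] == "singlet"
        assert row["best_match"] == "1"

    def test_cell_matching_even_synthetic_is_putative_doublet(self):
        """Cell DCP [0.5,0.5]: Euclidean distances 0.636/0.636 to the
        references and 0 to the even synthetic mean -> putative doublet."""
        cell_dcps, ref_dcps, synth, clusters = _setup_n2([[0.5, 0.5]])
        calls = remove_step(cell_dcps, ref_dcps, synth, clusters)
        row = calls.table.iloc[0]
        assert row["state"] == "putative_doublet"
        assert row["best_match"] == "1|2.even"
        assert row["similarity"] == pytest.approx(0.0, abs=1e-12)
        # hand distances to the references
        assert np.sqrt(2 * 0.45 ** 2) == pytest.approx(0.6364, abs=1e-4)

    def test_exact_tie_resolves_to_singlet(self):
        cell_dcps = pd.DataFrame([[0.5, 0.5]], index=["c0"], columns=[1, 2])
        ref_dcps = pd.DataFrame([[0.5, 0.5]], index=[1], columns=[1, 2])
        synth = pd.DataFrame([[0.5, 0.5]], index=["1|2.even"], columns=[1, 2])
        calls = remove_step(
            cell_dcps, ref_dcps, synth, pd.Series([1], index=["c0"])
        )
        assert calls.table.iloc[0]["state"] == "singlet"

    def test_pearson_used_above_two_references(self):
        refs = [1, 2, 3]
        cell_dcps = pd.DataFrame([[0.1, 0.6, 0.3]], index=["c0"], columns=refs)
        ref_dcps = pd.DataFrame(np.eye(3) * 0.9 + 0.05, index=refs, columns=refs)
        synth = pd.DataFrame(
            [[0.1, 0.6, 0.3]], index=["2|3.even"], columns=refs
        )
        calls = remove_step(
            cell_dcps, ref_dcps, synth, pd.Series([2], index=["c0"])
        )
        row = calls.table.iloc[0]
        assert row["state"] == "putative_doublet"
        assert row["similarity"] == pytest.approx(1.0)

    def test_constant_dcp_with_pearson_warns(self):
        refs = [1, 2, 3]
        cell_dcps = pd.DataFrame(
            [[1 / 3, 1 / 3, 1 / 3]], index=["c0"], columns=refs
        )
        ref_dcps = pd.DataFrame(np.eye(3), index=refs, columns=refs)
        synth = pd.DataFrame([[0.5, 0.5, 0.0]], index=["1|2.even"], columns=refs)
        with pytest.warns(UserWarning, match="constant DCP"):
            calls = remove_step(
                cell_dcps, ref_dcps, synth, pd.Series([1], index=["c0"])
            )
        assert calls.table.iloc[0]["state"] == "singlet"


class TestReclusterStep:
    @staticmethod
    def _calls_for(dcp_rows, best_matches, refs=(1, 2, 3)):
        cells = [f"c{i}" for i in range(len(dcp_rows))]
        cell_dcps = pd.DataFrame(dcp_rows, index=cells, columns=list(refs))
        table = pd.DataFrame(
            {
                "original_cluster": 1,
                "best_match": best_matches,
                "similarity": 1.0,
                "state": "putative_doublet",
                "recluster_label": "",
                "final_label": "",
            },
            index=cells,
        )
        return DoubletCalls(table), cell_dcps

    def test_top_two_components_sorted_ascending(self):
        calls, dcps = self._calls_for([[0.1, 0.6, 0.3]], ["2|3.even"])
        out = recluster_step(calls, dcps, only50=True)
        assert out.table.iloc[0]["recluster_label"] == "2|3"

    def test_weight_class_suffix_appended_in_weighted_mode(self):
        calls, dcps = self._calls_for([[0.3, 0.05, 0.65]], ["1|3.two"])
        out = recluster_step(calls, dcps, only50=False)
        assert out.table.iloc[0]["recluster_label"] == "1|3.two"

    def test_identical_dcps_share_a_label(self):
        calls, dcps = self._calls_for(
            [[0.2, 0.5, 0.3], [0.2, 0.5, 0.3]], ["2|3.even", "2|3.even"]
        )
        out = recluster_step(calls, dcps, only50=False)
        labels = out.table["recluster_label"].tolist()
        assert labels[0] == labels[1] == "2|3.even"

    def test_single_nonzero_component_tie_breaks_to_lowest_id(self):
        calls, dcps = self._calls_for([[1.0, 0.0, 0.0]], ["1|2.even"])
        out = recluster_step(calls, dcps, only50=True)
        assert out.table.iloc[0]["recluster_label"] == "1|2"


def _expression_for_groups(group_values, n_per_group=10, sd=0.1, seed=0):
    """One-gene expression with the given group means."""
    rng = np.random.default_rng(seed)
    cols, labels, vals = [], [], []
    for g, mean in group_values.items():
        for i in range(n_per_group):
            cols.append(f"{g}_{i}")
            labels.append(g)
            vals.append(max(mean + rng.normal(0, sd), 0.0))
    values = pd.DataFrame([vals], index=["gene"], columns=cols)
    return values, pd.Series(labels, index=cols)


class TestUniqueGenes:
    def test_high_focal_mean_is_unique(self):
        values, labels = _expression_for_groups(
            {"Z": 5.0, "A": 0.0, "B": 0.0, "C": 0.0}
        )
        zj = [c for c in values.columns if c.startswith("Z")]
        retained = labels[~labels.index.isin(zj)]
        assert unique_genes(values, zj, retained) == ["gene"]

    def test_identical_groups_not_unique(self):
        values, labels = _expression_for_groups(
            {"Z": 2.0, "A": 2.0, "B": 2.0}, sd=0.0
        )
        zj = [c for c in values.columns if c.startswith("Z")]
        retained = labels[~labels.index.isin(zj)]
        assert unique_genes(values, zj, retained) == []

    def test_higher_than_some_but_not_all_not_unique(self):
        values, labels = _expression_for_groups(
            {"Z": 3.0, "A": 0.0, "B": 0.0, "C": 5.0}
        )
        zj = [c for c in values.columns if c.startswith("Z")]
        retained = labels[~labels.index.isin(zj)]
        assert unique_genes(values, zj, retained) == []


class TestChunkedAnova:
    def test_two_groups_f_equals_t_squared(self):
        """With two equal-size groups, F equals the square of the pooled
        two-sample t statistic."""
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(
            rng.normal(2, 1, size=(20, 16)).clip(0),
            index=[f"g{i}" for i in range(20)],
            columns=[f"c{i}" for i in range(16)],
        )
        labels = pd.Series(["a"] * 8 + ["b"] * 8, index=vals.columns)
        res = chunked_anova(vals, labels, focal="a")
        t, p_t = stats.ttest_ind(
            vals.iloc[:, :8], vals.iloc[:, 8:], axis=1, equal_var=True
        )
        np.testing.assert_allclose(res["F"].to_numpy(), t ** 2, rtol=1e-10)
        np.testing.assert_allclose(res["p"].to_numpy(), p_t, rtol=1e-8)

    def test_constant_gene_gives_f_zero_p_one(self):
        vals = pd.DataFrame(
            np.full((3, 9), 2.0), index=["g0", "g1", "g2"],
            columns=[f"c{i}" for i in range(9)],
        )
        labels = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=vals.columns)
        res = chunked_anova(vals, labels, focal="a")
        assert (res["F"] == 0).all()
        assert (res["p"] == 1).all()

    @pytest.mark.parametrize("chunk_size", [7, 100, 1000])
    def test_chunk_boundaries_do_not_change_results(self, chunk_size):
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(
            rng.gamma(2, 1, size=(50, 24)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"c{i}" for i in range(24)],
        )
        labels = pd.Series(
            ["a"] * 6 + ["b"] * 6 + ["c"] * 6 + ["d"] * 6, index=vals.columns
        )
        full = chunked_anova(vals, labels, focal="a", chunk_size=10_000)
        chunked = chunked_anova(vals, labels, focal="a", chunk_size=chunk_size)
        pd.testing.assert_frame_equal(full, chunked)

    def test_agrees_with_direct_oracles(self):
        """Aggregated TS/TSS computation matches scipy.stats.f_oneway and
        scipy.stats.tukey_hsd per gene."""
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(
            rng.gamma(2, 1, size=(40, 28)),
            index=[f"g{i}" for i in range(40)],
            columns=[f"c{i}" for i in range(28)],
        )
        labels = pd.Series(
            ["z"] * 7 + ["a"] * 7 + ["b"] * 7 + ["c"] * 7, index=vals.columns
        )
        res = chunked_anova(vals, labels, focal="z")
        samples = {g: vals.loc[:, labels == g].to_numpy() for g in "zabc"}
        for gi, gene in enumerate(vals.index):
            groups = [samples[g][gi] for g in "zabc"]
            F, p = stats.f_oneway(*groups)
            assert res.loc[gene, "F"] == pytest.approx(F, rel=1e-10)
            assert res.loc[gene, "p"] == pytest.approx(p, rel=1e-8, abs=1e-12)
            hsd = stats.tukey_hsd(*groups)
            for j, g in enumerate("abc", start=1):
                assert res.loc[gene, f"tukey_p_{g}"] == pytest.approx(
                    hsd.pvalue[0, j], rel=1e-6, abs=1e-8
                )


class TestRescueStep:
    @staticmethod
    def _scenario(n_unique, U, n_members=6):
        """A doublet cluster over genes engineered to be unique or not."""
        rng = np.random.default_rng(0)
        n_genes = max(n_unique, 1) + 3
        cols, labels = [], {}
        groups = {"A": 1, "B": 2}
        data = {}
        for g, _ in groups.items():
            for i in range(8):
                c = f"{g}{i}"
                cols.append(c)
                labels[c] = g
                data[c] = rng.normal(1.0, 0.05, size=n_genes).clip(0)
        zj = []
        for i in range(n_members):
            c = f"Z{i}"
            cols.append(c)
            zj.append(c)
            prof = rng.normal(1.0, 0.05, size=n_genes).clip(0)
            prof[:n_unique] = 6.0 + rng.normal(0, 0.05, size=n_unique)
            data[c] = prof
        values = pd.DataFrame(
            data, index=[f"g{i}" for i in range(n_genes)]
        )[cols]
        table = pd.DataFrame(
            {
                "original_cluster": [labels.get(c, 1) for c in cols],
                "best_match": "1|2.even",
                "similarity": 1.0,
                "state": ["putative_doublet" if c in zj else "singlet"
                          for c in cols],
                "recluster_label": ["1|2.even" if c in zj else "" for c in cols],
                "final_label": "",
            },
            index=cols,
        )
        cell_cluster = pd.Series(
            [1 if labels.get(c) == "A" else 2 for c in cols], index=cols
        )
        ae = AnnotatedExpression(values, cell_cluster)
        return DoubletCalls(table), ae, zj

    def test_three_unique_genes_below_default_threshold_stay_doublets(self):
        calls, ae, zj = self._scenario(n_unique=3, U=4)
        out, report = rescue_step(calls, ae, U=4)
        assert report.clusters.loc["1|2.even", "unique_gene_count"] == 3
        assert (out.table.loc[zj, "state"] == "final_doublet").all()

    def test_threshold_zero_rescues_everything(self):
        calls, ae, zj = self._scenario(n_unique=0, U=0)
        out, _ = rescue_step(calls, ae, U=0)
        assert (out.table.loc[zj, "state"] == "rescued_singlet").all()

    def test_ten_engineered_unique_genes_rescue_at_default_threshold(self):
        calls, ae, zj = self._scenario(n_unique=10, U=4)
        out, report = rescue_step(calls, ae, U=4)
        assert report.clusters.loc["1|2.even", "unique_gene_count"] >= 10
        assert (out.table.loc[zj, "state"] == "rescued_singlet").all()
        # rescued cells return to their original cluster label
        assert (
            out.table.loc[zj, "final_label"]
            == out.table.loc[zj, "original_cluster"].astype(str)
        ).all()

    def test_negative_threshold_rejected(self):
        calls, ae, _ = self._scenario(n_unique=0, U=0)
        with pytest.raises(ValueError, match="U must be"):
            rescue_step(calls, ae, U=-1)

    def test_singlets_never_relabeled_and_final_doublet_monotone_in_U(self):
        calls, ae, zj = self._scenario(n_unique=5, U=0)
        prev = set()
        for U in [0, 3, 5, 6, 100]:
            out, _ = rescue_step(calls, ae, U=U)
            singlet_cells = calls.table.index[calls.table["state"] == "singlet"]
            assert (out.table.loc[singlet_cells, "state"] == "singlet").all()
            current = set(out.table.index[out.table["state"] == "final_doublet"])
            assert prev <= current
            prev = current
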