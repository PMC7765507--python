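"""Invasiveness: CPM filtering, EMT scoring, two-group DE, regulation labels."""

import numpy as np
import pandas as pd
import pytest

from neurocoopt import invasiveness as inv
from neurocoopt.errors import ConfigurationError, EmptyMatrixError


def _counts(rows, samples=None):
    frame = pd.DataFrame(rows).T
    frame.columns = samples or [f"s{i}" for i in range(frame.shape[1])]
    return frame


class TestCPM:
    def test_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(30, 8)) + 1)
        assert np.allclose(inv.cpm(counts).sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_library_raises(self):
        counts = pd.DataFrame({"s0": [0, 0], "s1": [1, 2]})
        with pytest.raises(EmptyMatrixError):
            inv.cpm(counts)


class TestCPMFilter:
    def test_hand_computed_toy_thresholds(self):
        # library sizes chosen so per-sample CPM is count/total*1e6
        counts = pd.DataFrame({
            "g_pass": [3, 3, 0, 0],       # CPM 0.6 in two samples
            "g_fail": [2, 2, 2, 2],       # CPM 0.4 everywhere
            "g_rest": [4999995, 4999995, 4999998, 4999998],
        }).T
        counts.columns = [f"s{i}" for i in range(4)]
        cpm = inv.cpm(counts)
        assert cpm.loc["g_pass"].round(6).tolist() == [0.6, 0.6, 0.0, 0.0]
        assert cpm.loc["g_fail"].round(6).tolist() == [0.4, 0.4, 0.4, 0.4]
        kept = inv.cpm_filter(counts, min_cpm=0.5, min_samples=2)
        assert "g_pass" in kept.index
        assert "g_fail" not in kept.index

    def test_all_zero_gene_removed(self):
        counts = _counts({"zero": [0, 0, 0], "ok": [10, 10, 10]})
        kept = inv.cpm_filter(counts, min_cpm=0.5, min_samples=1)
        assert list(kept.index) == ["ok"]

    def test_zero_thresholds_are_identity(self):
        counts = _counts({"a": [0, 1], "b": [2, 3]})
        kept = inv.cpm_filter(counts, min_cpm=0, min_samples=0)
        assert kept.equals(counts)

    def test_filtering_everything_raises(self):
        counts = _counts({"a": [1, 1], "b": [1, 1]})
        with pytest.raises(EmptyMatrixError):
            inv.cpm_filter(counts, min_cpm=1e9, min_samples=2)

    def test_min_samples_beyond_matrix_raises(self):
        counts = _counts({"a": [1, 1]})
        with pytest.raises(ValueError):
            inv.cpm_filter(counts, min_samples=5)


class TestEMTScore:
    @staticmethod
    def _matrix(cdh1, mes_each, samples=1):
        data = {"CDH1": [cdh1] * samples}
        for m in inv.DEFAULT_MESENCHYMAL_MARKERS:
            data[m] = [mes_each] * samples
        frame = pd.DataFrame(data).T
        frame.columns = [f"s{i}" for i in range(samples)]
        return frame

    def test_absent_epithelial_marker_scores_zero_and_high_invasive(self):
        norm = pd.concat([self._matrix(0.0, 10.0, 2), self._matrix(100.0, 10.0, 2)],
                         axis=1)
        norm.columns = list("abcd")
        tissues = pd.Series("t", index=norm.columns)
        scores = inv.emt_score(norm, tissues)
        assert scores.loc["a", "score"] == pytest.approx(0.0)
        assert scores.loc["a", "emt_class"] == inv.HIGH_INVASIVE

    def test_ratio_arithmetic(self):
        norm = self._matrix(100.0, 12.5, 1)  # mesenchymal sum 50
        score = inv.emt_score(
            norm, pd.Series("t", index=norm.columns)).loc["s0", "score"]
        assert score == pytest.approx(2.0, rel=1e-6)

    def test_missing_marker_names_the_absent_symbol(self):
        norm = self._matrix(1.0, 1.0).drop(index="ZEB1")
        with pytest.raises(ConfigurationError, match="ZEB1"):
            inv.emt_score(norm, pd.Series("t", index=norm.columns))

    def test_scale_invariance_per_sample(self, rng):
        norm = pd.DataFrame(
            rng.uniform(1, 100, size=(5, 6)),
            index=["CDH1", *inv.DEFAULT_MESENCHYMAL_MARKERS])
        tissues = pd.Series("t", index=norm.columns)
        base = inv.emt_score(norm, tissues)["score"]
        scaled = inv.emt_score(norm * 7.5, tissues)["score"]
        assert np.allclose(base, scaled, rtol=1e-6)

    def test_recovers_planted_invasive_labels(self, sim_lines):
        filtered = inv.cpm_filter(sim_lines.counts, min_cpm=0.5, min_samples=100)
        scores = inv.emt_score(inv.cpm(filtered), sim_lines.meta["tissue"])
        predicted = scores["emt_class"] == inv.HIGH_INVASIVE
        accuracy = (predicted == sim_lines.invasive_truth).mean()
        assert accuracy >= 0.95


class TestDETwoGroup:
    def test_identical_gene_is_ns_with_zero_logfc(self):
        expr = pd.DataFrame({f"s{i}": [1.0, float(i)] for i in range(8)},
                            index=["flat", "varying"])
        classes = pd.Series([inv.HIGH_INVASIVE] * 4 + [inv.LOW_INVASIVE] * 4,
                            index=expr.columns)
        table = inv.de_two_group(expr, classes)
        assert table.loc["flat", "logFC"] == 0.0
        assert table.loc["flat", "direction"] == "ns"

    def test_planted_fourfold_effect_is_recovered(self, rng):
        n_genes, n_per = 300, 20
        base = rng.normal(5, 0.25, size=(n_genes, 2 * n_per))
        up = rng.choice(n_genes, size=30, replace=False)
        base[up, :n_per] += 2.0  # 4-fold on log2 scale
        expr = pd.DataFrame(base, columns=[f"s{i}" for i in range(2 * n_per)])
        classes = pd.Series([inv.HIGH_INVASIVE] * n_per + [inv.LOW_INVASIVE] * n_per,
                            index=expr.columns)
        table = inv.de_two_group(expr, classes)
        called_up = set(table.index[table["direction"] == "up"])
        sensitivity = len(called_up & set(up)) / len(up)
        false_calls = len(called_up - set(up))
        assert sensitivity >= 0.9
        assert false_calls / max(1, len(called_up)) <= 0.1

    def test_permuted_labels_give_uniform_pvalues(self, rng):
        from scipy import stats
        expr = pd.DataFrame(rng.normal(size=(500, 40)),
                            columns=[f"s{i}" for i in range(40)])
        labels = np.array([inv.HIGH_INVASIVE] * 20 + [inv.LOW_INVASIVE] * 20)
        rng.shuffle(labels)
        table = inv.de_two_group(expr, pd.Series(labels, index=expr.columns))
        frac_sig = (table["p"] <= 0.05).mean()
        assert abs(frac_sig - 0.05) < 0.03
        assert stats.kstest(table["p"], "uniform").pvalue > 0.01

    def test_single_sample_class_raises(self):
        expr = pd.DataFrame(np.ones((3, 3)), columns=list("abc"))
        classes = pd.Series([inv.HIGH_INVASIVE, inv.LOW_INVASIVE, inv.LOW_INVASIVE],
                            index=expr.columns)
        with pytest.raises(ValueError):
            inv.de_two_group(expr, classes)


class TestClassifyRegulation:
    @staticmethod
    def _de(direction_by_gene):
        frame = pd.DataFrame({"direction": pd.Series(direction_by_gene)})
        frame["logFC"] = 0.0
        return frame

    @pytest.mark.parametrize("pooled, tissues, expected", [
        ("up", ["up", "up", "up"], "up_across"),
        ("down", ["ns", "ns", "ns"], "down_across"),
        ("ns", ["up", "ns", "ns"], "cancer_type_dependent_up"),
        ("ns", ["ns", "down", "ns"], "cancer_type_dependent_down"),
        ("ns", ["up", "down", "ns"], "mixed"),
        ("ns", ["ns", "ns", "ns"], "ns"),
    ])
    def test_rule_table(self, pooled, tissues, expected):
        pooled_de = self._de({"g": pooled})
        per_tissue = {f"t{i}": self._de({"g": d}) for i, d in enumerate(tissues)}
        labels = inv.classify_regulation(pooled_de, per_tissue)
        assert labels["g"] == expected

    def test_query_restricts_output_genes(self):
        pooled = self._de({"G1": "up", "G2": "down"})
        labels = inv.classify_regulation(pooled, {}, ["G1"])
        assert list(labels.index) == ["G1"]
        assert labels["G1"] == "up_across"


def test_de_recovers_planted_cellline_signal(sim_lines):
    filtered = inv.cpm_filter(sim_lines.counts, min_cpm=0.5, min_samples=100)
    logexpr = inv.log2cpm(filtered)
    scores = inv.emt_score(inv.cpm(filtered), sim_lines.meta["tissue"])
    table = inv.de_two_group(logexpr, scores["emt_class"])
    up = set(table.index[table["direction"] == "up"])
    down = set(table.index[table["direction"] == "down"])
    assert len(up & sim_lines.up_truth.genes) / len(sim_lines.up_truth) >= 0.9
    assert len(down & sim_lines.down_truth.genes) / len(sim_lines.down_truth) >= 0.9
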