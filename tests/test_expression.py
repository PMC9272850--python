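import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dmcortexome.expression import (
    assign_specificity,
    celltype_enrichment,
    classify_regulation,
    correlate_to_splicing,
    expression_score,
    prioritize_biomarkers,
)
from dmcortexome.io import SideTables
from dmcortexome.splicing import SeverityScores

from conftest import make_expr
from _oracles import fisher_two_sided_exact, pearson_bruteforce


def de_table(rows):
    return pd.DataFrame(rows, columns=["gene", "log2fc", "qvalue"]).set_index("gene")


def scores_for(samples, values):
    return SeverityScores(pd.DataFrame({"score": values},
                                       index=pd.Index(samples, name="sample")),
                          kind="splicing")


class TestClassifyRegulation:
    def test_rule_and_boundaries(self):
        de = de_table([("up1", 1.2, 0.005), ("weak", 0.9, 0.005),
                       ("down1", -1.5, 0.001), ("insig", 2.0, 0.02),
                       ("edge", 1.0, 0.005)])
        classes = classify_regulation(de, q_max=0.01, lfc_min=1.0)
        assert list(classes.up.index) == ["up1", "edge"]  # lfc >= 1 inclusive
        assert list(classes.down.index) == ["down1"]
        assert set(classes.unchanged.index) == {"weak", "insig"}

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="log2fc"):
            classify_regulation(pd.DataFrame({"qvalue": [0.1]}, index=["g"]))

    def test_matches_bruteforce_filter(self, default_cohort):
        _, _, _, de = default_cohort
        classes = classify_regulation(de)
        expected_up = {g for g in de.index
                       if de.loc[g, "qvalue"] < 0.01 and de.loc[g, "log2fc"] >= 1}
        assert set(classes.up.index) == expected_up
        assert not (set(classes.up.index) & set(classes.down.index))


class TestExpressionScore:
    def build(self):
        # 2 controls, 1 case; genes g0 (up), g1 (down)
        tpm = make_expr([[3.0, 3.0, 7.0], [15.0, 15.0, 3.0]],
                        ["u", "u", "d"])
        classes = classify_regulation(de_table([
            ("g0", 1.5, 0.001), ("g1", -1.5, 0.001)]))
        return tpm, classes

    def test_sample_at_control_mean_scores_zero(self):
        tpm, classes = self.build()
        g = expression_score(tpm, classes, "u")
        assert g.table.loc["s0", "score"] == pytest.approx(0.0)

    def test_two_fold_shift_scores_one(self):
        tpm = make_expr([[3.0, 3.0, 7.0], [7.0, 7.0, 15.0]], ["u", "u", "d"])
        classes = classify_regulation(de_table([
            ("g0", 1.5, 0.001), ("g1", 1.5, 0.001)]))
        g = expression_score(tpm, classes, "u")
        assert g.table.loc["s2", "score"] == pytest.approx(1.0)

    def test_hand_computed_five_gene_toy(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(1, 50, size=(5, 4))
        tpm = make_expr(vals, ["u", "u", "d", "d"])
        classes = classify_regulation(de_table(
            [(f"g{i}", 1.5, 0.001) for i in range(5)]))
        g = expression_score(tpm, classes, "u")
        log = np.log2(vals + 1)
        mu = log[:, :2].mean(axis=1)
        assert g.table.loc["s3", "score"] == pytest.approx(
            np.abs(log[:, 3] - mu).mean())

    def test_gene_missing_from_matrix_rejected(self):
        tpm, _ = self.build()
        classes = classify_regulation(de_table([("absent", 2.0, 0.001)]))
        with pytest.raises(ValueError, match="absent"):
            expression_score(tpm, classes, "u")

    def test_invariance_to_constant_offset(self, default_cohort):
        _, tpm, _, de = default_cohort[0], default_cohort[1], default_cohort[2], default_cohort[3]
        classes = classify_regulation(de)
        g1 = expression_score(tpm, classes, "unaffected")
        shifted = make_expr(
            (np.log2(tpm.values + 1) + 1.0).pipe(np.exp2) - 1,
            [tpm.groups[s] for s in tpm.samples],
            genes=tpm.genes, samples=tpm.samples)
        g2 = expression_score(shifted, classes, "unaffected")
        assert np.allclose(g1.table["score"], g2.table["score"], atol=1e-9)


class TestCorrelateToSplicing:
    def test_linear_gene_has_r_one(self):
        s = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
        tpm = make_expr([np.exp2(3 * s) - 1, np.full(6, 5.0) + np.arange(6) % 2],
                        ["u"] * 6)
        classes = classify_regulation(de_table([
            ("g0", 2.0, 0.001), ("g1", -2.0, 0.001)]))
        out = correlate_to_splicing(tpm, classes, scores_for(tpm.samples, s),
                                    seed=0)
        assert out["single"].loc["g0", "r"] == pytest.approx(1.0)

    def test_pair_cardinality(self):
        rng = np.random.default_rng(1)
        n_genes = 8
        tpm = make_expr(rng.uniform(1, 20, (n_genes, 6)), ["u"] * 6)
        classes = classify_regulation(de_table(
            [(f"g{i}", (1.5 if i % 2 else -1.5), 0.001) for i in range(n_genes)]))
        out = correlate_to_splicing(tpm, classes,
                                    scores_for(tpm.samples, rng.random(6)),
                                    pairs=True, seed=0)
        assert len(out["pairs"]) == n_genes * (n_genes - 1) // 2

    def test_observed_right_shifted_vs_null(self, default_cohort):
        _, tpm, truth, de = default_cohort
        classes = classify_regulation(de)
        s = [truth.severity[x] for x in tpm.samples]
        out = correlate_to_splicing(tpm, classes, scores_for(tpm.samples, s),
                                    n_shuffles=2, seed=3)
        obs = out["single"]["r"].abs().mean()
        assert obs > 2 * np.abs(out["null_r"]).mean()
        assert out["ks_pvalue"] < 1e-10

    def test_too_few_samples_rejected(self):
        tpm = make_expr([[1.0, 2.0]], ["u", "u"])
        classes = classify_regulation(de_table([("g0", 1.5, 0.001)]))
        with pytest.raises(ValueError, match="three"):
            correlate_to_splicing(tpm, classes, scores_for(["s0", "s1"], [0, 1]))


class TestSpecificity:
    def test_single_type_expression_scores_n_types(self):
        ref = pd.DataFrame([[0, 0, 0, 0, 10.0]], index=["g"],
                           columns=list("abcde"))
        out = assign_specificity(ref)
        assert out.loc["g", "score"] == pytest.approx(5.0)
        assert out.loc["g", "cell_type"] == "e"

    def test_uniform_gene_unassigned(self):
        ref = pd.DataFrame([[3.0, 3.0, 3.0]], index=["g"], columns=list("abc"))
        out = assign_specificity(ref)
        assert out.loc["g", "cell_type"] == ""
        assert out.loc["g", "score"] == pytest.approx(1.0)

    def test_scale_invariance_per_gene(self):
        rng = np.random.default_rng(2)
        ref = pd.DataFrame(rng.uniform(0.5, 9, (30, 5)),
                           index=[f"g{i}" for i in range(30)],
                           columns=list("abcde"))
        out1 = assign_specificity(ref)
        out2 = assign_specificity(ref * pd.Series(rng.uniform(0.1, 10, 30),
                                                  index=ref.index).to_frame().values)
        pd.testing.assert_frame_equal(out1, out2)

    def test_matches_bruteforce(self, default_cohort):
        _, _, truth, _ = default_cohort
        out = assign_specificity(truth.reference, threshold=3.0)
        expr = truth.reference.to_numpy()
        for i, g in enumerate(list(truth.reference.index)[::97]):
            row = expr[truth.reference.index.get_loc(g)]
            scores = row / row.mean()
            if scores.max() > 3.0:
                assert out.loc[g, "cell_type"] == \
                    truth.reference.columns[scores.argmax()]
            else:
                assert out.loc[g, "cell_type"] == ""


class TestCelltypeEnrichment:
    def assignments(self, mapping):
        return pd.DataFrame({"cell_type": pd.Series(mapping),
                             "score": 5.0})

    def test_symmetric_table_is_null(self):
        genes = [f"g{i}" for i in range(40)]
        mapping = {g: ("ct1" if i % 2 else "") for i, g in enumerate(genes)}
        table = celltype_enrichment(self.assignments(mapping),
                                    {"up": genes[:20]}, background=genes[20:])
        row = table.iloc[0]
        assert (row["a"], row["b"], row["c"], row["d"]) == (10, 10, 10, 10)
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["pvalue"] == pytest.approx(1.0)

    def test_p_equals_hypergeometric_enumeration(self):
        # contingency (8,2,2,8)
        genes = [f"g{i}" for i in range(20)]
        mapping = {}
        for i, g in enumerate(genes[:10]):
            mapping[g] = "ct1" if i < 8 else ""
        for i, g in enumerate(genes[10:]):
            mapping[g] = "ct1" if i < 2 else ""
        table = celltype_enrichment(self.assignments(mapping),
                                    {"up": genes[:10]}, background=genes[10:])
        row = table.iloc[0]
        assert (row["a"], row["b"], row["c"], row["d"]) == (8, 2, 2, 8)
        assert row["pvalue"] == pytest.approx(
            fisher_two_sided_exact(8, 2, 2, 8), rel=1e-10)

    def test_planted_neuron_down_signal(self, default_cohort):
        _, _, truth, de = default_cohort
        classes = classify_regulation(de)
        spec = assign_specificity(truth.reference, threshold=3.0)
        table = celltype_enrichment(
            spec, {"up": list(classes.up.index), "down": list(classes.down.index)},
            background=list(classes.unchanged.index))
        ndown = table[(table["set"] == "down") & (table["cell_type"] == "neuron")]
        assert ndown["pvalue"].iloc[0] < 0.01
        assert ndown["odds_ratio"].iloc[0] > 1

    def test_empty_class_skipped(self):
        genes = [f"g{i}" for i in range(10)]
        mapping = {g: "ct1" for g in genes}
        table = celltype_enrichment(self.assignments(mapping),
                                    {"up": []}, background=genes)
        assert len(table) == 0


class TestBiomarkers:
    def run(self, csf=("g0", "g2")):
        rng = np.random.default_rng(6)
        s = np.linspace(0, 1, 8)
        vals = []
        for i in range(4):
            vals.append(np.exp2(2 * s * (1 if i % 2 else -1)
                                + rng.normal(0, 0.05, 8) + 3) - 1)
        tpm = make_expr(np.array(vals), ["u", "u"] + ["d"] * 6)
        classes = classify_regulation(de_table(
            [(f"g{i}", (1.5 if i % 2 else -1.5), 0.001) for i in range(4)]))
        corr = correlate_to_splicing(tpm, classes, scores_for(tpm.samples, s),
                                     seed=0)
        side = SideTables(csf_detectable=set(csf),
                          signal_peptide={"g0": True})
        return prioritize_biomarkers(corr, side, tpm, "u")

    def test_csf_detectable_ranked_first(self):
        table = self.run()
        assert set(table.index[:2]) == {"g0", "g2"}
        assert table["csf_detectable"].iloc[:2].all()
        assert not table["csf_detectable"].iloc[2:].any()

    def test_tie_break_is_gene_identifier(self):
        tpm = make_expr(np.tile([[1.0, 2.0, 4.0, 8.0]], (3, 1)),
                        ["u", "u", "d", "d"], genes=["b", "c", "a"])
        classes = classify_regulation(de_table(
            [("b", 1.5, 0.001), ("c", 1.5, 0.001), ("a", 1.5, 0.001)]))
        corr = correlate_to_splicing(
            tpm, classes, scores_for(tpm.samples, [0, 0.2, 0.5, 1.0]), seed=0)
        table = prioritize_biomarkers(corr, SideTables(), tpm, "u")
        assert list(table.index) == ["a", "b", "c"]

    def test_planted_high_r_csf_genes_in_top(self, default_cohort):
        _, tpm, truth, de = default_cohort
        classes = classify_regulation(de)
        s = [truth.severity[x] for x in tpm.samples]
        corr = correlate_to_splicing(tpm, classes, scores_for(tpm.samples, s),
                                     seed=0)
        top_r = corr["single"]["r"].abs().nlargest(3).index
        side = SideTables(csf_detectable=set(top_r))
        table = prioritize_biomarkers(corr, side, tpm, "unaffected")
        assert set(top_r) <= set(table.index[:5])


def test_pearson_matches_bruteforce(default_cohort):
    _, tpm, truth, de = default_cohort
    classes = classify_regulation(de)
    s = np.array([truth.severity[x] for x in tpm.samples])
    out = correlate_to_splicing(tpm, classes, scores_for(tpm.samples, s), seed=0)
    g = classes.regulated[0]
    expected = pearson_bruteforce(np.log2(tpm.values.loc[g] + 1), s)
    assert out["single"].loc[g, "r"] == pytest.approx(expected, abs=1e-12)
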