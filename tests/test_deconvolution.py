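import numpy as np
import pandas as pd
import pytest

from dmcortexome.deconvolution import (
    CellTypeReference,
    compare_proportions,
    estimate_proportions,
    prune_and_refit,
    select_markers,
)
from dmcortexome.io import ExpressionMatrix

TYPES = ["neuron", "oligodendrocyte", "astrocyte", "endothelial", "microglia"]


def build_reference(n_per_type=37, seed=42, types=TYPES, fold=(6.0, 12.0)):
    rng = np.random.default_rng(seed)
    n = n_per_type * len(types)
    genes = [f"M{i:03d}" for i in range(n)]
    ref = np.empty((n, len(types)))
    assignment = {}
    i = 0
    for c, ct in enumerate(types):
        for _ in range(n_per_type):
            base = np.exp(rng.normal(2, 0.5))
            ref[i, :] = base
            ref[i, c] = base * rng.uniform(*fold)
            assignment[genes[i]] = ct
            i += 1
    return CellTypeReference(pd.DataFrame(ref, index=genes, columns=types),
                             assignment)


def bulk_from(reference, theta, cv=0.0, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    mix = np.atleast_2d(theta) @ reference.ref.to_numpy().T
    if cv > 0:
        mix = mix * rng.lognormal(0, np.sqrt(np.log1p(cv ** 2)), size=mix.shape)
    samples = [f"S{i}" for i in range(mix.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(mix.T * scale, index=reference.ref.index, columns=samples),
        {s: "x" for s in samples})


class TestSelectMarkers:
    def single_cell_table(self, n_types=6, n_specific=60, n_shared=200, seed=3):
        rng = np.random.default_rng(seed)
        types = [f"ct{i}" for i in range(n_types)]
        rows, genes = [], []
        for c in range(n_types):
            for j in range(n_specific):
                base = rng.uniform(1, 5)
                row = np.full(n_types, base)
                row[c] = base * rng.uniform(3, 20)
                rows.append(row)
                genes.append(f"spec{c}_{j}")
        for j in range(n_shared):
            rows.append(np.full(n_types, rng.uniform(1, 5)))
            genes.append(f"shared{j}")
        return pd.DataFrame(rows, index=genes, columns=types)

    def test_six_types_top50_gives_300(self):
        table = self.single_cell_table()
        ref = select_markers(table, top_n=50)
        assert len(ref.ref) == 300
        assert all(n == 50 for n in ref.markers_per_type().values())

    def test_uniform_gene_never_outranks_enriched_gene(self):
        table = pd.DataFrame({
            "a": [10.0, 4.0, 1.0, 1.0], "b": [10.0, 2.0, 6.0, 1.0],
            "c": [10.0, 2.0, 1.0, 6.0],
        }, index=["uniform", "enriched_a", "enriched_b", "enriched_c"])
        ref = select_markers(table, top_n=1)
        assert ref.marker_assignment["enriched_a"] == "a"
        assert "uniform" not in ref.marker_assignment

    def test_strongest_planted_markers_recovered(self):
        table = self.single_cell_table()
        ref = select_markers(table, top_n=50)
        for c in range(6):
            fold = table[f"ct{c}"] / table.drop(columns=f"ct{c}").mean(axis=1)
            planted = fold[fold.index.str.startswith(f"spec{c}_")]
            strongest = set(planted.nlargest(20).index)
            chosen = {g for g, ct in ref.marker_assignment.items() if ct == f"ct{c}"}
            assert strongest <= chosen

    def test_expression_intersection_after_top_n(self):
        table = self.single_cell_table()
        expressed = set(table.index[::2])
        ref = select_markers(table, top_n=50, expressed_genes=expressed)
        assert set(ref.ref.index) <= expressed
        assert all(n <= 50 for n in ref.markers_per_type().values())

    def test_zero_qualifying_markers_rejected(self):
        table = pd.DataFrame({"a": [1.0, 1.0], "b": [1.0, 1.0]},
                             index=["g1", "g2"])
        with pytest.raises(ValueError, match="no qualifying markers"):
            select_markers(table)


class TestEstimateProportions:
    def test_pure_mixture_identified(self):
        reference = build_reference()
        theta = np.zeros(5)
        theta[0] = 1.0
        bulk = bulk_from(reference, theta)
        est = estimate_proportions(bulk, reference, draws=1000, warmup=800, seed=3)
        assert est.means.iloc[0, 0] >= 0.95

    def test_even_mix_of_two_types(self):
        reference = build_reference()
        theta = np.array([0.5, 0.5, 0.0, 0.0, 0.0])
        bulk = bulk_from(reference, theta)
        est = estimate_proportions(bulk, reference, draws=1500, warmup=800, seed=4)
        assert abs(est.means.iloc[0, 0] - 0.5) < 0.05
        assert abs(est.means.iloc[0, 1] - 0.5) < 0.05

    def test_scale_invariance(self):
        reference = build_reference()
        theta = np.array([0.4, 0.3, 0.2, 0.05, 0.05])
        b1 = bulk_from(reference, theta, cv=0.2, seed=5)
        b2 = ExpressionMatrix(b1.values * 1000.0, dict(b1.groups))
        e1 = estimate_proportions(b1, reference, draws=500, warmup=500, seed=6)
        e2 = estimate_proportions(b2, reference, draws=500, warmup=500, seed=6)
        assert np.allclose(e1.means.to_numpy(), e2.means.to_numpy())

    def test_uninformative_reference_recovers_prior(self):
        # identical columns: posterior = Dirichlet(1) prior, mean 1/C
        genes = [f"M{i}" for i in range(40)]
        vals = np.tile(np.linspace(1, 5, 40)[:, None], (1, 4))
        reference = CellTypeReference(
            pd.DataFrame(vals, index=genes, columns=["a", "b", "c", "d"]),
            {g: "abcd"[i % 4] for i, g in enumerate(genes)})
        bulk = ExpressionMatrix(pd.DataFrame(vals[:, 0], index=genes,
                                             columns=["S0"]), {"S0": "x"})
        est = estimate_proportions(bulk, reference, draws=2000, warmup=800,
                                   seed=8, min_markers_per_type=5)
        assert np.allclose(est.means.iloc[0], 0.25, atol=0.03)

    def test_posterior_sums_to_one(self):
        reference = build_reference()
        bulk = bulk_from(reference, np.array([0.3, 0.3, 0.2, 0.1, 0.1]),
                         cv=0.2, seed=9)
        est = estimate_proportions(bulk, reference, draws=500, warmup=500, seed=10)
        assert abs(est.means.iloc[0].sum() - 1.0) < 1e-9

    def test_too_few_markers_rejected(self):
        reference = build_reference(n_per_type=4)
        bulk = bulk_from(reference, np.full(5, 0.2))
        with pytest.raises(ValueError, match="markers"):
            estimate_proportions(bulk, reference, draws=100, warmup=100, seed=1)


class TestPruneAndRefit:
    def test_rare_type_pruned_and_recovery_preserved(self):
        types = TYPES + ["OPC"]
        reference = build_reference(n_per_type=31, types=types)
        rng = np.random.default_rng(12)
        theta = rng.dirichlet([40, 25, 20, 10, 5], size=8)
        theta = np.concatenate([theta * 0.99, np.full((8, 1), 0.01)], axis=1)
        bulk = bulk_from(reference, theta, cv=0.2, seed=13)
        est = estimate_proportions(bulk, reference, draws=800, warmup=600, seed=14)
        refit, pruned_ref = prune_and_refit(est, bulk, reference,
                                            min_prop=0.025, draws=800,
                                            warmup=600, seed=15)
        assert "OPC" not in refit.cell_types
        err = np.abs(refit.means.to_numpy() - theta[:, :5]).mean()
        assert err <= 0.05

    def test_no_op_when_all_types_abundant(self):
        reference = build_reference()
        bulk = bulk_from(reference, np.full((3, 5), 0.2), cv=0.1, seed=16)
        est = estimate_proportions(bulk, reference, draws=500, warmup=500, seed=17)
        refit, ref2 = prune_and_refit(est, bulk, reference, min_prop=0.025)
        assert refit is est
        assert ref2 is reference

    def test_min_prop_zero_never_prunes(self):
        reference = build_reference()
        bulk = bulk_from(reference, np.array([0.96, 0.01, 0.01, 0.01, 0.01]),
                         seed=18)
        est = estimate_proportions(bulk, reference, draws=500, warmup=500, seed=19)
        refit, _ = prune_and_refit(est, bulk, reference, min_prop=0.0)
        assert refit is est


class TestCompareProportions:
    def test_identical_groups_all_p_one(self):
        reference = build_reference()
        theta = np.tile(np.array([0.4, 0.3, 0.15, 0.1, 0.05]), (6, 1))
        bulk = bulk_from(reference, theta)
        est = estimate_proportions(bulk, reference, draws=400, warmup=400, seed=20)
        # posterior means are near-identical across samples; use exact copies
        est.means.iloc[:] = theta
        groups = {f"S{i}": ("case" if i < 3 else "ctrl") for i in range(6)}
        table = compare_proportions(est, groups, "case", "ctrl")
        assert (table["pvalue"] == 1.0).all()

    def test_microglia_shift_detected_not_neuron_loss(self):
        """Across seeds the severity-linked microglial increase is detected
        while the neuron proportion shows no significant change."""
        from dmcortexome.deconvolution import ProportionEstimate
        from dmcortexome.simulate import CohortConfig, simulate_cohort
        mic_hits = neu_quiet = 0
        for seed in range(1, 11):
            truth = simulate_cohort(CohortConfig(seed=seed))[2]
            p = truth.proportions
            est = ProportionEstimate(p, p, p, pd.DataFrame(index=p.index),
                                     n_markers=0)
            table = compare_proportions(est, truth.groups, "DM1", "unaffected")
            mic_hits += table.loc["microglia", "qvalue"] < 0.05
            neu_quiet += table.loc["neuron", "qvalue"] > 0.05
        assert mic_hits >= 8
        assert neu_quiet >= 8
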