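"""Gene-expression dysregulation: regulated-gene classification, the
expression dysregulation score G, correlations of single genes and gene pairs
with splicing severity against a shuffled null, cell-type specificity with
Fisher enrichment, and CSF-accessible biomarker prioritization.

Fold-change thresholds are interpreted on the log2 scale (a linear
fold-change of 1 would be a tautology); all logged expression uses
log2(TPM + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SideTables
from .splicing import SeverityScores

__all__ = [
    "RegulationClasses",
    "classify_regulation",
    "expression_score",
    "correlate_to_splicing",
    "assign_specificity",
    "celltype_enrichment",
    "prioritize_biomarkers",
]


@dataclass
class RegulationClasses:
    """Disjoint up / down / unchanged gene sets with per-gene effect and q."""

    up: pd.DataFrame
    down: pd.DataFrame
    unchanged: pd.DataFrame
    q_max: float
    lfc_min: float

    @property
    def regulated(self) -> list[str]:
        return list(self.up.index) + list(self.down.index)

    def direction(self, gene: str) -> int:
        if gene in self.up.index:
            return 1
        if gene in self.down.index:
            return -1
        return 0


def classify_regulation(de_table: pd.DataFrame, q_max: float = 0.01,
                        lfc_min: float = 1.0) -> RegulationClasses:
    """Split genes into up (q < q_max and log2FC ≥ lfc_min), down (q < q_max
    and log2FC ≤ −lfc_min) and unchanged."""
    required = {"log2fc", "qvalue"}
    if not required <= set(de_table.columns):
        raise ValueError(f"de_table missing columns {sorted(required - set(de_table.columns))}")
    sig = de_table["qvalue"] < q_max
    up = de_table[sig & (de_table["log2fc"] >= lfc_min)]
    down = de_table[sig & (de_table["log2fc"] <= -lfc_min)]
    unchanged = de_table.drop(index=list(up.index) + list(down.index))
    return RegulationClasses(up, down, unchanged, q_max, lfc_min)


def expression_score(tpm: ExpressionMatrix, classes: RegulationClasses,
                     control_label: str) -> SeverityScores:
    """Gene-expression dysregulation score G per sample: the mean over
    regulated genes of |log2(TPM+1) − unaffected-mean log2(TPM+1)|."""
    regulated = classes.regulated
    if not regulated:
        raise ValueError("up ∪ down is empty")
    missing = [g for g in regulated if g not in tpm.values.index]
    if missing:
        raise ValueError(f"regulated genes absent from expression matrix: {missing}")
    log = np.log2(tpm.values.loc[regulated] + 1.0)
    ctrl = tpm.samples_in_group(control_label)
    mu = log[ctrl].mean(axis=1)
    dev = log.sub(mu, axis=0).abs()
    score = dev.mean(axis=0)
    table = pd.DataFrame({
        "score": score, "n_events": len(regulated),
        "group": [tpm.groups[s] for s in tpm.samples],
    }, index=pd.Index(tpm.samples, name="sample"))
    return SeverityScores(table, kind="expression")


def correlate_to_splicing(tpm: ExpressionMatrix, classes: RegulationClasses,
                          splicing_scores: SeverityScores, pairs: bool = False,
                          n_shuffles: int = 1, seed: int = 0) -> dict:
    """Pearson correlation of regulated-gene expression (and optionally
    gene-pair scores) with the splicing dysregulation score S.

    Pair scores: log2(TPM+1) sum for same-direction pairs, difference for
    opposite-direction pairs.  The null shuffles each gene's expression among
    samples and recomputes the single-gene correlations.
    """
    samples = [s for s in tpm.samples if s in splicing_scores.table.index]
    if len(samples) < 3:
        raise ValueError("need at least three samples with both scores")
    missing = set(splicing_scores.table.index) - set(samples)
    if missing:
        raise ValueError(f"splicing scores missing for samples: {sorted(missing)}")
    s = splicing_scores.table.loc[samples, "score"].to_numpy(dtype=float)
    regulated = classes.regulated
    log = np.log2(tpm.values.loc[regulated, samples].to_numpy(dtype=float) + 1.0)

    def corr_rows(mat: np.ndarray) -> np.ndarray:
        mc = mat - mat.mean(axis=1, keepdims=True)
        sc = s - s.mean()
        denom = np.sqrt((mc ** 2).sum(axis=1) * (sc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            return (mc @ sc) / denom

    single = pd.DataFrame({"gene": regulated, "r": corr_rows(log)}).set_index("gene")
    single["direction"] = [classes.direction(g) for g in regulated]

    rng = np.random.Generator(np.random.PCG64(seed))
    null = np.concatenate([
        corr_rows(rng.permuted(log, axis=1)) for _ in range(max(n_shuffles, 1))
    ])
    obs = single["r"].to_numpy()
    ks = stats.ks_2samp(np.abs(obs[~np.isnan(obs)]), np.abs(null[~np.isnan(null)]))

    out = {
        "single": single,
        "null_r": null,
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "samples": samples,
    }
    if pairs:
        n = len(regulated)
        iu, ju = np.triu_indices(n, k=1)
        dirs = np.array([classes.direction(g) for g in regulated])
        same = dirs[iu] == dirs[ju]
        pair_mat = np.where(same[:, None], log[iu] + log[ju], log[iu] - log[ju])
        pair_r = corr_rows(pair_mat)
        out["pairs"] = pd.DataFrame({
            "gene_a": np.array(regulated)[iu], "gene_b": np.array(regulated)[ju],
            "same_direction": same, "r": pair_r,
        })
    return out


def assign_specificity(reference: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """Cell-type specificity per gene: expression in a type divided by the
    mean over all types (the expected value were the gene uniformly
    expressed).  A gene is assigned to its argmax type when that score exceeds
    ``threshold``; genes expressed similarly across types get no assignment.
    """
    if reference.shape[1] < 2:
        raise ValueError("need at least two cell types")
    expr = reference.to_numpy(dtype=float)
    mean = expr.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(mean[:, None] > 0, expr / mean[:, None], 0.0)
    best = scores.argmax(axis=1)
    best_score = scores.max(axis=1)
    assigned = np.where(best_score > threshold,
                        reference.columns.to_numpy()[best], "")
    assigned = np.where(mean > 0, assigned, "")
    return pd.DataFrame({"cell_type": assigned, "score": best_score},
                        index=reference.index)


def celltype_enrichment(assignments: pd.DataFrame,
                        gene_sets: dict[str, list[str]],
                        background: list[str]) -> pd.DataFrame:
    """Fisher exact enrichment of cell-type-specific genes in each gene set.

    For every (set, cell type): a 2×2 table of set-vs-background membership ×
    specific-to-that-type vs not, two-sided Fisher p with odds ratio.  Empty
    sets are skipped.
    """
    rows = []
    assigned = assignments["cell_type"]
    for set_name, genes in gene_sets.items():
        genes = [g for g in genes if g in assigned.index]
        if not genes:
            continue
        bg = [g for g in background if g in assigned.index and g not in set(genes)]
        for cell_type in sorted({c for c in assigned.unique() if c}):
            in_set = assigned.loc[genes] == cell_type
            in_bg = assigned.loc[bg] == cell_type
            table = np.array([[in_set.sum(), len(genes) - in_set.sum()],
                              [in_bg.sum(), len(bg) - in_bg.sum()]])
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append({"set": set_name, "cell_type": cell_type,
                         "a": table[0, 0], "b": table[0, 1],
                         "c": table[1, 0], "d": table[1, 1],
                         "odds_ratio": odds, "pvalue": p})
    return pd.DataFrame(rows)


def prioritize_biomarkers(correlations: dict, side: SideTables,
                          tpm: ExpressionMatrix, control_label: str) -> pd.DataFrame:
    """Rank regulated genes as CSF-accessible biomarker candidates.

    Ordering is lexicographic: CSF-detectable first, then |R| with the
    splicing score descending, then control-mean log2(TPM+1) descending;
    ties broken by gene identifier for stability.
    """
    single = correlations["single"]
    ctrl = tpm.samples_in_group(control_label)
    log_ctrl = np.log2(tpm.values.loc[single.index, ctrl] + 1.0).mean(axis=1)
    table = pd.DataFrame({
        "direction": np.where(single["direction"] > 0, "up", "down"),
        "r": single["r"],
        "abs_r": single["r"].abs(),
        "control_mean_log2": log_ctrl,
        "csf_detectable": [g in side.csf_detectable for g in single.index],
        "signal_peptide": [bool(side.signal_peptide.get(g, False))
                           for g in single.index],
    }, index=single.index)
    table.index.name = "gene"
    table = (table.reset_index()
             .sort_values(by=["csf_detectable", "abs_r", "control_mean_log2", "gene"],
                          ascending=[False, False, False, True], kind="stable")
             .set_index("gene"))
    table["rank"] = np.arange(1, len(table) + 1)
    return table
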