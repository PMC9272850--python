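"""Mis-splicing detection, shuffle-based FDR, the splicing dysregulation
score, the low-variance display panel and pairwise ψ correlation structure.

The per-event test is a two-sided Wilcoxon rank-sum (Mann–Whitney) on the
non-missing ψ of the two groups.  An event is called significant when
|Δψ| > ``dpsi_min`` (affected mean − unaffected mean) **and** p < ``alpha``.
The false-discovery rate is estimated non-parametrically by permuting group
labels independently for each event and re-running the test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PsiMatrix

__all__ = [
    "SplicingResultSet",
    "SeverityScores",
    "CorrelationDistributions",
    "test_events",
    "estimate_fdr_by_shuffle",
    "splicing_score",
    "select_display_panel",
    "pairwise_correlations",
    "ranksum_matrix",
]


@dataclass
class SplicingResultSet:
    """Per-event outcomes.  ``table`` columns: mean_case, mean_control, dpsi,
    pvalue, testable, significant, direction ('included'/'excluded'/'')."""

    table: pd.DataFrame
    case_label: str
    control_label: str
    dpsi_min: float
    alpha: float

    @property
    def significant_events(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


@dataclass
class SeverityScores:
    """Per-sample dysregulation scores.  ``table`` columns: score, n_events,
    group; splicing (S) and expression (G) scores share this container."""

    table: pd.DataFrame
    kind: str  # "splicing" or "expression"


@dataclass
class CorrelationDistributions:
    observed: np.ndarray
    null: np.ndarray
    ks_statistic: float
    ks_pvalue: float
    n_events: int
    n_skipped_pairs: int


def ranksum_matrix(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p-values for each row of two (events × samples)
    arrays with no missing values.

    The exact null distribution is used whenever the pooled data are tie-free
    and the cohort is of desk scale (≤ 64 samples); tied data fall back to
    the normal approximation with midrank tie correction and continuity
    correction, which keeps discrete ψ estimates conservative.
    """
    n1, n2 = case.shape[1], control.shape[1]
    pooled = np.concatenate([case, control], axis=1)
    has_ties = (np.diff(np.sort(pooled, axis=1), axis=1) == 0).any()
    method = "exact" if (n1 + n2 <= 64 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(case, control, axis=1,
                             alternative="two-sided", method=method)
    return np.atleast_1d(res.pvalue)


def _ranksum_single(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or len(y) < 2:
        return np.nan
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 64 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def test_events(psi: PsiMatrix, case_label: str, control_label: str,
                dpsi_min: float = 0.2, alpha: float = 0.01) -> SplicingResultSet:
    """Rank-sum test of every event between two groups.

    Events with fewer than two non-missing values in either group are marked
    untestable (p = NaN) and are excluded from the multiple-testing family.
    """
    case_samples = psi.samples_in_group(case_label)
    ctrl_samples = psi.samples_in_group(control_label)
    case = psi.values[case_samples].to_numpy(dtype=float)
    ctrl = psi.values[ctrl_samples].to_numpy(dtype=float)

    mean_case = np.nanmean(np.where(np.isnan(case), np.nan, case), axis=1)
    mean_ctrl = np.nanmean(np.where(np.isnan(ctrl), np.nan, ctrl), axis=1)
    with np.errstate(invalid="ignore"):
        dpsi = mean_case - mean_ctrl

    n_case = (~np.isnan(case)).sum(axis=1)
    n_ctrl = (~np.isnan(ctrl)).sum(axis=1)
    testable = (n_case >= 2) & (n_ctrl >= 2)

    pvals = np.full(len(psi.events), np.nan)
    complete = testable & ~np.isnan(case).any(axis=1) & ~np.isnan(ctrl).any(axis=1)
    if complete.any():
        pvals[complete] = ranksum_matrix(case[complete], ctrl[complete])
    for i in np.nonzero(testable & ~complete)[0]:
        x = case[i][~np.isnan(case[i])]
        y = ctrl[i][~np.isnan(ctrl[i])]
        pvals[i] = _ranksum_single(x, y)

    significant = testable & (np.abs(dpsi) > dpsi_min) & (pvals < alpha)
    direction = np.where(significant, np.where(dpsi > 0, "included", "excluded"), "")
    table = pd.DataFrame({
        "mean_case": mean_case, "mean_control": mean_ctrl, "dpsi": dpsi,
        "pvalue": pvals, "n_case": n_case, "n_control": n_ctrl,
        "testable": testable, "significant": significant, "direction": direction,
    }, index=pd.Index(psi.events, name="event_id"))
    return SplicingResultSet(table, case_label, control_label, dpsi_min, alpha)


def estimate_fdr_by_shuffle(psi: PsiMatrix, case_label: str, control_label: str,
                            dpsi_min: float = 0.2, alpha: float = 0.01,
                            n_shuffles: int = 20, seed: int = 0,
                            per_event: bool = True) -> dict:
    """Shuffle-null estimate of the false-discovery rate.

    Group labels are permuted independently for each event (``per_event=True``,
    the default; a cohort-wise single permutation shared by all events is the
    alternative) and the full test is re-run.  The FDR estimate is the mean
    shuffled significant count divided by the observed significant count.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    observed = test_events(psi, case_label, control_label, dpsi_min, alpha)
    n_obs = observed.n_significant()
    rng = np.random.Generator(np.random.PCG64(seed))
    values = psi.values.to_numpy(dtype=float)
    counts = []
    for _ in range(n_shuffles):
        if per_event:
            shuffled = rng.permuted(values, axis=1)
        else:
            shuffled = values[:, rng.permutation(values.shape[1])]
        sh_psi = PsiMatrix(pd.DataFrame(shuffled, index=psi.events,
                                        columns=psi.samples), dict(psi.groups))
        counts.append(test_events(sh_psi, case_label, control_label,
                                  dpsi_min, alpha).n_significant())
    counts = np.array(counts)
    fdr = float(counts.mean() / n_obs) if n_obs > 0 else np.nan
    return {
        "fdr": fdr,
        "n_observed": n_obs,
        "shuffled_counts": counts,
        "mean_shuffled": float(counts.mean()),
        "n_shuffles": n_shuffles,
        "per_event": per_event,
    }


def splicing_score(psi: PsiMatrix, significant_events: list[str],
                   control_label: str) -> SeverityScores:
    """Splicing dysregulation score S per sample: the mean |ψ − μ_e| over the
    significant events, where μ_e is the unaffected-group mean of event e.
    Events missing for a sample are dropped from that sample's mean."""
    if not significant_events:
        raise ValueError("at least one significant event is required")
    missing = [e for e in significant_events if e not in psi.values.index]
    if missing:
        raise ValueError(f"events not in psi matrix: {missing}")
    sub = psi.values.loc[significant_events]
    ctrl = psi.samples_in_group(control_label)
    mu = sub[ctrl].mean(axis=1, skipna=True)
    dev = (sub.sub(mu, axis=0)).abs()
    score = dev.mean(axis=0, skipna=True)
    n_events = dev.notna().sum(axis=0)
    score[n_events == 0] = np.nan
    table = pd.DataFrame({
        "score": score, "n_events": n_events,
        "group": [psi.groups[s] for s in psi.samples],
    }, index=pd.Index(psi.samples, name="sample"))
    return SeverityScores(table, kind="splicing")


def select_display_panel(psi: PsiMatrix, significant_events: list[str],
                         control_label: str, range_max: float = 0.25) -> list[str]:
    """Significant events whose ψ range (max − min, non-missing) among
    unaffected samples is strictly below ``range_max``, ordered by event
    identifier.  Intended for heatmap display with samples ordered by S."""
    ctrl = psi.samples_in_group(control_label)
    sub = psi.values.loc[significant_events, ctrl]
    rng = sub.max(axis=1, skipna=True) - sub.min(axis=1, skipna=True)
    kept = rng.index[rng < range_max]
    return sorted(kept)


def pairwise_correlations(psi: PsiMatrix, events: list[str],
                          n_shuffles: int = 1, seed: int = 0) -> CorrelationDistributions:
    """Pearson R for every pair of the given events across all samples (both
    groups pooled), against a null built by shuffling each event's ψ among
    samples independently and recomputing all pairwise R."""
    if len(events) < 2:
        raise ValueError("need at least two events")
    values = psi.values.loc[events].to_numpy(dtype=float)
    rng = np.random.Generator(np.random.PCG64(seed))

    def all_pairs_r(mat: np.ndarray) -> tuple[np.ndarray, int]:
        ok_rows = ~np.isnan(mat).any(axis=1)
        skipped = 0
        if ok_rows.all():
            sd = mat.std(axis=1)
            keep = sd > 0
            skipped += int((~keep).sum())
            m = mat[keep]
            if len(m) < 2:
                return np.array([]), skipped
            R = np.corrcoef(m)
            iu = np.triu_indices(len(m), k=1)
            return R[iu], skipped
        # missing data: per-pair complete observations
        out = []
        n = mat.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                both = ~np.isnan(mat[i]) & ~np.isnan(mat[j])
                if both.sum() < 3:
                    skipped += 1
                    continue
                xi, xj = mat[i, both], mat[j, both]
                if xi.std() == 0 or xj.std() == 0:
                    skipped += 1
                    continue
                out.append(np.corrcoef(xi, xj)[0, 1])
        return np.array(out), skipped

    observed, skipped = all_pairs_r(values)
    nulls = []
    for _ in range(max(n_shuffles, 1)):
        shuffled = rng.permuted(values, axis=1)
        r, _ = all_pairs_r(shuffled)
        nulls.append(r)
    null = np.concatenate(nulls) if nulls else np.array([])
    if observed.size and null.size:
        ks = stats.ks_2samp(observed, null)
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat, ks_p = np.nan, np.nan
    return CorrelationDistributions(observed, null, ks_stat, ks_p,
                                    n_events=len(events), n_skipped_pairs=skipped)
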