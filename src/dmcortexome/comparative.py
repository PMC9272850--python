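"""Cross-tissue / cross-disease overlap of mis-spliced events, sub-sampling
capture estimates, and placement of patient severity between mouse MBNL-KO
genotypes via orthologous exons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import PsiMatrix
from .splicing import SeverityScores, SplicingResultSet, splicing_score, test_events

__all__ = [
    "OverlapSummary",
    "CaptureEstimate",
    "overlap_datasets",
    "subsample_overlap",
    "ko_severity_placement",
]


@dataclass
class OverlapSummary:
    """Reference-dataset event classification, Venn counts and Δψ concordance."""

    classification: pd.DataFrame      # reference-significant events × class
    venn: dict[str, int]              # joined dataset-name keys -> exclusive counts
    dpsi_correlations: pd.DataFrame   # pairwise Pearson R of Δψ on shared events
    significant: dict[str, list[str]]
    reference_name: str

    def class_fractions(self) -> pd.Series:
        return self.classification["class"].value_counts(normalize=True)


@dataclass
class CaptureEstimate:
    fractions: np.ndarray
    k: int
    reps: int

    def summary(self) -> dict[str, float]:
        lo, med, hi = np.percentile(self.fractions, [2.5, 50, 97.5])
        return {"p2.5": float(lo), "median": float(med), "p97.5": float(hi)}


def _resignify(res: SplicingResultSet, dpsi_min: float, alpha: float) -> pd.DataFrame:
    t = res.table.copy()
    t["significant"] = (t["testable"] & (t["dpsi"].abs() > dpsi_min)
                        & (t["pvalue"] < alpha))
    return t


def overlap_datasets(results: dict[str, SplicingResultSet],
                     dpsi_min: float = 0.1, alpha: float = 0.01,
                     reference_name: str | None = None) -> OverlapSummary:
    """Overlap of significant events across named datasets at a common
    (typically looser) threshold.

    Reference-significant events are classified per other dataset as shared
    (significant there too), expressed_not_dysregulated (testable but not
    significant) or not_expressed (untestable/absent); a single combined class
    uses 'shared' if shared anywhere, else 'expressed_not_dysregulated' if
    testable anywhere, else 'not_expressed'.
    """
    if len(results) < 2:
        raise ValueError("need at least two datasets")
    if reference_name is None:
        reference_name = next(iter(results))
    if reference_name not in results:
        raise ValueError(f"unknown reference dataset {reference_name!r}")

    tables = {name: _resignify(res, dpsi_min, alpha) for name, res in results.items()}
    sig = {name: list(t.index[t["significant"]]) for name, t in tables.items()}

    ref_events = sig[reference_name]
    others = [n for n in tables if n != reference_name]
    rows = []
    for event in ref_events:
        per = {}
        for name in others:
            t = tables[name]
            if event in t.index and t.loc[event, "testable"]:
                per[name] = "shared" if t.loc[event, "significant"] \
                    else "expressed_not_dysregulated"
            else:
                per[name] = "not_expressed"
        if "shared" in per.values():
            combined = "shared"
        elif "expressed_not_dysregulated" in per.values():
            combined = "expressed_not_dysregulated"
        else:
            combined = "not_expressed"
        rows.append({"event_id": event, "class": combined,
                     **{f"in_{n}": per[n] for n in others}})
    classification = pd.DataFrame(rows).set_index("event_id") if rows else \
        pd.DataFrame(columns=["class"]).rename_axis("event_id")

    # exclusive Venn regions over all datasets
    names = list(tables)
    sets = {n: set(sig[n]) for n in names}
    venn: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            venn["&".join(combo)] = len(inside - outside)

    corr_rows = []
    for a, b in combinations(names, 2):
        shared = sorted(sets[a] & sets[b])
        if len(shared) >= 3:
            r, p = stats.pearsonr(tables[a].loc[shared, "dpsi"],
                                  tables[b].loc[shared, "dpsi"])
        else:
            r, p = np.nan, np.nan
        corr_rows.append({"dataset_a": a, "dataset_b": b,
                          "n_shared": len(shared), "r": r, "pvalue": p})
    return OverlapSummary(classification, venn, pd.DataFrame(corr_rows),
                          sig, reference_name)


def subsample_overlap(psi_large: PsiMatrix, case_label: str, control_label: str,
                      k: int, reference_events: list[str],
                      dpsi_min: float = 0.1, alpha: float = 0.01,
                      reps: int = 100, seed: int = 0,
                      subsample_controls: bool = False,
                      n_controls: int | None = None) -> CaptureEstimate:
    """Capture-fraction estimate under case down-sampling.

    Per repetition, ``k`` case samples are drawn without replacement (controls
    kept whole unless ``subsample_controls``), events re-tested, and the
    fraction of ``reference_events`` recovered recorded.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    case = psi_large.samples_in_group(case_label)
    ctrl = psi_large.samples_in_group(control_label)
    if k > len(case):
        raise ValueError(f"k={k} exceeds the {len(case)} case samples")
    if not reference_events:
        raise ValueError("reference_events is empty")
    rng = np.random.Generator(np.random.PCG64(seed))
    ref = set(reference_events)
    fractions = []
    for _ in range(reps):
        cs = list(rng.choice(case, size=k, replace=False))
        ks = list(rng.choice(ctrl, size=n_controls, replace=False)) \
            if subsample_controls and n_controls else ctrl
        sub = psi_large.subset_samples(cs + ks)
        res = test_events(sub, case_label, control_label, dpsi_min, alpha)
        found = set(res.significant_events) & ref
        fractions.append(len(found) / len(ref))
    return CaptureEstimate(np.array(fractions), k=k, reps=reps)


def ko_severity_placement(human_results: SplicingResultSet,
                          human_psi: PsiMatrix,
                          mouse_psi_tables: dict[str, PsiMatrix],
                          ortholog_map: dict[str, str],
                          mouse_case_label: str = "KO",
                          mouse_control_label: str = "WT",
                          human_control_label: str = "unaffected",
                          dpsi_min: float = 0.1, alpha: float = 0.05,
                          dko_name: str | None = None) -> dict:
    """Place patient severity among knockout genotypes on shared orthologous
    exons.

    The shared exon set is: human-significant events (from ``human_results``)
    whose orthologs are significant (|Δψ| > dpsi_min, p < alpha vs WT) in the
    reference knockout genotype (``dko_name``, default the last table) and
    observed (testable) in every mouse dataset.  Splicing dysregulation scores
    are computed per sample against each species' own baseline, and a combined
    ordering across all samples is returned.
    """
    if not ortholog_map:
        raise ValueError("ortholog map is required")
    if len(set(ortholog_map.values())) != len(ortholog_map):
        raise ValueError("ortholog map is not one-to-one")
    if dko_name is None:
        dko_name = list(mouse_psi_tables)[-1]

    mouse_results = {
        name: test_events(psi, mouse_case_label, mouse_control_label,
                          dpsi_min, alpha)
        for name, psi in mouse_psi_tables.items()
    }
    dko_t = mouse_results[dko_name].table
    human_sig = set(human_results.significant_events)
    shared_human = []
    for h_event, m_event in ortholog_map.items():
        if h_event not in human_sig:
            continue
        if m_event not in dko_t.index or not dko_t.loc[m_event, "significant"]:
            continue
        if any(m_event not in r.table.index or not r.table.loc[m_event, "testable"]
               for r in mouse_results.values()):
            continue
        shared_human.append(h_event)
    if not shared_human:
        raise ValueError("empty shared orthologous exon set")
    shared_mouse = [ortholog_map[e] for e in shared_human]

    scores: dict[str, SeverityScores] = {
        "human": splicing_score(human_psi, shared_human, human_control_label)
    }
    for name, psi in mouse_psi_tables.items():
        scores[name] = splicing_score(psi, shared_mouse, mouse_control_label)

    ordering = pd.concat([
        s.table.assign(dataset=name) for name, s in scores.items()
    ]).sort_values("score")
    return {
        "shared_events": shared_human,
        "n_shared": len(shared_human),
        "scores": scores,
        "ordering": ordering,
    }
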