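"""Single-molecule repeat-length mosaicism: span→unit conversion, per-sample
percentile summaries, and correlation with splicing severity.

Repeat-unit estimates are the excess inter-label span over the zero-repeat
reference distance, divided by 3 bp per CTG unit.  Negative estimates are
retained — measurement noise at the normal allele makes them meaningful —
and percentiles operate on the pooled molecule population without separating
normal from expanded alleles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import MoleculeSet
from .splicing import SeverityScores

__all__ = ["spans_to_units", "repeat_percentiles", "correlate_repeats"]


def spans_to_units(molecules: MoleculeSet, reference_flank_bp: float) -> dict[str, np.ndarray]:
    """Convert inter-label spans to CTG repeat-unit estimates:
    ``units = (span − reference_flank_bp) / 3``, unclamped."""
    if reference_flank_bp < 0:
        raise ValueError("reference_flank_bp must be >= 0")
    return {
        sample: (df["span_bp"].to_numpy(dtype=float) - reference_flank_bp) / 3.0
        for sample, df in molecules.molecules.items()
    }


def repeat_percentiles(units: dict[str, np.ndarray],
                       probs: tuple[float, ...] = (50, 75, 90),
                       long_threshold: float = 1000.0) -> pd.DataFrame:
    """Per-sample percentiles of repeat-unit estimates (linear interpolation
    between closest ranks) plus the fraction of molecules above
    ``long_threshold`` units; samples with no molecules get missing values."""
    rows = {}
    for sample, u in units.items():
        u = np.asarray(u, dtype=float)
        if u.size == 0:
            rows[sample] = {f"P{int(p)}": np.nan for p in probs} | {
                "n_molecules": 0, "frac_long": np.nan}
            continue
        pct = np.percentile(u, probs, method="linear")
        rows[sample] = {f"P{int(p)}": float(v) for p, v in zip(probs, pct)}
        rows[sample]["n_molecules"] = int(u.size)
        rows[sample]["frac_long"] = float((u > long_threshold).mean())
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample")


def correlate_repeats(summaries: pd.DataFrame,
                      splicing_scores: SeverityScores) -> pd.DataFrame:
    """Pearson R between each percentile column and the splicing
    dysregulation score, pairwise-complete over samples."""
    pct_cols = [c for c in summaries.columns if c.startswith("P") and c[1:].isdigit()]
    scores = splicing_scores.table["score"]
    shared = [s for s in summaries.index if s in scores.index]
    rows = []
    for col in pct_cols:
        x = summaries.loc[shared, col]
        y = scores.loc[shared]
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < 3:
            raise ValueError(f"fewer than 3 samples with both {col} and scores")
        if x[ok].std() == 0 or y[ok].std() == 0:
            rows.append({"percentile": col, "r": np.nan, "pvalue": np.nan, "n": n})
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append({"percentile": col, "r": float(r), "pvalue": float(p), "n": n})
    return pd.DataFrame(rows).set_index("percentile")
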