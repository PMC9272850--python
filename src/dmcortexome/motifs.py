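"""k-mer enumeration and enrichment around direction-stratified cassette exons.

k-mers are counted in overlapping windows within each of the five regions
around an exon; windows containing ``N`` are skipped.  Enrichment of each
k-mer in a target event set (e.g. aberrantly included exons) over a background
event set (all other skipped exons) is tested per region with a one-sided
upper-tail binomial test, Bonferroni-corrected over the full family of
4^k k-mers × 5 regions within one direction set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import REGION_NAMES, RegionSequences, SideTables

__all__ = ["KmerCounts", "count_kmers", "kmer_enrichment", "join_bindnseq", "all_kmers"]

_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in product("ACGT", repeat=k)]


@dataclass
class KmerCounts:
    """Per-region overlapping k-mer counts and window totals."""

    k: int
    counts: pd.DataFrame  # 4^k k-mers × regions
    totals: pd.Series     # windows counted per region (N-windows excluded)


def _count_one(seq: str, k: int, out: np.ndarray) -> int:
    """Accumulate k-mer code counts of one sequence; returns windows counted."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return 0
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    ids = windows[valid] @ weights
    if ids.size:
        out += np.bincount(ids, minlength=4 ** k)
    return int(valid.sum())


def count_kmers(regions: Iterable[RegionSequences], k: int) -> KmerCounts:
    """Overlapping k-mer counts per region across a set of events."""
    regions = list(regions)
    if not regions:
        raise ValueError("empty region list")
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = {r: np.zeros(4 ** k, dtype=np.int64) for r in REGION_NAMES}
    totals = {r: 0 for r in REGION_NAMES}
    for reg in regions:
        for region, seq in reg.sequences.items():
            totals[region] += _count_one(seq, k, counts[region])
    index = pd.Index(all_kmers(k), name="kmer")
    df = pd.DataFrame({r: counts[r] for r in REGION_NAMES}, index=index)
    return KmerCounts(k, df, pd.Series(totals))


def kmer_enrichment(target_counts: KmerCounts, background_counts: KmerCounts,
                    alpha: float = 0.05, direction_label: str = "",
                    depletion: bool = False) -> pd.DataFrame:
    """Binomial enrichment of every k-mer per region against the background.

    For region r and k-mer w: p0 = background count / background total in r;
    the test is the exact binomial upper tail for x occurrences in n windows
    (lower tail when ``depletion``).  Bonferroni family size = 4^k × number of
    regions.  Rows with x = 0 or zero-background k-mers get p0 floored at one
    pseudo-occurrence to stay defined.
    """
    if target_counts.k != background_counts.k:
        raise ValueError("k mismatch between target and background tables")
    k = target_counts.k
    family = (4 ** k) * len(REGION_NAMES)
    rows = []
    for region in REGION_NAMES:
        n = int(target_counts.totals[region])
        n_bg = int(background_counts.totals[region])
        if n_bg <= 0:
            raise ValueError(f"background total is zero for region {region!r}")
        x = target_counts.counts[region].to_numpy()
        bg = background_counts.counts[region].to_numpy()
        p0 = np.maximum(bg, 1) / n_bg
        if depletion:
            pvals = stats.binom.cdf(x, n, p0)
        else:
            pvals = stats.binom.sf(x - 1, n, p0)  # P(X >= x)
        ratio = np.where(n > 0, (x / max(n, 1)) / p0, np.nan)
        rows.append(pd.DataFrame({
            "kmer": target_counts.counts.index,
            "region": region,
            "direction": direction_label,
            "x": x, "n": n, "p0": p0,
            "enrichment": ratio,
            "pvalue": pvals,
        }))
    table = pd.concat(rows, ignore_index=True)
    table["p_bonferroni"] = np.minimum(table["pvalue"] * family, 1.0)
    table["significant"] = table["p_bonferroni"] < alpha
    table.attrs["family_size"] = family
    table.attrs["k"] = k
    return table


def join_bindnseq(table: pd.DataFrame, side: SideTables) -> pd.DataFrame:
    """Left-join in-vitro Bind-N-Seq per-k-mer enrichments onto the motif
    table; k-mers absent from an assay are left missing, never zeroed."""
    out = table.copy()
    k = table.attrs.get("k") or len(table["kmer"].iloc[0])
    for protein, kmer_table in side.bindnseq.items():
        klen = {len(x) for x in kmer_table}
        if klen and klen != {k}:
            raise ValueError(
                f"bindnseq[{protein}] k-mer length {sorted(klen)} != table k {k}")
        out[f"bindnseq_{protein}"] = out["kmer"].map(kmer_table)
    out.attrs.update(table.attrs)
    return out
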