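"""Distance-resolved Fisher enrichment of gene sets near binding regions.

For each distance threshold x on a log grid, genes are split by whether
their TSS lies within x bp of the nearest region summit, and a one-sided
Fisher exact test asks whether the responsive set is enriched among the
near genes.  The ranked sliding-window fraction statistic summarises how a
binary gene label varies along a ranked heatmap.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import ConsensusRegion, GeneModel


def nearest_distance(
    genes: Sequence[GeneModel], regions: Sequence[ConsensusRegion]
) -> Dict[str, float]:
    """Gene -> bp distance from its TSS to the nearest region summit.

    0 when the TSS falls inside a region; +inf for genes on chromosomes
    carrying no region.
    """
    if not regions:
        raise ValueError("empty region set")
    summits: Dict[str, List[int]] = {}
    spans: Dict[str, List[Tuple[int, int]]] = {}
    for r in regions:
        if r.summit is None:
            raise ValueError("regions must have summits")
        summits.setdefault(r.interval.chrom, []).append(r.summit)
        spans.setdefault(r.interval.chrom, []).append((r.interval.start, r.interval.end))
    sorted_summits = {c: np.sort(np.array(v)) for c, v in summits.items()}

    out: Dict[str, float] = {}
    for g in genes:
        chrom = g.interval.chrom
        tss = g.tss
        if chrom not in sorted_summits:
            out[g.gene_id] = float("inf")
            continue
        if any(s <= tss < e for s, e in spans[chrom]):
            out[g.gene_id] = 0.0
            continue
        arr = sorted_summits[chrom]
        i = np.searchsorted(arr, tss)
        cand = []
        if i > 0:
            cand.append(abs(tss - arr[i - 1]))
        if i < arr.size:
            cand.append(abs(arr[i] - tss))
        out[g.gene_id] = float(min(cand))
    return out


def distance_grid(n: int = 50, lo: float = 1.0, hi: float = 1e8) -> np.ndarray:
    """Log-spaced distance thresholds over [lo, hi]."""
    return np.geomspace(lo, hi, n)


def fisher_curve(
    responsive: Sequence[str],
    universe: Sequence[str],
    distances: Dict[str, float],
    grid: np.ndarray = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """One-sided Fisher enrichment of the responsive set within x bp, per x.

    At each threshold x the 2x2 table is (responsive within x, responsive
    beyond, non-responsive within, non-responsive beyond).  Returns a
    DataFrame with the table entries, odds ratio, p and -log10 p per x.
    """
    if grid is None:
        grid = distance_grid()
    universe = list(universe)
    rset = set(responsive)
    if not rset:
        raise ValueError("responsive set is empty")
    if not rset < set(universe):
        if rset == set(universe):
            raise ValueError("responsive set equals the universe")
        raise ValueError("responsive set must be a subset of the universe")
    d = np.array([distances[g] for g in universe])
    is_resp = np.array([g in rset for g in universe])
    rows = []
    for x in np.asarray(grid):
        within = d <= x
        a = int((is_resp & within).sum())
        b = int((is_resp & ~within).sum())
        c = int((~is_resp & within).sum())
        dd = int((~is_resp & ~within).sum())
        odds, p = stats.fisher_exact([[a, b], [c, dd]], alternative=alternative)
        rows.append(
            {
                "x": float(x),
                "responsive_within": a,
                "responsive_beyond": b,
                "background_within": c,
                "background_beyond": dd,
                "odds_ratio": float(odds),
                "pvalue": float(p),
                "neg_log10_p": float(-np.log10(max(p, 1e-320))),
            }
        )
    return pd.DataFrame(rows)


def sliding_window_fraction(
    labels: Sequence[bool], window: int = 500, step: int = 1
) -> np.ndarray:
    """Fraction of positive labels in each contiguous window along a ranking."""
    lab = np.asarray(labels, dtype=float)
    n = lab.size
    if window > n:
        raise ValueError(f"window {window} exceeds list length {n}")
    csum = np.concatenate([[0.0], np.cumsum(lab)])
    frac = (csum[window:] - csum[:-window]) / window
    return frac[::step]
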