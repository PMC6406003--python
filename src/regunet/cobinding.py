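"""Co-binding trace quantification, normalisation, k-means and k selection.

The feature vector clustered for each region j is the max-normalised trace

    tau_j = (t_1j / sigma_1, ..., t_nj / sigma_n),   taubar_j = tau_j / max_k tau_jk

where t_ij concatenates the +Dox and -Dox binned rpm traces of factor i at
region j and sigma_i is the total +Dox occupancy of factor i over all regions
and positions.  Dividing by sigma_i removes global occupancy differences
between factors; dividing by the per-region maximum removes occupancy
differences between regions, so clusters reflect binding *patterns* only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import comb
from sklearn.cluster import KMeans

from .simulate import ReadTrack
from .types import ConsensusRegion

logger = logging.getLogger(__name__)


@dataclass
class SignalMatrix:
    """Binned, depth-normalised, replicate-averaged read counts.

    ``h`` has shape (n_factors, n_conditions, n_regions, n_bins) in rpm per
    bin; ``window``/``bin_bp`` describe the quantification geometry centred
    on each region summit.
    """

    h: np.ndarray
    factors: List[str]
    conditions: List[str]
    region_ids: List[str]
    window: int
    bin_bp: int

    @property
    def n_bins(self) -> int:
        return self.h.shape[3]


@dataclass
class NormalizedTraceSet:
    """Occupancy-scaled, max-normalised concatenated traces (the taubar_j)."""

    X: np.ndarray  # (n_clustered_regions, n_features)
    region_ids: List[str]
    excluded_ids: List[str]  # regions whose tau was all-zero
    factors: List[str]
    conditions: List[str]
    sigma: Dict[str, float]


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    assignment: Dict[str, int]
    seed: int
    inertia: float


@dataclass
class KSelectionReport:
    """Rand indices between assignments at consecutive k, and a recommendation.

    ``rand`` maps k -> RI(k, k+1); ``recommended_k`` is the smallest k whose
    RI with k+1 reaches the stability threshold (final choice rests with the
    analyst).
    """

    rand: Dict[int, float]
    recommended_k: Optional[int]
    threshold: float
    assignments: Dict[int, np.ndarray] = field(default_factory=dict)


def quantify_traces(
    regions: Sequence[ConsensusRegion],
    reads: Dict[Tuple[str, str], List[ReadTrack]],
    chrom_sizes: Dict[str, int],
    window: int = 1000,
    bin_bp: int = 10,
) -> SignalMatrix:
    """Per-bin rpm read-start counts in a window centred on each summit.

    Counts are rpm-normalised per replicate then averaged over the replicates
    of each (factor, condition).  Regions whose window would cross a
    chromosome edge are dropped with a logged warning.
    """
    if window % bin_bp != 0 or window % 2 != 0:
        raise ValueError("window must be an even multiple of bin_bp")
    factors = sorted({f for f, _ in reads})
    conditions = sorted({c for _, c in reads})
    if "+Dox" in conditions:  # +Dox leads, matching the trace concatenation order
        conditions = ["+Dox"] + [c for c in conditions if c != "+Dox"]
    half = window // 2
    m = window // bin_bp

    kept, region_ids = [], []
    for r in regions:
        if r.summit is None:
            raise ValueError("every region needs a summit")
        size = chrom_sizes.get(r.interval.chrom)
        if size is None:
            raise ValueError(f"unknown chromosome {r.interval.chrom}")
        if r.summit - half < 0 or r.summit + half > size:
            logger.warning(
                "dropping region %s: window crosses chromosome edge", r.interval.name
            )
            continue
        kept.append(r)
        region_ids.append(r.interval.name)

    edges = np.array(
        [[r.summit - half + b * bin_bp for b in range(m + 1)] for r in kept]
    )
    h = np.zeros((len(factors), len(conditions), len(kept), m))
    for fi, f in enumerate(factors):
        for ci, c in enumerate(conditions):
            reps = reads.get((f, c))
            if not reps:
                raise ValueError(f"no reads declared for factor {f} in {c}")
            for track in reps:
                per_rep = np.zeros((len(kept), m))
                for chrom in {r.interval.chrom for r in kept}:
                    pos = track.positions.get(chrom, np.empty(0, dtype=np.int64))
                    rows = [i for i, r in enumerate(kept) if r.interval.chrom == chrom]
                    if not rows:
                        continue
                    e = np.searchsorted(pos, edges[rows])
                    per_rep[rows] = np.diff(e, axis=1)
                h[fi, ci] += per_rep * 1e6 / track.library_size
            h[fi, ci] /= len(reps)
    return SignalMatrix(h, factors, conditions, region_ids, window, bin_bp)


def split_solo_cobinding(
    signal: SignalMatrix, threshold_rpm: float = 2.7
) -> Tuple[List[str], List[str]]:
    """Partition regions into solo and co-binding ids.

    A region is co-binding iff the maximum bin value of at least one factor
    in at least one condition reaches ``threshold_rpm`` (inclusive).
    """
    if threshold_rpm <= 0:
        raise ValueError("threshold must be positive")
    peak = signal.h.max(axis=3)  # (factor, cond, region)
    cobind = (peak >= threshold_rpm).any(axis=(0, 1))
    solo = [r for r, c in zip(signal.region_ids, cobind) if not c]
    co = [r for r, c in zip(signal.region_ids, cobind) if c]
    return solo, co


def normalize_traces(
    signal: SignalMatrix,
    factors: Optional[Sequence[str]] = None,
    region_ids: Optional[Sequence[str]] = None,
    flank: int = 250,
) -> NormalizedTraceSet:
    """Compute the taubar_j feature vectors over the central +/- ``flank`` bp.

    sigma_i is the summed +Dox signal of factor i over the clustered regions
    and restricted positions; an all-zero sigma is an error naming the
    factor.  Regions whose tau is all-zero are excluded and reported.
    """
    if factors is None:
        factors = signal.factors
    idx_f = [signal.factors.index(f) for f in factors]
    if region_ids is None:
        region_ids = signal.region_ids
    ridx = [signal.region_ids.index(r) for r in region_ids]

    center = signal.n_bins // 2
    nb = flank // signal.bin_bp
    sl = slice(center - nb, center + nb)
    try:
        plus = signal.conditions.index("+Dox")
    except ValueError:
        plus = 0

    # (factor, cond, region, bin) restricted
    hr = signal.h[np.ix_(idx_f, range(len(signal.conditions)), ridx)][:, :, :, sl]
    sigma = {}
    blocks = []
    for i, f in enumerate(factors):
        s = float(hr[i, plus].sum())
        if s <= 0:
            raise ValueError(f"factor {f} has zero +Dox occupancy (sigma = 0)")
        sigma[f] = s
        # concatenate conditions, +Dox first
        order = [plus] + [c for c in range(hr.shape[1]) if c != plus]
        blocks.append(np.concatenate([hr[i, c] for c in order], axis=1) / s)
    tau = np.concatenate(blocks, axis=1)  # (regions, features)

    maxima = tau.max(axis=1)
    nonzero = maxima > 0
    X = tau[nonzero] / maxima[nonzero, None]
    kept = [r for r, ok in zip(region_ids, nonzero) if ok]
    excluded = [r for r, ok in zip(region_ids, nonzero) if not ok]
    return NormalizedTraceSet(
        X, kept, excluded, list(factors), list(signal.conditions), sigma
    )


def kmeans_cluster(
    traces: NormalizedTraceSet,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> ClusterModel:
    """Euclidean k-means on the taubar_j (k-means++ init, best of n_init)."""
    n = traces.X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds the {n} clustered regions")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        tol=1e-6,
        random_state=seed,
    ).fit(traces.X)
    assignment = {r: int(l) for r, l in zip(traces.region_ids, km.labels_)}
    return ClusterModel(k, km.cluster_centers_, assignment, seed, float(km.inertia_))


def rand_index(a: Sequence, b: Sequence) -> float:
    """Rand index between two partitions of the same objects.

    Fraction of object pairs on which the partitions agree (grouped together
    in both, or apart in both).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same objects")
    n = a.size
    if n < 2:
        return 1.0
    ct = pd.crosstab(a, b).to_numpy()
    sum_ij = comb(ct, 2).sum()
    sum_a = comb(ct.sum(axis=1), 2).sum()
    sum_b = comb(ct.sum(axis=0), 2).sum()
    total = comb(n, 2)
    return float((total + 2 * sum_ij - sum_a - sum_b) / total)


def select_k(
    traces: NormalizedTraceSet,
    k_range: Tuple[int, int] = (2, 20),
    seed: int = 0,
    stability_threshold: float = 0.9,
    n_init: int = 10,
) -> KSelectionReport:
    """Cluster at every k in range and report RI between consecutive k.

    The same seed is used for every k.  The recommended k is the smallest
    one whose assignment agrees with k+1 at Rand index >= the threshold.
    """
    kmin, kmax = k_range
    n = traces.X.shape[0]
    if kmin < 2 or kmax < kmin or kmax + 1 > n - 1:
        raise ValueError(f"degenerate k range {k_range} for {n} regions")
    labels = {}
    for k in range(kmin, kmax + 2):
        model = kmeans_cluster(traces, k, seed=seed, n_init=n_init)
        labels[k] = np.array([model.assignment[r] for r in traces.region_ids])
    rand = {k: rand_index(labels[k], labels[k + 1]) for k in range(kmin, kmax + 1)}
    recommended = next(
        (k for k in range(kmin, kmax + 1) if rand[k] >= stability_threshold), None
    )
    return KSelectionReport(rand, recommended, stability_threshold, labels)


def cluster_summary(
    model: ClusterModel,
    signal: SignalMatrix,
    nanog_signal: Optional[Dict[str, float]] = None,
) -> Tuple[pd.DataFrame, List[str]]:
    """Per-cluster mean profiles and a heatmap-ready region ordering.

    Returns a long-format DataFrame (cluster, factor, condition, bin, mean
    rpm) and the region order: by cluster id, then by descending Nanog
    signal when given (falling back to the region's own summed signal).
    """
    ridx = {r: i for i, r in enumerate(signal.region_ids)}
    rows = []
    for c in sorted(set(model.assignment.values())):
        members = [ridx[r] for r in model.assignment if model.assignment[r] == c]
        mean = signal.h[:, :, members, :].mean(axis=2)  # (factor, cond, bin)
        for fi, f in enumerate(signal.factors):
            for ci, cond in enumerate(signal.conditions):
                for b in range(signal.n_bins):
                    rows.append(
                        {
                            "cluster": c,
                            "factor": f,
                            "condition": cond,
                            "bin": b,
                            "mean_rpm": mean[fi, ci, b],
                        }
                    )
    df = pd.DataFrame(rows)

    def sort_key(r: str) -> Tuple[int, float]:
        if nanog_signal is not None:
            strength = nanog_signal.get(r, 0.0)
        else:
            strength = float(signal.h[:, :, ridx[r], :].sum())
        return (model.assignment[r], -strength)

    order = sorted(model.assignment, key=sort_key)
    return df, order
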