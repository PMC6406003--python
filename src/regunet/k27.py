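"""Broad H3K27me3 domain assembly, replicate QC, dynamics and gene embedding.

Broad peaks from all samples are pooled and merged transitively whenever the
gap between them is at most 3 kb; domains are kept when supported by at
least 8 samples.  Replicates that dominate their condition (strict
within-condition maximum in >= 60% of domains) are flagged as outliers and
excluded before dynamics are clustered (k-means, k = 3, on condition means
max-normalised per domain).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

from .simulate import ReadTrack
from .types import GeneModel, GenomicInterval, K27Domain, PeakCall


def merge_domains(
    peak_sets: Dict[str, List[PeakCall]],
    gap_bp: int = 3000,
    min_support: int = 8,
) -> List[K27Domain]:
    """Pool broad peaks, merge within ``gap_bp`` and filter by sample support.

    Intervals whose inter-peak gap is <= ``gap_bp`` (inclusive) merge
    transitively; support counts distinct samples with >= 1 bp overlap with
    the merged interval.  Domains supported by fewer than ``min_support``
    samples are dropped.  Output is sorted and non-overlapping.
    """
    if gap_bp < 0:
        raise ValueError("gap_bp must be >= 0")
    if len(peak_sets) < min_support:
        raise ValueError(
            f"only {len(peak_sets)} samples provided, min_support = {min_support}"
        )
    pooled = [
        (p.interval.chrom, p.interval.start, p.interval.end, p.sample_id)
        for peaks in peak_sets.values()
        for p in peaks
    ]
    pooled.sort(key=lambda t: (t[0], t[1], t[2]))
    domains: List[K27Domain] = []
    cur: Optional[list] = None
    for chrom, start, end, sid in pooled:
        if cur is not None and chrom == cur[0] and start - cur[2] <= gap_bp:
            cur[2] = max(cur[2], end)
            cur[3].add(sid)
        else:
            if cur is not None:
                domains.append(_finish(cur))
            cur = [chrom, start, end, {sid}]
    if cur is not None:
        domains.append(_finish(cur))
    return [d for d in domains if d.support >= min_support]


def _finish(cur: list) -> K27Domain:
    chrom, start, end, sids = cur
    return K27Domain(
        interval=GenomicInterval(chrom, start, end, name=f"{chrom}:{start}-{end}"),
        support=len(sids),
    )


def count_reads_in_domains(
    tracks: Dict[str, ReadTrack], domains: Sequence[K27Domain]
) -> Tuple[List[str], List[str], np.ndarray]:
    """Domain x sample matrix of read starts falling inside each domain.

    A read counts toward a domain iff its start lies in [start, end).
    """
    sample_ids = list(tracks)
    matrix = np.zeros((len(domains), len(sample_ids)), dtype=np.int64)
    for si, sid in enumerate(sample_ids):
        track = tracks[sid]
        for di, d in enumerate(domains):
            pos = track.positions.get(d.interval.chrom)
            if pos is None:
                continue
            lo, hi = np.searchsorted(pos, [d.interval.start, d.interval.end])
            matrix[di, si] = hi - lo
            d.counts[sid] = int(hi - lo)
    domain_ids = [d.interval.name for d in domains]
    return domain_ids, sample_ids, matrix


def flag_outlier_replicates(
    matrix: np.ndarray,
    sample_ids: Sequence[str],
    condition_groups: Dict[str, List[str]],
    frac_threshold: float = 0.6,
) -> Dict[str, Tuple[float, bool]]:
    """Flag replicates that are the strict within-condition maximum too often.

    For each sample, computes the fraction of domains where its count is the
    strict maximum among its condition's replicates (ties count for no
    sample); the sample is excluded iff that fraction >= ``frac_threshold``.
    """
    col = {sid: i for i, sid in enumerate(sample_ids)}
    out: Dict[str, Tuple[float, bool]] = {}
    for cond, members in condition_groups.items():
        if len(members) < 2:
            raise ValueError(f"condition {cond} has fewer than 2 replicates")
        sub = matrix[:, [col[m] for m in members]]  # (domains, reps)
        order = np.sort(sub, axis=1)
        strict = order[:, -1] > order[:, -2]  # unique maximum exists
        argmax = np.argmax(sub, axis=1)
        for ri, sid in enumerate(members):
            frac = float(np.mean(strict & (argmax == ri)))
            out[sid] = (frac, frac >= frac_threshold)
    return out


def cluster_domain_dynamics(
    matrix: np.ndarray,
    sample_ids: Sequence[str],
    condition_groups: Dict[str, List[str]],
    retained: Optional[Sequence[str]] = None,
    k: int = 3,
    seed: int = 0,
    lif_plus_conditions: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, Dict[int, str], np.ndarray]:
    """Max-normalised condition-mean k-means with post-hoc class labels.

    Per domain, the mean count of each condition (over retained replicates)
    is divided by the maximum over conditions; k-means with k = 3 groups the
    resulting profiles.  Centroids are labelled by the sign of their mean
    -LIF minus +LIF difference: the largest positive difference is
    ``lif_gain``, the most negative ``lif_loss``, the rest ``stable``.

    Returns (labels per domain, cluster id -> class name, condition means).
    """
    if matrix.shape[0] < k:
        raise ValueError("need at least k domains")
    col = {sid: i for i, sid in enumerate(sample_ids)}
    conds = list(condition_groups)
    means = np.zeros((matrix.shape[0], len(conds)))
    for ci, cond in enumerate(conds):
        members = condition_groups[cond]
        if retained is not None:
            members = [m for m in members if m in set(retained)]
        if not members:
            raise ValueError(f"no retained replicates for condition {cond}")
        means[:, ci] = matrix[:, [col[m] for m in members]].mean(axis=1)
    maxima = means.max(axis=1)
    if (maxima == 0).any():
        raise ValueError("all-zero domain cannot be max-normalised")
    norm = means / maxima[:, None]

    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(norm)
    if lif_plus_conditions is None:
        lif_plus_conditions = [c for c in conds if "LIFp" in c or "LIF+" in c]
    plus_idx = [conds.index(c) for c in lif_plus_conditions]
    minus_idx = [i for i in range(len(conds)) if i not in plus_idx]
    diff = km.cluster_centers_[:, minus_idx].mean(axis=1) - km.cluster_centers_[
        :, plus_idx
    ].mean(axis=1)
    labels_map = {int(np.argmax(diff)): "lif_gain", int(np.argmin(diff)): "lif_loss"}
    for c in range(k):
        labels_map.setdefault(c, "stable")
    return km.labels_, labels_map, means


def assign_genes_to_domains(
    genes: Sequence[GeneModel],
    domains: Sequence[K27Domain],
    tss_window: int = 4000,
) -> Dict[str, Optional[str]]:
    """Gene -> responsible domain name (None when not embedded).

    A gene is embedded iff its body overlaps a domain by >= 1 bp, or a
    domain lies within ``tss_window`` of its TSS *and* that domain overlaps
    no other gene.
    """
    out: Dict[str, Optional[str]] = {}
    # precompute, per domain, the set of genes whose bodies overlap it
    overlap: Dict[str, set] = {d.interval.name: set() for d in domains}
    for g in genes:
        for d in domains:
            if g.interval.overlaps(d.interval):
                overlap[d.interval.name].add(g.gene_id)
    for g in genes:
        hit: Optional[str] = None
        for d in domains:
            if d.interval.chrom != g.interval.chrom:
                continue
            if g.gene_id in overlap[d.interval.name]:
                hit = d.interval.name
                break
            tss = g.tss
            dist = max(d.interval.start - tss, tss - (d.interval.end - 1), 0)
            others = overlap[d.interval.name] - {g.gene_id}
            if dist <= tss_window and not others:
                hit = d.interval.name
                break
        out[g.gene_id] = hit
    return out
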