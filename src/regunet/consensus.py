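"""Consensus binding regions from multiple peak-call sets, plus ATAC cut sites.

Peaks from all samples are pooled and union-merged (>= 1 bp overlap), the
number of distinct supporting samples is attached to each merged region, and
regions are filtered by support and by mean summit height in reads per
million.  All threshold comparisons are inclusive (>=).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .simulate import ReadTrack
from .types import ConsensusRegion, GenomicInterval, PeakCall


def build_consensus(
    peak_sets: Dict[str, List[PeakCall]],
    blacklist: Sequence[GenomicInterval] = (),
    excluded_chroms: Set[str] = frozenset(),
    min_support: int = 2,
) -> List[ConsensusRegion]:
    """Union-merge peaks across samples into supported consensus regions.

    Peaks overlapping a blacklist interval by >= 1 bp or lying on an excluded
    chromosome are removed first.  Remaining peaks merge transitively whenever
    they share >= 1 bp; each merged region's support is the number of distinct
    samples contributing at least one peak.  Regions with support below
    ``min_support`` are dropped.  Output is sorted and non-overlapping.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if not peak_sets:
        raise ValueError("need at least one peak set")

    bl_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in blacklist:
        bl_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    pooled: List[Tuple[str, int, int, str]] = []
    for sid, peaks in peak_sets.items():
        for p in peaks:
            iv = p.interval
            if iv.chrom in excluded_chroms:
                continue
            if any(
                iv.start < e and s < iv.end
                for s, e in bl_by_chrom.get(iv.chrom, ())
            ):
                continue
            pooled.append((iv.chrom, iv.start, iv.end, p.sample_id))

    pooled.sort(key=lambda t: (t[0], t[1], t[2]))
    regions: List[ConsensusRegion] = []
    cur: Optional[list] = None  # [chrom, start, end, sample set]
    for chrom, start, end, sid in pooled:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(sid)
        else:
            if cur is not None:
                regions.append(_finish(cur))
            cur = [chrom, start, end, {sid}]
    if cur is not None:
        regions.append(_finish(cur))
    return [r for r in regions if r.support >= min_support]


def _finish(cur: list) -> ConsensusRegion:
    chrom, start, end, sids = cur
    return ConsensusRegion(
        interval=GenomicInterval(chrom, start, end, name=f"{chrom}:{start}-{end}"),
        support=len(sids),
    )


def _region_counts(
    region: ConsensusRegion, track: ReadTrack
) -> np.ndarray:
    """Per-bp read-start counts within the region for one sample."""
    iv = region.interval
    pos = track.positions.get(iv.chrom)
    n = len(iv)
    if pos is None or pos.size == 0:
        return np.zeros(n, dtype=np.int64)
    lo, hi = np.searchsorted(pos, [iv.start, iv.end])
    return np.bincount(pos[lo:hi] - iv.start, minlength=n)


def height_filter(
    regions: Sequence[ConsensusRegion],
    tracks: Dict[str, ReadTrack],
    min_rpm: float = 1.0,
) -> List[ConsensusRegion]:
    """Keep regions whose mean per-sample summit height is >= ``min_rpm``.

    Per-sample height is the maximum per-bp read-start count within the
    region, scaled to reads per million by that sample's library size; the
    mean over samples is stored on each retained region.
    """
    for sid, tr in tracks.items():
        if tr.library_size <= 0:
            raise ValueError(f"library_size must be positive for {sid}")
    out = []
    for r in regions:
        heights = [
            _region_counts(r, tr).max() * 1e6 / tr.library_size
            for tr in tracks.values()
        ]
        mean_h = float(np.mean(heights))
        if mean_h >= min_rpm:
            r.mean_height_rpm = mean_h
            out.append(r)
    return out


def locate_summit(region: ConsensusRegion, coverage: np.ndarray) -> int:
    """Absolute position of maximal averaged coverage; leftmost tie wins."""
    coverage = np.asarray(coverage)
    if coverage.size != len(region.interval):
        raise ValueError("coverage must cover the region exactly")
    if coverage.size == 0:
        raise ValueError("empty region")
    return region.interval.start + int(np.argmax(coverage))


def locate_summits(
    regions: Sequence[ConsensusRegion], tracks: Dict[str, ReadTrack]
) -> List[ConsensusRegion]:
    """Set each region's summit from coverage averaged over the given samples."""
    for r in regions:
        cov = np.zeros(len(r.interval), dtype=float)
        for tr in tracks.values():
            cov += _region_counts(r, tr)
        r.summit = locate_summit(r, cov)
    return list(regions)


def atac_cutsites(
    replicate_fragments: Sequence[Sequence[Tuple[str, int, int]]],
    chrom_sizes: Dict[str, int],
    shift: int = 4,
    normalize: bool = True,
) -> Dict[str, np.ndarray]:
    """Cut-site track from paired-end fragments, averaged over replicates.

    For a fragment [s, e) the two transposition cut sites are taken as
    ``s + shift`` and ``(e - 1) - shift`` (both coordinates shifted inwards);
    each cut site contributes +1 at the site and at both flanking bases.
    Each replicate track is scaled to reads per million by its fragment
    count, then replicates are averaged.
    """
    tracks = []
    for frags in replicate_fragments:
        t = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
        nfrag = 0
        for chrom, s, e in frags:
            if e - s < 2 * shift + 1:
                raise ValueError(
                    f"fragment [{s},{e}) shorter than {2 * shift + 1} bp: "
                    "cut sites would cross"
                )
            nfrag += 1
            arr = t[chrom]
            for site in (s + shift, (e - 1) - shift):
                lo = max(site - 1, 0)
                hi = min(site + 2, arr.size)
                arr[lo:hi] += 1.0
        if nfrag == 0:
            raise ValueError("replicate with no fragments")
        if normalize:
            for arr in t.values():
                arr *= 1e6 / nfrag
        tracks.append(t)
    out = {}
    for chrom in chrom_sizes:
        out[chrom] = np.mean([t[chrom] for t in tracks], axis=0)
    return out
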