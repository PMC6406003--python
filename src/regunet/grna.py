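"""SpCas9 gRNA candidate enumeration, filtering and off-target counting.

Candidates are every 20-nt protospacer immediately 5' of an NGG PAM, on
both strands of the input sequence.  Filters: GC content within an
inclusive percentage range and no single-base homopolymer run of 4 or
more.  Off-targets are counted per Hamming-mismatch class over both
strands of subject sequences, requiring an NGG PAM at the site; ranking
and efficiency scoring are deliberately left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")
_ALLOWED = set("ACGTN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class GuideCandidate:
    """A 20-nt protospacer with NGG immediately 3' on its strand.

    ``position`` is the 0-based start of the protospacer on the + reference
    (for '-' strand guides this is the leftmost base of the site on the
    reference, i.e. reference position of the protospacer's last base).
    """

    protospacer: str
    strand: str
    position: int
    gc_percent: float = 0.0
    gc_pass: bool = True
    homopolymer_pass: bool = True

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be exactly 20 nt")


def _check_seq(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _ALLOWED
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters {sorted(bad)}")
    return seq


def enumerate_guides(sequence: str) -> List[GuideCandidate]:
    """All 20-nt + NGG candidates on both strands; no filters applied.

    A '+' candidate sits at i where sequence[i+21:i+23] == 'GG' (the PAM's
    first base is the N).  A '-' candidate corresponds to a CCN..N pattern
    on the + strand: sequence[j:j+2] == 'CC' with the protospacer being the
    reverse complement of sequence[j+3:j+23].
    """
    seq = _check_seq(sequence)
    if len(seq) < 23:
        raise ValueError("sequence must be at least 23 nt")
    out: List[GuideCandidate] = []
    for i in range(len(seq) - 22):
        if seq[i + 21 : i + 23] == "GG":
            out.append(GuideCandidate(seq[i : i + 20], "+", i))
        if seq[i : i + 2] == "CC":
            out.append(GuideCandidate(revcomp(seq[i + 3 : i + 23]), "-", i + 3))
    return out


def _gc_percent(protospacer: str) -> float:
    return 100.0 * sum(b in "GC" for b in protospacer) / len(protospacer)


def _max_run(protospacer: str) -> int:
    best = run = 1
    for a, b in zip(protospacer, protospacer[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def filter_guides(
    candidates: Sequence[GuideCandidate],
    gc_range: tuple = (35.0, 85.0),
    max_homopolymer: int = 3,
) -> List[GuideCandidate]:
    """Flag and keep candidates passing GC (inclusive) and homopolymer rules."""
    lo, hi = gc_range
    kept = []
    for cand in candidates:
        cand.gc_percent = _gc_percent(cand.protospacer)
        cand.gc_pass = lo <= cand.gc_percent <= hi
        cand.homopolymer_pass = _max_run(cand.protospacer) <= max_homopolymer
        if cand.gc_pass and cand.homopolymer_pass:
            kept.append(cand)
    return kept


def _mismatches(guide: str, site: str) -> int:
    """Hamming mismatches; N never matches (in guide or site)."""
    return sum(a != b or a == "N" or b == "N" for a, b in zip(guide, site))


def count_offtargets(
    guide: str,
    subjects: Dict[str, str],
    max_mismatches: int = 4,
) -> Dict[int, int]:
    """Histogram of PAM-adjacent sites by mismatch count (0..max_mismatches).

    Slides the 20-mer over both strands of every subject sequence; a site
    requires G at PAM positions 2 and 3 (N in position 1 matches anything).
    Sites with more than ``max_mismatches`` mismatches are ignored.  The
    exclusion decision (e.g. dropping guides with <= 2-mismatch hits beyond
    the intended site) is left to the caller.
    """
    guide = _check_seq(guide)
    if len(guide) != 20:
        raise ValueError("guide must be exactly 20 nt")
    hist = {m: 0 for m in range(max_mismatches + 1)}
    for seq in subjects.values():
        seq = _check_seq(seq)
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - 22):
                if strand_seq[i + 21 : i + 23] != "GG":
                    continue
                mm = _mismatches(guide, strand_seq[i : i + 20])
                if mm <= max_mismatches:
                    hist[mm] += 1
    return hist
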