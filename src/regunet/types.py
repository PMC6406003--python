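"""Core domain records shared by every pipeline stage.

All coordinates are 0-based, half-open (BED-native).  Conversion to and from
1-based coordinates happens only at file-format boundaries, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_STRANDS = {"+", "-", "."}


@dataclass
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(VALID_STRANDS)}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PeakCall:
    """A single peak call from one sample.

    ``summit_offset`` is relative to ``interval.start`` (narrowPeak column 10);
    ``None`` when the dialect carries no summit (broadPeak, plain BED).
    ``height`` is the dialect's signal value (reads or rpm).
    """

    interval: GenomicInterval
    sample_id: str
    summit_offset: Optional[int] = None
    height: float = 0.0

    def __post_init__(self) -> None:
        if self.summit_offset is not None:
            if not 0 <= self.summit_offset < len(self.interval):
                raise ValueError(
                    f"summit_offset {self.summit_offset} outside peak of length "
                    f"{len(self.interval)}"
                )

    @property
    def summit(self) -> Optional[int]:
        """Absolute summit coordinate, if the call carries one."""
        if self.summit_offset is None:
            return None
        return self.interval.start + self.summit_offset


@dataclass
class GeneModel:
    """A gene with its genomic span and transcription start site."""

    gene_id: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        """TSS: interval start on '+', last base (end - 1) on '-'."""
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


@dataclass
class Sample:
    """One sequencing sample with its experimental condition factors."""

    sample_id: str
    cell_system: str = "SunTag"  # SunTag | 44iN
    lif: str = "+"  # + | -
    dox: str = "-"  # + | -
    guide: str = "none"  # Nanog | NanogOtx2 | none
    library_size: int = 1_000_000

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.lif not in {"+", "-"} or self.dox not in {"+", "-"}:
            raise ValueError("lif and dox must be '+' or '-'")

    @property
    def condition(self) -> str:
        """Condition key combining LIF and Dox status, e.g. 'LIF+:Dox-'."""
        return f"LIF{self.lif}:Dox{self.dox}"


@dataclass
class ConsensusRegion:
    """A merged multi-sample binding region.

    ``support`` counts the distinct samples contributing at least one peak.
    ``summit`` is the absolute position of maximal averaged coverage (set by
    :func:`regunet.consensus.locate_summits`).  ``mean_height_rpm`` is the
    per-sample summit height in reads per million, averaged over samples.
    """

    interval: GenomicInterval
    support: int
    summit: Optional[int] = None
    mean_height_rpm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError("summit must lie inside the interval")


@dataclass
class K27Domain:
    """A merged broad H3K27me3 domain with per-sample read counts."""

    interval: GenomicInterval
    support: int
    counts: dict = field(default_factory=dict)  # sample_id -> reads in domain
    dynamics_class: Optional[str] = None  # stable | lif_loss | lif_gain

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass
class SimTruth:
    """Planted ground truth emitted by the synthetic-data generators.

    region_archetype : region id -> archetype index (co-binding regions)
    region_solo      : region id -> bool
    domain_class     : domain id -> stable | lif_loss | lif_gain
    gene_pattern     : gene id -> (lif_state, dox_plus_lif_state, dox_minus_lif_state)
    gene_lfc         : gene id -> planted log2 fold changes per contrast
    outlier_samples  : set of sample ids with inflated counts
    enrichment_d0    : planted TSS-to-summit linkage distance (bp)
    gene_distance    : gene id -> planted distance to nearest summit (bp)
    """

    region_archetype: dict = field(default_factory=dict)
    region_solo: dict = field(default_factory=dict)
    domain_class: dict = field(default_factory=dict)
    gene_pattern: dict = field(default_factory=dict)
    gene_lfc: dict = field(default_factory=dict)
    outlier_samples: set = field(default_factory=set)
    enrichment_d0: Optional[float] = None
    gene_distance: dict = field(default_factory=dict)
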