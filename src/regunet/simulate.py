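"""Synthetic-data generators with planted ground truth.

Every downstream stage of the pipeline (consensus regions, co-binding
clustering, H3K27me3 domain dynamics, response-pattern classification and
proximity enrichment) is exercised on data produced here, so each generator
plants an explicit truth label per record and is a pure function of its
parameters and seed.

The statistical structure emulated:

* multi-sample peak sets with partial (80%) per-sample recall of a common
  region set, so support filtering is non-trivial;
* Gaussian-shaped per-factor read pile-ups at region summits whose amplitude
  follows a per-archetype, per-condition table (co-binding) or stays below
  the occupancy threshold for every factor (solo);
* three classes of broad-domain counts (stable / lost on LIF withdrawal /
  gained on LIF withdrawal) over a 4-condition x 4-replicate layout, with an
  optional count-inflated outlier replicate;
* negative-binomial RNA-seq counts under a 2x2 LIF x Dox design with planted
  response-pattern triples, and TSSs of Dox-responsive genes placed at a
  controlled distance from planted co-binding summits.

Counts are negative binomial throughout with a single dispersion parameter
per generator, matching the downstream NB-GLM model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import GeneModel, GenomicInterval, PeakCall, Sample, SimTruth

FACTORS = ("Esrrb", "Oct4", "Sox2", "Brg1")

# default centre-to-centre spacing of planted binding regions (bp)
REGION_SPACING = 100_000
CONDITIONS = ("+Dox", "-Dox")

# Four-condition layout of the broad-mark experiment, in fixed order.
K27_CONDITIONS = ("LIFp_DOXm", "LIFp_DOXp", "LIFm_DOXm", "LIFm_DOXp")

STATES = ("up", "down", "ns")

# Planted response-pattern mixture over (LIF-withdrawal, Dox in +LIF,
# Dox in -LIF) state triples.  The bulk of the transcriptome is silent or
# responds to LIF withdrawal only; a few percent of genes are Nanog-rescued
# in -LIF in either direction; small Dox-only classes round out the mixture.
DEFAULT_PATTERN_MIXTURE: Dict[Tuple[str, str, str], float] = {
    ("ns", "ns", "ns"): 0.522,
    ("up", "ns", "ns"): 0.182,
    ("down", "ns", "ns"): 0.173,
    ("down", "ns", "up"): 0.047,
    ("up", "ns", "down"): 0.034,
    ("ns", "up", "ns"): 0.010,
    ("ns", "down", "ns"): 0.010,
    ("ns", "ns", "up"): 0.011,
    ("ns", "ns", "down"): 0.011,
}


@dataclass
class ReadTrack:
    """Read-start placements for one sample: chrom -> sorted positions."""

    positions: Dict[str, np.ndarray]
    library_size: int

    def n_reads(self) -> int:
        return int(sum(len(v) for v in self.positions.values()))


def nb_sample(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Draw NB2 counts with Var = mean + dispersion * mean**2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(
    n_chrom: int,
    chrom_length: int,
    n_genes: int,
    seed: int,
    min_gene_len: int = 2000,
    max_gene_len: int = 8000,
) -> Tuple[List[GeneModel], Dict[str, str]]:
    """Random genome: non-overlapping genes on random ACGT sequence.

    Genes are packed into equal slots of >= 10 kb each, so the call errors
    when ``n_genes * 10_000`` exceeds the total length.  Strands alternate,
    keeping the two balanced.
    """
    rng = np.random.default_rng(seed)
    total = n_chrom * chrom_length
    if n_genes * 10_000 > total:
        raise ValueError(
            f"cannot pack {n_genes} genes into {total} bp (need >= 10 kb per gene)"
        )
    sequences = {
        f"chr{c + 1}": _random_seq(rng, chrom_length) for c in range(n_chrom)
    }
    genes: List[GeneModel] = []
    if n_genes == 0:
        return genes, sequences
    per_chrom = int(np.ceil(n_genes / n_chrom))
    gi = 0
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        n_here = min(per_chrom, n_genes - gi)
        if n_here <= 0:
            break
        slot = chrom_length // n_here
        for s in range(n_here):
            glen = int(rng.integers(min_gene_len, max_gene_len + 1))
            lo = s * slot
            hi = (s + 1) * slot - glen
            start = int(rng.integers(lo, max(hi, lo + 1)))
            strand = "+" if gi % 2 == 0 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gi:05d}",
                    interval=GenomicInterval(
                        chrom, start, start + glen, f"gene_{gi:05d}", 0.0, strand
                    ),
                )
            )
            gi += 1
    return genes, sequences


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# TF binding
# ---------------------------------------------------------------------------


def default_archetypes(high: float = 200.0, low: float = 8.0) -> np.ndarray:
    """Amplitude table (archetype, factor, condition) in expected reads/region.

    Factor order is :data:`FACTORS`, condition order :data:`CONDITIONS`
    (+Dox first).  The eight shapes cover the co-binding behaviours of
    interest: pan-factor recruitment lost without the inducer, single- and
    double-factor dependence, inducer-independent binding, and factors whose
    binding increases when the inducer is withdrawn.
    """
    A = np.full((8, len(FACTORS), 2), low)
    A[0, :, 0] = high  # all factors bound, all lost on -Dox
    A[1, 0, 0] = high  # Esrrb-dominant, lost
    A[2, (0, 1), 0] = high  # Esrrb + Oct4, lost
    A[3, 1, 0] = 2 * high  # strong Oct4 lost; Sox2 independent
    A[3, 2, :] = high
    A[4, :, :] = high  # all factors, Dox-independent
    A[5, 0, :] = high  # Esrrb only, Dox-independent
    A[6, 1, 1] = high  # Oct4 gained on -Dox
    A[7, 2, 1] = high  # Sox2 gained on -Dox
    return A


def simulate_binding(
    n_regions: int = 2000,
    archetypes: Optional[np.ndarray] = None,
    solo_fraction: float = 0.45,
    window: int = 1000,
    depth: float = 1.0,
    nb_dispersion: float = 0.05,
    seed: int = 0,
    n_nanog_samples: int = 6,
    nanog_recall: float = 0.8,
    n_replicates: int = 2,
    spacing: int = 100_000,
    library_size: int = 1_000_000,
) -> Tuple[Dict[str, List[PeakCall]], Dict[Tuple[str, str], List[ReadTrack]], dict, SimTruth]:
    """Simulate multi-factor binding at regions along one synthetic chromosome.

    Returns ``(nanog_peak_sets, factor_reads, regions, truth)``:

    * ``nanog_peak_sets``: per pseudo-sample PeakCall lists, each recalling a
      random ~``nanog_recall`` subset of regions (plus boundary jitter);
    * ``factor_reads``: (factor, condition) -> replicate ReadTracks of
      read-start positions drawn around a Gaussian profile
      (sd = window / 8) at each region summit; the special factor ``"Nanog"``
      maps sample ids to ReadTracks for summit/height computation;
    * ``regions``: region id -> (chrom, true summit bp);
    * ``truth``: archetype and solo labels per region.

    Co-binding regions draw their per-factor amplitude from the archetype
    table; solo regions keep every factor at the sub-threshold floor.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= solo_fraction <= 1.0:
        raise ValueError("solo_fraction must be in [0, 1]")
    if archetypes is None:
        archetypes = default_archetypes()
    archetypes = np.asarray(archetypes, dtype=float)
    if (archetypes < 0).any():
        raise ValueError("archetype amplitudes must be >= 0")
    n_arch = archetypes.shape[0]

    rng = np.random.default_rng(seed)
    chrom = "chrB"
    sd = window / 8.0
    solo_amp = 8.0  # expected reads/region for every factor at solo regions

    summits = (np.arange(n_regions) + 1) * spacing
    region_ids = [f"region_{j:05d}" for j in range(n_regions)]
    is_solo = rng.random(n_regions) < solo_fraction
    arch = rng.integers(0, n_arch, size=n_regions)

    truth = SimTruth()
    for j, rid in enumerate(region_ids):
        truth.region_solo[rid] = bool(is_solo[j])
        truth.region_archetype[rid] = int(arch[j]) if not is_solo[j] else None

    regions = {rid: (chrom, int(summits[j])) for j, rid in enumerate(region_ids)}

    # per-factor, per-condition, per-replicate read tracks
    factor_reads: Dict[Tuple[str, str], List[ReadTrack]] = {}
    for fi, factor in enumerate(FACTORS):
        for ci, cond in enumerate(CONDITIONS):
            reps = []
            for _ in range(n_replicates):
                amps = np.where(is_solo, solo_amp, archetypes[arch, fi, ci]) * depth
                counts = nb_sample(rng, amps, nb_dispersion)
                pos = _gaussian_reads(rng, summits, counts, sd)
                reps.append(
                    ReadTrack({chrom: pos}, library_size=library_size)
                )
            factor_reads[(factor, cond)] = reps

    # Nanog coverage per pseudo-sample: co-binding regions bind Nanog more
    # strongly than solo ones, and every pseudo-sample recalls ~nanog_recall
    # of the regions.
    nanog_amp = np.where(is_solo, 60.0, 150.0) * depth
    nanog_peak_sets: Dict[str, List[PeakCall]] = {}
    nanog_tracks: Dict[str, ReadTrack] = {}
    half = 250
    for s in range(n_nanog_samples):
        sid = f"nanog_s{s + 1}"
        recalled = rng.random(n_regions) < nanog_recall
        counts = nb_sample(rng, nanog_amp * recalled, nb_dispersion)
        pos = _gaussian_reads(rng, summits, counts, sd)
        nanog_tracks[sid] = ReadTrack({chrom: pos}, library_size=library_size)
        peaks = []
        for j in np.flatnonzero(recalled):
            jit = rng.integers(-100, 101, size=2)
            start = max(0, int(summits[j] - half + jit[0]))
            end = int(summits[j] + half + jit[1])
            peaks.append(
                PeakCall(
                    GenomicInterval(chrom, start, end, f"{sid}_p{j}", 0.0, "."),
                    sample_id=sid,
                    summit_offset=int(summits[j] - start),
                    height=float(counts[j]),
                )
            )
        nanog_peak_sets[sid] = peaks
    factor_reads[("Nanog", "samples")] = [nanog_tracks[sid] for sid in sorted(nanog_tracks)]

    return nanog_peak_sets, factor_reads, regions, truth


def _gaussian_reads(
    rng: np.random.Generator, summits: np.ndarray, counts: np.ndarray, sd: float
) -> np.ndarray:
    """Draw read starts normal around each summit; returns one sorted array."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    centers = np.repeat(summits, counts)
    pos = np.rint(centers + rng.normal(0.0, sd, size=total)).astype(np.int64)
    pos = np.clip(pos, 0, None)
    pos.sort()
    return pos


# ---------------------------------------------------------------------------
# H3K27me3 domains
# ---------------------------------------------------------------------------

# Per-class mean multipliers over K27_CONDITIONS (LIF+Dox-, LIF+Dox+,
# LIF-Dox-, LIF-Dox+).
K27_CLASS_MULTIPLIERS = {
    "stable": (1.0, 1.0, 1.0, 1.0),
    "lif_loss": (1.0, 1.0, 0.3, 0.3),
    "lif_gain": (0.3, 0.3, 1.0, 1.0),
}


def simulate_k27(
    n_domains: int = 300,
    class_mixture: Optional[Dict[str, float]] = None,
    n_replicates_per_condition: int = 4,
    outlier: Optional[Tuple[str, float]] = None,
    seed: int = 0,
    nb_dispersion: float = 0.05,
    baseline_mean: float = 300.0,
    present_prob: float = 0.95,
    boundary_jitter: int = 300,
):
    """Simulate broad-domain peak sets and a domain x sample count matrix.

    Returns ``(broadpeak_sets, count_df_columns, truth)`` where
    ``broadpeak_sets`` maps sample id -> PeakCall list, the count matrix is a
    tuple ``(domain_ids, sample_ids, matrix)`` and ``truth`` carries the
    planted dynamics class per domain and the outlier sample, if any.

    ``outlier`` is ``(sample_id, inflation)`` with inflation > 1; the named
    sample's counts are multiplied by the inflation factor.
    """
    if class_mixture is None:
        class_mixture = {"stable": 0.6, "lif_loss": 0.25, "lif_gain": 0.15}
    probs = np.array([class_mixture.get(c, 0.0) for c in K27_CLASS_MULTIPLIERS])
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("class mixture must sum to 1")
    if outlier is not None and outlier[1] <= 1.0:
        raise ValueError("outlier inflation factor must be > 1")

    rng = np.random.default_rng(seed)
    classes = list(K27_CLASS_MULTIPLIERS)
    cls_idx = rng.choice(len(classes), size=n_domains, p=probs)

    # Domain layout: lengths 5-30 kb, gaps 8-20 kb (always > the 3 kb merge
    # gap, so distinct domains never fuse).
    lengths = rng.integers(5000, 30001, size=n_domains)
    gaps = rng.integers(8000, 20001, size=n_domains)
    starts = np.cumsum(gaps + np.concatenate([[0], lengths[:-1]]))
    ends = starts + lengths
    chrom = "chrK"

    sample_ids = [
        f"{cond}_r{r + 1}"
        for cond in K27_CONDITIONS
        for r in range(n_replicates_per_condition)
    ]

    truth = SimTruth()
    domain_ids = [f"domain_{d:05d}" for d in range(n_domains)]
    for d, did in enumerate(domain_ids):
        truth.domain_class[did] = classes[cls_idx[d]]
    if outlier is not None:
        truth.outlier_samples.add(outlier[0])

    mult = np.array([K27_CLASS_MULTIPLIERS[classes[i]] for i in cls_idx])  # (d, 4)
    baseline = rng.lognormal(np.log(baseline_mean), 0.4, size=n_domains)

    matrix = np.zeros((n_domains, len(sample_ids)), dtype=np.int64)
    broadpeak_sets: Dict[str, List[PeakCall]] = {}
    for si, sid in enumerate(sample_ids):
        ci = si // n_replicates_per_condition
        mean = baseline * mult[:, ci]
        counts = nb_sample(rng, mean, nb_dispersion)
        if outlier is not None and sid == outlier[0]:
            counts = np.rint(counts * outlier[1]).astype(np.int64)
        matrix[:, si] = counts
        present = rng.random(n_domains) < present_prob
        peaks = []
        for d in np.flatnonzero(present):
            jit = rng.integers(-boundary_jitter, boundary_jitter + 1, size=2)
            s0 = max(0, int(starts[d] + jit[0]))
            e0 = int(ends[d] + jit[1])
            peaks.append(
                PeakCall(
                    GenomicInterval(chrom, s0, e0, f"{sid}_d{d}", 0.0, "."),
                    sample_id=sid,
                    height=float(counts[d]),
                )
            )
        broadpeak_sets[sid] = peaks

    domain_coords = {
        domain_ids[d]: (chrom, int(starts[d]), int(ends[d])) for d in range(n_domains)
    }
    return broadpeak_sets, (domain_ids, sample_ids, matrix), domain_coords, truth


def k27_sample_conditions(sample_ids: Sequence[str]) -> Dict[str, List[str]]:
    """Group simulated K27 sample ids by their condition prefix."""
    groups: Dict[str, List[str]] = {c: [] for c in K27_CONDITIONS}
    for sid in sample_ids:
        cond = sid.rsplit("_r", 1)[0]
        groups.setdefault(cond, []).append(sid)
    return groups


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    genes: Sequence[GeneModel],
    pattern_mixture: Optional[Dict[Tuple[str, str, str], float]] = None,
    effect_size: float = 2.0,
    nb_dispersion: float = 0.05,
    n_replicates: int = 4,
    peak_link: Optional[dict] = None,
    seed: int = 0,
    baseline_median: float = 200.0,
):
    """NB expression counts under a 2x2 LIF x Dox design with planted patterns.

    The design is coded with an intercept at (+LIF, -Dox); ``lif_withdrawn``
    is 1 when LIF is removed and ``dox`` is 1 when Dox is added, so the three
    planted contrasts are: LIF-withdrawal effect (beta_L), Dox effect in +LIF
    (beta_D) and Dox effect in -LIF (beta_D + beta_LD).

    ``peak_link``, when given, is ``{"summits": [(chrom, bp), ...], "d0": bp}``:
    genes with a non-null planted Dox effect are relocated so their TSS lies
    within ``d0`` of a random planted summit; all other genes keep their
    original chromosomes (which carry no summits, hence are farther than
    10 * d0 from every summit).

    Returns ``(counts_df, samples, truth, genes_out)``.
    """
    import pandas as pd

    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    if baseline_median <= 0:
        raise ValueError("baseline must be positive")
    if pattern_mixture is None:
        pattern_mixture = DEFAULT_PATTERN_MIXTURE
    patterns = list(pattern_mixture)
    probs = np.array([pattern_mixture[p] for p in patterns], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("pattern mixture must sum to 1")

    rng = np.random.default_rng(seed)
    n_genes = len(genes)
    choice = rng.choice(len(patterns), size=n_genes, p=probs)

    sign = {"up": 1.0, "down": -1.0, "ns": 0.0}
    beta = np.zeros((n_genes, 3))  # beta_L, beta_D, beta_LD
    truth = SimTruth()
    genes_out: List[GeneModel] = []
    for g, gene in enumerate(genes):
        trip = patterns[choice[g]]
        bL = sign[trip[0]] * effect_size
        bD = sign[trip[1]] * effect_size
        b_dox_minus = sign[trip[2]] * effect_size
        beta[g] = (bL, bD, b_dox_minus - bD)
        truth.gene_pattern[gene.gene_id] = trip
        truth.gene_lfc[gene.gene_id] = {
            "lif_withdrawal": bL,
            "dox_plus_lif": bD,
            "dox_minus_lif": b_dox_minus,
        }

    # relocate linked genes next to planted summits
    if peak_link is not None:
        summits = list(peak_link["summits"])
        d0 = float(peak_link["d0"])
        truth.enrichment_d0 = d0
        for g, gene in enumerate(genes):
            trip = patterns[choice[g]]
            dox_responsive = trip[1] != "ns" or trip[2] != "ns"
            iv = gene.interval
            if dox_responsive and summits:
                chrom, spos = summits[int(rng.integers(len(summits)))]
                dist = float(rng.uniform(0.3 * d0, d0))
                side = 1 if rng.random() < 0.5 else -1
                tss = max(0, int(spos + side * dist))
                glen = len(iv)
                if iv.strand == "-":
                    start, end = max(0, tss - glen + 1), tss + 1
                else:
                    start, end = tss, tss + glen
                iv = GenomicInterval(chrom, start, end, iv.name, iv.score, iv.strand)
                truth.gene_distance[gene.gene_id] = abs(tss - spos)
            else:
                truth.gene_distance[gene.gene_id] = float("inf")
            genes_out.append(GeneModel(gene.gene_id, iv))
    else:
        genes_out = list(genes)

    samples: List[Sample] = []
    design_rows = []
    for lif in ("+", "-"):
        for dox in ("-", "+"):
            for r in range(n_replicates):
                sid = f"S_LIF{'p' if lif == '+' else 'm'}_DOX{'p' if dox == '+' else 'm'}_r{r + 1}"
                samples.append(
                    Sample(sid, cell_system="SunTag", lif=lif, dox=dox, guide="Nanog")
                )
                L = 1.0 if lif == "-" else 0.0
                D = 1.0 if dox == "+" else 0.0
                design_rows.append((L, D, L * D))
    X = np.array(design_rows)  # (samples, 3)

    baseline = rng.lognormal(np.log(baseline_median), 1.0, size=n_genes)
    depth = rng.uniform(0.7, 1.3, size=len(samples))
    log2_mu = np.log2(baseline)[:, None] + beta @ X.T  # (genes, samples)
    mu = (2.0 ** log2_mu) * depth[None, :]
    counts = nb_sample(rng, mu, nb_dispersion)

    counts_df = pd.DataFrame(
        counts,
        index=[g.gene_id for g in genes],
        columns=[s.sample_id for s in samples],
    )
    for s, d in zip(samples, depth):
        s.library_size = max(1, int(round(d * 1_000_000)))
    return counts_df, samples, truth, genes_out
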