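"""End-to-end orchestration: simulate -> consensus -> cobind -> k27 -> de -> enrich.

A single seed in the config is fanned out to per-stage seeds by a fixed
counter scheme (``stage_seed = (seed * 1009 + stage_index) % 2**31``), so
any stage can be re-run in isolation and reproduce its output.  Every run
writes a resolved copy of its configuration and a manifest recording the
package version, per-stage seeds and output checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path
import pandas as pd
import yaml

from . import __version__, cobinding, consensus, de, k27, proximity, simulate
from .io import write_gene_table, write_intervals, write_sample_sheet

STAGES = ("simulate", "consensus", "cobind", "k27", "de", "enrich")


@dataclass
class RunConfig:
    """Resolved parameters for a full synthetic pipeline run."""

    seed: int = 0
    out_dir: str = "regunet_run"
    # simulate
    n_regions: int = 500
    solo_fraction: float = 0.45
    n_domains: int = 150
    n_genes: int = 1500
    n_replicates: int = 4
    effect_size: float = 2.0
    nb_dispersion: float = 0.05
    enrichment_d0: float = 50_000.0
    # consensus
    min_support: int = 2
    min_rpm: float = 1.0
    # cobind
    window: int = 1000
    bin_bp: int = 10
    flank: int = 250
    solo_threshold: float = 2.7
    k: int = 8
    # k27
    gap_bp: int = 3000
    k27_min_support: int = 8
    outlier_frac: float = 0.6
    # de
    fdr: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def stage_seed(seed: int, stage: str) -> int:
    return (seed * 1009 + STAGES.index(stage)) % 2**31


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in dependency order; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.resolved.yaml").write_text(yaml.safe_dump(asdict(config)))
    manifest = {"version": __version__, "seed": config.seed, "stages": {}}

    # --- simulate -----------------------------------------------------------
    s_sim = stage_seed(config.seed, "simulate")
    peak_sets, factor_reads, regions_truth, bind_truth = simulate.simulate_binding(
        n_regions=config.n_regions,
        solo_fraction=config.solo_fraction,
        nb_dispersion=config.nb_dispersion,
        seed=s_sim,
    )
    for sid, peaks in peak_sets.items():
        write_intervals(peaks, out / f"{sid}.narrowPeak", "narrowPeak")
    bp_sets, (dom_ids, k27_sids, k27_counts), dom_coords, k27_truth = simulate.simulate_k27(
        n_domains=config.n_domains,
        nb_dispersion=config.nb_dispersion,
        outlier=(f"{simulate.K27_CONDITIONS[0]}_r1", 3.0),
        seed=s_sim + 1,
    )
    manifest["stages"]["simulate"] = {"seed": s_sim}

    # --- consensus ----------------------------------------------------------
    nanog_tracks = {
        f"nanog_s{i + 1}": tr
        for i, tr in enumerate(factor_reads[("Nanog", "samples")])
    }
    regions = consensus.build_consensus(peak_sets, min_support=config.min_support)
    regions = consensus.height_filter(regions, nanog_tracks, min_rpm=config.min_rpm)
    regions = consensus.locate_summits(regions, nanog_tracks)
    pd.DataFrame(
        [
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "name": r.interval.name,
                "support": r.support,
                "summit": r.summit,
                "mean_height_rpm": r.mean_height_rpm,
            }
            for r in regions
        ]
    ).to_csv(out / "consensus_regions.tsv", sep="\t", index=False)
    manifest["stages"]["consensus"] = {"n_regions": len(regions)}

    # --- cobind -------------------------------------------------------------
    s_cb = stage_seed(config.seed, "cobind")
    chrom_sizes = {"chrB": (config.n_regions + 2) * simulate.REGION_SPACING}
    tf_reads = {k: v for k, v in factor_reads.items() if k[0] != "Nanog"}
    signal = cobinding.quantify_traces(
        regions, tf_reads, chrom_sizes, window=config.window, bin_bp=config.bin_bp
    )
    solo_ids, co_ids = cobinding.split_solo_cobinding(signal, config.solo_threshold)
    traces = cobinding.normalize_traces(signal, region_ids=co_ids, flank=config.flank)
    model = cobinding.kmeans_cluster(traces, k=config.k, seed=s_cb)
    pd.Series(model.assignment, name="cluster").rename_axis("region").to_csv(
        out / "cobind_assignment.tsv", sep="\t"
    )
    pd.DataFrame(model.centroids).to_csv(out / "cobind_centroids.tsv", sep="\t")
    manifest["stages"]["cobind"] = {
        "seed": s_cb,
        "n_solo": len(solo_ids),
        "n_cobinding": len(co_ids),
    }

    # --- k27 ----------------------------------------------------------------
    s_k27 = stage_seed(config.seed, "k27")
    domains = k27.merge_domains(
        bp_sets, gap_bp=config.gap_bp, min_support=config.k27_min_support
    )
    groups = simulate.k27_sample_conditions(k27_sids)
    qc = k27.flag_outlier_replicates(
        k27_counts, k27_sids, groups, frac_threshold=config.outlier_frac
    )
    retained = [sid for sid, (_, excl) in qc.items() if not excl]
    labels, label_map, cond_means = k27.cluster_domain_dynamics(
        k27_counts, k27_sids, groups, retained=retained, seed=s_k27
    )
    with open(out / "k27_qc.json", "w") as fh:
        json.dump({s: {"max_fraction": f, "excluded": e} for s, (f, e) in qc.items()}, fh, indent=2)
    pd.DataFrame(
        {"domain": dom_ids, "dynamics_class": [label_map[int(l)] for l in labels]}
    ).to_csv(out / "k27_dynamics.tsv", sep="\t", index=False)
    manifest["stages"]["k27"] = {
        "seed": s_k27,
        "n_domains": len(domains),
        "excluded_samples": [s for s in qc if qc[s][1]],
    }

    # --- de -----------------------------------------------------------------
    s_de = stage_seed(config.seed, "de")
    genome_genes, _ = simulate.simulate_genome(
        n_chrom=2, chrom_length=max(10_000 * config.n_genes, 1_000_000),
        n_genes=config.n_genes, seed=s_de,
    )
    # planted summits of the non-solo regions anchor the gene linkage
    co_summits = [
        (chrom, pos)
        for rid, (chrom, pos) in regions_truth.items()
        if not bind_truth.region_solo[rid]
    ]
    counts_df, samples, expr_truth, genes = simulate.simulate_expression(
        genome_genes,
        effect_size=config.effect_size,
        nb_dispersion=config.nb_dispersion,
        n_replicates=config.n_replicates,
        peak_link={"summits": co_summits, "d0": config.enrichment_d0},
        seed=s_de,
    )
    counts_df.to_csv(out / "counts.tsv", sep="\t")
    write_sample_sheet(samples, out / "samples.tsv")
    write_gene_table(genes, out / "genes.tsv")
    norm, sf, kept_genes = de.normalize_and_filter(counts_df, samples)
    results = de.fit_nb_contrasts(
        counts_df.loc[kept_genes],
        samples,
        "~LIF + Dox + LIF:Dox",
        contrasts={
            "lif_withdrawal": {"lif_withdrawn": 1.0},
            "dox_plus_lif": {"dox": 1.0},
            "dox_minus_lif": {"dox": 1.0, "lif_withdrawn:dox": 1.0},
        },
        size_factors_=sf,
    )
    patterns = de.classify_patterns(
        results["lif_withdrawal"],
        results["dox_plus_lif"],
        results["dox_minus_lif"],
        fdr=config.fdr,
    )
    patterns.to_csv(out / "response_patterns.tsv", sep="\t")
    de.pattern_counts(patterns).rename("count").rename_axis("pattern").to_csv(
        out / "pattern_counts.tsv", sep="\t"
    )
    manifest["stages"]["de"] = {"seed": s_de, "n_tested": len(kept_genes)}

    # --- enrich -------------------------------------------------------------
    summits_regions = [
        consensus.ConsensusRegion(
            interval=r.interval, support=r.support, summit=r.summit
        )
        for r in regions
    ]
    distances = proximity.nearest_distance(
        [g for g in genes if g.gene_id in set(kept_genes)], summits_regions
    )
    responsive = patterns.index[patterns["dox_minus_lif_state"] != "ns"].tolist()
    universe = [g for g in kept_genes if g in distances]
    curve = None
    if responsive and set(responsive) < set(universe):
        curve = proximity.fisher_curve(responsive, universe, distances)
        curve.to_csv(out / "enrichment_curve.tsv", sep="\t", index=False)
    manifest["stages"]["enrich"] = {
        "n_responsive": len(responsive),
        "computed": curve is not None,
    }

    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
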