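#!/usr/bin/env python
"""Generate the synthetic input dataset with planted ground truth.

Writes per-sample narrowPeak (pseudo-Nanog) and broadPeak (H3K27me3) files,
the RNA-seq count matrix and sample sheet, the gene table, a promoter FASTA
and a truth.json recording every planted label, under results/synthetic/.
Downstream analysis scripts regenerate the same data deterministically from
the seed, so this directory is a human-inspectable record, not a dependency.
"""

import argparse
import json
from pathlib import Path

from regunet import io, simulate

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

peak_sets, reads, regions_truth, bind_truth = simulate.simulate_binding(
    n_regions=500, seed=args.seed
)
for sid, peaks in peak_sets.items():
    io.write_intervals(peaks, args.out / f"{sid}.narrowPeak", "narrowPeak")

bp_sets, (dids, sids, mat), coords, k27_truth = simulate.simulate_k27(
    n_domains=150, outlier=("LIFp_DOXm_r1", 3.0), seed=args.seed + 1
)
for sid, peaks in bp_sets.items():
    io.write_intervals(peaks, args.out / f"{sid}.broadPeak", "broadPeak")
io.write_count_matrix(dids, sids, mat, args.out / "k27_counts.tsv")

genes, seqs = simulate.simulate_genome(2, 8_000_000, 800, seed=args.seed + 2)
summits = [
    (c, p) for rid, (c, p) in regions_truth.items()
    if not bind_truth.region_solo[rid]
]
counts, samples, expr_truth, genes_out = simulate.simulate_expression(
    genes, seed=args.seed + 2, peak_link={"summits": summits, "d0": 50_000}
)
counts.to_csv(args.out / "rna_counts.tsv", sep="\t")
io.write_sample_sheet(samples, args.out / "rna_samples.tsv")
io.write_gene_table(genes_out, args.out / "genes.tsv")

prom_genes, prom_seqs = simulate.simulate_genome(1, 30_000, 2, seed=args.seed + 3)
io.write_fasta(prom_seqs, args.out / "promoters.fa")

truth = {
    "region_solo": bind_truth.region_solo,
    "region_archetype": bind_truth.region_archetype,
    "domain_class": k27_truth.domain_class,
    "gene_pattern": {g: list(t) for g, t in expr_truth.gene_pattern.items()},
    "outlier_samples": sorted(k27_truth.outlier_samples),
    "enrichment_d0": expr_truth.enrichment_d0,
}
(args.out / "truth.json").write_text(json.dumps(truth, indent=2))

n_solo = sum(bind_truth.region_solo.values())
print(f"wrote {len(peak_sets)} pseudo-Nanog peak sets over 500 regions "
      f"({n_solo} planted solo, {500 - n_solo} co-binding)")
print(f"wrote {len(bp_sets)} broadPeak samples over 150 planted domains "
      f"(outlier: {sorted(k27_truth.outlier_samples)})")
print(f"wrote counts for {len(counts)} genes x {len(samples)} samples -> {args.out}")
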