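#!/usr/bin/env python
"""Distance-resolved Fisher enrichment of responsive genes near summits.

Computes each tested gene's TSS distance to the nearest planted co-binding
summit, the one-sided Fisher enrichment curve over log-spaced distance
thresholds in [1, 1e8] bp, and the 500-gene sliding-window rescue fraction
along the LIF-response ranking.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from regunet import de, proximity, simulate
from regunet.types import ConsensusRegion, GenomicInterval

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results/enrichment"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

genes, _ = simulate.simulate_genome(2, 8_000_000, 800, seed=args.seed + 2)
summits = [("chrB", simulate.REGION_SPACING * (i + 1)) for i in range(200)]
counts, samples, truth, genes_out = simulate.simulate_expression(
    genes, seed=args.seed + 2, peak_link={"summits": summits, "d0": 50_000}
)
norm, sf, kept = de.normalize_and_filter(counts, samples)
results = de.fit_nb_contrasts(
    counts.loc[kept], samples, "~LIF + Dox + LIF:Dox",
    contrasts={
        "lif_withdrawal": {"lif_withdrawn": 1.0},
        "dox_plus_lif": {"dox": 1.0},
        "dox_minus_lif": {"dox": 1.0, "lif_withdrawn:dox": 1.0},
    },
    size_factors_=sf,
)
patterns = de.classify_patterns(
    results["lif_withdrawal"], results["dox_plus_lif"], results["dox_minus_lif"]
)

regions = [
    ConsensusRegion(GenomicInterval(c, p - 250, p + 250), support=2, summit=p)
    for c, p in summits
]
distances = proximity.nearest_distance(genes_out, regions)
universe = [g.gene_id for g in genes_out if g.gene_id in set(kept)]
responsive = [
    g for g in universe if patterns.loc[g, "dox_minus_lif_state"] != "ns"
]
curve = proximity.fisher_curve(responsive, universe, distances)
curve.to_csv(args.out / "enrichment_curve.tsv", sep="\t", index=False)
best = curve.loc[curve["neg_log10_p"].idxmax()]

# rescue fraction in a sliding window along the LIF-withdrawal ranking
ranked = results["lif_withdrawal"].loc[universe].sort_values("log2fc").index
labels = [patterns.loc[g, "rescue_category"].startswith("rescued") for g in ranked]
window = min(500, len(labels))
frac = proximity.sliding_window_fraction(labels, window=window)
pd.DataFrame({"position": np.arange(frac.size), "rescued_fraction": frac}).to_csv(
    args.out / "sliding_rescue_fraction.tsv", sep="\t", index=False
)

print(f"{len(responsive)} Dox-responsive genes among {len(universe)} tested")
print(f"enrichment peaks at x = {best['x'] / 1000:.0f} kb "
      f"(-log10 p = {best['neg_log10_p']:.1f}); planted d0 = 50 kb -> {args.out}")
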