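# regunet

Analyses for inducible-transcription-factor experiments in mouse embryonic
stem cells: how induction or withdrawal of a master factor (Nanog, driven
by doxycycline) reshapes co-factor binding at regulatory regions, broad
repressive H3K27me3 domains, and the LIF-dependent transcriptome.  The
package is written for computational biologists who have peak calls, binned
read placements and count matrices in hand and need the downstream
statistics; every stage is also exercised end-to-end on synthetic data with
planted ground truth, so the whole pipeline is testable without any
external download.

## What it computes

* **Consensus binding regions** — union-merge of multi-sample peak sets,
  sample-support filtering (≥ 2), mean summit height ≥ 1 rpm, summit
  location; ATAC cut-site tracks (±4 bp inward shift, cut site plus
  flanking bases marked).
* **Co-binding clustering** — per-factor, per-condition traces h±ᵢⱼₖ in a
  1 kb window around summits; solo vs co-binding split at 2.7 rpm; the
  normalised features τ̄ⱼ = τⱼ / maxₖ τⱼₖ with
  τⱼ = (t₁ⱼ/σ₁, …, tₙⱼ/σₙ), σᵢ = Σⱼₖ h⁺ᵢⱼₖ; Euclidean k-means and
  Rand-index stability across k for model selection.
* **H3K27me3 domains** — broad peaks merged within 3 kb, ≥ 8-sample
  support; outlier replicates flagged when they are the strict
  within-condition maximum in ≥ 60% of domains; domain dynamics
  (stable / lost on LIF withdrawal / gained) by k-means with k = 3 on
  max-normalised condition means; gene embedding by body overlap or a
  ≤ 4 kb TSS rule.
* **Gene response taxonomy** — median-of-ratios normalisation, expression
  filtering, per-gene NB GLM with Wald contrasts on
  ~LIF + Dox + LIF:Dox (LIF-withdrawal effect, Dox effect in +LIF, Dox
  effect in −LIF = Dox + LIF:Dox), likelihood-ratio combination across
  cell systems (~Cell + Dox + Cell:Dox vs ~Cell), the 27 response-state
  triples with rescue categories, 3×3 χ²/Cramér's V concordance, and the
  dual-guide compensation test.
* **Proximity enrichment** — TSS-to-nearest-summit distances, one-sided
  Fisher enrichment curves over log-spaced thresholds in [1, 10⁸] bp, and
  the 500-gene sliding-window rescue fraction.
* **gRNA design** — 20-nt + NGG candidate enumeration on both strands, GC
  (35–85%) and homopolymer (< 4) filters, and per-mismatch-class off-target
  histograms.

See `docs/methods.md` for the models, parameter defaults and design
choices, including what the synthetic generators do and do not emulate.

## Worked example

Run the numbered analysis scripts in order (each regenerates its inputs
deterministically from the seed and writes tables under `results/`):

```sh
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_build_consensus_regions.py --seed 1
python analysis/03_cluster_cobinding.py --seed 1
```

which prints

```
499 regions with support >= 2; 493 pass the 1 rpm filter
recovered 493/500 planted regions (98.6%) -> results/consensus_regions.tsv

231 solo and 262 co-binding regions at 2.7 rpm
Rand index k vs k+1: {2: 0.645, 3: 0.901, 4: 0.965, 5: 0.973, 6: 0.933,
                      7: 0.975, 8: 0.992, 9: 0.989, 10: 0.983}
k = 8 clustering vs planted archetypes: ARI = 0.990 -> results/cobinding
```

Reading: of 500 planted binding regions, 493 survive the ≥ 2-sample and
≥ 1 rpm filters (the planted pseudo-samples only recall 80% of regions
each, so a handful fall below support); the 2.7 rpm occupancy threshold
splits them into solo and co-binding almost exactly as planted; cluster
assignments stabilise (Rand index ≥ 0.9) from k ≈ 3–4 upward, and at the
planted k = 8 the recovered clusters agree with the planted archetypes at
adjusted Rand index 0.99.  Scripts 04–07 continue with domain dynamics,
response patterns (`results/de/pattern_counts.tsv` holds the 27-triple
table), the enrichment-distance curve (its peak falls at ~54 kb against a
planted 50 kb linkage), and gRNA candidates.

The same stages are available as a console tool (`regunet run --seed 1
--out run/`, plus `consensus`, `k27`, `de`, `grna` subcommands) and as a
library (`regunet.consensus`, `regunet.cobinding`, `regunet.k27`,
`regunet.de`, `regunet.proximity`, `regunet.grna`, `regunet.simulate`).

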