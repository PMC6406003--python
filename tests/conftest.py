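"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from regunet import consensus, simulate


@pytest.fixture(scope="session")
def binding_sim():
    """A 500-region binding simulation with default study conditions."""
    peak_sets, reads, regions_truth, truth = simulate.simulate_binding(
        n_regions=500, seed=101
    )
    return {
        "peak_sets": peak_sets,
        "reads": reads,
        "regions_truth": regions_truth,
        "truth": truth,
        "chrom_sizes": {"chrB": (500 + 2) * simulate.REGION_SPACING},
    }


@pytest.fixture(scope="session")
def consensus_regions(binding_sim):
    """Consensus regions with heights and summits from the binding fixture."""
    nanog = {
        f"nanog_s{i + 1}": tr
        for i, tr in enumerate(binding_sim["reads"][("Nanog", "samples")])
    }
    regions = consensus.build_consensus(binding_sim["peak_sets"], min_support=2)
    regions = consensus.height_filter(regions, nanog, min_rpm=1.0)
    regions = consensus.locate_summits(regions, nanog)
    return regions


@pytest.fixture(scope="session")
def k27_sim():
    """A 150-domain broad-mark simulation with one 3x-inflated replicate."""
    bp_sets, (dom_ids, sids, mat), coords, truth = simulate.simulate_k27(
        n_domains=150, outlier=("LIFp_DOXm_r1", 3.0), seed=202
    )
    return {
        "broadpeaks": bp_sets,
        "domain_ids": dom_ids,
        "sample_ids": sids,
        "matrix": mat,
        "coords": coords,
        "truth": truth,
        "groups": simulate.k27_sample_conditions(sids),
    }


@pytest.fixture(scope="session")
def expr_sim():
    """An 800-gene expression simulation under the default pattern mixture."""
    genes, _ = simulate.simulate_genome(2, 8_000_000, 800, seed=303)
    summits = [("chrB", simulate.REGION_SPACING * (i + 1)) for i in range(200)]
    counts, samples, truth, genes_out = simulate.simulate_expression(
        genes, seed=303, peak_link={"summits": summits, "d0": 50_000}
    )
    return {
        "counts": counts,
        "samples": samples,
        "truth": truth,
        "genes": genes_out,
        "summits": summits,
    }


def region_id_by_summit(regions_truth):
    """Map planted summit position -> region id (regions are unique per bp)."""
    return {pos: rid for rid, (_, pos) in regions_truth.items()}


def match_planted_region(region, regions_truth):
    """Planted region id whose summit is nearest a recovered region's summit."""
    positions = np.sort([pos for _, pos in regions_truth.values()])
    lookup = region_id_by_summit(regions_truth)
    i = np.searchsorted(positions, region.summit)
    cands = [positions[j] for j in (i - 1, i) if 0 <= j < positions.size]
    nearest = min(cands, key=lambda p: abs(p - region.summit))
    return lookup[int(nearest)]
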