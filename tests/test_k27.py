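"""Broad-domain merging, replicate QC, dynamics clustering, gene embedding."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from regunet import k27, simulate
from regunet.simulate import ReadTrack
from regunet.types import GeneModel, GenomicInterval, K27Domain, PeakCall


def _peak(chrom, start, end, sample):
    return PeakCall(GenomicInterval(chrom, start, end), sample_id=sample)


def _sets(peaks_by_sample):
    return {sid: [_peak(*p, sid) for p in peaks] for sid, peaks in peaks_by_sample.items()}


def naive_gap_merge(intervals, gap):
    """O(n^2) transitive closure of the 'within gap' relation."""
    items = [
        {"chrom": c, "start": s, "end": e, "sids": {sid}} for c, s, e, sid in intervals
    ]
    changed = True
    while changed:
        changed = False
        out = []
        for it in items:
            for o in out:
                if (
                    o["chrom"] == it["chrom"]
                    and it["start"] - o["end"] <= gap
                    and o["start"] - it["end"] <= gap
                ):
                    o["start"] = min(o["start"], it["start"])
                    o["end"] = max(o["end"], it["end"])
                    o["sids"] |= it["sids"]
                    changed = True
                    break
            else:
                out.append(dict(it))
        items = out
    return sorted((i["chrom"], i["start"], i["end"], len(i["sids"])) for i in items)


def test_gap_rule_inclusive():
    base = {f"s{i}": [("chr1", 0, 100)] for i in range(8)}
    base["s0"].append(("chr1", 3099, 3200))  # gap 2999 from [0,100)
    (d,) = k27.merge_domains(_sets(base), gap_bp=3000, min_support=8)
    assert (d.interval.start, d.interval.end) == (0, 3200)
    base["s0"][-1] = ("chr1", 3101, 3200)  # gap 3001 -> separate
    doms = k27.merge_domains(_sets(base), gap_bp=3000, min_support=1)
    assert len(doms) == 2


def test_support_filter():
    sets = {f"s{i}": [("chr1", 0, 100)] if i < 7 else [] for i in range(16)}
    assert k27.merge_domains(_sets(sets), min_support=8) == []
    sets["s7"] = [("chr1", 50, 120)]
    (d,) = k27.merge_domains(_sets(sets), min_support=8)
    assert d.support == 8


def test_merge_matches_naive_oracle_and_idempotent():
    rng = np.random.default_rng(21)
    intervals = []
    for i in range(100):
        c = f"chr{rng.integers(1, 3)}"
        s = int(rng.integers(0, 100_000))
        intervals.append((c, s, s + int(rng.integers(100, 3000)), f"s{rng.integers(10)}"))
    sets = {}
    for c, s, e, sid in intervals:
        sets.setdefault(sid, []).append(_peak(c, s, e, sid))
    got = k27.merge_domains(sets, gap_bp=3000, min_support=1)
    assert [
        (d.interval.chrom, d.interval.start, d.interval.end, d.support) for d in got
    ] == naive_gap_merge(intervals, 3000)
    again = k27.merge_domains(
        {"m": [PeakCall(d.interval, "m") for d in got]}, gap_bp=3000, min_support=1
    )
    assert [(d.interval.start, d.interval.end) for d in again] == [
        (d.interval.start, d.interval.end) for d in got
    ]


def test_planted_domain_recovery(k27_sim):
    """>= 95% of planted domains reconstructed within +/- gap_bp of truth."""
    doms = k27.merge_domains(k27_sim["broadpeaks"], gap_bp=3000, min_support=8)
    coords = list(k27_sim["coords"].values())
    hit = 0
    for chrom, s, e in coords:
        for d in doms:
            if (
                d.interval.chrom == chrom
                and abs(d.interval.start - s) <= 3000
                and abs(d.interval.end - e) <= 3000
            ):
                hit += 1
                break
    assert hit / len(coords) >= 0.95


def test_count_reads_half_open_and_oracle():
    doms = [
        K27Domain(GenomicInterval("chr1", 10, 20), support=8),
        K27Domain(GenomicInterval("chr1", 30, 40), support=8),
    ]
    tr = ReadTrack({"chr1": np.array([9, 10, 19, 20, 35])}, 1_000_000)
    _, _, mat = k27.count_reads_in_domains({"s": tr}, doms)
    # start at 10 counted, at 20 not (half-open)
    assert mat[:, 0].tolist() == [2, 1]
    rng = np.random.default_rng(8)
    pos = np.sort(rng.integers(0, 1000, size=300))
    tr2 = ReadTrack({"chr1": pos}, 1_000_000)
    doms2 = [
        K27Domain(GenomicInterval("chr1", int(s), int(s) + 50), support=8)
        for s in range(0, 900, 90)
    ]
    _, _, mat2 = k27.count_reads_in_domains({"s": tr2}, doms2)
    naive = [sum(1 for p in pos if d.interval.start <= p < d.interval.end) for d in doms2]
    assert mat2[:, 0].tolist() == naive


def test_outlier_flagging_rules():
    # 2 replicates, A strictly above B in 70% of domains -> A excluded
    rng = np.random.default_rng(9)
    n = 100
    b = rng.integers(50, 100, size=n)
    a = b.copy()
    a[:70] += 10
    a[70:] -= 10
    mat = np.stack([a, b], axis=1)
    qc = k27.flag_outlier_replicates(mat, ["A", "B"], {"c": ["A", "B"]})
    assert qc["A"] == (0.7, True) and qc["B"] == (0.3, False)
    # all ties -> all fractions 0, none excluded
    tied = np.full((50, 3), 7)
    qc2 = k27.flag_outlier_replicates(tied, ["x", "y", "z"], {"c": ["x", "y", "z"]})
    assert all(v == (0.0, False) for v in qc2.values())
    with pytest.raises(ValueError, match="fewer than 2"):
        k27.flag_outlier_replicates(mat, ["A", "B"], {"c": ["A"]})


def test_exchangeable_replicates_not_flagged():
    """Four exchangeable replicates have max-fractions near 1/4."""
    rng = np.random.default_rng(10)
    mat = rng.poisson(200, size=(300, 4))
    qc = k27.flag_outlier_replicates(
        mat, ["a", "b", "c", "d"], {"c": ["a", "b", "c", "d"]}
    )
    fracs = [f for f, _ in qc.values()]
    assert all(not e for _, e in qc.values())
    assert all(abs(f - 0.25) < 0.1 for f in fracs)


def test_dynamics_clustering_recovers_planted_classes(k27_sim):
    mat, sids, groups = k27_sim["matrix"], k27_sim["sample_ids"], k27_sim["groups"]
    qc = k27.flag_outlier_replicates(mat, sids, groups)
    retained = [s for s, (_, e) in qc.items() if not e]
    labels, lmap, means = k27.cluster_domain_dynamics(
        mat, sids, groups, retained=retained, seed=0
    )
    truth = [k27_sim["truth"].domain_class[d] for d in k27_sim["domain_ids"]]
    pred = [lmap[int(l)] for l in labels]
    assert adjusted_rand_score(truth, pred) >= 0.9
    assert set(lmap.values()) == {"stable", "lif_loss", "lif_gain"}


def test_dynamics_errors():
    with pytest.raises(ValueError, match="at least k"):
        k27.cluster_domain_dynamics(
            np.ones((2, 4)), ["a", "b", "c", "d"], {"c": ["a", "b", "c", "d"]}
        )
    mat = np.zeros((5, 4))
    with pytest.raises(ValueError, match="all-zero"):
        k27.cluster_domain_dynamics(
            mat, ["a", "b", "c", "d"], {"c1": ["a", "b"], "c2": ["c", "d"]}
        )


def test_gene_embedding_rules():
    dom = K27Domain(GenomicInterval("chrT", 10_000, 20_000), support=8)
    overlap = GeneModel("g1", GenomicInterval("chrT", 19_999, 25_000, strand="+"))
    near = GeneModel("g2", GenomicInterval("chrT", 23_500, 28_000, strand="+"))
    far = GeneModel("g3", GenomicInterval("chrT", 40_000, 45_000, strand="+"))
    res = k27.assign_genes_to_domains([overlap, near, far], [dom])
    # g1 overlaps by 1 bp; g2's TSS is 3.5 kb away BUT the domain overlaps g1
    assert res["g1"] == dom.interval.name
    assert res["g2"] is None
    assert res["g3"] is None
    # without the overlapping gene, the 3.5 kb rule applies
    res2 = k27.assign_genes_to_domains([near, far], [dom])
    assert res2["g2"] == dom.interval.name
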