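"""Trace quantification, normalisation, k-means, Rand index, k selection."""

import itertools

import numpy as np
import pytest

from regunet import cobinding
from regunet.cobinding import NormalizedTraceSet, SignalMatrix
from regunet.simulate import ReadTrack
from regunet.types import ConsensusRegion, GenomicInterval


def _region(name, summit, chrom="chr1"):
    return ConsensusRegion(
        GenomicInterval(chrom, max(0, summit - 500), summit + 500, name),
        support=2,
        summit=summit,
    )


def rand_oracle(a, b):
    """Exhaustive pair enumeration of the Rand index."""
    n = len(a)
    agree = total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += 1
        agree += (a[i] == a[j]) == (b[i] == b[j])
    return agree / total


def test_quantify_rpm_and_replicate_average():
    region = _region("r1", 5000)
    # 10 read starts in one bin, library 1e7 -> 1.0 rpm in that bin
    rep1 = ReadTrack({"chr1": np.full(10, 5001, dtype=np.int64)}, library_size=10_000_000)
    # second replicate: 30 reads in the same bin -> 3.0 rpm; average = 2.0
    rep2 = ReadTrack({"chr1": np.full(30, 5001, dtype=np.int64)}, library_size=10_000_000)
    reads = {("Esrrb", "+Dox"): [rep1, rep2], ("Esrrb", "-Dox"): [rep1, rep1]}
    sig = cobinding.quantify_traces([region], reads, {"chr1": 20_000})
    center_bin = sig.n_bins // 2  # summit sits at the start of this bin
    assert sig.h[0, 0, 0, center_bin] == pytest.approx(2.0)
    assert sig.h[0, 1, 0, center_bin] == pytest.approx(1.0)
    assert sig.h.sum() == pytest.approx(3.0)


def test_quantify_drops_edge_regions_and_missing_factor():
    edge = _region("edge", 300)
    reads = {("Esrrb", "+Dox"): [ReadTrack({"chr1": np.array([300])}, 1_000_000)]}
    sig = cobinding.quantify_traces([edge, _region("ok", 5000)], reads, {"chr1": 20_000})
    assert sig.region_ids == ["ok"]
    with pytest.raises(ValueError, match="no reads"):
        cobinding.quantify_traces(
            [_region("ok", 5000)], {("Esrrb", "+Dox"): []}, {"chr1": 20_000}
        )


def _toy_signal(h, factors=("A",), conditions=("+Dox", "-Dox"), ids=None):
    h = np.asarray(h, dtype=float)
    ids = ids or [f"r{i}" for i in range(h.shape[2])]
    return SignalMatrix(h, list(factors), list(conditions), ids, h.shape[3] * 10, 10)


def test_split_solo_boundary_inclusive():
    # region 0: all maxima 1.0 -> solo; region 1: 3.0 in -Dox -> co-binding;
    # region 2: exactly 2.7 -> co-binding (inclusive)
    h = np.zeros((1, 2, 3, 4))
    h[0, :, 0, :] = 1.0
    h[0, 1, 1, 2] = 3.0
    h[0, 0, 2, 1] = 2.7
    solo, co = cobinding.split_solo_cobinding(_toy_signal(h))
    assert solo == ["r0"] and co == ["r1", "r2"]


def test_normalize_uniform_and_scale_invariance():
    h = np.full((1, 2, 3, 50), 2.0)
    traces = cobinding.normalize_traces(_toy_signal(h), flank=250)
    assert np.allclose(traces.X, 1.0)
    # scaling one factor's h (both conditions) leaves taubar bit-identical
    # for an exactly representable (power-of-two) factor, and identical to
    # machine precision for any other factor
    h2 = np.random.default_rng(0).uniform(0.1, 5.0, size=(2, 2, 6, 50))
    sig_a = _toy_signal(h2, factors=("A", "B"))
    h3 = h2.copy()
    h3[1] *= 8.0
    tb = cobinding.normalize_traces(_toy_signal(h3, factors=("A", "B")), flank=250)
    ta = cobinding.normalize_traces(sig_a, flank=250)
    assert np.array_equal(ta.X, tb.X)
    h4 = h2.copy()
    h4[1] *= 10.0
    tc = cobinding.normalize_traces(_toy_signal(h4, factors=("A", "B")), flank=250)
    assert np.allclose(ta.X, tc.X, rtol=1e-12)
    assert np.allclose(ta.X.max(axis=1), 1.0)


def test_normalize_hand_computed_example():
    """Two factors, two positions: follow the sigma/tau/taubar arithmetic."""
    # h[factor, cond, region, pos]; one region
    h = np.array(
        [
            [[[2.0, 4.0]], [[1.0, 1.0]]],  # factor A: +Dox (2,4), -Dox (1,1)
            [[[8.0, 8.0]], [[4.0, 0.0]]],  # factor B: +Dox (8,8), -Dox (4,0)
        ]
    )
    sig = SignalMatrix(h, ["A", "B"], ["+Dox", "-Dox"], ["r0"], 20, 10)
    tr = cobinding.normalize_traces(sig, flank=10)
    # sigma_A = 6, sigma_B = 16; tau = (2/6,4/6,1/6,1/6, 8/16,8/16,4/16,0)
    tau = np.array([2 / 6, 4 / 6, 1 / 6, 1 / 6, 0.5, 0.5, 0.25, 0.0])
    assert np.allclose(tr.X[0], tau / tau.max())
    assert tr.sigma == {"A": 6.0, "B": 16.0}


def test_normalize_excludes_all_zero_regions_and_zero_sigma():
    h = np.zeros((1, 2, 2, 50))
    h[0, 0, 0, :] = 1.0
    tr = cobinding.normalize_traces(_toy_signal(h), flank=250)
    assert tr.region_ids == ["r0"] and tr.excluded_ids == ["r1"]
    with pytest.raises(ValueError, match="sigma"):
        cobinding.normalize_traces(_toy_signal(np.zeros((1, 2, 2, 50))), flank=250)


def _traces_from_points(X, ids=None):
    ids = ids or [f"r{i}" for i in range(len(X))]
    return NormalizedTraceSet(np.asarray(X, float), ids, [], ["A"], ["+Dox"], {"A": 1.0})


def test_kmeans_separable_and_inertia_zero():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 0.05, size=(30, 4))
    b = rng.normal(5, 0.05, size=(30, 4))
    tr = _traces_from_points(np.vstack([a, b]))
    model = cobinding.kmeans_cluster(tr, 2, seed=0)
    labels = np.array([model.assignment[r] for r in tr.region_ids])
    assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
    assert labels[0] != labels[-1]
    tiny = _traces_from_points(rng.normal(size=(5, 3)))
    assert cobinding.kmeans_cluster(tiny, 5, seed=0).inertia == pytest.approx(0.0)
    with pytest.raises(ValueError, match="exceeds"):
        cobinding.kmeans_cluster(tiny, 6, seed=0)


def test_rand_index_hand_examples_and_properties():
    assert cobinding.rand_index([1, 1, 2], [1, 2, 2]) == pytest.approx(1 / 3)
    assert cobinding.rand_index([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0
    assert cobinding.rand_index([1, 1, 1], [1, 2, 3]) == 0.0
    rng = np.random.default_rng(2)
    for _ in range(50):
        n = int(rng.integers(2, 13))
        a = rng.integers(0, 4, size=n)
        b = rng.integers(0, 4, size=n)
        assert cobinding.rand_index(a, b) == pytest.approx(rand_oracle(a, b))
        assert cobinding.rand_index(a, b) == pytest.approx(cobinding.rand_index(b, a))
    # relabelling invariance
    a = rng.integers(0, 3, size=20)
    assert cobinding.rand_index(a, 2 - a) == 1.0


def test_select_k_single_entry_and_duplicates():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(3, 4))
    X = np.repeat(X, 10, axis=0)  # 3 distinct profiles duplicated
    tr = _traces_from_points(X)
    rep = cobinding.select_k(tr, k_range=(2, 2), seed=0)
    assert set(rep.rand) == {2}
    rep2 = cobinding.select_k(tr, k_range=(3, 4), seed=0)
    assert rep2.rand[3] <= 1.0
    # identical duplicated regions only -> every RI = 1
    same = _traces_from_points(np.ones((20, 4)))
    rep3 = cobinding.select_k(same, k_range=(2, 3), seed=0)
    assert all(v == 1.0 for v in rep3.rand.values())
    with pytest.raises(ValueError, match="degenerate"):
        cobinding.select_k(tr, k_range=(2, 40), seed=0)


def test_kmeans_inertia_nonincreasing_in_k():
    rng = np.random.default_rng(5)
    tr = _traces_from_points(rng.normal(size=(60, 6)))
    inertias = [cobinding.kmeans_cluster(tr, k, seed=0).inertia for k in (2, 4, 8)]
    assert inertias == sorted(inertias, reverse=True)


def test_cluster_summary_matches_groupwise_means():
    h = np.random.default_rng(6).uniform(size=(1, 2, 6, 5))
    sig = _toy_signal(h)
    model = cobinding.ClusterModel(
        k=2,
        centroids=np.zeros((2, 1)),
        assignment={f"r{i}": i % 2 for i in range(6)},
        seed=0,
        inertia=0.0,
    )
    df, order = cobinding.cluster_summary(model, sig)
    for c in (0, 1):
        members = [i for i in range(6) if i % 2 == c]
        expect = h[:, :, members, :].mean(axis=2)
        got = df[df["cluster"] == c].sort_values(["factor", "condition", "bin"])[
            "mean_rpm"
        ].to_numpy()
        assert np.allclose(np.sort(got), np.sort(expect.ravel()))
    assert sorted(order) == [f"r{i}" for i in range(6)]
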