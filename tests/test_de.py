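"""Size factors, NB-GLM contrasts, LRT, BH, classification, concordance."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from regunet import de, simulate
from regunet.types import Sample


def _samples_2x2(n=4):
    out = []
    for lif in ("+", "-"):
        for dox in ("-", "+"):
            for r in range(n):
                out.append(
                    Sample(f"L{lif}D{dox}r{r}", "SunTag", lif, dox, "Nanog")
                )
    return out


CONTRASTS = {
    "lif_withdrawal": {"lif_withdrawn": 1.0},
    "dox_plus_lif": {"dox": 1.0},
    "dox_minus_lif": {"dox": 1.0, "lif_withdrawn:dox": 1.0},
}


def test_size_factors_symmetry_and_scale():
    counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]}, index=list("abc"))
    sf = de.size_factors(counts)
    assert np.allclose(sf, 1.0)
    counts["s2"] *= 2
    sf = de.size_factors(counts)
    assert sf["s2"] / sf["s1"] == pytest.approx(2.0)
    with pytest.raises(ValueError, match="all-positive"):
        de.size_factors(pd.DataFrame({"s1": [0, 1], "s2": [1, 0]}))


def test_filter_requires_all_replicates_of_one_condition():
    samples = [
        Sample("a1", lif="+", dox="-"), Sample("a2", lif="+", dox="-"),
        Sample("a3", lif="+", dox="-"), Sample("b1", lif="-", dox="-"),
        Sample("b2", lif="-", dox="-"), Sample("b3", lif="-", dox="-"),
    ]
    counts = pd.DataFrame(
        {
            "a1": [12, 9, 100], "a2": [11, 9, 100], "a3": [10, 9, 100],
            "b1": [2, 9, 100], "b2": [3, 9, 100], "b3": [1, 9, 100],
        },
        index=["kept", "dropped", "big"],
    )
    _, _, retained = de.normalize_and_filter(counts, samples)
    assert "kept" in retained and "dropped" not in retained


def test_design_matrix_codings():
    samples = _samples_2x2(2)
    X = de.design_matrix(samples, "~LIF + Dox + LIF:Dox")
    assert list(X.columns) == ["intercept", "lif_withdrawn", "dox", "lif_withdrawn:dox"]
    row = X.loc["L-D+r0"]
    assert row.tolist() == [1.0, 1.0, 1.0, 1.0]
    assert X.loc["L+D-r0"].tolist() == [1.0, 0.0, 0.0, 0.0]
    with pytest.raises(ValueError, match="full rank"):
        de.design_matrix([s for s in samples if s.lif == "+"], "~LIF + Dox")


def test_zero_contrast_gives_p_one():
    samples = _samples_2x2(2)
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.poisson(100, size=(5, len(samples))),
        index=[f"g{i}" for i in range(5)],
        columns=[s.sample_id for s in samples],
    )
    res = de.fit_nb_contrasts(
        counts, samples, "~LIF + Dox + LIF:Dox", {"zero": {}}
    )
    assert (res["zero"]["stat"] == 0).all()
    assert (res["zero"]["pvalue"] == 1.0).all()


def test_bh_matches_brute_force_oracle():
    def bh_oracle(p):
        p = np.asarray(p, float)
        n = p.size
        order = np.argsort(p, kind="mergesort")
        adj = p[order] * n / (np.arange(n) + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        out = np.empty(n)
        out[order] = np.minimum(adj, 1.0)
        return out

    rng = np.random.default_rng(1)
    for _ in range(200):
        p = rng.uniform(size=int(rng.integers(1, 50)))
        assert np.allclose(de.bh_adjust(p), bh_oracle(p))
    # monotone non-decreasing in p
    p = rng.uniform(size=100)
    adj = de.bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_nb_glm_matches_poisson_in_small_dispersion_limit():
    samples = _samples_2x2(3)
    rng = np.random.default_rng(2)
    mu = 200 * 2 ** (np.array([1.0 if s.dox == "+" else 0.0 for s in samples]))
    y = rng.poisson(mu)
    counts = pd.DataFrame([y], index=["g"], columns=[s.sample_id for s in samples])
    sf = pd.Series(1.0, index=counts.columns)
    disp = pd.Series(1e-10, index=["g"])
    res = de.fit_nb_contrasts(
        counts, samples, "~LIF + Dox + LIF:Dox", CONTRASTS,
        size_factors_=sf, dispersions=disp,
    )
    X = de.design_matrix(samples, "~LIF + Dox + LIF:Dox").to_numpy()
    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    got = res["dox_plus_lif"]["log2fc"].iloc[0] * de.LN2
    assert abs(got - pois.params[2]) < 1e-3


def test_wald_detects_planted_effect_and_directions():
    samples = _samples_2x2(4)
    rng = np.random.default_rng(3)
    mu = np.array(
        [400.0 if (s.dox == "+" and s.lif == "-") else 100.0 for s in samples]
    )
    y = simulate.nb_sample(rng, np.tile(mu, (30, 1)), 0.05)
    null = simulate.nb_sample(rng, np.full((170, len(samples)), 150.0), 0.05)
    counts = pd.DataFrame(
        np.vstack([y, null]),
        index=[f"g{i}" for i in range(200)],
        columns=[s.sample_id for s in samples],
    )
    res = de.fit_nb_contrasts(counts, samples, "~LIF + Dox + LIF:Dox", CONTRASTS)
    dm = res["dox_minus_lif"]
    assert (dm["fdr"].iloc[:30] < 0.05).mean() >= 0.9
    assert (dm["log2fc"].iloc[:30] > 1).all()
    assert (res["dox_plus_lif"]["fdr"].iloc[:30] > 0.05).mean() >= 0.9


def test_lrt_nesting_and_power():
    samples = []
    for cell in ("SunTag", "44iN"):
        for dox in ("-", "+"):
            for r in range(3):
                samples.append(Sample(f"{cell}{dox}{r}", cell, "+", dox, "Nanog"))
    rng = np.random.default_rng(4)
    mu = np.array([300.0 if s.dox == "+" else 100.0 for s in samples])
    sig = simulate.nb_sample(rng, np.tile(mu, (20, 1)), 0.05)
    null = simulate.nb_sample(rng, np.full((80, len(samples)), 150.0), 0.05)
    counts = pd.DataFrame(
        np.vstack([sig, null]),
        index=[f"g{i}" for i in range(100)],
        columns=[s.sample_id for s in samples],
    )
    res = de.lrt_combined(counts, samples)
    assert (res["fdr"].iloc[:20] < 0.05).all()
    assert res["df"].iloc[0] == 2
    with pytest.raises(ValueError, match="nested"):
        de.lrt_combined(counts, samples, "~Cell", "~Cell")


def test_responsive_union_provenance():
    idx = [f"g{i}" for i in range(12)]
    def mk(sig_idx, lfc=1.0):
        df = pd.DataFrame(
            {"log2fc": lfc, "fdr": 1.0, "converged": True}, index=idx
        )
        df.loc[sig_idx, "fdr"] = 0.01
        return df

    a = mk(idx[0:3])
    b = mk(idx[3:7])
    c = mk(idx[7:12], lfc=-1.0)
    out = de.responsive_union({"suntag": a, "i44": b, "lrt": c})
    assert len(out) == 12
    assert out.loc["g0", "selected_by"] == "suntag"
    assert out.loc["g8", "direction"] == "down"


def test_concordance_hand_table_and_extremes():
    # perfectly diagonal -> V = 1
    a = pd.Series(["up"] * 5 + ["down"] * 5 + ["ns"] * 5)
    res = de.concordance_3x3(a, a)
    assert res.cramers_v == pytest.approx(1.0)
    assert res.dof == 4
    # independence -> chi2 ~ 0
    b = pd.Series(["up", "down", "ns"] * 9)
    c = pd.Series(["up"] * 9 + ["down"] * 9 + ["ns"] * 9)
    res2 = de.concordance_3x3(b, c)
    assert res2.chi2 == pytest.approx(0.0, abs=1e-9)
    # hand table [[10,2,3],[1,12,2],[4,3,20]] vs direct summation
    table = np.array([[10, 2, 3], [1, 12, 2], [4, 3, 20]])
    states_a, states_b = [], []
    for i, ra in enumerate(["up", "down", "ns"]):
        for j, rb in enumerate(["up", "down", "ns"]):
            states_a += [ra] * table[i, j]
            states_b += [rb] * table[i, j]
    res3 = de.concordance_3x3(pd.Series(states_a), pd.Series(states_b))
    n = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / n
    chi2_manual = ((table - expected) ** 2 / expected).sum()
    assert res3.chi2 == pytest.approx(chi2_manual)
    assert res3.cramers_v == pytest.approx(np.sqrt(chi2_manual / (n * 2)))
    # zero margin -> not applicable
    d = pd.Series(["up"] * 10)
    res4 = de.concordance_3x3(d, d)
    assert res4.chi2 is None


def _result(states, idx):
    lfc = {"up": 2.0, "down": -2.0, "ns": 0.0}
    fdr = {"up": 0.01, "down": 0.01, "ns": 0.9}
    return pd.DataFrame(
        {
            "log2fc": [lfc[s] for s in states],
            "fdr": [fdr[s] for s in states],
            "converged": True,
        },
        index=idx,
    )


def test_classify_patterns_rules_and_partition():
    idx = ["g1", "g2", "g3", "g4"]
    lif = _result(["ns", "up", "down", "up"], idx)
    dp = _result(["ns", "ns", "ns", "ns"], idx)
    dm = _result(["ns", "down", "up", "ns"], idx)
    pats = de.classify_patterns(lif, dp, dm)
    assert pats.loc["g1", "pattern"] == "ns,ns,ns"
    assert pats.loc["g2", "rescue_category"] == "rescued_up"
    assert pats.loc["g3", "rescue_category"] == "rescued_down"
    assert pats.loc["g4", "rescue_category"] == "not_rescued_up"
    counts = de.pattern_counts(pats)
    assert counts.sum() == len(idx)
    assert len(counts) == 27


def test_otx2_compensation_rules():
    idx = ["g1", "g2", "g3"]
    nanog = de.classify_patterns(
        _result(["up", "up", "ns"], idx),
        _result(["ns", "ns", "ns"], idx),
        _result(["down", "down", "ns"], idx),
    )
    dual = de.classify_patterns(
        _result(["up", "up", "ns"], idx),
        _result(["ns", "ns", "ns"], idx),
        _result(["ns", "down", "ns"], idx),
    )
    comp = de.otx2_compensation(nanog, dual)
    assert comp.loc["g1", "compensated"]  # down -> ns
    assert not comp.loc["g2", "compensated"]  # unchanged
    assert not comp.loc["g3", "is_nanog_target"]


def test_zscore_matrix_conventions():
    norm = pd.DataFrame(
        {"s1": [5.0, 0.0], "s2": [5.0, 2.0]}, index=["const", "var"]
    )
    z = de.zscore_matrix(norm, ["const", "var"])
    assert (z.loc["const"] == 0).all()
    assert z.loc["var"].tolist() == pytest.approx([-1.0, 1.0])  # sd denominator n
    rng = np.random.default_rng(5)
    m = pd.DataFrame(rng.normal(size=(10, 8)))
    z2 = de.zscore_matrix(m, list(range(10)))
    assert np.allclose(z2.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(z2.std(axis=1, ddof=0), 1)
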