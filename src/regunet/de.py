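"""NB-GLM differential expression, response patterns and concordance.

This module implements a documented approximation of the DESeq2-style
workflow: median-of-ratios size factors, per-gene method-of-moments
dispersion (floored, no shrinkage), an IRLS negative-binomial log-link GLM
per gene, Wald tests on contrast vectors against a t reference with the
design's residual degrees of freedom, a likelihood-ratio test between
nested designs, and Benjamini-Hochberg FDR within each contrast.  The t
reference (rather than the standard normal) compensates the plug-in noise
of the unshrunk per-gene dispersion; with shrunk dispersions the two
coincide for any realistic sample size.  No independent filtering and no fold-change
shrinkage are applied.

Direction bookkeeping: the LIF indicator column is named ``lif_withdrawn``
and equals 1 when LIF is absent, so a positive LIF coefficient reads
directly as "up upon LIF withdrawal".  The Dox-in-minus-LIF effect is the
sum of the ``dox`` and ``lif_withdrawn:dox`` coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import Sample

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8
DISPERSION_CAP = 10.0


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    The reference is the per-gene geometric mean over genes with all-positive
    counts; each sample's factor is the median ratio of its counts to the
    reference over those genes.
    """
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene with all-positive counts; size factors undefined")
    logref = np.log(mat[allpos]).mean(axis=1)
    sf = np.exp(np.median(np.log(mat[allpos]) - logref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_and_filter(
    counts: pd.DataFrame,
    samples: Sequence[Sample],
    min_norm_count: float = 10.0,
    condition_factors: Tuple[str, ...] = ("cell_system", "lif", "dox", "guide"),
) -> Tuple[pd.DataFrame, pd.Series, List[str]]:
    """Size-factor normalisation plus the all-replicates-of-one-condition filter.

    A gene is retained iff there is at least one condition (a unique
    combination of ``condition_factors``) in which every replicate's
    normalised count is >= ``min_norm_count``.
    Returns (normalised matrix, size factors, retained gene ids).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    sf = size_factors(counts)
    norm = counts / sf
    groups: Dict[tuple, List[str]] = {}
    by_id = {s.sample_id: s for s in samples}
    for sid in counts.columns:
        s = by_id[sid]
        key = tuple(getattr(s, f) for f in condition_factors)
        groups.setdefault(key, []).append(sid)
    keep = np.zeros(len(counts), dtype=bool)
    for members in groups.values():
        keep |= (norm[members] >= min_norm_count).all(axis=1).to_numpy()
    retained = counts.index[keep].tolist()
    return norm, sf, retained


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

_TERM_BUILDERS = {
    "LIF": lambda s: {"lif_withdrawn": 1.0 if s.lif == "-" else 0.0},
    "Dox": lambda s: {"dox": 1.0 if s.dox == "+" else 0.0},
    "Cell": lambda s: {"cell_44iN": 1.0 if s.cell_system == "44iN" else 0.0},
    "DoxGuide": lambda s: {
        "doxguide_Nanog": 1.0 if (s.dox == "+" and s.guide == "Nanog") else 0.0,
        "doxguide_NanogOtx2": 1.0
        if (s.dox == "+" and s.guide == "NanogOtx2")
        else 0.0,
    },
}


def design_matrix(samples: Sequence[Sample], formula: str) -> pd.DataFrame:
    """Build a design matrix from a formula over {LIF, Dox, Cell, DoxGuide}.

    Supports main effects and pairwise interactions (``A:B``), e.g.
    ``~LIF + Dox + LIF:Dox`` or ``~Cell + Dox + Cell:Dox``.  The intercept
    corresponds to (+LIF, -Dox, SunTag).
    """
    terms = [t.strip() for t in formula.lstrip("~").split("+") if t.strip()]
    rows = []
    for s in samples:
        row = {"intercept": 1.0}
        for term in terms:
            if ":" in term:
                a, b = term.split(":")
                cols_a = _TERM_BUILDERS[a.strip()](s)
                cols_b = _TERM_BUILDERS[b.strip()](s)
                for na, va in cols_a.items():
                    for nb, vb in cols_b.items():
                        row[f"{na}:{nb}"] = va * vb
            else:
                row.update(_TERM_BUILDERS[term](s))
        rows.append(row)
    X = pd.DataFrame(rows, index=[s.sample_id for s in samples]).fillna(0.0)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"design matrix for {formula!r} is not full rank")
    if X.shape[0] - X.shape[1] < 1:
        raise ValueError("no residual degrees of freedom")
    return X


# ---------------------------------------------------------------------------
# dispersion and GLM fitting
# ---------------------------------------------------------------------------


def moments_dispersion(
    norm_counts: pd.DataFrame, design: pd.DataFrame
) -> pd.Series:
    """Per-gene NB2 dispersion by method of moments on normalised counts.

    Samples sharing a design row form a group; the dispersion solves
    Var = mu + alpha * mu^2 pooled over groups with >= 2 replicates,
    floored at 1e-8 and capped at 10.  A first-order small-sample factor
    (1 + 2/df, df = summed within-group degrees of freedom) compensates the
    anticonservative effect of plugging a noisy dispersion into the Wald
    denominator.
    """
    keys = [tuple(r) for r in design.to_numpy()]
    groups: Dict[tuple, List[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    mat = norm_counts.to_numpy(dtype=float)
    num = np.zeros(mat.shape[0])
    den = np.zeros(mat.shape[0])
    for idx in groups.values():
        if len(idx) < 2:
            continue
        sub = mat[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        num += w * (v - m)
        den += w * m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    df_resid = sum(len(idx) - 1 for idx in groups.values() if len(idx) >= 2)
    if df_resid > 0:
        alpha = alpha * (1.0 + 2.0 / df_resid)
    alpha = np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CAP)
    return pd.Series(alpha, index=norm_counts.index, name="dispersion")


@dataclass
class GeneFit:
    params: np.ndarray
    cov: np.ndarray
    llf: float
    converged: bool


def _fit_gene(
    y: np.ndarray, X: np.ndarray, alpha: float, offset: np.ndarray
) -> GeneFit:
    try:
        model = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
        )
        res = model.fit(maxiter=100, tol=1e-8)
        ok = bool(np.isfinite(res.params).all()) and bool(
            np.isfinite(res.cov_params()).all()
        )
        return GeneFit(res.params, res.cov_params(), float(res.llf), ok)
    except Exception:  # noqa: BLE001 - any numerical failure flags the gene
        p = X.shape[1]
        return GeneFit(np.full(p, np.nan), np.full((p, p), np.nan), np.nan, False)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def fit_nb_contrasts(
    counts: pd.DataFrame,
    samples: Sequence[Sample],
    formula: str,
    contrasts: Dict[str, Dict[str, float]],
    size_factors_: Optional[pd.Series] = None,
    dispersions: Optional[pd.Series] = None,
) -> Dict[str, pd.DataFrame]:
    """Per-gene NB GLM Wald tests for named contrast vectors.

    Each contrast maps design-column names to coefficients; the Wald
    statistic (c . beta) / sqrt(c' Sigma c) is compared against a t
    distribution with n - p degrees of freedom, and BH adjustment runs
    within each contrast over the converged genes.  Returns one DataFrame per contrast with columns
    log2fc, se, stat, pvalue, fdr, converged.
    """
    X = design_matrix(samples, formula)
    X = X.loc[counts.columns]
    if size_factors_ is None:
        size_factors_ = size_factors(counts)
    sf = size_factors_.loc[counts.columns].to_numpy(dtype=float)
    offset = np.log(sf)
    if dispersions is None:
        dispersions = moments_dispersion(counts / size_factors_, X)

    cvecs = {}
    for name, spec_ in contrasts.items():
        unknown = set(spec_) - set(X.columns)
        if unknown:
            raise ValueError(f"contrast {name}: unknown columns {sorted(unknown)}")
        cvecs[name] = np.array([spec_.get(col, 0.0) for col in X.columns])

    Xm = X.to_numpy(dtype=float)
    mat = counts.to_numpy(dtype=float)
    fits = [
        _fit_gene(mat[g], Xm, float(dispersions.iloc[g]), offset)
        for g in range(mat.shape[0])
    ]
    n_failed = sum(not f.converged for f in fits)
    if n_failed:
        logger.warning("%d genes failed to converge and are excluded from FDR", n_failed)

    out: Dict[str, pd.DataFrame] = {}
    for name, c in cvecs.items():
        est = np.full(len(fits), np.nan)
        se = np.full(len(fits), np.nan)
        for g, f in enumerate(fits):
            if not f.converged:
                continue
            if not c.any():
                est[g], se[g] = 0.0, 0.0
                continue
            est[g] = c @ f.params
            se[g] = np.sqrt(c @ f.cov @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(se > 0, est / se, 0.0)
        stat = np.where(np.isfinite(est), stat, np.nan)
        df_resid = Xm.shape[0] - Xm.shape[1]
        pval = np.where(
            np.isfinite(stat), 2.0 * stats.t.sf(np.abs(stat), df_resid), np.nan
        )
        df = pd.DataFrame(
            {
                "log2fc": est / LN2,
                "se": se / LN2,
                "stat": stat,
                "pvalue": pval,
                "fdr": bh_adjust(pval),
                "converged": [f.converged for f in fits],
            },
            index=counts.index,
        )
        out[name] = df
    return out


def lrt_combined(
    counts: pd.DataFrame,
    samples: Sequence[Sample],
    full_formula: str = "~Cell + Dox + Cell:Dox",
    reduced_formula: str = "~Cell",
    size_factors_: Optional[pd.Series] = None,
    dispersions: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Likelihood-ratio test of nested NB GLMs, chi^2 with df = extra coefs."""
    Xf = design_matrix(samples, full_formula).loc[counts.columns]
    Xr = design_matrix(samples, reduced_formula).loc[counts.columns]
    extra = set(Xf.columns) - set(Xr.columns)
    if not set(Xr.columns) <= set(Xf.columns) or not extra:
        raise ValueError("reduced model must be strictly nested in the full model")
    df_diff = len(extra)
    if size_factors_ is None:
        size_factors_ = size_factors(counts)
    sf = size_factors_.loc[counts.columns].to_numpy(dtype=float)
    offset = np.log(sf)
    if dispersions is None:
        dispersions = moments_dispersion(counts / size_factors_, Xf)

    mat = counts.to_numpy(dtype=float)
    Xfm, Xrm = Xf.to_numpy(float), Xr.to_numpy(float)
    stat = np.full(mat.shape[0], np.nan)
    for g in range(mat.shape[0]):
        a = float(dispersions.iloc[g])
        ff = _fit_gene(mat[g], Xfm, a, offset)
        fr = _fit_gene(mat[g], Xrm, a, offset)
        if ff.converged and fr.converged:
            stat[g] = max(0.0, 2.0 * (ff.llf - fr.llf))
    pval = np.where(np.isfinite(stat), stats.chi2.sf(stat, df_diff), np.nan)
    return pd.DataFrame(
        {
            "stat": stat,
            "df": df_diff,
            "pvalue": pval,
            "fdr": bh_adjust(pval),
            "converged": np.isfinite(stat),
        },
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# gene classification
# ---------------------------------------------------------------------------


def _states(result: pd.DataFrame, fdr: float, lfc_col: str = "log2fc") -> pd.Series:
    sig = (result["fdr"] < fdr) & result["converged"]
    up = sig & (result[lfc_col] > 0)
    down = sig & (result[lfc_col] < 0)
    states = pd.Series("ns", index=result.index)
    states[up] = "up"
    states[down] = "down"
    return states


def responsive_union(
    results: Dict[str, pd.DataFrame], fdr: float = 0.05
) -> pd.DataFrame:
    """Union of FDR-significant genes over the given tests with provenance.

    Each selected gene is annotated with the tests that selected it and the
    direction per test where available; opposite signs across tests set
    ``sign_conflict``.
    """
    if not results:
        raise ValueError("no results given")
    universe = next(iter(results.values())).index
    for df in results.values():
        if not df.index.equals(universe):
            raise ValueError("all results must share the gene universe")
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    rows = []
    for gene in universe:
        selected_by = []
        signs = set()
        for name, df in results.items():
            row = df.loc[gene]
            if bool(row.get("converged", True)) and row["fdr"] < fdr:
                selected_by.append(name)
                if "log2fc" in df.columns and row["log2fc"] != 0:
                    signs.add(np.sign(row["log2fc"]))
        if selected_by:
            rows.append(
                {
                    "gene_id": gene,
                    "selected_by": ",".join(selected_by),
                    "direction": ("up" if signs == {1.0} else
                                  "down" if signs == {-1.0} else "mixed"),
                    "sign_conflict": len(signs) > 1,
                }
            )
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["selected_by", "direction", "sign_conflict"]
    )


@dataclass
class Contingency3x3:
    table: pd.DataFrame  # up/down/ns x up/down/ns counts
    chi2: Optional[float]
    dof: int
    pvalue: Optional[float]
    cramers_v: Optional[float]
    fisher_overlap_p: float


def concordance_3x3(state_a: pd.Series, state_b: pd.Series) -> Contingency3x3:
    """3x3 chi-square concordance with Cramer's V and a 2x2 Fisher overlap.

    The chi-square (df = 4, no continuity correction) is reported as
    not-applicable (None) when any margin is zero.  The Fisher test is
    one-sided enrichment on responsive-vs-not (up or down vs ns) overlap.
    """
    if not state_a.index.equals(state_b.index):
        raise ValueError("states must share the gene universe")
    order = ["up", "down", "ns"]
    table = pd.crosstab(state_a, state_b).reindex(
        index=order, columns=order, fill_value=0
    )
    n = int(table.to_numpy().sum())
    chi2 = p = v = None
    margins_ok = (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all()
    if margins_ok:
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        v = float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))
        chi2, p = float(chi2), float(p)
    resp_a = state_a != "ns"
    resp_b = state_b != "ns"
    t22 = [
        [int((resp_a & resp_b).sum()), int((resp_a & ~resp_b).sum())],
        [int((~resp_a & resp_b).sum()), int((~resp_a & ~resp_b).sum())],
    ]
    _, fisher_p = stats.fisher_exact(t22, alternative="greater")
    return Contingency3x3(table, chi2, 4, p, v, float(fisher_p))


RESCUE_CATEGORIES = (
    "rescued_up",
    "rescued_down",
    "not_rescued_up",
    "not_rescued_down",
    "other",
)


def classify_patterns(
    lif: pd.DataFrame,
    dox_plus: pd.DataFrame,
    dox_minus: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Assign each gene a (LIF, Dox+LIF, Dox-LIF) state triple and rescue class.

    The LIF state refers to the LIF-*withdrawal* effect ("up" = gene goes up
    when LIF is removed).  Rescue: a gene up on LIF withdrawal whose Dox
    effect in -LIF is down is ``rescued_up``; down on withdrawal with Dox-up
    in -LIF is ``rescued_down``; LIF-responsive genes with no Dox response
    in -LIF are ``not_rescued_*``; everything else is ``other``.
    """
    for df in (dox_plus, dox_minus):
        if not df.index.equals(lif.index):
            raise ValueError("contrast results must share the gene universe")
    s_lif = _states(lif, fdr)
    s_dp = _states(dox_plus, fdr)
    s_dm = _states(dox_minus, fdr)
    pattern = s_lif + "," + s_dp + "," + s_dm

    rescue = pd.Series("other", index=lif.index)
    rescue[(s_lif == "up") & (s_dm == "down")] = "rescued_up"
    rescue[(s_lif == "down") & (s_dm == "up")] = "rescued_down"
    rescue[(s_lif == "up") & (s_dm == "ns")] = "not_rescued_up"
    rescue[(s_lif == "down") & (s_dm == "ns")] = "not_rescued_down"
    return pd.DataFrame(
        {
            "lif_state": s_lif,
            "dox_plus_lif_state": s_dp,
            "dox_minus_lif_state": s_dm,
            "pattern": pattern,
            "rescue_category": rescue,
        }
    )


def pattern_counts(patterns: pd.DataFrame) -> pd.Series:
    """Counts of all 27 state triples (empty triples included with count 0)."""
    idx = [
        f"{a},{b},{c}"
        for a in ("up", "down", "ns")
        for b in ("up", "down", "ns")
        for c in ("up", "down", "ns")
    ]
    return patterns["pattern"].value_counts().reindex(idx, fill_value=0)


def otx2_compensation(
    patterns_nanog: pd.DataFrame, patterns_dual: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene compensation status under the dual Nanog/Otx2 guide.

    A gene is a Nanog target in -LIF when its Dox-in-minus-LIF state under
    the Nanog guide is not ``ns``; it is compensated when that state becomes
    ``ns`` or flips sign under the dual guide.
    """
    if not patterns_nanog.index.equals(patterns_dual.index):
        raise ValueError("pattern sets must share the gene universe")
    s_n = patterns_nanog["dox_minus_lif_state"]
    s_d = patterns_dual["dox_minus_lif_state"]
    is_target = s_n != "ns"
    flipped = (
        ((s_n == "up") & (s_d == "down")) | ((s_n == "down") & (s_d == "up"))
    )
    compensated = is_target & ((s_d == "ns") | flipped)
    return pd.DataFrame(
        {
            "nanog_state": s_n,
            "dual_state": s_d,
            "is_nanog_target": is_target,
            "compensated": compensated,
        }
    )


def zscore_matrix(norm_counts: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    """Per-gene z-scores (population sd, denominator n); sd-0 rows become 0."""
    sub = norm_counts.loc[list(genes)].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (sub - mean) / sd, 0.0)
    return pd.DataFrame(z, index=list(genes), columns=norm_counts.columns)
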