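"""Differential expression, DEG counting, and gene-module discovery.

The built-in DE engine is deliberately simple — Welch t-tests on log2-CPM
with Benjamini–Hochberg adjustment — and is paired with a first-class import
path for externally computed DE tables (e.g. DESeq2 output), which are taken
verbatim.  Downstream operations (DEG counts, DEG–phenotype correlation,
top-gene selection, K-means modules with gap-statistic K selection, module
scores) only consume the (gene, lfc, p, q) contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

DE_COLUMNS = ["gene", "lfc", "p", "q", "contrast"]


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (robust to composition shifts).

    For each sample: median over genes of ``count / geometric-mean count``,
    computed on genes expressed everywhere.  Scaled so the factors have
    geometric mean 1 relative to total library size.
    """
    expressed = (counts > 0).all(axis=1)
    if expressed.sum() < 10:
        raise ValueError("too few universally expressed genes")
    logc = np.log(counts.loc[expressed])
    log_geo = logc.mean(axis=1)
    sf = np.exp((logc.sub(log_geo, axis=0)).median(axis=0))
    lib = counts.sum(axis=0)
    return sf * np.exp(np.mean(np.log(lib / sf)))


def log_normalize(counts: pd.DataFrame, pseudocount: float = 1.0,
                  method: str = "total") -> pd.DataFrame:
    """log2 counts-per-million: ``log2(count / libsize * 1e6 + pseudocount)``.

    ``method="total"`` divides by the total library size;
    ``method="median_ratio"`` divides by median-of-ratios size factors,
    which stay calibrated when strongly regulated genes shift the totals
    (composition bias).
    """
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    if method == "median_ratio":
        lib = median_ratio_size_factors(counts)
    elif method != "total":
        raise ValueError(f"unknown normalization method {method!r}")
    return np.log2(counts.div(lib, axis=1) * 1e6 + pseudocount)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement.

    NaN inputs propagate to NaN outputs and are excluded from the correction.
    """
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def _squeeze_variances(s2: np.ndarray, df: float,
                       abundance: np.ndarray | None = None,
                       ) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene variances toward a trend.

    Fits a scaled inverse-chi-squared prior with ``d0`` prior df around a
    mean-abundance trend of the log variances (genes at low counts are
    genuinely noisier on the log2-CPM scale, so a flat prior would inflate
    their statistics).  Returns posterior variances
    ``(d0*s0_g^2 + df*s^2) / (d0 + df)`` and ``d0``; ``d0 = inf`` collapses
    every gene onto its trend value.
    """
    from scipy.special import digamma, polygamma
    ok = s2 > 0
    z = np.log(np.where(ok, s2, np.nan))
    e = z - digamma(df / 2) + np.log(df / 2)
    if abundance is not None and ok.sum() > 50:
        # cubic polynomial trend in abundance — stiff on purpose: a local
        # smoother absorbs variance sampling noise and biases d0 upward
        V = np.polynomial.polynomial.polyvander(abundance[ok], 3)
        coef, *_ = np.linalg.lstsq(V, e[ok], rcond=None)
        trend = np.full_like(s2, np.nan)
        trend[ok] = V @ coef
        trend[~ok] = np.nanmean(trend)
    else:
        trend = np.full_like(s2, np.nanmean(e))
    resid = e[ok] - trend[ok]
    evar = resid.var(ddof=1) - polygamma(1, df / 2)
    if evar <= 0:
        d0 = np.inf
        s0 = np.exp(trend)
    else:
        # invert trigamma(d0/2) = evar by Newton iteration
        x = 0.5 + 1.0 / evar
        for _ in range(50):
            tri = polygamma(1, x)
            step = tri * (1 - tri / evar) / polygamma(2, x)
            x = x + step
            if abs(step) < 1e-8:
                break
        d0 = 2 * x
        s0 = np.exp(trend + digamma(x) - np.log(x))
    if np.isinf(d0):
        post = s0.copy()
    else:
        post = (d0 * s0 + df * np.where(ok, s2, 0.0)) / (d0 + df)
    return post, d0


def differential_expression(counts: pd.DataFrame, design: pd.DataFrame,
                            group_a: str, group_b: str,
                            pseudocount: float = 1.0,
                            moderate: bool = True) -> pd.DataFrame:
    """Per-gene DE between two conditions: lfc, moderated-t p, BH q.

    ``lfc`` is the mean log2-CPM difference (A minus B).  Variances are
    pooled across the two groups and, by default, shrunk toward a common
    prior with empirical-Bayes moderation — at n = 3 per side raw per-gene
    variance estimates are noisy enough that genes with accidentally tiny
    variance dominate the p-value tail and inflate the realized FDR.  The
    moderated statistic is referred to a t distribution with
    ``residual + prior`` degrees of freedom.  ``moderate=False`` gives the
    plain pooled-variance t-test.  Genes with zero variance everywhere get
    p = 1 when means are equal.
    """
    sa = design.loc[design["condition"] == group_a, "sample"]
    sb = design.loc[design["condition"] == group_b, "sample"]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each side of the contrast needs >= 2 samples")
    lcpm = log_normalize(counts, pseudocount, method="median_ratio")
    a = lcpm[list(sa)].to_numpy()
    b = lcpm[list(sb)].to_numpy()
    na, nb = a.shape[1], b.shape[1]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    df = na + nb - 2
    s2 = (a.var(axis=1, ddof=1) * (na - 1)
          + b.var(axis=1, ddof=1) * (nb - 1)) / df
    if moderate:
        abundance = np.hstack([a, b]).mean(axis=1)
        s2_post, d0 = _squeeze_variances(s2, df, abundance)
        df_total = df + d0 if np.isfinite(d0) else 1e6
    else:
        s2_post, df_total = s2, df
    with np.errstate(invalid="ignore", divide="ignore"):
        t = lfc / np.sqrt(s2_post * (1 / na + 1 / nb))
        p = 2 * stats.t.sf(np.abs(t), df_total)
    novar = s2_post == 0
    p = np.where(novar, np.where(lfc == 0, 1.0, 0.0), p)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({
        "gene": counts.index, "lfc": lfc, "p": p, "q": bh_adjust(p),
        "contrast": f"{group_a}_vs_{group_b}",
    }).reset_index(drop=True)


def import_de_table(table: pd.DataFrame, contrast: str | None = None,
                    ) -> pd.DataFrame:
    """Validate and pass through an externally computed DE table."""
    required = {"gene", "lfc", "p", "q"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    out = table.copy()
    for col in ("p", "q"):
        v = out[col].to_numpy(dtype=float)
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{col!r} outside [0, 1]")
    if contrast is not None:
        out["contrast"] = contrast
    elif "contrast" not in out.columns:
        out["contrast"] = "imported"
    return out


def count_degs(de: pd.DataFrame, lfc_thresh: float = 1.5,
               q_thresh: float = 0.05) -> int:
    """Number of genes with ``|lfc| > lfc_thresh`` and ``q < q_thresh`` (strict)."""
    return int(((de["lfc"].abs() > lfc_thresh)
                & (de["q"] < q_thresh)).sum())


def deg_phenotype_correlation(deg_counts: pd.Series, magnitudes: pd.Series,
                              ) -> dict[str, float]:
    """OLS of phenotype response magnitude on DEG count per condition."""
    joined = pd.concat([deg_counts.rename("x"), magnitudes.rename("y")],
                       axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 conditions")
    if joined["x"].nunique() == 1:
        raise ValueError("DEG counts have zero variance")
    res = stats.linregress(joined["x"], joined["y"])
    return {"R2": float(res.rvalue ** 2), "p": float(res.pvalue),
            "slope": float(res.slope), "n": len(joined)}


def select_top_genes(de_by_condition: dict[str, pd.DataFrame],
                     n_up: int = 200, n_down: int = 200,
                     p_thresh: float = 0.05, lfc_thresh: float = 1.5,
                     ) -> pd.DataFrame:
    """Top up-/down-regulated genes per condition; returns the union.

    Per condition, genes passing ``p < p_thresh`` and ``lfc > lfc_thresh``
    (or ``< -lfc_thresh`` for down) are ranked by lfc; ties break on gene id.
    The result has one row per union gene with boolean membership columns and
    a per-condition shortfall record in ``.attrs['shortfall']``.
    """
    membership: dict[str, set] = {}
    shortfall: dict[str, dict[str, int]] = {}
    for cond, de in de_by_condition.items():
        up = de[(de["p"] < p_thresh) & (de["lfc"] > lfc_thresh)]
        up = up.sort_values(["lfc", "gene"], ascending=[False, True])
        down = de[(de["p"] < p_thresh) & (de["lfc"] < -lfc_thresh)]
        down = down.sort_values(["lfc", "gene"], ascending=[True, True])
        shortfall[cond] = {"up": max(0, n_up - len(up)),
                           "down": max(0, n_down - len(down))}
        membership[cond] = set(up["gene"].head(n_up)) | \
            set(down["gene"].head(n_down))
    union = sorted(set().union(*membership.values())) if membership else []
    out = pd.DataFrame({"gene": union})
    for cond in de_by_condition:
        out[cond] = out["gene"].isin(membership[cond])
    out.attrs["shortfall"] = shortfall
    return out


def pairwise_lfc_correlation(lfc: pd.DataFrame,
                             high_thresh: float = 0.7) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-condition LFC vectors.

    Returns the correlation matrix with ``.attrs['high_pairs']`` listing
    condition pairs above ``high_thresh`` (high transcriptional similarity).
    """
    corr = lfc.corr(method="pearson")
    pairs = [(a, b) for i, a in enumerate(corr.columns)
             for b in corr.columns[i + 1:] if corr.loc[a, b] > high_thresh]
    corr.attrs["high_pairs"] = pairs
    return corr


# ---------------------------------------------------------------------------
# K-means modules with gap-statistic K selection
# ---------------------------------------------------------------------------

@dataclass
class GeneModuleSet:
    assignments: pd.Series        # gene -> module id (1..K)
    k: int
    gap_curve: pd.DataFrame       # columns k, gap, s_k, log_w
    module_scores: pd.DataFrame   # module x condition median lfc


def _pooled_within_dispersion(X: np.ndarray, k: int, seed: int,
                              n_init: int = 10) -> tuple[float, np.ndarray]:
    if k == 1:
        centroid = X.mean(axis=0, keepdims=True)
        return float(((X - centroid) ** 2).sum()), np.zeros(len(X), dtype=int)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                random_state=seed)
    labels = km.fit_predict(X)
    return float(km.inertia_), labels


def gap_statistic(X: np.ndarray, k_range: range, B: int = 50,
                  seed: int = 0) -> tuple[int, pd.DataFrame,
                                          dict[int, np.ndarray]]:
    """Tibshirani gap statistic with uniform bounding-box references.

    ``Gap(k) = mean_b log(W*_kb) - log(W_k)``; ``s_k = sd_b * sqrt(1 + 1/B)``.
    Chosen K is the smallest k with ``Gap(k) >= Gap(k+1) - s_{k+1}`` (the
    largest k in the range is taken if the rule never fires).
    """
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ks = list(k_range)
    log_w, gaps, s_ks, labels_by_k = [], [], [], {}
    ref_log_w = np.empty((B, len(ks)))
    refs = [rng.uniform(lo, hi, size=X.shape) for _ in range(B)]
    for j, k in enumerate(ks):
        w, labels = _pooled_within_dispersion(X, k, seed=seed + 1000 + k)
        labels_by_k[k] = labels
        log_w.append(np.log(w) if w > 0 else -np.inf)
        for b, ref in enumerate(refs):
            wb, _ = _pooled_within_dispersion(ref, k, seed=seed + 2000 + k)
            ref_log_w[b, j] = np.log(wb)
        gaps.append(ref_log_w[:, j].mean() - log_w[-1])
        s_ks.append(ref_log_w[:, j].std(ddof=1) * np.sqrt(1 + 1 / B))
    chosen = ks[-1]
    for j in range(len(ks) - 1):
        if gaps[j] >= gaps[j + 1] - s_ks[j + 1]:
            chosen = ks[j]
            break
    curve = pd.DataFrame({"k": ks, "gap": gaps, "s_k": s_ks, "log_w": log_w})
    return chosen, curve, labels_by_k


def cluster_gene_modules(lfc: pd.DataFrame, k_range: range = range(1, 16),
                         B: int = 50, seed: int = 0) -> GeneModuleSet:
    """Cluster selected genes (rows) into modules over condition LFC profiles.

    Module scores are the per-module median LFC in each condition.  If every
    gene profile is identical the degenerate K = 1 is returned directly.
    """
    X = lfc.to_numpy(dtype=float)
    if len(X) < max(k_range) + 1:
        raise ValueError("need more genes than max(k_range)")
    if np.allclose(X, X[0]):
        assignments = pd.Series(1, index=lfc.index, name="module")
        scores = pd.DataFrame([lfc.iloc[0]], index=pd.Index([1], name="module"))
        curve = pd.DataFrame({"k": [1], "gap": [np.nan], "s_k": [np.nan],
                              "log_w": [-np.inf]})
        return GeneModuleSet(assignments, 1, curve, scores)
    k, curve, labels_by_k = gap_statistic(X, k_range, B=B, seed=seed)
    assignments = pd.Series(labels_by_k[k] + 1, index=lfc.index, name="module")
    scores = lfc.groupby(assignments).median()
    scores.index.name = "module"
    return GeneModuleSet(assignments, k, curve, scores)
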