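"""PLS1 regression linking replicate-level expression to phenotype.

One model per phenotype metric (PLS1), fit by NIPALS on the autoscaled
sample x gene LFC matrix and the standardized response.  Component count is
chosen from the leave-one-out RRMSEP curve (RMSEP normalized by sd(y), so
1.0 is the no-skill reference) with an explicit elbow rule.  Gene importance
uses Variable Importance in Projection (VIP) scores, whose squares average
to 1 by construction; signatures are the top genes by VIP split by the sign
of their correlation with the first-component scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess


@dataclass
class PLSRModel:
    genes: list[str]
    n_components: int
    W: np.ndarray             # genes x A, unit-norm weight columns
    T: np.ndarray             # samples x A scores (mutually orthogonal)
    P: np.ndarray             # genes x A X-loadings
    c: np.ndarray             # A y-loadings
    ssy: np.ndarray           # response variance captured per component
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    warnings: list[str] = field(default_factory=list)

    @property
    def coef_standardized(self) -> np.ndarray:
        """Regression vector on the autoscaled X / standardized y scale."""
        R = self.W @ np.linalg.inv(self.P.T @ self.W)
        return R @ self.c

    @property
    def coef(self) -> np.ndarray:
        """Per-gene coefficients on the original scales."""
        return self.coef_standardized / self.x_scale * self.y_scale

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


@dataclass
class VIPVector:
    vip: pd.Series            # per selected gene, >= 0; mean(vip^2) = 1
    sign: pd.Series           # sign of correlation with first-component scores


@dataclass
class Signature:
    phenotype: str
    positive: list[str]       # descending VIP, correlation sign > 0
    negative: list[str]
    shortfall: dict[str, int] = field(default_factory=dict)


@dataclass
class RRMSEPCurve:
    n_components: np.ndarray
    rmsep: np.ndarray
    rrmsep: np.ndarray        # rmsep / sd(y)
    chosen: int


# ---------------------------------------------------------------------------
# variable-gene selection (variance-stabilizing ranking)
# ---------------------------------------------------------------------------

def select_variable_genes(expr: pd.DataFrame, n: int = 2500,
                          span: float = 0.3) -> list[str]:
    """Rank genes by standardized variance and return the top ``n``.

    A local-regression trend of log10 variance on log10 mean (over genes
    with positive variance) gives each gene an expected sd; observations are
    standardized by it, clipped at ``sqrt(n_samples)``, and genes are ranked
    by the variance of the clipped values.  ``expr`` is samples x genes.
    Mean-zero data (e.g. LFCs) are handled by offsetting means to positive
    values before taking logs of the absolute scale proxy.
    """
    X = expr.to_numpy(dtype=float)
    if X.shape[1] == 0 or np.allclose(X, X.flat[0]):
        raise ValueError("constant expression matrix")
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    genes = np.asarray(expr.columns)
    pos = var > 0
    if pos.sum() <= n:
        ranked = genes[pos]
        return list(ranked)
    # abs-mean proxy keeps the trend fit defined for signed inputs like LFCs
    mx = np.log10(np.abs(mean[pos]) + 1e-8)
    vy = np.log10(var[pos])
    fit = lowess(vy, mx, frac=span, xvals=mx)
    sd_pred = np.sqrt(np.power(10.0, fit))
    clip = np.sqrt(X.shape[0])
    Z = (X[:, pos] - mean[pos]) / sd_pred
    np.clip(Z, -clip, clip, out=Z)
    score = Z.var(axis=0, ddof=1)
    order = np.lexsort((genes[pos], -score))
    return list(genes[pos][order][:n])


# ---------------------------------------------------------------------------
# NIPALS PLS1
# ---------------------------------------------------------------------------

def _autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)  # constant genes -> zero weight
    return (X - mean) / scale, mean, scale


def fit_pls1(X: pd.DataFrame | np.ndarray, y: pd.Series | np.ndarray,
             n_components: int = 2) -> PLSRModel:
    """NIPALS PLS1 with internal autoscaling of X and standardization of y.

    Per component: ``w = X'y/||X'y||; t = Xw; p = X't/(t't); c = y't/(t't)``
    followed by deflation of X and y.  ``ssy_a = c_a^2 * (t_a' t_a)`` records
    the response variance captured by each component.  Requested components
    beyond the informative rank are truncated with a warning record.
    """
    genes = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{j}" for j in range(np.shape(X)[1])]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    if len(Xa) != len(ya):
        raise ValueError("X and y disagree on sample count")
    y_sd = ya.std(ddof=1)
    if y_sd == 0:
        raise ValueError("zero-variance response")
    Xs, x_mean, x_scale = _autoscale(Xa)
    ys = (ya - ya.mean()) / y_sd

    notes: list[str] = []
    Ws, Ts, Ps, cs, ssy = [], [], [], [], []
    Xd, yd = Xs.copy(), ys.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            notes.append(f"rank exhausted at component {a + 1}; truncated")
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt < 1e-12:
            notes.append(f"degenerate scores at component {a + 1}; truncated")
            break
        p = Xd.T @ t / tt
        c = yd @ t / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - c * t
        Ws.append(w); Ts.append(t); Ps.append(p); cs.append(c)
        ssy.append(c ** 2 * tt)
    if not Ws:
        raise ValueError("no informative component (X'y is zero)")
    return PLSRModel(
        genes=genes, n_components=len(Ws), W=np.column_stack(Ws),
        T=np.column_stack(Ts), P=np.column_stack(Ps), c=np.asarray(cs),
        ssy=np.asarray(ssy), x_mean=x_mean, x_scale=x_scale,
        y_mean=float(ya.mean()), y_scale=float(y_sd), warnings=notes,
    )


def loo_rrmsep_select(X: pd.DataFrame | np.ndarray,
                      y: pd.Series | np.ndarray,
                      a_max: int = 10,
                      improvement: float = 0.05) -> RRMSEPCurve:
    """Leave-one-out RRMSEP per component count and elbow-chosen A.

    Preprocessing is refit inside each fold.  RRMSEP = RMSEP / sd(y); a
    value near 1 means no predictive skill.  Chosen A is the smallest where
    the relative improvement to A+1 falls below ``improvement`` or the curve
    turns upward; otherwise the best A by RRMSEP.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    n = len(ya)
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out")
    a_max = min(a_max, n - 1)
    preds = np.full((n, a_max), np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_pls1(Xa[mask], ya[mask], n_components=a_max)
        Xs = (Xa[i] - model.x_mean) / model.x_scale
        # cumulative prediction over components from one NIPALS pass
        td = np.empty(model.n_components)
        xr = Xs.copy()
        yhat = 0.0
        for a in range(model.n_components):
            td[a] = xr @ model.W[:, a]
            xr = xr - td[a] * model.P[:, a]
            yhat = yhat + model.c[a] * td[a]
            preds[i, a] = model.y_mean + model.y_scale * yhat
        if model.n_components < a_max:  # pad truncated fits
            preds[i, model.n_components:] = preds[i, model.n_components - 1]
    rmsep = np.sqrt(np.nanmean((preds - ya[:, None]) ** 2, axis=0))
    rrmsep = rmsep / ya.std(ddof=1)
    chosen = int(np.argmin(rrmsep)) + 1
    for a in range(a_max - 1):
        if rrmsep[a + 1] >= rrmsep[a] or \
                (rrmsep[a] - rrmsep[a + 1]) / rrmsep[a] < improvement:
            chosen = a + 1
            break
    return RRMSEPCurve(np.arange(1, a_max + 1), rmsep, rrmsep, chosen)


def vip_scores(model: PLSRModel, X: pd.DataFrame | np.ndarray | None = None,
               ) -> VIPVector:
    """VIP scores and first-component correlation signs.

    ``VIP_j = sqrt(p * sum_a ssy_a * w_ja^2 / sum_a ssy_a)`` with unit-norm
    weight columns, so ``sum_j VIP_j^2 = p`` exactly.  The sign is the sign
    of the Pearson correlation between the (autoscaled) gene column and the
    first-component scores; if ``X`` is omitted the cached loadings-based
    equivalent ``sign(p_1)`` is used.
    """
    tot = model.ssy.sum()
    if tot <= 0:
        raise ValueError("model captured no response variance")
    p = len(model.genes)
    vip = np.sqrt(p * (model.W ** 2 @ model.ssy) / tot)
    if X is not None:
        Xs = (np.asarray(X, dtype=float) - model.x_mean) / model.x_scale
        t1 = model.T[:, 0]
        num = Xs.T @ (t1 - t1.mean())
        sign = np.sign(num)
    else:
        sign = np.sign(model.P[:, 0])
    return VIPVector(
        vip=pd.Series(vip, index=model.genes, name="vip"),
        sign=pd.Series(sign, index=model.genes, name="sign"),
    )


def extract_signature(vipv: VIPVector, phenotype: str = "",
                      n_each: int = 100) -> Signature:
    """Top-``n_each`` genes by VIP on each correlation side.

    Genes with exactly zero correlation sign are excluded from both lists;
    ties break on gene id for determinism.
    """
    df = pd.DataFrame({"vip": vipv.vip, "sign": vipv.sign})
    df = df.reset_index().rename(columns={"index": "gene"})
    df = df.sort_values(["vip", "gene"], ascending=[False, True])
    pos = df[df["sign"] > 0]["gene"].head(n_each).tolist()
    neg = df[df["sign"] < 0]["gene"].head(n_each).tolist()
    return Signature(
        phenotype=phenotype, positive=pos, negative=neg,
        shortfall={"positive": max(0, n_each - len(pos)),
                   "negative": max(0, n_each - len(neg))},
    )


def predict_phenotype(model: PLSRModel, external: pd.DataFrame) -> pd.Series:
    """Predict the modeled phenotype for external log2 expression profiles.

    ``external`` is genes x samples.  It is restricted to the model's genes,
    z-scored per gene within the external dataset, and missing model genes
    are imputed at 0 (the post-scaling mean).  The prediction applies the
    standardized-scale coefficients and returns values on the model's
    original y scale.
    """
    overlap = [g for g in model.genes if g in external.index]
    if not overlap:
        raise ValueError("no gene overlap with the model")
    frac = len(overlap) / len(model.genes)
    if frac < 0.5:
        warnings.warn(f"only {frac:.0%} of model genes present externally",
                      stacklevel=2)
    sub = external.loc[overlap]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1).replace(0.0, 1.0)
    Z = sub.sub(mu, axis=0).div(sd, axis=0)
    Zfull = pd.DataFrame(0.0, index=model.genes, columns=external.columns)
    Zfull.loc[overlap] = Z
    b = model.coef_standardized
    yhat = Zfull.T.to_numpy() @ b * model.y_scale + model.y_mean
    return pd.Series(yhat, index=external.columns, name="predicted")
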