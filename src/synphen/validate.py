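"""Orthogonal validation of signatures and phenotype predictions.

Signature genes can be checked against CRISPR-knockout essentiality (gene
effect scores, where <= -0.5 marks cell depletion) via a 2x2 chi-squared
enrichment, and model predictions against independently measured rates via
Pearson correlation.  Both operate on user-supplied tables or simulator
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnrichmentResult:
    table: np.ndarray         # 2x2: {in-signature, not} x {essential, not}
    chi2: float
    p: float
    n_dropped: int            # model genes without an effect score
    effect_thresh: float


def essentiality_enrichment(vip_genes: set[str] | list[str],
                            all_model_genes: set[str] | list[str],
                            gene_effect: pd.Series | pd.DataFrame,
                            effect_thresh: float = -0.5) -> EnrichmentResult:
    """Chi-squared enrichment of signature genes among essential genes.

    ``gene_effect`` maps gene -> score (or gene x cell-line scores, averaged
    across lines).  Essential means mean score <= ``effect_thresh``.  Model
    genes without a score are dropped (recorded); the scored fraction must
    cover at least half the model genes.  Pearson chi-squared without
    continuity correction.
    """
    if isinstance(gene_effect, pd.DataFrame):
        gene_effect = gene_effect.mean(axis=1)
    model = pd.Index(sorted(set(all_model_genes)))
    scored = model.intersection(gene_effect.index)
    n_dropped = len(model) - len(scored)
    if len(scored) < 0.5 * len(model):
        raise ValueError("gene_effect covers < 50% of model genes")
    in_sig = scored.isin(set(vip_genes))
    essential = gene_effect.loc[scored].to_numpy() <= effect_thresh
    table = np.array([
        [np.sum(in_sig & essential), np.sum(in_sig & ~essential)],
        [np.sum(~in_sig & essential), np.sum(~in_sig & ~essential)],
    ])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("empty margin in the contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return EnrichmentResult(table=table, chi2=float(chi2), p=float(p),
                            n_dropped=n_dropped, effect_thresh=effect_thresh)


def external_prediction_correlation(predicted: pd.Series,
                                    measured: pd.Series) -> dict[str, float]:
    """Squared Pearson correlation (and its t-test p) for paired samples."""
    joined = pd.concat([predicted.rename("pred"), measured.rename("meas")],
                       axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 paired samples")
    if joined["pred"].nunique() == 1 or joined["meas"].nunique() == 1:
        raise ValueError("zero variance in predictions or measurements")
    r, p = stats.pearsonr(joined["pred"], joined["meas"])
    return {"R2": float(r ** 2), "p": float(p), "n": len(joined)}
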