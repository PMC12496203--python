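"""Transcriptional additivity and HSA synergy calling.

Two complementary views of combination expression:

* the *additive null* — predicted combination LFC (vs T0) is the sum of the
  constituent single-ligand LFCs, assessed by OLS R^2 on genes upregulated
  (LFC > 0.5) in at least one single treatment;
* the *HSA synergy rule* — a gene is positively synergistic when its
  combination-vs-single LFC strictly exceeds 1.5 with adjusted p < 0.05
  against EVERY constituent single (negatively synergistic for < -1.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AdditivityFit:
    predicted: pd.Series      # sum of single-ligand LFCs, filtered genes
    observed: pd.Series       # combination LFC vs T0, same genes
    r2: float
    p: float
    n_genes: int
    lfc_filter: float


def additive_prediction(singles: list[pd.DataFrame], combo: pd.DataFrame,
                        lfc_filter: float = 0.5) -> AdditivityFit:
    """Test whether combination expression is the sum of single responses.

    All DE tables are vs-T0 contrasts on a shared gene universe.  Genes with
    ``lfc > lfc_filter`` in at least one single treatment are kept; predicted
    combination LFC is the sum of single LFCs; R^2 and p come from OLS of
    observed on predicted.
    """
    frames = [s.set_index("gene")["lfc"] for s in singles]
    obs = combo.set_index("gene")["lfc"]
    genes = reduce(lambda a, b: a.intersection(b),
                   [f.index for f in frames], obs.index)
    frames = [f.loc[genes] for f in frames]
    obs = obs.loc[genes]
    keep = reduce(np.logical_or, [f > lfc_filter for f in frames])
    if keep.sum() == 0:
        raise ValueError("no genes pass the single-ligand LFC filter")
    pred = sum(f[keep] for f in frames)
    res = stats.linregress(pred, obs[keep])
    return AdditivityFit(predicted=pred, observed=obs[keep],
                         r2=float(res.rvalue ** 2), p=float(res.pvalue),
                         n_genes=int(keep.sum()), lfc_filter=lfc_filter)


def call_synergistic_genes(de_vs_singles: list[pd.DataFrame],
                           lfc_thresh: float = 1.5,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Classify genes by the HSA rule against every constituent single.

    ``de_vs_singles`` holds one combination-vs-single DE table per
    constituent ligand (two for pairs, three for the triple — the triple is
    a generalization of the pairwise rule).  Returns a per-gene table with
    class in {positive, negative, none} and the lfc/q columns per contrast.
    """
    if len(de_vs_singles) < 2:
        raise ValueError("need a contrast vs each constituent single (>= 2)")
    base = de_vs_singles[0].set_index("gene")
    genes = base.index
    for other in de_vs_singles[1:]:
        if not genes.equals(pd.Index(other["gene"])):
            if set(genes) != set(other["gene"]):
                raise ValueError("gene universes differ between contrasts")
    out = pd.DataFrame(index=genes)
    pos = np.ones(len(genes), dtype=bool)
    neg = np.ones(len(genes), dtype=bool)
    for i, de in enumerate(de_vs_singles):
        d = de.set_index("gene").loc[genes]
        label = d["contrast"].iloc[0] if "contrast" in d else f"single{i}"
        out[f"lfc_vs_{label}"] = d["lfc"]
        out[f"q_vs_{label}"] = d["q"]
        sig = d["q"].to_numpy() < alpha
        pos &= (d["lfc"].to_numpy() > lfc_thresh) & sig
        neg &= (d["lfc"].to_numpy() < -lfc_thresh) & sig
    out["class"] = np.select([pos, neg], ["positive", "negative"], "none")
    return out.reset_index().rename(columns={"index": "gene"})


def synergy_overlap(calls: dict[str, pd.DataFrame],
                    which: str = "positive") -> dict[str, int]:
    """Set-intersection cardinalities of synergy genes across combinations.

    Returns per-combination counts plus every pairwise and higher-order
    intersection, keyed e.g. ``"EGF+OSM & EGF+TGFB"``.
    """
    if len(calls) < 2:
        raise ValueError("need at least two call sets")
    sets = {name: set(df.loc[df["class"] == which, "gene"])
            for name, df in calls.items()}
    names = list(sets)
    out = {name: len(s) for name, s in sets.items()}
    from itertools import combinations
    for r in range(2, len(names) + 1):
        for group in combinations(names, r):
            inter = set.intersection(*(sets[g] for g in group))
            out[" & ".join(group)] = len(inter)
    return out
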