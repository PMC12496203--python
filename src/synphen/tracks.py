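"""Track-derived phenotype metrics.

Turns per-cell, per-frame track tables into the four phenotype metrics used
throughout the analysis — T0-normalized cell count, motility (slope of the
mean squared displacement), Clark–Evans style nearest-neighbor ratio, and
mean cytoplasmic area — plus the 4-D PBS-relative response magnitude.

Conventions: positions in pixels (origin top-left, y down), time in hours
with frame 0 at treatment, frame interval 0.5 h unless the table says
otherwise.  For 2-D Brownian motion the MSD slope equals ``4*D``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import gammaln

PHENOTYPE_METRICS = ("count_fc", "motility", "nn_ratio", "cyto_area")


@dataclass
class MSDCurve:
    """Pooled time-averaged mean squared displacement per lag."""

    lags: np.ndarray          # hours, strictly increasing
    msd: np.ndarray           # px^2
    n_pairs: np.ndarray       # displacement pairs contributing per lag
    dropped: list = field(default_factory=list)  # lags with no pairs


@dataclass
class SpatialStats:
    n: int
    area: float
    intensity: float          # lambda = n / area
    r_mean: float             # observed mean k-th neighbor distance, px
    r_expected: float         # CSR expectation E_k, px
    ratio: float              # r_mean / r_expected
    k: int = 1


def filter_tracks(tracks: pd.DataFrame, max_jump: float = 200.0,
                  window: float = 0.5) -> pd.DataFrame:
    """Drop whole tracks containing an implausible jump.

    A track is removed entirely if any displacement across one frame window
    (consecutive observed frames no more than ``window`` hours apart) is
    strictly greater than ``max_jump`` pixels; all other tracks pass through
    unchanged.  Tracking artifacts (identity swaps between distant cells)
    produce such jumps.
    """
    if tracks.empty:
        return tracks.copy()
    df = tracks.sort_values(["condition", "replicate", "field", "cell_id",
                             "frame"], kind="stable")
    key = ["condition", "replicate", "field", "cell_id"]
    g = df.groupby(key, sort=False)
    dx = g["x"].diff()
    dy = g["y"].diff()
    dt = g["t"].diff()
    jump = np.hypot(dx, dy)
    bad_step = (jump > max_jump) & (dt <= window + 1e-9)
    bad_tracks = df.loc[bad_step, key].drop_duplicates()
    if bad_tracks.empty:
        return tracks.copy()
    merged = tracks.merge(bad_tracks.assign(_bad=True), on=key, how="left")
    return tracks.loc[merged["_bad"].isna().to_numpy()].copy()


def compute_msd(tracks: pd.DataFrame, lags: np.ndarray | list) -> MSDCurve:
    """Time-averaged MSD pooled over tracks, weighted by pair counts.

    For each lag the squared displacement is averaged over every overlapping
    frame pair within each track, then pooled across tracks (equivalent to a
    pair-count-weighted mean of per-track MSDs).  Tracks must have contiguous
    frames.  Lags with no contributing pair are dropped and recorded.
    """
    lags = np.sort(np.asarray(lags, dtype=float))
    if tracks.empty:
        return MSDCurve(np.array([]), np.array([]), np.array([], dtype=int),
                        dropped=list(lags))
    dt = _frame_interval(tracks)
    lag_frames = np.rint(lags / dt).astype(int)
    sums = np.zeros(len(lags))
    counts = np.zeros(len(lags), dtype=int)
    key = [c for c in ("condition", "replicate", "field", "cell_id")
           if c in tracks.columns]
    for _, tr in tracks.groupby(key, sort=False):
        tr = tr.sort_values("frame")
        x = tr["x"].to_numpy()
        y = tr["y"].to_numpy()
        m = len(x)
        for i, k in enumerate(lag_frames):
            if k <= 0 or k >= m:
                continue
            d2 = (x[k:] - x[:-k]) ** 2 + (y[k:] - y[:-k]) ** 2
            sums[i] += d2.sum()
            counts[i] += len(d2)
    keep = counts > 0
    dropped = [float(l) for l in lags[~keep]]
    return MSDCurve(lags[keep], sums[keep] / counts[keep], counts[keep],
                    dropped=dropped)


def motility_slope(curve: MSDCurve, lag_min: float = 0.5,
                   lag_max: float = 6.0) -> float:
    """OLS slope of MSD vs lag over ``[lag_min, lag_max]`` hours.

    The fit includes an intercept (localization noise offsets the curve).
    For ideal 2-D Brownian motion the slope equals ``4*D``.
    """
    sel = (curve.lags >= lag_min - 1e-9) & (curve.lags <= lag_max + 1e-9)
    if sel.sum() < 3:
        raise ValueError("need at least 3 lags within [lag_min, lag_max]")
    slope, _ = np.polyfit(curve.lags[sel], curve.msd[sel], 1)
    return float(slope)


def _expected_neighbor_distance(k: int, intensity: float) -> float:
    # E_k = Gamma(k + 1/2) / ((k-1)! * sqrt(pi * lambda)); E_1 = 1/(2*sqrt(lambda))
    logE = gammaln(k + 0.5) - gammaln(k) - 0.5 * np.log(np.pi * intensity)
    return float(np.exp(logE))


def nearest_neighbor_ratio(positions: np.ndarray, area: float,
                           k: int = 1) -> SpatialStats:
    """Clark–Evans style k-th nearest-neighbor ratio.

    ``ratio = mean observed k-th neighbor distance / CSR expectation``;
    values < 1 indicate clustering, > 1 spreading.  No edge correction is
    applied.  ``k=1`` means the nearest *other* cell.
    """
    pts = np.asarray(positions, dtype=float)
    if area <= 0:
        raise ValueError("area must be positive")
    n = len(pts)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k + 1)  # first neighbor is the point itself
    r_mean = float(dist[:, k].mean())
    lam = n / area
    e_k = _expected_neighbor_distance(k, lam)
    return SpatialStats(n=n, area=float(area), intensity=lam, r_mean=r_mean,
                        r_expected=e_k, ratio=r_mean / e_k, k=k)


def _frame_interval(tracks: pd.DataFrame) -> float:
    f = np.sort(tracks["frame"].unique())
    t = tracks.drop_duplicates("frame").set_index("frame")["t"].sort_index()
    if len(f) < 2:
        return 0.5
    return float(np.median(np.diff(t.to_numpy()) / np.diff(f)))


def summarize_phenotypes(tracks: pd.DataFrame, t_eval: float = 24.0,
                         field_area: float | None = None,
                         neighbor_k: int = 1,
                         lag_min: float = 0.5,
                         lag_max: float = 6.0) -> pd.DataFrame:
    """Per condition x replicate phenotype metrics from a filtered TrackTable.

    count_fc   : cell count at ``t_eval`` / count at t=0, per field, averaged
    motility   : MSD slope (px^2/h) over ``[lag_min, lag_max]`` h, pooled tracks
    nn_ratio   : nearest-neighbor ratio at ``t_eval``, averaged over fields
    cyto_area  : mean cytoplasmic area of cells present at ``t_eval``

    ``t_eval`` is snapped to the nearest available frame.  ``field_area``
    defaults to the bounding-box area of the observed positions.
    """
    if tracks.empty:
        raise ValueError("empty track table")
    dt = _frame_interval(tracks)
    frames = np.sort(tracks["frame"].unique())
    f_eval = int(frames[np.argmin(np.abs(frames * dt - t_eval))])
    if field_area is None:
        field_area = float(
            (tracks["x"].max() - min(tracks["x"].min(), 0.0))
            * (tracks["y"].max() - min(tracks["y"].min(), 0.0)))
    lags = np.arange(1, int(round(lag_max / dt)) + 1) * dt

    rows = []
    for (cond, rep), sub in tracks.groupby(["condition", "replicate"],
                                           sort=False):
        fcs, ratios = [], []
        for _, fsub in sub.groupby("field", sort=False):
            n0 = int((fsub["frame"] == 0).sum())
            if n0 == 0:
                raise ValueError(
                    f"no cells at t=0 for {cond!r} replicate {rep}")
            nt = int((fsub["frame"] == f_eval).sum())
            fcs.append(nt / n0)
            at_eval = fsub.loc[fsub["frame"] == f_eval, ["x", "y"]]
            if len(at_eval) >= neighbor_k + 1:
                ratios.append(nearest_neighbor_ratio(
                    at_eval.to_numpy(), field_area, k=neighbor_k).ratio)
        curve = compute_msd(sub, lags)
        rows.append({
            "condition": cond, "replicate": rep,
            "count_fc": float(np.mean(fcs)),
            "motility": motility_slope(curve, lag_min, lag_max),
            "nn_ratio": float(np.mean(ratios)) if ratios else np.nan,
            "cyto_area": float(
                sub.loc[sub["frame"] == f_eval, "area"].mean()),
        })
    return pd.DataFrame(rows)


def response_magnitude(metrics: pd.DataFrame,
                       reference: str = "PBS") -> pd.DataFrame:
    """PBS-relative 4-D response and its L2 magnitude, per replicate.

    ``rel_i = (m_i - m_i^ref) / m_i^ref`` for each metric, with the reference
    row taken from the same replicate; ``magnitude = ||rel||_2``.  The origin
    (all rel zero) means no change from the reference condition.
    """
    if reference not in metrics["condition"].values:
        raise ValueError(f"reference condition {reference!r} missing")
    ref = metrics.loc[metrics["condition"] == reference].set_index("replicate")
    out = metrics.copy()
    rel_cols = []
    for m in PHENOTYPE_METRICS:
        refvals = out["replicate"].map(ref[m])
        if np.any(refvals == 0):
            raise ValueError(f"reference metric {m!r} is zero")
        out[f"rel_{m}"] = (out[m] - refvals) / refvals
        rel_cols.append(f"rel_{m}")
    out["magnitude"] = np.sqrt((out[rel_cols] ** 2).sum(axis=1))
    return out
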