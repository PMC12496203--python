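"""Synthetic paired track + count data with known ground truth.

The generators emulate the experimental design the analysis modules assume:
eight treatment conditions (PBS vehicle, three single ligands, three pairs,
one triple) with three biological replicates, paired live-cell track tables
and bulk RNA-seq style count matrices.  Every stochastic choice flows from a
single master seed through :class:`numpy.random.SeedSequence` children, so a
run is a pure function of its parameters.

Tracks follow 2-D Brownian motion (per-axis step variance ``2*D*dt``) with
reflecting field boundaries, Poisson-thinned cell division, and lognormal
cytoplasmic areas.  Counts are negative binomial (``var = mu + phi*mu**2``)
around a log2-additive mean model: a combination's log2 mean is the baseline
plus the sum of its constituent single-ligand effects, plus an injected
synergy term for designated genes.  The linked experiment couples replicate
level expression to phenotype through driver-gene coefficients so signature
recovery can be scored against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LIGANDS: tuple[str, ...] = ("EGF", "OSM", "TGFB")

#: condition label -> constituent ligands (empty for controls)
CONDITION_LIGANDS: dict[str, tuple[str, ...]] = {
    "PBS": (),
    "EGF": ("EGF",),
    "OSM": ("OSM",),
    "TGFB": ("TGFB",),
    "EGF+OSM": ("EGF", "OSM"),
    "EGF+TGFB": ("EGF", "TGFB"),
    "OSM+TGFB": ("OSM", "TGFB"),
    "EGF+OSM+TGFB": ("EGF", "OSM", "TGFB"),
}

CONDITIONS: tuple[str, ...] = tuple(CONDITION_LIGANDS)
COMBINATIONS: tuple[str, ...] = tuple(
    c for c, parts in CONDITION_LIGANDS.items() if len(parts) >= 2
)

TRACK_COLUMNS = [
    "cell_id", "frame", "t", "x", "y", "area", "field", "condition", "replicate",
]


class ParameterError(ValueError):
    """Invalid simulation parameter."""


class ConfigurationError(ValueError):
    """Inconsistent experimental design."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class ConditionKinetics:
    """Per-condition motility/growth/morphology settings.

    diffusion      : Brownian diffusion coefficient D, px^2/h
    division_rate  : division events per cell per hour
    area_mean      : mean cytoplasmic area, px^2
    area_cv        : coefficient of variation of area (lognormal)
    """

    diffusion: float
    division_rate: float
    area_mean: float = 500.0
    area_cv: float = 0.2


@dataclass
class TrackSimParams:
    conditions: Mapping[str, ConditionKinetics]
    n_cells_init: int = 200
    field_size: tuple[float, float] = (1024.0, 1024.0)
    frame_interval: float = 0.5
    n_frames: int = 49
    n_replicates: int = 3
    n_fields: int = 1
    spatial_pattern: str = "poisson"
    pattern_params: dict = field(default_factory=dict)
    division_offset_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.n_cells_init < 1:
            raise ParameterError("n_cells_init must be >= 1")
        if min(self.field_size) <= 0:
            raise ParameterError("field_size must be positive")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be positive")
        if self.spatial_pattern not in ("poisson", "thomas_cluster", "grid"):
            raise ParameterError(f"unknown spatial_pattern {self.spatial_pattern!r}")
        for name, kin in self.conditions.items():
            for attr in ("diffusion", "division_rate", "area_mean", "area_cv"):
                v = getattr(kin, attr)
                if not np.isfinite(v) or v < 0:
                    raise ParameterError(f"{name}.{attr} must be finite and >= 0")


@dataclass
class CountSimParams:
    """Negative-binomial expression model parameters.

    ``single_ligand_effects`` is a genes x ligands array of log2 fold changes
    relative to the T0 baseline.  ``synergy_sets`` maps a combination label to
    ``[(gene_index, extra_log2), ...]``; the extra term is added on top of the
    additive (sum-of-singles) expectation for that combination only.
    """

    n_genes: int
    baseline_log2_mean: np.ndarray
    dispersion: float | np.ndarray = 0.005
    single_ligand_effects: np.ndarray | None = None
    synergy_sets: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    library_size: float = 8.0
    n_replicates: int = 3
    #: per-gene, per-sample biological variability (sd of a log2 random
    #: effect); 0 gives the pure NB model.  The linked experiment turns this
    #: on to give biological replicates identity beyond counting noise.
    replicate_log2_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        disp = np.asarray(self.dispersion, dtype=float)
        if np.any(disp < 0):
            raise ParameterError("dispersion must be >= 0")
        if self.library_size <= 0:
            raise ParameterError("library_size must be > 0")
        base = np.asarray(self.baseline_log2_mean, dtype=float)
        if base.shape != (self.n_genes,):
            raise ParameterError("baseline_log2_mean must have length n_genes")
        if self.single_ligand_effects is not None:
            eff = np.asarray(self.single_ligand_effects, dtype=float)
            if eff.shape != (self.n_genes, len(LIGANDS)):
                raise ParameterError("single_ligand_effects must be genes x 3")
        for combo, entries in self.synergy_sets.items():
            if combo not in COMBINATIONS:
                raise ConfigurationError(f"unknown combination {combo!r}")
            for g, _ in entries:
                if not 0 <= g < self.n_genes:
                    raise ParameterError(f"synergy gene index {g} out of range")


@dataclass
class GroundTruth:
    """Record of the generator state needed for recovery scoring."""

    true_diffusion: dict[str, float] = field(default_factory=dict)
    true_division_rate: dict[str, float] = field(default_factory=dict)
    synergy_genes: dict[str, list[str]] = field(default_factory=dict)
    synergy_extra: dict[str, dict[str, float]] = field(default_factory=dict)
    driver_genes: list[str] = field(default_factory=list)
    driver_beta: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    snr: float | None = None
    seed: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# spatial point patterns
# ---------------------------------------------------------------------------

def _initial_positions(pattern: str, n: int, size, rng: np.random.Generator,
                       params: dict) -> np.ndarray:
    w, h = size
    if pattern == "poisson":
        return rng.uniform((0, 0), (w, h), size=(n, 2))
    if pattern == "grid":
        # regular lattice, maximally dispersed
        ncol = int(np.ceil(np.sqrt(n * w / h)))
        nrow = int(np.ceil(n / ncol))
        xs = (np.arange(ncol) + 0.5) * w / ncol
        ys = (np.arange(nrow) + 0.5) * h / nrow
        pts = np.array([(x, y) for y in ys for x in xs])[:n]
        return pts
    if pattern == "thomas_cluster":
        parent_rate = params.get("parent_rate", max(2, n // 10))
        offspring_sd = params.get("offspring_sd", 20.0)
        n_parents = max(1, rng.poisson(parent_rate))
        parents = rng.uniform((0, 0), (w, h), size=(n_parents, 2))
        assign = rng.integers(0, n_parents, size=n)
        pts = parents[assign] + rng.normal(0.0, offspring_sd, size=(n, 2))
        return _reflect(pts, w, h)
    raise ParameterError(f"unknown spatial_pattern {pattern!r}")


def _reflect(pts: np.ndarray, w: float, h: float) -> np.ndarray:
    """Fold coordinates back into [0, w] x [0, h] (reflecting boundary)."""
    out = pts.copy()
    for dim, lim in ((0, w), (1, h)):
        v = np.mod(out[:, dim], 2 * lim)
        out[:, dim] = np.where(v > lim, 2 * lim - v, v)
    return out


# ---------------------------------------------------------------------------
# track simulation
# ---------------------------------------------------------------------------

def default_track_panel() -> dict[str, ConditionKinetics]:
    """Study-condition kinetics for the eight-treatment panel.

    Values are chosen to mirror the qualitative ordering reported for MCF10A:
    EGF drives proliferation, motility and larger cytoplasm; OSM a modest
    proliferative/motility effect with clustering; TGFB little change alone;
    EGF+OSM shows emergent proliferation and the strongest motility;
    EGF+TGFB emergent motility, spreading and cytoplasmic enlargement;
    OSM+TGFB emergent proliferation; the triple resembles EGF+OSM.
    """
    return {
        "PBS": ConditionKinetics(20.0, 0.004, 450.0, 0.2),
        "EGF": ConditionKinetics(60.0, 0.035, 520.0, 0.2),
        "OSM": ConditionKinetics(35.0, 0.018, 455.0, 0.2),
        "TGFB": ConditionKinetics(22.0, 0.006, 465.0, 0.2),
        "EGF+OSM": ConditionKinetics(100.0, 0.050, 530.0, 0.2),
        "EGF+TGFB": ConditionKinetics(85.0, 0.035, 660.0, 0.2),
        "OSM+TGFB": ConditionKinetics(32.0, 0.030, 470.0, 0.2),
        "EGF+OSM+TGFB": ConditionKinetics(95.0, 0.042, 540.0, 0.2),
    }


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2 if mean > 0 else 0.0
    return mu, np.sqrt(sigma2)


def _simulate_field(kin: ConditionKinetics, p: TrackSimParams,
                    rng: np.random.Generator) -> pd.DataFrame:
    w, h = p.field_size
    dt = p.frame_interval
    step_sd = np.sqrt(2.0 * kin.diffusion * dt)
    mu_a, sd_a = _lognormal_params(kin.area_mean, kin.area_cv)

    pos = _initial_positions(p.spatial_pattern, p.n_cells_init, p.field_size,
                             rng, p.pattern_params)
    n0 = len(pos)
    ids = np.arange(n0)
    areas = rng.lognormal(mu_a, sd_a, size=n0) if kin.area_cv > 0 else \
        np.full(n0, kin.area_mean)
    next_id = n0
    div_p = min(1.0, kin.division_rate * dt)

    frames = []
    for f in range(p.n_frames):
        frames.append(pd.DataFrame({
            "cell_id": ids.copy(), "frame": f, "x": pos[:, 0].copy(),
            "y": pos[:, 1].copy(), "area": areas.copy(),
        }))
        if f == p.n_frames - 1:
            break
        if step_sd > 0:
            pos = _reflect(pos + rng.normal(0.0, step_sd, size=pos.shape), w, h)
        if div_p > 0:
            dividing = rng.random(len(ids)) < div_p
            n_new = int(dividing.sum())
            if n_new:
                off = rng.normal(0.0, p.division_offset_sd, size=(n_new, 2))
                newpos = _reflect(pos[dividing] + off, w, h)
                newids = np.arange(next_id, next_id + n_new)
                next_id += n_new
                newareas = (rng.lognormal(mu_a, sd_a, size=n_new)
                            if kin.area_cv > 0 else np.full(n_new, kin.area_mean))
                pos = np.vstack([pos, newpos])
                ids = np.concatenate([ids, newids])
                areas = np.concatenate([areas, newareas])
    out = pd.concat(frames, ignore_index=True)
    out["t"] = out["frame"] * dt
    return out


def simulate_tracks(params: TrackSimParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate Brownian cell tracks for every condition/replicate/field.

    Returns a tidy TrackTable (columns ``cell_id, frame, t, x, y, area,
    field, condition, replicate``) and the :class:`GroundTruth` holding the
    diffusion coefficients and division rates actually used.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    children = iter(ss.spawn(len(params.conditions) * params.n_replicates
                             * params.n_fields))
    pieces = []
    for cond, kin in params.conditions.items():
        for rep in range(1, params.n_replicates + 1):
            for fld in range(1, params.n_fields + 1):
                rng = np.random.default_rng(next(children))
                df = _simulate_field(kin, params, rng)
                df["field"] = fld
                df["condition"] = cond
                df["replicate"] = rep
                pieces.append(df)
    table = pd.concat(pieces, ignore_index=True)[TRACK_COLUMNS]
    gt = GroundTruth(
        true_diffusion={c: k.diffusion for c, k in params.conditions.items()},
        true_division_rate={c: k.division_rate for c, k in params.conditions.items()},
        seed=params.seed,
    )
    return table, gt


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def default_count_params(n_genes: int = 2500, seed: int = 0,
                         dispersion: float = 0.005,
                         n_replicates: int = 3) -> CountSimParams:
    """Generate baseline abundances and sparse single-ligand effect matrices.

    Effect sparsity/scale per ligand mirrors the study's qualitative DEG
    burden: EGF strongest, OSM intermediate, TGFB weakest.  The default
    dispersion emulates clean cell-line biological replicates; baselines
    span ~2^4..2^10 relative abundance with a library factor of 8
    (mean counts roughly 1e2..1e4 per gene).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    baseline = rng.uniform(4.0, 10.0, size=n_genes)
    eff = np.zeros((n_genes, len(LIGANDS)))
    sparsity = {"EGF": 0.045, "OSM": 0.030, "TGFB": 0.012}
    scale = {"EGF": 1.3, "OSM": 1.1, "TGFB": 0.9}
    for j, lig in enumerate(LIGANDS):
        hit = rng.random(n_genes) < sparsity[lig]
        eff[hit, j] = rng.normal(0.0, scale[lig], size=int(hit.sum()))
    return CountSimParams(
        n_genes=n_genes, baseline_log2_mean=baseline, dispersion=dispersion,
        single_ligand_effects=eff,
        n_replicates=n_replicates, seed=seed,
    )


def make_design(n_replicates: int = 3,
                conditions: Sequence[str] = CONDITIONS) -> pd.DataFrame:
    """Sample sheet covering T0 plus the treatment panel."""
    rows = []
    for cond in ("T0", *conditions):
        for rep in range(1, n_replicates + 1):
            rows.append({
                "sample": f"{cond}_r{rep}", "condition": cond,
                "replicate": rep, "timepoint": 0.0 if cond == "T0" else 24.0,
            })
    return pd.DataFrame(rows)


def expected_log2_mean(params: CountSimParams, condition: str) -> np.ndarray:
    """Noise-free log2 mean for one condition (additive model + synergy)."""
    mu = np.asarray(params.baseline_log2_mean, dtype=float).copy()
    eff = params.single_ligand_effects
    if eff is not None:
        for lig in CONDITION_LIGANDS.get(condition, ()):
            mu += eff[:, LIGANDS.index(lig)]
    for g, extra in params.synergy_sets.get(condition, ()):  # combos only
        mu[g] += extra
    return mu


def inject_synergy(params: CountSimParams, combo: str, n_genes: int,
                   extra_log2: float, rng: np.random.Generator) -> list[int]:
    """Pick synergy genes for ``combo`` and register them in ``params``.

    The chosen genes get their constituent single-ligand effects zeroed so
    the injected ``extra_log2`` is exactly the expected combination-vs-single
    log2 fold change (the HSA excess being planted).
    """
    idx = rng.choice(params.n_genes, size=n_genes, replace=False)
    if params.single_ligand_effects is not None:
        for lig in CONDITION_LIGANDS[combo]:
            params.single_ligand_effects[idx, LIGANDS.index(lig)] = 0.0
    params.synergy_sets[combo] = [(int(g), float(extra_log2)) for g in idx]
    return [int(g) for g in idx]


def simulate_counts(params: CountSimParams,
                    design: pd.DataFrame | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a genes x samples NB count matrix for the design.

    Returns ``(counts, design, ground_truth)``.  Counts follow
    ``NB(mean = library_size * 2**log2_model, var = mu + phi*mu**2)``.
    """
    params.validate()
    if design is None:
        design = make_design(params.n_replicates)
    for cond in design["condition"].unique():
        if cond == "T0":
            continue
        if cond not in CONDITION_LIGANDS:
            raise ConfigurationError(f"unknown condition {cond!r} in design")
        for lig in CONDITION_LIGANDS[cond]:
            if len(CONDITION_LIGANDS[cond]) >= 2 and \
                    lig not in design["condition"].values:
                raise ConfigurationError(
                    f"design lacks single-ligand condition {lig!r} required "
                    f"by combination {cond!r}")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 29]))
    genes = [f"g{i:05d}" for i in range(params.n_genes)]
    disp = np.broadcast_to(np.asarray(params.dispersion, dtype=float),
                           (params.n_genes,))
    cols = {}
    for _, row in design.iterrows():
        log2mu = expected_log2_mean(params, row["condition"])
        if params.replicate_log2_sd > 0:
            log2mu = log2mu + rng.normal(0.0, params.replicate_log2_sd,
                                         size=params.n_genes)
        mu = params.library_size * np.power(2.0, log2mu)
        if np.all(disp == 0):
            counts = rng.poisson(mu)
        else:
            phi = np.where(disp > 0, disp, 1e-12)
            counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
        cols[row["sample"]] = counts
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    gt = GroundTruth(
        synergy_genes={c: [genes[g] for g, _ in s]
                       for c, s in params.synergy_sets.items()},
        synergy_extra={c: {genes[g]: x for g, x in s}
                       for c, s in params.synergy_sets.items()},
        seed=params.seed,
    )
    return counts, design, gt


# ---------------------------------------------------------------------------
# linked experiment: expression -> phenotype coupling
# ---------------------------------------------------------------------------

PHENOTYPE_METRICS = ("count_fc", "motility", "nn_ratio", "cyto_area")

#: additive offset keeping simulated phenotype values positive
_PHENOTYPE_OFFSET = 15.0


def _log2_cpm(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    lib = counts.sum(axis=0)
    return np.log2(counts.div(lib, axis=1) * 1e6 + pseudocount)


def replicate_lfc(counts: pd.DataFrame, design: pd.DataFrame,
                  reference: str = "T0") -> pd.DataFrame:
    """Per-sample log2 fold change vs the mean of the reference samples."""
    lcpm = _log2_cpm(counts)
    ref_samples = design.loc[design["condition"] == reference, "sample"]
    if ref_samples.empty:
        raise ConfigurationError(f"no {reference!r} samples in design")
    ref_mean = lcpm[list(ref_samples)].mean(axis=1)
    keep = design.loc[design["condition"] != reference, "sample"]
    return lcpm[list(keep)].sub(ref_mean, axis=0)


def simulate_linked_experiment(
    count_params: CountSimParams | None = None,
    track_params: TrackSimParams | None = None,
    n_drivers: int = 50,
    snr: float = 3.0,
    noise_sd: float = 1.0,
    driver_boost: float = 2.0,
    seed: int = 0,
) -> dict:
    """Paired counts + phenotype table with expression->phenotype coupling.

    Each replicate's phenotype metric is an affine function of that
    replicate's driver-gene log2 fold changes vs T0:
    ``metric = offset + snr * s_std + N(0, noise_sd)`` where ``s = beta . lfc``
    is standardized across samples.  Driver coefficients are supported on
    ``n_drivers`` genes with appreciable single-ligand effects; those genes'
    condition effects are amplified by ``driver_boost`` (phenotype drivers
    are themselves strong transcriptional responders) and the coefficients
    are sign-aligned with each gene's net effect, so transcriptionally
    stronger conditions move phenotype further from the PBS origin.

    Returns a dict with ``counts, design, lfc, phenotypes, ground_truth`` and,
    if ``track_params`` is given, ``tracks``.
    """
    if count_params is None:
        count_params = default_count_params(seed=seed)
        # biological replicate variability is the signal that lets the
        # replicate-paired design identify drivers beyond condition means
        count_params.replicate_log2_sd = 0.2
    eff = count_params.single_ligand_effects
    if eff is None:
        raise ConfigurationError("linked experiment needs single_ligand_effects")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    eligible = np.flatnonzero(np.abs(eff).max(axis=1) >= 0.5)
    if len(eligible) < n_drivers:
        raise ConfigurationError("not enough effect-bearing genes for drivers")
    drivers = np.sort(rng.choice(eligible, size=n_drivers, replace=False))
    eff[drivers] *= driver_boost
    net = eff.sum(axis=1)

    counts, design, gt = simulate_counts(count_params)
    lfc = replicate_lfc(counts, design)  # genes x treated samples
    driver_names = [counts.index[g] for g in drivers]

    pheno = design.loc[design["condition"] != "T0",
                       ["condition", "replicate", "sample"]].copy()
    X_driver = lfc.iloc[drivers].to_numpy().T  # samples x drivers
    beta = {}
    for metric in PHENOTYPE_METRICS:
        # magnitudes bounded away from zero: every driver genuinely drives
        b = rng.uniform(0.5, 1.5, size=n_drivers) * np.sign(net[drivers])
        b[b == 0] = 1.0
        s = X_driver @ b
        sd = s.std(ddof=0)
        s_std = (s - s.mean()) / sd if sd > 0 else s * 0.0
        eps = rng.normal(0.0, noise_sd, size=len(s)) if noise_sd > 0 else 0.0
        pheno[metric] = _PHENOTYPE_OFFSET + snr * s_std + eps
        beta[metric] = {driver_names[i]: float(b[i]) for i in range(n_drivers)}

    gt.driver_genes = driver_names
    gt.driver_beta = beta
    gt.noise_sd = {m: noise_sd for m in PHENOTYPE_METRICS}
    gt.snr = snr
    out = {
        "counts": counts, "design": design, "lfc": lfc,
        "phenotypes": pheno.drop(columns="sample"), "ground_truth": gt,
        "count_params": count_params,
    }
    if track_params is not None:
        tracks, tgt = simulate_tracks(track_params)
        gt.true_diffusion = tgt.true_diffusion
        gt.true_division_rate = tgt.true_division_rate
        out["tracks"] = tracks
    return out


def simulate_external_lines(count_params: CountSimParams, gt: GroundTruth,
                            metric: str = "count_fc", n_lines: int = 30,
                            noise_sd: float = 0.5, snr: float = 3.0,
                            seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Expression profiles for held-out 'cell lines' with known phenotype.

    Each line activates the three ligand-effect programs with random weights
    in [0, 1.5]; counts are drawn from the same NB model and returned as a
    log2-CPM matrix (genes x lines).  True phenotype uses the ground-truth
    driver coefficients on the within-set centered expression, plus noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 59]))
    eff = count_params.single_ligand_effects
    base = np.asarray(count_params.baseline_log2_mean, dtype=float)
    disp = np.broadcast_to(np.asarray(count_params.dispersion, dtype=float),
                           (count_params.n_genes,))
    genes = [f"g{i:05d}" for i in range(count_params.n_genes)]
    cols = {}
    for i in range(n_lines):
        w = rng.uniform(0.0, 1.5, size=len(LIGANDS))
        log2mu = base + eff @ w
        if count_params.replicate_log2_sd > 0:
            log2mu = log2mu + rng.normal(0.0, count_params.replicate_log2_sd,
                                         size=count_params.n_genes)
        mu = count_params.library_size * np.power(2.0, log2mu)
        phi = np.where(disp > 0, disp, 1e-12)
        cols[f"line{i:02d}"] = rng.negative_binomial(
            1.0 / phi, 1.0 / (1.0 + phi * mu))
    expr = _log2_cpm(pd.DataFrame(cols, index=pd.Index(genes, name="gene")))
    beta = pd.Series(gt.driver_beta[metric])
    centered = expr.loc[beta.index].sub(expr.loc[beta.index].mean(axis=1),
                                        axis=0)
    s = centered.T @ beta
    sd = s.std(ddof=0)
    s_std = (s - s.mean()) / sd if sd > 0 else s * 0.0
    eps = rng.normal(0.0, noise_sd, size=n_lines) if noise_sd > 0 else 0.0
    truth = _PHENOTYPE_OFFSET + snr * s_std + eps
    truth.name = metric
    return expr, truth
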