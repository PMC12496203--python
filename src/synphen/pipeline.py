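"""Configuration handling and the one-command analysis pipeline.

Stages run in dependency order: simulate -> phenotypes -> emergence -> de ->
synergy -> plsr -> validate.  Every output table is tab-delimited with a
leading comment line carrying the hash of the normalized configuration that
produced it, so a results directory is self-describing and a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import emergence as em_mod
from . import plsr as plsr_mod
from . import simulate as sim_mod
from . import synergy as syn_mod
from . import tracks as tr_mod
from . import validate as val_mod

log = logging.getLogger("synphen")

STAGES = ("simulate", "phenotypes", "emergence", "de", "synergy", "plsr",
          "validate")

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "synphen_results",
    "stages": {s: True for s in STAGES},
    "simulate": {
        "n_genes": 2500,
        "n_cells_init": 150,
        "n_frames": 49,
        "frame_interval": 0.5,
        "n_replicates": 3,
        "dispersion": 0.05,
        "synergy_genes_per_combo": 40,
        "synergy_extra_log2": 2.0,
        "n_drivers": 50,
        "snr": 3.0,
        "noise_sd": 1.0,
        "driver_boost": 2.0,
        "replicate_log2_sd": 0.2,
    },
    "phenotypes": {"t_eval": 24.0, "max_jump": 200.0, "neighbor_k": 1,
                   "lag_min": 0.5, "lag_max": 6.0},
    "emergence": {"alpha": 0.05},
    "de": {"lfc_thresh": 1.5, "q_thresh": 0.05, "top_n": 200,
           "p_thresh": 0.05, "k_max": 12, "gap_B": 50},
    "synergy": {"lfc_thresh": 1.5, "alpha": 0.05, "additive_filter": 0.5},
    "plsr": {"n_variable_genes": 2500, "a_max": 6, "n_signature": 100},
    "validate": {"n_external_lines": 30, "external_noise_sd": 0.5,
                 "effect_thresh": -0.5},
}

_NUMERIC_MIN = {  # key -> lower bound (inclusive) for rate-like parameters
    "n_genes": 1, "n_cells_init": 1, "n_frames": 2, "n_replicates": 2,
    "dispersion": 0.0, "snr": 0.0, "noise_sd": 0.0, "alpha": 0.0,
    "gap_B": 2, "a_max": 1, "n_signature": 1, "n_external_lines": 3,
    "frame_interval": 1e-9, "max_jump": 0.0, "external_noise_sd": 0.0,
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, override: dict, path: str = "",
           problems: list | None = None) -> dict:
    out = copy.deepcopy(defaults)
    for key, val in override.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            problems.append(f"unknown key: {where}")
            continue
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                problems.append(f"{where}: expected a mapping")
                continue
            out[key] = _merge(defaults[key], val, where, problems)
        else:
            base = defaults[key]
            if isinstance(base, bool):
                if not isinstance(val, bool):
                    problems.append(f"{where}: expected true/false")
                    continue
            elif isinstance(base, (int, float)):
                if isinstance(val, bool) or not isinstance(val, (int, float)):
                    problems.append(f"{where}: expected a number, got {val!r}")
                    continue
                lo = _NUMERIC_MIN.get(key)
                if lo is not None and val < lo:
                    problems.append(f"{where}: must be >= {lo}, got {val}")
                    continue
            out[key] = val
    return out


def validate_config(source: str | Path | dict | None = None,
                    **overrides) -> dict:
    """Normalize a config file/dict against the defaults.

    Unknown keys, wrong types, and out-of-range rates are all collected and
    reported in one error.  An empty file yields the full default config.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = copy.deepcopy(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    raw.update(overrides)
    problems: list[str] = []
    cfg = _merge(DEFAULTS, raw, problems=problems)
    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))
    return cfg


def config_hash(cfg: dict) -> str:
    """Hash of the scientific configuration (output location excluded)."""
    payload = {k: v for k, v in cfg.items() if k != "outdir"}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# table I/O (every table carries the producing config hash)
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: Path, chash: str,
                index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# synphen config_hash={chash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def read_table(path: Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _track_params(cfg: dict) -> sim_mod.TrackSimParams:
    s = cfg["simulate"]
    return sim_mod.TrackSimParams(
        conditions=sim_mod.default_track_panel(),
        n_cells_init=s["n_cells_init"], n_frames=s["n_frames"],
        frame_interval=s["frame_interval"], n_replicates=s["n_replicates"],
        seed=cfg["seed"],
    )


def _count_params(cfg: dict) -> sim_mod.CountSimParams:
    s = cfg["simulate"]
    params = sim_mod.default_count_params(
        n_genes=s["n_genes"], seed=cfg["seed"], dispersion=s["dispersion"],
        n_replicates=s["n_replicates"])
    params.replicate_log2_sd = s["replicate_log2_sd"]
    rng = np.random.default_rng(np.random.SeedSequence([cfg["seed"], 71]))
    for combo in ("EGF+OSM", "EGF+TGFB", "OSM+TGFB"):
        sim_mod.inject_synergy(params, combo, s["synergy_genes_per_combo"],
                               s["synergy_extra_log2"], rng)
    return params


def _stage_simulate(cfg: dict, out: Path, chash: str) -> None:
    s = cfg["simulate"]
    bundle = sim_mod.simulate_linked_experiment(
        count_params=_count_params(cfg), track_params=_track_params(cfg),
        n_drivers=s["n_drivers"], snr=s["snr"], noise_sd=s["noise_sd"],
        driver_boost=s["driver_boost"], seed=cfg["seed"])
    tracks = bundle["tracks"].rename(columns={
        "x": "x_px", "y": "y_px", "area": "area_px2"})
    cols = ["cell_id", "frame", "x_px", "y_px", "area_px2", "field",
            "condition", "replicate"]
    tracks[cols].to_csv(out / "tracks.csv", index=False,
                        float_format="%.6g")
    write_table(bundle["counts"], out / "counts.tsv", chash, index=True)
    write_table(bundle["design"], out / "design.tsv", chash)
    write_table(bundle["lfc"], out / "replicate_lfc.tsv", chash, index=True)
    write_table(bundle["phenotypes"], out / "phenotypes_linked.tsv", chash)
    bundle["ground_truth"].to_json(out / "ground_truth.json")


def _load_tracks(out: Path) -> pd.DataFrame:
    df = pd.read_csv(out / "tracks.csv")
    df = df.rename(columns={"x_px": "x", "y_px": "y", "area_px2": "area"})
    df["t"] = df["frame"] * df["frame"].map(lambda _: 0.5)
    return df


def _stage_phenotypes(cfg: dict, out: Path, chash: str) -> None:
    p = cfg["phenotypes"]
    tracks = pd.read_csv(out / "tracks.csv").rename(
        columns={"x_px": "x", "y_px": "y", "area_px2": "area"})
    tracks["t"] = tracks["frame"] * cfg["simulate"]["frame_interval"]
    filtered = tr_mod.filter_tracks(tracks, max_jump=p["max_jump"])
    pheno = tr_mod.summarize_phenotypes(
        filtered, t_eval=p["t_eval"], neighbor_k=p["neighbor_k"],
        lag_min=p["lag_min"], lag_max=p["lag_max"])
    pheno = tr_mod.response_magnitude(pheno, reference="PBS")
    write_table(pheno, out / "phenotypes_tracks.tsv", chash)


def _stage_emergence(cfg: dict, out: Path, chash: str) -> None:
    alpha = cfg["emergence"]["alpha"]
    pheno = read_table(out / "phenotypes_tracks.tsv")
    rows = []
    for combo, parts in sim_mod.CONDITION_LIGANDS.items():
        if len(parts) < 2:
            continue
        for metric in tr_mod.PHENOTYPE_METRICS:
            groups = {c: pheno.loc[pheno["condition"] == c, metric].to_numpy()
                      for c in (combo, *parts)}
            call = em_mod.classify_emergent(groups, combo, list(parts),
                                            alpha=alpha, metric=metric)
            row = {"combination": combo, "metric": metric,
                   "emergent": call.emergent, "direction": call.direction,
                   "hsa_expected": call.hsa_expected}
            for s, pv in call.p_vs_each_single.items():
                row[f"p_vs_{s}"] = pv
            rows.append(row)
    write_table(pd.DataFrame(rows), out / "emergence.tsv", chash)


def _read_counts_design(out: Path):
    counts = read_table(out / "counts.tsv", index_col=0)
    design = read_table(out / "design.tsv")
    return counts, design


def _stage_de(cfg: dict, out: Path, chash: str) -> None:
    d = cfg["de"]
    counts, design = _read_counts_design(out)
    conditions = [c for c in design["condition"].unique() if c != "T0"]
    de_t0, de_pbs = {}, {}
    for cond in conditions:
        de_t0[cond] = de_mod.differential_expression(counts, design, cond, "T0")
        if cond != "PBS":
            de_pbs[cond] = de_mod.differential_expression(counts, design,
                                                          cond, "PBS")
    for cond, tbl in de_t0.items():
        write_table(tbl, out / "de_vs_t0" / f"{cond}.tsv", chash)
    for cond, tbl in de_pbs.items():
        write_table(tbl, out / "de_vs_pbs" / f"{cond}.tsv", chash)

    degs = pd.Series({c: de_mod.count_degs(t, d["lfc_thresh"], d["q_thresh"])
                      for c, t in de_pbs.items()}, name="n_deg")
    pheno = read_table(out / "phenotypes_linked.tsv")
    pheno = tr_mod.response_magnitude(pheno, reference="PBS")
    mags = pheno.groupby("condition")["magnitude"].mean()
    corr = de_mod.deg_phenotype_correlation(degs, mags)
    write_table(degs.rename_axis("condition").reset_index(),
                out / "deg_counts.tsv", chash)
    (out / "deg_phenotype_corr.json").write_text(json.dumps(corr, indent=1))

    top = de_mod.select_top_genes(de_t0, n_up=d["top_n"], n_down=d["top_n"],
                                  p_thresh=d["p_thresh"],
                                  lfc_thresh=d["lfc_thresh"])
    write_table(top, out / "top_genes.tsv", chash)
    lfc_mat = pd.DataFrame({c: de_t0[c].set_index("gene")["lfc"]
                            for c in conditions}).loc[top["gene"]]
    k_max = min(d["k_max"], max(2, len(lfc_mat) - 1))
    modules = de_mod.cluster_gene_modules(
        lfc_mat, k_range=range(1, k_max + 1), B=d["gap_B"], seed=cfg["seed"])
    write_table(modules.assignments.rename_axis("gene").reset_index(),
                out / "modules.tsv", chash)
    write_table(modules.module_scores, out / "module_scores.tsv", chash,
                index=True)
    write_table(modules.gap_curve, out / "gap_curve.tsv", chash)
    corrmat = de_mod.pairwise_lfc_correlation(lfc_mat)
    write_table(corrmat, out / "lfc_condition_correlation.tsv", chash,
                index=True)


def _stage_synergy(cfg: dict, out: Path, chash: str) -> None:
    s = cfg["synergy"]
    counts, design = _read_counts_design(out)
    if not (out / "de_vs_t0").exists():
        raise FileNotFoundError(
            "synergy stage needs DE outputs; run the 'de' stage first")
    calls, additivity = {}, {}
    for combo, parts in sim_mod.CONDITION_LIGANDS.items():
        if len(parts) < 2:
            continue
        singles_t0 = [read_table(out / "de_vs_t0" / f"{p}.tsv")
                      for p in parts]
        combo_t0 = read_table(out / "de_vs_t0" / f"{combo}.tsv")
        fit = syn_mod.additive_prediction(singles_t0, combo_t0,
                                          lfc_filter=s["additive_filter"])
        additivity[combo] = {"R2": fit.r2, "p": fit.p, "n_genes": fit.n_genes}
        vs_singles = [de_mod.differential_expression(counts, design, combo, p)
                      for p in parts]
        call = syn_mod.call_synergistic_genes(vs_singles,
                                              lfc_thresh=s["lfc_thresh"],
                                              alpha=s["alpha"])
        calls[combo] = call
        write_table(call, out / "synergy" / f"{combo}.tsv", chash)
    overlap = {w: syn_mod.synergy_overlap(calls, which=w)
               for w in ("positive", "negative")}
    (out / "synergy_overlap.json").write_text(json.dumps(overlap, indent=1))
    (out / "additivity.json").write_text(json.dumps(additivity, indent=1))


def _stage_plsr(cfg: dict, out: Path, chash: str) -> None:
    p = cfg["plsr"]
    lfc = read_table(out / "replicate_lfc.tsv", index_col=0)
    pheno = read_table(out / "phenotypes_linked.tsv")
    X_all = lfc.T  # samples x genes
    sample_key = pheno["condition"] + "_r" + pheno["replicate"].astype(str)
    X_all = X_all.loc[list(sample_key)]
    genes = plsr_mod.select_variable_genes(X_all, n=p["n_variable_genes"])
    X = X_all[genes]
    summary = {}
    for metric in tr_mod.PHENOTYPE_METRICS:
        y = pheno[metric].to_numpy()
        curve = plsr_mod.loo_rrmsep_select(X, y, a_max=p["a_max"])
        model = plsr_mod.fit_pls1(X, y, n_components=curve.chosen)
        vipv = plsr_mod.vip_scores(model, X)
        sig = plsr_mod.extract_signature(vipv, phenotype=metric,
                                        n_each=p["n_signature"])
        vip_tbl = pd.DataFrame({"gene": model.genes,
                                "vip": vipv.vip.to_numpy(),
                                "sign": vipv.sign.to_numpy()})
        write_table(vip_tbl, out / "plsr" / f"vip_{metric}.tsv", chash)
        sig_tbl = pd.DataFrame(
            {"gene": sig.positive + sig.negative,
             "side": ["positive"] * len(sig.positive)
                     + ["negative"] * len(sig.negative)})
        write_table(sig_tbl, out / "plsr" / f"signature_{metric}.tsv", chash)
        write_table(pd.DataFrame({
            "n_components": curve.n_components, "rmsep": curve.rmsep,
            "rrmsep": curve.rrmsep}), out / "plsr" / f"rrmsep_{metric}.tsv",
            chash)
        summary[metric] = {
            "chosen_components": int(curve.chosen),
            "rrmsep": float(curve.rrmsep[curve.chosen - 1]),
            "n_genes": len(genes),
        }
    (out / "plsr" / "summary.json").write_text(json.dumps(summary, indent=1))


def _stage_validate(cfg: dict, out: Path, chash: str) -> None:
    v = cfg["validate"]
    gt = sim_mod.GroundTruth.from_json(out / "ground_truth.json")
    counts, design = _read_counts_design(out)
    lfc = read_table(out / "replicate_lfc.tsv", index_col=0)
    pheno = read_table(out / "phenotypes_linked.tsv")
    vip_tbl = read_table(out / "plsr" / "vip_count_fc.tsv")
    sig_tbl = read_table(out / "plsr" / "signature_count_fc.tsv")

    # synthetic essentiality: driver genes with positive count_fc coefficients
    # are made viability-limiting, everything else neutral
    rng = np.random.default_rng(np.random.SeedSequence([cfg["seed"], 83]))
    beta = gt.driver_beta["count_fc"]
    effect = pd.Series(rng.normal(0.0, 0.15, size=len(vip_tbl)),
                       index=vip_tbl["gene"])
    pos_drivers = [g for g, b in beta.items() if b > 0 and g in effect.index]
    effect.loc[pos_drivers] = rng.normal(-0.9, 0.2, size=len(pos_drivers))
    enrich = val_mod.essentiality_enrichment(
        set(sig_tbl.loc[sig_tbl["side"] == "positive", "gene"]),
        set(vip_tbl["gene"]), effect, effect_thresh=v["effect_thresh"])

    # held-out expression profiles with known phenotype; rebuild the exact
    # generator state of the simulate stage (same seed path incl. boost)
    params = _count_params(cfg)
    rng2 = np.random.default_rng(np.random.SeedSequence([cfg["seed"], 41]))
    eff = params.single_ligand_effects
    eligible = np.flatnonzero(np.abs(eff).max(axis=1) >= 0.5)
    drv = np.sort(rng2.choice(eligible, size=cfg["simulate"]["n_drivers"],
                              replace=False))
    eff[drv] *= cfg["simulate"]["driver_boost"]
    expr, truth = sim_mod.simulate_external_lines(
        params, gt, metric="count_fc", n_lines=v["n_external_lines"],
        noise_sd=v["external_noise_sd"], snr=cfg["simulate"]["snr"],
        seed=cfg["seed"])
    X = lfc.T
    sample_key = pheno["condition"] + "_r" + pheno["replicate"].astype(str)
    X = X.loc[list(sample_key)][list(vip_tbl["gene"])]
    curve = plsr_mod.loo_rrmsep_select(X, pheno["count_fc"].to_numpy(),
                                       a_max=cfg["plsr"]["a_max"])
    model = plsr_mod.fit_pls1(X, pheno["count_fc"].to_numpy(),
                              n_components=curve.chosen)
    pred = plsr_mod.predict_phenotype(model, expr)
    corr = val_mod.external_prediction_correlation(pred, truth)
    report = {
        "essentiality": {
            "chi2": enrich.chi2, "p": enrich.p,
            "table": enrich.table.tolist(),
            "n_dropped": enrich.n_dropped,
        },
        "external_prediction": corr,
        "signature_recall": _signature_recall(sig_tbl, gt),
    }
    (out / "validation.json").write_text(json.dumps(report, indent=1))


def _signature_recall(sig_tbl: pd.DataFrame, gt: sim_mod.GroundTruth) -> float:
    sig = set(sig_tbl["gene"])
    drivers = set(gt.driver_genes)
    return len(sig & drivers) / len(drivers) if drivers else float("nan")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "phenotypes": _stage_phenotypes,
    "emergence": _stage_emergence,
    "de": _stage_de,
    "synergy": _stage_synergy,
    "plsr": _stage_plsr,
    "validate": _stage_validate,
}

_STAGE_SENTINEL = {  # output proving a stage already ran (for --resume)
    "simulate": "counts.tsv",
    "phenotypes": "phenotypes_tracks.tsv",
    "emergence": "emergence.tsv",
    "de": "modules.tsv",
    "synergy": "synergy_overlap.json",
    "plsr": "plsr/summary.json",
    "validate": "validation.json",
}

_STAGE_NEEDS = {
    "phenotypes": ["simulate"],
    "emergence": ["phenotypes"],
    "de": ["simulate"],
    "synergy": ["simulate", "de"],
    "plsr": ["simulate"],
    "validate": ["simulate", "plsr"],
}


def run_pipeline(cfg: dict, resume: bool = False) -> dict:
    """Execute the enabled stages in order; returns run metadata."""
    cfg = validate_config(cfg)
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    (out / "config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True))
    ran, skipped = [], []
    for stage in STAGES:
        if not cfg["stages"][stage]:
            continue
        for dep in _STAGE_NEEDS.get(stage, []):
            if not (out / _STAGE_SENTINEL[dep]).exists():
                raise FileNotFoundError(
                    f"stage {stage!r} needs output of stage {dep!r} "
                    f"({_STAGE_SENTINEL[dep]}); enable it or point outdir at "
                    "a directory containing it")
        if resume and (out / _STAGE_SENTINEL[stage]).exists():
            log.info("stage %s: outputs present, skipping (resume)", stage)
            skipped.append(stage)
            continue
        log.info("stage %s: running", stage)
        _STAGE_FUNCS[stage](cfg, out, chash)
        ran.append(stage)
    meta = {"config_hash": chash, "stages_run": ran,
            "stages_skipped": skipped, "seed": cfg["seed"]}
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=1))
    return meta
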