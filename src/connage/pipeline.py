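"""Stage orchestration: simulate -> qc -> connect -> stats -> predict/classify.

Each stage reads only the on-disk products of earlier stages, writes TSV/JSON
outputs plus a manifest (parameter echo, input/output hashes, seed), and is
deterministic under a fixed config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import io as cio
from .classification import svm_loocv_classify
from .connectivity import rsfc_map, seed_from_labels
from .errors import ConnageError, EmptyFeatureError, InvalidConfigError, StageError
from .group_stats import (
    DIR_DECREASE,
    DIR_INCREASE,
    define_features,
    extract_feature_table,
    one_sample_t,
    residualize_covariates,
    two_sample_t,
    union_mask,
)
from .prediction import mvpa_nested_loocv, mvpa_per_fold_features, uvpa_loocv
from .qc import apply_exclusion, bandpass, qc_report_frame, regress_nuisance
from .synthetic import SimulationConfig, simulate_cohort, write_cohort_dir
from .types import OLDER, YOUNGER

logger = logging.getLogger(__name__)

DEFAULT_SEEDS = ["M1.L", "M1.R", "S1.L", "S1.R"]
ALL_STAGES = ["simulate", "qc", "connect", "stats", "predict", "classify", "report"]


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidConfigError("config file must contain a mapping")
    return cfg


def _section(config: dict, name: str) -> dict:
    sec = config.get(name, {}) or {}
    if not isinstance(sec, dict):
        raise InvalidConfigError(f"config section {name!r} must be a mapping")
    return dict(sec)


def stage_simulate(config: dict, out: Path) -> None:
    params = _section(config, "simulate")
    params.setdefault("rng_seed", int(config.get("seed", 0)))
    sim_cfg = SimulationConfig(**params)
    records, series, motions, truth = simulate_cohort(sim_cfg)
    write_cohort_dir(out, records, series, motions, truth, sim_cfg)
    outputs = [out / "cohort.tsv", out / "ground_truth.json"]
    cio.write_manifest(out / "manifest_simulate.json", "simulate", params,
                       [], outputs, seed=sim_cfg.rng_seed)


def stage_qc(config: dict, out: Path) -> None:
    params = _section(config, "qc")
    records = cio.read_cohort_table(out / "cohort.tsv")
    units = params.get("motion_units", "deg")
    traces = {}
    for rec in records:
        path = out / "motion" / f"{rec.subject_id}.tsv"
        if path.is_file():
            traces[rec.subject_id] = cio.read_motion(path, units=units)
    kept, results = apply_exclusion(
        records, traces,
        threshold_trans=float(params.get("threshold_trans", 1.0)),
        threshold_rot=float(params.get("threshold_rot", 1.0)),
    )
    qc_report_frame(results).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    cio.write_cohort_table(out / "cohort_kept.tsv", kept)
    cio.write_manifest(out / "manifest_qc.json", "qc", params,
                       [out / "cohort.tsv"],
                       [out / "qc_report.tsv", out / "cohort_kept.tsv"])


def stage_connect(config: dict, out: Path) -> None:
    params = _section(config, "connect")
    gsr = bool(config.get("gsr", True))
    low = float(params.get("low", 0.01))
    high = float(params.get("high", 0.08))
    seed_labels = list(params.get("seeds", DEFAULT_SEEDS))
    records = cio.read_cohort_table(out / "cohort_kept.tsv")
    conn_dir = out / "conn"
    conn_dir.mkdir(exist_ok=True)
    outputs = []
    for rec in records:
        ts = cio.read_timeseries(out / "timeseries" / f"{rec.subject_id}.tsv")
        motion = cio.read_motion(out / "motion" / f"{rec.subject_id}.tsv")
        ts = bandpass(ts, low=low, high=high)
        ts = regress_nuisance(ts, motion.values, include_global=gsr)
        for lab in seed_labels:
            seed = seed_from_labels(lab, ts.node_labels)
            cmap = rsfc_map(ts, seed, subject_id=rec.subject_id)
            path = conn_dir / f"{rec.subject_id}__{lab}.tsv"
            cmap.frame().to_csv(path, sep="\t", index=False)
            outputs.append(path)
    cio.write_manifest(out / "manifest_connect.json", "connect",
                       {**params, "gsr": gsr}, [out / "cohort_kept.tsv"],
                       outputs[:4])


def _load_zmaps(out: Path, records, seed_labels):
    """z-matrices per seed (subjects x nodes) plus the node label list."""
    zmaps = {}
    node_labels = None
    for lab in seed_labels:
        rows = []
        for rec in records:
            df = pd.read_csv(out / "conn" / f"{rec.subject_id}__{lab}.tsv",
                             sep="\t")
            if node_labels is None:
                node_labels = [str(n) for n in df["node_label"]]
            rows.append(df["z"].to_numpy(float))
        zmaps[lab] = np.vstack(rows)
    return zmaps, node_labels


def _covariate_matrix(records) -> np.ndarray:
    return np.column_stack([
        [r.gmv for r in records],
        [r.education_years for r in records],
        [1.0 if r.gender == "F" else 0.0 for r in records],
    ])


def stage_stats(config: dict, out: Path) -> None:
    params = _section(config, "stats")
    q = float(params.get("q", 0.05))
    k = int(params.get("cluster_k", 23))
    equal_var = bool(params.get("equal_var", True))
    seed_labels = list(_section(config, "connect").get("seeds", DEFAULT_SEEDS))
    records = cio.read_cohort_table(out / "cohort_kept.tsv")
    older = [r for r in records if r.group == OLDER]
    younger = [r for r in records if r.group == YOUNGER]
    zmaps, node_labels = _load_zmaps(out, records, seed_labels)
    is_older = np.array([r.group == OLDER for r in records])
    feature_defs = []
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    for lab in seed_labels:
        z = zmaps[lab]
        zo = residualize_covariates(z[is_older], _covariate_matrix(older))
        zy = residualize_covariates(z[~is_older], _covariate_matrix(younger))
        res_o = one_sample_t(zo, q=q, k=k)
        res_y = one_sample_t(zy, q=q, k=k)
        mask = union_mask(res_o, res_y)
        diff = two_sample_t(zo, zy, mask=mask, q=q, k=k, equal_var=equal_var)
        diff.frame(node_labels).to_csv(stats_dir / f"diff__{lab}.tsv",
                                       sep="\t", index=False)
        feature_defs.extend(define_features(diff, lab, node_labels))
    if not feature_defs:
        raise EmptyFeatureError("no altered connections survived thresholding")
    conn_maps = {}
    for rec in records:
        conn_maps[rec.subject_id] = {}
        for lab in seed_labels:
            df = pd.read_csv(out / "conn" / f"{rec.subject_id}__{lab}.tsv",
                             sep="\t")
            from .connectivity import ConnectivityMap

            conn_maps[rec.subject_id][lab] = ConnectivityMap(
                subject_id=rec.subject_id, seed_label=lab,
                node_labels=[str(n) for n in df["node_label"]],
                r_values=df["r"].to_numpy(float),
                z_values=df["z"].to_numpy(float),
            )
    table = extract_feature_table(conn_maps, feature_defs,
                                  subject_ids=[r.subject_id for r in records])
    table.frame().to_csv(out / "features.tsv", sep="\t", index=False)
    defs_json = [
        {"label": f.label, "seed_label": f.seed_label,
         "target_nodes": list(map(int, f.target_nodes)),
         "direction": int(f.direction)}
        for f in feature_defs
    ]
    (out / "feature_defs.json").write_text(json.dumps(defs_json, indent=1))
    cio.write_manifest(out / "manifest_stats.json", "stats", params,
                       [out / "cohort_kept.tsv"],
                       [out / "features.tsv", out / "feature_defs.json"])


def _older_feature_matrix(out: Path):
    df = pd.read_csv(out / "features.tsv", sep="\t")
    records = cio.read_cohort_table(out / "cohort_kept.tsv")
    ages = {r.subject_id: r.age for r in records if r.group == OLDER}
    sub = df[df["subject_id"].isin(ages)]
    labels = [c for c in df.columns if c != "subject_id"]
    X = sub[labels].to_numpy(float)
    y = np.array([ages[s] for s in sub["subject_id"]])
    return X, y, labels, list(sub["subject_id"])


def _per_fold_feature_builder(config: dict, out: Path, ages, older_sids):
    """Feature definitions recomputed with the held-out older subject removed
    from the group contrast (the stricter training-step reading)."""
    params = _section(config, "stats")
    q = float(params.get("q", 0.05))
    k = int(params.get("cluster_k", 23))
    seed_labels = list(_section(config, "connect").get("seeds", DEFAULT_SEEDS))
    records = cio.read_cohort_table(out / "cohort_kept.tsv")
    zmaps, node_labels = _load_zmaps(out, records, seed_labels)
    sids = [r.subject_id for r in records]
    is_older = np.array([r.group == OLDER for r in records])
    older = [r for r in records if r.group == OLDER]
    younger = [r for r in records if r.group == YOUNGER]
    older_rows = {sid: j for j, sid in enumerate(np.array(sids)[is_older])}

    def build_fold(i):
        drop = older_rows[older_sids[i]]
        keep = np.arange(len(older)) != drop
        cov_o = _covariate_matrix(older)[keep]
        values = []
        for lab in seed_labels:
            z = zmaps[lab]
            zo = residualize_covariates(z[is_older][keep], cov_o)
            zy = residualize_covariates(z[~is_older], _covariate_matrix(younger))
            mask = union_mask(one_sample_t(zo, q=q, k=k),
                              one_sample_t(zy, q=q, k=k))
            diff = two_sample_t(zo, zy, mask=mask, q=q, k=k)
            for fd in define_features(diff, lab, node_labels):
                cols = list(fd.target_nodes)
                values.append(np.nanmean(z[is_older][:, cols], axis=1))
        if not values:
            raise EmptyFeatureError("no features in training fold")
        Xall = np.column_stack(values)
        return Xall[keep], Xall[drop]

    return build_fold


def stage_predict(config: dict, out: Path) -> None:
    params = _section(config, "predict")
    mode = params.get("mode", "mvpa")
    n_perm = int(params.get("n_perm", 0))
    seed = int(params.get("seed", config.get("seed", 0)))
    X, y, labels, sids = _older_feature_matrix(out)
    if mode == "mvpa" and params.get("features_per_fold", False):
        build_fold = _per_fold_feature_builder(config, out, y, sids)
        result = mvpa_per_fold_features(
            build_fold, y, epsilon=float(params.get("epsilon", 0.001)),
            C=float(params.get("C", 1.0)),
            consensus_theta=float(params.get("consensus_theta", 0.5)),
        )
    elif mode == "mvpa":
        result = mvpa_nested_loocv(
            X, y, epsilon=float(params.get("epsilon", 0.001)),
            C=float(params.get("C", 1.0)),
            consensus_theta=float(params.get("consensus_theta", 0.5)),
            n_perm=n_perm, rng_seed=seed, feature_labels=labels,
        )
    elif mode == "uvpa":
        feature = params.get("feature")
        if feature is None:
            feature = labels[0]
        if feature not in labels:
            raise InvalidConfigError(f"unknown feature {feature!r}")
        result = uvpa_loocv(X[:, labels.index(feature)], y, n_perm=n_perm,
                            rng_seed=seed)
    else:
        raise InvalidConfigError(f"unknown prediction mode {mode!r}")
    (out / "prediction.json").write_text(
        json.dumps(result.to_jsonable(), indent=1))
    pd.DataFrame({
        "subject_id": sids,
        "observed_age": result.observed_ages,
        "predicted_age": result.predicted_ages,
    }).to_csv(out / "predictions.tsv", sep="\t", index=False)
    if params.get("plot", False):
        _scatter_plot(result, out / "prediction_scatter.png")
    cio.write_manifest(out / "manifest_predict.json", "predict", params,
                       [out / "features.tsv"],
                       [out / "prediction.json", out / "predictions.tsv"],
                       seed=seed)


def _scatter_plot(result, path):  # pragma: no cover - cosmetic
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(result.observed_ages, result.predicted_ages, s=12)
    lims = [min(result.observed_ages), max(result.observed_ages)]
    ax.plot(lims, lims, "k--", lw=0.8)
    ax.set_xlabel("chronological age (years)")
    ax.set_ylabel("predicted age (years)")
    ax.set_title(f"r={result.r_pred_obs:.3f}  MAE={result.mae:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def stage_classify(config: dict, out: Path) -> None:
    params = _section(config, "classify")
    n_perm = int(params.get("n_perm", 0))
    seed = int(params.get("seed", config.get("seed", 0)))
    df = pd.read_csv(out / "features.tsv", sep="\t")
    defs = json.loads((out / "feature_defs.json").read_text())
    records = cio.read_cohort_table(out / "cohort_kept.tsv")
    groups = {r.subject_id: r.group for r in records}
    labels = np.array([groups[s] for s in df["subject_id"]])
    metrics = {}
    for name, direction in (("increased", DIR_INCREASE),
                            ("decreased", DIR_DECREASE)):
        cols = [d["label"] for d in defs if d["direction"] == direction]
        if not cols:
            metrics[name] = None
            continue
        X = df[cols].to_numpy(float)
        if params.get("score_mode", "vector") == "mean":
            X = X.mean(axis=1, keepdims=True)
        res = svm_loocv_classify(X, labels, C=float(params.get("C", 1.0)),
                                 n_perm=n_perm, rng_seed=seed)
        metrics[name] = res.to_jsonable()
        pd.DataFrame(res.roc_points, columns=["fpr", "tpr"]).to_csv(
            out / f"roc_{name}.tsv", sep="\t", index=False)
    (out / "classification.json").write_text(json.dumps(metrics, indent=1))
    cio.write_manifest(out / "manifest_classify.json", "classify", params,
                       [out / "features.tsv"], [out / "classification.json"],
                       seed=seed)


def demographics_report(records, qc_results=None) -> dict:
    """Group summaries plus two-sample tests (and chi-square for gender)."""
    groups = {OLDER: [r for r in records if r.group == OLDER],
              YOUNGER: [r for r in records if r.group == YOUNGER]}
    if min(len(v) for v in groups.values()) < 3:
        raise InvalidConfigError("need at least 3 subjects per group")
    report: dict = {"groups": {}}

    def summary(vals):
        return {"mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1)),
                "n": len(vals)}

    fd = {}
    if qc_results:
        fd = {sid: r for sid, r in qc_results.items()}
    for g, recs in groups.items():
        entry = {
            "n": len(recs),
            "age": summary([r.age for r in recs]),
            "education_years": summary([r.education_years for r in recs]),
            "gmv": summary([r.gmv for r in recs]),
            "n_female": sum(1 for r in recs if r.gender == "F"),
        }
        if fd:
            entry["fd_translation"] = summary(
                [fd[r.subject_id].fd_translation for r in recs
                 if r.subject_id in fd])
            entry["fd_rotation"] = summary(
                [fd[r.subject_id].fd_rotation for r in recs
                 if r.subject_id in fd])
        report["groups"][g] = entry

    def ttest(attr):
        a = [getattr(r, attr) for r in groups[OLDER]]
        b = [getattr(r, attr) for r in groups[YOUNGER]]
        res = sstats.ttest_ind(a, b)
        return {"t": float(res.statistic), "p": float(res.pvalue)}

    report["tests"] = {
        "age": ttest("age"),
        "education_years": ttest("education_years"),
        "gmv": ttest("gmv"),
    }
    if fd:
        for key in ("fd_translation", "fd_rotation"):
            a = [getattr(fd[r.subject_id], key) for r in groups[OLDER]
                 if r.subject_id in fd]
            b = [getattr(fd[r.subject_id], key) for r in groups[YOUNGER]
                 if r.subject_id in fd]
            res = sstats.ttest_ind(a, b)
            report["tests"][key] = {"t": float(res.statistic),
                                    "p": float(res.pvalue)}
    table = np.array([
        [sum(1 for r in groups[g] if r.gender == "F"),
         sum(1 for r in groups[g] if r.gender == "M")]
        for g in (OLDER, YOUNGER)
    ])
    if np.all(table.sum(axis=0) > 0):
        chi = sstats.chi2_contingency(table)
        report["tests"]["gender"] = {"chi2": float(chi.statistic),
                                     "p": float(chi.pvalue)}
    return report


def stage_report(config: dict, out: Path) -> None:
    records = cio.read_cohort_table(out / "cohort_kept.tsv")
    qc_df = pd.read_csv(out / "qc_report.tsv", sep="\t")
    from .qc import QCResult

    qc_results = {
        str(row.subject_id): QCResult(
            str(row.subject_id), float(row.fd_translation),
            float(row.fd_rotation), float(row.max_abs_translation),
            float(row.max_abs_rotation), bool(row.excluded),
            "" if pd.isna(row.reason) else str(row.reason),
        )
        for row in qc_df.itertuples(index=False)
    }
    report = demographics_report(records, qc_results)
    (out / "report.json").write_text(json.dumps(report, indent=1))
    cio.write_manifest(out / "manifest_report.json", "report", {},
                       [out / "cohort_kept.tsv"], [out / "report.json"])


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "connect": stage_connect,
    "stats": stage_stats,
    "predict": stage_predict,
    "classify": stage_classify,
    "report": stage_report,
}


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the enabled stages in order; returns a small run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", ALL_STAGES)
    unknown = [s for s in stages if s not in STAGE_FUNCS]
    if unknown:
        raise InvalidConfigError(f"unknown stages: {unknown}")
    report = {"out_dir": str(out), "stages_run": []}
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        logger.info("running stage %s", stage)
        try:
            STAGE_FUNCS[stage](config, out)
        except InvalidConfigError:
            raise
        except ConnageError as exc:
            raise StageError(stage, str(exc)) from exc
        report["stages_run"].append(stage)
    (out / "run_report.json").write_text(json.dumps(report, indent=1))
    return report
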