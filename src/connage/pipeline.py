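"""End-to-end pipeline orchestration and matrix I/O.

Runs connectivity construction, graph metrics, the brain-age model and the
downstream inference on a cohort directory, writing every artifact plus a
run manifest so that a rerun with the same configuration reproduces all
numeric outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .brain_age import (
    assemble_feature_matrix,
    assemble_features,
    fit_predict_cv,
    select_features_cv,
)
from .connectivity import (
    SLParams,
    WindowSpec,
    dynamic_fc,
    scale_sc,
    sl_matrix,
    static_fc,
    temporal_variability,
)
from .graph_metrics import binarize_sparsity, compute_nodal_metrics
from .stats import (
    bh_fdr,
    cca_first_pair,
    independent_t_test,
    kmeans_classification_accuracy,
    partial_correlation,
    stratify_moca,
)
from .synthetic import BEHAVIOR_SCALES, SubjectRecord, read_cohort

logger = logging.getLogger("connage")

__all__ = ["PipelineConfig", "run_pipeline", "read_matrix", "write_matrix"]

#: Variable-set pairings analysed by CCA against the neurocognitive
#: age-related set (brain-age gap + resilience).
CCA_PAIRINGS = {
    "cognitive": ["MOCA", "AD8"],
    "performance": ["IADL", "PSQI", "LSNS"],
    "emotional": ["GDS", "UCLA_LS", "PSS"],
}

KMEANS_FEATURE_SETS = {
    "scores_and_gap": "all behavioural scores (excluding MOCA) plus gap",
    "gap_and_resilience": "gap + resilience",
    "gap_only": "gap",
    "resilience_only": "resilience",
}


@dataclass
class PipelineConfig:
    """Every tunable of the analysis chain, with the reference defaults:
    50-TR windows stepped by 2, 0.1 sparsity, tenfold CV with seed 42,
    10,000 permutations, 1000 k-means iterations."""

    cohort_dir: str | Path = "cohort"
    window_length: int = 50
    window_step: int = 2
    sparsity: float = 0.1
    folds: int = 10
    seed: int = 42
    dynamic_feature: str = "tv"  # "tv" | "sl"
    sl_params: SLParams = field(default_factory=SLParams)
    permutations: int = 10000
    kmeans_iterations: int = 1000
    partial_corr_method: str = "spearman"
    output_dir: str | Path = "results"

    def __post_init__(self) -> None:
        for name in ("window_length", "window_step", "folds", "permutations", "kmeans_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.sparsity < 1:
            raise ValueError("sparsity must lie in (0, 1)")
        if self.dynamic_feature not in ("tv", "sl"):
            raise ValueError("dynamic_feature must be 'tv' or 'sl'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort_dir"] = str(self.cohort_dir)
        d["output_dir"] = str(self.output_dir)
        return d


def write_matrix(matrix: np.ndarray, path: str | Path) -> Path:
    """Write a numeric matrix as tab-delimited text at full precision."""
    path = Path(path)
    np.savetxt(path, np.atleast_2d(np.asarray(matrix, dtype=float)), delimiter="\t")
    return path


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a tab-delimited numeric rectangle; errors name the first bad
    line."""
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(rows[-1])} cells, expected {len(rows[0])})"
                )
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    return np.asarray(rows, dtype=float)


def _behavior_frame(cohort: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in cohort:
        row = {
            "subject_id": s.subject_id,
            "age": s.age,
            "gender": 1.0 if s.gender == "M" else 0.0,
            "education": s.education,
        }
        row.update({scale: s.behaviors.get(scale, float("nan")) for scale in BEHAVIOR_SCALES})
        rows.append(row)
    return pd.DataFrame(rows)


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-14s %.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full chain on a cohort directory and write all artifacts.

    Returns a results bundle with the brain-age result, partial correlation
    table, CCA results, t-tests and k-means accuracies.
    """
    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    started = time.strftime("%Y-%m-%dT%H:%M:%S")

    cohort = read_cohort(cfg.cohort_dir)
    if not cohort:
        raise ValueError(f"no subjects found in {cfg.cohort_dir}")
    t0 = _stage("load", t0)

    # ---- connectivity + graph metrics + features -----------------------
    rows, names = [], None
    metric_records: list[dict] = []
    for s in cohort:
        fc = static_fc(s.time_series)
        sc = scale_sc(s.sc_counts, s.node_volumes)
        spec = WindowSpec(
            length=cfg.window_length,
            step=cfg.window_step,
            n_timepoints=s.time_series.shape[0],
        )
        if cfg.dynamic_feature == "tv":
            dyn = temporal_variability(dynamic_fc(s.time_series, spec))
            write_matrix(dyn[:, None], out / f"tv_{s.subject_id}.tsv")
        else:
            dyn_mat = sl_matrix(s.time_series, cfg.sl_params)
            write_matrix(dyn_mat.values, out / f"sl_{s.subject_id}.tsv")
            dyn = dyn_mat.values
        write_matrix(fc.values, out / f"fc_{s.subject_id}.tsv")
        write_matrix(sc.values, out / f"sc_scaled_{s.subject_id}.tsv")

        row, names = assemble_features(s, fc, sc, dyn, dynamic=cfg.dynamic_feature)
        rows.append(row)

        for kind, mat in (("fc", fc), ("sc", sc)):
            net = binarize_sparsity(mat, cfg.sparsity)
            metrics = compute_nodal_metrics(net)
            arr = metrics.as_array()
            header = "betweenness\tdegree\tefficiency\tclustering"
            np.savetxt(
                out / f"metrics_{kind}_{s.subject_id}.tsv",
                arr,
                delimiter="\t",
                header=header,
                comments="",
            )
            for region in range(arr.shape[0]):
                metric_records.append(
                    {
                        "subject_id": s.subject_id,
                        "network": kind,
                        "region": region,
                        "betweenness": arr[region, 0],
                        "degree": arr[region, 1],
                        "efficiency": arr[region, 2],
                        "clustering": arr[region, 3],
                    }
                )
    t0 = _stage("connectivity", t0)

    X = assemble_feature_matrix(rows, names, [s.subject_id for s in cohort])
    ages = np.array([s.age for s in cohort])

    # ---- brain-age model ----------------------------------------------
    selected = select_features_cv(X, ages, k=cfg.folds, seed=cfg.seed)
    if not selected:
        selected = set(X.feature_names)
    result = fit_predict_cv(X.restrict(selected), ages, k=cfg.folds, seed=cfg.seed)
    preds = pd.DataFrame(
        {
            "subject_id": result.subject_ids,
            "age": result.chronological_age,
            "predicted_age": result.predicted_age,
            "gap": result.gap,
            "fold": result.fold_assignments,
        }
    )
    preds.to_csv(out / "predictions.csv", index=False)
    (out / "selected_features.txt").write_text(
        "\n".join(sorted(selected)) + "\n"
    )
    (out / "metrics.json").write_text(
        json.dumps(
            {"mae": result.mae, "rmse": result.rmse, "alpha": result.alpha},
            indent=2,
        )
    )
    t0 = _stage("brain_age", t0)

    # ---- downstream inference -----------------------------------------
    beh = _behavior_frame(cohort)
    gap = result.gap
    Z = beh[["age", "gender", "education"]].to_numpy()
    covs = ["age", "gender", "education"]

    pc_rows = []
    for scale in BEHAVIOR_SCALES:
        vals = beh[scale].to_numpy()
        if np.isfinite(vals).sum() <= Z.shape[1] + 2:
            continue
        res = partial_correlation(
            gap, vals, Z, method=cfg.partial_corr_method, covariate_names=covs
        )
        pc_rows.append(
            {"variable": scale, "rho": res.rho, "p": res.p_value, "n": res.n_effective}
        )
    pc = pd.DataFrame(pc_rows)
    reject, p_adj = bh_fdr(pc["p"].to_numpy())
    pc["p_adjusted"] = p_adj
    pc["significant_fdr"] = reject
    pc.to_csv(out / "partial_correlations.csv", index=False)

    # gap vs nodal metrics, one FDR family per metric type per network
    mdf = pd.DataFrame(metric_records)
    nodal_rows = []
    for kind in ("fc", "sc"):
        for metric in ("betweenness", "degree", "efficiency", "clustering"):
            fam = []
            for region, sub in mdf[mdf.network == kind].groupby("region"):
                vals = sub.sort_values("subject_id")[metric].to_numpy()
                try:
                    res = partial_correlation(
                        gap, vals, Z, method=cfg.partial_corr_method, covariate_names=covs
                    )
                except ValueError:
                    continue  # metric constant across subjects in this region
                fam.append(
                    {
                        "network": kind,
                        "metric": metric,
                        "region": int(region),
                        "rho": res.rho,
                        "p": res.p_value,
                    }
                )
            if fam:
                rej, adj = bh_fdr(np.array([f["p"] for f in fam]))
                for f, r_, a_ in zip(fam, rej, adj):
                    f["p_adjusted"] = a_
                    f["significant_fdr"] = bool(r_)
                nodal_rows.extend(fam)
    pd.DataFrame(nodal_rows).to_csv(out / "nodal_correlations.csv", index=False)
    t0 = _stage("partial_corr", t0)

    rng = np.random.default_rng(cfg.seed)
    beh = beh.assign(gap=gap)
    cca_results = {}
    for name, y_cols in CCA_PAIRINGS.items():
        Xc = beh[["gap", "Resilience"]].to_numpy()
        Yc = beh[y_cols].to_numpy()
        try:
            res = cca_first_pair(Xc, Yc, rng=rng, n_permutations=cfg.permutations)
        except ValueError as exc:
            cca_results[name] = {"error": str(exc)}
            continue
        payload = {
            "x_variables": ["gap", "Resilience"],
            "y_variables": y_cols,
            "r": res.r,
            "p_perm": res.p_perm,
            "n_permutations": res.n_permutations,
            "structure_x": res.structure_x.tolist(),
            "structure_y": res.structure_y.tolist(),
        }
        cca_results[name] = payload
        (out / f"cca_{name}.json").write_text(json.dumps(payload, indent=2))
    t0 = _stage("cca", t0)

    labels = stratify_moca(beh["MOCA"].to_numpy())
    tt_rows = []
    for scale in [s for s in BEHAVIOR_SCALES if s != "MOCA"] + ["gap"]:
        vals = beh[scale].to_numpy() if scale != "gap" else gap
        a = vals[(labels == "MOCA+") & np.isfinite(vals)]
        b = vals[(labels == "MOCA-") & np.isfinite(vals)]
        if len(a) < 2 or len(b) < 2:
            continue
        try:
            t, p = independent_t_test(b, a)  # MOCA- minus MOCA+ ordering
        except ValueError:
            continue
        tt_rows.append({"variable": scale, "t": t, "p": p, "n_minus": len(b), "n_plus": len(a)})
    pd.DataFrame(tt_rows).to_csv(out / "ttests.csv", index=False)

    feature_sets = {
        "scores_and_gap": [s for s in BEHAVIOR_SCALES if s != "MOCA"] + ["gap"],
        "gap_and_resilience": ["gap", "Resilience"],
        "gap_only": ["gap"],
        "resilience_only": ["Resilience"],
    }
    kmeans_results = {}
    for name, cols in feature_sets.items():
        F = beh[cols].to_numpy()
        ok = np.isfinite(F).all(axis=1)
        try:
            acc, accs = kmeans_classification_accuracy(
                F[ok], labels[ok], iterations=cfg.kmeans_iterations, seed=rng
            )
        except ValueError as exc:
            kmeans_results[name] = {"error": str(exc)}
            continue
        hist_vals, hist_counts = np.unique(accs, return_counts=True)
        kmeans_results[name] = {
            "features": cols,
            "accuracy": acc,
            "iterations": cfg.kmeans_iterations,
            "histogram": {f"{v:.4f}": int(c) for v, c in zip(hist_vals, hist_counts)},
        }
    (out / "kmeans.json").write_text(json.dumps(kmeans_results, indent=2))
    t0 = _stage("groups", t0)

    manifest = {
        "config": cfg.to_dict(),
        "version": __version__,
        "numpy": np.__version__,
        "started": started,
        "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_subjects": len(cohort),
        "n_regions": cohort[0].n_regions,
        "n_features": X.values.shape[1],
        "n_selected": len(selected),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "brain_age": result,
        "partial_correlations": pc,
        "nodal_correlations": pd.DataFrame(nodal_rows),
        "cca": cca_results,
        "ttests": pd.DataFrame(tt_rows),
        "kmeans": kmeans_results,
        "manifest": manifest,
        "labels": labels,
    }
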