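"""Stage functions chaining the library into the full analysis.

Each stage reads its declared inputs from ``outdir``, writes its declared
TSV/JSON artifacts there, and drops a ``<stage>.provenance.json`` record
(seed, parameters, input hashes) so a run is auditable and exactly
reproducible.  The CLI and the ``analysis/`` drivers are thin layers over
these functions.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd

from ogttmet import io_tables
from ogttmet.synthetic import CohortConfig, generate_cohort, generate_fingerprints, derive_seed
from ogttmet.preprocess import presence_filter, sum_normalize
from ogttmet.clinical import cohort_indices
from ogttmet.excursion import subject_aucs, cohort_aucs, classify_responsiveness
from ogttmet.univariate import univariate_table, fasting_values
from ogttmet.plsda import (fit_plsda, select_features, combined_model,
                           performance_distributions, ogtt_time_model)
from ogttmet.chem_network import build_network, component_summary
from ogttmet.correlations import ccp, loading_prefilter

SCHEDULE = (0, 30, 60, 90, 120)


def _hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


def _provenance(outdir: str, stage: str, seed: int | None, params: dict,
                inputs: list[str]) -> None:
    rec = {"stage": stage, "seed": seed, "params": params,
           "inputs": {os.path.basename(p): _hash(p) for p in inputs if os.path.exists(p)},
           "version": "0.1.0"}
    io_tables.write_json(rec, os.path.join(outdir, f"{stage}.provenance.json"))


def stage_simulate(outdir: str, seed: int = 0, n_fp_clusters: int = 12,
                   **config_kwargs) -> CohortConfig:
    os.makedirs(outdir, exist_ok=True)
    config = CohortConfig(seed=seed, **config_kwargs)
    cohort = generate_cohort(config)
    io_tables.write_panel(cohort.panel, os.path.join(outdir, "panel.tsv"),
                          provenance={"seed": seed})
    io_tables.write_subjects(cohort.subjects, os.path.join(outdir, "subjects.tsv"),
                             provenance={"seed": seed})
    io_tables._write_tsv(cohort.truth, os.path.join(outdir, "truth.tsv"))
    io_tables._write_tsv(cohort.metabolite_info, os.path.join(outdir, "metabolite_info.tsv"))
    fps = generate_fingerprints(list(cohort.metabolite_info["metabolite_id"]),
                                n_clusters=n_fp_clusters,
                                seed=derive_seed(seed, "fp"))
    io_tables.write_fingerprints(fps, os.path.join(outdir, "fingerprints.tsv"))
    _provenance(outdir, "simulate", seed, {"n_fp_clusters": n_fp_clusters}, [])
    return config


def stage_preprocess(outdir: str, min_frac: float = 0.5) -> pd.DataFrame:
    panel = io_tables.read_panel(os.path.join(outdir, "panel.tsv"), SCHEDULE)
    filtered, report = presence_filter(panel, min_frac=min_frac)
    normalized = sum_normalize(filtered)
    io_tables.write_panel(normalized, os.path.join(outdir, "panel_norm.tsv"))
    io_tables._write_tsv(report, os.path.join(outdir, "presence_report.tsv"))
    _provenance(outdir, "preprocess", None, {"min_frac": min_frac},
                [os.path.join(outdir, "panel.tsv")])
    return normalized


def stage_indices(outdir: str):
    subjects = io_tables.read_subjects(os.path.join(outdir, "subjects.tsv"))
    indices, summary = cohort_indices(subjects, SCHEDULE)
    io_tables._write_tsv(indices, os.path.join(outdir, "indices.tsv"))
    io_tables.write_json(summary.to_dict(orient="records"),
                         os.path.join(outdir, "indices_summary.json"))
    _provenance(outdir, "indices", None, {}, [os.path.join(outdir, "subjects.tsv")])
    return indices, summary


def stage_auc(outdir: str):
    panel = io_tables.read_panel(os.path.join(outdir, "panel_norm.tsv"), SCHEDULE)
    per_subject = subject_aucs(panel)
    excursions = cohort_aucs(panel)
    classes = classify_responsiveness(excursions)
    io_tables._write_tsv(per_subject, os.path.join(outdir, "subject_aucs.tsv"))
    io_tables._write_tsv(excursions, os.path.join(outdir, "excursions.tsv"))
    io_tables._write_tsv(classes, os.path.join(outdir, "auc_classes.tsv"))
    _provenance(outdir, "auc", None, {}, [os.path.join(outdir, "panel_norm.tsv")])
    return per_subject, excursions, classes


def stage_univariate(outdir: str):
    panel = io_tables.read_panel(os.path.join(outdir, "panel_norm.tsv"), SCHEDULE)
    fast = univariate_table(fasting_values(panel), endpoint="fasting")
    aucs = io_tables.read_panel(os.path.join(outdir, "panel_norm.tsv"), SCHEDULE)
    per_subject = subject_aucs(aucs).rename(columns={"auc": "value"})
    auc_tab = univariate_table(per_subject, endpoint="auc")
    io_tables._write_tsv(fast, os.path.join(outdir, "univariate_fasting.tsv"))
    io_tables._write_tsv(auc_tab, os.path.join(outdir, "univariate_auc.tsv"))
    _provenance(outdir, "univariate", None, {}, [os.path.join(outdir, "panel_norm.tsv")])
    return fast, auc_tab


def _fasting_matrix(panel: pd.DataFrame) -> pd.DataFrame:
    fast = panel[panel["time_min"] == 0]
    wide = fast.pivot_table(index=["subject_id", "phase"], columns="metabolite_id",
                            values="intensity", observed=True)
    return np.log(wide.where(wide > 0))


def _auc_matrix(panel: pd.DataFrame) -> pd.DataFrame:
    per_subject = subject_aucs(panel)
    return per_subject.pivot_table(index=["subject_id", "phase"],
                                   columns="metabolite_id", values="auc",
                                   observed=True)


def _phase_labels(index: pd.MultiIndex) -> np.ndarray:
    return np.asarray(index.get_level_values("phase") == "post", dtype=float)


def stage_plsda(outdir: str, seed: int = 0, n_splits: int = 100,
                max_components: int = 5):
    panel = io_tables.read_panel(os.path.join(outdir, "panel_norm.tsv"), SCHEDULE)
    indices = pd.read_csv(os.path.join(outdir, "indices.tsv"), sep="\t",
                          dtype={"subject_id": str}, comment="#")

    fast_X = _fasting_matrix(panel)
    auc_X = _auc_matrix(panel)
    results = {}
    selections = {}
    for name, X in (("fasting", fast_X), ("auc", auc_X)):
        y = _phase_labels(X.index)
        model = fit_plsda(X, y, max_components=max_components)
        sel = select_features(model)
        io_tables._write_tsv(sel, os.path.join(outdir, f"selection_{name}.tsv"))
        io_tables.write_json({
            "n_components": model.n_components,
            "q2_path": model.q2_path,
            "features": model.feature_ids,
            "weights_lv1": model.W[:, 0],
            "loadings_lv1": model.P[:, 0],
        }, os.path.join(outdir, f"plsda_{name}.json"))
        scores = X.index.to_frame(index=False)
        for a in range(model.T.shape[1]):
            scores[f"lv{a + 1}"] = model.T[:, a]
        io_tables._write_tsv(scores, os.path.join(outdir, f"scores_{name}.tsv"))
        results[name] = model
        selections[name] = sel

    # Combined model over the samples present in both endpoint matrices.
    clin = indices.set_index(["subject_id", "phase"])[
        ["fasting_insulin", "fasting_glucose", "matsuda", "quicki"]]
    common = fast_X.index.intersection(auc_X.index).intersection(clin.index)
    comb_model, comb_table = combined_model(
        fast_X.loc[common], selections["fasting"],
        auc_X.loc[common], selections["auc"],
        clin.loc[common], _phase_labels(common),
        max_components=max_components)
    io_tables._write_tsv(comb_table, os.path.join(outdir, "combined_features.tsv"))
    comb_scores = common.to_frame(index=False)
    for a in range(comb_model.T.shape[1]):
        comb_scores[f"lv{a + 1}"] = comb_model.T[:, a]
    io_tables._write_tsv(comb_scores, os.path.join(outdir, "scores_combined.tsv"))

    perm = {}
    for name, X in (("fasting", fast_X), ("auc", auc_X)):
        perm[name] = performance_distributions(
            X, _phase_labels(X.index), n_splits=n_splits,
            seed=derive_seed(seed, f"perm-{name}"))
    io_tables.write_json({k: v.to_dict() for k, v in perm.items()},
                         os.path.join(outdir, "permutation_report.json"))
    report = perm
    _provenance(outdir, "plsda", seed, {"n_splits": n_splits,
                                        "max_components": max_components},
                [os.path.join(outdir, "panel_norm.tsv")])
    return results, selections, comb_model, comb_table, report


def stage_timecourse(outdir: str, max_components: int = 2):
    panel = io_tables.read_panel(os.path.join(outdir, "panel_norm.tsv"), SCHEDULE)
    model, scores, loadings = ogtt_time_model(panel, max_components=max_components)
    io_tables._write_tsv(scores, os.path.join(outdir, "time_scores.tsv"))
    io_tables._write_tsv(loadings.rename_axis("metabolite_id").reset_index(),
                         os.path.join(outdir, "time_loadings.tsv"))
    _provenance(outdir, "timecourse", None, {"max_components": max_components},
                [os.path.join(outdir, "panel_norm.tsv")])
    return model, scores, loadings


def stage_network(outdir: str, threshold: float = 0.7):
    fps = io_tables.read_fingerprints(os.path.join(outdir, "fingerprints.tsv"))
    loadings = pd.read_csv(os.path.join(outdir, "time_loadings.tsv"), sep="\t",
                           comment="#").set_index("metabolite_id")["loading_lv1"]
    retained = set(loadings.index)
    fps = [fp for fp in fps if fp.metabolite_id in retained]
    g = build_network(fps, loadings, threshold=threshold)
    io_tables.write_network_graphml(g, os.path.join(outdir, "network.graphml"))
    io_tables._write_tsv(component_summary(g), os.path.join(outdir, "network_components.tsv"))
    _provenance(outdir, "network", None, {"threshold": threshold},
                [os.path.join(outdir, "fingerprints.tsv"),
                 os.path.join(outdir, "time_loadings.tsv")])
    return g


def stage_correlate(outdir: str):
    panel = io_tables.read_panel(os.path.join(outdir, "panel_norm.tsv"), SCHEDULE)
    indices = pd.read_csv(os.path.join(outdir, "indices.tsv"), sep="\t",
                          dtype={"subject_id": str}, comment="#")
    fast_X = _fasting_matrix(panel)
    auc_X = _auc_matrix(panel)
    out = {}
    for name, X in (("fasting", fast_X), ("auc", auc_X)):
        model = fit_plsda(X, _phase_labels(X.index), compute_q2=True)
        keep = loading_prefilter(model.loadings_lv1)
        out[name] = X.loc[:, keep].add_prefix(f"{name}:")
    clin = indices.set_index(["subject_id", "phase"])[
        ["matsuda", "quicki", "fasting_insulin", "fasting_glucose"]]
    tables = []
    for phase in ("pre", "post"):
        blocks = []
        for name in ("fasting", "auc"):
            b = out[name]
            blocks.append(b[b.index.get_level_values("phase") == phase]
                          .reset_index(level="phase", drop=True))
        cb = clin[clin.index.get_level_values("phase") == phase].reset_index(
            level="phase", drop=True)
        joined = pd.concat(blocks + [cb], axis=1, join="outer")
        tab = ccp(joined, phase=phase, with_bh=True)
        io_tables._write_tsv(tab, os.path.join(outdir, f"ccp_{phase}.tsv"))
        tables.append(tab)
    _provenance(outdir, "correlate", None, {}, [os.path.join(outdir, "panel_norm.tsv")])
    return tables


def stage_report(outdir: str) -> dict:
    """Collate the analogues of the study's five result tables."""
    summary = json.load(open(os.path.join(outdir, "indices_summary.json")))
    excursions = pd.read_csv(os.path.join(outdir, "excursions.tsv"), sep="\t", comment="#")
    classes = pd.read_csv(os.path.join(outdir, "auc_classes.tsv"), sep="\t", comment="#")
    fast = pd.read_csv(os.path.join(outdir, "univariate_fasting.tsv"), sep="\t", comment="#")
    comb = pd.read_csv(os.path.join(outdir, "combined_features.tsv"), sep="\t", comment="#")
    perm = json.load(open(os.path.join(outdir, "permutation_report.json")))
    report = {
        "clinical_indices": summary,
        "excursions": {
            "n_nonzero_any_phase": int(classes["class"].isin(
                ["both", "pre_only", "post_only"]).sum()),
            "class_counts": classes["class"].value_counts().to_dict(),
            "n_tested": int(excursions["metabolite_id"].nunique()),
        },
        "fasting_univariate": {
            "n_raw_p05": int(fast["significant_raw"].sum()),
            "n_fdr_q05": int(fast["significant_fdr"].sum()),
        },
        "combined_model": {
            "category_counts": comb.groupby("category")["in_final"].sum().astype(int).to_dict(),
            "n_added_back": int(comb["added_back"].sum()),
            "n_final": int(comb["in_final"].sum()),
        },
        "permutation_p": {name: rec["p"] for name, rec in perm.items()},
    }
    io_tables.write_json(report, os.path.join(outdir, "report.json"))
    return report


STAGES = ["simulate", "preprocess", "indices", "auc", "univariate",
          "plsda", "timecourse", "network", "correlate", "report"]


def run_all(outdir: str, seed: int = 0, n_splits: int = 100) -> dict:
    stage_simulate(outdir, seed=seed)
    stage_preprocess(outdir)
    stage_indices(outdir)
    stage_auc(outdir)
    stage_univariate(outdir)
    stage_plsda(outdir, seed=seed, n_splits=n_splits)
    stage_timecourse(outdir)
    stage_network(outdir)
    stage_correlate(outdir)
    return stage_report(outdir)
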