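"""Cross-validation harness, classification metrics and the marker graph.

Patients are split into stratified folds by treatment x TS cell; before
assignment the sensitive/non-sensitive counts are equalized within each
treatment stratum by randomly undersampling the majority class, so fold-level
metrics are not dominated by prevalence.  Each fold's pipeline (selection,
extraction, optimization, training, threshold) is fit on the nine training
folds only; the held-out fold contributes scores and hard labels.  AUC uses
the rank (Mann-Whitney) formulation; accuracy, sensitivity and specificity
use each fold's own training-derived threshold.
"""

from __future__ import annotations

import traceback
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .core import Cohort, ContractError, DataError, fit_normalizer, one_hot_treatment
from .selection import STATUS_SELECTED, SelectionReport
from .training import MultSettings, train_mult, train_smla

PIPELINES = ("mult", "smla-gbt", "smla-mlp", "smla-svm")


# ---------------------------------------------------------------------------
# CV plan
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """Fold assignment plus the class-equalization log."""

    fold: pd.Series              # patient id -> fold index (retained patients)
    removed: list                # patient ids undersampled out
    n_folds: int
    seed: int


def make_cv_plan(cohort: Cohort, n_folds: int = 10, seed: int = 0) -> CVPlan:
    """Stratified, class-equalized fold assignment.

    Within each treatment stratum the majority TS class is randomly
    undersampled to the minority count; the retained patients of every
    treatment x TS cell are then dealt round-robin into ``n_folds`` folds, so
    per-cell fold sizes differ by at most one patient.
    """
    if cohort.ts is None:
        raise ContractError("cohort needs a TS outcome before CV planning")
    rng = np.random.default_rng(seed)
    fold: dict = {}
    removed: list = []
    for t in sorted(cohort.treatment.unique()):
        in_t = cohort.treatment.index[cohort.treatment == t]
        ts_t = cohort.ts.loc[in_t]
        cells = {c: list(ts_t.index[ts_t == c]) for c in (0, 1)}
        if not cells[0] or not cells[1]:
            warnings.warn(
                f"treatment stratum {t!r} lacks a TS class; kept unequalized")
            n_keep = None
        else:
            n_keep = min(len(cells[0]), len(cells[1]))
        for c, ids in cells.items():
            ids = list(rng.permutation(ids))
            if n_keep is not None and len(ids) > n_keep:
                removed.extend(ids[n_keep:])
                ids = ids[:n_keep]
            if 0 < len(ids) < n_folds:
                warnings.warn(
                    f"cell (treatment={t!r}, ts={c}) has {len(ids)} patients "
                    f"for {n_folds} folds; spread thinly across folds")
            for i, pid in enumerate(ids):
                fold[pid] = i % n_folds
    if not fold:
        raise DataError("CV plan is empty")
    order = [pid for pid in cohort.clinical.index if pid in fold]
    return CVPlan(fold=pd.Series({p: fold[p] for p in order}, dtype=int),
                  removed=removed, n_folds=n_folds, seed=seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc_score(labels, scores) -> float:
    """Rank-based (Mann-Whitney) AUC."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return float("nan")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def confusion_metrics(labels, preds) -> dict:
    labels = np.asarray(labels).astype(int)
    preds = np.asarray(preds).astype(int)
    tp = int(((preds == 1) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    return {
        "accuracy": (tp + tn) / max(len(labels), 1),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "tp": tp, "tn": tn, "fp": fp, "fn": fn, "n": len(labels),
    }


def paired_auc_test(aucs_a, aucs_b) -> float:
    """Two-sample t-test p-value comparing fold-level AUC vectors."""
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if len(a) != len(b):
        raise ContractError("per-fold AUC vectors must have equal length")
    if len(a) < 2:
        raise ContractError("need at least 2 folds for a t-test")
    if a.std() == 0.0 and b.std() == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b).pvalue)


# ---------------------------------------------------------------------------
# CV execution
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    pipeline: str
    plan: CVPlan
    scores: pd.DataFrame          # patient_id, fold, treatment, label, score, pred
    fold_metrics: pd.DataFrame    # per-fold AUC/accuracy/sensitivity/specificity
    pooled: dict
    per_treatment: pd.DataFrame
    reports: list = field(default_factory=list)   # SelectionReport per fold
    predictors: list = field(default_factory=list)
    failures: list = field(default_factory=list)  # (fold, message)

    @property
    def fold_aucs(self) -> np.ndarray:
        return self.fold_metrics["auc"].to_numpy()


def _merge_reports(reports: dict) -> SelectionReport:
    tables = []
    for role, rep in reports.items():
        t = rep.table.copy()
        t["role"] = role
        tables.append(t)
    merged = pd.concat(tables, ignore_index=True)
    any_rep = next(iter(reports.values()))
    return SelectionReport(table=merged, alpha=any_rep.alpha, beta=any_rep.beta)


def _fit_score_fold(cohort, train_ids, val_ids, pipeline, seed, settings):
    train = cohort.subset(train_ids)
    val = cohort.subset(val_ids)
    if pipeline == "mult":
        pred = train_mult(train, seed=seed, settings=settings)
        scores = pred.score(val).to_numpy()
        report = _merge_reports(pred.reports)
        return pred, report, scores
    model = pipeline.split("-", 1)[1]
    raw_tr = pd.concat([train.clinical, train.expression], axis=1)
    raw_va = pd.concat([val.clinical, val.expression], axis=1)
    norm = fit_normalizer(raw_tr)
    vocab = sorted(train.treatment.unique())
    pred = train_smla(
        norm.transform(raw_tr, clip=False), train.ts.to_numpy(), model=model,
        alpha=settings.alpha, beta=settings.beta, seed=seed, settings=settings,
        passthrough=one_hot_treatment(train.treatment, vocab))
    F_va = pd.concat([norm.transform(raw_va, clip=True),
                      one_hot_treatment(val.treatment, vocab)], axis=1)
    scores = pred.predict_scores(F_va)
    return pred, pred.report, scores


def run_cv(cohort: Cohort, plan: CVPlan, pipeline: str = "mult",
           seed: int = 0, settings: MultSettings | None = None) -> CVResult:
    """Run the chosen pipeline over every CV fold of ``plan``.

    Per fold, the pipeline is fit on the training folds only; validation
    patients contribute scores and thresholded labels.  Pipeline failures on
    a fold are recorded and the remaining folds still run.  Per-treatment
    metrics pool all validation scores into one table.
    """
    if pipeline not in PIPELINES:
        raise ContractError(f"unknown pipeline {pipeline!r}; one of {PIPELINES}")
    settings = settings or MultSettings()
    kept = cohort.subset(list(plan.fold.index))

    rows, fold_rows, reports, predictors, failures = [], [], [], [], []
    for k in range(plan.n_folds):
        val_ids = list(plan.fold.index[plan.fold == k])
        train_ids = list(plan.fold.index[plan.fold != k])
        if not val_ids:
            continue
        try:
            pred, report, scores = _fit_score_fold(
                kept, train_ids, val_ids, pipeline, seed + k, settings)
        except Exception as exc:  # fold failure: record, continue
            failures.append((k, f"{type(exc).__name__}: {exc}"))
            traceback.clear_frames(exc.__traceback__)
            continue
        labels = kept.ts.loc[val_ids].to_numpy()
        preds = (scores >= pred.threshold).astype(int)
        for pid, s, yhat, y in zip(val_ids, scores, preds, labels):
            rows.append({"patient_id": pid, "fold": k,
                         "treatment": kept.treatment.loc[pid],
                         "label": int(y), "score": float(s), "pred": int(yhat)})
        fold_rows.append({"fold": k, "n": len(val_ids),
                          "auc": auc_score(labels, scores),
                          "threshold": pred.threshold,
                          **{m: v for m, v in confusion_metrics(labels, preds).items()
                             if m in ("accuracy", "sensitivity", "specificity")}})
        reports.append(report)
        predictors.append(pred)

    scores_df = pd.DataFrame(
        rows, columns=["patient_id", "fold", "treatment", "label", "score", "pred"])
    fold_df = pd.DataFrame(
        fold_rows, columns=["fold", "n", "auc", "threshold",
                            "accuracy", "sensitivity", "specificity"])

    pooled: dict = {"n": len(scores_df)}
    if len(scores_df):
        pooled["auc"] = auc_score(scores_df["label"], scores_df["score"])
        pooled.update({k: v for k, v in
                       confusion_metrics(scores_df["label"], scores_df["pred"]).items()
                       if k != "n"})
        pooled["mean_fold_auc"] = float(np.nanmean(fold_df["auc"]))

    per_t = []
    for t, grp in scores_df.groupby("treatment"):
        per_t.append({"treatment": t, "n": len(grp),
                      "auc": auc_score(grp["label"], grp["score"]),
                      **{m: v for m, v in
                         confusion_metrics(grp["label"], grp["pred"]).items()
                         if m in ("accuracy", "sensitivity", "specificity")}})
    per_treatment = pd.DataFrame(
        per_t, columns=["treatment", "n", "auc", "accuracy",
                        "sensitivity", "specificity"])

    return CVResult(pipeline=pipeline, plan=plan, scores=scores_df,
                    fold_metrics=fold_df, pooled=pooled,
                    per_treatment=per_treatment, reports=reports,
                    predictors=predictors, failures=failures)


# ---------------------------------------------------------------------------
# Marker-relationship graph
# ---------------------------------------------------------------------------

def build_marker_graph(selection_reports: list[SelectionReport],
                       roles: dict | None = None) -> nx.Graph:
    """Undirected co-selection graph over CV-fold selection reports.

    One node per ever-selected marker: ``size`` counts the folds in which the
    marker was selected, ``intensity`` (1 - mean p-value across folds) rises
    with significance, ``role`` tags clinical vs gene when known.  Edge
    ``width`` counts the folds in which both endpoints were selected; pairs
    never co-selected get no edge.
    """
    G = nx.Graph()
    if not selection_reports:
        return G
    sel_per_fold = []
    pvals: dict[str, list[float]] = {}
    role_map = dict(roles or {})
    for rep in selection_reports:
        t = rep.table
        sel = t[t["status"] == STATUS_SELECTED]
        sel_per_fold.append(set(sel["marker"]))
        for _, row in sel.iterrows():
            pvals.setdefault(row["marker"], []).append(row["p_value"])
            if "role" in t.columns and row["marker"] not in role_map:
                role_map[row["marker"]] = row.get("role", "")
    for marker, ps in pvals.items():
        G.add_node(marker,
                   size=sum(marker in s for s in sel_per_fold),
                   intensity=float(1.0 - np.mean(ps)),
                   role=role_map.get(marker, ""))
    markers = sorted(pvals)
    for i, a in enumerate(markers):
        for b in markers[i + 1:]:
            w = sum((a in s) and (b in s) for s in sel_per_fold)
            if w > 0:
                G.add_edge(a, b, width=w)
    return G
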