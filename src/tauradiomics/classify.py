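"""Linear-SVM evaluation harness: split, covariate residualization,
repeated cross-validation, hold-out and external-test evaluation.

Protocol: subjects are split 0.7/0.3 into training and validation sets,
stratified by class; an external-site cohort, when present, is held out
entirely as an independent test set. On the training set a linear SVM
(C = 1) is evaluated with stratified 5-fold cross-validation repeated 100
times (new fold assignment per repetition); repetition-level metrics are
computed from the pooled fold predictions and summarized as mean +- SD.
Each repetition's fold models also score the validation/test sets (decision
values averaged over the 5 fold models), giving a per-repetition holdout
metric distribution and hence a mean +- SD there too. AUC is summarized as
median and interquartile range over repetitions.

Age and sex enter as covariates by training-fit linear residualization:
each feature is regressed on [1, age, sex] over training rows only and the
fitted coefficients are applied unchanged to held-out rows. Features are
then z-scored with training-fit parameters. The positive class (for
sensitivity) is always the patient group of the task.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SplitPlan",
    "EvalSection",
    "EvalReport",
    "make_split",
    "CovariateAdjuster",
    "adjust_covariates",
    "repeated_cv",
    "evaluate_holdout",
    "roc_summary",
    "run_model",
]


@dataclass
class SplitPlan:
    train_ids: List[str]
    validation_ids: List[str]
    test_ids: List[str]
    seed: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "train": self.train_ids, "validation": self.validation_ids,
            "test": self.test_ids, "seed": self.seed}, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(d["train"], d["validation"], d["test"], d["seed"])


def make_split(manifest: pd.DataFrame, task: Tuple[str, str],
               label_col: str = "group", train_frac: float = 0.7,
               seed: int = 0) -> SplitPlan:
    """Stratified train/validation split of the discovery cohort.

    Rows whose label is outside ``task`` are ignored; external-cohort rows
    (column ``cohort`` == "external") are assigned wholly to the test set
    and never appear in training or validation.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    df = manifest[manifest[label_col].isin(task)]
    has_cohort = "cohort" in df.columns
    disc = df[df["cohort"] == "discovery"] if has_cohort else df
    ext = df[df["cohort"] == "external"] if has_cohort else df.iloc[0:0]
    train, val = [], []
    for lab in task:
        ids = list(disc.loc[disc[label_col] == lab, "id"])
        if len(ids) < 5:
            raise ValueError(f"group {lab!r} has {len(ids)} subjects; "
                             "need >= 5 for cross-validation")
        perm = rng.permutation(len(ids))
        n_train = int(round(train_frac * len(ids)))
        train += [ids[i] for i in perm[:n_train]]
        val += [ids[i] for i in perm[n_train:]]
    return SplitPlan(sorted(train), sorted(val), sorted(ext["id"]), seed)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def _design(cov: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
    cols = ["age", "sex"]
    age = cov["age"].to_numpy(dtype=np.float64)
    sex = (cov["sex"].astype(str).str.upper() == "M").to_numpy(dtype=np.float64) \
        if cov["sex"].dtype == object else cov["sex"].to_numpy(dtype=np.float64)
    return np.column_stack([np.ones(len(cov)), age, sex]), ["intercept"] + cols


class CovariateAdjuster:
    """Training-fit OLS residualization of features against [1, age, sex].

    Covariate columns that are constant on the training rows make the
    design rank-deficient; they are dropped with a warning.
    """

    def __init__(self) -> None:
        self.coef_: Optional[np.ndarray] = None
        self.active_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray, cov: pd.DataFrame) -> "CovariateAdjuster":
        D, names = _design(cov)
        active = np.ones(D.shape[1], dtype=bool)
        for k in range(1, D.shape[1]):
            if np.std(D[:, k]) == 0:
                warnings.warn(f"covariate {names[k]!r} constant on training "
                              "rows; dropped from adjustment")
                active[k] = False
        self.active_ = active
        Da = D[:, active]
        self.coef_, *_ = np.linalg.lstsq(Da, np.asarray(X, dtype=np.float64),
                                         rcond=None)
        return self

    def transform(self, X: np.ndarray, cov: pd.DataFrame) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("adjuster not fitted")
        D, _ = _design(cov)
        return np.asarray(X, dtype=np.float64) - D[:, self.active_] @ self.coef_


def adjust_covariates(train_X, train_cov, apply_X, apply_cov):
    """Functional form: returns (train_residuals, apply_residuals, adjuster).

    The same training-fit coefficients are applied to the held-out rows; no
    refit happens on ``apply`` data.
    """
    adj = CovariateAdjuster().fit(train_X, train_cov)
    return adj.transform(train_X, train_cov), adj.transform(apply_X, apply_cov), adj


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Dict[str, float]:
    """Accuracy / sensitivity / specificity; positive class coded 1.

    One-class truths make sensitivity or specificity undefined -> NaN."""
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    pos, neg = tp + fn, tn + fp
    return {
        "accuracy": (tp + tn) / max(pos + neg, 1),
        "sensitivity": tp / pos if pos else float("nan"),
        "specificity": tn / neg if neg else float("nan"),
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }


def roc_summary(decision_values: Sequence[np.ndarray], labels: np.ndarray
                ) -> Dict[str, float]:
    """Per-repetition rank-based AUC summarized as median and 25-75% IQR."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC needs both classes present")
    aucs = [float(roc_auc_score(labels, d)) for d in decision_values]
    q25, q75 = np.percentile(aucs, [25, 75])
    return {"auc_median": float(np.median(aucs)), "auc_q25": float(q25),
            "auc_q75": float(q75), "auc_per_rep": aucs}


@dataclass
class EvalSection:
    accuracy: List[float]
    sensitivity: List[float]
    specificity: List[float]
    auc: List[float]
    confusion: Dict[str, int] = field(default_factory=dict)

    def summary(self) -> Dict[str, float]:
        def ms(v):
            a = np.asarray(v, dtype=np.float64)
            a = a[np.isfinite(a)]
            if a.size == 0:
                return float("nan"), float("nan")
            return float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0

        acc_m, acc_s = ms(self.accuracy)
        sen_m, sen_s = ms(self.sensitivity)
        spe_m, spe_s = ms(self.specificity)
        auc = np.asarray(self.auc, dtype=np.float64)
        auc = auc[np.isfinite(auc)]
        if auc.size:
            q25, q75 = np.percentile(auc, [25, 75])
            auc_med = float(np.median(auc))
        else:
            q25 = q75 = auc_med = float("nan")
        return {
            "accuracy_mean_pct": 100 * acc_m, "accuracy_sd_pct": 100 * acc_s,
            "sensitivity_mean_pct": 100 * sen_m, "sensitivity_sd_pct": 100 * sen_s,
            "specificity_mean_pct": 100 * spe_m, "specificity_sd_pct": 100 * spe_s,
            "auc_median": auc_med, "auc_q25": float(q25), "auc_q75": float(q75),
        }


@dataclass
class EvalReport:
    model: str
    task: Tuple[str, str]
    positive_label: str
    sections: Dict[str, EvalSection]
    n_features: int
    seed: int
    metadata: Dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "model": self.model, "task": list(self.task),
            "positive_label": self.positive_label,
            "n_features": self.n_features, "seed": self.seed,
            "metadata": self.metadata,
            "sections": {
                name: {"summary": sec.summary(),
                       "per_repetition": {
                           "accuracy": sec.accuracy,
                           "sensitivity": sec.sensitivity,
                           "specificity": sec.specificity,
                           "auc": sec.auc},
                       "confusion": sec.confusion}
                for name, sec in self.sections.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def table(self) -> str:
        """Human-readable summary: rows = dataset, metrics as mean +- SD."""
        lines = [f"model: {self.model}  task: {self.task[0]} vs {self.task[1]}"
                 f"  (positive = {self.positive_label}, "
                 f"n_features = {self.n_features})"]
        hdr = f"{'dataset':<12}{'Accuracy(%)':>16}{'Sensitivity(%)':>18}" \
              f"{'Specificity(%)':>18}{'AUC median (IQR)':>24}"
        lines.append(hdr)
        for name, sec in self.sections.items():
            s = sec.summary()
            lines.append(
                f"{name:<12}"
                f"{s['accuracy_mean_pct']:>9.1f} ± {s['accuracy_sd_pct']:<4.1f}"
                f"{s['sensitivity_mean_pct']:>11.1f} ± {s['sensitivity_sd_pct']:<4.1f}"
                f"{s['specificity_mean_pct']:>11.1f} ± {s['specificity_sd_pct']:<4.1f}"
                f"{s['auc_median']:>10.3f} ({s['auc_q25']:.3f}-{s['auc_q75']:.3f})"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Repeated CV + holdout
# ---------------------------------------------------------------------------

def _new_svm(C: float) -> SVC:
    return SVC(kernel="linear", C=C, class_weight="balanced")


def repeated_cv(X: np.ndarray, y: np.ndarray, k_folds: int = 5,
                n_reps: int = 100, C: float = 1.0, seed: int = 0,
                holdouts: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None):
    """Stratified k-fold CV repeated ``n_reps`` times with a linear SVM.

    Per repetition the fold assignment is re-drawn; repetition metrics come
    from the pooled out-of-fold predictions. If ``holdouts`` maps section
    names to (X_h, y_h), each repetition's 5 fold models also score them
    (decision values averaged) to yield per-repetition holdout metrics.

    Returns ``(sections, fold_models_last_rep)`` where sections maps
    "train_cv" and each holdout name to an :class:`EvalSection`.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training labels contain a single class")
    holdouts = holdouts or {}
    sec: Dict[str, EvalSection] = {
        name: EvalSection([], [], [], []) for name in ["train_cv", *holdouts]}
    models: List[SVC] = []
    for rep in range(n_reps):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                              random_state=(seed * 100003 + rep) % (2**31 - 1))
        oof_pred = np.empty_like(y)
        oof_dec = np.empty(len(y), dtype=np.float64)
        hold_dec = {name: np.zeros(len(yh), dtype=np.float64)
                    for name, (_, yh) in holdouts.items()}
        models = []
        for tr, te in skf.split(X, y):
            clf = _new_svm(C).fit(X[tr], y[tr])
            oof_pred[te] = clf.predict(X[te])
            oof_dec[te] = clf.decision_function(X[te])
            for name, (Xh, _) in holdouts.items():
                hold_dec[name] += clf.decision_function(Xh) / k_folds
            models.append(clf)
        m = _binary_metrics(y, oof_pred)
        sec["train_cv"].accuracy.append(m["accuracy"])
        sec["train_cv"].sensitivity.append(m["sensitivity"])
        sec["train_cv"].specificity.append(m["specificity"])
        sec["train_cv"].auc.append(float(roc_auc_score(y, oof_dec)))
        for name, (Xh, yh) in holdouts.items():
            dec = hold_dec[name]
            hm = _binary_metrics(yh, (dec > 0).astype(int))
            s = sec[name]
            s.accuracy.append(hm["accuracy"])
            s.sensitivity.append(hm["sensitivity"])
            s.specificity.append(hm["specificity"])
            if len(set(yh.tolist())) >= 2:
                s.auc.append(float(roc_auc_score(yh, dec)))
            else:
                s.auc.append(float("nan"))
            if rep == n_reps - 1:
                s.confusion = {k2: hm[k2] for k2 in ("tp", "tn", "fp", "fn")}
    return sec, models


def evaluate_holdout(models: Sequence[SVC], X: np.ndarray, y: np.ndarray
                     ) -> Dict[str, float]:
    """Score a holdout with an ensemble of fold models (averaged decisions)."""
    dec = np.mean([m.decision_function(X) for m in models], axis=0)
    out = _binary_metrics(np.asarray(y, dtype=int), (dec > 0).astype(int))
    if len(set(np.asarray(y).tolist())) >= 2:
        out["auc"] = float(roc_auc_score(y, dec))
    else:
        warnings.warn("one-class holdout: AUC and one of sens/spec undefined")
        out["auc"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# Full harness
# ---------------------------------------------------------------------------

def run_model(table: pd.DataFrame, features: Sequence[str], split: SplitPlan,
              task: Tuple[str, str], label_col: str = "group",
              covariate_mode: str = "residualize", k_folds: int = 5,
              n_reps: int = 100, C: float = 1.0, seed: int = 0,
              model_name: str = "model"):
    """End-to-end evaluation of one feature matrix under the shared protocol.

    All three models (radiomics, SUVR, clinical) run through this single
    code path. ``covariate_mode`` is "residualize" (default), "append"
    (covariates added as features) or "ignore".

    Returns ``(EvalReport, artifacts)`` where artifacts carries every
    training-fit object (covariate adjuster, scaler, final SVM) for
    provenance and leakage auditing.
    """
    df = table.set_index("id", drop=False)
    feats = list(features)
    missing_cols = [f for f in feats if f not in df.columns]
    if missing_cols:
        raise ValueError(f"holdout/table schema mismatch: missing {missing_cols[:3]}")

    def block(ids):
        sub = df.loc[[i for i in ids if i in df.index]]
        sub = sub[sub[label_col].isin(task)]
        X = sub[feats].to_numpy(dtype=np.float64)
        y = (sub[label_col] == task[0]).to_numpy(dtype=int)
        return sub, X, y

    tr_df, X_tr, y_tr = block(split.train_ids)
    va_df, X_va, y_va = block(split.validation_ids)
    te_df, X_te, y_te = block(split.test_ids)

    adj = None
    if covariate_mode == "residualize":
        adj = CovariateAdjuster().fit(X_tr, tr_df)
        X_tr = adj.transform(X_tr, tr_df)
        X_va = adj.transform(X_va, va_df) if len(va_df) else X_va
        X_te = adj.transform(X_te, te_df) if len(te_df) else X_te
    elif covariate_mode == "append":
        def app(X, d):
            D, _ = _design(d)
            return np.column_stack([X, D[:, 1:]])
        X_tr, X_va, X_te = app(X_tr, tr_df), \
            (app(X_va, va_df) if len(va_df) else X_va), \
            (app(X_te, te_df) if len(te_df) else X_te)
    elif covariate_mode != "ignore":
        raise ValueError(f"unknown covariate_mode {covariate_mode!r}")

    scaler = StandardScaler().fit(X_tr)
    X_tr = scaler.transform(X_tr)
    holdouts = {}
    if len(va_df):
        X_va = scaler.transform(X_va)
        holdouts["validation"] = (X_va, y_va)
    if len(te_df):
        X_te = scaler.transform(X_te)
        holdouts["external_test"] = (X_te, y_te)

    sections, fold_models = repeated_cv(X_tr, y_tr, k_folds=k_folds,
                                        n_reps=n_reps, C=C, seed=seed,
                                        holdouts=holdouts)
    final_svm = _new_svm(C).fit(X_tr, y_tr)
    report = EvalReport(
        model=model_name, task=task, positive_label=task[0],
        sections=sections, n_features=len(feats), seed=seed,
        metadata={"k_folds": k_folds, "n_reps": n_reps, "C": C,
                  "covariate_mode": covariate_mode,
                  "n_train": len(tr_df), "n_validation": len(va_df),
                  "n_external": len(te_df)},
    )
    artifacts = {"covariate_adjuster": adj, "scaler": scaler,
                 "svm": final_svm, "fold_models": fold_models,
                 "features": feats}
    return report, artifacts
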