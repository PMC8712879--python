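"""Supervised CRT-response classification on hybrid feature tables.

The pipeline mirrors common small-cohort practice: response labels from
echocardiographic remodeling criteria; preprocessing that drops features
with missing values, z-scores continuous ones and removes collinear pairs
(|r| > 0.85); feature selection *inside* the cross-validation loop (random
forest permutation importance, univariate statistical testing, or
L1-penalized logistic weights; top 8 kept); four linear/ensemble
classifiers (logistic regression, LDA, linear SVM, random forest); and
evaluation by leave-one-out (scores pooled into one ROC) or repeated
stratified 5-fold cross-validation (AUC mean +/- SD over folds x repeats).

Scalers, selectors and classifiers are fitted strictly on training folds;
the factory hooks let tests instrument every fit call to prove no test-fold
row leaks into training.  Binary metrics are reported at the Youden-J
cutoff of the pooled out-of-fold scores.  No hyperparameter search is
performed anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import LeaveOneOut, RepeatedStratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

PROVENANCES = ("clinical", "ctmri_model", "sim_lbbb", "sim_biv", "sim_delta")
CLASSIFIERS = ("LR", "LDA", "SVM", "RF")
SELECTORS = ("MDA", "UST", "L1")
CRITERIA = ("EF5", "EF10", "EF15", "ESV15", "EF10+ESV15")


@dataclass
class CohortTable:
    """Hybrid per-patient feature matrix with metadata and outcomes.

    ``data`` holds the features; ``meta`` (indexed by feature name) declares
    each column's kind (continuous/categorical), provenance and whether it
    is known before the implantation (post-operative outcomes never enter
    the classifier inputs); ``outcomes`` carries dEF_CRT (EF change in
    percentage points) and dESV_CRT (ESV change in percent).
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    outcomes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"features without metadata: {sorted(missing)}")

    def features(self, provenances=None) -> pd.DataFrame:
        """Pre-operative feature columns, optionally by provenance."""
        names = [c for c in self.data.columns
                 if bool(self.meta.loc[c, "preop_safe"])
                 and (provenances is None
                      or self.meta.loc[c, "provenance"] in provenances)]
        return self.data[names]

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.data.to_csv(prefix.with_suffix(".features.csv"), index_label="patient")
        self.outcomes.to_csv(prefix.with_suffix(".outcomes.csv"),
                             index_label="patient")
        self.meta.to_csv(prefix.with_suffix(".meta.csv"), index_label="feature")

    @classmethod
    def load(cls, prefix: str | Path) -> "CohortTable":
        prefix = Path(prefix)
        return cls(
            data=pd.read_csv(prefix.with_suffix(".features.csv"),
                             index_col="patient"),
            meta=pd.read_csv(prefix.with_suffix(".meta.csv"),
                             index_col="feature"),
            outcomes=pd.read_csv(prefix.with_suffix(".outcomes.csv"),
                                 index_col="patient"),
        )


@dataclass
class MLConfig:
    criterion: str = "EF10"
    classifier: str = "SVM"
    selector: str = "UST"
    cv: str = "loo"                 # 'loo' or '5fold'
    n_repeats: int = 1000           # for 5-fold
    top_k: int = 8
    collinearity_threshold: float = 0.85
    provenances: tuple | None = None   # None = all preop-safe features
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if self.selector not in SELECTORS:
            raise ValueError(f"selector must be one of {SELECTORS}")
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")
        if self.cv not in ("loo", "5fold"):
            raise ValueError("cv must be 'loo' or '5fold'")


@dataclass
class CVResult:
    auc: float
    auc_sd: float | None
    per_fold_auc: np.ndarray | None
    scores: np.ndarray | None       # pooled out-of-fold scores (LOO order)
    y: np.ndarray | None
    roc: tuple | None               # (fpr, tpr, thresholds)
    cutoff: float | None
    confusion: np.ndarray | None    # [[TP, FN], [FP, TN]]
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    selection_frequency: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# labels and preprocessing
# ---------------------------------------------------------------------------

def label_response(outcomes: pd.DataFrame, criterion: str = "EF10",
                   ) -> pd.Series:
    """Binary responder labels from post-operative remodeling.

    EF criteria test the absolute EF increment in percentage points
    (dEF_CRT > 5/10/15); ESV15 tests a relative end-systolic volume
    reduction of more than 15% (dESV_CRT < -15); the combined criterion is
    their conjunction.  Patients with a missing required outcome are
    dropped (logged).
    """
    need = {"EF5": ["dEF_CRT"], "EF10": ["dEF_CRT"], "EF15": ["dEF_CRT"],
            "ESV15": ["dESV_CRT"], "EF10+ESV15": ["dEF_CRT", "dESV_CRT"]}
    if criterion not in need:
        raise ValueError(f"unknown criterion {criterion!r}")
    cols = need[criterion]
    for c in cols:
        if c not in outcomes.columns:
            raise ValueError(f"outcome column {c!r} missing")
    ok = outcomes[cols].notna().all(axis=1)
    if (~ok).any():
        logger.info("%d patient(s) dropped for missing outcome", int((~ok).sum()))
    sub = outcomes[ok]
    if criterion in ("EF5", "EF10", "EF15"):
        thr = float(criterion[2:])
        lab = sub["dEF_CRT"] > thr
    elif criterion == "ESV15":
        lab = sub["dESV_CRT"] < -15.0
    else:
        lab = (sub["dEF_CRT"] > 10.0) & (sub["dESV_CRT"] < -15.0)
    return lab.astype(int)


def _priority_order(meta: pd.DataFrame, columns) -> list[str]:
    rank = {p: i for i, p in enumerate(PROVENANCES)}
    return sorted(columns,
                  key=lambda c: (rank.get(meta.loc[c, "provenance"], 99), c))


def preprocess(table: CohortTable, threshold: float = 0.85) -> CohortTable:
    """Dataset-level preprocessing before cross-validation.

    Drops feature columns containing any missing value (column-wise, no
    imputation) and zero-variance columns, then removes collinear features:
    columns are ranked by a declared priority (clinical before model-derived
    provenances, alphabetical within), and a column is dropped when its
    absolute Pearson correlation with an already-kept column exceeds the
    threshold.  Z-scoring is deliberately left to the per-fold scaler inside
    the cross-validation loop.
    """
    df = table.data
    if df.shape[1] < 2:
        raise ValueError("need at least two features")
    keep = [c for c in df.columns if not df[c].isna().any()]
    n_missing = df.shape[1] - len(keep)
    if n_missing:
        logger.info("%d feature(s) dropped for missing values", n_missing)
    nz = [c for c in keep if df[c].std() > 0]
    if len(nz) < len(keep):
        logger.warning("%d zero-variance feature(s) dropped", len(keep) - len(nz))

    ordered = _priority_order(table.meta, nz)
    corr = df[ordered].corr().abs()
    kept: list[str] = []
    for c in ordered:
        if all(corr.loc[c, k] <= threshold for k in kept):
            kept.append(c)
    kept = [c for c in df.columns if c in kept]  # original column order
    return CohortTable(data=df[kept].copy(), meta=table.meta.loc[kept].copy(),
                       outcomes=table.outcomes.copy())


# ---------------------------------------------------------------------------
# feature selection (train folds only)
# ---------------------------------------------------------------------------

def select_features(X: pd.DataFrame, y: np.ndarray, meta: pd.DataFrame,
                    selector: str = "UST", k: int = 8, seed: int = 0,
                    audit: dict | None = None) -> list[str]:
    """Rank features on training data and return the top k names.

    MDA: permutation importance of a random forest; UST: ascending p-value
    of a two-sample t-test (continuous) or an uncorrected chi-squared
    contingency test (categorical); L1: descending absolute weight of an
    L1-penalized logistic fit on z-scored inputs (with a small fixed C
    escalation if every weight vanishes — not a hyperparameter search, just
    a guard against an all-zero solution).
    """
    names = list(X.columns)
    if k >= len(names):
        if k > len(names):
            logger.warning("k=%d exceeds %d available features", k, len(names))
        return names
    y = np.asarray(y)
    if selector == "MDA":
        rf = RandomForestClassifier(n_estimators=200, random_state=seed)
        rf.fit(X.values, y)
        imp = permutation_importance(rf, X.values, y, n_repeats=5,
                                     random_state=seed)
        score = -imp.importances_mean  # ascending sort -> most important first
    elif selector == "UST":
        pvals = []
        for c in names:
            x = X[c].values
            if meta.loc[c, "kind"] == "categorical":
                tabxy = pd.crosstab(x, y)
                if tabxy.shape[0] < 2:
                    p = 1.0
                else:
                    _, p, _, _ = stats.chi2_contingency(tabxy, correction=False)
                test = "chi2"
            else:
                p = stats.ttest_ind(x[y == 1], x[y == 0],
                                    equal_var=False).pvalue
                test = "ttest"
            if audit is not None:
                audit[c] = test
            pvals.append(p if np.isfinite(p) else 1.0)
        score = np.asarray(pvals)
    elif selector == "L1":
        Xs = StandardScaler().fit_transform(X.values)
        coef = None
        for c_pen in (1.0, 10.0, 100.0):
            lr = LogisticRegression(l1_ratio=1.0, C=c_pen, solver="liblinear",
                                    random_state=seed)
            lr.fit(Xs, y)
            coef = np.abs(lr.coef_.ravel())
            if coef.max() > 1e-12:
                break
        score = -coef
    else:
        raise ValueError(f"unknown selector {selector!r}")
    order = np.argsort(score, kind="stable")
    return [names[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# classifiers and scoring
# ---------------------------------------------------------------------------

def _default_classifier(name: str, seed: int):
    if name == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "SVM":
        return SVC(kernel="linear", random_state=seed)
    if name == "RF":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def _score(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


def youden_cutoff(y: np.ndarray, scores: np.ndarray) -> float:
    """Score cutoff maximizing sensitivity + specificity - 1."""
    fpr, tpr, thr = roc_curve(y, scores)
    return float(thr[np.argmax(tpr - fpr)])


def binary_metrics(y: np.ndarray, scores: np.ndarray,
                   cutoff: float) -> dict[str, float]:
    pred = scores >= cutoff
    y = np.asarray(y).astype(bool)
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    def safe(a, b):
        return a / b if b else float("nan")
    return {
        "confusion": np.array([[tp, fn], [fp, tn]]),
        "accuracy": safe(tp + tn, tp + tn + fp + fn),
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp),
        "ppv": safe(tp, tp + fp),
        "npv": safe(tn, tn + fn),
    }


def evaluate(table: CohortTable, config: MLConfig,
             make_classifier=None, make_selector=None,
             make_scaler=None) -> CVResult:
    """Cross-validated classification with in-loop feature selection.

    LOO pools the n out-of-fold scores into a single ROC; repeated
    stratified 5-fold reports AUC mean +/- SD over folds x repeats (scores
    of the first repeat are pooled for the cutoff metrics).  The factory
    arguments exist so tests can instrument the fitted components.
    """
    y_all = label_response(table.outcomes, config.criterion)
    X_all = table.features(config.provenances).loc[y_all.index]
    if X_all.shape[1] == 0:
        raise ValueError("no usable features")
    y = y_all.values
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = X_all.reset_index(drop=True)
    meta = table.meta

    make_classifier = make_classifier or (
        lambda: _default_classifier(config.classifier, config.seed))
    make_selector = make_selector or (
        lambda Xt, yt: select_features(Xt, yt, meta, config.selector,
                                       k=config.top_k, seed=config.seed))
    make_scaler = make_scaler or StandardScaler

    sel_counts: dict[str, int] = {}
    n_folds = 0

    def run_fold(tr, te):
        nonlocal n_folds
        n_folds += 1
        X_tr, y_tr = X.iloc[tr], y[tr]
        chosen = make_selector(X_tr, y_tr)
        for c in chosen:
            sel_counts[c] = sel_counts.get(c, 0) + 1
        scaler = make_scaler()
        Z_tr = scaler.fit_transform(X_tr[chosen].values)
        clf = make_classifier()
        clf.fit(Z_tr, y_tr)
        Z_te = scaler.transform(X.iloc[te][chosen].values)
        return _score(clf, Z_te)

    if config.cv == "loo":
        scores = np.empty(len(y))
        for tr, te in LeaveOneOut().split(X):
            scores[te] = run_fold(tr, te)
        auc = roc_auc_score(y, scores)
        fpr, tpr, thr = roc_curve(y, scores)
        cutoff = youden_cutoff(y, scores)
        m = binary_metrics(y, scores, cutoff)
        per_fold = None
        auc_sd = None
        pooled_y, pooled_s = y, scores
    else:
        rskf = RepeatedStratifiedKFold(n_splits=5, n_repeats=config.n_repeats,
                                       random_state=config.seed)
        per_fold = []
        first_scores = np.empty(len(y))
        for i, (tr, te) in enumerate(rskf.split(X, y)):
            s = run_fold(tr, te)
            per_fold.append(roc_auc_score(y[te], s))
            if i < 5:
                first_scores[te] = s
        per_fold = np.asarray(per_fold)
        auc = float(per_fold.mean())
        auc_sd = float(per_fold.std(ddof=1))
        fpr, tpr, thr = roc_curve(y, first_scores)
        cutoff = youden_cutoff(y, first_scores)
        m = binary_metrics(y, first_scores, cutoff)
        pooled_y, pooled_s = y, first_scores

    freq = {c: v / n_folds for c, v in sorted(sel_counts.items())}
    return CVResult(auc=float(auc), auc_sd=auc_sd, per_fold_auc=per_fold,
                    scores=pooled_s, y=pooled_y, roc=(fpr, tpr, thr),
                    cutoff=cutoff, confusion=m["confusion"],
                    accuracy=m["accuracy"], sensitivity=m["sensitivity"],
                    specificity=m["specificity"], ppv=m["ppv"], npv=m["npv"],
                    selection_frequency=freq)


# ---------------------------------------------------------------------------
# PCA + logistic and unsupervised variants
# ---------------------------------------------------------------------------

def pca_lr(table: CohortTable, n_components_range=range(2, 11),
           criterion: str = "EF10", seed: int = 0) -> pd.DataFrame:
    """Leave-one-out logistic regression on principal-component scores.

    PCA (with the scaler) is refitted on each training fold.  Returns one
    row per component count with the pooled AUC and the mean explained
    variance fraction of the training-fold PCAs.
    """
    y = label_response(table.outcomes, criterion)
    X = table.features().loc[y.index].reset_index(drop=True)
    yv = y.values
    rank = int(np.linalg.matrix_rank(X.values - X.values.mean(axis=0)))
    rows = []
    for nc in n_components_range:
        nc_eff = min(nc, rank, X.shape[0] - 2)
        if nc_eff < nc:
            logger.warning("n_components=%d capped to %d", nc, nc_eff)
        scores = np.empty(len(yv))
        evar = []
        for tr, te in LeaveOneOut().split(X):
            scaler = StandardScaler().fit(X.iloc[tr].values)
            Z_tr = scaler.transform(X.iloc[tr].values)
            pca = PCA(n_components=nc_eff, random_state=seed).fit(Z_tr)
            evar.append(pca.explained_variance_ratio_.sum())
            lr = LogisticRegression(max_iter=5000, tol=1e-10,
                                    random_state=seed)
            lr.fit(pca.transform(Z_tr), yv[tr])
            scores[te] = lr.predict_proba(
                pca.transform(scaler.transform(X.iloc[te].values)))[:, 1]
        rows.append({"n_components": nc, "n_components_used": nc_eff,
                     "auc": roc_auc_score(yv, scores),
                     "explained_variance": float(np.mean(evar))})
    return pd.DataFrame(rows)


def kmeans_clusters(table: CohortTable, k: int = 2, seed: int = 0):
    """K-means on the first two principal components (best of 10 restarts).

    Returns the cluster labels and a per-cluster summary of the mean
    outcomes and the responder composition under the EF10 criterion.
    """
    X = table.features()
    Z = StandardScaler().fit_transform(X.values)
    pc = PCA(n_components=2, random_state=seed).fit_transform(Z)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pc)
    labels = km.labels_
    y = label_response(table.outcomes, "EF10").reindex(X.index)
    rows = []
    for c in range(k):
        sel = labels == c
        rows.append({
            "cluster": c,
            "n": int(sel.sum()),
            "mean_dEF": float(table.outcomes["dEF_CRT"][sel].mean()),
            "mean_dESV": float(table.outcomes["dESV_CRT"][sel].mean()),
            "n_responders": int(y[sel].sum()),
        })
    return labels, pd.DataFrame(rows), pc
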