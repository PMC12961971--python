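"""Within-patient multivariable phase classification.

Per contrast (peak-vs-trough, rising-vs-falling, peak-vs-rising,
rising-vs-trough, or four-class): standardize -> PCA (95% variance) ->
linear SVM (hinge loss, C=1, balanced class weights), 10-fold stratified
cross-validated AUROC from decision values, a label-permutation null for
significance, and back-projection of the SVM weights through the PCA
loadings to per-feature importances.  Standardization and PCA are fit
inside each fold (no leakage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .stats import sign_test_two_tailed
from .types import (
    ClassifierReport,
    DegenerateContrastError,
    EEG_FEATURES,
)

#: Binary contrasts as (positive bin, negative bin); positive = peak (or
#: rising for the falling/trough comparisons that include rising).
CONTRASTS: dict[str, tuple[str, str]] = {
    "PvT": ("peak", "trough"),
    "RvF": ("rising", "falling"),
    "PvR": ("peak", "rising"),
    "RvT": ("rising", "trough"),
}

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "eeg": EEG_FEATURES + ("tod",),
    "eeg+spikes": EEG_FEATURES + ("tod", "spike_rate"),
    "spikes": ("spike_rate", "tod"),
    "poststim": EEG_FEATURES + ("tod",),
}

PCA_VARIANCE = 0.95
SVM_C = 1.0
N_FOLDS = 10
MIN_ROWS_PER_CLASS = 20


def binary_auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUROC of decision values via the rank (Mann-Whitney) identity."""
    y_true = np.asarray(y_true).astype(bool)
    n1 = int(y_true.sum())
    n0 = len(y_true) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC needs both classes present")
    r = rankdata(scores)
    return float((r[y_true].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class _FittedPipeline:
    scaler: StandardScaler
    pca: PCA
    svm: LinearSVC
    feature_names: tuple[str, ...]


def _make_parts(seed: int):
    scaler = StandardScaler()
    pca = PCA(n_components=PCA_VARIANCE, svd_solver="full")
    svm = LinearSVC(
        C=SVM_C,
        loss="hinge",
        class_weight="balanced",
        max_iter=50_000,
        tol=1e-4,
        random_state=seed,
    )
    return scaler, pca, svm


def _fit_score(Xtr, ytr, Xte, yte, seed: int) -> float:
    scaler, pca, svm = _make_parts(seed)
    Ztr = pca.fit_transform(scaler.fit_transform(Xtr))
    Zte = pca.transform(scaler.transform(Xte))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # occasional non-convergence on nulls
        svm.fit(Ztr, ytr)
    scores = svm.decision_function(Zte)
    if scores.ndim == 1:
        return binary_auroc(yte, scores)
    # macro one-vs-rest AUROC from decision values
    aucs = [
        binary_auroc(yte == c, scores[:, i])
        for i, c in enumerate(svm.classes_)
        if len(np.unique(yte == c)) == 2
    ]
    return float(np.mean(aucs))


def _select(table: pd.DataFrame, contrast: str, feature_set: str):
    cols = FEATURE_SETS[feature_set]
    df = table
    if "segment_ok" in df.columns:
        df = df[df["segment_ok"]]
    if contrast == "fourclass":
        y = df["bin"].to_numpy()
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 4 or counts.min() < N_FOLDS:
            raise DegenerateContrastError(
                "four-class contrast needs all four bins populated"
            )
        y_enc = y
    else:
        pos, neg = CONTRASTS[contrast]
        df = df[df["bin"].isin((pos, neg))]
        counts = df["bin"].value_counts()
        if counts.get(pos, 0) < MIN_ROWS_PER_CLASS or counts.get(
            neg, 0
        ) < MIN_ROWS_PER_CLASS:
            raise DegenerateContrastError(
                f"{contrast}: need >= {MIN_ROWS_PER_CLASS} rows per class, "
                f"got {dict(counts)}"
            )
        y_enc = (df["bin"] == pos).astype(int).to_numpy()
    X = df[list(cols)].to_numpy(float)
    return X, y_enc, df


def cross_val_auroc(
    X: np.ndarray, y: np.ndarray, seed: int, n_folds: int = N_FOLDS
) -> np.ndarray:
    """Per-fold held-out AUROC under the standardize->PCA->SVM protocol."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return np.array(
        [
            _fit_score(X[tr], y[tr], X[te], y[te], seed)
            for tr, te in skf.split(X, y)
        ]
    )


def fit_full_pipeline(
    X: np.ndarray, y: np.ndarray, feature_names, seed: int
) -> _FittedPipeline:
    scaler, pca, svm = _make_parts(seed)
    Z = pca.fit_transform(scaler.fit_transform(X))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svm.fit(Z, y)
    return _FittedPipeline(scaler, pca, svm, tuple(feature_names))


def backproject_coefficients(pipeline: _FittedPipeline) -> pd.Series:
    """Map SVM weights from PC space back to the original features.

    Weights are pushed through the PCA loading matrix and divided by the
    training standard deviations, yielding one signed weight per input
    feature (positive = higher at the positive class: peak, or rising for
    RvF/RvT).
    """
    coef = np.atleast_2d(pipeline.svm.coef_)
    w = pipeline.pca.components_.T @ coef.T  # (n_features, n_models)
    w = w / pipeline.scaler.scale_[:, None]
    if w.shape[1] == 1:
        return pd.Series(w[:, 0], index=list(pipeline.feature_names))
    return pd.Series(
        list(w.T), index=[str(c) for c in pipeline.svm.classes_]
    )


def fit_eval_classifier(
    table: pd.DataFrame,
    contrast: str,
    feature_set: str = "eeg",
    seed: int = 0,
    n_folds: int = N_FOLDS,
) -> ClassifierReport:
    """Cross-validated phase classification for one contrast/feature set."""
    X, y, df = _select(table, contrast, feature_set)
    fold_aucs = cross_val_auroc(X, y, seed, n_folds)
    full = fit_full_pipeline(X, y, FEATURE_SETS[feature_set], seed)
    coeffs = backproject_coefficients(full)
    if contrast == "fourclass":
        counts = df["bin"].value_counts().to_dict()
    else:
        pos, neg = CONTRASTS[contrast]
        counts = {
            pos: int((y == 1).sum()), neg: int((y == 0).sum())
        }
    return ClassifierReport(
        contrast=contrast,
        feature_set=feature_set,
        fold_aucs=fold_aucs,
        mean_auc=float(fold_aucs.mean()),
        n_rows=len(y),
        class_counts=counts,
        coefficients=coeffs if contrast != "fourclass" else None,
    )


def permutation_significance(
    table: pd.DataFrame,
    contrast: str,
    feature_set: str = "eeg",
    n_perm: int = 1000,
    seed: int = 0,
    n_folds: int = N_FOLDS,
    report: ClassifierReport | None = None,
) -> ClassifierReport:
    """One-sided label-permutation test of the cross-validated AUROC.

    Labels are permuted within the patient's table; the identical CV
    protocol (standardize/PCA/SVM refit per fold) is applied per
    permutation; ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives an unstable permutation p-value",
            stacklevel=2,
        )
    X, y, _ = _select(table, contrast, feature_set)
    if report is None:
        report = fit_eval_classifier(table, contrast, feature_set, seed, n_folds)
    # the scaler and PCA are label-independent, so with fixed folds their
    # per-fold fits are identical across permutations and can be reused;
    # only the SVM is refit per permutation (exactly equivalent to a full
    # refit of the whole pipeline)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    for tr, te in skf.split(X, y):
        scaler, pca, _ = _make_parts(seed)
        Ztr = pca.fit_transform(scaler.fit_transform(X[tr]))
        Zte = pca.transform(scaler.transform(X[te]))
        folds.append((tr, te, Ztr, Zte))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_perm):
            yp = rng.permutation(y)
            fold_aucs = []
            for tr, te, Ztr, Zte in folds:
                if len(np.unique(yp[tr])) < 2 or len(np.unique(yp[te])) < 2:
                    continue
                _, _, svm = _make_parts(seed)
                svm.fit(Ztr, yp[tr])
                scores = svm.decision_function(Zte)
                if scores.ndim == 1:
                    fold_aucs.append(binary_auroc(yp[te], scores))
                else:
                    fold_aucs.append(
                        np.mean(
                            [
                                binary_auroc(yp[te] == c, scores[:, k])
                                for k, c in enumerate(svm.classes_)
                                if len(np.unique(yp[te] == c)) == 2
                            ]
                        )
                    )
            null[i] = float(np.mean(fold_aucs))
    report.null_aucs = null
    report.p_value = float(
        (1 + np.sum(null >= report.mean_auc)) / (n_perm + 1)
    )
    return report


def compare_feature_sets(
    tables: dict[str, dict[str, pd.DataFrame]],
    contrasts=("PvT", "RvF"),
    seed: int = 0,
    n_perm: int = 0,
    n_folds: int = N_FOLDS,
) -> dict:
    """Cohort comparison of feature sets across patients.

    ``tables`` maps patient id -> {"nostim": table, "poststim": table}
    (either may be absent).  The "eeg", "eeg+spikes" and "spikes" sets run
    on the stimulation-free table; "poststim" runs on the post-stimulation
    table.  Returns per-patient AUROCs, cohort medians, a paired sign test
    of PvT vs RvF within each set, and PvT sign tests of "eeg" against
    each other set.
    """
    records = []
    for pid, tabs in tables.items():
        for fset, tkey in (
            ("eeg", "nostim"),
            ("eeg+spikes", "nostim"),
            ("spikes", "nostim"),
            ("poststim", "poststim"),
        ):
            tab = tabs.get(tkey)
            if tab is None:
                continue
            for contrast in contrasts:
                try:
                    rep = fit_eval_classifier(tab, contrast, fset, seed, n_folds)
                    if n_perm > 0:
                        rep = permutation_significance(
                            tab, contrast, fset, n_perm, seed, n_folds, rep
                        )
                except DegenerateContrastError:
                    continue
                records.append(
                    {
                        "patient": pid,
                        "feature_set": fset,
                        "contrast": contrast,
                        "mean_auc": rep.mean_auc,
                        "p_value": rep.p_value,
                    }
                )
    frame = pd.DataFrame(records)
    out: dict = {"per_patient": frame}
    if frame.empty:
        return out
    out["cohort_median_auc"] = (
        frame.groupby(["feature_set", "contrast"])["mean_auc"]
        .median()
        .unstack()
    )
    pvt_rvf = {}
    for fset, grp in frame.groupby("feature_set"):
        wide = grp.pivot(index="patient", columns="contrast", values="mean_auc")
        if {"PvT", "RvF"} <= set(wide.columns):
            diff = (wide["PvT"] - wide["RvF"]).dropna()
            n_pos = int((diff > 0).sum())
            n_neg = int((diff < 0).sum())
            if n_pos + n_neg:
                pvt_rvf[fset] = {
                    "n_pos": n_pos,
                    "n_neg": n_neg,
                    "p": sign_test_two_tailed(n_pos, n_neg),
                }
    out["pvt_vs_rvf_sign_tests"] = pvt_rvf
    pvt = frame[frame["contrast"] == "PvT"].pivot(
        index="patient", columns="feature_set", values="mean_auc"
    )
    vs_eeg = {}
    for fset in ("spikes", "poststim", "eeg+spikes"):
        if "eeg" in pvt.columns and fset in pvt.columns:
            diff = (pvt["eeg"] - pvt[fset]).dropna()
            n_pos, n_neg = int((diff > 0).sum()), int((diff < 0).sum())
            if n_pos + n_neg:
                vs_eeg[fset] = {
                    "n_pos": n_pos,
                    "n_neg": n_neg,
                    "p": sign_test_two_tailed(n_pos, n_neg),
                }
    out["eeg_vs_other_sign_tests"] = vs_eeg
    return out
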