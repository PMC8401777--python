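"""Tanimoto / MMP kernel SVM classifiers and MMS-wise evaluation.

The decision function follows the convention

    f(x) = sign( sum_i alpha_i y_i K(sv_i, x) - b )

with ``alpha_i y_i`` stored as ``dual_coefs_`` and the bias ``b`` as
``bias_`` (note the minus sign; the backing solver's intercept is
reconciled to this convention at fit time).

Estimators follow the scikit-learn protocol (``fit`` / ``predict`` /
``decision_function`` / ``get_params``), but take lists of sparse
fingerprint objects rather than numeric arrays: the Gram matrix is
computed internally and handed to a precomputed-kernel SVC.  The
positive class (label 1) is the activity cliff.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Callable, Hashable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import matthews_corrcoef, recall_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import ConfigurationError
from .fingerprints import MMPFingerprint, build_universe, fingerprint_mmp
from .fragmentation import MMS, MMP
from .data_model import PairLabel

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


def tanimoto_kernel(u: frozenset | set, v: frozenset | set) -> float:
    """Tanimoto set similarity |u&v| / (|u| + |v| - |u&v|).

    The empty-vs-anything case (0/0 denominator included) is defined as
    0: similarity is never asserted from the absence of features.
    """
    inter = len(u & v)
    denom = len(u) + len(v) - inter
    return inter / denom if denom else 0.0


def mmp_kernel(x: MMPFingerprint, z: MMPFingerprint) -> float:
    """Product of core-wise and substituent-wise Tanimoto kernels."""
    return tanimoto_kernel(x.core_ids, z.core_ids) * tanimoto_kernel(x.sub_ids, z.sub_ids)


def gram_matrix(
    X: Sequence, Z: Sequence | None = None, kernel: Callable = mmp_kernel
) -> np.ndarray:
    """Pairwise kernel matrix K[i, j] = kernel(X[i], Z[j])."""
    if Z is None:
        n = len(X)
        K = np.empty((n, n))
        for i in range(n):
            K[i, i] = kernel(X[i], X[i])
            for j in range(i + 1, n):
                K[i, j] = K[j, i] = kernel(X[i], X[j])
        return K
    K = np.empty((len(X), len(Z)))
    for i, xi in enumerate(X):
        for j, zj in enumerate(Z):
            K[i, j] = kernel(xi, zj)
    return K


class _PrecomputedKernelSVC(BaseEstimator, ClassifierMixin):
    """Maximum-margin classifier on a precomputed set-similarity kernel.

    Parameters
    ----------
    C_grid : sequence of float
        Box-constraint candidates; a single value disables the search.
    cv : int
        Folds for the stratified cross-validated C search (MCC score).
    random_state : int or None
        Seed for the CV shuffling; fixes the chosen C and dual solution.
    """

    kernel_name = "abstract"

    def __init__(self, C_grid=DEFAULT_C_GRID, cv: int = 5, random_state=None):
        self.C_grid = C_grid
        self.cv = cv
        self.random_state = random_state

    def _kernel(self, a, b) -> float:  # pragma: no cover - overridden
        raise NotImplementedError

    def _gram(self, X, Z=None) -> np.ndarray:
        return gram_matrix(X, Z, kernel=self._kernel)

    def fit(self, X: Sequence, y):
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly two classes in y, got {classes}")
        if set(classes) != {0, 1}:
            raise ValueError("labels must be 0 (non-AC) and 1 (AC)")

        K = self._gram(X)
        grid = [float(c) for c in np.atleast_1d(np.asarray(self.C_grid, dtype=float))]
        self.C_ = grid[0] if len(grid) == 1 else self._select_C(K, y, grid)

        svc = SVC(kernel="precomputed", C=self.C_)
        svc.fit(K, y)
        support = svc.support_
        self.support_fingerprints_ = [X[i] for i in support]
        self.dual_coefs_ = svc.dual_coef_.ravel().copy()
        # sklearn: decision = sum dual_coef * K + intercept; ours: ... - bias
        self.bias_ = float(-svc.intercept_[0])
        self.n_support_ = len(support)
        self.classes_ = np.array([0, 1])
        return self

    def _select_C(self, K: np.ndarray, y: np.ndarray, grid: list[float]) -> float:
        min_class = int(np.bincount(y).min())
        n_splits = min(self.cv, min_class)
        if n_splits < 2:
            chosen = grid[len(grid) // 2]
            logger.warning(
                "too few samples per class for CV; fixing C=%.3g", chosen
            )
            return chosen
        skf = StratifiedKFold(
            n_splits=n_splits, shuffle=True, random_state=self.random_state
        )
        best = (-np.inf, np.inf)  # (mcc, -(-C)) -> prefer high MCC, small C
        best_C = grid[0]
        for C in grid:
            preds = np.empty_like(y)
            for tr, te in skf.split(np.zeros(len(y)), y):
                svc = SVC(kernel="precomputed", C=C)
                svc.fit(K[np.ix_(tr, tr)], y[tr])
                preds[te] = svc.predict(K[np.ix_(te, tr)])
            score = matthews_corrcoef(y, preds) if len(set(preds)) > 1 else 0.0
            if (score, -C) > best:
                best = (score, -C)
                best_C = C
        return best_C

    def decision_function(self, X: Sequence) -> np.ndarray:
        K = self._gram(X, self.support_fingerprints_)
        return K @ self.dual_coefs_ - self.bias_

    def predict(self, X: Sequence) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


class TanimotoKernelSVC(_PrecomputedKernelSVC):
    """SVM with the plain Tanimoto kernel over sparse bit sets."""

    kernel_name = "tanimoto"

    def _kernel(self, a, b) -> float:
        return tanimoto_kernel(a, b)


class MMPKernelSVC(_PrecomputedKernelSVC):
    """SVM with the MMP kernel (core x substituent Tanimoto product)."""

    kernel_name = "mmp"

    def _kernel(self, a, b) -> float:
        return mmp_kernel(a, b)


def train(
    fingerprints: Sequence[MMPFingerprint],
    labels: Sequence[int],
    C_grid=DEFAULT_C_GRID,
    cv_folds: int = 5,
    seed: int | None = None,
) -> MMPKernelSVC:
    """Fit an MMP-kernel SVM; thin functional wrapper over the estimator."""
    model = MMPKernelSVC(C_grid=C_grid, cv=cv_folds, random_state=seed)
    return model.fit(fingerprints, labels)


def metrics(y_true, y_pred, decision_values) -> tuple[float, float, float]:
    """(recall, AUC ROC, MCC) with AC as the positive class.

    MCC is 0 by convention when a confusion-matrix margin is zero; AUC is
    NaN when only one class is present in ``y_true``.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    decision_values = np.asarray(decision_values, dtype=float)
    if len(y_true) != len(y_pred) or len(y_true) != len(decision_values):
        raise ValueError("length mismatch")
    recall = recall_score(y_true, y_pred, pos_label=1, zero_division=0.0)
    auc = (
        roc_auc_score(y_true, decision_values)
        if len(np.unique(y_true)) == 2
        else float("nan")
    )
    mcc = matthews_corrcoef(y_true, y_pred)
    return float(recall), float(auc), float(mcc)


@dataclass
class EvalReport:
    """Pooled MMS leave-one-out predictions and aggregate metrics."""

    predictions: pd.DataFrame
    recall: float
    auc_roc: float
    mcc: float
    n_folds: int
    n_skipped_folds: int
    n_eliminated: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "recall": self.recall,
                "auc_roc": self.auc_roc,
                "mcc": self.mcc,
                "n_folds": self.n_folds,
                "n_skipped_folds": self.n_skipped_folds,
                "n_eliminated": self.n_eliminated,
            },
            allow_nan=True,
        )


def _compound_ids(mmps: Sequence[MMP]) -> set[str]:
    out: set[str] = set()
    for m in mmps:
        out.add(m.cpd_low.cid)
        out.add(m.cpd_high.cid)
    return out


def mms_loo_evaluate(
    mms_list: Sequence[MMS],
    C_grid=DEFAULT_C_GRID,
    seed: int | None = None,
    cv_folds: int = 5,
) -> EvalReport:
    """Leave-one-series-out evaluation with compound-overlap elimination.

    Each MMS in turn is the test set and the remaining series form the
    training set.  Test MMPs containing any compound that also occurs in
    a training MMP are eliminated, so neither a core nor a compound is
    ever shared across the train/test boundary.  The feature universe and
    the model are rebuilt per fold from training data only; predictions
    are pooled over folds before computing recall, AUC ROC and MCC.
    """
    if len(mms_list) < 2:
        raise ValueError("MMS-wise leave-one-out needs at least two series")

    rows = []
    n_skipped = 0
    n_eliminated = 0
    for k, test_mms in enumerate(mms_list):
        train_mmps = [m for i, s in enumerate(mms_list) if i != k for m in s.mmps]
        train_cpds = _compound_ids(train_mmps)
        test_mmps = [
            m
            for m in test_mms.mmps
            if m.cpd_low.cid not in train_cpds and m.cpd_high.cid not in train_cpds
        ]
        n_eliminated += len(test_mms.mmps) - len(test_mmps)
        if not test_mmps:
            logger.info("fold %d (%s): empty test set after elimination", k, test_mms.core_key)
            n_skipped += 1
            continue
        train_cores = {m.core for m in train_mmps}
        assert test_mms.core_key not in train_cores
        assert not (_compound_ids(test_mmps) & train_cpds)

        y_train = np.array([int(m.label is PairLabel.AC) for m in train_mmps])
        if len(np.unique(y_train)) < 2:
            logger.info("fold %d: single-class training set, skipped", k)
            n_skipped += 1
            continue
        universe = build_universe(train_mmps)
        X_train = [fingerprint_mmp(m, universe) for m in train_mmps]
        X_test = [fingerprint_mmp(m, universe) for m in test_mmps]
        model = MMPKernelSVC(C_grid=C_grid, cv=cv_folds, random_state=seed)
        model.fit(X_train, y_train)
        decision = model.decision_function(X_test)
        for m, d in zip(test_mmps, decision):
            rows.append(
                {
                    "mmp_id": m.mmp_id,
                    "mms_core": test_mms.core_key,
                    "decision_value": float(d),
                    "y_pred": int(d > 0),
                    "y_true": int(m.label is PairLabel.AC),
                }
            )

    predictions = pd.DataFrame(
        rows, columns=["mmp_id", "mms_core", "decision_value", "y_pred", "y_true"]
    )
    if len(predictions):
        recall, auc, mcc = metrics(
            predictions["y_true"], predictions["y_pred"], predictions["decision_value"]
        )
    else:
        recall = auc = mcc = float("nan")
    return EvalReport(
        predictions=predictions,
        recall=recall,
        auc_roc=auc,
        mcc=mcc,
        n_folds=len(mms_list),
        n_skipped_folds=n_skipped,
        n_eliminated=n_eliminated,
    )


# ---------------------------------------------------------------------------
# model (de)serialization


def _encode_token(token: Hashable):
    if isinstance(token, tuple):
        return ["t", list(token)]
    return ["v", token]


def _decode_token(obj) -> Hashable:
    kind, value = obj
    return tuple(value) if kind == "t" else value


def save_model(model: _PrecomputedKernelSVC, path) -> None:
    """Persist a fitted model (support sets, dual coefficients, bias) as JSON."""
    svs = []
    for fp in model.support_fingerprints_:
        if isinstance(fp, MMPFingerprint):
            svs.append(
                {
                    "core": [_encode_token(t) for t in sorted(fp.core_ids, key=repr)],
                    "sub": [_encode_token(t) for t in sorted(fp.sub_ids, key=repr)],
                    "mmp_id": fp.mmp_id,
                }
            )
        else:
            svs.append({"bits": [_encode_token(t) for t in sorted(fp, key=repr)]})
    payload = {
        "format": "mmpcliff-model",
        "version": 1,
        "kernel": model.kernel_name,
        "C": model.C_,
        "bias": model.bias_,
        "dual_coefs": model.dual_coefs_.tolist(),
        "support_vectors": svs,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> _PrecomputedKernelSVC:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != "mmpcliff-model":
        raise ConfigurationError(f"not an mmpcliff model file: {path}")
    cls = {"tanimoto": TanimotoKernelSVC, "mmp": MMPKernelSVC}[payload["kernel"]]
    model = cls(C_grid=(payload["C"],))
    model.C_ = payload["C"]
    model.bias_ = payload["bias"]
    model.dual_coefs_ = np.asarray(payload["dual_coefs"], dtype=float)
    svs = []
    for sv in payload["support_vectors"]:
        if "bits" in sv:
            svs.append(frozenset(_decode_token(t) for t in sv["bits"]))
        else:
            svs.append(
                MMPFingerprint(
                    core_ids=frozenset(_decode_token(t) for t in sv["core"]),
                    sub_ids=frozenset(_decode_token(t) for t in sv["sub"]),
                    mmp_id=sv.get("mmp_id"),
                )
            )
    model.support_fingerprints_ = svs
    model.n_support_ = len(svs)
    model.classes_ = np.array([0, 1])
    return model
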