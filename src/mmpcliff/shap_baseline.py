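"""Kernel SHAP explainer used as a model-independent control.

The explainer approximates the decision function locally by a linear
model ``g(x') = phi0 + sum_i phi_i x'_i`` over binary coalition vectors
``x'``, where ``phi_i`` estimates the Shapley value of feature ``i``.
Coalitions are enumerated exhaustively when feasible and otherwise
sampled in proportion to the Shapley kernel weight

    w(z) = (N - 1) / ( C(N, z) * z * (N - z) )

for a coalition of size ``z`` out of ``N`` features.  Off-coalition
features are replaced by values drawn from background (training)
instances — sampling from the marginal distribution — and the model
output is averaged over the background.  The baseline ``phi0`` is the
mean decision value over the background.  The full and empty coalitions
enter as hard constraints, not as sampled rows, so local accuracy
(``phi0 + sum phi_i`` = explained decision value) holds exactly under
exhaustive enumeration.

This module explains fingerprint bits through the same presence/absence
semantics the exact decomposition uses, which makes the two attributions
directly comparable feature by feature — including SHAP's tendency to
put weight on features *absent* from the explained instance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Hashable, Sequence

import numpy as np
import pandas as pd

from .fingerprints import MMPFingerprint
from .kernel_svm import _PrecomputedKernelSVC

logger = logging.getLogger(__name__)

DEFAULT_N_SAMPLES = 2048
DEFAULT_FEATURE_CAP = 64


def shap_kernel_weight(coalition_size: int, n_features: int) -> float:
    """Shapley kernel weight of a coalition of the given size.

    Defined for 0 < z < N; the empty and full coalitions carry infinite
    weight and are handled as hard constraints by the explainer.
    """
    z, n = coalition_size, n_features
    if not 0 < z < n:
        raise ValueError(f"coalition size must satisfy 0 < z < N, got z={z}, N={n}")
    return (n - 1) / (math.comb(n, z) * z * (n - z))


@dataclass
class ShapExplanation:
    """Shapley-value attribution of one prediction.

    ``phis[i]`` is the Shapley value of feature ``i`` in the feature
    list used for the explanation; ``features_present`` is the 0/1 mask
    of the explained instance over that list.
    """

    phi0: float
    phis: np.ndarray
    n_samples: int
    features_present: np.ndarray
    feature_names: list | None = None
    fx: float = float("nan")

    @property
    def local_accuracy_gap(self) -> float:
        return abs(self.phi0 + float(self.phis.sum()) - self.fx)


class KernelShapExplainer:
    """Kernel SHAP over a black-box function of binary feature vectors.

    Parameters
    ----------
    predict_fn : callable
        Maps an (m, N) 0/1 array to m decision values.
    background : array-like, shape (B, N)
        Training instances that define the marginal distribution of
        absent features and the baseline.
    seed : int, optional
        Seed for coalition sampling.
    """

    def __init__(self, predict_fn: Callable, background, seed: int | None = None):
        self.predict_fn = predict_fn
        self.background = np.asarray(background, dtype=float)
        if self.background.ndim != 2 or not len(self.background):
            raise ValueError("background must be a non-empty 2-D array")
        self.rng = np.random.default_rng(seed)

    def explain(self, x, n_samples: int = DEFAULT_N_SAMPLES) -> ShapExplanation:
        x = np.asarray(x, dtype=float)
        n = x.shape[0]
        if n == 0:
            raise ValueError("cannot explain an instance with zero features")
        if n != self.background.shape[1]:
            raise ValueError("instance and background dimensionality differ")

        phi0 = float(np.mean(self.predict_fn(self.background)))
        fx = float(self.predict_fn(x[None, :])[0])

        if n == 1:
            phis = np.array([fx - phi0])
            return ShapExplanation(phi0, phis, 0, x.astype(int), fx=fx)

        n_interior = 2**n - 2
        if n_interior <= n_samples:
            masks = self._all_masks(n)
            weights = np.array(
                [shap_kernel_weight(int(m.sum()), n) for m in masks]
            )
            used = len(masks)
        else:
            if n_samples < n + 2:
                raise ValueError(
                    f"n_samples={n_samples} too small for N={n} features (need >= N+2)"
                )
            masks = self._sample_masks(n, n_samples)
            weights = np.ones(len(masks))
            used = len(masks)

        ey = self._coalition_values(masks, x)
        phis = self._solve(masks, weights, ey, phi0, fx)
        return ShapExplanation(phi0, phis, used, x.astype(int), fx=fx)

    @staticmethod
    def _all_masks(n: int) -> np.ndarray:
        codes = np.arange(1, 2**n - 1, dtype=np.int64)
        return ((codes[:, None] >> np.arange(n)) & 1).astype(float)

    def _sample_masks(self, n: int, k: int) -> np.ndarray:
        sizes = np.arange(1, n)
        # P(z) proportional to kernel weight summed over coalitions of size z
        p = (n - 1) / (sizes * (n - sizes))
        p = p / p.sum()
        masks = np.zeros((k, n))
        zs = self.rng.choice(sizes, size=k, p=p)
        for row, z in enumerate(zs):
            on = self.rng.choice(n, size=int(z), replace=False)
            masks[row, on] = 1.0
        return masks

    def _coalition_values(self, masks: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Mean model output with off-coalition features from the background."""
        B = self.background
        ey = np.empty(len(masks))
        for i, m in enumerate(masks):
            rows = B * (1 - m) + x * m
            ey[i] = float(np.mean(self.predict_fn(rows)))
        return ey

    @staticmethod
    def _solve(masks, weights, ey, phi0, fx) -> np.ndarray:
        """Weighted least squares with the sum constraint eliminated."""
        n = masks.shape[1]
        target = ey - phi0 - masks[:, -1] * (fx - phi0)
        design = masks[:, :-1] - masks[:, -1:]
        w = np.sqrt(weights)
        sol, *_ = np.linalg.lstsq(design * w[:, None], target * w, rcond=None)
        phis = np.empty(n)
        phis[:-1] = sol
        phis[-1] = (fx - phi0) - sol.sum()
        return phis


def mmp_feature_space(
    model: _PrecomputedKernelSVC,
    x: MMPFingerprint,
    cap: int = DEFAULT_FEATURE_CAP,
) -> list[tuple[str, Hashable]]:
    """Feature list for a SHAP explanation of an MMP-kernel model.

    The space is the union of the instance's features and those active
    in at least one support vector, deterministically ordered and capped
    (instance features are kept preferentially) with a warning.
    """
    instance = [("core", t) for t in sorted(x.core_ids, key=repr)] + [
        ("sub", t) for t in sorted(x.sub_ids, key=repr)
    ]
    sv_core: set = set()
    sv_sub: set = set()
    for sv in model.support_fingerprints_:
        sv_core |= sv.core_ids
        sv_sub |= sv.sub_ids
    extra = [("core", t) for t in sorted(sv_core - x.core_ids, key=repr)] + [
        ("sub", t) for t in sorted(sv_sub - x.sub_ids, key=repr)
    ]
    features = instance + extra
    if len(features) > cap:
        logger.warning(
            "SHAP feature space capped at %d of %d features", cap, len(features)
        )
        features = features[:cap]
    return features


def _fingerprint_to_vector(fp: MMPFingerprint, features) -> np.ndarray:
    vec = np.zeros(len(features))
    for i, (segment, token) in enumerate(features):
        present = token in (fp.core_ids if segment == "core" else fp.sub_ids)
        vec[i] = float(present)
    return vec


def explain_mmp_shap(
    model: _PrecomputedKernelSVC,
    x: MMPFingerprint,
    background: Sequence[MMPFingerprint],
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int | None = None,
    cap: int = DEFAULT_FEATURE_CAP,
) -> ShapExplanation:
    """Kernel SHAP explanation of one MMP prediction.

    Binary coalition vectors are mapped back to fingerprint-like feature
    sets and pushed through the model's decision function; the
    background is the training-fold fingerprints.
    """
    features = mmp_feature_space(model, x, cap=cap)

    def predict(matrix: np.ndarray) -> np.ndarray:
        fps = []
        for row in np.atleast_2d(matrix):
            core = frozenset(t for (seg, t), v in zip(features, row) if seg == "core" and v > 0.5)
            sub = frozenset(t for (seg, t), v in zip(features, row) if seg == "sub" and v > 0.5)
            fps.append(MMPFingerprint(core_ids=core, sub_ids=sub))
        return model.decision_function(fps)

    bg = np.array([_fingerprint_to_vector(fp, features) for fp in background])
    explainer = KernelShapExplainer(predict, bg, seed=seed)
    expl = explainer.explain(_fingerprint_to_vector(x, features), n_samples=n_samples)
    expl.feature_names = features
    return expl


def force_report(expl: ShapExplanation) -> pd.DataFrame:
    """Shapley values ordered by magnitude, annotated with presence bits.

    Nonzero Shapley values on *absent* features are the phenomenon this
    control exposes: the explanation can lean on substructures that are
    not in the molecule at all.
    """
    order = np.argsort(-np.abs(expl.phis))
    names = expl.feature_names or [f"f{i}" for i in range(len(expl.phis))]
    return pd.DataFrame(
        {
            "feature": [repr(names[i]) for i in order],
            "present": [int(expl.features_present[i]) for i in order],
            "shapley_value": [float(expl.phis[i]) for i in order],
        }
    )


def plot_force(expl: ShapExplanation, path) -> None:
    """Horizontal force-plot-style bar chart of the Shapley values."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = force_report(expl)
    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(report))))
    colors = ["#d73027" if v > 0 else "#4575b4" for v in report["shapley_value"]]
    ax.barh(range(len(report)), report["shapley_value"], color=colors)
    ax.set_yticks(range(len(report)))
    ax.set_yticklabels(
        [f"{f} ({p})" for f, p in zip(report["feature"], report["present"])],
        fontsize=6,
    )
    ax.invert_yaxis()
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Shapley value")
    ax.set_title(f"baseline={expl.phi0:.3f}  output={expl.fx:.3f}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
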