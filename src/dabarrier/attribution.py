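"""Shapley-value feature attribution for the trained barrier models.

Shapley values distribute the deviation of a sample's prediction from the
background-mean prediction across the input features, satisfying the
efficiency, dummy and symmetry axioms.  Two routes are provided:

* ``exact_shapley`` -- brute-force coalition enumeration (2^k value-function
  evaluations) against an interventional (background-replacement) value
  function.  Works for any predictor; the correctness anchor.
* ``fast_shapley`` -- the same quantity for tree ensembles, computed by the
  closed-form per-leaf algorithm in :mod:`._treeshap`; polynomial in the
  tree size so it scales to the full descriptor set.

Attributions are in the target's units (kcal/mol for activation barriers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._treeshap import tree_ensemble_shapley

__all__ = [
    "AttributionResult",
    "exact_shapley",
    "fast_shapley",
    "rank_features",
    "shap_feature_reduction",
    "export_summary",
    "correlation_matrix",
]

_MAX_EXACT_FEATURES = 12


@dataclass
class AttributionResult:
    """Per-sample per-feature Shapley values plus the global ranking.

    ``phi`` has shape (n_samples, n_features); ``base_value`` is the mean
    background prediction; ``base_value + phi.sum(axis=1)`` reproduces the
    model's predictions (efficiency).  ``global_importance`` maps feature
    name -> mean |phi|.
    """

    phi: np.ndarray
    base_value: float
    feature_values: np.ndarray
    feature_names: List[str]
    predictions: np.ndarray

    @property
    def global_importance(self) -> Dict[str, float]:
        imp = np.abs(self.phi).mean(axis=0)
        return {name: float(v) for name, v in zip(self.feature_names, imp)}

    def efficiency_residuals(self) -> np.ndarray:
        return self.predictions - (self.base_value + self.phi.sum(axis=1))


def _as_predictor(model) -> Callable[[np.ndarray], np.ndarray]:
    if callable(model) and not hasattr(model, "predict"):
        return model
    return model.predict


def exact_shapley(
    model,
    samples: np.ndarray,
    background: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
    feature_subset: Optional[Sequence[int]] = None,
) -> AttributionResult:
    """Brute-force interventional Shapley values.

    ``model`` may be any object with ``.predict`` or a bare callable.
    ``feature_subset`` restricts attribution to the listed feature indices
    (at most 12; coalition enumeration is 2^k); features outside the
    subset always take their background values.  phi for excluded features
    is zero and efficiency then holds against v(full-subset).
    """
    predict = _as_predictor(model)
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    Z = np.atleast_2d(np.asarray(background, dtype=float))
    if len(Z) == 0:
        raise ValueError("background must be nonempty")
    n, d = X.shape
    subset = list(range(d)) if feature_subset is None else list(feature_subset)
    k = len(subset)
    if k > _MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact_shapley enumerates 2^k coalitions and is limited to "
            f"k <= {_MAX_EXACT_FEATURES} features (got {k}); use fast_shapley"
        )
    names = list(feature_names) if feature_names is not None else [f"x{i}" for i in range(d)]

    # weights w[s] = s!(k-s-1)!/k! for |S| = s
    fact = [1.0] * (k + 1)
    for i in range(2, k + 1):
        fact[i] = fact[i - 1] * i
    wt = [fact[s] * fact[k - 1 - s] / fact[k] for s in range(k)]

    phi = np.zeros((n, d))
    preds = predict(X)
    n_masks = 1 << k
    nz = len(Z)
    for i in range(n):
        # v(mask): mean over background rows of predict(hybrid); all
        # coalitions are evaluated in a single batched predict call
        H = np.tile(Z, (n_masks, 1))
        for j, fidx in enumerate(subset):
            masks_with_j = (np.arange(n_masks) >> j) & 1 == 1
            rows = np.repeat(masks_with_j, nz)
            H[rows, fidx] = X[i, fidx]
        v = np.asarray(predict(H), dtype=float).reshape(n_masks, nz).mean(axis=1)
        for j, fidx in enumerate(subset):
            bit = 1 << j
            total = 0.0
            for mask in range(1 << k):
                if mask & bit:
                    continue
                s = bin(mask).count("1")
                total += wt[s] * (v[mask | bit] - v[mask])
            phi[i, fidx] = total
    base_value = float(np.mean(predict(Z)))
    return AttributionResult(
        phi=phi,
        base_value=base_value,
        feature_values=X,
        feature_names=names,
        predictions=np.asarray(preds, dtype=float).ravel(),
    )


def fast_shapley(
    model,
    samples: np.ndarray,
    background: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
) -> AttributionResult:
    """Exact interventional Shapley values for a tree ensemble.

    Agrees with :func:`exact_shapley` (same value function) to float
    round-off; per-sample efficiency holds by construction.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    Z = np.atleast_2d(np.asarray(background, dtype=float))
    phi = tree_ensemble_shapley(model, X, Z)
    names = list(feature_names) if feature_names is not None else [f"x{i}" for i in range(X.shape[1])]
    return AttributionResult(
        phi=phi,
        base_value=float(np.mean(model.predict(Z))),
        feature_values=X,
        feature_names=names,
        predictions=np.asarray(model.predict(X), dtype=float).ravel(),
    )


def rank_features(result: AttributionResult) -> List[str]:
    """Features by descending mean |phi|; ties break alphabetically."""
    imp = result.global_importance
    if not imp:
        raise ValueError("empty attribution result")
    return sorted(imp, key=lambda name: (-imp[name], name))


def shap_feature_reduction(
    X: pd.DataFrame,
    y: np.ndarray,
    fit_fn: Callable[[pd.DataFrame, np.ndarray], object],
    threshold: Optional[float] = None,
    keep_k: Optional[int] = 13,
    n_explain: int = 128,
    background_size: int = 100,
    seed: int = 0,
):
    """Drop low-attribution features and retrain.

    Fits the full-feature model with ``fit_fn(X, y)``, computes global
    mean-|phi| importance on a seeded subsample, then keeps the top
    ``keep_k`` features (or, when ``threshold`` is given, all features
    with importance >= threshold) and retrains.  Returns
    (kept_features, reduced_model, full_result, reduced_X).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFE]))
    full_model = fit_fn(X, y)
    idx = rng.choice(len(X), size=min(n_explain, len(X)), replace=False)
    bg = rng.choice(len(X), size=min(background_size, len(X)), replace=False)
    res = fast_shapley(
        full_model,
        X.to_numpy(float)[idx],
        X.to_numpy(float)[bg],
        feature_names=list(X.columns),
    )
    ranking = rank_features(res)
    imp = res.global_importance
    if threshold is not None:
        kept = [f for f in ranking if imp[f] >= threshold]
    else:
        kept = ranking[: keep_k if keep_k is not None else len(ranking)]
    # preserve the original column order
    kept = [f for f in X.columns if f in kept]
    if len(kept) < 2:
        raise ValueError(
            f"feature reduction would keep {len(kept)} features; need >= 2"
        )
    X_red = X[kept]
    reduced_model = fit_fn(X_red, y)
    return kept, reduced_model, res, X_red


def export_summary(result: AttributionResult, path=None) -> pd.DataFrame:
    """Long-format table for beeswarm-style summary plots.

    One row per (sample, feature): Shapley value, the feature's raw value
    (drives the colour gradient in a summary plot) and the feature's
    global rank.  Written as CSV when *path* is given.
    """
    if result.phi.size == 0:
        raise ValueError("empty attribution result")
    ranking = rank_features(result)
    rank_of = {f: r for r, f in enumerate(ranking, start=1)}
    n, d = result.phi.shape
    frame = pd.DataFrame(
        {
            "sample": np.repeat(np.arange(n), d),
            "feature": np.tile(np.asarray(result.feature_names, dtype=object), n),
            "phi": result.phi.ravel(),
            "feature_value": result.feature_values.ravel(),
            "global_rank": [rank_of[f] for f in np.tile(result.feature_names, n)],
        }
    )
    if path is not None:
        frame.to_csv(path, index=False)
    return frame


def correlation_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix over the feature columns."""
    return X.corr(method="pearson")
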