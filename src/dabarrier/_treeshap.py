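"""Exact interventional Shapley values for tree ensembles.

For a decision tree and a single background row z, the value function
v(S) = f(hybrid), where the hybrid takes the explained sample's values on
the coalition S and z's values elsewhere, is a sum over leaves of
"conjunction games": a leaf is reached by the hybrid iff every path
feature on which x and z disagree is drawn from the right source.  Writing
A for the path features that *must* be in S (z fails the leaf's interval,
x passes) and B for those that must be out (x fails, z passes), the leaf
contributes its value w times

    phi_i = +w (a-1)! b! / (a+b)!   for i in A,
    phi_i = -w a! (b-1)! / (a+b)!   for i in B,      a=|A|, b=|B|,

and nothing to any other feature (dummy players drop out of the Shapley
average).  A leaf where some feature fails for both x and z is unreachable
for every coalition and contributes nothing.  Summing over leaves,
background rows and trees gives the exact interventional Shapley values --
the same quantity the brute-force coalition enumeration computes, in time
polynomial in the tree size.

The traversal enumerates only hybrid-reachable paths: at a split where x
and z agree it follows one child; where they disagree it branches, keeping
a per-feature requirement state (+1 in S / -1 out of S) and pruning
contradictions.  The kernel is numba-compiled when numba is available.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

__all__ = ["tree_ensemble_shapley", "extract_trees"]

_MAX_PATH_FEATURES = 64


def _coefficient_tables(kmax: int = _MAX_PATH_FEATURES):
    """C_plus[a, b] = (a-1)! b! / (a+b)!,  C_minus[a, b] = a! (b-1)! / (a+b)!."""
    cp = np.zeros((kmax, kmax))
    cm = np.zeros((kmax, kmax))
    for a in range(kmax):
        for b in range(kmax):
            if a >= 1:
                cp[a, b] = math.exp(
                    math.lgamma(a) + math.lgamma(b + 1) - math.lgamma(a + b + 1)
                )
            if b >= 1:
                cm[a, b] = math.exp(
                    math.lgamma(a + 1) + math.lgamma(b) - math.lgamma(a + b + 1)
                )
    return cp, cm


_CP, _CM = _coefficient_tables()


@njit(cache=True)
def _tree_shap_kernel(
    children_left,
    children_right,
    feature,
    threshold,
    leaf_value,
    X,
    Z,
    weight,
    cp,
    cm,
    phi,
):  # pragma: no cover - compiled
    n_x, n_feat = X.shape
    n_z = Z.shape[0]
    n_nodes = children_left.shape[0]
    max_stack = n_nodes + 2

    node_stack = np.empty(max_stack, dtype=np.int64)
    a_stack = np.empty(max_stack, dtype=np.int64)
    b_stack = np.empty(max_stack, dtype=np.int64)
    state_stack = np.zeros((max_stack, n_feat), dtype=np.int8)
    state_cur = np.zeros(n_feat, dtype=np.int8)

    inv_z = weight / n_z
    for ix in range(n_x):
        for iz in range(n_z):
            node_stack[0] = 0
            a_stack[0] = 0
            b_stack[0] = 0
            state_stack[0, :] = 0
            ssize = 1
            while ssize > 0:
                ssize -= 1
                node = node_stack[ssize]
                a = a_stack[ssize]
                b = b_stack[ssize]
                state_cur[:] = state_stack[ssize, :]
                while children_left[node] != -1:
                    f = feature[node]
                    thr = threshold[node]
                    x_left = X[ix, f] <= thr
                    z_left = Z[iz, f] <= thr
                    if x_left == z_left:
                        node = children_left[node] if x_left else children_right[node]
                        continue
                    x_child = children_left[node] if x_left else children_right[node]
                    z_child = children_left[node] if z_left else children_right[node]
                    st = state_cur[f]
                    if st == 1:
                        # f already committed to S: z-side is contradictory
                        node = x_child
                    elif st == -1:
                        node = z_child
                    else:
                        # defer the branch that keeps f out of S
                        node_stack[ssize] = z_child
                        a_stack[ssize] = a
                        b_stack[ssize] = b + 1
                        state_stack[ssize, :] = state_cur
                        state_stack[ssize, f] = -1
                        ssize += 1
                        # continue on x's side with f committed to S
                        a += 1
                        state_cur[f] = 1
                        node = x_child
                # leaf
                if a > 0 or b > 0:
                    w = leaf_value[node] * inv_z
                    for f in range(n_feat):
                        st = state_cur[f]
                        if st == 1:
                            phi[ix, f] += w * cp[a, b]
                        elif st == -1:
                            phi[ix, f] -= w * cm[a, b]


def extract_trees(model):
    """Normalise a fitted sklearn tree model/ensemble into
    (list of tree arrays, per-tree weight, constant offset)."""
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
    from sklearn.tree import DecisionTreeRegressor

    if isinstance(model, RandomForestRegressor):
        trees = [est.tree_ for est in model.estimators_]
        return trees, 1.0 / len(trees), 0.0
    if isinstance(model, GradientBoostingRegressor):
        trees = [stage[0].tree_ for stage in model.estimators_]
        offset = float(model._raw_predict_init(np.zeros((1, model.n_features_in_))).ravel()[0])
        return trees, float(model.learning_rate), offset
    if isinstance(model, DecisionTreeRegressor):
        return [model.tree_], 1.0, 0.0
    raise TypeError(
        f"tree Shapley attribution supports RandomForestRegressor, "
        f"GradientBoostingRegressor and DecisionTreeRegressor; got {type(model).__name__}"
    )


def tree_ensemble_shapley(model, X: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Interventional Shapley values phi with shape (len(X), n_features).

    ``base + phi.sum(1) == model.predict(X)`` with
    ``base = model.predict(background).mean()`` (efficiency), up to float
    round-off.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    Z = np.ascontiguousarray(np.asarray(background, dtype=np.float64))
    if X.ndim != 2 or Z.ndim != 2 or X.shape[1] != Z.shape[1]:
        raise ValueError("X and background must be 2-D with matching width")
    if len(Z) == 0:
        raise ValueError("background must be nonempty")
    trees, weight, _offset = extract_trees(model)
    phi = np.zeros_like(X)
    for tree in trees:
        _tree_shap_kernel(
            tree.children_left.astype(np.int64),
            tree.children_right.astype(np.int64),
            tree.feature.astype(np.int64),
            tree.threshold.astype(np.float64),
            tree.value.ravel().astype(np.float64),
            X,
            Z,
            weight,
            _CP,
            _CM,
            phi,
        )
    return phi
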