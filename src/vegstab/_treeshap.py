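"""Exact Shapley values for decision-tree ensembles.

Implements the polynomial-time tree traversal that computes, for every
feature, its exact Shapley contribution to a tree's cover-weighted
conditional expectation. Supports scikit-learn decision trees and
gradient-boosting regressors. Attributions satisfy local accuracy:
``base_value + phi.sum() == model.predict(x)`` to floating-point precision.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.tree import DecisionTreeRegressor

try:  # optional compiled fast path; the pure-Python reference always works
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["shap_values", "tree_expectation"]


class _Tree:
    """Flat arrays of one regression tree plus per-node cover weights."""

    def __init__(self, sk_tree, scale: float = 1.0):
        t = sk_tree.tree_
        self.left = t.children_left
        self.right = t.children_right
        self.feature = t.feature
        self.threshold = t.threshold
        self.value = t.value[:, 0, 0] * scale
        self.cover = t.weighted_n_node_samples

    def expectation(self) -> float:
        """Cover-weighted expectation of the tree output (v of the empty set)."""
        total = 0.0
        stack = [(0, 1.0)]
        while stack:
            node, w = stack.pop()
            if self.left[node] < 0:
                total += w * self.value[node]
            else:
                for child in (self.left[node], self.right[node]):
                    stack.append((child, w * self.cover[child] / self.cover[node]))
        return total


def _extend(path: list, pz: float, po: float, pi: int) -> list:
    l = len(path)
    path = [row[:] for row in path]
    path.append([pi, pz, po, 1.0 if l == 0 else 0.0])
    for i in range(l - 1, -1, -1):
        path[i + 1][3] += po * path[i][3] * (i + 1) / (l + 1)
        path[i][3] = pz * path[i][3] * (l - i) / (l + 1)
    return path


def _unwind(path: list, i: int) -> list:
    l = len(path) - 1
    one, zero = path[i][2], path[i][1]
    path = [row[:] for row in path]
    n = path[l][3]
    for j in range(l - 1, -1, -1):
        if one != 0:
            t = path[j][3]
            path[j][3] = n * (l + 1) / ((j + 1) * one)
            n = t - path[j][3] * zero * (l - j) / (l + 1)
        else:
            path[j][3] = path[j][3] * (l + 1) / (zero * (l - j))
    for j in range(i, l):
        path[j][0], path[j][1], path[j][2] = path[j + 1][0], path[j + 1][1], path[j + 1][2]
    path.pop()
    return path


def _unwound_sum(path: list, i: int) -> float:
    l = len(path) - 1
    one, zero = path[i][2], path[i][1]
    total = 0.0
    n = path[l][3]
    if one != 0:
        for j in range(l - 1, -1, -1):
            tmp = n / ((j + 1) * one)
            total += tmp
            n = path[j][3] - tmp * zero * (l - j)
    else:
        for j in range(l - 1, -1, -1):
            total += path[j][3] / (zero * (l - j))
    return total * (l + 1)


def _tree_shap(tree: _Tree, x: np.ndarray, phi: np.ndarray) -> None:
    def recurse(node: int, path: list, pz: float, po: float, pi: int) -> None:
        path = _extend(path, pz, po, pi)
        if tree.left[node] < 0:
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                phi[path[i][0]] += w * (path[i][2] - path[i][1]) * tree.value[node]
            return
        f = int(tree.feature[node])
        if x[f] <= tree.threshold[node]:
            hot, cold = tree.left[node], tree.right[node]
        else:
            hot, cold = tree.right[node], tree.left[node]
        iz, io = 1.0, 1.0
        k = next((i for i in range(len(path)) if path[i][0] == f), -1)
        if k >= 0:
            iz, io = path[k][1], path[k][2]
            path = _unwind(path, k)
        recurse(hot, path, iz * tree.cover[hot] / tree.cover[node], io, f)
        recurse(cold, path, iz * tree.cover[cold] / tree.cover[node], 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)


if _HAVE_NUMBA:

    @njit
    def _recurse_nb(node, left, right, feat, thr, val, cov, x, phi, pd_, pz_, po_, pw_, plen, pz, po, pi):
        m = plen
        d = np.empty(m + 1, np.int64)
        z = np.empty(m + 1, np.float64)
        o = np.empty(m + 1, np.float64)
        w = np.empty(m + 1, np.float64)
        for i in range(m):
            d[i] = pd_[i]
            z[i] = pz_[i]
            o[i] = po_[i]
            w[i] = pw_[i]
        d[m] = pi
        z[m] = pz
        o[m] = po
        w[m] = 1.0 if m == 0 else 0.0
        for i in range(m - 1, -1, -1):
            w[i + 1] += po * w[i] * (i + 1) / (m + 1)
            w[i] = pz * w[i] * (m - i) / (m + 1)
        mlen = m + 1
        if left[node] < 0:
            for ii in range(1, mlen):
                ln = mlen - 1
                one = o[ii]
                zero = z[ii]
                total = 0.0
                if one != 0.0:
                    nxt = w[ln]
                    for jj in range(ln - 1, -1, -1):
                        tmp = nxt / ((jj + 1) * one)
                        total += tmp
                        nxt = w[jj] - tmp * zero * (ln - jj)
                else:
                    for jj in range(ln - 1, -1, -1):
                        total += w[jj] / (zero * (ln - jj))
                total *= ln + 1
                phi[d[ii]] += total * (o[ii] - z[ii]) * val[node]
            return
        fnode = feat[node]
        if x[fnode] <= thr[node]:
            hot, cold = left[node], right[node]
        else:
            hot, cold = right[node], left[node]
        iz = 1.0
        io = 1.0
        k = -1
        for i in range(mlen):
            if d[i] == fnode:
                k = i
                break
        if k >= 0:
            iz = z[k]
            io = o[k]
            ln = mlen - 1
            nxt = w[ln]
            for jj in range(ln - 1, -1, -1):
                if io != 0.0:
                    t = w[jj]
                    w[jj] = nxt * (ln + 1) / ((jj + 1) * io)
                    nxt = t - w[jj] * iz * (ln - jj) / (ln + 1)
                else:
                    w[jj] = w[jj] * (ln + 1) / (iz * (ln - jj))
            for jj in range(k, ln):
                d[jj] = d[jj + 1]
                z[jj] = z[jj + 1]
                o[jj] = o[jj + 1]
            mlen -= 1
        _recurse_nb(hot, left, right, feat, thr, val, cov, x, phi, d, z, o, w, mlen,
                    iz * cov[hot] / cov[node], io, fnode)
        _recurse_nb(cold, left, right, feat, thr, val, cov, x, phi, d, z, o, w, mlen,
                    iz * cov[cold] / cov[node], 0.0, fnode)

    @njit
    def _tree_shap_nb(left, right, feat, thr, val, cov, X, phi):
        e_i = np.empty(0, np.int64)
        e_f = np.empty(0, np.float64)
        for i in range(X.shape[0]):
            _recurse_nb(0, left, right, feat, thr, val, cov, X[i], phi[i],
                        e_i, e_f, e_f, e_f, 0, 1.0, 1.0, -1)


def _collect_trees(model) -> tuple[list[_Tree], float]:
    """Extract (trees, constant offset) so prediction = offset + sum(tree(x))."""
    if isinstance(model, DecisionTreeRegressor):
        return [_Tree(model)], 0.0
    if isinstance(model, GradientBoostingRegressor):
        lr = model.learning_rate
        trees = [_Tree(est, scale=lr) for est in model.estimators_[:, 0]]
        if model.init_ == "zero":
            offset = 0.0
        else:
            n_feat = model.n_features_in_
            offset = float(model.init_.predict(np.zeros((1, n_feat)))[0])
        return trees, offset
    raise TypeError(f"unsupported model type {type(model).__name__}")


def tree_expectation(model) -> float:
    """Cover-weighted expected prediction of the ensemble (the base value)."""
    trees, offset = _collect_trees(model)
    return offset + sum(t.expectation() for t in trees)


def shap_values(model, X: np.ndarray, engine: str = "auto") -> tuple[np.ndarray, float]:
    """Exact per-sample, per-feature Shapley values for a tree ensemble.

    Returns ``(phi, base_value)`` with ``phi`` of shape
    ``(n_samples, n_features)`` and ``base_value + phi[i].sum()`` equal to
    ``model.predict(X[i])`` for every sample. ``engine`` selects the
    numba-compiled fast path ("numba"), the pure-Python reference
    ("python"), or whichever is available ("auto"); both produce identical
    values.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples, features)")
    if engine not in ("auto", "numba", "python"):
        raise ValueError("engine must be 'auto', 'numba' or 'python'")
    if engine == "numba" and not _HAVE_NUMBA:
        raise RuntimeError("numba is not available")
    use_numba = _HAVE_NUMBA and engine in ("auto", "numba")
    trees, offset = _collect_trees(model)
    base = offset + sum(t.expectation() for t in trees)
    phi = np.zeros_like(X)
    for t in trees:
        if use_numba:
            _tree_shap_nb(
                t.left.astype(np.int64),
                t.right.astype(np.int64),
                t.feature.astype(np.int64),
                t.threshold.astype(np.float64),
                t.value.astype(np.float64),
                t.cover.astype(np.float64),
                X,
                phi,
            )
        else:
            for i in range(X.shape[0]):
                _tree_shap(t, X[i], phi[i])
    return phi, float(base)
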