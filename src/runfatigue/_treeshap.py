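"""Exact path-dependent TreeSHAP for scikit-learn random forests.

Implements the polynomial-time tree-traversal algorithm for Shapley
values of tree ensembles (the "tree-path-dependent" formulation: absent
features are marginalised over the training cover of each split, with no
background dataset). For every observation the attributions satisfy
local accuracy exactly: base value + sum of per-feature SHAP values
equals the forest's predicted probability of the positive class.

The inner loops are numba-compiled; the recursion is unrolled into an
explicit stack with one path buffer per recursion depth.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forest_shap"]


@njit(cache=True)
def _tree_shap_obs(cl, cr, feat, thr, value, cover, x, phi,
                   pd_, pz_, po_, pw_, st_node, st_depth, st_plen, st_pz, st_po, st_pi):
    """Accumulate one tree's SHAP values for one observation into ``phi``."""
    top = 0
    st_node[0] = 0
    st_depth[0] = 0
    st_plen[0] = 0
    st_pz[0] = 1.0
    st_po[0] = 1.0
    st_pi[0] = -1
    top = 1
    while top > 0:
        top -= 1
        node = st_node[top]
        depth = st_depth[top]
        plen = st_plen[top]
        pz = st_pz[top]
        po = st_po[top]
        pi = st_pi[top]

        # copy the parent's (post-unwind) path, then extend with this split
        if depth > 0:
            for i in range(plen):
                pd_[depth, i] = pd_[depth - 1, i]
                pz_[depth, i] = pz_[depth - 1, i]
                po_[depth, i] = po_[depth - 1, i]
                pw_[depth, i] = pw_[depth - 1, i]
        l = plen
        pd_[depth, l] = pi
        pz_[depth, l] = pz
        po_[depth, l] = po
        pw_[depth, l] = 1.0 if l == 0 else 0.0
        for i in range(l - 1, -1, -1):
            pw_[depth, i + 1] += po * pw_[depth, i] * (i + 1.0) / (l + 1.0)
            pw_[depth, i] = pz * pw_[depth, i] * (l - i) / (l + 1.0)
        l += 1

        if cl[node] < 0:  # leaf
            v = value[node]
            for i in range(1, l):
                oi = po_[depth, i]
                zi = pz_[depth, i]
                total = 0.0
                nop = pw_[depth, l - 1]
                for j in range(l - 2, -1, -1):
                    if oi != 0.0:
                        tmp = nop * l / ((j + 1.0) * oi)
                        total += tmp
                        nop = pw_[depth, j] - tmp * zi * (l - 1.0 - j) / l
                    else:
                        total += pw_[depth, j] * l / (zi * (l - 1.0 - j))
                phi[pd_[depth, i]] += total * (oi - zi) * v
        else:
            split = feat[node]
            if x[split] <= thr[node]:
                hot, cold = cl[node], cr[node]
            else:
                hot, cold = cr[node], cl[node]
            iz = 1.0
            io = 1.0
            k = -1
            for i in range(1, l):
                if pd_[depth, i] == split:
                    k = i
                    break
            if k >= 0:
                iz = pz_[depth, k]
                io = po_[depth, k]
                nop = pw_[depth, l - 1]
                for j in range(l - 2, -1, -1):
                    if io != 0.0:
                        tmp = pw_[depth, j]
                        pw_[depth, j] = nop * l / ((j + 1.0) * io)
                        nop = tmp - pw_[depth, j] * iz * (l - 1.0 - j) / l
                    else:
                        pw_[depth, j] = pw_[depth, j] * l / (iz * (l - 1.0 - j))
                # weights were recomputed in place for the shorter path;
                # only the element descriptors shift down
                for j in range(k, l - 1):
                    pd_[depth, j] = pd_[depth, j + 1]
                    pz_[depth, j] = pz_[depth, j + 1]
                    po_[depth, j] = po_[depth, j + 1]
                l -= 1
            # push cold then hot (order irrelevant)
            st_node[top] = cold
            st_depth[top] = depth + 1
            st_plen[top] = l
            st_pz[top] = iz * cover[cold] / cover[node]
            st_po[top] = 0.0
            st_pi[top] = split
            top += 1
            st_node[top] = hot
            st_depth[top] = depth + 1
            st_plen[top] = l
            st_pz[top] = iz * cover[hot] / cover[node]
            st_po[top] = io
            st_pi[top] = split
            top += 1


@njit(cache=True)
def _tree_shap_all(cl, cr, feat, thr, value, cover, X, phi_out, max_depth):
    levels = max_depth + 2
    width = max_depth + 3
    pd_ = np.empty((levels, width), dtype=np.int64)
    pz_ = np.empty((levels, width), dtype=np.float64)
    po_ = np.empty((levels, width), dtype=np.float64)
    pw_ = np.empty((levels, width), dtype=np.float64)
    cap = 2 * levels + 4
    st_node = np.empty(cap, dtype=np.int64)
    st_depth = np.empty(cap, dtype=np.int64)
    st_plen = np.empty(cap, dtype=np.int64)
    st_pz = np.empty(cap, dtype=np.float64)
    st_po = np.empty(cap, dtype=np.float64)
    st_pi = np.empty(cap, dtype=np.int64)
    for r in range(X.shape[0]):
        _tree_shap_obs(cl, cr, feat, thr, value, cover, X[r], phi_out[r],
                       pd_, pz_, po_, pw_, st_node, st_depth, st_plen, st_pz, st_po, st_pi)


def _tree_arrays(tree, positive_class: int = 1):
    t = tree.tree_
    cl = t.children_left.astype(np.int64)
    cr = t.children_right.astype(np.int64)
    feat = t.feature.astype(np.int64)
    thr = t.threshold.astype(np.float64)
    raw = t.value[:, 0, :]
    value = (raw[:, positive_class] / raw.sum(axis=1)).astype(np.float64)
    cover = t.weighted_n_node_samples.astype(np.float64)
    return cl, cr, feat, thr, value, cover, int(t.max_depth)


def forest_shap(forest, X: np.ndarray, positive_class: int = 1
                ) -> tuple[np.ndarray, float]:
    """SHAP values of a fitted sklearn forest on the probability scale.

    Returns ``(phi, base)`` where ``phi`` has shape (n_obs, n_features)
    and ``base`` is the expected predicted probability of
    ``positive_class`` under the tree-path-dependent distribution
    (= the cover-weighted mean of leaf probabilities, averaged over
    trees). ``base + phi.sum(axis=1)`` reproduces
    ``forest.predict_proba(X)[:, positive_class]``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    n, m = X.shape
    phi = np.zeros((n, m), dtype=np.float64)
    base = 0.0
    n_trees = len(forest.estimators_)
    phi_tree = np.zeros((n, m), dtype=np.float64)
    for est in forest.estimators_:
        cl, cr, feat, thr, value, cover, max_depth = _tree_arrays(est, positive_class)
        phi_tree[:] = 0.0
        _tree_shap_all(cl, cr, feat, thr, value, cover, X, phi_tree, max_depth)
        phi += phi_tree
        leaves = cl < 0
        base += float(np.sum(cover[leaves] / cover[0] * value[leaves]))
    phi /= n_trees
    base /= n_trees
    return phi, base
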