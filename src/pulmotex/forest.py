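"""Random forest with Gini splitting, out-of-bag (OOB) accounting,
shadow-feature permutation importance, Wilcoxon screening and chi-square
feature grouping.

The forest is grown from bootstrap bags of the training table; at every
node a random ``mtry``-subset of features is scanned for the threshold
minimising the weighted child Gini impurity

    gini(t)  = 1 - sum_i p_i^2
    G_split  = (N1/N) gini(t1) + (N2/N) gini(t2)

Trees are grown unpruned until purity or the minimum node size ``nmin``.
Ties in split quality break toward the lowest feature index, then the
lowest threshold, so rebuilding with the same seed reproduces the forest
exactly. Tree growing and prediction are numba-compiled; each tree records
its bag so OOB votes, errors and permutation importances can be computed
afterwards.

The screening pipeline mirrors the shadow-feature (Boruta-style) scheme:
each replicate appends an independently permuted copy of every column,
fits a forest on the doubled table, and measures each column's permutation
importance (mean OOB error increase when the column is shuffled within a
tree's OOB samples). Real features are kept when a one-sided rank-sum test
says their R replicate scores exceed the R shadow-maximum scores; the kept
set is then split into strongly (``Ys``) and weakly (``Yw``) label-
associated groups by a chi-square test on quantile-binned contingency
tables. A group-stratified forest draws node candidates from both groups,
guaranteeing at least one strong feature per candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from numba import njit
from scipy import stats

from pulmotex.types import FeatureTable

__all__ = [
    "Forest",
    "ImportanceReport",
    "gini_and_split",
    "build_forest",
    "predict_majority",
    "oob_error",
    "shadow_importance",
    "wilcoxon_screen",
    "chi_square_group",
    "subset_probability",
    "screen_features",
]


# ---------------------------------------------------------------------------
# numba kernels: tree growing and prediction
# ---------------------------------------------------------------------------

_TREE_CAP_FACTOR = 4  # node array capacity = factor * n + 8


@njit(cache=True)
def _grow_tree(
    X, y, n_classes, cand_pool, n_strong, mtry, nmin, seed
):  # pragma: no cover - numba
    """Grow one Gini CART on (X, y); returns flat node arrays.

    cand_pool: feature indices eligible as candidates. The first
    ``n_strong`` entries form the strong group; when ``n_strong > 0`` the
    node candidate set draws ceil(mtry/2) strong and floor(mtry/2) weak
    indices (at least one strong). With ``n_strong == 0`` candidates are
    mtry uniform draws from the whole pool.
    """
    np.random.seed(seed)
    n, _ = X.shape
    cap = _TREE_CAP_FACTOR * n + 8
    feat = np.full(cap, -1, dtype=np.int64)
    thresh = np.zeros(cap, dtype=np.float64)
    left = np.full(cap, -1, dtype=np.int64)
    right = np.full(cap, -1, dtype=np.int64)
    leaf_class = np.full(cap, -1, dtype=np.int64)

    idx = np.arange(n)
    # stack of (node_id, start, end) over idx
    stack = np.zeros((cap, 3), dtype=np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n
    n_stack = 1
    n_nodes = 1

    pool = cand_pool.copy()
    n_pool = pool.shape[0]
    n_weak = n_pool - n_strong

    # reusable scratch buffers
    vals = np.empty(n, dtype=np.float64)
    counts = np.empty(n_classes, dtype=np.int64)
    lc = np.empty(n_classes, dtype=np.int64)
    rc = np.empty(n_classes, dtype=np.int64)
    cand = np.empty(n_pool, dtype=np.int64)

    while n_stack > 0:
        n_stack -= 1
        node = stack[n_stack, 0]
        start = stack[n_stack, 1]
        end = stack[n_stack, 2]
        m = end - start
        counts[:] = 0
        for t in range(start, end):
            counts[y[idx[t]]] += 1
        best_c = 0
        for c in range(1, n_classes):
            if counts[c] > counts[best_c]:
                best_c = c
        pure = counts[best_c] == m
        if m <= nmin or pure:
            leaf_class[node] = best_c
            continue

        # draw candidate features (sorted ascending for deterministic ties)
        if n_strong > 0:
            k_s = (mtry + 1) // 2
            if k_s > n_strong:
                k_s = n_strong
            k_w = mtry - k_s
            if k_w > n_weak:
                k_w = n_weak
            n_cand = k_s + k_w
            # partial Fisher-Yates over the strong prefix
            for a in range(k_s):
                b = a + np.random.randint(0, n_strong - a)
                tmp = pool[a]
                pool[a] = pool[b]
                pool[b] = tmp
                cand[a] = pool[a]
            for a in range(k_w):
                b = a + np.random.randint(0, n_weak - a)
                tmp = pool[n_strong + a]
                pool[n_strong + a] = pool[n_strong + b]
                pool[n_strong + b] = tmp
                cand[k_s + a] = pool[n_strong + a]
        else:
            n_cand = mtry if mtry < n_pool else n_pool
            for a in range(n_cand):
                b = a + np.random.randint(0, n_pool - a)
                tmp = pool[a]
                pool[a] = pool[b]
                pool[b] = tmp
                cand[a] = pool[a]
        cand[:n_cand] = np.sort(cand[:n_cand])

        best_gini = 1e18
        best_feat = -1
        best_thr = 0.0
        for ci in range(n_cand):
            f = cand[ci]
            for t in range(m):
                vals[t] = X[idx[start + t], f]
            order = np.argsort(vals[:m], kind="quicksort")
            lc[:] = 0
            lsq = 0.0
            rsq = 0.0
            rc[:] = counts
            for c in range(n_classes):
                rsq += rc[c] * rc[c]
            for t in range(m - 1):
                cl = y[idx[start + order[t]]]
                lsq += 2.0 * lc[cl] + 1.0
                rsq += -2.0 * rc[cl] + 1.0
                lc[cl] += 1
                rc[cl] -= 1
                v_here = vals[order[t]]
                v_next = vals[order[t + 1]]
                if v_next <= v_here:
                    continue
                nl = t + 1
                nr = m - nl
                g = (nl - lsq / nl + nr - rsq / nr) / m
                if g < best_gini - 1e-15:
                    best_gini = g
                    best_feat = f
                    best_thr = 0.5 * (v_here + v_next)
        if best_feat < 0:
            # all candidates constant on this node: leaf
            leaf_class[node] = best_c
            continue

        # partition idx[start:end] in place by the chosen split
        lo = start
        hi = end - 1
        while lo <= hi:
            if X[idx[lo], best_feat] <= best_thr:
                lo += 1
            else:
                tmp = idx[lo]
                idx[lo] = idx[hi]
                idx[hi] = tmp
                hi -= 1
        mid = lo
        if mid == start or mid == end:
            leaf_class[node] = best_c
            continue

        feat[node] = best_feat
        thresh[node] = best_thr
        left[node] = n_nodes
        right[node] = n_nodes + 1
        stack[n_stack, 0] = n_nodes
        stack[n_stack, 1] = start
        stack[n_stack, 2] = mid
        stack[n_stack + 1, 0] = n_nodes + 1
        stack[n_stack + 1, 1] = mid
        stack[n_stack + 1, 2] = end
        n_stack += 2
        n_nodes += 2

    return feat[:n_nodes], thresh[:n_nodes], left[:n_nodes], right[:n_nodes], leaf_class[:n_nodes]


@njit(cache=True)
def _forest_votes_binned(
    Xb_train, y, n_classes, Xb_test, K, mtry, nmin, seed
):  # pragma: no cover - numba
    """Grow K histogram CARTs on pre-binned uint8 features and return test
    vote counts. Used by the wrapper's cross-validated fitness, where the
    quantile-binned split search trades exact thresholds for speed."""
    np.random.seed(seed)
    n, M = Xb_train.shape
    n_test = Xb_test.shape[0]
    n_bins = 0
    for i in range(n):
        for j in range(M):
            if Xb_train[i, j] > n_bins:
                n_bins = Xb_train[i, j]
    n_bins += 1
    votes = np.zeros((n_test, n_classes), dtype=np.int64)

    cap = _TREE_CAP_FACTOR * n + 8
    feat = np.empty(cap, dtype=np.int64)
    thresh = np.empty(cap, dtype=np.int64)
    left = np.empty(cap, dtype=np.int64)
    right = np.empty(cap, dtype=np.int64)
    leaf_class = np.empty(cap, dtype=np.int64)
    stack = np.zeros((cap, 3), dtype=np.int64)
    hist = np.empty((n_bins, n_classes), dtype=np.int64)
    counts = np.empty(n_classes, dtype=np.int64)
    lc = np.empty(n_classes, dtype=np.int64)
    cand = np.empty(M, dtype=np.int64)
    pool = np.arange(M)
    Xbag = np.empty((n, M), dtype=np.uint8)
    ybag = np.empty(n, dtype=np.int64)

    for _k in range(K):
        for i in range(n):
            b = np.random.randint(0, n)
            ybag[i] = y[b]
            for j in range(M):
                Xbag[i, j] = Xb_train[b, j]
        feat[:] = -1
        leaf_class[:] = -1
        stack[0, 0] = 0
        stack[0, 1] = 0
        stack[0, 2] = n
        n_stack = 1
        n_nodes = 1
        idx = np.arange(n)
        while n_stack > 0:
            n_stack -= 1
            node = stack[n_stack, 0]
            start = stack[n_stack, 1]
            end = stack[n_stack, 2]
            m = end - start
            counts[:] = 0
            for t in range(start, end):
                counts[ybag[idx[t]]] += 1
            best_c = 0
            for c in range(1, n_classes):
                if counts[c] > counts[best_c]:
                    best_c = c
            if m <= nmin or counts[best_c] == m:
                leaf_class[node] = best_c
                continue
            n_cand = mtry if mtry < M else M
            for a in range(n_cand):
                bswap = a + np.random.randint(0, M - a)
                tmp = pool[a]
                pool[a] = pool[bswap]
                pool[bswap] = tmp
                cand[a] = pool[a]
            cand[:n_cand] = np.sort(cand[:n_cand])

            best_gini = 1e18
            best_feat = -1
            best_bin = -1
            for ci in range(n_cand):
                f = cand[ci]
                hist[:, :] = 0
                for t in range(start, end):
                    hist[Xbag[idx[t], f], ybag[idx[t]]] += 1
                lc[:] = 0
                nl = 0
                lsq = 0.0
                rsq = 0.0
                for c in range(n_classes):
                    rsq += counts[c] * counts[c]
                for b in range(n_bins - 1):
                    row_total = 0
                    for c in range(n_classes):
                        h = hist[b, c]
                        if h > 0:
                            lsq += 2.0 * lc[c] * h + h * h
                            rc_c = counts[c] - lc[c]
                            rsq += -2.0 * rc_c * h + h * h
                            lc[c] += h
                            row_total += h
                    nl += row_total
                    if row_total == 0 or nl == 0 or nl == m:
                        continue
                    nr = m - nl
                    g = (nl - lsq / nl + nr - rsq / nr) / m
                    if g < best_gini - 1e-15:
                        best_gini = g
                        best_feat = f
                        best_bin = b
            if best_feat < 0:
                leaf_class[node] = best_c
                continue
            lo = start
            hi = end - 1
            while lo <= hi:
                if Xbag[idx[lo], best_feat] <= best_bin:
                    lo += 1
                else:
                    tmp = idx[lo]
                    idx[lo] = idx[hi]
                    idx[hi] = tmp
                    hi -= 1
            mid = lo
            if mid == start or mid == end:
                leaf_class[node] = best_c
                continue
            feat[node] = best_feat
            thresh[node] = best_bin
            left[node] = n_nodes
            right[node] = n_nodes + 1
            stack[n_stack, 0] = n_nodes
            stack[n_stack, 1] = start
            stack[n_stack, 2] = mid
            stack[n_stack + 1, 0] = n_nodes + 1
            stack[n_stack + 1, 1] = mid
            stack[n_stack + 1, 2] = end
            n_stack += 2
            n_nodes += 2

        for i in range(n_test):
            node = 0
            while leaf_class[node] < 0:
                if Xb_test[i, feat[node]] <= thresh[node]:
                    node = left[node]
                else:
                    node = right[node]
            votes[i, leaf_class[node]] += 1
    return votes


@njit(cache=True)
def _predict_tree(feat, thresh, left, right, leaf_class, X):  # pragma: no cover - numba
    n = X.shape[0]
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        node = 0
        while leaf_class[node] < 0:
            if X[i, feat[node]] <= thresh[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = leaf_class[node]
    return out


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------


def quantile_bin(features: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Per-column quantile binning to uint8 codes (the fast-path input of
    the wrapper's cross-validated fitness)."""
    features = np.asarray(features, dtype=float)
    out = np.empty(features.shape, dtype=np.uint8)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(features.shape[1]):
        edges = np.unique(np.quantile(features[:, j], qs))
        out[:, j] = np.digitize(features[:, j], edges)
    return out


def gini_and_split(
    parent: np.ndarray, left: np.ndarray, right: np.ndarray
) -> tuple[float, float]:
    """Parent Gini impurity and the weighted child impurity of a split.

    ``parent``, ``left`` and ``right`` are per-class counts with
    ``left + right == parent``.
    """
    parent = np.asarray(parent, dtype=float)
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if not np.allclose(left + right, parent):
        raise ValueError("left + right must equal parent counts")
    n = parent.sum()
    if n == 0:
        raise ValueError("empty parent node")

    def _gini(c: np.ndarray) -> float:
        tot = c.sum()
        if tot == 0:
            return 0.0
        p = c / tot
        return float(1.0 - np.sum(p**2))

    g_parent = _gini(parent)
    g_split = (left.sum() / n) * _gini(left) + (right.sum() / n) * _gini(right)
    return g_parent, g_split


@dataclass
class _Tree:
    feat: np.ndarray
    thresh: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_class: np.ndarray
    bag: np.ndarray  # bootstrap sample indices (multiset, size N)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _predict_tree(
            self.feat, self.thresh, self.left, self.right, self.leaf_class,
            np.ascontiguousarray(X, dtype=np.float64),
        )


@dataclass
class Forest:
    """A trained forest: trees with recorded bags plus label bookkeeping."""

    trees: list[_Tree]
    classes: np.ndarray  # original labels, index = internal code
    n_samples: int
    mtry: int
    nmin: int
    groups: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def vote_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_classes) vote counts over trees."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        votes = np.zeros((X.shape[0], len(self.classes)), dtype=int)
        for tree in self.trees:
            pred = tree.predict(X)
            votes[np.arange(X.shape[0]), pred] += 1
        return votes


def build_forest(
    table: FeatureTable,
    K: int = 100,
    mtry: int | None = None,
    nmin: int = 1,
    rng: np.random.Generator | int | None = None,
    groups: tuple[np.ndarray, np.ndarray] | None = None,
) -> Forest:
    """Fit ``K`` Gini CARTs on bootstrap bags of ``table``.

    ``mtry`` defaults to ``ceil(sqrt(M))``. With ``groups=(Ys, Yw)``
    (index arrays of strong/weak features) each node's candidate set draws
    ``ceil(mtry/2)`` from Ys and ``floor(mtry/2)`` from Yw, always
    including at least one strong feature; without groups, candidates are
    uniform draws over all features.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    M = table.n_features
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(M)))
    if not 1 <= mtry <= M:
        raise ValueError("need 1 <= mtry <= M")
    rng = np.random.default_rng(rng)

    classes, y = np.unique(table.labels, return_inverse=True)
    X = np.ascontiguousarray(table.features, dtype=np.float64)
    N = table.n_samples

    if groups is not None:
        ys, yw = (np.asarray(g, dtype=np.int64) for g in groups)
        if ys.size == 0:
            raise ValueError("strong group Ys must be non-empty")
        cand_pool = np.concatenate([ys, yw])
        n_strong = ys.size
    else:
        cand_pool = np.arange(M, dtype=np.int64)
        n_strong = 0

    trees = []
    for _ in range(K):
        bag = rng.integers(0, N, size=N)
        seed = int(rng.integers(0, 2**31 - 1))
        arrays = _grow_tree(
            X[bag], y[bag].astype(np.int64), len(classes),
            cand_pool, n_strong, mtry, nmin, seed,
        )
        trees.append(_Tree(*arrays, bag=bag))
    return Forest(trees, classes, N, mtry, nmin, groups)


def predict_majority(forest: Forest, X: np.ndarray) -> np.ndarray:
    """Majority-vote class per row; ties break to the smallest class label."""
    if forest.n_trees == 0:
        raise ValueError("forest has no trees")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    votes = forest.vote_matrix(X)
    return forest.classes[np.argmax(votes, axis=1)]  # argmax ties -> lowest index


def oob_error(forest: Forest, table: FeatureTable) -> tuple[float, np.ndarray, int]:
    """OOB error rate and per-sample OOB majority predictions.

    Samples present in every bag get prediction 0 (no vote) and are
    excluded from the error average; their count is returned last.
    """
    if forest.n_trees == 0:
        raise ValueError("forest has no trees")
    N = table.n_samples
    X = np.ascontiguousarray(table.features, dtype=np.float64)
    votes = np.zeros((N, len(forest.classes)), dtype=int)
    for tree in forest.trees:
        oob_mask = np.ones(N, dtype=bool)
        oob_mask[tree.bag] = False
        if not oob_mask.any():
            continue
        pred = tree.predict(X[oob_mask])
        votes[np.flatnonzero(oob_mask), pred] += 1
    has_vote = votes.sum(axis=1) > 0
    preds = np.zeros(N, dtype=forest.classes.dtype)
    preds[has_vote] = forest.classes[np.argmax(votes[has_vote], axis=1)]
    n_uncovered = int(N - has_vote.sum())
    if has_vote.sum() == 0:
        raise ValueError("no sample has an OOB vote; increase K")
    err = float(np.mean(preds[has_vote] != table.labels[has_vote]))
    return err, preds, n_uncovered


def _per_tree_oob_permutation_importance(
    forest: Forest, X: np.ndarray, y_codes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Mean over trees of (OOB error with column j permuted - baseline)."""
    M = X.shape[1]
    deltas = np.zeros(M)
    n_used = 0
    for tree in forest.trees:
        oob_mask = np.ones(X.shape[0], dtype=bool)
        oob_mask[tree.bag] = False
        oob_idx = np.flatnonzero(oob_mask)
        if oob_idx.size == 0:
            continue
        n_used += 1
        X_oob = X[oob_idx]
        y_oob = y_codes[oob_idx]
        base_err = np.mean(tree.predict(X_oob) != y_oob)
        perm = rng.permutation(oob_idx.size)
        for j in range(M):
            X_perm = X_oob.copy()
            X_perm[:, j] = X_oob[perm, j]
            deltas[j] += np.mean(tree.predict(X_perm) != y_oob) - base_err
    if n_used == 0:
        raise ValueError("no tree has OOB samples")
    return deltas / n_used


def gini_importance(forest: Forest, table: FeatureTable) -> np.ndarray:
    """Per-feature summed Gini decrease, averaged over trees (the in-bag
    importance; reported for reference, the screen uses permutation
    scores)."""
    classes, y = np.unique(table.labels, return_inverse=True)
    X = table.features
    M = table.n_features
    total = np.zeros(M)
    for tree in forest.trees:
        Xb = X[tree.bag]
        yb = y[tree.bag]
        # recompute per-node sample routing to accumulate Gini decreases
        node_samples: dict[int, np.ndarray] = {0: np.arange(Xb.shape[0])}
        order = [0]
        while order:
            node = order.pop()
            idx = node_samples.pop(node)
            f = tree.feat[node]
            if f < 0 or idx.size == 0:
                continue
            go_left = Xb[idx, f] <= tree.thresh[node]
            li, ri = idx[go_left], idx[~go_left]
            counts = np.bincount(yb[idx], minlength=len(classes))
            lc = np.bincount(yb[li], minlength=len(classes))
            g_parent, g_split = gini_and_split(counts, lc, counts - lc)
            total[f] += g_parent - g_split
            node_samples[tree.left[node]] = li
            node_samples[tree.right[node]] = ri
            order.extend((tree.left[node], tree.right[node]))
    return total / max(len(forest.trees), 1)


def shadow_importance(
    table: FeatureTable,
    R: int = 20,
    K: int = 50,
    mtry: int | None = None,
    nmin: int = 1,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """R replicates of shadow-extended permutation importances.

    Each replicate appends an independently permuted copy of every column
    (the shadows), fits a forest on the doubled table, and records the
    permutation importance of the M real columns plus the maximum among
    the M shadow columns. Returns ``(scores[R, M], shadow_max[R])``.
    """
    if R < 5:
        raise ValueError("R must be >= 5 (the rank-sum screen needs replicates)")
    rng = np.random.default_rng(rng)
    N, M = table.features.shape
    scores = np.zeros((R, M))
    shadow_max = np.zeros(R)
    for r in range(R):
        shadows = np.empty_like(table.features)
        for j in range(M):
            shadows[:, j] = table.features[rng.permutation(N), j]
        extended = FeatureTable(
            np.hstack([table.features, shadows]),
            table.labels,
            table.feature_names + [f"shadow_{n}" for n in table.feature_names],
        )
        forest = build_forest(extended, K=K, mtry=mtry, nmin=nmin, rng=rng)
        _, y_codes = np.unique(table.labels, return_inverse=True)
        imp = _per_tree_oob_permutation_importance(
            forest, np.ascontiguousarray(extended.features), y_codes, rng
        )
        scores[r] = imp[:M]
        shadow_max[r] = imp[M:].max()
    return scores, shadow_max


def wilcoxon_screen(
    scores: np.ndarray, shadow_max: np.ndarray, theta: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Keep features whose R importance scores rank above the R shadow-max
    scores (one-sided rank-sum test at level ``theta``).

    Returns (kept feature indices, per-feature p-values). Degenerate
    zero-variance comparisons get p = 0.5.
    """
    scores = np.asarray(scores, float)
    shadow_max = np.asarray(shadow_max, float)
    R, M = scores.shape
    if R < 5 or shadow_max.shape[0] != R:
        raise ValueError("need R >= 5 replicates with matching shadow_max")
    pvals = np.empty(M)
    for j in range(M):
        a, b = scores[:, j], shadow_max
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            pvals[j] = 0.5
            continue
        method = "exact" if np.unique(np.concatenate([a, b])).size == 2 * R else "asymptotic"
        pvals[j] = stats.mannwhitneyu(a, b, alternative="greater", method=method).pvalue
    kept = np.flatnonzero(pvals <= theta)
    return kept, pvals


def chi_square_statistic(observed: np.ndarray) -> float:
    """Pearson chi-square statistic ``sum (O - E)^2 / E`` with
    ``E = row_total * col_total / N``; zero-margin rows/columns are
    dropped."""
    O = np.asarray(observed, dtype=float)
    O = O[O.sum(axis=1) > 0][:, O.sum(axis=0) > 0]
    n = O.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / n
    return float(np.sum((O - E) ** 2 / E))


def chi_square_group(
    table: FeatureTable,
    kept: np.ndarray,
    bins: int = 4,
    alpha2: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the screened features into strongly (``Ys``) and weakly
    (``Yw``) label-associated groups.

    Each kept feature is discretized into quantile bins; the chi-square
    statistic of its bins-x-classes contingency table is referred to the
    chi-square law with (rows-1)(cols-1) degrees of freedom. Duplicate
    quantile edges (heavily tied features) merge bins before testing.
    """
    kept = np.asarray(kept, dtype=int)
    if kept.size == 0:
        raise ValueError("kept feature set must be non-empty")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    classes = table.classes
    ys, yw = [], []
    for j in kept:
        col = table.features[:, j]
        edges = np.unique(np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1]))
        binned = np.digitize(col, edges)
        n_rows = binned.max() + 1
        observed = np.zeros((n_rows, classes.size))
        for ci, c in enumerate(classes):
            observed[:, ci] = np.bincount(binned[table.labels == c], minlength=n_rows)
        observed = observed[observed.sum(axis=1) > 0][:, observed.sum(axis=0) > 0]
        stat = chi_square_statistic(observed)
        dof = max((observed.shape[0] - 1) * (observed.shape[1] - 1), 1)
        p = float(stats.chi2.sf(stat, dof))
        (ys if p < alpha2 else yw).append(int(j))
    return np.array(ys, dtype=int), np.array(yw, dtype=int)


def subset_probability(M: int, D: int, m: int) -> tuple[float, float]:
    """Probability that a uniform m-subset of M features misses all D
    informative ones: exact ``C(M-D, m)/C(M, m)`` and the approximation
    ``(1 - D/M)**m``."""
    if not 0 <= D <= M:
        raise ValueError("need 0 <= D <= M")
    if not 1 <= m <= M:
        raise ValueError("need 1 <= m <= M")
    exact = comb(M - D, m) / comb(M, m) if m <= M - D else 0.0
    approx = (1.0 - D / M) ** m
    return exact, approx


@dataclass
class ImportanceReport:
    """Everything the bi-level screen produces."""

    scores: np.ndarray          # R x M permutation importances
    shadow_max: np.ndarray      # R shadow-maximum scores
    p_values: np.ndarray        # per-feature rank-sum p-values
    theta: float
    kept: np.ndarray            # screened-in feature indices
    strong: np.ndarray          # Ys
    weak: np.ndarray            # Yw
    gini_scores: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)


def screen_features(
    table: FeatureTable,
    R: int = 20,
    K: int = 50,
    theta: float = 0.05,
    bins: int = 4,
    alpha2: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> ImportanceReport:
    """Full shadow -> rank-sum -> chi-square screening pipeline."""
    rng = np.random.default_rng(rng)
    scores, shadow_max = shadow_importance(table, R=R, K=K, rng=rng)
    kept, pvals = wilcoxon_screen(scores, shadow_max, theta)
    if kept.size > 0:
        strong, weak = chi_square_group(table, kept, bins=bins, alpha2=alpha2)
    else:
        strong = np.array([], dtype=int)
        weak = np.array([], dtype=int)
    forest = build_forest(table, K=K, rng=rng)
    gini_scores = gini_importance(forest, table)
    return ImportanceReport(
        scores, shadow_max, pvals, theta, kept, strong, weak,
        gini_scores, list(table.feature_names),
    )
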