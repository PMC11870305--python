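"""Multivariate regression trees with cross-validated cost-complexity pruning.

CART-style binary recursive partitioning where the node impurity is the
sum, over several (standardized) response columns, of squared deviations
from the node mean vector.  Used here to partition clone growth records
(height, DBH, volume) on bioclimatic predictors and read off the climate
thresholds separating good from poor growth.

Splits are exhaustive over every predictor and every midpoint between
consecutive distinct values; the tree is grown best-first (largest
impurity reduction next) and pruned by the standard weakest-link
cost-complexity sequence with k-fold cross-validation and the 1-SE rule.
Ties between candidate splits are broken by predictor order then lower
threshold, on values only, so the fitted tree is invariant to row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Relative tolerance for treating two impurity reductions as tied.
_TIE_RTOL = 1e-9


def standardize_responses(Y):
    """Scale each response column to zero mean and unit sample SD.

    Returns ``(standardized, means, sds)`` so the transform can be
    inverted.  Raises on constant columns.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] < 2:
        raise ValueError("need >=2 rows")
    means = Y.mean(axis=0)
    sds = Y.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("constant response column cannot be standardized")
    return (Y - means) / sds, means, sds


@dataclass
class MrtNode:
    node_mean: np.ndarray
    sse: float
    n: int
    split_variable: str | None = None
    threshold: float | None = None
    left: "MrtNode | None" = None
    right: "MrtNode | None" = None
    reduction: float = 0.0  # impurity decrease achieved by this split

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self):
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def to_dict(self) -> dict:
        d = {
            "n": int(self.n),
            "sse": float(self.sse),
            "mean": [float(m) for m in self.node_mean],
        }
        if not self.is_leaf:
            d.update(
                variable=self.split_variable,
                threshold=float(self.threshold),
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d


@dataclass
class MrtControl:
    min_leaf: int = 5
    min_reduction_frac: float = 0.01  # fraction of root SSE
    max_size: int | None = None  # maximum number of leaves


@dataclass
class MrtTree:
    root: MrtNode
    response_names: list
    predictor_names: list
    control: MrtControl = field(default_factory=MrtControl)
    complexity: pd.DataFrame | None = None  # filled by cv_prune

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def rules_text(self) -> str:
        lines = []

        def walk(node, indent, label):
            tag = f"{node.sse:.4g} n={node.n}"
            if node.is_leaf:
                lines.append(f"{'  ' * indent}{label}leaf [{tag}]")
            else:
                lines.append(
                    f"{'  ' * indent}{label}{node.split_variable} < "
                    f"{node.threshold:g} [{tag}]"
                )
                walk(node.left, indent + 1, f"{node.split_variable} < {node.threshold:g}: ")
                walk(node.right, indent + 1, f"{node.split_variable} > {node.threshold:g}: ")

        walk(self.root, 0, "")
        return "\n".join(lines)


def _node_stats(Y):
    mean = Y.mean(axis=0)
    sse = float(((Y - mean) ** 2).sum())
    return mean, sse


def _column_sse_prefix(Ysorted):
    """Prefix SSEs of the first i rows, for i = 1..n, via running sums."""
    n = Ysorted.shape[0]
    csum = np.cumsum(Ysorted, axis=0)
    csq = np.cumsum(Ysorted**2, axis=0)
    counts = np.arange(1, n + 1)[:, None]
    sse = csq - csum**2 / counts
    return sse.sum(axis=1)


def best_split(X: pd.DataFrame, Y: np.ndarray, min_leaf: int = 1):
    """Exhaustive search for the best binary split of one node.

    Returns ``(variable, threshold, reduction)`` or ``None`` when no
    admissible split exists.  The threshold is the midpoint between the
    consecutive distinct values it separates; rows with a missing value
    for a predictor are excluded from splits on that predictor only.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = len(Y)
    if n < 2 * min_leaf:
        return None
    best = None  # (reduction, var_pos, threshold, variable)
    for var_pos, var in enumerate(X.columns):
        x = X[var].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        if ok.sum() < 2 * min_leaf:
            continue
        xv = x[ok]
        Yv = Y[ok]
        order = np.argsort(xv, kind="stable")
        xs = xv[order]
        Ys = Yv[order]
        _, parent_sse = _node_stats(Ys)
        left_sse = _column_sse_prefix(Ys)
        right_sse = _column_sse_prefix(Ys[::-1])[::-1]
        m = len(xs)
        for i in range(min_leaf - 1, m - min_leaf):
            if xs[i] == xs[i + 1]:
                continue
            red = parent_sse - (left_sse[i] + right_sse[i + 1])
            thr = 0.5 * (xs[i] + xs[i + 1])
            cand = (red, var_pos, thr)
            if best is None:
                best = cand + (var,)
                continue
            scale = max(abs(red), abs(best[0]), 1e-300)
            if red > best[0] + _TIE_RTOL * scale:
                best = cand + (var,)
            elif abs(red - best[0]) <= _TIE_RTOL * scale:
                # tie: earlier predictor, then lower threshold
                if (var_pos, thr) < (best[1], best[2]):
                    best = cand + (var,)
    if best is None or best[0] <= 0:
        return None
    return best[3], float(best[2]), float(best[0])


def grow_tree(X: pd.DataFrame, Y, control: MrtControl | None = None) -> MrtTree:
    """Grow a multivariate tree best-first under the stopping controls.

    The leaf with the largest admissible impurity reduction is split
    next, until ``max_size`` leaves, no split reduces impurity by at
    least ``min_reduction_frac`` of the root SSE, or leaves fall below
    ``2 * min_leaf`` rows.  Deterministic for a given input.
    """
    control = control or MrtControl()
    if isinstance(Y, pd.DataFrame):
        response_names = list(Y.columns)
    else:
        response_names = None
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if len(X) != len(Y):
        raise ValueError("X and Y must have the same number of rows")
    if len(Y) < 2 * control.min_leaf:
        raise ValueError("fewer rows than 2 * min_leaf")

    mean, sse = _node_stats(Y)
    root = MrtNode(node_mean=mean, sse=sse, n=len(Y))
    min_reduction = control.min_reduction_frac * sse

    # frontier entries: (node, row_index_array, candidate_split or None)
    idx_all = np.arange(len(Y))
    frontier = [(root, idx_all, best_split(X, Y, control.min_leaf))]
    n_leaves = 1
    while True:
        if control.max_size is not None and n_leaves >= control.max_size:
            break
        candidates = [
            (k, f) for k, f in enumerate(frontier)
            if f[2] is not None and f[2][2] >= min_reduction and f[2][2] > 0
        ]
        if not candidates:
            break
        k_best, (node, idx, split) = max(
            candidates, key=lambda kf: (kf[1][2][2], -kf[0])
        )
        var, thr, red = split
        x = X[var].to_numpy(dtype=float)[idx]
        go_left = x < thr
        missing = np.isnan(x)
        if missing.any():
            # route missing rows with the larger observed child
            go_left[missing] = go_left[~missing].sum() >= (~missing).sum() / 2
        li, ri = idx[go_left], idx[~go_left]
        lmean, lsse = _node_stats(Y[li])
        rmean, rsse = _node_stats(Y[ri])
        node.split_variable, node.threshold = var, thr
        node.reduction = red
        node.left = MrtNode(node_mean=lmean, sse=lsse, n=len(li))
        node.right = MrtNode(node_mean=rmean, sse=rsse, n=len(ri))
        frontier.pop(k_best)
        for child, cidx in ((node.left, li), (node.right, ri)):
            Xc = X.iloc[cidx]
            frontier.append((child, cidx, best_split(Xc, Y[cidx], control.min_leaf)))
        n_leaves += 1

    return MrtTree(
        root=root,
        response_names=(
            response_names or [f"y{j + 1}" for j in range(Y.shape[1])]
        ),
        predictor_names=list(X.columns),
        control=control,
    )


def _clone_tree(node: MrtNode) -> MrtNode:
    out = MrtNode(
        node_mean=node.node_mean.copy(),
        sse=node.sse,
        n=node.n,
        split_variable=node.split_variable,
        threshold=node.threshold,
        reduction=node.reduction,
    )
    if not node.is_leaf:
        out.left = _clone_tree(node.left)
        out.right = _clone_tree(node.right)
    return out


def _subtree_cost(node):
    """(sum of leaf SSEs, number of leaves) below a node."""
    leaves = node.leaves()
    return sum(l.sse for l in leaves), len(leaves)


def prune_sequence(root: MrtNode):
    """Weakest-link cost-complexity sequence.

    Returns a list of ``(alpha, size)`` pairs for the nested subtree
    sequence, starting at (0, full size) and ending at (alpha_max, 1).
    The tree passed in is not modified.
    """
    tree = _clone_tree(root)
    seq = [(0.0, len(tree.leaves()))]
    while not tree.is_leaf:
        # weakest link: internal node minimising (sse - subtree_sse)/(L-1)
        best_g, targets = np.inf, []

        def visit(node):
            nonlocal best_g, targets
            if node.is_leaf:
                return
            sub_sse, L = _subtree_cost(node)
            g = (node.sse - sub_sse) / (L - 1)
            if not targets:
                best_g, targets = g, [node]
            elif g < best_g - 1e-12 * max(1.0, abs(best_g)):
                best_g, targets = g, [node]
            elif abs(g - best_g) <= 1e-12 * max(1.0, abs(best_g), abs(g)):
                targets.append(node)
            visit(node.left)
            visit(node.right)

        visit(tree)
        for node in targets:
            node.left = node.right = None
            node.split_variable = node.threshold = None
        seq.append((max(best_g, 0.0), len(tree.leaves())))
    return seq


def prune_at(root: MrtNode, alpha: float) -> MrtNode:
    """Smallest subtree optimal at complexity ``alpha`` (copy)."""
    tree = _clone_tree(root)

    def collapse(node):
        if node.is_leaf:
            return
        collapse(node.left)
        collapse(node.right)
        sub_sse, L = _subtree_cost(node)
        if node.sse - sub_sse <= alpha * (L - 1) + 1e-12:
            node.left = node.right = None
            node.split_variable = node.threshold = None

    collapse(tree)
    return tree


def predict(tree: MrtTree | MrtNode, X: pd.DataFrame) -> np.ndarray:
    """Route each row to its leaf and return the leaf mean vector.

    Values below the threshold go left; missing split values are routed
    to the larger child.
    """
    root = tree.root if isinstance(tree, MrtTree) else tree
    out = np.empty((len(X), len(root.node_mean)))
    for i in range(len(X)):
        node = root
        while not node.is_leaf:
            x = X.iloc[i][node.split_variable]
            if pd.isna(x):
                node = node.left if node.left.n >= node.right.n else node.right
            else:
                node = node.left if x < node.threshold else node.right
        out[i] = node.node_mean
    return out


def cv_prune(
    tree: MrtTree,
    X: pd.DataFrame,
    Y,
    folds: int = 10,
    seed: int = 0,
    rule: str = "1se",
):
    """Choose tree size by k-fold cross-validation over the alpha sequence.

    For each candidate alpha (geometric means of the weakest-link
    sequence), trees grown on each training fold are pruned at that alpha
    and scored on the held-out rows; the selected size is the smallest
    whose CV error is within one standard error of the minimum (1-SE
    rule; ``rule="min"`` picks the minimiser instead).

    Returns ``(pruned_tree, complexity_table)``; the table also lands on
    ``pruned_tree.complexity``.
    """
    if rule not in ("1se", "min"):
        raise ValueError("rule must be '1se' or 'min'")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = len(Y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError("more folds than rows")

    seq = prune_sequence(tree.root)
    alphas = [a for a, _s in seq]
    sizes = [s for _a, s in seq]
    # candidate alphas: geometric means between consecutive sequence values
    cand = []
    for k in range(len(alphas)):
        if k + 1 < len(alphas):
            lo, hi = alphas[k], alphas[k + 1]
            cand.append(np.sqrt(max(lo, 1e-12) * max(hi, 1e-12)) if hi > 0 else 0.0)
        else:
            cand.append(alphas[k] * 2 + 1e-12)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f in range(folds):
        fold_of[perm[f::folds]] = f

    errs = np.zeros((len(cand), n))
    for f in range(folds):
        test = fold_of == f
        train = ~test
        sub = grow_tree(
            X.iloc[np.where(train)[0]].reset_index(drop=True),
            Y[train],
            tree.control,
        )
        for k, a in enumerate(cand):
            pruned = prune_at(sub.root, a)
            pred = predict(pruned, X.iloc[np.where(test)[0]].reset_index(drop=True))
            errs[k, test] = ((Y[test] - pred) ** 2).sum(axis=1)

    cv_mean = errs.mean(axis=1)
    cv_se = errs.std(axis=1, ddof=1) / np.sqrt(n)

    table = pd.DataFrame(
        {
            "size": sizes,
            "alpha": cand,
            "train_sse": [
                _subtree_cost(prune_at(tree.root, a))[0] for a in cand
            ],
            "cv_error": cv_mean,
            "cv_se": cv_se,
        }
    )
    k_min = int(np.argmin(cv_mean))
    if rule == "1se":
        threshold = cv_mean[k_min] + cv_se[k_min]
        admissible = [k for k in range(len(cand)) if cv_mean[k] <= threshold]
        k_sel = min(admissible, key=lambda k: (sizes[k], cv_mean[k]))
    else:
        k_sel = k_min
    pruned_root = prune_at(tree.root, cand[k_sel])
    out = MrtTree(
        root=pruned_root,
        response_names=tree.response_names,
        predictor_names=tree.predictor_names,
        control=tree.control,
        complexity=table,
    )
    return out, table
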