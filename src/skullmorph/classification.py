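"""Specimen-assignment machinery.

Three complementary routes for assigning specimens (including putative
hybrids) to species from shape data:

* UPGMA phenograms on Procrustes distances, with cophenetic correlation
  and bootstrap node supports — no a-priori groups.
* Stepwise linear discriminant analysis (forward Wilks'-lambda selection
  with removal, leave-one-out cross-validation, chi-square test) — the
  supervised route.
* k-means with k = 2 — unsupervised partition on shape variables only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2

__all__ = [
    "DendrogramResult",
    "DiscriminantResult",
    "upgma",
    "bootstrap_supports",
    "wilks_lambda",
    "stepwise_select",
    "lda_classify",
    "nested_cv_rate",
    "kmeans_two",
]


@dataclass
class DendrogramResult:
    """UPGMA tree: merge list, cophenetic structure and optional supports.

    ``merges`` follows the linkage convention: each row joins two node ids
    (leaves are 0..n-1, internal nodes n, n+1, ...) at a merge distance.
    The ultrametric *height* of a node (root-to-leaf depth on a drawn
    dendrogram) is half the merge distance; the cophenetic distance of a
    leaf pair is the full merge distance of their lowest common node, so
    it lives on the same scale as the input distances.
    """

    merges: np.ndarray  # (n-1) x 4 linkage matrix (id1, id2, distance, size)
    cophenetic: np.ndarray  # n x n, full-distance scale
    cophenetic_r: float
    labels: list[str]
    supports: np.ndarray | None = None  # per internal node, % of bootstrap trees

    @property
    def heights(self) -> np.ndarray:
        """Ultrametric node heights (merge distance / 2), in merge order."""
        return self.merges[:, 2] / 2.0

    def node_leafsets(self) -> list[frozenset[int]]:
        return _node_leafsets(self.merges)

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        text = {i: self.labels[i] for i in range(n)}
        for row_i, (a, b, dist, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            h = dist / 2.0
            node = n + row_i
            text[node] = (
                f"({text[a]}:{h - height[a]:.6g},{text[b]}:{h - height[b]:.6g})"
            )
            height[node] = h
        return text[n + len(self.merges) - 1] + ";"


@dataclass
class DiscriminantResult:
    """Two-group linear discriminant analysis output."""

    retained: list[int]  # predictor indices in entry order
    wilks_lambda: float
    chi_square: float
    df: int
    p_value: float
    per_group_rates: dict[str, float]  # % correct, resubstitution after CV
    cv_rate: float  # % correct leave-one-out
    assignments: dict[str, tuple[str, float]]  # query id -> (group, score)
    direction: np.ndarray
    group_means: dict[str, np.ndarray]
    confusion: pd.DataFrame


def _node_leafsets(merges: np.ndarray) -> list[frozenset[int]]:
    n = merges.shape[0] + 1
    sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    out = []
    for row_i, (a, b, _, _) in enumerate(merges):
        s = sets[int(a)] | sets[int(b)]
        sets[n + row_i] = s
        out.append(s)
    return out


def upgma(dist: np.ndarray, labels: list[str] | None = None) -> DendrogramResult:
    """Average-linkage (UPGMA) clustering of a distance matrix.

    Cophenetic distances are the merge distances of lowest common nodes;
    ``cophenetic_r`` is the Pearson correlation between the condensed
    input and cophenetic distances (NaN, with a warning, when the input
    distances are all equal).
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(dist)) > 1e-12) or np.any(dist < -1e-12):
        raise ValueError("distances must be non-negative with zero diagonal")
    condensed = squareform(0.5 * (dist + dist.T), checks=False)
    merges = linkage(condensed, method="average")
    coph_d = cophenet(merges)
    if np.ptp(condensed) == 0:
        import warnings

        warnings.warn("all pairwise distances equal; cophenetic correlation undefined")
        r = float("nan")
    else:
        r = float(np.corrcoef(condensed, coph_d)[0, 1])
    if labels is None:
        labels = [f"specimen_{i}" for i in range(n)]
    return DendrogramResult(
        merges=merges, cophenetic=squareform(coph_d), cophenetic_r=r, labels=list(labels)
    )


def bootstrap_supports(
    data: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    labels: list[str] | None = None,
) -> DendrogramResult:
    """UPGMA with bootstrap node supports.

    Variable columns of ``data`` (n specimens x p shape variables) are
    resampled with replacement; Euclidean distances and the UPGMA tree are
    recomputed per replicate, and each internal node of the original tree
    is scored by the percentage of replicate trees containing exactly the
    same specimen set.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[1] < 2:
        raise ValueError("need at least 2 variable columns to bootstrap")
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    tree = upgma(squareform(pdist(data)), labels=labels)
    target_sets = tree.node_leafsets()
    counts = np.zeros(len(target_sets))
    p = data.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, p, size=p)
        merges_b = linkage(pdist(data[:, cols]), method="average")
        boot_sets = set(_node_leafsets(merges_b))
        for i, s in enumerate(target_sets):
            if s in boot_sets:
                counts[i] += 1
    tree.supports = 100.0 * counts / n_boot
    return tree


def _sscp(x: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-group and total SSCP matrices."""
    xc = x - x.mean(axis=0)
    total = xc.T @ xc
    within = np.zeros_like(total)
    for g in np.unique(groups):
        xg = x[groups == g]
        xgc = xg - xg.mean(axis=0)
        within += xgc.T @ xgc
    return within, total


def wilks_lambda(x: np.ndarray, groups: np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T) for the given predictor set."""
    within, total = _sscp(np.atleast_2d(x), groups)
    sign_w, logdet_w = np.linalg.slogdet(within)
    sign_t, logdet_t = np.linalg.slogdet(total)
    if sign_t <= 0:
        raise ValueError("total SSCP is singular; reduce the predictor set")
    if sign_w <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


def stepwise_select(
    scores: np.ndarray,
    groups: np.ndarray,
    f_in: float = 3.84,
    f_out: float = 2.71,
    max_steps: int = 200,
) -> list[int]:
    """Forward-with-removal predictor selection minimising Wilks' lambda.

    At each step the candidate with the largest partial F enters if that F
    is at least ``f_in``; after every entry, any retained predictor whose
    partial F has dropped below ``f_out`` is removed.  The classical
    thresholds 3.84 / 2.71 are the defaults.  Entry order is returned.
    """
    if f_out >= f_in:
        raise ValueError("f_out must be < f_in to avoid cycling")
    x = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    n, m = x.shape
    g = len(np.unique(groups))
    if g < 2:
        raise ValueError("need at least two groups")
    selected: list[int] = []

    def lam(idx: list[int]) -> float:
        if not idx:
            return 1.0
        return wilks_lambda(x[:, idx], groups)

    def partial_f(lam_reduced: float, lam_full: float, p_full: int) -> float:
        # F for the one added variable: reduced model has p_full - 1 predictors
        if lam_full <= 0:
            return np.inf
        return (lam_reduced / lam_full - 1.0) * (n - g - p_full + 1) / (g - 1)

    for _ in range(max_steps):
        changed = False
        lam_cur = lam(selected)
        best_f, best_j = -np.inf, None
        for j in range(m):
            if j in selected:
                continue
            try:
                lam_new = lam(selected + [j])
            except ValueError:
                continue
            f = partial_f(lam_cur, lam_new, len(selected) + 1)
            if f > best_f:
                best_f, best_j = f, j
        if best_j is not None and best_f >= f_in and n - g - len(selected) > 0:
            selected.append(best_j)
            changed = True
        # removal sweep
        removed = True
        while removed and len(selected) > 1:
            removed = False
            lam_full = lam(selected)
            worst_f, worst_j = np.inf, None
            for j in selected:
                rest = [i for i in selected if i != j]
                f = partial_f(lam(rest), lam_full, len(selected))
                if f < worst_f:
                    worst_f, worst_j = f, j
            if worst_j is not None and worst_f < f_out:
                selected.remove(worst_j)
                removed = True
                changed = True
        if not changed:
            break
    return selected


def lda_classify(
    scores: np.ndarray,
    groups: np.ndarray,
    queries: np.ndarray | None = None,
    query_ids: list[str] | None = None,
) -> DiscriminantResult:
    """Two-group linear discriminant analysis with leave-one-out CV.

    The discriminant direction is ``pooled_cov^{-1} (mean_1 - mean_2)``;
    specimens are assigned by the sign of their score about the midpoint
    of the projected group means (equal priors).  Wilks' lambda is tested
    with the Bartlett chi-square approximation
    ``-(n - 1 - (p + g)/2) ln(lambda)`` on ``p (g - 1)`` degrees of
    freedom.  Cross-validation refits means and pooled covariance without
    the held-out specimen (the predictor set itself is fixed).
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise ValueError(f"two-group LDA requires exactly 2 groups, got {levels}")
    n, p = x.shape
    g = 2

    def fit(xx: np.ndarray, gg: np.ndarray) -> tuple[np.ndarray, float, dict[str, np.ndarray]]:
        means = {lv: xx[gg == lv].mean(axis=0) for lv in levels}
        within, _ = _sscp(xx, gg)
        pooled = within / (len(xx) - g)
        try:
            w = np.linalg.solve(pooled, means[levels[0]] - means[levels[1]])
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular pooled within-group covariance; reduce dimensionality "
                "(e.g. stepwise_select or fewer PC scores)"
            ) from exc
        thresh = float(w @ (means[levels[0]] + means[levels[1]]) / 2.0)
        return w, thresh, means

    w, thresh, means = fit(x, groups)
    lam = wilks_lambda(x, groups)
    chi_sq = -(n - 1 - (p + g) / 2.0) * np.log(max(lam, 1e-300))
    df = p * (g - 1)
    p_value = float(chi2.sf(chi_sq, df))

    def assign(w_, thresh_, row) -> tuple[str, float]:
        score = float(w_ @ row - thresh_)
        return (levels[0] if score > 0 else levels[1]), score

    cv_pred = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if min((groups[mask] == lv).sum() for lv in levels) < 2:
            raise ValueError("groups too small for leave-one-out CV")
        w_i, t_i, _ = fit(x[mask], groups[mask])
        cv_pred.append(assign(w_i, t_i, x[i])[0])
    cv_pred = np.array(cv_pred)
    per_group = {
        lv: 100.0 * float(np.mean(cv_pred[groups == lv] == lv)) for lv in levels
    }
    cv_rate = 100.0 * float(np.mean(cv_pred == groups))
    confusion = pd.DataFrame(
        {
            pred: [int(np.sum((groups == lv) & (cv_pred == pred))) for lv in levels]
            for pred in levels
        },
        index=levels,
    )

    assignments: dict[str, tuple[str, float]] = {}
    if queries is not None:
        q = np.atleast_2d(np.asarray(queries, dtype=float))
        if query_ids is None:
            query_ids = [f"query_{i}" for i in range(len(q))]
        for qid, row in zip(query_ids, q):
            assignments[qid] = assign(w, thresh, row)

    return DiscriminantResult(
        retained=list(range(p)),
        wilks_lambda=lam,
        chi_square=float(chi_sq),
        df=df,
        p_value=p_value,
        per_group_rates=per_group,
        cv_rate=cv_rate,
        assignments=assignments,
        direction=w,
        group_means=means,
        confusion=confusion,
    )


def nested_cv_rate(
    scores: np.ndarray,
    groups: np.ndarray,
    f_in: float = 3.84,
    f_out: float = 2.71,
) -> float:
    """Leave-one-out % correct with stepwise selection re-run in every fold.

    Unlike the fixed-selection rate in :func:`lda_classify` (the convention
    of the classical stepwise-DFA tools), this nested variant does not let
    the held-out specimen influence predictor selection, giving an honest
    error estimate.  Folds whose selection comes back empty fall back to
    the first principal predictor.
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise ValueError("nested CV requires exactly 2 groups")
    n = x.shape[0]
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sel = stepwise_select(x[mask], groups[mask], f_in=f_in, f_out=f_out) or [0]
        xt = x[mask][:, sel]
        means = {lv: xt[groups[mask] == lv].mean(axis=0) for lv in levels}
        within, _ = _sscp(xt, groups[mask])
        pooled = within / (len(xt) - 2)
        w = np.linalg.solve(pooled, means[levels[0]] - means[levels[1]])
        thresh = float(w @ (means[levels[0]] + means[levels[1]]) / 2.0)
        pred = levels[0] if float(w @ x[i, sel]) > thresh else levels[1]
        correct += pred == groups[i]
    return 100.0 * correct / n


def kmeans_two(
    data: np.ndarray, restarts: int = 25, seed: int = 0, max_iter: int = 300
) -> tuple[np.ndarray, float, np.ndarray]:
    """k-means with k = 2 (Lloyd iterations, best of ``restarts`` starts).

    Returns (labels, within-group SS, centroids).  Assignment ties go to
    the lower cluster index (via argmin), so results are deterministic for
    a given seed; a run that empties a cluster is redrawn.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    rng = np.random.default_rng(seed)
    best_ss, best_labels, best_centroids = np.inf, None, None
    attempts = 0
    done = 0
    while done < restarts and attempts < restarts * 10:
        attempts += 1
        idx = rng.choice(n, size=2, replace=False)
        if np.allclose(x[idx[0]], x[idx[1]]):
            continue
        centroids = x[idx].copy()
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            dists = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            new_labels = np.argmin(dists, axis=1)
            if np.all(new_labels == labels) and _ > 0:
                break
            labels = new_labels
            if len(np.unique(labels)) < 2:
                break
            centroids = np.stack([x[labels == c].mean(axis=0) for c in (0, 1)])
        if len(np.unique(labels)) < 2:
            continue  # empty cluster: restart this run
        done += 1
        ss = float(sum(((x[labels == c] - centroids[c]) ** 2).sum() for c in (0, 1)))
        if ss < best_ss - 1e-12:
            best_ss, best_labels, best_centroids = ss, labels.copy(), centroids.copy()
    if best_labels is None:
        raise ValueError("k-means failed to find a 2-cluster partition (degenerate data?)")
    # canonical labelling: cluster containing specimen 0 is cluster 0
    if best_labels[0] == 1:
        best_labels = 1 - best_labels
        best_centroids = best_centroids[::-1].copy()
    return best_labels, best_ss, best_centroids
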