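"""Differential miRNA analysis for minimal two-class designs.

Three tools, all rank/permutation-based so they remain honest at the tiny
sample sizes typical of pilot microarray experiments (down to 2 vs 2):

* **SAM** — the moderated difference statistic ``d_i = r_i / (s_i + s0)``
  with a permutation-derived expected order-statistic null and an FDR
  estimate.  ``r_i`` is the treated-minus-normal mean difference, ``s_i``
  the pooled standard error and ``s0`` a fudge constant chosen to minimise
  the coefficient of variation of ``|d|`` across windows of the ``s``
  distribution (or fixed by the caller).
* **average-linkage hierarchical clustering** of the called features, with
  1 - Pearson correlation as the default distance.
* **k-TSP** — the k top-scoring-pairs score: for features (i, j)

      delta_ij = | P(X_i < X_j | treated) - P(X_i < X_j | normal) |

  estimated by within-sample comparison frequencies (ties contribute to
  neither probability), with a secondary average-rank-difference score to
  break delta ties, and greedy selection of k feature-disjoint top pairs.
  The score depends only on within-sample orderings, so it is invariant
  under any strictly increasing transform of the data.

With a 2 vs 2 design the permutation null is exact and coarse: only 6
distinct assignments of samples to classes exist, so the attainable FDR
values are granular; the granularity (number of assignments) is reported
alongside the estimate rather than hidden.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.spatial.distance import squareform

from .simulate import ExpressionMatrix

__all__ = [
    "SAM",
    "SAMResults",
    "sam_statistic",
    "hierarchical_cluster",
    "ClusterTree",
    "KTSP",
    "KTSPResults",
]

# number of distinct class assignments below which the null is enumerated
EXACT_ENUMERATION_LIMIT = 1000


def _split(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    treated = matrix.values[matrix.samples_of("treated")].to_numpy()
    normal = matrix.values[matrix.samples_of("normal")].to_numpy()
    return treated, normal


def _d_and_s(
    values: np.ndarray, treat_idx: np.ndarray, norm_idx: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """d and pooled standard error for an arbitrary column split."""
    x, y = values[:, treat_idx], values[:, norm_idx]
    n1, n2 = x.shape[1], y.shape[1]
    r = x.mean(axis=1) - y.mean(axis=1)
    ss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (y - y.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    s = np.sqrt(a * ss)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(s + s0 > 0, r / (s + s0), 0.0)
    return d, s


def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Fudge constant minimising the coefficient of variation of |d| across
    s-quantile windows, over the percentile grid {0, 5, ..., 100} of s."""
    grid = np.percentile(s, np.arange(0, 101, 5))
    n_windows = min(10, max(2, len(s) // 5))
    edges = np.quantile(s, np.linspace(0, 1, n_windows + 1))
    win = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)
    best_s0, best_cv = float(grid[0]), np.inf
    for s0 in np.unique(grid):
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(s + s0 > 0, r / (s + s0), 0.0)
        mads = np.array(
            [np.median(np.abs(d[win == w])) for w in range(n_windows) if (win == w).any()]
        )
        m = mads.mean()
        cv = np.inf if m == 0 else mads.std() / m
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_statistic(
    matrix: ExpressionMatrix, s0: float | None = None
) -> tuple[pd.Series, pd.Series, float]:
    """Per-feature d statistic and pooled standard error.

    ``s0=None`` selects the fudge constant by CV-minimisation; a number
    fixes it.  Returns (d, s, s0_used).
    """
    for lbl in ("treated", "normal"):
        if len(matrix.samples_of(lbl)) < 2:
            raise ValueError(f"class {lbl!r} has fewer than 2 samples")
    values = matrix.values.to_numpy()
    cols = list(matrix.values.columns)
    treat_idx = np.array([cols.index(c) for c in matrix.samples_of("treated")])
    norm_idx = np.array([cols.index(c) for c in matrix.samples_of("normal")])
    _, s = _d_and_s(values, treat_idx, norm_idx, 0.0)
    r = values[:, treat_idx].mean(axis=1) - values[:, norm_idx].mean(axis=1)
    if s0 is None:
        s0 = _choose_s0(r, s)
    d, s = _d_and_s(values, treat_idx, norm_idx, s0)
    idx = matrix.values.index
    return pd.Series(d, index=idx, name="d"), pd.Series(s, index=idx, name="s"), s0


def _class_assignments(n_treated: int, n_total: int) -> list[tuple[int, ...]]:
    """All distinct assignments of n_treated of n_total samples to 'treated'."""
    return list(itertools.combinations(range(n_total), n_treated))


class SAM:
    """Significance analysis for a two-class expression matrix.

    Parameters
    ----------
    matrix
        Expression matrix with ``treated`` / ``normal`` class labels.
    s0
        Fudge constant; None (default) selects it by CV-minimisation over a
        percentile grid of the per-feature standard errors.
    """

    def __init__(self, matrix: ExpressionMatrix, s0: float | None = None) -> None:
        self.matrix = matrix
        self.s0 = s0
        self._prep: tuple | None = None  # permutation work is delta-independent

    def _prepare(self) -> tuple:
        if self._prep is not None:
            return self._prep
        matrix = self.matrix
        d, s, s0_used = sam_statistic(matrix, self.s0)

        values = matrix.values.to_numpy()
        cols = list(matrix.values.columns)
        treated = matrix.samples_of("treated")
        treat_idx = tuple(sorted(cols.index(c) for c in treated))
        n_total = len(cols)

        assignments = _class_assignments(len(treated), n_total)
        if len(assignments) > EXACT_ENUMERATION_LIMIT:
            raise NotImplementedError(
                "sampled permutation mode not needed below the enumeration limit"
            )
        perm_sorted = np.empty((len(assignments), values.shape[0]))
        for k, treat in enumerate(assignments):
            norm = tuple(i for i in range(n_total) if i not in treat)
            dk, _ = _d_and_s(values, np.array(treat), np.array(norm), s0_used)
            perm_sorted[k] = np.sort(dk)
        expected_d = perm_sorted.mean(axis=0)
        self._prep = (d, s, s0_used, treat_idx, assignments, perm_sorted, expected_d)
        return self._prep

    def fit(self, delta: float = 1.0) -> "SAMResults":
        """Call differential features at threshold ``delta``.

        Features are ordered by d; the null expectation at each rank is the
        permutation average of the rank-sorted d over all distinct class
        assignments (exact enumeration whenever their number is below the
        enumeration limit — 6 for a 2v2 design).  A feature is called when
        ``|d_(i) - expected_d_(i)| > delta``, up or down by the sign of the
        difference.  The FDR estimate is the median permutation false-call
        count (observed assignment excluded) divided by the observed call
        count, capped at 1; 0 by convention when nothing is called.
        """
        if delta < 0:
            raise ValueError("delta must be >= 0")
        d, s, s0_used, treat_idx, assignments, perm_sorted, expected_d = self._prepare()
        n_assign = len(assignments)

        order = np.argsort(d.to_numpy(), kind="stable")
        d_sorted = d.to_numpy()[order]
        diff = d_sorted - expected_d
        called_mask = np.abs(diff) > delta
        feat = d.index.to_numpy()[order]
        called_up = {f for f, m, dv in zip(feat, called_mask, diff) if m and dv > 0}
        called_down = {f for f, m, dv in zip(feat, called_mask, diff) if m and dv < 0}
        n_called = len(called_up) + len(called_down)

        # permutation false calls against the same expected_d, observed
        # assignment excluded from the null median
        false_counts = []
        for k, treat in enumerate(assignments):
            if tuple(sorted(treat)) == treat_idx:
                continue
            false_counts.append(int(np.sum(np.abs(perm_sorted[k] - expected_d) > delta)))
        if n_called == 0:
            fdr = 0.0
        else:
            fdr = min(1.0, float(np.median(false_counts)) / n_called)

        table = pd.DataFrame(
            {
                "feature": feat,
                "d": d_sorted,
                "expected_d": expected_d,
                "difference": diff,
                "called": called_mask,
                "direction": [
                    ("up" if dv > 0 else "down") if m else "none"
                    for m, dv in zip(called_mask, diff)
                ],
            }
        ).set_index("feature")

        return SAMResults(
            model=self,
            d=d,
            s=s,
            s0=s0_used,
            delta=delta,
            expected_d=pd.Series(expected_d, index=feat, name="expected_d"),
            table=table,
            called_up=called_up,
            called_down=called_down,
            fdr_estimate=fdr,
            n_permutations=n_assign,
        )

    # -- threshold helpers ----------------------------------------------
    def delta_for_call_count(self, n_calls: int) -> float:
        """Delta that calls exactly the ``n_calls`` most extreme features."""
        base = self.fit(delta=0.0)
        gaps = np.sort(np.abs(base.table["difference"].to_numpy()))[::-1]
        if n_calls <= 0 or n_calls > len(gaps):
            raise ValueError("n_calls outside [1, n_features]")
        hi = gaps[n_calls - 1]
        lo = gaps[n_calls] if n_calls < len(gaps) else 0.0
        return float((hi + lo) / 2.0)

    def delta_for_fdr(self, max_fdr: float) -> float:
        """Smallest delta on the observed |difference| grid whose estimated
        FDR is at most ``max_fdr``."""
        base = self.fit(delta=0.0)
        grid = np.sort(np.unique(np.abs(base.table["difference"].to_numpy())))
        for g in grid:
            res = self.fit(delta=float(g))
            if res.fdr_estimate <= max_fdr:
                return float(g)
        return float(grid[-1]) + 1.0


@dataclass
class SAMResults:
    """Fitted SAM call set with its permutation null."""

    model: SAM
    d: pd.Series
    s: pd.Series
    s0: float
    delta: float
    expected_d: pd.Series
    table: pd.DataFrame
    called_up: set
    called_down: set
    fdr_estimate: float
    n_permutations: int

    @property
    def called(self) -> set:
        return self.called_up | self.called_down

    def summary(self) -> str:
        return "\n".join(
            [
                "SAM two-class analysis",
                "======================",
                f"features: {len(self.d)}   s0: {self.s0:.4g}   delta: {self.delta:.4g}",
                f"permutation null: {self.n_permutations} distinct class assignments (exact)",
                f"called up: {len(self.called_up)}   called down: {len(self.called_down)}",
                f"estimated FDR: {self.fdr_estimate:.4g} "
                f"(granularity 1/{self.n_permutations - 1} permutations)",
            ]
        )


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class ClusterTree:
    """Average-linkage merge tree: (node_a, node_b, height) triples in merge
    order, scipy linkage matrix and the dendrogram leaf order."""

    merges: list[tuple[int, int, float]]
    linkage_matrix: np.ndarray
    leaf_order: list[str]

    def to_newick(self) -> str:
        labels = self.leaf_order  # leaves carry their feature ids
        n = len(labels)
        # rebuild names in original leaf index space
        names = {i: lbl for i, lbl in zip(self._leaf_ids, self._leaf_labels)}
        heights = {i: 0.0 for i in range(n)}
        node = dict(names)
        for k, (a, b, h) in enumerate(self.merges):
            branch_a = h - heights[a]
            branch_b = h - heights[b]
            node[n + k] = f"({node[a]}:{branch_a:.6g},{node[b]}:{branch_b:.6g})"
            heights[n + k] = h
        return node[n + len(self.merges) - 1] + ";"

    # populated by hierarchical_cluster
    _leaf_ids: list[int] = None  # type: ignore[assignment]
    _leaf_labels: list[str] = None  # type: ignore[assignment]


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    features: list[str] | None = None,
    metric: str = "correlation",
) -> ClusterTree:
    """Average-linkage agglomeration of features.

    ``metric``: ``"correlation"`` (1 - Pearson, the convention of the classic
    expression-clustering tools) or ``"euclidean"``.  Cluster-to-cluster
    distance is the mean pairwise distance.  A constant feature has no
    defined correlation distance and raises, naming the feature.
    """
    sub = matrix.values if features is None else matrix.values.loc[features]
    if len(sub) < 2:
        raise ValueError("need at least 2 features to cluster")
    x = sub.to_numpy()
    if metric == "correlation":
        sd = x.std(axis=1)
        if (sd == 0).any():
            bad = sub.index[sd == 0][0]
            raise ValueError(
                f"feature {bad!r} is constant; correlation distance undefined"
            )
        dist = 1.0 - np.corrcoef(x)
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        condensed = squareform(dist, checks=False)
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(x, metric="euclidean")
    else:
        raise ValueError("metric must be 'correlation' or 'euclidean'")
    z = linkage(condensed, method="average")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    order = leaves_list(z)
    labels = list(sub.index)
    tree = ClusterTree(
        merges=merges,
        linkage_matrix=z,
        leaf_order=[labels[i] for i in order],
    )
    tree._leaf_ids = list(range(len(labels)))
    tree._leaf_labels = labels
    return tree


# ---------------------------------------------------------------------------
# k-TSP


class KTSP:
    """k top-scoring-pairs model for a two-class expression matrix."""

    def __init__(self, matrix: ExpressionMatrix) -> None:
        self.matrix = matrix

    def fit(self, k: int = 1) -> "KTSPResults":
        """Score every ordered feature pair and greedily retain the top ``k``
        feature-disjoint pairs by (delta desc, secondary rank score desc)."""
        matrix = self.matrix
        n_features = len(matrix.values)
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > n_features // 2:
            raise ValueError(f"k={k} exceeds floor(n_features/2)={n_features // 2}")
        treated, normal = _split(matrix)
        feats = list(matrix.values.index)

        # within-sample ranks for the secondary score
        rank_t = pd.DataFrame(treated).rank(axis=0).to_numpy()
        rank_n = pd.DataFrame(normal).rank(axis=0).to_numpy()

        rows = []
        for i in range(n_features):
            for j in range(i + 1, n_features):
                p_t = np.mean(treated[i] < treated[j])
                p_n = np.mean(normal[i] < normal[j])
                delta = abs(p_t - p_n)
                gamma = abs(
                    (rank_t[i] - rank_t[j]).mean() - (rank_n[i] - rank_n[j]).mean()
                )
                rows.append((feats[i], feats[j], float(delta), float(gamma)))
        scores = pd.DataFrame(rows, columns=["feature_i", "feature_j", "delta", "gamma"])
        scores = scores.sort_values(
            ["delta", "gamma", "feature_i", "feature_j"],
            ascending=[False, False, True, True],
        ).reset_index(drop=True)

        used: set[str] = set()
        selected = []
        for _, r in scores.iterrows():
            if r["feature_i"] in used or r["feature_j"] in used:
                continue
            selected.append(r)
            used.update((r["feature_i"], r["feature_j"]))
            if len(selected) == k:
                break
        return KTSPResults(
            model=self, scores=scores, pairs=pd.DataFrame(selected).reset_index(drop=True), k=k
        )


@dataclass
class KTSPResults:
    """All pair scores plus the k selected disjoint top pairs."""

    model: KTSP
    scores: pd.DataFrame
    pairs: pd.DataFrame
    k: int

    def summary(self) -> str:
        lines = [
            "k-TSP pair discovery",
            "====================",
            f"k = {self.k}  (of {len(self.scores)} candidate pairs)",
            self.pairs.to_string(index=False),
        ]
        return "\n".join(lines)
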