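"""Feature-selection algorithms: t-test prefilter plus seven rankers.

The benchmark compares seven rankers — permutation random-forest
importance, l0-norm minimisation, infinite feature selection, feature
selection via concave minimisation (FSV), minimum-redundancy
maximum-relevance (mRMR), ReliefF, and the Laplacian score — each
producing a full ordering (best first) of the features surviving a
per-feature Welch t-test prefilter on the training fold.

All rankers are deterministic given their seed; score ties are broken by
ascending feature index. FSV and the l0 ranker approximate their
concave-minimisation and l0-norm objectives iteratively (successive LPs
and multiplicative margin reweighting respectively); exact combinatorial
solvers are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CohortTable",
    "RankingResult",
    "ttest_prefilter",
    "rank_rf_importance",
    "rank_l0",
    "rank_inf_fs",
    "rank_fsv",
    "rank_mrmr",
    "rank_relieff",
    "rank_laplacian",
    "SELECTORS",
]


@dataclass
class CohortTable:
    """Lesion-level feature matrix with labels and patient structure."""

    X: np.ndarray
    y: np.ndarray
    patient_ids: np.ndarray
    lesion_ids: np.ndarray
    diameters_mm: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=int)
        n = len(self.y)
        for name in ("patient_ids", "lesion_ids", "diameters_mm"):
            setattr(self, name, np.asarray(getattr(self, name)))
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != n samples")
        if self.X.shape != (n, len(self.feature_names)):
            raise ValueError("X shape inconsistent with labels/feature names")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.y)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortTable":
        meta = ["lesion_id", "patient_id", "label", "diameter_mm"]
        feats = [c for c in df.columns if c not in meta]
        return cls(
            X=df[feats].to_numpy(dtype=np.float64),
            y=df["label"].to_numpy(),
            patient_ids=df["patient_id"].to_numpy(),
            lesion_ids=df["lesion_id"].to_numpy(),
            diameters_mm=df["diameter_mm"].to_numpy(dtype=float),
            feature_names=tuple(feats),
        )

    def subset(self, rows=None, cols=None) -> "CohortTable":
        rows = slice(None) if rows is None else np.asarray(rows)
        tab = CohortTable(
            X=self.X[rows][:, cols] if cols is not None else self.X[rows],
            y=self.y[rows],
            patient_ids=self.patient_ids[rows],
            lesion_ids=self.lesion_ids[rows],
            diameters_mm=self.diameters_mm[rows],
            feature_names=tuple(np.asarray(self.feature_names)[cols])
            if cols is not None
            else self.feature_names,
        )
        return tab


@dataclass
class RankingResult:
    """Full ordering of feature indices, best first."""

    method: str
    order: np.ndarray
    scores: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.order = np.asarray(self.order, dtype=int)
        n = len(self.order)
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValueError(f"{self.method}: order is not a permutation")

    def top(self, k: int) -> np.ndarray:
        return self.order[: max(1, min(k, len(self.order)))]


def _rank_descending(method: str, scores: np.ndarray, seed=None) -> RankingResult:
    """Order by score descending, ties broken by ascending feature index."""
    scores = np.asarray(scores, dtype=np.float64)
    order = np.lexsort((np.arange(len(scores)), -scores))
    return RankingResult(method=method, order=order, scores=scores, seed=seed)


# ---------------------------------------------------------------------------
# t-test prefilter


def ttest_prefilter(table: CohortTable, alpha: float = 0.05) -> np.ndarray:
    """Indices of features with Welch two-sample t-test p < alpha.

    Zero-variance features are kept only if the class means differ
    exactly (p treated as 0) and dropped otherwise. If nothing survives,
    the single smallest-p feature is kept so downstream ranking always
    has input.
    """
    classes = np.unique(table.y)
    if len(classes) < 2:
        raise ValueError("prefilter needs both classes present")
    a = table.X[table.y == 0]
    b = table.X[table.y == 1]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("prefilter needs >= 2 samples per class")
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.asarray(p)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        means_differ = a.mean(axis=0) != b.mean(axis=0)
        p[degenerate & means_differ] = 0.0
        p[degenerate & ~means_differ] = 1.0
    keep = np.nonzero(p < alpha)[0]
    if len(keep) == 0:
        keep = np.array([int(np.argmin(p))])
    return keep


# ---------------------------------------------------------------------------
# permutation random-forest importance


def rank_rf_importance(
    table: CohortTable,
    n_trees: int = 100,
    seed: int = 0,
    max_oob_block: int = 64,
) -> RankingResult:
    """Permutation importance on out-of-bag samples of a bagged forest.

    Each tree is fit on a bootstrap sample; its out-of-bag accuracy is
    compared with the accuracy after permuting one feature column at a
    time, and the drop is averaged over trees.
    """
    X, y = np.ascontiguousarray(table.X, dtype=np.float32), table.y
    n, f = X.shape
    rng = np.random.default_rng(seed)
    drops = np.zeros(f)
    used = np.zeros(f)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        if len(oob) < 2:
            continue
        Xo, yo = X[oob], y[oob]
        base = np.mean(tree.predict(Xo) == yo)
        # batch permuted copies so each tree predicts once per feature block
        for start in range(0, f, max_oob_block):
            idx = np.arange(start, min(start + max_oob_block, f))
            block = np.repeat(Xo[None, :, :], len(idx), axis=0)
            for bi, fi in enumerate(idx):
                block[bi, :, fi] = Xo[rng.permutation(len(oob)), fi]
            preds = tree.predict(block.reshape(-1, f)).reshape(len(idx), -1)
            drops[idx] += base - (preds == yo[None, :]).mean(axis=1)
            used[idx] += 1
    scores = np.divide(drops, used, out=np.zeros(f), where=used > 0)
    return _rank_descending("rf", scores, seed=seed)


# ---------------------------------------------------------------------------
# mRMR


def _discretize_terciles(X: np.ndarray) -> np.ndarray:
    """Per-feature tercile binning to {0,1,2}."""
    q = np.quantile(X, [1 / 3, 2 / 3], axis=0)
    return (X > q[0]) .astype(np.int8) + (X > q[1]).astype(np.int8)


def _mi_all_vs(disc: np.ndarray, target: np.ndarray, n_target_levels: int) -> np.ndarray:
    """Plug-in mutual information (bits) of every column with ``target``."""
    n, f = disc.shape
    nb = 3
    flat = (
        np.repeat(np.arange(f), n) * (nb * n_target_levels)
        + disc.T.ravel() * n_target_levels
        + np.tile(target, f)
    )
    joint = np.bincount(flat, minlength=f * nb * n_target_levels).reshape(
        f, nb, n_target_levels
    ) / n
    px = joint.sum(axis=2, keepdims=True)
    py = joint.sum(axis=1, keepdims=True)
    with np.errstate(all="ignore"):
        term = joint * np.log2(joint / (px * py))
    return np.nansum(term, axis=(1, 2))


def rank_mrmr(table: CohortTable, k: int | None = None, seed: int = 0) -> RankingResult:
    """Greedy max-relevance min-redundancy ordering.

    Features are tercile-discretized; at each step the feature
    maximising I(f; y) minus the mean mutual information with the
    already-selected set is appended. ``k`` limits the greedy depth;
    remaining features are appended by residual mRMR score.
    """
    disc = _discretize_terciles(table.X)
    f = disc.shape[1]
    y = table.y.astype(np.int64)
    relevance = _mi_all_vs(disc, y, 2)
    k = f if k is None else min(k, f)

    selected: list[int] = []
    red_sum = np.zeros(f)
    available = np.ones(f, dtype=bool)
    final_scores = np.zeros(f)
    for step in range(k):
        crit = relevance - (red_sum / step if step else 0.0)
        crit_masked = np.where(available, crit, -np.inf)
        best = int(np.argmax(crit_masked))  # argmax takes lowest index on ties
        selected.append(best)
        available[best] = False
        final_scores[best] = f - step  # rank-encoded score, best first
        if step < k - 1:
            red_sum += _mi_all_vs(disc, disc[:, best].astype(np.int64), 3)
    if available.any():
        rest = np.nonzero(available)[0]
        crit = relevance[rest] - red_sum[rest] / max(len(selected), 1)
        order_rest = rest[np.lexsort((rest, -crit))]
        for i, fi in enumerate(order_rest):
            final_scores[fi] = -i
    return _rank_descending("mrmr", final_scores, seed=seed)


def mutual_information_with_label(table: CohortTable) -> np.ndarray:
    """Tercile plug-in MI (bits) of each feature with the label."""
    return _mi_all_vs(_discretize_terciles(table.X), table.y.astype(np.int64), 2)


# ---------------------------------------------------------------------------
# ReliefF


def rank_relieff(
    table: CohortTable, n_neighbors: int = 10, seed: int = 0
) -> RankingResult:
    """ReliefF weights from k nearest hits and misses of every instance.

    Features are internally min-max scaled; distances are Manhattan.
    Classes smaller than ``n_neighbors + 1`` reduce k with a warning.
    """
    X = table.X
    y = table.y
    n, f = X.shape
    rng_span = np.ptp(X, axis=0)
    rng_span[rng_span == 0] = 1.0
    Xs = (X - X.min(axis=0)) / rng_span

    min_class = min(np.sum(y == c) for c in np.unique(y))
    k = n_neighbors
    if min_class < k + 1:
        k = max(1, min_class - 1)
        warnings.warn(
            f"ReliefF: class with {min_class} members; reducing k to {k}",
            stacklevel=2,
        )
    w = np.zeros(f)
    for i in range(n):
        d = np.abs(Xs - Xs[i]).sum(axis=1)
        d[i] = np.inf
        same = np.nonzero(y == y[i])[0]
        diff = np.nonzero(y != y[i])[0]
        hits = same[np.argsort(d[same], kind="stable")[:k]]
        misses = diff[np.argsort(d[diff], kind="stable")[:k]]
        if len(hits):
            w -= np.abs(Xs[hits] - Xs[i]).mean(axis=0) / n
        if len(misses):
            w += np.abs(Xs[misses] - Xs[i]).mean(axis=0) / n
    return _rank_descending("relieff", w, seed=seed)


# ---------------------------------------------------------------------------
# Laplacian score


def rank_laplacian(
    table: CohortTable, n_neighbors: int = 5, bandwidth: float | None = None, seed: int = 0
) -> RankingResult:
    """Unsupervised Laplacian-score ranking (labels unused).

    A symmetric k-NN graph with heat-kernel weights is built on the
    standardized samples; each feature's score is its graph smoothness
    normalised by its variance, and *smaller* is better, so the ranking
    is by ascending score.
    """
    X = table.X
    n, f = X.shape
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd

    d2 = np.maximum(
        (Z**2).sum(1)[:, None] + (Z**2).sum(1)[None, :] - 2 * Z @ Z.T, 0.0
    )
    np.fill_diagonal(d2, np.inf)
    k = min(n_neighbors, n - 1)
    knn = np.argsort(d2, axis=1, kind="stable")[:, :k]
    adj = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    adj[rows, knn.ravel()] = True
    adj |= adj.T
    edge_d2 = d2[adj]
    t = bandwidth if bandwidth is not None else float(np.mean(edge_d2))
    if t <= 0:
        t = 1.0
    W = np.where(adj, np.exp(-d2 / t), 0.0)
    D = W.sum(axis=1)

    scores = np.empty(f)
    dsum = D.sum()
    for j in range(f):
        fr = X[:, j]
        fr = fr - (fr @ D) / dsum
        denom = fr @ (D * fr)
        num = fr @ (D * fr) - fr @ (W @ fr)  # fr' L fr
        scores[j] = num / denom if denom > 0 else np.inf
    # ascending score = best first; reuse descending ranker on negated scores
    finite = np.isfinite(scores)
    neg = np.where(finite, -scores, -np.inf)
    res = _rank_descending("laplacian", neg, seed=seed)
    res.scores = scores
    return res


# ---------------------------------------------------------------------------
# infinite feature selection


def rank_inf_fs(
    table: CohortTable, mixing: float = 0.5, r_factor: float = 0.9, seed: int = 0
) -> RankingResult:
    """Infinite feature selection: path-integral energy over a feature graph.

    Adjacency combines pairwise maximum dispersion and 1 - |correlation|;
    the score is the row sum of (I - rA)^-1 - I with r = r_factor /
    spectral_radius(A), i.e. the sum over paths of all lengths through
    each feature.
    """
    X = table.X
    f = X.shape[1]
    if f == 1:
        return RankingResult("inf_fs", np.array([0]), np.array([0.0]), seed=seed)
    sd = X.std(axis=0)
    sd_norm = sd / sd.max() if sd.max() > 0 else np.zeros_like(sd)
    with np.errstate(all="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    A = mixing * np.maximum.outer(sd_norm, sd_norm) + (1 - mixing) * (
        1 - np.abs(corr)
    )
    rho = float(np.max(np.abs(np.linalg.eigvalsh((A + A.T) / 2))))
    r = r_factor / rho if rho > 0 else r_factor
    eye = np.eye(f)
    for _ in range(8):
        try:
            S = np.linalg.inv(eye - r * A) - eye
            if np.isfinite(S).all():
                break
        except np.linalg.LinAlgError:
            pass
        r *= 0.5
        warnings.warn(f"inf_fs: (I - rA) ill-conditioned; reducing r to {r}", stacklevel=2)
    scores = S.sum(axis=1)
    return _rank_descending("inf_fs", scores, seed=seed)


def inf_fs_adjacency(table: CohortTable, mixing: float = 0.5):
    """Expose (A, r) used by rank_inf_fs, for series-convergence checks."""
    X = table.X
    sd = X.std(axis=0)
    sd_norm = sd / sd.max() if sd.max() > 0 else np.zeros_like(sd)
    with np.errstate(all="ignore"):
        corr = np.nan_to_num(np.corrcoef(X, rowvar=False), nan=0.0)
    A = mixing * np.maximum.outer(sd_norm, sd_norm) + (1 - mixing) * (1 - np.abs(corr))
    rho = float(np.max(np.abs(np.linalg.eigvalsh((A + A.T) / 2))))
    return A, rho


# ---------------------------------------------------------------------------
# FSV (concave minimisation)


def rank_fsv(
    table: CohortTable,
    regularization: float = 0.5,
    alpha: float = 0.5,
    n_iter: int = 8,
    seed: int = 0,
) -> RankingResult:
    """Feature selection via concave minimisation, by successive LPs.

    A linear separator w is fit with hinge slacks while the concave
    penalty sum(1 - exp(-alpha * |w|)) is linearised at each iterate,
    yielding a reweighted-l1 LP whose weights decay exponentially on
    already-small coefficients. Features are ranked by the final |w|;
    features the concave iteration drove to zero are ordered among
    themselves by their first-iteration (uniform-penalty) weights, so the
    ranking below the selected support still reflects separating power.
    The default concavity (alpha = 0.5) is deliberately gentle: the
    penalty 1 - exp(-alpha|w|) stays near-linear over typical weight
    magnitudes, so the iteration shrinks weights gradually and preserves
    a graded ordering instead of collapsing to a one-feature support,
    which is what a *ranking* use of the method needs.
    """
    X, y = table.X, np.where(table.y > 0, 1.0, -1.0)
    n, f = X.shape
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    pos, neg = y > 0, y < 0
    m_pos, m_neg = max(pos.sum(), 1), max(neg.sum(), 1)
    lam = regularization

    # variables: [w (f), v (f), gamma (1), slacks (n)]
    nv = 2 * f + 1 + n
    c = np.zeros(nv)
    c[2 * f + 1 :][pos] = (1 - lam) / m_pos
    c[2 * f + 1 :][neg] = (1 - lam) / m_neg

    rows = []
    b = []
    for i in range(n):
        row = np.zeros(nv)
        row[:f] = -y[i] * Xs[i]
        row[2 * f] = y[i]
        row[2 * f + 1 + i] = -1.0
        rows.append(row)
        b.append(-1.0)
    for j in range(f):  # w_j - v_j <= 0 and -w_j - v_j <= 0
        r1 = np.zeros(nv)
        r1[j], r1[f + j] = 1.0, -1.0
        r2 = np.zeros(nv)
        r2[j], r2[f + j] = -1.0, -1.0
        rows += [r1, r2]
        b += [0.0, 0.0]
    A_ub = np.vstack(rows)
    b_ub = np.asarray(b)
    bounds = (
        [(None, None)] * f + [(0, None)] * f + [(None, None)] + [(0, None)] * n
    )

    v = np.ones(f)
    w = np.zeros(f)
    w_first = np.zeros(f)
    for it in range(n_iter):
        eps = alpha * np.exp(-alpha * v)
        c_it = c.copy()
        c_it[f : 2 * f] = lam * eps
        res = optimize.linprog(c_it, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
        if not res.success:
            warnings.warn(
                "FSV LP failed; falling back to plain l1 weighting", stacklevel=2
            )
            c_it[f : 2 * f] = lam
            res = optimize.linprog(
                c_it, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs"
            )
            if not res.success:
                break
        w_new = res.x[:f]
        if it == 0:
            w_first = np.abs(w_new)
        if np.allclose(w_new, w, atol=1e-9):
            w = w_new
            break
        w = w_new
        v = np.abs(w)
    scores = np.abs(w)
    # lexicographic order: final weight, then first-pass weight, then index
    order = np.lexsort((np.arange(f), -w_first, -scores))
    return RankingResult(method="fsv", order=order, scores=scores, seed=seed)


# ---------------------------------------------------------------------------
# l0-norm minimisation


def rank_l0(
    table: CohortTable,
    budget: int | None = None,
    max_iter: int = 20,
    tol: float = 1e-6,
    seed: int = 0,
) -> RankingResult:
    """Approximate l0 minimisation by multiplicative margin reweighting.

    A linear SVM is refit on the feature-scaled data X * z, with
    z <- z * |w| renormalised each round; coordinates whose scale decays
    below ``tol`` (relative) are eliminated, and features are ranked by
    elimination round (survivors first, ordered by final weight).
    """
    X, y = table.X, table.y
    n, f = X.shape
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Xs = (X - X.mean(axis=0)) / sd_safe

    z = np.ones(f)
    alive = sd > 0  # constant columns can never carry margin: out first
    elimination_round = np.where(alive, np.inf, 0.0)
    final_w = np.zeros(f)
    target = budget if budget is not None else 1
    for it in range(1, max_iter + 1):
        if alive.sum() <= max(target, 1):
            break
        idx = np.nonzero(alive)[0]
        svm = LinearSVC(C=1.0, dual=False, max_iter=5000, random_state=0)
        svm.fit(Xs[:, idx] * z[idx], y)
        w = np.abs(svm.coef_.ravel())
        z_prev = z[idx].copy()
        z_new = z[idx] * w
        if z_new.max() <= 0:
            break
        z_new /= z_new.max()
        dropped = z_new < tol
        z[idx] = np.where(dropped, 0.0, z_new)
        final_w[idx] = z_new
        if dropped.any():
            elimination_round[idx[dropped]] = it
            alive[idx[dropped]] = False
        elif np.allclose(z_new, z_prev, atol=1e-12):
            break

    # survivors rank above eliminated; later elimination rounds rank higher
    survivor_bonus = np.where(np.isinf(elimination_round), 1e6, 0.0)
    scores = survivor_bonus + np.where(
        np.isinf(elimination_round), final_w, elimination_round
    )
    return _rank_descending("l0", scores, seed=seed)


SELECTORS = {
    "rf": rank_rf_importance,
    "l0": rank_l0,
    "inf_fs": rank_inf_fs,
    "fsv": rank_fsv,
    "mrmr": rank_mrmr,
    "relieff": rank_relieff,
    "laplacian": rank_laplacian,
}
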