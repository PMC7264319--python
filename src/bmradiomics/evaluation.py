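"""Selector x classifier benchmarking under cross-validation.

The benchmark grid crosses the seven feature rankers with four
classifiers (random forest, RBF support vector machine, AdaBoost stumps,
LASSO-regularised logistic regression). For every grid cell, each CV
fold runs the t-test prefilter and the ranker on the training lesions
only, fits the classifier on the top-k features for each candidate k,
and scores the held-out fold; the "optimal feature number" is the k
maximising the pooled test-fold AUC. Sensitivity, specificity and
accuracy are reported at the Youden-optimal threshold on pooled scores.

Statistical significance of an observed AUC is assessed by label
permutation: the labels are shuffled (patient-wise when folds are
grouped by patient), the *entire* cross-validated pipeline is rerun per
shuffle, and p = (1 + #{permuted AUC >= observed}) / (n_permutations + 1).

Subgroup analysis partitions the cohort at a diameter threshold
(default 10 mm): small lesions are evaluated with 10-fold CV, large
lesions with leave-one-out so enough training lesions remain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import (
    KFold,
    LeaveOneOut,
    StratifiedGroupKFold,
    StratifiedKFold,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import SELECTORS, CohortTable, ttest_prefilter

__all__ = [
    "CVPlan",
    "CellResult",
    "PermutationResult",
    "GridReport",
    "make_folds",
    "auc",
    "confusion_metrics",
    "youden_threshold",
    "build_classifier",
    "train_eval_cell",
    "run_grid",
    "permutation_test",
    "subgroup_grids",
    "render_grid",
    "CLASSIFIERS",
    "SELECTOR_ORDER",
    "CLASSIFIER_ORDER",
    "DEFAULT_K_GRID",
]

SELECTOR_ORDER = ("rf", "l0", "inf_fs", "fsv", "mrmr", "relieff", "laplacian")
CLASSIFIER_ORDER = ("rf", "svm", "adaboost", "lasso_lr")
DEFAULT_K_GRID = tuple(range(2, 51))


@dataclass(frozen=True)
class CVPlan:
    """Cross-validation scheme: k-fold or leave-one-out, lesion or patient folds."""

    scheme: str = "kfold"  # "kfold" | "loo"
    k: int = 10
    grouping: str = "lesion"  # "lesion" | "patient"
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in ("kfold", "loo"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")
        if self.grouping not in ("lesion", "patient"):
            raise ValueError(f"unknown grouping {self.grouping!r}")


def make_folds(table: CohortTable, plan: CVPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic fold index pairs (train, test) partitioning all lesions."""
    n = table.n_samples
    if plan.scheme == "loo":
        return [(tr, te) for tr, te in LeaveOneOut().split(np.zeros(n))]
    groups = table.patient_ids if plan.grouping == "patient" else None
    n_groups = len(np.unique(groups)) if groups is not None else n
    if plan.k > n_groups:
        raise ValueError(
            f"k={plan.k} exceeds the number of {plan.grouping}s ({n_groups})"
        )
    if plan.grouping == "patient":
        splitter = StratifiedGroupKFold(
            n_splits=plan.k, shuffle=True, random_state=plan.seed
        )
        return list(splitter.split(table.X, table.y, groups=groups))
    if plan.stratified:
        splitter = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
    else:
        splitter = KFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
    return list(splitter.split(table.X, table.y))


def auc(scores, labels) -> float:
    """Mann-Whitney AUC as a percentage; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2
    return 100.0 * u / (len(pos) * len(neg))


def youden_threshold(scores, labels) -> float:
    """Threshold maximising sensitivity + specificity - 1 on pooled scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cand = np.unique(scores)
    best_t, best_j = cand[0], -np.inf
    n1 = (labels == 1).sum()
    n0 = (labels == 0).sum()
    for t in cand:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n1
        spec = (~pred & (labels == 0)).sum() / n0
        j = sens + spec - 1
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def confusion_metrics(scores, labels, threshold: float) -> dict[str, float]:
    """Sensitivity / specificity / accuracy (percent) at a score threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("metrics need both classes present")
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fp = int((pred & (labels == 0)).sum())
    return {
        "sensitivity": 100.0 * tp / (tp + fn),
        "specificity": 100.0 * tn / (tn + fp),
        "accuracy": 100.0 * (tp + tn) / len(labels),
    }


class MedianGammaSVC(BaseEstimator, ClassifierMixin):
    """RBF SVM whose bandwidth is the inverse median pairwise squared distance."""

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X)
        n = len(X)
        d2 = (
            (X**2).sum(1)[:, None] + (X**2).sum(1)[None, :] - 2 * X @ X.T
        )[np.triu_indices(n, 1)]
        med = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
        self.gamma_ = 1.0 / med
        self.svc_ = SVC(kernel="rbf", C=self.C, gamma=self.gamma_)
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        return self

    def decision_function(self, X):
        return self.svc_.decision_function(np.asarray(X))

    def predict(self, X):
        return self.svc_.predict(np.asarray(X))


@dataclass
class ClassifierParams:
    """Hyperparameters of the four classifiers (none stated by the benchmark)."""

    rf_trees: int = 500
    svm_cost: float = 1.0
    adaboost_stumps: int = 200
    lasso_inner_cv: int = 5


def build_classifier(name: str, seed: int = 0, params: ClassifierParams | None = None):
    params = params or ClassifierParams()
    if name == "rf":
        return RandomForestClassifier(
            n_estimators=params.rf_trees, random_state=seed, n_jobs=1
        )
    if name == "svm":
        return Pipeline(
            [("scale", StandardScaler()), ("svc", MedianGammaSVC(C=params.svm_cost))]
        )
    if name == "adaboost":
        return AdaBoostClassifier(
            n_estimators=params.adaboost_stumps, random_state=seed
        )
    if name == "lasso_lr":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "lr",
                    LogisticRegressionCV(
                        penalty="l1",
                        solver="liblinear",
                        Cs=7,
                        cv=params.lasso_inner_cv,
                        random_state=seed,
                        max_iter=200,
                    ),
                ),
            ]
        )
    raise ValueError(f"unknown classifier {name!r}")


def _score_samples(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


@dataclass
class CellResult:
    selector: str
    classifier: str
    optimal_k: int
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    per_fold_scores: list = field(default_factory=list)
    audit: list = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "selector": self.selector,
            "classifier": self.classifier,
            "optimal_k": self.optimal_k,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def train_eval_cell(
    table: CohortTable,
    selector: str,
    classifier: str,
    plan: CVPlan,
    k_grid=DEFAULT_K_GRID,
    seed: int = 0,
    prefilter_alpha: float = 0.05,
    selector_kwargs: dict | None = None,
    classifier_params: ClassifierParams | None = None,
) -> CellResult:
    """Cross-validated evaluation of one selector/classifier pair.

    Selection (prefilter + ranking) and model fitting see only the
    training lesions of each fold; the audit list records every fold's
    train/test lesion ids so leakage is checkable after the fact.
    """
    if selector not in SELECTORS:
        raise ValueError(f"unknown selector {selector!r}")
    if classifier not in CLASSIFIER_ORDER:
        raise ValueError(f"unknown classifier {classifier!r}")
    rank_fn = SELECTORS[selector]
    # one kwargs dict may serve a whole grid of selectors: keep only the
    # keys this ranker's signature accepts
    import inspect

    accepted = set(inspect.signature(rank_fn).parameters)
    selector_kwargs = {
        k: v for k, v in (selector_kwargs or {}).items() if k in accepted
    }
    folds = make_folds(table, plan)
    k_grid = [int(k) for k in k_grid]

    pooled_scores = {k: np.empty(table.n_samples) for k in k_grid}
    audit = []
    for fold_no, (tr, te) in enumerate(folds):
        if len(np.unique(table.y[tr])) < 2:
            raise ValueError(f"fold {fold_no}: training set contains a single class")
        train = table.subset(rows=tr)
        keep = ttest_prefilter(train, alpha=prefilter_alpha)
        ranking = rank_fn(train.subset(cols=keep), seed=seed + fold_no, **selector_kwargs)
        ranked_global = keep[ranking.order]
        for k in k_grid:
            top = ranked_global[: max(1, min(k, len(ranked_global)))]
            model = build_classifier(classifier, seed=seed, params=classifier_params)
            model.fit(table.X[tr][:, top], table.y[tr])
            pooled_scores[k][te] = _score_samples(model, table.X[te][:, top])
        audit.append(
            {
                "fold": fold_no,
                "train_lesions": table.lesion_ids[tr].tolist(),
                "test_lesions": table.lesion_ids[te].tolist(),
            }
        )

    aucs = {k: auc(pooled_scores[k], table.y) for k in k_grid}
    optimal_k = min(k_grid, key=lambda k: (-aucs[k], k))
    best_scores = pooled_scores[optimal_k]
    thr = youden_threshold(best_scores, table.y)
    metrics = confusion_metrics(best_scores, table.y, thr)
    return CellResult(
        selector=selector,
        classifier=classifier,
        optimal_k=int(optimal_k),
        auc=float(aucs[optimal_k]),
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        accuracy=metrics["accuracy"],
        per_fold_scores=[best_scores[te].tolist() for _, te in folds],
        audit=audit,
    )


@dataclass
class GridReport:
    """All selector x classifier cells for one cohort (or subgroup)."""

    cells: dict
    subgroup: str = "all"
    diameter_threshold_mm: float = 10.0

    def to_dataframe(self) -> pd.DataFrame:
        rows = [self.cells[key].as_row() for key in sorted(self.cells)]
        return pd.DataFrame(rows)

    def auc_matrix(self) -> pd.DataFrame:
        """Classifiers as rows, selectors as columns (fixed registry order)."""
        selectors = [s for s in SELECTOR_ORDER if any(k[0] == s for k in self.cells)]
        classifiers = [c for c in CLASSIFIER_ORDER if any(k[1] == c for k in self.cells)]
        mat = pd.DataFrame(index=classifiers, columns=selectors, dtype=float)
        for (s, c), cell in self.cells.items():
            mat.loc[c, s] = cell.auc
        return mat


def run_grid(
    table: CohortTable,
    plan: CVPlan,
    selectors=SELECTOR_ORDER,
    classifiers=CLASSIFIER_ORDER,
    k_grid=DEFAULT_K_GRID,
    seed: int = 0,
    subgroup: str = "all",
    **cell_kwargs,
) -> GridReport:
    """Evaluate every selector x classifier cell on one cohort table."""
    cells = {}
    for s in selectors:
        for c in classifiers:
            cells[(s, c)] = train_eval_cell(
                table, s, c, plan, k_grid=k_grid, seed=seed, **cell_kwargs
            )
    return GridReport(cells=cells, subgroup=subgroup)


@dataclass
class PermutationResult:
    observed_auc: float
    n_permutations: int
    n_higher: int
    p_value: float
    permuted_aucs: list = field(default_factory=list)


def permutation_p_value(n_higher: int, n_permutations: int) -> float:
    """p = (1 + #{permutations with AUC >= observed}) / (n_permutations + 1)."""
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if not 0 <= n_higher <= n_permutations:
        raise ValueError("n_higher out of range")
    return (1 + n_higher) / (n_permutations + 1)


def permutation_test(
    table: CohortTable,
    selector: str,
    classifier: str,
    plan: CVPlan,
    n_permutations: int = 500,
    seed: int = 0,
    k_grid=DEFAULT_K_GRID,
    observed: CellResult | None = None,
    **cell_kwargs,
) -> PermutationResult:
    """Label-permutation significance of one grid cell's pooled AUC.

    Each permutation shuffles the labels (patient-wise under patient
    grouping, so all of a patient's lesions move together) and reruns
    the full cross-validated selection + classification pipeline.
    Counting ``>=`` as "higher" keeps the p-value conservative.
    """
    if observed is None:
        observed = train_eval_cell(
            table, selector, classifier, plan, k_grid=k_grid, seed=seed, **cell_kwargs
        )
    rng = np.random.default_rng(seed)
    permuted = []
    for perm in range(n_permutations):
        if plan.grouping == "patient":
            patients, first_idx = np.unique(table.patient_ids, return_index=True)
            plabels = table.y[first_idx]
            shuffled = plabels[rng.permutation(len(patients))]
            lut = dict(zip(patients, shuffled))
            y_perm = np.array([lut[p] for p in table.patient_ids])
        else:
            y_perm = table.y[rng.permutation(table.n_samples)]
        perm_table = CohortTable(
            X=table.X,
            y=y_perm,
            patient_ids=table.patient_ids,
            lesion_ids=table.lesion_ids,
            diameters_mm=table.diameters_mm,
            feature_names=table.feature_names,
        )
        try:
            cell = train_eval_cell(
                perm_table,
                selector,
                classifier,
                plan,
                k_grid=k_grid,
                seed=seed + 1000 + perm,
                **cell_kwargs,
            )
            permuted.append(cell.auc)
        except ValueError as err:  # degenerate permuted fold: skip, warn
            warnings.warn(f"permutation {perm} skipped: {err}", stacklevel=2)
    n_eff = len(permuted)
    n_higher = int(np.sum(np.asarray(permuted) >= observed.auc))
    return PermutationResult(
        observed_auc=observed.auc,
        n_permutations=n_eff,
        n_higher=n_higher,
        p_value=permutation_p_value(n_higher, n_eff),
        permuted_aucs=permuted,
    )


def subgroup_grids(
    table: CohortTable,
    threshold_mm: float = 10.0,
    seed: int = 0,
    selectors=SELECTOR_ORDER,
    classifiers=CLASSIFIER_ORDER,
    k_grid=DEFAULT_K_GRID,
    kfold_k: int = 10,
    grouping: str = "lesion",
    **cell_kwargs,
) -> dict[str, GridReport]:
    """Grids for the small (<= threshold, k-fold CV) and large (> threshold,
    leave-one-out) diameter subgroups; skips a subgroup lacking both classes."""
    out: dict[str, GridReport] = {}
    small_rows = np.nonzero(table.diameters_mm <= threshold_mm)[0]
    large_rows = np.nonzero(table.diameters_mm > threshold_mm)[0]
    for name, rows, plan in (
        ("small", small_rows, CVPlan("kfold", k=kfold_k, grouping=grouping, seed=seed)),
        ("large", large_rows, CVPlan("loo", grouping=grouping, seed=seed)),
    ):
        class_counts = np.bincount(table.y[rows], minlength=2) if len(rows) else np.zeros(2)
        if class_counts.min() < 4:  # too few for per-fold selection to be defined
            warnings.warn(
                f"subgroup {name!r} lacks enough lesions of both classes; skipped",
                stacklevel=2,
            )
            continue
        sub = table.subset(rows=rows)
        if plan.scheme == "kfold" and plan.k > len(rows):
            plan = CVPlan("loo", grouping=grouping, seed=seed)
        out[name] = run_grid(
            sub,
            plan,
            selectors=selectors,
            classifiers=classifiers,
            k_grid=k_grid,
            seed=seed,
            subgroup=name,
            **cell_kwargs,
        )
        out[name].diameter_threshold_mm = threshold_mm
    return out


def render_grid(report: GridReport, out_csv, out_png=None) -> pd.DataFrame:
    """Write the AUC matrix as CSV (and optionally a heatmap PNG)."""
    mat = report.auc_matrix()
    mat.to_csv(out_csv, index_label="classifier")
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        im = ax.imshow(mat.to_numpy(dtype=float), cmap="viridis", aspect="auto")
        ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(mat.index)), mat.index)
        for i in range(mat.shape[0]):
            for j in range(mat.shape[1]):
                ax.text(
                    j, i, f"{mat.iloc[i, j]:.1f}", ha="center", va="center",
                    color="white", fontsize=8,
                )
        ax.set_title(f"Pooled CV AUC ({report.subgroup} lesions)")
        fig.colorbar(im, ax=ax, label="AUC")
        fig.tight_layout()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return mat


CLASSIFIERS = {name: build_classifier for name in CLASSIFIER_ORDER}
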