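"""Gene-panel selection and subtype classifiers.

The panel is chosen by SVM recursive feature elimination: a linear SVM is
fitted, the gene with the smallest squared weight is dropped, and the
process repeats until one gene remains; the elimination order defines the
ranking.  Candidate panel sizes are scored by cross-validated accuracy, and
the chosen size is the smallest one whose accuracy is within a tolerance of
the best (the curve "plateaus").  Four classifier families — decision tree,
radial-kernel SVM, single-hidden-layer neural network, random forest — are
then tuned by replicated stratified k-fold grid search on mean AUC, and the
final model is evaluated on a held-out partition.

Base learners come from scikit-learn; the RFE wrapper, replication/fold
logic, metric aggregation, plateau rule, and the univariate-AUC importance
measure are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

FAMILIES = ("DT", "SVM", "ANN", "RF")

#: Default hyper-parameter grids per family.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "DT": {"cp": [0.001, 0.005, 0.01, 0.05]},
    "SVM": {"sigma": [0.001, 0.01, 0.1], "C": [0.25, 0.5, 1, 2]},
    "ANN": {"size": [1, 3, 5, 7], "decay": [0.1, 0.5, 1]},
    "RF": {"mtry": [2, 3, 4, 6]},
}


def auc_score(scores: np.ndarray, y: np.ndarray) -> float:
    """ROC AUC via the rank statistic (midranks for tied scores).

    AUC = (R1 - n1(n1+1)/2) / (n1 n0), with R1 the rank sum of the positive
    class under average ranks — the probability a random positive outscores
    a random negative, counting ties as 1/2.
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores, method="average")
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def filter_degs(
    diff: pd.DataFrame, lfc_min: float = 0.5, padj_max: float = 0.05
) -> list[str]:
    """Genes with log2fc > lfc_min and adjusted p < padj_max (strict), by |log2fc| desc."""
    if diff.empty:
        raise ValueError("differential table is empty")
    sel = diff[(diff["log2fc"] > lfc_min) & (diff["p_adj"] < padj_max)].copy()
    if sel.empty:
        warnings.warn("no genes pass the DEG filter", stacklevel=2)
        return []
    sel["abs_lfc"] = sel["log2fc"].abs()
    sel = sel.sort_values(["abs_lfc", "gene"], ascending=[False, True], kind="mergesort")
    return sel["gene"].tolist()


def svm_rfe_rank(
    X: np.ndarray, y: np.ndarray, gene_names: list[str], seed: int = 0, C: float = 1.0
) -> list[str]:
    """Rank genes by linear-SVM recursive feature elimination.

    Each round fits a linear SVM on the surviving genes and removes the one
    with the smallest squared weight (ties broken by gene name, removing the
    lexicographically later one first, so earlier names rank better).  The
    returned list is ordered best-first: the last survivor is rank 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise ValueError("need two classes")
    if X.shape[1] != len(gene_names):
        raise ValueError("gene_names must match X columns")
    if X.shape[1] < 2:
        raise ValueError("need at least two genes")
    surviving = list(range(X.shape[1]))
    eliminated: list[int] = []
    while len(surviving) > 1:
        clf = SVC(kernel="linear", C=C, random_state=seed)
        clf.fit(X[:, surviving], y)
        w2 = np.asarray(clf.coef_).ravel() ** 2
        # Smallest weight goes; among ties drop the later gene name.
        order = sorted(
            range(len(surviving)),
            key=lambda i: (w2[i], tuple(-ord(ch) for ch in gene_names[surviving[i]])),
        )
        drop = surviving[order[0]]
        eliminated.append(drop)
        surviving.remove(drop)
    ranked_idx = surviving + eliminated[::-1]
    return [gene_names[i] for i in ranked_idx]


@dataclass
class PanelSelection:
    sizes: list[int]
    accuracy: dict[int, float]
    chosen_size: int
    genes: list[str]
    tolerance: float


def _cv_accuracy_linear_svm(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(X[tr], y[tr])
        accs.append(float((clf.predict(X[te]) == y[te]).mean()))
    return float(np.mean(accs))


def select_size(
    X: np.ndarray,
    y: np.ndarray,
    gene_names: list[str],
    sizes: tuple[int, ...] = (3, 6, 9, 12, 15, 18),
    folds: int = 5,
    seed: int = 0,
    tolerance: float = 0.005,
) -> PanelSelection:
    """Plateau rule over candidate panel sizes.

    For each size s the top-s RFE genes are scored by stratified k-fold CV
    accuracy of a linear SVM; the chosen size is the smallest s whose
    accuracy is within ``tolerance`` of the maximum.
    """
    ranked = svm_rfe_rank(X, y, gene_names, seed=seed)
    usable = [s for s in sizes if s <= len(ranked)]
    if len(usable) < len(sizes):
        warnings.warn(
            f"dropping sizes beyond the {len(ranked)} available genes", stacklevel=2
        )
    if not usable:
        raise ValueError("no candidate size fits the available genes")
    pos = {g: i for i, g in enumerate(gene_names)}
    acc: dict[int, float] = {}
    for s in usable:
        cols = [pos[g] for g in ranked[:s]]
        acc[s] = _cv_accuracy_linear_svm(X[:, cols], y, folds, seed)
    chosen = choose_plateau_size(usable, [acc[s] for s in usable], tolerance)
    return PanelSelection(
        sizes=usable,
        accuracy=acc,
        chosen_size=chosen,
        genes=ranked[:chosen],
        tolerance=tolerance,
    )


def choose_plateau_size(
    sizes: list[int], accuracies: list[float], tolerance: float = 0.005
) -> int:
    """Smallest size whose accuracy is within ``tolerance`` of the best."""
    best = max(accuracies)
    for s, a in zip(sizes, accuracies):
        if a >= best - tolerance:
            return s
    return sizes[-1]  # unreachable; max always qualifies


def _build_estimator(family: str, params: dict, seed: int):
    if family == "DT":
        return DecisionTreeClassifier(ccp_alpha=params["cp"], random_state=seed)
    if family == "SVM":
        return SVC(kernel="rbf", gamma=params["sigma"], C=params["C"], random_state=seed)
    if family == "ANN":
        return MLPClassifier(
            hidden_layer_sizes=(params["size"],),
            alpha=params["decay"],
            max_iter=500,
            random_state=seed,
        )
    if family == "RF":
        return RandomForestClassifier(
            n_estimators=200, max_features=params["mtry"], random_state=seed
        )
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


class FittedModel:
    """A trained subtype classifier exposing class scores in [0, 1].

    For the SVM the score is the logistic transform of the signed margin
    (monotone, boundary at 0.5); the other families expose predict_proba.
    """

    def __init__(self, family: str, params: dict, estimator, genes: list[str], seed: int):
        self.family = family
        self.params = dict(params)
        self.estimator = estimator
        self.genes = list(genes)
        self.seed = seed

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.family == "SVM":
            return expit(self.estimator.decision_function(X))
        return self.estimator.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_score(X) >= 0.5).astype(int)

    def manifest(self) -> dict:
        return {
            "family": self.family,
            "params": self.params,
            "genes": self.genes,
            "seed": self.seed,
        }


def train_final(
    X: np.ndarray, y: np.ndarray, family: str, params: dict, genes: list[str], seed: int = 0
) -> FittedModel:
    """Fit the chosen family with tuned hyper-parameters on the full training data."""
    est = _build_estimator(family, params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(np.asarray(X, dtype=float), np.asarray(y))
    return FittedModel(family, params, est, genes, seed)


def _simplicity_key(family: str, params: dict) -> tuple:
    """Tie-break toward the simpler model: larger cp/decay, smaller size/C/mtry/sigma."""
    if family == "DT":
        return (-params["cp"],)
    if family == "SVM":
        return (params["C"], params["sigma"])
    if family == "ANN":
        return (params["size"], -params["decay"])
    return (params["mtry"],)


@dataclass
class GridSearchResult:
    family: str
    best_params: dict
    best_auc: float
    best_accuracy: float
    table: pd.DataFrame = field(repr=False)


def cv_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    grid: dict[str, list] | None = None,
    folds: int = 5,
    replicates: int = 50,
    seed: int = 0,
) -> GridSearchResult:
    """Replicated stratified k-fold grid search.

    Every grid point is scored by ``replicates`` independent stratified
    k-fold splits; fold metrics are accuracy at a 0.5 score threshold and
    AUC of the held-out scores.  The winner maximizes mean AUC, ties broken
    by mean accuracy, then by the simpler model.
    """
    if grid is None:
        grid = DEFAULT_GRIDS[family]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be nonempty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    keys = sorted(grid)
    points = [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]

    # Pre-draw the fold splits once so every grid point sees the same folds.
    splits = []
    for rep in range(replicates):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        splits.extend(skf.split(X, y))
    for tr, te in splits:
        if len(set(y[te].tolist())) < 2 or len(set(y[tr].tolist())) < 2:
            raise ValueError("a fold contains a single class; need more balanced data")

    rows = []
    for params in points:
        accs, aucs = [], []
        for tr, te in splits:
            model = train_final(X[tr], y[tr], family, params, genes=[], seed=seed)
            s = model.predict_score(X[te])
            accs.append(float(((s >= 0.5).astype(int) == y[te]).mean()))
            aucs.append(auc_score(s, y[te]))
        rows.append({**params, "mean_accuracy": np.mean(accs), "mean_auc": np.mean(aucs)})
    table = pd.DataFrame(rows)
    best_i = min(
        range(len(points)),
        key=lambda i: (
            -round(rows[i]["mean_auc"], 12),
            -round(rows[i]["mean_accuracy"], 12),
            _simplicity_key(family, points[i]),
        ),
    )
    return GridSearchResult(
        family=family,
        best_params=points[best_i],
        best_auc=float(rows[best_i]["mean_auc"]),
        best_accuracy=float(rows[best_i]["mean_accuracy"]),
        table=table,
    )


@dataclass
class EvalResult:
    auc: float
    accuracy: float
    n: int


def evaluate(model: FittedModel, X_test: np.ndarray, y_test: np.ndarray) -> EvalResult:
    """Held-out AUC (midrank convention) and accuracy at the 0.5 threshold."""
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    if model.genes and X_test.shape[1] != len(model.genes):
        raise ValueError(
            f"test matrix has {X_test.shape[1]} genes; model expects {len(model.genes)}"
        )
    s = model.predict_score(X_test)
    return EvalResult(
        auc=auc_score(s, y_test),
        accuracy=float(((s >= 0.5).astype(int) == y_test).mean()),
        n=len(y_test),
    )


def importance(X: np.ndarray, y: np.ndarray, gene_names: list[str]) -> pd.Series:
    """Per-gene folded univariate AUC, max(AUC, 1 - AUC), sorted descending.

    A filter-style importance: how well the gene alone separates the
    classes, direction ignored.  Ties in the sort fall back to gene name.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise ValueError("need two classes")
    vals = {}
    for j, g in enumerate(gene_names):
        a = auc_score(X[:, j], y)
        vals[g] = max(a, 1.0 - a)
    ser = pd.Series(vals)
    order = sorted(ser.index, key=lambda g: (-ser[g], g))
    return ser.loc[order]
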