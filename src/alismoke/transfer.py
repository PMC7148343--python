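"""Cross-dataset signature transfer.

A gene signature derived in one dataset (e.g. smoke-exposed ALI cultures)
is evaluated against a second, independently acquired dataset (e.g.
airway brushings from smokers).  Platform differences are removed by
normalizing every transcript to the [0, 1] range *independently per
dataset* before joining; samples are then clustered with average-linkage
(UPGMA) agglomeration on the correlation distance 1 - r, classified with
a cross-validated random forest using the signature as feature vector,
and checked for robustness by removing the most label-correlated
transcripts and re-classifying.  Agreement between the two datasets'
differential-expression results is quantified as the fraction of shared
significant transcripts deregulated in the same direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .expression import DEResult, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "ClusteringResult",
    "ClassificationReport",
    "OverlapReport",
    "minmax_normalize",
    "upgma_cluster",
    "join_and_cluster",
    "rf_classify_cv",
    "rank_features_by_correlation",
    "ablate_and_reclassify",
    "direction_overlap",
]


@dataclass(frozen=True)
class NormalizedMatrix:
    """Per-transcript min-max normalized expression in [0, 1].

    ``provenance`` maps each sample id to the dataset it came from;
    normalization is always performed within one dataset at a time.
    Constant transcripts map to all-zero rows.
    """

    values: pd.DataFrame
    provenance: dict[str, str]


@dataclass(frozen=True)
class ClusteringResult:
    """UPGMA dendrogram over rows or columns of a matrix."""

    linkage_matrix: np.ndarray  # scipy (n-1, 4) linkage
    labels: list[str]  # leaf labels in input order
    leaf_order: list[str]  # labels in dendrogram display order
    axis: str  # "rows" | "columns"

    def cut(self, k: int) -> dict[str, int]:
        """Assign each leaf to one of ``k`` flat clusters."""
        assignment = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignment)))

    def to_newick(self) -> str:
        """Serialize the dendrogram as a newick string."""
        from skbio import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.labels)
        return str(tree)


@dataclass(frozen=True)
class ClassificationReport:
    """Cross-validated random-forest classification summary."""

    roc_points: np.ndarray  # (n, 2) of (false-positive rate, true-positive rate)
    auc: float
    confusion_matrix: np.ndarray  # 2x2 counts, rows true / cols predicted
    cv_scheme: str
    n_trees: int
    features_per_split: int
    seed: int
    positive_label: str
    features: tuple[str, ...]


@dataclass(frozen=True)
class OverlapReport:
    """Direction-consistency overlap between two DE comparisons."""

    n_only_a: int
    n_only_b: int
    n_shared: int
    n_consistent: int
    consistent_fraction: float  # NaN when n_shared == 0
    scatter_pairs: pd.DataFrame  # transcript-indexed (log_fold_change_a, log_fold_change_b)


def minmax_normalize(matrix: ExpressionMatrix, dataset: str = "dataset") -> NormalizedMatrix:
    """Scale every transcript to the [0, 1] range across samples.

    ``(x - min) / (max - min)`` per row; constant rows become all-zero
    (with a logged warning) rather than dividing by zero.  Sample order is
    preserved.
    """
    values = matrix.values
    if values.shape[1] < 2:
        raise ValueError("min-max normalization needs at least two samples")
    lo = values.min(axis=1)
    hi = values.max(axis=1)
    span = hi - lo
    constant = span == 0
    if constant.any():
        logger.warning(
            "%d constant transcript(s) mapped to all-zero rows during normalization",
            int(constant.sum()),
        )
    safe_span = span.where(~constant, 1.0)
    normalized = values.sub(lo, axis=0).div(safe_span, axis=0)
    normalized.loc[constant] = 0.0
    provenance = {s: dataset for s in values.columns}
    return NormalizedMatrix(values=normalized, provenance=provenance)


def _correlation_distance(data: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r between rows; zero-variance rows get r = 0."""
    sd = data.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance leaf(s): correlation set to 0 (distance 1)",
            stacklevel=3,
        )
    centered = data - data.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    safe_norm = np.where(degenerate, 1.0, norm)
    unit = centered / safe_norm[:, None]
    r = unit @ unit.T
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    d = 1.0 - np.clip(r, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def upgma_cluster(matrix: NormalizedMatrix | pd.DataFrame, axis: str = "columns") -> ClusteringResult:
    """Average-linkage (UPGMA) clustering on the correlation distance.

    The distance between leaves is ``1 - r`` (Pearson), ranging over
    [0, 2]; merge order is deterministic (ties resolved by scipy's
    nearest-neighbor-chain ordering, which is stable for fixed input).
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    data = values.to_numpy(dtype=float)
    labels = list(values.index if axis == "rows" else values.columns)
    if axis == "columns":
        data = data.T
    if len(labels) < 2:
        raise ValueError("clustering needs at least two leaves")
    dist = _correlation_distance(data)
    Z = linkage(squareform(dist, checks=False), method="average")
    order = [labels[i] for i in leaves_list(Z)]
    return ClusteringResult(linkage_matrix=Z, labels=labels, leaf_order=order, axis=axis)


def join_and_cluster(
    de_a: DEResult,
    de_b: DEResult,
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    q_cut: float = 0.05,
    dataset_names: tuple[str, str] = ("A", "B"),
) -> tuple[NormalizedMatrix, ClusteringResult | None]:
    """Join two cohorts on transcripts significant in *both* comparisons.

    Transcripts with q below ``q_cut`` in both DE results are retained
    regardless of direction (no directionality filter); each dataset is
    min-max normalized independently, samples are concatenated, and the
    combined columns are clustered with UPGMA.  With a single shared
    transcript the combined matrix is returned without a column
    dendrogram (correlation over one value is undefined).
    """
    sig_a = set(de_a.table.index[de_a.table["q_value"] < q_cut])
    sig_b = set(de_b.table.index[de_b.table["q_value"] < q_cut])
    shared = sorted(sig_a & sig_b & set(matrix_a.values.index) & set(matrix_b.values.index))
    if not shared:
        raise ValueError("no transcript is significant in both comparisons")
    norm_a = minmax_normalize(
        ExpressionMatrix(matrix_a.values.loc[shared], matrix_a.metadata), dataset_names[0]
    )
    norm_b = minmax_normalize(
        ExpressionMatrix(matrix_b.values.loc[shared], matrix_b.metadata), dataset_names[1]
    )
    combined = pd.concat([norm_a.values, norm_b.values], axis=1)
    if combined.columns.duplicated().any():
        combined.columns = [
            f"{dataset_names[0]}:{c}" for c in norm_a.values.columns
        ] + [f"{dataset_names[1]}:{c}" for c in norm_b.values.columns]
        provenance = {c: c.split(":", 1)[0] for c in combined.columns}
    else:
        provenance = {**norm_a.provenance, **norm_b.provenance}
    joined = NormalizedMatrix(values=combined, provenance=provenance)
    clustering = None
    if len(shared) >= 2:
        clustering = upgma_cluster(joined, axis="columns")
    else:
        logger.info("single shared transcript: skipping column clustering")
    return joined, clustering


def _fold_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def rf_classify_cv(
    matrix: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series,
    signature: list[str] | None = None,
    folds: int = 50,
    n_trees: int = 100,
    features_per_split: int = 10,
    seed: int = 0,
    positive_label: str | None = None,
) -> ClassificationReport:
    """Stratified k-fold cross-validated random-forest classification.

    Out-of-fold class-vote fractions are pooled into a single ROC curve
    and AUC; the confusion matrix thresholds the vote fraction at 0.5.
    When the smaller class has fewer members than ``folds`` the scheme
    degrades to leave-one-out (logged).  ``features_per_split`` mirrors
    the forest's per-split feature subsampling and is capped at the number
    of available features.
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    if signature is not None:
        missing = [t for t in signature if t not in values.index]
        if missing:
            raise ValueError(f"signature transcripts absent from matrix: {missing}")
        values = values.loc[list(signature)]
    labels = pd.Series(labels).loc[values.columns]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if positive_label is None:
        positive_label = classes[1]
    y = (labels == positive_label).to_numpy(int)
    X = values.to_numpy(dtype=float).T  # samples x features

    min_class = int(np.bincount(y).min())
    if min_class < folds:
        splitter = LeaveOneOut()
        cv_scheme = f"leave-one-out (requested {folds}-fold; smallest class has {min_class})"
        logger.info("fold count degraded to leave-one-out: %s", cv_scheme)
        split_iter = splitter.split(X)
        n_splits = X.shape[0]
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        cv_scheme = f"stratified {folds}-fold"
        split_iter = splitter.split(X, y)
        n_splits = folds

    max_features = min(features_per_split, X.shape[1])
    fold_seeds = _fold_seeds(seed, n_splits)
    scores = np.empty(X.shape[0])
    for k, (train, test) in enumerate(split_iter):
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=int(fold_seeds[k]),
        )
        clf.fit(X[train], y[train])
        proba = clf.predict_proba(X[test])
        pos_col = list(clf.classes_).index(1) if 1 in clf.classes_ else None
        scores[test] = proba[:, pos_col] if pos_col is not None else 0.0

    fpr, tpr, _ = roc_curve(y, scores)
    roc_auc = float(sk_auc(fpr, tpr))
    predicted = (scores >= 0.5).astype(int)
    cm = sk_confusion(y, predicted, labels=[0, 1])
    return ClassificationReport(
        roc_points=np.column_stack([fpr, tpr]),
        auc=roc_auc,
        confusion_matrix=cm,
        cv_scheme=cv_scheme,
        n_trees=n_trees,
        features_per_split=max_features,
        seed=seed,
        positive_label=str(positive_label),
        features=tuple(values.index),
    )


def rank_features_by_correlation(
    matrix: NormalizedMatrix | pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Rank features by |Pearson r| with the 0/1 class label, descending.

    Ties (including duplicated features) are broken by transcript id.
    Zero-variance features score 0.
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    labels = pd.Series(labels).loc[values.columns]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    y = (labels == classes[1]).to_numpy(float)
    y = y - y.mean()
    y_norm = np.sqrt((y**2).sum())
    data = values.to_numpy(dtype=float)
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ y) / (norms * y_norm)
    score = np.abs(np.where(norms == 0, 0.0, r))
    ranking = pd.DataFrame({"feature": values.index, "score": score})
    ranking = ranking.sort_values("feature", kind="stable").sort_values(
        "score", ascending=False, kind="stable"
    )
    return ranking.reset_index(drop=True)


def ablate_and_reclassify(
    matrix: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series,
    signature: list[str],
    k_remove: int = 10,
    **cv_kwargs,
) -> tuple[ClassificationReport, ClassificationReport]:
    """Classify with the full signature and after removing top features.

    The ``k_remove`` features most correlated with the label — ranked on
    the full dataset, before cross-validation — are dropped and the
    identical cross-validation is repeated.  Returns (full, reduced).
    """
    if k_remove >= len(signature):
        raise ValueError(
            f"k_remove={k_remove} would empty the signature of {len(signature)} transcripts"
        )
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    full = rf_classify_cv(values, labels, signature=signature, **cv_kwargs)
    ranking = rank_features_by_correlation(values.loc[list(signature)], labels)
    removed = set(ranking["feature"].head(k_remove))
    reduced_signature = [t for t in signature if t not in removed]
    reduced = rf_classify_cv(values, labels, signature=reduced_signature, **cv_kwargs)
    return full, reduced


def direction_overlap(de_a: DEResult, de_b: DEResult, q_cut: float = 0.05) -> OverlapReport:
    """Overlap of significant transcripts and their direction consistency.

    Transcripts significant (q < ``q_cut``) only in A, only in B, and in
    both are counted; among the shared ones, *consistent* means the log
    fold changes carry the same nonzero sign (two exact zeros also count
    as consistent).  With no shared transcript the fraction is NaN.
    """
    sig_a = de_a.table[de_a.table["q_value"] < q_cut]
    sig_b = de_b.table[de_b.table["q_value"] < q_cut]
    shared = sorted(set(sig_a.index) & set(sig_b.index))
    lfc_a = sig_a.loc[shared, "log_fold_change"]
    lfc_b = sig_b.loc[shared, "log_fold_change"]
    sign_a = np.sign(lfc_a.to_numpy())
    sign_b = np.sign(lfc_b.to_numpy())
    consistent = (sign_a == sign_b) & ((sign_a != 0) | (sign_b == 0))
    n_shared = len(shared)
    n_consistent = int(consistent.sum())
    fraction = n_consistent / n_shared if n_shared else float("nan")
    scatter = pd.DataFrame(
        {"log_fold_change_a": lfc_a, "log_fold_change_b": lfc_b}, index=pd.Index(shared)
    )
    return OverlapReport(
        n_only_a=len(sig_a) - n_shared,
        n_only_b=len(sig_b) - n_shared,
        n_shared=n_shared,
        n_consistent=n_consistent,
        consistent_fraction=fraction,
        scatter_pairs=scatter,
    )
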