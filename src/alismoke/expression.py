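"""Per-transcript linear-model differential expression.

Expression matrices (transcripts x samples, log scale, already
normalized upstream) are analyzed with an ordinary least-squares linear
model per transcript: cell-means coding of the condition factor plus
donor/subject covariates when the design is paired (the ``~0 + group +
donorID`` design).  The condition contrast gives a log fold change and a
two-sided t-test p-value per transcript; Benjamini-Hochberg step-up
adjustment across transcripts yields q-values, and the significature set
at a q cutoff forms the gene signature consumed downstream.

Moderated (empirical-Bayes) variance shrinkage is deliberately not
implemented: the downstream uses of the results (signature membership,
direction, ranking) depend on direction and ordering, which plain OLS
preserves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "fit_linear_de",
    "bh_adjust",
    "select_signature",
]

REQUIRED_METADATA = ("condition", "donor")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Transcripts x samples with per-sample metadata.

    ``values``: DataFrame indexed by transcript id, columns are sample ids.
    ``metadata``: DataFrame indexed by sample id with at least a
    ``condition`` column (exposure label) and a ``donor`` column; a
    ``cohort`` column records provenance when two datasets are joined.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript ids: {dupes}")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        for col in REQUIRED_METADATA:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        extra = [s for s in self.metadata.index if s not in self.values.columns]
        if extra:
            warnings.warn(f"metadata has {len(extra)} rows without matching samples", stacklevel=2)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def aligned_metadata(self) -> pd.DataFrame:
        return self.metadata.loc[self.values.columns]


@dataclass(frozen=True)
class DEResult:
    """Per-transcript condition-contrast statistics.

    ``table`` columns: log_fold_change, t, p_value, q_value, direction
    (sign of the log fold change), indexed by transcript id.
    """

    table: pd.DataFrame
    contrast: tuple[str, str]  # (numerator condition, reference condition)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} m * p_(j) / j`` over the sorted p-values, capped
    at 1, then restored to the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _design_matrix(meta: pd.DataFrame, contrast: tuple[str, str], adjust_donor: bool):
    """Cell-means condition columns plus (optionally) donor dummies."""
    conditions = meta["condition"].astype(str)
    levels = sorted(conditions.unique())
    for c in contrast:
        if c not in levels:
            raise ValueError(f"contrast condition {c!r} not found; levels: {levels}")
    cols: dict[str, np.ndarray] = {}
    for lev in levels:
        cols[f"condition[{lev}]"] = (conditions == lev).to_numpy(float)
    if adjust_donor:
        donors = meta["donor"].astype(str)
        donor_levels = sorted(donors.unique())
        for d in donor_levels[1:]:  # first donor absorbed into the condition means
            cols[f"donor[{d}]"] = (donors == d).to_numpy(float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # point at columns whose removal restores full rank
        confounded = []
        for j, name in enumerate(names):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                confounded.append(name)
        raise ValueError(f"design matrix not full rank; confounded columns: {confounded}")
    contrast_vec = np.zeros(X.shape[1])
    contrast_vec[names.index(f"condition[{contrast[0]}]")] = 1.0
    contrast_vec[names.index(f"condition[{contrast[1]}]")] = -1.0
    return X, names, contrast_vec


def fit_linear_de(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    adjust_donor: bool | None = None,
    variance_mode: str = "per_transcript",
) -> DEResult:
    """OLS differential expression for one condition contrast.

    The per-transcript model regresses expression on condition cell means
    plus donor dummy covariates; ``adjust_donor=None`` includes donors
    automatically when any donor contributes more than one sample (paired
    design).  The log fold change is the ``contrast[0] - contrast[1]``
    difference of condition means; p-values are two-sided t-tests, and
    q-values are BH-adjusted across transcripts.

    ``variance_mode="per_transcript"`` (default) uses each transcript's own
    residual variance on its residual degrees of freedom.
    ``variance_mode="pooled"`` assumes a common residual variance across
    transcripts (estimated from the pooled residual sum of squares, with
    correspondingly pooled degrees of freedom) — the small-sample mode for
    designs with very few donors, where per-transcript variance estimates
    are too unstable to detect anything.
    """
    if variance_mode not in ("per_transcript", "pooled"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    meta = matrix.aligned_metadata()
    counts = meta["condition"].value_counts()
    for c in contrast:
        if counts.get(c, 0) < 2:
            raise ValueError(f"need >=2 samples in condition {c!r}")
    if adjust_donor is None:
        adjust_donor = bool(meta["donor"].duplicated().any())
    X, names, cvec = _design_matrix(meta, contrast, adjust_donor)
    Y = matrix.values.to_numpy(dtype=float).T  # samples x transcripts
    n, p_cols = X.shape
    dof = n - p_cols
    if dof < 1:
        raise ValueError("no residual degrees of freedom (saturated design)")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)  # p x m
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    t_dof = dof
    if variance_mode == "pooled":
        m = sigma2.size
        sigma2 = np.full(m, sigma2.mean())
        t_dof = dof * m
    cvar = float(cvec @ xtx_inv @ cvec)
    lfc = cvec @ beta
    se = np.sqrt(sigma2 * cvar)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.sign(lfc) * np.inf))
    p = 2.0 * sps.t.sf(np.abs(t), t_dof)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "log_fold_change": lfc,
            "t": t,
            "p_value": p,
            "q_value": q,
            "direction": np.sign(lfc).astype(int),
        },
        index=matrix.values.index,
    )
    return DEResult(table=table, contrast=tuple(contrast))


def select_signature(de: DEResult, q_cut: float = 0.05) -> pd.DataFrame:
    """Transcripts with q below the cutoff, best (smallest q) first.

    Returns a DataFrame (transcript index; q_value, log_fold_change,
    direction) sorted by q, then p, then transcript id.
    """
    table = de.table
    hits = table[table["q_value"] < q_cut]
    # stable sort after ordering by id => ties broken by transcript id
    hits = hits.sort_index(kind="stable").sort_values(["q_value", "p_value"], kind="stable")
    return hits[["log_fold_change", "p_value", "q_value", "direction"]]
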