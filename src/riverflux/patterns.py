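"""Pattern matrices and principal component analysis of monitoring series.

Two rectangular total-flux matrices feed the PCA:

* site matrix — rows are stations, columns are campaign months, each cell
  the sum of mass flow over the station's analyte panel in that month;
* category matrix — rows are therapeutic categories, columns are months,
  each cell the sum over the category's members and all stations.

Site-months without a sampling event are filled with 0 so the matrix is
rectangular; a parallel completeness matrix records the filled fraction.
PCA is run on the column-mean-centred matrix (optionally unit-variance
scaled); scores place the rows in a low-dimensional pattern space, loadings
weight the months.  A deterministic sign convention — the largest-magnitude
loading of every component is positive — makes the output reproducible
bit-for-bit.

Cluster/group assignment of the score plots is deliberately *not*
automated: the module emits scores and a score-distance matrix, and any
grouping stays a human annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SKPCA

from .io import AnalyteRegistry, SiteRegistry

__all__ = ["PcaResult", "PatternPCA", "build_site_matrix", "build_category_matrix", "pca"]


def _complete_matrix(df: pd.DataFrame, row_col: str, months=None):
    """Pivot to rows × months, filling unsampled cells with 0.

    Returns ``(matrix, completeness)`` where completeness holds the fraction
    of expected member series actually present per cell.
    """
    totals = df.pivot_table(
        index=row_col, columns="month", values="mass_flow_ug_s", aggfunc="sum", observed=True
    )
    counts = df.pivot_table(
        index=row_col, columns="month", values="mass_flow_ug_s", aggfunc="size", observed=True
    )
    expected = (
        df.drop_duplicates([row_col, "site_code", "analyte"])
        .groupby(row_col, observed=True)
        .size()
    )
    if months is not None:
        totals = totals.reindex(columns=list(months))
        counts = counts.reindex(columns=list(months))
    completeness = counts.fillna(0).div(expected, axis=0)
    return totals.fillna(0.0), completeness


def build_site_matrix(flows: pd.DataFrame, sites: SiteRegistry | None = None,
                      months=None) -> pd.DataFrame:
    """Stations × months matrix of panel-summed mass flow (µg/s).

    ``sites`` fixes the row order (downstream order per river); None orders
    rows by observed site code.  ``months`` fixes the column axis (e.g. the
    full campaign); None uses the observed months.
    """
    matrix, completeness = _complete_matrix(flows, "site_code", months)
    if sites is not None:
        order = [s.code for r in sites.rivers() for s in sites.by_river(r)]
        order = [c for c in order if c in matrix.index]
        matrix = matrix.reindex(order)
        completeness = completeness.reindex(order)
    matrix.attrs["completeness"] = completeness
    return matrix


def build_category_matrix(flows: pd.DataFrame, registry: AnalyteRegistry,
                          months=None) -> pd.DataFrame:
    """Categories × months matrix summed over member analytes and all sites."""
    cat_of = {a.name: a.category for a in registry}
    unmapped = sorted(set(flows["analyte"]) - set(cat_of))
    if unmapped:
        raise ValueError(f"analytes without a category mapping: {unmapped}")
    tagged = flows.assign(category=flows["analyte"].map(cat_of))
    matrix, completeness = _complete_matrix(tagged, "category", months)
    order = [c for c in dict.fromkeys(a.category for a in registry) if c in matrix.index]
    matrix = matrix.reindex(order)
    matrix.attrs["completeness"] = completeness.reindex(order)
    return matrix


@dataclass(frozen=True)
class PcaResult:
    """Scores, loadings and explained-variance fractions of a pattern PCA."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray

    def __post_init__(self):
        evf = np.asarray(self.explained_variance_fraction, dtype=float)
        if ((evf < -1e-12) | (evf > 1 + 1e-12)).any():
            raise ValueError("explained fractions must lie in [0, 1]")
        if (np.diff(evf) > 1e-12).any():
            raise ValueError("explained fractions must be non-increasing")
        if evf.sum() > 1 + 1e-9:
            raise ValueError("explained fractions must sum to <= 1")


class PatternPCA(BaseEstimator, TransformerMixin):
    """PCA of a pattern matrix with a deterministic sign convention.

    Rows are observations (stations or categories), columns are months.
    Columns are mean-centred; with ``standardize=True`` they are also scaled
    to unit variance (all mass flows share a unit, so the default is
    centring only).  Components are oriented so that each one's
    largest-magnitude loading is positive, making scores files reproducible
    across runs and platforms.

    Fitted attributes: ``scores_`` (rows × components), ``loadings_``
    (months × components), ``explained_variance_ratio_``,
    ``score_distances_`` (pairwise Euclidean distances between row scores,
    the companion output for any human grouping of the score plot).
    """

    def __init__(self, n_components: int = 2, standardize: bool = False):
        self.n_components = n_components
        self.standardize = standardize

    def fit(self, X: pd.DataFrame, y=None):
        X = self._as_frame(X)
        n_rows, n_cols = X.shape
        if n_rows < 2 or n_cols < 2:
            raise ValueError(f"need at least a 2x2 matrix, got {n_rows}x{n_cols}")
        if self.n_components > min(n_rows, n_cols):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(rows, cols)={min(n_rows, n_cols)}"
            )
        values = X.to_numpy(dtype=float)
        self.mean_ = values.mean(axis=0)
        centred = values - self.mean_
        if not (centred != 0).any():
            raise ValueError("degenerate input: all rows identical (zero total variance)")
        if self.standardize:
            scale = centred.std(axis=0, ddof=0)
            if (scale == 0).any():
                dead = [str(c) for c, s in zip(X.columns, scale) if s == 0]
                raise ValueError(f"cannot standardize zero-variance columns: {dead}")
            self.scale_ = scale
            centred = centred / scale
        else:
            self.scale_ = np.ones(n_cols)

        sk = _SKPCA(n_components=self.n_components, svd_solver="full")
        scores = sk.fit_transform(centred)
        components = sk.components_  # (k, n_cols)
        # Sign convention: largest-|loading| entry of each component positive.
        for k in range(components.shape[0]):
            j = int(np.argmax(np.abs(components[k])))
            if components[k, j] < 0:
                components[k] *= -1
                scores[:, k] *= -1
        names = [f"PC{i + 1}" for i in range(self.n_components)]
        self.components_ = components
        self.scores_ = pd.DataFrame(scores, index=X.index, columns=names)
        self.loadings_ = pd.DataFrame(components.T, index=X.columns, columns=names)
        self.explained_variance_ratio_ = sk.explained_variance_ratio_.copy()
        diff = self.scores_.to_numpy()[:, None, :] - self.scores_.to_numpy()[None, :, :]
        self.score_distances_ = pd.DataFrame(
            np.sqrt((diff**2).sum(axis=2)), index=X.index, columns=X.index
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "components_"):
            raise RuntimeError("PatternPCA is not fitted")
        X = self._as_frame(X)
        centred = (X.to_numpy(dtype=float) - self.mean_) / self.scale_
        scores = centred @ self.components_.T
        return pd.DataFrame(scores, index=X.index, columns=self.scores_.columns)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        arr = np.asarray(X, dtype=float)
        return pd.DataFrame(arr)

    def result(self) -> PcaResult:
        return PcaResult(self.scores_, self.loadings_, self.explained_variance_ratio_)


def pca(matrix: pd.DataFrame, n_components: int = 2, standardize: bool = False) -> PcaResult:
    """Functional wrapper over :class:`PatternPCA`."""
    return PatternPCA(n_components=n_components, standardize=standardize).fit(matrix).result()
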