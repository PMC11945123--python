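"""Feature-space PCA and the trendline + z-score outlier filter.

Before model fitting the assembled feature matrix is standardized and
projected onto its first two principal components.  An ordinary least-squares
trendline of the experimental affinity on those two components defines an
"expected affinity"; complexes whose residual z-score falls outside +-3 are
removed from the *training* data only.  The Pearson correlation between
affinity and trendline is recorded before and after removal.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted


class StandardizedPCA(BaseEstimator, TransformerMixin):
    """PCA on a standardized feature matrix (zero-variance columns dropped).

    Parameters
    ----------
    n_components : int, default 2
        Number of principal components retained; the affinity pipeline keeps
        the first two.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < self.n_components:
            raise ValueError(
                f"need at least {self.n_components} rows for {self.n_components} components")
        std = X.std(axis=0)
        self.kept_columns_ = np.flatnonzero(std > 0)
        n_dropped = X.shape[1] - self.kept_columns_.size
        if n_dropped:
            warnings.warn(f"dropping {n_dropped} zero-variance columns before PCA")
        if self.kept_columns_.size < self.n_components:
            raise ValueError("fewer informative columns than requested components")
        self.scaler_ = StandardScaler().fit(X[:, self.kept_columns_])
        self.pca_ = PCA(n_components=self.n_components, svd_solver="full").fit(
            self.scaler_.transform(X[:, self.kept_columns_]))
        self.explained_variance_ratio_ = self.pca_.explained_variance_ratio_
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "pca_")
        X = np.asarray(X, dtype=float)
        return self.pca_.transform(self.scaler_.transform(X[:, self.kept_columns_]))


@dataclass
class OutlierReport:
    removed_ids: list
    z_scores: np.ndarray
    threshold: float
    pcc_before: float
    pcc_after: float
    degenerate: bool = False
    skipped: bool = False

    def write_csv(self, path, ids=None) -> None:
        removed = set(self.removed_ids)
        ids = list(ids) if ids is not None else list(range(len(self.z_scores)))
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "z", "removed"])
            for i, z in zip(ids, self.z_scores):
                writer.writerow([i, f"{z:.6f}", int(i in removed)])


class ResidualOutlierFilter(BaseEstimator):
    """Trendline + z-score filter over (two-PC coordinates, affinity) pairs.

    fit(X2, y) regresses y on the two retained principal components, z-scores
    the residuals with the sample (n-1) standard deviation and marks rows with
    |z| strictly greater than ``z_threshold`` for removal.  Below ``min_rows``
    rows filtering is skipped entirely; a perfectly collinear fit (residual
    std ~ 0) removes nothing.
    """

    def __init__(self, z_threshold: float = 3.0, min_rows: int = 10):
        self.z_threshold = z_threshold
        self.min_rows = min_rows

    def fit(self, X2, y, ids=None):
        X2 = np.asarray(X2, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        ids = list(ids) if ids is not None else list(range(n))
        if n < self.min_rows:
            warnings.warn(f"only {n} rows; outlier filtering disabled")
            self.kept_mask_ = np.ones(n, dtype=bool)
            self.report_ = OutlierReport(removed_ids=[], z_scores=np.zeros(n),
                                         threshold=self.z_threshold,
                                         pcc_before=np.nan, pcc_after=np.nan,
                                         skipped=True)
            return self

        trend = LinearRegression().fit(X2, y)
        yhat = trend.predict(X2)
        residuals = y - yhat
        sd = residuals.std(ddof=1)
        pcc_before = _safe_pearson(y, yhat)
        if sd < 1e-12:
            self.kept_mask_ = np.ones(n, dtype=bool)
            self.report_ = OutlierReport(removed_ids=[], z_scores=np.zeros(n),
                                         threshold=self.z_threshold,
                                         pcc_before=pcc_before, pcc_after=pcc_before,
                                         degenerate=True)
            return self
        z = (residuals - residuals.mean()) / sd
        keep = np.abs(z) <= self.z_threshold  # ties at the threshold are kept
        removed_ids = [ids[i] for i in np.flatnonzero(~keep)]
        pcc_after = _safe_pearson(y[keep], yhat[keep]) if keep.sum() >= 2 else np.nan
        self.kept_mask_ = keep
        self.trend_ = trend
        self.report_ = OutlierReport(removed_ids=removed_ids, z_scores=z,
                                     threshold=self.z_threshold,
                                     pcc_before=pcc_before, pcc_after=pcc_after)
        return self

    def kept_indices(self) -> np.ndarray:
        check_is_fitted(self, "kept_mask_")
        return np.flatnonzero(self.kept_mask_)


def _safe_pearson(a, b) -> float:
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(stats.pearsonr(a, b).statistic)


def fit_pca(X, n_components: int = 2) -> StandardizedPCA:
    """Functional wrapper: standardize + PCA, returning the fitted state."""
    return StandardizedPCA(n_components=n_components).fit(X)


def remove_outliers(y, X2, z_threshold: float = 3.0, ids=None
                    ) -> tuple[np.ndarray, OutlierReport]:
    """Functional wrapper returning (kept index array, report)."""
    filt = ResidualOutlierFilter(z_threshold=z_threshold).fit(X2, y, ids=ids)
    return filt.kept_indices(), filt.report_
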