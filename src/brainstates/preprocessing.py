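"""Per-subject standardization, cohort concatenation, and shared-basis PCA.

ROI time courses are z-scored within each subject, stacked across the
cohort into one matrix, and projected onto a single group-level principal
component basis so that state parameters estimated downstream live in one
shared space for all subjects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


@dataclass
class SubjectSeries:
    """One subject's ROI time-series matrix plus identity and covariates.

    ``data`` is a T x R array: T timepoints, R regions of interest.
    """

    subject_id: str
    group: str
    site: str
    age: float
    fiq: float
    mean_fd: float
    data: np.ndarray
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"subject {self.subject_id}: data must be 2-D (T x R)")
        if self.data.shape[0] < 2:
            raise ValueError(f"subject {self.subject_id}: need at least 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id}: data contains non-finite values")
        if not self.roi_labels:
            self.roi_labels = [f"ROI_{i + 1:03d}" for i in range(self.data.shape[1])]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def standardize(series: SubjectSeries) -> SubjectSeries:
    """Z-score each ROI channel: subtract its mean, divide by its sample SD.

    The sample SD uses the n-1 denominator. A zero-variance channel is a
    hard error because the division is undefined.
    """
    x = series.data
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        labels = ", ".join(series.roi_labels[i] for i in bad)
        raise ValueError(
            f"subject {series.subject_id}: zero-variance channel(s): {labels}"
        )
    return replace(series, data=(x - mean) / sd)


def concatenate(cohort: Sequence[SubjectSeries]) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Stack subjects' matrices row-wise in manifest order.

    Returns the (sum T) x R stacked matrix and per-subject half-open row
    spans ``(start, stop)`` that partition its rows exactly.
    """
    if len(cohort) == 0:
        raise ValueError("cannot concatenate an empty cohort")
    n_regions = cohort[0].n_regions
    for s in cohort:
        if s.n_regions != n_regions:
            raise ValueError(
                f"subject {s.subject_id}: has {s.n_regions} regions, expected {n_regions}"
            )
    spans: list[tuple[int, int]] = []
    start = 0
    for s in cohort:
        spans.append((start, start + s.n_timepoints))
        start += s.n_timepoints
    stacked = np.vstack([s.data for s in cohort])
    return stacked, spans


class CohortPCA(BaseEstimator, TransformerMixin):
    """PCA on the concatenated cohort matrix with a shared basis.

    Parameters
    ----------
    n_components : int, optional
        Fixed number of retained components. Takes precedence over
        ``variance_target`` when both are given (the achieved variance is
        logged).
    variance_target : float, default 0.90
        Retain the smallest number of components whose cumulative
        explained-variance ratio reaches this fraction.

    Attributes
    ----------
    center_ : (R,) column means of the training matrix.
    loadings_ : (R, P) orthonormal columns; each column's largest-magnitude
        entry is made positive so maps are reproducible across runs.
    explained_variance_ratio_ : (P,) non-increasing ratios.
    n_components_ : retained component count P.
    """

    def __init__(self, n_components: int | None = None, variance_target: float = 0.90):
        self.n_components = n_components
        self.variance_target = variance_target

    def fit(self, X: np.ndarray, y=None) -> "CohortPCA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, r = X.shape
        if self.n_components is None:
            v = self.variance_target
            if not (0.0 < v <= 1.0):
                raise ValueError(f"variance_target must lie in (0, 1], got {v}")
        if n < r:
            warnings.warn(
                f"fewer rows ({n}) than channels ({r}); PCA rank is limited to {n}",
                stacklevel=2,
            )
        full = PCA(n_components=min(n, r), svd_solver="full").fit(X)
        ratios = full.explained_variance_ratio_
        if self.n_components is not None:
            p = int(self.n_components)
            if not (1 <= p <= len(ratios)):
                raise ValueError(f"n_components must lie in [1, {len(ratios)}], got {p}")
            achieved = float(ratios[:p].sum())
            logger.info("PCA: fixed P=%d retains %.4f of the variance", p, achieved)
        else:
            cum = np.cumsum(ratios)
            # rank-deficient data can max out below the target
            reachable = min(self.variance_target, cum[-1])
            p = int(np.searchsorted(cum, reachable - 1e-12) + 1)
            logger.info(
                "PCA: variance target %.3f met at P=%d (achieved %.4f)",
                self.variance_target, p, float(cum[p - 1]),
            )
        loadings = full.components_[:p].T.copy()
        signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(p)])
        signs[signs == 0] = 1.0
        loadings *= signs
        self.center_ = full.mean_
        self.loadings_ = loadings
        self.explained_variance_ratio_ = ratios[:p].copy()
        self.n_components_ = p
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.loadings_.shape[0]:
            raise ValueError(
                f"X has {X.shape[-1]} channels, transform expects {self.loadings_.shape[0]}"
            )
        return (X - self.center_) @ self.loadings_

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        Z = np.asarray(Z, dtype=float)
        if Z.shape[-1] != self.loadings_.shape[1]:
            raise ValueError(
                f"Z has {Z.shape[-1]} components, expected {self.loadings_.shape[1]}"
            )
        return Z @ self.loadings_.T + self.center_


def fit_pca(
    stacked: np.ndarray,
    n_components: int | None = None,
    variance_target: float = 0.90,
) -> CohortPCA:
    """Fit the shared PCA basis on the stacked cohort matrix."""
    return CohortPCA(n_components=n_components, variance_target=variance_target).fit(stacked)


def project(stacked: np.ndarray, transform: CohortPCA) -> np.ndarray:
    """Project rows of ``stacked`` onto the retained components."""
    return transform.transform(stacked)


def backproject(vector: np.ndarray, transform: CohortPCA) -> np.ndarray:
    """Map component-space coordinates back to ROI space (adds the center)."""
    return transform.inverse_transform(vector)
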