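"""Sample-outlier detection and high-leverage value masking/imputation.

Outlying samples are flagged by a chi-square test on squared Mahalanobis
distances computed in a truncated principal-component score space of the
log10-transformed matrix.  High-leverage single values are masked by
per-aptamer z-scores on raw intensities and imputed with the column
minimum (low side) or maximum (high side) over the remaining cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from serumscape.types import (
    MASK_IMPUTED,
    MASK_MISSING,
    MASK_OBSERVED,
    IntensityMatrix,
)

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    """Outcome of a QC pass."""

    d2: Optional[pd.Series] = None          # per-sample squared Mahalanobis distance
    p: Optional[pd.Series] = None           # chi-square upper-tail p per sample
    flagged: list = field(default_factory=list)
    n_components: int = 0
    explained_variance: float = 0.0
    masked_per_aptamer: Optional[pd.Series] = None
    imputation_log: list = field(default_factory=list)  # (sample, aptamer, old, new, side)


def detect_sample_outliers(
    matrix: IntensityMatrix,
    alpha: float = 0.1,
    variance_target: float = 0.9,
) -> QcReport:
    """Flag outlier samples via chi-square on PC-space Mahalanobis distances.

    The log10 matrix is column-centered and projected onto the smallest
    number of principal components explaining >= ``variance_target`` of the
    variance (capped at n - 2).  In that score space the squared Mahalanobis
    distance is the sum of squared standardized scores and is chi-square(k)
    under normality; samples with upper-tail p < ``alpha`` are flagged.
    """
    n = matrix.shape[0]
    if n < 5:
        raise ValueError(f"need >= 5 samples for outlier detection, got {n}")
    X = matrix.log10().to_numpy()
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s ** 2 / (n - 1)
    total = var.sum()
    if total <= 0:
        raise ValueError("matrix has no variance")
    frac = np.cumsum(var) / total
    k = int(np.searchsorted(frac, variance_target) + 1)
    k = max(1, min(k, n - 2, int((var > 1e-12 * total).sum())))
    scores = U[:, :k] * s[:k]
    d2 = np.sum(scores ** 2 / var[:k], axis=1)
    p = stats.chi2.sf(d2, df=k)
    d2_s = pd.Series(d2, index=matrix.values.index, name="d2")
    p_s = pd.Series(p, index=matrix.values.index, name="p")
    flagged = list(p_s.index[p_s < alpha])
    return QcReport(
        d2=d2_s, p=p_s, flagged=flagged, n_components=k,
        explained_variance=float(frac[k - 1]),
    )


def remove_samples(matrix: IntensityMatrix, sample_ids) -> IntensityMatrix:
    keep = [s for s in matrix.sample_ids if s not in set(sample_ids)]
    return matrix.subset_samples(keep)


def mask_and_impute_leverage_points(
    matrix: IntensityMatrix, z_cut: float = 1.8
) -> tuple[IntensityMatrix, QcReport]:
    """Mask |z| > ``z_cut`` cells per aptamer and impute with column min/max.

    z-scores use raw intensities with sample mean/sd (n-1 denominator);
    zero-variance columns are left untouched.  Low-side cells get the column
    minimum over remaining cells, high-side the maximum.  Pre-existing
    missing cells are imputed with the column minimum.  The output contains
    no missing values.
    """
    values = matrix.values.copy()
    mask = matrix.mask.copy()
    arr = values.to_numpy()
    marr = mask.to_numpy()
    log = []
    masked_counts = np.zeros(arr.shape[1], dtype=int)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        pre_missing = marr[:, j] == MASK_MISSING
        obs = ~pre_missing
        x = col[obs]
        hit = np.zeros(arr.shape[0], dtype=bool)
        z = np.zeros(arr.shape[0])
        if x.size >= 2:
            sd = x.std(ddof=1)
            if sd > 0:
                z[obs] = (x - x.mean()) / sd
                hit = obs & (np.abs(z) > z_cut)
        remaining = obs & ~hit
        if not remaining.any():
            continue  # nothing left to impute from; leave column as is
        lo, hi = col[remaining].min(), col[remaining].max()
        for i in np.where(hit)[0]:
            side = "high" if z[i] > 0 else "low"
            new = hi if side == "high" else lo
            log.append((values.index[i], values.columns[j], float(col[i]), float(new), side))
            arr[i, j] = new
            marr[i, j] = MASK_IMPUTED
            masked_counts[j] += 1
        for i in np.where(pre_missing)[0]:
            log.append((values.index[i], values.columns[j], float("nan"), float(lo), "low"))
            arr[i, j] = lo
            marr[i, j] = MASK_IMPUTED
            masked_counts[j] += 1
    out = IntensityMatrix(
        pd.DataFrame(arr, index=values.index, columns=values.columns),
        pd.DataFrame(marr, index=values.index, columns=values.columns, dtype=np.int8),
    )
    report = QcReport(
        masked_per_aptamer=pd.Series(masked_counts, index=values.columns, name="n_masked"),
        imputation_log=log,
    )
    return out, report
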