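"""Sample-space analyses: PCA, PERMANOVA, covariate projection, variance partitioning."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from serumscape.diff import build_design, _check_full_rank
from serumscape.types import IntensityMatrix, metadata_frame


@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples x PCs
    explained: np.ndarray         # variance fractions, nonincreasing
    loadings: pd.DataFrame        # aptamers x PCs


@dataclass
class PermanovaResult:
    f: float
    r2: float
    p: float
    permutations: int


@dataclass
class EnvfitResult:
    table: pd.DataFrame  # per covariate: pc1, pc2 (unit direction), r2, p


def pca_project(matrix: Union[IntensityMatrix, pd.DataFrame], k: int) -> PcaResult:
    """Covariance PCA of the column-centered log2 matrix via SVD.

    No unit-variance scaling.  Sign convention: the largest-magnitude
    loading of each component is made positive.
    """
    X = matrix.log2() if isinstance(matrix, IntensityMatrix) else matrix
    arr = X.to_numpy(dtype=float)
    n, m = arr.shape
    if k > min(n - 1, m):
        raise ValueError(f"k={k} exceeds min(n-1, m)={min(n - 1, m)}")
    centered = arr - arr.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    explained = (s ** 2) / (s ** 2).sum()
    scores = U[:, :k] * s[:k]
    loads = Vt[:k].T
    for j in range(k):
        i = int(np.argmax(np.abs(loads[:, j])))
        if loads[i, j] < 0:
            loads[:, j] *= -1
            scores[:, j] *= -1
    pcs = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=X.index, columns=pcs),
        explained=explained[:k],
        loadings=pd.DataFrame(loads, index=X.columns, columns=pcs),
    )


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from a squared-distance matrix and group labels."""
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    groups = np.unique(labels)
    ss_within = 0.0
    for g in groups:
        idx = np.where(labels == g)[0]
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    g = len(groups)
    f = (ss_between / (g - 1)) / (ss_within / (n - g))
    return float(f), float(ss_between / ss_total)


def permanova(
    data: Union[IntensityMatrix, np.ndarray, pd.DataFrame],
    labels: Sequence,
    permutations: int = 999,
    seed: Optional[int] = None,
    method: str = "permutation",
) -> PermanovaResult:
    """Permutational multivariate ANOVA on Euclidean (or supplied) distances.

    ``data`` is either an intensity matrix (Euclidean distances on log2
    values) or a precomputed square distance matrix.  ``method='exact'``
    enumerates all distinct label arrangements instead of sampling.
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 distinct groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 members")
    if isinstance(data, IntensityMatrix):
        X = data.log2().to_numpy()
        diff = X[:, None, :] - X[None, :, :]
        d2 = (diff ** 2).sum(axis=-1)
    else:
        D = np.asarray(data, dtype=float)
        if D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        d2 = D ** 2
    if d2.shape[0] != len(labels):
        raise ValueError("labels length does not match matrix")
    f_obs, r2 = _pseudo_f(d2, labels)
    if method == "exact":
        perms = {p for p in itertools.permutations(labels)}
        f_perm = np.array([_pseudo_f(d2, np.asarray(p))[0] for p in perms])
        p = float((f_perm >= f_obs - 1e-12).sum() / len(perms))
        used = len(perms)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            f_p, _ = _pseudo_f(d2, rng.permutation(labels))
            if f_p >= f_obs - 1e-12:
                count += 1
        p = (1.0 + count) / (permutations + 1.0)
        used = permutations
    else:
        raise ValueError(f"unknown method {method!r}")
    return PermanovaResult(f=f_obs, r2=r2, p=p, permutations=used)


def envfit_covariates(
    pca: PcaResult,
    metadata,
    permutations: int = 999,
    seed: Optional[int] = None,
    covariates: Sequence[str] = ("age", "bmi", "sex", "fasting"),
) -> EnvfitResult:
    """Project covariates onto the (PC1, PC2) plane.

    Each covariate is regressed on the first two score columns; the fitted
    coefficient vector, normalized to unit length, gives the direction, and
    the regression r^2 is tested by permuting the covariate.
    """
    md = metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
    md = md.loc[pca.scores.index]
    S = pca.scores.iloc[:, :2].to_numpy()
    X = np.column_stack([np.ones(len(S)), S])
    rng = np.random.default_rng(seed)
    rows = []
    for cov in covariates:
        if cov == "sex":
            y = (md["sex"] == "F").astype(float).to_numpy()
        elif cov == "fasting":
            y = md["fasting"].astype(float).to_numpy()
        else:
            y = md[cov].astype(float).to_numpy()
        if np.ptp(y) == 0:
            warnings.warn(f"constant covariate {cov!r} skipped")
            continue

        def fit_r2(yv: np.ndarray) -> tuple[np.ndarray, float]:
            beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
            resid = yv - X @ beta
            tss = ((yv - yv.mean()) ** 2).sum()
            return beta, 1.0 - (resid ** 2).sum() / tss

        beta, r2 = fit_r2(y)
        direction = beta[1:3]
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else direction
        count = sum(fit_r2(rng.permutation(y))[1] >= r2 - 1e-15
                    for _ in range(permutations))
        rows.append({"covariate": cov, "pc1": direction[0], "pc2": direction[1],
                     "r2": r2, "p": (1.0 + count) / (permutations + 1.0)})
    table = pd.DataFrame(rows, columns=["covariate", "pc1", "pc2", "r2", "p"])
    return EnvfitResult(table=table.set_index("covariate"))


def variance_partition(
    matrix: IntensityMatrix,
    metadata,
    covariates: Sequence[str] = ("sex", "age", "bmi", "fasting"),
) -> pd.DataFrame:
    """Per-aptamer variance fractions by drop-one R^2 increments.

    fraction(term) = R^2(full) - R^2(without term); residual = 1 - R^2(full).
    Fractions are reported as-is (they need not sum to 1 when covariates
    correlate).
    """
    md = metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
    md = md.loc[matrix.values.index]
    X_full = build_design(md, covariates)
    _check_full_rank(X_full)
    Y = matrix.log2().to_numpy()
    Yc = Y - Y.mean(axis=0, keepdims=True)
    tss = (Yc ** 2).sum(axis=0)
    tss = np.where(tss > 0, tss, np.nan)

    def r2_of(X: pd.DataFrame) -> np.ndarray:
        Xa = X.to_numpy()
        beta, *_ = np.linalg.lstsq(Xa, Y, rcond=None)
        resid = Y - Xa @ beta
        return 1.0 - (resid ** 2).sum(axis=0) / tss

    r2_full = r2_of(X_full)
    terms = [c for c in X_full.columns if c != "intercept"]
    out = {"residual": 1.0 - r2_full}
    for term in terms:
        r2_red = r2_of(X_full.drop(columns=[term]))
        name = "ME" if term == "group" else term
        out[name] = np.clip(r2_full - r2_red, 0.0, 1.0)
    cols = ["ME"] + [t for t in out if t not in ("ME", "residual")] + ["residual"]
    return pd.DataFrame(out, index=matrix.values.columns)[cols]
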