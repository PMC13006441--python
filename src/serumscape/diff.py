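"""Covariate-adjusted per-aptamer group comparison.

Ordinary least squares on the log2 matrix with design
[intercept, group, covariates], empirical-Bayes variance moderation of the
group t statistic (scaled chi-square / log-F moment matching), BH FDR,
Welch tests, and rank-based univariate classifier metrics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import special, stats

from serumscape.types import IntensityMatrix, metadata_frame

DEFAULT_COVARIATES = ("sex", "age", "bmi", "fasting")


@dataclass
class ModerationPrior:
    """Prior degrees of freedom and variance for the moderated statistic."""

    d0: float
    s02: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0 or math.isinf(self.d0)):
            raise ValueError("d0 must be >= 0 or infinite")
        if self.s02 <= 0 and self.d0 > 0:
            raise ValueError("s02 must be positive")


@dataclass
class LinearFits:
    """Per-aptamer OLS results on the shared design matrix."""

    aptamer_ids: list
    coef: pd.DataFrame        # aptamers x design terms
    s2: np.ndarray            # residual variances
    df_residual: int
    se_unscaled: float        # design-based unscaled SE of the group term
    terms: list


def build_design(metadata, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix: intercept, group (ME=1), then covariates.

    Sex and fasting are 0/1 indicators; age and BMI enter unscaled.
    """
    md = metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
    cols = {"intercept": np.ones(len(md)), "group": (md["group"] == "ME").astype(float)}
    for cov in covariates:
        if cov == "sex":
            cols["sex"] = (md["sex"] == "F").astype(float)
        elif cov == "fasting":
            cols["fasting"] = md["fasting"].astype(float)
        elif cov == "metabotype":
            cols["metabotype_M1"] = (md["metabotype"] == "M1").astype(float)
        else:
            cols[cov] = md[cov].astype(float)
    return pd.DataFrame(cols, index=md.index)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the collinear columns via QR pivoting
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in range(len(diag)) if diag[i] < 1e-10 * diag.max()]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_covariate_model(
    matrix: IntensityMatrix,
    metadata,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> LinearFits:
    """Per-aptamer OLS of log2 intensity on [intercept, group, covariates].

    The group coefficient is the covariate-adjusted log2 fold change
    (ME - HC).  Residual df is n - rank(design).
    """
    md = metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
    md = md.loc[matrix.values.index]
    X = build_design(md, covariates)
    _check_full_rank(X)
    Xa = X.to_numpy()
    Y = matrix.log2().to_numpy()
    n, p = Xa.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    xtx_inv = np.linalg.inv(Xa.T @ Xa)
    beta = xtx_inv @ Xa.T @ Y                  # p x m
    resid = Y - Xa @ beta
    dof = n - p
    s2 = (resid ** 2).sum(axis=0) / dof
    gi = list(X.columns).index("group")
    return LinearFits(
        aptamer_ids=list(matrix.values.columns),
        coef=pd.DataFrame(beta.T, index=matrix.values.columns, columns=X.columns),
        s2=s2,
        df_residual=dof,
        se_unscaled=float(np.sqrt(xtx_inv[gi, gi])),
        terms=list(X.columns),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if x <= 0:
            x = 1e-8
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation_prior(s2: np.ndarray, df: int) -> ModerationPrior:
    """Moment-match log residual variances against a scaled log-F.

    With s^2 ~ s0^2 * F(df, d0), e = log(s^2) - digamma(df/2) + log(df/2)
    has mean log(s0^2) + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2) beyond trigamma(df/2); d0 is recovered by inverting the
    trigamma function.  Non-positive excess variance yields d0 = inf.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive residual variances to estimate the prior")
    z = np.log(s2[ok])
    if np.ptp(z) == 0:
        # degenerate ensemble: all residual variances identical
        return ModerationPrior(d0=math.inf, s02=float(s2[ok][0]))
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = ((e - emean) ** 2).sum() / (n - 1)
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return ModerationPrior(d0=math.inf, s02=float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return ModerationPrior(d0=d0, s02=s02)


def moderate_statistics(
    fits: LinearFits,
    prior: Union[ModerationPrior, str] = "estimate",
) -> pd.DataFrame:
    """Moderated group t statistics, two-sided p, and shrunken variances.

    ``s_tilde^2 = (d0 s0^2 + d s^2) / (d0 + d)``; the t statistic uses the
    design-based unscaled standard error and d0 + d degrees of freedom.
    ``prior='estimate'`` fits (d0, s0^2) from the variance ensemble;
    d0 = 0 reproduces the ordinary OLS t.
    """
    if isinstance(prior, str):
        if prior != "estimate":
            raise ValueError(f"unknown prior spec {prior!r}")
        if len(fits.aptamer_ids) < 2:
            raise ValueError("need >= 2 aptamers to estimate the moderation prior")
        prior = estimate_moderation_prior(fits.s2, fits.df_residual)
    d0, s02 = prior.d0, prior.s02
    d = fits.df_residual
    s2 = fits.s2
    if math.isinf(d0):
        s2_tilde = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0:
        s2_tilde = s2.copy()
        df_total = float(d)
    else:
        s2_tilde = (d0 * s02 + d * s2) / (d0 + d)
        df_total = float(d0 + d)
    beta_g = fits.coef["group"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_g / (np.sqrt(s2_tilde) * fits.se_unscaled)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return pd.DataFrame(
        {
            "aptamer_id": fits.aptamer_ids,
            "log2fc": beta_g,
            "s2": s2,
            "s2_tilde": s2_tilde,
            "t": t,
            "df": df_total,
            "p": p,
            "d0": d0,
            "s02": s02,
        }
    ).set_index("aptamer_id")


def adjust_fdr_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t test; returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        return math.inf if x.mean() > y.mean() else -math.inf, float(x.size + y.size - 2), 0.0
    se2 = vx / x.size + vy / y.size
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return float(t), float(df), float(p)


def rank_classifier_metrics(scores, labels) -> tuple[float, float, float, float]:
    """AUC (Mann-Whitney with ties counted 1/2) plus the Youden operating point.

    Equivalent to the ROC of a univariate logistic / monotone score.
    Returns (auc, threshold, sensitivity, specificity); ties on Youden J
    break toward higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1] if labels.dtype.kind in "biu" else scores[labels == "ME"]
    neg = scores[labels == 0] if labels.dtype.kind in "biu" else scores[labels == "HC"]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (pos.size * neg.size)
    best = (-1.0, -np.inf, 0.0, 0.0)
    for thr in np.unique(scores):
        sens = float((pos >= thr).mean())
        spec = float((neg < thr).mean())
        j = sens + spec - 1.0
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and spec > best[3]):
            best = (j, float(thr), sens, spec)
    return float(auc), best[1], best[2], best[3]


def differential_abundance(
    matrix: IntensityMatrix,
    metadata,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    moderation: Union[ModerationPrior, str, None] = "estimate",
    classifier_metrics: bool = False,
) -> pd.DataFrame:
    """Full per-aptamer differential-abundance table.

    Fits the covariate model, moderates the group statistic (or uses plain
    OLS with ``moderation=None``), applies BH FDR, and optionally appends
    rank-classifier metrics computed from the raw log2 values.
    """
    fits = fit_covariate_model(matrix, metadata, covariates)
    if moderation is None:
        moderation = ModerationPrior(d0=0.0, s02=1.0)
    res = moderate_statistics(fits, moderation)
    res["q"] = adjust_fdr_bh(res["p"].to_numpy())
    if classifier_metrics:
        md = metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
        md = md.loc[matrix.values.index]
        labels = (md["group"] == "ME").astype(int).to_numpy()
        log2 = matrix.log2()
        metrics = [rank_classifier_metrics(log2[a].to_numpy(), labels)
                   for a in res.index]
        res["auc"] = [m[0] for m in metrics]
        res["youden_threshold"] = [m[1] for m in metrics]
        res["sensitivity"] = [m[2] for m in metrics]
        res["specificity"] = [m[3] for m in metrics]
    return res
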