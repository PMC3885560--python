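"""Per-metabolite pre/post inference: mixed models, paired t, folds, FDR.

The workhorse is a random-intercept linear mixed model

    y_ij = mu + beta * phase_ij + b_i + e_ij,
    b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2),

fit by REML with the single variance ratio psi = sigma_b^2 / sigma_e^2
profiled by one-dimensional optimization (per-subject Sherman-Morrison
inverses keep each fit closed-form given psi).  Inference on the phase
effect uses a Wald t with residual/containment degrees of freedom
N - n_subjects - 1, which is conservative for this unbalanced 15-pre /
12-post design.  The paired t-test over completers is the cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ogttmet.preprocess import select_transform


@dataclass
class MixedFitResult:
    beta: float          # fixed phase effect (post minus pre) on the model scale
    se: float
    t: float
    p: float
    df: float
    mu: float
    sigma2_b: float
    sigma2_e: float
    boundary: bool       # sigma_b^2 pinned at the zero boundary
    reml: float          # restricted log-likelihood at the optimum


def _reml_profile(psi: float, y: np.ndarray, X: np.ndarray, groups: list[np.ndarray]):
    """Profiled REML pieces at a fixed variance ratio psi = s2b/s2e.

    Returns (negative restricted log-likelihood, beta_hat, cov_unscaled,
    sigma2_e_hat).  V_i = I + psi * J has the Sherman-Morrison inverse
    I - (psi / (1 + n_i psi)) J and log-determinant log(1 + n_i psi).
    """
    n, p = X.shape
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    logdet_v = 0.0
    pieces = []
    for idx in groups:
        Xi, yi = X[idx], y[idx]
        ni = len(idx)
        c = psi / (1.0 + ni * psi)
        sx = Xi.sum(axis=0)
        sy = yi.sum()
        xtvx += Xi.T @ Xi - c * np.outer(sx, sx)
        xtvy += Xi.T @ yi - c * sx * sy
        logdet_v += math.log1p(ni * psi)
        pieces.append((Xi, yi, ni, c, sx, sy))
    beta = np.linalg.solve(xtvx, xtvy)
    quad = 0.0
    for Xi, yi, ni, c, sx, sy in pieces:
        ri = yi - Xi @ beta
        sr = ri.sum()
        quad += ri @ ri - c * sr * sr
    quad = max(quad, 1e-300)
    s2e = quad / (n - p)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    nll = 0.5 * ((n - p) * math.log(s2e) + logdet_v + logdet_xtvx + (n - p))
    return nll, beta, np.linalg.inv(xtvx), s2e


def fit_random_intercept(y, phase, subject) -> MixedFitResult:
    """REML fit of the random-intercept pre/post model.

    ``phase`` holds "pre"/"post" labels (or 0/1); ``subject`` arbitrary
    ids.  Handles unbalanced data (subjects observed in one phase only
    still inform the subject variance).  A variance-ratio estimate at the
    zero boundary is allowed and reported via ``boundary``.
    """
    y = np.asarray(y, dtype=float)
    phase = np.asarray(phase)
    subject = np.asarray(subject)
    mask = np.isfinite(y)
    y, phase, subject = y[mask], phase[mask], subject[mask]
    if phase.dtype.kind in "OU":
        ph = np.where(phase == "post", 1.0, 0.0)
    else:
        ph = phase.astype(float)
    subjects = pd.unique(subject)
    if len(subjects) < 3:
        raise ValueError("fit_random_intercept: need >= 3 subjects")
    both = sum(1 for s in subjects
               if len(set(ph[subject == s])) == 2)
    if both < 2:
        raise ValueError("fit_random_intercept: need >= 2 subjects observed in both phases")
    X = np.column_stack([np.ones_like(y), ph])
    groups = [np.flatnonzero(subject == s) for s in subjects]
    n = len(y)

    if np.allclose(y, y[0]):
        return MixedFitResult(beta=0.0, se=0.0, t=0.0, p=1.0,
                              df=n - len(subjects) - 1, mu=float(y[0]),
                              sigma2_b=0.0, sigma2_e=0.0, boundary=True, reml=math.inf)

    def nll_of_log_psi(lp):
        return _reml_profile(math.exp(lp), y, X, groups)[0]

    res = optimize.minimize_scalar(nll_of_log_psi, bounds=(math.log(1e-8), math.log(1e8)),
                                   method="bounded", options={"xatol": 1e-6})
    nll_hat = res.fun
    psi_hat = math.exp(res.x)
    nll0 = _reml_profile(0.0, y, X, groups)[0]
    boundary = nll0 <= nll_hat
    if boundary:
        psi_hat, nll_hat = 0.0, nll0
    _, beta, cov_unscaled, s2e = _reml_profile(psi_hat, y, X, groups)
    se = math.sqrt(s2e * cov_unscaled[1, 1])
    df = n - len(subjects) - 1
    if df < 1:
        raise ValueError("fit_random_intercept: non-positive residual degrees of freedom")
    t = beta[1] / se if se > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(t), df) if se > 0 else 1.0
    return MixedFitResult(beta=float(beta[1]), se=float(se), t=float(t), p=float(p),
                          df=float(df), mu=float(beta[0]),
                          sigma2_b=float(psi_hat * s2e), sigma2_e=float(s2e),
                          boundary=bool(boundary), reml=float(-nll_hat))


class PairedTResult(NamedTuple):
    t: float
    p: float
    degenerate: bool


def paired_t(pre, post) -> PairedTResult:
    """Two-sided paired t over complete pairs, df = n_pairs - 1.

    Zero-variance differences are degenerate: identical pre/post reports
    (t=0, p=1); a constant nonzero difference has no finite t.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired_t: unequal series lengths")
    mask = np.isfinite(pre) & np.isfinite(post)
    d = post[mask] - pre[mask]
    if d.size < 3:
        raise ValueError("paired_t: need >= 3 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return PairedTResult(t=0.0, p=1.0, degenerate=True)
        return PairedTResult(t=math.copysign(math.inf, d.mean()), p=0.0, degenerate=True)
    t = d.mean() / (sd / math.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), d.size - 1)
    return PairedTResult(t=float(t), p=float(p), degenerate=False)


def fold_change(pre_mean: float, post_mean: float) -> float:
    """Post/pre ratio of raw-scale group means."""
    if pre_mean <= 0:
        raise ValueError("fold_change: pre-intervention mean must be positive")
    return post_mean / pre_mean


def bh_fdr(pvalues, q_max: float = 0.05):
    """Benjamini-Hochberg step-up q-values and rejection flags.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1; reject where
    q <= q_max.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("bh_fdr: p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= q_max


def _phase_means(values: pd.DataFrame) -> tuple[float, float]:
    pre = values.loc[values["phase"] == "pre", "value"].mean()
    post = values.loc[values["phase"] == "post", "value"].mean()
    return float(pre), float(post)


def univariate_table(values: pd.DataFrame, endpoint: str = "fasting",
                     q_max: float = 0.05) -> pd.DataFrame:
    """Per-metabolite intervention table (fold, mixed-model p, BH q).

    ``values`` is long-form with columns metabolite_id, subject_id, phase,
    value — fasting intensities or per-subject incremental AUCs depending
    on ``endpoint``.  Each metabolite is transformed to approximate
    normality (feasible candidates only: AUCs can be negative), tested
    with the random-intercept mixed model on the transformed scale, and
    summarized with raw-scale phase means and the post/pre fold.  Raw-p
    and q-based significance are reported separately.
    """
    rows = []
    for mid, grp in values.groupby("metabolite_id", sort=True):
        grp = grp.dropna(subset=["value"])
        pre_mean, post_mean = _phase_means(grp)
        row = {"metabolite_id": mid, "endpoint": endpoint,
               "pre_mean": pre_mean, "post_mean": post_mean,
               "fold": post_mean / pre_mean if pre_mean > 0 else float("nan"),
               "transform": "identity", "beta": float("nan"), "se": float("nan"),
               "t": float("nan"), "p": float("nan"), "testable": False}
        try:
            choice = select_transform(grp["value"].to_numpy(), metabolite_id=mid)
            ty = choice.apply(grp["value"].to_numpy())
            row["transform"] = choice.family
        except ValueError:
            ty = grp["value"].to_numpy()
        try:
            fit = fit_random_intercept(ty, grp["phase"].to_numpy(), grp["subject_id"].to_numpy())
            row.update(beta=fit.beta, se=fit.se, t=fit.t, p=fit.p, testable=True)
        except ValueError:
            pass
        rows.append(row)
    table = pd.DataFrame(rows)
    testable = table["testable"] & table["p"].notna()
    q = np.full(len(table), np.nan)
    reject = np.zeros(len(table), dtype=bool)
    if testable.any():
        qv, rj = bh_fdr(table.loc[testable, "p"].to_numpy(), q_max=q_max)
        q[testable.to_numpy()] = qv
        reject[testable.to_numpy()] = rj
    table["q"] = q
    table["significant_raw"] = table["p"] < 0.05
    table["significant_fdr"] = reject
    table["direction"] = np.where(table["fold"] > 1, "up",
                                  np.where(table["fold"] < 1, "down", "flat"))
    return table


def fasting_values(panel: pd.DataFrame) -> pd.DataFrame:
    """Extract long-form fasting (t=0) values for :func:`univariate_table`."""
    fast = panel[panel["time_min"] == 0]
    return fast.rename(columns={"intensity": "value"})[
        ["metabolite_id", "subject_id", "phase", "value"]]
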