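"""Loading-prefiltered Spearman cross-correlation of phenotype and metabolites.

Variables entering the cross-correlation panel are restricted to those
whose PLS-DA loading deviates from the mean loading by more than one SD.
Correlations are Spearman (average-tied ranks, t-approximation p-values,
pairwise-complete observations) and reported with the conventional star
coding (* p<=0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    n: int


def spearman(x, y) -> SpearmanResult:
    """Spearman rho with average ties and two-sided t-approximation p.

    Pairwise-complete: rows where either variable is missing are dropped.
    |rho| = 1 reports p at the smallest positive float rather than 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"spearman: need >= 3 pairwise-complete observations, got {n}")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("spearman: a variable is all-tied (rank correlation undefined)")
    rho, p = stats.spearmanr(x, y)
    if abs(rho) >= 1.0:
        p = float(np.finfo(float).tiny)
    return SpearmanResult(rho=float(rho), p=float(p), n=n)


def loading_prefilter(loadings) -> list:
    """Retain ids whose |loading - mean| strictly exceeds the loading SD."""
    s = pd.Series(loadings, dtype=float)
    if s.size < 3:
        raise ValueError("loading_prefilter: need >= 3 loadings")
    sd = s.std(ddof=1)
    if sd == 0:
        warnings.warn("loading_prefilter: zero loading SD; nothing retained")
        return []
    dev = (s - s.mean()).abs()
    return list(s.index[dev > sd])


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def ccp(variables: pd.DataFrame, phase: str | None = None,
        with_bh: bool = False) -> pd.DataFrame:
    """All-pairs Spearman cross-correlation panel.

    ``variables`` is samples x variables (metabolite features and
    phenotype indices as columns); pairs with < 3 pairwise-complete
    observations or an all-tied variable are skipped.  Returns long-form
    (var_a, var_b, rho, p, n, stars) over unordered pairs a < b; an
    optional BH-adjusted q column can be appended.
    """
    cols = list(variables.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            try:
                res = spearman(variables[a], variables[b])
            except ValueError:
                continue
            rows.append({"phase": phase, "var_a": a, "var_b": b,
                         "rho": res.rho, "p": res.p, "n": res.n,
                         "stars": stars(res.p)})
    out = pd.DataFrame(rows)
    if with_bh and not out.empty:
        from ogttmet.univariate import bh_fdr
        out["q"], _ = bh_fdr(out["p"].to_numpy())
    return out


def ccp_matrix(long: pd.DataFrame) -> pd.DataFrame:
    """Square rho matrix from :func:`ccp` output (diagonal 1)."""
    ids = sorted(set(long["var_a"]) | set(long["var_b"]))
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for _, r in long.iterrows():
        mat.loc[r["var_a"], r["var_b"]] = r["rho"]
        mat.loc[r["var_b"], r["var_a"]] = r["rho"]
    return mat
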