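"""Reporting filter, sum normalization, transform-to-normality, autoscaling.

The preprocessing chain mirrors standard GC-TOF reporting practice: a
metabolite is reported if detected in at least half of all samples (one
sample = one subject/phase/time injection); reported peak heights are
normalized to each sample's total reported intensity; per-metabolite
transforms to approximate normality are chosen by minimizing the
Anderson-Darling A-squared statistic over a fixed log/power candidate
family; multivariate modeling consumes autoscaled (mean-0, SD-1) data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SAMPLE_KEY = ["subject_id", "phase", "time_min"]


def presence_filter(panel: pd.DataFrame, min_frac: float = 0.5):
    """Keep metabolites present (non-missing) in >= min_frac of samples.

    Returns ``(filtered_panel, report)`` where the report lists every
    metabolite with its presence fraction and retained flag.  The
    threshold is inclusive: present in exactly half the samples retains.
    """
    if not (0.0 < min_frac <= 1.0):
        raise ValueError("min_frac must be in (0, 1]")
    if panel.empty:
        warnings.warn("presence_filter: empty panel")
        report = pd.DataFrame(columns=["metabolite_id", "n_present", "n_samples",
                                       "presence_frac", "retained"])
        return panel.copy(), report
    n_samples = len(panel[SAMPLE_KEY].drop_duplicates())
    present = (panel.assign(present=panel["intensity"].notna())
               .groupby("metabolite_id", sort=True)["present"].sum())
    frac = present / n_samples
    report = pd.DataFrame({
        "metabolite_id": frac.index,
        "n_present": present.values.astype(int),
        "n_samples": n_samples,
        "presence_frac": frac.values,
        "retained": (frac.values >= min_frac),
    }).reset_index(drop=True)
    keep = set(report.loc[report["retained"], "metabolite_id"])
    return panel[panel["metabolite_id"].isin(keep)].reset_index(drop=True), report


def sum_normalize(panel: pd.DataFrame) -> pd.DataFrame:
    """Divide each intensity by its sample's total reported intensity.

    Missing values stay missing and do not contribute to the sum.  A
    sample whose intensities are all missing is an error (it has no
    normalizer).
    """
    out = panel.copy()
    sums = out.groupby(SAMPLE_KEY)["intensity"].transform("sum")
    counts = out.groupby(SAMPLE_KEY)["intensity"].transform("count")
    if (counts == 0).any():
        bad = out.loc[counts == 0, SAMPLE_KEY].drop_duplicates().iloc[0].tolist()
        raise ValueError(f"sum_normalize: sample {tuple(bad)} has no reported intensities")
    out["intensity"] = out["intensity"] / sums
    return out


def anderson_darling(values) -> float:
    """Anderson-Darling A-squared for composite normality.

    Mean and SD are estimated from the data (n-1 SD); the small-sample
    multiplier (1 + 4/n - 25/n^2) is applied to the statistic, so the
    result compares directly with the published 5% critical value 0.752.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 8:
        raise ValueError(f"anderson_darling: need >= 8 finite values, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("anderson_darling: constant input, normality undefined")
    z = np.sort((x - x.mean()) / sd)
    i = np.arange(1, n + 1)
    log_cdf = stats.norm.logcdf(z)
    log_sf = stats.norm.logsf(z)
    a2 = -n - np.mean((2 * i - 1) * (log_cdf + log_sf[::-1]))
    return float(a2 * (1 + 4.0 / n - 25.0 / n**2))


@dataclass
class TransformChoice:
    """The transform minimizing Anderson-Darling A-squared for one variable."""

    metabolite_id: str
    family: str
    ad_statistic: float
    lam: float | None = None
    candidate_stats: dict = field(default_factory=dict)

    def apply(self, values):
        return apply_transform(values, self.family, self.lam)


_BOXCOX_LAMBDAS = (-2.0, -1.0, -0.5, 0.5, 1.0, 2.0)
# Fixed tie-break order: simpler families first.
_FAMILY_ORDER = ["identity", "log", "sqrt", "cube-root", "square"] + [
    f"box-cox({lam:g})" for lam in _BOXCOX_LAMBDAS]


def apply_transform(values, family: str, lam: float | None = None):
    x = np.asarray(values, dtype=float)
    if family == "identity":
        return x
    if family == "log":
        return np.log(x)
    if family == "sqrt":
        return np.sqrt(x)
    if family == "cube-root":
        return np.cbrt(x)
    if family == "square":
        return np.square(x)
    if family.startswith("box-cox"):
        if lam is None:
            lam = float(family[len("box-cox("):-1])
        return (np.power(x, lam) - 1.0) / lam
    raise ValueError(f"unknown transform family {family!r}")


def _feasible(x: np.ndarray, family: str) -> bool:
    if family in ("log",) or family.startswith("box-cox"):
        return bool((x > 0).all())
    if family == "sqrt":
        return bool((x >= 0).all())
    return True


def select_transform(values, candidates: list[str] | None = None,
                     metabolite_id: str = "") -> TransformChoice:
    """Pick the candidate transform minimizing A-squared.

    Candidates with nonpositive values under log/Box-Cox are infeasible
    (no silent offsets).  Ties break toward the earlier (simpler) family
    in the fixed order identity < log < sqrt < cube-root < square <
    box-cox.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if candidates is None:
        candidates = list(_FAMILY_ORDER)
    stats_by_family: dict[str, float] = {}
    best = None
    for family in candidates:
        if not _feasible(x, family):
            stats_by_family[family] = float("nan")
            continue
        try:
            a2 = anderson_darling(apply_transform(x, family))
        except ValueError:
            stats_by_family[family] = float("nan")
            continue
        stats_by_family[family] = a2
        if best is None or a2 < best[1]:
            best = (family, a2)
    if best is None:
        raise ValueError("select_transform: no feasible candidate transform")
    lam = float(best[0][len("box-cox("):-1]) if best[0].startswith("box-cox") else None
    return TransformChoice(metabolite_id=metabolite_id, family=best[0],
                           ad_statistic=best[1], lam=lam,
                           candidate_stats=stats_by_family)


def autoscale(X):
    """Center each column to mean 0 and scale to SD 1 (n-1 convention).

    ``X`` is samples x features.  Returns (scaled, centers, scales); test
    samples must be projected with :func:`apply_autoscale` using the
    training centers/scales, never their own.
    """
    X = np.asarray(X, dtype=float)
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(scales == 0)
    if zero.size:
        raise ValueError(f"autoscale: zero-variance feature(s) at column(s) {zero.tolist()}")
    return (X - centers) / scales, centers, scales


def apply_autoscale(X, centers, scales):
    return (np.asarray(X, dtype=float) - centers) / scales
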