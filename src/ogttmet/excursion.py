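"""Post-OGTT incremental AUC excursions and responsiveness classes.

The incremental AUC is the trapezoidal integral of (value(t) - value(0))
over the observed span of the OGTT.  It is signed: metabolites that are
suppressed after the glucose drink (most lipids) have negative AUCs.
Interior missing timepoints are bridged linearly between their flanking
observations; a missing terminal timepoint restricts integration to the
observed span (no extrapolation).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats


def incremental_auc(times, values, total: bool = False) -> float:
    """Signed baseline-subtracted trapezoid AUC of one excursion series.

    Requires the t=0 baseline and at least 3 non-missing observations.
    ``total=True`` integrates the raw (not baseline-subtracted) curve,
    for sensitivity analyses only.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("incremental_auc: times and values differ in length")
    if t.size == 0 or t[0] != 0:
        raise ValueError("incremental_auc: series must start at t=0")
    if np.any(np.diff(t) <= 0):
        raise ValueError("incremental_auc: times must be strictly increasing")
    if not np.isfinite(v[0]):
        raise ValueError("incremental_auc: missing baseline (t=0) value")
    obs = np.isfinite(v)
    if obs.sum() < 3:
        raise ValueError("incremental_auc: need >= 3 observed timepoints including t=0")
    t_obs, v_obs = t[obs], v[obs]
    y = v_obs if total else v_obs - v_obs[0]
    return float(np.trapezoid(y, t_obs))


def subject_aucs(panel: pd.DataFrame, total: bool = False) -> pd.DataFrame:
    """Per (metabolite, phase, subject) incremental AUC; unusable series skipped.

    A subject contributes if their series has a baseline and >= 3 observed
    timepoints.  Returns long-form with columns metabolite_id, phase,
    subject_id, auc, span_max (last observed timepoint).
    """
    rows = []
    for (mid, ph, s), grp in panel.groupby(["metabolite_id", "phase", "subject_id"], sort=True):
        series = grp.sort_values("time_min")
        t = series["time_min"].to_numpy(dtype=float)
        v = series["intensity"].to_numpy(dtype=float)
        if t.size == 0 or t[0] != 0:
            continue
        try:
            a = incremental_auc(t, v, total=total)
        except ValueError:
            continue
        rows.append((mid, ph, s, a, float(t[np.isfinite(v)].max())))
    return pd.DataFrame(rows, columns=["metabolite_id", "phase", "subject_id",
                                       "auc", "span_max"])


def cohort_aucs(panel: pd.DataFrame, alpha: float = 0.05,
                total: bool = False) -> pd.DataFrame:
    """Group-level excursion table: mean +/- SEM AUC and one-sample t vs 0.

    Per (metabolite, phase): n, mean, SEM, two-sided one-sample t with
    df = n-1, and the ``nonzero`` flag (p < alpha, equivalent to the
    (1-alpha) confidence interval excluding zero).  Phases with n < 3 are
    flagged untestable; zero-variance AUCs are flagged degenerate.
    """
    per_subject = subject_aucs(panel, total=total)
    rows = []
    for (mid, ph), grp in per_subject.groupby(["metabolite_id", "phase"], sort=True):
        a = grp["auc"].to_numpy()
        n = a.size
        row = {"metabolite_id": mid, "phase": ph, "n": n,
               "mean_auc": float(a.mean()) if n else float("nan"),
               "sem_auc": float("nan"), "t": float("nan"), "p": float("nan"),
               "nonzero": False, "untestable": n < 3, "degenerate": False}
        if n >= 3:
            sd = a.std(ddof=1)
            if sd == 0:
                row["degenerate"] = True
            else:
                sem = sd / math.sqrt(n)
                t = a.mean() / sem
                p = 2.0 * stats.t.sf(abs(t), n - 1)
                row.update(sem_auc=float(sem), t=float(t), p=float(p),
                           nonzero=bool(p < alpha))
        rows.append(row)
    return pd.DataFrame(rows)


def classify_responsiveness(excursions: pd.DataFrame) -> pd.DataFrame:
    """Four-way class from the two phase-level nonzero flags.

    both / pre_only / post_only / neither; an untestable phase counts as
    not-nonzero and sets the ``flagged`` column.
    """
    rows = []
    for mid, grp in excursions.groupby("metabolite_id", sort=True):
        flags = {row["phase"]: (bool(row["nonzero"]), bool(row["untestable"]))
                 for _, row in grp.iterrows()}
        pre, pre_un = flags.get("pre", (False, True))
        post, post_un = flags.get("post", (False, True))
        cls = {(True, True): "both", (True, False): "pre_only",
               (False, True): "post_only", (False, False): "neither"}[(pre, post)]
        rows.append({"metabolite_id": mid, "class": cls,
                     "flagged": pre_un or post_un})
    return pd.DataFrame(rows)


def compare_auc_phases(per_subject: pd.DataFrame):
    """Pre-vs-post mixed-model comparison of per-subject AUCs.

    ``per_subject`` is the output of :func:`subject_aucs` restricted to
    one metabolite.  Returns (delta, p) where delta is the post-minus-pre
    fixed effect from the random-intercept model.
    """
    from ogttmet.univariate import fit_random_intercept

    n_pairs = (per_subject.groupby("subject_id")["phase"].nunique() == 2).sum()
    if n_pairs < 3:
        raise ValueError("compare_auc_phases: need >= 3 paired completers")
    fit = fit_random_intercept(per_subject["auc"].to_numpy(),
                               per_subject["phase"].to_numpy(),
                               per_subject["subject_id"].to_numpy())
    return fit.beta, fit.p
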