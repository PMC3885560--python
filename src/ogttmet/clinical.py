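"""Insulin-sensitivity indices from OGTT glucose/insulin series.

Conventions (mg/dL glucose, uU/mL insulin):

* QUICKI = 1 / (log10 I0 + log10 G0)
* HOMA-IR = G0 * I0 / 405
* Matsuda = 10000 / sqrt(G0 * I0 * Gbar * Ibar), with Gbar, Ibar the
  unweighted means over the full OGTT schedule (0, 30, 60, 90, 120 min).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def quicki(g0: float, i0: float) -> float:
    """Quantitative insulin sensitivity check index from fasting values."""
    if g0 <= 0 or i0 <= 0:
        raise ValueError("quicki: glucose and insulin must be positive")
    denom = math.log10(i0) + math.log10(g0)
    if denom <= 0:
        raise ValueError("quicki: log10(I0) + log10(G0) <= 0 (non-physiological input)")
    return 1.0 / denom


def homa(g0: float, i0: float) -> float:
    """HOMA-IR under the mg/dL convention (divisor 405)."""
    if g0 <= 0 or i0 <= 0:
        raise ValueError("homa: glucose and insulin must be positive")
    return g0 * i0 / 405.0


def matsuda(g_series, i_series, times=None) -> float:
    """Matsuda-DeFronzo whole-body insulin sensitivity index.

    The first element of each series must be the fasting (t=0) value;
    means are unweighted over all scheduled timepoints.
    """
    g = np.asarray(g_series, dtype=float)
    i = np.asarray(i_series, dtype=float)
    if g.shape != i.shape:
        raise ValueError("matsuda: glucose and insulin series differ in length")
    if times is not None:
        times = list(times)
        if len(times) != g.size:
            missing = "schedule length mismatch"
            raise ValueError(f"matsuda: {missing}")
        if times[0] != 0:
            raise ValueError("matsuda: missing timepoint 0 (fasting values)")
    if np.any(~np.isfinite(g)) or np.any(~np.isfinite(i)):
        k = int(np.flatnonzero(~np.isfinite(g * i))[0])
        label = times[k] if times is not None else k
        raise ValueError(f"matsuda: missing value at timepoint {label}")
    if np.any(g <= 0) or np.any(i <= 0):
        raise ValueError("matsuda: all glucose and insulin values must be positive")
    return 10000.0 / math.sqrt(g[0] * i[0] * g.mean() * i.mean())


def cohort_indices(subjects: pd.DataFrame, schedule=(0, 30, 60, 90, 120)):
    """Per-subject indices plus a phase-level summary (mean, SEM, paired p).

    Returns ``(indices, summary)``.  The paired comparison uses completers
    (subjects observed in both phases) via the paired t-test; a phase with
    a single subject reports SEM as missing.
    """
    from ogttmet.univariate import paired_t

    schedule = [int(t) for t in schedule]
    rows = []
    for (s, ph), grp in subjects.groupby(["subject_id", "phase"], sort=True):
        series = grp.set_index("time_min").sort_index()
        missing = [t for t in schedule if t not in series.index]
        if missing:
            raise ValueError(f"cohort_indices: subject {s} phase {ph} missing timepoint(s) {missing}")
        g = series.loc[schedule, "glucose_mgdl"].to_numpy()
        i = series.loc[schedule, "insulin_uUml"].to_numpy()
        rows.append({
            "subject_id": s, "phase": ph,
            "fasting_glucose": g[0], "fasting_insulin": i[0],
            "matsuda": matsuda(g, i, schedule),
            "quicki": quicki(g[0], i[0]),
            "homa": homa(g[0], i[0]),
        })
    indices = pd.DataFrame(rows)

    summary_rows = []
    for name in ("matsuda", "quicki", "homa", "fasting_glucose", "fasting_insulin"):
        for ph in ("pre", "post"):
            vals = indices.loc[indices["phase"] == ph, name].to_numpy()
            n = vals.size
            summary_rows.append({
                "index": name, "phase": ph, "n": n,
                "mean": float(vals.mean()) if n else float("nan"),
                "sem": float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
            })
    summary = pd.DataFrame(summary_rows)

    # Paired comparison over completers.
    wide = indices.pivot(index="subject_id", columns="phase", values="matsuda").dropna()
    pvals = {}
    for name in ("matsuda", "quicki", "homa", "fasting_glucose", "fasting_insulin"):
        w = indices.pivot(index="subject_id", columns="phase", values=name).dropna()
        if len(w) >= 3 and {"pre", "post"} <= set(w.columns):
            res = paired_t(w["pre"].to_numpy(), w["post"].to_numpy())
            pvals[name] = res.p
        else:
            pvals[name] = float("nan")
    summary["paired_p"] = summary["index"].map(pvals)
    _ = wide
    return indices, summary
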