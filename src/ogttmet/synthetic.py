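"""Synthetic OGTT metabolomics cohorts with planted ground truth.

The generator emulates the design of a pre/post diet-and-exercise
intervention study in insulin-resistant women: 15 subjects at baseline,
12 completers re-examined post-intervention, OGTT blood draws at
0/30/60/90/120 min, ~321 GC-TOF plasma metabolites, and improved
post-intervention insulin sensitivity.  Peak heights are log-normal with
a per-(subject, metabolite) random intercept; each metabolite follows one
of five OGTT response archetypes; a configurable set of "planted"
metabolites carries a pre-vs-post intervention effect on its fasting
level or its post-OGTT incremental AUC, providing a recoverable ground
truth for every downstream stage.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

PHASES = ("pre", "post")

ARCHETYPES = ("lipid_suppressed", "carb_raised", "late_rise_xeno", "fasting_shifted", "inert")

# Log-scale time-course templates (units of one total log-SD) at the five
# scheduled timepoints.  Lipids fall monotonically after the insulin surge;
# carbohydrate products peak at 30-60 min; xeno-metabolites of the glucose
# drink rise late; fasting-shifted and inert metabolites are flat in time.
_TEMPLATES = {
    "lipid_suppressed": np.array([0.0, -0.30, -0.60, -0.85, -1.00]),
    "carb_raised": np.array([0.0, 1.00, 0.80, 0.40, 0.10]),
    "late_rise_xeno": np.array([0.0, 0.10, 0.40, 0.80, 1.00]),
    "fasting_shifted": np.zeros(5),
    "inert": np.zeros(5),
}

# Shape of the planted AUC-channel effect over the schedule: zero at the
# fasting draw (the incremental AUC is baseline-subtracted) and peaking
# mid-excursion.
_AUC_BUMP = np.array([0.0, 0.75, 1.0, 0.75, 0.4])


def derive_seed(seed: int, name: str) -> int:
    """Stable per-stage sub-seed (< 2**31) from a master seed and a label."""
    return zlib.crc32(f"{int(seed)}:{name}".encode()) & 0x7FFFFFFF


@dataclass
class CohortConfig:
    """Study-design and noise parameters for the synthetic cohort.

    Defaults mirror the emulated study: 15 subjects enrolled pre-
    intervention, 12 completers, pre-intervention OGTT series available
    for 13 subjects, 321 detected metabolites, draws at 0/30/60/90/120
    min.  Dropout is nested: completers are a subset of the OGTT-pre
    subjects, which are a subset of all enrolled subjects.
    """

    n_subjects_pre: int = 15
    n_completers: int = 12
    n_ogtt_pre: int = 13
    n_metabolites: int = 321
    timepoints: Sequence[int] = (0, 30, 60, 90, 120)
    class_mix: dict = field(default_factory=lambda: {
        "lipid_suppressed": 0.25,
        "carb_raised": 0.20,
        "late_rise_xeno": 0.05,
        "fasting_shifted": 0.10,
        "inert": 0.40,
    })
    effect_size_fasting: float = 1.5   # planted fasting shift, total log-SD units
    effect_size_auc: float = 1.5       # planted excursion shift, total log-SD units
    n_planted: int = 20
    subject_sd: float = 0.35           # log-scale between-subject SD
    residual_sd: float = 0.30          # log-scale residual SD
    missing_frac: float = 0.05         # MCAR missingness per metabolite-sample
    amp_range: tuple = (0.6, 1.4)      # per-metabolite archetype amplitude range
    # Phenotype (glucose/insulin) generator parameters.
    pheno_subject_sd: float = 0.20     # log-scale between-subject phenotype SD
    pheno_noise_sd: float = 0.06       # log-scale per-measurement noise
    insulin_improvement: float = 0.74  # post/pre fold of fasting insulin (13.7/18.5)
    glucose_improvement: float = 0.95  # post/pre fold of fasting glucose (84.6/89.1)
    excursion_improvement: float = 0.85  # post/pre fold of insulin excursion
    response_sd: float = 0.30          # between-subject spread of the response magnitude
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_pre < 1:
            raise ValueError("n_subjects_pre must be >= 1")
        if not (1 <= self.n_completers <= self.n_subjects_pre):
            raise ValueError("n_completers must satisfy 1 <= n_completers <= n_subjects_pre")
        if not (self.n_completers <= self.n_ogtt_pre <= self.n_subjects_pre):
            raise ValueError("n_ogtt_pre must satisfy n_completers <= n_ogtt_pre <= n_subjects_pre")
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be >= 1")
        tp = list(self.timepoints)
        if len(tp) < 2 or tp[0] != 0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing and start at 0")
        if set(self.class_mix) != set(ARCHETYPES):
            raise ValueError(f"class_mix must have exactly the keys {ARCHETYPES}")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix fractions must sum to 1")
        if any(v < 0 for v in self.class_mix.values()):
            raise ValueError("class_mix fractions must be non-negative")
        for name in ("subject_sd", "residual_sd", "pheno_noise_sd", "pheno_subject_sd",
                     "response_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.subject_sd == 0 and self.residual_sd == 0:
            raise ValueError("subject_sd and residual_sd cannot both be 0")
        if not (0.0 <= self.missing_frac < 1.0):
            raise ValueError("missing_frac must be in [0, 1)")
        if not (0 <= self.n_planted <= self.n_metabolites):
            raise ValueError("n_planted must be in [0, n_metabolites]")
        if self.amp_range[0] <= 0 or self.amp_range[1] < self.amp_range[0]:
            raise ValueError("amp_range must be positive and non-decreasing")

    @property
    def total_sd(self) -> float:
        return float(np.hypot(self.subject_sd, self.residual_sd))


@dataclass
class Cohort:
    """Bundle returned by :func:`generate_cohort`."""

    panel: pd.DataFrame          # subject_id, phase, time_min, metabolite_id, intensity
    subjects: pd.DataFrame       # subject_id, phase, time_min, glucose_mgdl, insulin_uUml
    truth: pd.DataFrame          # metabolite_id, direction, channel
    metabolite_info: pd.DataFrame  # metabolite_id, archetype, base_log, amplitude


def _subject_ids(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def _metabolite_ids(n: int) -> list[str]:
    return [f"M{i + 1:03d}" for i in range(n)]


def _assign_archetypes(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic archetype counts from the mix (largest remainder)."""
    m = config.n_metabolites
    fracs = np.array([config.class_mix[a] for a in ARCHETYPES])
    counts = np.floor(fracs * m).astype(int)
    rem = m - counts.sum()
    order = np.argsort(-(fracs * m - counts))
    counts[order[:rem]] += 1
    labels = np.repeat(np.array(ARCHETYPES, dtype=object), counts)
    rng.shuffle(labels)
    return labels


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the intensity panel, phenotype series and planted truth.

    Log intensity of metabolite *m* for subject *s* in phase *ph* at time *t*:

        log I = base_m + sigma * amp_m * template_m(t) + b_{s,m} + effect + eps

    with ``b ~ N(0, subject_sd^2)``, ``eps ~ N(0, residual_sd^2)`` and
    ``sigma`` the total log-SD.  Planted fasting-channel responders get a
    constant ``direction * effect_size_fasting * sigma`` shift in the post
    phase (level shift: visible at t=0, invisible to the baseline-
    subtracted AUC); AUC-channel responders get a mid-excursion bump of
    peak height ``direction * effect_size_auc * sigma`` in the post phase.
    """
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed, "cohort"))
    tp = np.asarray(list(config.timepoints), dtype=float)
    n_tp = len(tp)
    sigma = config.total_sd

    subjects = _subject_ids(config.n_subjects_pre)
    completers = subjects[: config.n_completers]
    ogtt_pre = subjects[: config.n_ogtt_pre]
    mets = _metabolite_ids(config.n_metabolites)

    archetypes = _assign_archetypes(config, rng)
    base = rng.uniform(np.log(1e4), np.log(1e6), size=config.n_metabolites)
    amp = rng.uniform(*config.amp_range, size=config.n_metabolites)

    # Planted truth: responders alternate fasting / auc channels.
    planted_idx = rng.choice(config.n_metabolites, size=config.n_planted, replace=False)
    channels = np.array(["fasting", "auc"], dtype=object)[np.arange(config.n_planted) % 2]
    directions = rng.choice([-1, 1], size=config.n_planted)
    truth = pd.DataFrame({
        "metabolite_id": [mets[i] for i in planted_idx],
        "direction": directions,
        "channel": channels,
    })
    fast_shift = np.zeros(config.n_metabolites)
    auc_shift = np.zeros(config.n_metabolites)
    for i, ch, d in zip(planted_idx, channels, directions):
        if ch == "fasting":
            fast_shift[i] = d * config.effect_size_fasting * sigma
        else:
            auc_shift[i] = d * config.effect_size_auc * sigma

    # Sample grid: pre rows for OGTT-pre subjects at every timepoint, the
    # remaining enrolled subjects at t=0 only; post rows for completers.
    rows = []
    for s in subjects:
        times = tp if s in ogtt_pre else tp[:1]
        for t in times:
            rows.append((s, "pre", t))
    for s in completers:
        for t in tp:
            rows.append((s, "post", t))
    grid = pd.DataFrame(rows, columns=["subject_id", "phase", "time_min"])

    t_index = {t: k for k, t in enumerate(tp)}
    templates = np.stack([_TEMPLATES[a][: n_tp] if len(_TEMPLATES[a]) >= n_tp
                          else np.resize(_TEMPLATES[a], n_tp) for a in archetypes])
    bump = np.resize(_AUC_BUMP, n_tp)

    # Subject random intercepts, per subject x metabolite.
    b = rng.normal(0.0, config.subject_sd, size=(config.n_subjects_pre, config.n_metabolites))
    s_index = {s: k for k, s in enumerate(subjects)}

    records = []
    for s, phase, t in grid.itertuples(index=False):
        k = t_index[t]
        mu = (base
              + sigma * amp * templates[:, k]
              + b[s_index[s]])
        if phase == "post":
            mu = mu + fast_shift + auc_shift * bump[k]
        logval = mu + rng.normal(0.0, config.residual_sd, size=config.n_metabolites)
        inten = np.exp(logval)
        if config.missing_frac > 0:
            miss = rng.random(config.n_metabolites) < config.missing_frac
            inten = np.where(miss, np.nan, inten)
        records.append(pd.DataFrame({
            "subject_id": s, "phase": phase, "time_min": int(t),
            "metabolite_id": mets, "intensity": inten,
        }))
    panel = pd.concat(records, ignore_index=True)

    info = pd.DataFrame({
        "metabolite_id": mets,
        "archetype": archetypes,
        "base_log": base,
        "amplitude": amp,
    })
    pheno = generate_glucose_insulin(config)
    return Cohort(panel=panel, subjects=pheno, truth=truth, metabolite_info=info)


# OGTT multiplicative excursion shapes relative to the fasting value.
# Calibrated so that the pre-intervention cohort-mean Matsuda index sits
# near 2 (insulin-resistant) and rises post-intervention.
_GLUCOSE_SHAPE = np.array([1.0, 1.55, 1.45, 1.25, 1.10])
_INSULIN_SHAPE = np.array([1.0, 10.0, 9.0, 7.5, 5.5])

_FASTING_GLUCOSE = 89.1   # mg/dL, pre-intervention cohort mean
_FASTING_INSULIN = 18.5   # uU/mL, pre-intervention cohort mean


def generate_glucose_insulin(config: CohortConfig) -> pd.DataFrame:
    """Per-subject OGTT glucose/insulin series for both phases.

    Fasting insulin falls and the insulin excursion shrinks post-
    intervention (``insulin_improvement``, ``excursion_improvement``), so
    the cohort-mean Matsuda index rises pre -> post.  With zero phenotype
    SDs and all improvement factors at 1 the pre and post series coincide.
    """
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed, "phenotype"))
    tp = np.asarray(list(config.timepoints), dtype=float)
    n_tp = len(tp)
    gshape = np.resize(_GLUCOSE_SHAPE, n_tp)
    ishape = np.resize(_INSULIN_SHAPE, n_tp)

    subjects = _subject_ids(config.n_subjects_pre)
    completers = set(subjects[: config.n_completers])

    rows = []
    for s in subjects:
        u_i = rng.normal(0.0, config.pheno_subject_sd)
        u_g = rng.normal(0.0, config.pheno_subject_sd / 3.0)
        i0 = _FASTING_INSULIN * np.exp(u_i)
        g0 = _FASTING_GLUCOSE * np.exp(u_g)
        # Per-subject response magnitude, multiplying the log-fold of each
        # improvement factor so a null effect (factor 1) stays exactly null.
        resp = math.exp(rng.normal(0.0, config.response_sd))
        for phase in PHASES:
            if phase == "post" and s not in completers:
                continue
            if phase == "post":
                i0_ph = i0 * config.insulin_improvement ** resp
                g0_ph = g0 * config.glucose_improvement ** resp
                exc = config.excursion_improvement ** resp
            else:
                i0_ph, g0_ph, exc = i0, g0, 1.0
            g_noise = np.exp(rng.normal(0.0, config.pheno_noise_sd, n_tp))
            i_noise = np.exp(rng.normal(0.0, config.pheno_noise_sd, n_tp))
            glucose = g0_ph * (1.0 + (gshape - 1.0) * exc) * g_noise
            insulin = i0_ph * (1.0 + (ishape - 1.0) * exc) * i_noise
            # keep the fasting draw exactly at the fasting value
            glucose[0] = g0_ph
            insulin[0] = i0_ph
            glucose = np.maximum(glucose, 40.0)
            insulin = np.maximum(insulin, 0.5)
            for t, g, i in zip(tp, glucose, insulin):
                rows.append((s, phase, int(t), g, i))
    return pd.DataFrame(rows, columns=["subject_id", "phase", "time_min",
                                       "glucose_mgdl", "insulin_uUml"])


def generate_fingerprints(ids: Sequence[str], n_bits: int = 256,
                          n_clusters: int = 8, seed: int = 0,
                          flip_prob: float = 0.05) -> list:
    """Clustered binary chemical fingerprints.

    Each cluster has a random prototype bitvector (density 0.5); members
    flip each prototype bit independently with probability ``flip_prob``.
    Small ``flip_prob`` concentrates within-cluster Tanimoto similarity
    above 0.7 ((1-2e)/(1+2e) in expectation) while between-cluster
    similarity concentrates near 1/3.
    """
    from ogttmet.io_tables import Fingerprint

    if n_bits < 16:
        raise ValueError("n_bits must be >= 16")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > len(ids):
        raise ValueError(f"n_clusters ({n_clusters}) exceeds number of ids ({len(ids)})")
    if not (0.0 <= flip_prob < 0.5):
        raise ValueError("flip_prob must be in [0, 0.5)")
    rng = np.random.default_rng(derive_seed(seed, "fingerprints"))
    prototypes = rng.random((n_clusters, n_bits)) < 0.5
    assignment = np.arange(len(ids)) % n_clusters
    fps = []
    for mid, c in zip(ids, assignment):
        flips = rng.random(n_bits) < flip_prob
        bits = np.logical_xor(prototypes[c], flips)
        if not bits.any():          # guarantee at least one set bit
            bits[int(rng.integers(n_bits))] = True
        fps.append(Fingerprint(metabolite_id=str(mid), bits=bits))
    return fps
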