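"""PLS-DA from scratch: NIPALS, LOO-CV, weight jackknife, permutation nulls.

Partial least squares discriminant analysis with a single dummy-coded
response (y in {0,1}, centered).  Components are extracted by NIPALS
deflation; the component count is chosen by leave-one-out Q2 (autoscaling
re-estimated inside each fold); features are retained by the sign-split
weight filter: within each sign group of full-model LV1 weights, a
feature's LOO fold-wise weights are tested against the group's mean
weight by a one-sample t-test (p < 0.05, and the feature's mean weight
more extreme than the group mean).  Model validation draws observed and
permuted-label null distributions of Q2, RMSEP and AUROC over random
2/3-1/3 train/test splits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# core NIPALS machinery


def _scale_fit(X: np.ndarray):
    """Autoscale tolerant of constant columns (scale 1, centered to 0)."""
    centers = np.nanmean(X, axis=0)
    scales = np.nanstd(X, axis=0, ddof=1)
    scales = np.where((scales == 0) | ~np.isfinite(scales), 1.0, scales)
    return centers, scales


def _scale_apply(X: np.ndarray, centers, scales):
    Xs = (X - centers) / scales
    return np.nan_to_num(Xs, nan=0.0)  # missing -> training mean


def _nipals(Xs: np.ndarray, yc: np.ndarray, n_components: int):
    """PLS1 NIPALS on pre-scaled data.

    Returns (W, P, T, q) with unit-norm weight vectors w_a, loadings p_a,
    mutually orthogonal scores t_a and y-loadings q_a.
    """
    n, m = Xs.shape
    A = max(1, min(n_components, n - 1, m))
    X = Xs.copy()
    y = yc.astype(float).copy()
    W = np.zeros((m, A))
    P = np.zeros((m, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    actual = 0
    for a in range(A):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < 1e-12:
            break
        p = X.T @ t / tt
        qa = y @ t / tt
        X = X - np.outer(t, p)
        y = y - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p, t, qa
        actual += 1
    if actual == 0:
        raise ValueError("nipals: response is orthogonal to every feature")
    return W[:, :actual], P[:, :actual], T[:, :actual], q[:actual]


def _coefficients(W, P, q, a: int) -> np.ndarray:
    """Regression vector for the first ``a`` components: B = W (P'W)^-1 q."""
    Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


@dataclass
class PlsDaModel:
    """Fitted PLS-DA (or continuous-response PLS) model."""

    feature_ids: list
    centers: np.ndarray
    scales: np.ndarray
    y_mean: float
    n_components: int
    W: np.ndarray          # weights, features x A, unit norm
    P: np.ndarray          # X loadings
    T: np.ndarray          # training scores, samples x A
    q: np.ndarray          # y loadings
    coef: np.ndarray       # regression vector at n_components
    y: np.ndarray
    q2_path: np.ndarray | None = None
    fold_weights: np.ndarray | None = None   # LOO folds x features, LV1
    notes: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.feature_ids)
        Xs = _scale_apply(X, self.centers, self.scales)
        return Xs @ self.coef + self.y_mean

    @property
    def loadings_lv1(self) -> pd.Series:
        return pd.Series(self.P[:, 0], index=self.feature_ids, name="loading_lv1")

    @property
    def weights_lv1(self) -> pd.Series:
        return pd.Series(self.W[:, 0], index=self.feature_ids, name="weight_lv1")

    def scores(self) -> np.ndarray:
        return self.T


def _as_matrix(X, feature_ids=None):
    if isinstance(X, pd.DataFrame):
        if feature_ids is not None:
            X = X.loc[:, list(feature_ids)]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _feature_ids(X) -> list:
    if isinstance(X, pd.DataFrame):
        return list(X.columns)
    return list(range(np.asarray(X).shape[1]))


def loo_q2(X, y, max_components: int = 5):
    """Leave-one-out Q2 per component count, with fold-wise LV1 weights.

    Q2(a) = 1 - PRESS(a) / TSS where PRESS comes from LOO refits with
    autoscaling re-estimated inside each fold and TSS is the total sum of
    squares about the overall response mean (the standard chemometrics
    convention).  Returns (q2 array for a = 1..A, best component count
    a* = argmax Q2, fold weight matrix, n_skipped degenerate folds).
    """
    ids = _feature_ids(X)
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("loo_q2: need >= 3 samples")
    binary = set(np.unique(y)) <= {0.0, 1.0}
    A = max(1, min(max_components, n - 2, Xm.shape[1]))
    press = np.zeros(A)
    ybar = y.mean()
    tss = 0.0
    fold_w = []
    skipped = 0
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        ytr = y[tr]
        if binary and len(np.unique(ytr)) < 2:
            skipped += 1
            continue
        centers, scales = _scale_fit(Xm[tr])
        Xtr = _scale_apply(Xm[tr], centers, scales)
        ymean = ytr.mean()
        try:
            W, P, T, qv = _nipals(Xtr, ytr - ymean, A)
        except ValueError:
            skipped += 1
            continue
        xi = _scale_apply(Xm[i:i + 1], centers, scales)
        for a in range(1, W.shape[1] + 1):
            yhat = (xi @ _coefficients(W, P, qv, a)).item() + ymean
            press[a - 1] += (y[i] - yhat) ** 2
        for a in range(W.shape[1] + 1, A + 1):   # rank-truncated folds reuse max a
            yhat = (xi @ _coefficients(W, P, qv, W.shape[1])).item() + ymean
            press[a - 1] += (y[i] - yhat) ** 2
        tss += (y[i] - ybar) ** 2
        fold_w.append(W[:, 0])
    if tss == 0 or not fold_w:
        raise ValueError("loo_q2: degenerate response (no usable folds)")
    q2 = 1.0 - press / tss
    best = int(np.argmax(q2)) + 1
    _ = ids
    return q2, best, np.array(fold_w), skipped


def fit_plsda(X, y, n_components: int | None = None, max_components: int = 5,
              orient: str = "class", compute_q2: bool = True) -> PlsDaModel:
    """Fit PLS-DA (binary y) or PLS regression (continuous y, orient="time").

    Autoscales X internally (missing values imputed with the feature's
    training mean, i.e. 0 after scaling), centers y, runs NIPALS, and
    when ``n_components`` is None picks the LOO-Q2-maximizing component
    count (capped at ``max_components``).  LV1 is oriented so the class-1
    mean score (or the score-time correlation, for orient="time") is
    positive.  Fold-wise LV1 weights from the LOO pass are retained for
    the feature-selection jackknife.
    """
    ids = _feature_ids(X)
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if Xm.shape[0] != y.size:
        raise ValueError("fit_plsda: X and y disagree on the number of samples")
    q2_path = best = fold_w = None
    skipped = 0
    if compute_q2 or n_components is None:
        q2_path, best, fold_w, skipped = loo_q2(Xm, y, max_components=max_components)
    A = int(n_components) if n_components is not None else best
    centers, scales = _scale_fit(Xm)
    Xs = _scale_apply(Xm, centers, scales)
    ymean = float(y.mean())
    W, P, T, qv = _nipals(Xs, y - ymean, A)
    A = W.shape[1]

    # Sign convention for LV1.
    flip = False
    if orient == "class":
        flip = T[y == y.max(), 0].mean() < T[y == y.min(), 0].mean()
    elif orient == "time":
        flip = np.corrcoef(T[:, 0], y)[0, 1] < 0
    if flip:
        W[:, 0] *= -1; P[:, 0] *= -1; T[:, 0] *= -1; qv[0] *= -1
    if fold_w is not None and fold_w.size:
        # align each fold's LV1 weights with the full-model orientation
        signs = np.sign(fold_w @ W[:, 0])
        signs[signs == 0] = 1.0
        fold_w = fold_w * signs[:, None]

    coef = _coefficients(W, P, qv, A)
    return PlsDaModel(feature_ids=ids, centers=centers, scales=scales,
                      y_mean=ymean, n_components=A, W=W, P=P, T=T, q=qv,
                      coef=coef, y=y, q2_path=q2_path, fold_weights=fold_w,
                      notes={"skipped_folds": skipped})


# ---------------------------------------------------------------------------
# feature selection


def select_features(model: PlsDaModel, alpha: float = 0.05) -> pd.DataFrame:
    """Sign-split weight filter on LOO fold-wise LV1 weights.

    Features are grouped by the sign of their full-model LV1 weight;
    within each group every feature's fold-wise weights are tested
    against the group's mean weight with a one-sample t whose standard
    error is the leave-one-out jackknife SE,

        se_j = sqrt((n-1)/n * sum_f (w_jf - wbar_j)^2),

    since each LOO fold perturbs only one sample and the raw fold-to-fold
    scatter understates sampling variance.  A feature is selected iff
    p < alpha AND its mean fold weight is more extreme (further from
    zero) than the group mean.
    """
    if model.fold_weights is None or model.fold_weights.size == 0:
        raise ValueError("select_features: model has no LOO fold weights")
    w_full = model.W[:, 0]
    fw = model.fold_weights
    nf = fw.shape[0]
    rows = []
    for sign, label in ((1, "positive"), (-1, "negative")):
        idx = np.flatnonzero(np.sign(w_full) == sign)
        if idx.size == 0:
            continue
        mu_g = w_full[idx].mean()
        if idx.size < 2 or nf < 2:
            for j in idx:
                rows.append({"feature_id": model.feature_ids[j], "sign_group": label,
                             "mean_fold_weight": float(fw[:, j].mean()),
                             "t": float("nan"), "p": float("nan"), "selected": False})
            continue
        for j in idx:
            wj = fw[:, j]
            wbar = wj.mean()
            se = math.sqrt((nf - 1) / nf * float(np.sum((wj - wbar) ** 2)))
            if se <= 1e-12 * max(1.0, abs(wbar)):
                t = p = float("nan")
                sel = False
            else:
                t = (wbar - mu_g) / se
                p = 2.0 * stats.t.sf(abs(t), nf - 1)
                sel = bool(p < alpha and abs(wbar) > abs(mu_g))
            rows.append({"feature_id": model.feature_ids[j], "sign_group": label,
                         "mean_fold_weight": float(wbar),
                         "t": float(t), "p": float(p), "selected": sel})
    return pd.DataFrame(rows)


def combined_model(fasting_X: pd.DataFrame, fasting_sel: pd.DataFrame,
                   auc_X: pd.DataFrame, auc_sel: pd.DataFrame,
                   clinical_X: pd.DataFrame, y,
                   max_components: int = 5):
    """Combined fasting + AUC + clinical-index model with add-back.

    Candidate features = selected fasting features UNION selected AUC
    features UNION the clinical block (fasting insulin/glucose, Matsuda,
    QUICKI).  The candidate matrix is refit and re-selected; base-model
    features dropped by re-selection are added back and flagged.  The
    final table reports the provenance category of every feature
    (fasting_only / auc_only / both / clinical) and the add-back flag.
    """
    fsel = set(fasting_sel.loc[fasting_sel["selected"], "feature_id"])
    asel = set(auc_sel.loc[auc_sel["selected"], "feature_id"])
    if not fsel or not asel:
        raise ValueError("combined_model: both base selections must be non-empty")
    blocks = []
    if fsel:
        blocks.append(fasting_X.loc[:, sorted(fsel)].add_prefix("fast:"))
    if asel:
        blocks.append(auc_X.loc[:, sorted(asel)].add_prefix("auc:"))
    blocks.append(clinical_X.add_prefix("clin:"))
    Xc = pd.concat(blocks, axis=1)
    model = fit_plsda(Xc, y, max_components=max_components)
    resel = select_features(model)
    kept = set(resel.loc[resel["selected"], "feature_id"])
    rows = []
    for fid in Xc.columns:
        ns, bare = fid.split(":", 1)
        in_f, in_a = bare in fsel and ns == "fast", bare in asel and ns == "auc"
        if ns == "clin":
            category = "clinical"
        elif bare in fsel and bare in asel:
            category = "both"
        elif in_f:
            category = "fasting_only"
        else:
            category = "auc_only"
        reselected = fid in kept
        add_back = (ns in ("fast", "auc")) and not reselected
        rows.append({"feature_id": fid, "category": category,
                     "reselected": reselected, "added_back": add_back,
                     "in_final": reselected or add_back})
    return model, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# performance statistics and permutation validation


def auroc(scores, labels) -> float:
    """Area under the ROC curve by Mann-Whitney pair counting (ties half)."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    pos = s[lab == 1]
    neg = s[lab == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("auroc: both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _stratified_split(y: np.ndarray, train_frac: float, rng: np.random.Generator):
    train = np.zeros(y.size, dtype=bool)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        k = int(round(train_frac * idx.size))
        k = min(max(k, 1), idx.size - 1)
        train[idx[:k]] = True
    return train


@dataclass
class PermutationReport:
    """Observed vs permuted-label distributions of Q2 / RMSEP / AUROC."""

    observed: dict    # statistic -> np.ndarray of length n_splits
    null: dict
    p: dict           # statistic -> add-one empirical p
    n_splits: int

    def to_dict(self) -> dict:
        return {"n_splits": self.n_splits,
                "observed": {k: list(map(float, v)) for k, v in self.observed.items()},
                "null": {k: list(map(float, v)) for k, v in self.null.items()},
                "p": {k: float(v) for k, v in self.p.items()}}


def performance_distributions(X, y, n_splits: int = 100, train_frac: float = 2 / 3,
                              max_components: int = 2, seed: int = 0,
                              max_retries: int = 50) -> PermutationReport:
    """Resampling distributions of Q2, RMSEP and AUROC with permutation nulls.

    Each split: stratified 2/3-1/3 train/test partition; the model is fit
    on the training block (Q2 = best LOO Q2 on that block) and evaluated
    on the held-out block (RMSEP, AUROC of predicted scores).  The null
    repeats the identical procedure with class labels permuted
    independently per split.  Empirical p uses the add-one rule against
    the observed median: #{null >= median}/(n+1) for Q2 and AUROC,
    #{null <= median} for RMSEP.
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    obs = {k: [] for k in ("Q2", "RMSEP", "AUROC")}
    nul = {k: [] for k in ("Q2", "RMSEP", "AUROC")}

    def one_split(labels):
        for _ in range(max_retries):
            train = _stratified_split(labels, train_frac, rng)
            if len(np.unique(labels[train])) == 2 and len(np.unique(labels[~train])) == 2:
                break
        else:
            raise RuntimeError("performance_distributions: could not form a valid split")
        model = fit_plsda(Xm[train], labels[train], max_components=max_components)
        q2 = float(np.max(model.q2_path))
        yhat = model.predict(Xm[~train])
        rmsep = float(np.sqrt(np.mean((labels[~train] - yhat) ** 2)))
        au = auroc(yhat, labels[~train])
        return q2, rmsep, au

    for _ in range(n_splits):
        q2, rmsep, au = one_split(y)
        obs["Q2"].append(q2); obs["RMSEP"].append(rmsep); obs["AUROC"].append(au)
        yperm = rng.permutation(y)
        q2, rmsep, au = one_split(yperm)
        nul["Q2"].append(q2); nul["RMSEP"].append(rmsep); nul["AUROC"].append(au)

    obs = {k: np.array(v) for k, v in obs.items()}
    nul = {k: np.array(v) for k, v in nul.items()}
    p = {}
    for k in ("Q2", "AUROC"):
        med = np.median(obs[k])
        p[k] = (1 + int((nul[k] >= med).sum())) / (n_splits + 1)
    med = np.median(obs["RMSEP"])
    p["RMSEP"] = (1 + int((nul["RMSEP"] <= med).sum())) / (n_splits + 1)
    return PermutationReport(observed=obs, null=nul, p=p, n_splits=n_splits)


# ---------------------------------------------------------------------------
# OGTT time-course model


def ogtt_time_model(panel: pd.DataFrame, max_components: int = 2):
    """Intervention-adjusted PLS of the metabolite matrix on OGTT time.

    Log-intensities are adjusted by subtracting each metabolite's
    phase-specific mean (removing the intervention effect), then modeled
    against time in minutes as a continuous response.  LV1 is oriented so
    the score-time correlation is positive: metabolites rising through
    the OGTT load positively, suppressed metabolites negatively.

    Returns (model, scores, loadings): per-sample LV scores keyed by
    subject/phase/time, and the LV1 loading per metabolite (the vertex
    attribute of the chemical-similarity network).
    """
    wide = panel.pivot_table(index=["subject_id", "phase", "time_min"],
                             columns="metabolite_id", values="intensity",
                             observed=True)
    logw = np.log(wide.where(wide > 0))
    phase = logw.index.get_level_values("phase")
    adjusted = logw.copy()
    for ph in ("pre", "post"):
        sel = phase == ph
        if sel.any():
            adjusted.loc[sel] = logw.loc[sel] - logw.loc[sel].mean()
    y = wide.index.get_level_values("time_min").to_numpy(dtype=float)
    model = fit_plsda(adjusted, y, n_components=max_components,
                      max_components=max_components, orient="time")
    T = model.T
    scores = wide.index.to_frame(index=False)
    for a in range(T.shape[1]):
        scores[f"lv{a + 1}"] = T[:, a]
    return model, scores, model.loadings_lv1
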