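"""Ensemble ecological niche model, thresholding and suitability change.

Presence records are distance-thinned, predictor grids pruned for
collinearity (pairwise |r| then variance inflation), and pseudo-absence
(background) sets sampled from non-presence cells.  Five presence/background
classifiers are fitted over replicates and pseudo-absence sets — a natural-
cubic-spline logistic (GAM-like), an L1-penalized logistic (lasso), a
class-balanced random forest, boosted trees, and a maxent-style penalized
logistic on quadratic features — and evaluated on a held-out split with AUC,
Somer's D (= 2 AUC - 1), the true skill statistic TSS (max over thresholds
of sensitivity + specificity - 1), and the continuous Boyce index.

Only fits with positive Somer's D enter the ensemble, weighted by TSS.
Suitability grids are thresholded (default: the cutoff maximizing
sensitivity + specificity on the pooled evaluations) into binary suitable
maps; niche suitability change is NSC = current - future suitability per
cell (positive = deteriorating), and suitable-area change is reported as a
percentage of the current suitable area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler

from .grids import Grid, check_aligned

logger = logging.getLogger(__name__)

MODEL_TYPES = ("spline_logistic", "lasso_logistic", "balanced_rf",
               "boosted_trees", "maxent_like")


def _make_model(kind: str, seed: int):
    if kind == "spline_logistic":
        return make_pipeline(StandardScaler(),
                             SplineTransformer(n_knots=4, degree=3),
                             LogisticRegression(max_iter=1000))
    if kind == "lasso_logistic":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(l1_ratio=1.0, C=1.0,
                                                solver="liblinear",
                                                random_state=seed))
    if kind == "balanced_rf":
        return RandomForestClassifier(n_estimators=200,
                                      class_weight="balanced_subsample",
                                      random_state=seed)
    if kind == "boosted_trees":
        return GradientBoostingClassifier(n_estimators=100, random_state=seed)
    if kind == "maxent_like":
        return make_pipeline(StandardScaler(),
                             PolynomialFeatures(degree=2, include_bias=False),
                             LogisticRegression(C=1.0, max_iter=1000))
    raise ValueError(f"unknown model type {kind!r}")


# ---------------------------------------------------------------------------
# Input preparation
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceSet:
    presences: pd.DataFrame          # thinned lon/lat
    pa_sets: list                    # list of (row, col) index arrays
    variables: list                  # selected predictor names
    env_presence: np.ndarray         # presence x variables
    env_pa: list                     # per PA set: background x variables
    grid_shape: tuple


def thin_occurrences(occ: pd.DataFrame, thin_dist: float) -> pd.DataFrame:
    """Greedy distance thinning in stable (input) order.

    Coordinates are treated as planar in their own units; for lon/lat data
    a 5-km rule at these latitudes corresponds to ~0.045 degrees.
    """
    kept: list[int] = []
    pts = occ[["lon", "lat"]].to_numpy(dtype=float)
    for i in range(len(pts)):
        if all(np.hypot(*(pts[i] - pts[j])) >= thin_dist for j in kept):
            kept.append(i)
    return occ.iloc[kept].reset_index(drop=True)


def vif_scores(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor per column (1/(1-R^2) of each on the rest)."""
    n, p = X.shape
    out = np.ones(p)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    for j in range(p):
        others = np.delete(Xs, j, axis=1)
        if others.shape[1] == 0:
            continue
        beta, *_ = np.linalg.lstsq(others, Xs[:, j], rcond=None)
        resid = Xs[:, j] - others @ beta
        r2 = 1.0 - resid.var() / Xs[:, j].var()
        out[j] = 1.0 / max(1.0 - r2, 1e-12)
    return out


def select_variables(grids: dict, r_max: float = 0.7,
                     vif_max: float = 10.0) -> list[str]:
    """Pairwise-correlation pruning then iterative VIF pruning on grid cells."""
    names = list(grids)
    flat = {v: grids[v].values.ravel() for v in names}
    kept: list[str] = []
    for v in names:
        if all(abs(np.corrcoef(flat[v], flat[k])[0, 1]) < r_max for k in kept):
            kept.append(v)
    while len(kept) > 2:
        X = np.column_stack([flat[v] for v in kept])
        vifs = vif_scores(X)
        worst = int(np.argmax(vifs))
        if vifs[worst] <= vif_max:
            break
        kept.pop(worst)
    if len(kept) < 2:
        raise ValueError("fewer than 2 predictors survive collinearity pruning")
    return kept


def prepare_inputs(occurrences: pd.DataFrame, grids: dict,
                   thin_dist: float = 0.045, vif_max: float = 10.0,
                   r_max: float = 0.7, n_pa: int = 10_000, pa_reps: int = 3,
                   seed: int = 0) -> OccurrenceSet:
    """Thin presences, select predictors, and sample pseudo-absence sets.

    ``n_pa`` background points are drawn per replicate from cells containing
    no presence (capped at the number of available cells).  Deterministic
    under ``seed``.
    """
    if len(occurrences) < 10:
        raise ValueError("need at least 10 presence records")
    rng = np.random.default_rng(seed)
    pres = thin_occurrences(occurrences, thin_dist)
    variables = select_variables(grids, r_max=r_max, vif_max=vif_max)
    ref = grids[variables[0]]
    shape = ref.shape
    pres_cells = {ref.cell_of(x, y) for x, y in zip(pres["lon"], pres["lat"])}
    pres_idx = np.array([r * shape[1] + c for r, c in pres_cells])
    free = np.setdiff1d(np.arange(shape[0] * shape[1]), pres_idx)
    n_pa_eff = min(n_pa, len(free))
    stack = np.stack([grids[v].values.ravel() for v in variables], axis=-1)
    env_pres = np.array([[grids[v].value_at(x, y) for v in variables]
                         for x, y in zip(pres["lon"], pres["lat"])])
    pa_sets, env_pa = [], []
    for _ in range(pa_reps):
        pick = rng.choice(free, size=n_pa_eff, replace=False)
        pa_sets.append(pick)
        env_pa.append(stack[pick])
    return OccurrenceSet(presences=pres, pa_sets=pa_sets, variables=variables,
                         env_presence=env_pres, env_pa=env_pa,
                         grid_shape=shape)


# ---------------------------------------------------------------------------
# Single-model fitting and evaluation
# ---------------------------------------------------------------------------

@dataclass
class SDMFit:
    model_type: str
    replicate: int
    pa_set: int
    auc: float
    somers_d: float
    tss: float
    boyce: float
    model: object
    variables: list
    holdout_scores: np.ndarray = field(repr=False, default=None)
    holdout_labels: np.ndarray = field(repr=False, default=None)


def tss_from_scores(labels: np.ndarray, scores: np.ndarray) -> float:
    """Max over thresholds of sensitivity + specificity - 1."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.max(tpr - fpr))


def boyce_index(pres_scores: np.ndarray, bg_scores: np.ndarray,
                n_windows: int = 10) -> float:
    """Continuous Boyce index over overlapping suitability windows.

    Spearman rank correlation of the predicted-to-expected ratio (presence
    fraction / background fraction per window) against window rank.
    """
    lo, hi = bg_scores.min(), bg_scores.max()
    if hi <= lo:
        return np.nan
    width = (hi - lo) / (n_windows / 2.0)
    starts = np.linspace(lo, hi - width, n_windows)
    pe = []
    for s in starts:
        p = np.mean((pres_scores >= s) & (pres_scores <= s + width))
        e = np.mean((bg_scores >= s) & (bg_scores <= s + width))
        if e > 0:
            pe.append(p / e)
        else:
            pe.append(np.nan)
    pe = np.asarray(pe)
    ok = ~np.isnan(pe)
    if ok.sum() < 3 or np.all(pe[ok] == pe[ok][0]):
        return np.nan
    return float(stats.spearmanr(np.arange(len(pe))[ok], pe[ok]).statistic)


def fit_and_evaluate(occ_set: OccurrenceSet,
                     model_types=MODEL_TYPES, reps: int = 10,
                     split: float = 0.75, seed: int = 0) -> list[SDMFit]:
    """Train each model type x replicate x pseudo-absence set.

    Presences and background are split ``split``/(1-``split``) per replicate
    (stratified); metrics are computed on the holdout.  Replicates whose
    holdout degenerates to a single class are dropped with a log message.
    """
    rng = np.random.default_rng(seed)
    fits = []
    for ipa, env_pa in enumerate(occ_set.env_pa):
        X = np.vstack([occ_set.env_presence, env_pa])
        y = np.r_[np.ones(len(occ_set.env_presence)), np.zeros(len(env_pa))]
        for rep in range(reps):
            idx1 = rng.permutation(np.flatnonzero(y == 1))
            idx0 = rng.permutation(np.flatnonzero(y == 0))
            n1, n0 = int(split * len(idx1)), int(split * len(idx0))
            train = np.r_[idx1[:n1], idx0[:n0]]
            test = np.r_[idx1[n1:], idx0[n0:]]
            if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
                logger.info("degenerate holdout dropped (pa=%d rep=%d)", ipa, rep)
                continue
            for kind in model_types:
                model = _make_model(kind, seed=int(rng.integers(2 ** 31)))
                model.fit(X[train], y[train])
                scores = model.predict_proba(X[test])[:, 1]
                auc = roc_auc_score(y[test], scores)
                fits.append(SDMFit(
                    model_type=kind, replicate=rep, pa_set=ipa,
                    auc=float(auc), somers_d=float(2 * auc - 1),
                    tss=tss_from_scores(y[test], scores),
                    boyce=boyce_index(scores[y[test] == 1], scores[y[test] == 0]),
                    model=model, variables=list(occ_set.variables),
                    holdout_scores=scores, holdout_labels=y[test]))
    return fits


# ---------------------------------------------------------------------------
# Ensemble, threshold, NSC
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    weights: dict                    # (model_type, rep, pa) -> weight
    current: Grid
    future: dict                     # scenario -> gcm -> Grid
    future_mean: dict                # scenario -> Grid (GCM average)
    threshold: float
    suitable_current: Grid           # binary
    suitable_future: dict            # scenario -> binary Grid (GCM-averaged)
    nsc: dict                        # scenario -> Grid
    area_change_pct: dict            # scenario -> percent of current area lost
    metrics: pd.DataFrame


def _predict_grid(fit: SDMFit, grids: dict) -> np.ndarray:
    X = np.stack([grids[v].values.ravel() for v in fit.variables], axis=-1)
    return fit.model.predict_proba(X)[:, 1].reshape(grids[fit.variables[0]].shape)


def ensemble_and_nsc(fits: list[SDMFit], current_grids: dict,
                     future_grids: dict, threshold_rule: str = "max_sens_spec",
                     gcm_weights: dict | None = None) -> EnsembleResult:
    """TSS-weighted ensemble suitability, threshold, NSC and area change.

    ``future_grids``: scenario -> gcm -> var -> Grid.  Only fits with
    positive Somer's D are retained; weights are their TSS values normalized
    to one.  NSC = current - future suitability per cell, averaged over GCMs
    within each scenario; suitable-area change is
    (current - future) / current x 100 over thresholded cells.
    """
    retained = [f for f in fits if f.somers_d > 0]
    if not retained:
        raise ValueError("no fit with positive Somer's D; ensemble undefined")
    tss = np.array([max(f.tss, 0.0) for f in retained])
    if tss.sum() == 0:
        tss = np.ones(len(retained))
    w = tss / tss.sum()
    check_aligned(*current_grids.values())
    extent = next(iter(current_grids.values())).extent

    cur = sum(wi * _predict_grid(f, current_grids)
              for wi, f in zip(w, retained))
    future, future_mean, nsc, suit_future, area_change = {}, {}, {}, {}, {}

    # threshold from pooled holdout evaluations of the retained fits
    labels = np.concatenate([f.holdout_labels for f in retained])
    scores = np.concatenate([f.holdout_scores for f in retained])
    threshold = _threshold(labels, scores, threshold_rule)

    suit_cur = cur > threshold
    n_cur = int(suit_cur.sum())
    for scen, by_gcm in future_grids.items():
        future[scen] = {}
        acc = np.zeros_like(cur)
        gw = gcm_weights or {g: 1.0 for g in by_gcm}
        total = sum(gw[g] for g in by_gcm)
        for gcm, layer in by_gcm.items():
            fut = sum(wi * _predict_grid(f, layer) for wi, f in zip(w, retained))
            future[scen][gcm] = Grid(fut, extent)
            acc += gw[gcm] / total * fut
        future_mean[scen] = Grid(acc, extent)
        nsc[scen] = Grid(cur - acc, extent)
        sf = acc > threshold
        suit_future[scen] = Grid(sf.astype(float), extent)
        n_fut = int(sf.sum())
        area_change[scen] = (100.0 * (n_cur - n_fut) / n_cur
                             if n_cur else np.nan)
    metrics = pd.DataFrame([{
        "model_type": f.model_type, "replicate": f.replicate,
        "pa_set": f.pa_set, "auc": f.auc, "somers_d": f.somers_d,
        "tss": f.tss, "boyce": f.boyce, "weight": wi}
        for f, wi in zip(retained, w)])
    return EnsembleResult(
        weights={(f.model_type, f.replicate, f.pa_set): float(wi)
                 for f, wi in zip(retained, w)},
        current=Grid(cur, extent), future=future, future_mean=future_mean,
        threshold=threshold, suitable_current=Grid(suit_cur.astype(float), extent),
        suitable_future=suit_future, nsc=nsc, area_change_pct=area_change,
        metrics=metrics)


def _threshold(labels, scores, rule):
    if rule == "max_sens_spec":
        fpr, tpr, thr = roc_curve(labels, scores)
        return float(thr[int(np.argmax(tpr - fpr))])
    if rule == "sens_eq_spec":
        fpr, tpr, thr = roc_curve(labels, scores)
        return float(thr[int(np.argmin(np.abs(tpr - (1 - fpr))))])
    if rule == "prevalence":
        return float(np.mean(labels))
    raise ValueError(f"unknown threshold rule {rule!r}")
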