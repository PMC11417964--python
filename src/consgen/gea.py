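"""Genotype-environment association: univariate scan, RDA, intersection.

Two complementary detectors identify SNPs whose allele frequencies track
climate:

* a univariate population-level test — per SNP and variable, a weighted
  linear regression of population allele frequency on the standardized
  variable plus structure covariates (leading PCs of the frequency matrix),
  weights proportional to population sample size, BH q-values per variable;
* redundancy analysis (RDA) — multivariate least squares of centered sample
  dosages on the environmental predictors, constrained ordination axes from
  the fitted values, a permutation test gating the scan, and per-axis SNP
  loadings flagged beyond +-3 standard deviations (two-tailed normal tail
  mass 0.0027).

Candidate environment-associated SNPs are the intersection of the two hit
sets; each hit is assigned the variable it correlates with most strongly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .variants import MISSING, VariantTable


def standardize_env(env: pd.DataFrame) -> pd.DataFrame:
    """Mean-variance standardized copy of an environment table."""
    return (env - env.mean()) / env.std(ddof=0)


def prune_env(env: pd.DataFrame, r_max: float = 0.7) -> list[str]:
    """Greedy pairwise pruning: drop one of each pair with |r| >= r_max.

    Variables are visited in column order; a variable is kept if its
    absolute Pearson correlation with every already-kept variable stays
    below ``r_max``.
    """
    kept: list[str] = []
    for v in env.columns:
        if all(abs(env[v].corr(env[k])) < r_max for k in kept):
            kept.append(v)
    return kept


def population_frequencies(table: VariantTable, pop_map: pd.DataFrame
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Alternate-allele frequency per site x population, plus sizes."""
    freqs, sizes = {}, {}
    for pop, grp in pop_map.groupby("population_id", sort=True):
        idx = [table.samples.index(s) for s in grp["sample_id"]]
        gt = table.gt[idx]
        called = gt != MISSING
        nhap = 2 * called.sum(axis=0)
        alt = np.where(called, gt, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[pop] = np.where(nhap > 0, alt / np.maximum(nhap, 1), np.nan)
        sizes[pop] = len(idx)
    return pd.DataFrame(freqs), pd.Series(sizes)


@dataclass
class GEAResult:
    pvalues: pd.DataFrame = None       # SNP x variable
    qvalues: pd.DataFrame = None
    effects: pd.DataFrame = None
    hits: set = field(default_factory=set)
    best_variable: dict = field(default_factory=dict)
    method: str = ""
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Univariate population-level scan
# ---------------------------------------------------------------------------

def univariate_gea(pop_freqs: pd.DataFrame, env: pd.DataFrame,
                   pop_sizes: pd.Series | None = None, n_pcs: int = 2,
                   q_cut: float = 0.05) -> GEAResult:
    """Structure-corrected weighted regression of frequencies on climate.

    ``pop_freqs`` is sites x populations; ``env`` is populations x variables
    (standardized internally).  The structure covariates are the leading
    ``n_pcs`` PCs of the (population-standardized) frequency matrix, so only
    the environmental effect beyond shared drift is tested.  Variables whose
    design would leave no residual degrees of freedom are skipped with a
    warning.
    """
    from scipy import stats as sps

    pops = list(pop_freqs.columns)
    if len(pops) < 4:
        raise ValueError("need at least 4 populations")
    Y = pop_freqs.to_numpy(dtype=float)        # (m, P)
    Y = np.nan_to_num(Y, nan=np.nanmean(Y))
    z = standardize_env(env.loc[pops])
    w = (pop_sizes.loc[pops].to_numpy(dtype=float)
         if pop_sizes is not None else np.ones(len(pops)))
    w = w / w.sum()
    # structure covariates: PCs of the centered frequency matrix over pops
    Yc = Y - Y.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(Yc, full_matrices=False)
    pcs = vt[:n_pcs].T                          # (P, n_pcs)
    m = Y.shape[0]
    pv, ev = {}, {}
    for var in env.columns:
        e = z[var].to_numpy()
        # a PC that is itself a proxy for the tested gradient (|r| >= 0.7)
        # would absorb the signal under test; keep only non-collinear PCs
        use = pcs
        if pcs.shape[1]:
            cor = np.abs([np.corrcoef(pcs[:, k], e)[0, 1]
                          for k in range(pcs.shape[1])])
            use = pcs[:, np.nan_to_num(cor) < 0.7]
        X = np.column_stack([np.ones(len(pops)), e, use])
        k = X.shape[1]
        dof = len(pops) - k
        if dof < 1:
            import logging
            logging.getLogger(__name__).warning(
                "variable %s skipped: %d populations < %d parameters + 1",
                var, len(pops), k)
            continue
        Xw = X * w[:, None]
        XtWX_inv = np.linalg.inv(X.T @ Xw)
        B = XtWX_inv @ (Xw.T @ Y.T)             # (k, m)
        resid = Y.T - X @ B
        s2 = (w[:, None] * resid ** 2).sum(axis=0) / dof
        se = np.sqrt(np.maximum(s2 * XtWX_inv[1, 1], 1e-300))
        t = B[1] / se
        pv[var] = 2 * sps.t.sf(np.abs(t), dof)
        ev[var] = B[1]
    pvalues = pd.DataFrame(pv)
    qvalues = pvalues.copy()
    for var in pvalues.columns:
        qvalues[var] = multipletests(pvalues[var], method="fdr_bh")[1]
    hit_mask = (qvalues < q_cut).any(axis=1)
    hits = set(np.flatnonzero(hit_mask.to_numpy()).tolist())
    best = {}
    for j in hits:
        best[j] = qvalues.columns[int(np.argmin(qvalues.iloc[j].to_numpy()))]
    return GEAResult(pvalues=pvalues, qvalues=qvalues,
                     effects=pd.DataFrame(ev), hits=hits,
                     best_variable=best, method="univariate")


# ---------------------------------------------------------------------------
# Redundancy analysis
# ---------------------------------------------------------------------------

def rda_outliers(table: VariantTable, env_samples: pd.DataFrame,
                 sd_cut: float = 3.0, n_perm: int = 999, alpha: float = 0.05,
                 n_axes: int | None = None, seed: int = 0) -> GEAResult:
    """RDA of sample dosages on environment with a +-``sd_cut``-SD scan.

    ``env_samples`` is samples x variables, row order matching the table
    (values typically inherited from each sample's population coordinates).
    Columns should be pruned to |r| < 0.7 beforehand (see :func:`prune_env`).
    A global permutation test of the constrained-variance ratio gates the
    loading scan; with no significant model the hit set is empty.
    """
    from .structure import dosage_matrix

    rng = np.random.default_rng(seed)
    Y = dosage_matrix(table)
    Y = Y - Y.mean(axis=0)
    keep = Y.std(axis=0) > 0
    Z = standardize_env(env_samples).to_numpy(dtype=float)
    stat_obs, loadings, svals = _rda_fit(Y, Z)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        perm[b] = _rda_fit(Y, Z[rng.permutation(len(Z))], stat_only=True)
    p_global = (1.0 + np.sum(perm >= stat_obs)) / (n_perm + 1.0)
    k = n_axes if n_axes is not None else int(np.sum(svals > 1e-9))
    hits: set[int] = set()
    if p_global <= alpha:
        for a in range(min(k, loadings.shape[1])):
            load = loadings[:, a]
            mu, sd = load.mean(), load.std()
            if sd == 0:
                continue
            hits |= set(np.flatnonzero(np.abs(load - mu) > sd_cut * sd).tolist())
    hits = {h for h in hits if keep[h]}
    best = {}
    if hits:
        cols = list(env_samples.columns)
        for j in hits:
            r = [abs(np.corrcoef(Y[:, j], Z[:, v])[0, 1]) for v in range(Z.shape[1])]
            best[j] = cols[int(np.argmax(np.nan_to_num(r)))]
    return GEAResult(hits=hits, best_variable=best, method="rda",
                     extras={"p_global": float(p_global),
                             "constrained_ratio": float(stat_obs),
                             "n_axes": int(k),
                             "loadings": loadings, "singular_values": svals})


def _rda_fit(Y, Z, stat_only=False):
    B, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    Yhat = Z @ B
    ss_fit = float(np.sum(Yhat ** 2))
    ss_tot = float(np.sum(Y ** 2))
    stat = ss_fit / ss_tot if ss_tot > 0 else 0.0
    if stat_only:
        return stat
    # constrained axes: SVD of fitted values; SNP loadings are the right
    # singular vectors (species scores)
    _, s, vt = np.linalg.svd(Yhat, full_matrices=False)
    return stat, vt.T, s


def normal_tail_mass(sd_cut: float = 3.0) -> float:
    """Two-tailed standard-normal mass beyond +-``sd_cut`` (0.0027 at 3)."""
    from scipy.stats import norm

    return float(2.0 * norm.sf(sd_cut))


def candidate_set(uni: GEAResult, rda: GEAResult) -> GEAResult:
    """Environment-associated SNPs = hits of both methods, with provenance."""
    hits = set(uni.hits) & set(rda.hits)
    best = {j: rda.best_variable.get(j, uni.best_variable.get(j))
            for j in hits}
    return GEAResult(hits=hits, best_variable=best, method="intersection",
                     extras={"univariate_hits": set(uni.hits),
                             "rda_hits": set(rda.hits)})
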