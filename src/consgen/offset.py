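"""Gradient-forest allele-turnover model and the genomic-offset map.

Per SNP, a random-forest regression relates its per-population minor allele
frequency to the climate variables (500 trees by default).  Each split's
impurity decrease is accrued to its predictor at its split value; pooling
these split importances across all SNPs — each forest weighted by its
positive out-of-bag R^2 — and cumulatively summing them along each
predictor's range yields the monotone cumulative-importance functions
F_v(x): the expected compositional turnover of allele frequencies along
gradient v.

Genomic offset (GO) at a location is the Euclidean distance between the
F-transformed current and future climate vectors,

    GO = sqrt( sum_v ( F_v(future_v) - F_v(current_v) )^2 ),

a proxy for the allele-frequency change required to track the new climate.
Offsets under several global climate models are combined by (default equal)
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .grids import Grid, check_aligned
from .variants import MISSING, VariantTable


def maf_per_population(table: VariantTable, pop_map: pd.DataFrame,
                       maf_min: float = 0.10) -> pd.DataFrame:
    """Minor-allele frequency per population for globally common SNPs.

    SNPs with global MAF > ``maf_min`` are converted to per-population
    frequencies of the globally minor allele (the standard gradient-forest
    response).  Returns sites x populations with the retained site indices
    in ``attrs["site_index"]``.
    """
    from .gea import population_frequencies

    freqs, _ = population_frequencies(table, pop_map)
    called = table.gt != MISSING
    nhap = 2 * called.sum(axis=0)
    alt = np.where(called, table.gt, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nhap > 0, alt / np.maximum(nhap, 1), np.nan)
    keep = np.minimum(p, 1 - p) > maf_min
    vals = freqs.loc[keep].to_numpy(dtype=float)
    flip = p[keep] > 0.5
    vals[flip] = 1.0 - vals[flip]
    out = pd.DataFrame(vals, columns=freqs.columns)
    out.attrs["site_index"] = np.flatnonzero(keep)
    return out


@dataclass
class GFModel:
    predictors: list
    bin_edges: dict        # var -> (n_bins+1,) edges over the observed range
    cum_importance: dict   # var -> (n_bins+1,) F_v at the edges, F_v(min)=0
    importance: dict       # var -> overall importance (F_v at range top)
    snp_r2: np.ndarray     # out-of-bag R^2 per SNP
    n_trees: int
    seed: int

    def transform(self, var: str, x) -> np.ndarray:
        """F_v(x); values beyond the training range are clamped to its ends."""
        e = self.bin_edges[var]
        return np.interp(np.asarray(x, dtype=float), e, self.cum_importance[var])


def _split_importances(forest, n_features):
    """(feature, threshold, impurity_decrease) triples over all trees."""
    feats, thrs, gains = [], [], []
    for est in forest.estimators_:
        t = est.tree_
        internal = t.children_left != -1
        idx = np.flatnonzero(internal)
        w = t.weighted_n_node_samples
        gain = (w[idx] * t.impurity[idx]
                - w[t.children_left[idx]] * t.impurity[t.children_left[idx]]
                - w[t.children_right[idx]] * t.impurity[t.children_right[idx]])
        gain /= w[0]
        feats.append(t.feature[idx])
        thrs.append(t.threshold[idx])
        gains.append(np.maximum(gain, 0.0))
    return (np.concatenate(feats), np.concatenate(thrs),
            np.concatenate(gains))


def fit_gradient_forest(pop_freqs: pd.DataFrame, env: pd.DataFrame,
                        n_trees: int = 500, seed: int = 0,
                        n_bins: int = 200) -> GFModel:
    """Fit per-SNP random forests and build cumulative importance curves.

    ``pop_freqs``: sites x populations (e.g. from :func:`maf_per_population`);
    ``env``: populations x predictors, row-aligned to the frequency columns.
    Only SNPs with positive out-of-bag R^2 contribute; if none has, the model
    is invalid and a ``ValueError`` is raised.
    """
    pops = list(pop_freqs.columns)
    X = env.loc[pops].to_numpy(dtype=float)
    predictors = list(env.columns)
    p = len(predictors)
    mtry = max(1, int(np.ceil(p / 3)))
    edges = {v: np.linspace(X[:, k].min(), X[:, k].max(), n_bins + 1)
             for k, v in enumerate(predictors)}
    hist = {v: np.zeros(n_bins) for v in predictors}
    m = pop_freqs.shape[0]
    r2 = np.full(m, -np.inf)
    rng = np.random.default_rng(seed)
    import warnings

    for j in range(m):
        y = pop_freqs.iloc[j].to_numpy(dtype=float)
        if np.nanstd(y) == 0:
            continue
        forest = RandomForestRegressor(
            n_estimators=n_trees, max_features=mtry, bootstrap=True,
            oob_score=True, random_state=int(rng.integers(2 ** 31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            forest.fit(X, y)
            r2[j] = forest.oob_score_
        if r2[j] <= 0:
            continue
        feats, thrs, gains = _split_importances(forest, p)
        total = gains.sum()
        if total <= 0:
            continue
        # each SNP contributes total mass R^2_j, spread over its splits
        gains = gains * (r2[j] / total)
        for k, v in enumerate(predictors):
            sel = feats == k
            if not sel.any():
                continue
            b = np.clip(np.searchsorted(edges[v], thrs[sel], side="right") - 1,
                        0, n_bins - 1)
            np.add.at(hist[v], b, gains[sel])
    pos = r2 > 0
    if not pos.any():
        raise ValueError("no SNP with positive R^2; gradient-forest model invalid")
    norm = float(pos.sum())
    cum = {v: np.concatenate([[0.0], np.cumsum(hist[v]) / norm])
           for v in predictors}
    importance = {v: float(cum[v][-1]) for v in predictors}
    return GFModel(predictors=predictors, bin_edges=edges, cum_importance=cum,
                   importance=importance, snp_r2=np.where(np.isfinite(r2), r2, np.nan),
                   n_trees=n_trees, seed=seed)


# ---------------------------------------------------------------------------
# Offset maps
# ---------------------------------------------------------------------------

@dataclass
class OffsetMap:
    per_gcm: dict          # gcm -> Grid of GO
    combined: Grid         # weighted mean over GCMs
    weights: dict


def genomic_offset(gf: GFModel, current_grids: dict,
                   future_grids_by_gcm: dict,
                   weights: dict | None = None) -> OffsetMap:
    """Per-cell genomic offset for each climate model, then averaged.

    ``current_grids``: var -> :class:`~consgen.grids.Grid`;
    ``future_grids_by_gcm``: gcm -> var -> Grid on the same extent.
    GO is zero wherever future equals current, and is symmetric in swapping
    the two climate states.
    """
    grids = [current_grids[v] for v in gf.predictors]
    check_aligned(*grids)
    cur_t = {v: gf.transform(v, current_grids[v].values) for v in gf.predictors}
    weights = weights or {g: 1.0 for g in future_grids_by_gcm}
    total_w = sum(weights[g] for g in future_grids_by_gcm)
    per_gcm = {}
    combined = np.zeros_like(grids[0].values, dtype=float)
    for gcm, layer in future_grids_by_gcm.items():
        check_aligned(grids[0], *[layer[v] for v in gf.predictors])
        sq = np.zeros_like(combined)
        for v in gf.predictors:
            d = gf.transform(v, layer[v].values) - cur_t[v]
            sq += d * d
        go = np.sqrt(sq)
        per_gcm[gcm] = Grid(go, grids[0].extent)
        combined += weights[gcm] / total_w * go
    return OffsetMap(per_gcm=per_gcm, combined=Grid(combined, grids[0].extent),
                     weights={g: weights[g] / total_w for g in future_grids_by_gcm})


def offset_at_points(offset: OffsetMap, points: pd.DataFrame,
                     altitude: pd.Series | None = None) -> pd.DataFrame:
    """Combined GO at (lon, lat) points, optionally with altitude correlation.

    Returns a frame with a ``go`` column; if ``altitude`` is given the
    Pearson correlation is stored in ``attrs["altitude_correlation"]``.
    """
    go = [offset.combined.value_at(x, y)
          for x, y in zip(points["lon"], points["lat"])]
    out = points.copy()
    out["go"] = go
    if altitude is not None:
        r = float(np.corrcoef(out["go"], altitude.loc[out.index])[0, 1])
        out.attrs["altitude_correlation"] = r
    return out
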