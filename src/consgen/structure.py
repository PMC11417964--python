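"""Population structure: PCA outlier scan, admixture factorization, NJ trees.

The PCA scan follows the pcadapt recipe: dosages are mean-imputed, centered
and scaled by sqrt(p(1-p)); per-SNP z-scores from the regression on the K
leading principal components are combined into a Mahalanobis statistic,
rescaled by a median-based genomic inflation factor against chi-square(K),
and thresholded by Benjamini-Hochberg FDR.

Admixture fractions come from a masked-cross-validation nonnegative matrix
factorization of G/2 ~ Q F^T with Q rows on the probability simplex — the
same model family as likelihood-based admixture programs, but deterministic
under a seed and selecting K by held-out squared error.  A residual scan
over the fitted ancestral frequencies provides the second outlier method;
the adaptive-locus set is the intersection of the two scans.

Neighbor joining is implemented from the canonical agglomeration formulas,
with allele-sharing distance (1 - IBS) as the default sample distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variants import MISSING, VariantTable


def dosage_matrix(table: VariantTable, impute: bool = True) -> np.ndarray:
    """Float dosage matrix with missing as NaN (or column-mean imputed)."""
    g = table.gt.astype(float)
    g[table.gt == MISSING] = np.nan
    if impute:
        means = np.nanmean(g, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        ii = np.where(np.isnan(g))
        g[ii] = means[ii[1]]
    return g


# ---------------------------------------------------------------------------
# PCA and the Mahalanobis outlier scan
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray            # (n_samples, K)
    explained_variance: np.ndarray  # fractions, non-increasing
    zscores: np.ndarray           # (n_snps_tested, K)
    stat: np.ndarray              # Mahalanobis distances
    pvalues: np.ndarray
    qvalues: np.ndarray
    tested_sites: np.ndarray      # indices into the input table
    gif: float


def pca_and_outliers(table: VariantTable, K: int, fdr: float = 0.01
                     ) -> tuple[PCAResult, set]:
    """PCA of scaled dosages and a per-SNP Mahalanobis outlier scan."""
    if table.n_samples < K + 1:
        raise ValueError("need at least K+1 samples")
    g = dosage_matrix(table)
    p = g.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    g = g[:, keep]
    p = p[keep]
    x = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total_var = float((s ** 2).sum())
    explained = (s ** 2) / total_var if total_var > 0 else s * 0
    pcs = u[:, :K]                      # orthonormal columns
    # regression of each scaled SNP on the K PCs; z = beta / se
    beta = pcs.T @ x                    # (K, m) since pcs orthonormal
    resid = x - pcs @ beta
    dof = max(table.n_samples - K - 1, 1)
    sigma2 = (resid ** 2).sum(axis=0) / dof
    sigma2 = np.maximum(sigma2, 1e-8 * np.median(sigma2) + 1e-300)
    z = (beta / np.sqrt(sigma2)).T      # (m, K); se of beta_k is sigma
    z = np.nan_to_num(z)
    # robust covariance: true outliers must not inflate the null spread
    cov = _robust_cov(z)
    d2 = np.einsum("ij,jk,ik->i", z, np.linalg.inv(cov), z)
    gif = float(np.median(d2) / stats.chi2.ppf(0.5, K))
    gif = max(gif, 1e-12)
    pvals = stats.chi2.sf(d2 / gif, K)
    rej, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    tested = np.flatnonzero(keep)
    outliers = set(tested[rej].tolist())
    res = PCAResult(scores=u * s, explained_variance=explained,
                    zscores=z, stat=d2, pvalues=pvals, qvalues=qvals,
                    tested_sites=tested, gif=gif)
    return res, outliers


def _robust_cov(z: np.ndarray) -> np.ndarray:
    """Minimum-covariance-determinant estimate with empirical fallback."""
    K = z.shape[1]
    try:
        from sklearn.covariance import MinCovDet

        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cov = MinCovDet(random_state=0).fit(z).covariance_
    except Exception:
        cov = np.cov(z, rowvar=False)
    return np.atleast_2d(cov) + 1e-10 * np.eye(K)


# ---------------------------------------------------------------------------
# Masked-CV nonnegative factorization (admixture proxy)
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureResult:
    Q: np.ndarray                # (n_samples, K*) ancestry fractions
    F: np.ndarray                # (n_sites, K*) ancestral frequencies
    K: int
    cv_error: dict               # K -> held-out mean squared error
    objective: list              # objective trace for the selected K
    converged: bool


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of v onto the probability simplex."""
    n, k = v.shape
    u = np.sort(v, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(v - theta[:, None], 0.0)


def _masked_objective(X, W, Q, F):
    return float(np.sum(W * (X - Q @ F.T) ** 2))


def _spectral_init(X, W, K, rng):
    """Q from k-means on the leading principal components (hard clusters
    softened), F from per-cluster means — a structure-aware starting point."""
    from sklearn.cluster import KMeans

    Xc = np.where(W > 0, X, np.nan)
    col = np.nanmean(Xc, axis=0)
    Xi = np.where(np.isnan(Xc), col[None, :], Xc)
    Xi = Xi - Xi.mean(axis=0)
    u, s, _ = np.linalg.svd(Xi, full_matrices=False)
    k_eff = max(K - 1, 1)
    labels = KMeans(n_clusters=K, n_init=5,
                    random_state=int(rng.integers(2 ** 31))
                    ).fit(u[:, :k_eff] * s[:k_eff]).labels_
    Q = np.full((X.shape[0], K), 0.05 / max(K - 1, 1))
    Q[np.arange(len(labels)), labels] = 0.95
    Q = _project_simplex(Q)
    F = np.vstack([np.nanmean(Xc[labels == k], axis=0) for k in range(K)]).T
    F = np.clip(np.nan_to_num(F, nan=0.5), 0, 1)
    return Q, F


def _fit_nmf(X, W, K, rng, max_iter=200, tol=1e-7, init="random"):
    """Alternating ridge-regularized least squares with monotone acceptance.

    Q rows live on the simplex, F entries in [0, 1].  Each alternation is
    accepted only if the masked objective does not increase, which makes the
    trace monotone by construction; lack of progress stops the loop.
    """
    n, m = X.shape
    if init == "spectral" and K > 1:
        Q, F = _spectral_init(X, W, K, rng)
    else:
        Q = _project_simplex(rng.dirichlet(np.ones(K), size=n) + 0.01)
        F = np.clip(rng.uniform(0.1, 0.9, size=(m, K)), 0, 1)
    obj = [_masked_objective(X, W, Q, F)]
    eye = 1e-6 * np.eye(K)
    for _ in range(max_iter):
        # F update: weighted least squares per site, clipped to [0, 1]
        F_new = F.copy()
        for j in range(m):
            w = W[:, j]
            A = (Q * w[:, None]).T @ Q + eye
            b = (Q * w[:, None]).T @ X[:, j]
            F_new[j] = np.clip(np.linalg.solve(A, b), 0.0, 1.0)
        # Q update: weighted least squares per sample, simplex projection
        Q_new = Q.copy()
        for i in range(n):
            w = W[i]
            A = (F * w[:, None]).T @ F + eye
            b = (F * w[:, None]).T @ X[i]
            Q_new[i] = np.linalg.solve(A, b)
        Q_new = _project_simplex(Q_new)
        cand = _masked_objective(X, W, Q_new, F_new)
        if cand <= obj[-1]:
            Q, F = Q_new, F_new
            obj.append(cand)
            if obj[-2] - obj[-1] < tol * max(obj[0], 1e-12):
                return Q, F, obj, True
        else:  # half-step fallback keeps the trace monotone
            Qh, Fh = (Q + Q_new) / 2, np.clip((F + F_new) / 2, 0, 1)
            Qh = _project_simplex(Qh)
            cand = _masked_objective(X, W, Qh, Fh)
            if cand <= obj[-1]:
                Q, F = Qh, Fh
                obj.append(cand)
            else:
                return Q, F, obj, True
    return Q, F, obj, False


def admixture_factorization(table: VariantTable, K_range=range(1, 6),
                            mask_fraction: float = 0.05, seed: int = 0,
                            max_iter: int = 200,
                            n_init: int = 3) -> AdmixtureResult:
    """Estimate ancestry fractions Q and ancestral frequencies F.

    The most likely number of ancestral populations K* minimizes the
    held-out (masked-entry) squared error; each K is fitted from ``n_init``
    restarts, keeping the best training objective (the alternating solver
    can stall in local optima).  K = 1 degenerates to Q = 1 and F = the mean
    frequencies.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    g = dosage_matrix(table, impute=False)
    X = g / 2.0
    observed = ~np.isnan(X)
    X = np.nan_to_num(X)
    mask = observed & (rng.random(X.shape) < mask_fraction)
    W_train = (observed & ~mask).astype(float)
    cv = {}
    fits = {}
    for K in K_range:
        if K < 1:
            raise ValueError("K must be >= 1")
        best = None
        for init in range(n_init):
            cand = _fit_nmf(X, W_train, K,
                            np.random.default_rng(seed + 1000 * K + init),
                            max_iter=max_iter,
                            init="spectral" if init == 0 else "random")
            if best is None or cand[2][-1] < best[2][-1]:
                best = cand
        Q, F, obj, conv = best
        pred = Q @ F.T
        held = mask.sum()
        cv[K] = (float(np.sum((mask * (X - pred)) ** 2) / held)
                 if held else obj[-1])
        fits[K] = (Q, F, obj, conv)
    K_star = min(cv, key=cv.get)
    Q, F, obj, conv = fits[K_star]
    if not conv:
        import logging
        logging.getLogger(__name__).warning(
            "factorization did not converge at K=%d; best iterate returned",
            K_star)
    return AdmixtureResult(Q=Q, F=F, K=K_star, cv_error=cv, objective=obj,
                           converged=conv)


def factorization_outliers(table: VariantTable, result: AdmixtureResult,
                           fdr: float = 0.01) -> set:
    """Differentiation scan across the fitted ancestral frequencies F.

    Per SNP an FST-like statistic over the K estimated ancestral populations
    (weighted variance of F relative to pbar(1-pbar), weights = total
    ancestry share of each component) is rescaled against its chi-square
    (K-1) null via a median-based genomic inflation factor; BH at ``fdr``
    flags SNPs whose differentiation among ancestral components exceeds the
    genome-wide drift background.  K = 1 flags nothing by construction.
    """
    K = result.K
    if K < 2:
        return set()
    w = result.Q.sum(axis=0)
    w = w / w.sum()
    F = result.F                                      # (m, K)
    pbar = F @ w
    var = ((F - pbar[:, None]) ** 2) @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = var / (pbar * (1 - pbar))
    n = table.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        score = fst * (2 * n - K) / np.maximum(1 - fst, 1e-12)
    ok = np.isfinite(score) & (pbar > 0) & (pbar < 1)
    gif = np.median(score[ok]) / stats.chi2.ppf(0.5, K - 1)
    gif = max(float(gif), 1e-12)
    pvals = stats.chi2.sf(score[ok] / gif, K - 1)
    rej = multipletests(pvals, alpha=fdr, method="fdr_bh")[0]
    return set(np.flatnonzero(ok)[rej].tolist())


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------

def allele_sharing_distance(table: VariantTable) -> pd.DataFrame:
    """1 - IBS distance between samples over jointly called sites."""
    g = table.gt.astype(float)
    g[table.gt == MISSING] = np.nan
    n = table.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(g[i]) & ~np.isnan(g[j])
            if not ok.any():
                raise ValueError("no shared called sites between samples")
            ibs = 1.0 - np.abs(g[i, ok] - g[j, ok]) / 2.0
            D[i, j] = D[j, i] = 1.0 - float(ibs.mean())
    return pd.DataFrame(D, index=table.samples, columns=table.samples)


def neighbor_joining(dist: pd.DataFrame) -> str:
    """Canonical neighbor joining; returns a Newick string.

    Branch lengths follow the standard two-point formulas; negative lengths
    are clamped to zero (transferring the deficit to the sister branch is
    deliberately not done — lengths stay interpretable on noisy input).
    """
    D = np.asarray(dist, dtype=float)
    labels = [str(x) for x in dist.index]
    if D.shape[0] != D.shape[1] or len(labels) < 3:
        raise ValueError("need a square matrix over >= 3 taxa")
    if np.any(np.isnan(D)):
        raise ValueError("NaN distances")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    nodes = list(labels)
    D = D.copy()
    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Qm = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Qm, np.inf)
        i, j = np.unravel_index(np.argmin(Qm), Qm.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        du = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = du[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
    # three-point closing: lengths solve the three-point equations exactly
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max(0.5 * (d01 + d02 - d12), 0.0)
    l1 = max(0.5 * (d01 + d12 - d02), 0.0)
    l2 = max(0.5 * (d02 + d12 - d01), 0.0)
    return (f"({nodes[0]}:{l0:.10g},{nodes[1]}:{l1:.10g},"
            f"{nodes[2]}:{l2:.10g});")


# ---------------------------------------------------------------------------
# Adaptive / neutral partition
# ---------------------------------------------------------------------------

@dataclass
class LociPartition:
    adaptive: set
    neutral: set
    scanA: set
    scanB: set


def partition_loci(scanA_hits: set, scanB_hits: set,
                   tested_sites: set) -> LociPartition:
    """Adaptive = intersection of both scans; neutral = the rest."""
    A = set(scanA_hits) & set(tested_sites)
    B = set(scanB_hits) & set(tested_sites)
    if not set(scanA_hits) <= set(tested_sites) or \
       not set(scanB_hits) <= set(tested_sites):
        raise ValueError("hit sets must be subsets of tested sites")
    adaptive = A & B
    return LociPartition(adaptive=adaptive,
                         neutral=set(tested_sites) - adaptive,
                         scanA=A, scanB=B)
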