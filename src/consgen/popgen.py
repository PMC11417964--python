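"""Diversity and differentiation statistics.

Per-population nucleotide diversity (theta_pi), Watterson's theta, individual
heterozygosity rates — overall and per site class (intergenic, intron, CDS,
0-fold, 4-fold degenerate) — pairwise FST (Hudson ratio-of-averages by
default, Weir-Cockerham optionally), LD decay curves and site frequency
spectra.

Per-site pi uses the unbiased haplotype-pair form pi = 2 c (n - c) / (n (n-1))
with c the alternate-haplotype count and n the non-missing haplotype count.
theta_pi is the sum of per-site pi divided by the callable length of the
region class; theta_w is S / (a_n * L) with a_n the harmonic number for
n = 2 x (median non-missing diploids).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .variants import MISSING, VariantTable

CLASS_ORDER = ("whole", "intergenic", "intron", "cds", "fold0", "fold4")


def site_class_key(annotation: pd.DataFrame) -> np.ndarray:
    """Collapse class/degeneracy columns into one label per site."""
    return np.where(annotation["degeneracy"].isin(["fold0", "fold4"]),
                    annotation["degeneracy"], annotation["class"]).astype(object)


def class_mask(annotation: pd.DataFrame, klass: str) -> np.ndarray:
    """Site mask for a region class; "cds" spans both degeneracy classes."""
    if klass == "whole":
        return np.ones(len(annotation), dtype=bool)
    if klass in ("fold0", "fold4"):
        return (annotation["degeneracy"] == klass).to_numpy()
    return (annotation["class"] == klass).to_numpy()


def _per_site_pi(gt: np.ndarray) -> np.ndarray:
    """Unbiased per-site pi over non-missing haplotypes; NaN if n < 2."""
    called = gt != MISSING
    n = 2 * called.sum(axis=0).astype(float)
    c = np.where(called, gt, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * c * (n - c) / (n * (n - 1.0))
    pi[n < 2] = np.nan
    return pi


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def diversity_stats(table: VariantTable, annotation: pd.DataFrame,
                    callable_length: dict, pop_map: pd.DataFrame,
                    windows: pd.DataFrame | None = None) -> pd.DataFrame:
    """theta_pi, theta_w and heterozygosity per population and site class.

    ``callable_length`` maps each class (and "whole") to the monomorphic +
    polymorphic base count used as the denominator; it is an explicit input
    because callable fractions cannot be inferred from a SNP-only table.
    Returns a long-format table (population, region class, statistic, value).
    Individual heterozygosity rates are returned as extra rows with
    statistic ``het_rate`` (population mean) alongside a per-individual
    attribute-free encoding via statistic ``het_rate_<sample>`` kept out of
    the default output; use :func:`individual_heterozygosity` for those.
    """
    rows = []
    for pop, grp in pop_map.groupby("population_id", sort=True):
        idx = [table.samples.index(s) for s in grp["sample_id"]]
        gt = table.gt[idx]
        pi_site = _per_site_pi(gt)
        called = gt != MISSING
        for klass in CLASS_ORDER:
            if klass not in callable_length:
                continue
            sel = class_mask(annotation, klass)
            L = float(callable_length[klass])
            if L <= 0:
                rows.append((pop, klass, "theta_pi", np.nan))
                rows.append((pop, klass, "theta_w", np.nan))
                rows.append((pop, klass, "het_rate", np.nan))
                continue
            pi = np.nansum(pi_site[sel]) / L
            # segregating sites within this population
            alt = np.where(called[:, sel], gt[:, sel], 0).sum(axis=0)
            nhap = 2 * called[:, sel].sum(axis=0)
            seg = (alt > 0) & (alt < nhap)
            n_dip = np.median(called[:, sel].sum(axis=0)) if sel.any() else 0
            n = int(2 * n_dip)
            theta_w = (seg.sum() / (_harmonic(n) * L)) if n >= 2 else np.nan
            het = (gt[:, sel] == 1).sum(axis=1) / L
            rows.append((pop, klass, "theta_pi", float(pi)))
            rows.append((pop, klass, "theta_w", float(theta_w)))
            rows.append((pop, klass, "het_rate", float(het.mean())))
    out = pd.DataFrame(rows, columns=["population", "region_class",
                                      "statistic", "value"])
    if windows is not None:
        out = pd.concat([out, _windowed_pi(table, pop_map, windows)],
                        ignore_index=True)
    return out


def _windowed_pi(table, pop_map, windows):
    rows = []
    for pop, grp in pop_map.groupby("population_id", sort=True):
        idx = [table.samples.index(s) for s in grp["sample_id"]]
        pi_site = _per_site_pi(table.gt[idx])
        for _, w in windows.iterrows():
            sel = ((table.chrom == w["chrom"]) & (table.pos >= w["start"])
                   & (table.pos <= w["end"]))
            L = w["end"] - w["start"] + 1
            rows.append((pop, f"{w['chrom']}:{w['start']}-{w['end']}",
                         "theta_pi_window", float(np.nansum(pi_site[sel]) / L)))
    return pd.DataFrame(rows, columns=["population", "region_class",
                                       "statistic", "value"])


def individual_heterozygosity(table: VariantTable, annotation: pd.DataFrame,
                              callable_length: dict) -> pd.DataFrame:
    """Per-individual heterozygous-call rate per site class."""
    rows = []
    for klass in CLASS_ORDER:
        if klass not in callable_length:
            continue
        sel = class_mask(annotation, klass)
        L = float(callable_length[klass])
        het = (table.gt[:, sel] == 1).sum(axis=1) / L
        for s, h in zip(table.samples, het):
            rows.append((s, klass, float(h)))
    return pd.DataFrame(rows, columns=["sample_id", "region_class", "het_rate"])


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def _pop_counts(table, pop_map):
    """Alt and called-haplotype counts per population: dicts of arrays."""
    alt, nhap = {}, {}
    for pop, grp in pop_map.groupby("population_id", sort=True):
        idx = [table.samples.index(s) for s in grp["sample_id"]]
        gt = table.gt[idx]
        called = gt != MISSING
        alt[pop] = np.where(called, gt, 0).sum(axis=0).astype(float)
        nhap[pop] = 2.0 * called.sum(axis=0)
    return alt, nhap


def hudson_fst_components(c1, n1, c2, n2):
    """Per-site Hudson numerator/denominator (Bhatia et al. formulation)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = c1 / n1, c2 / n2
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _wc_fst(c1, n1, c2, n2):
    """Weir-Cockerham (1984) two-population theta, ratio of averages.

    Formulated on allele (haplotype) counts — the haploid variant of the
    estimator, appropriate since ``n1``/``n2`` count haplotypes.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = c1 / n1, c2 / n2
        nbar = (n1 + n2) / 2.0
        nc = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2))
        pbar = (c1 + c2) / (n1 + n2)
        s2 = ((n1 * (p1 - pbar) ** 2) + (n2 * (p2 - pbar) ** 2)) / nbar
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2.0)
    return a, a + b


def pairwise_fst(table: VariantTable, pop_map: pd.DataFrame,
                 estimator: str = "hudson", loci_label: str = "all",
                 site_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Pairwise FST matrix (ratio of per-site averages), clipped to [0, 1].

    Hudson's estimator is the default for its small-sample robustness; the
    Weir-Cockerham estimator is available via ``estimator="wc"``.  Sites
    monomorphic across both populations (or with <2 haplotypes in either)
    are skipped.
    """
    alt, nhap = _pop_counts(table, pop_map)
    pops = sorted(alt)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    M = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            c1, n1 = alt[pops[i]], nhap[pops[i]]
            c2, n2 = alt[pops[j]], nhap[pops[j]]
            ok = (n1 >= 2) & (n2 >= 2)
            poly = ((c1 + c2) > 0) & ((c1 + c2) < (n1 + n2))
            ok &= poly
            if site_mask is not None:
                ok &= site_mask
            if estimator == "hudson":
                num, den = hudson_fst_components(c1[ok], n1[ok], c2[ok], n2[ok])
            elif estimator == "wc":
                num, den = _wc_fst(c1[ok], n1[ok], c2[ok], n2[ok])
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
            fst = np.nansum(num) / np.nansum(den) if np.nansum(den) > 0 else np.nan
            M[i, j] = M[j, i] = np.clip(fst, 0.0, 1.0)
    out = pd.DataFrame(M, index=pops, columns=pops)
    out.attrs["loci"] = loci_label
    out.attrs["estimator"] = estimator
    return out


# ---------------------------------------------------------------------------
# LD decay and site frequency spectra
# ---------------------------------------------------------------------------

def ld_decay(table: VariantTable, max_dist: int = 100_000,
             n_bins: int = 20) -> pd.DataFrame:
    """Mean r^2 of dosage vectors per physical-distance bin.

    All intra-chromosome pairs within ``max_dist`` are binned by distance;
    bins partition the pairs (sum of counts = number of eligible pairs).
    """
    edges = np.linspace(0, max_dist, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    gt = table.gt.astype(float)
    gt[table.gt == MISSING] = np.nan
    for c in np.unique(table.chrom):
        idx = np.flatnonzero(table.chrom == c)
        for a_i, a in enumerate(idx):
            for b in idx[a_i + 1:]:
                d = int(table.pos[b] - table.pos[a])
                if d > max_dist:
                    break
                ok = ~np.isnan(gt[:, a]) & ~np.isnan(gt[:, b])
                if ok.sum() < 2:
                    continue
                x, y = gt[ok, a], gt[ok, b]
                if x.std() == 0 or y.std() == 0:
                    continue
                r2 = np.corrcoef(x, y)[0, 1] ** 2
                k = min(np.searchsorted(edges, d, side="right") - 1, n_bins - 1)
                sums[k] += r2
                counts[k] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"dist_low": edges[:-1], "dist_high": edges[1:],
                         "mean_r2": mean, "n_pairs": counts})


def site_frequency_spectrum(table: VariantTable,
                            ancestral: np.ndarray | None = None,
                            folded: bool = True) -> np.ndarray:
    """Site frequency spectrum over fully-called sites.

    Folded: bins 1..n/2 by minor-allele count.  Unfolded: bins 1..n-1 by
    derived-allele count, requiring an ancestral call ("REF"/"ALT") per site;
    sites with "NA" ancestral are skipped.  Index 0 of the returned vector is
    unused (kept so bin i = count class i).
    """
    complete = (table.gt != MISSING).all(axis=0)
    n = 2 * table.n_samples
    gt = table.gt[:, complete]
    alt = gt.sum(axis=0)
    if folded:
        minor = np.minimum(alt, n - alt)
        sfs = np.zeros(n // 2 + 1, dtype=int)
        seg = (minor > 0)
        np.add.at(sfs, minor[seg], 1)
        return sfs
    if ancestral is None:
        raise ValueError("unfolded SFS requires ancestral alleles")
    anc = np.asarray(ancestral)[complete]
    known = np.isin(anc, ["REF", "ALT"])
    derived = np.where(anc[known] == "REF", alt[known], n - alt[known])
    sfs = np.zeros(n, dtype=int)
    seg = (derived > 0) & (derived < n)
    np.add.at(sfs, derived[seg], 1)
    return sfs


def fold_sfs(unfolded: np.ndarray) -> np.ndarray:
    """Fold an unfolded SFS: bin i merges derived classes i and n-i."""
    n = len(unfolded)
    folded = np.zeros(n // 2 + 1, dtype=unfolded.dtype)
    for i in range(1, n):
        folded[min(i, n - i)] += unfolded[i]
    return folded
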