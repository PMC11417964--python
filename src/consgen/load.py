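"""Deleterious-mutation genetic load and genetic-rescue donor ranking.

Coding variants are classified by a SIFT-like score into deleterious
(score < 0.05), tolerated (score >= 0.05) or synonymous; the derived allele
is the non-ancestral one.  Realized load per individual is the
homozygous-derived deleterious ratio: of the deleterious sites where the
individual carries at least one derived allele, the fraction at which it is
homozygous derived.  Masked versus purged load is probed by the ratio of
0-fold to 4-fold heterozygosity against neutral (intergenic)
heterozygosity.  Shared homozygous load between populations is summarized as
Venn region counts, and candidate pollen-donor populations are ranked by an
equal-weight rank mean over diversity, heterozygosity, inbreeding, load and
differentiation criteria, excluding maximally diverged candidates to guard
against outbreeding depression.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .variants import MISSING, VariantTable

SIFT_DELETERIOUS = 0.05


def classify_variants(annotation: pd.DataFrame) -> pd.DataFrame:
    """Effect class and derived allele per site.

    Synonymous label (4-fold degenerate CDS) wins regardless of score;
    other CDS sites need a score and a known ancestral allele, else they are
    excluded.  Non-coding sites are excluded from load accounting.
    Returns a frame with columns ``effect`` in {deleterious, tolerated,
    synonymous, excluded} and ``derived`` in {REF, ALT, NA}.
    """
    cls = annotation["class"].to_numpy()
    deg = annotation["degeneracy"].to_numpy()
    sift = annotation["sift_score"].to_numpy(dtype=float)
    anc = annotation["ancestral"].to_numpy()
    derived = np.where(anc == "REF", "ALT", np.where(anc == "ALT", "REF", "NA"))
    effect = np.full(len(annotation), "excluded", dtype=object)
    coding = cls == "cds"
    effect[coding & (deg == "fold4")] = "synonymous"
    scored = coding & (deg != "fold4") & ~np.isnan(sift) & (derived != "NA")
    effect[scored & (sift < SIFT_DELETERIOUS)] = "deleterious"
    effect[scored & (sift >= SIFT_DELETERIOUS)] = "tolerated"
    return pd.DataFrame({"effect": effect, "derived": derived},
                        index=annotation.index)


def derived_dosage(table: VariantTable, derived: np.ndarray) -> np.ndarray:
    """Per-genotype derived-allele dosage (-1 where missing or unpolarized)."""
    d = table.gt.astype(np.int8).copy()
    flip = derived == "REF"
    d[:, flip] = np.where(d[:, flip] == MISSING, MISSING, 2 - d[:, flip])
    d[:, derived == "NA"] = MISSING
    return d


def load_metrics(table: VariantTable, effect: pd.DataFrame,
                 annotation: pd.DataFrame, pop_map: pd.DataFrame,
                 callable_length: dict | None = None) -> dict:
    """Per-individual load summary plus the het0/het4-vs-neutral correlation.

    Returns a dict with:

    ``individuals``: frame (sample, population, n_hom_del, n_del_carrier,
    homdel_ratio, het_fold0, het_fold4, het0_het4_ratio, het_intergenic);
    ``correlation``: Pearson r and p of het0/het4 vs intergenic
    heterozygosity across individuals with defined ratios;
    ``population_test``: Kruskal-Wallis on homdel_ratio across populations
    plus a compact letter display from pairwise BH-corrected rank tests.
    """
    from .popgen import site_class_key

    key = site_class_key(annotation)
    deleterious = (effect["effect"] == "deleterious").to_numpy()
    d = derived_dosage(table, effect["derived"].to_numpy())
    pop_of = dict(zip(pop_map["sample_id"], pop_map["population_id"]))
    L0 = (callable_length or {}).get("fold0", int((key == "fold0").sum()) or 1)
    L4 = (callable_length or {}).get("fold4", int((key == "fold4").sum()) or 1)
    Li = (callable_length or {}).get("intergenic",
                                     int((key == "intergenic").sum()) or 1)
    rows = []
    for i, s in enumerate(table.samples):
        dd = d[i, deleterious]
        carrier = dd >= 1
        hom = dd == 2
        n_car, n_hom = int(carrier.sum()), int(hom.sum())
        ratio = n_hom / n_car if n_car else np.nan
        het0 = (table.gt[i, key == "fold0"] == 1).sum() / L0
        het4 = (table.gt[i, key == "fold4"] == 1).sum() / L4
        het_i = (table.gt[i, key == "intergenic"] == 1).sum() / Li
        rows.append((s, pop_of.get(s), n_hom, n_car, ratio, het0, het4,
                     het0 / het4 if het4 > 0 else np.nan, het_i))
    ind = pd.DataFrame(rows, columns=["sample_id", "population", "n_hom_del",
                                      "n_del_carrier", "homdel_ratio",
                                      "het_fold0", "het_fold4",
                                      "het0_het4_ratio", "het_intergenic"])
    ok = ind["het0_het4_ratio"].notna() & ind["het_intergenic"].notna()
    if ok.sum() >= 3:
        r, p = stats.pearsonr(ind.loc[ok, "het0_het4_ratio"],
                              ind.loc[ok, "het_intergenic"])
    else:
        r = p = np.nan
    groups = [g["homdel_ratio"].dropna().to_numpy()
              for _, g in ind.groupby("population", sort=True)]
    if len(groups) >= 2 and all(len(g) for g in groups):
        kw = stats.kruskal(*groups)
        letters = _letter_groups(ind.dropna(subset=["homdel_ratio"]))
    else:
        kw, letters = None, {}
    return {"individuals": ind,
            "correlation": {"r": float(r), "p": float(p)},
            "population_test": {
                "kruskal_H": float(kw.statistic) if kw else np.nan,
                "p": float(kw.pvalue) if kw else np.nan,
                "letters": letters}}


def _letter_groups(ind: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Compact letter display from pairwise Mann-Whitney tests (BH)."""
    from statsmodels.stats.multitest import multipletests

    pops = sorted(ind["population"].unique(),
                  key=lambda p: ind.loc[ind["population"] == p,
                                        "homdel_ratio"].median())
    pairs = list(combinations(pops, 2))
    if not pairs:
        return {p: "a" for p in pops}
    pvals = []
    for a, b in pairs:
        x = ind.loc[ind["population"] == a, "homdel_ratio"]
        y = ind.loc[ind["population"] == b, "homdel_ratio"]
        try:
            pvals.append(stats.mannwhitneyu(x, y).pvalue)
        except ValueError:
            pvals.append(1.0)
    rej = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    differ = {pair for pair, r in zip(pairs, rej) if r}
    # greedy insertion: walk sorted pops, open a new letter at each break
    letters: dict[str, str] = {p: "" for p in pops}
    current, letter = [], 0
    for p in pops:
        if any((min(q, p), max(q, p)) in differ for q in current):
            for q in current:
                letters[q] += chr(ord("a") + letter)
            letter += 1
            current = [q for q in current
                       if (min(q, p), max(q, p)) not in differ]
        current.append(p)
    for q in current:
        letters[q] += chr(ord("a") + letter)
    return letters


# ---------------------------------------------------------------------------
# Shared homozygous deleterious load (Venn)
# ---------------------------------------------------------------------------

def population_homdel_sets(table: VariantTable, effect: pd.DataFrame,
                           pop_map: pd.DataFrame, pops: list[str],
                           rule: str = "any_hom",
                           freq_threshold: float = 0.5) -> dict:
    """Per-population sets of sites carrying homozygous-derived deleterious
    variants.

    ``rule="any_hom"`` (default): a site belongs to a population if at least
    one member is homozygous for the derived deleterious allele.
    ``rule="freq"``: if the derived-homozygote frequency among called members
    exceeds ``freq_threshold``.
    """
    deleterious = np.flatnonzero((effect["effect"] == "deleterious").to_numpy())
    d = derived_dosage(table, effect["derived"].to_numpy())
    sets = {}
    for pop in pops:
        members = [table.samples.index(s)
                   for s, p in zip(pop_map["sample_id"], pop_map["population_id"])
                   if p == pop]
        dd = d[np.ix_(members, deleterious)]
        hom = dd == 2
        if rule == "any_hom":
            present = hom.any(axis=0)
        elif rule == "freq":
            called = dd != MISSING
            with np.errstate(invalid="ignore"):
                frac = hom.sum(axis=0) / np.maximum(called.sum(axis=0), 1)
            present = frac > freq_threshold
        else:
            raise ValueError(f"unknown membership rule {rule!r}")
        sets[pop] = set(deleterious[present].tolist())
    return sets


def shared_homozygous_deleterious(table: VariantTable, effect: pd.DataFrame,
                                  pop_map: pd.DataFrame, pops: list[str],
                                  rule: str = "any_hom") -> dict:
    """Venn region counts of homozygous deleterious sites over populations.

    Returns ``{"sets": {pop: set}, "regions": {frozenset: count}}`` with one
    exclusive region per nonempty subset of populations; region counts sum
    to the size of the union.
    """
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    sets = population_homdel_sets(table, effect, pop_map, pops, rule=rule)
    return {"sets": sets, "regions": venn_regions(sets)}


def venn_regions(sets: dict) -> dict:
    """Exclusive region counts for all 2^k - 1 nonempty subsets."""
    pops = list(sets)
    regions = {}
    for r in range(1, len(pops) + 1):
        for sub in combinations(pops, r):
            inter = set.intersection(*(sets[p] for p in sub))
            others = set().union(*(sets[p] for p in pops if p not in sub)) \
                if len(sub) < len(pops) else set()
            regions[frozenset(sub)] = len(inter - others)
    return regions


# ---------------------------------------------------------------------------
# Donor ranking
# ---------------------------------------------------------------------------

#: criterion name -> (higher_is_better)
DONOR_CRITERIA = {"theta_pi": True, "heterozygosity": True, "froh": False,
                  "homdel_ratio": False, "shared_load": False,
                  "fst_to_target": False}


def rank_donors(target_pop: str, candidates: list[str],
                criteria: pd.DataFrame) -> pd.DataFrame:
    """Rank candidate donor populations for genetic rescue of ``target_pop``.

    ``criteria`` is indexed by candidate population with the columns of
    :data:`DONOR_CRITERIA` (FST to target computed on adaptive loci).
    Candidates attaining the maximal adaptive FST to the target are excluded
    outright (outbreeding-depression guard); the rest are ranked by the
    equal-weight mean of within-criterion ranks, ties broken by lower shared
    load.  Excluded candidates are returned with a reason and no rank.
    """
    missing = [c for c in candidates if c not in criteria.index]
    if missing:
        raise ValueError(f"criteria missing for candidates: {missing}")
    cols = list(DONOR_CRITERIA)
    tab = criteria.loc[candidates, cols].astype(float)
    fmax = tab["fst_to_target"].max()
    excluded = tab.index[tab["fst_to_target"] == fmax].tolist()
    kept = [c for c in candidates if c not in excluded]
    if len(kept) < 2:
        import logging
        logging.getLogger(__name__).warning(
            "fewer than 2 candidates remain after the FST exclusion")
    sub = tab.loc[kept]
    ranks = pd.DataFrame(index=sub.index)
    for col, higher in DONOR_CRITERIA.items():
        ranks[col] = sub[col].rank(ascending=not higher, method="average")
    score = ranks.mean(axis=1)
    order = pd.DataFrame({"rank_mean": score,
                          "shared_load": sub["shared_load"]})
    order = order.sort_values(["rank_mean", "shared_load"])
    out = pd.DataFrame({
        "candidate": list(order.index) + excluded,
        "rank": list(range(1, len(order) + 1)) + [np.nan] * len(excluded),
        "rank_mean": list(order["rank_mean"]) + [np.nan] * len(excluded),
        "excluded_reason": [""] * len(order)
        + ["maximal adaptive-loci FST to target"] * len(excluded),
    })
    for col in cols:
        out[col] = tab.loc[out["candidate"], col].to_numpy()
    out.attrs["target"] = target_pop
    return out
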