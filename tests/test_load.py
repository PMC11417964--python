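"""Effect classification, load metrics, Venn arithmetic, donor ranking."""

import numpy as np
import pandas as pd
import pytest

from consgen import load, syndata
from consgen.variants import MISSING

from conftest import make_table


def ann_frame(cls, deg, anc, sift):
    return pd.DataFrame({"chrom": ["chr1"] * len(cls),
                         "pos": range(1, len(cls) + 1),
                         "class": cls, "degeneracy": deg,
                         "ancestral": anc, "sift_score": sift})


def test_sift_threshold_boundary():
    ann = ann_frame(["cds", "cds"], ["fold0", "fold0"], ["REF", "REF"],
                    [0.049, 0.05])
    eff = load.classify_variants(ann)
    assert eff["effect"].tolist() == ["deleterious", "tolerated"]


def test_synonymous_wins_regardless_of_score():
    ann = ann_frame(["cds"], ["fold4"], ["REF"], [0.01])
    assert load.classify_variants(ann)["effect"].item() == "synonymous"


def test_unscored_or_unpolarized_sites_excluded():
    ann = ann_frame(["cds", "cds", "intergenic"], ["fold0", "fold0", "NA"],
                    ["NA", "REF", "REF"], [0.01, np.nan, 0.01])
    assert load.classify_variants(ann)["effect"].tolist() == ["excluded"] * 3


def test_class_counts_on_constructed_fixture():
    cls = ["cds"] * 60
    deg = ["fold0"] * 30 + ["fold4"] * 30
    sift = [0.01] * 10 + [0.5] * 20 + [np.nan] * 30
    ann = ann_frame(cls, deg, ["REF"] * 60, sift)
    eff = load.classify_variants(ann)
    counts = eff["effect"].value_counts()
    assert counts["deleterious"] == 10
    assert counts["tolerated"] == 20
    assert counts["synonymous"] == 30


def _load_fixture(dosages):
    """One individual; all sites deleterious with ALT derived."""
    gt = np.asarray(dosages, np.int8)[None, :]
    m = gt.shape[1]
    ann = ann_frame(["cds"] * m, ["fold0"] * m, ["REF"] * m, [0.01] * m)
    t = make_table(gt)
    eff = load.classify_variants(ann)
    pm = pd.DataFrame({"sample_id": ["S1"], "population_id": ["A"]})
    return t, eff, ann, pm


def test_homdel_ratio_examples():
    # homozygous derived at 4 of 10 carrier sites -> 0.4
    t, eff, ann, pm = _load_fixture([2, 2, 2, 2, 1, 1, 1, 1, 1, 1])
    out = load.load_metrics(t, eff, ann, pm)
    assert out["individuals"]["homdel_ratio"].item() == pytest.approx(0.4)
    # every deleterious site heterozygous -> ratio 0
    t, eff, ann, pm = _load_fixture([1, 1, 1])
    out = load.load_metrics(t, eff, ann, pm)
    assert out["individuals"]["homdel_ratio"].item() == 0.0


def test_ratio_invariant_to_tolerated_and_synonymous_sites():
    t, eff, ann, pm = _load_fixture([2, 2, 1, 1, 1])
    base = load.load_metrics(t, eff, ann, pm)["individuals"]["homdel_ratio"].item()
    gt = np.array([[2, 2, 1, 1, 1, 2, 1, 0]], np.int8)
    ann2 = ann_frame(["cds"] * 8, ["fold0"] * 5 + ["fold0", "fold4", "fold0"],
                     ["REF"] * 8, [0.01] * 5 + [0.8, np.nan, 0.6])
    eff2 = load.classify_variants(ann2)
    pm = pd.DataFrame({"sample_id": ["S1"], "population_id": ["A"]})
    out = load.load_metrics(make_table(gt), eff2, ann2, pm)
    assert out["individuals"]["homdel_ratio"].item() == pytest.approx(base)


def test_inbreeding_couples_with_realized_load():
    """Individuals whose planted ROH span deleterious sites expose more
    homozygous load: Spearman(detected FROH, hom-del ratio) > 0."""
    from scipy.stats import spearmanr

    from consgen import roh

    rng = np.random.default_rng(5)
    n_sites, n_ind = 2000, 12
    anc = rng.uniform(0.2, 0.4, n_sites)     # common enough to be carried
    chrom, pos = syndata.assign_positions(n_sites, 1, 10_000_000, rng)
    t, pm = syndata.simulate_genotypes(anc[:, None], [n_ind], rng=rng,
                                       chrom=chrom, pos=pos)
    plan = []
    for i, mb in enumerate([0] * 4 + [1] * 4 + [4] * 4):
        if mb:
            start = int(rng.integers(1, 10_000_000 - mb * 1_000_000))
            plan.append((t.samples[i], "chr1", start, start + mb * 1_000_000))
    syndata.plant_roh_tracts(t, plan, chrom_length=10_000_000, rng=rng)
    ann = ann_frame(["cds"] * n_sites, ["fold0"] * n_sites,
                    ["REF"] * n_sites, [0.01] * n_sites)
    ann["chrom"], ann["pos"] = chrom, pos
    eff = load.classify_variants(ann)
    out = load.load_metrics(t, eff, ann, pm)
    ind = out["individuals"].set_index("sample_id")
    segs = roh.detect_roh(t, min_length=100_000, min_snps=10)
    summ = roh.froh_and_timing(segs, effective_length=1e7,
                               individuals=t.samples)
    froh = summ[summ.level == "individual"].set_index("name")["froh"]
    joined = ind.join(froh.rename("froh_det")).dropna(
        subset=["froh_det", "homdel_ratio"])
    rho = spearmanr(joined["froh_det"], joined["homdel_ratio"]).statistic
    assert rho > 0


def test_venn_regions_exhaustive_toy():
    sets = {"A": {1, 2, 3}, "B": {2, 3}, "C": {3}}
    regions = load.venn_regions(sets)
    assert regions[frozenset({"A"})] == 1
    assert regions[frozenset({"B"})] == 0
    assert regions[frozenset({"C"})] == 0
    assert regions[frozenset({"A", "B"})] == 1
    assert regions[frozenset({"A", "C"})] == 0
    assert regions[frozenset({"B", "C"})] == 0
    assert regions[frozenset({"A", "B", "C"})] == 1
    assert sum(regions.values()) == len({1, 2, 3})


def test_identical_populations_share_everything():
    gt = np.array([[2, 2, 1], [2, 2, 1]], np.int8)
    ann = ann_frame(["cds"] * 3, ["fold0"] * 3, ["REF"] * 3, [0.01] * 3)
    eff = load.classify_variants(ann)
    pm = pd.DataFrame({"sample_id": ["S1", "S2"],
                       "population_id": ["A", "B"]})
    out = load.shared_homozygous_deleterious(make_table(gt), eff, pm,
                                             ["A", "B"])
    assert out["sets"]["A"] == out["sets"]["B"] == {0, 1}
    assert out["regions"][frozenset({"A", "B"})] == 2
    assert out["regions"][frozenset({"A"})] == 0


def test_venn_conservation_on_simulated_data(demo_data, demo_filtered,
                                             demo_annotation_filtered):
    table, _ = demo_filtered
    eff = load.classify_variants(demo_annotation_filtered)
    pops = sorted(demo_data.pop_map["population_id"].unique())[:3]
    out = load.shared_homozygous_deleterious(table, eff, demo_data.pop_map,
                                             pops)
    union = set().union(*out["sets"].values())
    assert sum(out["regions"].values()) == len(union)


def donor_table():
    return pd.DataFrame({
        "theta_pi": [5.0, 3.0, 2.0, 1.0],
        "heterozygosity": [0.5, 0.3, 0.2, 0.1],
        "froh": [0.05, 0.2, 0.3, 0.4],
        "homdel_ratio": [0.1, 0.3, 0.4, 0.5],
        "shared_load": [100, 300, 400, 500],
        "fst_to_target": [0.4, 0.5, 0.6, 0.9],
    }, index=["BM", "LY", "FS", "DX"])


def test_dominating_candidate_ranks_first_and_max_fst_excluded():
    out = load.rank_donors("JM", ["BM", "LY", "FS", "DX"], donor_table())
    ranked = out.dropna(subset=["rank"]).set_index("candidate")
    assert ranked.loc["BM", "rank"] == 1
    excluded = out[out["excluded_reason"] != ""]
    assert excluded["candidate"].tolist() == ["DX"]


def test_ranking_invariant_to_monotone_rescale():
    tab = donor_table()
    base = load.rank_donors("JM", list(tab.index), tab)
    tab2 = tab.copy()
    tab2["theta_pi"] = np.exp(tab2["theta_pi"])        # monotone increasing
    tab2["shared_load"] = tab2["shared_load"] ** 3
    out = load.rank_donors("JM", list(tab2.index), tab2)
    assert out["candidate"].tolist() == base["candidate"].tolist()
    np.testing.assert_array_equal(out["rank"].to_numpy(),
                                  base["rank"].to_numpy())


def test_missing_candidate_criteria_rejected():
    with pytest.raises(ValueError):
        load.rank_donors("JM", ["BM", "ZZ"], donor_table())
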