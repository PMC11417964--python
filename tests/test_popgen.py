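"""Diversity estimators against independent oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest

from consgen import popgen, syndata
from consgen.variants import MISSING

from conftest import make_table


def brute_force_pi(gt):
    """Average pairwise haplotype differences per site, by explicit loops."""
    total = 0.0
    for j in range(gt.shape[1]):
        haps = []
        for g in gt[:, j]:
            if g == MISSING:
                continue
            haps += [1, 1] if g == 2 else ([0, 1] if g == 1 else [0, 0])
        n = len(haps)
        diffs = sum(abs(haps[a] - haps[b])
                    for a in range(n) for b in range(a + 1, n))
        total += diffs / (n * (n - 1) / 2)
    return total


def uniform_annotation(m):
    return pd.DataFrame({"chrom": ["chr1"] * m, "pos": range(1, m + 1),
                         "class": ["intergenic"] * m, "degeneracy": ["NA"] * m,
                         "ancestral": ["REF"] * m,
                         "sift_score": [np.nan] * m})


def one_pop_map(samples):
    return pd.DataFrame({"sample_id": samples, "population_id": "A"})


def test_theta_pi_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    gt = rng.integers(0, 3, size=(4, 5)).astype(np.int8)
    t = make_table(gt)
    L = 1000.0
    out = popgen.diversity_stats(t, uniform_annotation(5), {"whole": L},
                                 one_pop_map(t.samples))
    got = out.loc[(out.region_class == "whole")
                  & (out.statistic == "theta_pi"), "value"].item()
    assert got == pytest.approx(brute_force_pi(gt) / L, rel=1e-12)


def test_theta_w_closed_form():
    # 3 segregating sites, 4 haplotypes, 1000 bp callable:
    # theta_w = 3 / ((1 + 1/2 + 1/3) * 1000)
    gt = np.array([[0, 0, 0, 1], [1, 1, 0, 0]], dtype=np.int8).T[:2]
    gt = np.array([[1, 1, 1, 0], [0, 0, 0, 0]], dtype=np.int8)  # 2 diploids
    gt = np.array([[1, 1, 1, 0],
                   [0, 0, 0, 0]], dtype=np.int8)
    t = make_table(gt)  # 2 diploids = 4 haplotypes, sites 1-3 segregating
    out = popgen.diversity_stats(t, uniform_annotation(4), {"whole": 1000.0},
                                 one_pop_map(t.samples))
    got = out.loc[(out.statistic == "theta_w"), "value"].item()
    assert got == pytest.approx(3 / ((1 + 0.5 + 1 / 3) * 1000), rel=1e-12)


def test_monomorphic_data_has_zero_diversity():
    t = make_table(np.zeros((4, 6), np.int8))
    out = popgen.diversity_stats(t, uniform_annotation(6), {"whole": 100.0},
                                 one_pop_map(t.samples))
    vals = out[out.statistic.isin(["theta_pi", "theta_w"])]["value"]
    assert (vals == 0).all()


def test_diversity_ordering_tracks_constraint(demo_data, demo_filtered,
                                              demo_annotation_filtered):
    """Generator-suppressed classes order as intergenic > fold4 > intron >
    cds > fold0, the purifying-selection signature."""
    table, _ = demo_filtered
    # equal callable length per class isolates the per-site diversity signal
    lens = {k: 1e6 for k in ("intergenic", "fold4", "intron", "cds", "fold0")}
    out = popgen.diversity_stats(table, demo_annotation_filtered, lens,
                                 demo_data.pop_map)
    pi = (out[out.statistic == "theta_pi"]
          .groupby("region_class")["value"].mean())
    counts = {k: popgen.class_mask(demo_annotation_filtered, k).sum()
              for k in lens}
    per_site = {k: pi[k] / counts[k] for k in lens}
    assert per_site["intergenic"] > per_site["fold4"] > per_site["intron"] \
        > per_site["cds"] > per_site["fold0"]


def test_fst_fixed_difference_is_one():
    gt = np.vstack([np.zeros((4, 10)), np.full((4, 10), 2)]).astype(np.int8)
    pm = pd.DataFrame({"sample_id": [f"S{i+1}" for i in range(8)],
                       "population_id": ["A"] * 4 + ["B"] * 4})
    fst = popgen.pairwise_fst(make_table(gt), pm)
    assert fst.loc["A", "B"] == pytest.approx(1.0)
    assert fst.loc["A", "A"] == 0.0


def test_fst_identical_pops_near_zero():
    rng = np.random.default_rng(3)
    freqs = np.repeat(rng.uniform(0.2, 0.8, size=(2000, 1)), 2, axis=1)
    t, pm = syndata.simulate_genotypes(freqs, [30, 30], seed=4)
    fst = popgen.pairwise_fst(t, pm)
    assert abs(fst.iloc[0, 1]) < 0.01


@pytest.mark.parametrize("estimator", ["hudson", "wc"])
def test_fst_estimators_recover_balding_nichols(estimator):
    anc, freqs = syndata.simulate_frequencies(8000, 4, 0.1, seed=5)
    t, pm = syndata.simulate_genotypes(freqs, [10] * 4, seed=6)
    fst = popgen.pairwise_fst(t, pm, estimator=estimator)
    off = fst.to_numpy()[np.triu_indices(4, 1)]
    assert abs(off.mean() - 0.1) < 0.02


def test_theta_pi_theta_w_agree_under_neutrality():
    """theta_pi and theta_w share the expectation 4 Ne mu only when allele
    frequencies follow the neutral coalescent spectrum, so the check runs on
    an msprime panmictic simulation (also an independent oracle for pi via
    tskit's diversity)."""
    import msprime

    ts = msprime.sim_ancestry(samples=20, ploidy=2, population_size=10_000,
                              sequence_length=5e5, recombination_rate=1e-8,
                              random_seed=7)
    ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=8,
                               model=msprime.BinaryMutationModel())
    geno = ts.genotype_matrix()                      # sites x haplotypes
    gt = (geno[:, ::2] + geno[:, 1::2]).T.astype(np.int8)
    t = make_table(gt, pos=ts.sites_position.astype(np.int64) + 1)
    L = ts.sequence_length
    out = popgen.diversity_stats(t, uniform_annotation(t.n_sites),
                                 {"whole": L}, one_pop_map(t.samples))
    pi = out.loc[out.statistic == "theta_pi", "value"].item()
    w = out.loc[out.statistic == "theta_w", "value"].item()
    assert pi == pytest.approx(float(ts.diversity()), rel=1e-6)
    assert abs(pi - w) / pi < 0.1


def test_ld_duplicated_adjacent_snp():
    rng = np.random.default_rng(9)
    col = rng.integers(0, 3, size=(30, 1)).astype(np.int8)
    gt = np.hstack([col, col])
    curve = popgen.ld_decay(make_table(gt, pos=[100, 150]), max_dist=10_000,
                            bins=5) if False else \
        popgen.ld_decay(make_table(gt, pos=[100, 150]), max_dist=10_000,
                        n_bins=5)
    assert curve["mean_r2"].iloc[0] == pytest.approx(1.0)
    assert curve["n_pairs"].sum() == 1


def test_ld_bins_partition_pairs():
    rng = np.random.default_rng(10)
    gt = rng.integers(0, 3, size=(20, 12)).astype(np.int8)
    pos = np.sort(rng.choice(np.arange(1, 50_000), 12, replace=False))
    curve = popgen.ld_decay(make_table(gt, pos=pos), max_dist=50_000, n_bins=8)
    assert curve["n_pairs"].sum() == 12 * 11 // 2


def naive_sfs(gt, ancestral, folded):
    """Direct per-site counting loop, the independent oracle."""
    n = 2 * gt.shape[0]
    counts = {}
    for j in range(gt.shape[1]):
        if np.any(gt[:, j] == MISSING):
            continue
        alt = int(gt[:, j].sum())
        if folded:
            k = min(alt, n - alt)
        else:
            if ancestral[j] == "REF":
                k = alt
            elif ancestral[j] == "ALT":
                k = n - alt
            else:
                continue
            if k in (0, n):
                continue
        if 0 < k:
            counts[k] = counts.get(k, 0) + 1
    size = n // 2 + 1 if folded else n
    out = np.zeros(size, dtype=int)
    for k, v in counts.items():
        out[k] = v
    return out


def test_sfs_matches_naive_loop_and_folding_identity():
    rng = np.random.default_rng(11)
    gt = rng.integers(0, 3, size=(6, 300)).astype(np.int8)
    gt[rng.random(gt.shape) < 0.05] = MISSING
    anc = rng.choice(["REF", "ALT", "NA"], size=300, p=[0.7, 0.2, 0.1])
    t = make_table(gt)
    unfolded = popgen.site_frequency_spectrum(t, ancestral=anc, folded=False)
    folded = popgen.site_frequency_spectrum(t, folded=True)
    np.testing.assert_array_equal(unfolded, naive_sfs(gt, anc, folded=False))
    np.testing.assert_array_equal(folded, naive_sfs(gt, anc, folded=True))
    # folding the unfolded spectrum equals direct folding, over polarized sites
    anc_all = np.array(["REF"] * 300)
    unf_all = popgen.site_frequency_spectrum(t, ancestral=anc_all, folded=False)
    np.testing.assert_array_equal(popgen.fold_sfs(unf_all), folded)


def test_singleton_goes_to_bin_one():
    gt = np.zeros((4, 1), np.int8)
    gt[0, 0] = 1
    sfs = popgen.site_frequency_spectrum(make_table(gt),
                                         ancestral=np.array(["REF"]),
                                         folded=False)
    assert sfs[1] == 1 and sfs.sum() == 1
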