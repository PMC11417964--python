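"""PCA outlier scan, admixture factorization, neighbor joining, partition."""

import io

import numpy as np
import pandas as pd
import pytest

from consgen import popgen, structure, syndata

from conftest import make_table


def two_block_table(seed=0, n_per=15, m_diff=30, m_same=70):
    """Two populations fixed for different alleles at the first sites."""
    rng = np.random.default_rng(seed)
    a = np.hstack([np.zeros((n_per, m_diff)),
                   rng.integers(0, 3, (n_per, m_same))])
    b = np.hstack([np.full((n_per, m_diff), 2),
                   rng.integers(0, 3, (n_per, m_same))])
    return make_table(np.vstack([a, b]).astype(np.int8))


def test_pca_separates_blocks_and_flags_fixed_sites():
    t = two_block_table()
    res, outliers = structure.pca_and_outliers(t, K=2, fdr=0.01)
    pc1 = res.scores[:, 0]
    assert np.sign(pc1[:15]).min() == np.sign(pc1[:15]).max()
    assert np.sign(pc1[15:]).min() == np.sign(pc1[15:]).max()
    assert np.sign(pc1[0]) != np.sign(pc1[15])
    flagged_diff = len(outliers & set(range(30))) / 30
    assert flagged_diff >= 0.9


def test_explained_variance_ordered_and_bounded():
    t = two_block_table(seed=1)
    res, _ = structure.pca_and_outliers(t, K=3)
    ev = res.explained_variance
    assert np.all(np.diff(ev) <= 1e-12)
    assert 0 <= ev.sum() <= 1 + 1e-9
    # scores are orthogonal (left singular vectors scaled)
    g = res.scores[:, :3]
    off = g.T @ g - np.diag(np.diag(g.T @ g))
    assert np.allclose(off, 0, atol=1e-8)


def test_null_outlier_fraction_controlled():
    """Pure Balding-Nichols drift, no planted outliers: the BH scan at FDR
    0.01 flags at most 1.5% of SNPs."""
    anc, freqs = syndata.simulate_frequencies(2000, 4, 0.1, seed=2)
    t, _ = syndata.simulate_genotypes(freqs, [10] * 4, seed=3)
    res, outliers = structure.pca_and_outliers(t, K=3, fdr=0.01)
    assert len(outliers) / len(res.tested_sites) <= 0.015


def test_factorization_k1_degenerates_to_mean():
    anc, freqs = syndata.simulate_frequencies(200, 2, 0.05, seed=4)
    t, _ = syndata.simulate_genotypes(freqs, [8, 8], seed=5)
    res = structure.admixture_factorization(t, K_range=[1], seed=0)
    assert res.K == 1
    np.testing.assert_allclose(res.Q, 1.0, atol=1e-9)
    g = structure.dosage_matrix(t) / 2.0
    assert np.corrcoef(res.F[:, 0], g.mean(axis=0))[0, 1] > 0.99


def test_factorization_recovers_two_diverged_pops():
    anc, freqs = syndata.simulate_frequencies(800, 2, 0.5, seed=6)
    t, _ = syndata.simulate_genotypes(freqs, [10, 10], seed=7)
    res = structure.admixture_factorization(t, K_range=[1, 2, 3, 4], seed=1)
    assert res.K == 2
    assert np.all(res.Q.max(axis=1) >= 0.95)
    # simplex invariant at the solution
    np.testing.assert_allclose(res.Q.sum(axis=1), 1.0, atol=1e-8)
    assert np.all(res.Q >= 0)


def test_factorization_objective_monotone():
    anc, freqs = syndata.simulate_frequencies(150, 3, 0.2, seed=8)
    t, _ = syndata.simulate_genotypes(freqs, [6, 6, 6], seed=9,
                                      missing_rate=0.05)
    res = structure.admixture_factorization(t, K_range=[3], seed=2)
    obj = np.array(res.objective)
    assert np.all(np.diff(obj) <= 1e-9)


def test_factorization_determinism():
    anc, freqs = syndata.simulate_frequencies(100, 2, 0.3, seed=10)
    t, _ = syndata.simulate_genotypes(freqs, [5, 5], seed=11)
    a = structure.admixture_factorization(t, K_range=[2], seed=3)
    b = structure.admixture_factorization(t, K_range=[2], seed=3)
    np.testing.assert_array_equal(a.Q, b.Q)
    np.testing.assert_array_equal(a.F, b.F)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def additive_four_taxon_matrix():
    # unrooted tree: A,B on one side, C,D on the other, internal branch 1
    # external branches: A=1, B=2, C=3, D=4
    D = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0]], dtype=float)
    return pd.DataFrame(D, index=list("ABCD"), columns=list("ABCD"))


def _skbio_tree(newick):
    from skbio import TreeNode

    return TreeNode.read(io.StringIO(newick))


def _split_of(newick):
    """The non-trivial bipartition of a 4-taxon unrooted tree."""
    tree = _skbio_tree(newick)
    for node in tree.non_tips():
        tips = frozenset(t.name for t in node.tips())
        if len(tips) == 2:
            return tips
    return None


def test_nj_recovers_additive_tree_and_lengths():
    D = additive_four_taxon_matrix()
    nwk = structure.neighbor_joining(D)
    assert _split_of(nwk) in ({frozenset({"A", "B"}), frozenset({"C", "D"})})
    # patristic distances on the recovered tree reproduce the input exactly
    tree = _skbio_tree(nwk)
    for a in "ABCD":
        for b in "ABCD":
            if a < b:
                d = tree.find(a).distance(tree.find(b))
                assert d == pytest.approx(D.loc[a, b], abs=1e-9)


def test_nj_matches_skbio_on_random_distances():
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(12)
    pts = rng.normal(size=(6, 4))
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    labels = [f"T{i}" for i in range(6)]
    ours = _skbio_tree(structure.neighbor_joining(
        pd.DataFrame(D, index=labels, columns=labels)))
    ref = skbio_nj(DistanceMatrix(D, ids=labels))
    assert ours.compare_rfd(ref) == 0.0


def test_nj_three_taxa_closed_form():
    D = pd.DataFrame([[0, 4, 6], [4, 0, 8], [6, 8, 0]],
                     index=list("XYZ"), columns=list("XYZ"))
    tree = _skbio_tree(structure.neighbor_joining(D))
    # three-point formulas: x=(4+6-8)/2=1, y=(4+8-6)/2=3, z=(6+8-4)/2=5
    assert tree.find("X").length == pytest.approx(1.0)
    assert tree.find("Y").length == pytest.approx(3.0)
    assert tree.find("Z").length == pytest.approx(5.0)


def test_nj_rejects_bad_input():
    D = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
    D.iloc[0, 1] = np.nan
    with pytest.raises(ValueError):
        structure.neighbor_joining(D)
    with pytest.raises(ValueError):
        structure.neighbor_joining(pd.DataFrame([[0.0]], index=["a"],
                                                columns=["a"]))


def test_allele_sharing_distance_extremes():
    gt = np.array([[0, 0, 0], [2, 2, 2], [0, 0, 0]], np.int8)
    D = structure.allele_sharing_distance(make_table(gt))
    assert D.iloc[0, 1] == pytest.approx(1.0)
    assert D.iloc[0, 2] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# Partition and the adaptive/neutral FST contrast
# ---------------------------------------------------------------------------

def test_partition_set_arithmetic():
    part = structure.partition_loci({1, 2, 3}, {2, 3, 4}, set(range(1, 6)))
    assert part.adaptive == {2, 3}
    assert part.neutral == {1, 4, 5}
    assert structure.partition_loci(set(), {1}, {1, 2}).adaptive == set()
    full = structure.partition_loci({1, 2}, {1, 2}, {1, 2})
    assert full.neutral == set()
    with pytest.raises(ValueError):
        structure.partition_loci({9}, set(), {1})


def test_adaptive_fst_exceeds_neutral_fst():
    """With planted strongly differentiated sites, the intersection scan
    partition yields adaptive-loci FST >= neutral-loci FST."""
    rng = np.random.default_rng(13)
    anc, weak = syndata.simulate_frequencies(500, 2, 0.05, seed=14)
    _, strong = syndata.simulate_frequencies(40, 2, 0.7, seed=15)
    freqs = np.vstack([strong, weak])
    t, pm = syndata.simulate_genotypes(freqs, [12, 12], seed=16)
    res, pca_hits = structure.pca_and_outliers(t, K=1, fdr=0.05)
    adm = structure.admixture_factorization(t, K_range=[2], seed=4)
    fact_hits = structure.factorization_outliers(t, adm, fdr=0.05)
    part = structure.partition_loci(pca_hits, fact_hits,
                                    set(range(t.n_sites)))
    assert part.adaptive
    mask_a = np.zeros(t.n_sites, bool)
    mask_a[sorted(part.adaptive)] = True
    fst_a = popgen.pairwise_fst(t, pm, site_mask=mask_a).iloc[0, 1]
    fst_n = popgen.pairwise_fst(t, pm, site_mask=~mask_a).iloc[0, 1]
    assert fst_a >= fst_n
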