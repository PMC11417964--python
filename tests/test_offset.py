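"""Gradient-forest model and genomic-offset maps."""

import numpy as np
import pandas as pd
import pytest

from consgen import offset, syndata
from consgen.grids import Extent, Grid
from consgen.offset import GFModel
from consgen.variants import MISSING

from conftest import make_table


def manual_gf(curves):
    """GFModel with hand-specified linear cumulative-importance curves.

    ``curves``: var -> (range_min, range_max, total_importance); F_v rises
    linearly from 0 to the total over the range.
    """
    edges, cum, imp = {}, {}, {}
    for v, (lo, hi, tot) in curves.items():
        edges[v] = np.linspace(lo, hi, 201)
        cum[v] = np.linspace(0.0, tot, 201)
        imp[v] = tot
    return GFModel(predictors=list(curves), bin_edges=edges,
                   cum_importance=cum, importance=imp,
                   snp_r2=np.array([1.0]), n_trees=1, seed=0)


def grid_of(values, cell=0.1):
    values = np.asarray(values, dtype=float)
    e = Extent(0.0, values.shape[1] * cell, 0.0, values.shape[0] * cell, cell)
    return Grid(values, e)


def test_offset_zero_when_future_equals_current():
    gf = manual_gf({"a": (0, 1, 0.6), "b": (0, 1, 0.4)})
    cur = {"a": grid_of(np.random.default_rng(0).random((5, 5))),
           "b": grid_of(np.random.default_rng(1).random((5, 5)))}
    out = offset.genomic_offset(gf, cur, {"g1": cur, "g2": cur})
    assert np.all(out.combined.values == 0)
    for g in out.per_gcm.values():
        assert np.all(g.values == 0)


def test_single_active_predictor_is_absolute_difference():
    gf = manual_gf({"a": (0, 1, 1.0), "b": (0, 1, 0.0)})
    cur = {"a": grid_of([[0.2]]), "b": grid_of([[0.5]])}
    fut = {"a": grid_of([[0.7]]), "b": grid_of([[0.1]])}
    out = offset.genomic_offset(gf, cur, {"g": fut})
    # F_a is linear with unit total: |F(0.7) - F(0.2)| = 0.5
    assert out.combined.values[0, 0] == pytest.approx(0.5)


def test_pythagorean_combination():
    gf = manual_gf({"a": (0, 1, 1.0), "b": (0, 1, 1.0)})
    cur = {"a": grid_of([[0.1]]), "b": grid_of([[0.2]])}
    fut = {"a": grid_of([[0.4]]), "b": grid_of([[0.6]])}  # deltas 0.3, 0.4
    out = offset.genomic_offset(gf, cur, {"g": fut})
    assert out.combined.values[0, 0] == pytest.approx(0.5)


def test_offset_symmetric_and_triangle_inequality():
    gf = manual_gf({"a": (0, 1, 0.7), "b": (0, 1, 0.3)})
    rng = np.random.default_rng(2)
    s1 = {v: grid_of(rng.random((4, 4))) for v in "ab"}
    s2 = {v: grid_of(rng.random((4, 4))) for v in "ab"}
    s3 = {v: grid_of(rng.random((4, 4))) for v in "ab"}
    d12 = offset.genomic_offset(gf, s1, {"g": s2}).combined.values
    d21 = offset.genomic_offset(gf, s2, {"g": s1}).combined.values
    d13 = offset.genomic_offset(gf, s1, {"g": s3}).combined.values
    d32 = offset.genomic_offset(gf, s3, {"g": s2}).combined.values
    np.testing.assert_allclose(d12, d21)
    assert np.all(d12 <= d13 + d32 + 1e-12)


def test_extent_mismatch_rejected():
    gf = manual_gf({"a": (0, 1, 1.0)})
    cur = {"a": grid_of([[0.1]])}
    fut = {"a": grid_of([[0.1, 0.2]])}
    with pytest.raises(ValueError):
        offset.genomic_offset(gf, cur, {"g": fut})


def test_values_beyond_training_range_are_clamped():
    gf = manual_gf({"a": (0, 1, 1.0)})
    cur = {"a": grid_of([[0.9]])}
    fut = {"a": grid_of([[5.0]])}  # beyond range: clamps to F(1)
    out = offset.genomic_offset(gf, cur, {"g": fut})
    assert out.combined.values[0, 0] == pytest.approx(0.1)


def test_gcm_weights_average():
    gf = manual_gf({"a": (0, 1, 1.0)})
    cur = {"a": grid_of([[0.0]])}
    futA = {"a": grid_of([[0.2]])}
    futB = {"a": grid_of([[0.6]])}
    out = offset.genomic_offset(gf, cur, {"A": futA, "B": futB},
                                weights={"A": 3.0, "B": 1.0})
    assert out.combined.values[0, 0] == pytest.approx(0.75 * 0.2 + 0.25 * 0.6)


def test_maf_per_population_filters_and_flips():
    # site 0: global alt freq 0.8 -> minor allele is REF, frequencies flipped
    # site 1: global MAF 0.1, not above the 10% floor -> dropped
    gt = np.array([[2, 0], [2, 0], [2, 0], [1, 1], [1, 0]], np.int8)
    pm = pd.DataFrame({"sample_id": [f"S{i+1}" for i in range(5)],
                       "population_id": ["A", "A", "A", "B", "B"]})
    out = offset.maf_per_population(make_table(gt), pm, maf_min=0.10)
    assert out.shape == (1, 2)
    assert out.attrs["site_index"].tolist() == [0]
    assert out.iloc[0]["A"] == pytest.approx(0.0)       # flipped from 1.0
    assert out.iloc[0]["B"] == pytest.approx(1 - 2 / 4)


def _driver_fixture(seed=3, n_snps=60, n_pops=12):
    """Per-population frequencies driven by BIO1; BIO2-BIO4 inert."""
    rng = np.random.default_rng(seed)
    env = pd.DataFrame({"BIO1": np.linspace(-1.5, 1.5, n_pops),
                        "BIO2": rng.standard_normal(n_pops),
                        "BIO3": rng.standard_normal(n_pops),
                        "BIO4": rng.standard_normal(n_pops)},
                       index=[f"P{k+1}" for k in range(n_pops)])
    from scipy.special import expit

    centers = rng.uniform(-1, 1, n_snps)
    f = expit(2.0 * (env["BIO1"].to_numpy()[None, :] - centers[:, None]))
    f = np.clip(f + rng.normal(0, 0.03, f.shape), 0, 1)
    freqs = pd.DataFrame(f, columns=env.index)
    return freqs, env


def test_importance_concentrates_on_the_driver():
    freqs, env = _driver_fixture()
    gf = offset.fit_gradient_forest(freqs, env, n_trees=50, seed=1)
    inert = max(gf.importance[v] for v in ("BIO2", "BIO3", "BIO4"))
    assert gf.importance["BIO1"] > inert
    # inert predictors' cumulative curves stay comparatively flat
    assert inert < 0.5 * gf.importance["BIO1"]


def test_gf_deterministic_under_seed():
    freqs, env = _driver_fixture(seed=4, n_snps=20)
    a = offset.fit_gradient_forest(freqs, env, n_trees=30, seed=9)
    b = offset.fit_gradient_forest(freqs, env, n_trees=30, seed=9)
    for v in a.predictors:
        np.testing.assert_array_equal(a.cum_importance[v], b.cum_importance[v])


def test_permuted_responses_have_low_r2():
    freqs, env = _driver_fixture(seed=5, n_snps=100, n_pops=24)
    rng = np.random.default_rng(6)
    shuffled = freqs.copy()
    for j in range(len(shuffled)):
        shuffled.iloc[j] = rng.permutation(shuffled.iloc[j].to_numpy())
    try:
        gf = offset.fit_gradient_forest(shuffled, env, n_trees=50, seed=2)
        r2 = gf.snp_r2[np.isfinite(gf.snp_r2)]
    except ValueError:  # every forest at R^2 <= 0 is the extreme of the claim
        return
    assert np.mean(r2 <= 0.1) >= 0.95


def test_monotone_shift_increases_offset():
    freqs, env = _driver_fixture(seed=7)
    gf = offset.fit_gradient_forest(freqs, env, n_trees=50, seed=3)
    rng = np.random.default_rng(8)
    base = {v: grid_of(rng.uniform(-1, 1, (6, 6)))
            for v in ("BIO1", "BIO2", "BIO3", "BIO4")}
    medians = []
    for shift in (0.0, 0.5, 1.0):
        fut = dict(base)
        fut["BIO1"] = grid_of(base["BIO1"].values + shift)
        out = offset.genomic_offset(gf, base, {"g": fut})
        medians.append(np.median(out.combined.values))
    assert medians[0] <= medians[1] <= medians[2]
    assert medians[2] > medians[0]


def test_go_declines_with_altitude_on_default_landscape():
    """The generator's climate-favored derived alleles are rare and rise
    toward the warm (low-altitude) end of the gradient, so under the default
    terrain-amplified warming the per-population GO of a gradient forest on
    the linked sites correlates negatively with altitude."""
    from consgen import gea

    cfg = syndata.SimulationConfig(
        n_pops=16, samples_per_pop=[10] * 16, n_sites=800, n_chroms=3,
        rng_seed=22, grid_shape=(20, 20), missing_rate=0.03)
    d = syndata.simulate_dataset(cfg)
    freqs, _ = gea.population_frequencies(d.table, d.pop_map)
    resp = freqs.iloc[d.truth.env_linked_sites].reset_index(drop=True)
    env_vars = [c for c in d.env.columns if c.startswith("BIO")]
    gf = offset.fit_gradient_forest(resp, d.env[env_vars], n_trees=60, seed=5)
    om = offset.genomic_offset(gf, d.landscape.current, d.landscape.future)
    pts = offset.offset_at_points(om, d.env[["lon", "lat"]],
                                  altitude=d.env["altitude"])
    assert pts.attrs["altitude_correlation"] < 0
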