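import numpy as np
import pandas as pd
import pytest

from consgen import syndata
from consgen.variants import MISSING, VariantTable


def make_table(gt, chrom=None, pos=None, dp=10, gq=40, ref=None, alt=None,
               samples=None, multiallelic=None):
    """Small VariantTable from a (samples x sites) dosage array."""
    gt = np.asarray(gt, dtype=np.int8)
    n, m = gt.shape
    chrom = np.asarray(chrom) if chrom is not None else np.array(["chr1"] * m)
    pos = (np.asarray(pos, np.int64) if pos is not None
           else np.arange(1, m + 1, dtype=np.int64))
    dp = np.full(gt.shape, dp, np.int32) if np.isscalar(dp) else np.asarray(dp, np.int32)
    gq = np.full(gt.shape, gq, np.int32) if np.isscalar(gq) else np.asarray(gq, np.int32)
    return VariantTable(
        chrom=chrom, pos=pos,
        ref=np.asarray(ref) if ref is not None else np.array(["A"] * m),
        alt=np.asarray(alt) if alt is not None else np.array(["T"] * m),
        gt=gt, dp=dp, gq=gq,
        samples=samples or [f"S{i + 1}" for i in range(n)],
        multiallelic=(np.asarray(multiallelic, bool)
                      if multiallelic is not None else None))


@pytest.fixture(scope="session")
def demo_config():
    return syndata.SimulationConfig(
        n_pops=6, samples_per_pop=[8] * 6, n_sites=800, n_chroms=3,
        chrom_length=10_000_000, rng_seed=11, grid_shape=(20, 20),
        n_presences=120, missing_rate=0.03)


@pytest.fixture(scope="session")
def demo_data(demo_config):
    """One small simulated dataset shared across the suite."""
    return syndata.simulate_dataset(demo_config)


@pytest.fixture(scope="session")
def demo_filtered(demo_data):
    from consgen import variants

    table, report = variants.apply_filter_ladder(demo_data.table)
    return table, report


@pytest.fixture(scope="session")
def demo_annotation_filtered(demo_data, demo_filtered):
    table, _ = demo_filtered
    ann = demo_data.annotation
    idx = pd.MultiIndex.from_arrays([table.chrom, table.pos])
    ai = pd.MultiIndex.from_arrays([ann["chrom"], ann["pos"]])
    return ann.loc[ai.isin(idx)].reset_index(drop=True)


@pytest.fixture(scope="session")
def filtered_site_origin(demo_data, demo_filtered):
    """Filtered-site index -> original site index (for truth lookups)."""
    table, _ = demo_filtered
    orig = {(c, p): i for i, (c, p)
            in enumerate(zip(demo_data.table.chrom, demo_data.table.pos))}
    return np.array([orig[(c, p)] for c, p in zip(table.chrom, table.pos)])
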