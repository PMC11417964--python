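"""Synthetic data generator with recorded ground truth.

Every input the pipeline consumes can be generated here: a multi-population
genotype matrix diverged at a target FST under the Balding-Nichols model,
planted identical-by-descent tracts (runs of homozygosity), deleterious
alleles at low derived frequency, environment-linked allele frequencies with
a logistic link, bioclim-style climate grids for current and future periods,
and occurrence records drawn from a known suitability surface.  The
:class:`TruthBundle` records what was planted so downstream detectors can be
scored against it.

The default configuration mirrors the study design this toolkit was built
around: 16 populations of ~10 diploids (165 genomes total in the original
survey), ~6.5x mean sequencing depth, 13 chromosomes, a 10-year generation
time species, and 19 bioclim-style variables reduced to a handful of drivers.
Site counts and chromosome lengths are desk-scale so a full pipeline run
completes in minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .grids import Extent, Grid, write_grid
from .variants import MISSING, VariantTable, write_vcf

logger = logging.getLogger(__name__)

SITE_CLASSES = ("intergenic", "intron", "cds")


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_pops: int = 16
    samples_per_pop: list = None          # default: 10 per population
    n_sites: int = 5000
    n_chroms: int = 13
    chrom_length: int = 10_000_000
    fst_target: float = 0.15
    frac_deleterious: float = 0.02
    frac_synonymous: float = 0.05
    missing_rate: float = 0.05
    mean_depth: float = 6.5
    roh_plan: list = None                 # (individual, chrom, start, end); None = auto
    env_link_plan: list = None            # (site index, env var, slope); None = auto
    n_env: int = 4
    env_link_slope: float = 2.0
    n_linked_sites: int = 25
    grid_shape: tuple = (40, 40)
    n_presences: int = 200
    rng_seed: int = 0
    # heterozygosity suppression per site class, emulating purifying selection
    class_diversity_scaling: dict = field(default_factory=lambda: {
        "intergenic": 1.0, "fold4": 0.8, "intron": 0.6, "cds": 0.45, "fold0": 0.3})

    def __post_init__(self):
        if self.samples_per_pop is None:
            self.samples_per_pop = [10] * self.n_pops
        if len(self.samples_per_pop) != self.n_pops:
            raise ValueError("samples_per_pop length must equal n_pops")
        if not (0 <= self.fst_target < 1):
            raise ValueError("fst_target must lie in [0, 1)")
        if self.frac_deleterious + self.frac_synonymous > 1:
            raise ValueError("class fractions must sum to <= 1")


@dataclass
class TruthBundle:
    """Ground truth recorded while generating; queryable by tests."""

    ancestral_freqs: np.ndarray = None
    pop_freqs: np.ndarray = None                  # (n_sites, n_pops)
    roh_intervals: dict = field(default_factory=dict)   # individual -> [(chrom, start, end)]
    env_links: list = field(default_factory=list)       # (site index, env var, slope)
    suitability_params: dict = None
    suitability_grid: "Grid" = None

    @property
    def env_linked_sites(self):
        return sorted({s for s, _, _ in self.env_links})


# ---------------------------------------------------------------------------
# Allele frequencies and genotypes
# ---------------------------------------------------------------------------

def simulate_frequencies(n_sites: int, n_pops: int, fst_target: float,
                         seed=None, rng: np.random.Generator | None = None,
                         ancestral: np.ndarray | None = None,
                         low: float = 0.05, high: float = 0.95):
    """Balding-Nichols population frequencies around uniform ancestral p.

    Each population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), whose mean
    is p and whose variance is F p(1-p) — the definition of FST.  F = 0
    degenerates to every population equal to its ancestral frequency.
    Ancestral support [low, high] keeps sites informative after MAF filtering.

    Returns ``(ancestral, pop_freqs)`` with shapes (n_sites,), (n_sites, n_pops).
    """
    if not 0 <= fst_target < 1:
        raise ValueError("fst_target must lie in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    p = (rng.uniform(low, high, size=n_sites)
         if ancestral is None else np.asarray(ancestral, dtype=float))
    if fst_target == 0:
        return p, np.repeat(p[:, None], n_pops, axis=1)
    ratio = (1 - fst_target) / fst_target
    a = p * ratio
    b = (1 - p) * ratio
    freqs = rng.beta(a[:, None], b[:, None], size=(n_sites, n_pops))
    return p, freqs


def simulate_genotypes(pop_freqs: np.ndarray, samples_per_pop: list[int],
                       seed=None, rng: np.random.Generator | None = None,
                       missing_rate: float = 0.0, mean_depth: float = 6.5,
                       chrom: np.ndarray | None = None,
                       pos: np.ndarray | None = None,
                       low_gq_frac: float = 0.1) -> tuple[VariantTable, pd.DataFrame]:
    """Draw diploid genotypes Binomial(2, freq) per individual under HWE.

    Per-genotype depth is Poisson(``mean_depth``) and genotype quality is a
    mixture (a ``low_gq_frac`` fraction uniform on [10, 60), the rest uniform
    on [30, 60)) so the depth/quality recoding branch of the filter ladder is
    exercised without dominating missingness.  Returns the
    :class:`VariantTable` and a sample->population map.
    """
    pop_freqs = np.asarray(pop_freqs, dtype=float)
    if np.any(pop_freqs < 0) or np.any(pop_freqs > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n_sites, n_pops = pop_freqs.shape
    if len(samples_per_pop) != n_pops:
        raise ValueError("samples_per_pop length mismatch with pop_freqs")
    blocks, samples, pops = [], [], []
    for k, n_k in enumerate(samples_per_pop):
        blocks.append(rng.binomial(2, pop_freqs[:, k], size=(n_k, n_sites)))
        samples += [f"P{k + 1}_{i + 1}" for i in range(n_k)]
        pops += [f"P{k + 1}"] * n_k
    gt = np.concatenate(blocks, axis=0).astype(np.int8)
    n = gt.shape[0]
    if missing_rate > 0:
        gt[rng.random(gt.shape) < missing_rate] = MISSING
    dp = rng.poisson(mean_depth, size=gt.shape).astype(np.int32)
    gq = rng.integers(30, 60, size=gt.shape).astype(np.int32)
    low = rng.random(gt.shape) < low_gq_frac
    gq[low] = rng.integers(10, 60, size=int(low.sum()))
    if chrom is None or pos is None:
        chrom = np.array(["chr1"] * n_sites)
        pos = np.arange(1, n_sites + 1, dtype=np.int64)
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n_sites)]
    alt = bases[(np.char.find("ACGT", ref.astype(str)) +
                 rng.integers(1, 4, n_sites)) % 4]
    table = VariantTable(chrom=np.asarray(chrom), pos=np.asarray(pos, np.int64),
                         ref=ref, alt=alt, gt=gt, dp=dp, gq=gq, samples=samples)
    pop_map = pd.DataFrame({"sample_id": samples, "population_id": pops})
    return table, pop_map


def assign_positions(n_sites: int, n_chroms: int, chrom_length: int,
                     rng: np.random.Generator):
    """Spread sites over chromosomes at sorted unique random positions."""
    per = np.full(n_chroms, n_sites // n_chroms)
    per[: n_sites % n_chroms] += 1
    chrom, pos = [], []
    for c in range(n_chroms):
        p = np.sort(rng.choice(np.arange(1, chrom_length + 1), size=per[c],
                               replace=False))
        chrom += [f"chr{c + 1}"] * per[c]
        pos.append(p)
    return np.array(chrom), np.concatenate(pos) if pos else np.array([], np.int64)


# ---------------------------------------------------------------------------
# Planted signals
# ---------------------------------------------------------------------------

def _merge_intervals(ivals):
    out = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def plant_roh_tracts(table: VariantTable, roh_plan, chrom_length: int,
                     rng: np.random.Generator | None = None,
                     truth: TruthBundle | None = None, seed=None) -> TruthBundle:
    """Make individuals homozygous over planned tracts (in place).

    Inside each tract every non-missing genotype of the individual is set
    homozygous for one haplotype sampled from its own two alleles, so no
    heterozygote survives and allele frequencies are roughly preserved.
    Overlapping tracts for one individual are merged with a warning.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    truth = truth if truth is not None else TruthBundle()
    by_ind: dict[tuple, list] = {}
    for ind, chrom, start, end in roh_plan:
        if start < 1 or end > chrom_length or end < start:
            raise ValueError(f"tract ({chrom}:{start}-{end}) outside bounds")
        by_ind.setdefault((ind, chrom), []).append((int(start), int(end)))
    for (ind, chrom), ivals in by_ind.items():
        merged = _merge_intervals(ivals)
        if len(merged) < len(ivals):
            logger.warning("overlapping ROH tracts for %s on %s merged", ind, chrom)
        i = table.samples.index(ind) if isinstance(ind, str) else int(ind)
        name = table.samples[i]
        for start, end in merged:
            inside = (table.chrom == chrom) & (table.pos >= start) & (table.pos <= end)
            idx = np.flatnonzero(inside)
            g = table.gt[i, idx]
            hap = np.where(g == 1, 2 * rng.integers(0, 2, size=len(idx)),
                           g)  # hom calls keep their allele
            hap = np.where(g == MISSING, MISSING, hap)
            table.gt[i, idx] = hap.astype(np.int8)
            truth.roh_intervals.setdefault(name, []).append((chrom, start, end))
    return truth


def simulate_environment_links(pop_freqs: np.ndarray, env_table: pd.DataFrame,
                               env_link_plan, ancestral: np.ndarray | None = None,
                               truth: TruthBundle | None = None) -> np.ndarray:
    """Rewrite linked sites' population frequencies with a logistic link.

    For plan entry (site j, variable v, slope b) the frequency in population
    k becomes expit(logit(p_j) + b * z_vk) with z the standardized variable,
    so b = 0 leaves the site untouched.  Returns a modified copy.
    """
    freqs = np.asarray(pop_freqs, dtype=float).copy()
    truth = truth if truth is not None else TruthBundle()
    z = (env_table - env_table.mean()) / env_table.std(ddof=0)
    for site, var, slope in env_link_plan:
        p0 = (ancestral[site] if ancestral is not None
              else float(np.clip(freqs[site].mean(), 0.02, 0.98)))
        freqs[site] = expit(logit(np.clip(p0, 1e-6, 1 - 1e-6))
                            + slope * z[var].to_numpy())
        truth.env_links.append((int(site), str(var), float(slope)))
    return freqs


# ---------------------------------------------------------------------------
# Landscape: climate grids, suitability, occurrences
# ---------------------------------------------------------------------------

@dataclass
class LandscapeBundle:
    current: dict            # var -> Grid
    future: dict             # gcm -> var -> Grid
    occurrences: pd.DataFrame  # lon, lat
    altitude: Grid
    truth: TruthBundle


def _smooth_field(shape, rng, sigma=6.0):
    """Standardized smooth random field (Gaussian-filtered white noise)."""
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    return (f - f.mean()) / f.std()


def simulate_landscape(grid_shape=(40, 40), n_env: int = 4,
                       suitability_params: dict | None = None,
                       n_presences: int = 200, seed=None,
                       rng: np.random.Generator | None = None,
                       future_shifts: dict | None = None,
                       warming_amplification: float = 0.5,
                       extent: Extent | None = None) -> LandscapeBundle:
    """Smooth climate fields, a known suitability surface and presences.

    Future grids are ``current + shift`` per variable and climate model
    (a zero shift reproduces the current grids exactly).  Presences are
    sampled with probability proportional to a logistic suitability of the
    standardized fields, whose parameters are recorded as truth.
    """
    if n_env < 2:
        raise ValueError("need at least 2 environmental variables")
    rng = rng if rng is not None else np.random.default_rng(seed)
    extent = extent or Extent(xmin=104.0, xmax=108.0, ymin=22.0, ymax=26.0,
                              cell_size=4.0 / grid_shape[0])
    names = [f"BIO{i + 1}" for i in range(n_env)]
    current = {v: Grid(_smooth_field(grid_shape, rng), extent) for v in names}
    if suitability_params is None:
        # cool-adapted species: suitability declines along the first
        # (temperature-like) field, so the default future warming shift
        # shrinks the favorable envelope
        coef = np.zeros(n_env)
        coef[0], coef[1] = -2.0, -1.0
        suitability_params = {"intercept": -0.5, "coef": coef}
    coef = np.asarray(suitability_params["coef"], dtype=float)
    stack = np.stack([current[v].values for v in names], axis=-1)
    suit = expit(suitability_params["intercept"] + stack @ coef)
    # occurrences ~ suitability
    prob = (suit / suit.sum()).ravel()
    cells = rng.choice(prob.size, size=n_presences, replace=True, p=prob)
    rows, cols = np.unravel_index(cells, grid_shape)
    xy = [current[names[0]].cell_center(r, c) for r, c in zip(rows, cols)]
    occ = pd.DataFrame(xy, columns=["lon", "lat"])
    # future scenarios: per-GCM shifts on the first (temperature-like) field,
    # amplified where that field is already warm — valley floors at low
    # altitude warm more than ridgetops, so the shift is spatially graded
    if future_shifts is None:
        # 0.4-0.6 SD of the spatial field per climate model: strong enough to
        # move the favorable envelope, modest enough that most locations'
        # future climates remain inside the calibration range
        future_shifts = {f"GCM{m + 1}": {names[0]: 0.4 + 0.1 * m} for m in range(3)}
    amp = 1.0 + warming_amplification * current[names[0]].values
    future = {}
    for gcm, shifts in future_shifts.items():
        future[gcm] = {v: Grid(current[v].values
                               + shifts.get(v, 0.0)
                               * (amp if v == names[0] else 1.0), extent)
                       for v in names}
    # altitude strongly anti-correlated with the first (temperature-like) field
    alt = Grid(1000.0 - 400.0 * current[names[0]].values
               + 50.0 * _smooth_field(grid_shape, rng, sigma=3.0), extent)
    truth = TruthBundle(suitability_params=suitability_params,
                        suitability_grid=Grid(suit, extent))
    return LandscapeBundle(current=current, future=future, occurrences=occ,
                           altitude=alt, truth=truth)


# ---------------------------------------------------------------------------
# Site annotation
# ---------------------------------------------------------------------------

def build_annotation(table: VariantTable, frac_deleterious: float,
                     frac_synonymous: float, rng: np.random.Generator) -> pd.DataFrame:
    """Per-site class, degeneracy, ancestral allele and SIFT-like score.

    Deleterious sites are 0-fold CDS with score < 0.05, synonymous sites are
    4-fold CDS with no score; remaining CDS sites are 0-fold tolerated.  The
    ancestral allele is REF for most sites, ALT for some, NA for a few.
    """
    m = table.n_sites
    n_del = int(round(frac_deleterious * m))
    n_syn = int(round(frac_synonymous * m))
    n_tol = int(round(0.08 * m))
    idx = rng.permutation(m)
    cls = np.full(m, "intergenic", dtype=object)
    deg = np.full(m, "NA", dtype=object)
    sift = np.full(m, np.nan)
    i = 0
    for n_k, klass, dg in ((n_del, "cds", "fold0"), (n_syn, "cds", "fold4"),
                           (n_tol, "cds", "fold0")):
        sel = idx[i:i + n_k]
        cls[sel], deg[sel] = klass, dg
        i += n_k
    sift[idx[:n_del]] = rng.uniform(0.0, 0.05, n_del)
    sift[idx[n_del + n_syn:i]] = rng.uniform(0.05, 1.0, n_tol)
    n_intron = int(round(0.25 * m))
    cls[idx[i:i + n_intron]] = "intron"
    anc = np.where(rng.random(m) < 0.90, "REF",
                   np.where(rng.random(m) < 0.5, "ALT", "NA"))
    return pd.DataFrame({"chrom": table.chrom, "pos": table.pos, "class": cls,
                         "degeneracy": deg, "ancestral": anc, "sift_score": sift})


def _scale_heterozygosity(freqs: np.ndarray, factor: float) -> np.ndarray:
    """Shrink frequencies toward the nearest boundary, reducing diversity."""
    return np.where(freqs < 0.5, freqs * factor, 1.0 - (1.0 - freqs) * factor)


# ---------------------------------------------------------------------------
# Whole-bundle assembly and serialization
# ---------------------------------------------------------------------------

@dataclass
class SimulatedData:
    config: SimulationConfig
    table: VariantTable
    pop_map: pd.DataFrame
    annotation: pd.DataFrame
    env: pd.DataFrame          # per-population variables + lon/lat/altitude
    landscape: LandscapeBundle
    truth: TruthBundle


def simulate_dataset(config: SimulationConfig) -> SimulatedData:
    """Run the full generator under one seed; bit-reproducible."""
    rng = np.random.default_rng(config.rng_seed)
    land = simulate_landscape(config.grid_shape, n_env=config.n_env,
                              n_presences=config.n_presences, rng=rng)
    names = list(land.current)
    # population sites on the landscape
    nrow, ncol = config.grid_shape
    cells = rng.choice(nrow * ncol, size=config.n_pops, replace=False)
    rows, cols = np.unravel_index(cells, (nrow, ncol))
    env = pd.DataFrame({v: [land.current[v].values[r, c] for r, c in zip(rows, cols)]
                        for v in names},
                       index=[f"P{k + 1}" for k in range(config.n_pops)])
    coords = [land.current[names[0]].cell_center(r, c) for r, c in zip(rows, cols)]
    env["lon"] = [x for x, _ in coords]
    env["lat"] = [y for _, y in coords]
    env["altitude"] = [land.altitude.values[r, c] for r, c in zip(rows, cols)]

    anc, freqs = simulate_frequencies(config.n_sites, config.n_pops,
                                      config.fst_target, rng=rng)
    chrom, pos = assign_positions(config.n_sites, config.n_chroms,
                                  config.chrom_length, rng)
    # annotation first so deleterious sites can be pushed to low derived freq
    dummy = VariantTable(chrom=chrom, pos=pos,
                         ref=np.full(config.n_sites, "A"),
                         alt=np.full(config.n_sites, "C"),
                         gt=np.zeros((1, config.n_sites), np.int8),
                         dp=np.zeros((1, config.n_sites), np.int32),
                         gq=np.zeros((1, config.n_sites), np.int32),
                         samples=["_"])
    ann = build_annotation(dummy, config.frac_deleterious, config.frac_synonymous, rng)
    deleterious = (ann["sift_score"] < 0.05).fillna(False).to_numpy()
    if deleterious.any():
        # deleterious derived alleles segregate at low frequency
        ann.loc[deleterious, "ancestral"] = "REF"
        p_low = rng.uniform(0.02, 0.15, int(deleterious.sum()))
        anc[deleterious] = p_low
        _, freqs[deleterious] = simulate_frequencies(
            int(deleterious.sum()), config.n_pops, config.fst_target,
            rng=rng, ancestral=p_low)
    # purifying-selection-like diversity suppression per site class
    key = np.where(ann["degeneracy"].isin(["fold0", "fold4"]),
                   ann["degeneracy"], ann["class"])
    for klass, factor in config.class_diversity_scaling.items():
        sel = (key == klass) & ~deleterious
        freqs[sel] = _scale_heterozygosity(freqs[sel], factor)

    truth = TruthBundle(ancestral_freqs=anc, pop_freqs=freqs,
                        suitability_params=land.truth.suitability_params,
                        suitability_grid=land.truth.suitability_grid)
    plan = config.env_link_plan
    if plan is None:
        # climate-favored derived alleles are globally rare and frequent only
        # in the warmest populations (range-edge local adaptation), so the
        # ancestral frequency of linked sites is drawn low: allele turnover
        # then concentrates toward the warm, low-altitude end of the gradient
        neutral_idx = np.flatnonzero((key == "intergenic") & ~deleterious)
        chosen = rng.choice(neutral_idx, size=min(config.n_linked_sites,
                                                  len(neutral_idx)), replace=False)
        anc[chosen] = rng.uniform(0.03, 0.12, size=len(chosen))
        var = names[0]
        plan = [(int(j), var, config.env_link_slope) for j in chosen]
    freqs = simulate_environment_links(freqs, env[names], plan,
                                       ancestral=anc, truth=truth)
    truth.pop_freqs = freqs

    table, pop_map = simulate_genotypes(
        freqs, config.samples_per_pop, rng=rng,
        missing_rate=config.missing_rate, mean_depth=config.mean_depth,
        chrom=chrom, pos=pos)
    roh_plan = config.roh_plan
    if roh_plan is None:
        # individuals of the first population carry one 2-Mb tract each
        roh_plan = []
        inbred = [s for s, p in zip(pop_map["sample_id"], pop_map["population_id"])
                  if p == "P1"]
        for s in inbred:
            c = f"chr{rng.integers(1, config.n_chroms + 1)}"
            start = int(rng.integers(1, config.chrom_length - 2_000_000))
            roh_plan.append((s, c, start, start + 2_000_000 - 1))
    if roh_plan:
        plant_roh_tracts(table, roh_plan, config.chrom_length, rng=rng, truth=truth)
    return SimulatedData(config=config, table=table, pop_map=pop_map,
                         annotation=ann, env=env, landscape=land, truth=truth)


def write_bundle(data: SimulatedData, directory: str | Path) -> dict:
    """Serialize every generated input; round-trips through module readers.

    Returns a manifest of written paths.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {}
    try:
        write_vcf(data.table, d / "variants.vcf")
        paths["vcf"] = d / "variants.vcf"
        data.pop_map.to_csv(d / "popmap.tsv", sep="\t", index=False)
        paths["popmap"] = d / "popmap.tsv"
        data.annotation.to_csv(d / "annotation.tsv", sep="\t", index=False,
                               na_rep="NA")
        paths["annotation"] = d / "annotation.tsv"
        data.env.to_csv(d / "environment.csv")
        paths["environment"] = d / "environment.csv"
        data.landscape.occurrences.to_csv(d / "occurrences.csv", index=False)
        paths["occurrences"] = d / "occurrences.csv"
        gdir = d / "grids"
        gdir.mkdir(exist_ok=True)
        for v, g in data.landscape.current.items():
            write_grid(g, gdir / f"current_{v}.txt")
        for gcm, layer in data.landscape.future.items():
            for v, g in layer.items():
                write_grid(g, gdir / f"future_{gcm}_{v}.txt")
        write_grid(data.landscape.altitude, gdir / "altitude.txt")
        paths["grids"] = gdir
    except OSError as exc:
        raise OSError(f"failed writing bundle under {d}: {exc}") from exc
    return paths
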