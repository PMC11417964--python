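"""End-to-end pipeline: simulate -> filter -> popgen/roh/load/structure ->
gea -> offset, plus the independent niche-modeling stage, under one config
with one seed and a provenance manifest.

The pipeline is a plain Python function over the library modules; stages
communicate only through the files and frames a stage declares, and a rerun
with the same config reproduces every deterministic output bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enm, gea, load, offset, popgen, roh, structure, syndata, variants

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One block per stage; defaults follow the documented study values."""

    out_dir: str = "consgen_run"
    seed: int = 0
    simulation: syndata.SimulationConfig = None
    filter: variants.FilterConfig = field(default_factory=variants.FilterConfig)
    roh_min_length: int = 100_000
    roh_min_snps: int = 25
    roh_het_per_mb: float = 1.0
    generation_time: float = 10.0
    gea_q_cut: float = 0.05
    rda_sd_cut: float = 3.0
    rda_n_perm: int = 199
    pca_K: int = 4
    outlier_fdr: float = 0.01
    admixture_K_range: tuple = (1, 2, 3, 4)
    gf_n_trees: int = 100
    gf_maf_min: float = 0.10
    gf_thin_bp: int = 100_000
    enm_reps: int = 2
    enm_pa: int = 500
    enm_pa_reps: int = 2

    def __post_init__(self):
        if self.simulation is None:
            self.simulation = syndata.SimulationConfig(rng_seed=self.seed)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    d = dataclasses.asdict(config)
    d.pop("out_dir", None)  # where results land is not part of the science
    blob = json.dumps(d, default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in dependency order; returns the run directory.

    A stage failure aborts downstream stages but keeps partial outputs.
    ``manifest.json`` records the config hash, seed, stage timings and the
    SHA-256 of every written file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": _config_hash(config), "seed": config.seed,
                "stages": {}}
    t0 = time.time()

    def done(stage):
        manifest["stages"][stage] = round(time.time() - t0, 3)

    try:
        # --- simulate ---------------------------------------------------
        data = syndata.simulate_dataset(config.simulation)
        syndata.write_bundle(data, out / "inputs")
        done("simulate")

        # --- filter -----------------------------------------------------
        table = variants.read_vcf(str(out / "inputs" / "variants.vcf"))
        filtered, report = variants.apply_filter_ladder(table, config.filter)
        (out / "filter_report.json").write_text(json.dumps(report.to_dict()))
        variants.write_vcf(filtered, out / "dataset2.vcf")
        done("filter")

        ann = data.annotation
        in_filtered = pd.MultiIndex.from_arrays([filtered.chrom, filtered.pos])
        ann_idx = pd.MultiIndex.from_arrays([ann["chrom"], ann["pos"]])
        ann_f = ann.loc[ann_idx.isin(in_filtered)].reset_index(drop=True)

        # --- popgen -----------------------------------------------------
        key = popgen.site_class_key(ann_f)
        callable_len = {"whole": config.simulation.n_chroms
                        * config.simulation.chrom_length}
        frac = {k: (key == k).mean() for k in
                ("intergenic", "intron", "cds", "fold0", "fold4")}
        for k, f in frac.items():
            callable_len[k] = max(f * callable_len["whole"], 1.0)
        div = popgen.diversity_stats(filtered, ann_f, callable_len, data.pop_map)
        div.to_csv(out / "diversity.tsv", sep="\t", index=False)
        fst = popgen.pairwise_fst(filtered, data.pop_map)
        fst.to_csv(out / "fst_all.tsv", sep="\t")
        done("popgen")

        # --- roh --------------------------------------------------------
        segs = roh.detect_roh(filtered, min_length=config.roh_min_length,
                              min_snps=config.roh_min_snps,
                              het_per_mb=config.roh_het_per_mb)
        eff_len = _effective_length(filtered)
        summary = roh.froh_and_timing(segs, eff_len, pop_map=data.pop_map,
                                      individuals=filtered.samples,
                                      generation_time=config.generation_time)
        roh.segments_to_bed(segs).to_csv(out / "roh_segments.tsv", sep="\t",
                                         index=False)
        summary.to_csv(out / "roh_summary.tsv", sep="\t", index=False)
        done("roh")

        # --- load -------------------------------------------------------
        effect = load.classify_variants(ann_f)
        metrics = load.load_metrics(filtered, effect, ann_f, data.pop_map)
        metrics["individuals"].to_csv(out / "load_individuals.tsv", sep="\t",
                                      index=False)
        pops = sorted(data.pop_map["population_id"].unique())[:5]
        venn = load.shared_homozygous_deleterious(filtered, effect,
                                                  data.pop_map, pops)
        (out / "venn.json").write_text(json.dumps(
            {"|".join(sorted(k)): v for k, v in venn["regions"].items()}))
        done("load")

        # --- structure --------------------------------------------------
        pca_res, pca_hits = structure.pca_and_outliers(
            filtered, K=config.pca_K, fdr=config.outlier_fdr)
        adm = structure.admixture_factorization(
            filtered, K_range=config.admixture_K_range, seed=config.seed)
        fact_hits = structure.factorization_outliers(
            filtered, adm, fdr=config.outlier_fdr)
        part = structure.partition_loci(pca_hits, fact_hits,
                                        set(range(filtered.n_sites)))
        np.savetxt(out / "pca_scores.tsv", pca_res.scores[:, :config.pca_K],
                   delimiter="\t")
        pd.DataFrame(adm.Q).to_csv(out / "admixture_Q.tsv", sep="\t",
                                   index=False)
        pop_fst = popgen.pairwise_fst(filtered, data.pop_map)
        dist = 1.0 - pop_fst  # population-level NJ input; samples also possible
        tree = structure.neighbor_joining(pop_fst) \
            if pop_fst.shape[0] >= 3 else ""
        (out / "nj_populations.nwk").write_text(tree)
        done("structure")

        # --- gea --------------------------------------------------------
        env_vars = [c for c in data.env.columns
                    if c.startswith("BIO")]
        kept_vars = gea.prune_env(data.env[env_vars])
        freqs, sizes = gea.population_frequencies(filtered, data.pop_map)
        uni = gea.univariate_gea(freqs, data.env[kept_vars], sizes,
                                 q_cut=config.gea_q_cut)
        env_samples = data.env.loc[
            [data.pop_map.set_index("sample_id")["population_id"][s]
             for s in filtered.samples], kept_vars]
        env_samples.index = filtered.samples
        rda = gea.rda_outliers(filtered, env_samples,
                               sd_cut=config.rda_sd_cut,
                               n_perm=config.rda_n_perm, seed=config.seed)
        cand = gea.candidate_set(uni, rda)
        (out / "gea_hits.json").write_text(json.dumps({
            "univariate": sorted(uni.hits), "rda": sorted(rda.hits),
            "candidates": sorted(cand.hits)}))
        done("gea")

        # --- offset -----------------------------------------------------
        thinned = variants.thin_by_distance(filtered, config.gf_thin_bp)
        maf = offset.maf_per_population(thinned, data.pop_map,
                                        maf_min=config.gf_maf_min)
        gf = offset.fit_gradient_forest(maf, data.env[kept_vars],
                                        n_trees=config.gf_n_trees,
                                        seed=config.seed)
        omap = offset.genomic_offset(
            gf, data.landscape.current,
            {g: data.landscape.future[g] for g in data.landscape.future})
        np.savetxt(out / "go_combined.txt", omap.combined.values)
        (out / "gf_importance.json").write_text(json.dumps(gf.importance))
        done("offset")

        # --- enm (independent) ------------------------------------------
        occ_set = enm.prepare_inputs(data.landscape.occurrences,
                                     data.landscape.current,
                                     n_pa=config.enm_pa,
                                     pa_reps=config.enm_pa_reps,
                                     seed=config.seed)
        fits = enm.fit_and_evaluate(occ_set, reps=config.enm_reps,
                                    seed=config.seed)
        scenarios = {"future": data.landscape.future}
        ens = enm.ensemble_and_nsc(fits, data.landscape.current, scenarios)
        np.savetxt(out / "nsc_future.txt", ens.nsc["future"].values)
        ens.metrics.to_csv(out / "enm_metrics.tsv", sep="\t", index=False)
        (out / "enm_summary.json").write_text(json.dumps(
            {"threshold": ens.threshold,
             "area_change_pct": ens.area_change_pct}))
        done("enm")
    finally:
        # stage timings are wall-clock and excluded from the reproducible part
        files = {str(p.relative_to(out)): _sha(p)
                 for p in sorted(out.rglob("*")) if p.is_file()
                 and p.name != "manifest.json"}
        (out / "manifest.json").write_text(json.dumps(
            {"config_hash": manifest["config_hash"], "seed": manifest["seed"],
             "completed_stages": sorted(manifest["stages"]), "files": files},
            indent=1, sort_keys=True))
    return out


def _effective_length(table) -> float:
    """Span from first to last SNP, summed over chromosomes."""
    total = 0.0
    for c in np.unique(table.chrom):
        p = table.pos[table.chrom == c]
        if len(p) > 1:
            total += float(p[-1] - p[0] + 1)
    return max(total, 1.0)
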