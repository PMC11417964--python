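"""Variant tables, VCF I/O and the post-calling filter ladder.

The central container is :class:`VariantTable`: a samples x sites diploid
dosage matrix (0/1/2 alternate-allele copies, -1 = missing) with per-genotype
depth (DP) and genotype quality (GQ), linked to chromosome/position.  The
filter ladder reproduces the standard post-calling cleanup applied to
resequencing SNP calls, in this fixed order:

  (i)   drop sites whose mean coverage is <0.5x or >2x the genome-wide mean
        site coverage;
  (ii)  drop sites on excluded contigs (organelles, unanchored scaffolds);
  (iii) recode individual genotypes with DP<3 or GQ<20 as missing;
  (iv)  keep biallelic SNPs only;
  (v)   drop sites with missing rate >20%  ("dataset 1");
  (vi)  drop sites with minor allele frequency <0.05  ("dataset 2").

Two thinning schemes are provided: physical-distance thinning (one SNP per
window, used ahead of gradient-forest modeling) and greedy sliding-window
LD pruning on r^2 of dosage vectors (PLINK ``--indep-pairwise`` style).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class VariantTable:
    """Diploid genotype matrix with site metadata.

    Attributes
    ----------
    chrom, pos : arrays of length n_sites; ``pos`` is 1-based and strictly
        increasing within each chromosome.
    ref, alt : allele strings per site (``alt`` holds the first ALT; sites
        with more than one ALT are flagged in ``multiallelic``).
    gt : (n_samples, n_sites) int8 dosage of the alternate allele, -1 missing.
    dp, gq : per-genotype depth and genotype quality, same shape as ``gt``.
    samples : sample identifiers, row order of ``gt``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    samples: list[str]
    multiallelic: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.multiallelic is None:
            self.multiallelic = np.zeros(self.n_sites, dtype=bool)
        self._check_sorted()

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return self.gt.shape[0]

    def _check_sorted(self):
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c!r}")

    def take_sites(self, index) -> "VariantTable":
        """Subset sites by boolean mask or integer index, keeping order."""
        return VariantTable(
            chrom=self.chrom[index], pos=self.pos[index],
            ref=self.ref[index], alt=self.alt[index],
            gt=self.gt[:, index], dp=self.dp[:, index], gq=self.gq[:, index],
            samples=list(self.samples), multiallelic=self.multiallelic[index],
        )

    def copy(self) -> "VariantTable":
        return VariantTable(
            chrom=self.chrom.copy(), pos=self.pos.copy(), ref=self.ref.copy(),
            alt=self.alt.copy(), gt=self.gt.copy(), dp=self.dp.copy(),
            gq=self.gq.copy(), samples=list(self.samples),
            multiallelic=self.multiallelic.copy(),
        )

    # -- per-site summaries ---------------------------------------------
    def missing_rate(self) -> np.ndarray:
        return np.mean(self.gt == MISSING, axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency over non-missing haplotypes."""
        called = self.gt != MISSING
        n_hap = 2 * called.sum(axis=0)
        alt = np.where(called, self.gt, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_hap > 0, alt / np.maximum(n_hap, 1), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def site_mean_depth(self) -> np.ndarray:
        return self.dp.mean(axis=0)


@dataclass
class FilterConfig:
    """Thresholds of the filter ladder; defaults are the standard values."""

    min_cov_factor: float = 0.5
    max_cov_factor: float = 2.0
    excluded_contigs: tuple = ()
    min_depth: int = 3
    min_gq: int = 20
    max_missing: float = 0.2
    min_maf: float = 0.05


@dataclass
class FilterReport:
    """Ordered per-rule removal counts; removed + surviving = input."""

    input_sites: int
    removed: dict  # rule name -> count, insertion order = application order
    surviving: int

    def __post_init__(self):
        assert self.input_sites == self.surviving + sum(self.removed.values())

    def to_dict(self) -> dict:
        return {"input_sites": self.input_sites, "removed": dict(self.removed),
                "surviving": self.surviving}


RULE_NAMES = ("coverage", "excluded_contig", "biallelic", "missing_rate", "maf")


def apply_filter_ladder(table: VariantTable, config: FilterConfig | None = None
                        ) -> tuple[VariantTable, FilterReport]:
    """Apply the six-rule post-calling filter ladder in its fixed order.

    Rule (iii) recodes genotypes rather than removing sites, so it appears in
    the report with count 0 sites removed; its effect shows up at rule (v).
    Returns the surviving table ("dataset 2") and a :class:`FilterReport`.
    """
    cfg = config or FilterConfig()
    t = table.copy()
    removed: dict[str, int] = {}
    n0 = t.n_sites

    # (i) site coverage relative to genome-wide mean site coverage
    site_cov = t.site_mean_depth()
    mean_cov = site_cov.mean() if t.n_sites else 0.0
    keep = (site_cov >= cfg.min_cov_factor * mean_cov) & \
           (site_cov <= cfg.max_cov_factor * mean_cov)
    removed["coverage"] = int((~keep).sum())
    t = t.take_sites(keep)

    # (ii) excluded contigs
    keep = ~np.isin(t.chrom, list(cfg.excluded_contigs))
    removed["excluded_contig"] = int((~keep).sum())
    t = t.take_sites(keep)

    # (iii) low-confidence genotypes -> missing; sites with no surviving call
    # are unusable and are dropped here, attributed to this rule
    mask = (t.dp < cfg.min_depth) | (t.gq < cfg.min_gq)
    t.gt = np.where(mask, MISSING, t.gt).astype(np.int8)
    keep = (t.gt != MISSING).any(axis=0)
    removed["genotype_recode"] = int((~keep).sum())
    t = t.take_sites(keep)

    # (iv) biallelic SNPs only
    snp = np.array([len(r) == 1 and len(a) == 1 for r, a in zip(t.ref, t.alt)])
    keep = snp & ~t.multiallelic
    removed["multiallelic_or_indel"] = int((~keep).sum())
    t = t.take_sites(keep)

    # (v) missing rate
    keep = t.missing_rate() <= cfg.max_missing
    removed["missing_rate"] = int((~keep).sum())
    t = t.take_sites(keep)

    # (vi) minor allele frequency over non-missing haplotypes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        keep = t.maf() >= cfg.min_maf
    keep &= ~np.isnan(t.maf())
    removed["maf"] = int((~keep).sum())
    t = t.take_sites(keep)

    if t.n_sites == 0:
        logger.warning("filter ladder removed every site")
    return t, FilterReport(input_sites=n0, removed=removed, surviving=t.n_sites)


def thin_by_distance(table: VariantTable, window_bp: int = 100_000) -> VariantTable:
    """Keep the first SNP in each non-overlapping ``window_bp`` window."""
    keep = np.zeros(table.n_sites, dtype=bool)
    for c in np.unique(table.chrom):
        idx = np.flatnonzero(table.chrom == c)
        win = (table.pos[idx] - 1) // window_bp
        first = np.r_[True, np.diff(win) != 0]
        keep[idx[first]] = True
    return table.take_sites(keep)


def _dosage_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over jointly
    non-missing samples; 0.0 when undefined (constant or <2 shared calls)."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        return 0.0
    a, b = g1[ok].astype(float), g2[ok].astype(float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def prune_by_r2(table: VariantTable, window_snps: int = 50, step_snps: int = 10,
                r2_max: float = 0.2) -> VariantTable:
    """Greedy sliding-window LD pruning (PLINK ``--indep-pairwise`` style).

    Within each window, for every pair with r^2 > ``r2_max`` the later SNP of
    the pair is dropped; windows slide by ``step_snps`` within chromosomes.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    keep = np.ones(table.n_sites, dtype=bool)
    for c in np.unique(table.chrom):
        idx = np.flatnonzero(table.chrom == c)
        start = 0
        while start < len(idx):
            win = [j for j in idx[start:start + window_snps] if keep[j]]
            for a in range(len(win)):
                if not keep[win[a]]:
                    continue
                for b in range(a + 1, len(win)):
                    if not keep[win[b]]:
                        continue
                    if _dosage_r2(table.gt[:, win[a]], table.gt[:, win[b]]) > r2_max:
                        keep[win[b]] = False
            if start + window_snps >= len(idx):
                break
            start += step_snps
    return table.take_sites(keep)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> VariantTable:
    """Read a VCFv4.x file into a :class:`VariantTable` (GT, DP, GQ).

    Multi-allelic records are retained with their first ALT and flagged; they
    are removed later by the biallelic rule of the filter ladder.
    """
    from pathlib import Path

    from cyvcf2 import VCF

    if not Path(path).exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chrom, pos, ref, alt, multi = [], [], [], [], []
    gts, dps, gqs = [], [], []
    for i, v in enumerate(vcf):
        try:
            chrom.append(v.CHROM)
            pos.append(v.POS)
            ref.append(v.REF)
            alt.append(v.ALT[0] if v.ALT else ".")
            multi.append(len(v.ALT) > 1)
            g = v.gt_types.astype(np.int8)  # gts012: 0,1,2, 3=unknown
            g[g == 3] = MISSING
            gts.append(g)
            dp = v.format("DP")
            gq = v.format("GQ")
            dps.append(np.zeros(len(samples), np.int32) if dp is None
                       else np.nan_to_num(dp[:, 0], nan=0).astype(np.int32))
            gqs.append(np.zeros(len(samples), np.int32) if gq is None
                       else np.nan_to_num(gq[:, 0], nan=0).astype(np.int32))
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed VCF record #{i + 1} in {path}") from exc
    return VariantTable(
        chrom=np.array(chrom), pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref), alt=np.array(alt),
        gt=np.array(gts, dtype=np.int8).T if gts else np.zeros((len(samples), 0), np.int8),
        dp=np.array(dps, dtype=np.int32).T if dps else np.zeros((len(samples), 0), np.int32),
        gq=np.array(gqs, dtype=np.int32).T if gqs else np.zeros((len(samples), 0), np.int32),
        samples=samples, multiallelic=np.array(multi, dtype=bool),
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: VariantTable, path: str) -> None:
    """Write a minimal VCFv4.2 file (GT:DP:GQ, single ALT per record)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(table.chrom.tolist()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for j in range(table.n_sites):
            cols = [str(table.chrom[j]), str(table.pos[j]), ".", str(table.ref[j]),
                    str(table.alt[j]), ".", "PASS", ".", "GT:DP:GQ"]
            for i in range(table.n_samples):
                cols.append(f"{_GT_STR[int(table.gt[i, j])]}:{int(table.dp[i, j])}"
                            f":{int(table.gq[i, j])}")
            fh.write("\t".join(cols) + "\n")
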