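"""Runs of homozygosity, FROH and the ROH-length inbreeding clock.

A run of homozygosity (ROH) is a contiguous tract over which an individual's
two haplotypes are identical by descent, observable as an absence of
heterozygous calls.  FROH — the fraction of the effective genome covered by
ROH longer than a minimum length (100 kb here) — is a genomic inbreeding
coefficient.  Because recombination shortens IBD tracts each generation, the
mean ROH length L (in Mb) dates the inbreeding event:

    g = 100 / (2 L)      generations to the common ancestor,

and g x generation_time gives years (10 y per generation for a slow-maturing
tree).  Detection uses a transparent greedy scan (the widely used detectors
do not publish their internals): runs extend over consecutive non-missing
calls and a heterozygous call terminates the run unless the running
heterozygote count stays within ``het_per_mb`` per megabase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .variants import MISSING, VariantTable

MEDIUM_MAX = 1_000_000  # boundary between medium (100 kb - 1 Mb) and long ROH


def detect_roh(table: VariantTable, min_length: int = 100_000,
               min_snps: int = 25, het_per_mb: float = 1.0) -> pd.DataFrame:
    """Greedy per-individual, per-chromosome homozygosity scan.

    Segment coordinates are SNP-delimited: closed intervals from the first to
    the last homozygous call of the run.  Runs shorter than ``min_length`` or
    with fewer than ``min_snps`` informative (non-missing) sites are dropped.
    Returns a data frame (individual, chrom, start, end, length, n_snps,
    n_het).
    """
    segments = []
    for c in np.unique(table.chrom):
        idx = np.flatnonzero(table.chrom == c)
        pos = table.pos[idx]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"unsorted positions on {c!r}")
        for i, ind in enumerate(table.samples):
            calls = table.gt[i, idx]
            segments.extend(
                _scan_one(calls, pos, ind, c, min_length, min_snps, het_per_mb))
    return pd.DataFrame(segments, columns=["individual", "chrom", "start",
                                           "end", "length", "n_snps", "n_het"])


def _scan_one(calls, pos, ind, chrom, min_length, min_snps, het_per_mb):
    out = []
    start_pos = last_hom = None
    n_snps = n_het = 0

    def close():
        nonlocal start_pos, last_hom, n_snps, n_het
        if start_pos is not None and last_hom is not None:
            length = int(last_hom - start_pos + 1)
            if length >= min_length and n_snps >= min_snps:
                out.append((ind, chrom, int(start_pos), int(last_hom),
                            length, n_snps, n_het))
        start_pos = last_hom = None
        n_snps = n_het = 0

    for g, p in zip(calls, pos):
        if g == MISSING:
            continue
        if g in (0, 2):
            if start_pos is None:
                start_pos = p
            last_hom = p
            n_snps += 1
            continue
        # heterozygous call: tolerated while running het density stays low
        if start_pos is not None:
            run_mb = (p - start_pos) / 1e6
            if (n_het + 1) <= het_per_mb * run_mb:
                n_het += 1
                n_snps += 1
                continue
        close()
    close()
    return out


def froh_and_timing(segments: pd.DataFrame, effective_length: float,
                    pop_map: pd.DataFrame | None = None,
                    individuals: list[str] | None = None,
                    min_length: int = 100_000,
                    generation_time: float = 10.0) -> pd.DataFrame:
    """FROH, ROH length classes and the inbreeding clock per individual.

    FROH = sum of ROH lengths above ``min_length`` / ``effective_length``.
    L is the mean retained-segment length in Mb; g = 100/(2 L) generations,
    rounded to the nearest integer for reporting, and years = round(g) x
    ``generation_time``.  Individuals without retained segments get FROH 0
    and NaN clock values (flagged via ``n_roh`` = 0).

    If ``pop_map`` is given, a per-population block (population means and a
    population-level clock from the pooled mean length) is appended with
    ``level`` = "population".
    """
    if effective_length <= 0:
        raise ValueError("effective_length must be positive")
    seg = segments[segments["length"] >= min_length]
    inds = individuals
    if inds is None:
        inds = sorted(segments["individual"].unique())
    rows = []
    for ind in inds:
        s = seg[seg["individual"] == ind]
        total = float(s["length"].sum())
        froh = total / effective_length
        n_medium = int(((s["length"] >= min_length)
                        & (s["length"] <= MEDIUM_MAX)).sum())
        n_long = int((s["length"] > MEDIUM_MAX).sum())
        if len(s):
            L = float(s["length"].mean()) / 1e6
            g = 100.0 / (2.0 * L)
            years = round(g) * generation_time
        else:
            L = g = years = np.nan
        rows.append(("individual", ind, froh, n_medium, n_long, len(s),
                     L, g, years))
    out = pd.DataFrame(rows, columns=["level", "name", "froh", "n_medium",
                                      "n_long", "n_roh", "mean_length_mb",
                                      "generations", "years"])
    if pop_map is not None:
        pop_of = dict(zip(pop_map["sample_id"], pop_map["population_id"]))
        seg2 = seg.assign(population=seg["individual"].map(pop_of))
        prow = []
        for pop, s in seg2.groupby("population", sort=True):
            members = [i for i in inds if pop_of.get(i) == pop]
            froh = float(out[out["name"].isin(members)]["froh"].mean())
            if len(s):
                L = float(s["length"].mean()) / 1e6
                g = 100.0 / (2.0 * L)
                years = round(g) * generation_time
            else:
                L = g = years = np.nan
            prow.append(("population", pop, froh,
                         int(((s["length"] <= MEDIUM_MAX)).sum()),
                         int((s["length"] > MEDIUM_MAX).sum()), len(s),
                         L, g, years))
        out = pd.concat([out, pd.DataFrame(prow, columns=out.columns)],
                        ignore_index=True)
    return out


def generations_to_ancestor(mean_length_mb: float) -> float:
    """Inbreeding clock: g = 100 / (2 L), L in megabases."""
    if mean_length_mb <= 0:
        raise ValueError("mean ROH length must be positive")
    return 100.0 / (2.0 * mean_length_mb)


def segments_to_bed(segments: pd.DataFrame) -> pd.DataFrame:
    """BED-like frame (chrom, 0-based half-open start, end, individual, n_snps)."""
    return pd.DataFrame({
        "chrom": segments["chrom"], "start": segments["start"] - 1,
        "end": segments["end"], "individual": segments["individual"],
        "n_snps": segments["n_snps"]})


def interval_jaccard(a: tuple, b: tuple) -> float:
    """Jaccard overlap of two closed bp intervals (start, end)."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union if union else 0.0
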