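"""Editing-level quantification and site-inclusion filtering.

The editing level at a site is G reads / (A + G) reads. Replicates of a
population are pooled by summing counts (never by averaging levels — the
two differ whenever replicate coverage differs). A site enters comparative
analysis only if it is adequately covered in enough populations and its
replicate levels agree within a spread tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import BASES, CountMatrix, SampleSheet, SiteKey


def editing_level(a: int, g: int) -> float:
    """g/(a+g); NaN when there is no coverage."""
    if a < 0 or g < 0:
        raise ValueError("counts must be non-negative")
    total = a + g
    return g / total if total else math.nan


@dataclass
class InclusionRule:
    """Coverage/reproducibility rule for admitting a site to comparisons.

    A site is kept iff it reaches ``min_coverage`` pooled reads in at
    least ``min_populations`` of ``total_populations`` populations
    (boundaries inclusive) and, in every covered population, the spread
    (max − min) of replicate editing levels is at most
    ``reproducibility_max_spread``.
    """

    min_coverage: int = 20
    min_populations: int = 7
    total_populations: int = 10
    reproducibility_max_spread: float = 0.2

    def __post_init__(self) -> None:
        if self.min_populations > self.total_populations:
            raise ValueError("min_populations cannot exceed total_populations")


def pool_replicates(counts: CountMatrix, sheet: SampleSheet) -> CountMatrix:
    """Sum replicate counts within each population.

    Pooling precedes level computation: the pooled level is Σg/Σ(a+g),
    which equals the coverage-weighted (not plain) mean of replicate levels.
    """
    pops = sheet.populations
    n_sites = len(counts.sites)
    a = np.zeros((n_sites, len(pops)), dtype=np.int64)
    g = np.zeros_like(a)
    bc = (
        {b: np.zeros_like(a) for b in BASES} if counts.base_counts is not None else None
    )
    for j, pop in enumerate(pops):
        cols = [counts.sample_index(s) for s in sheet.samples_of(pop) if s in counts.samples]
        if not cols:
            continue
        a[:, j] = counts.a[:, cols].sum(axis=1)
        g[:, j] = counts.g[:, cols].sum(axis=1)
        if bc is not None:
            for b in BASES:
                bc[b][:, j] = counts.base_counts[b][:, cols].sum(axis=1)
    return CountMatrix(counts.sites, pops, a, g, bc, counts.ref)


def levels_frame(counts: CountMatrix, sheet: SampleSheet | None = None) -> pd.DataFrame:
    """Long-format per-sample levels table (chrom, pos, strand, sample, a, g, level)."""
    lv = counts.levels()
    rows = []
    for i, s in enumerate(counts.sites):
        for j, smp in enumerate(counts.samples):
            rows.append(
                {
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "strand": s.strand,
                    "sample": smp,
                    "population": sheet.population_of(smp) if sheet else smp,
                    "a": int(counts.a[i, j]),
                    "g": int(counts.g[i, j]),
                    "level": lv[i, j],
                }
            )
    return pd.DataFrame(rows)


def apply_inclusion(
    counts: CountMatrix, sheet: SampleSheet, rule: InclusionRule | None = None
) -> tuple[list[SiteKey], pd.DataFrame]:
    """Filter sites by the coverage + reproducibility rule.

    Returns the kept sites and a per-site QC report with the number of
    covered populations, the worst replicate spread among covered
    populations, and the individual pass flags.
    """
    rule = rule or InclusionRule()
    pooled = pool_replicates(counts, sheet)
    pooled_tot = pooled.totals()
    lv = counts.levels()
    tot = counts.totals()
    pops = sheet.populations
    kept: list[SiteKey] = []
    rows = []
    for i, site in enumerate(counts.sites):
        covered = [j for j, _ in enumerate(pops) if pooled_tot[i, j] >= rule.min_coverage]
        max_spread = 0.0
        for j in covered:
            cols = [
                counts.sample_index(s)
                for s in sheet.samples_of(pops[j])
                if s in counts.samples
            ]
            reps = [lv[i, c] for c in cols if tot[i, c] > 0]
            if len(reps) >= 2:
                max_spread = max(max_spread, max(reps) - min(reps))
        pass_cov = len(covered) >= rule.min_populations
        pass_rep = max_spread <= rule.reproducibility_max_spread
        keep = pass_cov and pass_rep
        if keep:
            kept.append(site)
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "strand": site.strand,
                "n_covered_populations": len(covered),
                "max_replicate_spread": max_spread,
                "pass_coverage": pass_cov,
                "pass_reproducibility": pass_rep,
                "keep": keep,
            }
        )
    return kept, pd.DataFrame(rows)


def overall_editing(
    counts: CountMatrix, sample: str, sites: list[SiteKey] | None = None
) -> float:
    """Σg / Σ(a+g) over a site set for one sample (coverage-weighted mean level)."""
    mat = counts if sites is None else counts.select_sites(sites)
    j = mat.sample_index(sample)
    denom = int(mat.a[:, j].sum() + mat.g[:, j].sum())
    return int(mat.g[:, j].sum()) / denom if denom else math.nan
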