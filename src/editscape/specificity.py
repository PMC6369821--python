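"""Population-specific editing-site calling and enrichment.

A site is specific to one population when every replicate of that
population is an outlier (|z| > 1.65, common sign) against the grand
mean/SD of all replicate levels at the site, and the population's pooled
level is at least 10 percentage points away from the next closest
population. The specific set is then tested for annotation-category
enrichment against all tested sites by χ².
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import CountMatrix, SampleSheet, SiteAnnotation, SiteKey
from .quantify import pool_replicates


def zscores(
    counts: CountMatrix,
    sheet: SampleSheet,
    sites: list[SiteKey] | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-replicate z-scores of editing level against all replicates.

    The mean and SD are taken over every covered replicate of every
    population at the site (sample SD by default; ``ddof=0`` for the
    population SD). Sites with fewer than two covered replicates or zero
    SD are skipped — every replicate is then exactly at the mean and no
    outlier statement is possible.
    """
    mat = counts if sites is None else counts.select_sites(sites)
    lv = mat.levels()
    tot = mat.totals()
    rows = []
    for i, site in enumerate(mat.sites):
        cov = [j for j in range(len(mat.samples)) if tot[i, j] > 0]
        if len(cov) < 2:
            continue
        vals = np.array([lv[i, j] for j in cov])
        sd = vals.std(ddof=ddof)
        if sd < 1e-12:  # degenerate: every replicate at the mean
            continue
        mean = vals.mean()
        for j, v in zip(cov, vals):
            smp = mat.samples[j]
            rows.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "strand": site.strand,
                    "sample": smp,
                    "population": sheet.population_of(smp),
                    "level": v,
                    "z": (v - mean) / sd,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "sample", "population", "level", "z"]
    )


def call_specific(
    counts: CountMatrix,
    sheet: SampleSheet,
    sites: list[SiteKey] | None = None,
    z_thresh: float = 1.65,
    min_gap: float = 0.10,
    ddof: int = 1,
) -> pd.DataFrame:
    """Call sites with population-specific high or low editing.

    A population is called at a site iff (a) all of its replicates are
    covered and have |z| > ``z_thresh`` with one common sign, and (b) the
    absolute difference between its pooled level and the pooled level of
    the next closest other population is at least ``min_gap``. The gate on
    the *nearest* other population makes the call conservative under ties.
    At most one population is reported per site per direction (largest
    minimum |z| wins).

    Columns: chrom, pos, strand, population, direction, min_abs_z,
    gap_to_next, level, next_level.
    """
    mat = counts if sites is None else counts.select_sites(sites)
    zf = zscores(mat, sheet, ddof=ddof)
    if zf.empty:
        return pd.DataFrame(
            columns=[
                "chrom", "pos", "strand", "population", "direction",
                "min_abs_z", "gap_to_next", "level", "next_level",
            ]
        )
    pooled = pool_replicates(mat, sheet)
    plv = pooled.levels()
    ptot = pooled.totals()
    pops = pooled.samples
    site_idx = {(s.chrom, s.pos, s.strand): i for i, s in enumerate(mat.sites)}
    calls = []
    for (chrom, pos, strand), grp in zf.groupby(["chrom", "pos", "strand"], sort=False):
        i = site_idx[(chrom, pos, strand)]
        for pop in grp["population"].unique():
            expected = set(sheet.samples_of(pop))
            sub = grp[grp["population"] == pop]
            if set(sub["sample"]) != expected:  # all replicates must be covered
                continue
            z = sub["z"].to_numpy()
            if (np.abs(z) <= z_thresh).any():
                continue
            if not (np.all(z > 0) or np.all(z < 0)):
                continue
            jp = pops.index(pop)
            if ptot[i, jp] == 0:
                continue
            others = [
                plv[i, j]
                for j, q in enumerate(pops)
                if q != pop and ptot[i, j] > 0 and not np.isnan(plv[i, j])
            ]
            if not others:
                continue
            gaps = [abs(plv[i, jp] - o) for o in others]
            k = int(np.argmin(gaps))
            if gaps[k] < min_gap:
                continue
            calls.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": strand,
                    "population": pop,
                    "direction": "high" if z[0] > 0 else "low",
                    "min_abs_z": float(np.abs(z).min()),
                    "gap_to_next": float(gaps[k]),
                    "level": float(plv[i, jp]),
                    "next_level": float(others[k]),
                }
            )
    frame = pd.DataFrame(
        calls,
        columns=[
            "chrom", "pos", "strand", "population", "direction",
            "min_abs_z", "gap_to_next", "level", "next_level",
        ],
    )
    if frame.empty:
        return frame
    # one population per site per direction: keep the strongest outlier
    frame = (
        frame.sort_values("min_abs_z", ascending=False)
        .drop_duplicates(["chrom", "pos", "strand", "direction"], keep="first")
        .sort_values(["chrom", "pos", "strand"])
        .reset_index(drop=True)
    )
    return frame


def category_enrichment(
    specific_sites: list[SiteKey],
    tested_sites: list[SiteKey],
    annotations: SiteAnnotation,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """χ² enrichment of annotation categories in the specific set.

    One 2×2 test per category: membership in the category for the
    specific set vs the full tested background (the comparison quoted as
    "X% of specific sites vs Y% of tested sites"). Pearson's χ² without
    continuity correction by default.
    """
    from .io_model import ANNOTATION_CATEGORIES

    lut = annotations.lookup()

    def cat(s: SiteKey) -> str:
        return lut.get(s, {"category": "intergenic"})["category"]

    spec_cats = [cat(s) for s in specific_sites]
    test_cats = [cat(s) for s in tested_sites]
    n_spec, n_test = len(spec_cats), len(test_cats)
    rows = []
    for category in ANNOTATION_CATEGORIES:
        a = sum(c == category for c in spec_cats)
        b = sum(c == category for c in test_cats)
        table = np.array([[a, n_spec - a], [b, n_test - b]])
        if n_spec == 0 or n_test == 0 or table.sum(axis=0).min() == 0:
            chi2, p = np.nan, np.nan
        else:
            chi2, p = stats.chi2_contingency(table, correction=continuity_correction)[:2]
        pct_spec = a / n_spec if n_spec else np.nan
        pct_bg = b / n_test if n_test else np.nan
        rows.append(
            {
                "category": category,
                "n_specific": a,
                "n_background": b,
                "pct_specific": pct_spec,
                "pct_background": pct_bg,
                "ratio": pct_spec / pct_bg if pct_bg else np.nan,
                "chi2": chi2,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
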