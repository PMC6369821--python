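"""Pairwise differential editing between populations.

Each site is compared between every pair of populations with a two-sided
Fisher exact test on the pooled (A, G) counts; a comparison is flagged
only if it is both statistically significant and passes an absolute
editing-level difference gate (default 20 percentage points), mirroring
the usual practice of pairing an exact test with an effect-size floor.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import CountMatrix, SampleSheet, SiteKey
from .quantify import pool_replicates

CORRECTIONS = ("bh", "bonferroni", "none")


def fisher_site(a1: int, g1: int, a2: int, g2: int) -> float:
    """Two-sided Fisher exact p for the 2×2 table [[g1, a1], [g2, a2]]."""
    if min(a1, g1, a2, g2) < 0:
        raise ValueError("counts must be non-negative")
    if a1 + g1 + a2 + g2 == 0:
        warnings.warn("all-zero table; p set to 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact([[g1, a1], [g2, a2]], alternative="two-sided")[1])


def pairwise_differential(
    counts: CountMatrix,
    sheet: SampleSheet,
    sites: list[SiteKey] | None = None,
    alpha: float = 0.05,
    min_delta: float = 0.20,
    correction: str = "bh",
    min_coverage: int = 20,
) -> pd.DataFrame:
    """Fisher tests of pooled counts for every site × population pair.

    Replicates are pooled per population first. A (site, pair) record is
    emitted only when both populations reach ``min_coverage`` pooled
    reads; missing coverage skips that pair only. Multiplicity correction
    (``bh``, ``bonferroni`` or ``none``) is applied jointly across all
    emitted tests, and ``significant`` requires both the corrected p below
    ``alpha`` and |delta| > ``min_delta``.

    Columns: chrom, pos, strand, pop_a, pop_b, level_a, level_b, delta,
    p_value, p_adjusted, significant. Pairs are stored once with
    pop_a/pop_b in sheet order; delta = level_a − level_b, so the reversed
    orientation is the exact negation with an identical p-value.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {CORRECTIONS}")
    mat = counts if sites is None else counts.select_sites(sites)
    pooled = pool_replicates(mat, sheet)
    tot = pooled.totals()
    lv = pooled.levels()
    pops = pooled.samples
    rows = []
    for i, site in enumerate(mat.sites):
        for ja, jb in combinations(range(len(pops)), 2):
            if tot[i, ja] < min_coverage or tot[i, jb] < min_coverage:
                continue
            p = fisher_site(
                int(pooled.a[i, ja]), int(pooled.g[i, ja]),
                int(pooled.a[i, jb]), int(pooled.g[i, jb]),
            )
            rows.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "strand": site.strand,
                    "pop_a": pops[ja],
                    "pop_b": pops[jb],
                    "level_a": lv[i, ja],
                    "level_b": lv[i, jb],
                    "delta": lv[i, ja] - lv[i, jb],
                    "p_value": p,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "strand", "pop_a", "pop_b",
            "level_a", "level_b", "delta", "p_value",
        ],
    )
    if frame.empty:
        frame["p_adjusted"] = pd.Series(dtype=float)
        frame["significant"] = pd.Series(dtype=bool)
        return frame
    if correction == "none":
        frame["p_adjusted"] = frame["p_value"]
    else:
        method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[correction]
        frame["p_adjusted"] = multipletests(frame["p_value"].to_numpy(), method=method)[1]
    frame["significant"] = (frame["p_adjusted"] < alpha) & (frame["delta"].abs() > min_delta)
    return frame


def population_summary(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population counts of sites with higher/lower editing.

    For each population P, a site counts toward ``n_higher`` if it is
    significantly more edited in P than in at least one other population
    (and symmetrically for ``n_lower``); a call higher in P vs Q is by
    construction lower in Q vs P. The companion frame bins each (site,
    population, direction) by how many other populations differ.
    """
    sig = results[results["significant"]]
    per: dict[tuple, dict[str, set]] = {}
    bins: dict[tuple, int] = {}
    for _, r in sig.iterrows():
        site = (r["chrom"], r["pos"], r["strand"])
        hi, lo = (r["pop_a"], r["pop_b"]) if r["delta"] > 0 else (r["pop_b"], r["pop_a"])
        per.setdefault(hi, {"higher": set(), "lower": set()})["higher"].add(site)
        per.setdefault(lo, {"higher": set(), "lower": set()})["lower"].add(site)
        bins[(hi, site, "higher")] = bins.get((hi, site, "higher"), 0) + 1
        bins[(lo, site, "lower")] = bins.get((lo, site, "lower"), 0) + 1

    pops = sorted(set(results["pop_a"]) | set(results["pop_b"])) if not results.empty else []
    summary = pd.DataFrame(
        [
            {
                "population": p,
                "n_higher": len(per.get(p, {}).get("higher", ())),
                "n_lower": len(per.get(p, {}).get("lower", ())),
            }
            for p in pops
        ]
    )
    bin_rows = [
        {
            "population": pop,
            "chrom": site[0],
            "pos": site[1],
            "strand": site[2],
            "direction": direction,
            "n_populations_differing": n,
        }
        for (pop, site, direction), n in sorted(bins.items())
    ]
    return summary, pd.DataFrame(
        bin_rows,
        columns=["population", "chrom", "pos", "strand", "direction", "n_populations_differing"],
    )
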