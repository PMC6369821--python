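"""De novo editing-site discovery from full base counts.

A filter cascade turns pooled per-population A/C/G/T tallies into variant
calls of all 12 ref→alt conversion classes; the fraction that are A→G or
T→C is the usual sanity statistic for an editing screen (inosine is read
as G, so true editing shows up only in those two classes). Downstream
helpers split calls into known/novel, summarize annotation categories and
repeat overlap, and chain nearby sites into loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_model import BASES, CountMatrix, SiteAnnotation, SiteKey

CONVERSIONS = [f"{r}>{a}" for r in BASES for a in BASES if r != a]


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.alt_count > self.depth:
            raise ValueError("alt_count exceeds depth")

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def conversion(self) -> str:
        return f"{self.ref}>{self.alt}"


@dataclass(frozen=True)
class Locus:
    """Run of editing sites on one chrom/strand with small adjacent gaps."""

    sites: tuple[SiteKey, ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("empty locus")
        chroms = {s.chrom for s in self.sites}
        strands = {s.strand for s in self.sites}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError("locus sites must share chrom and strand")
        pos = [s.pos for s in self.sites]
        if pos != sorted(pos):
            raise ValueError("locus sites must be sorted by position")

    @property
    def span(self) -> int:
        return self.sites[-1].pos - self.sites[0].pos + 1


@dataclass
class DiscoveryConfig:
    """Thresholds of the variant-calling cascade.

    Defaults follow common editing-pipeline practice; every value is
    configurable so a specific published filter set can be matched.
    """

    min_depth: int = 20
    min_alt_reads: int = 3
    min_alt_fraction: float = 0.05
    max_alt_fraction: float = 0.95
    snp_exclusion: frozenset = field(default_factory=frozenset)  # {(chrom, pos)}
    locus_gap: int = 100

    def __post_init__(self) -> None:
        if not (0 <= self.min_alt_fraction < self.max_alt_fraction <= 1):
            raise ValueError("need 0 <= min_alt_fraction < max_alt_fraction <= 1")


def call_variants(counts: CountMatrix, cfg: DiscoveryConfig | None = None) -> list[VariantCall]:
    """Call variants from pooled full base counts.

    ``counts`` must carry ``base_counts`` and ``ref``; columns are pooled
    across all its samples (pool replicates of one population upstream).
    Every non-reference base passing min_depth / min_alt_reads /
    min_alt_fraction / max_alt_fraction, at a position not on the SNP
    exclusion list, yields one call. All 12 conversion classes are kept so
    the A→G + T→C fraction can be tallied honestly.
    """
    cfg = cfg or DiscoveryConfig()
    if counts.base_counts is None or counts.ref is None:
        raise ValueError("call_variants needs full base counts and reference bases")
    calls: list[VariantCall] = []
    for i, site in enumerate(counts.sites):
        if (site.chrom, site.pos) in cfg.snp_exclusion:
            continue
        pooled = {b: int(counts.base_counts[b][i].sum()) for b in BASES}
        depth = sum(pooled.values())
        if depth < cfg.min_depth:
            continue
        ref = counts.ref[i]
        for alt in BASES:
            if alt == ref:
                continue
            n_alt = pooled[alt]
            frac = n_alt / depth
            if (
                n_alt >= cfg.min_alt_reads
                and frac >= cfg.min_alt_fraction
                and frac <= cfg.max_alt_fraction
            ):
                calls.append(VariantCall(site.chrom, site.pos, ref, alt, depth, n_alt))
    return calls


def conversion_tally(variants: Iterable[VariantCall]) -> pd.DataFrame:
    """Tally the 12 ref→alt conversion classes.

    Returns one row per class with its count; the A>G + T>C fraction (the
    editing-indicative share) is available via :func:`ag_tc_fraction`.
    """
    counts = {c: 0 for c in CONVERSIONS}
    total = 0
    for v in variants:
        counts[v.conversion] += 1
        total += 1
    frame = pd.DataFrame(
        {"conversion": list(counts), "count": list(counts.values())}
    )
    frame["fraction"] = frame["count"] / total if total else 0.0
    return frame


def ag_tc_fraction(tally: pd.DataFrame) -> float:
    """Fraction of variants that are A→G or T→C (A-to-I indicative)."""
    total = int(tally["count"].sum())
    if total == 0:
        return 0.0
    sub = tally[tally["conversion"].isin(["A>G", "T>C"])]
    return float(sub["count"].sum()) / total


def split_known_novel(
    sites: Iterable[SiteKey], known_list: Iterable[SiteKey]
) -> tuple[set[SiteKey], set[SiteKey]]:
    """Partition sites into (known, novel) against a known-site list."""
    sites = set(sites)
    known_set = set(known_list)
    known = sites & known_set
    return known, sites - known


def cluster_loci(sites: Sequence[SiteKey], locus_gap: int = 100) -> list[Locus]:
    """Group sites into loci by single-linkage chaining.

    Adjacent sites (same chrom/strand) closer than ``locus_gap`` bases
    share a locus; a gap of ``locus_gap`` or more splits. Input order does
    not matter.
    """
    groups: dict[tuple[str, str], list[SiteKey]] = {}
    for s in sites:
        groups.setdefault((s.chrom, s.strand), []).append(s)
    loci: list[Locus] = []
    for key in sorted(groups):
        run: list[SiteKey] = []
        for s in sorted(set(groups[key]), key=lambda x: x.pos):
            if run and s.pos - run[-1].pos >= locus_gap:
                loci.append(Locus(tuple(run)))
                run = []
            run.append(s)
        if run:
            loci.append(Locus(tuple(run)))
    return loci


def annotation_summary(
    sites: Iterable[SiteKey], annotations: SiteAnnotation
) -> pd.DataFrame:
    """Counts per annotation category split by known/novel, plus repeat stats.

    Sites absent from the annotation table default to intergenic, novel,
    non-repeat. Returns a category × {known, novel} count table with a
    trailing repeat-overlap row expressed as fractions.
    """
    from .io_model import ANNOTATION_CATEGORIES

    lut = annotations.lookup()
    rows = []
    for s in sites:
        ann = lut.get(s, {"known": False, "category": "intergenic", "repeat_overlap": False})
        rows.append((ann["category"], bool(ann["known"]), bool(ann["repeat_overlap"])))
    frame = pd.DataFrame(rows, columns=["category", "known", "repeat_overlap"])
    out = []
    for cat in ANNOTATION_CATEGORIES:
        sub = frame[frame["category"] == cat]
        out.append(
            {
                "category": cat,
                "known": int(sub["known"].sum()),
                "novel": int((~sub["known"]).sum()),
            }
        )
    summary = pd.DataFrame(out)
    n_known = int(frame["known"].sum())
    n_novel = len(frame) - n_known
    rep_known = int(frame[frame["known"]]["repeat_overlap"].sum())
    rep_novel = int(frame[~frame["known"]]["repeat_overlap"].sum())
    summary.attrs["repeat_fraction_known"] = rep_known / n_known if n_known else np.nan
    summary.attrs["repeat_fraction_novel"] = rep_novel / n_novel if n_novel else np.nan
    return summary
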