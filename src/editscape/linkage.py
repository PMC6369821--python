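"""Clustered-site editing-isoform (read-backed haplotype) analysis.

Editing sites within a read length of each other can be phased directly:
every read spanning all sites of a cluster carries one editing isoform, a
string over {A, G} (e.g. "GA" = first site edited, second not). Comparing
the observed isoform distribution with the independence expectation built
from the same reads' per-site marginals reveals coregulation: an excess of
the fully-unedited and fully-edited isoforms (and a deficit of mixed ones)
means the sites tend to be edited together on the same transcript.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .io_model import SampleSheet, SiteKey


def isoform_labels(k: int) -> list[str]:
    """All 2^k editing isoforms over k sites, in lexicographic order."""
    return ["".join(p) for p in product("AG", repeat=k)]


@dataclass(frozen=True)
class SiteCluster:
    """2+ editing sites on one chrom/strand, phaseable by single reads.

    Isoform tables grow as 2^k; clusters beyond four sites are unusual
    (the largest coregulated cluster reported in fly neurons has four)
    and trigger a warning downstream, not an error.
    """

    sites: tuple[SiteKey, ...]

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise ValueError("a cluster needs at least 2 sites")
        if len({s.chrom for s in self.sites}) != 1 or len({s.strand for s in self.sites}) != 1:
            raise ValueError("cluster sites must share chrom and strand")
        pos = [s.pos for s in self.sites]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise ValueError("cluster sites must be sorted and distinct")

    @property
    def k(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.pos for s in self.sites)


@dataclass
class IsoformCounts:
    """Spanning-read counts per editing isoform for one cluster and sample."""

    cluster: SiteCluster
    sample: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = set(isoform_labels(self.cluster.k))
        for key, n in self.counts.items():
            if key not in valid:
                raise ValueError(f"invalid isoform {key!r} for k={self.cluster.k}")
            if n < 0:
                raise ValueError("negative isoform count")
        if self.cluster.k > 4:
            warnings.warn(
                f"cluster of {self.cluster.k} sites: isoform table has "
                f"{2 ** self.cluster.k} cells", stacklevel=2,
            )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict[str, float]:
        t = self.total
        return {iso: self.counts.get(iso, 0) / t if t else np.nan
                for iso in isoform_labels(self.cluster.k)}

    def marginals(self) -> list[float]:
        """Per-site G fraction computed from the same spanning reads."""
        t = self.total
        out = []
        for i in range(self.cluster.k):
            gi = sum(n for iso, n in self.counts.items() if iso[i] == "G")
            out.append(gi / t if t else np.nan)
        return out


def find_clusters(
    sites: Sequence[SiteKey], cluster_window: int = 40
) -> list[SiteCluster]:
    """Chain sites within ``cluster_window`` bases into clusters (size ≥ 2).

    Single-linkage: each member is within the window of at least one other
    member, which is exactly the connected components of the pairwise
    proximity graph. Singletons are dropped.
    """
    groups: dict[tuple[str, str], list[SiteKey]] = {}
    for s in sites:
        groups.setdefault((s.chrom, s.strand), []).append(s)
    clusters: list[SiteCluster] = []
    for key in sorted(groups):
        run: list[SiteKey] = []
        for s in sorted(set(groups[key]), key=lambda x: x.pos):
            if run and s.pos - run[-1].pos >= cluster_window:
                if len(run) >= 2:
                    clusters.append(SiteCluster(tuple(run)))
                run = []
            run.append(s)
        if len(run) >= 2:
            clusters.append(SiteCluster(tuple(run)))
    return clusters


def isoform_counts(
    calls: Iterable[str], cluster: SiteCluster, sample: str = "sample"
) -> IsoformCounts:
    """Tally editing isoforms from per-read logical base calls.

    Each element of ``calls`` is one read's strand-adjusted base string
    over the cluster sites, in site order. Reads with any base other than
    A or G at a cluster site, or not covering all sites (string length
    mismatch / gap characters), are discarded — only fully spanning,
    cleanly called reads are phase-informative.
    """
    counts: dict[str, int] = {}
    for call in calls:
        if len(call) != cluster.k or any(b not in "AG" for b in call):
            continue
        counts[call] = counts.get(call, 0) + 1
    return IsoformCounts(cluster, sample, counts)


def isoform_counts_from_alignments(
    alignments: str | Path,
    cluster: SiteCluster,
    min_base_qual: int = 25,
    min_map_qual: int = 20,
    sample: str | None = None,
) -> IsoformCounts:
    """Extract isoform counts from a SAM/BAM file.

    Mates of a read pair are combined (both must together span all cluster
    sites); on a conflicting double-covered site, the first mate's call
    wins and the read is still counted. Strand adjustment maps genome-
    strand T/C on '-' sites to logical A/G.
    """
    path = Path(alignments)
    if not path.exists():
        raise FileNotFoundError(path)
    sample = sample or path.stem
    pos_index = {p: i for i, p in enumerate(cluster.positions)}
    chrom, strand = cluster.sites[0].chrom, cluster.sites[0].strand
    per_read: dict[str, dict[int, tuple[str, bool]]] = {}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or (read.mapping_quality or 0) < min_map_qual
                or read.reference_name != chrom
            ):
                continue
            seq = read.query_sequence
            if seq is None:
                continue
            quals = read.query_qualities
            slot = per_read.setdefault(read.query_name, {})
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                i = pos_index.get(rpos + 1)
                if i is None:
                    continue
                if quals is not None and quals[qpos] < min_base_qual:
                    continue
                is_first = not read.is_paired or read.is_read1
                if i in slot and slot[i][1] and not is_first:
                    continue  # first-mate priority on conflict
                slot[i] = (seq[qpos].upper(), is_first)

    calls = []
    for bases in per_read.values():
        if len(bases) != cluster.k:
            continue
        logical = []
        for i in range(cluster.k):
            b = bases[i][0]
            if strand == "-":
                b = {"T": "A", "C": "G"}.get(b, b)
            logical.append(b)
        calls.append("".join(logical))
    return isoform_counts(calls, cluster, sample)


def expected_independent(marginals: Sequence[float]) -> dict[str, float]:
    """Isoform fractions expected if sites were edited independently.

    P(isoform) = Π over sites of (pᵢ if G else 1−pᵢ); this is also the
    multinomial MLE under an independence model. Sums to 1 exactly.
    """
    for p in marginals:
        if not (0 <= p <= 1):
            raise ValueError("marginals must lie in [0, 1]")
    out = {}
    for iso in isoform_labels(len(marginals)):
        prob = 1.0
        for b, p in zip(iso, marginals):
            prob *= p if b == "G" else 1 - p
        out[iso] = prob
    return out


def linkage_stats(observed: Sequence[IsoformCounts]) -> pd.DataFrame:
    """Observed vs independence-expected isoform usage across replicates.

    For every replicate the expectation is built from that replicate's own
    spanning-read marginals, so observed and expected are internally
    consistent. Per isoform: mean observed and expected fractions, their
    difference (which sums to 0 over isoforms), and a Student's t test of
    the per-replicate differences against zero (paired test; NaN with a
    single replicate). A positive difference for the fully-unedited and
    fully-edited isoforms with negative mixed isoforms is the coregulation
    signature.
    """
    if not observed:
        raise ValueError("need at least one replicate")
    k = observed[0].cluster.k
    labels = isoform_labels(k)
    obs = np.array([[o.fractions()[iso] for iso in labels] for o in observed])
    exp = np.array(
        [[expected_independent(o.marginals())[iso] for iso in labels] for o in observed]
    )
    diffs = obs - exp
    rows = []
    for j, iso in enumerate(labels):
        if len(observed) >= 2 and np.ptp(diffs[:, j]) > 0:
            t, p = stats.ttest_rel(obs[:, j], exp[:, j])
        elif len(observed) >= 2:
            t, p = 0.0, 1.0
        else:
            t, p = np.nan, np.nan
        rows.append(
            {
                "isoform": iso,
                "observed": obs[:, j].mean(),
                "expected": exp[:, j].mean(),
                "diff": diffs[:, j].mean(),
                "t_stat": t,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def population_vs_others(
    counts_by_sample: Mapping[str, IsoformCounts],
    sheet: SampleSheet,
    focal: str,
    min_diff: float = 0.10,
) -> pd.DataFrame:
    """Welch's t test of isoform usage, focal population vs all others.

    Significance requires both the Welch p-value and a mean usage
    difference above ``min_diff`` (default 10 percentage points).
    """
    some = next(iter(counts_by_sample.values()))
    labels = isoform_labels(some.cluster.k)
    focal_samples = [s for s in sheet.samples_of(focal) if s in counts_by_sample]
    other_samples = [
        s for s in counts_by_sample if sheet.population_of(s) != focal
    ]
    if len(focal_samples) < 2 or len(other_samples) < 2:
        raise ValueError("need >=2 replicates on each side for Welch's t test")
    rows = []
    for iso in labels:
        f = np.array([counts_by_sample[s].fractions()[iso] for s in focal_samples])
        o = np.array([counts_by_sample[s].fractions()[iso] for s in other_samples])
        if np.ptp(f) == 0 and np.ptp(o) == 0:
            t, p = (0.0, 1.0) if f.mean() == o.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(f, o, equal_var=False)
        rows.append(
            {
                "isoform": iso,
                "mean_focal": f.mean(),
                "mean_others": o.mean(),
                "mean_diff": f.mean() - o.mean(),
                "t_stat": t,
                "p_value": p,
                "significant": bool(p < 0.05 and abs(f.mean() - o.mean()) > min_diff),
            }
        )
    return pd.DataFrame(rows)


def ordering_inference(
    counts: IsoformCounts, noise_floor: float = 0.02
) -> list[tuple[int, int]]:
    """Infer a sequential-editing partial order over cluster sites.

    Site i precedes site j when reads edited at j but not i are absent (below
    ``noise_floor`` of spanning reads) while reads edited at i but not j are
    common (at or above the floor) — the asymmetry implying editing at i is
    required before j. Symmetric or fully linked patterns yield no edges.
    Returns precedence edges as (i, j) index pairs into the cluster's sites.
    """
    t = counts.total
    if t == 0:
        return []
    fr = counts.fractions()
    k = counts.cluster.k
    edges = []
    for i, j in combinations(range(k), 2):
        def frac(gi: str, gj: str) -> float:
            return sum(
                f for iso, f in fr.items() if iso[i] == gi and iso[j] == gj
            )
        a_i_g_j = frac("A", "G")  # edited at j without i
        g_i_a_j = frac("G", "A")  # edited at i without j
        if a_i_g_j < noise_floor <= g_i_a_j:
            edges.append((i, j))
        elif g_i_a_j < noise_floor <= a_i_g_j:
            edges.append((j, i))
    return edges
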