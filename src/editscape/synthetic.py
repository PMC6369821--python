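"""Ground-truth synthetic data for every pipeline stage.

Emulates the study design the pipeline targets: 10 neuronal populations ×
3 biological replicates, per-site editing levels in [0, 1] with
population-specific shifts, negative-binomial coverage with beta-binomial
read sampling, SNP-like and spurious-conversion artifact positions,
repeat-region site clusters, and joint editing-isoform distributions over
2–4 linked sites with tunable departure from independence. Everything is
deterministic under a fixed seed and every generated quantity is
recoverable from the truth object for test assertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import BASES, ANNOTATION_CATEGORIES, CountMatrix, SampleSheet, SiteAnnotation, SiteKey
from .linkage import IsoformCounts, SiteCluster, expected_independent, isoform_labels

LINKAGE_MODES = ("independent", "fully_linked", "sequential", "custom")


@dataclass
class LinkageSpec:
    """Joint isoform distribution over a cluster of 2–4 sites.

    Modes: ``independent`` (product of marginals), ``fully_linked``
    (comonotone coupling — sites share one latent 'edit this transcript'
    draw, maximizing all-A/all-G isoforms at the given marginals),
    ``sequential`` (the first site is a prerequisite: downstream sites can
    only be edited on transcripts edited at site 1, conditionally
    independently), and ``custom`` (explicit table). The derived joint
    table always reproduces the declared marginals to 1e-9.
    """

    marginals: tuple[float, ...]
    mode: str = "independent"
    table: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.marginals = tuple(float(p) for p in self.marginals)
        if not (2 <= self.k <= 4):
            raise ValueError("cluster size must be 2–4")
        if any(not (0 <= p <= 1) for p in self.marginals):
            raise ValueError("marginals must lie in [0, 1]")
        if self.mode not in LINKAGE_MODES:
            raise ValueError(f"mode must be one of {LINKAGE_MODES}")
        if self.mode == "custom":
            if self.table is None:
                raise ValueError("custom mode needs an explicit table")
        elif self.mode == "sequential":
            if any(p > self.marginals[0] + 1e-12 for p in self.marginals[1:]):
                raise ValueError(
                    "sequential mode requires the first-site marginal to be largest"
                )
        tab = self.joint_table()
        if abs(sum(tab.values()) - 1.0) > 1e-9:
            raise ValueError("joint table must sum to 1")
        for i, p in enumerate(self.marginals):
            m = sum(v for iso, v in tab.items() if iso[i] == "G")
            if abs(m - p) > 1e-9:
                raise ValueError(
                    f"joint table marginal at site {i} is {m:.12f}, declared {p:.12f}"
                )

    @property
    def k(self) -> int:
        return len(self.marginals)

    @classmethod
    def from_table(cls, table: dict[str, float]) -> "LinkageSpec":
        """Custom joint distribution with marginals derived from the table.

        Use this when only the joint isoform fractions are known: rounded
        published marginals are generally inconsistent with rounded
        isoform fractions, so deriving keeps the object self-consistent.
        """
        k = len(next(iter(table)))
        total = sum(table.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"table sums to {total}, expected 1")
        marginals = tuple(
            sum(v for iso, v in table.items() if iso[i] == "G") for i in range(k)
        )
        return cls(marginals, "custom", dict(table))

    def joint_table(self) -> dict[str, float]:
        if self.mode == "custom":
            labels = isoform_labels(self.k)
            return {iso: float(self.table.get(iso, 0.0)) for iso in labels}
        if self.mode == "independent":
            return expected_independent(self.marginals)
        if self.mode == "fully_linked":
            return self._comonotone()
        return self._sequential()

    def _comonotone(self) -> dict[str, float]:
        # latent u ~ U(0,1); site i edited iff u < p_i
        pts = sorted({0.0, 1.0, *self.marginals})
        table = {iso: 0.0 for iso in isoform_labels(self.k)}
        for lo, hi in zip(pts, pts[1:]):
            mid = (lo + hi) / 2
            iso = "".join("G" if p > mid else "A" for p in self.marginals)
            table[iso] += hi - lo
        return table

    def _sequential(self) -> dict[str, float]:
        m1 = self.marginals[0]
        cond = [p / m1 if m1 > 0 else 0.0 for p in self.marginals[1:]]
        table = {iso: 0.0 for iso in isoform_labels(self.k)}
        table["A" * self.k] += 1 - m1
        for iso in isoform_labels(self.k - 1):
            prob = m1
            for b, c in zip(iso, cond):
                prob *= c if b == "G" else 1 - c
            table["G" + iso] += prob
        return table


@dataclass
class SyntheticTruth:
    """Complete ground truth for one simulated experiment."""

    populations: list[str]
    replicates_per_pop: int
    sites: list[SiteKey]
    kinds: list[str]  # 'edit' | 'snp' | 'noise'
    ref: list[str]  # genome-strand reference base
    alt: list[str]  # genome-strand alternative base
    levels: np.ndarray  # (n_sites, n_populations) true alt fraction
    known: np.ndarray  # bool per site
    repeat: np.ndarray  # bool per site
    specific: pd.DataFrame  # chrom, pos, strand, population, shift
    mean_depth: float
    depth_dispersion: float
    overdispersion: float
    seed: int
    clusters: list[tuple[SiteCluster, dict[str, LinkageSpec]]] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return [
            f"{pop}_r{r}"
            for pop in self.populations
            for r in range(1, self.replicates_per_pop + 1)
        ]

    def sheet(self) -> SampleSheet:
        return SampleSheet(
            [
                (f"{pop}_r{r}", pop, r)
                for pop in self.populations
                for r in range(1, self.replicates_per_pop + 1)
            ]
        )

    def edit_sites(self) -> list[SiteKey]:
        return [s for s, k in zip(self.sites, self.kinds) if k == "edit"]


def default_populations(n: int = 10) -> list[str]:
    return [f"pop{i:02d}" for i in range(1, n + 1)]


def make_truth(
    n_sites: int = 200,
    n_populations: int = 10,
    replicates_per_pop: int = 3,
    mean_depth: float = 200.0,
    depth_dispersion: float = 0.1,
    overdispersion: float = 0.01,
    snp_rate: float = 0.05,
    conversion_noise_rate: float = 0.05,
    shift_values: Sequence[float] | None = None,
    known_fraction: float = 0.3,
    n_repeat_loci: int = 4,
    sites_per_repeat_locus: int = 8,
    minus_strand_fraction: float = 0.3,
    populations: Sequence[str] | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Build a ground-truth design.

    ``shift_values`` plants population-specific editing: value v at index
    i shifts one (deterministically chosen) population's true level at
    site i by +v, clipped to [0, 0.98]; unshifted populations share the
    base level. ``snp_rate`` / ``conversion_noise_rate`` add artifact
    positions as fractions of n_sites: SNP-like sites at alt fraction 0.5
    or 1.0 uniform across populations, and non-editing conversion noise
    at low alt fraction.
    """
    rng = np.random.default_rng(seed)
    pops = list(populations) if populations is not None else default_populations(n_populations)
    n_pops = len(pops)
    n_repeat = n_repeat_loci * sites_per_repeat_locus
    if n_repeat > n_sites:
        raise ValueError("repeat-locus sites exceed n_sites")

    sites: list[SiteKey] = []
    kinds: list[str] = []
    refs: list[str] = []
    alts: list[str] = []
    repeat_flags: list[bool] = []
    pos = 10_000
    # repeat loci: tight runs (<100 b gaps) of novel-style sites
    for _ in range(n_repeat_loci):
        pos += int(rng.integers(5_000, 20_000))
        strand = "+" if rng.random() > minus_strand_fraction else "-"
        for _ in range(sites_per_repeat_locus):
            sites.append(SiteKey("chr2L", pos, strand))
            kinds.append("edit")
            refs.append("A" if strand == "+" else "T")
            alts.append("G" if strand == "+" else "C")
            repeat_flags.append(True)
            pos += int(rng.integers(5, 60))
    # dispersed sites
    for _ in range(n_sites - n_repeat):
        pos += int(rng.integers(1_000, 5_000))
        strand = "+" if rng.random() > minus_strand_fraction else "-"
        sites.append(SiteKey("chr2L", pos, strand))
        kinds.append("edit")
        refs.append("A" if strand == "+" else "T")
        alts.append("G" if strand == "+" else "C")
        repeat_flags.append(False)
    # artifacts
    n_snp = int(round(snp_rate * n_sites))
    n_noise = int(round(conversion_noise_rate * n_sites))
    for _ in range(n_snp):
        pos += int(rng.integers(1_000, 5_000))
        sites.append(SiteKey("chr2L", pos, "+"))
        kinds.append("snp")
        refs.append("A")
        alts.append("G")
        repeat_flags.append(False)
    noise_conversions = [
        (r, a)
        for r in BASES
        for a in BASES
        if r != a and (r, a) not in (("A", "G"), ("T", "C"))
    ]
    for _ in range(n_noise):
        pos += int(rng.integers(1_000, 5_000))
        r, a = noise_conversions[int(rng.integers(len(noise_conversions)))]
        sites.append(SiteKey("chr2L", pos, "+"))
        kinds.append("noise")
        refs.append(r)
        alts.append(a)
        repeat_flags.append(False)

    n_total = len(sites)
    levels = np.zeros((n_total, n_pops))
    n_shift = len(shift_values) if shift_values is not None else 0
    spec_rows = []
    for i in range(n_total):
        if kinds[i] == "snp":
            levels[i, :] = 0.5 if rng.random() < 0.5 else 1.0
        elif kinds[i] == "noise":
            levels[i, :] = rng.uniform(0.05, 0.30)
        elif shift_values is not None and i < n_shift:
            base = rng.uniform(0.05, 0.45)
            levels[i, :] = base
            pop_j = int(rng.integers(n_pops))
            shift = float(shift_values[i])
            levels[i, pop_j] = min(base + shift, 0.98)
            spec_rows.append(
                {
                    "chrom": sites[i].chrom,
                    "pos": sites[i].pos,
                    "strand": sites[i].strand,
                    "population": pops[pop_j],
                    "shift": shift,
                }
            )
        else:
            levels[i, :] = np.clip(rng.beta(0.8, 2.0), 0.01, 0.95)

    known = np.array(
        [k == "edit" and not rep and rng.random() < known_fraction
         for k, rep in zip(kinds, repeat_flags)]
    )
    return SyntheticTruth(
        populations=pops,
        replicates_per_pop=replicates_per_pop,
        sites=sites,
        kinds=kinds,
        ref=refs,
        alt=alts,
        levels=levels,
        known=known,
        repeat=np.array(repeat_flags),
        specific=pd.DataFrame(
            spec_rows, columns=["chrom", "pos", "strand", "population", "shift"]
        ),
        mean_depth=mean_depth,
        depth_dispersion=depth_dispersion,
        overdispersion=overdispersion,
        seed=seed,
    )


def gen_counts(truth: SyntheticTruth) -> tuple[CountMatrix, SampleSheet]:
    """Draw the full base-count matrix for every site × replicate.

    Depth per cell is negative-binomial with the configured mean and
    dispersion (variance = m + d·m²; d = 0 collapses to constant depth).
    The alt-base count is beta-binomial around the true level with
    within-replicate overdispersion ρ (ρ = 0 → plain binomial); remaining
    reads carry the reference base. Deterministic under truth.seed.
    """
    rng = np.random.default_rng(truth.seed + 1)
    sheet = truth.sheet()
    samples = sheet.samples
    pop_of = {s: truth.populations.index(sheet.population_of(s)) for s in samples}
    n_sites, n_smp = len(truth.sites), len(samples)
    bc = {b: np.zeros((n_sites, n_smp), dtype=np.int64) for b in BASES}
    m, d, rho = truth.mean_depth, truth.depth_dispersion, truth.overdispersion
    for i in range(n_sites):
        for j, smp in enumerate(samples):
            depth = _draw_depth(rng, m, d)
            level = truth.levels[i, pop_of[smp]]
            alt = _draw_alt(rng, depth, level, rho)
            bc[truth.alt[i]][i, j] += alt
            bc[truth.ref[i]][i, j] += depth - alt
    a = np.zeros((n_sites, n_smp), dtype=np.int64)
    g = np.zeros_like(a)
    for i, s in enumerate(truth.sites):
        a[i] = bc[s.ref_base][i]
        g[i] = bc[s.edited_as][i]
    return CountMatrix(truth.sites, samples, a, g, bc, truth.ref), sheet


def _draw_depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if dispersion <= 0:
        return int(round(mean))
    size = 1.0 / dispersion
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def _draw_alt(rng: np.random.Generator, depth: int, level: float, rho: float) -> int:
    if depth == 0:
        return 0
    if rho <= 0 or level in (0.0, 1.0):
        return int(rng.binomial(depth, level))
    nu = 1.0 / rho - 1.0
    p = rng.beta(level * nu, (1 - level) * nu)
    return int(rng.binomial(depth, p))


def gen_annotations(truth: SyntheticTruth) -> SiteAnnotation:
    """Annotate the generated sites with plausible functional categories.

    Repeat-locus sites are intergenic with repeat_overlap set; other
    editing sites draw a category from a distribution resembling a
    neuronal editing screen (recoding and intronic sites prominent).
    Deterministic under truth.seed.
    """
    rng = np.random.default_rng(truth.seed + 2)
    cats = list(ANNOTATION_CATEGORIES)
    probs = np.array([0.36, 0.08, 0.12, 0.04, 0.28, 0.05, 0.07])
    rows = []
    for i, s in enumerate(truth.sites):
        if truth.repeat[i]:
            category = "intergenic"
        else:
            category = cats[int(rng.choice(len(cats), p=probs))]
        rows.append(
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "strand": s.strand,
                "known": bool(truth.known[i]),
                "category": category,
                "repeat_overlap": bool(truth.repeat[i]),
                "gene": f"gene{i // 5:03d}" if category != "intergenic" else "",
            }
        )
    return SiteAnnotation(pd.DataFrame(rows))


def gen_cluster_reads(
    spec: LinkageSpec,
    n_reads: int,
    seed: int,
    cluster: SiteCluster | None = None,
    sample: str = "sim",
) -> IsoformCounts:
    """Draw spanning-read isoform counts from a joint table (multinomial)."""
    rng = np.random.default_rng(seed)
    if cluster is None:
        cluster = SiteCluster(
            tuple(SiteKey("chr2L", 1_000 + 20 * i, "+") for i in range(spec.k))
        )
    table = spec.joint_table()
    labels = isoform_labels(spec.k)
    draws = rng.multinomial(n_reads, [table[iso] for iso in labels])
    return IsoformCounts(cluster, sample, {iso: int(n) for iso, n in zip(labels, draws) if n})


def cluster_reads_to_sam(
    path: str | Path,
    cluster: SiteCluster,
    iso_counts: IsoformCounts,
    read_pad: int = 10,
    base_qual: int = 40,
    map_qual: int = 60,
) -> None:
    """Write the drawn isoforms as a toy SAM of reads spanning the cluster.

    Reads carry reference base A (or T on '-') at non-site positions and
    the strand-adjusted isoform base at each cluster site, full-match
    CIGAR, constant base qualities — enough to exercise pileup and
    read-backed isoform extraction.
    """
    import pysam

    chrom = cluster.sites[0].chrom
    strand = cluster.sites[0].strand
    start = cluster.positions[0] - read_pad
    end = cluster.positions[-1] + read_pad
    length = end - start + 1
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": chrom, "LN": end + 1_000}],
        }
    )
    filler = "A" if strand == "+" else "T"
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        n = 0
        for iso in sorted(iso_counts.counts):
            for _ in range(iso_counts.counts[iso]):
                seq = [filler] * length
                for b, p in zip(iso, cluster.positions):
                    gb = b if strand == "+" else {"A": "T", "G": "C"}[b]
                    seq[p - start] = gb
                read = pysam.AlignedSegment(header)
                read.query_name = f"read{n:06d}"
                read.query_sequence = "".join(seq)
                read.reference_id = 0
                read.reference_start = start - 1  # 0-based
                read.mapping_quality = map_qual
                read.cigarstring = f"{length}M"
                read.query_qualities = pysam.qualitystring_to_array(
                    chr(base_qual + 33) * length
                )
                read.flag = 0
                out.write(read)
                n += 1


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """Every ground-truth value as one tidy table (identical across runs)."""
    spec_lut = {
        (r["chrom"], r["pos"], r["strand"]): (r["population"], r["shift"])
        for _, r in truth.specific.iterrows()
    }
    rows = []
    for i, s in enumerate(truth.sites):
        spec = spec_lut.get((s.chrom, s.pos, s.strand))
        row = {
            "chrom": s.chrom,
            "pos": s.pos,
            "strand": s.strand,
            "kind": truth.kinds[i],
            "ref": truth.ref[i],
            "alt": truth.alt[i],
            "known": bool(truth.known[i]),
            "repeat": bool(truth.repeat[i]),
            "specific_population": spec[0] if spec else "",
            "specific_shift": spec[1] if spec else 0.0,
        }
        for j, pop in enumerate(truth.populations):
            row[f"level_{pop}"] = truth.levels[i, j]
        rows.append(row)
    return pd.DataFrame(rows)
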