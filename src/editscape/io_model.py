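"""Domain types and I/O for editing-site analysis.

A-to-I editing is read out as A→G mismatches on the transcribed strand.
Sites on the '-' genomic strand therefore appear as T→C on the reference;
all logic downstream works on the strand-adjusted (logical A/G) counts.

Coordinates are 1-based inclusive internally (VCF convention); BED input is
converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
ANNOTATION_CATEGORIES = (
    "nonsynonymous",
    "synonymous",
    "UTR3",
    "UTR5",
    "intron",
    "ncRNA",
    "intergenic",
)


class SchemaError(ValueError):
    """A table is missing required columns."""


@dataclass(frozen=True, order=True)
class SiteKey:
    """One editing-site coordinate (1-based) with strand.

    On strand '+' the genomic reference base is A and editing is observed
    as G; on strand '-' the genomic reference is T and editing is observed
    as C. The logical representation is always A→G after strand adjustment.
    """

    chrom: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def ref_base(self) -> str:
        """Genome-strand reference base (A on '+', T on '-')."""
        return "A" if self.strand == "+" else "T"

    @property
    def edited_as(self) -> str:
        """Genome-strand base observed when the site is edited."""
        return "G" if self.strand == "+" else "C"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.pos}({self.strand})"


@dataclass
class SampleSheet:
    """Maps sample ids to (population, replicate)."""

    entries: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        seen: set[tuple[str, int]] = set()
        for _, pop, rep in self.entries:
            if (pop, rep) in seen:
                raise ValueError(f"duplicate replicate {rep} in population {pop}")
            seen.add((pop, rep))

    @property
    def samples(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def populations(self) -> list[str]:
        out: list[str] = []
        for _, pop, _ in self.entries:
            if pop not in out:
                out.append(pop)
        return out

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p, _ in self.entries if p == population]

    def population_of(self, sample: str) -> str:
        for s, p, _ in self.entries:
            if s == sample:
                return p
        raise KeyError(sample)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["sample", "population", "replicate"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleSheet":
        _require_columns(frame, ["sample", "population", "replicate"])
        return cls(
            [
                (str(r["sample"]), str(r["population"]), int(r["replicate"]))
                for _, r in frame.iterrows()
            ]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


class CountMatrix:
    """Per (site, sample) strand-adjusted edited/unedited read counts.

    ``a`` and ``g`` are (n_sites, n_samples) integer arrays of unedited /
    edited read counts after strand adjustment. ``base_counts`` optionally
    carries the full genome-strand A/C/G/T counts (used for de novo
    discovery); ``ref`` the genome-strand reference base per site.
    """

    def __init__(
        self,
        sites: Sequence[SiteKey],
        samples: Sequence[str],
        a: np.ndarray,
        g: np.ndarray,
        base_counts: dict[str, np.ndarray] | None = None,
        ref: Sequence[str] | None = None,
    ) -> None:
        self.sites = list(sites)
        self.samples = list(samples)
        self.a = np.asarray(a, dtype=np.int64)
        self.g = np.asarray(g, dtype=np.int64)
        shape = (len(self.sites), len(self.samples))
        if self.a.shape != shape or self.g.shape != shape:
            raise ValueError(
                f"count arrays must have shape {shape}, got {self.a.shape}/{self.g.shape}"
            )
        if (self.a < 0).any() or (self.g < 0).any():
            raise ValueError("counts must be non-negative")
        if base_counts is not None:
            for b in BASES:
                if b not in base_counts:
                    raise ValueError(f"base_counts missing base {b}")
                base_counts[b] = np.asarray(base_counts[b], dtype=np.int64)
                if base_counts[b].shape != shape:
                    raise ValueError("base_counts shape mismatch")
        self.base_counts = base_counts
        self.ref = list(ref) if ref is not None else None
        if self.ref is not None and len(self.ref) != len(self.sites):
            raise ValueError("ref length mismatch")

    # -- derived quantities ------------------------------------------------

    def totals(self) -> np.ndarray:
        return self.a + self.g

    def levels(self) -> np.ndarray:
        """Editing level g/(a+g) per cell; NaN where coverage is zero."""
        tot = self.totals()
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = np.where(tot > 0, self.g / np.maximum(tot, 1), np.nan)
        return np.where(tot > 0, lv, np.nan)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def site_index(self) -> dict[SiteKey, int]:
        return {s: i for i, s in enumerate(self.sites)}

    def select_sites(self, keep: Iterable[SiteKey]) -> "CountMatrix":
        idx = self.site_index()
        rows = [idx[s] for s in keep]
        bc = None
        if self.base_counts is not None:
            bc = {b: self.base_counts[b][rows] for b in BASES}
        ref = [self.ref[i] for i in rows] if self.ref is not None else None
        return CountMatrix(
            [self.sites[i] for i in rows], self.samples, self.a[rows], self.g[rows], bc, ref
        )

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = ["chrom", "pos", "strand", "sample", "a", "g"]
        if self.ref is not None:
            cols.append("ref")
        if self.base_counts is not None:
            cols += [f"n{b}" for b in BASES]
        rows = []
        for i, s in enumerate(self.sites):
            for j, smp in enumerate(self.samples):
                row = {
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "strand": s.strand,
                    "sample": smp,
                    "a": int(self.a[i, j]),
                    "g": int(self.g[i, j]),
                }
                if self.ref is not None:
                    row["ref"] = self.ref[i]
                if self.base_counts is not None:
                    for b in BASES:
                        row[f"n{b}"] = int(self.base_counts[b][i, j])
                rows.append(row)
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        _require_columns(frame, ["chrom", "pos", "strand", "sample", "a", "g"])
        sites: list[SiteKey] = []
        samples: list[str] = []
        seen_sites: dict[SiteKey, int] = {}
        seen_samples: dict[str, int] = {}
        for _, r in frame.iterrows():
            sk = SiteKey(str(r["chrom"]), int(r["pos"]), str(r["strand"]))
            if sk not in seen_sites:
                seen_sites[sk] = len(sites)
                sites.append(sk)
            smp = str(r["sample"])
            if smp not in seen_samples:
                seen_samples[smp] = len(samples)
                samples.append(smp)
        shape = (len(sites), len(samples))
        a = np.zeros(shape, dtype=np.int64)
        g = np.zeros(shape, dtype=np.int64)
        has_full = all(f"n{b}" in frame.columns for b in BASES)
        bc = {b: np.zeros(shape, dtype=np.int64) for b in BASES} if has_full else None
        ref = [""] * len(sites) if "ref" in frame.columns else None
        for _, r in frame.iterrows():
            i = seen_sites[SiteKey(str(r["chrom"]), int(r["pos"]), str(r["strand"]))]
            j = seen_samples[str(r["sample"])]
            a[i, j] = int(r["a"])
            g[i, j] = int(r["g"])
            if bc is not None:
                for b in BASES:
                    bc[b][i, j] = int(r[f"n{b}"])
            if ref is not None:
                ref[i] = str(r["ref"])
        return cls(sites, samples, a, g, bc, ref)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "CountMatrix":
        frame = pd.read_csv(path, sep="\t")
        if frame.empty:
            return cls([], [], np.zeros((0, 0)), np.zeros((0, 0)))
        return cls.from_frame(frame)


@dataclass
class SiteAnnotation:
    """Per-site annotations: known/novel, functional category, repeat overlap."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "pos", "strand", "known", "category", "repeat_overlap", "gene"]
        )
    )

    def __post_init__(self) -> None:
        _require_columns(
            self.frame, ["chrom", "pos", "strand", "known", "category", "repeat_overlap", "gene"]
        )
        bad = set(self.frame["category"]) - set(ANNOTATION_CATEGORIES)
        if bad:
            raise ValueError(f"unknown annotation categories: {sorted(bad)}")
        keys = list(zip(self.frame["chrom"], self.frame["pos"], self.frame["strand"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate sites in annotation (one category per site)")

    def category_of(self, site: SiteKey) -> str:
        m = self.frame[
            (self.frame["chrom"] == site.chrom)
            & (self.frame["pos"] == site.pos)
            & (self.frame["strand"] == site.strand)
        ]
        if m.empty:
            return "intergenic"
        return str(m.iloc[0]["category"])

    def lookup(self) -> dict[SiteKey, dict]:
        out = {}
        for _, r in self.frame.iterrows():
            out[SiteKey(str(r["chrom"]), int(r["pos"]), str(r["strand"]))] = {
                "known": bool(r["known"]),
                "category": str(r["category"]),
                "repeat_overlap": bool(r["repeat_overlap"]),
                "gene": "" if pd.isna(r["gene"]) else str(r["gene"]),
            }
        return out

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "SiteAnnotation":
        return cls(pd.read_csv(path, sep="\t", keep_default_na=True))


# ---------------------------------------------------------------------------
# site-list readers


def read_sites(path: str | Path, format: str = "tsv") -> list[SiteKey]:
    """Read an ordered, deduplicated site list.

    BED input (0-based half-open) is converted to 1-based positions.
    VCF-like input needs CHROM/POS/REF/ALT; a T→C record is represented as
    a logical A→G site on the '-' strand.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"bed": _read_bed, "vcf_like": _read_vcf_like, "tsv": _read_tsv_sites}
    if format not in readers:
        raise ValueError(f"unknown site-list format {format!r}")
    sites = readers[format](path)
    out: list[SiteKey] = []
    seen: set[SiteKey] = set()
    for s in sites:
        if s in seen:
            warnings.warn(f"duplicate site {s} dropped", stacklevel=2)
            continue
        seen.add(s)
        out.append(s)
    return out


def _read_bed(path: Path) -> list[SiteKey]:
    sites = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: malformed BED line (need >=3 fields)")
            try:
                start = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer BED start") from exc
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "+"
            sites.append(SiteKey(parts[0], start + 1, strand))
    return sites


def _read_vcf_like(path: Path) -> list[SiteKey]:
    sites = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{ln}: malformed VCF-like line (need >=5 fields)")
            chrom, pos_s, _id, ref, alt = parts[:5]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer POS") from exc
            ref, alt = ref.upper(), alt.upper()
            if (ref, alt) == ("A", "G"):
                strand = "+"
            elif (ref, alt) == ("T", "C"):
                strand = "-"
            else:
                raise ValueError(
                    f"{path}:{ln}: {ref}>{alt} is not an A-to-I editing record"
                )
            sites.append(SiteKey(chrom, pos, strand))
    return sites


def _read_tsv_sites(path: Path) -> list[SiteKey]:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, ["chrom", "pos", "strand"])
    return [
        SiteKey(str(r["chrom"]), int(r["pos"]), str(r["strand"])) for _, r in frame.iterrows()
    ]


# ---------------------------------------------------------------------------
# pileup


def pileup_counts(
    alignments: str | Path,
    sites: Sequence[SiteKey],
    min_base_qual: int = 25,
    min_map_qual: int = 20,
    min_end_distance: int = 0,
    sample: str | None = None,
    exclude_duplicates: bool = True,
) -> CountMatrix:
    """Count bases at editing sites from a SAM/BAM file (one sample column).

    Reads flagged secondary, supplementary, unmapped or (optionally)
    duplicate, and reads with mapping quality below ``min_map_qual``, are
    excluded — "uniquely mapped" reads in the usual pileup sense. Base
    calls below ``min_base_qual`` or within ``min_end_distance`` bases of a
    read end are ignored. Counts are strand-adjusted (a = unedited,
    g = edited) and the full genome-strand A/C/G/T tallies are kept.
    """
    path = Path(alignments)
    if not path.exists():
        raise FileNotFoundError(path)
    sample = sample or path.stem
    by_pos: dict[tuple[str, int], list[int]] = {}
    for i, s in enumerate(sites):
        by_pos.setdefault((s.chrom, s.pos), []).append(i)

    shape = (len(sites), 1)
    bc = {b: np.zeros(shape, dtype=np.int64) for b in BASES}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or (exclude_duplicates and read.is_duplicate)
                or (read.mapping_quality or 0) < min_map_qual
            ):
                continue
            seq = read.query_sequence
            if seq is None:
                continue
            quals = read.query_qualities
            rlen = len(seq)
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                key = (read.reference_name, rpos + 1)
                if key not in by_pos:
                    continue
                if quals is not None and quals[qpos] < min_base_qual:
                    continue
                if min(qpos, rlen - 1 - qpos) < min_end_distance:
                    continue
                base = seq[qpos].upper()
                if base not in BASES:
                    continue
                for i in by_pos[key]:
                    bc[base][i, 0] += 1

    a = np.zeros(shape, dtype=np.int64)
    g = np.zeros(shape, dtype=np.int64)
    ref = []
    for i, s in enumerate(sites):
        a[i, 0] = bc[s.ref_base][i, 0]
        g[i, 0] = bc[s.edited_as][i, 0]
        ref.append(s.ref_base)
    return CountMatrix(sites, [sample], a, g, bc, ref)


# ---------------------------------------------------------------------------
# generic table round-trip


def write_table(obj, path: str | Path) -> None:
    """Write any of the domain tables (or a DataFrame) to TSV."""
    if isinstance(obj, (CountMatrix, SampleSheet, SiteAnnotation)):
        obj.write(path)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")


def read_table(path: str | Path, kind: str = "frame"):
    """Read a TSV back as ``counts``, ``sheet``, ``annotation`` or ``frame``."""
    kinds = {
        "counts": CountMatrix.read,
        "sheet": SampleSheet.read,
        "annotation": SiteAnnotation.read,
        "frame": lambda p: pd.read_csv(p, sep="\t"),
    }
    if kind not in kinds:
        raise ValueError(f"unknown table kind {kind!r}")
    return kinds[kind](path)


def _require_columns(frame: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise SchemaError(f"table is missing columns: {missing}")
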