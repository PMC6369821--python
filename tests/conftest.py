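import numpy as np
import pytest

from editscape import SampleSheet, SiteKey, gen_counts, make_truth

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr2L\tLN:100000\n"


def sam_line(
    name: str,
    pos: int,
    seq: str,
    flag: int = 0,
    mapq: int = 60,
    qual: str | None = None,
    chrom: str = "chr2L",
    cigar: str | None = None,
) -> str:
    qual = qual or "I" * len(seq)  # 'I' = Q40
    cigar = cigar or f"{len(seq)}M"
    return "\t".join(
        [name, str(flag), chrom, str(pos), str(mapq), cigar, "*", "0", "0", seq, qual]
    ) + "\n"


@pytest.fixture
def toy_sam(tmp_path):
    """10 reads over a minus-strand site at chr2L:100 — genome-strand T×7, C×3.

    Reads are 10 bp starting at position 96, so the site is query offset 4.
    Expected strand-adjusted counts: a=7 (T), g=3 (C).
    """
    path = tmp_path / "toy.sam"
    lines = [SAM_HEADER]
    for i in range(7):
        lines.append(sam_line(f"t{i}", 96, "AAAATAAAAA"))
    for i in range(3):
        lines.append(sam_line(f"c{i}", 96, "AAAACAAAAA"))
    path.write_text("".join(lines))
    return path


@pytest.fixture
def small_truth():
    return make_truth(
        n_sites=30,
        n_populations=4,
        replicates_per_pop=3,
        mean_depth=100,
        snp_rate=0.1,
        conversion_noise_rate=0.1,
        n_repeat_loci=1,
        sites_per_repeat_locus=5,
        seed=11,
    )


@pytest.fixture
def small_counts(small_truth):
    return gen_counts(small_truth)


@pytest.fixture
def three_pop_sheet():
    return SampleSheet(
        [(f"{p}_r{r}", p, r) for p in ("alpha", "beta", "gamma") for r in (1, 2, 3)]
    )


def site(pos: int, strand: str = "+", chrom: str = "chr2L") -> SiteKey:
    return SiteKey(chrom, pos, strand)
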