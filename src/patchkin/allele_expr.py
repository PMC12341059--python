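"""Allele-specific expression from read pileups at a variant site.

Counts reference/alternate bases among aligned reads covering one
genomic position (the mpileup step of an RNA-seq variant profile),
estimates allele fractions with an exact binomial imbalance test
against the heterozygous 50:50 expectation, and simulates pileups of
stated depth and allele fraction for testing.

Coordinates are 1-based inclusive; counting is strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

__all__ = [
    "AlignedBaseCall",
    "PileupCounts",
    "AlleleCall",
    "pileup",
    "allele_fractions",
    "simulate_pileup",
    "read_basecalls_tsv",
    "read_basecalls_sam",
]

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class AlignedBaseCall:
    """One read's base call at the position of interest."""

    read_id: str
    base: str  # A/C/G/T/N
    base_quality: float  # phred
    map_quality: float  # phred

    def __post_init__(self) -> None:
        if self.base not in BASES + ("N",):
            raise ValueError(f"invalid base {self.base!r}")
        if self.base_quality < 0 or self.map_quality < 0:
            raise ValueError("qualities must be >= 0")


@dataclass(frozen=True)
class PileupCounts:
    """Per-base tallies at one position after quality filtering."""

    contig: str
    position: int  # 1-based
    counts: dict[str, int]
    depth: int
    n_filtered: int = 0

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.depth:
            raise ValueError("depth must equal the sum of base counts")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative base count")


@dataclass(frozen=True)
class AlleleCall:
    """Allele fractions at a het site with an exact imbalance test."""

    ref_base: str
    alt_base: str
    ref_count: int
    alt_count: int
    ref_fraction: float
    alt_fraction: float
    binom_p: float  # two-sided exact test of alt vs 0.5
    ci95: tuple[float, float]  # Clopper-Pearson interval on alt_fraction


def pileup(
    calls,
    contig: str = "",
    position: int = 0,
    min_base_q: float = 20.0,
    min_map_q: float = 20.0,
) -> PileupCounts:
    """Tally A/C/G/T counts from base calls at one position.

    N calls and calls failing either quality floor are excluded; depth
    counts only retained calls. An empty stream yields a valid depth-0
    pileup.
    """
    counts = {b: 0 for b in BASES}
    n_filtered = 0
    for call in calls:
        if (
            call.base == "N"
            or call.base_quality < min_base_q
            or call.map_quality < min_map_q
        ):
            n_filtered += 1
            continue
        counts[call.base] += 1
    return PileupCounts(
        contig=contig,
        position=position,
        counts=counts,
        depth=sum(counts.values()),
        n_filtered=n_filtered,
    )


def allele_fractions(counts: PileupCounts, ref: str, alt: str) -> AlleleCall:
    """Ref/alt fractions of total depth plus an exact 50:50 test.

    Fractions are relative to the full retained depth (so they need not
    sum to 1 when other bases are present); the binomial test and the
    95% Clopper-Pearson interval are computed on the ref+alt calls only.
    """
    if ref == alt:
        raise ValueError("ref and alt bases must differ")
    if counts.depth < 1:
        raise ValueError("pileup has zero depth")
    n_ref = counts.counts.get(ref, 0)
    n_alt = counts.counts.get(alt, 0)
    n_ra = n_ref + n_alt
    if n_ra == 0:
        raise ValueError("no ref or alt calls at this position")
    test = _stats.binomtest(n_alt, n_ra, p=0.5, alternative="two-sided")
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    return AlleleCall(
        ref_base=ref,
        alt_base=alt,
        ref_count=n_ref,
        alt_count=n_alt,
        ref_fraction=n_ref / counts.depth,
        alt_fraction=n_alt / counts.depth,
        binom_p=float(test.pvalue),
        ci95=(float(ci.low), float(ci.high)),
    )


def simulate_pileup(
    depth: int,
    alt_fraction: float,
    error_rate: float = 0.001,
    seed: int | np.random.Generator = 0,
    ref: str = "T",
    alt: str = "C",
) -> list[AlignedBaseCall]:
    """Simulate base calls at a het site of given depth and allele ratio.

    Each read carries the alt allele with probability ``alt_fraction``;
    a sequencing error then replaces the base with a uniformly chosen
    different base at ``error_rate``. Base qualities are drawn around
    Q30, mapping qualities around Q60.
    """
    if not 0.0 <= alt_fraction <= 1.0:
        raise ValueError("alt_fraction must be in [0, 1]")
    if not 0.0 <= error_rate < 0.1:
        raise ValueError("error_rate must be in [0, 0.1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    calls = []
    for i in range(depth):
        base = alt if rng.random() < alt_fraction else ref
        if error_rate > 0 and rng.random() < error_rate:
            base = BASES[rng.choice([j for j, b in enumerate(BASES) if b != base])]
        baseq = float(np.clip(rng.normal(30.0, 3.0), 2.0, 41.0))
        mapq = float(np.clip(rng.normal(55.0, 4.0), 0.0, 60.0))
        calls.append(
            AlignedBaseCall(
                read_id=f"read{i:06d}", base=base,
                base_quality=baseq, map_quality=mapq,
            )
        )
    return calls


def read_basecalls_tsv(path) -> list[AlignedBaseCall]:
    """Read base calls from a TSV of (read_id, base, baseq, mapq)."""
    import csv

    calls = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            rid, base, bq, mq = row[:4]
            calls.append(
                AlignedBaseCall(
                    read_id=rid, base=base.upper(),
                    base_quality=float(bq), map_quality=float(mq),
                )
            )
    return calls


def read_basecalls_sam(path, contig: str, position: int) -> list[AlignedBaseCall]:
    """Extract base calls overlapping a 1-based position from SAM/BAM."""
    import pysam  # optional dependency

    calls = []
    with pysam.AlignmentFile(str(path)) as af:
        for col in af.pileup(contig, position - 1, position, truncate=True,
                             min_base_quality=0, min_mapping_quality=0):
            if col.reference_pos != position - 1:
                continue
            for pr in col.pileups:
                if pr.is_del or pr.is_refskip or pr.query_position is None:
                    continue
                aln = pr.alignment
                calls.append(
                    AlignedBaseCall(
                        read_id=aln.query_name,
                        base=aln.query_sequence[pr.query_position].upper(),
                        base_quality=float(
                            aln.query_qualities[pr.query_position]
                        ),
                        map_quality=float(aln.mapping_quality),
                    )
                )
    return calls
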