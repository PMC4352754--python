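"""Clone-level off-target attribution filters.

Whole-genome comparison of independently derived edited clones rests on the
observation that Cas9-induced repair outcomes differ between clones, so a
true de novo mutation should be private to one sample.  Three filters
implement that logic:

* sample-specific variant selection — discard every variant shared by two
  or more samples (removes pre-existing germline variation and recurrent
  pipeline artifacts);
* discordant-read support — keep only rearrangement calls backed by at
  least four discordant read pairs / split reads;
* flanking homology search — around each retained indel, slide the guide
  across a ±100 bp window on both strands looking for a gRNA homologue
  (more than 15 of 20 matched bases, i.e. >75% identity); a passing hit
  attributes the indel to Cas9 activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_io import Genome, GenomicInterval, reverse_complement
from .offtarget_scan import GuideRna

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    type: str  # {snv, indel}

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SampleVariantTable:
    sample_id: str
    variants: tuple[Variant, ...]

    def __post_init__(self) -> None:
        keys = [v.key() for v in self.variants]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate variants in sample {self.sample_id!r}")


@dataclass(frozen=True)
class RearrangementCall:
    sample_id: str
    type: str  # {deletion, duplication, inversion, translocation}
    breakpoints: tuple[GenomicInterval, GenomicInterval]
    support: int  # discordant read count

    def __post_init__(self) -> None:
        if self.support < 0:
            raise ValueError("support must be non-negative")


@dataclass(frozen=True)
class HomologyHit:
    """An ungapped guide match near an indel locus."""

    locus: GenomicInterval  # the indel locus the window is anchored on
    offset: int  # guide start relative to the locus midpoint
    strand: str
    matched_bases: int
    passes: bool
    mismatch_positions: tuple[int, ...] = ()  # PAM-anchored, passing hits only


def sample_specific_variants(
    tables: Sequence[SampleVariantTable],
) -> dict[str, list[Variant]]:
    """Retain, per sample, the variants present in that sample and no other.

    Variants are keyed by (chrom, pos, ref, alt).  Requires at least two
    samples — with a single sample the shared-variant filter is undefined.
    """
    if len(tables) < 2:
        raise ValueError("sample-specific filtering requires at least two samples")
    occurrence: dict[tuple, int] = {}
    for table in tables:
        for v in table.variants:
            occurrence[v.key()] = occurrence.get(v.key(), 0) + 1
    return {
        table.sample_id: [v for v in table.variants if occurrence[v.key()] == 1]
        for table in tables
    }


def filter_rearrangements(
    calls: Iterable[RearrangementCall], min_support: int = 4
) -> list[RearrangementCall]:
    """Keep rearrangement calls supported by >= ``min_support`` discordant reads."""
    return [c for c in calls if c.support >= min_support]


def flanking_homology_search(
    genome: Genome,
    locus: GenomicInterval,
    guide: GuideRna,
    flank: int = 100,
    min_matched: int = 16,
) -> list[HomologyHit]:
    """Slide the guide across ±``flank`` bp around the locus midpoint, both
    strands, scoring ungapped identity at every offset.

    Hits with ``matched_bases >= min_matched`` (default 16 of 20, i.e. the
    ">15 bp / >75%" homology rule) have ``passes=True`` and carry their
    PAM-anchored mismatch positions.  All evaluated offsets are returned so
    callers can inspect the best non-passing score.  Windows truncated at
    chromosome ends are allowed (and logged).
    """
    chrom_len = genome.chrom_length(locus.chrom)
    seq = genome[locus.chrom]
    L = guide.length
    mid = (locus.start + locus.end) // 2
    lo = max(0, mid - flank)
    hi = min(chrom_len - L, mid + flank)
    if lo != mid - flank or hi != mid + flank:
        logger.info(
            "homology window at %s:%d truncated to [%d, %d]", locus.chrom, mid, lo, hi
        )
    hits: list[HomologyHit] = []
    for start in range(lo, hi + 1):
        window = seq[start : start + L]
        for strand, candidate in (("+", window), ("-", reverse_complement(window))):
            mismatches = [
                L - j for j in range(L) if guide.protospacer[j] != candidate[j]
            ]
            matched = L - len(mismatches)
            passes = matched >= min_matched
            hits.append(
                HomologyHit(
                    locus=locus,
                    offset=start - mid,
                    strand=strand,
                    matched_bases=matched,
                    passes=passes,
                    mismatch_positions=tuple(sorted(mismatches)) if passes else (),
                )
            )
    return hits


def passing_homology_hits(hits: Iterable[HomologyHit]) -> list[HomologyHit]:
    return [h for h in hits if h.passes]


def best_homology_score(hits: Iterable[HomologyHit]) -> int:
    return max((h.matched_bases for h in hits), default=0)
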