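"""Sequence and variant input/output, plus the coordinate conventions shared
by every other module.

Conventions
-----------
* All internal coordinates are **0-based half-open** on the plus strand of a
  chromosome.  1-based inclusive coordinates appear only at I/O boundaries:
  VCF positions and "printed" loci such as ``chr5:7,924,778-7,924,799``.
  :func:`printed_to_interval` / :func:`interval_to_printed` convert between
  the two and are exact inverses of each other.
* Sequences are uppercase strings over the alphabet ``{A, C, G, T, N}``.
  ``N`` is permitted in a genome; downstream scanners discard any candidate
  site containing it.
* A minus-strand sequence request returns the reverse complement, i.e. the
  5'->3' sequence of the minus strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeError(ValueError):
    """Malformed genome input (duplicate names, empty or illegal sequence)."""


@dataclass(frozen=True)
class Genome:
    """An in-memory genome: chromosome name -> uppercase ACGTN sequence."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise GenomeError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise GenomeError(
                    f"chromosome {name!r} contains illegal characters {sorted(bad)}"
                )

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def chrom_length(self, chrom: str) -> int:
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return len(self.sequences[chrom])

    def items(self) -> Iterable[tuple[str, str]]:
        return self.sequences.items()


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def printed_to_interval(chrom: str, first: int, last: int, strand: str = "+") -> GenomicInterval:
    """Convert a printed 1-based inclusive locus to an internal interval.

    ``chr5:7,924,778-7,924,799`` becomes ``[7924777, 7924799)`` (length 22).
    """
    return GenomicInterval(chrom, first - 1, last, strand)


def interval_to_printed(interval: GenomicInterval) -> tuple[str, int, int]:
    """Inverse of :func:`printed_to_interval`."""
    return interval.chrom, interval.start + 1, interval.end


@dataclass(frozen=True)
class Snv:
    """A biallelic single-base substitution. ``pos`` is 1-based as in VCF."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    zygosity: str = "unknown"  # {het, hom, unknown}
    id: str | None = None

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("SNV ref and alt bases must differ")
        for b in (self.ref_base, self.alt_base):
            if len(b) != 1 or b not in "ACGT":
                raise ValueError(f"SNV alleles must be single A/C/G/T bases, got {b!r}")
        if self.zygosity not in ("het", "hom", "unknown"):
            raise ValueError(f"invalid zygosity {self.zygosity!r}")

    @property
    def index(self) -> int:
        """0-based position on the chromosome."""
        return self.pos - 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Lower-case input is upcased; multi-line records are concatenated.
    Duplicate names, empty records, and characters outside ACGTN raise
    :class:`GenomeError`.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise GenomeError(f"duplicate FASTA record name {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise GenomeError(f"no FASTA records found in {path}")
    return Genome(sequences)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def extract_sequence(genome: Genome, interval: GenomicInterval) -> str:
    """Sequence of ``interval``; minus-strand requests are reverse complemented."""
    length = genome.chrom_length(interval.chrom)
    if interval.end > length:
        raise ValueError(
            f"interval [{interval.start}, {interval.end}) exceeds "
            f"{interval.chrom} length {length}"
        )
    seq = genome[interval.chrom][interval.start : interval.end]
    return reverse_complement(seq) if interval.strand == "-" else seq


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_snvs(path: str | Path) -> list[Snv]:
    """Read the biallelic single-base substitutions from a VCF 4.x file.

    Indels and multi-allelic records are skipped (counts are logged).  The
    first sample's genotype, when present, sets zygosity; sites without a
    genotype are ``unknown``.
    """
    from cyvcf2 import VCF

    snvs: list[Snv] = []
    n_skipped = 0
    vcf = VCF(str(path))
    has_samples = len(vcf.samples) > 0
    for variant in vcf:
        alts = variant.ALT
        if len(alts) != 1 or len(variant.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        ref, alt = variant.REF.upper(), alts[0].upper()
        if ref not in "ACGT" or alt not in "ACGT":
            n_skipped += 1
            continue
        zygosity = "unknown"
        if has_samples:
            gt_type = variant.gt_types[0]  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            if gt_type == 1:
                zygosity = "het"
            elif gt_type == 3:
                zygosity = "hom"
        snvs.append(
            Snv(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref_base=ref,
                alt_base=alt,
                zygosity=zygosity,
                id=variant.ID,
            )
        )
    vcf.close()
    if n_skipped:
        logger.info("read_vcf_snvs: skipped %d non-SNV/multi-allelic records", n_skipped)
    return snvs


_GT_BY_ZYGOSITY = {"het": "0/1", "hom": "1/1", "unknown": "./."}


def write_vcf_snvs(
    snvs: Iterable[Snv],
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
    sample: str = "sample1",
) -> None:
    """Write SNVs as a minimal VCF 4.2 file with a single sample's GT field."""
    snvs = sorted(snvs, key=lambda s: (s.chrom, s.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cas9audit\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for s in snvs:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.id or '.'}\t{s.ref_base}\t{s.alt_base}"
                f"\t.\t.\t.\tGT\t{_GT_BY_ZYGOSITY[s.zygosity]}\n"
            )


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read id, uppercase sequence) pairs from a FASTQ file."""
    for record in SeqIO.parse(str(path), "fastq"):
        yield record.id, str(record.seq).upper()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I") -> None:
    """Write (id, sequence) pairs as FASTQ with a constant quality string."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
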