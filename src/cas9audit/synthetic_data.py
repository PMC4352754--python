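"""Synthetic inputs with exact ground truth for every pipeline stage.

The generators emulate the study conditions end to end: a genome carrying
one on-target site and planted off-target families at chosen mismatch
counts/positions, personal SNVs (background density plus explicit
mismatch-correcting SNVs), amplicon reads with programmed per-allele indel
fractions and a heterozygous discriminating SNV, and multi-clone variant
tables with shared and sample-unique records.

Construction is verified, not trusted: a genome build is accepted only
after a brute-force scan confirms the planted sites are *exactly* the
``<= max_mm`` hit set (no accidental background hits), which makes the
oracle tests exact.  All randomness flows from a single seeded
``numpy.random.Generator``, so a fixed seed reproduces every byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .clone_screen import RearrangementCall, SampleVariantTable, Variant
from .genome_io import Genome, GenomicInterval, Snv, reverse_complement
from .offtarget_scan import GuideRna, OffTargetHit, scan_offtargets
from .amplicon_indels import Amplicon

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_sequence(length: int, gc_fraction: float, rng: np.random.Generator) -> str:
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return _BASES[idx].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Genome with planted off-target families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSiteSpec:
    """Request for planted sites: ``copies`` sites with ``mismatch_count``
    mismatches at ``positions`` (PAM-anchored; None = random positions)."""

    mismatch_count: int
    positions: tuple[int, ...] | None = None
    copies: int = 1

    def __post_init__(self) -> None:
        if self.positions is not None and len(self.positions) != self.mismatch_count:
            raise ValueError("positions must match mismatch_count")
        if self.copies < 0:
            raise ValueError("copies must be non-negative")


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth record of one planted site (plus-strand protospacer
    interval; sequences reported on the guide-matching strand)."""

    start: int
    end: int
    strand: str
    mismatch_count: int
    mismatch_positions: frozenset[int]
    protospacer_seq: str
    pam_seq: str

    def interval(self, chrom: str) -> GenomicInterval:
        return GenomicInterval(chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class ConversionTruth:
    """A planted SNV that corrects one mismatch of a planted site."""

    site_index: int
    snv: Snv
    position: int  # PAM-anchored position corrected
    m_after: int


@dataclass(frozen=True)
class ReadLabel:
    read_id: str
    allele: str  # {ref, var, single}
    has_indel: bool
    indel_type: str | None = None
    indel_length: int = 0


@dataclass
class GroundTruth:
    """Accumulated truth across generators (sections filled as used)."""

    chrom: str = "chr_sim"
    sites: tuple[PlantedSite, ...] = ()
    snvs: tuple[Snv, ...] = ()
    conversions: tuple[ConversionTruth, ...] = ()
    read_labels: tuple[ReadLabel, ...] = ()
    clone_unique: dict[str, tuple[Variant, ...]] = field(default_factory=dict)
    clone_shared: tuple[Variant, ...] = ()
    rearrangement_supports: tuple[int, ...] = ()


@dataclass(frozen=True)
class GenomeSimConfig:
    genome_length: int = 100_000
    gc_fraction: float = 0.41  # human-like background composition
    chrom: str = "chr_sim"
    planted: tuple[PlantedSiteSpec, ...] = (
        PlantedSiteSpec(0, (), 1),
        PlantedSiteSpec(3, None, 5),
    )
    max_mm: int = 3
    max_resamples: int = 30

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must be within [0, 1]")


def _mutate_protospacer(
    protospacer: str, positions: Sequence[int], rng: np.random.Generator
) -> str:
    L = len(protospacer)
    seq = list(protospacer)
    for pos in positions:  # PAM-anchored position -> 0-based 5' offset
        j = L - pos
        choices = [b for b in "ACGT" if b != seq[j]]
        seq[j] = choices[rng.integers(0, 3)]
    return "".join(seq)


def _attempt_build(
    guide: GuideRna, config: GenomeSimConfig, rng: np.random.Generator
) -> tuple[Genome, tuple[PlantedSite, ...]]:
    L, P = guide.length, guide.pam_length
    footprint = L + P
    total = sum(s.copies for s in config.planted)
    if config.genome_length < 10 * footprint * max(total, 1):
        raise ValueError("genome_length too small for the requested planted sites")
    background = list(random_sequence(config.genome_length, config.gc_fraction, rng))

    # non-overlapping embedding slots, padded so sites cannot interact
    starts: list[int] = []
    guard = footprint + 10
    attempts = 0
    while len(starts) < total:
        cand = int(rng.integers(0, config.genome_length - footprint))
        if all(abs(cand - s) >= guard for s in starts):
            starts.append(cand)
        attempts += 1
        if attempts > 1000 * max(total, 1):
            raise ValueError("could not place planted sites without overlap")

    planted: list[PlantedSite] = []
    slot = 0
    for spec in config.planted:
        for _ in range(spec.copies):
            embed_at = starts[slot]
            slot += 1
            if spec.positions is not None:
                positions = tuple(spec.positions)
            else:
                positions = tuple(
                    sorted(
                        int(p)
                        for p in rng.choice(
                            np.arange(1, L + 1), size=spec.mismatch_count, replace=False
                        )
                    )
                )
            proto = _mutate_protospacer(guide.protospacer, positions, rng)
            pam = "ACGT"[rng.integers(0, 4)] + "GG"
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                text = proto + pam
                proto_start = embed_at
            else:
                text = reverse_complement(proto + pam)
                proto_start = embed_at + P
            background[embed_at : embed_at + footprint] = list(text)
            planted.append(
                PlantedSite(
                    start=proto_start,
                    end=proto_start + L,
                    strand=strand,
                    mismatch_count=len(positions),
                    mismatch_positions=frozenset(positions),
                    protospacer_seq=proto,
                    pam_seq=pam,
                )
            )
    genome = Genome({config.chrom: "".join(background)})
    return genome, tuple(sorted(planted, key=lambda s: (s.start, s.strand)))


def _hits_match_truth(hits: list[OffTargetHit], planted: tuple[PlantedSite, ...]) -> bool:
    got = {
        (h.site.interval.start, h.site.interval.strand, h.mismatch_count, h.mismatch_positions)
        for h in hits
    }
    want = {
        (s.start, s.strand, s.mismatch_count, s.mismatch_positions) for s in planted
    }
    return got == want


def build_genome(
    guide: GuideRna, config: GenomeSimConfig, seed
) -> tuple[Genome, GroundTruth]:
    """Construct a genome whose ``<= max_mm`` hit set is exactly the planted
    sites, verified by a brute-force scan (resampled on collision)."""
    rng = _rng(seed)
    last_error: Exception | None = None
    for _ in range(config.max_resamples):
        genome, planted = _attempt_build(guide, config, rng)
        hits = scan_offtargets(guide, genome, max_mm=config.max_mm, method="brute")
        if _hits_match_truth(hits, planted):
            return genome, GroundTruth(chrom=config.chrom, sites=planted)
    raise RuntimeError(
        f"could not build a collision-free genome in {config.max_resamples} resamples"
    ) from last_error


# ---------------------------------------------------------------------------
# SNV planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnvSimConfig:
    background_density: float = 0.0005  # per bp, outside planted footprints
    n_converting: int = 2
    converting_zygosity: str = "het"
    explicit_conversions: tuple[tuple[int, int], ...] | None = None  # (site_idx, position)

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_density <= 1.0):
            raise ValueError("background_density must be within [0, 1]")


def _converting_snv(
    genome: Genome,
    chrom: str,
    guide: GuideRna,
    site: PlantedSite,
    position: int,
    zygosity: str,
) -> Snv:
    """An SNV whose alternate allele restores the guide base at a
    mismatching PAM-anchored ``position`` of ``site``."""
    if position not in site.mismatch_positions:
        raise ValueError(
            f"site at {site.start} has no mismatch at position {position}"
        )
    L = guide.length
    j = L - position  # 0-based guide-strand protospacer offset
    if site.strand == "+":
        idx = site.start + j
        ref_plus = site.protospacer_seq[j]
        alt_plus = guide.protospacer[j]
    else:
        idx = site.end - 1 - j
        ref_plus = _COMP[site.protospacer_seq[j]]
        alt_plus = _COMP[guide.protospacer[j]]
    assert genome[chrom][idx] == ref_plus
    return Snv(chrom, idx + 1, ref_plus, alt_plus, zygosity)


def plant_snvs(
    genome: Genome,
    truth: GroundTruth,
    guide: GuideRna,
    config: SnvSimConfig,
    seed,
) -> tuple[list[Snv], GroundTruth]:
    """Plant mismatch-correcting SNVs on three-mismatch sites plus background
    SNVs that avoid every planted protospacer/PAM footprint."""
    rng = _rng(seed)
    chrom = truth.chrom
    seq = genome[chrom]
    L, P = guide.length, guide.pam_length

    three_mm = [i for i, s in enumerate(truth.sites) if s.mismatch_count == 3]
    if config.explicit_conversions is not None:
        chosen = list(config.explicit_conversions)
    else:
        if config.n_converting > len(three_mm):
            raise ValueError(
                f"requested {config.n_converting} converting SNVs but only "
                f"{len(three_mm)} three-mismatch sites are planted"
            )
        site_indices = rng.choice(len(three_mm), size=config.n_converting, replace=False)
        chosen = []
        for si in site_indices:
            site = truth.sites[three_mm[int(si)]]
            positions = sorted(site.mismatch_positions)
            chosen.append((three_mm[int(si)], positions[int(rng.integers(0, len(positions)))]))

    snvs: list[Snv] = []
    conversions: list[ConversionTruth] = []
    for site_index, position in chosen:
        site = truth.sites[site_index]
        snv = _converting_snv(
            genome, chrom, guide, site, position, config.converting_zygosity
        )
        snvs.append(snv)
        conversions.append(
            ConversionTruth(site_index, snv, position, site.mismatch_count - 1)
        )

    # background SNVs outside every planted footprint (protospacer + PAM +/- 1)
    excluded = set(s.pos - 1 for s in snvs)
    for site in truth.sites:
        lo = site.start - P - 1 if site.strand == "-" else site.start - 1
        hi = site.end + P + 1 if site.strand == "+" else site.end + 1
        excluded.update(range(max(0, lo), min(len(seq), hi)))
    n_background = int(rng.binomial(len(seq), config.background_density))
    placed = 0
    attempts = 0
    while placed < n_background and attempts < 50 * max(n_background, 1):
        attempts += 1
        idx = int(rng.integers(0, len(seq)))
        if idx in excluded or seq[idx] == "N":
            continue
        excluded.add(idx)
        ref = seq[idx]
        alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
        zyg = "het" if rng.random() < 0.5 else "hom"
        snvs.append(Snv(chrom, idx + 1, ref, alt, zyg))
        placed += 1

    snvs.sort(key=lambda s: s.pos)
    new_truth = replace_truth(truth, snvs=tuple(snvs), conversions=tuple(conversions))
    return snvs, new_truth


def replace_truth(truth: GroundTruth, **kwargs) -> GroundTruth:
    data = {
        "chrom": truth.chrom,
        "sites": truth.sites,
        "snvs": truth.snvs,
        "conversions": truth.conversions,
        "read_labels": truth.read_labels,
        "clone_unique": truth.clone_unique,
        "clone_shared": truth.clone_shared,
        "rearrangement_supports": truth.rearrangement_supports,
    }
    data.update(kwargs)
    return GroundTruth(**data)


# ---------------------------------------------------------------------------
# Amplicon read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmpliconSimConfig:
    n_reads: int = 10_000
    indel_fraction: float = 0.54  # single-allele (or ref-allele) indel fraction
    var_indel_fraction: float | None = None  # per-allele mode when set
    var_allele_fraction: float = 0.5
    substitution_error: float = 0.002
    deletion_prob: float = 0.8  # remaining mass is insertions
    deletion_lengths: tuple[int, int] = (1, 10)  # uniform, inclusive
    insertion_lengths: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        for f in (
            self.indel_fraction,
            self.var_allele_fraction,
            self.substitution_error,
            self.deletion_prob,
        ):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must be within [0, 1]")
        if self.var_indel_fraction is not None and not (0.0 <= self.var_indel_fraction <= 1.0):
            raise ValueError("fractions must be within [0, 1]")


def _apply_indel(
    seq: str, cut: int, config: AmpliconSimConfig, rng: np.random.Generator
) -> tuple[str, str, int]:
    if rng.random() < config.deletion_prob:
        lo, hi = config.deletion_lengths
        length = int(rng.integers(lo, hi + 1))
        # start so the deletion always removes the base 5' of the cut boundary
        start = cut - int(rng.integers(1, length + 1))
        start = max(1, min(start, len(seq) - length - 1))
        return seq[:start] + seq[start + length :], "del", length
    lo, hi = config.insertion_lengths
    length = int(rng.integers(lo, hi + 1))
    pos = cut + int(rng.integers(-3, 4))
    pos = max(1, min(pos, len(seq) - 1))
    insert = random_sequence(length, 0.5, rng)
    return seq[:pos] + insert + seq[pos:], "ins", length


def _apply_substitution_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


def simulate_amplicon_reads(
    amplicon: Amplicon, config: AmpliconSimConfig, seed
) -> tuple[list[tuple[str, str]], list[ReadLabel]]:
    """Simulate amplicon-spanning reads with programmed per-allele indel
    fractions, cut-site-overlapping indels, and uniform substitution error.

    With ``var_indel_fraction`` set (requires an amplicon SNV) reads are
    drawn from the ref/var alleles at ``var_allele_fraction``; otherwise a
    single allele with ``indel_fraction`` is simulated.  Per-read truth
    labels record allele and indel status.
    """
    rng = _rng(seed)
    two_allele = config.var_indel_fraction is not None
    if two_allele and amplicon.snv_offset is None:
        raise ValueError("per-allele simulation requires an amplicon SNV")
    var_seq = amplicon.variant_sequence() if amplicon.snv_offset is not None else None
    reads: list[tuple[str, str]] = []
    labels: list[ReadLabel] = []
    for i in range(config.n_reads):
        if two_allele:
            is_var = rng.random() < config.var_allele_fraction
            allele = "var" if is_var else "ref"
            template = var_seq if is_var else amplicon.sequence
            f_indel = config.var_indel_fraction if is_var else config.indel_fraction
        else:
            allele = "single"
            template = amplicon.sequence
            f_indel = config.indel_fraction
        has_indel = rng.random() < f_indel
        indel_type: str | None = None
        indel_len = 0
        seq = template
        if has_indel:
            seq, indel_type, indel_len = _apply_indel(
                seq, amplicon.cut_offset, config, rng
            )
        seq = _apply_substitution_errors(seq, config.substitution_error, rng)
        read_id = f"{amplicon.name}_read{i}"
        reads.append((read_id, seq))
        labels.append(ReadLabel(read_id, allele, has_indel, indel_type, indel_len))
    return reads, labels


# ---------------------------------------------------------------------------
# Clone variant tables and rearrangements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CloneSimConfig:
    n_samples: int = 3
    n_shared: int = 5
    unique_counts: tuple[int, ...] = (3, 4, 2)
    rearrangement_supports: tuple[int, ...] = (3, 4, 5)
    chrom: str = "chr_sim"
    genome_length: int = 100_000
    indel_prob: float = 0.5  # fraction of variants that are indels

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if len(self.unique_counts) != self.n_samples:
            raise ValueError("unique_counts must have one entry per sample")


def _random_variant(chrom: str, pos: int, rng: np.random.Generator, indel_prob: float) -> Variant:
    ref = "ACGT"[rng.integers(0, 4)]
    if rng.random() < indel_prob:
        extra = random_sequence(int(rng.integers(1, 6)), 0.5, rng)
        return Variant(chrom, pos, ref, ref + extra, "indel")
    alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
    return Variant(chrom, pos, ref, alt, "snv")


def simulate_clone_tables(
    config: CloneSimConfig, seed
) -> tuple[list[SampleVariantTable], list[RearrangementCall], GroundTruth]:
    """Multi-sample variant tables with shared (>= 2 samples) and
    sample-unique records, plus rearrangement calls at given supports."""
    rng = _rng(seed)
    sample_ids = [f"clone{i + 1}" for i in range(config.n_samples)]
    n_total = config.n_shared + sum(config.unique_counts)
    positions = rng.choice(
        np.arange(1, config.genome_length + 1), size=n_total, replace=False
    )
    positions = [int(p) for p in positions]
    variants = [
        _random_variant(config.chrom, p, rng, config.indel_prob) for p in positions
    ]
    shared = variants[: config.n_shared]
    per_sample: dict[str, list[Variant]] = {s: [] for s in sample_ids}
    for v in shared:
        k = int(rng.integers(2, config.n_samples + 1))
        carriers = rng.choice(config.n_samples, size=k, replace=False)
        for c in carriers:
            per_sample[sample_ids[int(c)]].append(v)
    unique: dict[str, list[Variant]] = {s: [] for s in sample_ids}
    cursor = config.n_shared
    for sid, count in zip(sample_ids, config.unique_counts):
        for _ in range(count):
            v = variants[cursor]
            cursor += 1
            per_sample[sid].append(v)
            unique[sid].append(v)
    tables = [
        SampleVariantTable(sid, tuple(sorted(per_sample[sid], key=lambda v: v.pos)))
        for sid in sample_ids
    ]
    calls = []
    for support in config.rearrangement_supports:
        sid = sample_ids[int(rng.integers(0, config.n_samples))]
        rtype = ["deletion", "duplication", "inversion", "translocation"][
            int(rng.integers(0, 4))
        ]
        b1 = int(rng.integers(0, config.genome_length - 1))
        b2 = int(rng.integers(0, config.genome_length - 1))
        calls.append(
            RearrangementCall(
                sid,
                rtype,
                (
                    GenomicInterval(config.chrom, b1, b1 + 1),
                    GenomicInterval(config.chrom, b2, b2 + 1),
                ),
                int(support),
            )
        )
    truth = GroundTruth(
        chrom=config.chrom,
        clone_unique={s: tuple(unique[s]) for s in sample_ids},
        clone_shared=tuple(shared),
        rearrangement_supports=tuple(config.rearrangement_supports),
    )
    return tables, calls, truth
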