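"""Genome-wide enumeration of PAM-adjacent candidate sites and k-mismatch
off-target search.

A guide is a protospacer of length ``L`` (default 20 nt) plus an IUPAC PAM
pattern (default ``NGG``, the S. pyogenes motif).  Mismatch positions are
numbered from the PAM: position 1 is the base immediately adjacent to the
PAM (PAM-proximal), position ``L`` is the 5'-most, PAM-distal base.

Two scan strategies are provided and must agree exactly:

* ``brute`` — position-wise comparison of every genomic window on both
  strands (vectorised with numpy).
* ``seed``  — pigeonhole seeding: the protospacer is split into
  ``max_mm + 1`` contiguous seeds; any site with at most ``max_mm``
  mismatches must contain at least one seed exactly, so exact seed matches
  generate the candidate set, which is then verified base by base.

Candidate windows containing ``N`` are discarded: an ambiguous base cannot
be confidently matched against the guide.  Two hits on opposite strands at
the same locus are distinct records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .genome_io import Genome, GenomicInterval, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class GuideRna:
    """A guide RNA: protospacer (5'->3', DNA alphabet) plus PAM pattern."""

    name: str
    protospacer: str
    pam_pattern: str = "NGG"

    def __post_init__(self) -> None:
        if len(self.protospacer) < 10:
            raise ValueError("protospacer must be at least 10 nt")
        if set(self.protospacer) - set("ACGT"):
            raise ValueError("protospacer must be over A/C/G/T")
        if set(self.pam_pattern) - set(IUPAC):
            raise ValueError(f"invalid IUPAC code in PAM pattern {self.pam_pattern!r}")

    @property
    def length(self) -> int:
        return len(self.protospacer)

    @property
    def pam_length(self) -> int:
        return len(self.pam_pattern)


@dataclass(frozen=True)
class TargetSite:
    """A PAM-valid genomic window.

    ``interval`` spans the protospacer in plus-strand coordinates.  On the
    minus strand, ``protospacer_seq`` and ``pam_seq`` are reported 5'->3' on
    the guide-matching (minus) strand; the PAM then lies immediately to the
    *left* of ``interval`` in plus-strand coordinates.
    """

    interval: GenomicInterval
    protospacer_seq: str
    pam_seq: str

    @property
    def strand(self) -> str:
        return self.interval.strand

    def pam_interval(self) -> GenomicInterval:
        """Plus-strand coordinates of the PAM."""
        p = len(self.pam_seq)
        if self.strand == "+":
            return GenomicInterval(self.interval.chrom, self.interval.end, self.interval.end + p, "+")
        return GenomicInterval(self.interval.chrom, self.interval.start - p, self.interval.start, "-")


@dataclass(frozen=True)
class OffTargetHit:
    """A target site together with its mismatch profile against a guide."""

    site: TargetSite
    mismatch_count: int
    mismatch_positions: frozenset[int]  # PAM-anchored, 1 = PAM-proximal

    def __post_init__(self) -> None:
        if self.mismatch_count != len(self.mismatch_positions):
            raise ValueError("mismatch_count must equal |mismatch_positions|")

    def sort_key(self) -> tuple:
        i = self.site.interval
        return (i.chrom, i.start, i.strand)


def pam_matches(pam_pattern: str, seq: str) -> bool:
    """True iff ``seq`` matches the IUPAC ``pam_pattern`` (N in the genome
    never matches — ambiguous bases are not trusted)."""
    if len(seq) != len(pam_pattern):
        return False
    return all(base in IUPAC[code] for code, base in zip(pam_pattern, seq))


def mismatch_profile(guide: GuideRna | str, site_seq: str) -> tuple[int, frozenset[int]]:
    """Compare a protospacer to a site sequence of equal length.

    Returns ``(m, positions)`` with PAM-anchored numbering: position ``i``
    compares the base ``i`` steps upstream of the PAM, so position 1 is the
    3'-terminal protospacer base and position ``L`` the 5'-most.
    """
    proto = guide.protospacer if isinstance(guide, GuideRna) else guide
    L = len(proto)
    if len(site_seq) != L:
        raise ValueError(f"site sequence length {len(site_seq)} != protospacer length {L}")
    positions = frozenset(L - j for j in range(L) if proto[j] != site_seq[j])
    return len(positions), positions


# ---------------------------------------------------------------------------
# Candidate enumeration and scanning
# ---------------------------------------------------------------------------

def _strand_views(seq: str) -> list[tuple[str, str]]:
    """The two strand-specific texts to scan: (text, strand). A hit at offset
    ``i`` in the minus-strand text maps back to plus coordinates
    ``[G - i - L, G - i)`` for the protospacer."""
    return [(seq, "+"), (reverse_complement(seq), "-")]


def _site_from_offset(chrom: str, glen: int, text: str, strand: str, i: int, L: int, P: int) -> TargetSite:
    proto = text[i : i + L]
    pam = text[i + L : i + L + P]
    if strand == "+":
        interval = GenomicInterval(chrom, i, i + L, "+")
    else:
        interval = GenomicInterval(chrom, glen - i - L, glen - i, "-")
    return TargetSite(interval, proto, pam)


def enumerate_pam_sites(genome: Genome, guide: GuideRna) -> Iterator[TargetSite]:
    """Yield every N-free, PAM-valid candidate window on both strands."""
    L, P = guide.length, guide.pam_length
    for chrom, seq in genome.items():
        glen = len(seq)
        for text, strand in _strand_views(seq):
            for i in range(glen - L - P + 1):
                window = text[i : i + L + P]
                if "N" in window:
                    continue
                if pam_matches(guide.pam_pattern, window[L:]):
                    yield _site_from_offset(chrom, glen, text, strand, i, L, P)


def _scan_text_brute(text: str, guide: GuideRna, max_mm: int) -> Iterator[tuple[int, int]]:
    """Yield (offset, mismatch_count) of PAM-valid windows with m <= max_mm
    in a single strand text, vectorised."""
    L, P = guide.length, guide.pam_length
    W = len(text) - L - P + 1
    if W <= 0:
        return
    arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    garr = np.frombuffer(guide.protospacer.encode("ascii"), dtype=np.uint8)
    mm = np.zeros(W, dtype=np.int16)
    for j in range(L):
        mm += arr[j : j + W] != garr[j]
    # exclude any window (protospacer + PAM) containing N
    n_cum = np.concatenate(([0], np.cumsum(arr == ord("N"))))
    has_n = (n_cum[L + P :] - n_cum[: -(L + P)]) > 0
    pam_ok = np.ones(W, dtype=bool)
    for k, code in enumerate(guide.pam_pattern):
        allowed = np.frombuffer(IUPAC[code].encode("ascii"), dtype=np.uint8)
        pam_ok &= np.isin(arr[L + k : L + k + W], allowed)
    valid = np.flatnonzero(pam_ok & ~has_n & (mm <= max_mm))
    for i in valid:
        yield int(i), int(mm[i])


def _pigeonhole_seeds(protospacer: str, k: int) -> list[tuple[int, str]]:
    """Split the protospacer into k contiguous seeds, as evenly as possible."""
    L = len(protospacer)
    bounds = np.linspace(0, L, k + 1).astype(int)
    return [(int(a), protospacer[a:b]) for a, b in zip(bounds[:-1], bounds[1:])]


def _scan_text_seed(text: str, guide: GuideRna, max_mm: int) -> Iterator[tuple[int, int]]:
    """Seed-and-verify scan of a single strand text."""
    L, P = guide.length, guide.pam_length
    limit = len(text) - L - P
    if limit < 0:
        return
    candidates: set[int] = set()
    for off, seed in _pigeonhole_seeds(guide.protospacer, max_mm + 1):
        pos = text.find(seed)
        while pos != -1:
            i = pos - off
            if 0 <= i <= limit:
                candidates.add(i)
            pos = text.find(seed, pos + 1)
    for i in sorted(candidates):
        window = text[i : i + L + P]
        if "N" in window:
            continue
        if not pam_matches(guide.pam_pattern, window[L:]):
            continue
        m = sum(a != b for a, b in zip(guide.protospacer, window[:L]))
        if m <= max_mm:
            yield i, m


def scan_offtargets(
    guide: GuideRna,
    genome: Genome,
    max_mm: int = 3,
    method: str = "seed",
) -> list[OffTargetHit]:
    """All PAM-valid sites with at most ``max_mm`` mismatches, both strands.

    ``method`` selects ``"brute"`` (exhaustive window comparison) or
    ``"seed"`` (pigeonhole-accelerated); the two return identical hit sets.
    Hits are sorted by (chrom, start, strand).
    """
    if max_mm > guide.length:
        raise ValueError(f"max_mm={max_mm} exceeds protospacer length {guide.length}")
    if method not in ("brute", "seed"):
        raise ValueError(f"unknown scan method {method!r}")
    scan_text = _scan_text_brute if method == "brute" else _scan_text_seed
    L, P = guide.length, guide.pam_length
    hits: list[OffTargetHit] = []
    for chrom, seq in genome.items():
        glen = len(seq)
        for text, strand in _strand_views(seq):
            for i, m in scan_text(text, guide, max_mm):
                site = _site_from_offset(chrom, glen, text, strand, i, L, P)
                m_check, positions = mismatch_profile(guide, site.protospacer_seq)
                assert m_check == m
                hits.append(OffTargetHit(site, m, positions))
    hits.sort(key=OffTargetHit.sort_key)
    return hits


def count_offtargets_per_target(
    targets: Iterable[GuideRna],
    genome: Genome,
    mm: int = 3,
    loci: dict[str, GenomicInterval] | None = None,
    method: str = "seed",
) -> dict[str, int]:
    """Per-guide count of off-target sites with exactly ``mm`` mismatches.

    The guide's own locus is excluded.  When ``loci`` gives a guide's stated
    on-target interval, the genome is checked to carry the protospacer there
    (error otherwise); without stated loci every perfect-match site is
    treated as the target's own locus and excluded.
    """
    counts: dict[str, int] = {}
    for guide in targets:
        hits = scan_offtargets(guide, genome, max_mm=mm, method=method)
        own: GenomicInterval | None = loci.get(guide.name) if loci else None
        if own is not None:
            at_locus = [h for h in hits if h.site.interval == own and h.mismatch_count == 0]
            if not at_locus:
                raise ValueError(
                    f"target {guide.name!r} not found at stated locus {own}"
                )
        counts[guide.name] = sum(
            1
            for h in hits
            if h.mismatch_count == mm
            and (own is None or h.site.interval != own)
        )
    return counts


# ---------------------------------------------------------------------------
# TSV / BED interchange
# ---------------------------------------------------------------------------

def read_guides_tsv(path: str | Path) -> list[GuideRna]:
    """Read guides from a TSV with columns: name, protospacer, pam."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "protospacer"}
    if not required <= set(df.columns):
        raise ValueError(f"guide TSV must have columns {sorted(required)}")
    guides = []
    for row in df.itertuples(index=False):
        pam = getattr(row, "pam", None) or "NGG"
        guides.append(GuideRna(row.name, row.protospacer.upper(), pam))
    return guides


def hits_to_frame(guide: GuideRna, hits: Iterable[OffTargetHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        i = h.site.interval
        rows.append(
            {
                "guide": guide.name,
                "chrom": i.chrom,
                "start": i.start,
                "end": i.end,
                "strand": i.strand,
                "mismatches": h.mismatch_count,
                "mismatch_positions": ",".join(map(str, sorted(h.mismatch_positions))),
                "site_seq": h.site.protospacer_seq,
                "pam_seq": h.site.pam_seq,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "guide", "chrom", "start", "end", "strand",
            "mismatches", "mismatch_positions", "site_seq", "pam_seq",
        ],
    )


def write_hits_tsv(guide: GuideRna, hits: Iterable[OffTargetHit], path: str | Path) -> None:
    hits_to_frame(guide, hits).to_csv(path, sep="\t", index=False)


def write_hits_bed(guide: GuideRna, hits: Iterable[OffTargetHit], path: str | Path) -> None:
    """BED6 export: name = guide, score = mismatch count."""
    with open(path, "w") as fh:
        for h in hits:
            i = h.site.interval
            fh.write(
                f"{i.chrom}\t{i.start}\t{i.end}\t{guide.name}\t{h.mismatch_count}\t{i.strand}\n"
            )
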