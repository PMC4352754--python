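"""Amplicon deep-sequencing indel quantification.

Cas9 activity at a site is measured as the fraction of amplicon reads
carrying an insertion or deletion overlapping a window around the nuclease
cut site (the blunt cut falls between protospacer positions 3 and 4
upstream of the PAM).  When the amplicon carries a heterozygous
discriminating SNV, reads are assigned to the reference or variant allele
by the base observed at that position, yielding per-allele indel fractions
— the readout that separates a two-mismatch variant allele from its
three-mismatch reference counterpart.  Off-target efficiencies are
normalised to the on-target indel fraction ("relative efficiency").

Reads are globally aligned to the amplicon reference with affine gap
penalties (match +2, mismatch -3, gap open -6, gap extend -1); end gaps on
the read are free so partial-coverage reads align to their sub-interval.
Reads below a 60% identity floor over the aligned span are excluded from
all denominators.  Substitution errors never count as indels, so a pure
substitution error process cannot inflate the indel fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    from Bio import Align

DEFAULT_WINDOW = 10  # bp either side of the cut
DEFAULT_MIN_IDENTITY = 0.6
DEFAULT_MIN_READS = 100


@dataclass(frozen=True)
class Amplicon:
    """An amplicon reference with its protospacer, cut site and optional
    allele-discriminating SNV (offsets are 0-based within the amplicon)."""

    name: str
    sequence: str
    protospacer_start: int
    protospacer_end: int
    strand: str = "+"
    cut_offset: int | None = None
    snv_offset: int | None = None
    snv_ref: str | None = None
    snv_alt: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.protospacer_start < self.protospacer_end <= len(self.sequence)):
            raise ValueError("protospacer interval outside the amplicon")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.cut_offset is None:
            object.__setattr__(self, "cut_offset", self.default_cut_offset())
        if not (self.protospacer_start <= self.cut_offset <= self.protospacer_end):
            raise ValueError("cut_offset outside the protospacer")
        if self.snv_offset is not None:
            if not (0 <= self.snv_offset < len(self.sequence)):
                raise ValueError("snv_offset outside the amplicon")
            if self.snv_ref is None or self.snv_alt is None:
                raise ValueError("snv_offset requires snv_ref and snv_alt")
            if self.sequence[self.snv_offset] != self.snv_ref:
                raise ValueError("amplicon sequence does not carry snv_ref at snv_offset")

    def default_cut_offset(self) -> int:
        """Blunt-cut boundary between protospacer positions 3 and 4 upstream
        of the PAM: 3 bp inside the PAM-proximal end of the protospacer."""
        if self.strand == "+":
            return self.protospacer_end - 3
        return self.protospacer_start + 3

    def variant_sequence(self) -> str:
        if self.snv_offset is None:
            raise ValueError("amplicon has no discriminating SNV")
        s = list(self.sequence)
        s[self.snv_offset] = self.snv_alt
        return "".join(s)


@dataclass(frozen=True)
class Indel:
    """An insertion or deletion in amplicon coordinates.  A deletion of
    length k removes reference bases [offset, offset+k); an insertion adds
    k read bases at the reference boundary ``offset``."""

    offset: int
    length: int
    type: str  # {ins, del}


@dataclass(frozen=True)
class ReadAlignment:
    aligned: bool
    indels: tuple[Indel, ...] = ()
    identity: float = 0.0
    ref_span: tuple[int, int] = (0, 0)
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = ()  # ((t0,t1),(q0,q1))


@dataclass(frozen=True)
class ReadCall:
    read_id: str
    aligned: bool
    has_indel_in_window: bool = False
    indels: tuple[Indel, ...] = ()
    allele: str = "undetermined"  # {ref, var, undetermined}


@dataclass(frozen=True)
class AlleleStats:
    n: int
    n_indel: int

    @property
    def fraction(self) -> float:
        return self.n_indel / self.n if self.n else float("nan")


@dataclass(frozen=True)
class SiteEfficiencyReport:
    """Per-site indel quantification with Wilson 95% interval and, when an
    allele-discriminating SNV is defined, the per-allele split."""

    name: str
    n_total: int
    n_pass: int
    n_indel: int
    indel_fraction: float
    ci_low: float
    ci_high: float
    per_allele: dict[str, AlleleStats] = field(default_factory=dict)
    relative_efficiency: float | None = None
    low_coverage: bool = False


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=2,
        mismatch_score=-3,
        open_gap_score=-6,
        extend_gap_score=-1,
    )
    aligner.end_deletion_score = 0  # free end gaps on the read
    return aligner


_ALIGNER = _make_aligner()


def align_read(
    read_seq: str,
    amplicon: Amplicon,
    reference: str | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> ReadAlignment:
    """Global affine-gap alignment of a read to the amplicon reference.

    ``reference`` overrides the amplicon sequence (used to align against
    the variant allele).  Identity is matches over all alignment columns
    between the first and last aligned reference base (internal gap columns
    included); reads under ``min_identity`` are marked unaligned.
    """
    target = reference if reference is not None else amplicon.sequence
    if len(read_seq) < 30:
        return ReadAlignment(aligned=False)
    aln = _ALIGNER.align(target, read_seq)[0]
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return ReadAlignment(aligned=False)
    matches = 0
    columns = 0
    indels: list[Indel] = []
    for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
        seg_t = target[t0:t1]
        seg_q = read_seq[q0:q1]
        matches += sum(a == b for a, b in zip(seg_t, seg_q))
        columns += t1 - t0
    for k in range(1, len(t_blocks)):
        t_gap = int(t_blocks[k][0] - t_blocks[k - 1][1])
        q_gap = int(q_blocks[k][0] - q_blocks[k - 1][1])
        boundary = int(t_blocks[k - 1][1])
        if t_gap > 0:
            indels.append(Indel(boundary, t_gap, "del"))
        if q_gap > 0:
            indels.append(Indel(boundary, q_gap, "ins"))
        columns += t_gap + q_gap
    identity = matches / columns if columns else 0.0
    if identity < min_identity:
        return ReadAlignment(aligned=False, identity=identity)
    blocks = tuple(
        ((int(t0), int(t1)), (int(q0), int(q1)))
        for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks)
    )
    return ReadAlignment(
        aligned=True,
        indels=tuple(sorted(indels, key=lambda d: d.offset)),
        identity=identity,
        ref_span=(int(t_blocks[0][0]), int(t_blocks[-1][1])),
        blocks=blocks,
    )


def _indel_overlaps_window(indel: Indel, lo: int, hi: int) -> bool:
    if indel.type == "del":
        return indel.offset < hi and indel.offset + indel.length > lo
    return lo <= indel.offset <= hi


def _read_base_at(alignment: ReadAlignment, read_seq: str, ref_pos: int) -> str | None:
    """Read base aligned to ``ref_pos``, or None if uncovered/deleted."""
    for (t0, t1), (q0, q1) in alignment.blocks:
        if t0 <= ref_pos < t1:
            return read_seq[q0 + (ref_pos - t0)]
    return None


def classify_read(
    read_id: str,
    read_seq: str,
    alignment: ReadAlignment,
    amplicon: Amplicon,
    window: int = DEFAULT_WINDOW,
) -> ReadCall:
    """Call indel status within ±``window`` bp of the cut and, when the
    amplicon defines a discriminating SNV, the read's allele.

    A read whose base at the SNV offset is deleted or uncovered is
    allele-undetermined rather than guessed.
    """
    if not alignment.aligned:
        return ReadCall(read_id, aligned=False)
    cut = amplicon.cut_offset
    lo, hi = cut - window, cut + window
    has_indel = any(_indel_overlaps_window(d, lo, hi) for d in alignment.indels)
    allele = "undetermined"
    if amplicon.snv_offset is not None:
        base = _read_base_at(alignment, read_seq, amplicon.snv_offset)
        if base == amplicon.snv_ref:
            allele = "ref"
        elif base == amplicon.snv_alt:
            allele = "var"
    return ReadCall(read_id, True, has_indel, alignment.indels, allele)


def call_reads(
    reads: Iterable[tuple[str, str]],
    amplicon: Amplicon,
    window: int = DEFAULT_WINDOW,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[ReadCall]:
    calls = []
    for read_id, seq in reads:
        aln = align_read(seq, amplicon, min_identity=min_identity)
        calls.append(classify_read(read_id, seq, aln, amplicon, window=window))
    return calls


def site_efficiency(
    reads: Iterable[tuple[str, str]],
    amplicon: Amplicon,
    on_target_fraction: float | None = None,
    window: int = DEFAULT_WINDOW,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_reads: int = DEFAULT_MIN_READS,
) -> SiteEfficiencyReport:
    """Quantify indel frequency at an amplicon from (id, sequence) reads.

    ``f_indel`` is indel reads over aligned ("passing") reads, with a Wilson
    95% interval.  With a discriminating SNV the per-allele split is
    reported (ref + var + undetermined = passing).  ``relative_efficiency``
    is ``f_indel / on_target_fraction`` when the latter is given.  Fewer
    than ``min_reads`` passing reads flags the report as low-coverage.
    """
    calls = call_reads(reads, amplicon, window=window, min_identity=min_identity)
    n_total = len(calls)
    passing = [c for c in calls if c.aligned]
    n_pass = len(passing)
    n_indel = sum(c.has_indel_in_window for c in passing)
    if n_pass:
        f = n_indel / n_pass
        lo, hi = proportion_confint(n_indel, n_pass, alpha=0.05, method="wilson")
    else:
        f, lo, hi = float("nan"), float("nan"), float("nan")
    per_allele: dict[str, AlleleStats] = {}
    if amplicon.snv_offset is not None:
        for allele in ("ref", "var", "undetermined"):
            sub = [c for c in passing if c.allele == allele]
            per_allele[allele] = AlleleStats(len(sub), sum(c.has_indel_in_window for c in sub))
    rel = None
    if on_target_fraction is not None and on_target_fraction > 0 and n_pass:
        rel = f / on_target_fraction
    return SiteEfficiencyReport(
        name=amplicon.name,
        n_total=n_total,
        n_pass=n_pass,
        n_indel=n_indel,
        indel_fraction=f,
        ci_low=float(lo),
        ci_high=float(hi),
        per_allele=per_allele,
        relative_efficiency=rel,
        low_coverage=n_pass < min_reads,
    )


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

def read_amplicons_tsv(path: str | Path) -> list[Amplicon]:
    """Amplicon spec TSV: name, sequence, protospacer_start, protospacer_end,
    strand, [cut_offset], [snv_offset, snv_ref, snv_alt]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    amplicons = []
    for row in df.itertuples(index=False):
        def _opt_int(v):
            return None if v is None or pd.isna(v) or v == "" else int(float(v))

        def _opt_str(v):
            return None if v is None or pd.isna(v) or v == "" else str(v)

        amplicons.append(
            Amplicon(
                name=row.name,
                sequence=row.sequence.upper(),
                protospacer_start=int(row.protospacer_start),
                protospacer_end=int(row.protospacer_end),
                strand=getattr(row, "strand", "+") or "+",
                cut_offset=_opt_int(getattr(row, "cut_offset", None)),
                snv_offset=_opt_int(getattr(row, "snv_offset", None)),
                snv_ref=_opt_str(getattr(row, "snv_ref", None)),
                snv_alt=_opt_str(getattr(row, "snv_alt", None)),
            )
        )
    return amplicons


def report_to_frame(reports: Sequence[SiteEfficiencyReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "name": r.name,
            "n_total": r.n_total,
            "n_pass": r.n_pass,
            "n_indel": r.n_indel,
            "indel_fraction": r.indel_fraction,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "relative_efficiency": r.relative_efficiency,
            "low_coverage": r.low_coverage,
        }
        for allele, st in r.per_allele.items():
            row[f"{allele}_n"] = st.n
            row[f"{allele}_indel_fraction"] = st.fraction
        rows.append(row)
    return pd.DataFrame(rows)
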