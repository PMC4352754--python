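"""Personal-genome overlay: apply SNVs to off-target sites and detect
mismatch "conversion" events.

A heterozygous or homozygous SNV falling inside an off-target protospacer
changes that allele's mismatch count to the guide: an SNV at a mismatching
position whose alternate base restores the guide base *corrects* the
mismatch; an SNV at a matching position breaks it.  A conversion event is a
three-mismatch reference site whose variant allele reaches at most two
mismatches — the situation in which a personal genome carries a
higher-risk off-target invisible to reference-genome prediction.

SNV effects are restricted to protospacer positions.  SNVs that create or
destroy PAMs are detected and reported separately (``pam_snvs``) but never
counted in the headline conversion rate, which is defined purely on
mismatch-count conversion.  Multiple SNVs on one site are applied jointly
to a single variant haplotype (phase assumed cis); such sites are flagged
``multi_snv``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import Genome, GenomicInterval, Snv, reverse_complement
from .offtarget_scan import (
    GuideRna,
    OffTargetHit,
    TargetSite,
    mismatch_profile,
    scan_offtargets,
)

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SnvRefMismatchError(ValueError):
    """An SNV's REF allele disagrees with the genome base at its position."""


@dataclass(frozen=True)
class AppliedSnv:
    """An SNV expressed in guide-strand protospacer coordinates."""

    snv: Snv
    protospacer_offset: int  # 0-based from the 5' end of the guide-strand protospacer
    position: int  # PAM-anchored position, 1 = PAM-proximal
    ref_base: str  # guide-strand ref base
    alt_base: str  # guide-strand alt base


@dataclass(frozen=True)
class PersonalizedSite:
    """An off-target site with reference and variant allele mismatch profiles."""

    site: TargetSite
    applied_snvs: tuple[AppliedSnv, ...]
    ref_allele_seq: str
    var_allele_seq: str
    m_ref: int
    m_var: int
    zygosity: str
    pam_snvs: tuple[Snv, ...] = ()
    multi_snv: bool = False


@dataclass(frozen=True)
class ConversionEvent:
    """An SNV-driven reduction of an off-target's mismatch count below the
    detection threshold (canonically 3 -> <=2)."""

    guide_name: str
    offtarget: PersonalizedSite
    m_before: int
    m_after: int


@dataclass(frozen=True)
class ConversionRateReport:
    """Fraction of guides with at least one conversion event."""

    numerator: int
    denominator: int
    events_by_guide: dict[str, int] = field(default_factory=dict)

    @property
    def rate(self) -> float:
        return self.numerator / self.denominator


def _snv_in_protospacer(site: TargetSite, snv: Snv) -> AppliedSnv | None:
    """Express an SNV in guide-strand coordinates, or None if outside the
    protospacer.  Raises if the SNV REF disagrees with the site sequence."""
    iv = site.interval
    if snv.chrom != iv.chrom or not (iv.start <= snv.index < iv.end):
        return None
    L = len(site.protospacer_seq)
    if iv.strand == "+":
        offset = snv.index - iv.start
        ref_gs, alt_gs = snv.ref_base, snv.alt_base
    else:
        offset = iv.end - 1 - snv.index
        ref_gs, alt_gs = _COMP[snv.ref_base], _COMP[snv.alt_base]
    if site.protospacer_seq[offset] != ref_gs:
        raise SnvRefMismatchError(
            f"SNV {snv.chrom}:{snv.pos} {snv.ref_base}>{snv.alt_base} disagrees "
            f"with site base {site.protospacer_seq[offset]!r} at offset {offset}"
        )
    return AppliedSnv(snv, offset, L - offset, ref_gs, alt_gs)


def overlay_snvs(guide: GuideRna, site: TargetSite, snvs: Sequence[Snv]) -> PersonalizedSite:
    """Build the variant allele of ``site`` by substituting the alternate
    bases of every overlapping SNV (strand-adjusted), and record both
    alleles' mismatch profiles against the guide.

    SNVs overlapping the PAM are collected into ``pam_snvs`` and do not
    enter the variant protospacer.  Raises :class:`SnvRefMismatchError` if
    an SNV's REF allele disagrees with the genome.
    """
    pam_iv = site.pam_interval()
    applied: list[AppliedSnv] = []
    pam_hits: list[Snv] = []
    for snv in snvs:
        if snv.chrom == pam_iv.chrom and pam_iv.start <= snv.index < pam_iv.end:
            pam_hits.append(snv)
            continue
        expressed = _snv_in_protospacer(site, snv)
        if expressed is not None:
            applied.append(expressed)
    var_seq = list(site.protospacer_seq)
    for a in applied:
        var_seq[a.protospacer_offset] = a.alt_base
    var_allele = "".join(var_seq)
    m_ref, _ = mismatch_profile(guide, site.protospacer_seq)
    m_var, _ = mismatch_profile(guide, var_allele)
    zygosities = {a.snv.zygosity for a in applied}
    if not zygosities:
        zygosity = "unknown"
    elif zygosities == {"hom"}:
        zygosity = "hom"
    elif "het" in zygosities:
        zygosity = "het"
    else:
        zygosity = "unknown"
    return PersonalizedSite(
        site=site,
        applied_snvs=tuple(applied),
        ref_allele_seq=site.protospacer_seq,
        var_allele_seq=var_allele,
        m_ref=m_ref,
        m_var=m_var,
        zygosity=zygosity,
        pam_snvs=tuple(pam_hits),
        multi_snv=len(applied) > 1,
    )


def detect_conversions(
    guide: GuideRna,
    hits: Iterable[OffTargetHit],
    snvs: Sequence[Snv],
    threshold: int = 2,
) -> list[ConversionEvent]:
    """One event per off-target hit whose variant allele reaches
    ``m_var <= threshold`` while the reference allele exceeds it.

    ``hits`` are reference-genome hits (canonically at m = 3).  Sites whose
    overlapping SNV contradicts the genome sequence are flagged and skipped.
    Zygosity does not gate detection — a heterozygous conversion counts.
    """
    by_chrom: dict[str, list[Snv]] = {}
    for s in snvs:
        by_chrom.setdefault(s.chrom, []).append(s)
    events: list[ConversionEvent] = []
    for hit in hits:
        iv = hit.site.interval
        pam_iv = hit.site.pam_interval()
        lo = min(iv.start, pam_iv.start)
        hi = max(iv.end, pam_iv.end)
        local = [s for s in by_chrom.get(iv.chrom, []) if lo <= s.index < hi]
        if not local:
            continue
        try:
            psite = overlay_snvs(guide, hit.site, local)
        except SnvRefMismatchError as exc:
            logger.warning("skipping site %s:%d: %s", iv.chrom, iv.start, exc)
            continue
        if psite.m_var <= threshold < psite.m_ref:
            events.append(
                ConversionEvent(guide.name, psite, m_before=psite.m_ref, m_after=psite.m_var)
            )
    return events


def genome_conversion_rate(
    targets: Sequence[GuideRna],
    genome: Genome,
    snvs: Sequence[Snv],
    max_mm: int = 3,
    threshold: int = 2,
    method: str = "seed",
) -> ConversionRateReport:
    """Fraction of guides for which personal SNVs convert at least one
    ``max_mm``-mismatch off-target to ``<= threshold`` mismatches.

    The numerator counts guides, not events; each guide's exact-``max_mm``
    hits (its own perfect-match locus excluded by the mismatch filter) feed
    :func:`detect_conversions`.
    """
    if not targets:
        raise ValueError("empty target list")
    events_by_guide: dict[str, int] = {}
    converted = 0
    for guide in targets:
        hits = [
            h
            for h in scan_offtargets(guide, genome, max_mm=max_mm, method=method)
            if h.mismatch_count == max_mm
        ]
        events = detect_conversions(guide, hits, snvs, threshold=threshold)
        events_by_guide[guide.name] = len(events)
        if events:
            converted += 1
    return ConversionRateReport(converted, len(targets), events_by_guide)


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

def conversions_to_frame(events: Iterable[ConversionEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        iv = e.offtarget.site.interval
        rows.append(
            {
                "guide": e.guide_name,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "strand": iv.strand,
                "m_ref": e.m_before,
                "m_var": e.m_after,
                "snv_ids": ",".join(a.snv.id or f"{a.snv.chrom}:{a.snv.pos}" for a in e.offtarget.applied_snvs),
                "snv_positions": ",".join(str(a.position) for a in e.offtarget.applied_snvs),
                "zygosity": e.offtarget.zygosity,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "guide", "chrom", "start", "end", "strand",
            "m_ref", "m_var", "snv_ids", "snv_positions", "zygosity",
        ],
    )


def write_conversions_tsv(events: Iterable[ConversionEvent], path: str | Path) -> None:
    conversions_to_frame(events).to_csv(path, sep="\t", index=False)
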