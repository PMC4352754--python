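"""Orchestration of the two audit workflows into machine-readable reports.

``run_audit`` chains scan -> personalize -> stats (-> amplicon when reads
are supplied) for a set of guides against one genome and SNV call set.
``run_clone_screen`` applies the clone-level filters (sample-specific
variants, rearrangement support, flanking homology) to multi-sample
variant tables.  Reports are plain dicts, JSON-serialisable and
byte-stable for identical inputs: optional-stage failures degrade the
report with an explicit flag, they never silently drop a required stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import __version__
from .clone_screen import (
    RearrangementCall,
    SampleVariantTable,
    filter_rearrangements,
    flanking_homology_search,
    passing_homology_hits,
    sample_specific_variants,
)
from .conversion_stats import (
    ConversionSummary,
    fit_summaries_through_origin,
)
from .genome_io import Genome, Snv
from .offtarget_scan import GuideRna, scan_offtargets
from .snv_personalization import detect_conversions

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class AuditOptions:
    max_mm: int = 3
    conversion_threshold: int = 2
    scan_method: str = "seed"
    bin_width: float = 5
    fit_range: tuple[float, float] = (0, 100)
    seed: int | None = None


def _hit_record(hit) -> dict:
    iv = hit.site.interval
    return {
        "chrom": iv.chrom,
        "start": iv.start,
        "end": iv.end,
        "strand": iv.strand,
        "mismatches": hit.mismatch_count,
        "mismatch_positions": sorted(hit.mismatch_positions),
        "site_seq": hit.site.protospacer_seq,
        "pam_seq": hit.site.pam_seq,
    }


def _conversion_record(event) -> dict:
    iv = event.offtarget.site.interval
    return {
        "chrom": iv.chrom,
        "start": iv.start,
        "end": iv.end,
        "strand": iv.strand,
        "m_before": event.m_before,
        "m_after": event.m_after,
        "zygosity": event.offtarget.zygosity,
        "snv_positions": [a.position for a in event.offtarget.applied_snvs],
    }


def run_audit(
    genome: Genome,
    guides: Sequence[GuideRna],
    snvs: Sequence[Snv] | None = None,
    amplicon_results: dict | None = None,
    options: AuditOptions = AuditOptions(),
) -> dict:
    """Run the population audit: per-guide off-target scan, SNV conversion
    detection (when SNVs are given), and the cohort conversion statistics.

    ``amplicon_results`` may carry precomputed
    :class:`~cas9audit.amplicon_indels.SiteEfficiencyReport` objects keyed
    by guide name; they are embedded into the report.  Raises on an empty
    guide list (a required input).
    """
    if not guides:
        raise ValueError("empty guide list")
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": __version__,
        "seed": options.seed,
        "stages": {"scan": "ok"},
        "guides": {},
    }
    summaries: list[ConversionSummary] = []
    for guide in guides:
        hits = scan_offtargets(
            guide, genome, max_mm=options.max_mm, method=options.scan_method
        )
        on_target = [h for h in hits if h.mismatch_count == 0]
        offtargets = [h for h in hits if h.mismatch_count == options.max_mm]
        by_m: dict[int, int] = {}
        for h in hits:
            by_m[h.mismatch_count] = by_m.get(h.mismatch_count, 0) + 1
        entry: dict = {
            "on_target": [_hit_record(h) for h in on_target],
            "hits_by_mismatches": {str(m): by_m[m] for m in sorted(by_m)},
            "n3": len(offtargets),
            "hits": [_hit_record(h) for h in hits],
        }
        if snvs is not None:
            events = detect_conversions(
                guide, offtargets, snvs, threshold=options.conversion_threshold
            )
            entry["conversions"] = [_conversion_record(e) for e in events]
            summaries.append(
                ConversionSummary(guide.name, len(offtargets), bool(events))
            )
        if amplicon_results and guide.name in amplicon_results:
            r = amplicon_results[guide.name]
            entry["amplicon"] = {
                "n_pass": r.n_pass,
                "indel_fraction": r.indel_fraction,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "relative_efficiency": r.relative_efficiency,
            }
        report["guides"][guide.name] = entry
        logger.info(
            "audit: guide %s — %d hits, %d at m=%d",
            guide.name, len(hits), len(offtargets), options.max_mm,
        )

    if snvs is None:
        report["stages"]["personalize"] = "skipped (no SNVs supplied)"
        report["stages"]["stats"] = "skipped (no SNVs supplied)"
    else:
        report["stages"]["personalize"] = "ok"
        n_converted = sum(s.converted for s in summaries)
        stats: dict = {
            "n_guides": len(summaries),
            "n_converted": n_converted,
            "conversion_rate_percent": 100.0 * n_converted / len(summaries),
        }
        distinct_bins = {s.n3 // options.bin_width for s in summaries if s.n3 > 0}
        if len(distinct_bins) >= 2:
            try:
                series, regression = fit_summaries_through_origin(
                    summaries,
                    bin_width=options.bin_width,
                    fit_range=options.fit_range,
                )
                stats["regression"] = {
                    "slope_percent": regression.slope_percent,
                    "r_squared": regression.r_squared,
                    "stderr_percent": regression.stderr_percent,
                    "bins": {
                        "centers": list(series.centers),
                        "fractions": list(series.fractions),
                        "counts": list(series.counts),
                    },
                }
                report["stages"]["stats"] = "ok"
            except ValueError as exc:
                report["stages"]["stats"] = f"degraded ({exc})"
        else:
            report["stages"]["stats"] = "degraded (too few off-target bins for regression)"
        report["conversion_stats"] = stats
    if amplicon_results:
        report["stages"]["amplicon"] = "ok"
    return report


def run_clone_screen(
    sample_tables: Sequence[SampleVariantTable],
    rearrangements: Sequence[RearrangementCall],
    genome: Genome,
    guide: GuideRna,
    flank: int = 100,
    min_support: int = 4,
    min_matched: int = 16,
) -> dict:
    """Run the clone screen: sample-specific variants, supported
    rearrangements, and the flanking homology search around every retained
    indel."""
    retained = sample_specific_variants(sample_tables)
    passing_calls = filter_rearrangements(rearrangements, min_support=min_support)
    homology: dict[str, list[dict]] = {}
    for sample_id, variants in retained.items():
        for v in variants:
            if v.type != "indel":
                continue
            from .genome_io import GenomicInterval

            locus = GenomicInterval(v.chrom, v.pos - 1, v.pos - 1 + max(len(v.ref), 1))
            hits = flanking_homology_search(
                genome, locus, guide, flank=flank, min_matched=min_matched
            )
            for h in passing_homology_hits(hits):
                homology.setdefault(sample_id, []).append(
                    {
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "offset": h.offset,
                        "strand": h.strand,
                        "matched_bases": h.matched_bases,
                    }
                )
    report = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": __version__,
        "retained_variants": {
            sid: [
                {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt, "type": v.type}
                for v in variants
            ]
            for sid, variants in retained.items()
        },
        "retained_counts": {sid: len(v) for sid, v in retained.items()},
        "passing_rearrangements": [
            {
                "sample": c.sample_id,
                "type": c.type,
                "support": c.support,
                "breakpoints": [
                    {"chrom": b.chrom, "start": b.start, "end": b.end}
                    for b in c.breakpoints
                ],
            }
            for c in passing_calls
        ],
        "homology_hits": homology,
    }
    logger.info(
        "clone screen: retained %s, %d/%d rearrangements pass, %d samples with homology hits",
        report["retained_counts"], len(passing_calls), len(rearrangements), len(homology),
    )
    return report


def write_report(report: dict, path: str | Path) -> None:
    """Serialise a report deterministically (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
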