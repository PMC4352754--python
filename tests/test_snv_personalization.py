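"""SNV overlay, conversion detection, and the genome-wide conversion rate."""

import numpy as np
import pytest

import cas9audit as ca
from cas9audit.snv_personalization import SnvRefMismatchError


def _hit_for_site(guide, genome, site):
    hits = ca.scan_offtargets(guide, genome, max_mm=3)
    for h in hits:
        if h.site.interval.start == site.start and h.site.strand == site.strand:
            return h
    raise AssertionError("planted site not found by scan")


def _matching_position_snv(genome, truth, guide, site):
    """An SNV at a protospacer position that currently matches the guide."""
    L = guide.length
    matching = sorted(set(range(1, L + 1)) - site.mismatch_positions)
    position = matching[0]
    j = L - position
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if site.strand == "+":
        idx = site.start + j
        ref = site.protospacer_seq[j]
    else:
        idx = site.end - 1 - j
        ref = comp[site.protospacer_seq[j]]
    assert genome[truth.chrom][idx] == ref
    alt = next(b for b in "ACGT" if b != ref)
    return ca.Snv(truth.chrom, idx + 1, ref, alt, "het"), position


class TestOverlaySnvs:
    def test_correcting_snv_reduces_mismatch_count(self, guide, planted_bundle):
        genome, truth, _ = planted_bundle
        conv = truth.conversions[0]
        site = truth.sites[conv.site_index]
        hit = _hit_for_site(guide, genome, site)
        psite = ca.overlay_snvs(guide, hit.site, [conv.snv])
        assert (psite.m_ref, psite.m_var) == (3, 2)
        assert psite.zygosity == "het"

    def test_match_breaking_snv_increases_mismatch_count(self, guide, planted_bundle):
        genome, truth, _ = planted_bundle
        site = next(s for s in truth.sites if s.mismatch_count == 3)
        hit = _hit_for_site(guide, genome, site)
        snv, _ = _matching_position_snv(genome, truth, guide, site)
        psite = ca.overlay_snvs(guide, hit.site, [snv])
        assert psite.m_var == psite.m_ref + 1

    def test_joint_correcting_and_breaking_snvs_cancel(self, guide, planted_bundle):
        genome, truth, _ = planted_bundle
        conv = truth.conversions[0]
        site = truth.sites[conv.site_index]
        hit = _hit_for_site(guide, genome, site)
        breaking, _ = _matching_position_snv(genome, truth, guide, site)
        psite = ca.overlay_snvs(guide, hit.site, [conv.snv, breaking])
        assert psite.m_var == psite.m_ref
        assert psite.multi_snv
        # oracle: recompute the profile from the edited sequence directly
        m_direct, _ = ca.mismatch_profile(guide, psite.var_allele_seq)
        assert m_direct == psite.m_var

    def test_variant_allele_differs_exactly_at_applied_offsets(self, guide, planted_bundle):
        genome, truth, _ = planted_bundle
        conv = truth.conversions[0]
        hit = _hit_for_site(guide, genome, truth.sites[conv.site_index])
        psite = ca.overlay_snvs(guide, hit.site, [conv.snv])
        diffs = {
            j for j, (a, b) in enumerate(zip(psite.ref_allele_seq, psite.var_allele_seq))
            if a != b
        }
        assert diffs == {a.protospacer_offset for a in psite.applied_snvs}

    def test_inconsistent_ref_allele_raises(self, guide, planted_bundle):
        genome, truth, _ = planted_bundle
        site = truth.sites[0]
        hit = _hit_for_site(guide, genome, site)
        base = genome[truth.chrom][site.start]
        wrong_ref = next(b for b in "ACGT" if b != base)
        alt = next(b for b in "ACGT" if b not in (wrong_ref,))
        bad = ca.Snv(truth.chrom, site.start + 1, wrong_ref, alt)
        with pytest.raises(SnvRefMismatchError):
            ca.overlay_snvs(guide, hit.site, [bad])

    def test_pam_snv_reported_separately(self, guide, planted_bundle):
        genome, truth, _ = planted_bundle
        site = next(s for s in truth.sites if s.strand == "+")
        hit = _hit_for_site(guide, genome, site)
        pam_iv = hit.site.pam_interval()
        ref = genome[truth.chrom][pam_iv.start]
        alt = next(b for b in "ACGT" if b != ref)
        snv = ca.Snv(truth.chrom, pam_iv.start + 1, ref, alt)
        psite = ca.overlay_snvs(guide, hit.site, [snv])
        assert psite.pam_snvs == (snv,)
        assert psite.applied_snvs == ()
        assert psite.m_var == psite.m_ref


class TestDetectConversions:
    def test_planted_conversions_found_exactly(self, guide, planted_bundle):
        genome, truth, snvs = planted_bundle
        hits = [
            h for h in ca.scan_offtargets(guide, genome, max_mm=3)
            if h.mismatch_count == 3
        ]
        events = ca.detect_conversions(guide, hits, snvs)
        assert len(events) == len(truth.conversions) == 2
        got = {e.offtarget.site.interval.start for e in events}
        want = {truth.sites[c.site_index].start for c in truth.conversions}
        assert got == want
        assert all(e.m_before == 3 and e.m_after == 2 for e in events)

    def test_two_of_ten_sites_convert(self, guide):
        config = ca.GenomeSimConfig(
            genome_length=200_000,
            planted=(ca.PlantedSiteSpec(0, (), 1), ca.PlantedSiteSpec(3, None, 10)),
        )
        genome, truth = ca.build_genome(guide, config, seed=21)
        snvs, truth = ca.plant_snvs(
            genome, truth, guide, ca.SnvSimConfig(background_density=0, n_converting=2), seed=22
        )
        hits = [
            h for h in ca.scan_offtargets(guide, genome, max_mm=3)
            if h.mismatch_count == 3
        ]
        assert len(hits) == 10
        events = ca.detect_conversions(guide, hits, snvs)
        assert len(events) == 2

    def test_snvs_at_matching_positions_give_no_events(self, guide, planted_bundle):
        genome, truth, _ = planted_bundle
        site = next(s for s in truth.sites if s.mismatch_count == 3)
        snv, _ = _matching_position_snv(genome, truth, guide, site)
        hits = [
            h for h in ca.scan_offtargets(guide, genome, max_mm=3)
            if h.mismatch_count == 3
        ]
        assert ca.detect_conversions(guide, hits, [snv]) == []

    def test_events_lie_at_mismatching_positions(self, guide, planted_bundle):
        genome, truth, snvs = planted_bundle
        hits = [
            h for h in ca.scan_offtargets(guide, genome, max_mm=3)
            if h.mismatch_count == 3
        ]
        by_start = {h.site.interval.start: h for h in hits}
        for e in ca.detect_conversions(guide, hits, snvs):
            hit = by_start[e.offtarget.site.interval.start]
            for applied in e.offtarget.applied_snvs:
                assert applied.position in hit.mismatch_positions

    def test_strand_correctness_under_genome_reversal(self, guide, planted_bundle):
        """Reverse-complementing the genome (with SNV alleles complemented
        and positions mirrored) preserves every conversion event."""
        genome, truth, snvs = planted_bundle
        length = genome.chrom_length(truth.chrom)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc_genome = ca.Genome({truth.chrom: ca.reverse_complement(genome[truth.chrom])})
        rc_snvs = [
            ca.Snv(s.chrom, length - s.pos + 1, comp[s.ref_base], comp[s.alt_base], s.zygosity)
            for s in snvs
        ]
        hits = [
            h for h in ca.scan_offtargets(guide, genome, max_mm=3)
            if h.mismatch_count == 3
        ]
        rc_hits = [
            h for h in ca.scan_offtargets(guide, rc_genome, max_mm=3)
            if h.mismatch_count == 3
        ]
        events = ca.detect_conversions(guide, hits, snvs)
        rc_events = ca.detect_conversions(guide, rc_hits, rc_snvs)
        assert len(events) == len(rc_events)
        assert sorted((e.m_before, e.m_after) for e in events) == sorted(
            (e.m_before, e.m_after) for e in rc_events
        )


class TestGenomeConversionRate:
    def test_no_snvs_gives_zero(self, guide, planted_bundle):
        genome, _, _ = planted_bundle
        report = ca.genome_conversion_rate([guide], genome, [])
        assert report.rate == 0.0
        assert (report.numerator, report.denominator) == (0, 1)

    def test_every_target_converting_gives_one(self, guide, planted_bundle):
        genome, _, snvs = planted_bundle
        report = ca.genome_conversion_rate([guide], genome, snvs)
        assert report.rate == 1.0

    def test_empty_target_list_rejected(self, planted_bundle):
        genome, _, snvs = planted_bundle
        with pytest.raises(ValueError):
            ca.genome_conversion_rate([], genome, snvs)

    def test_rate_matches_closed_form_for_independent_conversion(self):
        """Targets whose N3 off-targets each convert independently with
        probability p show a rate near mean(1 - (1-p)^N3)."""
        rng = np.random.default_rng(31)
        p = 0.35
        guides, genomes, all_snvs = [], {}, []
        expected = []
        for i in range(12):
            proto = "".join("ACGT"[k] for k in rng.integers(0, 4, size=20))
            g = ca.GuideRna(f"t{i}", proto)
            n3 = int(rng.integers(1, 6))
            chrom = f"chr_t{i}"
            config = ca.GenomeSimConfig(
                genome_length=30_000,
                chrom=chrom,
                planted=(ca.PlantedSiteSpec(0, (), 1), ca.PlantedSiteSpec(3, None, n3)),
            )
            genome, truth = ca.build_genome(g, config, seed=int(rng.integers(0, 2**31)))
            three_mm = [k for k, s in enumerate(truth.sites) if s.mismatch_count == 3]
            converting = [k for k in three_mm if rng.random() < p]
            if converting:
                explicit = tuple(
                    (k, sorted(truth.sites[k].mismatch_positions)[0]) for k in converting
                )
                snvs, truth = ca.plant_snvs(
                    genome, truth, g,
                    ca.SnvSimConfig(background_density=0, explicit_conversions=explicit),
                    seed=1,
                )
                all_snvs.extend(snvs)
            guides.append(g)
            genomes[chrom] = genome[chrom]
            expected.append(1 - (1 - p) ** n3)
        merged = ca.Genome(genomes)
        report = ca.genome_conversion_rate(guides, merged, all_snvs)
        mean_expected = float(np.mean(expected))
        sd = float(np.sqrt(np.mean([e * (1 - e) for e in expected]) / len(expected)))
        assert abs(report.rate - mean_expected) <= 3 * sd
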