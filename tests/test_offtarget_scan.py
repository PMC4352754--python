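"""PAM-anchored mismatch profiles and the genome-wide off-target scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cas9audit as ca
from cas9audit.offtarget_scan import enumerate_pam_sites, pam_matches
from cas9audit.synthetic_data import random_sequence

proto20 = st.text(alphabet="ACGT", min_size=20, max_size=20)


def brute_profile(proto: str, site: str):
    """Independent position-wise oracle for the PAM-anchored profile."""
    L = len(proto)
    positions = set()
    for j in range(L):
        if proto[j] != site[j]:
            positions.add(L - j)  # position 1 is adjacent to the PAM
    return len(positions), positions


class TestMismatchProfile:
    def test_identical_sequences(self, guide):
        assert ca.mismatch_profile(guide, guide.protospacer) == (0, frozenset())

    def test_pam_distal_substitution_is_position_20(self):
        guide = ca.GuideRna("g", "A" * 20)
        site = "C" + "A" * 19  # 5'-most base differs
        assert ca.mismatch_profile(guide, site) == (1, frozenset({20}))

    def test_three_mismatches_at_11_15_19(self, guide):
        site = list(guide.protospacer)
        for pos in (11, 15, 19):  # PAM-anchored positions
            j = 20 - pos
            site[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[j]]
        m, positions = ca.mismatch_profile(guide, "".join(site))
        assert (m, set(positions)) == brute_profile(guide.protospacer, "".join(site))
        assert (m, positions) == (3, frozenset({11, 15, 19}))

    def test_length_mismatch_rejected(self, guide):
        with pytest.raises(ValueError):
            ca.mismatch_profile(guide, "ACGT")

    @given(a=proto20, b=proto20)
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_symmetric_and_zero_iff_equal(self, a, b):
        m_ab, pos_ab = ca.mismatch_profile(a, b)
        m_ba, pos_ba = ca.mismatch_profile(b, a)
        assert (m_ab, pos_ab) == (m_ba, pos_ba)
        assert (m_ab == 0) == (a == b)
        assert all(1 <= p <= 20 for p in pos_ab)


class TestEnumeratePamSites:
    def test_matches_brute_force_window_oracle(self, guide):
        rng = np.random.default_rng(3)
        seq = random_sequence(500, 0.5, rng)
        genome = ca.Genome({"c": seq})
        sites = list(enumerate_pam_sites(genome, guide))
        # oracle: explicit window walk on both strand texts
        expected = 0
        for text in (seq, ca.reverse_complement(seq)):
            for i in range(len(text) - 22):
                window = text[i : i + 23]
                if "N" not in window and window[21:23] == "GG":
                    expected += 1
        assert len(sites) == expected
        assert all(pam_matches("NGG", s.pam_seq) for s in sites)

    def test_poly_t_genome_has_no_pam(self, guide):
        genome = ca.Genome({"c": "T" * 100})
        assert list(enumerate_pam_sites(genome, guide)) == []

    def test_window_containing_n_excluded(self):
        guide = ca.GuideRna("g", "A" * 20)
        genome = ca.Genome({"c": "A" * 10 + "N" + "A" * 9 + "AGG" + "A" * 5})
        starts = [s.interval.start for s in enumerate_pam_sites(genome, guide)]
        assert 0 not in starts  # its window spans the N


class TestScanOfftargets:
    def test_planted_sites_recovered_exactly(self, guide, planted_bundle):
        genome, truth, _ = planted_bundle
        hits = ca.scan_offtargets(guide, genome, max_mm=3)
        assert len(hits) == len(truth.sites) == 6
        got = {
            (h.site.interval.start, h.site.strand, h.mismatch_count, h.mismatch_positions)
            for h in hits
        }
        want = {
            (s.start, s.strand, s.mismatch_count, s.mismatch_positions)
            for s in truth.sites
        }
        assert got == want

    def test_exact_match_only(self, guide):
        genome, truth = ca.build_genome(
            guide,
            ca.GenomeSimConfig(genome_length=20_000, planted=(ca.PlantedSiteSpec(0, (), 1),)),
            seed=2,
        )
        hits = ca.scan_offtargets(guide, genome, max_mm=0)
        assert len(hits) == 1 and hits[0].mismatch_count == 0

    def test_monotone_in_max_mm(self, guide, planted_bundle):
        genome, _, _ = planted_bundle
        for k in range(3):
            smaller = set(
                (h.site.interval, h.mismatch_positions)
                for h in ca.scan_offtargets(guide, genome, max_mm=k)
            )
            larger = set(
                (h.site.interval, h.mismatch_positions)
                for h in ca.scan_offtargets(guide, genome, max_mm=k + 1)
            )
            assert smaller <= larger

    def test_reverse_complement_genome_mirrors_hits(self, guide, planted_bundle):
        genome, _, _ = planted_bundle
        length = genome.chrom_length("chr_sim")
        rc_genome = ca.Genome({"chr_sim": ca.reverse_complement(genome["chr_sim"])})
        hits = ca.scan_offtargets(guide, genome, max_mm=3)
        rc_hits = ca.scan_offtargets(guide, rc_genome, max_mm=3)
        mirrored = {
            (length - h.site.interval.end, "-" if h.site.strand == "+" else "+",
             h.mismatch_count, h.mismatch_positions)
            for h in hits
        }
        got = {
            (h.site.interval.start, h.site.strand, h.mismatch_count, h.mismatch_positions)
            for h in rc_hits
        }
        assert got == mirrored

    def test_max_mm_above_length_rejected(self, guide):
        genome = ca.Genome({"c": "A" * 100})
        with pytest.raises(ValueError):
            ca.scan_offtargets(guide, genome, max_mm=21)

    def test_seed_and_brute_agree_on_planted_genome(self, guide, planted_bundle):
        genome, _, _ = planted_bundle
        assert ca.scan_offtargets(guide, genome, method="seed") == ca.scan_offtargets(
            guide, genome, method="brute"
        )


class TestCountOfftargets:
    def test_planted_count_excludes_own_locus(self, guide, planted_bundle):
        genome, truth, _ = planted_bundle
        counts = ca.count_offtargets_per_target([guide], genome, mm=3)
        assert counts == {"guide1": 5}

    def test_no_offtargets_is_zero(self, guide):
        genome, _ = ca.build_genome(
            guide,
            ca.GenomeSimConfig(genome_length=20_000, planted=(ca.PlantedSiteSpec(0, (), 1),)),
            seed=4,
        )
        assert ca.count_offtargets_per_target([guide], genome, mm=3) == {"guide1": 0}

    def test_two_targets_share_an_offtarget(self):
        rng = np.random.default_rng(11)
        site = random_sequence(20, 0.5, rng)

        def mutate(seq, offsets):
            out = list(seq)
            for j in offsets:
                out[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[j]]
            return "".join(out)

        guide_a = ca.GuideRna("a", mutate(site, (0, 5, 9)))
        guide_b = ca.GuideRna("b", mutate(site, (2, 7, 12)))
        background = random_sequence(6000, 0.5, rng)
        # shared off-target + each guide's own perfect site, well separated
        seq = (
            background[:1000] + site + "TGG"
            + background[1000:3000] + guide_a.protospacer + "AGG"
            + background[3000:5000] + guide_b.protospacer + "CGG"
            + background[5000:]
        )
        genome = ca.Genome({"c": seq})
        counts = ca.count_offtargets_per_target([guide_a, guide_b], genome, mm=3)
        # oracle: brute-force scan per guide
        for g in (guide_a, guide_b):
            brute = [
                h for h in ca.scan_offtargets(g, genome, max_mm=3, method="brute")
                if h.mismatch_count == 3
            ]
            assert counts[g.name] == len(brute)
        assert counts["a"] >= 1 and counts["b"] >= 1

    def test_missing_target_at_stated_locus_errors(self, guide, planted_bundle):
        genome, _, _ = planted_bundle
        wrong_locus = ca.GenomicInterval("chr_sim", 10, 30, "+")
        with pytest.raises(ValueError, match="not found"):
            ca.count_offtargets_per_target(
                [guide], genome, mm=3, loci={"guide1": wrong_locus}
            )
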