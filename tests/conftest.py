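"""Shared fixtures: a planted synthetic bundle reused across module tests."""

from __future__ import annotations

import numpy as np
import pytest

import cas9audit as ca

GUIDE_SEQ = "GCTGATGCGGACTAGCCATA"


@pytest.fixture(scope="session")
def guide() -> ca.GuideRna:
    return ca.GuideRna("guide1", GUIDE_SEQ)


@pytest.fixture(scope="session")
def planted_bundle(guide):
    """Genome with 1 on-target + 5 three-mismatch sites, 2 converting SNVs."""
    genome, truth = ca.build_genome(guide, ca.GenomeSimConfig(), seed=7)
    snvs, truth = ca.plant_snvs(genome, truth, guide, ca.SnvSimConfig(), seed=8)
    return genome, truth, snvs


@pytest.fixture(scope="session")
def het_amplicon(guide):
    """A 200 bp amplicon around the guide site with a PAM-distal
    discriminating SNV (outside deletion reach of the cut)."""
    rng = np.random.default_rng(5)
    from cas9audit.synthetic_data import random_sequence

    background = random_sequence(200, 0.45, rng)
    seq = background[:80] + GUIDE_SEQ + "TGG" + background[103:]
    snv_offset = 81  # protospacer position 19
    alt = next(b for b in "ACGT" if b != seq[snv_offset])
    return ca.Amplicon(
        "het_offtarget",
        seq,
        protospacer_start=80,
        protospacer_end=100,
        strand="+",
        snv_offset=snv_offset,
        snv_ref=seq[snv_offset],
        snv_alt=alt,
    )
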