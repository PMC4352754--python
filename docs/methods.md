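# Methods

## The problem

S. pyogenes Cas9 cuts where its guide RNA's ~20-nt protospacer-matching
region pairs with genomic DNA immediately 5' of an NGG PAM.  Tolerance of
up to roughly three mismatches creates off-target risk, and standard
practice enumerates PAM-valid near-matches in a *reference* genome.  A
personal SNV inside such a site can remove one mismatch on one haplotype,
converting a weakly-cut three-mismatch site into an efficiently-cut
two-mismatch allele that reference-based prediction cannot see.  This
package quantifies that conversion process and implements the surrounding
measurement workflow: off-target enumeration, amplicon-sequencing activity
quantification, and whole-genome clone screening.

## Coordinate and orientation conventions

All internal coordinates are 0-based half-open on the plus strand;
1-based inclusive coordinates appear only at I/O boundaries (VCF, printed
loci), and the two conversions are exact inverses.  Mismatch positions
are PAM-anchored: position 1 is the protospacer base adjacent to the PAM,
position L (default 20) the 5'-most.  A minus-strand site is recorded by
the plus-strand interval of its protospacer with sequences reported
5'→3' on the guide-matching strand; the PAM then lies immediately left of
the interval in plus-strand coordinates.  Genome `N` bases are permitted
but any candidate window containing `N` is discarded — an ambiguous base
cannot be confidently scored against the guide, and the IUPAC `N` in a PAM
pattern likewise never matches a genomic `N`.

## Off-target scanning

Two strategies share one contract and are tested for exact set equality:

* **brute** — vectorised position-wise comparison of every window on both
  strands (the oracle).
* **seed** — pigeonhole acceleration: with at most `max_mm` mismatches
  allowed, the protospacer is split into `max_mm + 1` contiguous seeds of
  near-equal length; any admissible site must contain at least one seed
  exactly, so exact seed occurrences generate candidates that are then
  verified base by base.  This is exact, not heuristic.

Overlapping windows are all evaluated; hits on opposite strands at one
locus are distinct records.  The PAM is fixed to NGG by default (the
S. pyogenes setting); relaxed PAMs (NAG/NGA) are deliberately not counted.
Per-guide off-target counts (N₃) use sites with exactly `mm` mismatches
and exclude the guide's own locus.

## SNV overlay and conversion events

SNVs from a VCF are restricted to biallelic single-base substitutions
(indels and multi-allelic records are skipped with a logged count).  For
each off-target, overlapping SNVs are expressed in guide-strand
coordinates (complemented exactly once for minus-strand sites), checked
against the genome base, and applied jointly to a single variant
haplotype (phase assumed cis; multi-SNV sites carry a `multi_snv` flag).
Both alleles' mismatch profiles are recomputed from sequence rather than
tracked incrementally.  A **conversion event** is a site with
m_ref > threshold and m_var ≤ threshold; the canonical setting is 3 → ≤2.
The threshold is "at most 2" rather than "exactly 2": a double correction
to m = 1 is a strictly more dangerous site and should count.  SNVs that
create or destroy PAMs are detected and reported separately (`pam_snvs`)
but excluded from the headline conversion rate, which is defined purely on
protospacer mismatch counts.  Zygosity never gates detection — a
heterozygous conversion is a conversion — and is carried through for
downstream activity extrapolation.  The genome-wide conversion rate counts
*guides* with at least one event over guides tested, reported with
numerator and denominator.

## Conversion-rate regression

Per-guide outcomes (N₃, converted?) are binned by N₃ (width 5 over
[0, 100]; empty bins omitted; bin centers as x).  The paper-style model is
a line through the origin, f = β·N₃: with no off-targets there is nothing
to convert, so a free intercept is physically meaningless.  We fit
weighted least squares with bin counts as weights, which makes the binned
fit identical to the per-target through-origin fit:
β = Σ wᵢxᵢfᵢ / Σ wᵢxᵢ².  β is reported in percent per off-target site, so
a per-site conversion probability of 0.00145 appears as 0.145.  Because
the centered R² is ill-defined without an intercept, the uncentered form
R² = 1 − SS_res / Σ wᵢfᵢ² is used.  The slope's standard error propagates
the per-bin binomial variance fᵢ(1−fᵢ)/nᵢ, giving the 3-SE coverage
criterion used in the recovery tests.  `predict_rate` is β·N̄₃ (percent);
`extrapolate_clinical_rate` multiplies a conversion percentage by a
relative-activity fraction.  Distribution comparisons use a plain
two-sided Z-test on summary statistics — at the sample sizes involved
(10⁵–10⁶ sites) the normal approximation is exact for practical purposes
and p-values may underflow to exactly 0.

## Amplicon indel quantification

Reads are globally aligned to the amplicon reference with affine gaps
(match +2, mismatch −3, open −6, extend −1; Needleman–Wunsch via
Biopython's pairwise aligner).  End gaps on the read are free so
partial-coverage reads align to their sub-interval; reads under 60%
identity over the aligned span (or shorter than 30 bp) are excluded from
every denominator.  A read counts as edited iff an insertion or deletion
overlaps a ±10 bp window around the blunt-cut boundary between
protospacer positions 3 and 4 upstream of the PAM — wide enough to
capture NHEJ indel spectra, narrow enough to exclude amplicon-end
artifacts; substitutions never count, so sequencing error cannot inflate
the indel fraction above its binomial floor.  With a discriminating SNV
defined, the read base aligned to that offset assigns the allele; a read
whose SNV base is deleted or uncovered is `undetermined`, never guessed
(ref + var + undetermined = passing).  Fractions carry Wilson 95%
intervals; relative efficiency divides by a supplied on-target fraction;
fewer than 100 passing reads flags the report low-coverage.  All
thresholds are configurable.

## Clone screen

Independently derived clones acquire distinct Cas9 repair outcomes, so a
true de novo event should be private to one clone.  `sample_specific_variants`
keeps, per sample, the variants (keyed chrom/pos/ref/alt) seen in no other
sample; it is idempotent, order-independent, and undefined for a single
sample (error).  Rearrangement calls pass at ≥4 supporting discordant
reads.  The flanking homology search slides the guide over every offset in
a ±100 bp window around the indel-locus **midpoint** (start/end/midpoint
is otherwise arbitrary; the midpoint is symmetric), both strands, scoring
ungapped identity; "both directions and orientations" collapses into full
window coverage on both strands.  A hit passes at ≥16 of 20 matched bases,
the integer form of ">15 bp (>75%)"; both the count and the window are
configurable.  Windows truncated at chromosome ends are allowed and
logged.  Upstream variant calling (alignment, genotyping, copy-number
segmentation) is out of scope; the module consumes variant and
rearrangement tables.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* of the study's inputs, not human
genome biology:

* **Genome** — i.i.d. background at a human-like 41% GC, one planted
  on-target and off-target families at requested mismatch
  counts/positions, each followed by a valid NGG.  Construction is
  verified: the build is accepted only when a brute-force scan returns
  exactly the planted set, resampling otherwise, so oracle tests are
  exact.  Real genomes' repeats, segmental duplications and biased
  composition — the main driver of large N₃ values — are not modelled.
* **SNVs** — explicit mismatch-correcting SNVs (default heterozygous, as
  in the motivating observation) on three-mismatch sites, plus background
  SNVs at 5×10⁻⁴ per bp placed outside planted footprints.  No linkage,
  no mutation spectrum, no indel variants.
* **Amplicon reads** — full-length amplicon reads drawn per allele
  (default 50/50 for heterozygous sites), programmed per-allele indel
  fractions, deletions of 1–10 bp (80%) and insertions of 1–3 bp (20%)
  always overlapping the cut, and a uniform 0.2% substitution error.  The
  defaults mirror the observed activity regime: 54% on-target, 36.7%
  variant-allele and 1% reference-allele editing at a converted site.  No
  quality-score model, PCR bias, or paired-end structure.  The default
  test amplicon places the discriminating SNV 16 bp from the cut, outside
  deletion reach, so allele assignment is unbiased; assays whose SNV sits
  inside the indel window will push indel reads into `undetermined` and
  bias per-allele fractions downwards — a real limitation of SNV-based
  allele splitting, surfaced rather than hidden.
* **Clone tables** — configurable shared (≥2 samples) and sample-unique
  variant counts and rearrangement supports; positions uniform.

Passing closed-loop tests therefore demonstrates that the analysis
recovers what the generators planted under these idealised conditions;
it does not certify performance on repetitive real genomes or real
sequencing artifacts.

## Problem sizes and numerical choices

Scanner equivalence is exercised on twenty 100–200 kb genomes × 20 guides
(mixed random and genome-derived); regression recovery uses cohorts of
20,000–50,000 simulated guides with N₃ uniform on [0, 100] and per-site
conversion probabilities 0.0008 and 0.00145; amplicon recovery uses
10,000 reads per condition at planted fractions
{0.0015, 0.01, 0.189, 0.367, 0.54}.  These sizes give the statistical
checks (3-SE / 3-SD / Wilson coverage) comfortable power while keeping
the whole suite fast on a single core.  Statistical recovery tests
compare the estimator to the *realised* ground-truth labels of the
generated data (and separately check realised vs planted at 3 binomial
SDs): the measurement machinery is tested deterministically instead of
re-testing the binomial draw.  Ties and degenerate inputs: equal-scoring
alignments take the aligner's first optimum (deletions may slide within
repeats; indel calling is window-based so this does not change calls);
zero-variance Z-tests return (0, 1) on equal means; all-zero bins make
the regression slope undefined (error); R² of an all-zero response is
defined as 1.

## Known limitations

* Ungapped site model: DNA/RNA bulge off-targets are out of scope, as is
  activity scoring (CFD/MIT) and relaxed-PAM (NAG) scanning.
* The printed-locus convention for a 22 bp target span is ambiguous at
  one base; conversions are exact for the coordinates as given.
* The protospacer length is configurable (default 20 nt) since assay
  descriptions vary between 19 and 20 nt effective lengths.
* Phasing: multiple SNVs on one site are assumed cis; trans configurations
  would split into two weaker alleles and are only flagged.
* The conversion-rate regression is a first-order model; saturation at
  very large N₃ (f → 1) is outside the fitted 0–100 range.
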