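# Methods

This note documents the models, rules and numerical choices behind
`mitovar`, and what the synthetic-data tests do and do not establish.

## Reference model

The human mitochondrial genome is modelled as a circular 16,569-bp sequence
in 1-based rCRS coordinates with the standard NC_012920 gene boundaries.
Only the control region (D-loop, 16024→576) wraps the origin; samples are
accepted linearized at position 1. Position 3107 is the legacy placeholder
`N` and is never called as a variant. Protein genes ending in an incomplete
stop codon (T or TA) are padded with A's before translation, matching the
polyadenylation-completed stop of the mature mRNA; the reference product
length of a gene is its padded codon count (e.g. 175 for ND6), and a
truncated product length counts residues before the premature stop.
Translation uses the vertebrate mitochondrial code (NCBI table 2):
UGA=Trp, AGA/AGG=Ter, AUA=Met. All truncating calls in the packaged tables
reproduce under table 2; no alternative stop rules are emulated.

### The synthetic reference fixture

The real NC_012920 record is not redistributable here, so the bundled
FASTA is a clearly-labelled synthetic stand-in built deterministically by
`mitovar.refbuild`. Its design constraints:

* every variant position appearing in the packaged tables has the exact
  codon context implied by the printed amino-acid changes (e.g. TGG at
  4968–4970 so that G4969A is Trp→Ter; coding GGA at ND6 codon 122 so that
  C14310A is Gly→Trp);
* the homopolymer/repeat tracts behind the printed indel labels exist
  verbatim (A7 at 11032–11038, C5 at 11673–11677 and 13128–13132, A8 at
  12418–12425, (AAAT)2 at 14495–14502, the three mtMSI windows);
* the ND6 frameshift introduces its stop at codon 59, truncating the
  175-codon product to 58 residues;
* no protein gene contains an internal stop, including both frames of the
  ATP8/ATP6 and ND4L/ND4 overlaps. Filler codons inside the dual-frame
  ATP8/ATP6 overlap are drawn from A-free sense codons (no mitochondrial
  stop triplet lacks A, so an A-free stretch is stop-free in every frame);
  elsewhere filler is any sense codon, which leaves shifted frames free to
  contain stops — as on the real molecule — so frameshifts truncate.

Consequence logic itself is sequence-agnostic; a user-supplied real
reference can be swapped in without code changes.

## Alignment and variant normalization

Whole-molecule global alignment uses edlib (Needleman–Wunsch path),
rejecting inputs whose length deviates by > 600 nt or whose identity falls
below 95%. Because edit distance ties can represent two nearby
substitutions as an insertion+deletion pair, any cluster of raw
differences containing an indel is locally realigned under affine scoring
(match +1, mismatch −2, gap open −6, gap extend −0.5) with Biopython's
`PairwiseAligner` on an 8-bp-padded window; these parameters prefer
mismatches over spurious gaps and keep a repeat-unit deletion as one gap.
Indels are then shifted to their 3′-most equivalent placement (the
mitochondrial reporting convention) and labelled as tract copy-number
changes when a homopolymer run or a perfect repeat of ≥ 2 copies is
involved. Deleting either AAAT copy of a (AAAT)2 tract therefore yields
the identical normalized variant. VCF export left-aligns with an anchor
base per the VCF convention and carries the 3′ label in INFO; the reader
re-normalizes on import.

Heteroplasmy is a binary state: Sanger-style consensus data carries no read
depth, so a variant present in one of two alleles gets a conventional
fraction of 0.5 and no fraction otherwise. Somatic status ignores
zygosity; a different normal variant touching the same position leaves the
tumor call undetermined rather than somatic.

## Pathogenicity rule

Candidate filters for non-synonymous substitutions: control frequency
< 1% (a frequency of exactly 1% is resolved to *polymorphism*, the
conservative reading), absence from normal thyroid, and conservation index
strictly > 75%. The conservation index denominator is 41 with the human
row included — the only convention under which the printed CI values
(24.4, 43.9, 78.05, 97.6, …) all lie on the 100/41 lattice. Alignment gaps
count as non-wild-type.

The seven-program vote binarizes each output (PolyPhen-2
Probably/Possibly; SIFT Not Tolerated; MutationAssessor High/Medium/Low;
PROVEAN Deleterious; SNP&GO Disease; Align-GVGD C65 only; PANTHER
P<sub>del</sub> > 0.5) and requires ≥ 4 votes of a fixed denominator of 7;
NA never votes and the denominator is never renormalized (two packaged
profiles pass with six available programs). The MutationAssessor-Low and
PolyPhen-2-Possibly rules are reverse-engineered: they are required for
the packaged outcome set, and `scripts/validate_binarization.py` shows by
enumeration that among the plausible binarization choices only those
including both reproduce it (the Align-GVGD C65-vs-C55 choice is not
separated by the surviving rows; the C65-only reading follows the
published footnote). The vote applies only to non-synonymous
substitutions; nonsense and frameshift mutations bypass it.

## Haplogroup scoring

Nodes are scored as `matched/expected` over the defining variants of the
root path — a simplified Kulczynski-style rank. Private variants are never
penalized; ties break toward the deeper node, then lexicographically, and
an all-zero profile lands at the root. PhyloTree back-mutation notation
(`!`) is rejected explicitly rather than misread. The packaged 16-node
tree (macro-haplogroups M and N with the C/D/G/Z and A/A4/B4/B4a/B4g/F/R/Y
sublineages) uses synthetic defining variants placed at reserved reference
positions; any user tree in the TSV/JSON schema can be supplied.

## Copy number

Relative content defaults to `2^(ΔCt)` with ΔCt = mean Ct(nuclear) − mean
Ct(mt); the efficiency-corrected ratio `E_mt^(−Ct_mt)/E_nuc^(−Ct_nuc)` is
available when standard-curve efficiencies are known. Replicate SDs above
0.5 cycles warn. The cohort comparison follows the emulated design: an
*unpaired* two-sided Mann–Whitney U test applied to paired data; a paired
Wilcoxon signed-rank option is exposed but non-default. Because
mean-of-ratios and ratio-of-means differ for skewed fold distributions,
the report prints both, labelled.

## Association statistics

Odds ratios use the Woolf log-normal CI; the CI method is a package choice
(the emulated study names none, and its underlying counts are
unpublished, so only structure-level reproduction is possible).
Haldane–Anscombe +0.5 applies on any zero cell and is flagged. The
chi-square test is Pearson without continuity correction; when any
expected count is ≤ 5 the test falls back to two-sided Fisher (the
boundary is inclusive so that a fully separated 10+10 table is handled
exactly). Screens report per-factor 2×2 results sorted by p, significant
at α = 0.05 with no multiplicity correction by default (an optional
Benjamini–Hochberg column is available). Scipy provides the test
implementations; the test suite checks them against independent
enumeration oracles (all rank configurations for the Mann–Whitney at
n ≤ 8; hypergeometric enumeration for Fisher over small tables and a
seeded sweep up to N = 40).

## Synthetic cohorts

Defaults emulate the study conditions: 66 tumor/normal pairs, 376 blood
controls, 16 normal thyroid samples; haplogroup backbones drawn with the
30:36 M:N split spread over the sublineages; Poisson(0.8) somatic
substitutions per tumor (52 somatic mutations over 66 tumors ≈ 0.79),
heteroplasmic with probability 0.8 (realized as a second allele);
Poisson(3) private germline substitutions per subject; mtMSI stutter with
probability 0.15 across the three repeat windows. The copy-number fold is
log2-normal with mean 0.93 and SD 1.76 — the unique choice matching both
emulated statements simultaneously (mean tumor/normal ratio ≈ 4, and
P(fold > 1) ≈ 0.70 ≈ 46/66). Ct tables use a nuclear baseline near 25
cycles, per-subject baseline content `2^N(4, 0.5)` and replicate noise of
0.15 cycles. Planted case–control enrichment converts a requested odds
ratio and control carriage into case carriage via the odds transform and
refuses near-saturated (unidentifiable) combinations. All randomness comes
from `numpy` generators seeded as `(seed, stream)`, so outputs are
bit-reproducible and adding an output stream never perturbs existing ones.

Planted somatic substitutions avoid the mtMSI windows, the engineered
tracts, the placeholder and the tree/mtSNP defining sites, and keep ≥ 10 nt
spacing, so the planted truth stays unambiguous after normalization. What
passing recovery tests show is therefore that the calling/annotation/
classification machinery is internally correct under the stated noise
model; they do not certify performance on real chromatogram artifacts,
NUMT contamination, low-level heteroplasmy below the two-allele
abstraction, or alignment ambiguity outside the modelled repeat classes.

## Problem sizes in the test suite

The suite favors sizes that keep a full run near ten seconds on one CPU:
the full-pipeline recovery property uses a 200-sample cohort (60 pairs, 70
controls, 10 thyroid), haplogroup recovery uses 100 samples, the type-I
calibration uses 200 seeds × 20 factors at 66 cases / 376 controls, and
the copy-number power property uses 200 seeds of 66 pairs. Exactness
checks enumerate completely where cheap (Mann–Whitney n ≤ 8, Fisher over
all tables with cells ≤ 5) and sweep a seeded random sample of larger
tables up to N = 40.

## Known limitations

* Sanger-era abstraction: no read-level calling, no quantitative
  heteroplasmic fractions, no phasing beyond two alleles, no NUMT
  screening.
* The packaged known-variant catalog and haplogroup tree are small local
  snapshots; novelty and haplogroup granularity are only as good as the
  supplied files.
* The seven external predictors are consumed as data, never re-scored.
* CI values computed from a supplied alignment are data-dependent; when a
  variant appears with different CIs in different inputs the reports carry
  both rather than reconciling them.
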