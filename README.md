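# mitovar

Mitochondrial genome characterization for tumor/normal cohort studies —
built around the analysis design used for papillary thyroid cancer (PTC)
cohorts: whole-mtDNA Sanger-style sequences from tumors, adjacent normal
tissue, normal thyroid and population blood controls, plus qPCR copy-number
measurements.

The package is aimed at analysts who need the complete downstream stack
after sequencing: variant calling against an rCRS-style reference,
consequence annotation under the vertebrate mitochondrial code, a
transparent rule-based pathogenicity classifier, haplogroup assignment,
relative copy-number quantification, and case–control association
statistics — all exercised end-to-end on synthetic cohorts with known
ground truth.

## What it computes

**Variant calling.** Sample sequences (1–2 alleles per tissue; IUPAC
two-way codes expand to two alleles) are globally aligned to the circular
16,569-bp reference. Indels are merged, shifted to their 3′-most placement
and labelled in the mitochondrial convention (`309insC`,
`11032-11038 A7-6`, `14495-14502 (AAAT)2-1`). A variant in a proper subset
of a sample's alleles is *heteroplasmic*; a tumor variant absent at that
position in the paired normal is *somatic*. Indels intersecting the mtMSI
repeat windows (np 303–315, 16184–16193, 514–523) are flagged. The
variation load of a gene or complex is
`altered nucleotides / unit length × 100`.

**Consequences.** Coding substitutions are synonymous, non-synonymous or
nonsense under translation table 2 (UGA→Trp, AGA/AGG→Ter, AUA→Met);
L-strand genes (ND6, eight tRNAs) are read as the reverse complement.
Non-triplet indels are frameshifts: the mutant CDS is rebuilt and
translated to the first stop to get the truncated product length. RNA
variants are screened against stem base-pair maps for Watson–Crick
disruption. The conservation index of a site is
`CI = (# of 41 primates carrying the human wild-type) / 41 × 100`.

**Pathogenicity.** A non-synonymous substitution is a *candidate* when (1)
its carrier frequency among blood controls is < 1%, (2) it is absent from
normal thyroid, and (3) CI > 75%. Candidates face a seven-predictor
majority vote — PolyPhen-2 (Probably/Possibly), SIFT (Not Tolerated),
MutationAssessor (High/Medium/Low), PROVEAN (Deleterious), SNP&GO
(Disease), Align-GVGD (C65), PANTHER (P<sub>deleterious</sub> > 0.5); NA
never votes — and are pathogenic at ≥ 4 of 7 votes. Nonsense and
frameshift mutations are pathogenic unconditionally.
`scripts/validate_binarization.py` re-derives the two non-obvious
binarization rules by brute force.

**Haplogroups.** A PhyloTree-style tree of defining variants is scored per
node as `matched/expected` over the root path; private variants are not
penalized.

**Copy number.** Relative mtDNA content is `2^(Ct_nuclear − Ct_mt)` (ideal
efficiency; standard-curve efficiencies optional), fold change is the
tumor/normal content ratio, and cohorts are compared with a two-sided
Mann–Whitney U test (exact for small groups).

**Association.** Odds ratios with Woolf 95% CIs
(`exp(ln OR ± 1.96·SE)`, Haldane–Anscombe +0.5 on zero cells), Pearson
chi-square without continuity correction, and an automatic Fisher-exact
fallback at small expected counts.

## Reference fixture

The bundled reference (`mitovar/data/rcrs_synthetic.fasta`) is a
**synthetic** rCRS-like record built deterministically by
`mitovar.refbuild`: 16,569 bp, the standard NC_012920 gene boundaries, the
legacy `N` placeholder at 3107, and engineered codon context at every
position used by the packaged variant tables, so consequence calls behave
as on the real molecule. Any user-supplied full-length reference plus
annotation TSV can be used instead via `load_reference`.

## Worked example

```bash
python examples/03_pathogenicity.py
```

prints one line per packaged candidate profile, e.g.

```
G3392A     ND1   votes=6/7 PATHOGENIC
T3644C     ND1   votes=4/7 PATHOGENIC
G3745A     ND1   votes=2/7
...
15 voted non-synonymous + 7 nonsense + 11 frameshift = 33 pathogenic mutations
```

`T3644C` survives with exactly four deleterious calls (SIFT,
MutationAssessor, PROVEAN, Align-GVGD) while `G3745A` falls short with two;
combining the vote survivors with the truncating mutations gives the final
pathogenic set of 33. The other examples cover calling
(`01_call_variants.py`), consequences and the ND6 175→58 aa truncation
(`02_consequences.py`), haplogroups, copy number, association, and the full
pipeline over a simulated cohort (`07_full_pipeline.py`).

A thin CLI wraps the same stages:

```bash
mitovar simulate --seed 1 --out run1
mitovar all --run-dir run1 --out run1/results
```

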