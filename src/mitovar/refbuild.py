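"""Deterministic builder for the bundled SYNTHETIC rCRS-like reference.

The real rCRS (GenBank NC_012920) cannot be redistributed here, so the
packaged fixture ``data/rcrs_synthetic.fasta`` is a synthetic stand-in built
by this module: 16,569 bp, the standard NC_012920 gene boundaries, the legacy
``N`` placeholder at position 3107, the three mitochondrial microsatellite
(mtMSI) repeat windows, and — crucially — engineered codon context at every
position exercised by the packaged variant tables, so that consequence calls
(e.g. Trp->Ter at 4969, the ND6 (AAAT)2->1 frameshift truncating a 175-codon
product to 58 residues) behave exactly as they do on the real molecule.

Construction rules that make the sequence globally consistent:

* Protein-gene filler codons are drawn from the 27 sense codons over
  ``{C,G,T}``.  None of the vertebrate-mitochondrial stop triplets
  (TAA/TAG/AGA/AGG) contains C, and all four contain A, so an A-free stretch
  can never harbour a stop in *any* reading frame — which keeps the
  overlapping ATP8/ATP6 and ND4L/ND4 frames simultaneously open with no
  search.
* Explicitly placed codons (table positions, start/stop codons, homopolymer
  tracts, overlap junctions) are sense codons verified by the validation pass.
* Leftover positions inside partially pre-set codons are filled with C (on
  the coding strand), which can never complete a stop triplet.
* The haplogroup-defining sites and mtSNP sites used by the packaged tree and
  the cohort simulator get fixed reference bases.

``build_reference()`` is deterministic: no RNG state leaks in, the same
sequence is produced on every call.
"""

from __future__ import annotations

import random

from .reference import (
    MT_LENGTH,
    GeneFeature,
    MitoReference,
    reverse_complement,
    translate,
)

# name, start, end, strand, kind — standard NC_012920 boundaries
ANNOTATIONS = [
    ("D-loop", 16024, 576, "H", "control-region"),
    ("tRNA-Phe", 577, 647, "H", "tRNA"),
    ("12S rRNA", 648, 1601, "H", "rRNA"),
    ("tRNA-Val", 1602, 1670, "H", "tRNA"),
    ("16S rRNA", 1671, 3229, "H", "rRNA"),
    ("tRNA-Leu(UUR)", 3230, 3304, "H", "tRNA"),
    ("ND1", 3307, 4262, "H", "protein"),
    ("tRNA-Ile", 4263, 4331, "H", "tRNA"),
    ("tRNA-Gln", 4329, 4400, "L", "tRNA"),
    ("tRNA-Met", 4402, 4469, "H", "tRNA"),
    ("ND2", 4470, 5511, "H", "protein"),
    ("tRNA-Trp", 5512, 5579, "H", "tRNA"),
    ("tRNA-Ala", 5587, 5655, "L", "tRNA"),
    ("tRNA-Asn", 5657, 5729, "L", "tRNA"),
    ("tRNA-Cys", 5761, 5826, "L", "tRNA"),
    ("tRNA-Tyr", 5826, 5891, "L", "tRNA"),
    ("COI", 5904, 7445, "H", "protein"),
    ("tRNA-Ser(UCN)", 7446, 7514, "L", "tRNA"),
    ("tRNA-Asp", 7518, 7585, "H", "tRNA"),
    ("COII", 7586, 8269, "H", "protein"),
    ("tRNA-Lys", 8295, 8364, "H", "tRNA"),
    ("ATP8", 8366, 8572, "H", "protein"),
    ("ATP6", 8527, 9207, "H", "protein"),
    ("COIII", 9207, 9990, "H", "protein"),
    ("tRNA-Gly", 9991, 10058, "H", "tRNA"),
    ("ND3", 10059, 10404, "H", "protein"),
    ("tRNA-Arg", 10405, 10469, "H", "tRNA"),
    ("ND4L", 10470, 10766, "H", "protein"),
    ("ND4", 10760, 12137, "H", "protein"),
    ("tRNA-His", 12138, 12206, "H", "tRNA"),
    ("tRNA-Ser(AGY)", 12207, 12265, "H", "tRNA"),
    ("tRNA-Leu(CUN)", 12266, 12336, "H", "tRNA"),
    ("ND5", 12337, 14148, "H", "protein"),
    ("ND6", 14149, 14673, "L", "protein"),
    ("tRNA-Glu", 14674, 14742, "L", "tRNA"),
    ("Cytb", 14747, 15887, "H", "protein"),
    ("tRNA-Thr", 15888, 15953, "H", "tRNA"),
    ("tRNA-Pro", 15956, 16023, "L", "tRNA"),
]

# Respiratory-complex groupings used by variation-load reports.
COMPLEXES = {
    "Complex I": ["ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6"],
    "Complex III": ["Cytb"],
    "Complex IV": ["COI", "COII", "COIII"],
    "Complex V": ["ATP6", "ATP8"],
    "rRNA": ["12S rRNA", "16S rRNA"],
    "tRNA": [n for n, *_ in ANNOTATIONS if n.startswith("tRNA")],
    "D-loop": ["D-loop"],
}

# mtMSI windows: poly-C tracts and the CA dinucleotide stretch.
MTMSI_WINDOWS = [(303, 315), (16184, 16193), (514, 523)]

# (gene, anchor position, codon in coding orientation).  The codon written is
# the full triplet containing the anchor; for L-strand ND6 the anchor is the
# rCRS position of the codon's *first* coding base.
_EXPLICIT_CODONS = [
    # ND1 — table substitution contexts
    ("ND1", 3307, "ATG"),
    ("ND1", 3392, "GGC"),   # G3392A: Gly->Asp
    ("ND1", 3644, "GTA"),   # T3644C: Val->Ala
    ("ND1", 3679, "TCC"),   # T3679C: Ser->Pro
    ("ND1", 3745, "GCA"),   # G3745A: Ala->Thr
    # ND2
    ("ND2", 4470, "ATG"),
    ("ND2", 4520, "CCA"),   # delAC context (4520-4521)
    ("ND2", 4521, "CTC"),
    ("ND2", 4875, "CTA"),   # C4875T: Leu->Leu
    ("ND2", 4969, "TGG"),   # G4969A: Trp->Ter
    ("ND2", 4971, "GGC"),   # G4971A: Gly->Ser
    ("ND2", 5460, "GCC"),   # mtSNP G5460A: Ala->Thr
    # COI
    ("COI", 5904, "ATG"),
    ("COI", 5977, "TGG"),   # G5977A: Trp->Ter
    ("COI", 6238, "CTA"),   # T6238C: Leu->Pro
    ("COI", 6340, "ACC"),   # C6340T: Thr->Ile
    ("COI", 6680, "CAT"),   # mtSNP T6680C: His->His
    ("COI", 6681, "TAC"),   # T6681C: Tyr->His
    ("COI", 7104, "TCA"),   # T7104C: Ser->Pro
    ("COI", 7329, "TTC"),   # T7329C: Phe->Leu
    ("COI", 7445, "TAA"),
    # COII
    ("COII", 7586, "ATG"),
    ("COII", 7750, "ATC"),  # C7750A: Ile->Met
    ("COII", 7928, "GGA"),  # G7928A: Gly->Ter (GGA->AGA)
    ("COII", 8156, "GTG"),  # G8156A: Val->Met
    ("COII", 8267, "TAA"),
    # ATP8 / ATP6 overlap region (frames interlock; all junction codons fixed)
    ("ATP8", 8366, "ATG"),
    ("ATP6", 8527, "ATG"),
    ("ATP6", 8530, "CTG"),
    ("ATP6", 8569, "CTA"),  # makes ATP8's terminal codon (8570-8572) = TAA
    ("ATP6", 8572, "ACC"),
    ("ATP6", 8989, "GCC"),  # G8989A: Ala->Thr
    ("ATP6", 9121, "CTG"),  # mtSNP G9123A: Leu->Leu
    ("ATP6", 9187, "TAT"),  # T9187C: Tyr->His
    ("ATP6", 9205, "TAA"),
    # COIII (shares position 9207 with ATP6's terminal A)
    ("COIII", 9208, "ATG"),
    ("COIII", 9253, "TGG"),  # G9253A: Trp->Ter
    ("COIII", 9355, "AAC"),  # A9355G: Asn->Ser
    # ND3
    ("ND3", 10059, "ATG"),
    ("ND3", 10398, "ACC"),  # haplogroup-M defining A10398G: Thr->Ala
    # ND4L / ND4 overlap
    ("ND4L", 10470, "ATG"),
    ("ND4L", 10521, "GGA"),  # G10521A: Gly->Ter
    ("ND4L", 10573, "GGA"),  # G10573A: Gly->Glu
    ("ND4L", 10622, "ACC"),  # C10622T: Thr->Thr
    ("ND4", 10760, "ATG"),
    ("ND4", 10763, "CTA"),   # also completes ND4L codons 98/99 (TGC, TAA)
    ("ND4", 10766, "ACC"),
    # ND4 indel contexts
    ("ND4", 10949, "CCG"),   # bounds the single C at 10952
    ("ND4", 10952, "CTG"),   # 10952insC context
    ("ND4", 11030, "CCA"),   # A7 tract 11032-11038
    ("ND4", 11033, "AAA"),
    ("ND4", 11036, "AAA"),
    ("ND4", 11039, "CCT"),
    ("ND4", 11645, "CTG"),   # 11646insT context
    ("ND4", 11672, "TCC"),   # C5 tract 11673-11677
    ("ND4", 11675, "CCC"),
    ("ND4", 11678, "GTT"),
    # ND5
    ("ND5", 12337, "ATG"),
    ("ND5", 12415, "CCC"),   # A8 tract 12418-12425
    ("ND5", 12418, "AAA"),
    ("ND5", 12421, "AAA"),
    ("ND5", 12424, "AAC"),
    ("ND5", 12794, "TTA"),   # T12794A: Leu->Ter (TTA->TAA)
    ("ND5", 12850, "ATC"),   # A12850G: Ile->Val
    ("ND5", 12856, "GCT"),   # 12858insT context
    ("ND5", 12859, "CCG"),
    ("ND5", 12943, "CTC"),   # C12943T: Leu->Phe
    ("ND5", 13126, "GTC"),   # C5 tract 13128-13132
    ("ND5", 13129, "CCC"),
    ("ND5", 13132, "CTG"),
    ("ND5", 13165, "CCC"),   # single A at 13170 (13170delA)
    ("ND5", 13168, "CCA"),
    ("ND5", 13171, "CTC"),
    ("ND5", 13535, "AAC"),   # A13535G: Asn->Ser
    ("ND5", 13621, "CTT"),   # C13621T: Leu->Phe
    ("ND5", 13748, "AAT"),   # A13748G: Asn->Ser
    ("ND5", 13825, "GGA"),   # G13825A: Gly->Ter
    ("ND5", 14146, "TAA"),
    # ND6 (L-strand; anchor = rCRS position of the codon's first coding base)
    ("ND6", 14673, "ATG"),
    ("ND6", 14587, "GCT"),   # mtSNP A14587G: Ala->Ala
    ("ND6", 14503, "TCC"),   # bounds the (AAAT)2 tract on its 3' (coding 5') side
    ("ND6", 14502, "ATT"),   # codon 58 — tract 14495-14502 = AAATAAAT on rCRS
    ("ND6", 14499, "TAT"),   # codon 59: becomes TAG after the 4-nt deletion
    ("ND6", 14496, "TTA"),   # codon 60
    ("ND6", 14493, "GCC"),   # codon 61
    ("ND6", 14463, "ACA"),   # T14463C: Thr->Ala
    ("ND6", 14310, "GGA"),   # C14310A: Gly->Trp (coding GGA->TGA, Trp in table 2)
    ("ND6", 14149, "TAA"),
    # Cytb
    ("Cytb", 14747, "ATG"),
    ("Cytb", 14774, "CTT"),  # C14774A: Leu->Ile
    ("Cytb", 15018, "TTC"),  # T15018A: Phe->Tyr
    ("Cytb", 15045, "CGA"),  # G15045A: Arg->Gln
    ("Cytb", 15090, "ATC"),  # T15090C: Ile->Thr
    ("Cytb", 15479, "TTC"),  # T15479C: Phe->Leu
    ("Cytb", 15483, "TCA"),  # C15483T: Ser->Leu
]

# Terminal bases for genes whose mRNA ends in an incomplete stop codon
# (T or TA completed to TAA by polyadenylation).
_PARTIAL_STOPS = {
    "ND1": "TA",
    "ND2": "T",
    "COIII": "T",
    "ND3": "T",
    "ND4": "T",
    "Cytb": "T",
}

# Fixed single bases outside protein genes.
_EXPLICIT_BASES = {
    3107: "N",
    # tRNA / rRNA sites from the novel-variant table (pair partners included)
    1629: "A", 1652: "T",      # tRNA-Val stem pair (A-U)
    2274: "A",                  # 16S rRNA
    3275: "C", 3276: "A", 3277: "G",  # tRNA-Leu(UUR) delCA context
    4272: "T", 4300: "A",      # tRNA-Ile stem pair (U-A)
    5834: "C", 5835: "T", 5836: "C",  # tRNA-Tyr insT context
    5860: "C", 5881: "G",      # tRNA-Tyr stem pair (molecule C-G; L strand)
    10040: "C",                 # tRNA-Gly loop
    # 12S mtSNP
    709: "G",
    # D-loop mtSNPs
    16164: "A", 16266: "C", 16362: "T",
    # haplogroup defining sites (control region / rRNA)
    73: "A", 150: "C", 152: "T", 195: "C", 235: "A", 489: "T",
    663: "A", 1736: "A", 1888: "T", 2092: "C", 2706: "T",
    16092: "T", 16126: "T", 16140: "T", 16217: "T", 16227: "A",
    16231: "A", 16260: "C", 16261: "C", 16290: "C", 16304: "T", 16319: "G",
}

# mtMSI repeat windows written verbatim (tract + bounding bases).
_EXPLICIT_RUNS = [
    (302, "ACCCCCCCTCCCCCT"),          # 302..316: C7 (303-309), T, C5 (311-315)
    (512, "TTCACACACACAT"),            # 512..524: (CA)5 at 514-523
    (16183, "ACCCCCTCCCCA"),           # 16183..16194: C5 (16184-16188), T, C4
]

_SAFE_CODONS = [
    a + b + c
    for a in "CGT"
    for b in "CGT"
    for c in "CGT"
]  # A-free => cannot contain or compose a stop triplet in any frame

_STOPS = {"TAA", "TAG", "AGA", "AGG"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]  # safe within a gene's own frame; shifted frames may (realistically) stop

_FEATURES = [GeneFeature(*row) for row in ANNOTATIONS]
_BY_NAME = {f.name: f for f in _FEATURES}


class _Builder:
    def __init__(self):
        self.seq: list = [None] * (MT_LENGTH + 1)  # 1-based

    def put(self, pos: int, base: str):
        cur = self.seq[pos]
        if cur is not None and cur != base:
            raise AssertionError(
                f"conflicting base at {pos}: {cur} vs {base} (builder bug)"
            )
        self.seq[pos] = base

    def put_codon(self, gene: str, anchor: int, codon: str):
        feat = _BY_NAME[gene]
        if feat.strand == "H":
            idx = (anchor - feat.start) // 3
            start = feat.start + 3 * idx
            for k, base in enumerate(codon):
                self.put(start + k, base)
        else:
            coding_pos = feat.end - anchor + 1
            idx = (coding_pos - 1) // 3
            first_coding = 3 * idx + 1
            for k, base in enumerate(codon):
                p = feat.end - (first_coding + k) + 1
                self.put(p, _complement(base))


def _complement(b: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}[b]


def _fill_proteins(b: _Builder, rng: random.Random):
    order = [
        "ND1", "ND2", "COI", "COII", "ATP6", "ATP8", "COIII", "ND3",
        "ND4L", "ND4", "ND5", "ND6", "Cytb",
    ]
    for name in order:
        feat = _BY_NAME[name]
        n_full = len(feat) // 3
        for idx in range(n_full):
            if feat.strand == "H":
                positions = [feat.start + 3 * idx + k for k in range(3)]
            else:
                positions = [feat.end - (3 * idx + k) for k in range(3)]
            states = [b.seq[p] for p in positions]
            if all(s is None for s in states):
                # inside the ATP8/ATP6 dual-frame region only A-free codons
                # are safe; elsewhere any sense codon keeps the frame open
                dual_frame = name == "ATP6" and min(positions) <= 8572
                codon = rng.choice(_SAFE_CODONS if dual_frame else _SENSE_CODONS)
                for p, base in zip(
                    positions,
                    codon if feat.strand == "H" else [_complement(c) for c in codon],
                ):
                    b.seq[p] = base
            else:
                # complete a partially pre-set codon with coding-strand C
                for p, s in zip(positions, states):
                    if s is None:
                        b.seq[p] = "C" if feat.strand == "H" else "G"
        # incomplete terminal codon
        rem = len(feat) % 3
        if rem:
            tail = _PARTIAL_STOPS[name]
            assert len(tail) == rem, name
            for k, base in enumerate(tail):
                pos = feat.end - rem + 1 + k
                b.put(pos, base)


def build_reference() -> MitoReference:
    """Build the synthetic rCRS-like reference (deterministic)."""
    rng = random.Random(16569)
    b = _Builder()
    for pos, base in _EXPLICIT_BASES.items():
        b.put(pos, base)
    for start, run in _EXPLICIT_RUNS:
        for k, base in enumerate(run):
            b.put(start + k, base)
    for gene, anchor, codon in _EXPLICIT_CODONS:
        b.put_codon(gene, anchor, codon)
    _fill_proteins(b, rng)
    for pos in range(1, MT_LENGTH + 1):
        if b.seq[pos] is None:
            b.seq[pos] = rng.choice("ACGT")
    ref = MitoReference(
        sequence="".join(b.seq[1:]), name="rCRS-synthetic", features=list(_FEATURES)
    )
    _validate(ref)
    return ref


def _validate(ref: MitoReference):
    assert len(ref) == MT_LENGTH
    assert ref.base(3107) == "N"
    for feat in ref.features:
        if feat.kind != "protein":
            continue
        cds = ref.coding_sequence(feat)
        assert len(cds) % 3 == 0, feat.name
        peptide = translate(cds)
        # no internal stop: translation must run to the final codon
        n_codons = len(cds) // 3
        assert len(peptide) == n_codons - 1, (
            f"{feat.name}: internal stop (peptide {len(peptide)} aa, "
            f"{n_codons} codons)"
        )
    # ND6 product length matches the 175-codon gene model
    nd6 = ref.feature_by_name("ND6")
    assert len(ref.coding_sequence(nd6)) // 3 == 175


def write_fixture_files(outdir):
    """Write the reference FASTA + annotation TSV fixtures."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = build_reference()
    with open(outdir / "rcrs_synthetic.fasta", "w") as fh:
        fh.write(
            ">rCRS-synthetic synthetic stand-in for NC_012920 "
            "(rCRS-style coordinates; built by mitovar.refbuild)\n"
        )
        for i in range(0, len(ref.sequence), 70):
            fh.write(ref.sequence[i : i + 70] + "\n")
    with open(outdir / "gene_annotations.tsv", "w") as fh:
        fh.write("name\tstart\tend\tstrand\tkind\n")
        for name, start, end, strand, kind in ANNOTATIONS:
            fh.write(f"{name}\t{start}\t{end}\t{strand}\t{kind}\n")


if __name__ == "__main__":
    import sys

    write_fixture_files(sys.argv[1] if len(sys.argv) > 1 else "src/mitovar/data")
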