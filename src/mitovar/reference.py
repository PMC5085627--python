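"""Circular mitochondrial reference model.

The human mitochondrial genome is a 16,569 bp circular molecule conventionally
numbered 1..16569 on the rCRS (revised Cambridge Reference Sequence) light
strand as written.  Thirteen protein genes, 22 tRNAs and two rRNAs are encoded
on both strands; ND6 and eight tRNAs are read from the opposite (L) strand,
i.e. their coding sequence is the reverse complement of the reference as
written.  The non-coding control region (D-loop) wraps the origin
(~16024..576).  Position 3107 is a legacy placeholder kept as ``N`` so that
historical position numbering is preserved.

Protein genes are translated with the vertebrate mitochondrial genetic code
(NCBI translation table 2: UGA=Trp, AGA/AGG=Ter, AUA=Met).  Several mRNAs end
in an incomplete stop codon (T or TA) completed by polyadenylation; here the
final partial codon is padded with A's before translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable

MT_LENGTH = 16569
PLACEHOLDER_POS = 3107  # legacy rCRS spacer, always N

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Vertebrate mitochondrial code (NCBI table 2).
_TABLE2 = _BioCodonTable.unambiguous_dna_by_id[2]

STOP_CODONS = frozenset(_TABLE2.stop_codons)  # TAA, TAG, AGA, AGG


@dataclass(frozen=True)
class CodonTable:
    """Codon -> amino acid map for the vertebrate mitochondrial code."""

    code: dict
    start_codons: frozenset

    def translate_codon(self, codon: str) -> str:
        """One-letter amino acid, ``*`` for stop, ``X`` for ambiguous codons."""
        codon = codon.upper()
        if codon in STOP_CODONS:
            return "*"
        aa = self.code.get(codon)
        return aa if aa is not None else "X"


def vertebrate_mito_table() -> CodonTable:
    return CodonTable(
        code=dict(_TABLE2.forward_table),
        start_codons=frozenset(_TABLE2.start_codons),
    )


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature in rCRS coordinates (1-based, inclusive).

    Only the control region may wrap the circular origin (start > end).
    """

    name: str
    start: int
    end: int
    strand: str  # "H" or "L"
    kind: str  # protein | tRNA | rRNA | control-region

    def __post_init__(self):
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be H or L, got {self.strand!r}")
        if self.kind not in ("protein", "tRNA", "rRNA", "control-region"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (1 <= self.start <= MT_LENGTH and 1 <= self.end <= MT_LENGTH):
            raise ValueError(f"{self.name}: coordinates outside 1..{MT_LENGTH}")
        if self.start > self.end and self.kind != "control-region":
            raise ValueError(
                f"{self.name}: start {self.start} > end {self.end} is only "
                "allowed for the control region (circular wrap)"
            )

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def __len__(self) -> int:
        if self.wraps:
            return MT_LENGTH - self.start + 1 + self.end
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end


@dataclass
class MitoReference:
    """The circular reference sequence plus its gene annotation."""

    sequence: str
    name: str = "chrM"
    circular: bool = True
    features: list = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"reference contains non-ACGTN symbols: {sorted(bad)}")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based rCRS position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside 1..{len(self.sequence)}")
        return self.sequence[position - 1]

    def slice(self, start: int, end: int) -> str:
        """Inclusive 1-based slice; wraps the origin when start > end."""
        if start > end:
            return self.sequence[start - 1 :] + self.sequence[:end]
        return self.sequence[start - 1 : end]

    def feature_at(self, position: int) -> list:
        """All features whose (circular-aware) interval contains the position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside 1..{len(self.sequence)}")
        return [f for f in self.features if f.contains(position)]

    def feature_by_name(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def coding_sequence(self, feature: GeneFeature) -> str:
        """Coding-orientation nucleotide sequence of a feature.

        L-strand genes come back reverse complemented.  Protein genes with an
        incomplete terminal codon are padded with A's (polyadenylation
        completes the stop codon in vivo).
        """
        seq = self.slice(feature.start, feature.end)
        if feature.strand == "L":
            seq = reverse_complement(seq)
        if feature.kind == "protein" and len(seq) % 3:
            seq += "A" * (3 - len(seq) % 3)
        return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nucleotides: str, codon_table: CodonTable | None = None) -> str:
    """Translate codon-by-codon, truncating at the first stop.

    Codons containing N translate to ``X`` (never silently skipped).  A
    trailing partial codon is ignored.
    """
    if len(nucleotides) < 3:
        raise ValueError("need at least one full codon")
    table = codon_table or vertebrate_mito_table()
    peptide = []
    for i in range(0, len(nucleotides) - len(nucleotides) % 3, 3):
        aa = table.translate_codon(nucleotides[i : i + 3])
        if aa == "*":
            break
        peptide.append(aa)
    return "".join(peptide)


def codon_at(
    reference: MitoReference, feature: GeneFeature, position: int
) -> tuple[str, int, int]:
    """Codon (coding orientation) containing an rCRS position.

    Returns ``(codon, offset_in_codon 1..3, codon_number counted from the
    feature's start codon)``.
    """
    if feature.kind != "protein":
        raise ValueError(f"{feature.name} is not a protein feature")
    if not feature.contains(position):
        raise ValueError(f"position {position} outside {feature.name}")
    if feature.strand == "H":
        coding_pos = position - feature.start + 1  # 1-based within CDS
    else:
        coding_pos = feature.end - position + 1
    codon_number = (coding_pos - 1) // 3 + 1
    offset = (coding_pos - 1) % 3 + 1
    cds = reference.coding_sequence(feature)
    codon = cds[(codon_number - 1) * 3 : codon_number * 3]
    return codon, offset, codon_number


def load_annotation(path) -> list:
    """Read the TSV annotation table (``name start end strand kind``)."""
    features = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["name", "start", "end", "strand", "kind"]
        if header != expected:
            raise ValueError(f"annotation header must be {expected}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            name, start, end, strand, kind = line.rstrip("\n").split("\t")
            features.append(
                GeneFeature(name, int(start), int(end), strand=strand, kind=kind)
            )
    return features


def load_reference(ref_path, annotation_path) -> MitoReference:
    """Load a FASTA or GenBank reference plus its annotation TSV.

    The reference must be full length (16,569 bp); anything else raises with
    the observed length.  Protein features must have a length divisible by 3
    after incomplete-stop padding (always true for any integer length, so the
    structural check here is start<=end except for the wrapping control
    region, enforced by :class:`GeneFeature`).
    """
    ref_path = Path(ref_path)
    fmt = "genbank" if ref_path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    record = next(SeqIO.parse(str(ref_path), fmt))
    seq = str(record.seq).upper()
    if len(seq) != MT_LENGTH:
        raise ValueError(
            f"reference length {len(seq)} != expected {MT_LENGTH} (not an rCRS-style record)"
        )
    features = load_annotation(annotation_path)
    return MitoReference(sequence=seq, name=record.id, features=features)


def bundled_reference() -> MitoReference:
    """The packaged reference fixture (synthetic rCRS-like record)."""
    from importlib.resources import files

    data = files("mitovar") / "data"
    return load_reference(
        str(data / "rcrs_synthetic.fasta"), str(data / "gene_annotations.tsv")
    )
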