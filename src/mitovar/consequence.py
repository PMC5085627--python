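"""Consequence annotation of mtDNA variants.

Coding substitutions are classified synonymous / non-synonymous / nonsense by
recomputing the affected codon in coding orientation (L-strand genes such as
ND6 are read as the reverse complement) under the vertebrate mitochondrial
code.  Indels in protein genes of non-triplet length are frameshifts: the
mutant coding sequence is rebuilt and translated to the first stop to obtain
the truncated product length.  RNA-gene substitutions are screened against
published secondary-structure base-pair maps for Watson-Crick disruption, and
cross-species conservation is summarized as the conservation index (CI): the
percentage of a 41-primate alignment (human included) carrying the human
wild-type residue or nucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass

from .calling import Variant
from .reference import (
    CodonTable,
    GeneFeature,
    MitoReference,
    codon_at,
    reverse_complement,
    translate,
    vertebrate_mito_table,
)

N_PRIMATES = 41

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter", "X": "Xaa",
}


@dataclass
class Consequence:
    variant: Variant
    gene: str
    category: str  # synonymous | non-synonymous | nonsense | frameshift |
    #                in-frame-indel | rna | control-region
    aa_change: str = ""  # e.g. "Leu->Pro", "Trp->Ter"
    product_length_ref: int | None = None  # codons incl. terminal stop
    product_length_alt: int | None = None  # residues before premature stop
    transition_or_transversion: str = ""
    notes: str = ""


@dataclass
class RnaPairingMap:
    """Stem base pairs of one RNA gene, in rCRS coordinates."""

    gene: str
    pairs: set  # of frozenset({pos1, pos2})

    def partner(self, position: int) -> int | None:
        for pair in self.pairs:
            if position in pair:
                (other,) = pair - {position}
                return other
        return None


@dataclass
class ConservationResult:
    site: object
    wildtype_count: int

    @property
    def ci_percent(self) -> float:
        return self.wildtype_count / N_PRIMATES * 100.0


def transition_or_transversion(ref: str, alt: str) -> str:
    return "transition" if (ref, alt) in _TRANSITIONS else "transversion"


def annotate_substitution(
    variant: Variant,
    reference: MitoReference,
    feature: GeneFeature | None = None,
    codon_table: CodonTable | None = None,
) -> Consequence:
    """Classify a substitution; non-protein positions get rna/control-region."""
    if variant.kind != "substitution":
        raise ValueError("annotate_substitution expects a substitution")
    table = codon_table or vertebrate_mito_table()
    if feature is None:
        feats = reference.feature_at(variant.start)
        proteins = [f for f in feats if f.kind == "protein"]
        feature = proteins[0] if proteins else (feats[0] if feats else None)
    titv = transition_or_transversion(variant.ref, variant.alt)
    if feature is None or feature.kind != "protein":
        category = (
            "control-region"
            if feature is not None and feature.kind == "control-region"
            else "rna"
            if feature is not None
            else "control-region"
        )
        return Consequence(
            variant=variant,
            gene=feature.name if feature else "intergenic",
            category=category,
            transition_or_transversion=titv,
        )
    codon, offset, codon_number = codon_at(reference, feature, variant.start)
    alt_base = variant.alt if feature.strand == "H" else _comp(variant.alt)
    ref_base_coding = variant.ref if feature.strand == "H" else _comp(variant.ref)
    assert codon[offset - 1] == ref_base_coding, (variant, codon, offset)
    alt_codon = codon[: offset - 1] + alt_base + codon[offset:]
    aa_ref = table.translate_codon(codon)
    aa_alt = table.translate_codon(alt_codon)
    n_codons = len(reference.coding_sequence(feature)) // 3
    if aa_alt == "*":
        category = "nonsense"
        plen_alt = codon_number - 1
    elif aa_ref == aa_alt:
        category = "synonymous"
        plen_alt = None
    else:
        category = "non-synonymous"
        plen_alt = None
    return Consequence(
        variant=variant,
        gene=feature.name,
        category=category,
        aa_change=f"{AA3[aa_ref]}->{AA3[aa_alt]}",
        product_length_ref=n_codons,
        product_length_alt=plen_alt,
        transition_or_transversion=titv,
    )


def _comp(b: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}[b]


def annotate_indel(
    variant: Variant,
    reference: MitoReference,
    feature: GeneFeature | None = None,
    codon_table: CodonTable | None = None,
) -> Consequence:
    """Classify an indel in a protein gene; frameshifts are translated.

    Non-triplet length shifts the frame; the mutant coding sequence is
    rebuilt (strand-aware), padded, and translated to the first stop;
    ``product_length_alt`` is the residue count before that stop.  In-frame
    indels are classified separately.
    """
    if not variant.is_indel:
        raise ValueError("annotate_indel expects an insertion or deletion")
    table = codon_table or vertebrate_mito_table()
    if feature is None:
        feats = set(reference.feature_at(variant.start)) | set(
            reference.feature_at(variant.end)
        )
        proteins = sorted(
            (f for f in feats if f.kind == "protein"), key=lambda f: f.start
        )
        if not proteins:
            nonprot = sorted(feats, key=lambda f: f.start)
            if not nonprot:
                return Consequence(variant, "intergenic", "control-region")
            f0 = nonprot[0]
            cat = "control-region" if f0.kind == "control-region" else "rna"
            return Consequence(variant, f0.name, cat)
        feature = proteins[0]
    notes = ""
    if not (feature.contains(variant.start) and feature.contains(variant.end)):
        notes = "indel spans a feature boundary"
    shift = abs(variant.indel_length) % 3
    n_codons_ref = len(reference.coding_sequence(feature)) // 3
    mutant_cds = _mutant_cds(variant, reference, feature)
    peptide = translate(mutant_cds, table) if len(mutant_cds) >= 3 else ""
    stop_found = len(peptide) < len(mutant_cds) // 3
    category = "frameshift" if shift else "in-frame-indel"
    return Consequence(
        variant=variant,
        gene=feature.name,
        category=category,
        product_length_ref=n_codons_ref,
        product_length_alt=len(peptide) if stop_found else None,
        notes=notes or ("no stop before feature end" if not stop_found else ""),
    )


def _mutant_cds(variant: Variant, reference: MitoReference, feature: GeneFeature) -> str:
    """Coding sequence of the feature with the indel applied.

    The edit is applied to the extracted coding-orientation sequence, so the
    truncation search never reads past the annotated gene (transcripts are
    cleaved at gene boundaries).
    """
    cds_region = reference.slice(feature.start, feature.end)
    local_start = variant.start - feature.start  # 0-based in region
    if variant.kind == "deletion":
        local_end = variant.end - feature.start
        local_start = max(local_start, 0)
        local_end = min(local_end, len(cds_region) - 1)
        region = cds_region[:local_start] + cds_region[local_end + 1 :]
    else:
        cut = min(max(local_start + 1, 0), len(cds_region))
        region = cds_region[:cut] + variant.alt + cds_region[cut:]
    if feature.strand == "L":
        region = reverse_complement(region)
    if len(region) % 3:
        region += "A" * (3 - len(region) % 3)
    return region


def annotate_rna(
    variant: Variant,
    pairing_map: RnaPairingMap | None,
    reference: MitoReference,
    feature: GeneFeature | None = None,
) -> tuple[bool | None, str]:
    """Does an RNA-gene substitution abolish a Watson-Crick stem pair?

    Returns ``(disrupted, description)``; ``disrupted`` is None when no
    pairing map is available (undetermined) or the position is unpaired.
    Bases are compared in molecule orientation (L-strand genes are
    complemented), and pairs are described RNA-style, e.g. ``A-U|``.
    """
    if variant.kind != "substitution":
        raise ValueError("pairing disruption is defined for substitutions")
    if pairing_map is None:
        return None, "no pairing map"
    partner = pairing_map.partner(variant.start)
    if partner is None:
        return None, "unpaired (loop) position"
    if feature is None:
        feats = [f for f in reference.feature_at(variant.start) if f.kind in ("tRNA", "rRNA")]
        feature = feats[0] if feats else None
    flip = feature is not None and feature.strand == "L"
    ref_b = _rna(_maybe_comp(variant.ref, flip))
    alt_b = _rna(_maybe_comp(variant.alt, flip))
    partner_b = _rna(_maybe_comp(reference.base(partner), flip))
    was_wc = {ref_b, partner_b} in ({"A", "U"}, {"G", "C"})
    now_wc = {alt_b, partner_b} in ({"A", "U"}, {"G", "C"})
    pair_desc = f"{ref_b}-{partner_b}"
    if was_wc and not now_wc:
        return True, f"{pair_desc}|"  # pair abolished
    return False, pair_desc


def _maybe_comp(b: str, flip: bool) -> str:
    return _comp(b) if flip else b


def _rna(b: str) -> str:
    return "U" if b == "T" else b


def conservation_index(column, human_wildtype: str) -> ConservationResult:
    """CI of one alignment column of 41 primate symbols (human included).

    ``ci_percent = count(symbol == human_wildtype) / 41 * 100``.  Gaps count
    as non-wild-type.  The comparison is case-insensitive.
    """
    symbols = list(column)
    if len(symbols) != N_PRIMATES:
        raise ValueError(f"expected {N_PRIMATES} aligned symbols, got {len(symbols)}")
    wt = human_wildtype.upper()
    count = sum(1 for s in symbols if s.upper() == wt)
    return ConservationResult(site=None, wildtype_count=count)
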