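"""Consequence classes, truncation lengths, RNA pairing, conservation."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitovar.calling import Variant, apply_variants
from mitovar.consequence import (
    N_PRIMATES,
    annotate_indel,
    annotate_rna,
    annotate_substitution,
    conservation_index,
    transition_or_transversion,
)
from mitovar.reference import reverse_complement, vertebrate_mito_table


@pytest.mark.parametrize(
    "pos,ref,alt,category,aa_change,gene",
    [
        (12794, "T", "A", "nonsense", "Leu->Ter", "ND5"),
        (4875, "C", "T", "synonymous", "Leu->Leu", "ND2"),
        (6238, "T", "C", "non-synonymous", "Leu->Pro", "COI"),
        (4969, "G", "A", "nonsense", "Trp->Ter", "ND2"),
        (14310, "C", "A", "non-synonymous", "Gly->Trp", "ND6"),
        (14463, "T", "C", "non-synonymous", "Thr->Ala", "ND6"),
    ],
)
def test_substitution_classes(reference, pos, ref, alt, category, aa_change, gene):
    cons = annotate_substitution(
        Variant(pos, pos, "substitution", ref, alt), reference
    )
    assert (cons.gene, cons.category, cons.aa_change) == (gene, category, aa_change)


def test_substitution_outside_protein(reference):
    rna = annotate_substitution(Variant(1629, 1629, "substitution", "A", "T"), reference)
    assert rna.category == "rna" and rna.gene == "tRNA-Val"
    dloop = annotate_substitution(
        Variant(16300, 16300, "substitution", reference.base(16300),
                "A" if reference.base(16300) != "A" else "G"),
        reference,
    )
    assert dloop.category == "control-region"


def test_every_protein_substitution_has_one_class(reference):
    rng = random.Random(3)
    proteins = [f for f in reference.features if f.kind == "protein"]
    for _ in range(150):
        feat = rng.choice(proteins)
        pos = rng.randint(feat.start, feat.end)
        ref = reference.base(pos)
        if ref == "N":
            continue
        alt = rng.choice([b for b in "ACGT" if b != ref])
        cons = annotate_substitution(
            Variant(pos, pos, "substitution", ref, alt), reference, feature=feat
        )
        assert cons.category in ("synonymous", "non-synonymous", "nonsense")


def test_nd6_frameshift_truncation(reference):
    """The (AAAT)2->1 deletion truncates the 175-codon ND6 product to 58 aa."""
    cons = annotate_indel(
        Variant(14499, 14502, "deletion", "AAAT", ""), reference
    )
    assert cons.category == "frameshift"
    assert cons.product_length_ref == 175
    assert cons.product_length_alt == 58


def test_insertion_frameshift(reference):
    cons = annotate_indel(Variant(10952, 10952, "insertion", "", "C"), reference)
    assert cons.gene == "ND4" and cons.category == "frameshift"


def test_inframe_indel_not_frameshift(reference):
    nd1 = reference.feature_by_name("ND1")
    pos = nd1.start + 150  # codon-aligned 3-nt deletion
    v = Variant(pos, pos + 2, "deletion", reference.slice(pos, pos + 2), "")
    assert annotate_indel(v, reference).category == "in-frame-indel"


def _bruteforce_truncation(reference, variant, gene):
    """Independent oracle: apply the edit to the genome, re-slice, translate."""
    feat = reference.feature_by_name(gene)
    mutant = apply_variants(reference.sequence, [variant])
    net = variant.indel_length
    region = mutant[feat.start - 1 : feat.end + net]
    if feat.strand == "L":
        region = reverse_complement(region)
    if len(region) % 3:
        region += "A" * (3 - len(region) % 3)
    table = vertebrate_mito_table()
    count = 0
    for i in range(0, len(region) - len(region) % 3, 3):
        if table.translate_codon(region[i : i + 3]) == "*":
            return count
        count += 1
    return None


@pytest.mark.parametrize(
    "variant,gene",
    [
        (Variant(14499, 14502, "deletion", "AAAT", ""), "ND6"),
        (Variant(4520, 4521, "deletion", "AC", ""), "ND2"),
        (Variant(12425, 12425, "deletion", "A", ""), "ND5"),
        (Variant(12858, 12858, "insertion", "", "T"), "ND5"),
        (Variant(10952, 10952, "insertion", "", "C"), "ND4"),
    ],
)
def test_truncation_matches_bruteforce_oracle(reference, variant, gene):
    cons = annotate_indel(variant, reference)
    assert cons.product_length_alt == _bruteforce_truncation(
        reference, variant, gene
    )


def test_strand_symmetry_of_classes(reference):
    """Class logic is strand-agnostic: H-strand ND5 and L-strand ND6 agree."""
    # both are Gly->Ter style nonsense under the mito code
    h = annotate_substitution(Variant(13825, 13825, "substitution", "G", "A"), reference)
    # coding GGA->TGA on L strand is Trp (not Ter) under table 2
    l = annotate_substitution(Variant(14310, 14310, "substitution", "C", "A"), reference)
    assert h.category == "nonsense"
    assert l.category == "non-synonymous" and l.aa_change == "Gly->Trp"


@pytest.mark.parametrize(
    "pos,ref,alt,expected_desc",
    [
        (1629, "A", "T", "A-U|"),
        (4272, "T", "C", "U-A|"),
    ],
)
def test_rna_pair_disruption(reference, pairing_maps, pos, ref, alt, expected_desc):
    feats = [f for f in reference.feature_at(pos) if f.kind == "tRNA"]
    pm = pairing_maps[feats[0].name]
    disrupted, desc = annotate_rna(
        Variant(pos, pos, "substitution", ref, alt), pm, reference
    )
    assert disrupted is True
    assert desc == expected_desc


def test_rna_l_strand_pair_in_molecule_orientation(reference, pairing_maps):
    """tRNA-Tyr is L-strand: rCRS G5881C abolishes a molecule-space C-G pair."""
    disrupted, desc = annotate_rna(
        Variant(5881, 5881, "substitution", "G", "C"),
        pairing_maps["tRNA-Tyr"],
        reference,
    )
    assert disrupted is True
    assert desc == "C-G|"


def test_rna_loop_and_missing_map(reference, pairing_maps):
    loop, desc = annotate_rna(
        Variant(10040, 10040, "substitution", "C", "A"), None, reference
    )
    assert loop is None and "no pairing map" in desc
    unpaired, desc = annotate_rna(
        Variant(1630, 1630, "substitution", reference.base(1630), "A"),
        pairing_maps["tRNA-Val"],
        reference,
    )
    assert unpaired is None and "loop" in desc


@pytest.mark.parametrize(
    "wildtype_count,expected",
    [(41, 100.0), (32, 78.048780487804876), (10, 24.390243902439025)],
)
def test_conservation_index_values(wildtype_count, expected):
    column = ["L"] * wildtype_count + ["P"] * (41 - wildtype_count)
    result = conservation_index(column, "L")
    assert result.wildtype_count == wildtype_count
    assert result.ci_percent == pytest.approx(expected)


def test_conservation_index_rejects_wrong_width():
    with pytest.raises(ValueError, match="41"):
        conservation_index(["A"] * 40, "A")


def test_gaps_count_as_non_wildtype():
    column = ["A"] * 30 + ["-"] * 11
    assert conservation_index(column, "A").wildtype_count == 30


@settings(max_examples=60, derandomize=True)
@given(st.lists(st.sampled_from("ACDEFGHIKLMNPQRSTVWY-"), min_size=41, max_size=41))
def test_ci_always_multiple_of_100_over_41(column):
    ci = conservation_index(column, "L").ci_percent
    assert abs(round(ci / (100 / N_PRIMATES)) - ci / (100 / N_PRIMATES)) < 1e-9
    assert 0 <= ci <= 100


def test_titv():
    assert transition_or_transversion("A", "G") == "transition"
    assert transition_or_transversion("C", "T") == "transition"
    assert transition_or_transversion("C", "A") == "transversion"
    assert transition_or_transversion("G", "T") == "transversion"
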