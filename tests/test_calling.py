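"""Alignment, variant extraction/normalization, zygosity and origin."""

import pytest

from mitovar.calling import (
    MTMSI_WINDOWS,
    SampleSequence,
    Variant,
    align_to_reference,
    apply_variants,
    call_sample,
    classify_origin,
    extract_variants,
    flag_mtMSI,
    normalize_indel,
    variant_label,
    variation_load,
)
from mitovar.io import novel_variant_table, truncating_mutation_table


def _edit_distance(a: str, b: str) -> int:
    """Tiny DP oracle for alignment cost checks on short windows."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def test_self_alignment_has_no_variants(reference):
    aln = align_to_reference(reference.sequence, reference)
    assert aln.edit_distance == 0
    assert extract_variants(aln) == []


def test_single_substitution_recovered(reference):
    planted = Variant(4969, 4969, "substitution", "G", "A")
    mutant = apply_variants(reference.sequence, [planted])
    aln = align_to_reference(mutant, reference)
    assert extract_variants(aln) == [planted]


def test_repeat_unit_deletion_single_gap(reference):
    """Deleting one AAAT from the (AAAT)2 tract aligns as one 4-nt gap."""
    planted = Variant(14495, 14498, "deletion", "AAAT", "")
    mutant = apply_variants(reference.sequence, [planted])
    aln = align_to_reference(mutant, reference)
    variants = extract_variants(aln)
    assert variants == [Variant(14499, 14502, "deletion", "AAAT", "")]
    # brute-force check on the 60-bp window around the planted edit
    ref_win = reference.slice(14465, 14525)
    smp_win = mutant[14464 : 14520]
    assert _edit_distance(ref_win, smp_win) <= 4 + abs(len(ref_win) - len(smp_win))
    assert aln.edit_distance == 4


def test_nearby_substitutions_not_traded_for_indels(reference):
    """Two close substitutions must not come back as an ins+del pair."""
    planted = [
        Variant(150, 150, "substitution", "C", "T"),
        Variant(152, 152, "substitution", "T", "C"),
    ]
    mutant = apply_variants(reference.sequence, planted)
    aln = align_to_reference(mutant, reference)
    assert extract_variants(aln) == sorted(planted)


def test_length_and_identity_guards(reference):
    with pytest.raises(ValueError, match="length"):
        align_to_reference("ACGT" * 1000, reference)
    scrambled = reference.sequence[:8000][::-1] + reference.sequence[8000:]
    with pytest.raises(ValueError, match="not an mtDNA"):
        align_to_reference(scrambled, reference)


def test_placeholder_3107_never_called(reference):
    mutant = reference.sequence[:3106] + "A" + reference.sequence[3107:]
    aln = align_to_reference(mutant, reference)
    assert extract_variants(aln) == []


@pytest.mark.parametrize(
    "copy_start",
    [14495, 14499],
)
def test_indel_normalization_independent_of_deleted_copy(reference, copy_start):
    """Deleting either AAAT copy normalizes to the same 3'-most variant."""
    v = Variant(copy_start, copy_start + 3, "deletion", "AAAT", "")
    assert normalize_indel(v, reference) == Variant(
        14499, 14502, "deletion", "AAAT", ""
    )


def test_insertion_normalizes_3prime(reference):
    # poly-C tract 303-309: an insertion anywhere inside shifts to 309
    v = normalize_indel(Variant(304, 304, "insertion", "", "C"), reference)
    assert v == Variant(309, 309, "insertion", "", "C")
    assert variant_label(v, reference) == "303-309 C7-8"


def test_fixture_labels_round_trip(reference):
    """Canonical labels regenerate exactly for every packaged table row."""
    for table in (novel_variant_table(), truncating_mutation_table()):
        for _, row in table.iterrows():
            assert variant_label(row["variant"], reference) == row["label"]


def test_iupac_expansion_yields_heteroplasmy(reference):
    seq = reference.sequence[:6237] + "Y" + reference.sequence[6238:]
    assert reference.base(6238) == "T"
    sample = SampleSequence("s", "tumor", [seq], "subj")
    calls = call_sample(sample, reference)
    assert len(calls) == 1
    call = calls[0]
    assert call.variant == Variant(6238, 6238, "substitution", "T", "C")
    assert call.zygosity == "heteroplasmic"
    assert call.heteroplasmic_fraction == 0.5


def test_dual_allele_zygosity(reference):
    shared = Variant(4875, 4875, "substitution", "C", "T")
    private = Variant(6238, 6238, "substitution", "T", "C")
    a1 = apply_variants(reference.sequence, [shared, private])
    a2 = apply_variants(reference.sequence, [shared])
    calls = {c.variant: c for c in call_sample(
        SampleSequence("s", "tumor", [a1, a2], "subj"), reference
    )}
    assert calls[shared].zygosity == "homoplasmic"
    assert calls[private].zygosity == "heteroplasmic"


def test_grossly_different_alleles_rejected(reference):
    with pytest.raises(ValueError, match="different length"):
        SampleSequence("s", "tumor", [reference.sequence, reference.sequence[:15000]])


def test_classify_origin(reference):
    somatic = Variant(6238, 6238, "substitution", "T", "C")
    germ = Variant(4875, 4875, "substitution", "C", "T")
    tumor_seq = apply_variants(reference.sequence, [somatic, germ])
    normal_seq = apply_variants(reference.sequence, [germ])
    tc = call_sample(SampleSequence("s|t", "tumor", [tumor_seq], "p1"), reference)
    nc = call_sample(
        SampleSequence("s|n", "adjacent-normal", [normal_seq], "p1"), reference
    )
    classified = {c.variant: c for c in classify_origin(tc, nc, "p1", "p1")}
    assert classified[somatic].origin == "somatic"
    assert classified[germ].origin == "germline"
    # no paired normal: origin stays undetermined
    assert all(c.origin == "undetermined" for c in tc)
    with pytest.raises(ValueError, match="subject mismatch"):
        classify_origin(tc, nc, "p1", "p2")


def test_no_call_is_both_germline_and_somatic(reference, small_cohort):
    _, cohort = small_cohort
    from mitovar.pipeline import call_stage

    calls = call_stage(cohort.samples, reference)
    for sample_calls in calls.values():
        for c in sample_calls:
            assert c.origin in ("somatic", "germline", "undetermined")


@pytest.mark.parametrize(
    "variant,expected",
    [
        (Variant(309, 309, "insertion", "", "C"), True),
        (Variant(522, 523, "deletion", "CA", ""), True),
        (Variant(16190, 16190, "insertion", "", "C"), True),
        (Variant(14499, 14502, "deletion", "AAAT", ""), False),
        (Variant(309, 309, "substitution", "C", "T"), False),
    ],
)
def test_flag_mtmsi(variant, expected):
    assert flag_mtMSI(variant) is expected


def test_mtmsi_windows_match_config():
    assert MTMSI_WINDOWS == [(303, 315), (16184, 16193), (514, 523)]


def test_variation_load(reference):
    from mitovar.calling import VariantCall

    nd2 = reference.feature_by_name("ND2")

    def call_at(pos):
        return VariantCall(
            variant=Variant(pos, pos, "substitution", reference.base(pos), "A"
                            if reference.base(pos) != "A" else "G"),
            sample_id="s", zygosity="homoplasmic",
        )

    calls = [call_at(p) for p in (4875, 4969, 4971, 5000, 5001)]
    result = variation_load(calls, reference, "ND2")
    assert result.altered_nucleotides == 5
    assert result.unit_length == len(nd2)
    assert result.load == pytest.approx(5 / len(nd2) * 100)
    # duplicate positions count once; empty calls -> load 0
    assert variation_load(calls + calls, reference, "ND2").altered_nucleotides == 5
    assert variation_load([], reference, "ND2").load == 0
    # complexes aggregate member genes
    complex_result = variation_load(calls, reference, "Complex I")
    assert complex_result.altered_nucleotides == 5
    with pytest.raises(ValueError, match="unknown"):
        variation_load(calls, reference, "Complex IX")


def test_planted_set_round_trip(reference, small_cohort):
    """Synthetic cohort: extract o align recovers every planted variant."""
    _, cohort = small_cohort
    from mitovar.pipeline import call_stage

    calls = call_stage(cohort.samples, reference)
    for sample in cohort.samples:
        expected = {
            (e["label"], e["zygosity"], e["origin"])
            for e in cohort.truth.variants[sample.sample_id]
        }
        got = {
            (c.label, c.zygosity, c.origin) for c in calls[sample.sample_id]
        }
        assert got == expected, sample.sample_id
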