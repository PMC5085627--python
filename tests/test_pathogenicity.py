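"""Novelty, candidate filters, predictor binarization and majority vote."""

import pytest

from mitovar.io import (
    load_catalog,
    novel_variant_table,
    predictor_profile_table,
    truncating_mutation_table,
)
from mitovar.pathogenicity import (
    CandidateContext,
    PredictorProfile,
    binarize_predictor,
    classify_pathogenic,
    context_from_row,
    is_novel,
    majority_vote,
    passes_candidate_filters,
    profile_from_row,
)

MARKED = {
    "G3392A", "T3644C", "T3679C", "G4971A", "T6238C", "T7104C", "G8156A",
    "G8989A", "T9187C", "G10573A", "C14310A", "T15018A", "G15045A",
    "T15090C", "C15483T",
}


def test_is_novel_against_catalog():
    catalog = load_catalog()
    assert is_novel("G4969A", catalog)  # not recorded
    assert not is_novel("10952insC", catalog)  # recorded
    assert is_novel("anything", set())  # empty catalog: everything novel


def test_candidate_filters():
    ok, reasons = passes_candidate_filters(
        CandidateContext("x", control_count=2, control_total=376, ci_percent=97.6)
    )
    assert ok
    rejected, reasons = passes_candidate_filters(
        CandidateContext("x", ci_percent=58.5)
    )
    assert not rejected and any("conservation" in r for r in reasons)
    poly, reasons = passes_candidate_filters(
        CandidateContext("x", control_count=4, control_total=376, ci_percent=100)
    )
    assert not poly and any("polymorphism" in r for r in reasons)
    # exactly 1% resolves to polymorphism (conservative boundary)
    boundary, _ = passes_candidate_filters(
        CandidateContext("x", control_count=4, control_total=400, ci_percent=100)
    )
    assert not boundary
    tissue, reasons = passes_candidate_filters(
        CandidateContext("x", normal_thyroid_count=1, ci_percent=100)
    )
    assert not tissue and any("tissue-specific" in r for r in reasons)
    missing, reasons = passes_candidate_filters(CandidateContext("x", ci_percent=None))
    assert not missing and "CI unavailable" in reasons


@pytest.mark.parametrize(
    "program,value,expected",
    [
        ("align_gvgd", "C55", False),
        ("align_gvgd", "C65", True),
        ("panther", 0.5134, True),
        ("panther", 0.5, False),
        ("panther", "NA", False),
        ("mutation_assessor", "Low", True),
        ("mutation_assessor", "Neutral", False),
        ("polyphen2", "Possibly", True),
        ("polyphen2", "Benign", False),
        ("sift", "Not Tolerated", True),
        ("sift", "NA", False),
        ("snp_and_go", "Disease", True),
        ("provean", "Neutral", False),
    ],
)
def test_binarize_predictor(program, value, expected):
    assert binarize_predictor(program, value) is expected


def test_binarize_rejects_unknown_token():
    with pytest.raises(ValueError, match="wobbly"):
        binarize_predictor("sift", "wobbly")
    with pytest.raises(ValueError, match="program"):
        binarize_predictor("oracle", "Disease")


def test_majority_vote_fixture_rows():
    table = predictor_profile_table()
    row_3644 = table[table["label"] == "T3644C"].iloc[0]
    assert majority_vote(profile_from_row(row_3644)) == (4, True)
    row_13535 = table[table["label"] == "A13535G"].iloc[0]
    assert majority_vote(profile_from_row(row_13535)) == (3, False)
    assert majority_vote(PredictorProfile("allna")) == (0, False)


def test_vote_reproduces_marked_set():
    table = predictor_profile_table()
    selected = {
        row["label"]
        for _, row in table.iterrows()
        if majority_vote(profile_from_row(row))[1]
    }
    assert selected == MARKED


def test_vote_monotone_in_votes():
    """Adding a deleterious call never flips pathogenic -> not."""
    table = predictor_profile_table()
    for _, row in table.iterrows():
        base_votes, base_patho = majority_vote(profile_from_row(row))
        boosted = profile_from_row(row)
        boosted = PredictorProfile(
            variant_label=boosted.variant_label,
            polyphen2="Probably",
            sift=boosted.sift,
            mutation_assessor=boosted.mutation_assessor,
            provean=boosted.provean,
            snp_and_go=boosted.snp_and_go,
            align_gvgd=boosted.align_gvgd,
            panther=boosted.panther,
        )
        new_votes, new_patho = majority_vote(boosted)
        assert new_votes >= base_votes
        assert not (base_patho and not new_patho)


def _fixture_inputs():
    reference_free = {}
    contexts, profiles = {}, {}
    for _, row in predictor_profile_table().iterrows():
        reference_free[row["label"]] = "non-synonymous"
        contexts[row["label"]] = context_from_row(row)
        profiles[row["label"]] = profile_from_row(row)
    return reference_free, contexts, profiles


def test_classify_pathogenic_on_fixtures():
    consequences, contexts, profiles = _fixture_inputs()
    verdicts = classify_pathogenic(consequences, contexts, profiles)
    final = {v.variant_label for v in verdicts if v.final_pathogenic}
    assert final == MARKED


def test_classify_is_order_invariant():
    consequences, contexts, profiles = _fixture_inputs()
    forward = classify_pathogenic(consequences, contexts, profiles)
    reversed_inputs = dict(reversed(list(consequences.items())))
    backward = classify_pathogenic(reversed_inputs, contexts, profiles)
    assert [(v.variant_label, v.final_pathogenic) for v in forward] == [
        (v.variant_label, v.final_pathogenic) for v in backward
    ]


def test_truncating_bypass_and_gates():
    consequences = {
        "nonsense-1": "nonsense",
        "frameshift-1": "frameshift",
        "silent-1": "synonymous",
        "ns-nocontext": "non-synonymous",
        "ns-noprofile": "non-synonymous",
    }
    perfect = PredictorProfile(
        "x", polyphen2="Probably", sift="Not Tolerated",
        mutation_assessor="High", provean="Deleterious",
        snp_and_go="Disease", align_gvgd="C65", panther=0.99,
    )
    contexts = {
        "ns-noprofile": CandidateContext("ns-noprofile", ci_percent=100.0),
        "silent-1": CandidateContext("silent-1", ci_percent=100.0),
    }
    verdicts = {
        v.variant_label: v
        for v in classify_pathogenic(consequences, contexts, {"silent-1": perfect})
    }
    assert verdicts["nonsense-1"].final_pathogenic
    assert verdicts["frameshift-1"].final_pathogenic
    # synonymous never goes through the vote, even with a perfect profile
    assert not verdicts["silent-1"].final_pathogenic
    assert verdicts["ns-nocontext"].undetermined
    assert verdicts["ns-noprofile"].undetermined  # candidate but no profile


def test_lowering_control_frequency_never_unmakes_candidates():
    base = CandidateContext("x", control_count=3, control_total=376, ci_percent=90.0)
    lower = CandidateContext("x", control_count=0, control_total=376, ci_percent=90.0)
    assert passes_candidate_filters(base)[0]
    assert passes_candidate_filters(lower)[0]


def test_novelty_of_all_table1_rows_under_empty_catalog():
    table = novel_variant_table()
    assert len(table) == 33
    assert all(is_novel(label, set()) for label in table["label"])


def test_truncating_fixture_reported_flags():
    table = truncating_mutation_table()
    catalog = load_catalog()
    for _, row in table.iterrows():
        assert is_novel(row["label"], catalog) == (row["reported"] == "N")
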