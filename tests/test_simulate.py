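"""Synthetic-cohort generator: determinism, truth round-trips, knobs."""

import json

import numpy as np
import pytest

from mitovar.consequence import conservation_index
from mitovar.simulate import (
    SimConfig,
    generate_cohort,
    generate_predictor_table,
    generate_primate_alignment,
    parse_substitution_label,
    write_cohort,
)


def test_seed_determinism_byte_identical(tmp_path, reference, tree):
    config = SimConfig(seed=3, n_pairs=3, n_controls=4, n_normal_thyroid=1)
    for d in ("a", "b"):
        write_cohort(tmp_path / d, generate_cohort(config, reference, tree), config)
    for name in ("samples.fasta", "ct.csv", "clinical.tsv", "truth.json"):
        assert (tmp_path / "a" / name).read_bytes() == (
            tmp_path / "b" / name
        ).read_bytes(), name


def test_different_seeds_differ(reference, tree):
    a = generate_cohort(SimConfig(seed=1, n_pairs=2, n_controls=2), reference, tree)
    b = generate_cohort(SimConfig(seed=2, n_pairs=2, n_controls=2), reference, tree)
    assert a.truth.variants != b.truth.variants


def test_zero_somatic_rate_gives_identical_pairs(reference, tree):
    config = SimConfig(
        seed=4, n_pairs=4, n_controls=0, n_normal_thyroid=0,
        somatic_rate=0.0, mtMSI_stutter_prob=0.0,
    )
    cohort = generate_cohort(config, reference, tree)
    by_id = {s.sample_id: s for s in cohort.samples}
    for i in range(4):
        subject = f"S{i + 1:03d}"
        tumor = by_id[f"{subject}|tumor"]
        normal = by_id[f"{subject}|adjacent-normal"]
        assert tumor.alleles == [normal.alleles[0]]


def test_full_heteroplasmy_round_trips_through_calling(reference, tree):
    from mitovar.calling import call_sample

    config = SimConfig(
        seed=6, n_pairs=5, n_controls=0, n_normal_thyroid=0,
        somatic_rate=2.0, heteroplasmy_prob=1.0, mtMSI_stutter_prob=0.0,
    )
    cohort = generate_cohort(config, reference, tree)
    for sample in cohort.samples:
        if sample.tissue != "tumor":
            continue
        somatic_truth = {
            e["label"]
            for e in cohort.truth.variants[sample.sample_id]
            if e["origin"] == "somatic"
        }
        if not somatic_truth:
            continue
        calls = {c.label: c for c in call_sample(sample, reference)}
        for label in somatic_truth:
            assert calls[label].zygosity == "heteroplasmic", label


def test_cohort_counts_and_truth_alignment(small_cohort):
    config, cohort = small_cohort
    tissues = [s.tissue for s in cohort.samples]
    assert tissues.count("tumor") == config.n_pairs
    assert tissues.count("adjacent-normal") == config.n_pairs
    assert tissues.count("blood-control") == config.n_controls
    assert tissues.count("normal-thyroid") == config.n_normal_thyroid
    assert set(cohort.truth.variants) == {s.sample_id for s in cohort.samples}


def test_primate_alignment_fully_conserved(reference):
    rows, ci = generate_primate_alignment(
        reference, conserved_fraction=1.0, seed=1, start=3307, end=3406
    )
    assert len(rows) == 41
    assert all(r == rows[0] for r in rows)
    assert np.allclose(ci, 100.0)


def test_primate_alignment_truth_matches_conservation_index(reference):
    rows, ci = generate_primate_alignment(
        reference, conserved_fraction=0.8, seed=2, start=5904, end=6003
    )
    for site in range(100):
        column = [row[site] for row in rows]
        assert conservation_index(column, rows[0][site]).ci_percent == pytest.approx(
            ci[site]
        )


def test_forced_32_wildtype_column():
    column = ["A"] * 32 + ["C"] * 9
    assert conservation_index(column, "A").ci_percent == pytest.approx(78.05, abs=0.005)


def test_predictor_table_perfect_and_inverted():
    from mitovar.pathogenicity import majority_vote

    truth = [(f"V{i}", i % 2 == 0) for i in range(30)]

    def recovered(miscall):
        table = generate_predictor_table(truth, miscall_rate=miscall, seed=5)
        out = set()
        for _, row in table.iterrows():
            from mitovar.pathogenicity import PredictorProfile

            profile = PredictorProfile(
                row["label"],
                polyphen2=row["polyphen2"], sift=row["sift"],
                mutation_assessor=row["mutation_assessor"], provean=row["provean"],
                snp_and_go=row["snp_go"], align_gvgd=row["align_gvgd"],
                panther=float(row["panther"]),
            )
            if majority_vote(profile)[1]:
                out.add(row["label"])
        return out

    planted = {label for label, flag in truth if flag}
    assert recovered(0.0) == planted
    assert recovered(1.0) == {label for label, flag in truth if not flag}


def test_predictor_table_fixture_flag():
    table = generate_predictor_table([], published_fixture=True)
    assert len(table) == 25
    assert "polyphen2" in table.columns


def test_infeasible_planted_association_rejected(reference, tree):
    config = SimConfig(
        seed=1, n_pairs=2, n_controls=2,
        planted_association={
            "label": "G709A", "odds_ratio": 1e9, "control_carriage": 0.999999,
        },
    )
    with pytest.raises(ValueError, match="infeasible"):
        generate_cohort(config, reference, tree)


def test_planted_mtsnp_enrichment_recovered(reference, tree):
    config = SimConfig(
        seed=8, n_pairs=40, n_controls=80, n_normal_thyroid=0,
        germline_rate=0.5,
        planted_association={"label": "G709A", "odds_ratio": 6.0,
                             "control_carriage": 0.15},
    )
    cohort = generate_cohort(config, reference, tree)
    carriers = cohort.truth.mtsnp_carriers
    case_rate = np.mean([carriers[f"S{i + 1:03d}"] for i in range(40)])
    ctrl_rate = np.mean([carriers[f"C{i + 1:03d}"] for i in range(80)])
    assert case_rate > ctrl_rate
    # carried variants actually sit in the sequences
    planted = parse_substitution_label("G709A", reference)
    by_id = {s.sample_id: s for s in cohort.samples}
    for i in range(40):
        subject = f"S{i + 1:03d}"
        seq = by_id[f"{subject}|tumor"].alleles[-1]
        assert (seq[planted.start - 1] == "A") == carriers[subject]


def test_truth_labels_are_well_formed(small_cohort, reference):
    _, cohort = small_cohort
    from mitovar.calling import Variant, variant_label

    for entries in cohort.truth.variants.values():
        for e in entries:
            v = Variant(e["start"], e["end"], e["kind"], e["ref"], e["alt"])
            assert variant_label(v, reference) == e["label"]


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(heteroplasmy_prob=1.5)
    with pytest.raises(ValueError):
        SimConfig(somatic_rate=-1)


def test_written_cohort_round_trips_through_readers(tmp_path, reference, tree):
    from mitovar.copynumber import read_ct_table
    from mitovar.io import read_samples_fasta

    config = SimConfig(seed=13, n_pairs=2, n_controls=3, n_normal_thyroid=1)
    cohort = generate_cohort(config, reference, tree)
    write_cohort(tmp_path, cohort, config)
    samples = read_samples_fasta(tmp_path / "samples.fasta")
    assert {s.sample_id for s in samples} == {s.sample_id for s in cohort.samples}
    for reread, orig in zip(
        sorted(samples, key=lambda s: s.sample_id),
        sorted(cohort.samples, key=lambda s: s.sample_id),
    ):
        assert reread.alleles == orig.alleles
    records = read_ct_table(tmp_path / "ct.csv")
    assert set(records) == set(cohort.ct_records)
    truth = json.loads((tmp_path / "truth.json").read_text())
    assert truth["haplogroups"] == cohort.truth.haplogroups
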