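"""End-to-end orchestration: cohort in, report tables out.

``run_pipeline`` drives the stages — variant calling, consequence
annotation, novelty lookup, pathogenicity classification, haplogroup
assignment, copy-number quantification, case-control association — over a
run directory (typically produced by the cohort simulator) and emits the
report bundle: a novel-variant table, a truncating-mutation table, a
pathogenicity table with vote counts, haplogroup / copy-number / association
tables, and a JSON summary of headline counts.  Every number in the reports
is produced by a stage; the report layer only collates.

``fixture_report`` runs the classification stages over the packaged tables
transcribed from the study (18 truncating mutations + the predictor
profiles), reproducing its pathogenic-set arithmetic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, consequence, copynumber, haplogroups, io, pathogenicity
from .reference import MitoReference, bundled_reference

logger = logging.getLogger("mitovar")


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run (defaults = study values)."""

    run_dir: str = "."
    out_dir: str = "results"
    reference_fasta: str | None = None  # None -> bundled synthetic fixture
    annotation_tsv: str | None = None
    catalog_tsv: str | None = None
    tree_file: str | None = None
    pairing_maps_tsv: str | None = None
    predictor_tsv: str | None = None
    samples_fasta: str | None = None  # default: <run_dir>/samples.fasta
    ct_csv: str | None = None  # default: <run_dir>/ct.csv
    ci_cutoff: float = 75.0
    polymorphism_cutoff: float = 0.01
    vote_threshold: int = 4
    alpha: float = 0.05
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        defaults = RunConfig.__dataclass_fields__
        for name in ("ci_cutoff", "polymorphism_cutoff", "vote_threshold", "alpha"):
            if getattr(self, name) != defaults[name].default:
                self.overrides[name] = getattr(self, name)
                logger.warning("threshold override: %s = %s", name, getattr(self, name))


def _load_reference(config: RunConfig) -> MitoReference:
    if config.reference_fasta:
        from .reference import load_reference

        return load_reference(
            config.reference_fasta,
            config.annotation_tsv or io.data_path("gene_annotations.tsv"),
        )
    return bundled_reference()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: %.2fs", name, time.time() - t0)
            return result

        return inner

    return wrap


@_stage("call")
def call_stage(samples, reference):
    """Call every sample; classify somatic/germline for tumor/normal pairs."""
    calls_by_sample = {}
    for sample in samples:
        calls_by_sample[sample.sample_id] = calling.call_sample(sample, reference)
    by_subject_tissue = {s.sample_id: s for s in samples}
    for sample in samples:
        if sample.tissue != "tumor":
            continue
        normal_id = f"{sample.subject_id}|adjacent-normal"
        if normal_id in by_subject_tissue:
            calls_by_sample[sample.sample_id] = calling.classify_origin(
                calls_by_sample[sample.sample_id],
                calls_by_sample[normal_id],
                sample.subject_id,
                sample.subject_id,
            )
            # back-label the normal tissue: shared with tumor => germline
            tumor_variants = {c.variant for c in calls_by_sample[sample.sample_id]}
            calls_by_sample[normal_id] = [
                replace(c, origin="germline") if c.variant in tumor_variants else c
                for c in calls_by_sample[normal_id]
            ]
    return calls_by_sample


@_stage("annotate")
def annotate_stage(calls_by_sample, reference, pairing_maps=None):
    """Consequence per unique variant (+ RNA pairing disruption)."""
    unique = {}
    for calls in calls_by_sample.values():
        for c in calls:
            unique[c.label] = c.variant
    rows = {}
    for label, variant in sorted(unique.items(), key=lambda kv: kv[1].start):
        if variant.kind == "substitution":
            cons = consequence.annotate_substitution(variant, reference)
            disruption = ""
            if cons.category == "rna" and pairing_maps is not None:
                pm = pairing_maps.get(cons.gene)
                disrupted, desc = consequence.annotate_rna(
                    variant, pm, reference
                )
                disruption = desc if disrupted else ""
        else:
            cons = consequence.annotate_indel(variant, reference)
            disruption = ""
        rows[label] = {
            "label": label,
            "gene": cons.gene,
            "category": cons.category,
            "aa_change": cons.aa_change,
            "product_length_ref": cons.product_length_ref,
            "product_length_alt": cons.product_length_alt,
            "titv": cons.transition_or_transversion,
            "pairing_disruption": disruption,
        }
    return rows


@_stage("classify")
def classify_stage(annotations, contexts, profiles):
    consequences = {label: row["category"] for label, row in annotations.items()}
    return pathogenicity.classify_pathogenic(consequences, contexts, profiles)


@_stage("haplogroup")
def haplogroup_stage(calls_by_sample, tree):
    rows = []
    for sample_id, calls in sorted(calls_by_sample.items()):
        labels = {c.label for c in calls}
        a = haplogroups.assign_haplogroup(labels, tree, sample_id)
        rows.append(
            {
                "sample_id": sample_id,
                "haplogroup": a.haplogroup,
                "macro": haplogroups.macro_haplogroup(tree, a.haplogroup) or "",
                "matched": a.matched,
                "expected": a.expected,
                "score": a.score,
                "runner_up": a.runner_up or "",
            }
        )
    return pd.DataFrame(rows)


@_stage("copynumber")
def copynumber_stage(ct_records):
    results = copynumber.subject_results(ct_records)
    by_id = {r.sample_id: r for r in results}
    rows = []
    tumor_contents, normal_contents = [], []
    for r in results:
        rows.append(
            {
                "sample_id": r.sample_id,
                "tissue": r.tissue,
                "relative_content": r.relative_content,
                "delta_ct": r.delta_ct,
            }
        )
    frame = pd.DataFrame(rows)
    folds = []
    for sample_id, r in sorted(by_id.items()):
        if r.tissue != "tumor":
            continue
        subject = sample_id.split("|")[0]
        normal = by_id.get(f"{subject}|adjacent-normal")
        if normal is None:
            continue
        folds.append(
            {
                "subject": subject,
                "fold_change": copynumber.fold_change(r, normal),
                "tumor_content": r.relative_content,
                "normal_content": normal.relative_content,
            }
        )
        tumor_contents.append(r.relative_content)
        normal_contents.append(normal.relative_content)
    fold_frame = pd.DataFrame(folds)
    stats = {}
    if len(tumor_contents) >= 2:
        u, p = copynumber.cohort_compare(tumor_contents, normal_contents)
        increased = int((fold_frame["fold_change"] > 1).sum())
        stats = {
            "mannwhitney_u": u,
            "p_value": p,
            "n_pairs": len(fold_frame),
            "n_increased": increased,
            "mean_of_ratios": float(fold_frame["fold_change"].mean()),
            "ratio_of_means": float(np.mean(tumor_contents) / np.mean(normal_contents)),
        }
    return frame, fold_frame, stats


@_stage("associate")
def associate_stage(calls_by_sample, haplo_frame, mtsnp_labels=None):
    from .association import screen_factors
    from .simulate import MTSNP_LABELS

    mtsnp_labels = mtsnp_labels or MTSNP_LABELS
    case_sets, control_sets = [], []
    haplo_by_sample = dict(
        zip(haplo_frame["sample_id"], haplo_frame["haplogroup"])
    )
    for sample_id, calls in sorted(calls_by_sample.items()):
        tissue = sample_id.split("|")[1]
        labels = {c.label for c in calls}
        factors = {l for l in labels if l in mtsnp_labels}
        if sample_id in haplo_by_sample:
            factors.add(f"hg:{haplo_by_sample[sample_id]}")
        if tissue == "tumor":
            case_sets.append(factors)
        elif tissue == "blood-control":
            control_sets.append(factors)
    if not case_sets or not control_sets:
        return pd.DataFrame()
    results = screen_factors(case_sets, control_sets)
    return pd.DataFrame(
        [
            {
                "factor": r.factor,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "method": r.method,
                "haldane_corrected": r.corrected,
            }
            for r in results
        ]
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage over a simulated (or user-supplied) run directory."""
    run_dir = Path(config.run_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        reference = _load_reference(config)
        tree = (
            haplogroups.load_tree(config.tree_file)
            if config.tree_file
            else haplogroups.bundled_tree()
        )
        catalog = io.load_catalog(config.catalog_tsv)
        pairing = io.load_pairing_maps(config.pairing_maps_tsv)
        samples = io.read_samples_fasta(
            config.samples_fasta or run_dir / "samples.fasta"
        )
        calls_by_sample = call_stage(samples, reference)
        annotations = annotate_stage(calls_by_sample, reference, pairing)

        # variant-level collation
        all_calls = [c for calls in calls_by_sample.values() for c in calls]
        variant_frame = io.calls_to_frame(all_calls)
        variant_frame["gene"] = variant_frame["label"].map(
            lambda l: annotations[l]["gene"]
        )
        variant_frame["category"] = variant_frame["label"].map(
            lambda l: annotations[l]["category"]
        )
        variant_frame["novel"] = variant_frame["label"].map(
            lambda l: pathogenicity.is_novel(l, catalog)
        )

        # cohort counts per variant for the candidate filters
        n_controls = sum(1 for s in samples if s.tissue == "blood-control")
        n_thyroid = sum(1 for s in samples if s.tissue == "normal-thyroid")
        contexts = {}
        for label, ann in annotations.items():
            sub = variant_frame[variant_frame["label"] == label]
            tissues = sub["sample_id"].str.split("|").str[1]
            contexts[label] = pathogenicity.CandidateContext(
                variant_label=label,
                control_count=int((tissues == "blood-control").sum()),
                control_total=max(n_controls, 1),
                normal_thyroid_count=int((tissues == "normal-thyroid").sum()),
                normal_thyroid_total=max(n_thyroid, 1),
                ci_percent=None,  # conservation requires a primate alignment
                known_in_catalog=not pathogenicity.is_novel(label, catalog),
                category=ann["category"],
            )
        profiles = {}
        if config.predictor_tsv:
            table = pd.read_csv(
                config.predictor_tsv, sep="\t", keep_default_na=False, na_values=[]
            )
            for _, row in table.iterrows():
                profiles[row["label"]] = pathogenicity.profile_from_row(row)
        verdicts = classify_stage(annotations, contexts, profiles)
        verdict_frame = pd.DataFrame(
            [
                {
                    "label": v.variant_label,
                    "candidate": v.candidate,
                    "votes_deleterious": v.votes_deleterious,
                    "vote_pathogenic": v.vote_pathogenic,
                    "final_pathogenic": v.final_pathogenic,
                    "undetermined": v.undetermined,
                    "reasons": "; ".join(v.reasons),
                }
                for v in verdicts
            ]
        )

        haplo_frame = haplogroup_stage(calls_by_sample, tree)
        ct_path = config.ct_csv or run_dir / "ct.csv"
        if Path(ct_path).exists():
            content_frame, fold_frame, cn_stats = copynumber_stage(
                copynumber.read_ct_table(ct_path)
            )
        else:
            content_frame, fold_frame, cn_stats = pd.DataFrame(), pd.DataFrame(), {}
        assoc_frame = associate_stage(calls_by_sample, haplo_frame)

        truncating = variant_frame[
            variant_frame["category"].isin(["nonsense", "frameshift"])
        ].drop_duplicates("label")
        n_het_samples = variant_frame[
            variant_frame["zygosity"] == "heteroplasmic"
        ]["sample_id"].nunique()
        summary = {
            "n_samples": len(samples),
            "n_variant_calls": len(variant_frame),
            "n_distinct_sites": int(variant_frame["position"].nunique()),
            "n_novel": int(
                variant_frame.drop_duplicates("label")["novel"].sum()
            ),
            "n_heteroplasmic_samples": int(n_het_samples),
            "n_somatic_calls": int((variant_frame["origin"] == "somatic").sum()),
            "n_truncating": int(len(truncating)),
            "n_pathogenic": int(verdict_frame["final_pathogenic"].sum()),
            "copy_number": cn_stats,
        }
        outputs = {
            "variants.tsv": variant_frame.drop(columns=["end"]),
            "truncating.tsv": truncating,
            "pathogenicity.tsv": verdict_frame,
            "haplogroups.tsv": haplo_frame,
            "copynumber_content.tsv": content_frame,
            "copynumber_folds.tsv": fold_frame,
            "association.tsv": assoc_frame,
        }
        for name, frame in outputs.items():
            path = out_dir / name
            frame.to_csv(path, sep="\t", index=False)
            written.append(path)
        vcf_path = out_dir / "variants.vcf"
        io.write_vcf(vcf_path, all_calls, reference)
        written.append(vcf_path)
        summary_path = out_dir / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=1)
        written.append(summary_path)
        return {"summary": summary, "frames": outputs, "out_dir": str(out_dir)}
    except Exception:
        for path in written:  # remove partial outputs
            Path(path).unlink(missing_ok=True)
        raise


def fixture_report() -> dict:
    """Pathogenic-set arithmetic over the packaged study tables.

    The predictor profiles go through the candidate filters + majority vote;
    the truncating mutations are pathogenic unconditionally; the result is
    the study's 15 + 7 + 11 = 33 arithmetic, with the nonsense/frameshift
    split recomputed on the bundled reference.
    """
    reference = bundled_reference()
    trunc = io.truncating_mutation_table()
    profiles_table = io.predictor_profile_table()
    consequences, contexts, profiles = {}, {}, {}
    for _, row in trunc.iterrows():
        v = row["variant"]
        if v.kind == "substitution":
            cons = consequence.annotate_substitution(v, reference)
        else:
            cons = consequence.annotate_indel(v, reference)
        consequences[row["label"]] = cons.category
    for _, row in profiles_table.iterrows():
        consequences[row["label"]] = "non-synonymous"
        contexts[row["label"]] = pathogenicity.context_from_row(row)
        profiles[row["label"]] = pathogenicity.profile_from_row(row)
    verdicts = pathogenicity.classify_pathogenic(consequences, contexts, profiles)
    by_category: dict = {}
    for v in verdicts:
        if v.final_pathogenic:
            by_category.setdefault(consequences[v.variant_label], []).append(
                v.variant_label
            )
    return {
        "verdicts": verdicts,
        "n_nonsense": len(by_category.get("nonsense", [])),
        "n_frameshift": len(by_category.get("frameshift", [])),
        "n_nonsynonymous": len(by_category.get("non-synonymous", [])),
        "n_pathogenic_total": sum(len(v) for v in by_category.values()),
        "pathogenic_labels": sorted(
            label for labels in by_category.values() for label in labels
        ),
    }
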