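"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the study design this package reimplements: 66
tumor/adjacent-normal pairs, 16 normal thyroid tissues and 376 healthy blood
controls, each subject drawn on a haplogroup backbone (the defining variants
of a tree node applied to the reference), tumors carrying Poisson-distributed
somatic substitutions (heteroplasmic with a configurable probability,
realized as a second allele sequence), optional mtMSI stutter indels in the
three microsatellite windows, qPCR Ct tables with replicate noise around
per-subject true copy-number fold changes, and an optionally planted
case-control mtSNP enrichment at a requested odds ratio.

Every draw comes from ``numpy`` generators seeded from ``(seed, stream)``
pairs, so outputs are bit-reproducible and adding a new output stream never
perturbs existing ones.  The ground truth written alongside the cohort
records exactly what was planted.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import (
    MTMSI_WINDOWS,
    SampleSequence,
    Variant,
    apply_variants,
    normalize_indel,
    variant_label,
)
from .copynumber import CtRecord
from .haplogroups import HaploTree
from .reference import MT_LENGTH, MitoReference

MTSNP_LABELS = [
    "A16164G", "C16266T", "G5460A", "T6680C",
    "G9123A", "A14587G", "T16362C", "G709A",
]

_SUB_LABEL = re.compile(r"^([ACGT])(\d+)([ACGT])$")


def parse_substitution_label(label: str, reference: MitoReference) -> Variant:
    m = _SUB_LABEL.match(label)
    if not m:
        raise ValueError(f"cannot parse substitution label {label!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if reference.base(pos) != ref:
        raise ValueError(
            f"label {label!r}: reference has {reference.base(pos)} at {pos}"
        )
    return Variant(pos, pos, "substitution", ref, alt)


@dataclass
class SimConfig:
    """Study-condition knobs; defaults mirror the emulated cohort."""

    seed: int = 0
    n_pairs: int = 66
    n_controls: int = 376
    n_normal_thyroid: int = 16
    haplogroup_frequencies: dict | None = None  # node -> probability
    somatic_rate: float = 0.8       # mean somatic substitutions per tumor
    germline_rate: float = 3.0      # mean private germline substitutions
    heteroplasmy_prob: float = 0.8  # P(somatic variant is heteroplasmic)
    mtMSI_stutter_prob: float = 0.15
    pathogenic_fraction: float = 0.2  # P(somatic variant marked truly pathogenic)
    log2_fold_mean: float = 0.93    # tumor/normal copy-number fold (log2)
    log2_fold_sd: float = 1.76
    ct_noise_sd: float = 0.15       # cycles, per replicate
    ct_replicates: int = 3
    planted_association: dict | None = None  # {"label": ..., "odds_ratio": ...,
    #                                           "control_carriage": ...}
    min_variant_spacing: int = 10

    def __post_init__(self):
        for name in ("heteroplasmy_prob", "mtMSI_stutter_prob", "pathogenic_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("somatic_rate", "germline_rate", "ct_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticTruth:
    """Exactly what was planted, keyed the way the pipeline reports."""

    variants: dict = field(default_factory=dict)  # sample_id -> list of dicts
    haplogroups: dict = field(default_factory=dict)  # subject -> node
    fold_changes: dict = field(default_factory=dict)  # subject -> fold
    mtsnp_carriers: dict = field(default_factory=dict)  # subject -> bool
    planted_label: str | None = None


@dataclass
class Cohort:
    samples: list  # SampleSequence (tumor + adjacent-normal + controls + thyroid)
    ct_records: dict  # (sample_id, target) -> CtRecord
    clinical: pd.DataFrame
    truth: SyntheticTruth


def _default_frequencies(tree: HaploTree) -> dict:
    """30/66 of subjects on M sublineages, 36/66 on N, as in the cohort."""
    m_nodes = [n for n in ("C", "D", "G", "Z") if n in tree.nodes]
    n_nodes = [n for n in ("A", "A4", "B4a", "B4g", "F", "R", "Y") if n in tree.nodes]
    freqs = {}
    for n in m_nodes:
        freqs[n] = (30 / 66) / len(m_nodes)
    for n in n_nodes:
        freqs[n] = (36 / 66) / len(n_nodes)
    return freqs


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, stream])


def _safe_positions(reference: MitoReference, tree: HaploTree) -> np.ndarray:
    """Positions where a planted substitution round-trips unambiguously."""
    excluded = {3107}
    pad = 6
    for ws, we in MTMSI_WINDOWS:
        excluded.update(range(ws - pad, we + pad + 1))
    # engineered homopolymer/repeat tracts
    for ts, te in [(11032, 11038), (11673, 11677), (12418, 12425),
                   (13128, 13132), (14495, 14502)]:
        excluded.update(range(ts - pad, te + pad + 1))
    for node in tree.nodes.values():
        for label in node.defining_variants:
            m = _SUB_LABEL.match(label)
            if m:
                excluded.add(int(m.group(2)))
    for label in MTSNP_LABELS:
        excluded.add(int(_SUB_LABEL.match(label).group(2)))
    return np.array(
        [p for p in range(1, MT_LENGTH + 1) if p not in excluded], dtype=int
    )


def _draw_substitutions(rng, reference, pool, taken, count, spacing) -> list:
    """`count` substitutions at positions >= `spacing` apart from `taken`."""
    out = []
    attempts = 0
    while len(out) < count and attempts < 100 * (count + 1):
        attempts += 1
        pos = int(rng.choice(pool))
        if any(abs(pos - t) < spacing for t in taken):
            continue
        ref = reference.base(pos)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        out.append(Variant(pos, pos, "substitution", ref, alt))
        taken.add(pos)
    return out


def _stutter_variant(rng, reference) -> Variant:
    """One-unit ins/del in a random mtMSI window, 3'-normalized."""
    ws, we = MTMSI_WINDOWS[int(rng.integers(len(MTMSI_WINDOWS)))]
    if (ws, we) == (514, 523):
        unit = reference.slice(514, 515)  # CA
        if rng.random() < 0.5:
            v = Variant(514, 515, "deletion", unit, "")
        else:
            v = Variant(523, 523, "insertion", "", unit)
    else:
        # first C of the leading poly-C tract
        pos = ws
        base = reference.base(pos)
        if rng.random() < 0.5:
            v = Variant(pos, pos, "deletion", base, "")
        else:
            v = Variant(pos, pos, "insertion", "", base)
    return normalize_indel(v, reference)


def _carriage_probs(odds_ratio: float, control_carriage: float) -> tuple[float, float]:
    if not 0 < control_carriage < 1 or odds_ratio <= 0:
        raise ValueError("infeasible planted association: bad inputs")
    odds0 = control_carriage / (1 - control_carriage)
    odds1 = odds_ratio * odds0
    p1 = odds1 / (1 + odds1)
    # near-saturated carriage makes the requested OR unidentifiable in a cohort
    if not 0.001 < p1 < 0.995:
        raise ValueError(
            f"infeasible planted association: OR {odds_ratio} at control "
            f"carriage {control_carriage} implies case carriage {p1:.4f}"
        )
    return p1, control_carriage


def generate_cohort(config: SimConfig, reference: MitoReference, tree: HaploTree) -> Cohort:
    freqs = config.haplogroup_frequencies or _default_frequencies(tree)
    nodes = sorted(freqs)
    probs = np.array([freqs[n] for n in nodes], dtype=float)
    if not np.isclose(probs.sum(), 1.0, atol=1e-6):
        probs = probs / probs.sum()
    pool = _safe_positions(reference, tree)
    truth = SyntheticTruth()
    samples: list = []
    ct_records: dict = {}
    clinical_rows = []

    planted = config.planted_association
    if planted:
        p_case, p_control = _carriage_probs(
            planted["odds_ratio"], planted.get("control_carriage", 0.15)
        )
        planted_variant = parse_substitution_label(planted["label"], reference)
        truth.planted_label = planted["label"]

    def backbone_variants(rng) -> tuple[str, list]:
        node = str(rng.choice(nodes, p=probs))
        variants = [
            parse_substitution_label(lbl, reference)
            for lbl in tree.path_variants(node)
        ]
        return node, variants

    # --- tumor / adjacent-normal pairs -----------------------------------
    for i in range(config.n_pairs):
        rng = _rng(config.seed, 1000 + i)
        subject = f"S{i + 1:03d}"
        node, backbone = backbone_variants(rng)
        truth.haplogroups[subject] = node
        taken = {v.start for v in backbone}
        n_germ = int(rng.poisson(config.germline_rate))
        germline = _draw_substitutions(
            rng, reference, pool, taken, n_germ, config.min_variant_spacing
        )
        carrier = False
        if planted:
            carrier = bool(rng.random() < p_case)
            if carrier and planted_variant.start not in taken:
                germline.append(planted_variant)
                taken.add(planted_variant.start)
        truth.mtsnp_carriers[subject] = carrier
        n_som = int(rng.poisson(config.somatic_rate))
        somatic = _draw_substitutions(
            rng, reference, pool, taken, n_som, config.min_variant_spacing
        )
        stutter = []
        if rng.random() < config.mtMSI_stutter_prob:
            stutter = [_stutter_variant(rng, reference)]
        shared = backbone + germline
        het_flags = [bool(rng.random() < config.heteroplasmy_prob) for _ in somatic]
        tumor_all = shared + somatic + stutter
        tumor_shared_only = shared + [
            v for v, h in zip(somatic, het_flags) if not h
        ] + stutter
        if any(het_flags):
            tumor_alleles = [
                apply_variants(reference.sequence, tumor_all),
                apply_variants(reference.sequence, tumor_shared_only),
            ]
        else:
            tumor_alleles = [apply_variants(reference.sequence, tumor_all)]
        normal_seq = apply_variants(reference.sequence, shared)
        samples.append(
            SampleSequence(f"{subject}|tumor", "tumor", tumor_alleles, subject)
        )
        samples.append(
            SampleSequence(
                f"{subject}|adjacent-normal", "adjacent-normal", [normal_seq], subject
            )
        )
        entries = []
        for v in shared:
            entries.append(
                _truth_entry(v, reference, "germline", "homoplasmic")
            )
        for v, h in zip(somatic, het_flags):
            entries.append(
                _truth_entry(
                    v, reference, "somatic",
                    "heteroplasmic" if h else "homoplasmic",
                )
            )
        for v in stutter:
            entries.append(_truth_entry(v, reference, "somatic", "homoplasmic"))
        truth.variants[f"{subject}|tumor"] = entries
        truth.variants[f"{subject}|adjacent-normal"] = [
            _truth_entry(v, reference, "germline", "homoplasmic") for v in shared
        ]

        # qPCR records
        rng_ct = _rng(config.seed, 5000 + i)
        fold = float(2.0 ** rng_ct.normal(config.log2_fold_mean, config.log2_fold_sd))
        truth.fold_changes[subject] = fold
        normal_content = float(2.0 ** rng_ct.normal(4.0, 0.5))
        ct_nuc = float(rng_ct.normal(25.0, 0.3))
        for tissue, content in (
            ("tumor", normal_content * fold),
            ("adjacent-normal", normal_content),
        ):
            sid = f"{subject}|{tissue}"
            noise = rng_ct.normal(0.0, config.ct_noise_sd, size=2 * config.ct_replicates)
            ct_mt = ct_nuc - float(np.log2(content))
            ct_records[(sid, "mt")] = CtRecord(
                sid, tissue, "mt",
                [ct_mt + float(n) for n in noise[: config.ct_replicates]],
            )
            ct_records[(sid, "nuclear")] = CtRecord(
                sid, tissue, "nuclear",
                [ct_nuc + float(n) for n in noise[config.ct_replicates :]],
            )
        rng_cl = _rng(config.seed, 7000 + i)
        clinical_rows.append(
            {
                "id": subject,
                "group": "case",
                "age_group": "older" if rng_cl.random() < 0.5 else "younger",
                "stage": "advanced" if rng_cl.random() < 0.4 else "early",
            }
        )

    # --- population controls and normal thyroid --------------------------
    for j, (prefix, tissue, total) in enumerate(
        [("C", "blood-control", config.n_controls),
         ("NT", "normal-thyroid", config.n_normal_thyroid)]
    ):
        for k in range(total):
            rng = _rng(config.seed, 20000 + 10000 * j + k)
            subject = f"{prefix}{k + 1:03d}"
            node, backbone = backbone_variants(rng)
            truth.haplogroups[subject] = node
            taken = {v.start for v in backbone}
            germline = _draw_substitutions(
                rng, reference, pool, taken,
                int(rng.poisson(config.germline_rate)),
                config.min_variant_spacing,
            )
            carrier = False
            if planted and tissue == "blood-control":
                carrier = bool(rng.random() < p_control)
                if carrier and planted_variant.start not in taken:
                    germline.append(planted_variant)
                    taken.add(planted_variant.start)
            truth.mtsnp_carriers[subject] = carrier
            shared = backbone + germline
            seq = apply_variants(reference.sequence, shared)
            sid = f"{subject}|{tissue}"
            samples.append(SampleSequence(sid, tissue, [seq], subject))
            truth.variants[sid] = [
                _truth_entry(v, reference, "undetermined", "homoplasmic")
                for v in shared
            ]

    clinical = pd.DataFrame(clinical_rows)
    return Cohort(samples=samples, ct_records=ct_records, clinical=clinical, truth=truth)


def _truth_entry(variant, reference, origin, zygosity) -> dict:
    return {
        "label": variant_label(variant, reference),
        "start": variant.start,
        "end": variant.end,
        "kind": variant.kind,
        "ref": variant.ref,
        "alt": variant.alt,
        "origin": origin,
        "zygosity": zygosity,
    }


# ---------------------------------------------------------------------------
# primate alignment


def generate_primate_alignment(
    reference: MitoReference,
    conserved_fraction: float,
    seed: int = 0,
    start: int = 1,
    end: int | None = None,
) -> tuple[list, np.ndarray]:
    """41-row primate-style alignment + per-site true CI (percent).

    The human row equals the reference slice; each of the 40 non-human rows
    carries the wild-type base independently with probability
    ``conserved_fraction``, otherwise a random different base.  Returns
    (rows, ci_percent array); rows[0] is human.
    """
    if not 0 <= conserved_fraction <= 1:
        raise ValueError("conserved_fraction must be in [0, 1]")
    end = end or MT_LENGTH
    human = reference.slice(start, end)
    rng = _rng(seed, 31)
    n_sites = len(human)
    others = np.empty((40, n_sites), dtype="<U1")
    bases = np.array(list("ACGT"))
    wt_counts = np.ones(n_sites, dtype=int)  # human always matches
    for r in range(40):
        keep = rng.random(n_sites) < conserved_fraction
        row = np.array(list(human))
        subs = ~keep
        if subs.any():
            for idx in np.flatnonzero(subs):
                choices = bases[bases != human[idx]]
                row[idx] = rng.choice(choices)
        others[r] = row
        wt_counts += (row == np.array(list(human))).astype(int)
    rows = [human] + ["".join(r) for r in others]
    return rows, wt_counts / 41.0 * 100.0


def write_primate_fasta(path, rows: list):
    names = ["Homo_sapiens"] + [f"Primate_{i:02d}" for i in range(1, 41)]
    with open(path, "w") as fh:
        for name, seq in zip(names, rows):
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 70):
                fh.write(seq[k : k + 70] + "\n")


# ---------------------------------------------------------------------------
# predictor tables


_PROGRAMS = [
    "polyphen2", "sift", "mutation_assessor", "provean", "snp_go",
    "align_gvgd", "panther",
]
_DELETERIOUS_VALUES = {
    "polyphen2": ["Probably", "Possibly"],
    "sift": ["Not Tolerated"],
    "mutation_assessor": ["High", "Medium", "Low"],
    "provean": ["Deleterious"],
    "snp_go": ["Disease"],
    "align_gvgd": ["C65"],
}
_BENIGN_VALUES = {
    "polyphen2": ["Benign"],
    "sift": ["Tolerated"],
    "mutation_assessor": ["Neutral"],
    "provean": ["Neutral"],
    "snp_go": ["Neutral"],
    "align_gvgd": ["C55", "C45", "C35", "C25", "C15", "C0"],
}


def generate_predictor_table(
    truth_labels: list,
    miscall_rate: float = 0.0,
    seed: int = 0,
    published_fixture: bool = False,
) -> pd.DataFrame:
    """Predictor-output table for (label, is_pathogenic) pairs.

    A truly pathogenic variant receives >= 4 deleterious program calls with
    probability ``1 - miscall_rate`` (and <= 3 otherwise); benign variants
    the reverse.  ``published_fixture=True`` ignores the inputs and returns the
    packaged table transcribed from the study verbatim.
    """
    if published_fixture:
        from .io import predictor_profile_table

        return predictor_profile_table()
    if not 0 <= miscall_rate <= 1:
        raise ValueError("miscall_rate must be in [0, 1]")
    rng = _rng(seed, 47)
    rows = []
    for label, is_pathogenic in truth_labels:
        correct = rng.random() >= miscall_rate
        deleterious_target = is_pathogenic == correct
        n_del = int(rng.integers(4, 8)) if deleterious_target else int(rng.integers(0, 4))
        del_programs = set(
            rng.choice(_PROGRAMS, size=n_del, replace=False)
        ) if n_del else set()
        row = {"label": label}
        for prog in _PROGRAMS:
            if prog == "panther":
                row[prog] = (
                    round(float(rng.uniform(0.51, 0.99)), 5)
                    if prog in del_programs
                    else round(float(rng.uniform(0.01, 0.49)), 5)
                )
            elif prog in del_programs:
                row[prog] = str(rng.choice(_DELETERIOUS_VALUES[prog]))
            else:
                row[prog] = str(rng.choice(_BENIGN_VALUES[prog]))
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_ct_cohort(
    seed: int,
    n_pairs: int = 66,
    log2_fold_mean: float = 0.93,
    log2_fold_sd: float = 1.76,
    ct_noise_sd: float = 0.15,
    ct_replicates: int = 3,
) -> tuple[dict, dict]:
    """Ct records only (no sequences) for copy-number studies.

    Returns ``(ct_records, true_folds)`` with the same qPCR model as
    :func:`generate_cohort`: per-subject baseline content ``2^N(4, 0.5)``,
    tumor content scaled by ``2^N(log2_fold_mean, log2_fold_sd)``, nuclear Ct
    around 25 cycles, Gaussian replicate noise.
    """
    ct_records: dict = {}
    true_folds: dict = {}
    for i in range(n_pairs):
        rng_ct = _rng(seed, 5000 + i)
        subject = f"S{i + 1:03d}"
        fold = float(2.0 ** rng_ct.normal(log2_fold_mean, log2_fold_sd))
        true_folds[subject] = fold
        normal_content = float(2.0 ** rng_ct.normal(4.0, 0.5))
        ct_nuc = float(rng_ct.normal(25.0, 0.3))
        for tissue, content in (
            ("tumor", normal_content * fold),
            ("adjacent-normal", normal_content),
        ):
            sid = f"{subject}|{tissue}"
            noise = rng_ct.normal(0.0, ct_noise_sd, size=2 * ct_replicates)
            ct_mt = ct_nuc - float(np.log2(content))
            ct_records[(sid, "mt")] = CtRecord(
                sid, tissue, "mt", [ct_mt + float(n) for n in noise[:ct_replicates]]
            )
            ct_records[(sid, "nuclear")] = CtRecord(
                sid, tissue, "nuclear",
                [ct_nuc + float(n) for n in noise[ct_replicates:]],
            )
    return ct_records, true_folds


# ---------------------------------------------------------------------------
# null association screens (type-I error studies)


def null_screen_cohort(
    seed: int, n_cases: int, n_controls: int, n_factors: int = 20,
    carriage: float = 0.2,
) -> tuple[list, list]:
    """Case/control factor sets with no true enrichment."""
    rng = _rng(seed, 63)
    factors = [f"F{i:02d}" for i in range(n_factors)]
    cases = [
        {f for f in factors if rng.random() < carriage} for _ in range(n_cases)
    ]
    controls = [
        {f for f in factors if rng.random() < carriage} for _ in range(n_controls)
    ]
    return cases, controls


# ---------------------------------------------------------------------------
# run-directory output


def write_cohort(outdir, cohort: Cohort, config: SimConfig):
    """Write FASTA / Ct CSV / clinical TSV / truth + manifest JSON."""
    from dataclasses import asdict

    from .io import write_samples_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_samples_fasta(outdir / "samples.fasta", cohort.samples)
    rows = []
    for (sid, target), rec in sorted(cohort.ct_records.items()):
        row = {"sample_id": sid, "tissue": rec.tissue, "target": target}
        for i, ct in enumerate(rec.replicates, start=1):
            row[f"ct{i}"] = round(ct, 4)
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "ct.csv", index=False)
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "variants": cohort.truth.variants,
                "haplogroups": cohort.truth.haplogroups,
                "fold_changes": cohort.truth.fold_changes,
                "mtsnp_carriers": cohort.truth.mtsnp_carriers,
                "planted_label": cohort.truth.planted_label,
            },
            fh,
            indent=1,
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(
            {
                "config": asdict(config),
                "files": ["samples.fasta", "ct.csv", "clinical.tsv", "truth.json"],
            },
            fh,
            indent=1,
        )
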