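"""Rule-based pathogenicity classification of mtDNA variants.

The decision procedure mirrors the study design it reimplements:

1. *Novelty*: a variant label absent from a local known-variant catalog
   (Mitomap-style snapshot) is novel.
2. *Candidate filters* for non-synonymous substitutions:
   (1) carried by fewer than 1% of the healthy blood controls (frequency
   >= 1% marks a population polymorphism), (2) absent from normal thyroid
   tissue (otherwise tissue-specific), and (3) high cross-species
   conservation, CI > 75%.
3. *Predictor majority vote*: seven program outputs are binarized
   (PolyPhen-2 Probably/Possibly damaging; SIFT Not Tolerated;
   MutationAssessor High/Medium/Low; PROVEAN Deleterious; SNP&GO Disease;
   Align-GVGD C65 only; PANTHER Pdeleterious > 0.5) and a variant is voted
   pathogenic when more than half of the seven programs — i.e. at least
   four — call it deleterious.  Missing outputs (NA) never vote and the
   threshold stays at 4 of 7.
4. *Final set*: every nonsense or frameshift coding mutation is pathogenic
   outright; a non-synonymous substitution is pathogenic iff it passed the
   candidate filters and won the vote.

The MutationAssessor "Low" and PolyPhen-2 "Possibly" rules are
reverse-engineered from the study's printed outcomes (they are the unique
binarization reproducing its 15 marked variants); ``scripts/
validate_binarization.py`` re-derives this by brute force over all
candidate binarizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

POLYMORPHISM_FREQ = 0.01  # criterion 1 threshold (>= 1% fails)
CI_CUTOFF = 75.0  # criterion 3: CI must exceed this (strict)
VOTE_THRESHOLD = 4  # strict majority of the 7 programs
N_PROGRAMS = 7

PREDICTOR_VOCABULARY = {
    "polyphen2": {"probably", "possibly", "benign", "na"},
    "sift": {"nottolerated", "tolerated", "na"},
    "mutation_assessor": {"high", "medium", "low", "neutral", "na"},
    "provean": {"deleterious", "neutral", "na"},
    "snp_and_go": {"disease", "neutral", "na"},
    "align_gvgd": {"c65", "c55", "c45", "c35", "c25", "c15", "c0", "na"},
}

_DELETERIOUS = {
    "polyphen2": {"probably", "possibly"},
    "sift": {"nottolerated"},
    "mutation_assessor": {"high", "medium", "low"},
    "provean": {"deleterious"},
    "snp_and_go": {"disease"},
    "align_gvgd": {"c65"},
}

PANTHER_CUTOFF = 0.5  # Pdeleterious > 0.5 is deleterious


def _norm(value) -> str:
    return str(value).strip().replace(" ", "").replace("-", "").replace("_", "").lower()


@dataclass(frozen=True)
class PredictorProfile:
    """Outputs of the seven programs for one candidate variant.

    Categorical values are case-normalized on construction; ``panther`` is
    the Pdeleterious probability or None (NA).
    """

    variant_label: str
    polyphen2: str = "NA"
    sift: str = "NA"
    mutation_assessor: str = "NA"
    provean: str = "NA"
    snp_and_go: str = "NA"
    align_gvgd: str = "NA"
    panther: float | None = None

    def values(self) -> dict:
        return {
            "polyphen2": self.polyphen2,
            "sift": self.sift,
            "mutation_assessor": self.mutation_assessor,
            "provean": self.provean,
            "snp_and_go": self.snp_and_go,
            "align_gvgd": self.align_gvgd,
        }


@dataclass
class CandidateContext:
    """Cohort counts + conservation for the candidate filters."""

    variant_label: str
    control_count: int = 0
    control_total: int = 376
    normal_thyroid_count: int = 0
    normal_thyroid_total: int = 16
    ci_percent: float | None = None
    known_in_catalog: bool = False
    category: str = ""  # consequence category

    def __post_init__(self):
        if self.control_count > self.control_total:
            raise ValueError("control_count exceeds control_total")
        if self.normal_thyroid_count > self.normal_thyroid_total:
            raise ValueError("normal_thyroid_count exceeds total")
        if self.ci_percent is not None and not 0 <= self.ci_percent <= 100:
            raise ValueError("ci_percent outside [0, 100]")


@dataclass
class PathogenicityVerdict:
    variant_label: str
    candidate: bool = False
    votes_deleterious: int = 0
    vote_pathogenic: bool = False
    final_pathogenic: bool = False
    undetermined: bool = False
    reasons: list = field(default_factory=list)


def is_novel(variant_label: str, catalog: set) -> bool:
    """Novel iff the label is absent from the local catalog snapshot."""
    return variant_label not in catalog


def passes_candidate_filters(context: CandidateContext) -> tuple[bool, list]:
    """Apply the three candidate-selection criteria; returns (flag, reasons)."""
    reasons = []
    ok = True
    freq = context.control_count / context.control_total
    if freq >= POLYMORPHISM_FREQ:
        ok = False
        reasons.append(
            f"population polymorphism: {context.control_count}/{context.control_total}"
            f" = {freq:.2%} >= 1%"
        )
    else:
        reasons.append(f"control frequency {freq:.2%} < 1%")
    if context.normal_thyroid_count > 0:
        ok = False
        reasons.append(
            f"tissue-specific: present in {context.normal_thyroid_count} normal thyroid samples"
        )
    else:
        reasons.append("absent from normal thyroid")
    if context.ci_percent is None:
        ok = False
        reasons.append("CI unavailable")
    elif context.ci_percent <= CI_CUTOFF:
        ok = False
        reasons.append(f"low conservation: CI {context.ci_percent:.2f}% <= {CI_CUTOFF}%")
    else:
        reasons.append(f"CI {context.ci_percent:.2f}% > {CI_CUTOFF}%")
    return ok, reasons


def binarize_predictor(program: str, value) -> bool:
    """One program's output -> deleterious vote (NA never votes)."""
    if program == "panther":
        if value is None or (isinstance(value, str) and _norm(value) == "na"):
            return False
        return float(value) > PANTHER_CUTOFF
    norm = _norm(value)
    vocab = PREDICTOR_VOCABULARY.get(program)
    if vocab is None:
        raise ValueError(f"unknown predictor program {program!r}")
    if norm not in vocab:
        raise ValueError(f"unknown {program} value {value!r}")
    return norm in _DELETERIOUS[program]


def majority_vote(profile: PredictorProfile) -> tuple[int, bool]:
    """Count deleterious votes over all seven programs.

    The threshold is a fixed >=4 of 7 even when NAs reduce the number of
    available programs (the denominator is never renormalized).
    """
    votes = sum(
        binarize_predictor(program, value)
        for program, value in profile.values().items()
    )
    votes += binarize_predictor("panther", profile.panther)
    return votes, votes >= VOTE_THRESHOLD


def classify_pathogenic(
    consequences: dict,
    contexts: dict,
    profiles: dict,
) -> list:
    """Full verdicts for a set of variants keyed by label.

    ``consequences`` maps label -> consequence category; ``contexts`` and
    ``profiles`` carry the filter inputs and predictor outputs for
    non-synonymous candidates.  Nonsense and frameshift coding mutations are
    pathogenic unconditionally; a non-synonymous substitution needs both the
    candidate filters and the majority vote; everything else is benign for
    this rule.  Output order follows sorted labels (input order never
    matters).
    """
    verdicts = []
    for label in sorted(consequences):
        category = consequences[label]
        verdict = PathogenicityVerdict(variant_label=label)
        if category in ("nonsense", "frameshift"):
            verdict.final_pathogenic = True
            verdict.reasons.append(f"{category}: pathogenic unconditionally")
        elif category == "non-synonymous":
            context = contexts.get(label)
            if context is None:
                verdict.undetermined = True
                verdict.reasons.append("no cohort context available")
            else:
                verdict.candidate, reasons = passes_candidate_filters(context)
                verdict.reasons.extend(reasons)
            if verdict.candidate:
                profile = profiles.get(label)
                if profile is None:
                    verdict.undetermined = True
                    verdict.reasons.append("predictor profile missing")
                else:
                    verdict.votes_deleterious, verdict.vote_pathogenic = majority_vote(
                        profile
                    )
                    verdict.reasons.append(
                        f"{verdict.votes_deleterious}/7 programs deleterious"
                    )
                    verdict.final_pathogenic = verdict.vote_pathogenic
        else:
            verdict.reasons.append(f"category {category!r}: vote not applicable")
        verdicts.append(verdict)
    return verdicts


def profile_from_row(row) -> PredictorProfile:
    """Build a profile from a predictor-table row (fixture schema)."""
    panther = row["panther"]
    panther = None if _norm(panther) == "na" else float(panther)
    return PredictorProfile(
        variant_label=row["label"],
        polyphen2=str(row["polyphen2"]),
        sift=str(row["sift"]),
        mutation_assessor=str(row["mutation_assessor"]),
        provean=str(row["provean"]),
        snp_and_go=str(row["snp_go"]),
        align_gvgd=str(row["align_gvgd"]),
        panther=panther,
    )


def context_from_row(row) -> CandidateContext:
    return CandidateContext(
        variant_label=row["label"],
        control_count=int(row["control_count"]),
        control_total=int(row.get("control_total", 376)),
        normal_thyroid_count=int(row["thyroid_count"]),
        normal_thyroid_total=int(row.get("thyroid_total", 16)),
        ci_percent=float(row["ci_percent"]),
        known_in_catalog=str(row.get("reported", "N")).upper() == "Y",
        category="non-synonymous",
    )
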