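"""Relative mtDNA copy number from qPCR Ct values.

The mtDNA content of a sample is measured relative to a single-copy nuclear
reference amplicon (18S): with ideal amplification efficiency the relative
content is ``2^(Ct_nuclear - Ct_mt)`` — one cycle of earlier mtDNA
amplification doubles the inferred ratio.  Per-subject tumor/normal fold
changes and the cohort-level tumor-vs-normal comparison (two-sided
Mann-Whitney U, the unpaired test the source study applied; a paired
Wilcoxon signed-rank alternative is exposed but non-default) complete the
module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

CT_MIN, CT_MAX = 10.0, 40.0
REPLICATE_SD_WARN = 0.5  # cycles


@dataclass
class CtRecord:
    sample_id: str
    tissue: str
    target: str  # "mt" | "nuclear"
    replicates: list  # Ct cycles, typically 3

    def __post_init__(self):
        if self.target not in ("mt", "nuclear"):
            raise ValueError("target must be 'mt' or 'nuclear'")
        if not self.replicates:
            raise ValueError("at least one Ct replicate required")
        for ct in self.replicates:
            if not CT_MIN <= ct <= CT_MAX:
                raise ValueError(f"Ct {ct} outside plausible range {CT_MIN}-{CT_MAX}")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd_ct(self) -> float:
        return float(np.std(self.replicates, ddof=1)) if len(self.replicates) > 1 else 0.0


@dataclass
class CopyNumberResult:
    sample_id: str
    relative_content: float
    delta_ct: float
    tissue: str = ""


def relative_content(
    ct_mt: CtRecord,
    ct_nuc: CtRecord,
    efficiency_mt: float = 2.0,
    efficiency_nuc: float = 2.0,
) -> CopyNumberResult:
    """Relative mtDNA content ``E_nuc^Ct_nuc-normalized`` ratio.

    Default efficiencies of 2.0 give the classical ``2^dCt`` with
    ``dCt = mean Ct_nuclear - mean Ct_mt``.  Efficiencies estimated from a
    standard curve (``E = 10^(-1/slope)``) may be supplied instead.
    """
    if ct_mt.sample_id != ct_nuc.sample_id:
        raise ValueError(
            f"sample mismatch: {ct_mt.sample_id!r} vs {ct_nuc.sample_id!r}"
        )
    if ct_mt.target != "mt" or ct_nuc.target != "nuclear":
        raise ValueError("records must be (mt, nuclear) in that order")
    for rec in (ct_mt, ct_nuc):
        if rec.sd_ct > REPLICATE_SD_WARN:
            warnings.warn(
                f"{rec.sample_id}/{rec.target}: replicate SD {rec.sd_ct:.2f} cycles"
                " exceeds 0.5",
                stacklevel=2,
            )
    # content = E_mt^(-Ct_mt) / E_nuc^(-Ct_nuc)
    content = efficiency_mt ** (-ct_mt.mean_ct) / efficiency_nuc ** (-ct_nuc.mean_ct)
    return CopyNumberResult(
        sample_id=ct_mt.sample_id,
        relative_content=content,
        delta_ct=ct_nuc.mean_ct - ct_mt.mean_ct,
        tissue=ct_mt.tissue,
    )


def fold_change(tumor: CopyNumberResult, normal: CopyNumberResult) -> float:
    """Tumor/normal content ratio for one subject; > 1 means increased."""
    if normal.relative_content <= 0 or not math.isfinite(normal.relative_content):
        raise ValueError("normal content must be positive and finite")
    return tumor.relative_content / normal.relative_content


def cohort_compare(tumor_contents, normal_contents, paired: bool = False):
    """Two-sided tumor-vs-normal comparison of relative contents.

    Default is the unpaired Mann-Whitney U (exact when both n <= 10 with no
    ties, tie-corrected normal approximation otherwise).  ``paired=True``
    switches to the Wilcoxon signed-rank test (non-default alternative for
    genuinely paired designs).
    """
    x = np.asarray(list(tumor_contents), dtype=float)
    y = np.asarray(list(normal_contents), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired comparison needs equal-length groups")
        res = stats.wilcoxon(x, y, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def read_ct_table(path) -> dict:
    """CSV ``sample_id,tissue,target,ct1,ct2,ct3`` -> {(sample_id, target): CtRecord}."""
    import pandas as pd

    df = pd.read_csv(path)
    records = {}
    for _, row in df.iterrows():
        reps = [
            float(row[c])
            for c in df.columns
            if c.startswith("ct") and not pd.isna(row[c])
        ]
        rec = CtRecord(
            sample_id=str(row["sample_id"]),
            tissue=str(row["tissue"]),
            target=str(row["target"]),
            replicates=reps,
        )
        records[(rec.sample_id, rec.target)] = rec
    return records


def subject_results(records: dict) -> list:
    """Pair mt/nuclear records per sample into CopyNumberResult objects."""
    out = []
    for (sample_id, target), rec in sorted(records.items()):
        if target != "mt":
            continue
        nuc = records.get((sample_id, "nuclear"))
        if nuc is None:
            raise ValueError(f"no nuclear record for sample {sample_id!r}")
        out.append(relative_content(rec, nuc))
    return out
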