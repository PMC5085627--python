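"""Variant calling against the circular mitochondrial reference.

Sample sequences (Sanger-style consensus, one or two allele strings per
tissue) are globally aligned to the reference, differences are extracted and
normalized, and calls are labelled with zygosity (homoplasmic vs
heteroplasmic), origin (somatic vs germline via tumor/normal pairing) and
mtMSI status (indels inside the three microsatellite repeat windows).

Indel normalization follows the mitochondrial reporting convention: indels
are shifted to the 3'-most equivalent position of their repeat tract and
homopolymer/repeat-unit changes are labelled as tract-interval copy-number
changes, e.g. ``11032-11038 A7-6`` or ``14495-14502 (AAAT)2-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib

from .reference import MT_LENGTH, MitoReference

MTMSI_WINDOWS = [(303, 315), (16184, 16193), (514, 523)]

MAX_LENGTH_DEVIATION = 600
MIN_IDENTITY = 0.95

_IUPAC2 = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
}


@dataclass(frozen=True, order=True)
class Variant:
    """One normalized mtDNA change in rCRS coordinates.

    * substitution: ``start == end``, single-base ``ref`` and ``alt``
    * deletion: ``ref`` = deleted bases spanning ``start..end``, ``alt`` empty
    * insertion: ``alt`` inserted *after* position ``start`` (== ``end``),
      ``ref`` empty; the anchor is the 3'-most equivalent position
    """

    start: int
    end: int
    kind: str
    ref: str
    alt: str

    def __post_init__(self):
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if not (1 <= self.start <= MT_LENGTH and 1 <= self.end <= MT_LENGTH):
            raise ValueError("variant coordinates outside 1..16569")
        if self.kind == "substitution":
            if self.start != self.end or len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("substitution must be single-base, start==end")
        elif self.kind == "deletion":
            if self.alt or len(self.ref) != self.end - self.start + 1:
                raise ValueError("deletion ref must span start..end, alt empty")
        else:
            if self.ref or not self.alt or self.start != self.end:
                raise ValueError("insertion must have empty ref and an anchor")

    @property
    def is_indel(self) -> bool:
        return self.kind != "substitution"

    @property
    def indel_length(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass
class VariantCall:
    variant: Variant
    sample_id: str
    zygosity: str  # homoplasmic | heteroplasmic
    origin: str = "undetermined"  # somatic | germline | undetermined
    heteroplasmic_fraction: float | None = None
    mtMSI: bool = False
    label: str = ""


@dataclass
class SampleSequence:
    """One tissue sample: 1-2 full-length allele sequences.

    A single sequence containing two-way IUPAC ambiguity codes is expanded to
    two alleles (Sanger secondary peaks), so heteroplasmy is represented
    either way as a two-allele sample.
    """

    sample_id: str
    tissue: str  # tumor | adjacent-normal | normal-thyroid | blood-control
    alleles: list
    subject_id: str = ""

    def __post_init__(self):
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError("a sample carries 1 or 2 allele sequences")
        if len(self.alleles) == 2:
            if abs(len(self.alleles[0]) - len(self.alleles[1])) > MAX_LENGTH_DEVIATION:
                raise ValueError("alleles of grossly different length")

    def expanded_alleles(self) -> list:
        if len(self.alleles) == 1 and any(
            b in _IUPAC2 for b in self.alleles[0].upper()
        ):
            a1, a2 = [], []
            for b in self.alleles[0].upper():
                if b in _IUPAC2:
                    x, y = _IUPAC2[b]
                    a1.append(x)
                    a2.append(y)
                else:
                    a1.append(b)
                    a2.append(b)
            return ["".join(a1), "".join(a2)]
        return [a.upper() for a in self.alleles]


@dataclass
class PairwiseAlignment:
    """Global sample-vs-reference alignment (edlib NW path)."""

    cigar: str
    sample: str
    reference: MitoReference
    edit_distance: int

    @property
    def identity(self) -> float:
        return 1.0 - self.edit_distance / len(self.reference)


@dataclass
class VariationLoadResult:
    unit: str
    altered_nucleotides: int
    unit_length: int

    @property
    def load(self) -> float:
        return self.altered_nucleotides / self.unit_length * 100.0


def align_to_reference(sample_allele: str, reference: MitoReference) -> PairwiseAlignment:
    """Globally align one allele sequence to the reference.

    The sample is expected linearized at rCRS position 1.  Sequences whose
    length deviates by more than 600 nt, or whose identity falls below 95%,
    are rejected as non-mtDNA input.
    """
    seq = sample_allele.upper()
    if abs(len(seq) - len(reference)) > MAX_LENGTH_DEVIATION:
        raise ValueError(
            f"sequence length {len(seq)} too far from reference {len(reference)}"
        )
    res = edlib.align(seq, reference.sequence, mode="NW", task="path")
    aln = PairwiseAlignment(
        cigar=res["cigar"], sample=seq, reference=reference,
        edit_distance=res["editDistance"],
    )
    if aln.identity < MIN_IDENTITY:
        raise ValueError(
            f"identity {aln.identity:.3f} < {MIN_IDENTITY}: not an mtDNA sequence"
        )
    return aln


def _parse_cigar(cigar: str):
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            yield int(n), ch
            n = ""


def extract_variants(alignment: PairwiseAlignment) -> list:
    """Walk the alignment and emit normalized variants.

    The fast edlib path minimizes edit distance, which can represent two
    nearby substitutions as an equal-cost insertion+deletion pair.  Any
    cluster of raw differences containing an indel is therefore locally
    realigned with affine gap scores (match +1, mismatch -2, open -6,
    extend -0.5), under which mismatches are preferred and repeat-unit
    deletions stay as a single gap.  Adjacent gap columns of the same type
    merge into one indel; every indel is 3'-shifted afterwards.  Columns
    involving the reference ``N`` placeholder (position 3107) are never
    called.
    """
    ref = alignment.reference
    raw, s_of_r = _raw_differences(alignment)
    clusters = _cluster(raw, gap=20)
    out = []
    for cluster in clusters:
        if len(cluster) > 1 and any(k != "substitution" for k, *_ in cluster):
            cluster = _realign_cluster(cluster, alignment, s_of_r)
        for kind, start, end, rbases, sbases in cluster:
            if "N" in rbases or "N" in sbases:
                continue
            if kind == "substitution":
                out.append(Variant(start, end, "substitution", rbases, sbases))
            elif kind == "deletion":
                out.append(
                    normalize_indel(
                        Variant(start, end, "deletion", rbases, ""), ref
                    )
                )
            else:
                out.append(
                    normalize_indel(
                        Variant(max(start, 1), max(start, 1), "insertion", "", sbases),
                        ref,
                    )
                )
    return sorted(set(out))


def _raw_differences(alignment: PairwiseAlignment):
    """First pass: raw difference tuples + sample index per ref position.

    Returns ``(raw, s_of_r)`` where raw tuples are
    ``(kind, ref_start, ref_end, ref_bases, sample_bases)`` (insertions are
    anchored after ``ref_start == ref_end``) and ``s_of_r[p]`` is the
    0-based sample index aligned to 1-based reference position ``p``.
    """
    refseq = alignment.reference.sequence
    sample = alignment.sample
    s_of_r = [0] * (len(refseq) + 2)
    raw = []
    rpos = spos = 0
    pending = None  # (kind, anchor, ref_bases, sample_bases)
    for length, op in _parse_cigar(alignment.cigar):
        if op in ("=", "M", "X"):
            if pending:
                raw.append(pending)
                pending = None
            for k in range(length):
                s_of_r[rpos + k + 1] = spos + k
                if op == "X":
                    raw.append(
                        (
                            "substitution",
                            rpos + k + 1,
                            rpos + k + 1,
                            refseq[rpos + k],
                            sample[spos + k],
                        )
                    )
            rpos += length
            spos += length
        elif op == "D":
            bases = refseq[rpos : rpos + length]
            for k in range(length):
                s_of_r[rpos + k + 1] = spos
            if pending and pending[0] == "deletion":
                pending = ("deletion", pending[1], pending[2] + bases, "")
            else:
                if pending:
                    raw.append(pending)
                pending = ("deletion", rpos + 1, bases, "")
            rpos += length
        elif op == "I":
            bases = sample[spos : spos + length]
            if pending and pending[0] == "insertion":
                pending = ("insertion", pending[1], "", pending[3] + bases)
            else:
                if pending:
                    raw.append(pending)
                pending = ("insertion", rpos, "", bases)
            spos += length
        else:
            raise ValueError(f"unexpected CIGAR op {op!r}")
    if pending:
        raw.append(pending)
    # expand pending tuples to uniform (kind, start, end, rbases, sbases)
    uniform = []
    for item in raw:
        if item[0] == "substitution":
            uniform.append(item)
        elif item[0] == "deletion":
            _, anchor, rbases, _ = item
            uniform.append(("deletion", anchor, anchor + len(rbases) - 1, rbases, ""))
        else:
            _, anchor, _, sbases = item
            uniform.append(("insertion", anchor, anchor, "", sbases))
    uniform.sort(key=lambda t: (t[1], t[2]))
    return uniform, s_of_r


def _cluster(raw, gap=20):
    clusters = []
    for item in raw:
        if clusters and item[1] - clusters[-1][-1][2] <= gap:
            clusters[-1].append(item)
        else:
            clusters.append([item])
    return clusters


_REALIGN_PAD = 8

_affine_aligner = None


def _get_affine_aligner():
    global _affine_aligner
    if _affine_aligner is None:
        from Bio import Align

        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1
        a.mismatch_score = -2
        a.open_gap_score = -6
        a.extend_gap_score = -0.5
        _affine_aligner = a
    return _affine_aligner


def _realign_cluster(cluster, alignment: PairwiseAlignment, s_of_r):
    """Re-extract one difference cluster under affine gap scoring."""
    refseq = alignment.reference.sequence
    sample = alignment.sample
    a = max(1, cluster[0][1] - _REALIGN_PAD)
    b = min(len(refseq), cluster[-1][2] + _REALIGN_PAD)
    sa = s_of_r[a]
    sb = s_of_r[b]
    ref_win = refseq[a - 1 : b]
    smp_win = sample[sa : sb + 1]
    if not ref_win or not smp_win:
        return cluster
    aln = _get_affine_aligner().align(ref_win, smp_win)[0]
    coords = aln.coordinates  # 2 x k block boundaries (target=ref, query=sample)
    out = []
    for i in range(coords.shape[1] - 1):
        r0, r1 = int(coords[0, i]), int(coords[0, i + 1])
        q0, q1 = int(coords[1, i]), int(coords[1, i + 1])
        if r1 > r0 and q1 > q0:  # aligned block: scan for mismatches
            for k in range(r1 - r0):
                rb, qb = ref_win[r0 + k], smp_win[q0 + k]
                if rb != qb:
                    pos = a + r0 + k
                    out.append(("substitution", pos, pos, rb, qb))
        elif r1 > r0:  # gap in sample: deletion
            out.append(("deletion", a + r0, a + r1 - 1, ref_win[r0:r1], ""))
        elif q1 > q0:  # gap in reference: insertion after a+r0-1
            out.append(("insertion", a + r0 - 1, a + r0 - 1, "", smp_win[q0:q1]))
    return out


def normalize_indel(variant: Variant, reference: MitoReference) -> Variant:
    """Shift an indel to its 3'-most equivalent placement (no origin wrap)."""
    if variant.kind == "substitution":
        return variant
    seq = reference.sequence
    if variant.kind == "deletion":
        s, e = variant.start, variant.end
        while e + 1 <= MT_LENGTH and seq[s - 1] == seq[e]:
            s += 1
            e += 1
        return Variant(s, e, "deletion", seq[s - 1 : e], "")
    ins = variant.alt
    p = variant.start
    while p + 1 <= MT_LENGTH and ins[0] == seq[p]:
        ins = ins[1:] + ins[0]
        p += 1
    return Variant(p, p, "insertion", "", ins)


def _homopolymer_run(reference: MitoReference, pos: int, base: str):
    """Maximal run of `base` containing `pos` (no origin wrap)."""
    seq = reference.sequence
    if seq[pos - 1] != base:
        return None
    s = e = pos
    while s > 1 and seq[s - 2] == base:
        s -= 1
    while e < MT_LENGTH and seq[e] == base:
        e += 1
    return s, e


def variant_label(variant: Variant, reference: MitoReference) -> str:
    """Canonical mitochondrial-style label for a (normalized) variant."""
    if variant.kind == "substitution":
        return f"{variant.ref}{variant.start}{variant.alt}"
    unit = variant.ref or variant.alt
    # homopolymer tract?
    if len(set(unit)) == 1:
        base = unit[0]
        anchor = variant.start if variant.kind == "deletion" else variant.start
        run = _homopolymer_run(reference, anchor, base)
        if run and run[1] - run[0] + 1 >= 2:
            ts, te = run
            n_ref = te - ts + 1
            n_alt = n_ref + variant.indel_length
            return f"{ts}-{te} {base}{n_ref}-{n_alt}"
    # multi-base repeat unit?
    if len(unit) >= 2 and variant.kind == "deletion":
        seq = reference.sequence
        u = len(unit)
        ts = variant.start
        while ts - u >= 1 and seq[ts - u - 1 : ts - 1] == unit:
            ts -= u
        te = variant.end
        while te + u <= MT_LENGTH and seq[te : te + u] == unit:
            te += u
        copies = (te - ts + 1) // u
        if copies >= 2:
            first_unit = seq[ts - 1 : ts - 1 + u]
            return f"{ts}-{te} ({first_unit}){copies}-{copies - 1}"
    if variant.kind == "deletion":
        if len(variant.ref) == 1:
            return f"{variant.start}del{variant.ref}"
        return f"{variant.start}-{variant.end}del{variant.ref}"
    return f"{variant.start}ins{variant.alt}"


def flag_mtMSI(variant: Variant, windows=None) -> bool:
    """True iff an indel intersects one of the mtMSI repeat windows."""
    if not variant.is_indel:
        return False
    windows = windows if windows is not None else MTMSI_WINDOWS
    for ws, we in windows:
        if variant.start <= we and variant.end >= ws:
            return True
    return False


def call_sample(sample: SampleSequence, reference: MitoReference) -> list:
    """Align each allele, extract variants, and assign zygosity.

    A variant present in every allele is homoplasmic; present in a proper
    subset it is heteroplasmic (fraction fixed at 0.5: dual-allele Sanger
    evidence carries no quantitative fraction).
    """
    alleles = sample.expanded_alleles()
    per_allele = []
    for allele in alleles:
        aln = align_to_reference(allele, reference)
        per_allele.append(set(extract_variants(aln)))
    union = set().union(*per_allele)
    calls = []
    for v in sorted(union):
        n_carrying = sum(v in s for s in per_allele)
        het = n_carrying < len(per_allele)
        calls.append(
            VariantCall(
                variant=v,
                sample_id=sample.sample_id,
                zygosity="heteroplasmic" if het else "homoplasmic",
                heteroplasmic_fraction=0.5 if het else None,
                mtMSI=flag_mtMSI(v),
                label=variant_label(v, reference),
            )
        )
    return calls


detect_heteroplasmy = call_sample  # descriptive alias


def classify_origin(tumor_calls: list, normal_calls: list,
                    tumor_subject: str = "", normal_subject: str = "") -> list:
    """Label tumor calls somatic/germline by comparison with paired normal.

    Somatic: absent at that position in the paired normal.  Germline: the
    same variant present in both.  A different normal variant touching the
    same position leaves the call undetermined.  Zygosity is ignored: a
    variant heteroplasmic in tumor and absent in normal is somatic.
    """
    if tumor_subject != normal_subject:
        raise ValueError(
            f"subject mismatch: {tumor_subject!r} vs {normal_subject!r}"
        )
    normal_variants = {c.variant for c in normal_calls}
    normal_spans = [(c.variant.start, c.variant.end) for c in normal_calls]
    out = []
    for call in tumor_calls:
        v = call.variant
        if v in normal_variants:
            origin = "germline"
        elif any(v.start <= e and v.end >= s for s, e in normal_spans):
            origin = "undetermined"
        else:
            origin = "somatic"
        out.append(replace(call, origin=origin))
    return out


def variation_load(calls: list, reference: MitoReference, unit: str,
                   complexes: dict | None = None) -> VariationLoadResult:
    """Altered nucleotides per gene/complex as a percentage of its length.

    Altered nucleotides are counted as distinct reference positions touched
    by any variant in the unit (two variants at one site count once).
    """
    if complexes is None:
        from .refbuild import COMPLEXES as complexes
    try:
        feats = [reference.feature_by_name(unit)]
    except KeyError:
        if unit not in complexes:
            raise ValueError(f"unknown gene or complex {unit!r}") from None
        feats = [reference.feature_by_name(g) for g in complexes[unit]]
    positions = set()
    for call in calls:
        v = call.variant
        for p in range(v.start, v.end + 1):
            if any(f.contains(p) for f in feats):
                positions.add(p)
    return VariationLoadResult(
        unit=unit,
        altered_nucleotides=len(positions),
        unit_length=sum(len(f) for f in feats),
    )


def apply_variants(sequence: str, variants: list) -> str:
    """Apply variants (rCRS coordinates) to a reference-length sequence."""
    ordered = sorted(variants, key=lambda v: (v.start, v.kind), reverse=True)
    seq = sequence
    seen = set()
    for v in ordered:
        key = (v.start, v.end, v.kind)
        if key in seen:
            raise ValueError(f"conflicting variants at {v.start}")
        seen.add(key)
        if v.kind == "substitution":
            assert seq[v.start - 1] == v.ref, (v, seq[v.start - 1])
            seq = seq[: v.start - 1] + v.alt + seq[v.start :]
        elif v.kind == "deletion":
            assert seq[v.start - 1 : v.end] == v.ref, v
            seq = seq[: v.start - 1] + seq[v.end :]
        else:
            seq = seq[: v.start] + v.alt + seq[v.start :]
    return seq
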