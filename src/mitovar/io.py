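"""Readers and writers for the package's tabular formats.

Packaged fixtures (variant tables transcribed from the study's printed
tables, the known-variant catalog, RNA pairing maps, the haplogroup tree)
live under ``mitovar/data`` and are loaded through the helpers here.  Sample
sequences travel as FASTA with ``subject|tissue|allele`` headers; call sets
as TSV; VCF export uses pysam (contig ``chrM``, left-anchored indels, with
the mitochondrial-style 3' label carried in INFO).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .calling import SampleSequence, Variant, VariantCall, variant_label
from .consequence import RnaPairingMap
from .reference import MT_LENGTH, MitoReference


def data_path(name: str) -> str:
    return str(files("mitovar") / "data" / name)


def _row_to_variant(row) -> Variant:
    ref = "" if pd.isna(row.get("ref")) else str(row["ref"])
    alt = "" if pd.isna(row.get("alt")) else str(row["alt"])
    return Variant(int(row["start"]), int(row["end"]), row["kind"], ref, alt)


def read_variant_table(path) -> pd.DataFrame:
    """Read a variant fixture/results TSV; adds a ``variant`` object column."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    if "end" not in df.columns:
        df["end"] = df["start"]
    df["variant"] = df.apply(_row_to_variant, axis=1)
    return df


def novel_variant_table() -> pd.DataFrame:
    """The 33 novel variants transcribed from the source study's tables."""
    return read_variant_table(data_path("table_novel_variants.tsv"))


def truncating_mutation_table() -> pd.DataFrame:
    """The 18 nonsense/frameshift mutations transcribed from the source study."""
    return read_variant_table(data_path("table_truncating_mutations.tsv"))


def predictor_profile_table() -> pd.DataFrame:
    """Candidate non-synonymous variants with 7-program outputs
    (25 of the source study's 26 printed rows survive in the available
    transcription)."""
    df = pd.read_csv(
        data_path("table_predictor_profiles.tsv"),
        sep="\t",
        keep_default_na=False,
        na_values=[],
    )
    return df


def load_catalog(path=None) -> set:
    """Known-variant catalog (local Mitomap-like snapshot) as a label set."""
    path = path or data_path("catalog_known_variants.tsv")
    df = pd.read_csv(path, sep="\t")
    return set(df["label"].astype(str))


def load_pairing_maps(path=None) -> dict:
    """RNA stem base-pair maps keyed by gene name."""
    path = path or data_path("pairing_maps.tsv")
    df = pd.read_csv(path, sep="\t")
    maps: dict = {}
    for _, row in df.iterrows():
        gene = row["gene"]
        maps.setdefault(gene, RnaPairingMap(gene=gene, pairs=set()))
        pair = frozenset({int(row["pos1"]), int(row["pos2"])})
        for existing in maps[gene].pairs:
            if existing & pair and existing != pair:
                raise ValueError(f"{gene}: position in more than one pair")
        maps[gene].pairs.add(pair)
    return maps


def read_samples_fasta(path) -> list:
    """FASTA with ``subject|tissue|allele`` headers -> SampleSequence list."""
    groups: dict = {}
    for record in SeqIO.parse(str(path), "fasta"):
        try:
            subject, tissue, allele = record.id.split("|")
        except ValueError as exc:
            raise ValueError(
                f"FASTA header {record.id!r} is not subject|tissue|allele"
            ) from exc
        groups.setdefault((subject, tissue), []).append(
            (int(allele), str(record.seq))
        )
    samples = []
    for (subject, tissue), alleles in sorted(groups.items()):
        alleles.sort()
        samples.append(
            SampleSequence(
                sample_id=f"{subject}|{tissue}",
                tissue=tissue,
                alleles=[seq for _, seq in alleles],
                subject_id=subject,
            )
        )
    return samples


def write_samples_fasta(path, samples: list):
    with open(path, "w") as fh:
        for s in samples:
            for i, allele in enumerate(s.alleles, start=1):
                fh.write(f">{s.subject_id}|{s.tissue}|{i}\n")
                for k in range(0, len(allele), 70):
                    fh.write(allele[k : k + 70] + "\n")


def calls_to_frame(calls: list, gene_of=None) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "position": c.variant.start,
                "end": c.variant.end,
                "label": c.label,
                "kind": c.variant.kind,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "zygosity": c.zygosity,
                "origin": c.origin,
                "mtMSI": c.mtMSI,
                "gene": gene_of(c.variant) if gene_of else "",
            }
        )
    return pd.DataFrame(rows)


def write_calls_tsv(path, calls: list, gene_of=None):
    calls_to_frame(calls, gene_of).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF export / import (pysam)

def _left_anchor(variant: Variant, reference: MitoReference):
    """VCF-style left-aligned POS/REF/ALT with anchor base."""
    seq = reference.sequence
    if variant.kind == "substitution":
        return variant.start, variant.ref, variant.alt
    if variant.kind == "deletion":
        s, e = variant.start, variant.end
        # shift left while the bases allow (mirror of 3' normalization)
        while s > 1 and seq[s - 2] == seq[e - 1]:
            s -= 1
            e -= 1
        pos = s - 1 if s > 1 else e + 1  # anchor base before (or after at origin)
        if s > 1:
            return pos, seq[pos - 1 : e], seq[pos - 1]
        return 1, seq[0 : e + 1], seq[e]
    ins = variant.alt
    p = variant.start
    while p > 0 and seq[p - 1] == ins[-1]:
        ins = ins[-1] + ins[:-1]
        p -= 1
    if p == 0:
        p = 1
        return p, seq[0], seq[0] + ins  # degenerate origin case
    return p, seq[p - 1], seq[p - 1] + ins


def write_vcf(path, calls: list, reference: MitoReference):
    """Write calls as VCF 4.2 on contig chrM (pysam)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID=chrM,length={MT_LENGTH}>")
    header.add_line(
        '##INFO=<ID=LABEL,Number=1,Type=String,Description="3-prime mitochondrial-style label">'
    )
    header.add_line('##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity">')
    header.add_line('##INFO=<ID=ORIGIN,Number=1,Type=String,Description="Somatic status">')
    header.add_line('##INFO=<ID=MTMSI,Number=0,Type=Flag,Description="mtMSI-region indel">')
    header.add_line('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">')
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (c.variant.start, c.sample_id)):
            pos, ref, alt = _left_anchor(call.variant, reference)
            rec = vcf.new_record(
                contig="chrM", start=pos - 1, alleles=(ref, alt), filter="PASS"
            )
            rec.info["LABEL"] = call.label.replace(" ", "_")
            rec.info["ZYG"] = call.zygosity
            rec.info["ORIGIN"] = call.origin
            if call.mtMSI:
                rec.info["MTMSI"] = True
            rec.info["SAMPLE"] = call.sample_id.replace(" ", "_")
            vcf.write(rec)


def read_vcf(path, reference: MitoReference) -> list:
    """Read an exported VCF back into normalized VariantCall objects."""
    import pysam

    from .calling import flag_mtMSI, normalize_indel

    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) == 1 and len(alt) == 1:
                v = Variant(rec.pos, rec.pos, "substitution", ref, alt)
            elif len(ref) > len(alt):
                v = Variant(
                    rec.pos + 1, rec.pos + len(ref) - 1, "deletion", ref[1:], ""
                )
            else:
                v = Variant(rec.pos, rec.pos, "insertion", "", alt[len(ref):])
            v = normalize_indel(v, reference)
            calls.append(
                VariantCall(
                    variant=v,
                    sample_id=str(rec.info.get("SAMPLE", "")),
                    zygosity=str(rec.info.get("ZYG", "")),
                    origin=str(rec.info.get("ORIGIN", "undetermined")),
                    mtMSI=flag_mtMSI(v),
                    label=variant_label(v, reference),
                )
            )
    return calls
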