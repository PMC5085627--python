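"""Brute-force validation of the predictor binarization rules.

Two of the seven binarization rules cannot be read off the source tables'
footnotes and were reverse-engineered from the printed outcomes:
PolyPhen-2 "Possibly damaging" counting as deleterious, and
MutationAssessor "Low" counting as deleterious.  This script enumerates
every candidate binarization over the genuinely ambiguous choices

* PolyPhen-2: {Probably} vs {Probably, Possibly}
* MutationAssessor: {High} / {High, Medium} / {High, Medium, Low}
* Align-GVGD: {C65} vs {C65, C55}
* SIFT, PROVEAN, SNP&GO, PANTHER(>0.5): fixed by their footnotes/semantics

and reports which combinations reproduce the study's marked variant set
(the 15 rows voted deleterious by >= 4 of 7 programs) exactly on all
packaged profiles.
"""

from __future__ import annotations

import itertools

from mitovar.io import predictor_profile_table

MARKED_POSITIONS = {
    3392, 3644, 3679, 4971, 6238, 7104, 8156, 8989, 9187, 10573,
    14310, 15018, 15045, 15090, 15483,
}

PP2_CHOICES = [{"probably"}, {"probably", "possibly"}]
MA_CHOICES = [{"high"}, {"high", "medium"}, {"high", "medium", "low"}]
GVGD_CHOICES = [{"c65"}, {"c65", "c55"}]


def norm(v) -> str:
    return str(v).strip().replace(" ", "").lower()


def votes(row, pp2, ma, gvgd) -> int:
    count = 0
    count += norm(row["polyphen2"]) in pp2
    count += norm(row["sift"]) == "nottolerated"
    count += norm(row["mutation_assessor"]) in ma
    count += norm(row["provean"]) == "deleterious"
    count += norm(row["snp_go"]) == "disease"
    count += norm(row["align_gvgd"]) in gvgd
    panther = norm(row["panther"])
    count += panther != "na" and float(row["panther"]) > 0.5
    return count


def main():
    table = predictor_profile_table()
    matches = []
    for pp2, ma, gvgd in itertools.product(PP2_CHOICES, MA_CHOICES, GVGD_CHOICES):
        selected = {
            int(row["start"])
            for _, row in table.iterrows()
            if votes(row, pp2, ma, gvgd) >= 4
        }
        ok = selected == MARKED_POSITIONS
        print(
            f"PolyPhen-2={sorted(pp2)} MutationAssessor={sorted(ma)} "
            f"AlignGVGD={sorted(gvgd)} -> {len(selected)} selected"
            f" {'== MARKED SET' if ok else ''}"
        )
        if ok:
            matches.append((pp2, ma, gvgd))
    print(f"\n{len(matches)} of {len(PP2_CHOICES) * len(MA_CHOICES) * len(GVGD_CHOICES)}"
          " binarizations reproduce the marked set")
    assert matches, "no binarization reproduces the marked set"


if __name__ == "__main__":
    main()
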