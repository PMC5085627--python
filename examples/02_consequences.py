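"""Consequence classes of the packaged truncating mutations.

Classifies the bundled nonsense/frameshift table on the reference and
prints the class split plus the ND6 truncation: the (AAAT)2->1 deletion
shifts the frame so translation stops after 58 of the 175 codons.
"""

from mitovar import annotate_indel, annotate_substitution, bundled_reference
from mitovar.io import truncating_mutation_table

reference = bundled_reference()
counts = {}
for _, row in truncating_mutation_table().iterrows():
    variant = row["variant"]
    if variant.kind == "substitution":
        cons = annotate_substitution(variant, reference)
    else:
        cons = annotate_indel(variant, reference)
    counts[cons.category] = counts.get(cons.category, 0) + 1
    extra = f" {cons.aa_change}" if cons.aa_change else ""
    if cons.product_length_alt is not None and cons.category == "frameshift":
        extra = f" product {cons.product_length_ref}->{cons.product_length_alt} aa"
    print(f"{row['label']:24s} {cons.gene:6s} {cons.category}{extra}")

print("\nclass counts:", counts)  # 7 nonsense + 11 frameshift
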