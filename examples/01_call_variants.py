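"""Call variants from a sample sequence against the bundled reference.

Plants a somatic-style substitution, a repeat-unit deletion and an mtMSI
insertion into the reference, then recovers them with mitochondrial-style
labels.  The heteroplasmic variant is represented by a two-allele sample.
"""

from mitovar import SampleSequence, Variant, bundled_reference, call_sample
from mitovar.calling import apply_variants

reference = bundled_reference()

planted = [
    Variant(6238, 6238, "substitution", "T", "C"),       # COI missense
    Variant(14495, 14498, "deletion", "AAAT", ""),       # ND6 frameshift
    Variant(305, 305, "insertion", "", "C"),             # mtMSI poly-C stutter
]
allele_with = apply_variants(reference.sequence, planted)
allele_without = apply_variants(reference.sequence, planted[1:])  # 6238 is heteroplasmic

sample = SampleSequence("demo|tumor", "tumor", [allele_with, allele_without], "demo")
for call in call_sample(sample, reference):
    print(f"{call.label:24s} {call.variant.kind:12s} {call.zygosity:14s} mtMSI={call.mtMSI}")

# The deletion is reported 3'-shifted as a repeat copy-number change
# (14495-14502 (AAAT)2-1), the poly-C insertion lands at the tract end
# (303-309 C7-8) and is flagged mtMSI, and the substitution present in only
# one of the two alleles is called heteroplasmic.
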