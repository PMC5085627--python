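"""The full pathogenicity decision over the packaged study tables.

Non-synonymous candidates go through the seven-predictor binarization and
the >=4-of-7 majority vote; nonsense and frameshift mutations are
pathogenic unconditionally.  Prints the vote count per candidate and the
final arithmetic (15 voted + 7 nonsense + 11 frameshift = 33).
"""

from mitovar.io import predictor_profile_table
from mitovar.pathogenicity import majority_vote, profile_from_row
from mitovar.pipeline import fixture_report

for _, row in predictor_profile_table().iterrows():
    votes, pathogenic = majority_vote(profile_from_row(row))
    marker = "PATHOGENIC" if pathogenic else ""
    print(f"{row['label']:10s} {row['gene']:5s} votes={votes}/7 {marker}")

report = fixture_report()
print(
    f"\n{report['n_nonsynonymous']} voted non-synonymous"
    f" + {report['n_nonsense']} nonsense + {report['n_frameshift']} frameshift"
    f" = {report['n_pathogenic_total']} pathogenic mutations"
)
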