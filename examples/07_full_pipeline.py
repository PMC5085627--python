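"""Simulate a cohort and run every pipeline stage over it.

Generates a small tumor/normal cohort with controls on haplogroup
backbones, writes a run directory, executes calling, annotation, novelty,
pathogenicity, haplogroups, copy number and association, and prints the
summary of headline counts.
"""

import json
import tempfile
from pathlib import Path

from mitovar import RunConfig, bundled_reference, bundled_tree, run_pipeline
from mitovar.simulate import SimConfig, generate_cohort, write_cohort

with tempfile.TemporaryDirectory() as tmp:
    run_dir = Path(tmp) / "run"
    config = SimConfig(seed=7, n_pairs=8, n_controls=20, n_normal_thyroid=3)
    cohort = generate_cohort(config, bundled_reference(), bundled_tree())
    write_cohort(run_dir, cohort, config)

    result = run_pipeline(RunConfig(run_dir=str(run_dir), out_dir=str(run_dir / "results")))
    print(json.dumps(result["summary"], indent=1))

# n_somatic_calls counts tumor variants absent from the paired normal;
# n_pathogenic applies the nonsense/frameshift bypass (no predictor table is
# supplied here, so non-synonymous candidates stay undetermined); the
# copy-number block reports the Mann-Whitney comparison and how many
# subjects had an increased tumor/normal fold.
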