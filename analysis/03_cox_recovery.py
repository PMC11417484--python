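#!/usr/bin/env python
"""Cox hazard-ratio recovery: one biobank-scale (n=35 000) fit of the
categorical hypertrophy and per-SD models against their generative truths,
plus the 200-replicate CI-coverage battery at n=5000.

Writes results/headline_hazards.tsv and results/cox_coverage.json.
Pass a smaller replicate count as the first argument for a quick look.
"""

import json
import sys
from pathlib import Path

from cardiomass import experiments as ex

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
n_rep = int(sys.argv[1]) if len(sys.argv) > 1 else 200

head = ex.headline_hazard_recovery(n_subjects=35_000, seed=0)
cols = ["group", "hazard_ratio", "ci_low", "ci_high", "true_hr", "n_group", "n_events"]
head[cols].to_csv(OUT / "headline_hazards.tsv", sep="\t", index=False, float_format="%.6g")
print("single 35 000-subject replicate, fitted vs generative hazard ratios:")
print(head[cols].round(2).to_string(index=False))

cov = ex.cox_coverage(n_replicates=n_rep, n_subjects=5000, seed=0)
(OUT / "cox_coverage.json").write_text(json.dumps(cov, indent=2))
print(
    f"\n{n_rep}-replicate coverage at n=5000 (~{cov['mean_events']:.0f} events each): "
    f"per-SD {100 * cov['coverage_per_sd']:.1f}%, "
    f"categorical global {100 * cov['coverage_cat_global']:.1f}%, "
    f"septal-attenuation {100 * cov['coverage_attenuation_septal']:.1f}%, "
    f"null CI contains 1 in {100 * cov['coverage_null']:.1f}%"
)
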