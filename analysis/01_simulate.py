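#!/usr/bin/env python
"""Generate the synthetic two-arm time-course study.

Emulates the profiled design: parental replicates at generation 0 plus
drug-treated and vehicle-control arms over 11 generations, measured on
expression (log2) and promoter methylation (beta + intensities), with five
planted expression and three planted methylation pattern archetypes and 20
anti-correlated driver genes. Writes tab-separated matrices plus the truth
record under results/simulated/.
"""

import json
from pathlib import Path

from omicspatterns import SimConfig, generate_time_course
from omicspatterns.synthetic_data import write_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 20

config = SimConfig(n_genes=2000, seed=SEED)
expression, methylation, annotation, truth = generate_time_course(config)
write_dataset(OUT, expression, methylation, annotation, truth)
(OUT / "sim_config.json").write_text(json.dumps(config.__dict__, indent=1))

print(f"wrote {expression.n_features} genes x {expression.n_samples} samples -> {OUT}")
print(f"planted drivers: {len(truth.driver_genes)}; "
      f"expression archetypes: {truth.pattern_labels['expression']}; "
      f"methylation archetypes: {truth.pattern_labels['methylation']}")
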