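#!/usr/bin/env python
"""Project the learned signatures into an external-style expression cohort.

Builds a synthetic two-group cohort (resistant-like vs sensitive-like
samples constructed from the planted amplitudes), z-scores it, projects it
onto the fitted expression amplitude signature, and compares the groups
per pattern with Welch t-tests — the transfer-learning use of the
signatures on data the model never saw.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from omicspatterns import compare_groups, io_prep, project_samples

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "projection"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 27

A_fit = io_prep.read_matrix_tsv(BASE / "factorization" / "A_expression.tsv")
truth = json.loads((BASE / "simulated" / "truth.json").read_text())
A_true = pd.DataFrame(truth["A_true"]["expression"])
P_true = pd.DataFrame(truth["P_true"]["expression"])

# cohort: 15 "resistant" samples drawn near the late-treated pattern state,
# 15 "sensitive" near the control state, independent noise
rng = np.random.default_rng(SEED)
resistant_state = P_true["CTX_G11"].to_numpy()
sensitive_state = P_true["PBS_G11"].to_numpy()
cols, profiles, groups = [], [], {}
for i in range(15):
    for tag, state in (("resistant", resistant_state), ("sensitive", sensitive_state)):
        sid = f"{tag}_{i + 1:02d}"
        p = np.clip(state + rng.normal(0, 0.05, len(state)), 0, None)
        x = A_true.to_numpy() @ p
        profiles.append(np.clip(x + rng.normal(0, 0.5, len(x)), 0, None))
        cols.append(sid)
        groups[sid] = tag
cohort = pd.DataFrame(np.array(profiles).T, index=A_true.index, columns=cols)
io_prep.write_matrix_tsv(cohort, OUT / "cohort_expression.tsv")

result = project_samples(cohort, A_fit)
result.weights.to_csv(OUT / "projected_weights.tsv", sep="\t", index_label="sample_id")
tests = compare_groups(result, pd.Series(groups))
tests.to_csv(OUT / "group_tests.tsv", sep="\t")

labels = pd.read_csv(BASE / "patterns" / "labels_expression.tsv", sep="\t", index_col=0)
print(f"projected {len(cols)} cohort samples on {result.n_shared} shared genes")
for pat, row in tests.iterrows():
    lab = labels.loc[pat, "label"] if pat in labels.index else "?"
    print(f"  {pat} ({lab}): t={row['t']:+.2f} p={row['p']:.3g}")
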