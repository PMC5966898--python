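"""Projection of amplitude signatures into external expression data.

Scores new samples on previously learned patterns by regressing each
sample's expression profile on the shared-gene sub-matrix of a fixed
amplitude signature A. By default each gene row of the new data is
z-scored across samples before the regression, which makes the weights
invariant to per-gene affine rescaling (platform and unit differences are
absorbed); the recovered weights then track the training patterns up to a
per-pattern affine map, so comparisons should use correlations or group
contrasts. ``standardize=False`` regresses on the raw scale and recovers
the pattern weights of noiseless data exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .containers import OmicsMatrix


@dataclass
class ProjectionResult:
    weights: pd.DataFrame  # samples x patterns
    n_shared: int
    shared_genes: list


def collapse_probes_max_sd(values: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse multi-probe genes to the probe with the highest SD across
    samples; the output is indexed by gene."""
    sd = values.std(axis=1, ddof=0)
    df = values.copy()
    df["_gene"] = probe_to_gene.reindex(values.index)
    df["_sd"] = sd
    df = df.dropna(subset=["_gene"])
    best = df.sort_values("_sd", ascending=False).groupby("_gene", sort=True).head(1)
    out = best.drop(columns=["_sd"]).set_index("_gene")
    out.index.name = None
    return out


def project_samples(
    new_expr,
    A_signature: pd.DataFrame,
    min_shared: int = 10,
    standardize: bool = True,
    nonnegative: bool = False,
) -> ProjectionResult:
    """Ordinary-least-squares projection of samples onto pattern signatures.

    Each sample's profile over the shared genes (z-scored per gene when
    ``standardize``) is regressed on the corresponding rows of A; the
    coefficients are the sample's pattern weights (unbounded sign unless
    ``nonnegative``).
    """
    values = new_expr.values if isinstance(new_expr, OmicsMatrix) else new_expr
    shared = [g for g in A_signature.index if g in values.index]
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} genes shared with the signature (need >= {min_shared})"
        )
    X = values.loc[shared].to_numpy(float)
    A = A_signature.loc[shared].to_numpy(float)
    if standardize:
        sd = X.std(axis=1, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    if nonnegative:
        from scipy.optimize import nnls

        W = np.empty((X.shape[1], A.shape[1]))
        for j in range(X.shape[1]):
            W[j], _ = nnls(A, X[:, j])
    else:
        W, *_ = np.linalg.lstsq(A, X, rcond=None)
        W = W.T
    weights = pd.DataFrame(W, index=values.columns, columns=A_signature.columns)
    return ProjectionResult(weights=weights, n_shared=len(shared), shared_genes=shared)


def compare_groups(result: ProjectionResult, labels: pd.Series) -> pd.DataFrame:
    """Welch two-sample t-test on projected weights, per pattern.

    ``labels`` maps sample id to one of exactly two group labels. Constant
    weights give p = NaN (degenerate, reported missing).
    """
    labels = labels.reindex(result.weights.index)
    groups = labels.dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    g1 = result.weights[labels == groups[0]]
    g2 = result.weights[labels == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both groups need >= 2 samples")
    rows = []
    for pat in result.weights.columns:
        a, b = g1[pat].to_numpy(float), g2[pat].to_numpy(float)
        if np.std(a) == 0 and np.std(b) == 0:
            rows.append({"pattern": pat, "t": np.nan, "p": np.nan,
                         "mean_diff": float(a.mean() - b.mean())})
            continue
        res = ttest_ind(a, b, equal_var=False)
        rows.append({"pattern": pat, "t": float(res.statistic), "p": float(res.pvalue),
                     "mean_diff": float(a.mean() - b.mean())})
    return pd.DataFrame(rows).set_index("pattern")
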