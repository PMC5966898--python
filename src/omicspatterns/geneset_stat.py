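"""Permutation gene-set activity statistic on amplitude weights.

For a gene set S and pattern k the observed statistic is the mean amplitude
of the set's members in column k. The null distribution draws random gene
sets of the same size (without replacement) from the measured universe;
one-sided p-values use the add-one rule p = (1 + #{null >= obs}) / (n_perm + 1),
so p is never zero and a fixed seed is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection


@dataclass
class GeneSetResult:
    set_name: str
    pattern: str
    n_members: int
    statistic: float
    p_up: float
    p_down: float
    n_perm: int


def _null_means(amplitudes: np.ndarray, m: int, n_perm: int, rng) -> np.ndarray:
    n = len(amplitudes)
    # vectorized sampling without replacement: random keys, take smallest m
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    return amplitudes[idx].mean(axis=1)


def geneset_activity(
    A: pd.DataFrame,
    gene_set,
    pattern: str,
    n_perm: int = 1000,
    seed: int = 0,
    set_name: str = "set",
) -> GeneSetResult:
    """One-sided permutation test of a gene set's mean amplitude in a pattern."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    members = [g for g in gene_set if g in A.index]
    if not members:
        raise KeyError(f"gene set {set_name!r} has no members in the amplitude matrix")
    amplitudes = A[pattern].to_numpy(float)
    observed = float(A.loc[members, pattern].mean())
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, len(members)]))
    null = _null_means(amplitudes, len(members), n_perm, rng)
    # ties count toward the p-value; tolerance absorbs summation-order noise
    eps = 1e-9 * max(1.0, abs(observed))
    p_up = (1.0 + np.sum(null >= observed - eps)) / (n_perm + 1.0)
    p_down = (1.0 + np.sum(null <= observed + eps)) / (n_perm + 1.0)
    return GeneSetResult(
        set_name=set_name,
        pattern=pattern,
        n_members=len(members),
        statistic=observed,
        p_up=float(p_up),
        p_down=float(p_down),
        n_perm=n_perm,
    )


def geneset_activity_table(
    A: pd.DataFrame,
    collection: GeneSetCollection,
    patterns=None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """All sets x all patterns, with Benjamini-Hochberg q-values per pattern.

    Raw one-sided p-values are the primary output; q-values are additional,
    clearly labelled columns.
    """
    if patterns is None:
        patterns = list(A.columns)
    rows = []
    for pattern in patterns:
        for name, genes in collection.items():
            res = geneset_activity(A, genes, pattern, n_perm=n_perm, seed=seed, set_name=name)
            rows.append(res.__dict__)
    table = pd.DataFrame(rows)
    table["q_up"] = np.nan
    table["q_down"] = np.nan
    for pattern in patterns:
        mask = table["pattern"] == pattern
        for side in ("up", "down"):
            table.loc[mask, f"q_{side}"] = multipletests(
                table.loc[mask, f"p_{side}"], method="fdr_bh"
            )[1]
    return table
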