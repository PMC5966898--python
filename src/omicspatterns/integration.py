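"""Cross-platform integration: pattern correlation, timing delay, drivers.

Epigenetic drivers of the resistant phenotype are called among the
PatternMarker genes of the resistance-associated methylation patterns:
genes whose expression and methylation beta are significantly negatively
correlated across the shared time-course samples (Pearson, BH-adjusted).
An optional clone-panel validation requires a stable resistant clone in
which the gene is demethylated relative to a methylated parental line and
overexpressed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

from .containers import OmicsMatrix
from .pattern_analysis import PatternLabel

log = logging.getLogger(__name__)


def pattern_correlation(P_expr: pd.DataFrame, P_meth: pd.DataFrame, shared=None) -> pd.DataFrame:
    """Pearson correlation between expression and methylation pattern rows
    over the shared samples (NaN where a row is constant)."""
    if shared is None:
        shared = [s for s in P_expr.columns if s in set(P_meth.columns)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    out = pd.DataFrame(index=P_expr.index, columns=P_meth.index, dtype=float)
    for ke, re_ in P_expr[shared].iterrows():
        for km, rm in P_meth[shared].iterrows():
            if re_.std() == 0 or rm.std() == 0:
                out.loc[ke, km] = np.nan
            else:
                out.loc[ke, km] = pearsonr(re_, rm).statistic
    return out


def timing_delay(labels_expr: list[PatternLabel], labels_meth: list[PatternLabel]) -> pd.DataFrame:
    """Onset delay of methylation resistance patterns relative to expression.

    For every separating methylation pattern, reports its separation
    generation minus each separating expression (resistance or immediate)
    pattern's, plus ``delay_min`` relative to the earliest expression onset.
    """
    expr_sep = {
        l.pattern: l.separation_generation
        for l in labels_expr
        if l.label in ("resistance", "immediate", "repression") and l.separation_generation is not None
    }
    meth_sep = {
        l.pattern: l.separation_generation
        for l in labels_meth
        if l.separation_generation is not None
    }
    if not expr_sep or not meth_sep:
        log.warning("no separating pattern on one platform; delays missing")
        return pd.DataFrame(columns=["meth_pattern", "expr_pattern", "delay", "delay_min"])
    earliest = min(expr_sep.values())
    rows = []
    for mp, ms in meth_sep.items():
        for ep, es in expr_sep.items():
            rows.append(
                {
                    "meth_pattern": mp,
                    "expr_pattern": ep,
                    "delay": ms - es,
                    "delay_min": ms - earliest,
                }
            )
    return pd.DataFrame(rows)


def _pearson_table(expr_vals: pd.DataFrame, meth_vals: pd.DataFrame, genes, shared) -> pd.DataFrame:
    rows = []
    for gene in genes:
        x = expr_vals.loc[gene, shared].to_numpy(float)
        y = meth_vals.loc[gene, shared].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            rows.append({"gene": gene, "r": np.nan, "p": np.nan})
            continue
        res = pearsonr(x[ok], y[ok])
        rows.append({"gene": gene, "r": res.statistic, "p": res.pvalue})
    return pd.DataFrame(rows).set_index("gene")


def call_epigenetic_drivers(
    expr: OmicsMatrix,
    meth: OmicsMatrix,
    markers_meth: pd.DataFrame,
    resistance_meth_patterns,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """DriverTable: anti-correlated markers of resistance methylation patterns.

    Candidates are the PatternMarker genes of the given methylation
    patterns; per gene a Pearson correlation between expression and beta is
    computed over the shared time-course samples and a gene is called iff
    r < 0 and q < alpha. The reported p is the two-sided correlation
    p-value; q is the BH adjustment of the one-sided anti-correlation
    p-values, because the hypothesis of interest is directional (a
    two-sided BH would let the many genuinely positively correlated
    candidates relax the threshold for weak negative correlations).
    """
    shared = [s for s in expr.sample_ids if s in set(meth.sample_ids)]
    if len(shared) < 5:
        raise ValueError("need at least 5 shared samples")
    resistance_meth_patterns = list(resistance_meth_patterns)
    cand = markers_meth[markers_meth["assigned_pattern"].isin(resistance_meth_patterns)]
    candidates, skipped = [], []
    for gene in cand.index:
        if gene in expr.values.index and gene in meth.values.index:
            candidates.append(gene)
        else:
            skipped.append(gene)
    if skipped:
        log.info("%d candidate genes absent from the expression matrix; skipped", len(skipped))
    table = _pearson_table(expr.values, meth.values, candidates, shared)
    table["meth_pattern"] = cand.loc[candidates, "assigned_pattern"]
    ok = table["p"].notna()
    table["q"] = np.nan
    if ok.any():
        p_neg = np.where(
            table.loc[ok, "r"] < 0, table.loc[ok, "p"] / 2, 1 - table.loc[ok, "p"] / 2
        )
        table.loc[ok, "q"] = multipletests(p_neg, method="fdr_bh")[1]
    table["called"] = (table["r"] < 0) & (table["q"] < alpha)
    return table[["meth_pattern", "r", "p", "q", "called"]].sort_values("q")


def clone_validation(
    drivers: pd.DataFrame,
    clone_expr: OmicsMatrix,
    clone_meth: OmicsMatrix,
    parental_id: str,
    unmeth_thr: float = 0.1,
    meth_thr: float = 0.3,
    lfc_thr: float = 1.0,
) -> pd.DataFrame:
    """Fill ``clone_validated``: some clone is demethylated (beta <=
    unmeth_thr) while the parental is methylated (beta >= meth_thr), the
    clone overexpresses the gene (> lfc_thr log2 above parental), and the
    gene's expression/methylation correlation across the panel is negative."""
    if unmeth_thr >= meth_thr:
        raise ValueError("unmethylated threshold must be below methylated threshold")
    if parental_id not in clone_expr.sample_ids or parental_id not in clone_meth.sample_ids:
        raise KeyError(f"parental sample {parental_id!r} missing from clone panel")
    clones = [s for s in clone_expr.sample_ids if s != parental_id]
    out = drivers.copy()
    out["clone_validated"] = False
    panel = list(clone_expr.sample_ids)
    for gene in out.index:
        if gene not in clone_expr.values.index or gene not in clone_meth.values.index:
            continue
        e = clone_expr.values.loc[gene]
        b = clone_meth.values.loc[gene]
        if b[parental_id] < meth_thr:
            continue  # no methylation switch available to detect
        hit = ((b[clones] <= unmeth_thr) & (e[clones] - e[parental_id] > lfc_thr)).any()
        if not hit:
            continue
        x, y = e[panel].to_numpy(float), b[panel].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        out.loc[gene, "clone_validated"] = bool(pearsonr(x, y).statistic < 0)
    return out
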