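"""Input/output and preprocessing: beta values, uncertainties, and gene filters.

The factorization consumes normalized matrices. This module turns raw inputs
into analysis-ready data:

* methylation beta fractions ``beta = M / (M + U)`` and their beta-distribution
  standard deviation ``sqrt(beta (1 - beta) / (M + U + 1))``;
* the expression uncertainty rule ``max(0.1 * signal, 0.5)`` on log2 values;
* promoter-probe selection (CpG-island probe closest to the TSS, < 200 bp,
  sex-chromosome and SNP probes removed);
* the dynamic-gene filters (log fold change > 1 within an arm with replicate
  spread < 2; methylation switch beta < 0.1 to beta > 0.3) and their union.

All thresholds default to the published values and are keyword-configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    SEX_CHROMOSOMES,
    GeneSetCollection,
    OmicsMatrix,
    UncertaintyMatrix,
    validate_annotation,
    validate_sample_meta,
)

DEFAULT_COVERAGE = 100.0  # fallback total intensity when M/U are unavailable
UNMETHYLATED_BETA = 0.1
METHYLATED_BETA = 0.3
MAX_TSS_DISTANCE = 200.0
EXPRESSION_LFC = 1.0
REPLICATE_SPREAD = 2.0


# ---------------------------------------------------------------------------
# per-entry formulas
# ---------------------------------------------------------------------------

def compute_beta(M, U):
    """Methylation fraction beta = M / (M + U).

    Entries with zero total intensity are undefined and returned as NaN
    (flagged missing; downstream they receive zero weight).
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if (M < 0).any() or (U < 0).any():
        raise ValueError("intensities must be non-negative")
    total = M + U
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, M / np.where(total > 0, total, 1.0), np.nan)
    if beta.ndim == 0:
        return float(beta)
    return beta


def methylation_sd(beta, M=None, U=None, coverage: float = DEFAULT_COVERAGE):
    """Beta-distribution standard deviation of a methylation fraction.

    sigma = sqrt(beta * (1 - beta) / (M + U + 1)). When intensities are not
    available the total intensity falls back to ``coverage`` so the variance
    keeps its beta-distribution shape.
    """
    beta = np.asarray(beta, dtype=float)
    if np.nanmin(beta, initial=0.0) < 0 or np.nanmax(beta, initial=0.0) > 1:
        raise ValueError("beta values must lie in [0, 1]")
    if M is None or U is None:
        total = np.full_like(beta, float(coverage))
    else:
        total = np.asarray(M, dtype=float) + np.asarray(U, dtype=float)
    sd = np.sqrt(beta * (1.0 - beta) / (total + 1.0))
    if sd.ndim == 0:
        return float(sd)
    return sd


def expression_sd(D):
    """Expression uncertainty: 10% of the log2 signal with a floor of 0.5."""
    D = np.asarray(D, dtype=float)
    if np.nanmin(D, initial=0.0) < 0:
        raise ValueError("log-scale expression must be non-negative")
    sd = np.maximum(0.1 * D, 0.5)
    if sd.ndim == 0:
        return float(sd)
    return sd


def uncertainty_for(omics: OmicsMatrix, coverage: float = DEFAULT_COVERAGE) -> UncertaintyMatrix:
    """Model-implied per-entry standard deviations for a platform matrix."""
    if omics.platform == "expression":
        sd = expression_sd(omics.values.to_numpy(float))
    else:
        M = None if omics.M is None else omics.M.to_numpy(float)
        U = None if omics.U is None else omics.U.to_numpy(float)
        sd = methylation_sd(omics.values.to_numpy(float), M, U, coverage=coverage)
    return UncertaintyMatrix(
        sigma=pd.DataFrame(sd, index=omics.feature_ids, columns=omics.sample_ids)
    )


# ---------------------------------------------------------------------------
# probe and gene filters
# ---------------------------------------------------------------------------

def select_promoter_probes(
    meth: OmicsMatrix,
    annotation: pd.DataFrame,
    max_tss_distance: float = MAX_TSS_DISTANCE,
) -> OmicsMatrix:
    """Reduce a probe-level methylation matrix to one promoter probe per gene.

    Sex-chromosome and SNP-annotated probes are removed first; per gene the
    CpG-island probe with minimal TSS distance is kept, and genes whose kept
    probe lies >= ``max_tss_distance`` bp from the TSS are dropped. The output
    matrix is indexed by gene.
    """
    ann = validate_annotation(annotation).set_index("probe_id")
    missing = [p for p in meth.feature_ids if p not in ann.index]
    if missing:
        raise KeyError(f"probes missing from annotation: {missing[:10]}")
    ann = ann.loc[meth.feature_ids]
    ann.index.name = "probe_id"
    keep = (
        ~ann["chrom"].isin(SEX_CHROMOSOMES)
        & ~ann["snp"]
        & ann["cpg_island"]
    )
    ann = ann[keep]
    # closest-to-TSS island probe per gene; deterministic tie-break by probe id
    ann = ann.sort_values(["gene", "tss_distance"]).reset_index()
    best = ann.groupby("gene", sort=True).first()
    best = best[best["tss_distance"] < max_tss_distance]
    probes = best["probe_id"].tolist()
    sub = meth.subset_features(probes)
    rename = dict(zip(best["probe_id"], best.index))
    values = sub.values.rename(index=rename)
    return OmicsMatrix(
        values=values,
        samples=meth.samples,
        platform="methylation",
        M=None if sub.M is None else sub.M.rename(index=rename),
        U=None if sub.U is None else sub.U.rename(index=rename),
    )


def _arm_mask(meta: pd.DataFrame, arm: str) -> np.ndarray:
    # parental generation-0 samples count toward both arms' baselines
    return ((meta["arm"] == arm) | (meta["arm"] == "parental")).to_numpy()


def filter_expression_genes(
    expr: OmicsMatrix,
    lfc: float = EXPRESSION_LFC,
    replicate_spread: float = REPLICATE_SPREAD,
) -> set:
    """Dynamic-expression filter on the log2 scale.

    A gene is retained iff its max-min range over generations within the
    treated arm or within the control arm exceeds ``lfc`` AND the maximum
    pairwise difference among generation-0 replicates is below
    ``replicate_spread``.
    """
    meta = expr.samples
    rep0 = (meta["generation"] == 0).to_numpy()
    if rep0.sum() < 2:
        raise ValueError("need >= 2 generation-0 replicates for the stability clause")
    vals = expr.values.to_numpy(float)
    ranges = []
    for arm in ("treated", "control"):
        mask = _arm_mask(meta, arm)
        if mask.sum() == 0:
            raise ValueError(f"no samples in arm {arm!r}")
        sub = vals[:, mask]
        ranges.append(np.nanmax(sub, axis=1) - np.nanmin(sub, axis=1))
    dynamic = (ranges[0] > lfc) | (ranges[1] > lfc)
    reps = vals[:, rep0]
    spread = np.nanmax(reps, axis=1) - np.nanmin(reps, axis=1)
    stable = spread < replicate_spread
    keep = dynamic & stable
    return set(expr.feature_ids[keep])


def filter_methylation_genes(
    meth: OmicsMatrix,
    unmethylated: float = UNMETHYLATED_BETA,
    methylated: float = METHYLATED_BETA,
) -> set:
    """Methylation-switch filter: some sample beta < 0.1 and some beta > 0.3.

    Thresholds are strict inequalities.
    """
    vals = meth.values.to_numpy(float)
    lo = np.nanmin(vals, axis=1)
    hi = np.nanmax(vals, axis=1)
    keep = (lo < unmethylated) & (hi > methylated)
    return set(meth.feature_ids[keep])


def union_filter(expr_set: set, meth_set: set, expr_features, meth_features):
    """Per-platform analysis sets: the union of both filters intersected with
    each platform's measured feature universe."""
    union = set(expr_set) | set(meth_set)
    expr_analysis = union & set(expr_features)
    meth_analysis = union & set(meth_features)
    return expr_analysis, meth_analysis


# ---------------------------------------------------------------------------
# file formats (tab-separated matrices/metadata, GMT gene sets)
# ---------------------------------------------------------------------------

def write_matrix_tsv(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="feature_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate feature ids {dups[:10]}")
    return df


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    return validate_sample_meta(meta)


def read_annotation_tsv(path) -> pd.DataFrame:
    return validate_annotation(pd.read_csv(path, sep="\t"))


def write_annotation_tsv(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT rows need name, description and >=1 gene"
                )
            name, desc, *genes = parts
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
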