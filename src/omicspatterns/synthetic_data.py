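"""Synthetic two-arm time-course generator with planted pattern structure.

Emulates the study design the pipeline targets: a parental cell line
(generation 0, replicated) and two arms — drug-treated and vehicle control —
passaged through generations 1..G, profiled on both gene expression (log2)
and DNA methylation (beta fractions with intensity channels).

Planted structure:

* expression patterns: an *immediate* therapeutic-response step at
  generation 1, a sigmoidal *resistance* pattern switching on at the
  resistance onset generation, a gradual *repression* ramp from onset, a
  *technical* parental-vs-passaged contrast, and a *flat* highly-expressed
  signature;
* methylation patterns: a *control-drift* ramp rising in both arms, and
  rapid *demethylation* / *hypermethylation* switches in the treated arm at
  the (later) methylation onset generation;
* *driver* genes: hypermethylated at baseline, following the demethylation
  archetype in methylation while their expression follows the resistance
  archetype — anti-correlated by construction.

Expression noise is Gaussian with the model-implied heteroscedastic scale
``max(0.1 * signal, 0.5)``; methylation noise is beta-distributed with a
Poisson total intensity, so the beta-variance formula used downstream is the
exact noise model of the generated data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OmicsMatrix

EXPRESSION_ARCHETYPES = ("immediate", "resistance", "repression", "technical", "flat")
METHYLATION_ARCHETYPES = ("control-drift", "demethylation", "hypermethylation")

_BASELINE = 0.1  # inactive pattern weight (relative units, pattern rows max 1)


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic time course."""

    n_genes: int = 2000
    n_generations: int = 11
    n_parental_replicates: int = 3
    p_expr: int = 5
    p_meth: int = 3
    onset_generation: int = 4
    meth_onset_generation: int = 5
    noise_scale: float = 1.0
    coverage: float = 100.0
    n_drivers: int = 20
    marker_sparsity: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite config value {name}={value}")
        if not (1 <= self.onset_generation <= self.meth_onset_generation <= self.n_generations):
            raise ValueError("need onset <= meth_onset <= n_generations")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.n_drivers > self.n_genes:
            raise ValueError("n_drivers cannot exceed n_genes")
        if not (0 <= self.marker_sparsity <= 1):
            raise ValueError("marker_sparsity must be in [0, 1]")
        if not (1 <= self.p_expr <= len(EXPRESSION_ARCHETYPES)):
            raise ValueError(f"p_expr must be in 1..{len(EXPRESSION_ARCHETYPES)}")
        if not (1 <= self.p_meth <= len(METHYLATION_ARCHETYPES)):
            raise ValueError(f"p_meth must be in 1..{len(METHYLATION_ARCHETYPES)}")


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the generator."""

    A_true: dict[str, pd.DataFrame]
    P_true: dict[str, pd.DataFrame]
    pattern_labels: dict[str, list[str]]
    separation_generation: dict[str, dict[str, int | None]]
    driver_genes: list[str]
    filter_genes: dict[str, set] = field(default_factory=dict)
    dominant_pattern: dict[str, pd.Series] = field(default_factory=dict)
    #: platform -> {archetype: genes loading on that archetype alone}
    marker_genes: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "pattern_labels": self.pattern_labels,
            "separation_generation": self.separation_generation,
            "driver_genes": self.driver_genes,
            "filter_genes": {k: sorted(v) for k, v in self.filter_genes.items()},
            "A_true": {k: v.to_dict() for k, v in self.A_true.items()},
            "P_true": {k: v.to_dict() for k, v in self.P_true.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# design and pattern rows
# ---------------------------------------------------------------------------

def make_sample_meta(config: SimConfig) -> pd.DataFrame:
    """Sample table: parental replicates at generation 0 plus both arms 1..G."""
    rows = []
    for r in range(config.n_parental_replicates):
        rows.append((f"PAR_R{r + 1}", "parental", 0, f"R{r + 1}"))
    for g in range(1, config.n_generations + 1):
        rows.append((f"CTX_G{g}", "treated", g, "R1"))
    for g in range(1, config.n_generations + 1):
        rows.append((f"PBS_G{g}", "control", g, "R1"))
    meta = pd.DataFrame(rows, columns=["sample_id", "arm", "generation", "replicate"])
    return meta.set_index("sample_id")


def _clipped_logistic(g: np.ndarray, onset: float, width: float) -> np.ndarray:
    """Logistic rise that is exactly zero before ``onset - 1`` generations.

    The raw logistic is shifted and rescaled so its value one generation
    before onset is 0 — the arms are identical before onset by construction.
    """
    raw = 1.0 / (1.0 + np.exp(-(g - onset) / width))
    floor = 1.0 / (1.0 + np.exp(1.0 / width))  # value at onset - 1
    return np.clip((raw - floor) / (1.0 - floor), 0.0, 1.0)


def archetype_row(name: str, meta: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Pattern weight across samples for one planted archetype (max 1)."""
    arm = meta["arm"].to_numpy()
    g = meta["generation"].to_numpy(float)
    G = float(config.n_generations)
    treated = arm == "treated"
    lo = _BASELINE
    row = np.full(len(meta), lo)
    if name == "immediate":
        row[treated] = 1.0
    elif name == "resistance":
        rise = _clipped_logistic(g, config.onset_generation, width=1.0)
        row[treated] = lo + (1.0 - lo) * rise[treated]
    elif name == "repression":
        row = np.full(len(meta), 1.0)
        ramp = np.clip((g - config.onset_generation + 1) / (G - config.onset_generation + 1), 0, 1)
        row[treated] = 1.0 - 0.8 * ramp[treated]
    elif name == "technical":
        row[arm == "parental"] = 1.0
    elif name == "flat":
        row = np.full(len(meta), 1.0)
    elif name == "control-drift":
        row = lo + (1.0 - lo) * g / G
    elif name == "demethylation":
        drop = _clipped_logistic(g, config.meth_onset_generation, width=0.5)
        row = np.full(len(meta), 1.0)
        row[treated] = 1.0 - (1.0 - lo) * drop[treated]
    elif name == "hypermethylation":
        rise = _clipped_logistic(g, config.meth_onset_generation, width=0.5)
        row[treated] = lo + (1.0 - lo) * rise[treated]
    else:
        raise ValueError(f"unknown archetype {name!r}")
    return row


def _truth_separations(config: SimConfig) -> dict[str, dict[str, int | None]]:
    return {
        "expression": {
            "immediate": 1,
            "resistance": config.onset_generation,
            "repression": config.onset_generation,
            "technical": None,
            "flat": None,
        },
        "methylation": {
            "control-drift": None,
            "demethylation": config.meth_onset_generation,
            "hypermethylation": config.meth_onset_generation,
        },
    }


# ---------------------------------------------------------------------------
# amplitude assignment
# ---------------------------------------------------------------------------

# expression archetypes a gene may carry given its methylation archetype,
# chosen so that only planted drivers are expression/methylation
# anti-correlated (demethylation pairs only with falling-or-flat expression,
# hypermethylation with rising-or-flat expression; technical expression is
# excluded for hypermethylation because its parental spike anti-correlates
# with a late-treated methylation rise).
_COMPATIBLE_EXPR = {
    "control-drift": ("immediate", "repression", "technical", "flat"),
    "demethylation": ("repression", "technical", "flat"),
    "hypermethylation": ("immediate", "resistance", "flat"),
}


def _amplitude_rows(
    genes: list[str],
    labels: list[str],
    assignment: dict[str, list[str]],
    loads: dict[str, float],
    rng: np.random.Generator,
    prefix: str,
) -> pd.DataFrame:
    """Amplitude matrix from per-gene pattern assignments.

    A gene assigned one pattern gets its whole loading there (marker gene);
    a gene assigned several gets Dirichlet-split loadings (mixed gene).
    """
    p = len(labels)
    A = np.zeros((len(genes), p))
    label_pos = {lab: k for k, lab in enumerate(labels)}
    for i, gene in enumerate(genes):
        pats = assignment[gene]
        load = loads[gene]
        if len(pats) == 1:
            A[i, label_pos[pats[0]]] = load
        else:
            w = rng.dirichlet(np.ones(len(pats)))
            for lab, wk in zip(pats, w):
                A[i, label_pos[lab]] = load * wk
    return pd.DataFrame(A, index=genes, columns=[f"{prefix}{k + 1}" for k in range(p)])


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def _sample_beta_noise(
    mu: np.ndarray, config: SimConfig, rng: np.random.Generator
):
    """Beta-distributed noise around mu with Poisson total intensity.

    Returns (beta, M, U). ``noise_scale`` rescales the effective
    pseudo-count so the standard deviation scales linearly with it;
    noise_scale 0 returns mu exactly.
    """
    total = rng.poisson(config.coverage, size=mu.shape).astype(float)
    total = np.maximum(total, 2.0)
    if config.noise_scale == 0:
        beta = mu.copy()
    else:
        nu = np.maximum(total / config.noise_scale**2, 1e-3)
        beta = rng.beta(np.maximum(mu * nu, 1e-8), np.maximum((1 - mu) * nu, 1e-8))
    M = beta * total
    U = (1.0 - beta) * total
    return beta, M, U


def _noiseless_filter_truth(
    expr_vals: np.ndarray,
    meth_vals: np.ndarray,
    genes: list[str],
    meta: pd.DataFrame,
) -> dict[str, set]:
    """Which genes the dynamic filters retain on the noiseless matrices.

    Inline re-derivation (range > 1 within an arm incl. the shared parental
    baseline; beta switch 0.1 -> 0.3) kept independent of the filter code so
    tests can compare the two routes.
    """
    arm = meta["arm"].to_numpy()
    out: dict[str, set] = {}
    keep_expr = np.zeros(len(genes), bool)
    for a in ("treated", "control"):
        mask = (arm == a) | (arm == "parental")
        sub = expr_vals[:, mask]
        keep_expr |= (sub.max(axis=1) - sub.min(axis=1)) > 1.0
    out["expression"] = {g for g, k in zip(genes, keep_expr) if k}
    keep_meth = (meth_vals.min(axis=1) < 0.1) & (meth_vals.max(axis=1) > 0.3)
    out["methylation"] = {g for g, k in zip(genes, keep_meth) if k}
    return out


def generate_time_course(config: SimConfig):
    """Generate expression + methylation time courses with planted truth.

    Returns ``(expression, methylation, annotation, truth)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    meta = make_sample_meta(config)
    genes = [f"gene_{i + 1:05d}" for i in range(config.n_genes)]

    expr_labels = list(EXPRESSION_ARCHETYPES[: config.p_expr])
    meth_labels = list(METHYLATION_ARCHETYPES[: config.p_meth])

    P_expr = pd.DataFrame(
        [archetype_row(lab, meta, config) for lab in expr_labels],
        index=[f"EP{k + 1}" for k in range(len(expr_labels))],
        columns=meta.index,
    )
    P_meth = pd.DataFrame(
        [archetype_row(lab, meta, config) for lab in meth_labels],
        index=[f"MP{k + 1}" for k in range(len(meth_labels))],
        columns=meta.index,
    )

    # choose drivers, then per-gene archetypes under the compatibility rule
    # that keeps expression/methylation anti-correlation exclusive to drivers;
    # mixed (multi-pattern) genes also draw only from the compatible lists
    driver_genes = [str(g) for g in rng.choice(genes, size=config.n_drivers, replace=False)]
    driver_set = set(driver_genes)
    assign_expr: dict[str, list[str]] = {}
    assign_meth: dict[str, list[str]] = {}
    loads_expr: dict[str, float] = {}
    loads_meth: dict[str, float] = {}
    for gene in genes:
        if gene in driver_set:
            assign_meth[gene] = ["demethylation" if "demethylation" in meth_labels else meth_labels[0]]
            assign_expr[gene] = ["resistance" if "resistance" in expr_labels else expr_labels[0]]
            # strong loadings so driver dynamic range is unambiguous
            loads_expr[gene] = rng.exponential(scale=2.0) + 3.0
            loads_meth[gene] = rng.uniform(0.85, 0.95)
            continue
        m_lab = meth_labels[rng.integers(len(meth_labels))]
        compatible = [e for e in _COMPATIBLE_EXPR.get(m_lab, expr_labels) if e in expr_labels]
        if not compatible:
            compatible = ["flat"] if "flat" in expr_labels else expr_labels[:1]
        if rng.random() < config.marker_sparsity or len(compatible) < 2:
            assign_expr[gene] = [compatible[rng.integers(len(compatible))]]
        else:
            picked = rng.choice(len(compatible), size=2, replace=False)
            assign_expr[gene] = [compatible[k] for k in picked]
        assign_meth[gene] = [m_lab]
        loads_expr[gene] = rng.exponential(scale=3.0) + 1.5
        loads_meth[gene] = rng.uniform(0.8, 0.95)

    A_expr = _amplitude_rows(genes, expr_labels, assign_expr, loads_expr, rng, "EP")
    A_meth = _amplitude_rows(genes, meth_labels, assign_meth, loads_meth, rng, "MP")
    dom_expr = pd.Series({g: assign_expr[g][0] for g in genes}, index=genes)
    dom_meth = pd.Series({g: assign_meth[g][0] for g in genes}, index=genes)
    marker_genes = {
        "expression": {
            lab: [g for g in genes if assign_expr[g] == [lab]] for lab in expr_labels
        },
        "methylation": {
            lab: [g for g in genes if assign_meth[g] == [lab]] for lab in meth_labels
        },
    }

    expr_clean = A_expr.to_numpy() @ P_expr.to_numpy()
    meth_mu = np.clip(A_meth.to_numpy() @ P_meth.to_numpy(), 0.01, 0.99)

    if config.noise_scale == 0:
        expr_vals = expr_clean.copy()
    else:
        sigma = np.maximum(0.1 * expr_clean, 0.5) * config.noise_scale
        expr_vals = np.clip(expr_clean + rng.normal(0.0, 1.0, expr_clean.shape) * sigma, 0.0, None)
    beta, Mch, Uch = _sample_beta_noise(meth_mu, config, rng)

    expression = OmicsMatrix(
        values=pd.DataFrame(expr_vals, index=genes, columns=meta.index),
        samples=meta,
        platform="expression",
    )
    probes = [f"cg{i + 1:07d}" for i in range(config.n_genes)]
    methylation = OmicsMatrix(
        values=pd.DataFrame(beta, index=probes, columns=meta.index),
        samples=meta,
        platform="methylation",
        M=pd.DataFrame(Mch, index=probes, columns=meta.index),
        U=pd.DataFrame(Uch, index=probes, columns=meta.index),
    )
    annotation = pd.DataFrame(
        {
            "probe_id": probes,
            "gene": genes,
            "chrom": [f"chr{1 + i % 22}" for i in range(config.n_genes)],
            "tss_distance": rng.integers(0, 200, size=config.n_genes),
            "cpg_island": True,
            "snp": False,
        }
    )

    truth = SyntheticTruth(
        A_true={"expression": A_expr, "methylation": A_meth},
        P_true={"expression": P_expr, "methylation": P_meth},
        pattern_labels={"expression": expr_labels, "methylation": meth_labels},
        separation_generation={
            "expression": {k: v for k, v in _truth_separations(config)["expression"].items() if k in expr_labels},
            "methylation": {k: v for k, v in _truth_separations(config)["methylation"].items() if k in meth_labels},
        },
        driver_genes=driver_genes,
        filter_genes=_noiseless_filter_truth(expr_clean, meth_mu, genes, meta),
        dominant_pattern={"expression": dom_expr, "methylation": dom_meth},
        marker_genes=marker_genes,
    )
    return expression, methylation, annotation, truth


# ---------------------------------------------------------------------------
# probe annotation generator (exercises the promoter-probe filters)
# ---------------------------------------------------------------------------

def generate_probe_annotation(
    n_genes: int,
    frac_sex: float = 0.0,
    frac_snp: float = 0.0,
    frac_far_tss: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Annotation table with 1-3 candidate probes per gene and exact flagged
    fractions: ``frac_sex`` of genes carry a sex-chromosome probe,
    ``frac_snp`` a SNP-flagged probe, and ``frac_far_tss`` of genes have
    their nearest island probe >= 200 bp from the TSS."""
    for f in (frac_sex, frac_snp, frac_far_tss):
        if not 0 <= f <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    if frac_sex + frac_snp + frac_far_tss > 1:
        raise ValueError("flagged fractions must sum to <= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    genes = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    n_sex = round(frac_sex * n_genes)
    n_snp = round(frac_snp * n_genes)
    n_far = round(frac_far_tss * n_genes)
    order = rng.permutation(n_genes)
    sex_genes = set(order[:n_sex])
    snp_genes = set(order[n_sex : n_sex + n_snp])
    far_genes = set(order[n_sex + n_snp : n_sex + n_snp + n_far])
    rows = []
    probe_no = 0
    for i, gene in enumerate(genes):
        n_probes = int(rng.integers(1, 4))
        near = int(rng.integers(0, 200))
        for j in range(n_probes):
            probe_no += 1
            dist = near if j == 0 else int(rng.integers(0, 5000))
            if i in far_genes:
                dist = int(rng.integers(200, 5000))
            rows.append(
                {
                    "probe_id": f"cg{probe_no:07d}",
                    "gene": gene,
                    "chrom": "chrX" if (i in sex_genes and j == 0) else f"chr{1 + i % 22}",
                    "tss_distance": dist,
                    "cpg_island": True,
                    "snp": bool(i in snp_genes and j == 0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clone panel
# ---------------------------------------------------------------------------

def generate_clone_panel(config: SimConfig, n_clones: int = 10):
    """Parental profile plus stable single-cell clone profiles.

    Exactly one designated clone (the first) has every planted driver gene
    demethylated (beta <= 0.05) and overexpressed (log2 difference +2.5 vs
    parental); the other clones draw heterogeneous profiles uncorrelated
    with the time-course resistance signature.
    """
    if n_clones < 2:
        raise ValueError("need n_clones >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    expression, methylation, annotation, truth = generate_time_course(
        SimConfig(**{**asdict(config), "noise_scale": 0.0})
    )
    genes = list(expression.feature_ids)
    par_col = expression.samples.index[expression.samples["arm"] == "parental"][0]
    expr_base = expression.values[par_col].to_numpy()
    probes = list(methylation.feature_ids)
    meth_base = methylation.values[par_col].to_numpy()
    # baseline for drivers: hypermethylated, low expression
    driver_idx = [genes.index(g) for g in truth.driver_genes]
    meth_base = meth_base.copy()
    meth_base[driver_idx] = 0.8
    expr_base = expr_base.copy()

    cols = ["parental"] + [f"clone_{i + 1:02d}" for i in range(n_clones)]
    E = np.tile(expr_base[:, None], (1, len(cols)))
    B = np.tile(meth_base[:, None], (1, len(cols)))
    noise = config.noise_scale
    for c in range(1, len(cols)):
        E[:, c] = np.clip(expr_base + rng.normal(0, 0.5 + 0.5 * noise, len(genes)), 0, None)
        jitter = rng.normal(0, 0.03 * (1 + noise), len(probes))
        B[:, c] = np.clip(meth_base + jitter, 0.0, 1.0)
    designated = 1  # clone_01
    for gi in driver_idx:
        B[gi, designated] = 0.05
        E[gi, designated] = expr_base[gi] + 2.5
    meta = pd.DataFrame(
        {
            "arm": ["parental"] + ["treated"] * n_clones,
            "generation": [0] + [1] * n_clones,
            "replicate": cols,
        },
        index=pd.Index(cols, name="sample_id"),
    )
    clone_expr = OmicsMatrix(
        values=pd.DataFrame(E, index=genes, columns=cols), samples=meta, platform="expression"
    )
    gene_index = dict(zip(probes, genes))
    clone_meth = OmicsMatrix(
        values=pd.DataFrame(B, index=probes, columns=cols).rename(index=gene_index),
        samples=meta,
        platform="methylation",
    )
    panel_truth = {
        "designated_clone": cols[designated],
        "driver_genes": truth.driver_genes,
        "parental": "parental",
    }
    return clone_expr, clone_meth, panel_truth


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------

def write_dataset(outdir, expression, methylation, annotation, truth) -> None:
    """Write a generated dataset as tab-separated text plus a truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    expression.values.to_csv(out / "expression.tsv", sep="\t", index_label="feature_id")
    methylation.values.to_csv(out / "methylation_beta.tsv", sep="\t", index_label="feature_id")
    if methylation.M is not None:
        methylation.M.to_csv(out / "methylation_M.tsv", sep="\t", index_label="feature_id")
        methylation.U.to_csv(out / "methylation_U.tsv", sep="\t", index_label="feature_id")
    expression.samples.to_csv(out / "samples.tsv", sep="\t", index_label="sample_id")
    annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
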