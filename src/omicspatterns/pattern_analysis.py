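"""Pattern interpretation: marker genes, biological labels, onset timing.

* :func:`pattern_markers` — the PatternMarker statistic: each gene's
  amplitude row (over non-excluded patterns) is scaled to unit maximum and
  its Euclidean distance to each unit basis vector computed; the gene is a
  marker of the nearest pattern, ranked by that distance.
* :func:`separation_generation` — first generation at which treated and
  control arm weights diverge persistently (difference beyond ``c`` noise
  SDs with constant sign through the end of the course).
* :func:`classify_patterns` — labels each pattern as immediate response,
  acquired resistance, repression, technical (parental contrast),
  control drift, flat, or unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .factorization import Factorization

PATTERN_LABELS = (
    "immediate", "resistance", "repression", "technical", "flat",
    "control-drift", "unclassified",
)


@dataclass
class PatternLabel:
    pattern: str
    label: str
    separation_generation: int | None
    direction: int  # sign of treated - control after separation (0 if none)


def pattern_markers(A: pd.DataFrame, exclude=()) -> pd.DataFrame:
    """PatternMarker table: gene, assigned pattern, statistic, rank.

    ``exclude`` names patterns (e.g. a flat highly-expressed signature)
    removed before scaling; ties in the distance statistic break to the
    lowest pattern index. Genes whose row is all zero over the kept patterns
    are reported with assigned_pattern NA and no rank.
    """
    if (A.to_numpy(float) < 0).any():
        raise ValueError("amplitude matrix must be non-negative")
    bad = [e for e in exclude if e not in A.columns]
    if bad:
        raise KeyError(f"excluded patterns not in amplitude matrix: {bad}")
    kept = [c for c in A.columns if c not in set(exclude)]
    if not kept:
        raise ValueError("all patterns excluded")
    X = A[kept].to_numpy(float)
    rowmax = X.max(axis=1)
    nz = rowmax > 0
    scaled = np.zeros_like(X)
    scaled[nz] = X[nz] / rowmax[nz, None]
    k = len(kept)
    # distance from scaled row to each unit basis vector e_j
    sq = (scaled**2).sum(axis=1)
    dist = np.sqrt(np.maximum(sq[:, None] - 2 * scaled + 1.0, 0.0))
    assigned_idx = np.argmin(dist, axis=1)  # argmin breaks ties to lowest index
    stat = dist[np.arange(len(A)), assigned_idx]
    table = pd.DataFrame(
        {
            "gene": A.index,
            "assigned_pattern": [kept[j] if ok else pd.NA for j, ok in zip(assigned_idx, nz)],
            "statistic": np.where(nz, stat, np.nan),
        }
    ).set_index("gene")
    table["rank"] = pd.NA
    for pat in kept:
        mask = table["assigned_pattern"] == pat
        order = table.loc[mask, "statistic"].rank(method="first").astype(int)
        table.loc[mask, "rank"] = order
    return table


def marker_heatmap_order(markers: pd.DataFrame, patterns=None) -> list:
    """Gene order for a marker heatmap: grouped by pattern, ranked within."""
    tab = markers.dropna(subset=["assigned_pattern"])
    if patterns is None:
        patterns = list(dict.fromkeys(tab["assigned_pattern"]))
    order = []
    for pat in patterns:
        sub = tab[tab["assigned_pattern"] == pat].sort_values("rank")
        order.extend(sub.index.tolist())
    return order


def marker_average_pattern(values: pd.DataFrame, genes) -> pd.Series:
    """Empirical pattern trajectory: mean of max-normalized marker-gene rows.

    For genes dominated by a single pattern, each row is proportional to
    that pattern's trajectory plus noise, so the average of the rows scaled
    to unit maximum is a cheap data-driven estimate of the pattern row.
    """
    genes = [g for g in genes if g in values.index]
    if not genes:
        raise KeyError("no marker genes present in the matrix")
    X = values.loc[genes].to_numpy(float)
    rowmax = X.max(axis=1, keepdims=True)
    rowmax[rowmax == 0] = 1.0
    return pd.Series((X / rowmax).mean(axis=0), index=values.columns)


def _arm_trajectories(pattern_row: pd.Series, meta: pd.DataFrame):
    """Mean pattern weight per (arm, generation); parental values separately."""
    vals = pattern_row.to_numpy(float)
    arm = meta["arm"].to_numpy()
    gen = meta["generation"].to_numpy(int)
    gens = sorted(set(gen[arm != "parental"]))
    traj = {}
    for a in ("treated", "control"):
        if not (arm == a).any():
            raise ValueError(f"no samples in arm {a!r}")
        traj[a] = np.array([vals[(arm == a) & (gen == g)].mean() for g in gens])
    parental = vals[arm == "parental"]
    return np.array(gens), traj["treated"], traj["control"], parental


def separation_generation(
    pattern_row: pd.Series,
    meta: pd.DataFrame,
    c: float = 2.0,
    min_effect: float = 0.05,
):
    """Smallest generation g from which the arms stay apart.

    Requires, for every g' >= g, a constant sign of treated-control and
    |difference| above both ``c * s`` and ``min_effect`` times the pattern's
    overall magnitude, where s is the SD of the pre-g differences (parental
    replicate spread when fewer than two earlier generations exist). The
    relative floor guards against the small persistent cross-arm bias a
    fitted pattern inherits from imperfectly separated co-patterns, which
    would otherwise count as divergence from generation 1. Returns None
    when no such generation exists.
    """
    gens, treated, control, parental = _arm_trajectories(pattern_row, meta)
    d = treated - control
    scale = float(np.max(np.abs(pattern_row.to_numpy(float)))) or 1.0
    parental_sd = float(np.std(parental)) if len(parental) else 0.0
    for gi, g in enumerate(gens):
        prior = d[:gi]
        s = float(np.std(prior)) if len(prior) >= 2 else parental_sd
        thr = max(c * s, min_effect * scale)
        tail = d[gi:]
        if (np.abs(tail) > thr).all() and len(set(np.sign(tail))) == 1:
            return int(g)
    return None


def classify_patterns(
    F: Factorization | pd.DataFrame,
    meta: pd.DataFrame,
    c: float = 2.0,
    cv_min: float = 0.1,
    spearman_min: float = 0.8,
    min_effect: float = 0.05,
) -> list[PatternLabel]:
    """Assign a biological label to every pattern row.

    Order of rules: flat (coefficient of variation < ``cv_min``); separating
    patterns become immediate (separation at generation 1) or
    resistance/repression (later separation, by direction); non-separating
    patterns become control-drift when both arms trend monotonically over
    the generations, technical when the parental-vs-rest contrast dominates;
    else unclassified. Control drift is tested before the technical contrast
    because a shared monotone ramp necessarily makes the generation-0
    parental samples extreme, which would otherwise masquerade as a
    parental batch effect.
    """
    P = F.P if isinstance(F, Factorization) else F
    labels = []
    for pat, row in P.iterrows():
        vals = row.to_numpy(float)
        mean = vals.mean()
        cv = vals.std() / mean if mean > 0 else 0.0
        if cv < cv_min:
            labels.append(PatternLabel(pat, "flat", None, 0))
            continue
        gens, treated, control, parental = _arm_trajectories(row, meta)
        scale = float(np.max(np.abs(vals))) or 1.0
        max_d = float(np.max(np.abs(treated - control)))
        # shared monotone ramp in both arms with no appreciable arm split
        if len(gens) >= 3 and max_d < 2.0 * min_effect * scale:
            rho_t = spearmanr(gens, treated).statistic
            rho_c = spearmanr(gens, control).statistic
            if (
                np.isfinite(rho_t) and np.isfinite(rho_c)
                and abs(rho_t) > spearman_min and abs(rho_c) > spearman_min
                and np.sign(rho_t) == np.sign(rho_c)
            ):
                labels.append(PatternLabel(pat, "control-drift", None, 0))
                continue
        # parental batch contrast dominating any residual arm separation
        rest = np.concatenate([treated, control])
        pooled = np.sqrt((np.var(parental) + np.var(rest)) / 2.0)
        contrast = abs(parental.mean() - rest.mean()) if len(parental) else 0.0
        if len(parental) and contrast > 2.0 * pooled and contrast > 2.0 * max_d:
            labels.append(PatternLabel(pat, "technical", None, 0))
            continue
        sep = separation_generation(row, meta, c=c, min_effect=min_effect)
        if sep is not None:
            direction = int(np.sign((treated - control)[gens >= sep].mean()))
            if sep == 1:
                labels.append(PatternLabel(pat, "immediate", 1, direction))
            else:
                lab = "resistance" if direction > 0 else "repression"
                labels.append(PatternLabel(pat, lab, sep, direction))
            continue
        labels.append(PatternLabel(pat, "unclassified", None, 0))
    return labels


def labels_table(labels: list[PatternLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pattern": [l.pattern for l in labels],
            "label": [l.label for l in labels],
            "separation_generation": [l.separation_generation for l in labels],
            "direction": [l.direction for l in labels],
        }
    ).set_index("pattern")
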