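"""Heteroscedastic non-negative matrix factorization D ~ A P.

The model is D_ij ~ Normal((A P)_ij, Sigma_ij) with A, P entrywise
non-negative: each row of P is a pattern (a trajectory across samples,
scaled to maximum 1) and each column of A holds the gene weights for that
pattern. The fit minimizes the weighted residual

    chi2 = sum_ij ((D - A P)_ij / Sigma_ij)^2  (+ optional L1 penalty on A)

by multiplicative block updates followed by exact per-row non-negative
least-squares polish, with multiple random restarts. Dimensionality is
chosen by a cross-restart pattern-reproducibility sweep, and a parallel-set
consensus mode refits patterns on random feature subsets and averages the
matched rows (genome-wide consensus fitting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.cluster import KMeans

from .containers import OmicsMatrix, UncertaintyMatrix

_EPS = 1e-12


@dataclass
class Factorization:
    """Result of a non-negative factorization fit."""

    A: pd.DataFrame  # features x p
    P: pd.DataFrame  # p x samples
    p: int
    chi2: float
    n_restarts: int
    seed: int
    converged: bool = True
    objective_trace: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def reconstruct(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.A.to_numpy() @ self.P.to_numpy(),
            index=self.A.index,
            columns=self.P.columns,
        )


@dataclass
class RobustnessSweep:
    """Cross-restart pattern reproducibility per candidate dimensionality.

    ``similarity`` holds the mean matched-pattern similarity across restart
    pairs; ``min_similarity`` the mean of each pair's worst-matched pattern,
    which is what dimensionality selection uses (one irreproducible pattern
    disqualifies a dimensionality even when the rest reproduce perfectly).
    """

    similarity: dict[int, float | None]
    min_similarity: dict[int, float | None]
    chi2: dict[int, list[float]]


def _as_arrays(D, sigma):
    if isinstance(D, OmicsMatrix):
        index, columns = D.feature_ids, D.sample_ids
        Dv = D.values.to_numpy(float)
    else:
        index, columns = D.index, D.columns
        Dv = D.to_numpy(float)
    Sv = sigma.sigma.to_numpy(float) if isinstance(sigma, UncertaintyMatrix) else np.asarray(sigma, float)
    if Sv.shape != Dv.shape:
        raise ValueError("uncertainty shape does not match data shape")
    # missing entries (NaN data or infinite/zero-weight sigma) get weight 0
    W = np.zeros_like(Dv)
    ok = np.isfinite(Dv) & np.isfinite(Sv) & (Sv > 0)
    W[ok] = 1.0 / Sv[ok] ** 2
    Dv = np.where(np.isfinite(Dv), Dv, 0.0)
    return Dv, W, index, columns


def _objective(D, W, A, P, sparsity):
    R = D - A @ P
    return float(np.sum(W * R * R) + sparsity * np.sum(A))


def _svd_init(D, p, rng):
    """Truncated-SVD based non-negative initialization (NNDSVD-style clip)."""
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    k = min(p, len(s))
    A0 = np.abs(U[:, :k] * np.sqrt(s[:k]))
    P0 = np.abs(np.sqrt(s[:k])[:, None] * Vt[:k])
    if k < p:
        scale = max(D.mean(), _EPS)
        A0 = np.hstack([A0, rng.uniform(0, np.sqrt(scale), (D.shape[0], p - k))])
        P0 = np.vstack([P0, rng.uniform(0, np.sqrt(scale), (p - k, D.shape[1]))])
    return np.maximum(A0, _EPS), np.maximum(P0, _EPS)


def _random_init(D, p, rng):
    scale = np.sqrt(max(np.mean(D), _EPS) / p)
    A0 = rng.uniform(0.1, 1.0, (D.shape[0], p)) * scale
    P0 = rng.uniform(0.1, 1.0, (p, D.shape[1])) * scale
    return A0, P0


def _cluster_init(D, W, p, rng, n_init=10):
    """Marker-structure (separability) initialization.

    Rows of genes dominated by one pattern are proportional to that
    pattern's trajectory, so k-means centroids of the unit-normalized rows
    seed P near the archetypes; A follows by weighted NNLS. This anchors
    the factorization to the marker-respecting basin, which generic
    initializations miss (rotated bases can reach equal or lower chi2
    without being interpretable).
    """
    norms = np.linalg.norm(D, axis=1)
    keep = norms > 0
    X = D[keep] / norms[keep, None]
    k = min(p, X.shape[0])
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(rng.integers(2**31)))
    km.fit(X)
    P0 = np.maximum(km.cluster_centers_, _EPS)
    if k < p:
        P0 = np.vstack([P0, rng.uniform(_EPS, 1.0, (p - k, D.shape[1]))])
    A0 = np.maximum(_nnls_rows(P0, D, W), _EPS)
    return A0, P0


def _mu_iterations(D, W, A, P, sparsity, max_iter, tol, check_every=10):
    """Weighted multiplicative updates; monotone for the weighted Frobenius
    objective (+L1 on A). Returns A, P, trace, converged."""
    WD = W * D
    trace = [_objective(D, W, A, P, sparsity)]
    converged = False
    for it in range(1, max_iter + 1):
        AP = A @ P
        A *= (WD @ P.T) / ((W * AP) @ P.T + sparsity + _EPS)
        AP = A @ P
        P *= (A.T @ WD) / (A.T @ (W * AP) + _EPS)
        if it % check_every == 0 or it == max_iter:
            obj = _objective(D, W, A, P, sparsity)
            prev = trace[-1]
            trace.append(obj)
            if abs(prev - obj) <= tol * max(abs(prev), _EPS):
                converged = True
                break
    return A, P, trace, converged


def _nnls_rows(X, Y, W):
    """Row-wise weighted NNLS: for each row i solve
    min_{b>=0} || sqrt(W_i) * (Y_i - b X) ||^2 (X is p x m)."""
    out = np.empty((Y.shape[0], X.shape[0]))
    Xt = X.T  # m x p
    for i in range(Y.shape[0]):
        w = np.sqrt(W[i])
        out[i], _ = nnls(Xt * w[:, None], Y[i] * w)
    return out


def _nnls_polish(D, W, A, P, n_passes, tol=1e-6):
    """Exact alternating block NNLS passes (unpenalized objective).

    Returns (A, P, converged) where converged means the last pass changed
    the objective by less than ``tol`` relatively.
    """
    prev = _objective(D, W, A, P, 0.0)
    converged = False
    for _ in range(n_passes):
        A = _nnls_rows(P, D, W)
        P = _nnls_rows(A.T, D.T, W.T).T
        obj = _objective(D, W, A, P, 0.0)
        if abs(prev - obj) <= tol * max(prev, _EPS):
            converged = True
            break
        prev = obj
    return A, P, converged


def _normalize(A, P):
    """Scale each pattern row to max 1, moving magnitude into A."""
    scale = P.max(axis=1)
    scale = np.where(scale > 0, scale, 1.0)
    return A * scale, P / scale[:, None]


def _fit_single(D, W, p, rng, *, sparsity, max_iter, tol, polish_iters, init,
                cluster_n_init=10):
    if init == "svd":
        A, P = _svd_init(D, p, rng)
    elif init == "random":
        A, P = _random_init(D, p, rng)
    else:
        A, P = _cluster_init(D, W, p, rng, n_init=cluster_n_init)
    init_obj = _objective(D, W, A, P, sparsity)
    A, P, trace, converged = _mu_iterations(D, W, A, P, sparsity, max_iter, tol)
    if polish_iters > 0 and sparsity == 0:
        A, P, polish_conv = _nnls_polish(D, W, A, P, polish_iters, tol=tol)
        converged = converged or polish_conv
        trace.append(_objective(D, W, A, P, sparsity))
    A, P = _normalize(A, P)
    chi2 = float(np.sum(W * (D - A @ P) ** 2))
    objective = chi2 + sparsity * float(A.sum())
    return A, P, chi2, objective, [init_obj] + trace, converged


def fit(
    D,
    sigma,
    p: int,
    n_restarts: int = 3,
    seed: int = 0,
    *,
    sparsity: float = 0.0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    polish_iters: int = 2,
    init: str = "cluster",
) -> Factorization:
    """Fit the weighted non-negative factorization, returning the restart
    minimizing the (penalized) objective. By default every restart is
    seeded from a differently-randomized marker-structure clustering
    (``init="svd"`` gives one SVD restart plus random restarts instead);
    a fixed seed gives a bit-identical result."""
    Dv, W, index, columns = _as_arrays(D, sigma)
    if p < 1:
        raise ValueError("p must be >= 1")
    if p >= min(Dv.shape):
        raise ValueError(f"p={p} must be < min(data dimensions) {min(Dv.shape)}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best = None
    traces = []
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, r]))
        if init == "cluster":
            r_init = "cluster"
        else:
            r_init = init if r == 0 else "random"
        A, P, chi2, objective, trace, converged = _fit_single(
            Dv, W, p, rng, sparsity=sparsity, max_iter=max_iter, tol=tol,
            polish_iters=polish_iters, init=r_init,
        )
        traces.append(trace)
        if best is None or objective < best[2]:
            best = (A, P, objective, chi2, r, converged)
    A, P, _, chi2, r_best, converged = best
    notes = []
    if not converged:
        notes.append("best restart hit the iteration cap before the tolerance")
        warnings.warn(notes[-1], RuntimeWarning, stacklevel=2)
    pat_ids = [f"P{k + 1}" for k in range(p)]
    return Factorization(
        A=pd.DataFrame(A, index=index, columns=pat_ids),
        P=pd.DataFrame(P, index=pat_ids, columns=columns),
        p=p,
        chi2=chi2,
        n_restarts=n_restarts,
        seed=seed,
        converged=converged,
        objective_trace=traces[r_best],
        notes=notes,
    )


def fit_amplitudes(D, sigma, P: pd.DataFrame) -> pd.DataFrame:
    """Weighted NNLS fit of amplitudes for all features with P fixed."""
    Dv, W, index, _ = _as_arrays(D, sigma)
    A = _nnls_rows(P.to_numpy(float), Dv, W)
    return pd.DataFrame(A, index=index, columns=P.index)


# ---------------------------------------------------------------------------
# pattern matching across restarts / feature sets
# ---------------------------------------------------------------------------

def _rowwise_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix between rows of X and rows of Y."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    yn = np.linalg.norm(Yc, axis=1)
    denom = np.outer(xn, yn)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (Xc @ Yc.T) / np.where(denom > 0, denom, np.nan)
    return C


def greedy_match(C: np.ndarray):
    """Greedy maximum matching with exclusion on a similarity matrix.

    Returns list of (row, col, similarity), NaNs treated as -inf.
    """
    C = np.array(C, float)
    C[~np.isfinite(C)] = -np.inf
    pairs = []
    n = min(C.shape)
    used_r, used_c = set(), set()
    for _ in range(n):
        best = None
        for i in range(C.shape[0]):
            if i in used_r:
                continue
            for j in range(C.shape[1]):
                if j in used_c:
                    continue
                if best is None or C[i, j] > best[2]:
                    best = (i, j, C[i, j])
        if best is None or not np.isfinite(best[2]):
            break
        pairs.append(best)
        used_r.add(best[0])
        used_c.add(best[1])
    return pairs


def sweep_dimensions(
    D,
    sigma,
    p_range,
    n_restarts: int = 3,
    seed: int = 0,
    subsample: float = 0.5,
    **fit_kwargs,
) -> RobustnessSweep:
    """Pattern-reproducibility sweep over candidate dimensionalities.

    Each restart fits a random ``subsample`` fraction of the features, so
    reproducibility measures generalization of the patterns across genes
    rather than mere optimizer stability: on the same data, a surplus
    pattern can absorb dataset-specific residual structure reproducibly,
    but it does not survive independent feature subsets. Restart pairs are
    matched greedily on pattern correlation; the mean and the worst matched
    similarity are recorded per p.
    """
    p_range = list(p_range)
    if not p_range:
        raise ValueError("p_range must be non-empty")
    if not (0 < subsample <= 1):
        raise ValueError("subsample must be in (0, 1]")
    Dv, W, _, _ = _as_arrays(D, sigma)
    similarity: dict[int, float | None] = {}
    min_similarity: dict[int, float | None] = {}
    chi2s: dict[int, list[float]] = {}
    n_rows = Dv.shape[0]
    n_sub = max(int(subsample * n_rows), 2)
    for p in p_range:
        fits = []
        for r in range(n_restarts):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, p, r]))
            rows = rng.choice(n_rows, size=n_sub, replace=False) if n_sub < n_rows else np.arange(n_rows)
            A, P, chi2, _, _, _ = _fit_single(
                Dv[rows], W[rows], p, rng,
                sparsity=fit_kwargs.get("sparsity", 0.0),
                max_iter=fit_kwargs.get("max_iter", 1500),
                tol=fit_kwargs.get("tol", 1e-6),
                polish_iters=fit_kwargs.get("polish_iters", 2),
                init=fit_kwargs.get("init", "cluster"),
            )
            fits.append((P, chi2))
        chi2s[p] = [f[1] for f in fits]
        if n_restarts < 2:
            similarity[p] = None
            min_similarity[p] = None
            continue
        means, mins = [], []
        for a in range(n_restarts):
            for b in range(a + 1, n_restarts):
                C = _rowwise_pearson(fits[a][0], fits[b][0])
                pairs = greedy_match(C)
                matched = [max(0.0, min(1.0, s)) for _, _, s in pairs]
                matched += [0.0] * (p - len(matched))  # unmatchable patterns
                means.append(np.mean(matched))
                mins.append(np.min(matched))
        similarity[p] = float(np.mean(means))
        min_similarity[p] = float(np.mean(mins))
    return RobustnessSweep(similarity=similarity, min_similarity=min_similarity, chi2=chi2s)


def select_dimensionality(sweep: RobustnessSweep, threshold: float = 0.85):
    """Largest p up to which pattern reproducibility stays above threshold.

    Walks p upward and stops at the first dimensionality whose mean matched
    similarity falls below the threshold: extra patterns beyond the
    supported rank fit noise irreproducibly, but reproducibility can
    rebound spuriously at even larger p, so contiguity from the smallest p
    is required. If even the smallest p fails, it is returned with a
    warning flag. Returns (p_star, passed).
    """
    source = sweep.min_similarity if any(
        s is not None for s in sweep.min_similarity.values()
    ) else sweep.similarity
    usable = {p: s for p, s in source.items() if s is not None}
    if not usable:
        raise ValueError("sweep has no similarity values (n_restarts < 2?)")
    p_sorted = sorted(usable)
    if usable[p_sorted[0]] < threshold:
        warnings.warn(
            "no dimensionality passed the similarity threshold; returning the smallest",
            RuntimeWarning,
            stacklevel=2,
        )
        return p_sorted[0], False
    p_star = p_sorted[0]
    for p in p_sorted[1:]:
        if usable[p] < threshold:
            break
        p_star = p
    return p_star, True


def parallel_sets_consensus(
    D,
    sigma,
    p: int,
    n_sets: int = 4,
    seed: int = 0,
    n_restarts: int = 2,
    min_match: float = 0.5,
    **fit_kwargs,
) -> Factorization:
    """Genome-wide consensus fit: partition features into ``n_sets`` random
    subsets, fit each independently, match patterns across subsets by
    correlation, average the matched rows into consensus patterns, and refit
    amplitudes on all features with the consensus P fixed."""
    if n_sets < 2:
        raise ValueError("n_sets must be >= 2")
    Dv, W, index, columns = _as_arrays(D, sigma)
    if Dv.shape[0] < n_sets * p:
        raise ValueError("need at least n_sets * p features")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 77]))
    perm = rng.permutation(Dv.shape[0])
    subsets = np.array_split(perm, n_sets)
    Ps = []
    for s_idx, rows in enumerate(subsets):
        sub_fit = fit(
            pd.DataFrame(Dv[rows], columns=columns),
            UncertaintyMatrix(sigma=pd.DataFrame(
                np.where(W[rows] > 0, 1.0 / np.sqrt(np.maximum(W[rows], _EPS)), np.inf),
                columns=columns,
            )),
            p,
            n_restarts=n_restarts,
            seed=int(np.random.SeedSequence([int(seed) % 2**31, 78, s_idx]).generate_state(1)[0] % 2**31),
            **fit_kwargs,
        )
        Ps.append(sub_fit.P.to_numpy())
    ref = Ps[0]
    groups = [[ref[k]] for k in range(p)]
    dropped = 0
    for other in Ps[1:]:
        C = _rowwise_pearson(ref, other)
        pairs = greedy_match(C)
        for k, j, r in pairs:
            if r >= min_match:
                groups[k].append(other[j])
    consensus_rows = []
    for k, rows in enumerate(groups):
        if len(rows) < max(2, len(Ps) // 2):
            dropped += 1
            continue
        rows = np.array([r / max(r.max(), _EPS) for r in rows])
        consensus_rows.append(rows.mean(axis=0))
    if not consensus_rows:
        raise RuntimeError("no pattern was reproducible across feature sets")
    notes = []
    if dropped:
        notes.append(f"{dropped} pattern(s) not reproducible across feature sets; consensus p reduced")
        warnings.warn(notes[-1], RuntimeWarning, stacklevel=2)
    P = np.array(consensus_rows)
    P = P / np.maximum(P.max(axis=1, keepdims=True), _EPS)
    pat_ids = [f"P{k + 1}" for k in range(P.shape[0])]
    P_df = pd.DataFrame(P, index=pat_ids, columns=columns)
    sig_df = UncertaintyMatrix(sigma=pd.DataFrame(
        np.where(W > 0, 1.0 / np.sqrt(np.maximum(W, _EPS)), np.inf),
        index=index, columns=columns,
    ))
    A_df = fit_amplitudes(pd.DataFrame(Dv, index=index, columns=columns), sig_df, P_df)
    chi2 = float(np.sum(W * (Dv - A_df.to_numpy() @ P) ** 2))
    return Factorization(
        A=A_df, P=P_df, p=P.shape[0], chi2=chi2,
        n_restarts=n_restarts, seed=seed, converged=True, notes=notes,
    )
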