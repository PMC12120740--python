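"""Cross-modal association: gene-feature correlation and joint factorisation.

Expression is QC-filtered (spots with fewer than 1000 unique genes removed,
mitochondrial/ribosomal genes dropped by symbol prefix) and normalised so
every spot carries the median pre-normalisation total count.  Each gene is
then correlated with a spot-level electrophysiological feature with
Spearman's rho, the p-values are Benjamini-Hochberg adjusted over the gene
set tested, and the significant genes plus the (min-max scaled) feature
column form a joint non-negative matrix V.  V is factorised as V ~ W H
under the sparsity-regularised squared-Frobenius objective

    min_{W,H >= 0}  ||V - WH||_F^2 + alpha ||W||_F^2 + beta sum_j ||H[:, j]||^2

solved by multiplicative updates (monotone in the objective), with the
factor rank chosen at the elbow of the reconstruction-error curve via a
best two-segment piecewise-linear fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, PipelineError, ValidationError

MITO_RIBO_PREFIXES = ("mt-", "Rps", "Rpl", "Mrps", "Mrpl")


# ---------------------------------------------------------------------------
# quality control and normalisation
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    removed_spots: list[str]
    removed_genes: list[str]
    min_unique_genes: int


def qc_filter_spots(
    expr: ExpressionMatrix,
    min_unique_genes: int = 1000,
    drop_prefixes: tuple[str, ...] = MITO_RIBO_PREFIXES,
) -> tuple[ExpressionMatrix, QCReport]:
    """Remove low-complexity spots and mitochondrial/ribosomal genes.

    A spot is kept when it expresses at least ``min_unique_genes`` genes
    (count > 0).  Genes whose symbol starts with one of ``drop_prefixes``
    are removed regardless of spot filtering.
    """
    if min_unique_genes < 0:
        raise ValueError("min_unique_genes must be >= 0")
    unique_genes = (expr.counts > 0).sum(axis=0)
    keep_spots = unique_genes >= min_unique_genes
    if not keep_spots.any():
        raise PipelineError(
            f"QC removed all spots (max unique genes "
            f"{int(unique_genes.max()) if unique_genes.size else 0} < "
            f"{min_unique_genes})"
        )
    keep_genes = np.array(
        [not g.startswith(drop_prefixes) for g in expr.genes], dtype=bool
    )
    out = expr.subset_spots(keep_spots).subset_genes(keep_genes)
    report = QCReport(
        removed_spots=[s for s, k in zip(expr.spots, keep_spots) if not k],
        removed_genes=[g for g, k in zip(expr.genes, keep_genes) if not k],
        min_unique_genes=min_unique_genes,
    )
    return out, report


def normalize_total_counts(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every spot to the median pre-normalisation total count.

    Spots with zero total are dropped (with the event recorded implicitly
    by their absence).  Within-spot gene proportions are preserved exactly.
    """
    totals = expr.counts.sum(axis=0)
    nonzero = totals > 0
    if not nonzero.all():
        expr = expr.subset_spots(nonzero)
        totals = totals[nonzero]
    target = float(np.median(totals))
    scaled = expr.counts * (target / totals)[None, :]
    out = ExpressionMatrix(
        genes=list(expr.genes),
        spots=list(expr.spots),
        counts=scaled,
        spot_xy=expr.spot_xy.copy(),
        region=list(expr.region),
        normalized=True,
    )
    return out


# ---------------------------------------------------------------------------
# Spearman correlation with BH adjustment
# ---------------------------------------------------------------------------

def _spearman_exact_p(rho: float, n: int, feature: np.ndarray, gene: np.ndarray) -> float:
    """Exact two-sided permutation p-value for small n (< 10)."""
    gr = stats.rankdata(gene)
    null = []
    for perm in permutations(stats.rankdata(feature)):
        null.append(np.corrcoef(np.asarray(perm), gr)[0, 1])
    null = np.asarray(null)
    return float(np.mean(np.abs(null) >= abs(rho) - 1e-12))


def correlate_genes_features(
    expr: ExpressionMatrix,
    spot_features: pd.DataFrame,
    feature_name: str,
    gene_family: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of every (family) gene with one n-Ephys feature.

    Spots are restricted to those with a non-missing feature value.  Rho
    uses average ranks for ties; two-sided p-values come from the
    t-approximation for n >= 10 and exact permutation enumeration below
    that.  The returned table carries ``rho``, ``p_value``, ``p_adj``
    (Benjamini-Hochberg over the genes tested) and ``n_spots``, sorted by
    ``p_adj`` then ``p_value``.
    """
    if feature_name not in spot_features.columns:
        raise KeyError(f"unknown feature {feature_name!r}")
    feat = spot_features[feature_name].reindex(expr.spots)
    usable = feat.notna().to_numpy()
    if usable.sum() < 5:
        raise PipelineError(
            f"only {int(usable.sum())} spots have feature {feature_name!r}; need >= 5"
        )
    sub = expr.subset_spots(usable)
    f = feat.to_numpy(dtype=float)[usable]
    n = f.size

    if gene_family is not None:
        idx = sub.gene_index(gene_family)
        sub = sub.subset_genes(idx)
    x = sub.counts  # genes x spots

    f_rank = stats.rankdata(f)
    g_rank = np.apply_along_axis(stats.rankdata, 1, x)
    fr = f_rank - f_rank.mean()
    gr = g_rank - g_rank.mean(axis=1, keepdims=True)
    denom = np.sqrt((gr**2).sum(axis=1) * (fr**2).sum())
    constant = (x.std(axis=1) == 0) | (denom == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (gr @ fr) / denom
    rho[constant] = np.nan

    p = np.full(rho.shape, np.nan)
    valid = ~constant
    if n >= 10:
        r = np.clip(rho[valid], -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p[valid] = 2 * stats.t.sf(np.abs(t), df=n - 2)
    else:
        for g in np.flatnonzero(valid):
            p[g] = _spearman_exact_p(rho[g], n, f, x[g])

    p_adj = np.full(p.shape, np.nan)
    tested = np.isfinite(p)
    if tested.any():
        p_adj[tested] = multipletests(p[tested], method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": sub.genes,
            "rho": rho,
            "p_value": p,
            "p_adj": p_adj,
            "n_spots": n,
        }
    )
    return table.sort_values(["p_adj", "p_value"], kind="mergesort").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# joint matrix and sparsity-constrained NMF
# ---------------------------------------------------------------------------

def build_joint_matrix(
    expr: ExpressionMatrix,
    correlation_table: pd.DataFrame,
    spot_features: pd.DataFrame,
    feature_name: str,
    p_adj_cutoff: float = 0.05,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the joint spots x (genes + feature) matrix V.

    Columns are the normalised expression of genes significant at
    ``p_adj < cutoff`` plus one column holding the chosen feature min-max
    scaled to the significant genes' global maximum, so all columns share
    one non-negative scale.  Returns ``(V, column_names)`` with the feature
    column last.
    """
    sig = correlation_table.loc[
        correlation_table["p_adj"] < p_adj_cutoff, "gene"
    ].tolist()
    if not sig:
        raise PipelineError(
            f"no gene reaches p_adj < {p_adj_cutoff}; consider relaxing the cutoff"
        )
    feat = spot_features[feature_name].reindex(expr.spots)
    usable = feat.notna().to_numpy()
    sub = expr.subset_spots(usable)
    f = feat.to_numpy(dtype=float)[usable]
    gene_idx = sub.gene_index(sig)
    gene_block = sub.counts[gene_idx, :].T  # spots x genes
    global_max = gene_block.max() if gene_block.size else 1.0
    f_span = f.max() - f.min()
    f_scaled = (
        (f - f.min()) / f_span * global_max if f_span > 0 else np.zeros_like(f)
    )
    v = np.column_stack([gene_block, f_scaled])
    return v, sig + [feature_name]


@dataclass
class NMFModel:
    """Result of a sparsity-regularised non-negative factorisation."""

    V: np.ndarray
    W: np.ndarray
    H: np.ndarray
    rank: int
    alpha: float
    beta: float
    recon_error: float
    objective: float
    objective_history: np.ndarray
    n_iter: int
    seed: int
    restarts: int
    converged: bool
    column_names: list[str] | None = None

    @property
    def relative_error(self) -> float:
        norm = np.linalg.norm(self.V)
        return self.recon_error / norm if norm > 0 else 0.0

    def dominant_columns(self, top: int = 5) -> list[list[str]]:
        """Per factor, the ``top`` column labels with largest H loading."""
        names = self.column_names or [str(j) for j in range(self.H.shape[1])]
        out = []
        for r in range(self.rank):
            order = np.argsort(self.H[r])[::-1][:top]
            out.append([names[j] for j in order])
        return out


def _nmf_objective(v, w, h, alpha, beta) -> float:
    resid = v - w @ h
    return float(
        np.sum(resid**2) + alpha * np.sum(w**2) + beta * np.sum(h**2)
    )


def _nmf_once(
    v: np.ndarray,
    rank: int,
    alpha: float,
    beta: float,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    w_init: np.ndarray | None = None,
    h_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    n, m = v.shape
    scale = np.sqrt(v.mean() / max(rank, 1)) if v.size else 1.0
    w = w_init.copy() if w_init is not None else rng.random((n, rank)) * scale + 1e-4
    h = h_init.copy() if h_init is not None else rng.random((rank, m)) * scale + 1e-4
    eps = 1e-12
    history = [_nmf_objective(v, w, h, alpha, beta)]
    converged = False
    for _ in range(max_iter):
        # multiplicative updates for the Tikhonov-regularised objective
        h *= (w.T @ v) / (w.T @ w @ h + beta * h + eps)
        w *= (v @ h.T) / (w @ (h @ h.T) + alpha * w + eps)
        obj = _nmf_objective(v, w, h, alpha, beta)
        history.append(obj)
        prev = history[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            converged = True
            break
    return w, h, np.asarray(history), converged


def fit_nmf(
    v: np.ndarray,
    rank: int,
    alpha: float = 0.1,
    beta: float = 0.1,
    seed: int = 0,
    restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 1000,
    column_names: list[str] | None = None,
    w_init: np.ndarray | None = None,
    h_init: np.ndarray | None = None,
) -> NMFModel:
    """Factorise ``v ~ W H`` (W: n x p, H: p x m) with non-negative factors.

    Multiplicative updates minimise
    ``||V - WH||_F^2 + alpha ||W||_F^2 + beta sum_j ||H[:,j]||^2``;
    the best of ``restarts`` random initialisations (by final objective)
    is returned.  The objective history of the winning run is monotone
    non-increasing.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 2:
        raise ValidationError("V must be a 2-D matrix")
    if v.size and v.min() < 0:
        raise ValidationError("V must be non-negative")
    n, m = v.shape
    if not (1 <= rank <= min(n, m)):
        raise ValueError(f"rank {rank} outside [1, {min(n, m)}]")
    if alpha < 0 or beta < 0:
        raise ValueError("regularization weights must be non-negative")
    if restarts < 1:
        raise ValueError("need at least one restart")

    best = None
    for r in range(restarts):
        rng = np.random.default_rng(seed + 7919 * r)
        w, h, history, converged = _nmf_once(
            v, rank, alpha, beta, rng, tol, max_iter,
            w_init if r == 0 else None, h_init if r == 0 else None,
        )
        if best is None or history[-1] < best[2][-1]:
            best = (w, h, history, converged)
    w, h, history, converged = best
    recon = float(np.linalg.norm(v - w @ h))
    return NMFModel(
        V=v,
        W=w,
        H=h,
        rank=rank,
        alpha=alpha,
        beta=beta,
        recon_error=recon,
        objective=float(history[-1]),
        objective_history=history,
        n_iter=len(history) - 1,
        seed=seed,
        restarts=restarts,
        converged=converged,
        column_names=column_names,
    )


def _two_segment_break(x: np.ndarray, y: np.ndarray) -> int:
    """Index of the breakpoint minimising total SSR of two linear fits."""
    best_idx, best_ssr = None, np.inf
    for b in range(1, x.size - 1):  # interior breakpoints; point b in both fits
        ssr = 0.0
        for seg in (slice(0, b + 1), slice(b, x.size)):
            xs, ys = x[seg], y[seg]
            coef = np.polyfit(xs, ys, 1)
            ssr += float(np.sum((np.polyval(coef, xs) - ys) ** 2))
        if ssr < best_ssr - 1e-15:
            best_ssr, best_idx = ssr, b
    return best_idx


def select_rank_elbow(
    v: np.ndarray,
    p_min: int,
    p_max: int,
    alpha: float = 0.1,
    beta: float = 0.1,
    seed: int = 0,
    restarts: int = 3,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[int, pd.DataFrame]:
    """Factorisation rank at the elbow of the reconstruction-error curve.

    Reconstruction error ``||V - WH||_F`` is computed for each rank in
    ``[p_min, p_max]`` (each fit warm-started from the previous rank's
    solution padded with one small factor, keeping the curve monotone),
    and the elbow is the breakpoint of the best two-segment
    piecewise-linear fit to (rank, error).
    """
    if p_max - p_min < 3:
        raise ValueError("need p_max - p_min >= 3 to fit two segments")
    ranks = np.arange(p_min, p_max + 1)
    errors = []
    prev_w, prev_h = None, None
    n, m = np.asarray(v).shape
    for p in ranks:
        w_init = h_init = None
        if prev_w is not None and p == prev_w.shape[1] + 1:
            rng = np.random.default_rng(seed + p)
            w_init = np.column_stack([prev_w, rng.random(n) * 1e-3])
            h_init = np.vstack([prev_h, rng.random(m) * 1e-3])
        model = fit_nmf(
            v, int(p), alpha, beta, seed=seed, restarts=restarts,
            tol=tol, max_iter=max_iter, w_init=w_init, h_init=h_init,
        )
        errors.append(model.recon_error)
        prev_w, prev_h = model.W, model.H
    errors = np.asarray(errors)
    b = _two_segment_break(ranks.astype(float), errors)
    curve = pd.DataFrame({"rank": ranks, "recon_error": errors})
    return int(ranks[b]), curve
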