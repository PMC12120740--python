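"""Multiscale dynamics: diffusion pseudotime over spots and
center-of-activity trajectories over electrodes.

The transcriptomic side orders spots along a latent progression: a
diffusion map is built from a Gaussian kernel with adaptive per-point
bandwidth (distance to the ``n_neighbors``-th neighbour), symmetrised and
row-normalised into a transition operator, and the pseudotime of a spot is
its Euclidean distance from a root spot in the diffusion space with each
component rescaled by lambda / (1 - lambda).  The electrophysiological
side tracks the activity-weighted centroid of electrode firing (center of
activity, CA) through each network event, yielding a trajectory whose path
length over duration is the rate of spatiotemporal displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.neighbors import NearestNeighbors

from .datatypes import ExpressionMatrix, ValidationError


# ---------------------------------------------------------------------------
# diffusion map + pseudotime
# ---------------------------------------------------------------------------

@dataclass
class DiffusionEmbedding:
    components: np.ndarray  # n_samples x n_components (nontrivial eigenvectors)
    eigenvalues: np.ndarray
    sample_ids: list[str]


@dataclass
class PseudotimeResult:
    root: str
    dpt: pd.Series
    eigenvalues: np.ndarray
    region_means: pd.Series | None


def diffusion_embedding(
    expr: ExpressionMatrix | np.ndarray,
    n_neighbors: int = 15,
    n_components: int = 10,
    sample_ids: list[str] | None = None,
) -> DiffusionEmbedding:
    """Diffusion-map embedding of spots (or any sample x feature matrix).

    A Gaussian kernel with adaptive bandwidth (each point's distance to
    its ``n_neighbors``-th neighbour) is symmetrised and row-normalised
    into a Markov transition operator; the leading nontrivial eigenpairs
    are returned.  Duplicate points share identical kernel rows and are
    handled without jitter.  Eigenvector sign is fixed by making each
    component's largest-magnitude entry positive, so the embedding is
    deterministic.
    """
    if isinstance(expr, ExpressionMatrix):
        x = expr.counts.T  # spots x genes
        ids = list(expr.spots)
    else:
        x = np.asarray(expr, dtype=float)
        ids = sample_ids or [str(i) for i in range(x.shape[0])]
    n = x.shape[0]
    if n_neighbors < 2:
        raise ValueError("need n_neighbors >= 2")
    k = min(n_neighbors, n - 1)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, _ = nn.kneighbors(x)
    bandwidth = dist[:, -1]
    bandwidth[bandwidth == 0] = np.min(bandwidth[bandwidth > 0], initial=1.0)

    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    kern = np.exp(-d2 / (bandwidth[:, None] * bandwidth[None, :]))
    kern = 0.5 * (kern + kern.T)
    row_sums = kern.sum(axis=1)

    # symmetric conjugate of the row-normalised operator keeps eigh applicable
    d_inv_sqrt = 1.0 / np.sqrt(row_sums)
    sym = kern * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    n_comp = min(n_components, n - 1)
    vals, vecs = eigh(sym, subset_by_index=(n - n_comp - 1, n - 1))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # back-transform to right eigenvectors of the Markov operator and drop
    # the trivial stationary component
    psi = vecs * d_inv_sqrt[:, None]
    psi = psi / np.linalg.norm(psi, axis=0, keepdims=True)
    vals, psi = vals[1:], psi[:, 1:]
    for c in range(psi.shape[1]):
        if psi[np.argmax(np.abs(psi[:, c])), c] < 0:
            psi[:, c] *= -1
    return DiffusionEmbedding(
        components=psi, eigenvalues=np.clip(vals, None, 1.0 - 1e-12), sample_ids=ids
    )


def diffusion_pseudotime(
    embedding: DiffusionEmbedding,
    root: str | None = None,
    regions: list[str] | None = None,
) -> PseudotimeResult:
    """Pseudotime = distance from the root in rescaled diffusion space.

    Components are weighted by ``lambda / (1 - lambda)``; the root
    defaults to the extremum (largest value) of the first diffusion
    component.  Per-region mean pseudotime is reported when region labels
    are given.
    """
    ids = embedding.sample_ids
    if root is None:
        root = ids[int(np.argmax(embedding.components[:, 0]))]
    if root not in ids:
        raise KeyError(f"root {root!r} not among samples")
    r_idx = ids.index(root)
    weights = embedding.eigenvalues / (1.0 - embedding.eigenvalues)
    coords = embedding.components * weights[None, :]
    d = np.linalg.norm(coords - coords[r_idx], axis=1)
    dpt = pd.Series(d, index=pd.Index(ids, name="spot"), name="dpt")
    region_means = None
    if regions is not None:
        region_means = dpt.groupby(pd.Index(regions, name="region")).mean()
    return PseudotimeResult(
        root=root, dpt=dpt, eigenvalues=embedding.eigenvalues, region_means=region_means
    )


# ---------------------------------------------------------------------------
# center-of-activity trajectories
# ---------------------------------------------------------------------------

@dataclass
class CATResult:
    """Center-of-activity trajectory for one network event."""

    times: np.ndarray  # window centres (s)
    points: np.ndarray  # CA coordinates (µm), one row per nonempty window
    duration: float
    path_length: float
    displacement_rate: float
    degenerate: bool


def center_of_activity(
    event_table,
    t_start: float,
    t_end: float,
    weighting: str = "count",
) -> np.ndarray | None:
    """Activity-weighted electrode centroid over one time window.

    ``CA = sum_i a_i x_i / sum_i a_i`` with ``a_i`` the electrode's event
    count (default) or summed absolute amplitude in the window; None when
    the window holds no events.
    """
    if t_end <= t_start:
        raise ValueError("window must have positive length")
    ev = event_table.events
    in_win = ev[(ev["time"] >= t_start) & (ev["time"] < t_end)]
    if in_win.empty:
        return None
    ids = in_win["electrode_id"].to_numpy()
    int_ids = np.array([int(i) for i in ids])
    xy = event_table.array_spec.electrode_xy(int_ids)
    if weighting == "count":
        w = np.ones(len(in_win))
    elif weighting == "amplitude":
        w = np.abs(in_win["amplitude"].to_numpy(dtype=float))
        if not np.isfinite(w).all() or w.sum() == 0:
            w = np.ones(len(in_win))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return (xy * w[:, None]).sum(axis=0) / w.sum()


def cat_trajectory(
    event_table,
    onset: float,
    offset: float,
    window_s: float = 0.01,
    weighting: str = "count",
) -> CATResult:
    """CA computed per window across one network event.

    Duration is ``offset - onset``; path length sums consecutive CA
    distances; the displacement rate is path length over duration.
    Events with fewer than two nonempty windows are flagged degenerate.
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    if offset <= onset:
        raise ValidationError("network event must have positive duration")
    edges = np.arange(onset, offset + window_s * 0.5, window_s)
    if edges[-1] < offset:
        edges = np.append(edges, offset)
    times, points = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        ca = center_of_activity(event_table, lo, hi, weighting=weighting)
        if ca is not None:
            times.append(0.5 * (lo + hi))
            points.append(ca)
    points_arr = np.asarray(points) if points else np.empty((0, 2))
    duration = offset - onset
    if len(points) >= 2:
        steps = np.linalg.norm(np.diff(points_arr, axis=0), axis=1)
        path = float(steps.sum())
        degenerate = False
    else:
        path = 0.0
        degenerate = True
    return CATResult(
        times=np.asarray(times),
        points=points_arr,
        duration=float(duration),
        path_length=path,
        displacement_rate=path / duration,
        degenerate=degenerate,
    )


def cat_table(results: list[CATResult]) -> pd.DataFrame:
    """Summary table over network events."""
    return pd.DataFrame(
        {
            "duration": [r.duration for r in results],
            "path_length": [r.path_length for r in results],
            "displacement_rate": [r.displacement_rate for r in results],
            "n_windows": [len(r.times) for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
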