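"""Graph construction and topology over spots (transcriptomic) and
electrodes (functional).

Transcriptomic similarity between spots is normalized mutual information
(arithmetic-mean normalisation) between discretized expression profiles
over a gene family; functional connectivity between electrodes is the
Pearson correlation of their binned event counts.  Similarity matrices are
thresholded into weighted undirected graphs (absolute cutoff, top edge
fraction, or mean + c*SD), on which node metrics, hub scores, rich-club
membership and degree-distribution fits (lognormal / Pareto power-law
tail) are computed.

Hub definition: a node is a hub when it lies in the top 20% for at least
two of {strength, clustering coefficient, nodal efficiency}; rich-club
nodes are hubs with degree above the network mean, and the rich-club
coefficient is phi(k) = 2 E_{>k} / (n_{>k} (n_{>k} - 1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import normalized_mutual_info_score

from .datatypes import ExpressionMatrix, PipelineError, ValidationError


# ---------------------------------------------------------------------------
# similarity matrices
# ---------------------------------------------------------------------------

def _discretize_profile(profile: np.ndarray, n_bins: int) -> np.ndarray | None:
    """Equal-frequency discretisation of one spot's expression profile.

    Returns None for a constant profile (undefined entropy partner).
    """
    if np.all(profile == profile[0]):
        return None
    ranks = stats.rankdata(profile, method="average")
    bins = np.ceil(ranks / profile.size * n_bins).astype(int) - 1
    return np.clip(bins, 0, n_bins - 1)


def mutual_information_matrix(
    expr: ExpressionMatrix,
    gene_family: list[str] | None = None,
    n_bins: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Spot x spot normalized-mutual-information similarity.

    Each spot's expression profile over the family genes is discretized
    into ``n_bins`` equal-frequency bins and pairwise NMI (arithmetic mean
    of entropies) is computed.  Returns ``(nmi, distance)`` with
    ``distance = 1 - nmi``; the diagonal is 1 (0); pairs involving a
    constant-profile spot are NaN.
    """
    if n_bins < 2:
        raise ValueError("need n_bins >= 2")
    sub = expr
    if gene_family is not None:
        if len(gene_family) < 2:
            raise ValueError("gene family needs >= 2 genes")
        sub = expr.subset_genes(expr.gene_index(gene_family))
    profiles = sub.counts.T  # spots x genes
    n = profiles.shape[0]
    discrete = [_discretize_profile(profiles[s], n_bins) for s in range(n)]
    nmi = np.full((n, n), np.nan)
    np.fill_diagonal(nmi, 1.0)
    for a in range(n):
        if discrete[a] is None:
            continue
        for b in range(a + 1, n):
            if discrete[b] is None:
                continue
            v = normalized_mutual_info_score(
                discrete[a], discrete[b], average_method="arithmetic"
            )
            nmi[a, b] = nmi[b, a] = v
    return nmi, 1.0 - nmi


def functional_connectivity(
    event_table,
    bin_s: float = 0.1,
) -> tuple[np.ndarray, list[str]]:
    """Electrode x electrode Pearson correlation of binned event counts.

    Events are binned on a common ``bin_s`` grid across the recording;
    electrodes with zero variance are excluded.  Returns the correlation
    matrix (diagonal 1) and the retained electrode ids.
    """
    ev = event_table.events
    ids = sorted(ev["electrode_id"].unique())
    id_code = {eid: c for c, eid in enumerate(ids)}
    n_bins = max(int(np.ceil(event_table.duration / bin_s)), 1)
    codes = ev["electrode_id"].map(id_code).to_numpy()
    bins = np.minimum(
        (ev["time"].to_numpy(dtype=float) / bin_s).astype(int), n_bins - 1
    )
    binned = np.zeros((len(ids), n_bins))
    np.add.at(binned, (codes, bins), 1.0)
    active = binned.std(axis=1) > 0
    if active.sum() < 2:
        raise PipelineError("fewer than 2 electrodes with varying activity")
    kept = [i for i, a in zip(ids, active) if a]
    corr = np.corrcoef(binned[active])
    np.fill_diagonal(corr, 1.0)
    return corr, kept


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

@dataclass
class GraphModel:
    """Weighted undirected graph over spots or electrodes."""

    graph: nx.Graph
    provenance: str  # {"SRT", "nEphys"}
    threshold_rule: str

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def threshold_graph(
    matrix: np.ndarray,
    node_ids: list[str],
    rule: str = "absolute",
    value: float = 0.8,
    provenance: str = "SRT",
    node_xy: np.ndarray | None = None,
    node_module: list[str] | None = None,
) -> GraphModel:
    """Threshold a symmetric similarity matrix into a weighted graph.

    Rules: ``absolute`` keeps edges with weight >= value (inclusive);
    ``top_fraction`` keeps the ceil(value * n_candidate) strongest edges
    (ties at the cut broken by larger weight, then lexicographic node
    pair); ``mean_plus_sd`` keeps edges with weight >= mean + value * SD of
    the candidate weights.  Isolated nodes are retained with degree 0;
    NaN entries are never candidates.
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if m.shape != (n, n) or len(node_ids) != n:
        raise ValidationError("matrix must be square and match node_ids")
    iu, ju = np.triu_indices(n, k=1)
    w = m[iu, ju]
    ok = np.isfinite(w)
    iu, ju, w = iu[ok], ju[ok], w[ok]

    if rule == "absolute":
        keep = w >= value
        iu, ju, w = iu[keep], ju[keep], w[keep]
    elif rule == "mean_plus_sd":
        cut = w.mean() + value * w.std() if w.size else np.inf
        keep = w >= cut
        iu, ju, w = iu[keep], ju[keep], w[keep]
    elif rule == "top_fraction":
        if not 0 < value <= 1:
            raise ValueError("top fraction must lie in (0, 1]")
        k = int(np.ceil(value * w.size))
        # decreasing weight; ties broken by lexicographic node-id pair
        lex_rank = {nid: r for r, nid in enumerate(sorted(str(x) for x in node_ids))}
        ranks = np.array([lex_rank[str(x)] for x in node_ids])
        order = np.lexsort((ranks[ju], ranks[iu], -w))[:k]
        iu, ju, w = iu[order], ju[order], w[order]
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")

    g = nx.Graph()
    for idx, nid in enumerate(node_ids):
        attrs = {}
        if node_xy is not None:
            attrs["xy"] = (float(node_xy[idx, 0]), float(node_xy[idx, 1]))
        if node_module is not None:
            attrs["module"] = node_module[idx]
        g.add_node(str(nid), **attrs)
    g.add_edges_from(
        (str(node_ids[a]), str(node_ids[b]), {"weight": float(x)})
        for a, b, x in zip(iu, ju, w)
    )
    rule_tag = f"{rule}({value})"
    if g.number_of_edges() == 0:
        import warnings

        warnings.warn(f"threshold {rule_tag} removed all edges", stacklevel=2)
    return GraphModel(graph=g, provenance=provenance, threshold_rule=rule_tag)


# ---------------------------------------------------------------------------
# node metrics, hubs, rich club
# ---------------------------------------------------------------------------

def node_metrics(model: GraphModel | nx.Graph) -> pd.DataFrame:
    """Degree, strength, clustering coefficient and nodal efficiency.

    Degree and clustering are computed on the binarized graph; strength
    sums incident edge weights; nodal efficiency is the mean of inverse
    (binary) shortest-path lengths to every other node, 0 toward
    unreachable nodes.
    """
    g = model.graph if isinstance(model, GraphModel) else model
    if g.number_of_nodes() == 0:
        raise ValidationError("graph is empty")
    nodes = list(g.nodes)
    n = len(nodes)
    degree = dict(g.degree())
    strength = dict(g.degree(weight="weight"))
    clustering = nx.clustering(g)  # binary triangle density
    if n > 1:
        # unweighted all-pairs BFS in compiled code
        from scipy.sparse.csgraph import shortest_path

        adj = nx.to_scipy_sparse_array(g, nodelist=nodes, weight=None, format="csr")
        dist = shortest_path(adj, method="D", unweighted=True, directed=False)
        with np.errstate(divide="ignore"):
            inv = 1.0 / dist
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        eff = inv.sum(axis=1) / (n - 1)
    else:
        eff = np.zeros(1)
    return pd.DataFrame(
        {
            "degree": [degree[u] for u in nodes],
            "strength": [strength[u] for u in nodes],
            "clustering": [clustering[u] for u in nodes],
            "efficiency": eff,
        },
        index=pd.Index(nodes, name="node"),
    )


def detect_hubs(metrics: pd.DataFrame, top_fraction: float = 0.2) -> pd.DataFrame:
    """Hub score = number of {strength, clustering, efficiency} in whose
    top 20% the node lies (ties at the 80th percentile included);
    ``is_hub`` when the score reaches 2 of 3.

    A ``degenerate`` flag marks the all-tied case where every node lands
    in every top set.
    """
    if len(metrics) < 5:
        raise ValueError("hub detection needs >= 5 nodes")
    out = metrics.copy()
    score = np.zeros(len(metrics), dtype=int)
    criteria = ["strength", "clustering", "efficiency"]
    for c in criteria:
        vals = metrics[c].to_numpy(dtype=float)
        cut = np.quantile(vals, 1.0 - top_fraction)
        # tolerance keeps exact ties at the cut inside the top set even
        # when accumulation order perturbs the last float digit
        tol = 1e-9 * max(1.0, abs(cut))
        score += (vals >= cut - tol).astype(int)
    out["hub_score"] = score
    out["is_hub"] = score >= 2
    out.attrs["degenerate"] = bool((score == len(criteria)).all())
    return out


def rich_club(
    model: GraphModel | nx.Graph, metrics: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Rich-club coefficient curve and rich-club node flags.

    ``phi(k) = 2 E_{>k} / (n_{>k} (n_{>k} - 1))`` over the subgraph of
    nodes with degree strictly greater than k, for k from 0 to
    max degree - 1; NaN where fewer than two such nodes exist.  Rich-club
    nodes are hubs whose degree exceeds the network mean degree.
    """
    g = model.graph if isinstance(model, GraphModel) else model
    degree = dict(g.degree())
    max_k = max(degree.values()) if degree else 0
    # n_{>k} from the degree histogram; E_{>k} from each edge's smaller
    # endpoint degree (an edge is internal to the >k subgraph iff
    # min(deg_u, deg_v) > k) — one pass over edges for every k
    deg_vals = np.array(list(degree.values()), dtype=int)
    n_gt = np.array([(deg_vals > k).sum() for k in range(max_k)], dtype=float)
    edge_min = np.array(
        [min(degree[u], degree[v]) for u, v in g.edges], dtype=int
    )
    phi = {}
    for k in range(max_k):
        n_k = n_gt[k]
        if n_k < 2:
            phi[k] = np.nan
            continue
        e_k = int((edge_min > k).sum())
        phi[k] = 2.0 * e_k / (n_k * (n_k - 1))
    phi_series = pd.Series(phi, name="phi", dtype=float)
    phi_series.index.name = "k"
    mean_degree = np.mean(list(degree.values())) if degree else 0.0
    flags = pd.Series(
        {
            u: bool(metrics.loc[u, "is_hub"]) and degree[u] > mean_degree
            for u in g.nodes
        },
        name="is_rich_club",
    )
    return phi_series, flags


# ---------------------------------------------------------------------------
# degree-distribution fitting
# ---------------------------------------------------------------------------

@dataclass
class DegreeFit:
    """Lognormal and Pareto power-law-tail fits to a degree sample."""

    degrees: np.ndarray
    lognorm_mu: float
    lognorm_sigma: float
    lognorm_r2_ccdf: float
    lognorm_ks: float
    lognorm_ks_p: float
    pareto_alpha: float
    pareto_xmin: float
    pareto_r2_pdf: float
    pareto_ks: float
    pareto_ks_p: float


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = np.sum((y_true - y_pred) ** 2)
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return float(max(0.0, 1.0 - ss_res / ss_tot))


def fit_degree_distribution(
    degrees: np.ndarray,
    pareto_xmin: float | None = None,
    n_bins: int = 20,
    seed: int = 0,
) -> DegreeFit:
    """Fit lognormal (MLE) and Pareto-tail (conditional MLE) models.

    The lognormal goodness of fit is the R^2 between empirical and fitted
    complementary CDFs on log-log axes; the Pareto fit uses linear binning
    of the tail sample against the fitted density.  Each model is also
    compared to the data with a two-sample KS test against a same-size
    sample drawn from the fitted model (fixed seed).
    """
    degrees = np.asarray(degrees, dtype=float)
    degrees = degrees[degrees > 0]
    if degrees.size < 30:
        raise ValueError("need >= 30 nonzero degrees")
    if np.all(degrees == degrees[0]):
        raise ValueError("degenerate (all-equal) degree sample")
    rng = np.random.default_rng(seed)

    # lognormal MLE on the positive sample
    log_d = np.log(degrees)
    mu, sigma = float(log_d.mean()), float(log_d.std())
    if sigma == 0:
        raise ValueError("zero-variance log degrees")

    # empirical vs fitted cCDF on log-log axes
    x_sorted = np.sort(degrees)
    ccdf_emp = 1.0 - np.arange(1, degrees.size + 1) / degrees.size
    keep = ccdf_emp > 0
    ccdf_fit = stats.lognorm.sf(x_sorted[keep], s=sigma, scale=np.exp(mu))
    pos = ccdf_fit > 0
    r2_ln = _r2(np.log10(ccdf_emp[keep][pos]), np.log10(ccdf_fit[pos]))
    ln_sample = rng.lognormal(mu, sigma, size=degrees.size)
    ks_ln, ksp_ln = stats.ks_2samp(degrees, ln_sample)

    # Pareto tail: conditional MLE (Hill estimator) above x_min
    xmin = float(pareto_xmin) if pareto_xmin is not None else float(np.median(degrees))
    tail = degrees[degrees >= xmin]
    if tail.size < 10 or np.all(tail == tail[0]):
        raise ValueError("Pareto tail too small or degenerate")
    ratios = np.log(tail / xmin)
    ratios = ratios[ratios > 0]
    alpha = float(ratios.size / ratios.sum())

    hist, edges = np.histogram(tail, bins=n_bins, density=True)
    # bin-averaged fitted density (CDF increment / width): the pdf varies
    # steeply within wide linear bins, so pointwise evaluation misleads
    cdf = stats.pareto.cdf(edges, b=alpha, scale=xmin)
    pdf_fit = np.diff(cdf) / np.diff(edges)
    nonzero = hist > 0
    r2_par = _r2(hist[nonzero], pdf_fit[nonzero])
    par_sample = stats.pareto.rvs(
        b=alpha, scale=xmin, size=tail.size, random_state=rng
    )
    ks_par, ksp_par = stats.ks_2samp(tail, par_sample)

    return DegreeFit(
        degrees=degrees,
        lognorm_mu=mu,
        lognorm_sigma=sigma,
        lognorm_r2_ccdf=r2_ln,
        lognorm_ks=float(ks_ln),
        lognorm_ks_p=float(ksp_ln),
        pareto_alpha=alpha,
        pareto_xmin=xmin,
        pareto_r2_pdf=r2_par,
        pareto_ks=float(ks_par),
        pareto_ks_p=float(ksp_par),
    )
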