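"""Condensate network topology and dynamics.

A condensate graph has one node per chain in the largest connected
cluster; an undirected edge joins two chains whenever any pair of
stickers between them sit within sqrt(3) lattice units.  On these
graphs we compute betweenness centrality, mean path length L and mean
clustering coefficient C, and normalize L and C by their Erdos-Renyi
expectations (log n / log <k> and <k> / n) to expose the small-world
character of condensates: L / L_ER near 1 but C / C_ER well above 1.

Sticker-level statistics cover the ratio of association g_a (sticker
partner preference relative to the homopolymer reference) and the
discrete-Weibull distribution of sticker-cluster sizes,
P(s) = 1 - exp(-((s+1)/lambda)^k), fitted on the linearized CDF.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .contacts import chain_adjacency_pairs, nonbonded_pairs
from .mc import LatticeConfiguration, Trajectory, chain_coms
from .phase import assign_phases
from .sequences import ContactModel


# ---------------------------------------------------------------------------
# Graph construction and core metrics
# ---------------------------------------------------------------------------

def build_condensate_graph(
    config: LatticeConfiguration, model: ContactModel | None = None
) -> nx.Graph:
    """Chain-contact graph restricted to the largest connected component.

    Edges come from inter-chain sticker-sticker adjacency only; node
    labels are chain indices in ``config``.
    """
    if config.n_chains == 0:
        raise ValueError("no chains: cannot build a condensate graph")
    g = nx.Graph()
    g.add_nodes_from(range(config.n_chains))
    for a, b in chain_adjacency_pairs(config, sticker_only=True):
        g.add_edge(int(a), int(b))
    comps = list(nx.connected_components(g))
    largest = max(comps, key=len)
    return g.subgraph(largest).copy()


def betweenness(graph: nx.Graph, ordered: bool = False) -> dict[int, float]:
    """Unnormalized betweenness centrality g(n).

    Default is the undirected (unordered-pair) convention; set
    ``ordered=True`` to count each pair in both directions (x2).
    """
    bc = nx.betweenness_centrality(graph, normalized=False)
    if ordered:
        bc = {n: 2 * v for n, v in bc.items()}
    return bc


@dataclass
class SmallWorldSummary:
    n: int
    mean_degree: float
    L: float
    C: float
    L_er: float
    C_er: float

    @property
    def L_ratio(self) -> float:
        return self.L / self.L_er

    @property
    def C_ratio(self) -> float:
        return self.C / self.C_er


def small_world_summary(graph: nx.Graph) -> SmallWorldSummary:
    """L, C and their Erdos-Renyi references for one (giant) component.

    L is the mean shortest-path length over unordered node pairs; C is
    the mean of the local clustering coefficients.  References:
    L_ER = log n / log<k>, C_ER = <k> / n.
    """
    if not nx.is_connected(graph):
        warnings.warn("graph disconnected; restricting to giant component")
        giant = max(nx.connected_components(graph), key=len)
        graph = graph.subgraph(giant).copy()
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError("small-world summary needs >= 3 nodes")
    k = 2 * graph.number_of_edges() / n
    L = nx.average_shortest_path_length(graph)
    C = nx.average_clustering(graph)
    if k <= 1:
        raise ValueError("mean degree <= 1: Erdos-Renyi reference undefined")
    return SmallWorldSummary(
        n=n, mean_degree=k, L=L, C=C,
        L_er=math.log(n) / math.log(k), C_er=k / n,
    )


def betweenness_by_degree(graph: nx.Graph, degree: int,
                          ordered: bool = False) -> np.ndarray:
    """Betweenness sample conditioned on a fixed node degree
    (disentangles the degree-betweenness correlation).  Empty degree
    classes yield an empty array."""
    bc = betweenness(graph, ordered=ordered)
    vals = [bc[v] for v in graph if graph.degree[v] == degree]
    return np.array(vals, dtype=float)


# ---------------------------------------------------------------------------
# Centrality in space and time
# ---------------------------------------------------------------------------

def top_central_chains(graph: nx.Graph, top_fraction: float = 0.05,
                       ordered: bool = False) -> list[int]:
    """Chains in the top betweenness fraction; ties at the cutoff are
    broken deterministically by chain id (flagged via sort key)."""
    bc = betweenness(graph, ordered=ordered)
    n_top = max(2, int(round(top_fraction * graph.number_of_nodes())))
    ranked = sorted(bc, key=lambda v: (-bc[v], v))
    return ranked[:n_top]


def centrality_distance_distribution(
    config: LatticeConfiguration,
    graph: nx.Graph,
    top_fraction: float = 0.05,
) -> np.ndarray:
    """Pairwise minimum-image COM distances among the most central chains."""
    if graph.number_of_nodes() < 20:
        raise ValueError("need a condensate of >= 20 chains for a top-5% sample")
    top = top_central_chains(graph, top_fraction)
    if len(top) < 2:
        raise ValueError("fewer than 2 chains selected")
    coms = np.array([config.chain_com(c) % config.box_side for c in top])
    box = config.box_side
    out = []
    for i in range(len(top)):
        d = coms[i + 1:] - coms[i]
        d -= box * np.round(d / box)
        out.extend(np.sqrt((d**2).sum(axis=1)))
    return np.array(out)


def centrality_persistence(
    traj: Trajectory,
    lag: int,
    model: ContactModel | None = None,
    top_fraction: float = 0.05,
    frames: list[int] | None = None,
) -> float:
    """Probability that a top-5% betweenness chain is still top-5%
    ``lag`` frames later, averaged over frame pairs.

    The uncorrelated null is ``top_fraction`` exactly; a frozen
    trajectory gives 1.
    """
    if not traj.local_only:
        raise ValueError("centrality persistence requires a local-only trajectory")
    if frames is None:
        frames = traj.equilibrated()
    if lag < 1 or lag >= len(frames):
        raise ValueError("lag out of range")
    tops = []
    for fi in frames:
        g = build_condensate_graph(traj.configuration(fi), model)
        tops.append(set(top_central_chains(g, top_fraction)))
    stay, total = 0, 0
    for a, b in zip(tops[:-lag], tops[lag:]):
        stay += len(a & b)
        total += len(a)
    if total == 0:
        raise ValueError("no central chains found")
    return stay / total


def rmsd_by_centrality(
    traj: Trajectory,
    lag_frames: int,
    model: ContactModel | None = None,
    n_bins: int = 4,
    frames: list[int] | None = None,
):
    """Chain COM displacement over ``lag_frames``, binned by betweenness.

    Returns (bin_edges, rmsd_per_bin, count_per_bin).  Requires a
    local-only trajectory so MC moves are a valid time proxy.
    """
    if not traj.local_only:
        raise ValueError("RMSD analysis requires a local-only trajectory")
    if frames is None:
        frames = traj.equilibrated()
    if lag_frames < 1 or lag_frames >= len(frames):
        raise ValueError("lag out of range")
    coms = chain_coms(traj, frames)
    cent_samples: list[tuple[float, float]] = []  # (betweenness, sq disp)
    for t0 in range(len(frames) - lag_frames):
        g = build_condensate_graph(traj.configuration(frames[t0]), model)
        bc = betweenness(g)
        for c in g.nodes:
            d2 = float(((coms[t0 + lag_frames, c] - coms[t0, c]) ** 2).sum())
            cent_samples.append((bc[c], d2))
    arr = np.array(cent_samples)
    edges = np.quantile(arr[:, 0], np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    rmsd = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        m = (arr[:, 0] >= edges[b]) & (arr[:, 0] < edges[b + 1])
        counts[b] = int(m.sum())
        if counts[b]:
            rmsd[b] = math.sqrt(arr[m, 1].mean())
    return edges, rmsd, counts


def sticker_contact_lifetime(
    traj: Trajectory, frames: list[int] | None = None
) -> float:
    """Mean persistence (in MC moves) of specific sticker-sticker contacts.

    A contact's lifetime is the length of a maximal run of consecutive
    frames in which the same bead pair stays in contact, converted to
    MC-move units via the frame stamps.  Runs still open at the last
    frame are counted at their observed length (a lower bound).
    """
    if not traj.local_only:
        raise ValueError("contact lifetimes require a local-only trajectory")
    if frames is None:
        frames = traj.equilibrated()
    if len(frames) < 2:
        raise ValueError("need >= 2 frames")
    steps = np.array([traj.frames[fi].step for fi in frames])
    dt = np.diff(steps)
    if not np.allclose(dt, dt[0]):
        raise ValueError("frames must be evenly spaced in MC moves")
    per_frame = float(dt[0])
    st_mask = None
    open_runs: dict[tuple[int, int], int] = {}
    lifetimes: list[int] = []
    for fi in frames:
        cfg = traj.configuration(fi)
        if st_mask is None:
            st_mask = cfg.sticker_mask
        i, j = nonbonded_pairs(cfg)
        keep = st_mask[i] & st_mask[j]
        now = {(int(a), int(b)) for a, b in
               zip(np.minimum(i[keep], j[keep]), np.maximum(i[keep], j[keep]))}
        for pair in list(open_runs):
            if pair not in now:
                lifetimes.append(open_runs.pop(pair))
        for pair in now:
            open_runs[pair] = open_runs.get(pair, 0) + 1
    lifetimes.extend(open_runs.values())
    if not lifetimes:
        raise ValueError("no sticker-sticker contacts observed")
    return float(np.mean(lifetimes)) * per_frame


# ---------------------------------------------------------------------------
# Ratio of association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    g_a: float
    p_a_seq: float
    p_a_ref: float


def _sticker_partner_probability(config: LatticeConfiguration,
                                 model: ContactModel | None = None,
                                 dense_only: bool = True) -> float:
    """p_a = sum(n_st) / (sum(n_st) + sum(n_sp)) over dense-phase
    stickers; neighbors are occupied nonbonded sites within sqrt(3)."""
    st = config.sticker_mask
    if not st.any():
        raise ValueError("configuration has no stickers")
    if dense_only:
        labels = assign_phases(config, model)
        in_dense = labels.dense[config.chain_of]
    else:
        in_dense = np.ones(config.n_beads, dtype=bool)
    i, j = nonbonded_pairs(config)
    n_st = 0
    n_sp = 0
    for a, b in ((i, j), (j, i)):
        focal = st[a] & in_dense[a]
        n_st += int((focal & st[b]).sum())
        n_sp += int((focal & ~st[b]).sum())
    if n_st + n_sp == 0:
        raise ValueError("no sticker neighbors found")
    return n_st / (n_st + n_sp)


def ratio_of_association(
    config_seq: LatticeConfiguration,
    config_ref: LatticeConfiguration,
    model: ContactModel | None = None,
    model_ref: ContactModel | None = None,
    dense_only: bool = True,
) -> AssociationResult:
    """g_a = p_a,seq / p_a,ref.

    ``config_ref`` is the homopolymer-equivalent system carrying the
    wild-type sticker-spacer architecture in its sticker mask.  g_a of
    a system against itself is 1 by construction.
    """
    p_seq = _sticker_partner_probability(config_seq, model, dense_only)
    p_ref = _sticker_partner_probability(config_ref, model_ref, dense_only)
    if p_ref == 0:
        raise ValueError("reference sticker-neighbor probability is zero")
    return AssociationResult(g_a=p_seq / p_ref, p_a_seq=p_seq, p_a_ref=p_ref)


# ---------------------------------------------------------------------------
# Sticker clusters and the discrete Weibull fit
# ---------------------------------------------------------------------------

def sticker_cluster_sizes(config: LatticeConfiguration) -> np.ndarray:
    """Sizes of connected sticker clusters (intra- and inter-chain
    sticker-sticker adjacency within sqrt(3); bonded pairs excluded)."""
    st = config.sticker_mask
    idx = np.nonzero(st)[0]
    if len(idx) == 0:
        return np.empty(0, dtype=np.int64)
    remap = -np.ones(config.n_beads, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    i, j = nonbonded_pairs(config)
    keep = st[i] & st[j]
    a, b = remap[i[keep]], remap[j[keep]]
    n = len(idx)
    if len(a):
        m = coo_matrix((np.ones(len(a)), (a, b)), shape=(n, n))
        _, labels = connected_components(m, directed=False)
    else:
        labels = np.arange(n)
    return np.bincount(labels).astype(np.int64)


@dataclass
class StickerClusterDistribution:
    """Per-sticker cluster-size probabilities.

    ``pmf[s]`` is the probability that a randomly chosen sticker sits
    in a cluster of exactly ``s`` stickers (cluster frequencies
    weighted by size); ``cdf`` its cumulative form used for fitting.
    """

    sizes: np.ndarray
    pmf: np.ndarray
    cdf: np.ndarray = field(init=False)

    def __post_init__(self):
        self.cdf = np.cumsum(self.pmf)


def sticker_cluster_distribution(
    configs: list[LatticeConfiguration],
) -> StickerClusterDistribution:
    """Aggregate per-sticker cluster-size distribution over snapshots."""
    counts: dict[int, float] = {}
    for cfg in configs:
        for s in sticker_cluster_sizes(cfg):
            counts[int(s)] = counts.get(int(s), 0.0) + float(s)
    if not counts:
        raise ValueError("no sticker clusters found")
    sizes = np.array(sorted(counts), dtype=np.int64)
    w = np.array([counts[int(s)] for s in sizes])
    return StickerClusterDistribution(sizes=sizes, pmf=w / w.sum())


def discrete_weibull_cdf(s, lam: float, k: float):
    """P(size <= s) = 1 - exp(-((s+1)/lambda)^k)."""
    return 1.0 - np.exp(-(((np.asarray(s, dtype=float) + 1.0) / lam) ** k))


@dataclass
class WeibullFit:
    lam: float
    k: float
    se_lam: float
    se_k: float
    n_points: int
    outliers_removed: int


def fit_weibull_linearized(
    sizes: np.ndarray,
    cdf: np.ndarray,
    weights: np.ndarray | None = None,
    mad_threshold: float = 3.0,
) -> WeibullFit:
    """Fit (lambda, k) on the linearized CDF.

    Regression of y = ln(-ln(1 - P(s))) on x = ln(s + 1) gives slope k
    and intercept -k ln(lambda).  Points with P(s) >= 1 are excluded
    (y undefined); residual outliers beyond ``mad_threshold`` scaled
    median absolute deviations are removed and the fit repeated once.
    """
    sizes = np.asarray(sizes, dtype=float)
    cdf = np.asarray(cdf, dtype=float)
    valid = (cdf > 0) & (cdf < 1)
    if valid.sum() < 3:
        raise ValueError("fewer than 3 usable sizes for the Weibull fit")
    x = np.log(sizes[valid] + 1.0)
    y = np.log(-np.log(1.0 - cdf[valid]))
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)[valid]

    def wfit(x, y, w):
        W = np.diag(w)
        A = np.vstack([x, np.ones_like(x)]).T
        cov_inv = A.T @ W @ A
        coef = np.linalg.solve(cov_inv, A.T @ W @ y)
        resid = y - A @ coef
        dof = max(len(x) - 2, 1)
        s2 = float((w * resid**2).sum() / w.sum()) * len(x) / dof
        cov = s2 * np.linalg.inv(cov_inv)
        return coef, resid, cov

    coef, resid, cov = wfit(x, y, w)
    med = np.median(resid)
    mad = 1.4826 * np.median(np.abs(resid - med))
    removed = 0
    if mad > 0:
        keep = np.abs(resid - med) <= mad_threshold * mad
        removed = int((~keep).sum())
        if removed and keep.sum() >= 3:
            coef, resid, cov = wfit(x[keep], y[keep], w[keep])
    k = float(coef[0])
    lam = float(math.exp(-coef[1] / k))
    se_k = float(math.sqrt(max(cov[0, 0], 0.0)))
    # delta method for lambda = exp(-b/k)
    b = float(coef[1])
    grad = np.array([b / k**2 * lam, -lam / k])
    se_lam = float(math.sqrt(max(grad @ cov @ grad, 0.0)))
    if lam <= 0 or k <= 0:
        raise ValueError("degenerate Weibull fit")
    return WeibullFit(lam=lam, k=k, se_lam=se_lam, se_k=se_k,
                      n_points=len(resid), outliers_removed=removed)


def sticker_cluster_weibull(
    configs: list[LatticeConfiguration],
) -> tuple[StickerClusterDistribution, WeibullFit]:
    """Cluster-size distribution plus its discrete-Weibull fit."""
    dist = sticker_cluster_distribution(configs)
    if len(dist.sizes) < 3:
        raise ValueError(
            "sticker cluster distribution degenerate (fewer than 3 sizes)"
        )
    fit = fit_weibull_linearized(dist.sizes, dist.cdf)
    return dist, fit


def fit_weibull_from_samples(samples: np.ndarray) -> WeibullFit:
    """Fit (lambda, k) from raw per-sticker cluster-size samples."""
    samples = np.asarray(samples, dtype=np.int64)
    sizes, counts = np.unique(samples, return_counts=True)
    cdf = np.cumsum(counts) / counts.sum()
    return fit_weibull_linearized(sizes, cdf, weights=counts.astype(float))
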