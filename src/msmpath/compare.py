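"""Two-ensemble comparison: PCA, symmetrized K-L divergence, MI networks.

Quantifies how an agonist-bound conformational ensemble differs from a
partial-agonist-bound one.  Feature distributions are compared with the
symmetrized Kullback-Leibler divergence (the sum of both directed
divergences on shared histogram bins) and aggregated per residue; residue
dihedral coupling is measured with normalized mutual information
(MI / min(H_a, H_b)), gated by spatial contact (< 6 Å) and statistical
significance, and allosteric pathways are minimum-cost routes through the
resulting graph with edge cost -ln(nMI) (Dijkstra), so "shortest" means
"highest information flow".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "EnsembleMatrix",
    "PcaComparison",
    "MutualInfoNetwork",
    "pca_compare",
    "top_weight_features",
    "symmetrized_kl",
    "per_residue_divergence",
    "dihedral_mutual_information",
    "mi_matrix",
    "mi_significance_threshold",
    "build_mi_graph",
    "shortest_allosteric_path",
]


@dataclass
class EnsembleMatrix:
    """A labelled frames × features matrix with residue annotations.

    ``feature_residues`` maps each feature name to the residue pair (for
    distance features) or single residue (for dihedral features) it reports
    on.
    """

    label: str
    X: np.ndarray
    feature_names: list[str]
    feature_residues: dict[str, tuple[int, ...] | int]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not np.all(np.isfinite(self.X)):
            raise ValueError("ensemble contains non-finite values")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match columns")
        missing = set(self.feature_names) - set(self.feature_residues)
        if missing:
            raise ValueError(f"feature_residues misses {sorted(missing)}")

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.feature_names.index(name)]


@dataclass
class PcaComparison:
    projection_a: np.ndarray
    projection_b: np.ndarray
    loadings: np.ndarray  # P x n_components
    explained_variance_ratio: np.ndarray
    feature_names: list[str]


def pca_compare(
    ens_a: EnsembleMatrix, ens_b: EnsembleMatrix, n_components: int = 2
) -> PcaComparison:
    """PCA fitted on the pooled (mean-centered) frames of both ensembles,
    then both ensembles projected onto it."""
    if ens_a.feature_names != ens_b.feature_names:
        raise ValueError("ensembles must share an identical feature set")
    pooled = np.vstack([ens_a.X, ens_b.X])
    pca = PCA(n_components=n_components, svd_solver="full").fit(pooled)
    return PcaComparison(
        projection_a=pca.transform(ens_a.X),
        projection_b=pca.transform(ens_b.X),
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        feature_names=list(ens_a.feature_names),
    )


def top_weight_features(
    pca: PcaComparison | np.ndarray,
    component: int,
    n: int,
    feature_names: list[str] | None = None,
) -> list[tuple[str, float]]:
    """Features ranked by |loading| on one component, with signs."""
    if isinstance(pca, PcaComparison):
        loadings = pca.loadings
        feature_names = pca.feature_names
    else:
        loadings = np.asarray(pca)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(loadings.shape[0])]
    if not 0 <= component < loadings.shape[1]:
        raise ValueError(f"component {component} does not exist")
    if n > loadings.shape[0]:
        raise ValueError("n exceeds the number of features")
    col = loadings[:, component]
    order = np.argsort(-np.abs(col), kind="stable")[:n]
    return [(feature_names[i], float(col[i])) for i in order]


def symmetrized_kl(
    samples_a: np.ndarray,
    samples_b: np.ndarray,
    n_bins: int = 30,
    pseudocount: float = 1e-10,
) -> float:
    """Symmetrized K-L divergence KL(P||Q) + KL(Q||P) in nats.

    Both samples are histogrammed on shared bins spanning their common
    range; a pseudocount keeps empty bins finite.  Identical samples give 0
    exactly; a degenerate common range (all values equal) is defined as 0.
    """
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p = np.histogram(a, bins=edges)[0].astype(float) + pseudocount
    q = np.histogram(b, bins=edges)[0].astype(float) + pseudocount
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))


def per_residue_divergence(
    feature_divergences: dict[str, float],
    feature_residues: dict[str, tuple[int, ...] | int],
) -> dict[int, float]:
    """Mean divergence per residue over the features that involve it."""
    acc: dict[int, list[float]] = {}
    for name, d in feature_divergences.items():
        if name not in feature_residues:
            raise ValueError(f"feature {name!r} has no residue mapping")
        res = feature_residues[name]
        residues = (res,) if isinstance(res, (int, np.integer)) else tuple(res)
        for r in residues:
            acc.setdefault(int(r), []).append(float(d))
    return {r: float(np.mean(v)) for r, v in sorted(acc.items())}


_ANGLE_EDGES_CACHE: dict[int, np.ndarray] = {}


def _angle_edges(n_bins: int) -> np.ndarray:
    if n_bins not in _ANGLE_EDGES_CACHE:
        _ANGLE_EDGES_CACHE[n_bins] = np.linspace(-180.0, 180.0, n_bins + 1)
    return _ANGLE_EDGES_CACHE[n_bins]


def dihedral_mutual_information(
    angles_a: np.ndarray, angles_b: np.ndarray, n_bins: int = 24
) -> float:
    """Normalized mutual information between two dihedral series.

    Histograms over fixed [-180, 180) bins; MI in nats is normalized by the
    smaller marginal entropy and clipped to [0, 1].  A constant series has
    zero entropy and yields 0 by convention.
    """
    a = np.asarray(angles_a, dtype=float).ravel()
    b = np.asarray(angles_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("series must have equal length")
    edges = _angle_edges(n_bins)
    joint = np.histogram2d(a, b, bins=(edges, edges))[0]
    n = joint.sum()
    pj = joint / n
    pa = pj.sum(axis=1)
    pb = pj.sum(axis=0)
    ha = -np.sum(pa[pa > 0] * np.log(pa[pa > 0]))
    hb = -np.sum(pb[pb > 0] * np.log(pb[pb > 0]))
    if min(ha, hb) <= 0:
        return 0.0
    nz = pj > 0
    mi = np.sum(pj[nz] * np.log(pj[nz] / np.outer(pa, pb)[nz]))
    return float(np.clip(mi / min(ha, hb), 0.0, 1.0))


def mi_matrix(D: np.ndarray, n_bins: int = 24) -> np.ndarray:
    """Pairwise normalized MI over the columns of a frames × residues
    dihedral matrix (diagonal set to 1)."""
    D = np.asarray(D, dtype=float)
    n = D.shape[1]
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = dihedral_mutual_information(D[:, i], D[:, j], n_bins)
    return M


def mi_significance_threshold(
    D: np.ndarray,
    n_bins: int = 24,
    n_shuffles: int = 20,
    quantile: float = 0.975,
    seed: int = 0,
) -> np.ndarray:
    """Per-pair permutation-null MI threshold.

    Finite samples never give exactly zero MI, so "nonzero MI" is read as
    "MI above the ``quantile`` of a shuffled null": for each pair, one
    column is randomly permuted ``n_shuffles`` times and the null nMI
    quantile recorded.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    thr = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            null = np.empty(n_shuffles)
            for s in range(n_shuffles):
                perm = rng.permutation(D.shape[0])
                null[s] = dihedral_mutual_information(D[:, i], D[perm, j], n_bins)
            thr[i, j] = thr[j, i] = np.quantile(null, quantile)
    return thr


@dataclass
class MutualInfoNetwork:
    """Residue graph gated by spatial contact and mutual information.

    Edge (i, j) exists iff contact_distances[i, j] < distance_cutoff and
    mi[i, j] > the (scalar or per-pair) MI threshold; the traversal cost of
    an edge is min(-ln nMI, cost_ceiling).
    """

    n_residues: int
    mi: np.ndarray
    contact_distances: np.ndarray
    distance_cutoff: float
    mi_threshold: np.ndarray | float
    cost_ceiling: float
    graph: nx.Graph = field(repr=False, default=None)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def edge_table(self):
        import pandas as pd

        rows = [
            {
                "residue_i": i,
                "residue_j": j,
                "distance": self.contact_distances[i, j],
                "nmi": self.mi[i, j],
                "cost": self.graph[i][j]["weight"],
            }
            for i, j in self.edges
        ]
        return pd.DataFrame(rows)


def build_mi_graph(
    mi: np.ndarray,
    contact_distances: np.ndarray,
    distance_cutoff: float = 6.0,
    mi_threshold: np.ndarray | float = 0.0,
    cost_ceiling: float = 50.0,
) -> MutualInfoNetwork:
    """Build the gated residue graph with edge cost -ln(nMI)."""
    mi = np.asarray(mi, dtype=float)
    cd = np.asarray(contact_distances, dtype=float)
    if mi.shape != cd.shape or mi.shape[0] != mi.shape[1]:
        raise ValueError("mi and contact_distances must be same-size square")
    if not (np.allclose(mi, mi.T) and np.allclose(cd, cd.T)):
        raise ValueError("mi and contact_distances must be symmetric")
    n = mi.shape[0]
    thr = np.broadcast_to(np.asarray(mi_threshold, dtype=float), mi.shape)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if cd[i, j] < distance_cutoff and mi[i, j] > thr[i, j]:
                cost = cost_ceiling if mi[i, j] <= 0 else min(
                    -np.log(mi[i, j]), cost_ceiling
                )
                g.add_edge(i, j, weight=float(max(cost, 0.0)))
    return MutualInfoNetwork(
        n_residues=n,
        mi=mi,
        contact_distances=cd,
        distance_cutoff=distance_cutoff,
        mi_threshold=mi_threshold,
        cost_ceiling=cost_ceiling,
        graph=g,
    )


def shortest_allosteric_path(
    net: MutualInfoNetwork, source: int, target: int
) -> list[int] | None:
    """Minimum-total-cost path between two residues (Dijkstra).

    Returns the residue index sequence, or None when no path exists.  Nodes
    are inserted in ascending order so tie-breaks are deterministic.
    """
    if source not in net.graph or target not in net.graph:
        raise ValueError("source/target residue not in network")
    try:
        return nx.dijkstra_path(net.graph, source, target, weight="weight")
    except nx.NetworkXNoPath:
        return None
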