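"""Whole-network descriptors of skull integration.

For each specimen the analysis reduces the bone-contact graph to ten
numbers: node count N, edge count K, density D, mean local clustering C,
mean shortest path length L, degree heterogeneity H (SD of degree / mean
degree), the S- and Q-module counts, maximum modularity Q_max and
parcellation P. The first six are purely graph-topological and computed
here; the module-based four are filled in by :mod:`cranionet.modules`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import networkx as nx
import numpy as np

from .netio import BoneNetwork


@dataclass
class NetworkParams:
    N: int
    K: int
    D: float
    C: float
    L: float
    H: float
    n_S_modules: int | None = None
    n_Q_modules: int | None = None
    Q_max: float | None = None
    P: float | None = None

    COLUMNS = ("N", "K", "D", "C", "L", "H", "n_S_modules", "n_Q_modules", "Q_max", "P")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def degree_heterogeneity(degrees: np.ndarray, ddof: int = 1) -> float:
    """SD of the degree sequence divided by its mean.

    Despite sometimes being called a "variance" of connectivity, this is a
    normalized dispersion (coefficient of variation) of node degree; the
    sample (n-1) SD is the default, matching R's ``sd``. Zero iff the graph
    is regular.
    """
    degrees = np.asarray(degrees, dtype=float)
    if len(degrees) < 2:
        return 0.0
    return float(np.std(degrees, ddof=ddof) / degrees.mean())


def compute_params(
    net: BoneNetwork,
    include_low_degree_in_c: bool = True,
    ddof: int = 1,
) -> NetworkParams:
    """Compute N, K, D, C, L, H for one connected bone network.

    D = 2K / (N(N-1)); C averages the local clustering coefficient over all
    nodes (degree-<2 nodes contribute 0 unless ``include_low_degree_in_c``
    is False, in which case they are excluded); L averages shortest-path
    lengths over unordered node pairs; H is SD(degree)/mean(degree).
    """
    if net.n_nodes < 2:
        raise ValueError("network parameters need at least 2 bones")
    g = net.to_networkx()
    if not nx.is_connected(g):
        raise ValueError(
            f"{net.meta.specimen_id}: mean path length undefined on a disconnected graph"
        )
    n = net.n_nodes
    k = net.n_edges
    d = 2.0 * k / (n * (n - 1))
    local = nx.clustering(g)  # 0 for degree < 2 nodes
    if include_low_degree_in_c:
        c = float(np.mean(list(local.values())))
    else:
        vals = [v for node, v in local.items() if g.degree(node) >= 2]
        c = float(np.mean(vals)) if vals else 0.0
    l = nx.average_shortest_path_length(g)
    h = degree_heterogeneity(net.degree(), ddof=ddof)
    return NetworkParams(N=n, K=k, D=d, C=c, L=float(l), H=h)
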