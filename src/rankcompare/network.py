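"""Profile-similarity networks and affinity-propagation clustering.

A distance matrix (TES scale, values in [0, 2]) is turned into a
similarity network by mapping each pair to weight 2 - D and keeping
edges at or above a threshold; RRHO-derived weights (signed -log10 p)
are used directly in similarity mode.  Networks export to GraphML or a
TSV edge list.  Profiles are grouped without a preset cluster count by
affinity propagation on similarity = -distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .rrho import RRHOGrid
from .signatures import DistanceMatrix

__all__ = [
    "ProfileNetwork",
    "ClusterAssignment",
    "build_network",
    "rrho_edge_weight",
    "affinity_propagation",
    "export_network",
    "read_network",
]


@dataclass(frozen=True)
class ProfileNetwork:
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]
    threshold: float

    def __post_init__(self) -> None:
        seen = set()
        for a, b, w in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            pair = frozenset((a, b))
            if pair in seen:
                raise ValueError(f"duplicate edge {a!r}-{b!r}")
            seen.add(pair)
            if w < self.threshold:
                raise ValueError(f"edge {a!r}-{b!r} below threshold")


@dataclass(frozen=True)
class ClusterAssignment:
    labels: dict[str, int]
    exemplars: dict[int, str]
    converged: bool = True

    def __post_init__(self) -> None:
        for cid, name in self.exemplars.items():
            if self.labels.get(name) != cid:
                raise ValueError(f"exemplar {name!r} not in its own cluster {cid}")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def build_network(
    dist: DistanceMatrix, threshold: float, mode: str = "distance"
) -> ProfileNetwork:
    """Threshold a distance (or similarity) matrix into a weighted graph.

    distance mode: weight = 2 - D (TES-scale similarity); requires a
    non-negative threshold.  similarity mode: the matrix entries are
    edge weights as-is (e.g. RRHO map maxima).  An edge is kept iff its
    weight >= threshold; all nodes are kept regardless.
    """
    if mode not in ("distance", "similarity"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "distance" and threshold < 0:
        raise ValueError("threshold must be non-negative in distance mode")
    names = dist.names
    v = dist.values
    edges = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            w = 2.0 - v[i, j] if mode == "distance" else v[i, j]
            if w >= threshold:
                edges.append((names[i], names[j], float(w)))
    return ProfileNetwork(tuple(names), tuple(edges), threshold)


def rrho_edge_weight(grid: RRHOGrid) -> float:
    """Scalar edge weight for an RRHO comparison: the grid's maximum
    signed -log10 p (strongest co-regulation signal anywhere on the map)."""
    return float(grid.values.max())


def affinity_propagation(
    dist: DistanceMatrix,
    damping: float = 0.9,
    max_iter: int = 1000,
    preference: float | None = None,
) -> ClusterAssignment:
    """Affinity propagation on similarity = -distance.

    Preference defaults to the median similarity (the algorithm's
    standard choice, favoring a moderate number of exemplars).  If
    message passing has not converged after ``max_iter`` iterations a
    warning is issued and each profile falls back to its own singleton
    cluster rather than being left unlabeled.
    """
    if not (0.5 <= damping < 1.0):
        raise ValueError("damping must be in [0.5, 1)")
    sim = -np.asarray(dist.values, dtype=float)
    model = AffinityPropagation(
        affinity="precomputed",
        damping=damping,
        max_iter=max_iter,
        preference=preference,
        random_state=0,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        labels_arr = model.fit_predict(sim)
        converged = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
    names = dist.names
    if not converged or len(model.cluster_centers_indices_) == 0:
        warnings.warn(
            f"affinity propagation did not converge in {max_iter} iterations; "
            "returning singleton clusters",
            RuntimeWarning,
            stacklevel=2,
        )
        labels = {name: i for i, name in enumerate(names)}
        exemplars = {i: name for i, name in enumerate(names)}
        return ClusterAssignment(labels, exemplars, converged=False)
    labels = {name: int(lab) for name, lab in zip(names, labels_arr)}
    exemplars = {
        int(labels_arr[idx]): names[idx] for idx in model.cluster_centers_indices_
    }
    return ClusterAssignment(labels, exemplars, converged=True)


def _to_graph(net: ProfileNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for a, b, w in net.edges:
        g.add_edge(a, b, weight=w)
    return g


def export_network(net: ProfileNetwork, path, format: str = "graphml") -> None:
    """Write the network as GraphML or a 3-column TSV edge list.

    The edge-list variant prefixes one ``# node: NAME`` comment line per
    node so isolated nodes survive a round trip.
    """
    if format == "graphml":
        nx.write_graphml(_to_graph(net), path)
    elif format == "edgelist":
        with open(path, "w") as fh:
            for node in net.nodes:
                fh.write(f"# node: {node}\n")
            fh.write("source\ttarget\tweight\n")
            for a, b, w in net.edges:
                fh.write(f"{a}\t{b}\t{w:.10g}\n")
    else:
        raise ValueError(f"unknown format {format!r}: expected graphml or edgelist")


def read_network(path, format: str = "graphml", threshold: float = 0.0) -> ProfileNetwork:
    """Parse a file written by :func:`export_network` back into a network."""
    if format == "graphml":
        g = nx.read_graphml(path)
        nodes = tuple(g.nodes)
        edges = tuple((a, b, float(d["weight"])) for a, b, d in g.edges(data=True))
    elif format == "edgelist":
        nodes_list: list[str] = []
        edges_list: list[tuple[str, str, float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# node: "):
                    nodes_list.append(line[len("# node: ") :])
                elif line and not line.startswith("source\t"):
                    a, b, w = line.split("\t")
                    edges_list.append((a, b, float(w)))
        nodes, edges = tuple(nodes_list), tuple(edges_list)
    else:
        raise ValueError(f"unknown format {format!r}")
    return ProfileNetwork(nodes, edges, threshold)
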