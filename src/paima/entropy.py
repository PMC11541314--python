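"""Information-theoretic SNP-SNP interaction analysis.

For a binary phenotype Y and genotype attributes A, B, C (each 0/1/2):

* main effect of A: the mutual information I(A;Y);
* pairwise interaction information
  IG(A;B;Y) = I(AB;Y) - I(A;Y) - I(B;Y), positive for synergy (the pair
  carries information about Y that neither locus carries alone, e.g.
  epistasis) and negative for redundancy (shared information, typically
  linkage disequilibrium);
* three-way interaction gain
  TIG(A;B;C;Y) = I(ABC;Y) - sum of pairwise IG - sum of main effects,
  the information about Y attributable only to the joint triple.

These satisfy the exact decomposition
``I(ABC;Y) = sum(main) + sum(pairwise IG) + TIG`` by construction.

Scores are reported in bits (log base 2) and, in the interaction graph,
as percentages of the phenotype entropy H(Y) — percentages are
base-invariant.  The default estimator is the maximum-likelihood
(plug-in) one, matching the MDR and ViSEN tools; note that plug-in
information estimates carry a positive O(K / 2N) small-sample bias (K =
number of joint states), so pairwise IG on null data centres near
+ (K_AB - K_A - K_B + 1)/(2 N ln 2) bits rather than 0.  A Miller-Madow
bias correction is available via ``estimator="miller_madow"``.

Missing genotypes are handled listwise per quantity: rows missing any of
the attributes involved are excluded from that computation.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage

from .cohort import CohortDataset
from .variants import MISSING

log = logging.getLogger(__name__)

_LN2 = math.log(2.0)

EDGE_CLASSES = ("synergy_strong", "synergy", "additivity", "redundancy")

#: Edge-class bin edges in percent of H(Y):
#: > strong_cut synergy_strong; (0, strong_cut] synergy;
#: [additivity_floor, 0] additivity; < additivity_floor redundancy.
DEFAULT_EDGE_BINS = {"strong_cut": 2.0, "additivity_floor": -0.5}

#: Display cutoff for node scores, in percent of H(Y).
DEFAULT_NODE_THRESHOLD = 0.0667


def _check_estimator(estimator: str) -> None:
    if estimator not in ("plugin", "miller_madow"):
        raise ValueError("estimator must be 'plugin' or 'miller_madow'")


def entropy(labels: Sequence | np.ndarray, estimator: str = "plugin") -> float:
    """Shannon entropy in bits of a discrete vector (0 log 0 = 0)."""
    _check_estimator(estimator)
    x = np.asarray(labels)
    if x.size == 0:
        raise ValueError("cannot compute the entropy of an empty vector")
    _, counts = np.unique(x, return_counts=True)
    return _entropy_from_counts(counts, estimator)


def _entropy_from_counts(counts: np.ndarray, estimator: str) -> float:
    n = counts.sum()
    p = counts / n
    h = float(-(p * np.log2(p)).sum())
    if estimator == "miller_madow":
        h += (len(counts) - 1) / (2.0 * n * _LN2)
    return h


def _joint_code(columns: list[np.ndarray]) -> np.ndarray:
    """Encode rows of equal-length discrete vectors as one joint variable."""
    stacked = np.stack(columns, axis=1)
    _, codes = np.unique(stacked, axis=0, return_inverse=True)
    return codes


def _complete_rows(*vectors: np.ndarray) -> list[np.ndarray]:
    arrays = [np.asarray(v) for v in vectors]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("vectors must have equal length")
    ok = np.ones(n, dtype=bool)
    for a in arrays:
        ok &= a != MISSING
    if not ok.any():
        raise ValueError("no complete rows after removing missing entries")
    return [a[ok] for a in arrays]


def mutual_information(a, y, estimator: str = "plugin") -> float:
    """I(A;Y) = H(A) + H(Y) - H(A,Y) in bits (rows with missing excluded)."""
    a, y = _complete_rows(a, y)
    return (
        entropy(a, estimator)
        + entropy(y, estimator)
        - entropy(_joint_code([a, y]), estimator)
    )


def interaction_information(a, b, y, estimator: str = "plugin") -> float:
    """Pairwise interaction information IG(A;B;Y) in bits (may be negative)."""
    a, b, y = _complete_rows(a, b, y)
    ab = _joint_code([a, b])
    return (
        mutual_information(ab, y, estimator)
        - mutual_information(a, y, estimator)
        - mutual_information(b, y, estimator)
    )


def three_way_gain(a, b, c, y, estimator: str = "plugin") -> float:
    """Three-way interaction gain TIG(A;B;C;Y) in bits.

    All terms are evaluated on the rows complete in all four vectors, so
    the decomposition identity holds exactly.
    """
    a, b, c, y = _complete_rows(a, b, c, y)
    abc = _joint_code([a, b, c])
    total = mutual_information(abc, y, estimator)
    pair_gain = (
        interaction_information(a, b, y, estimator)
        + interaction_information(a, c, y, estimator)
        + interaction_information(b, c, y, estimator)
    )
    mains = (
        mutual_information(a, y, estimator)
        + mutual_information(b, y, estimator)
        + mutual_information(c, y, estimator)
    )
    return total - pair_gain - mains


def classify_edge(percent: float, bins: dict | None = None) -> str:
    """Bin an edge score (percent of H(Y)) into a synergy/redundancy class."""
    bins = dict(DEFAULT_EDGE_BINS, **(bins or {}))
    if percent > bins["strong_cut"]:
        return "synergy_strong"
    if percent > 0:
        return "synergy"
    if percent >= bins["additivity_floor"]:
        return "additivity"
    return "redundancy"


@dataclass
class InteractionGraph:
    """Entropy-based interaction network over the variants of a cohort.

    Node scores are main-effect information gains I(A;Y) as percent of
    H(Y); edge scores pairwise interaction information as percent of
    H(Y); triangles (optional) three-way gains.  Scores below the display
    thresholds are flagged ``hidden`` but never removed.
    """

    graph: nx.Graph
    h_y: float
    node_threshold: float
    edge_bins: dict
    triangles: dict[tuple[str, str, str], float] = field(default_factory=dict)
    triangle_threshold: float | None = None

    @property
    def labels(self) -> list[str]:
        return list(self.graph.nodes)

    def node_scores(self) -> dict[str, float]:
        return {v: d["score"] for v, d in self.graph.nodes(data=True)}

    def edge_scores(self) -> dict[tuple[str, str], float]:
        return {(u, v): d["score"] for u, v, d in self.graph.edges(data=True)}

    def visible_subgraph(self) -> nx.Graph:
        """Subgraph of non-hidden nodes and edges (the displayed network)."""
        vis = self.graph.edge_subgraph(
            [(u, v) for u, v, d in self.graph.edges(data=True) if not d["hidden"]]
        ).copy()
        vis.add_nodes_from(
            v for v, d in self.graph.nodes(data=True) if not d["hidden"]
        )
        return vis

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "h_y_bits": self.h_y,
            "node_threshold": self.node_threshold,
            "edge_bins": dict(self.edge_bins),
            "triangle_threshold": self.triangle_threshold,
            "nodes": [
                {"id": v, "score_percent": d["score"], "hidden": bool(d["hidden"])}
                for v, d in self.graph.nodes(data=True)
            ],
            "edges": [
                {
                    "source": u,
                    "target": v,
                    "score_percent": d["score"],
                    "class": d["cls"],
                    "hidden": bool(d["hidden"]),
                }
                for u, v, d in self.graph.edges(data=True)
            ],
            "triangles": [
                {"nodes": list(tri), "score_percent": s} for tri, s in self.triangles.items()
            ],
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload


def build_graph(
    data: CohortDataset,
    node_threshold: float = DEFAULT_NODE_THRESHOLD,
    edge_bins: dict | None = None,
    include_triangles: bool = False,
    triangle_threshold: float | None = None,
    edge_threshold: float | None = None,
    estimator: str = "plugin",
) -> InteractionGraph:
    """Score all main effects, pairs, and optionally triples of a cohort.

    Edge display: an edge is hidden when ``edge_threshold`` (percent) is
    given and the score falls below it; nodes are hidden below
    ``node_threshold``.  Hidden elements stay in the graph.
    """
    if data.n_variants < 2:
        raise ValueError("need at least two variants")
    bins = dict(DEFAULT_EDGE_BINS, **(edge_bins or {}))
    y = data.phenotype.astype(np.int64)
    h_y = entropy(y, estimator)
    if h_y <= 0:
        raise ValueError("phenotype entropy must be positive")
    labels = data.column_labels()
    cols = [data.genotypes[:, j].astype(np.int64) for j in range(data.n_variants)]

    g = nx.Graph()
    for lab, col in zip(labels, cols):
        score = 100.0 * mutual_information(col, y, estimator) / h_y
        g.add_node(lab, score=score, hidden=bool(score < node_threshold))
    for (i, a), (j, b) in itertools.combinations(enumerate(cols), 2):
        score = 100.0 * interaction_information(a, b, y, estimator) / h_y
        hidden = bool(edge_threshold is not None and score < edge_threshold)
        g.add_edge(labels[i], labels[j], score=score, cls=classify_edge(score, bins), hidden=hidden)

    triangles: dict[tuple[str, str, str], float] = {}
    if include_triangles:
        for (i, a), (j, b), (k, c) in itertools.combinations(enumerate(cols), 3):
            score = 100.0 * three_way_gain(a, b, c, y, estimator) / h_y
            triangles[(labels[i], labels[j], labels[k])] = score
    return InteractionGraph(
        graph=g,
        h_y=h_y,
        node_threshold=node_threshold,
        edge_bins=bins,
        triangles=triangles,
        triangle_threshold=triangle_threshold,
    )


@dataclass
class Dendrogram:
    """Average-linkage merge tree over variants.

    Built from the dissimilarity d(A,B) = max(edge) - edge(A,B), so the
    strongest synergistic pair merges first.  Leaves are ordered
    lexicographically, which also makes tie-breaks deterministic.
    """

    linkage_matrix: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        """Per merge step, the two leaf sets joined and the merge height."""
        clusters: dict[int, frozenset] = {
            i: frozenset({lab}) for i, lab in enumerate(self.labels)
        }
        out = []
        n = len(self.labels)
        for step, (a, b, h, _) in enumerate(self.linkage_matrix):
            left, right = clusters[int(a)], clusters[int(b)]
            out.append((left, right, float(h)))
            clusters[n + step] = left | right
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.labels)
        return str(tree).strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def dendrogram(graph: InteractionGraph) -> Dendrogram:
    """Agglomerate variants by interaction strength (average linkage)."""
    labels = sorted(graph.labels)
    if len(labels) < 2:
        raise ValueError("need at least two nodes")
    scores = graph.edge_scores()

    def edge(u: str, v: str) -> float:
        return scores.get((u, v), scores.get((v, u), 0.0))

    m = max(scores.values())
    condensed = np.array(
        [m - edge(u, v) for u, v in itertools.combinations(labels, 2)]
    )
    z = linkage(condensed, method="average")
    return Dendrogram(linkage_matrix=z, labels=labels)


@dataclass
class GraphStats:
    """Summary statistics of (by default) the visible network."""

    n_nodes: int
    n_edges: int
    edge_sd: float
    max_betweenness: float
    max_closeness: float
    betweenness: dict[str, float]
    closeness: dict[str, float]

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "edge_score_sd": self.edge_sd,
            "max_betweenness": self.max_betweenness,
            "max_closeness": self.max_closeness,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload


def graph_stats(graph: InteractionGraph, visible_only: bool = True) -> GraphStats:
    """Edge-score SD plus betweenness/closeness centralities and maxima.

    Betweenness is the unnormalized shortest-path pair count; closeness
    the standard inverse-mean-distance (per connected component).  On an
    empty visible subgraph, zeros are returned with a warning.
    """
    g = graph.visible_subgraph() if visible_only else graph.graph
    scores = [d["score"] for _, _, d in g.edges(data=True)]
    if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
        log.warning("graph has no visible edges; returning zero statistics")
        return GraphStats(g.number_of_nodes(), 0, 0.0, 0.0, 0.0, {}, {})
    betw = nx.betweenness_centrality(g, normalized=False)
    clos = nx.closeness_centrality(g)
    sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
    return GraphStats(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        edge_sd=sd,
        max_betweenness=float(max(betw.values())),
        max_closeness=float(max(clos.values())),
        betweenness=betw,
        closeness=clos,
    )
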