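"""Citation graph construction, neighborhood queries and the shuffle null model.

Articles are nodes; citations are directed (citing → cited) edges that the
analysis treats as undirected connections unless a direction mode is chosen.
Direction vocabulary follows bibliometric usage: the *citing* neighbors of a
focal article are the articles that cite it (its in-edges); its *cited*
neighbors are the references appearing in the article itself (out-edges).

Second-degree neighborhoods (everything within two undirected steps, first
degree included) are computed lazily per focal article by a depth-limited
traversal; they are never materialized corpus-wide, since at bibliographic
scale the second-degree pair set is orders of magnitude larger than the edge
list.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .ingest import AnnotationStore, ArticleID

MODES = ("undirected", "citing", "cited")


@dataclass
class CitationGraph:
    """Directed citation-pair store with derived adjacency.

    Self-loops are dropped and duplicate directed pairs collapsed at build
    time; both counts are retained for provenance.
    """

    _g: nx.DiGraph = field(default_factory=nx.DiGraph, repr=False)
    n_self_loops_dropped: int = 0
    n_duplicates_dropped: int = 0

    @property
    def nodes(self) -> set[ArticleID]:
        return set(self._g.nodes)

    @property
    def directed_pairs(self) -> set[tuple[ArticleID, ArticleID]]:
        return set(self._g.edges)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, node: ArticleID) -> bool:
        return node in self._g

    def out_neighbors(self, node: ArticleID) -> set[ArticleID]:
        """Articles cited by ``node`` (its references)."""
        return set(self._g.successors(node)) if node in self._g else set()

    def in_neighbors(self, node: ArticleID) -> set[ArticleID]:
        """Articles citing ``node``."""
        return set(self._g.predecessors(node)) if node in self._g else set()

    def undirected_neighbors(self, node: ArticleID) -> set[ArticleID]:
        return self.out_neighbors(node) | self.in_neighbors(node)


def build_graph(pairs: Iterable[tuple[ArticleID, ArticleID]]) -> CitationGraph:
    """Build a :class:`CitationGraph` from (citing, cited) pairs.

    Duplicate directed pairs collapse; self-citations are dropped. Both are
    counted on the returned graph. An empty input yields a valid empty graph.
    """
    g = nx.DiGraph()
    self_loops = 0
    duplicates = 0
    for citing, cited in pairs:
        # every endpoint is a node, even when its edge is dropped
        g.add_node(citing)
        g.add_node(cited)
        if citing == cited:
            self_loops += 1
            continue
        if g.has_edge(citing, cited):
            duplicates += 1
            continue
        g.add_edge(citing, cited)
    return CitationGraph(g, n_self_loops_dropped=self_loops,
                         n_duplicates_dropped=duplicates)


def neighbors(
    graph: CitationGraph,
    focal: ArticleID,
    mode: str = "undirected",
    degree: int = 1,
) -> set[ArticleID]:
    """Neighbor set of ``focal`` under a direction mode and degree.

    ``undirected`` unions in- and out-neighbors; ``citing`` keeps only
    articles citing the focal; ``cited`` only the focal's references. Degree 2
    comprises first- and second-degree neighbors (two applications of the
    chosen step), always excluding the focal itself. A focal absent from the
    graph yields the empty set.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if degree not in (1, 2):
        raise ValueError(f"degree must be 1 or 2, got {degree!r}")
    if focal not in graph:
        return set()
    step = {
        "undirected": graph.undirected_neighbors,
        "citing": graph.in_neighbors,
        "cited": graph.out_neighbors,
    }[mode]
    first = step(focal)
    if degree == 1:
        return first - {focal}
    out = set(first)
    for n in first:
        out |= step(n)
    out.discard(focal)
    return out


def randomize_graph(
    pairs: Sequence[tuple[ArticleID, ArticleID]],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CitationGraph, dict]:
    """Null model: permute the multiset of citing-side identifiers.

    The first element of every pair is replaced by a random permutation of
    all first elements; second elements stay in place. This destroys topical
    structure while preserving each side's marginal counts. The shuffled raw
    pairs then pass through :func:`build_graph` cleanup (self-loop drop,
    duplicate collapse), whose attrition is reported in the metadata dict.
    """
    if not pairs:
        raise ValueError("randomize_graph requires a non-empty pair list")
    if rng is None:
        rng = np.random.default_rng(seed)
    firsts = [p[0] for p in pairs]
    perm = rng.permutation(len(firsts))
    shuffled = [(firsts[perm[i]], pairs[i][1]) for i in range(len(pairs))]
    graph = build_graph(shuffled)
    meta = {
        "seed": seed,
        "n_input_pairs": len(pairs),
        "n_self_loops_dropped": graph.n_self_loops_dropped,
        "n_duplicates_dropped": graph.n_duplicates_dropped,
        "n_edges": graph.n_edges,
    }
    return graph, meta


@dataclass
class NeighborhoodProfile:
    """Annotation document frequencies over one article's citation neighborhood.

    ``freq[a]`` counts the *distinct* annotated neighbors whose annotation set
    contains ``a``; the focal article's own annotations are never included.
    """

    focal: ArticleID
    mode: str
    degree: int
    total_neighbors: int
    annotated_neighbors: int
    freq: dict[str, int] = field(default_factory=dict)

    @property
    def unique_annotations(self) -> frozenset[str]:
        return frozenset(self.freq)

    def __bool__(self) -> bool:
        return bool(self.freq)


def neighborhood_profile(
    graph: CitationGraph,
    store: AnnotationStore,
    focal: ArticleID,
    mode: str = "undirected",
    degree: int = 1,
) -> NeighborhoodProfile:
    """Profile the annotations carried by ``focal``'s neighbors.

    A focal absent from the graph yields a zero-neighbor profile rather than
    an error, so corpus sweeps can count such exclusions.
    """
    nbrs = neighbors(graph, focal, mode=mode, degree=degree)
    counts: Counter[str] = Counter()
    annotated = 0
    for n in nbrs:
        annots = store.get(n)
        if annots:
            annotated += 1
            counts.update(annots)
    return NeighborhoodProfile(
        focal=focal,
        mode=mode,
        degree=degree,
        total_neighbors=len(nbrs),
        annotated_neighbors=annotated,
        freq=dict(counts),
    )
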