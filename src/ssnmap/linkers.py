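"""Linker discovery: similarity paths, control censuses, tree selection.

A "linker" is a sequence (or representative node) lying on a similarity
path that connects two otherwise distinct subgroups.  Given a thresholded
representative network and a founder sequence per subgroup, the shortest
path between the two founder-containing anchor nodes is extracted either
by unweighted hops or with edges weighted by ``1 / -log10(score)`` so that
more significant edges are shorter.  Because small numbers of edges
linking highly diverse subgroups can be statistically suspect, a control
census expands the neighborhood of the crossing edges (two hops by
default), rebuilds the one-sequence-per-node network over all member
sequences of the collected nodes, and counts the sequence-level edges that
cross the two subgroups at the subgrouping threshold.  Finally, the
tree-input selection procedure picks, from each first-neighbor node of the
linker nodes, the member scoring highest against that node's profile,
keeping only fused-length sequences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .pairwise import ScoringScheme, SimilarityEdge, align_pair, make_aligner
from .records import SequenceRecord
from .repnet import RepresentativeNetwork
from .subgroups import SubgroupProfile, build_msa, build_profile, score_sequence

logger = logging.getLogger(__name__)


@dataclass
class LinkerPath:
    """An ordered node path between two founder anchors."""

    nodes: tuple[str, ...]
    edge_scores: tuple[float, ...]  # geometric-mean E-value per step
    step_identities: tuple[float, ...]  # identity of representative pair
    weighting: str = "hops"
    alternates: tuple[tuple[str, ...], ...] = ()
    connected: bool = True

    def __post_init__(self) -> None:
        if self.connected and len(self.nodes) >= 1:
            if len(self.edge_scores) != len(self.nodes) - 1:
                raise ValueError("need one edge score per step")
            if len(set(self.nodes)) != len(self.nodes):
                raise ValueError("path must not repeat nodes")

    @property
    def n_steps(self) -> int:
        return max(len(self.nodes) - 1, 0)

    def report_rows(self) -> list[dict]:
        return [
            {
                "step": i + 1,
                "node_a": self.nodes[i],
                "node_b": self.nodes[i + 1],
                "log10_score": math.log10(self.edge_scores[i]),
                "identity": self.step_identities[i],
            }
            for i in range(self.n_steps)
        ]


@dataclass
class ControlCensus:
    """Expanded-neighborhood inter-subgroup edge census."""

    seed_nodes: tuple[str, ...]
    expanded_nodes: tuple[str, ...]
    crossing_edge_count: int
    min_crossing_evalue: float
    max_crossing_evalue: float
    crossing_edges: tuple[SimilarityEdge, ...] = ()

    def __post_init__(self) -> None:
        if not set(self.seed_nodes) <= set(self.expanded_nodes):
            raise ValueError("expanded node set must contain the seed nodes")


@dataclass
class TreeSelection:
    """Sequences selected for phylogenetic reconstruction."""

    selected: tuple[str, ...]
    provenance: dict[str, dict]  # seq id -> {node, profile_score}
    min_length: int
    dropped_nodes: tuple[str, ...] = ()


def find_anchor_node(network: RepresentativeNetwork, founder_id: str) -> str:
    """The unique representative node containing the founder sequence."""
    for node in network.nodes:
        if founder_id in node.members:
            return node.node_id
    raise KeyError(f"founder sequence {founder_id!r} not found in any node")


def shortest_similarity_path(
    network: RepresentativeNetwork,
    src_node: str,
    dst_node: str,
    weighting: str = "hops",
    records: Mapping[str, SequenceRecord] | None = None,
    scheme: ScoringScheme | None = None,
) -> LinkerPath:
    """Shortest path between two anchor nodes.

    ``weighting='hops'`` is unweighted BFS; ``weighting='neglog'`` weights
    each edge by ``1 / -log10(score)`` so that more significant edges are
    shorter.  All tying shortest paths are enumerated; the lexicographically
    smallest node sequence is primary and the rest are reported as
    alternates.  A disconnected pair yields an explicit ``connected=False``
    result, not an exception.
    """
    if weighting not in ("hops", "neglog"):
        raise ValueError("weighting must be 'hops' or 'neglog'")
    g = network.graph()
    for node in (src_node, dst_node):
        if node not in g:
            raise KeyError(f"node {node!r} not in network")
    for a, b, data in g.edges(data=True):
        neg = -math.log10(max(data["score"], 1e-300))
        g[a][b]["w"] = 1.0 / neg if neg > 0 else math.inf
    weight = None if weighting == "hops" else "w"
    if src_node == dst_node:
        return LinkerPath(nodes=(src_node,), edge_scores=(),
                          step_identities=(), weighting=weighting)
    try:
        paths = sorted(
            tuple(p) for p in nx.all_shortest_paths(
                g, src_node, dst_node, weight=weight)
        )
    except nx.NetworkXNoPath:
        return LinkerPath(nodes=(), edge_scores=(), step_identities=(),
                          weighting=weighting, connected=False)
    primary = paths[0]
    scores = tuple(
        g[primary[i]][primary[i + 1]]["score"] for i in range(len(primary) - 1)
    )
    identities: tuple[float, ...]
    if records is not None:
        scheme = scheme or ScoringScheme()
        aligner = make_aligner(scheme)
        node_map = network.node_map()
        identities = tuple(
            align_pair(
                records[node_map[primary[i]].representative],
                records[node_map[primary[i + 1]].representative],
                scheme, aligner=aligner,
            ).identity
            for i in range(len(primary) - 1)
        )
    else:
        identities = tuple(float("nan") for _ in range(len(primary) - 1))
    return LinkerPath(
        nodes=primary,
        edge_scores=scores,
        step_identities=identities,
        weighting=weighting,
        alternates=tuple(p for p in paths[1:]),
    )


def control_expansion(
    network: RepresentativeNetwork,
    crossing_edges: Sequence[tuple[str, str]],
    subgroup_of_sequence: Mapping[str, str],
    records: Mapping[str, SequenceRecord],
    crossing_threshold: float,
    hops: int = 2,
    member_edges: Iterable[SimilarityEdge] | None = None,
    scheme: ScoringScheme | None = None,
) -> ControlCensus:
    """Two-hop control census of inter-subgroup sequence-level edges.

    ``crossing_edges`` are the representative-node pairs whose edges cross
    the two subgroups.  Nodes within ``hops`` of any incident node are
    collected, the one-sequence-per-node network over all their member
    sequences is built (from ``member_edges`` if provided, otherwise by
    aligning all pairs), and the sequence-level edges that join the two
    subgroup labels with E-values more significant than
    ``crossing_threshold`` are counted and ranged.
    """
    if hops < 0:
        raise ValueError("hops must be >= 0")
    seeds = sorted({n for pair in crossing_edges for n in pair})
    if not seeds:
        return ControlCensus(seed_nodes=(), expanded_nodes=(),
                             crossing_edge_count=0,
                             min_crossing_evalue=math.nan,
                             max_crossing_evalue=math.nan)
    g = network.graph()
    expanded: set[str] = set()
    for seed in seeds:
        expanded.update(
            nx.single_source_shortest_path_length(g, seed, cutoff=hops))
    node_map = network.node_map()
    member_ids = sorted(
        m for n in expanded for m in node_map[n].members
    )
    member_set = set(member_ids)
    labels = {m: subgroup_of_sequence.get(m) for m in member_ids}
    present = sorted({v for v in labels.values() if v})
    if member_edges is None:
        scheme = scheme or ScoringScheme()
        aligner = make_aligner(scheme)
        candidates = []
        for i, a in enumerate(member_ids):
            for b in member_ids[i + 1:]:
                candidates.append(
                    align_pair(records[a], records[b], scheme, aligner=aligner))
        member_edges = candidates
    crossing: list[SimilarityEdge] = []
    for e in member_edges:
        if e.query not in member_set or e.subject not in member_set:
            continue
        la, lb = labels[e.query], labels[e.subject]
        if la is None or lb is None or la == lb:
            continue
        if e.evalue < crossing_threshold:
            crossing.append(e)
    if len(present) > 2:
        logger.warning("census saw %d subgroup labels; counting all "
                       "between-label edges", len(present))
    evals = [e.evalue for e in crossing]
    return ControlCensus(
        seed_nodes=tuple(seeds),
        expanded_nodes=tuple(sorted(expanded)),
        crossing_edge_count=len(crossing),
        min_crossing_evalue=min(evals) if evals else math.nan,
        max_crossing_evalue=max(evals) if evals else math.nan,
        crossing_edges=tuple(crossing),
    )


def select_tree_sequences(
    network: RepresentativeNetwork,
    linker_nodes: Sequence[str],
    records: Mapping[str, SequenceRecord],
    min_len: int = 110,
    fused_only: bool = True,
    profiles: Mapping[str, SubgroupProfile] | None = None,
) -> TreeSelection:
    """Pick one best sequence per first-neighbor node of the linker nodes.

    For every node adjacent to (or equal to) a named linker node, the member
    scoring highest against that node's profile is selected (profiles are
    built from the node's members when not supplied; a singleton node
    contributes its only member directly).  With ``fused_only`` enabled,
    members of length <= ``min_len`` are dropped first; nodes left empty by
    the filter are dropped with a log entry.  Ties in profile score break
    by sequence id.
    """
    g = network.graph()
    node_map = network.node_map()
    chosen_nodes: set[str] = set()
    for ln in linker_nodes:
        if ln not in g:
            raise KeyError(f"linker node {ln!r} not in network")
        chosen_nodes.add(ln)
        chosen_nodes.update(g.neighbors(ln))
    selected: list[str] = []
    provenance: dict[str, dict] = {}
    dropped: list[str] = []
    for node_id in sorted(chosen_nodes):
        members = [records[m] for m in node_map[node_id].members]
        if fused_only:
            members = [m for m in members if len(m.sequence) > min_len]
        if not members:
            logger.info("node %s has no member above length %d; dropped",
                        node_id, min_len)
            dropped.append(node_id)
            continue
        if len(members) == 1:
            best, best_score = members[0], math.nan
        else:
            if profiles is not None and node_id in profiles:
                profile = profiles[node_id]
            else:
                profile = build_profile(
                    build_msa(members), label=node_id)
            scored = sorted(
                ((score_sequence(profile, m), m.id) for m in members),
                key=lambda t: (-t[0], t[1]),
            )
            best_score = scored[0][0]
            best = next(m for m in members if m.id == scored[0][1])
        selected.append(best.id)
        provenance[best.id] = {"node": node_id, "profile_score": best_score}
    return TreeSelection(
        selected=tuple(selected),
        provenance=provenance,
        min_length=min_len,
        dropped_nodes=tuple(dropped),
    )
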