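"""Representative sequence similarity networks.

A representative network compresses a one-sequence-per-node similarity
network: sequences are first binned into representative nodes by greedy
incremental clustering at a pairwise-identity cutoff (CD-HIT style: longest
sequence founds a cluster, later sequences join the first cluster whose
representative they match above the cutoff, identity counted over the
shorter sequence), and an edge is drawn between two representative nodes
whenever at least one member-level hit crosses them.  The representative
edge score is the geometric mean of all crossing member E-values,

    s_AB = 10 ** mean(log10 E_i),

which lies between the smallest and largest member E-value.  Thresholding
the network at an E-value ``T`` retains edges with ``s_AB < T`` (strictly
"more significant than") while keeping all nodes, and connected components
of the thresholded network are the basis of subgroup definitions.
"""

from __future__ import annotations

import math
import xml.sax.saxutils as saxutils
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .pairwise import (
    E_VALUE_FLOOR,
    ScoringScheme,
    SimilarityEdge,
    align_pair,
    make_aligner,
)
from .records import SequenceRecord


@dataclass(frozen=True)
class RepresentativeNode:
    """A cluster of sequences at an identity cutoff."""

    node_id: str
    representative: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be one of the members")

    @property
    def member_count(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RepresentativeEdge:
    """Geometric-mean-scored link between two representative nodes."""

    node_a: str
    node_b: str
    score: float  # geometric mean of member E-values
    member_edge_count: int

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError("representative self-edges are not allowed")
        if self.member_edge_count < 1:
            raise ValueError("a representative edge needs >= 1 member edge")

    @property
    def log10_score(self) -> float:
        return math.log10(max(self.score, E_VALUE_FLOOR))


@dataclass
class RepresentativeNetwork:
    """Nodes plus (optionally thresholded) representative edges."""

    nodes: list[RepresentativeNode]
    edges: list[RepresentativeEdge]
    threshold: float | None = None

    def node_of_sequence(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for n in self.nodes:
            for m in n.members:
                out[m] = n.node_id
        return out

    def node_map(self) -> dict[str, RepresentativeNode]:
        return {n.node_id: n for n in self.nodes}

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(n.node_id for n in self.nodes)
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, score=e.score,
                       log10_score=e.log10_score, k=e.member_edge_count)
        return g


def deduplicate(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Collapse exact-string duplicates.

    Returns the nonredundant records (first occurrence kept) and a map from
    every original id to the id of the sequence kept for it.
    """
    seen: dict[str, str] = {}
    kept: list[SequenceRecord] = []
    mapping: dict[str, str] = {}
    for r in records:
        if r.sequence in seen:
            mapping[r.id] = seen[r.sequence]
        else:
            seen[r.sequence] = r.id
            mapping[r.id] = r.id
            kept.append(r)
    return kept, mapping


def cluster_representatives(
    records: Sequence[SequenceRecord],
    identity_cutoff: float,
    scheme: ScoringScheme | None = None,
    inclusive: bool = False,
) -> list[RepresentativeNode]:
    """Greedy incremental clustering at a pairwise-identity cutoff.

    Sequences are processed by decreasing length (ties broken by id); each
    joins the first existing cluster whose representative it matches at an
    identity above the cutoff (counted over the shorter sequence), else it
    founds a new cluster.  The comparison is strict (``>``) by default;
    ``inclusive=True`` switches to ``>=``.
    """
    if not 0.0 < identity_cutoff <= 1.0:
        raise ValueError("identity cutoff must lie in (0, 1]")
    scheme = scheme or ScoringScheme()
    scheme = replace(scheme, identity_denominator="shorter")
    aligner = make_aligner(scheme)
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[SequenceRecord] = []
    members: list[list[str]] = []
    for rec in ordered:
        placed = False
        for ci, rep in enumerate(reps):
            if rec.sequence == rep.sequence:
                identity = 1.0
            else:
                identity = align_pair(rep, rec, scheme, aligner=aligner).identity
            hit = identity >= identity_cutoff if inclusive \
                else identity > identity_cutoff
            if hit:
                members[ci].append(rec.id)
                placed = True
                break
        if not placed:
            reps.append(rec)
            members.append([rec.id])
    return [
        RepresentativeNode(node_id=rep.id, representative=rep.id,
                           members=tuple(mem))
        for rep, mem in zip(reps, members)
    ]


def build_representative_edges(
    nodes: Sequence[RepresentativeNode],
    member_edges: Iterable[SimilarityEdge],
) -> list[RepresentativeEdge]:
    """Geometric-mean representative edges from member-level hits.

    A representative edge exists iff at least one member edge crosses the
    node pair; its score is 10 raised to the mean log10 of all crossing
    member E-values (clamped at the floor before taking logs).  Member
    edges inside a single node are ignored; edges naming unknown sequence
    ids are an error.
    """
    seq_to_node: dict[str, str] = {}
    for n in nodes:
        for m in n.members:
            seq_to_node[m] = n.node_id
    sums: dict[tuple[str, str], list[float]] = {}
    for e in member_edges:
        for sid in (e.query, e.subject):
            if sid not in seq_to_node:
                raise KeyError(f"member edge references unknown sequence {sid!r}")
        a, b = seq_to_node[e.query], seq_to_node[e.subject]
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        sums.setdefault(key, []).append(
            math.log10(max(e.evalue, E_VALUE_FLOOR)))
    edges = []
    for (a, b), logs in sorted(sums.items()):
        edges.append(
            RepresentativeEdge(
                node_a=a,
                node_b=b,
                score=10.0 ** (sum(logs) / len(logs)),
                member_edge_count=len(logs),
            )
        )
    return edges


def build_representative_network(
    records: Sequence[SequenceRecord],
    member_edges: Iterable[SimilarityEdge],
    identity_cutoff: float,
    scheme: ScoringScheme | None = None,
) -> RepresentativeNetwork:
    """Cluster records and build the (unthresholded) representative network."""
    nodes = cluster_representatives(records, identity_cutoff, scheme)
    edges = build_representative_edges(nodes, member_edges)
    return RepresentativeNetwork(nodes=nodes, edges=edges)


def apply_threshold(network: RepresentativeNetwork, T: float) -> RepresentativeNetwork:
    """Keep edges strictly more significant than ``T``; nodes always stay."""
    if T <= 0:
        raise ValueError("threshold must be positive")
    return RepresentativeNetwork(
        nodes=list(network.nodes),
        edges=[e for e in network.edges if e.score < T],
        threshold=T,
    )


def connected_components(network: RepresentativeNetwork) -> list[tuple[str, ...]]:
    """Undirected components, each sorted, ordered by smallest node id."""
    comps = nx.connected_components(network.graph())
    return sorted((tuple(sorted(c)) for c in comps), key=lambda c: c[0])


def sequence_partition(
    network: RepresentativeNetwork,
    components: Sequence[tuple[str, ...]] | None = None,
) -> dict[str, int]:
    """Map every member sequence to its component index."""
    if components is None:
        components = connected_components(network)
    node_comp = {n: i for i, comp in enumerate(components) for n in comp}
    seq_node = network.node_of_sequence()
    return {seq: node_comp[node] for seq, node in seq_node.items()}


# ---------------------------------------------------------------------------
# Export


def export_network(
    network: RepresentativeNetwork,
    out_path: str | Path,
    fmt: str = "tsv",
    node_annotations: Mapping[str, Mapping[str, object]] | None = None,
) -> Path:
    """Write the network as an edge TSV, SIF, or XGMML file.

    The TSV carries node and edge tables in two sections; SIF and XGMML are
    loadable by standard network viewers.  ``node_annotations`` maps node id
    to extra attribute columns (subgroup, taxon, census flags ...).
    """
    out_path = Path(out_path)
    ann = node_annotations or {}
    if fmt == "tsv":
        _export_tsv(network, out_path, ann)
    elif fmt == "sif":
        with open(out_path, "w") as fh:
            for e in network.edges:
                fh.write(f"{e.node_a}\tsim\t{e.node_b}\n")
    elif fmt == "xgmml":
        _export_xgmml(network, out_path, ann)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return out_path


def _export_tsv(network, out_path, ann) -> None:
    keys = sorted({k for a in ann.values() for k in a})
    with open(out_path, "w") as fh:
        fh.write("#nodes\n")
        fh.write("\t".join(["node", "representative", "member_count"] + keys) + "\n")
        for n in network.nodes:
            extra = [str(ann.get(n.node_id, {}).get(k, "")) for k in keys]
            fh.write("\t".join([n.node_id, n.representative,
                                str(n.member_count)] + extra) + "\n")
        fh.write("#edges\n")
        fh.write("node_a\tnode_b\tlog10_score\tmember_edge_count\n")
        for e in network.edges:
            fh.write(f"{e.node_a}\t{e.node_b}\t{e.log10_score:.12g}\t"
                     f"{e.member_edge_count}\n")


def read_network_tsv(path: str | Path) -> RepresentativeNetwork:
    """Read a network written by :func:`export_network` (tsv format)."""
    nodes: list[RepresentativeNode] = []
    edges: list[RepresentativeEdge] = []
    section = None
    header: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line == "#nodes":
                section, header = "nodes", []
                continue
            if line == "#edges":
                section, header = "edges", []
                continue
            if not header:
                header = line.split("\t")
                continue
            parts = line.split("\t")
            if section == "nodes":
                # Members other than the representative are not serialized
                # in the edge TSV; nodes round-trip as singleton stubs with
                # the recorded member count.
                nodes.append(
                    RepresentativeNode(node_id=parts[0], representative=parts[0],
                                       members=(parts[0],) * 1)
                )
            else:
                edges.append(
                    RepresentativeEdge(
                        node_a=parts[0],
                        node_b=parts[1],
                        score=10.0 ** float(parts[2]),
                        member_edge_count=int(parts[3]),
                    )
                )
    return RepresentativeNetwork(nodes=nodes, edges=edges)


def _export_xgmml(network, out_path, ann) -> None:
    esc = saxutils.quoteattr
    with open(out_path, "w") as fh:
        fh.write('<?xml version="1.0" encoding="UTF-8"?>\n')
        fh.write('<graph label="ssnmap network" directed="0" '
                 'xmlns="http://www.cs.rpi.edu/XGMML">\n')
        for n in network.nodes:
            fh.write(f"  <node id={esc(n.node_id)} label={esc(n.node_id)}>\n")
            fh.write(f'    <att name="member_count" type="integer" '
                     f'value="{n.member_count}"/>\n')
            for k, v in sorted(ann.get(n.node_id, {}).items()):
                fh.write(f"    <att name={esc(str(k))} type=\"string\" "
                         f"value={esc(str(v))}/>\n")
            fh.write("  </node>\n")
        for e in network.edges:
            fh.write(f"  <edge source={esc(e.node_a)} target={esc(e.node_b)}>\n")
            fh.write(f'    <att name="log10_score" type="real" '
                     f'value="{e.log10_score:.12g}"/>\n')
            fh.write("  </edge>\n")
        fh.write("</graph>\n")
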