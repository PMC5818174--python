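"""Representative network: clustering, geometric-mean edges, components."""

from __future__ import annotations

import xml.etree.ElementTree as ET

import numpy as np
import pytest

import ssnmap as m
from ssnmap.pairwise import SimilarityEdge
from ssnmap.records import SequenceRecord
from ssnmap.repnet import RepresentativeNode, read_network_tsv

import oracles


def _edge(q, s, e):
    return SimilarityEdge(query=q, subject=s, score=100.0, evalue=e,
                          identity=0.5, align_len=50)


class TestDeduplicate:
    def test_two_identical_collapse(self):
        recs = [SequenceRecord("a", "MPAAAA"), SequenceRecord("b", "MPAAAA")]
        kept, mapping = m.deduplicate(recs)
        assert len(kept) == 1
        assert mapping == {"a": "a", "b": "a"}

    def test_all_unique_is_identity(self, family):
        kept, mapping = m.deduplicate(family.records)
        assert len(kept) == len({r.sequence for r in family.records})
        assert all(mapping[r.id] == r.id for r in kept)

    def test_planted_duplicates_counted_by_set_cardinality(self, family):
        recs = list(family.records) + [
            SequenceRecord(f"dup{i}", family.records[i].sequence)
            for i in range(10)
        ]
        kept, mapping = m.deduplicate(recs)
        assert len(kept) == len({r.sequence for r in recs})
        assert len(mapping) == len(recs)


class TestClustering:
    def test_cutoff_one_keeps_distinct_sequences_apart(self):
        recs = [SequenceRecord(f"s{i}", seq) for i, seq in enumerate(
            ["MPVIAQEMKHRAWLEG", "MPVIAQEMKHRAWLEC", "MPWWCCDDEEFFGGHH"])]
        nodes = m.cluster_representatives(recs, 1.0)
        assert len(nodes) == 3

    def test_hand_checkable_three_sequence_case(self):
        base = "MPVIAQEMKHRAWLEGHIKVDNMPRSTW"  # 28 residues
        near = base[:-3] + "WYC"  # ~89% identical to base
        far = "MPCWYGHDNEAKRSTVLIFQCWYGHDNE"
        recs = [SequenceRecord("a", base), SequenceRecord("b", near),
                SequenceRecord("c", far)]
        nodes = m.cluster_representatives(recs, 0.5)
        assert len(nodes) == 2
        by_rep = {n.representative: set(n.members) for n in nodes}
        assert {"a", "b"} in by_rep.values()

    def test_partition_property(self, family):
        nodes = m.cluster_representatives(family.records, 0.5)
        members = [s for n in nodes for s in n.members]
        assert sorted(members) == sorted(r.id for r in family.records)

    def test_finer_cutoff_refines_coarser(self, family):
        fine = m.cluster_representatives(family.records, 0.9)
        coarse = m.cluster_representatives(family.records, 0.5)
        coarse_of = {s: n.node_id for n in coarse for s in n.members}
        for n in fine:
            assert len({coarse_of[s] for s in n.members}) == 1

    def test_invalid_cutoff_rejected(self, family):
        with pytest.raises(ValueError):
            m.cluster_representatives(family.records[:3], 0.0)


class TestRepresentativeEdges:
    def _nodes(self):
        return [
            RepresentativeNode("A", "a1", ("a1", "a2")),
            RepresentativeNode("B", "b1", ("b1",)),
        ]

    def test_single_member_edge_passes_through(self):
        edges = m.build_representative_edges(self._nodes(),
                                             [_edge("a1", "b1", 1e-9)])
        assert len(edges) == 1
        assert edges[0].score == pytest.approx(1e-9)
        assert edges[0].member_edge_count == 1

    def test_two_member_edges_log_average(self):
        edges = m.build_representative_edges(
            self._nodes(), [_edge("a1", "b1", 1e-10), _edge("a2", "b1", 1e-12)])
        assert edges[0].score == pytest.approx(1e-11, rel=1e-9)

    def test_intra_node_edges_ignored(self):
        edges = m.build_representative_edges(self._nodes(),
                                             [_edge("a1", "a2", 1e-50)])
        assert edges == []

    def test_unknown_sequence_id_is_error(self):
        with pytest.raises(KeyError):
            m.build_representative_edges(self._nodes(),
                                         [_edge("a1", "zz", 1e-9)])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_log_average_oracle_and_bounds(self, seed):
        """Geometric mean matches the oracle and sits within member range."""
        rng = np.random.default_rng(seed)
        evals = list(10.0 ** -rng.uniform(5, 50, size=rng.integers(1, 11)))
        nodes = [
            RepresentativeNode("A", "a0", tuple(f"a{i}" for i in range(10))),
            RepresentativeNode("B", "b0", tuple(f"b{i}" for i in range(10))),
        ]
        member_edges = [
            _edge(f"a{i % 10}", f"b{(i * 3) % 10}", e)
            for i, e in enumerate(evals)
        ]
        [edge] = m.build_representative_edges(nodes, member_edges)
        assert edge.score == pytest.approx(
            oracles.geometric_mean_evalue(evals), rel=1e-12)
        assert min(evals) <= edge.score <= max(evals)

    def test_brute_force_equivalence_on_small_instance(self, family):
        """Representative edges equal direct enumeration over member pairs."""
        recs = family.records[:30]
        edges = m.all_by_all(recs)
        nodes = m.cluster_representatives(recs, 0.5)
        got = {(e.node_a, e.node_b): (e.score, e.member_edge_count)
               for e in m.build_representative_edges(nodes, edges)}
        node_of = {s: n.node_id for n in nodes for s in n.members}
        expected: dict[tuple[str, str], list[float]] = {}
        for e in edges:
            a, b = sorted((node_of[e.query], node_of[e.subject]))
            if a != b:
                expected.setdefault((a, b), []).append(e.evalue)
        assert set(got) == set(expected)
        for key, evals in expected.items():
            assert got[key][0] == pytest.approx(
                oracles.geometric_mean_evalue(evals), rel=1e-12)
            assert got[key][1] == len(evals)


class TestThresholdAndComponents:
    def _network(self):
        nodes = [RepresentativeNode(c, f"{c.lower()}0", (f"{c.lower()}0",))
                 for c in "ABCD"]
        edges = m.build_representative_edges(
            nodes,
            [_edge("a0", "b0", 1e-20), _edge("b0", "c0", 1e-10),
             _edge("c0", "d0", 1e-6)],
        )
        return m.RepresentativeNetwork(nodes=nodes, edges=edges)

    def test_threshold_above_max_keeps_all(self):
        net = self._network()
        assert len(m.apply_threshold(net, 1.0).edges) == 3

    def test_threshold_below_min_isolates_all(self):
        net = self._network()
        thr = m.apply_threshold(net, 1e-30)
        assert thr.edges == []
        assert len(m.connected_components(thr)) == 4

    def test_sweep_monotone_nonincreasing_edge_count(self):
        net = self._network()
        counts = [len(m.apply_threshold(net, 10.0 ** -k).edges)
                  for k in range(2, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_stricter_threshold_refines_components(self):
        net = self._network()
        coarse = m.sequence_partition(m.apply_threshold(net, 1e-5))
        fine = m.sequence_partition(m.apply_threshold(net, 1e-15))
        for s1 in fine:
            for s2 in fine:
                if fine[s1] == fine[s2]:
                    assert coarse[s1] == coarse[s2]

    def test_edgeless_network_gives_singletons(self):
        nodes = [RepresentativeNode(f"n{i}", f"s{i}", (f"s{i}",))
                 for i in range(6)]
        net = m.RepresentativeNetwork(nodes=nodes, edges=[])
        assert len(m.connected_components(net)) == 6

    def test_planted_subgroups_recovered_as_components(
            self, family, family_network):
        thr = m.apply_threshold(family_network, 1e-11)
        part = m.sequence_partition(thr)
        labels = family.truth.set_index("id")["subgroup"].to_dict()
        # Components and planted subgroups induce the same partition.
        by_comp: dict[int, set[str]] = {}
        for seq, comp in part.items():
            by_comp.setdefault(comp, set()).add(labels[seq])
        assert all(len(sgs) == 1 for sgs in by_comp.values())
        assert len(by_comp) == 5

    def test_linker_chain_merges_exactly_two_subgroups(self, chain_network,
                                                       chain_family):
        part = m.sequence_partition(chain_network)
        labels = chain_family.truth.set_index("id")["subgroup"].to_dict()
        comp_of_sg = {}
        for seq, comp in part.items():
            comp_of_sg.setdefault(labels[seq], set()).add(comp)
        # Both subgroups (and the chain) collapse into one component.
        assert comp_of_sg["SG0"] == comp_of_sg["SG1"]
        assert len(comp_of_sg["SG0"]) == 1


class TestExport:
    def test_edge_tsv_round_trip(self, chain_network, tmp_path):
        assert chain_network.edges  # the chain study network has real edges
        p = m.export_network(chain_network, tmp_path / "net.tsv", fmt="tsv")
        back = read_network_tsv(p)
        got = {(e.node_a, e.node_b): e.score for e in back.edges}
        want = {(e.node_a, e.node_b): e.score for e in chain_network.edges}
        assert set(got) == set(want)
        for k in want:
            assert got[k] == pytest.approx(want[k], rel=1e-9)

    def test_sif_line_count_equals_edge_count(self, chain_network, tmp_path):
        p = m.export_network(chain_network, tmp_path / "net.sif", fmt="sif")
        assert len(p.read_text().splitlines()) == len(chain_network.edges)

    def test_xgmml_well_formed(self, chain_network, tmp_path):
        p = m.export_network(chain_network, tmp_path / "net.xgmml",
                             fmt="xgmml",
                             node_annotations={"SG0_0000": {"subgroup": "SG0"}})
        root = ET.parse(p).getroot()
        ns = "{http://www.cs.rpi.edu/XGMML}"
        assert len(root.findall(f"{ns}node")) == len(chain_network.nodes)

    def test_unknown_format_rejected(self, family_network, tmp_path):
        with pytest.raises(ValueError):
            m.export_network(family_network, tmp_path / "x", fmt="gexf")
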