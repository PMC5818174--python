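"""Discover the planted linker chain bridging two subgroups.

Two fused subgroups are connected by a four-sequence mutational-walk
bridge.  The shortest similarity path between the founder anchor nodes
recovers the chain, and the two-hop control census confirms the number of
statistically significant sequence-level edges crossing the subgroups.
"""

import math

import ssnmap as m

cfg = m.GeneratorConfig(
    n_subgroups=2, subgroup_sizes=(15, 15), fused=(True, True),
    within_divergence=0.1, between_divergence=1.2,
    linker_chain_length=4, linker_subgroups=(0, 1),
    non_pro1_fraction=0.0, rng_seed=0)
fam = m.generate_superfamily(cfg)
edges = m.all_by_all(fam.records)
net = m.build_representative_network(fam.records, edges, 0.5)
thr = m.apply_threshold(net, 1e-9)

a = m.find_anchor_node(thr, fam.founders[0])
b = m.find_anchor_node(thr, fam.founders[1])
path = m.shortest_similarity_path(thr, a, b, records=fam.record_map())
print("shortest similarity path between founder anchors:")
for row in path.report_rows():
    print(f"  step {row['step']}: {row['node_a']} -> {row['node_b']}  "
          f"log10 E = {row['log10_score']:.2f}, identity = "
          f"{row['identity']:.2f}")

labels = fam.truth.set_index("id")["subgroup"].to_dict()
node_label = {n.node_id: {labels[s] for s in n.members} for n in thr.nodes}
crossing = [(e.node_a, e.node_b) for e in thr.edges
            if node_label[e.node_a] != node_label[e.node_b]]
census = m.control_expansion(thr, crossing, labels, fam.record_map(),
                             crossing_threshold=1e-9, hops=2)
print(f"\ncontrol census (two hops out from the crossing edges): "
      f"{census.crossing_edge_count} significant sequence-level crossing "
      f"edge(s), E-value range "
      f"10^{math.log10(census.min_crossing_evalue):.2f}.."
      f"10^{math.log10(census.max_crossing_evalue):.2f}")
# The path visits each planted bridge sequence in order; the census shows
# the bridge rests on real member-level similarity, not a single fluke hit.
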