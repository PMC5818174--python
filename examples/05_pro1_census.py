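"""Census of members lacking the catalytic N-terminal proline.

Generates a 1000-sequence family with 3% non-Pro-1 members, 85% of them
planted in one subgroup, and shows that the census recovers the planted
counts, the concentration, and the replacement-residue spectrum.
"""

import ssnmap as m
from ssnmap.census import classify_nterm, census

cfg = m.GeneratorConfig(
    n_subgroups=5, subgroup_sizes=(300, 200, 200, 150, 150),
    non_pro1_fraction=0.03, non_pro1_target_subgroup=4,
    non_pro1_target_share=0.85, rng_seed=7)
fam = m.generate_superfamily(cfg)

calls = [classify_nterm(r) for r in fam.records]
labels = fam.truth.set_index("id")["subgroup"].to_dict()
report = census(calls, labels, records=fam.record_map())

print(f"total {report.total}, lacking Pro-1: {report.non_pro1_total}")
print(report.per_subgroup.round(3).to_string())
print(f"replacement residues: {dict(sorted(report.replacement_histogram.items()))}")
print(f"modal replacement: {report.modal_replacement}")
print(f"architectures: {report.architecture_counts}")

taxa = m.taxon_summary(fam.records, labels)
print("\ndominant taxonomic division per subgroup:")
print(taxa.loc["dominant"].to_string())
# The non-Pro-1 counts match the planted truth exactly; serine is the
# modal replacement by construction of the replacement spectrum.
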