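"""Subgroup naming, MSAs, profile scoring, cross-hits, subdivision."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

import ssnmap as m
from ssnmap.records import AMINO_ACIDS, SequenceRecord
from ssnmap.subgroups import (
    MSA,
    build_profile,
    read_msa_fasta,
    read_profile_tsv,
    score_sequence,
)


def _members_by_subgroup(fam):
    recs = fam.record_map()
    out: dict[str, list] = {}
    for _, row in fam.truth.iterrows():
        out.setdefault(row["subgroup"], []).append(recs[row["id"]])
    return out


@pytest.fixture(scope="module")
def thresholded(family, family_network):
    return m.apply_threshold(family_network, 1e-11)


class TestDefineSubgroups:
    def test_five_planted_components_named_with_founders(
            self, family, thresholded):
        comps = m.connected_components(thresholded)
        founders = {f"SG{i}": f"SG{i}_0000" for i in range(5)}
        named, unassigned = m.define_subgroups(
            thresholded, comps, min_size=1, founders=founders)
        assert {s.label for s in named} == set(founders)
        assert unassigned == []
        labels = family.truth.set_index("id")["subgroup"].to_dict()
        node_map = thresholded.node_map()
        for sub in named:
            member_ids = {mm for n in sub.member_nodes
                          for mm in node_map[n].members}
            assert {labels[i] for i in member_ids} == {sub.label}

    def test_small_component_stays_unassigned(self, thresholded):
        comps = m.connected_components(thresholded)
        named, unassigned = m.define_subgroups(thresholded, comps, min_size=7)
        # Each planted subgroup collapses to a single representative node
        # at 50% identity, so all components are below a 7-node minimum.
        assert named == []
        assert len(unassigned) == len(comps)

    def test_empty_component_list(self, thresholded):
        named, unassigned = m.define_subgroups(thresholded, [])
        assert named == [] and unassigned == []

    def test_unknown_founder_is_error(self, thresholded):
        comps = m.connected_components(thresholded)
        with pytest.raises(KeyError):
            m.define_subgroups(thresholded, comps,
                               founders={"X": "missing_seq"})


class TestBuildMsa:
    def test_identical_sequences_align_gap_free(self):
        recs = [SequenceRecord(f"s{i}", "MPVIAQEMKHRAWLEG") for i in range(4)]
        msa = m.build_msa(recs)
        assert all(row == "MPVIAQEMKHRAWLEG" for row in msa.rows)

    def test_two_sequences_match_independent_global_aligner_score(self):
        """The 2-sequence MSA realizes the optimal global alignment score."""
        rng = np.random.default_rng(8)
        a = "".join(rng.choice(list(AMINO_ACIDS), 45))
        b = "".join(rng.choice(list(AMINO_ACIDS), 52))
        msa = m.build_msa([SequenceRecord("a", a), SequenceRecord("b", b)])
        # Score the produced alignment column by column.
        mat = substitution_matrices.load("BLOSUM62")
        score, in_gap = 0.0, False
        for ca, cb in zip(msa.rows[0], msa.rows[1]):
            if ca == "-" or cb == "-":
                score += -1.0 if in_gap else -11.0
                in_gap = True
            else:
                score += mat[ca, cb]
                in_gap = False
        aligner = PairwiseAligner(mode="global", substitution_matrix=mat,
                                  open_gap_score=-11, extend_gap_score=-1)
        assert score == pytest.approx(aligner.align(a, b).score)

    def test_single_sequence_trivial_msa(self):
        msa = m.build_msa([SequenceRecord("x", "MPAAA")])
        assert msa.rows == ["MPAAA"]

    def test_progressive_alignment_covers_all_inputs(self, family):
        members = _members_by_subgroup(family)["SG1"][:8]
        msa = m.build_msa(members)
        assert sorted(msa.ids) == sorted(r.id for r in members)
        for sid, row in zip(msa.ids, msa.rows):
            original = next(r.sequence for r in members if r.id == sid)
            assert row.replace("-", "") == original

    def test_external_msa_ingested_verbatim(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nMP-VI\n>b\nMPAVI\n")
        msa = read_msa_fasta(p)
        assert msa.ids == ["a", "b"]
        assert msa.rows == ["MP-VI", "MPAVI"]

    def test_stockholm_and_fasta_export(self, tmp_path):
        msa = MSA(ids=["a", "b"], rows=["MP-VI", "MPAVI"])
        msa.write_fasta(tmp_path / "x.fasta")
        msa.write_stockholm(tmp_path / "x.sto")
        assert read_msa_fasta(tmp_path / "x.fasta").rows == msa.rows
        assert "# STOCKHOLM 1.0" in (tmp_path / "x.sto").read_text()


class TestProfiles:
    def test_single_sequence_profile_prefers_its_own_sequence(self):
        seq = "MPVIAQEMKHRAWLEG"
        profile = build_profile(MSA(ids=["s"], rows=[seq]))
        base = score_sequence(profile, seq)
        for pos in (1, 7, 15):
            for alt in "ACDW":
                if alt == seq[pos]:
                    continue
                variant = seq[:pos] + alt + seq[pos + 1:]
                assert score_sequence(profile, variant) < base

    def test_consensus_scores_maximal(self, family):
        members = _members_by_subgroup(family)["SG2"][:10]
        profile = build_profile(m.build_msa(members), label="SG2")
        cons = profile.consensus()
        best = score_sequence(profile, cons)
        assert best == pytest.approx(
            float(profile.scores.max(axis=1).clip(min=0).sum()), abs=1e-9)
        for r in members:
            assert score_sequence(profile, r) <= best

    def test_reversed_consensus_scores_strictly_lower(self, family):
        members = _members_by_subgroup(family)["SG3"][:10]
        profile = build_profile(m.build_msa(members))
        cons = profile.consensus()
        assert score_sequence(profile, cons[::-1]) < \
            score_sequence(profile, cons)

    def test_random_sequences_score_below_threshold(self, family, rng):
        members = _members_by_subgroup(family)["SG1"][:10]
        profile = build_profile(m.build_msa(members))
        n_len = len(members[0].sequence)
        scores = []
        for _ in range(200):
            seq = "".join(rng.choice(list(AMINO_ACIDS), n_len))
            scores.append(score_sequence(profile, seq))
        assert np.mean(scores) < profile.threshold

    def test_all_gap_columns_rejected(self):
        with pytest.raises(ValueError):
            build_profile(MSA(ids=["a", "b"], rows=["--", "--"]))

    def test_profile_tsv_round_trip(self, family, tmp_path):
        members = _members_by_subgroup(family)["SG0"][:6]
        profile = build_profile(m.build_msa(members), label="SG0")
        profile.write_tsv(tmp_path / "p.tsv")
        back = read_profile_tsv(tmp_path / "p.tsv")
        assert back.label == "SG0"
        assert back.threshold == pytest.approx(profile.threshold, rel=1e-4)
        np.testing.assert_allclose(back.scores, profile.scores, atol=1e-6)
        seq = members[0].sequence
        assert score_sequence(back, seq) == pytest.approx(
            score_sequence(profile, seq), abs=1e-3)

    def test_scoring_reproducible_bit_for_bit(self, family):
        members = _members_by_subgroup(family)["SG4"][:8]
        profile = build_profile(m.build_msa(members))
        seq = members[0].sequence
        assert score_sequence(profile, seq) == score_sequence(profile, seq)


@pytest.fixture(scope="module")
def split_profiles(family):
    members = _members_by_subgroup(family)
    profiles, held = {}, {}
    for sg, recs in members.items():
        profiles[sg] = build_profile(m.build_msa(recs[::2]), label=sg)
        held[sg] = recs[1::2]
    return profiles, held


class TestCrossHits:
    def test_diagonal_dominance_on_planted_subgroups(self, split_profiles):
        profiles, held = split_profiles
        x = m.crosshit_matrix(profiles, held)
        assert x.diagonal_dominant()
        for sg in profiles:
            assert x.fraction_above.at[sg, sg] >= 0.95
            off = x.fraction_above.loc[sg].drop(sg)
            assert (off <= 0.05).all()

    def test_label_permutation_destroys_diagonal(self, split_profiles):
        profiles, held = split_profiles
        labels = sorted(held)
        shuffled = {a: held[b] for a, b in zip(labels, labels[1:] + labels[:1])}
        x = m.crosshit_matrix(profiles, shuffled)
        diag = [x.fraction_above.at[sg, sg] for sg in labels]
        assert max(diag) <= 0.05

    def test_empty_profiles_rejected(self):
        with pytest.raises(ValueError):
            m.crosshit_matrix({}, {})


class TestSubdivide:
    def test_two_lobe_subgroup_splits_into_level2(self, chain_family):
        """A component merged by the chain splits back at a stricter level.

        The chain study's two planted subgroups form one Level-1 component;
        re-clustering at 90% identity and thresholding harder separates the
        lobes again, and each Level-2 subgroup nests inside the parent.
        """
        edges = m.all_by_all(chain_family.records)
        net = m.build_representative_network(chain_family.records, edges, 0.5)
        thr = m.apply_threshold(net, 1e-9)
        comps = m.connected_components(thr)
        named, _ = m.define_subgroups(
            thr, comps, min_size=1, founders={"SG0": "SG0_0000"})
        parent = next(s for s in named if s.label == "SG0")
        records = chain_family.record_map()
        level2 = m.subdivide(parent, thr, records, edges,
                             finer_threshold=1e-40,
                             finer_identity_cutoff=0.9, min_size=5)
        labels = chain_family.truth.set_index("id")["subgroup"].to_dict()
        assert len(level2) == 2
        parent_members = {
            mm for n in parent.member_nodes
            for mm in thr.node_map()[n].members}
        seen_groups = []
        for sub in level2:
            assert sub.level == 2 and sub.parent == "SG0"
            # Level-2 nodes are representative sequence ids from the finer
            # clustering; they must all be parent members (nesting).
            member_ids = set(sub.member_nodes)
            assert member_ids <= parent_members
            seen_groups.append({labels[i] for i in member_ids})
        assert {"SG0"} in seen_groups and {"SG1"} in seen_groups

    def test_not_more_stringent_threshold_rejected(self, chain_family):
        sub = m.SubgroupDefinition(label="x", member_nodes=("SG0_0000",),
                                   threshold=1e-11)
        with pytest.raises(ValueError):
            m.subdivide(sub, m.RepresentativeNetwork(nodes=[], edges=[]),
                        {}, [], finer_threshold=1e-5,
                        finer_identity_cutoff=0.9)
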