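"""Subgroup definition, profile models, and cross-hit validation.

Connected components of a thresholded representative network become named
Level-1 subgroups (components that are too small stay unassigned, and a
component containing a declared founder sequence takes the founder's name).
For each named subgroup a multiple sequence alignment is built, condensed
into a position-specific log-odds profile, and the profile is scored
against every superfamily member to verify that each subgroup's profile
uniquely recognizes its own members (diagonal dominance of the cross-hit
matrix).  Subgroups too diverse for one good alignment can be re-partitioned
at a finer identity cutoff and a more stringent E-value threshold into
Level-2 subgroups that nest inside their parent.

The profile is a pseudocounted log-odds PSSM with affine gap costs, not a
full profile HMM: the pipeline uses profiles only as subgroup
discriminators, and externally built profile score files can be ingested
for parity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .pairwise import ScoringScheme, align_pair, make_aligner
from .records import AMINO_ACIDS, SequenceRecord
from .repnet import (
    RepresentativeNetwork,
    apply_threshold,
    build_representative_edges,
    cluster_representatives,
    connected_components,
)

#: Background amino-acid frequencies (BLOSUM62 marginals).
BLOSUM62_BACKGROUND: dict[str, float] = {
    "A": 0.0742, "R": 0.0516, "N": 0.0446, "D": 0.0536, "C": 0.0246,
    "Q": 0.0342, "E": 0.0543, "G": 0.0741, "H": 0.0262, "I": 0.0679,
    "L": 0.0989, "K": 0.0582, "M": 0.0221, "F": 0.0473, "P": 0.0392,
    "S": 0.0572, "T": 0.0509, "W": 0.0131, "Y": 0.0321, "V": 0.0729,
}

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_BACKGROUND = np.array([BLOSUM62_BACKGROUND[a] for a in AMINO_ACIDS])
_BACKGROUND /= _BACKGROUND.sum()


@dataclass(frozen=True)
class SubgroupDefinition:
    """A named (or unassigned) subgroup of representative nodes."""

    label: str
    member_nodes: tuple[str, ...]
    threshold: float
    level: int = 1
    founder_id: str | None = None
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.level not in (1, 2):
            raise ValueError("subgroup level must be 1 or 2")
        if self.level == 2 and self.parent is None:
            raise ValueError("a Level-2 subgroup needs a parent label")


# ---------------------------------------------------------------------------
# Subgroup naming


def define_subgroups(
    network: RepresentativeNetwork,
    components: Sequence[tuple[str, ...]],
    min_size: int = 7,
    founders: Mapping[str, str] | None = None,
    threshold: float | None = None,
) -> tuple[list[SubgroupDefinition], list[tuple[str, ...]]]:
    """Name components with at least ``min_size`` representative nodes.

    ``founders`` maps a subgroup name to a founder sequence id; a component
    containing a founder takes that name.  Returns the named subgroups and
    the unassigned ("gray") components.
    """
    founders = founders or {}
    seq_to_node = network.node_of_sequence()
    founder_node: dict[str, str] = {}
    for name, seq_id in founders.items():
        if seq_id not in seq_to_node:
            raise KeyError(f"founder sequence {seq_id!r} not found in network")
        founder_node[seq_to_node[seq_id]] = name
    T = threshold if threshold is not None else (network.threshold or math.nan)
    named: list[SubgroupDefinition] = []
    unassigned: list[tuple[str, ...]] = []
    counter = 0
    for comp in components:
        founder_names = [founder_node[n] for n in comp if n in founder_node]
        if len(comp) < min_size and not founder_names:
            unassigned.append(comp)
            continue
        if founder_names:
            label = founder_names[0]
            founder_id = founders[label]
        else:
            label = f"subgroup_{counter:02d}"
            founder_id = None
            counter += 1
        named.append(
            SubgroupDefinition(label=label, member_nodes=comp, threshold=T,
                               founder_id=founder_id)
        )
    return named, unassigned


# ---------------------------------------------------------------------------
# Multiple sequence alignment (progressive, profile-profile)


@dataclass
class MSA:
    """An aligned set of sequences (rows of equal length, '-' for gaps)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("MSA rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n")
                for k in range(0, len(row), 60):
                    fh.write(row[k:k + 60] + "\n")

    def write_stockholm(self, path: str | Path) -> None:
        width = max(len(s) for s in self.ids) + 2
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            for sid, row in zip(self.ids, self.rows):
                fh.write(f"{sid:<{width}}{row}\n")
            fh.write("//\n")


def read_msa_fasta(path: str | Path) -> MSA:
    """Ingest an externally provided aligned FASTA verbatim."""
    ids: list[str] = []
    rows: list[str] = []
    current: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if ids:
                    rows.append("".join(current))
                ids.append(line[1:].split()[0])
                current = []
            elif line:
                current.append(line.upper())
    if ids:
        rows.append("".join(current))
    return MSA(ids=ids, rows=rows)


def _profile_counts(rows: Sequence[str], matrix: np.ndarray) -> np.ndarray:
    """Per-column residue frequency vectors (n_cols x 20, gaps excluded)."""
    n_cols = len(rows[0])
    counts = np.zeros((n_cols, 20))
    for row in rows:
        for i, ch in enumerate(row):
            j = _AA_INDEX.get(ch)
            if j is not None:
                counts[i, j] += 1.0
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.where(totals > 0, counts / np.maximum(totals, 1e-9), 0.0)
    return freqs


def _align_profiles(
    rows_a: list[str], rows_b: list[str], sub: np.ndarray,
    gap_open: float, gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Global affine-gap (Gotoh) alignment of two profiles.

    Column-column score is the expected substitution score between the two
    column residue distributions.  Returns the two row sets padded with gap
    columns so that they share one coordinate system.
    """
    fa = _profile_counts(rows_a, sub)
    fb = _profile_counts(rows_b, sub)
    S = fa @ sub @ fb.T  # (la, lb) expected column-column scores
    la, lb = S.shape
    NEG = -1e30
    H = np.full((la + 1, lb + 1), NEG)
    E = np.full((la + 1, lb + 1), NEG)  # gap in A (consume B)
    F = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A)
    H[0, 0] = 0.0
    for j in range(1, lb + 1):
        E[0, j] = -gap_open - (j - 1) * gap_extend
        H[0, j] = E[0, j]
    for i in range(1, la + 1):
        F[i, 0] = -gap_open - (i - 1) * gap_extend
        H[i, 0] = F[i, 0]
    for i in range(1, la + 1):
        E[i, 1:] = NEG
        row_s = S[i - 1]
        for j in range(1, lb + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            H[i, j] = max(H[i - 1, j - 1] + row_s[j - 1], E[i, j], F[i, j])
    # Traceback.
    out_a: list[str] = []
    out_b: list[str] = []
    gap_a = "-" * len(rows_a)
    gap_b = "-" * len(rows_b)
    i, j = la, lb
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and math.isclose(
                    H[i, j], H[i - 1, j - 1] + S[i - 1, j - 1], abs_tol=1e-9):
                out_a.append("".join(r[i - 1] for r in rows_a))
                out_b.append("".join(r[j - 1] for r in rows_b))
                i, j = i - 1, j - 1
                continue
            if j > 0 and math.isclose(H[i, j], E[i, j], abs_tol=1e-9):
                state = "E"
                continue
            state = "F"
            continue
        if state == "E":
            out_a.append(gap_a)
            out_b.append("".join(r[j - 1] for r in rows_b))
            if j > 1 and math.isclose(E[i, j], E[i, j - 1] - gap_extend,
                                      abs_tol=1e-9):
                j -= 1
                continue
            j -= 1
            state = "H"
            continue
        # state == "F"
        out_a.append("".join(r[i - 1] for r in rows_a))
        out_b.append(gap_b)
        if i > 1 and math.isclose(F[i, j], F[i - 1, j] - gap_extend,
                                  abs_tol=1e-9):
            i -= 1
            continue
        i -= 1
        state = "H"
    out_a.reverse()
    out_b.reverse()
    # Transpose the column lists back into per-sequence rows.
    new_a = ["".join(col[k] for col in out_a) for k in range(len(rows_a))]
    new_b = ["".join(col[k] for col in out_b) for k in range(len(rows_b))]
    return new_a, new_b


def build_msa(
    records: Sequence[SequenceRecord],
    scheme: ScoringScheme | None = None,
) -> MSA:
    """Progressive multiple alignment.

    Pairwise identity distances feed an average-linkage guide tree; leaves
    are merged bottom-up by global profile-profile alignment (expected
    BLOSUM62 column scores, affine gaps).  Deterministic for a fixed input
    order.  A single sequence yields a trivial one-row MSA.
    """
    if not records:
        raise ValueError("cannot align an empty record set")
    scheme = scheme or ScoringScheme()
    if len(records) == 1:
        return MSA(ids=[records[0].id], rows=[records[0].sequence])
    sub = np.asarray(
        [[scheme.substitution_matrix()[a, b] for b in AMINO_ACIDS]
         for a in AMINO_ACIDS]
    )
    n = len(records)
    if n == 2:
        rows_a, rows_b = _align_profiles(
            [records[0].sequence], [records[1].sequence], sub,
            float(scheme.gap_open), float(scheme.gap_extend))
        return MSA(ids=[records[0].id, records[1].id],
                   rows=[rows_a[0], rows_b[0]])
    aligner = make_aligner(scheme)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = align_pair(records[i], records[j], scheme,
                               aligner=aligner).identity
            dist[i, j] = dist[j, i] = 1.0 - ident
    tree = linkage(squareform(dist, checks=False), method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([records[i].id], [records[i].sequence]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(tree):
        ids_a, rows_a = clusters.pop(int(a))
        ids_b, rows_b = clusters.pop(int(b))
        new_a, new_b = _align_profiles(rows_a, rows_b, sub,
                                       float(scheme.gap_open),
                                       float(scheme.gap_extend))
        clusters[n + step] = (ids_a + ids_b, new_a + new_b)
    ids, rows = clusters.popitem()[1]
    return MSA(ids=ids, rows=rows)


# ---------------------------------------------------------------------------
# Profiles


@dataclass
class SubgroupProfile:
    """Position-specific log-odds scores (bits) with a membership threshold.

    ``scores`` has one row per retained MSA column and one column per amino
    acid in :data:`ssnmap.records.AMINO_ACIDS`.  Columns with more than 50%
    gaps in the source MSA are removed before scoring.
    """

    label: str
    scores: np.ndarray  # (n_columns, 20), bits
    gap_open: float
    gap_extend: float
    threshold: float
    source_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("profile scores must have shape (n_columns, 20)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("profile scores must be finite (pseudocounted)")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.scores.argmax(axis=1))

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.scores, columns=list(AMINO_ACIDS))
        df.insert(0, "column", np.arange(1, self.length + 1))
        with open(path, "w") as fh:
            fh.write(f"#label={self.label}\tthreshold={self.threshold:.6g}\t"
                     f"gap_open={self.gap_open:.6g}\t"
                     f"gap_extend={self.gap_extend:.6g}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_profile_tsv(path: str | Path) -> SubgroupProfile:
    """Ingest an externally built per-column score table."""
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(
            item.split("=", 1) for item in header.lstrip("#").split("\t")
        )
        df = pd.read_csv(fh, sep="\t")
    return SubgroupProfile(
        label=meta.get("label", "profile"),
        scores=df[list(AMINO_ACIDS)].to_numpy(dtype=float),
        gap_open=float(meta.get("gap_open", 4.0)),
        gap_extend=float(meta.get("gap_extend", 0.25)),
        threshold=float(meta.get("threshold", 0.0)),
    )


def _position_based_weights(rows: Sequence[str]) -> np.ndarray:
    """Henikoff position-based sequence weights (robust to redundancy)."""
    n = len(rows)
    weights = np.zeros(n)
    for col in zip(*rows):
        residues = [c for c in col if c in _AA_INDEX]
        if not residues:
            continue
        kinds = set(residues)
        r = len(kinds)
        counts = {a: residues.count(a) for a in kinds}
        for i, c in enumerate(col):
            if c in counts:
                weights[i] += 1.0 / (r * counts[c])
    total = weights.sum()
    return weights / total if total > 0 else np.full(n, 1.0 / n)


def build_profile(
    msa: MSA,
    label: str = "profile",
    pseudocount: float = 0.5,
    gap_open: float = 4.0,
    gap_extend: float = 0.25,
    max_gap_fraction: float = 0.5,
    threshold_margin: float = 1.0,
) -> SubgroupProfile:
    """Condense an MSA into a log-odds profile (scores in bits).

    Column score for residue ``a`` is
    ``log2(((w_a + pc * bg_a) / (1 + pc)) / bg_a)`` with ``w_a`` the
    position-weighted residue frequency and ``bg`` the BLOSUM62 background.

    The membership threshold is set from held-in scores computed by
    leave-one-out (each source sequence scored against a profile built
    without it, so the estimate is free of self-inclusion bias):
    threshold = min(LOO scores) - max(threshold_margin, 3 * SD(LOO scores)).
    For a single-sequence MSA the self score minus the margin is used.
    """
    if not msa.rows:
        raise ValueError("cannot build a profile from an empty MSA")
    profile = _profile_from_rows(msa, label, pseudocount, gap_open,
                                 gap_extend, max_gap_fraction)
    if len(msa.rows) == 1:
        held_in = [score_sequence(profile, msa.rows[0].replace("-", ""))]
    else:
        held_in = []
        for i in range(len(msa.rows)):
            rest = MSA(
                ids=[s for j, s in enumerate(msa.ids) if j != i],
                rows=[r for j, r in enumerate(msa.rows) if j != i],
            )
            loo = _profile_from_rows(rest, label, pseudocount, gap_open,
                                     gap_extend, max_gap_fraction)
            held_in.append(score_sequence(loo, msa.rows[i].replace("-", "")))
    margin = max(threshold_margin, 3.0 * float(np.std(held_in)))
    profile.threshold = min(held_in) - margin
    return profile


def _profile_from_rows(
    msa: MSA,
    label: str,
    pseudocount: float,
    gap_open: float,
    gap_extend: float,
    max_gap_fraction: float,
) -> SubgroupProfile:
    keep = [
        i for i in range(msa.n_columns)
        if msa.column(i).count("-") / len(msa.rows) <= max_gap_fraction
    ]
    if not keep:
        raise ValueError("all MSA columns exceed the gap-fraction limit")
    weights = _position_based_weights(msa.rows)
    n_cols = len(keep)
    freq = np.zeros((n_cols, 20))
    for out_i, col_i in enumerate(keep):
        for row, w in zip(msa.rows, weights):
            j = _AA_INDEX.get(row[col_i])
            if j is not None:
                freq[out_i, j] += w
    totals = freq.sum(axis=1, keepdims=True)
    freq = np.where(totals > 0, freq / np.maximum(totals, 1e-12), _BACKGROUND)
    mixed = (freq + pseudocount * _BACKGROUND) / (1.0 + pseudocount)
    scores = np.log2(mixed / _BACKGROUND)
    return SubgroupProfile(
        label=label,
        scores=scores,
        gap_open=gap_open,
        gap_extend=gap_extend,
        threshold=-math.inf,
        source_ids=tuple(msa.ids),
    )


def score_sequence(profile: SubgroupProfile, seq: str | SequenceRecord) -> float:
    """Best local alignment score (bits) of a sequence against the profile.

    Affine-gap Smith-Waterman-style dynamic programming over profile
    columns; reproducible bit-for-bit for fixed inputs.
    """
    seq = seq.sequence if isinstance(seq, SequenceRecord) else seq
    if not seq:
        raise ValueError("cannot score an empty sequence")
    cols = profile.scores  # (L, 20)
    L = profile.length
    go, ge = profile.gap_open, profile.gap_extend
    idx = np.array([_AA_INDEX.get(c, -1) for c in seq])
    H = np.zeros(L + 1)
    E = np.full(L + 1, -np.inf)
    best = 0.0
    ext = np.arange(L + 1) * ge
    for j in range(len(seq)):
        s = cols[:, idx[j]] if idx[j] >= 0 else np.zeros(L)
        diag = H[:-1] + s
        E = np.maximum(H - go, E - ge)  # insertion in sequence
        H_new = np.zeros(L + 1)
        H_new[1:] = np.maximum(diag, E[1:])
        H_new = np.maximum(H_new, 0.0)
        # Deletion of profile columns (gap in sequence) within this column:
        # F[i] = max_{k < i}(H_new[k] - go - (i-k-1) * ge), exact via a
        # running max because opening from a gap-ended cell never wins.
        A = H_new + ext
        runmax = np.maximum.accumulate(A)
        F = np.full(L + 1, -np.inf)
        F[1:] = runmax[:-1] - go - ext[1:] + ge
        H_new = np.maximum(H_new, F)
        H_new = np.maximum(H_new, 0.0)
        best = max(best, float(H_new.max()))
        H = H_new
    return best


# ---------------------------------------------------------------------------
# Cross-hit validation


@dataclass
class CrossHitMatrix:
    """Profile x subgroup score statistics and above-threshold fractions."""

    mean_scores: pd.DataFrame
    max_scores: pd.DataFrame
    fraction_above: pd.DataFrame

    def diagonal_dominant(self) -> bool:
        f = self.fraction_above
        for label in f.index:
            row = f.loc[label]
            if label in f.columns and (row.drop(label) > row[label]).any():
                return False
        return True

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#fraction_above_threshold\n")
            self.fraction_above.to_csv(fh, sep="\t")
            fh.write("#mean_scores\n")
            self.mean_scores.to_csv(fh, sep="\t")
            fh.write("#max_scores\n")
            self.max_scores.to_csv(fh, sep="\t")


def crosshit_matrix(
    profiles: Mapping[str, SubgroupProfile],
    members: Mapping[str, Sequence[SequenceRecord]],
) -> CrossHitMatrix:
    """Score every profile against every subgroup's member sequences."""
    if not profiles:
        raise ValueError("need at least one profile")
    labels = list(profiles)
    groups = list(members)
    mean_s = pd.DataFrame(index=labels, columns=groups, dtype=float)
    max_s = pd.DataFrame(index=labels, columns=groups, dtype=float)
    frac = pd.DataFrame(index=labels, columns=groups, dtype=float)
    for p_label, profile in profiles.items():
        for g_label, recs in members.items():
            scores = np.array([score_sequence(profile, r) for r in recs])
            mean_s.at[p_label, g_label] = scores.mean() if scores.size else np.nan
            max_s.at[p_label, g_label] = scores.max() if scores.size else np.nan
            frac.at[p_label, g_label] = float(
                (scores > profile.threshold).mean()) if scores.size else np.nan
    return CrossHitMatrix(mean_scores=mean_s, max_scores=max_s,
                          fraction_above=frac)


# ---------------------------------------------------------------------------
# Level-2 subdivision


def subdivide(
    subgroup: SubgroupDefinition,
    parent_network: RepresentativeNetwork,
    records: Mapping[str, SequenceRecord],
    member_edges: Iterable,
    finer_threshold: float,
    finer_identity_cutoff: float,
    min_size: int = 2,
    scheme: ScoringScheme | None = None,
) -> list[SubgroupDefinition]:
    """Re-partition an over-diverse subgroup into Level-2 subgroups.

    Members are re-clustered at the finer identity cutoff, representative
    edges rebuilt from the member-level hits restricted to the subgroup,
    and components at the more stringent threshold named largest-first.
    ``finer_threshold`` must be more stringent than the Level-1 threshold.
    """
    if not (finer_threshold < subgroup.threshold):
        raise ValueError(
            "Level-2 threshold must be more stringent than the Level-1 threshold")
    node_map = parent_network.node_map()
    member_ids = {
        m for node in subgroup.member_nodes for m in node_map[node].members
    }
    member_records = [records[m] for m in sorted(member_ids)]
    nodes = cluster_representatives(member_records, finer_identity_cutoff,
                                    scheme)
    inner_edges = [
        e for e in member_edges
        if e.query in member_ids and e.subject in member_ids
    ]
    rep_edges = build_representative_edges(nodes, inner_edges)
    fine = apply_threshold(
        RepresentativeNetwork(nodes=nodes, edges=rep_edges), finer_threshold)
    comps = connected_components(fine)
    counts = {n.node_id: n.member_count for n in fine.nodes}
    comp_size = lambda c: sum(counts[n] for n in c)
    comps = sorted(comps, key=lambda c: (-comp_size(c), c[0]))
    out: list[SubgroupDefinition] = []
    for i, comp in enumerate(comps):
        size = comp_size(comp)
        if size < min_size:
            continue
        out.append(
            SubgroupDefinition(
                label=f"{subgroup.label}.{i + 1}",
                member_nodes=comp,
                threshold=finer_threshold,
                level=2,
                parent=subgroup.label,
            )
        )
    return out
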