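"""Structural comparison: Kabsch superposition, TM-score, structure networks.

Structures are reduced to ordered C-alpha traces.  Pairs are compared by
the length-normalized TM-score

    TM = (1 / L_target) * sum_i 1 / (1 + (d_i / d0)^2),
    d0(L) = 1.24 * (L - 15)^(1/3) - 1.8   (floored at 0.5),

maximized over rigid superpositions with the standard iterative
fragment-seeding refinement: superpositions are seeded from contiguous
fragments of the alignment, residue pairs closer than a distance cutoff
are re-selected and re-superposed until the selection is stable, and the
best score over all seeds is kept.  A score of 0.5 or higher is
conventionally considered statistically significant; the structure network
draws an edge when the larger of the two per-length normalizations reaches
the chosen cutoff (0.8 by default).

The residue correspondence may come from the sequences (global alignment;
appropriate for families with planted homology) or from the
sequence-independent mode, which alternates distance-matrix dynamic
programming with re-superposition, as structure aligners do.

Synthetic test structures are smoothed self-avoiding random chains with
3.8 A steps, plus duplicated-and-perturbed families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .pairwise import ScoringScheme, make_aligner
from .records import AMINO_ACIDS

CA_CA_DISTANCE = 3.8


@dataclass(frozen=True)
class StructureModel:
    """An ordered C-alpha trace with its residue sequence."""

    structure_id: str
    coords: np.ndarray  # (n, 3) Angstroms
    sequence: str
    chain_id: str = "A"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if len(self.sequence) != coords.shape[0]:
            raise ValueError("coordinate count must equal residue count")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class TMResult:
    """TM-scores (both normalizations), RMSD, and alignment bookkeeping."""

    id_a: str
    id_b: str
    tm_norm_a: float
    tm_norm_b: float
    rmsd: float
    aligned: int
    d0_a: float
    d0_b: float

    def __post_init__(self) -> None:
        for tm in (self.tm_norm_a, self.tm_norm_b):
            if not 0.0 < tm <= 1.0 + 1e-12:
                raise ValueError(f"TM-score must lie in (0, 1], got {tm}")
        if self.rmsd < 0:
            raise ValueError("RMSD must be >= 0")

    @property
    def tm_max(self) -> float:
        return max(self.tm_norm_a, self.tm_norm_b)


def d0_length(L: int) -> float:
    """TM-score distance scale; floored at 0.5 for short chains."""
    if L > 21:
        return max(0.5, 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8)
    return 0.5


def kabsch_superpose(
    A: np.ndarray,
    B: np.ndarray,
    correspondence: Sequence[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Least-squares rigid superposition of B onto A.

    Returns ``(rotation, translation, rmsd, degenerate)`` such that
    ``B @ rotation.T + translation`` approximates A; the rotation is proper
    (determinant +1).  ``degenerate`` flags (near-)collinear point sets,
    for which the in-plane orientation is not unique; the RMSD is still
    the minimized value.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if correspondence is not None:
        ia = [i for i, _ in correspondence]
        ib = [j for _, j in correspondence]
        A, B = A[ia], B[ib]
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("superposition needs equal-length (n, 3) arrays")
    if A.shape[0] < 3:
        raise ValueError("superposition needs at least 3 corresponded points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    H = Bc.T @ Ac
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = (Bc @ R.T) - Ac
    rmsd = float(np.sqrt((diff ** 2).sum() / A.shape[0]))
    degenerate = bool(S[1] < 1e-8 * max(S[0], 1.0))
    return R, t, rmsd, degenerate


def _tm_sum(d2: np.ndarray, d0: float) -> float:
    return float((1.0 / (1.0 + d2 / (d0 * d0))).sum())


def tm_score(
    A: StructureModel,
    B: StructureModel,
    alignment: Sequence[tuple[int, int]],
) -> TMResult:
    """TM-score of two structures under a fixed residue correspondence.

    The score is maximized over superpositions seeded from contiguous
    alignment fragments (full, half, quarter length) with iterative
    reselection of close residue pairs, and reported normalized by each
    structure's length.  The RMSD reported is that of the final (best)
    superposition over its selected residue set.
    """
    pairs = list(alignment)
    if len(pairs) < 3:
        raise ValueError("alignment must cover at least 3 residue pairs")
    ia = np.array([i for i, _ in pairs])
    ib = np.array([j for _, j in pairs])
    ca = A.coords[ia]
    cb = B.coords[ib]
    n = len(pairs)
    La, Lb = len(A), len(B)
    d0a, d0b = d0_length(La), d0_length(Lb)
    d0_search = max(d0_length(min(La, Lb)), 1.0)
    best_a = best_b = 0.0
    best_rmsd = math.inf
    best_aligned = n
    frag_lens = sorted({n, max(n // 2, 4), max(n // 4, 4)}, reverse=True)
    for fl in frag_lens:
        starts = range(0, n - fl + 1, max(fl // 2, 1))
        for s0 in starts:
            subset = np.arange(s0, s0 + fl)
            prev: np.ndarray | None = None
            for _ in range(20):
                if subset.size < 3:
                    break
                R, t, rmsd, _ = kabsch_superpose(ca[subset], cb[subset])
                moved = cb @ R.T + t
                d2 = ((moved - ca) ** 2).sum(axis=1)
                tm_a = _tm_sum(d2, d0a) / La
                tm_b = _tm_sum(d2, d0b) / Lb
                if tm_a > best_a:
                    best_a, best_rmsd, best_aligned = tm_a, rmsd, subset.size
                if tm_b > best_b:
                    best_b = tm_b
                cutoff = d0_search
                new = np.nonzero(d2 < cutoff ** 2)[0]
                while new.size < 3 and cutoff < 8.0 * d0_search:
                    cutoff += 0.5
                    new = np.nonzero(d2 < cutoff ** 2)[0]
                if prev is not None and new.size == prev.size \
                        and np.array_equal(new, prev):
                    break
                prev = subset = new
    return TMResult(
        id_a=A.structure_id,
        id_b=B.structure_id,
        tm_norm_a=min(best_a, 1.0),
        tm_norm_b=min(best_b, 1.0),
        rmsd=best_rmsd,
        aligned=best_aligned,
        d0_a=d0a,
        d0_b=d0b,
    )


# ---------------------------------------------------------------------------
# Residue correspondences


def sequence_alignment_pairs(
    A: StructureModel, B: StructureModel, scheme: ScoringScheme | None = None
) -> list[tuple[int, int]]:
    """Residue correspondence from a global sequence alignment."""
    scheme = scheme or ScoringScheme()
    aligner = make_aligner(scheme, mode="global")
    best = aligner.align(A.sequence, B.sequence)[0]
    pairs: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*best.aligned):
        pairs.extend(
            (a_start + k, b_start + k) for k in range(a_end - a_start)
        )
    return pairs


def structural_alignment_pairs(
    A: StructureModel, B: StructureModel, max_rounds: int = 10,
    gap_open: float = 0.6,
) -> list[tuple[int, int]]:
    """Sequence-independent residue correspondence.

    Gapless threading of the shorter chain onto the longer at several
    offsets seeds rigid superpositions; each round scores all residue pairs
    by ``1 / (1 + (d_ij / d0)^2)``, realigns them by dynamic programming,
    and re-superposes, keeping the correspondence with the best TM-sum.
    """
    La, Lb = len(A), len(B)
    d0 = max(d0_length(min(La, Lb)), 1.0)
    short_len = min(La, Lb)
    offsets = range(0, abs(La - Lb) + 1, max((abs(La - Lb) + 1) // 8, 1))
    seeds: list[list[tuple[int, int]]] = []
    for off in offsets:
        if La >= Lb:
            seeds.append([(i + off, i) for i in range(short_len)])
        else:
            seeds.append([(i, i + off) for i in range(short_len)])
    # Fragment seeds at both termini for partially overlapping folds.
    half = max(short_len // 2, 4)
    seeds.append([(i, i) for i in range(half)])
    seeds.append([(La - half + i, Lb - half + i) for i in range(half)])
    best_pairs: list[tuple[int, int]] = []
    best_score = -math.inf
    for seed in seeds:
        pairs = seed
        for _ in range(max_rounds):
            R, t, _, _ = kabsch_superpose(A.coords, B.coords, pairs)
            moved = B.coords @ R.T + t
            d2 = ((A.coords[:, None, :] - moved[None, :, :]) ** 2).sum(axis=2)
            S = 1.0 / (1.0 + d2 / (d0 * d0))
            new_pairs = _dp_pairs(S, gap_open)
            if len(new_pairs) < 3:
                break
            score = sum(S[i, j] for i, j in new_pairs)
            if score > best_score:
                best_score, best_pairs = score, new_pairs
            if new_pairs == pairs:
                break
            pairs = new_pairs
    return best_pairs


def _dp_pairs(S: np.ndarray, gap: float) -> list[tuple[int, int]]:
    """Global alignment (linear gap) on a similarity matrix; traceback."""
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    H[1:, 0] = -gap * np.arange(1, n + 1)
    H[0, 1:] = -gap * np.arange(1, m + 1)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        diag = H[i - 1, :-1] + S[i - 1]
        for j in range(1, m + 1):
            up = H[i - 1, j] - gap
            left = H[i, j - 1] - gap
            d = diag[j - 1]
            if d >= up and d >= left:
                H[i, j], ptr[i, j] = d, 0
            elif up >= left:
                H[i, j], ptr[i, j] = up, 1
            else:
                H[i, j], ptr[i, j] = left, 2
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0:
        p = ptr[i, j]
        if p == 0:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def compare_structures(
    A: StructureModel,
    B: StructureModel,
    mode: str = "sequence",
) -> TMResult:
    """TM-score with the correspondence chosen by ``mode``.

    ``mode='sequence'`` uses the global sequence alignment;
    ``mode='structure'`` uses the sequence-independent iterative mode.
    """
    if mode == "sequence":
        pairs = sequence_alignment_pairs(A, B)
    elif mode == "structure":
        pairs = structural_alignment_pairs(A, B)
    else:
        raise ValueError("mode must be 'sequence' or 'structure'")
    if len(pairs) < 3:
        pairs = [(i, i) for i in range(min(len(A), len(B)))]
    return tm_score(A, B, pairs)


def structure_guided_identity(
    A: StructureModel, B: StructureModel, mode: str = "structure"
) -> float:
    """Fraction of identical residues among structurally aligned pairs."""
    pairs = structural_alignment_pairs(A, B) if mode == "structure" \
        else sequence_alignment_pairs(A, B)
    if not pairs:
        return 0.0
    matches = sum(1 for i, j in pairs if A.sequence[i] == B.sequence[j])
    return matches / len(pairs)


# ---------------------------------------------------------------------------
# Structure network


@dataclass
class StructureNetwork:
    """All-by-all TM results plus the thresholded edge list."""

    structures: list[StructureModel]
    results: list[TMResult]
    edges: list[tuple[str, str, float]]  # (id_a, id_b, tm_max)
    cutoff: float


def build_structure_network(
    structures: Sequence[StructureModel],
    cutoff: float = 0.8,
    mode: str = "sequence",
) -> StructureNetwork:
    """All-by-all TM comparison; edge iff max normalization >= cutoff.

    Each node is a single structure.  The edge criterion uses the larger of
    the two per-length normalizations.
    """
    if len(structures) < 2:
        raise ValueError("need at least two structures")
    results: list[TMResult] = []
    edges: list[tuple[str, str, float]] = []
    for i in range(len(structures)):
        for j in range(i + 1, len(structures)):
            r = compare_structures(structures[i], structures[j], mode=mode)
            results.append(r)
            if r.tm_max >= cutoff:
                edges.append((r.id_a, r.id_b, r.tm_max))
    return StructureNetwork(structures=list(structures), results=results,
                            edges=edges, cutoff=cutoff)


def write_tm_results(results: Sequence[TMResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\ttm_norm_a\ttm_norm_b\ttm_max\trmsd\taligned\n")
        for r in results:
            fh.write(f"{r.id_a}\t{r.id_b}\t{r.tm_norm_a:.6f}\t"
                     f"{r.tm_norm_b:.6f}\t{r.tm_max:.6f}\t{r.rmsd:.4f}\t"
                     f"{r.aligned}\n")


# ---------------------------------------------------------------------------
# PDB ingest and synthetic chains


def read_pdb_ca(path: str | Path, chain: str | None = None,
                structure_id: str | None = None) -> StructureModel:
    """C-alpha trace of the first model of a PDB file (one chain).

    Standard ATOM records only; the first chain is used unless ``chain``
    names another.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    coords: list[list[float]] = []
    seq: list[str] = []
    chain_id = None
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        chain_id = ch.name
        for res in ch:
            ca = res.find_atom("CA", "*")
            if ca is None or res.het_flag != "A":
                continue
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            code = gemmi.find_tabulated_residue(res.name)
            seq.append(code.one_letter_code.upper()
                       if code and code.is_amino_acid() else "X")
        break
    if not coords:
        raise ValueError(f"no C-alpha atoms found in {path}")
    return StructureModel(
        structure_id=structure_id or Path(path).stem,
        coords=np.asarray(coords),
        sequence="".join(seq),
        chain_id=chain_id or "A",
    )


_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}


def write_pdb_ca(model: StructureModel, path: str | Path) -> None:
    """Write the C-alpha trace as a minimal standard PDB file."""
    with open(path, "w") as fh:
        for i, (xyz, res) in enumerate(zip(model.coords, model.sequence),
                                       start=1):
            name = _THREE_LETTER.get(res, "UNK")
            fh.write(
                f"ATOM  {i:>5}  CA  {name} {model.chain_id}{i:>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"           C\n"
            )
        fh.write("END\n")


def random_chain(
    length: int,
    rng: np.random.Generator,
    structure_id: str = "chain",
    stiffness: float = 0.65,
    min_separation: float = 3.6,
) -> StructureModel:
    """A smoothed self-avoiding random C-alpha chain (3.8 A steps).

    Successive step directions are correlated (``stiffness`` toward the
    previous direction) so the trace is locally smooth; steps clashing with
    earlier residues are re-drawn.
    """
    coords = np.zeros((length, 3))
    direction = _random_unit(rng)
    for i in range(1, length):
        for _ in range(200):
            proposal = stiffness * direction + (1 - stiffness) * _random_unit(rng)
            proposal /= np.linalg.norm(proposal)
            candidate = coords[i - 1] + CA_CA_DISTANCE * proposal
            if i < 3:
                break
            d = np.linalg.norm(coords[: i - 2] - candidate, axis=1)
            if (d >= min_separation).all():
                break
        else:  # fall back to a straight continuation
            candidate = coords[i - 1] + CA_CA_DISTANCE * direction
            proposal = direction
        coords[i] = candidate
        direction = proposal
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return StructureModel(structure_id=structure_id, coords=coords, sequence=seq)


def perturbed_copy(
    model: StructureModel,
    rng: np.random.Generator,
    sigma: float = 0.5,
    structure_id: str | None = None,
) -> StructureModel:
    """A rigid copy with isotropic Gaussian coordinate noise (sigma in A)."""
    R = _random_rotation(rng)
    t = rng.normal(scale=20.0, size=3)
    coords = model.coords @ R.T + t + rng.normal(scale=sigma,
                                                 size=model.coords.shape)
    return StructureModel(
        structure_id=structure_id or f"{model.structure_id}_pert",
        coords=coords,
        sequence=model.sequence,
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
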