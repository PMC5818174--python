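"""All-by-all pairwise local alignment with E-value scoring.

Pairs of protein sequences are compared by optimal Smith-Waterman local
alignment (BLOSUM62, affine gaps) and the raw score ``S`` is converted to an
expectation value with the Karlin-Altschul formula

    E = K * m * n * exp(-lambda * S)

where ``m`` and ``n`` are the query and subject lengths.  The default
``lambda`` and ``K`` are the standard literature values for gapped BLOSUM62
with gap penalties 11/1.  The pipeline consumes E-values only through
logarithms and thresholds, so BLAST's finite-size edge corrections are
deliberately omitted; exact BLAST parity is available by ingesting BLAST
tabular output instead (:func:`read_tabular_hits`).

Hits computed by an external BLAST run can be read from the standard
12-column tabular format (``-outfmt 6``) and symmetrized the same way as
internally computed edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .records import SequenceRecord, as_mapping

logger = logging.getLogger(__name__)

#: Smallest E-value ever reported; underflowed values are clamped here so
#: that log10 stays finite for geometric-mean edges.
E_VALUE_FLOOR = 1e-300

#: Default reporting threshold ("more significant than 1e-5", strict).
DEFAULT_REPORT_THRESHOLD = 1e-5

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters and Karlin-Altschul statistics.

    ``lambda_`` is in nats per raw score unit and ``K`` is dimensionless;
    the effective search space is the plain product of the two sequence
    lengths.  ``identity_denominator`` selects how percent identity is
    reported: over all alignment columns (gap columns count as non-matches,
    the default) or over the shorter sequence (the convention of greedy
    clustering tools).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    K: float = 0.041
    identity_denominator: str = "columns"  # or "shorter"

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.identity_denominator not in ("columns", "shorter"):
            raise ValueError("identity_denominator must be 'columns' or 'shorter'")

    def substitution_matrix(self):
        m = substitution_matrices.load(self.matrix_name)
        if "X" in m.alphabet:
            # X tolerated but uninformative: scored 0 against everything.
            xi = m.alphabet.index("X")
            m[xi, :] = 0.0
            m[:, xi] = 0.0
        return m

    def evalue(self, score: float, m: int, n: int) -> float:
        """Karlin-Altschul expectation for raw score ``score``."""
        e = self.K * m * n * math.exp(-self.lambda_ * score)
        return max(e, E_VALUE_FLOOR)


@dataclass(frozen=True)
class SimilarityEdge:
    """A symmetrized pairwise hit between two sequences."""

    query: str
    subject: str
    score: float
    evalue: float
    identity: float
    align_len: int
    query_cov: float = 0.0
    subject_cov: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered pair key."""
        return (self.query, self.subject) if self.query <= self.subject \
            else (self.subject, self.query)


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"sequence {name!r} is empty")
    for i, ch in enumerate(seq):
        if ch not in _VALID_RESIDUES:
            raise ValueError(
                f"sequence {name!r} has non-residue character {ch!r} at position {i + 1}"
            )


def make_aligner(scheme: ScoringScheme, mode: str = "local") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = scheme.substitution_matrix()
    aligner.open_gap_score = -float(scheme.gap_open)
    aligner.extend_gap_score = -float(scheme.gap_extend)
    if mode == "global":
        # End gaps are free so that the global mode produces the overlap
        # alignments used for profile guide distances.
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, int]:
    """(identities, columns, aligned_query_span) of a local alignment."""
    counts = alignment.counts()
    gaps = counts.internal_insertions + counts.internal_deletions
    columns = counts.aligned + gaps
    return counts.identities, columns, columns


def align_pair(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scheme: ScoringScheme | None = None,
    aligner: PairwiseAligner | None = None,
) -> SimilarityEdge:
    """Optimal local alignment of two sequences with E-value scoring.

    Accepts either :class:`SequenceRecord` objects or plain strings (ids
    default to ``"a"``/``"b"``).
    """
    scheme = scheme or ScoringScheme()
    a = a if isinstance(a, SequenceRecord) else SequenceRecord("a", a)
    b = b if isinstance(b, SequenceRecord) else SequenceRecord("b", b)
    _check_sequence(a.sequence, a.id)
    _check_sequence(b.sequence, b.id)
    if aligner is None:
        aligner = make_aligner(scheme)
    alignments = aligner.align(a.sequence, b.sequence)
    score = float(alignments.score)
    best = alignments[0]
    identities, columns, _ = _alignment_stats(best)
    if scheme.identity_denominator == "shorter":
        denom = min(len(a.sequence), len(b.sequence))
    else:
        denom = columns
    identity = identities / denom if denom else 0.0
    # Aligned span on each sequence, for coverage fractions.
    (qstart, qend) = (best.aligned[0][0][0], best.aligned[0][-1][1])
    (sstart, send) = (best.aligned[1][0][0], best.aligned[1][-1][1])
    e = scheme.evalue(score, len(a.sequence), len(b.sequence))
    return SimilarityEdge(
        query=a.id,
        subject=b.id,
        score=score,
        evalue=e,
        identity=min(identity, 1.0),
        align_len=columns,
        query_cov=(qend - qstart) / len(a.sequence),
        subject_cov=(send - sstart) / len(b.sequence),
    )


def all_by_all(
    records: Sequence[SequenceRecord],
    scheme: ScoringScheme | None = None,
    report_threshold: float = DEFAULT_REPORT_THRESHOLD,
) -> list[SimilarityEdge]:
    """All unordered pairs with E strictly below ``report_threshold``.

    Self-pairs are excluded; duplicate ids are rejected.  This is exhaustive
    dynamic programming over all C(n, 2) pairs - no heuristic seeding.
    """
    if len(records) < 2:
        raise ValueError("all_by_all needs at least two records")
    as_mapping(records)  # raises on duplicate ids
    scheme = scheme or ScoringScheme()
    aligner = make_aligner(scheme)
    edges: list[SimilarityEdge] = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            edge = align_pair(records[i], records[j], scheme, aligner=aligner)
            if edge.evalue < report_threshold:
                edges.append(edge)
    return edges


def symmetrize(edges: Iterable[SimilarityEdge]) -> list[SimilarityEdge]:
    """Collapse reciprocal hits, keeping the more significant direction."""
    best: dict[tuple[str, str], SimilarityEdge] = {}
    for e in edges:
        key = e.pair
        kept = best.get(key)
        if kept is None or e.evalue < kept.evalue:
            best[key] = e
    return [best[k] for k in sorted(best)]


def read_tabular_hits(path: str | Path) -> list[SimilarityEdge]:
    """Read BLAST 12-column tabular hits (``-outfmt 6``) and symmetrize.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore.  Malformed rows are skipped with a logged line
    number; a file with no parseable row is an error.  Self-hits are
    dropped.
    """
    edges: list[SimilarityEdge] = []
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n_rows += 1
            parts = line.split("\t")
            try:
                if len(parts) != 12:
                    raise ValueError(f"expected 12 columns, got {len(parts)}")
                q, s = parts[0], parts[1]
                pident = float(parts[2])
                length = int(parts[3])
                evalue = max(float(parts[10]), E_VALUE_FLOOR)
                bitscore = float(parts[11])
            except ValueError as exc:
                logger.warning("skipping malformed row %d of %s: %s",
                               lineno, path, exc)
                continue
            if q == s:
                continue
            edges.append(
                SimilarityEdge(
                    query=q,
                    subject=s,
                    score=bitscore,
                    evalue=evalue,
                    identity=pident / 100.0,
                    align_len=length,
                )
            )
    if n_rows and not edges:
        raise ValueError(f"all {n_rows} rows of {path} were malformed or self-hits")
    return symmetrize(edges)


def write_tabular_hits(edges: Iterable[SimilarityEdge], path: str | Path) -> None:
    """Write edges in the BLAST 12-column tabular dialect."""
    with open(path, "w") as fh:
        for e in edges:
            fh.write(
                "\t".join(
                    [
                        e.query,
                        e.subject,
                        f"{e.identity * 100.0:.10g}",
                        str(e.align_len),
                        "0",
                        "0",
                        "0",
                        "0",
                        "0",
                        "0",
                        f"{e.evalue:.6g}",
                        f"{e.score:.10g}",
                    ]
                )
                + "\n"
            )
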