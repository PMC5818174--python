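"""N-terminal proline census, architecture bins, and taxon summaries.

The catalytic residue of the superfamily is the N-terminal proline, Pro-1:
the proline immediately following the initiator methionine (which may or
may not be retained in database records).  The census classifies every
sequence by the Pro-1 convention below, tallies the members lacking Pro-1
per subgroup, histograms the residues that replace it, and bins sequence
lengths into the short (single beta-alpha-beta unit) and fused (two
concatenated units) architectures.

Convention: if a sequence starts with Met, the Pro-1 position is residue 2
(initiator assumed cleaved in the mature protein); if it starts with a
non-Met residue, position 1 is assessed directly and a non-standard-start
flag is raised (Pro at position 1 counts as Pro-1 - the record is taken to
be the already-processed form).  Suspicious records (non-Met start, or
length below the short-architecture minimum suggesting truncation) are
flagged for review, never silently dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import SequenceRecord

#: Taxonomic divisions conventionally counted as eukaryotic.
EUKARYOTE_DIVISIONS = frozenset(
    {"fungi", "plants", "invertebrates", "vertebrates", "mammals", "eukaryota"}
)


@dataclass(frozen=True)
class NTermCall:
    """Pro-1 determination for one sequence."""

    sequence_id: str
    has_initiator_met: bool
    has_pro1: bool
    observed_residue: str
    non_standard_start: bool = False
    suspect_truncation: bool = False


@dataclass
class CensusReport:
    """Superfamily-wide Pro-1 census."""

    total: int
    non_pro1_total: int
    per_subgroup: pd.DataFrame  # index subgroup: columns total, non_pro1, share
    replacement_histogram: dict[str, int]
    architecture_counts: dict[str, int]
    excluded_eukaryotes: int = 0

    @property
    def modal_replacement(self) -> str | None:
        if not self.replacement_histogram:
            return None
        return max(sorted(self.replacement_histogram),
                   key=lambda r: self.replacement_histogram[r])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#total={self.total}\tnon_pro1={self.non_pro1_total}\t"
                     f"excluded_eukaryotes={self.excluded_eukaryotes}\n")
            self.per_subgroup.to_csv(fh, sep="\t")
            fh.write("#replacements\n")
            for res, n in sorted(self.replacement_histogram.items()):
                fh.write(f"{res}\t{n}\n")
            fh.write("#architectures\n")
            for arch, n in sorted(self.architecture_counts.items()):
                fh.write(f"{arch}\t{n}\n")


def classify_nterm(record: SequenceRecord | str, seq_id: str = "") -> NTermCall:
    """Pure Pro-1 call for one sequence (see module docstring)."""
    if isinstance(record, SequenceRecord):
        seq, seq_id = record.sequence, record.id
    else:
        seq = record
    if not seq:
        raise ValueError("cannot classify an empty sequence")
    has_met = seq[0] == "M"
    if has_met:
        observed = seq[1] if len(seq) > 1 else ""
    else:
        observed = seq[0]
    return NTermCall(
        sequence_id=seq_id,
        has_initiator_met=has_met,
        has_pro1=observed == "P",
        observed_residue=observed,
        non_standard_start=not has_met,
        suspect_truncation=len(seq) < 58,
    )


def classify_architecture(
    seq: SequenceRecord | str,
    short_range: tuple[int, int] = (58, 84),
    fused_min: int = 110,
) -> str:
    """Bin a sequence length into short, fused, or other.

    Short members span ``short_range`` (inclusive); fused members are
    strictly longer than ``fused_min``; lengths in between (or below the
    short minimum) are "other".  The bins are disjoint and exhaustive.
    """
    length = len(seq.sequence if isinstance(seq, SequenceRecord) else seq)
    lo, hi = short_range
    if lo <= length <= hi:
        return "short"
    if length > fused_min:
        return "fused"
    return "other"


def census(
    calls: Sequence[NTermCall],
    subgroup_labels: Mapping[str, str],
    records: Mapping[str, SequenceRecord] | None = None,
    taxon_labels: Mapping[str, str] | None = None,
    exclude_eukaryotes: bool = False,
    short_range: tuple[int, int] = (58, 84),
    fused_min: int = 110,
) -> CensusReport:
    """Tally Pro-1 absence per subgroup with replacement histogram.

    Every call id must have a subgroup label; unlabeled ids are an error.
    ``exclude_eukaryotes`` drops sequences whose taxon division is
    eukaryotic before counting (the optional prokaryote-only mode).
    Per-subgroup shares are fractions of the total non-Pro-1 count.
    """
    unlabeled = [c.sequence_id for c in calls
                 if c.sequence_id not in subgroup_labels]
    if unlabeled:
        raise KeyError(f"unlabeled sequence ids: {unlabeled[:10]}"
                       + ("..." if len(unlabeled) > 10 else ""))
    excluded = 0
    kept: list[NTermCall] = []
    for c in calls:
        if exclude_eukaryotes:
            taxon = (taxon_labels or {}).get(c.sequence_id, "")
            if taxon.lower() in EUKARYOTE_DIVISIONS:
                excluded += 1
                continue
        kept.append(c)
    totals: Counter[str] = Counter()
    non_pro1: Counter[str] = Counter()
    replacements: Counter[str] = Counter()
    for c in kept:
        sg = subgroup_labels[c.sequence_id]
        totals[sg] += 1
        if not c.has_pro1:
            non_pro1[sg] += 1
            if c.observed_residue:
                replacements[c.observed_residue] += 1
    n_np = sum(non_pro1.values())
    rows = []
    for sg in sorted(totals):
        rows.append(
            {
                "subgroup": sg,
                "total": totals[sg],
                "non_pro1": non_pro1.get(sg, 0),
                "share": (non_pro1.get(sg, 0) / n_np) if n_np else 0.0,
            }
        )
    per_subgroup = pd.DataFrame(rows).set_index("subgroup") if rows else \
        pd.DataFrame(columns=["total", "non_pro1", "share"])
    arch: Counter[str] = Counter()
    if records is not None:
        for c in kept:
            arch[classify_architecture(records[c.sequence_id], short_range,
                                       fused_min)] += 1
    return CensusReport(
        total=len(kept),
        non_pro1_total=n_np,
        per_subgroup=per_subgroup,
        replacement_histogram=dict(replacements),
        architecture_counts=dict(arch),
        excluded_eukaryotes=excluded,
    )


def write_calls_tsv(calls: Iterable[NTermCall], path: str | Path) -> None:
    pd.DataFrame([vars(c) for c in calls]).to_csv(path, sep="\t", index=False)


def taxon_summary(
    records: Sequence[SequenceRecord],
    subgroup_labels: Mapping[str, str],
    taxon_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-subgroup taxonomic division counts with the dominant division.

    Taxa come from ``taxon_labels`` when given, else from the records'
    ``taxon`` attribute.  Returns a division x subgroup count table with an
    extra ``dominant`` row; counts sum to the record count.
    """
    counts: dict[str, Counter[str]] = {}
    for r in records:
        sg = subgroup_labels.get(r.id, "unassigned")
        taxon = (taxon_labels or {}).get(r.id, r.taxon) or "unknown"
        counts.setdefault(sg, Counter())[taxon] += 1
    table = pd.DataFrame(counts).fillna(0).astype(int)
    table = table.sort_index().sort_index(axis=1)
    dominant = {
        sg: max(sorted(col.index), key=lambda t: col[t])
        for sg, col in table.items()
    }
    table.loc["dominant"] = pd.Series(dominant)
    return table
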