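"""Synthetic protein superfamilies with planted ground truth.

The generator emulates the coarse anatomy of a tautomerase-like enzyme
superfamily: several subgroups of unequal size descended from a common
root ancestor, "short" members of 58-84 residues carrying a single
beta-alpha-beta unit and "fused" members carrying two concatenated,
independently diverged copies of the unit (roughly twice as long), an
optional chain of bridge ("linker") sequences connecting two subgroups with
stepwise intermediate similarity, a small fraction of members lacking the
N-terminal proline (concentrated in one target subgroup), and per-sequence
taxonomic division labels.  Every emitted sequence is recorded in a truth
table so downstream network, profile, path and census stages can be scored
against the planted structure.

Substitution model
------------------
Mutation is Poisson per site: a site with divergence ``d`` (expected
substitutions per site) is hit by at least one event with probability
``1 - exp(-d)``, and the final residue is drawn uniformly from the 19
alternatives.  There is no rate matrix: downstream stages only need
controllable identity gradients, not realistic protein evolution.  Indels
are off by default; a small-indel mode (geometric lengths) exists for
alignment-robustness tests.

Linker chains
-------------
A chain of ``k`` bridge sequences is built as a stepwise mutational walk
that starts at the source subgroup's (fused) ancestor and ends at the
destination subgroup's ancestor.  The walk step sizes are chosen so that
consecutive chain members share statistically significant similarity while
members two steps apart do not, which makes the planted chain the unique
shortest similarity path between the two subgroups - the situation the
linker-discovery stage is designed to detect.  As a consequence, when a
chain is requested the destination subgroup's divergence from the source
arises through the walk rather than through the root.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .records import (
    AMINO_ACIDS,
    SequenceRecord,
    TRUTH_COLUMNS,
    read_fasta,
    read_truth_table,
    write_fasta,
    write_truth_table,
)

#: Residues observed to replace the N-terminal proline, weighted so that
#: serine is modal, followed by isoleucine and alanine.
PRO1_REPLACEMENT_WEIGHTS: dict[str, float] = {
    "S": 0.32,
    "I": 0.22,
    "A": 0.18,
}

#: Taxonomic divisions used for per-sequence labels.
TAXON_DIVISIONS = (
    "bacteria",
    "archaea",
    "fungi",
    "plants",
    "invertebrates",
    "vertebrates",
)

_ALPHABET = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")


def _default_taxon_mixture(subgroup: int) -> dict[str, float]:
    # One subgroup is archaea-enriched, one has broad eukaryotic
    # representation; the rest are bacteria-dominated.
    if subgroup == 0:
        return {"bacteria": 0.40, "archaea": 0.55, "fungi": 0.05}
    if subgroup == 2:
        return {
            "bacteria": 0.25,
            "fungi": 0.25,
            "plants": 0.10,
            "invertebrates": 0.20,
            "vertebrates": 0.20,
        }
    return {"bacteria": 0.85, "fungi": 0.10, "archaea": 0.05}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of a planted synthetic superfamily.

    Divergences are expected substitutions per site.  ``subgroup_sizes``
    counts the members emitted per subgroup (the first member of each
    subgroup is its unmutated ancestor and serves as the subgroup founder).
    ``fused`` marks which subgroups carry two concatenated beta-alpha-beta
    units; short members have lengths in ``unit_length_range`` and fused
    members exceed twice that minus nothing plus a 3-10 residue spacer, so
    they are always longer than 110 residues.
    """

    n_subgroups: int = 5
    subgroup_sizes: tuple[int, ...] = (40, 30, 30, 25, 25)
    unit_length_range: tuple[int, int] = (58, 84)
    fused: tuple[bool, ...] | None = None  # default: subgroup 0 short, rest fused
    within_divergence: float = 0.25
    between_divergence: float = 1.2
    duplication_divergence: float = 0.3
    linker_chain_length: int = 0
    linker_subgroups: tuple[int, int] = (0, 1)
    linker_attach_divergence: float = 0.9
    linker_step_divergence: float = 1.05
    non_pro1_fraction: float = 0.03
    non_pro1_target_subgroup: int | None = None  # default: last subgroup
    non_pro1_target_share: float = 0.85
    n_singletons: int = 0
    indel_rate: float = 0.0
    taxon_mixtures: Mapping[int, Mapping[str, float]] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subgroups < 1:
            raise ValueError("need at least one subgroup")
        if len(self.subgroup_sizes) != self.n_subgroups:
            raise ValueError("subgroup_sizes length must equal n_subgroups")
        if any(s < 1 for s in self.subgroup_sizes):
            raise ValueError("subgroup sizes must be positive")
        for name in ("within_divergence", "between_divergence",
                     "duplication_divergence", "linker_attach_divergence",
                     "linker_step_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 3.0:
                raise ValueError(f"{name} must lie in [0, 3], got {v}")
        if not 0.0 <= self.non_pro1_fraction < 1.0:
            raise ValueError("non_pro1_fraction must lie in [0, 1)")
        if not 0.0 <= self.non_pro1_target_share <= 1.0:
            raise ValueError("non_pro1_target_share must lie in [0, 1]")
        if self.non_pro1_target_subgroup is not None and \
                not 0 <= self.non_pro1_target_subgroup < self.n_subgroups:
            raise ValueError("non_pro1_target_subgroup out of range")
        lo, hi = self.unit_length_range
        if not (2 < lo <= hi):
            raise ValueError("invalid unit_length_range")
        if self.linker_chain_length:
            src, dst = self.linker_subgroups
            for sg in (src, dst):
                if not 0 <= sg < self.n_subgroups:
                    raise ValueError(f"linker subgroup {sg} out of range")
            if src == dst:
                raise ValueError("linker subgroups must differ")

    @property
    def fused_flags(self) -> tuple[bool, ...]:
        if self.fused is not None:
            if len(self.fused) != self.n_subgroups:
                raise ValueError("fused flag list length must equal n_subgroups")
            return tuple(self.fused)
        return tuple(i != 0 for i in range(self.n_subgroups))

    @property
    def total_size(self) -> int:
        return sum(self.subgroup_sizes) + self.linker_chain_length + self.n_singletons


@dataclass
class SyntheticSuperfamily:
    """Generated records plus the planted truth labels."""

    records: list[SequenceRecord]
    truth: pd.DataFrame
    founders: dict[int, str]
    config: GeneratorConfig

    def record_map(self) -> dict[str, SequenceRecord]:
        return {r.id: r for r in self.records}


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    body = rng.choice(list(AMINO_ACIDS), size=length - 2)
    return "MP" + "".join(body)


def _mutate(seq: str, divergence: float, rng: np.random.Generator,
            protect_prefix: int = 2, exact: bool = False) -> str:
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if divergence == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    p = 1.0 - np.exp(-divergence)
    mutable = np.arange(protect_prefix, arr.size)
    if exact:
        # Deterministic substitution count (random positions): used for the
        # linker-chain walk so step similarities sit at their design values.
        k = min(int(round(p * mutable.size)), mutable.size)
        idx = rng.choice(mutable, size=k, replace=False)
    else:
        hit = rng.random(arr.size) < p
        hit[:protect_prefix] = False
        idx = np.nonzero(hit)[0]
    for i in idx:
        current = arr[i]
        choices = _ALPHABET[_ALPHABET != current]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def mutate_sequence(seq: str, divergence: float, seed: int | np.random.Generator,
                    protect_prefix: int = 2) -> str:
    """Poisson per-site substitution with a protected N-terminal prefix.

    Position 1 (the initiator Met) is never mutated and position 2 (Pro-1)
    is protected by default; conversion to a non-Pro-1 record is a separate
    deliberate step (:func:`convert_non_pro1`).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return _mutate(seq, divergence, rng, protect_prefix=protect_prefix)


def draw_pro1_replacement(rng: np.random.Generator) -> str:
    """Draw the residue replacing Pro-1, weighted toward Ser, Ile, Ala."""
    named = PRO1_REPLACEMENT_WEIGHTS
    others = [a for a in AMINO_ACIDS if a not in named and a not in "PM"]
    rest = 1.0 - sum(named.values())
    residues = list(named) + others
    weights = list(named.values()) + [rest / len(others)] * len(others)
    return str(rng.choice(residues, p=np.asarray(weights) / sum(weights)))


def convert_non_pro1(seq: str, rng: np.random.Generator) -> tuple[str, str]:
    """Replace the Pro following the initiator Met; returns (seq, residue)."""
    if len(seq) < 2 or seq[0] != "M":
        raise ValueError("expected a Met-initiated sequence")
    repl = draw_pro1_replacement(rng)
    return seq[0] + repl + seq[2:], repl


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Optional small-indel mode: geometric lengths (p=0.5), prefix kept."""
    if rate <= 0:
        return seq
    out = [seq[:2]]
    i = 2
    while i < len(seq):
        if rng.random() < rate:
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # deletion
                i += length
                continue
            out.append("".join(rng.choice(list(AMINO_ACIDS), size=length)))
        out.append(seq[i])
        i += 1
    s = "".join(out)
    return s if len(s) > 2 else seq


def _fuse(unit: str, rng: np.random.Generator, duplication_divergence: float) -> str:
    """Two concatenated unit copies with a short variable spacer.

    The first copy keeps the Met-Pro start; the second is an independently
    diverged duplicate whose start is free to drift.
    """
    spacer_len = int(rng.integers(3, 11))
    spacer = "".join(rng.choice(list(AMINO_ACIDS), size=spacer_len))
    second = _mutate(unit, duplication_divergence, rng, protect_prefix=0)
    return unit + spacer + second


def _draw_taxon(subgroup: int, config: GeneratorConfig,
                rng: np.random.Generator) -> str:
    mixtures = config.taxon_mixtures or {}
    mix = dict(mixtures.get(subgroup, _default_taxon_mixture(subgroup)))
    names = list(mix)
    probs = np.asarray([mix[n] for n in names], dtype=float)
    return str(rng.choice(names, p=probs / probs.sum()))


def generate_superfamily(config: GeneratorConfig) -> SyntheticSuperfamily:
    """Generate a planted superfamily; deterministic for a fixed seed.

    Subgroup ancestors are mutated copies of a single root ancestor (except
    the linker-chain destination, whose ancestor is the endpoint of the
    chain walk); members are mutated copies of their subgroup ancestor;
    fused members duplicate the subgroup unit with divergence.  The first
    member of each subgroup is the unmutated ancestor and acts as founder.
    """
    rng = np.random.default_rng(config.rng_seed)
    fused = config.fused_flags
    lo, hi = config.unit_length_range
    unit_len = int(rng.integers(lo, hi + 1))
    root = _random_sequence(unit_len, rng)

    # Subgroup ancestors (unit form), then architecture form.
    unit_ancestors = [
        _mutate(root, config.between_divergence, rng)
        for _ in range(config.n_subgroups)
    ]
    ancestors = [
        _fuse(a, rng, config.duplication_divergence) if fused[i] else a
        for i, a in enumerate(unit_ancestors)
    ]

    chain_seqs: list[str] = []
    if config.linker_chain_length:
        src, dst = config.linker_subgroups
        walk = ancestors[src] if fused[src] else _fuse(
            unit_ancestors[src], rng, config.duplication_divergence)
        current = walk
        for _ in range(config.linker_chain_length):
            current = _mutate(current, config.linker_attach_divergence
                              if not chain_seqs else config.linker_step_divergence,
                              rng, exact=True)
            chain_seqs.append(current)
        # The destination subgroup descends from the end of the walk.
        end = _mutate(current, config.linker_attach_divergence, rng, exact=True)
        ancestors[dst] = end if fused[dst] else end[:unit_len]

    records: list[SequenceRecord] = []
    rows: list[dict] = []

    def emit(seq_id: str, seq: str, subgroup: str, architecture: str,
             taxon: str, linker_pos: int | None) -> None:
        records.append(SequenceRecord(id=seq_id, sequence=seq, taxon=taxon))
        rows.append(
            {
                "id": seq_id,
                "subgroup": subgroup,
                "architecture": architecture,
                "has_pro1": True,
                "replacement": "",
                "taxon": taxon,
                "linker_pos": "" if linker_pos is None else str(linker_pos),
            }
        )

    for sg in range(config.n_subgroups):
        arch = "fused" if fused[sg] else "short"
        label = f"SG{sg}"
        for j in range(config.subgroup_sizes[sg]):
            seq = ancestors[sg] if j == 0 else _mutate(
                ancestors[sg], config.within_divergence, rng)
            if config.indel_rate and j > 0:
                seq = _apply_indels(seq, config.indel_rate, rng)
            emit(f"SG{sg}_{j:04d}", seq, label, arch,
                 _draw_taxon(sg, config, rng), None)

    if config.linker_chain_length:
        src, dst = config.linker_subgroups
        k = config.linker_chain_length
        for t, seq in enumerate(chain_seqs, start=1):
            # First half of the chain belongs to the source subgroup,
            # second half to the destination (linkers sit inside the
            # flanking subgroups, as on real similarity paths).
            sg = src if t <= (k + 1) // 2 else dst
            emit(f"LNK_{t:02d}", seq, f"SG{sg}", "fused",
                 _draw_taxon(sg, config, rng), t)

    for j in range(config.n_singletons):
        length = int(rng.integers(lo, hi + 1))
        emit(f"SGL_{j:04d}", _random_sequence(length, rng), "singleton",
             "short", "bacteria", None)

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)

    # Plant non-Pro-1 members: founders and chain members stay canonical.
    n_np = int(round(config.non_pro1_fraction * len(records)))
    if n_np:
        eligible = truth.index[
            truth["id"].str.match(r"SG\d+_") & ~truth["id"].str.endswith("_0000")
        ]
        target_sg = config.non_pro1_target_subgroup
        if target_sg is None:
            target_sg = config.n_subgroups - 1
        target_label = f"SG{target_sg}"
        in_target = [i for i in eligible if truth.at[i, "subgroup"] == target_label]
        elsewhere = [i for i in eligible if truth.at[i, "subgroup"] != target_label]
        n_target = min(int(round(config.non_pro1_target_share * n_np)),
                       len(in_target))
        n_other = min(n_np - n_target, len(elsewhere))
        chosen = list(rng.choice(in_target, size=n_target, replace=False)) + \
            list(rng.choice(elsewhere, size=n_other, replace=False))
        for i in chosen:
            rec = records[i]
            seq, repl = convert_non_pro1(rec.sequence, rng)
            records[i] = replace(rec, sequence=seq)
            truth.at[i, "has_pro1"] = False
            truth.at[i, "replacement"] = repl

    founders = {sg: f"SG{sg}_0000" for sg in range(config.n_subgroups)}
    return SyntheticSuperfamily(records=records, truth=truth,
                                founders=founders, config=config)


# ---------------------------------------------------------------------------
# Fixture I/O


def write_config(config: GeneratorConfig, path: str | Path) -> None:
    """Serialize the config as a flat key=value text file."""
    with open(path, "w") as fh:
        for name, value in vars(config).items():
            if value is None:
                continue
            if isinstance(value, (tuple, list)):
                value = ",".join(str(v) for v in value)
            elif isinstance(value, Mapping):
                continue  # taxon mixtures are code-level configuration
            fh.write(f"{name} = {value}\n")


def read_config(path: str | Path) -> GeneratorConfig:
    kwargs: dict = {}
    bools = {"True": True, "False": False}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, raw = line.partition("=")
            name, raw = name.strip(), raw.strip()
            if "," in raw or name in ("subgroup_sizes", "fused",
                                      "linker_subgroups", "unit_length_range"):
                items = [x for x in raw.split(",") if x]
                if all(x in bools for x in items):
                    kwargs[name] = tuple(bools[x] for x in items)
                else:
                    kwargs[name] = tuple(int(x) for x in items)
            elif raw in bools:
                kwargs[name] = bools[raw]
            else:
                try:
                    kwargs[name] = int(raw)
                except ValueError:
                    kwargs[name] = float(raw)
    return GeneratorConfig(**kwargs)


def write_fixture(result: SyntheticSuperfamily, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA + truth TSV + config; round-trips through the readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "sequences.fasta",
        "truth": out / "truth.tsv",
        "config": out / "config.txt",
    }
    write_fasta(result.records, paths["fasta"])
    write_truth_table(result.truth, paths["truth"])
    write_config(result.config, paths["config"])
    return paths


def read_fixture(out_dir: str | Path) -> SyntheticSuperfamily:
    out = Path(out_dir)
    config = read_config(out / "config.txt")
    records = read_fasta(out / "sequences.fasta")
    truth = read_truth_table(out / "truth.tsv")
    founders = {sg: f"SG{sg}_0000" for sg in range(config.n_subgroups)}
    return SyntheticSuperfamily(records=records, truth=truth,
                                founders=founders, config=config)
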