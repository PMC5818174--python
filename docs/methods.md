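# Methods

This note documents the models and procedures implemented in `ssnmap`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic studies do and do not demonstrate.

## Pairwise comparison and E-values

Pairs of protein sequences are compared by optimal Smith–Waterman local
alignment with BLOSUM62 and affine gap penalties (open 11, extend 1); the
dynamic programming is exhaustive (no word-hit seeding), which is
appropriate at the scales the package targets (hundreds to a few thousand
sequences). The raw score `S` is converted to an expectation value with
the simple Karlin–Altschul form

    E = K · m · n · exp(−λS),   λ = 0.267 nats/score unit, K = 0.041,

where `m`, `n` are the two sequence lengths. These are the standard
literature constants for gapped BLOSUM62 11/1. Finite-size edge
corrections and composition-based statistics are deliberately omitted:
the pipeline consumes E-values only through logarithms and thresholds, so
a monotone, well-calibrated-in-order-of-magnitude statistic suffices, and
exact parity with a particular BLAST build is available by ingesting its
tabular output instead. E-values that underflow are clamped at 1e-300 so
that log10 stays finite everywhere downstream. "More significant than a
threshold" is always the strict inequality `E < T`.

Percent identity is reported over alignment columns (gap columns count as
non-matches) by default; the greedy clustering step uses the
identities-over-the-shorter-sequence convention of clustering tools, via
a scheme switch. An `X` residue is tolerated and scored 0 against
everything.

## Representative networks

Sequences are binned into representative nodes by greedy incremental
clustering: sequences sorted by decreasing length (ties by id), each
joining the first existing cluster whose representative it matches at an
identity strictly above the cutoff, else founding a new cluster. The
strict comparison has an inclusive override. Member-pair identity is
computed by the alignment engine directly — no k-mer prescreen — which is
exact and affordable at these scales.

A representative edge exists between two nodes iff at least one member
hit crosses them; its score is the geometric mean of all crossing member
E-values, `10^mean(log10 E)`, which provably lies between the smallest
and largest member E-value. Representative self-edges are never emitted.
Thresholding keeps edges strictly more significant than `T` and keeps all
nodes (isolated nodes are meaningful singletons). Components of the
thresholded graph are computed with networkx and labeled deterministically
by smallest node id.

## Subgroups and profiles

Components with at least `min_size` representative nodes are named;
a component containing a declared founder sequence takes the founder's
name; the rest stay unassigned. Level-2 subgroups re-cluster one
subgroup's members at a finer identity cutoff (e.g. 90% vs 50%), rebuild
representative edges from the member hits restricted to the subgroup, and
take components at a strictly more stringent threshold; nesting inside
the parent is guaranteed by construction.

MSAs are built progressively: pairwise identity distances feed an
average-linkage guide tree, and profiles are merged bottom-up by global
profile–profile alignment under expected BLOSUM62 column scores with
affine gaps (Gotoh). For two sequences this reduces to the optimal global
alignment. Externally built alignments are ingested verbatim.

Profiles are pseudocounted log-odds PSSMs rather than full profile HMMs:
columns with more than 50% gaps are dropped; residue frequencies are
weighted by Henikoff position-based sequence weights; the column score
for residue *a* is `log2(((w_a + c·bg_a)/(1+c))/bg_a)` in bits, with
pseudocount weight `c = 0.5` and BLOSUM62 marginal background
frequencies. Sequences are scored against a profile by local affine-gap
dynamic programming over profile columns (gap open 4 bits, extend 0.25
bits), reproducible bit-for-bit. This is sufficient because profiles act
purely as subgroup discriminators here; insert-state emission modeling
would add machinery without changing the decision boundary, and an ingest
path accepts externally computed per-column score tables for parity
checks.

**Membership threshold.** The natural rule "minimum held-in score minus a
margin" is biased if held-in scores are computed against a profile that
contains the scored sequence: self-inclusion inflates scores by a
substantial, alignment-length-dependent amount, and held-out members of
the same subgroup then fall below the threshold. The package therefore
computes held-in scores by leave-one-out (each source sequence scored
against a profile rebuilt without it) and sets

    threshold = min(LOO scores) − max(1 bit, 3 · SD(LOO scores)).

The adaptive margin tracks the subgroup's own score spread; the
inter-subgroup score gap (hundreds of bits at the study divergences)
leaves the discriminative property untouched.

## Linker discovery

Anchors are the representative nodes containing the two founder
sequences. The shortest path between them defaults to unweighted hops —
the natural reading of "shortest path" on a thresholded network — with an
optional `1/−log10(E)` edge weighting under which more significant edges
are shorter; both can be reported, ties are enumerated and the
lexicographically smallest path is primary. A disconnected pair is a
result, not an exception.

The control census guards against spurious single-edge bridges: nodes
within two hops (configurable) of any node incident to a crossing
representative edge are collected, the one-sequence-per-node network over
all their member sequences is rebuilt, and the sequence-level edges that
cross the two subgroup labels at the subgrouping threshold are counted
and ranged. The census is validated against exhaustive pair enumeration
in the tests on every run.

Tree-input selection takes the first neighbors of the named linker nodes,
drops members at or below the fused-length minimum (110 residues) when
fused-only filtering is on, and picks from each node the member scoring
highest against that node's own profile (ties by id; singleton nodes
contribute their only member). Bayesian tree inference itself is out of
scope; the selection exports FASTA plus provenance.

## Structure comparison

Rigid superposition uses the SVD form of the Kabsch algorithm with the
determinant correction to enforce a proper rotation; near-collinear point
sets are flagged as orientation-degenerate but still return the minimized
RMSD. The TM-score of an aligned structure pair is maximized over
superpositions seeded from contiguous alignment fragments (full, half,
quarter length at staggered offsets), each refined by iteratively
re-selecting residue pairs closer than the distance scale and
re-superposing until stable, and is reported under both per-length
normalizations with `d0(L) = 1.24(L−15)^⅓ − 1.8` floored at 0.5.
Which normalization a published network thresholded is typically
unstated, so the network edge criterion uses the larger of the two — the
declared, conservative-inclusion choice — with the 0.8 default cutoff and
0.5 as the conventional significance floor.

Residue correspondences come either from a global sequence alignment
(adequate for families with real sequence homology, including all
synthetic families here) or from a sequence-independent mode that
alternates distance-matrix dynamic programming with re-superposition from
gapless threading seeds, as structure aligners do. The latter also backs
`structure_guided_identity`, the fraction of identical residues among
structurally aligned positions.

Synthetic test structures are smoothed self-avoiding random Cα chains
(3.8 Å steps, direction-correlated, clash-rejected) plus
duplicated-and-perturbed families; real structures are ingested from
standard PDB ATOM records (first model, Cα only) via gemmi.

## The synthetic superfamily generator

The generator is the package's study-condition definition, not a tuning
knob. It emulates: several subgroups of unequal size descended from a
root ancestor; short members (58–84 residues, one β-α-β unit) and fused
members (two concatenated, independently diverged unit copies joined by a
3–10 residue spacer, always >110 residues); every sequence starting
Met-Pro unless deliberately converted to non-Pro-1; a configurable
fraction of non-Pro-1 members (default 3%) with a configurable share
(default 85%) planted in one target subgroup and replacement residues
drawn from a spectrum in which serine is modal, followed by isoleucine
and alanine; per-sequence taxon divisions with one archaea-enriched and
one eukaryote-rich subgroup by default; and an optional linker chain.

Substitution is Poisson per site — a site with divergence `d` (expected
substitutions/site) changes with probability `1 − e^(−d)`, the new
residue drawn uniformly from the 19 alternatives; there is no rate
matrix, because downstream stages need controllable identity gradients,
not evolutionary realism. Defaults: within-subgroup divergence 0.25
(members ~60% identical), between-subgroup divergence 1.2 (inter-subgroup
identity near the random background, so subgroups separate at any
reasonable threshold). Indels are off by default; a geometric small-indel
mode exists for alignment-robustness tests.

**Linker chains.** A chain of `k` bridge sequences is a stepwise
mutational walk from the source subgroup's fused ancestor to the
destination subgroup's ancestor (attach divergence 0.9 at both ends, step
divergence 1.05 between bridges). Walk steps substitute an exact count of
positions (`round(p·L)` at random positions) rather than per-site
binomial draws, so the planted step identities sit at their design values
in every run. The design calculus: adjacent chain identities (~0.36–0.43)
give member-level E-values around 1e-12..1e-20 at the generated lengths —
comfortably significant — while two-step identities (~0.15) are
chance-level, so no shortcut edges survive thresholding and the planted
chain is the unique shortest similarity path. The chain-study analyses
threshold at 1e-9, between those two scales. Because the walk must end at
the destination ancestor, that one subgroup's divergence from the source
arises through the chain rather than through the root — the one place the
generator departs from the pure star phylogeny.

## Problem sizes and what the tests show

The default studies use 150-sequence five-subgroup families (the network
and profile studies), 1000 sequences for the census, 20 independent
34-sequence runs for the linker study, and 50 unrelated chain pairs for
the structure floor — sizes at which the full pipeline, including
exhaustive-enumeration oracles, runs in well under an hour on one core.

Passing on these synthetic families demonstrates that the machinery is
correct (clustering partitions, geometric-mean arithmetic, path and
census recovery, profile discrimination, superposition optimality), not
that the biological conclusions of any real superfamily analysis are
reproduced: real sequence sets have indels, compositional bias,
non-uniform substitution, database redundancy structure, and annotation
noise that the generator deliberately does not model. The one worked
example against real data — the structure-guided identities along a
similarity path between six real structures — requires the corresponding
PDB entries to be supplied locally, since coordinate files are not
redistributed with the package.

## Numerical and degenerate-input conventions

E-values clamp at 1e-300 before logs; geometric means are computed in
log10 space; thresholds and identity cutoffs compare strictly by default
with documented overrides; clustering ties break by sequence id;
component labels sort by smallest node id; shortest-path ties enumerate
with a lexicographic primary; profile scoring of an empty sequence, an
all-gap MSA column set, alignments of fewer than three residue pairs, and
superposition of fewer than three points are errors; an empty record set
round-trips through the fixture writers as valid empty files.
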