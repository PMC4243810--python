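# Methods

This note records the models, conventions, parameter choices and known
limitations behind each stage of the pipeline, in the order the pipeline
runs them.

## Synthetic gene families (`lygevol.sim`)

**Species trees.** Either the packaged vertebrate tree — 13 species covering
mammals, birds, reptiles (together the amniotes), an amphibian, a
lobe-finned fish, teleosts and a jawless-fish outgroup, ultrametric in units
of 100 Myr with named ancestors (`amniote_ancestor`, `mammal_ancestor`,
`teleost_ancestor`, …) — or a Yule pure-birth tree conditioned on *n* tips.
The vertebrate depths are round figures encoding the standard divergence
order, not estimates.

**Gene families.** A linear birth–death process runs along every
species-tree branch starting from one gene at the root: duplications (rate
λ) split a lineage in place, losses (rate μ) terminate it, and speciation
nodes copy every surviving lineage into both daughters. The returned gene
tree is pruned to lineages with extant descendants (unary nodes spliced,
root at the MRCA of extant copies); the event history keeps everything,
including events inside fully extinct clades — deliberately, so tests can
quantify what reconciliation cannot see. Surviving duplication nodes carry
their event id as the internal-node name, making truth-to-inference matching
exact. Defaults λ = 0.2, μ = 0.05 per 100 Myr give a realistic mix of
ancient and lineage-specific duplications at family sizes of a few copies
per species; the underlying biology supplies no rate estimates, so these are
calibration choices, stated once here and not tuned.

**Sequences.** Independent-site substitution with Poisson event counts per
branch; each event moves the site to one of the 19 other residues uniformly
(a 20×20 jump matrix is pluggable). The uniform model was chosen because it
has a closed form — the probability two sequences at total path t·rate
differ at a site is (19/20)(1 − e^{−(20/19)·rate·t}), and the exact distance
correction is d = −(19/20) ln(1 − (20/19) p) — making simulator and
distance code mutually checkable. The default root sequence is a 20-residue
strongly hydrophobic signal peptide plus a 185-residue mature region with E
at mature position 73 and D at 86 and 97, mirroring the goose-lysozyme
coordinate system; catalytic sites evolve at rate × 0 by default (fully
conserved). The default substitution rate 0.08/site/100 Myr puts the deepest
tip pairs at roughly 50–60% observed divergence — the regime where distant
family members are still alignable; rates several-fold higher saturate the
alignment and are not representative of this family.

**Functional decay.** For each surviving duplication (oldest first), one
randomly chosen daughter clade may receive catalytic substitutions (E→Q at
the site-73 analogue, D→N at 86/97; probability 0.5 per duplication) and/or
whole-prefix signal-peptide deletion (probability 0.3), the sibling left
intact. A daughter is only degraded if afterwards every species carrying any
degraded copy still carries an intact one (checked globally; the other
daughter is tried on failure, and the event is skipped if neither passes).
Compensation is therefore an exact construction invariant, matching the
empirical pattern the functional scan is meant to detect, and tests assert
it exhaustively rather than statistically. Because the only indel is the
signal-prefix deletion, the simulator can emit the exact true alignment
(gap-padded prefixes), which the functional-scan tests use to separate
classification errors from alignment errors.

**Randomness.** Every operation draws from its own named stream:
`SeedSequence(seed, spawn_key=(crc32(name),))`. Adding an operation never
perturbs another's draws; all outputs are bit-reproducible under a fixed
seed.

**What the generator does not emulate.** Indels other than signal loss, rate
heterogeneity across sites/lineages, codon structure and selection,
assembly artifacts, and partial sequences. Tests passing on this generator
therefore validate the algorithmic machinery and its bookkeeping, not
robustness to alignment-hostile real data.

## Alignment and trimming (`lygevol.align`)

Pairwise alignment is global Needleman–Wunsch with affine gaps in the
standard three-state (M/Ix/Iy) formulation: the first gapped position costs
`gap_open + gap_extend`, later ones `gap_extend`; terminal gaps are
penalised like internal ones; traceback ties prefer substitution over a gap
in the second sequence over a gap in the first, fixing the usual
cross-implementation ambiguity. Scores are verified against exhaustive
enumeration (lengths ≤ 6) and against Biopython's `PairwiseAligner` on
longer random pairs. The default matrix is BLOSUM62 taken from Biopython's
`substitution_matrices`, with gap open −10 and extend −1.

The guide tree comes from Euclidean distances between 3-mer count vectors
clustered by UPGMA, written in-house because deterministic lexicographic
tie-breaking on sequence ids is required for reproducibility and is not
exposed by library linkage routines. Progressive alignment is
profile–profile ("once a gap, always a gap"), scoring column pairs by the
average substitution score over residue pairs; for two sequences it reduces
exactly to the pairwise aligner.

Column confidence follows the alignment-perturbation idea: the k-mer count
matrix is bootstrap-resampled along its k-mer dimension `n_perturb` times
(default 20), each perturbed guide tree yields a realignment, and a column's
score is the mean fraction of its aligned residue pairs co-occurring in the
perturbed alignments. Columns with fewer than two residues score 1.0
vacuously. Trimming keeps columns with score ≥ cutoff (default 0.93); the
boundary is kept — "≥" rather than ">" — so a perfect-confidence alignment
survives cutoff 1.0. Trimmed sets retain a column→original-column map so
site states can be traced through trimming. Internal coordinates are 0-based
half-open; all file coordinates 1-based inclusive.

## Distances, NJ, bootstrap, rooting (`lygevol.phylo`)

Distances are pairwise-deletion *p*-distances corrected by d = −ln(1 − p)
(Poisson) by default; the correction is a pluggable callable, and the exact
20-state correction is shipped for calibration. A pair with fewer than 20
shared non-gap columns (configurable) is flagged undefined rather than
corrected from almost no data. The pipeline's analytic default replaces the
model-specific distances of typical published protocols to keep the stage
verifiable in closed form; the hook accepts any correction.

Neighbor joining is the Saitou–Nei algorithm; the Q-minimising pair is
joined with ties broken by the lexicographically smallest sorted id pair;
negative branch-length estimates are clamped to zero with the deficit moved
to the sibling branch, preserving the pair's path length (allowing negatives
is a one-line change in the split formula, deliberately not exposed as a
default). On exactly additive matrices NJ provably recovers the generating
topology; the test suite exercises this on 500 random trees and checks
reconstructed path lengths to 1e−9.

Bootstrap support resamples alignment columns with replacement, rebuilds NJ
per replicate, and reports the percentage of successful replicates
containing each internal bipartition of the reference tree (default 1000
replications); replicates with undefined distances are skipped and counted,
with a warning beyond 10%. Rooting is by outgroup when configured (placing
the root mid-edge on the outgroup split; a non-monophyletic outgroup roots
at the maximum-purity edge with a warning) and by midpoint otherwise.

## Reconciliation and naming (`lygevol.reconcile`)

The LCA map is computed in one postorder pass; a node is a duplication iff a
child maps to the same species node. Losses on a gene edge (u, v) equal the
number of species edges between M(u) and M(v), minus one when u is a
speciation; each loss is attributed to the species branch the lineage failed
to enter, so per-branch counts sum exactly to the total. Both counts are
tested against exhaustive enumeration of all valid embeddings on small
instances.

Two blind spots are inherent and quantified against simulated truth rather
than hidden: a duplication whose descendants were entirely lost is invisible
(its events remain only in the simulator's history), and a surviving
duplication whose two daughters ended up confined to complementary species
subtrees is indistinguishable from a speciation (rare at the tested rates:
about 1 in 900 surviving duplications at λ = 0.2, μ = 0.05). Likewise, when
losses contract a duplication's surviving span, the inferred age label is
the most recent common ancestor of the survivors, which can postdate the
true event branch (~0.1% of cases at those rates).

Naming is tiered by the age of the duplication's mapped species node:
duplications at or above a configurable age threshold (default half the
species-tree height) letter their clades A, B, C… by decreasing clade size
(ties by earliest leaf id); younger internal duplications append numbers;
within-species duplications append lowercase letters — composing to
LygA → LygA1 → LygA1a. Chained duplications of one tier are flattened into a
single multi-way series, so an unresolved ancestral triplication reads
A/B/C rather than nested pairs; consecutive same-node duplications are also
reported as an ordered series. The ordering convention is stated because
gene-nomenclature practice leaves it implicit; it makes names deterministic
and invariant under input permutation. Names encode paralog groups, not
orthology claims.

Gene-tree uncertainty is handled upstream (bootstrap supports), not inside
reconciliation, which takes the point-estimate tree.

## Functional scan (`lygevol.function`)

Every row of the alignment is mapped onto mature numbering of a designated
reference: the reference's ungapped position minus `mature_offset` (its
signal-peptide length — always supplied, never guessed, since
precursor/mature confusion is the main off-by-k hazard). Internal gaps
report "gap"; positions outside a row's first/last residue report "missing"
(truncation). Catalytic verdicts apply, in order: E/D/D intact; non-E site
73 abolishes (Q by mutagenesis, K/G and others by structural inference —
the note records the grade) except D, which reduces; with E73, one replaced
aspartate reduces, both abolish; any required site gap/missing gives
"unknown". Replacement counts exclude gap/missing states, which are tallied
separately.

Secretion follows external predictor annotations when supplied
(classical > nonclassical_possible at score ≥ 0.5 > intracellular);
otherwise an 8-residue sliding window over the first 30 positions with mean
Kyte–Doolittle hydropathy ≥ 1.6 calls "classical", explicitly marked
"heuristic, low confidence" — this crude stand-in never feeds the headline
compensation statistics. The compensation cross-tab reports per-species
copy/status counts and flags species with at least one reduced/abolished
copy and no intact copy. A coverage helper supports a near-full-length
filter (≥ 90% of the mature reference by default) for survey-style use.

## Synteny (`lygevol.synteny`)

A focal gene's neighborhood is its k nearest non-family genes per side on
the same scaffold (default k = 3). Conservation between neighborhoods is the
Jaccard index of case-insensitive symbol sets — a membership formalisation
chosen because cross-species cluster comparisons are membership arguments;
adjacency-order scoring is deliberately deferred. This score is the
package's own quantification of "conserved neighborhood" and is labelled as
such in reports. Tandem clusters chain family genes whose inter-gene gap
(next.start − prev.end − 1, 1-based inclusive coordinates) is at most
`max_gap`; 200 kb by default, covering the observed ~30 kb human pair with
margin. Increasing `max_gap` only coarsens the partition.

## Pipeline (`lygevol.pipeline`, `lygevol.cli`)

Stages communicate through plain-text artifacts (aligned/trimmed FASTA,
Newick with supports, PHYLIP distance matrix, TSV tables, a JSON report) so
each stage is independently runnable and testable; the CLI exposes one
subcommand per stage plus `all`. The config file round-trips through YAML;
the two protocol-stated defaults (trim cutoff 0.93, 1000 bootstrap
replications) each live in exactly one field. Input validation returns
machine-readable diagnostics instead of raising. Logging records stage,
seed, config hash and record counts to stderr; output files contain no
timestamps, so identically configured runs are byte-identical. If trimming
removes every column (possible on saturated inputs), the pipeline logs a
warning and builds the tree from the untrimmed alignment rather than
failing. Sequences mapping to species absent from the species tree (e.g. an
external outgroup) are dropped from reconciliation with a logged note.

## Problem sizes used in the checks

The oracle and calibration checks run at sizes where their ground truth is
exact or tight: exhaustive alignment enumeration at lengths ≤ 6 (200
pairs), exhaustive embedding enumeration at ≤ 6 leaves (200 pairs), NJ
recovery on 500 random additive matrices of 4–8 taxa, copy-number
calibration at 1000 birth–death replicates (3-SE band against e^{(λ−μ)T}),
distance recovery at sequence length 5000, the compensation invariant over
500 simulated families, and full-pipeline determinism on a five-species
fixture with 25 bootstrap replicates. End-to-end demonstration runs use the
13-species vertebrate tree with bootstrap and confidence replicate counts
scaled to keep examples quick; the protocol defaults (1000 replications)
remain the configured defaults.
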