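# Methods

This note documents the models and procedures implemented in `refdb16s`,
the parameters that matter, the numerical choices, and the limits of what
the synthetic fixtures demonstrate.

## Identity semantics

All similarity decisions in the toolkit reduce to one pairwise identity
definition. Sequences are aligned globally with free end gaps (overlap
alignment) under match +1, mismatch −2, gap −2 — the megablast-style
parameter set (`-reward 1 -penalty -2 -gapopen 0 -gapextend 0`). Identity
is computed from the traceback, not the score:

* aligned region = traceback path between the first and last aligned pair;
  end-gap columns lie outside it and are never counted;
* matched columns are identical A/C/G/T pairs; internal gap columns and any
  column involving a non-ACGT character count as mismatches (an `N` never
  matches anything, including another `N`);
* `pct_identity = 100 · matches / aligned columns`.

Overlap alignment was chosen over local alignment because candidate
references are near-full-length: results are deterministic, independent of
heuristic seeding, and checkable against an exhaustive
dynamic-programming oracle (the test suite enumerates every end-trim and
alignment path on small pairs and compares score and identity). Local
high-identity/short-overlap artefacts are handled instead by the coverage
rule: a hit must cover at least 80% of the shorter sequence
(`min_coverage = 0.8`, configurable, applied to every search — the rule
exists to suppress short spurious matches, which affect every metric, not
only cross-validation). Hits are ranked by percent identity (descending),
then alignment length (descending), then subject id (ascending); the order
is total, so any permutation of input yields the same ranking. Identity is
made symmetric by construction: the pair is canonically ordered (shorter
first, ties lexicographic) before aligning, which pins down one of the
possibly many co-optimal tracebacks.

Tie-breaks inside the aligner prefer diagonal over up over left moves, and
the traceback starts at the best border cell scanned from the corner
outward; both choices are arbitrary but fixed.

The search backend is pluggable: the internal aligner is the default, and
precomputed tabular hits (outfmt-6 dialect) can be replayed through the
same filter and sort contract, so imported search results and internal
ones are treated identically downstream.

## Thresholds

All of the method's constants are parameters with these defaults:

| parameter | default | role |
|---|---|---|
| dereplication identity | 99.7% | group near-duplicates (0.3% ≈ error level over ~1.5 kb) |
| within-taxon retention | <99.0% | keep variants diverging >1% from everything retained |
| species OTU threshold | ≥98.0% | single-linkage clustering (inclusive) |
| bootstrap support | ≥70% | statistical support for a clade separation |
| read assignment | ≥98.0% | best-match threshold |
| expansion group size | >25 | unmatched-read groups that nominate additions |
| frequency filter | ≥25 reads | minimum support to retain an entry |
| read length filter | >350 bp | strict, after primer trimming |
| read quality filter | mean Phred >25 | "cumulative quality" read as per-read mean |
| coverage rule | ≥0.8 | aligned region / shorter sequence |

The expansion and retention rules are deliberately asymmetric (≥26 to
expand, ≥25 to retain), following the stated wording of each rule.
"Cumulative quality score over 25" is interpreted as mean Phred over the
read ≥/> 25 (strictly greater, matching the strict length rule); a
per-read sum would make the cutoff length-dependent, which seems
unintended.

## OTU assignment

Species-level OTUs are exactly the connected components of the graph with
an edge between every pair at ≥98% identity (nearest-neighbour /
single-linkage). This is order-independent, unlike greedy dereplication,
and is implemented by union-find; the tests cross-check against networkx
connected components. Distance is the deciding criterion: naming and
bootstrap support annotate clusters and raise conflict flags but never
override the partition.

Genus-level OTUs are not distance-thresholded (empirically, genera span
too wide a similarity range for a single cutoff). Instead: prior genus
names seed clusters; an unnamed species OTU is attached, iterating to a
fixpoint, whenever exactly one named genus remains monophyletic after the
attachment; species OTUs still unplaced are grouped into maximal clades
containing only unplaced exemplars and labelled `unclassified_<most
specific shared lineage>`. Monophyly is evaluated on the tree induced on
one exemplar leaf per species OTU (the representative), so the supplied
tree may carry either the dereplicated set or every record. Rooting is
never inferred: a bifurcating root is honoured as a rooted tree; a
multifurcating root is treated as unrooted and both bipartition sides are
tested. A named genus that no attachment can make monophyletic is emitted
with a conflict flag — the analogue of the manual renaming such cases
require.

Cluster labels: one validly named species → that binomial; several named
species that clustering cannot separate → a combination name joining the
epithets alphabetically under the shared genus (e.g.
`Streptococcus infantis/mitis/oralis/pneumoniae`); no named member →
`unclassified_` plus the most specific shared taxonomy label. Duplicate
labels get numeric suffixes.

Within-cluster divergence statistics use 100 − identity over all
within-cluster pairs; singletons are excluded and the pooled mean weights
clusters by pair count (population SD).

## Curation loop

One iteration: assign reads (best hit at ≥98%, ties by the hit-list
contract; a read never splits support) → dereplicate unassigned reads at
99.7% → for groups larger than 25, nominate the longest pool sequence at
≥98% identity to the group representative that is also longer than it
(ranked by length, then identity, then oral/airway provenance), or flag
the representative as novel → re-assign → drop entries with fewer than 25
supporting reads, logging every removal. The loop runs a configurable
number of iterations (default 1) and stops early when nothing is added.
Support counts are defined as the number of reads whose best hit is the
entry at the assignment threshold, which keeps the invariant that support
sums to the number of assigned reads.

Chimera detection is out of scope: reads carry a boolean flag from an
external checker and flagged reads are dropped during QC.

## Variation map

Column entropy uses base-2 logarithms by default (0–2 bits; natural log
available). Gaps and IUPAC ambiguity codes are excluded from the
frequencies, not fractionally distributed — the simplest defensible
reading of per-position base composition. A column with no countable base
is undefined and excluded from window means; a window with no defined
column is itself undefined. Coordinates are 1-based alignment columns;
`reference_positions` optionally remaps onto an ungapped reference row
(e.g. an *E. coli* sequence in the alignment), since gap insertion makes
raw column numbers organism-specific. Both coordinate systems can be
emitted side by side.

## Evaluation

* **First named match**: 1-based rank of the first hit whose subject
  carries a full Latin binomial, among hits ≥98%; placeholder epithets
  (`sp.`) and `unclassified` labels do not count as named.
* **Completeness**: % of queries with an empty hit list per threshold;
  monotone non-decreasing in the threshold by construction.
* **Ambiguity**: mean number of distinct OTU labels among a query's hits
  per threshold, labels counted rather than entries. Queries with no hit
  at a threshold are excluded from that mean. Note a consequence: the
  *per-query* label count is monotone non-increasing in the threshold, but
  the conditional mean need not be — a query that loses its last
  (unambiguous) hit leaves the mean computed over a more ambiguous
  remainder. The monotonicity tests therefore use query sets in which
  every query retains a hit at the highest threshold.
* **LOOCV**: every database sequence queries the whole database; the exact
  self-match is dropped (exact duplicates under a different id are legal
  subjects), the best remaining hit must satisfy the coverage rule, and
  only queries from genera with at least two database sequences are
  eligible. An eligible query with no qualifying non-self hit counts as a
  mismatch (conservative). Accuracy = 100 · (eligible − mismatches) /
  eligible.

## Synthetic communities

The generator plants a genus → species → sequence hierarchy on a random
root sequence. Defaults: 3 genera × 3 species × 3 sequences of 1500 bp;
divergence targets 1% within species, 7% between species within a genus,
15% between genera — emulating the empirical 16S structure (conspecific
~98–99% identity, congeneric mean ~93%, genus range roughly 78–97%).
Branch mutation counts are Jukes–Cantor-inverted so the *realized* mean
pairwise divergence hits each target within about ±0.5% despite site
collisions. Mutations are substitutions at distinct sites by default
(`indel_rate_factor = 0`), keeping identity targets analytic; an indel
knob exists for stress-testing the aligner. Reads are 350–500 bp windows
with per-base substitution error (default 0.5%), optional two-parent
chimeras, and contaminant lineages outside the reference set, each
receiving fewer than 25 reads by construction. One integer seed makes
records, tree, reads and tags bit-reproducible.

What the fixtures do *not* emulate: 16S secondary-structure-constrained
evolution, PCR/primer bias, homopolymer-specific error profiles, real
rank-abundance distributions, and chimeras formed mid-PCR from partially
extended fragments. Passing the planted-recovery tests therefore shows the
algorithms are correct under their stated assumptions (clean clade
structure, divergence separation), not that a real oral community will be
resolved at the same rates.

## Problem sizes

The tests and the acceptance script run at desk scale: oracle-equivalence
checks on 20-record instances of 150 bp; partition recovery on 27-record
communities at 500–700 bp over 20 seeded replicates; curation recovery
with 10 residents × 100 reads plus 5 contaminants at 700 bp references and
350–400 bp reads. These sizes were chosen as the smallest at which the
planted structure is non-trivial (multiple clusters per level, reads
shorter than references, contaminants below the support threshold); all
thresholds are identical to the full-scale defaults.

## Known limitations

* The internal aligner is exact O(nm) dynamic programming — appropriate
  for databases of order 10³ × 1.5 kb, not for millions of reads; for
  large runs, precomputed tabular hits can be imported through the same
  contract.
* Genus attachment considers single-OTU attachments to fixpoint; it does
  not search over joint multi-OTU rearrangements, so an unnamed OTU whose
  placement is only resolvable jointly stays unclassified.
* Combination labels across *different* genera (clusters merging two named
  genera) fall back to joining full binomials; such clusters always carry
  a conflict annotation at genus level.
* Tree supports are consumed, never recomputed; trees and multiple
  alignments are produced externally.
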