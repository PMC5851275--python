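# Methods

## The problem

Symbiogenetic genes (S-genes) are eukaryotic chimeras: genes assembled
within a eukaryotic lineage from at least one fragment of prokaryotic
ancestry, usually joined to fragments of other origins.  Detecting them
from sequence data requires a chain of decisions — what counts as a
homology family, what counts as a fusion, when a prokaryotic match is
"full-length" versus "partial", how to assign an origin to a fragment,
and how to date a family on the eukaryote tree.  This package implements
that chain as a deterministic pipeline over standard inputs (BLAST
tabular hits, FASTA, Newick, plain TSV annotations), with every rule and
threshold explicit and overridable.

## Pipeline model

**Homology families.**  An undirected graph joins two sequences when a
single local alignment between them has E-value < 1e-5 (strict), percent
identity ≥ 30, and mutual coverage ≥ 0.8, where mutual coverage is
min(aligned span / length) over the two partners.  HSPs are never
chained, and one qualifying HSP suffices for an edge.  Connected
components are the families; sequences without a qualifying edge are
singleton families, so the families partition the input.  Candidate
families for the downstream stages are eukaryote-only with members from
at least three species.

**Composite (triplet) test.**  A gene C is chimeric when two genes A ≠ B
from outside C's family each align to ≥ 30 aa of C, neither alignment
reaches mutual coverage 0.8 with C (no full-length explanation), and the
two spans on C overlap by ≤ 20 aa.  This is a from-scratch
operationalisation of the classical "Rosetta stone" triplet idea; it
does not reproduce any particular tool's internal scores, and both
constants sit in `Thresholds` for sensitivity analysis.  A family is
called composite when strict majorities (> 0.5) of its members are
triplet-flagged *and* carry ≥ 2 annotated domains.

**Classification.**  Composite families are compared against prokaryotic
sequences (typically a larger search set than the clustering set — the
two are separate inputs):
full-length prokaryotic homology (mutual coverage ≥ 0.8) ⇒ the fusion
predates eukaryotes (`PROK_FULL`); no prokaryotic similarity below the
E-value cutoff ⇒ `EUK_INNOVATION`; partial similarity only ⇒ `S_GENE`.
An optional HMM-profile table then demotes S-genes with full-length
profile matches to `PROK_FULL` and rescues innovations with partial
profile matches to `S_GENE` (a full-length profile match on an
innovation also demotes to `PROK_FULL`).  Curated exclusions (e.g.,
suspected eukaryote-to-prokaryote transfers) are consumed as an explicit
id list, never re-derived.

**Components and origins.**  Every qualifying partial, non-family
alignment onto an S-gene defines a component instance; instances on one
composite are single-linkage clustered at > 70% reciprocal span overlap,
and clusters are merged to a fixpoint when one representative is
included in another by > 70% of the smaller length.  The representative
span is the low median of member starts/ends — integral, deterministic,
robust to outlier spans; the family-level interval is otherwise
undefined by the procedure this follows.  Origins come from the ten best
prokaryotic supporters by bitscore (ties broken by E-value, then id):
all bacterial ⇒ BAC, all archaeal ⇒ ARC, fewer than ten or mixed ⇒
PROK, none ⇒ EUK.  A conservative variant relabels ARC/BAC components
overlapping small or low-complexity domains (WD40, TPR, ankyrin and
kin — the list ships in `components.SMALL_DOMAIN_LIST`) as PROK; EUK
labels are never touched, so counts of eukaryotic-component-bearing
genes are invariant under it.  Per family, the origin profile is the
fraction of member genes with ≥ 1 component of each origin; labels such
as BAC-EUK come from a deterministic rule (origins with ratio > 0.5,
ordered ARC before PROK before BAC before EUK), with average-linkage
hierarchical clustering available for exploratory heat-map-style
grouping only.

**Ages.**  Family presence/absence across species is mapped on a rooted
species tree whose deepest split separates Opimoda from Diphoda.  Dollo
parsimony places the single gain at the MRCA of the present leaves and
one loss on the edge above each maximal all-absent subtree below it;
placing the gain higher only adds losses, a fact the tests verify
against exhaustive enumeration rather than assume.  Age classes: EARLY
(present on both sides of the root split), LINEAGE_SPECIFIC (one
supergroup), INTERMEDIATE (otherwise).  For gene trees with bootstrap
supports, a resolved bipartition (support ≥ 85) "mixes" supergroups when
some supergroup has leaves on both sides and neither side is pure for a
single supergroup; no mixing ⇒ OLD, mixing confined within one megagroup
⇒ LIKELY_OLD, Opimoda and Diphoda joined on a smaller side ⇒
INCONCLUSIVE.  The naive reading "smaller side spans > 1 supergroup"
was rejected because it would flag the clean deep split of a perfectly
vertical tree as a mixture.

**Auxiliary evidence.**  A composite is operon-like when two of its
component families are supported by two *different* prokaryotic genes
sharing one operon of one genome.  Intron conservation compares intron
positions mapped to alignment columns (intron after residue k ⇒ column
of residue k+1; past the final residue ⇒ sentinel column n+1) between
Opimoda and Diphoda members; the default match is exact column identity
(a tolerance is configurable — exactness is the only reproducible
default for a comparison that was historically done by eye), and a
conserved pair sits BETWEEN_COMPONENTS only when both introns fall
within 20 aa of a component border in their own coordinates.  A family
is organelle/secretory-targeted when a strict majority of members are
predicted MITO, CHLORO or SIGNAL.

**Statistics.**  Pearson chi-square without continuity correction;
Benjamini–Hochberg adjustment across a set of tests (the field default
where only "adjusted P" is specified; note BH is *not* idempotent —
re-adjusting adjusted values can change them).  The resampling test
draws `n_resample` (default 100) samples of families without replacement
from a background pool, counts positives, and standardises the observed
count by the replicate mean and population SD; both one- and two-sided
normal tails are reported because a depletion-style result is naturally
one-sided.  An exhaustive mode enumerates all subsets for small pools,
where the replicate distribution is exactly hypergeometric.

## Synthetic data: what it emulates and what it does not

The generator plants every structure the pipeline claims to detect, at a
scale a laptop can verify end to end:

* a species tree with `n_supergroups` supergroups (default 4, 3 species
  each) split across Opimoda and Diphoda, ladder topologies, labelled
  internal nodes;
* a domain library (default 120 domains of 60–120 aa) partitioned into
  bacterial, archaeal and eukaryote-only domains; prokaryotic genomes
  (default 10 bacteria + 10 archaea) each carry one single-domain gene
  per domain of their side, so a genuinely bacterial component has
  exactly ten bacterial supporters and the top-ten rule resolves it;
* 30 S-genes (2–4 fragments, ≥ 1 prokaryotic), 10 full-length transfers
  (2 prokaryotic fragments whose exact fusion exists in a small
  *extended* prokaryote set that never enters the clustering dataset —
  the only way a eukaryote-only family can have a full-length
  prokaryotic homolog, mirroring the two-dataset design of large
  surveys), 10 innovations (eukaryote-only domains), and one
  single-domain donor family per eukaryotic domain;
* gains planted at the root, megagroup and supergroup nodes (every
  conserved-intron family gains at the root so both megagroups carry
  it), with occasional single-leaf losses constrained to keep the MRCA
  at the planted gain;
* operons containing the two bacterial donors of the first five S-genes
  (plus unrelated background operon pairs as negative controls), and
  introns planted at shared positions either within 10 aa of the first
  component border (positives) or at fragment centres > 20 aa from any
  border (negatives), plus one private intron;
* mitochondrial-targeting predictions for a subset of S-gene families
  *and* a subset of donor families, so the family-level resampling test
  has a non-degenerate background pool.

Sequences evolve by uniform random substitution at a per-branch
probability (default 0.1, validity bound < 0.5); there are **no
indels**, so planted spans are exact and interval-level recovery can be
scored unambiguously.  Hit statistics are closed-form conventions, not
claims about BLAST: pct identity is the observed Hamming identity,
bitscore = round(1.8 · L · identity), E-value = min(1, 10^(−bitscore/5)).
With `hit_noise` > 0 that fraction of directed hit records is dropped
(each orientation independently — all-vs-all searches emit both, and
the pipeline is orientation-agnostic) and an equal number of short
spurious records with E-value ≥ 1e-3 is added; spurious records can
therefore never satisfy the family-edge or triplet E-value criteria by
construction.

Consequently, passing the planted-recovery tests shows the pipeline's
*logic* is faithful — it says nothing about robustness to indels, domain
shuffling, rate heterogeneity, alignment-boundary jitter, profile-search
sensitivity, or the curation steps real data need.  Those remain the
responsibility of the upstream aligner and the analyst.

## Numerical choices and degenerate inputs

* Coordinates are 1-based inclusive everywhere; interval length =
  end − start + 1.
* Strictness follows the stated rules exactly: E-value `<`, identity
  `≥`, coverage `≥`, majorities `>`, component overlap and merge
  inclusion `>`.
* Deterministic tie-breaks throughout: family ids are the smallest
  member id; component ids are ordered by representative span; supporter
  ranking is (−bitscore, evalue, subject id); merge candidates are
  processed by (descending member count, leftmost start).
* All-absent presence rows, empty families, degenerate contingency
  margins and zero-variance resampling pools raise errors rather than
  return placeholders.
* Every stage is a pure function of inputs + config + seed; re-running
  a stage reproduces byte-identical files.

## Problem sizes used in the shipped analyses

The study configuration (the generator defaults) produces ~1 400
sequences and ~68 000 hit records; the full pipeline completes in about
ten seconds and the oracle comparisons (100 clustering instances of up
to 500 hits, 40 triplet instances of up to 50 proteins, 200 Dollo rows
on trees of up to 8 leaves, 1 000 null resampling runs) in well under
two minutes.  These sizes were chosen so that exhaustive enumeration
remains a usable oracle; nothing in the implementation depends on them.

## Known limitations

* The triplet criterion is a reconstruction of the published tool-chain
  step from its stated intent; exact per-triplet scores of the original
  tool are out of scope.
* Component origins use the ten-best-supporters rule per component
  family (the per-interval reading); phylogeny-based confirmation of
  origins beyond the codified resolved-partition test requires expert
  inspection of the component trees.
* The species tree is an input; published alternative topologies change
  the Dollo and age results and are supported simply by passing a
  different Newick file.
* Hierarchical origin-profile clustering is exploratory; the rule-based
  labels are the citable output.
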