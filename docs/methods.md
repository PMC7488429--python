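# Methods

## Model and assumptions

The quality model is the standard single-copy marker gene (SCMG) argument:
within a suitable clade, a curated collection of gene families is expected to
occur exactly once per genome. For a query bin scored against a set S of such
families, the fraction found at least once estimates completeness and the
fraction found in two or more copies estimates contamination. The estimates
are meaningful only insofar as (a) the set is appropriate for the query's
clade, (b) the markers are spread roughly uniformly along the genome so that
losing a random x% of the genome loses ≈ x% of the markers, and (c) the gene
prediction and HMM annotation feeding the counts are accurate. (a) is
addressed by dynamic set selection, (b) is a measurable diagnostic (below),
and (c) is outside the package: annotation quality is inherited from the
external predictor/scanner.

Contamination counts each duplicated family once, whatever its copy number:
the score is a fraction of profiles, not of copies. Copy numbers are written
to the per-profile report so heavier duplication remains visible. A
duplicated profile is by definition also a found profile, so contamination ≤
completeness always; this is asserted on every report.

## Database construction

**Bit-score thresholds.** For each profile the candidate grid is the set of
distinct observed bit scores (any threshold between two observed scores
yields identical counts, so the grid is exhaustive). The chosen threshold
maximises the number of reference genomes with exactly one hit at or above
it; ties are resolved toward the *largest* score, the most stringent cutoff,
because the purpose of per-profile thresholds is paralog separation. Counting
genomes with exactly one surviving hit (rather than at least one) is what
makes the calibration favour thresholds that cut paralogs without cutting the
ortholog. Calibration can be restricted to a taxonomically balanced genome
subset (at most 30 genomes per major clade, drawn round-robin across the
phyla within each clade with a seeded shuffle); by default all genomes are
used, and balancing is applied when the caller supplies a clade/phylum table
— rank vocabularies in lineage strings are too heterogeneous for the package
to guess those labels reliably.

**Copy counts.** count(g, p) is the number of *distinct* proteins of genome g
with a hit to p scoring ≥ τ_p (inclusive). Deduplication by protein means
domain-level multiple matches of one protein count once.

**Clade sets.** Every internal node whose clade holds ≥ `min_species` (3)
leaves is examined. A profile qualifies when its single-copy prevalence —
the fraction of clade genomes with count exactly 1 — reaches
`prevalence_cutoff` (0.98); a set is emitted when ≥ `min_profiles` (20)
qualify. Both rules are applied jointly and every emitted set stores its
per-profile prevalences, which tests re-derive from the matrix and compare
exactly.

**Placement reference set.** A greedy multicover: repeatedly select the
profile that is single-copy in the most genomes still below `min_cover` (3)
coverage, ties toward the lexicographically smallest profile id, stopping
when all genomes are covered or no profile helps. Infeasible instances
return the best-effort set together with the under-covered genomes rather
than failing; the greedy solution is within the classical (1 + ln n) factor
of optimal, which the tests verify against exhaustive enumeration on small
instances. No upper coverage cap is imposed: high observed coverage of some
genomes is a by-product of overlap, not a constraint.

## Set selection

Placements are read from jplace v3 (edge numbers resolved to tree nodes by
leaf-set identity; support taken from a posterior-probability field when
declared, else the likelihood weight ratio) or produced by the built-in
fallback, which assigns each query protein to its best-scoring reference
profile and places it on the leaf of that profile's exemplar genome with
support 1.0. The fallback is a deliberately crude nearest-exemplar rule that
keeps the pipeline runnable without an external placer; it is not a
phylogenetic method.

Per protein the best-supported placement wins; support ties resolve rootward
(the conservative choice — never over-commit to a narrow clade), then by node
id for determinism. Candidate sets are all sets whose clade contains at least
one placement, plus the nearest set-bearing ancestor of the placements' LCA.
The winner maximises encapsulated placements; ties go to the deeper (more
specific) node, then to the set id. Equal-coverage and equal-support
tie-breaking rules are this package's own choices; they are stated here
because no published convention exists. Low coverage (< 1) and thin placement
evidence (< 20% of reference profiles placed, configurable) produce warnings
but still return a choice: reporting with a caveat is more useful than
refusing.

## Diagnostics

**Unassessed fraction** — genome length on contigs carrying no marker hit,
divided by total length. Marker-silent contigs are invisible to SCMG scoring;
this quantifies how much of the bin the estimate actually saw.

**Marker uniformity** — non-overlapping 5-kb windows are drawn uniformly at
random without replacement (the genome is tiled into windows, the tiling is
shuffled); after each draw the cumulative sampled length and the number of
distinct markers recovered are recorded, and the Pearson r over the series is
returned. Uniform marker placement gives near-perfect linearity (r > 0.99 at
10 Mb / 200 markers); clustering lowers r on the same seeds. Sampling without
replacement is essential — overlapping draws would recount the same markers
and inflate the correlation.

## Simulator

Fragment lengths are max(`min_step`, `step_unit` · Poisson(λ)) with defaults
λ = 100, unit 100 bp, floor 2000 bp, i.e. ~2–20 kb fragments resembling
metagenome-assembly contigs. The unit exists because a literal base-pair
Poisson(100) draw is always dominated by the 2000-bp floor, collapsing the
length distribution to a constant; `step_unit=1` recovers that degenerate
literal reading if wanted. Fragments tile each chromosome exactly (asserted),
are kept independently with probability `target_fraction`, and contamination
is expressed as a fraction of the *contaminant* genome's length — the same
size-fraction logic as completeness. In `random_dna` mode the contaminant is
an i.i.d. sequence with configurable GC, synthesised at the target genome's
total length so the fraction logic is unchanged; since random DNA carries no
marker loci it serves as the negative control for the contamination score.
Truth records store total and kept base pairs for both sources, so any
alternative denominator can be recomputed. All coordinates are 0-based,
half-open; FASTA headers encode source, coordinates and label.

## Synthetic reference corpus

The fixture generator emits a random rooted species tree (random recursive
bipartition to a depth cap), tree-derived lineages, a copy-count matrix in
which each cell is single-copy with probability 1 − dropout, absent with
probability dropout · (1 − duplication_rate) and duplicated otherwise, a hit
table and proteomes exactly consistent with the matrix (plus sub-threshold
decoy hits at rate 0.1 so calibration has noise to reject), and per-species
genome coordinates with one marker locus per counted copy, placed uniformly.
Defaults — 16 species, 100 profiles, 5-Mb genomes in 4 contigs, 2% dropout,
10% duplication among dropped cells — give a corpus in which roughly 1 marker
falls per 50 kb, so co-location of two markers on one ~10-kb fragment is rare
and marker retention under fragment subsampling is nearly binomial. The
`annotate` method of a fixture is an exact-annotation oracle: every marker
locus on a kept fragment yields a hit scored 60 bits above the generating
threshold, which is above any cutoff calibratable from the corpus (reference
scores top out at threshold + 50). This separates estimator error from
annotation error, which is precisely what parameter-recovery experiments
need.

What the fixture does *not* model: phylogenetic correlation of marker loss
(dropout is i.i.d. across species), gene prediction failure modes, sequence
similarity between paralogs, or compositional signal in the DNA (sequences
are i.i.d. and only materialised on demand). Passing recovery tests therefore
demonstrates correctness of the counting, selection and scoring machinery
under ideal annotation — not robustness to annotation error on real genomes.

## Problem sizes and determinism

Recovery experiments use one 5-Mb, 100-marker genome per run with 50 seeds
per completeness level (0.5–1.0) and 12 seeds per contamination level
(0–15%); oracle-equivalence checks use 200 random calibration tables and 100
random tree/placement instances; invariant fuzzing uses 1000 random count
vectors. These sizes keep the full suite under ~30 s while leaving the
binomial 3σ acceptance bands far from their failure thresholds. Every
stochastic component takes an explicit seed (numpy `default_rng`); fixed
seeds make every test and the acceptance script bit-reproducible. Completeness
recovery is run with a perfect anchor placement at the target's own leaf so
that it measures the estimator alone; placement selection has its own
exhaustive oracle test, and the naive-placement path is exercised end to end
separately.

## Known limitations

- The fallback placer ignores branch lengths and sequence divergence; with a
  sparse placement reference set it can mis-place queries from taxa distant
  from every exemplar. Real use should supply pplacer jplace output.
- Strict-consensus lineage stops at the first disagreement; one aberrant
  reference species truncates the reported lineage (a majority rule would be
  less conservative; strictness was chosen deliberately).
- Contamination from very close relatives is invisible in principle: a
  contaminant sharing the target's single-copy markers raises completeness
  before it raises contamination, and the simulator reproduces (rather than
  corrects) this behaviour.
- Thresholds calibrated from few genomes are fragile; the calibration has no
  shrinkage and will overfit a profile observed in only a handful of genomes.
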