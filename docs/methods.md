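# Methods

## The PHF model

A phage host family (PHF) is the bacterial family of a phage contig's most
confident host prediction. The package treats host evidence as two ranked
lists per contig: computational predictions ordered by confidence score,
and proximity-ligation (Hi-C) links ordered by link strength. All taxonomy
comparisons are exact, case-sensitive matches on bare names at a single
rank; rank prefixes (`f__`-style) are stripped at parse time and never
consulted again. An empty name at a rank never matches anything — contigs
unresolved at a rank count *against* concordance rather than leaving the
denominator, because the concordance statistic is defined over all compared
contigs, not over contigs resolvable at each rank. A `drop_unnamed` flag
switches to the denominator-shrinking convention for sensitivity analysis.

Ties in confidence (and in link strength, when ranks must be derived from
strengths) are broken by the lexicographically smallest serialised lineage.
This is an arbitrary but deterministic convention; it only matters when two
predictions carry identical scores.

## Concordance

For contigs with both evidence types, concordance at rank *r* under mode
*m* is:

- `strict` — best prediction matches the top link at *r*;
- `top_vs_any` — best prediction matches any link at *r*;
- `any_vs_any` — any prediction matches any link at *r*.

The accepted-match sets are nested, so percent concordance is provably
non-decreasing from `strict` to `any_vs_any`; the test suite asserts this
on every instance and checks exact equality with a brute-force enumerator
on random instances. With internally consistent lineages (agreement at a
rank implies agreement at all shallower ranks), concordance is also
non-increasing from phylum to genus within a mode.

Concordance is reported for phylum through genus. The species rank is
carried in the data model but not scored: genus is already the noise floor
of current host-prediction tools.

## Agglomeration and why distances shrink

`agglomerate` sums features sharing a host family, conserving per-sample
totals exactly, and is idempotent. For Bray-Curtis, grouping can only
reduce dissimilarity: for grouped sums, `|Σx − Σy| ≤ Σ|x − y|` per group,
so BC(PHF table) ≤ BC(vOTU table) for every sample pair, to machine
precision. This inequality is the mechanism behind lower PHF-level
ecological distances and is asserted to 1e-12 over hundreds of random
tables. The analogous empirical (not provable) effect holds for stability:
`1 − distance` between consecutive samples of an individual rises under
agglomeration.

Contigs with no prediction carry the sentinel family `"Unknown"`. A
prediction whose family name is empty is also mapped to `"Unknown"` (its
confidence is retained): a family-level unit cannot be built from an
unnamed family, and treating such contigs as host-unknown keeps the
unknown-fraction sample filter honest. `"Unknown"` participates in relative
abundance and in the unknown-fraction filter, but should be excluded from
PHF-level distance and prevalence analyses (drop the feature before
computing distances); the filters leave that choice to the caller.

## Distances

Bray-Curtis is `Σ|x−y| / Σ(x+y)`. UniFrac is computed against a rooted
host tree by a single postorder accumulation of per-branch descendant
abundance:

- unweighted: branch length leading to tips present in exactly one sample,
  over branch length leading to tips present in either;
- weighted, normalised: `Σ L_b |p_b(x) − p_b(y)| / Σ L_b (p_b(x) + p_b(y))`
  with `p_b` the fraction of a sample's total abundance under branch *b*.

The normalised weighted variant (the phyloseq `wunifrac` convention) keeps
both metrics in [0, 1]; it equals 1 when the two samples occupy disjoint
subtrees of a root bifurcation. Correctness is checked two independent
ways: an exhaustive branch-enumeration oracle on 1,000 random small trees
(tolerance 1e-10), and scikit-bio's implementations on random inputs.
Distances are intended to be computed on the filtered, renormalised
relative-abundance table. For genome-level reference trees,
`prune_to_families` keeps the first tip per family in a deterministic
preorder traversal and renames it to the family, yielding the family-level
tree that PHF tables need; callers may instead supply their own
family-level tree.

## Filters, presence, prevalence

- Unknown-host filter: keep samples whose `"Unknown"` mass is strictly
  below 30% (literal reading of "less than 30%").
- Depth filter: length-normalised count is reads per kilobase summed over
  features (the conventional choice; the normaliser is pluggable since the
  definition is not standardised), threshold 1,500, keep `>=`.
- Presence: breadth-of-coverage thresholds stratified by contig length —
  50% below 5 kb, 30% in [5, 20) kb, 10% at or above 20 kb, with the
  boundary inequalities applied literally.
- Good's coverage: `1 − singletons/total` per sample.
- Dereplication: greedy longest-first clustering at ANI ≥ 95% and
  alignment fraction (of the shorter sequence) ≥ 85%. The thresholds are
  standard; the greedy longest-first rule is the conventional vOTU
  clustering and implies that chains are not transitively merged — a
  contig joins a cluster only through a direct passing hit to the
  representative.
- Prevalence: a feature is present in an individual if present in any of
  that individual's samples; "prevalent" means strictly more than 50% of
  individuals.

## Statistics

Matched distance sets (e.g. vOTU-BC, PHF-BC, PHF-wUniFrac over identical
sample pairs) are compared with the Friedman test plus two-sided pairwise
Wilcoxon signed-rank tests, Bonferroni-multiplied by the number of pairwise
tests performed and capped at 1; median paired differences give effect
direction. Degenerate inputs (identical groups, all-zero differences)
return statistic 0 and p = 1 rather than erroring. PHF–host abundance
associations use Spearman's rank correlation across shared samples, with
family names translated through an NCBI–GTDB fraction-mapping table at
threshold 0.6 and Benjamini–Hochberg adjustment across the testable pairs;
constant profiles are flagged and excluded rather than given a fabricated
correlation.

## The synthetic cohort generator

`generate_cohort` emulates the structure the PHF argument rests on:

- a cohort-level base family profile, with per-individual profiles drawn
  from `Dirichlet(concentration · base)` so family composition is shared
  (default concentration 50);
- per-individual vOTU pools per family, mostly private: each of the
  (default 8) slots per family draws from a small shared pool with
  probability `shared_votu_fraction` (default 0.05), so contig-level
  overlap between individuals is low and interindividual vOTU-level
  Bray-Curtis sits near 1;
- log-abundance AR(1) dynamics per vOTU (`persistence` 0.8, stationary
  σ = 1.0) over the collection series (default 10 individuals × 14
  collections);
- negative-binomial counts at a mean depth of 50,000 reads per sample
  (gamma–Poisson, dispersion 0.3); zeros are real zeros;
- host-assignment tables derived from the true lineages: 86.3% of contigs
  receive a prediction, with per-rank error 2/3/4/7/33% from phylum to
  genus (the observed degradation profile of host prediction below the
  family rank), 30% of predicted contigs receiving up to 3 extra
  lower-confidence predictions, and Hi-C links that are correct at the top
  rank by default with 30% of contigs receiving extra lower-ranked links;
- prophage flags at rate 0.234 with AMG counts Poisson at 18.5/Mb
  (prophage) and 12.3/Mb (other) — the carriage contrast the density
  summary is meant to expose;
- a family-level host tree following the synthetic taxonomy's hierarchy
  with uniform-random branch lengths.

Corruption keeps lineages internally consistent: an error planted at rank
*r* replaces names at *r* and deeper with a sibling taxon's names that
agree with the truth above *r*, drawn so the marginal error rate at each
rank equals the configured rate exactly. This is what makes the rank-
monotonicity property hold on synthetic data and mirrors how a wrong
family implies a wrong genus in real predictions.

`plant_prevalence` builds family-level tables where exactly *k* features
exceed 50% prevalence, for exact recovery tests. `sample_depths` draws
log-normal per-sample depths calibrated so a chosen fraction (default
31.5%) falls below the 1,500-count threshold.

What the generator does *not* emulate: sequence content (no reads or
assemblies — the pipeline starts at tables), compositional coupling
between phage and bacterial communities, realistic zero-inflation beyond
what negative-binomial sampling produces, batch effects, or diagnosis-
dependent effect sizes. Passing tests therefore demonstrate correctness of
the operations and recoverability of planted structure, not performance on
real sequencing data.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately modest scales chosen to
exercise every code path: cohorts of up to ~3,400 contigs × 140 samples,
concordance recovery on twenty 1,243-contig replicates, UniFrac oracle
equivalence on 1,000 trees of ≤ 6 tips, and the aggregation inequality on
hundreds of random tables. Relative-abundance columns are validated to sum
to 1 within 1e-9; distance matrices are validated symmetric with zero
diagonal at 1e-12; percentage outputs are written at one decimal place.

Known limitations: the dereplication input is a pairwise hit table (no
alignment is performed); differential abundance itself is delegated to
external tooling — the package implements only the prevalence prefilter
and the paired-design individual selection; and UniFrac pairwise loops are
quadratic in samples, fine at cohort scale but not for thousands of
samples.
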