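# Methods

This note documents the models and procedures implemented in `odpeval`,
the parameter choices that matter, and the limits of what the synthetic
evaluation can show.

## Ontology model

An ontology is a rooted DAG of named classes with two edge types, `is_a`
and `part_of`, read from OBO flat files (`[Term]` stanzas; only `id`,
`name`, `is_a`, `relationship: part_of` and `is_obsolete` are
interpreted; obsolete terms are dropped). If a file has several
top-level classes a fresh root (`ROOT:<slug>`) is inserted and all of
them attached beneath it — the usual preprocessing step before
computing taxonomy statistics, and required so that information content
and depth are well defined. `is_a` cycles are fatal; `part_of` cycles
are structurally possible in third-party files and only provoke a
warning, because nothing downstream requires part_of acyclicity. Class
IDs are exact, case-sensitive strings; no CURIE expansion is attempted.

## Compound patterns and the structural classifier

One compound class is created per distinct (anatomy, pathology) pair
observed in the data — never for the full cross product. Subsumption
between compound classes of the same pattern is decided by the
component-wise rule described in the README. For the axiom fragment the
patterns generate (a named class conjoined with a single existential
restriction over `has_lesion`/`affects`, transitive `part_of`, and the
top-level contextualization axioms), this rule is sound and complete,
so the structural classifier reproduces what a DL reasoner would infer
while staying linear-algebra-friendly. The classified hierarchy is the
transitive reduction of the union graph (both source taxonomies, the
compound classes, their inferred mutual subsumptions, and each compound
class's backbone attachment) under a fresh top node standing in for
`owl:Thing`.

Two deliberate modelling choices:

* **Backbone attachment of the T variants.** `∃part_of.A ⊓ …` is not
  logically a subclass of `A`, but MAPT/PAMT compound classes are
  nevertheless attached beneath their anatomy/pathology class so the
  result is a single rooted taxonomy. This mirrors how the inferred
  hierarchies of such patterns are presented in practice and keeps
  every downstream metric defined; it is an approximation, and the
  only place the pattern semantics and the emitted graph diverge.
* **Root-context pairs collapse as equivalences.** A pair whose
  pathology component is the pathology root means "A with some lesion",
  which the contextualization axiom makes equivalent to `A` itself
  (symmetrically for PAM/PAMT with the anatomy root). Such pairs are
  merged onto the backbone class, with the compound ID recorded as a
  synonym, rather than materialised as a duplicate node. Consequently
  the compound-class count equals the number of distinct observed pairs
  minus any root-context pairs.

An `asserted` mode (`classify=False`) keeps only the backbone
attachments, which is what the pre-reasoning ontology looks like; the
package's tests verify that classification can only increase
tangledness, never decrease it.

## Structural metrics

`TMOnto` is the fraction of classes with more than one direct is_a
parent; `WMCOnto` the mean depth of leaf classes; `DITOnto` the maximum
leaf depth. Depth is the number of is_a edges from the root (root = 0)
along the *longest* path by default. The longest/shortest convention is
configurable because the definition is genuinely ambiguous on DAGs and
published metric tables rarely state which was used; all package
defaults and tests use longest-path. Metrics can be restricted to a
class subset (e.g. only the newly created compound classes), in which
case the class and leaf sets are intersected with the subset while
depths are still measured in the full graph.

## Information content and similarity

The IC corpus counts each distinct class once per mouse (annotation
sets are deduplicated), so repeated necropsy line items for the same
animal do not inflate a class's probability; this is a choice — raw
diagnosis multiplicities are preserved in the cohort for anyone who
wants multiplicity-weighted counts. A class's probability accumulates
the direct counts of its is_a descendants-or-self, normalised by the
total number of direct annotations, so the root has probability 1 and
IC 0. Logs are natural (configurable base). Classes never annotated
receive the floor probability 1/N, are flagged, and are excluded from
MICA searches so that an unobserved class can never serve as evidence
of similarity. Healthy mice are annotated with the view's root class,
giving them zero similarity to everything — the intended behaviour:
absence of disease carries no phenotype information in this framework.

Mouse-to-mouse similarity is best-match-average over Resnik class
similarities. The matrix implementation precomputes the class-by-class
Resnik matrix for the classes actually used and assembles BMA values
vectorised; tests verify it against the direct per-pair definition.

## Enrichment

Annotations are propagated to all is_a ancestors (reflexive) plus a
shared top node before testing. Per class, the raw p-value is the
hypergeometric upper tail for the strain/rest split. FWER follows the
random-set procedure: case/control labels are permuted (preserving the
case count), the minimum p over all classes is recorded per
permutation, and a class's FWER is the fraction of permutations whose
minimum p is ≤ its observed p. Classes are ranked by raw p ascending
with ties broken by class ID. Cross-view rank comparison pools
(strain, anatomy, pathology) keys over all strains by default (a
per-strain mode exists); only classes that decompose to an observed
pair in both views are compared, which excludes backbone classes
dragged in by propagation. On default-scale synthetic cohorts the
MAP/PAM rank correlation is high (τ ≈ 0.93); on very small cohorts the
differing interleaving of backbone classes adds rank noise and τ drops,
so rank-comparison tests run at default scale.

## Clustering and evaluation

Similarities convert to distances by global-max subtraction with the
diagonal forced to zero (the conversion formula is a package choice).
Complete linkage and UPGMA use SciPy's agglomerative linkage; neighbor
joining implements the canonical Q-criterion with ties broken by
smaller pair distance then smaller index (needed for determinism on
degenerate, heavily tied matrices), and continues joining past the
3-taxon point so partitions are defined for every cluster count;
k-medoids is PAM with the deterministic greedy BUILD initialisation and
best-improvement SWAP. For the agglomerative methods, clusters at k
replay the first M−k merges; purity is evaluated for every k and
summarised by the trapezoidal AUC normalised by M−1. Modal-strain ties
inside a cluster break lexicographically.

ROC curves rank, per probe mouse, all other mice by descending
similarity with ties broken by ascending mouse ID (an average-rank
alternative is not implemented; the deterministic rule is documented
and tested). Self-similarity is excluded, so the candidate count per
probe is M−1. The trapezoidal AUC of the pooled curve equals the
pooled pair-ordering probability (verified exhaustively in tests). The
Wilcoxon rank-sum comparison between views uses per-mouse one-vs-rest
retrieval AUCs as the sampling unit; comparing the raw pairwise
similarities instead is possible via the same function but conflates
dependent pairs, so per-mouse AUCs are the default reported by the
acceptance script. Bonferroni correction over view pairs is left to
the caller, which reports raw p-values alongside the number of
comparisons.

## Synthetic data

The generator emulates an aging-colony necropsy study: N inbred
strains, a fixed number of mice per strain, zero or more (anatomy leaf,
pathology leaf) diagnoses per mouse, sex and age-group metadata
assigned round-robin. Defaults: 8 strains × 20 mice, Poisson(12)
diagnoses per mouse (matching the roughly twelve diagnoses per animal
of large published necropsy datasets), 10% of mice forced healthy, a
40-pair vocabulary over random toy ontologies of 40 anatomy / 30
pathology classes with depth 4 and part_of density 0.15. Strain
structure enters through symmetric-Dirichlet propensities over the pair
vocabulary (concentration 0.5 by default; as concentration → ∞ strains
become exchangeable and every view's ROC AUC falls to 0.5 — tested).

The *combination-only* mode pairs a fixed set of anatomy leaves with a
fixed set of pathology leaves via a per-strain random permutation, so
every strain has exactly the same anatomy marginal and the same
pathology marginal and differs only in the pairing. Single-axis views
are then uninformative by construction (ROC AUC ≈ 0.5) while the
compound views separate strains — the synthetic analogue of the claim
that compound ontologies open an axis of analysis the source
ontologies cannot express.

What the generator does **not** emulate: real ontology shapes (toy DAGs
are far smaller and more regular than MA/MPATH), age-dependent lesion
incidence, strain attrition, mixed-granularity annotation (diagnoses
use leaf classes only, which in particular makes MAP and MAPT coincide
unless pairs include internal classes), severity modifiers, and
correlated diagnoses within a mouse. Passing tests on synthetic
cohorts therefore demonstrate correctness of the computations and
qualitative behaviour of the patterns, not quantitative predictions
for any real colony.

## Problem sizes and numerics

Tests and the acceptance script run the full pipeline at the default
8 × 20 cohort (160 mice, ≈1,700 diagnoses) and smaller toys; the PAM
purity sweep, which re-runs PAM for every cluster count, is evaluated
on the largest sex/age subgroup (≈27 mice) where the other three
methods sweep the whole cohort. Floating-point comparisons in tests use
absolute tolerances of 1e-12 where an identity is exact and looser,
explicitly stated bands for Monte-Carlo quantities. All stochastic
operations draw from a single seeded NumPy generator per entry point.
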