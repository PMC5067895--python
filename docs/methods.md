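# Methods

This note records the measurement model, the numerical choices and the
boundaries of what the test suite demonstrates.

## Structural model of an ontology version

A version is reduced to a purely structural view (`OntologyGraph`): named
classes, the asserted subClassOf DAG, declared object/data properties, and
per-class counts of annotation assertions, restriction expressions, property
usages, individuals and deprecation flags. The implicit root (`owl:Thing`)
is never a class but is a valid edge endpoint; on construction, every
parentless class is attached to the root so the DAG is connected and path
metrics are defined.

Counting conventions, chosen once and applied uniformly:

- **Property usage** = one occurrence of a property IRI inside a
  class-expression axiom (restrictions under `subClassOf` /
  `equivalentClass`, recursing through boolean combinations and fillers) or
  one property assertion on an individual. Declarations and domain/range
  axioms are not usages. This matches the reading that a usage links a
  property to an entity *through an axiom*, and it makes usage-heavy and
  usage-light corpora clearly distinguishable in `NOMOnto`/`RROnto`.
- **Annotations** = assertions whose predicate is `rdfs:label`,
  `rdfs:comment`, a handful of common annotation IRIs, or any declared
  `owl:AnnotationProperty` — minus deprecation markers, which are modelled
  as flags, not annotations.
- **Deprecation** = `owl:deprecated true`, an oboInOwl-style `is_obsolete`
  marker, or a label starting with `OBSOLETE` (the convention several
  biomedical vocabularies use). The predicate set is a parameter of
  `read_ontology`.
- **Individuals** are attributed to one named class (the lexicographically
  first of their asserted types, for determinism); their property assertions
  are attributed to that class.
- A subclass **cycle among named classes is an error**, not silently broken:
  depth and path metrics are undefined on cyclic graphs, and silently
  breaking an edge would make results depend on traversal order.

Normalisation removes deprecated classes and everything asserted about them;
children whose parents were all removed are re-attached to the root. The
operation is idempotent and the identity on clean graphs. Consistency
checking with a DL reasoner is deliberately out of scope; a pre-filter can
simply exclude files before they reach the pipeline.

Version diffing fingerprints each shared class by its direct parents,
annotation count, restrictions, usages, individuals and deprecation flag.
Logical-axiom edits and annotation-only edits both count as "changed": the
activity measure is meant to capture editorial effort, and annotation
curation is a large fraction of it in practice.

## Metrics

All 14 metrics are ratios or path statistics with guarded denominators;
an undefined value (zero denominator, empty ontology) is an explicit `None`
marker that propagates to an undefined score and is dropped — with a
warning and re-normalised weights — during aggregation. Coercing to 0 would
silently bias lower-is-better metrics toward perfect scores.

- Path lengths are counted in **edges**; the root is a path endpoint.
- "Classes minus subclasses of Thing" in the `CBOnto`/`NOCOnto`/`RFCOnto`
  denominators means classes that are not **direct** children of the root.
- `TMOnto` is the **fraction** of classes with more than one direct parent
  (in [0, 1]). The framework's own materials are ambiguous here (a worked
  example uses a raw value of 1.28, while corpus tables and prose report
  fractions like 0.10–0.26); the fraction reading is adopted because it is
  the only one consistent with the corpus-level values, and static-scale
  inputs below the lowest printed bin clamp to the best score as a
  documented consequence.
- `LCOMOnto` averages over **every distinct leaf-to-root path**: a
  memoised DAG traversal (paths and total length per node) keeps the cost
  polynomial in the path count, with a cap (default 10⁶ paths) beyond which
  a `PathExplosionError` is raised rather than stalling.
- Percent-unit metrics (`ANOnto`, `AROnto`, `INROnto`, `CROnto`, `RROnto`)
  can exceed 100 % on real data (e.g. more than one annotation per class);
  they clamp to the best bin.

## Scaling

The static scale is the fixed threshold table; bins are half-open exactly as
published (boundary values belong to the better bin, so `LCOMOnto` = 2.0
scores 5 and 2.0001 scores 4).

The dynamic scale clusters each metric's observed corpus values into
k = min(5, #distinct) groups and orients them by the metric's direction:
the best cluster scores 5, and with fewer than five clusters the **low**
scores stay empty, so the best observed value always scores 5 and a
constant metric is simply "as good as this corpus gets". Scoring a value
outside every fitted interval clamps to the nearest interval (ties to the
better score); fitted scales serialise to JSON for reuse.

The clustering is an **exact 1-D k-means**: dynamic programming over
contiguous partitions of the sorted values, minimising the within-cluster
sum of squares, O(k·n²) with prefix sums. It is seed-free, deterministic
(ties break toward the smaller split index) and globally optimal, which a
Lloyd iteration from any fixed initialisation cannot guarantee; the package
therefore states its k-means invariant ("equals the exhaustive
variance-minimising partition") as a theorem of the algorithm and tests it
against brute force up to 12 distinct values.

## Aggregation

Subcharacteristic scores are weighted means of metric scores (default
weights equal — no published weighting exists); characteristic scores are
unweighted means of subcharacteristics; the overall score is the mean of the
characteristics (averaging characteristics rather than pooling all
subcharacteristics matches the published worked example; the alternative
would weight characteristics by their subcharacteristic counts). The default
configuration ships the published association subset (Structural,
Functional adequacy, Maintainability, Reliability, Operability); the full
mapping is user-configurable via the same YAML contract.

## Evolution statistics

Definitions follow the published formalisation exactly: change in scale
l = s_i − s_{i−1} componentwise over the metrics defined in both versions;
frequency distribution over levels −4…4; forward/backward mean changes
undefined (not zero) when no level points that way, so tables can print
"-"; magnitude in percent; sizes as the weighted sums (backward in absolute
value); accumulative profile as the running sum of mean changes. Statistics
are always computed against the previous **processed** version, so skipped
(unparseable) releases do not break the chain. Two inconsistencies in the
published running example (one printed change row, and a magnitude sentence
that matches the following version) are resolved in favour of the
definitions.

## Version ranking and activity analysis

For each consecutive pair, the 14 absolute raw-metric differences enter a
one-sided Wilcoxon signed-rank test of median > 0; the reported "critical
value" estimate is the sample median of the absolute differences. The null
distribution is enumerated exactly for n ≤ 20 (zero differences dropped,
mid-ranks for ties, convolution over doubled ranks to stay integral); a
tie-corrected normal approximation covers larger n. scipy's exact method
refuses tied data, so the enumeration is implemented here and cross-checked
against scipy on tie-free samples. An all-zero pair is flagged degenerate
rather than tested.

The activity PCA standardises six variables (classes added / deleted /
changed; backward size, forward size, mean change under the dynamic scale)
and eigendecomposes their correlation matrix — correlation rather than
covariance because the variables have heterogeneous units. Loadings are
variable-factor correlations (eigenvectors scaled by the square root of the
eigenvalues); signs are fixed by making each factor's largest loading
positive, and tests compare magnitudes only, since PCA signs are arbitrary.
Constant variables are excluded with a warning.

## Synthetic data

The generator emulates a small curated biomedical vocabulary. Defaults:
60 classes, depth 6, 10 % multi-parent classes (the tangledness level
reported for a real mid-size corpus), 4 object + 2 data properties, one
annotation per class (label-style curation), 0.3 restrictions, 0.2
individuals and 0.5 property assertions per class, 5 % deprecated classes.
A backbone chain pins the depth exactly; extra classes attach one level up,
and second parents come from strictly shallower levels, so generated graphs
are acyclic by construction and their depth, tangledness and all count
densities are known exactly at construction time. Mutation operators
(add/delete class, deprecate, add restriction/usage, edit annotation) touch
pairwise-distinct classes and deletions pick leaves, so each plan's activity
delta is exact.

What the generator does **not** emulate: realistic lexical content,
imports, punning, property hierarchies, GCIs, reasoned (inferred)
hierarchies, and the heavy-tailed size distributions of real repositories.
Passing tests therefore demonstrate the correctness of the measurement and
statistics machinery on structurally faithful inputs, not the empirical
behaviour of any particular real ontology.

## Problem sizes and determinism

Tests run on graphs of ≤ 60 classes (where exhaustive path enumeration and
brute-force partitioning are feasible oracles) and corpora of ≤ 6 versions;
property tests are derandomised. Everything in the analysis pipeline is
deterministic; randomness exists only in the generator and is fully
seed-driven (same seed ⇒ byte-identical OWL output, via deterministic IRIs
and blank-node labels).

## Known limitations

- Only asserted hierarchies are measured; an ontology whose interesting
  structure lives in inferred subsumptions will look flatter than it is.
- RDF/XML and Turtle are the supported dialects; OBO flat files and imports
  closure are not resolved.
- The OWL writer assumes one property per restriction (true of generated
  graphs); hand-built graphs violating this round-trip only approximately.
- With few version pairs the PCA factors are noisy and rotation-degenerate
  when variable blocks explain similar variance; interpret loadings on
  small corpora qualitatively.
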