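# Methods

## The model

Over-representation analysis treats the query list as an unordered draw of
`k` genes from a fixed background universe of `N` genes. For a term
annotated to `m` background genes, the number `x` of query genes carrying
the term is, under the null of no association, hypergeometric:
`X ~ Hypergeom(N, m, k)`. The reported p-value is the one-sided upper tail
`P(X ≥ x)`; depletion is deliberately not tested. The assumptions worth
keeping in mind:

- **The universe defines the question.** With a user-supplied background
  (third query-file column) the universe is exactly that list: annotated
  genes outside it are discarded from every term set, and background genes
  with no annotation still count toward `N`. Without one, the universe is
  every gene with at least one surviving annotation in the namespace. These
  two conventions give different `N` and therefore different p-values; the
  first matches the common practice of using "all proteins detected in the
  experiment" as reference.
- **Genes are exchangeable under the null.** Correlated annotation blocks
  (paralog families, multi-subunit complexes) violate this in real data and
  make p-values anti-conservative there; nothing in the synthetic studies
  models that.
- **Terms are tested marginally.** The GO DAG induces strong dependence
  between a term and its ancestors, especially with true-path propagation
  enabled; BH is robust to positive dependence but the adjusted values are
  not independent evidence.

## Numerical evaluation of the tail

The tail is summed term-by-term from probability masses evaluated through
log-gamma, accumulated with Neumaier compensated summation and clamped to
[0, 1]; this is accurate to ~1e-14 relative error up to N ≈ 1e6. An exact
rational path (`fractions.Fraction` over binomial coefficients) exists for
moderate N and pins the floating-point path in tests; the test suite
additionally checks the tail against exhaustive subset enumeration for all
N ≤ 12, k ≤ 6. Domain violations (x > min(m, k), m > N, k > N, negatives)
raise an error naming the violated inequality rather than returning a
number.

## Multiple testing

Two corrections are offered:

- **BH step-up FDR (default):** `q_(i) = min_{j≥i} p_(j)·M/j`, capped at 1,
  where `M` is the number of tested terms. Chosen as the default because
  FDR thresholds are the working convention in enrichment practice.
- **Modified Bonferroni:** each p multiplied by the number of terms with
  `x ≥ 1` (not the total number of indexed terms), capped at 1. Counting
  only represented categories follows the convention of category-test tools
  that restrict the family to hypotheses actually instantiated by the study
  set.

Terms with `x = 0` are excluded from the report and from both multipliers:
they cannot be over-represented and reporting them is uninformative. Ties
in p-value are broken lexicographically by term id so output order is
deterministic.

## Annotation handling

Only `is_a` edges are read from OBO — the minimal GO backbone with clean
propagation semantics; `part_of` and other relations are ignored. The
`is_a` graph is verified acyclic at load time. GAF records with a `NOT`
qualifier are negative assertions and never enter an index. Alternate ids
resolve to their canonical term; obsolete terms and unresolvable ids are
dropped with a logged count (parsers never silently drop rows).

True-path propagation (annotating each gene to all ancestors of its direct
terms) is available behind an explicit flag and **defaults to off**: the
index then reflects the association file as distributed, which is the more
transparent default, and propagation strictly enlarges `m` (a tested
invariant) so the two modes bracket the analysis. Evidence-code filtering
(e.g. `{IEA}` vs experimental codes) composes with everything else.
Identifier matching is exact and case-sensitive — isoform suffixes are not
stripped — to avoid silent collisions.

## Networks and plots

The bipartite network has one node per significant term and per member
gene and one edge per (term, member) pair, so the edge count equals Σx and
gene degree counts term memberships (degree ≥ 2 flags multifunctional
genes). Edges serialize as `Source`/`Target` TSV for Cytoscape/Gephi; the
node table adds values, p-values and degrees, and round-trips exactly.

All renderers are deterministic: the force-directed ("random") layout is
seeded, SVG output uses a fixed hash salt and no embedded date, so
identical inputs give identical bytes. Quantitative channels are fixed
transforms of report values — bar length = −log10(p) (with reference lines
at −log10(0.05) and −log10(α)), heatmap color = log10(count + 1). The +1
pseudo-count makes empty cells representable where a plain log10 of the
count is undefined at zero. Bars carry stable SVG ids plus two calibration
lines at x = 0 and x = 1 in data coordinates, so tests parse the emitted
SVG and recover bar lengths in data units to ~1e-7. Hierarchical clustering
of the term×condition matrix uses Euclidean distance on log10(count+1) with
average linkage; rows are pre-sorted lexicographically so the clustered
order is independent of input order. The UpSet renderer plots *exclusive*
intersections (each gene counted once, under its exact membership pattern),
sets ordered by size, intersections by exclusive count with lexicographic
tie-break.

## The synthetic-data generator

Fixtures emulate the shape of real inputs: `N` background genes
(`G000001…`), `n_terms` terms in a layered random `is_a` DAG (each
non-root term gets one parent and, with probability 0.3, a second —
creating the diamond motifs that exercise propagation), term sizes uniform
on a configurable range, GAF lines with a 70/30 electronic/experimental
evidence mix, and a mirrored KEGG mapping (`syn00001…`) with the same
memberships. A planted term overlaps the query in exactly
`round(fraction·k)` genes — planted terms get mutually disjoint gene sets
and the filler query is drawn outside them, so the recorded truth
(x, k, m, N) is exact by construction and the full file→parse→index→test
pipeline must reproduce it bit-for-bit (a tested invariant). Planted query
genes draw values from Normal(2.0, 0.5) against Normal(0, 1) for the rest,
emulating a strong fold-change signal.

What the generator does **not** emulate: realistic GO topology (depth,
fan-out, term-size power law), annotation correlations between related
genes, inconsistent identifier usage, or evidence-code biases. Passing
tests therefore demonstrate statistical and mechanical correctness of the
machinery, not robustness to the pathologies of real annotation corpora.

### Study sizes used in verification

- Planted recovery: N=1000, 40 terms (sizes 10–100), planted m=50, k=100,
  x=30, 200 seeded replicates — the planted term ranks first and passes BH
  at α=0.05 in every replicate (expected: its tail probability is ~1e-19
  while the best null term rarely beats 1e-4).
- Null calibration: N=500, 40 terms (sizes 10–100), k=50, 2000 uniform
  replicates. Because the hypergeometric test is discrete, the null
  rejection probability at nominal 0.05 is not 0.05 but the largest
  achievable tail ≤ 0.05, here ≈0.031 averaged over terms (computed
  exactly from the null distribution). The empirical rate matches that
  exact level within Monte-Carlo error, per term and pooled — the correct
  calibration statement for a discrete test, which is conservative by
  construction at any fixed nominal level.

## Degenerate inputs and edge behavior

Empty query files, empty mappings, all-zero matrices, single-set UpSet
requests, zero-edge networks and zero significant terms at plot time all
raise validation errors with actionable messages (partial CLI outputs are
removed on failure). `x = 0` returns p = 1 without computation. Duplicate
query ids collapse to the first occurrence with a warning. Excel exports
are post-processed to remove embedded wall-clock timestamps so runs are
byte-reproducible.

## Known limitations

- Only `is_a` propagation; GO-slim mapping and cross-namespace relations
  are out of scope.
- One-sided over-representation only; no depletion or ranked-list (GSEA)
  statistics.
- The chord renderer draws one curved stroke per edge rather than filled
  ribbons; legibility is capped at a configurable 30 sectors.
- Orthology-based pathway assignment for unannotated organisms is not
  implemented; supply a precomputed gene→pathway mapping instead.
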