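# oranet

Over-representation analysis (ORA) of gene/protein lists against Gene
Ontology or KEGG pathway annotations, with bipartite-network exports and
publication-style visualizations — entirely from local files, with no
database downloads.

## Who this is for

Researchers with a list of interesting genes or proteins from an OMICs
experiment (differential proteomics, transcriptomics, phospho-enrichment, …)
who want to know which biological processes, molecular functions, cellular
components or pathways are statistically over-represented in that list, and
how the member genes distribute across the enriched terms. Inputs are plain
files: an OBO ontology, a GAF 2.x association file (or a two-column KEGG
gene→pathway mapping), and a 1–3 column tab-separated query file
(identifiers, optional abundance values such as log2 fold-changes, optional
background list).

## The statistic

For a background universe of `N` genes of which `m` are annotated to a term,
and an effective query of `k` genes (query ∩ background) of which `x` carry
the term, the one-sided over-representation p-value is the hypergeometric
upper tail

```
P(X ≥ x) = Σ_{i=x}^{min(m,k)}  C(m,i) · C(N−m, k−i) / C(N,k)
```

evaluated in log space with compensated summation (an exact rational path is
available for moderate `N`). Multiple testing is controlled either by
Benjamini–Hochberg step-up FDR (default) or by a modified Bonferroni
correction whose multiplier counts only the terms actually represented in
the query (x ≥ 1). A term is *significant* when its adjusted p-value is at
most the chosen α.

## Worked example

The built-in generator creates a complete offline study: 1000 background
genes, 40 terms in a layered `is_a` DAG, and a 100-gene query that overlaps
one 50-gene term in exactly 30 genes.

```python
from oranet import SyntheticSpec, generate_fixture, OverRepresentationAnalysis

spec = SyntheticSpec(N=1000, n_terms=40, term_size_range=(10, 100),
                     planted=[(0, 0.30)], planted_size=50, k=100, seed=11)
fx = generate_fixture(spec, "example")
model = OverRepresentationAnalysis.from_files(
    fx.query_path, obo_path=fx.obo_path, gaf_path=fx.gaf_path)
report = model.fit(alpha=0.05, correction="fdr_bh")
print(report.summary())
```

```
Over-representation analysis
========================================================================
namespace:       biological_process
background N:    1000
effective k:     100
terms tested:    37
significant:     1 at alpha=0.05 (fdr_bh)
------------------------------------------------------------------------
   term_id                 name  x   m  p_value  p_adjusted
GO:9000001  synthetic process 1 30  50 1.32e-19    4.89e-18
GO:9000015 synthetic process 15 12  51  0.00295      0.0545
GO:9000006  synthetic process 6 13  77   0.0351       0.433
...
```

The planted term ranks first: 30 of the 100 query genes hit a term that
covers only 50 of the 1000 background genes, where a uniform draw would
expect k·m/N = 5. Its raw p-value (1.32 × 10⁻¹⁹) survives BH adjustment
easily; the runner-up (x=12 of m=51, p=0.003) just misses the 0.05 FDR bar
after correction across the 37 represented terms.

The same analysis from a shell, with network exports and plots:

```sh
oranet example/query.tsv --analysis go \
    --obo example/ontology.obo --gaf example/annotations.gaf \
    --alpha 0.05 --plots circular,chord,upset --out results_run --seed 0
```

which writes `report_biological_process.tsv` / `.xlsx`, a Cytoscape/Gephi
edge list (`Source`/`Target`), a node table carrying values, p-values and
degrees, and the requested SVGs. In every network plot the bar panel shows
−log10(p) per term with the member count at the bar end, a black reference
line at −log10(0.05) and a blue one at −log10(α); gene nodes are colored by
their abundance value on a zero-centered diverging map, so multifunctional
genes (degree ≥ 2) and their regulation direction are visible at a glance.
Cross-condition results can be assembled into a clustered term×condition
heatmap (`build_term_condition_matrix` + `render_heatmap`), colored by
log10(member count + 1).

## Scope notes

Identifier matching is exact and case-sensitive; translating identifiers
between databases (e.g. TAIR → UniProt) is upstream of this tool. Live
downloads of `go.obo`, GOA proteome files or KEGG REST content are out of
scope by design: point the readers at the release snapshot you want, and
record its date with your analysis.
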