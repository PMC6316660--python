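import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oranet import (
    AnnotationRecord,
    AnnotationSet,
    Ontology,
    OntologyTerm,
    SyntheticSpec,
    build_term_index,
    enrich,
    generate_fixture,
    generate_null_replicates,
    hypergeom_upper_tail,
    read_query_file,
)

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


def make_ontology(edges: dict[str, list[str]], namespace: str = "biological_process") -> Ontology:
    """Ontology from a {child: [parents]} adjacency mapping."""
    ids = set(edges) | {p for ps in edges.values() for p in ps}
    terms = {
        tid: OntologyTerm(tid, name=f"term {tid}", namespace=namespace,
                          parent_ids=list(edges.get(tid, [])))
        for tid in ids
    }
    return Ontology(terms=terms)


def make_annotations(pairs: list[tuple[str, str]], aspect: str = "P") -> AnnotationSet:
    return AnnotationSet(records=[AnnotationRecord(g, t, aspect=aspect) for g, t in pairs])


@pytest.fixture(scope="session")
def planted_fixture(tmp_path_factory):
    """A planted-enrichment study: N=1000, term of 50 genes overlapping a
    100-gene query in 30 genes."""
    out = tmp_path_factory.mktemp("planted")
    spec = SyntheticSpec(
        N=1000, n_terms=40, term_size_range=(10, 100), planted=[(0, 0.30)],
        planted_size=50, k=100, seed=11,
    )
    return spec, generate_fixture(spec, out)


@pytest.fixture(scope="session")
def planted_report(planted_fixture):
    spec, fx = planted_fixture
    from oranet import OverRepresentationAnalysis

    model = OverRepresentationAnalysis.from_files(
        fx.query_path, obo_path=fx.obo_path, gaf_path=fx.gaf_path
    )
    return model.fit(alpha=0.05, correction="fdr_bh"), fx, model


@pytest.fixture(scope="session")
def null_simulation(tmp_path_factory):
    """The null (type-I error) harness: a fixed annotation universe of
    N=500 genes and 40 terms, queried by 2000 uniform 50-gene subsets.

    Returns per-term empirical rejection rates at nominal p<=0.05, the exact
    achievable per-term levels of the discrete test, and the pooled
    empirical fraction.
    """
    out = tmp_path_factory.mktemp("null")
    spec = SyntheticSpec(N=500, n_terms=40, term_size_range=(10, 100), k=50, seed=101)
    fx = generate_fixture(spec, out)

    from oranet import read_gaf, read_obo

    ontology = read_obo(fx.obo_path)
    annotations = read_gaf(fx.gaf_path)
    index = build_term_index(
        annotations, ontology, "biological_process",
        background_ids=fx.background_ids,
    )
    genes = fx.background_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    tids = sorted(index.term_to_genes)
    member = np.zeros((len(tids), len(genes)), dtype=bool)
    for ti, tid in enumerate(tids):
        for g in index.term_to_genes[tid]:
            member[ti, gene_pos[g]] = True

    N, k = index.N, spec.k
    # per-term p-value lookup by x, and the exact achievable level <= 0.05
    p_table = []
    alpha_star = []
    for tid in tids:
        m = index.m(tid)
        tails = np.array([hypergeom_upper_tail(x, k, m, N) for x in range(min(m, k) + 1)])
        p_table.append(tails)
        achievable = tails[tails <= 0.05]
        alpha_star.append(achievable.max() if achievable.size else 0.0)

    reps = 2000
    reject = np.zeros((len(tids), reps), dtype=bool)
    for r, ids in enumerate(generate_null_replicates(spec, reps)):
        idx = [gene_pos[g] for g in ids]
        xs = member[:, idx].sum(axis=1)
        for ti in range(len(tids)):
            reject[ti, r] = p_table[ti][xs[ti]] <= 0.05
    return {
        "reps": reps,
        "term_rates": reject.mean(axis=1),
        "alpha_star": np.array(alpha_star),
        "pooled_fraction": reject.mean(),
        "per_replicate_fraction": reject.mean(axis=0),
    }
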