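"""Deterministic synthetic fixtures: toy ontologies, GAF files, KEGG
mappings and query lists with planted enrichment signal.

The generator emulates the shape of real over-representation inputs — a
background universe, terms of varying size arranged in a layered ``is_a``
DAG (with diamond motifs), and a query list that overlaps chosen terms by a
specified fraction — while recording the ground truth (x, k, m, N per
planted term) so tests can compute expected p-values independently.  Gene
and term identifiers live in reserved synthetic ranges (``G…``,
``GO:9…``, ``syn0…``) to avoid collision with real accessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .annotation_io import Ontology, OntologyTerm, write_obo
from .exceptions import ValidationError


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    ``planted`` lists (term index, query-overlap fraction) pairs: the query
    will contain ``round(fraction * k)`` genes of that term.  Query genes on
    planted terms draw their abundance value from
    Normal(planted_value_mean, planted_value_sd); all other query genes from
    Normal(background_value_mean, background_value_sd).
    """

    N: int = 1000
    n_terms: int = 40
    term_size_range: tuple[int, int] = (10, 100)
    planted: list[tuple[int, float]] = field(default_factory=list)
    planted_size: int | None = None
    k: int = 100
    planted_value_mean: float = 2.0
    planted_value_sd: float = 0.5
    background_value_mean: float = 0.0
    background_value_sd: float = 1.0
    dag_depth: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k > self.N:
            raise ValidationError(f"k={self.k} exceeds N={self.N}")
        if min(self.N, self.n_terms, self.k, self.dag_depth) < 1:
            raise ValidationError("all counts must be >= 1")
        lo, hi = self.term_size_range
        if not 1 <= lo <= hi <= self.N:
            raise ValidationError(f"invalid term_size_range {self.term_size_range}")
        for ti, frac in self.planted:
            if not 0 <= ti < self.n_terms:
                raise ValidationError(f"planted term index {ti} out of range")
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"overlap fraction {frac} outside [0, 1]")
        if self.planted_size is not None and not 1 <= self.planted_size <= self.N:
            raise ValidationError(f"planted_size {self.planted_size} outside [1, N]")


@dataclass
class PlantedTruth:
    term_id: str
    x: int
    k: int
    m: int
    N: int


@dataclass
class GeneratedFixture:
    """Paths of the generated files plus the ground-truth record."""

    obo_path: Path
    gaf_path: Path
    kegg_map_path: Path
    kegg_names_path: Path
    query_path: Path
    truth_path: Path
    truth: list[PlantedTruth]
    query_ids: list[str]
    background_ids: list[str]
    term_ids: list[str]


def _term_id(i: int) -> str:
    return f"GO:9{i + 1:06d}"


def _pathway_id(i: int) -> str:
    return f"syn{i + 1:05d}"


def _build_dag(spec: SyntheticSpec, rng: np.random.Generator) -> Ontology:
    # Layered random tree with occasional extra is_a edges creating diamonds.
    terms: dict[str, OntologyTerm] = {}
    layers: list[list[int]] = [[] for _ in range(spec.dag_depth)]
    for i in range(spec.n_terms):
        layers[min(i * spec.dag_depth // spec.n_terms, spec.dag_depth - 1)].append(i)
    for d, layer in enumerate(layers):
        for i in layer:
            parents: list[str] = []
            if d > 0 and layers[d - 1]:
                prev = layers[d - 1]
                first = int(rng.integers(len(prev)))
                parents.append(_term_id(prev[first]))
                if len(prev) > 1 and rng.random() < 0.3:
                    second = int(rng.integers(len(prev)))
                    if second != first:
                        parents.append(_term_id(prev[second]))
            terms[_term_id(i)] = OntologyTerm(
                term_id=_term_id(i),
                name=f"synthetic process {i + 1}",
                namespace="biological_process",
                parent_ids=parents,
            )
    return Ontology(terms=terms)


def generate_fixture(spec: SyntheticSpec, out_dir: str | Path) -> GeneratedFixture:
    """Write a complete offline fixture (OBO, GAF, KEGG mapping, query file,
    truth record) into ``out_dir``.  Byte-identical for identical specs.

    Raises :class:`ValidationError` when a planted overlap is infeasible
    (x > min(m, k)).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    genes = [f"G{i + 1:06d}" for i in range(spec.N)]
    ontology = _build_dag(spec, rng)
    term_ids = [_term_id(i) for i in range(spec.n_terms)]

    lo, hi = spec.term_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_terms)
    term_genes: dict[str, list[str]] = {}
    for i, tid in enumerate(term_ids):
        idx = rng.choice(spec.N, size=int(sizes[i]), replace=False)
        term_genes[tid] = sorted(genes[j] for j in np.sort(idx))

    # Planted terms get mutually disjoint gene sets so every planted overlap
    # is exact by construction.
    planted_idx = [ti for ti, _ in spec.planted]
    if len(set(planted_idx)) != len(planted_idx):
        raise ValidationError("a term index appears twice in `planted`")
    claimed: set[str] = set()
    for ti, _ in spec.planted:
        tid = term_ids[ti]
        size = spec.planted_size if spec.planted_size is not None else int(sizes[ti])
        pool = [g for g in genes if g not in claimed]
        if len(pool) < size:
            raise ValidationError("not enough genes to keep planted terms disjoint")
        idx = rng.choice(len(pool), size=size, replace=False)
        term_genes[tid] = sorted(pool[j] for j in np.sort(idx))
        claimed |= set(term_genes[tid])

    # Query: exact planted overlaps first, uniform filler outside all planted
    # term gene sets.
    truth: list[PlantedTruth] = []
    query: list[str] = []
    for ti, frac in spec.planted:
        tid = term_ids[ti]
        m = len(term_genes[tid])
        x = round(frac * spec.k)
        if x > min(m, spec.k):
            raise ValidationError(
                f"planted overlap infeasible for {tid}: x={x} > min(m={m}, k={spec.k})"
            )
        members = term_genes[tid]
        pick = rng.choice(m, size=x, replace=False)
        query.extend(members[j] for j in np.sort(pick))
        truth.append(PlantedTruth(term_id=tid, x=x, k=spec.k, m=m, N=spec.N))
    planted_members = set(query)
    filler_pool = [g for g in genes if g not in claimed]
    n_filler = spec.k - len(query)
    if n_filler < 0 or n_filler > len(filler_pool):
        raise ValidationError("planted overlaps exceed the query size k")
    idx = rng.choice(len(filler_pool), size=n_filler, replace=False)
    query.extend(filler_pool[j] for j in np.sort(idx))

    values: dict[str, float] = {}
    for gid in query:
        if gid in planted_members:
            values[gid] = float(rng.normal(spec.planted_value_mean, spec.planted_value_sd))
        else:
            values[gid] = float(rng.normal(spec.background_value_mean, spec.background_value_sd))

    # --- files -----------------------------------------------------------
    obo_path = out / "ontology.obo"
    write_obo(ontology, obo_path)

    gaf_path = out / "annotations.gaf"
    evidence_pool = ["IEA", "IEA", "IEA", "EXP", "IDA"]
    with open(gaf_path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for tid in term_ids:
            for gid in term_genes[tid]:
                ev = evidence_pool[int(rng.integers(len(evidence_pool)))]
                cols = [
                    "synDB", gid, gid, "involved_in", tid, "REF:0000000",
                    ev, "", "P", "", "", "protein", "taxon:0000",
                    "20180101", "synDB", "", "",
                ]
                fh.write("\t".join(cols) + "\n")

    kegg_map_path = out / "kegg_mapping.tsv"
    kegg_names_path = out / "kegg_pathway_names.tsv"
    with open(kegg_map_path, "w", encoding="utf-8") as fh:
        for i, tid in enumerate(term_ids):
            for gid in term_genes[tid]:
                fh.write(f"{gid}\t{_pathway_id(i)}\n")
    with open(kegg_names_path, "w", encoding="utf-8") as fh:
        for i in range(spec.n_terms):
            fh.write(f"{_pathway_id(i)}\tsynthetic pathway {i + 1}\n")

    query_path = out / "query.tsv"
    with open(query_path, "w", encoding="utf-8") as fh:
        n_rows = max(len(query), spec.N)
        for i in range(n_rows):
            qid = query[i] if i < len(query) else ""
            val = f"{values[qid]:.6f}" if qid else ""
            bid = genes[i] if i < spec.N else ""
            fh.write(f"{qid}\t{val}\t{bid}\n")

    truth_path = out / "truth.tsv"
    with open(truth_path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tx\tk\tm\tN\n")
        for t in truth:
            fh.write(f"{t.term_id}\t{t.x}\t{t.k}\t{t.m}\t{t.N}\n")

    return GeneratedFixture(
        obo_path=obo_path,
        gaf_path=gaf_path,
        kegg_map_path=kegg_map_path,
        kegg_names_path=kegg_names_path,
        query_path=query_path,
        truth_path=truth_path,
        truth=truth,
        query_ids=query,
        background_ids=genes,
        term_ids=term_ids,
    )


def generate_null_replicates(
    spec: SyntheticSpec, reps: int, out_dir: str | Path | None = None
) -> Iterator[list[str] | Path]:
    """Yield ``reps`` independent null queries: uniform k-subsets of the
    background, seeded reproducibly per replicate index.

    Yields gene-id lists, or file paths when ``out_dir`` is given.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    genes = [f"G{i + 1:06d}" for i in range(spec.N)]
    for rep in range(reps):
        rng = np.random.default_rng([spec.seed, rep])
        idx = rng.choice(spec.N, size=spec.k, replace=False)
        ids = [genes[j] for j in np.sort(idx)]
        if out_dir is None:
            yield ids
        else:
            path = Path(out_dir) / f"null_query_{rep:05d}.tsv"
            with open(path, "w", encoding="utf-8") as fh:
                fh.writelines(f"{gid}\n" for gid in ids)
            yield path
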