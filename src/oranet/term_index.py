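"""Term→gene-set indexing over a fixed background universe.

The index is the bridge between raw annotations and the hypergeometric test:
for one namespace it holds, for every term, the set of background genes
annotated to it.  ``N`` (the universe size) and ``m`` per term (the term's
annotated-gene count) are read straight off this structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .annotation_io import (
    ASPECT_TO_NAMESPACE,
    AnnotationSet,
    Ontology,
    canonical_namespace,
)
from .exceptions import ValidationError

log = logging.getLogger(__name__)


@dataclass
class TermGeneIndex:
    """Per-namespace mapping term → set of annotated background genes.

    Invariants: every gene in any term's set belongs to ``background``;
    ``N >= 1``; no term maps to an empty set; no obsolete term appears.
    """

    namespace: str
    term_to_genes: dict[str, frozenset[str]]
    background: frozenset[str]
    term_names: dict[str, str] = field(default_factory=dict)

    @property
    def N(self) -> int:
        """Background (universe) size."""
        return len(self.background)

    def m(self, term_id: str) -> int:
        """Number of background genes annotated to ``term_id``."""
        return len(self.term_to_genes[term_id])

    def __len__(self) -> int:
        return len(self.term_to_genes)

    def export_tsv(self, path: str | Path) -> None:
        """Audit export: one (term_id, gene_id) pair per line."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term_id\tgene_id\n")
            for tid in sorted(self.term_to_genes):
                for gid in sorted(self.term_to_genes[tid]):
                    fh.write(f"{tid}\t{gid}\n")


def propagate_annotations(
    ontology: Ontology, gene_terms: Mapping[str, Iterable[str]]
) -> dict[str, set[str]]:
    """Apply the true-path rule: extend each gene's term set with every
    ``is_a`` ancestor of its direct terms.

    Term ids are resolved through the ontology's alternate-id table first;
    ids that resolve to nothing (unknown or obsolete) are dropped with a
    logged count.
    """
    dropped = 0
    out: dict[str, set[str]] = {}
    for gene, tids in gene_terms.items():
        closed: set[str] = set()
        for tid in tids:
            canon = ontology.resolve(tid)
            if canon is None:
                dropped += 1
                continue
            closed.add(canon)
            closed |= ontology.ancestors(canon)
        out[gene] = closed
    if dropped:
        log.warning("propagate_annotations: dropped %d unresolvable term id(s)", dropped)
    return out


def build_term_index(
    annotations: AnnotationSet,
    ontology: Ontology,
    namespace: str,
    background_ids: Iterable[str] | None = None,
    propagate: bool = False,
    evidence_filter: set[str] | None = None,
    min_term_size: int = 1,
) -> TermGeneIndex:
    """Build the term→gene index for one namespace over a fixed background.

    Filtering order: negated records are discarded; records are restricted to
    the requested namespace and, when given, to evidence codes in
    ``evidence_filter``; term ids are resolved through alt_ids, dropping
    unresolvable or obsolete ids with a logged count; the true-path closure
    is applied when ``propagate`` is true.

    The universe is the user's ``background_ids`` when supplied — annotated
    genes outside it are excluded from every term set, while background genes
    without any annotation still count toward ``N``.  Without an explicit
    background the universe is every gene with at least one surviving
    annotation in the namespace.  Terms with fewer than ``min_term_size``
    genes are dropped.
    """
    ns = canonical_namespace(namespace)

    gene_terms: dict[str, set[str]] = {}
    unresolved = 0
    for rec in annotations:
        if rec.negated:
            continue
        rec_ns = ASPECT_TO_NAMESPACE.get(rec.aspect, rec.aspect)
        if rec_ns != ns:
            continue
        if evidence_filter is not None and rec.evidence_code not in evidence_filter:
            continue
        canon = ontology.resolve(rec.term_id)
        if canon is None:
            unresolved += 1
            continue
        gene_terms.setdefault(rec.gene_id, set()).add(canon)
    if unresolved:
        log.warning(
            "build_term_index: dropped %d record(s) with unresolvable or obsolete term ids",
            unresolved,
        )

    if propagate:
        gene_terms = propagate_annotations(ontology, gene_terms)

    if background_ids is not None:
        background = frozenset(background_ids)
        if not background:
            raise ValidationError("explicit background list is empty")
    else:
        background = frozenset(gene_terms)

    term_to_genes: dict[str, set[str]] = {}
    for gene, tids in gene_terms.items():
        if gene not in background:
            continue
        for tid in tids:
            term_to_genes.setdefault(tid, set()).add(gene)

    kept = {
        tid: frozenset(genes)
        for tid, genes in term_to_genes.items()
        if len(genes) >= max(1, min_term_size)
    }
    if not kept:
        raise ValidationError(
            f"no term survives filtering (namespace={ns}, min_term_size={min_term_size})"
        )

    names = {tid: ontology.terms[tid].name for tid in kept if tid in ontology.terms}
    return TermGeneIndex(
        namespace=ns, term_to_genes=kept, background=background, term_names=names
    )
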