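"""Readers and writers for the annotation file formats used in over-representation
analysis: OBO ontologies, GAF 2.x gene-association files, two-column KEGG
gene→pathway mappings, and the 1–3 column tab-separated query file.

All parsers are strict about the invariants downstream statistics rely on
(non-empty identifiers, acyclic ``is_a`` graphs, numeric abundance values) and
never silently drop rows: every skipped row is counted and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

from .exceptions import ValidationError

log = logging.getLogger(__name__)

#: Canonical namespace strings.  GO aspects P/F/C map onto the first three;
#: KEGG pathway records use the fourth.
NAMESPACES = ("biological_process", "molecular_function", "cellular_component", "pathway")

ASPECT_TO_NAMESPACE = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
    "pathway": "pathway",
}

NAMESPACE_ALIASES = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
    "biological_process": "biological_process",
    "molecular_function": "molecular_function",
    "cellular_component": "cellular_component",
    "pathway": "pathway",
}


def canonical_namespace(namespace: str) -> str:
    """Map a namespace alias (``"BP"``, ``"P"``, …) to its canonical name."""
    try:
        return NAMESPACE_ALIASES[namespace]
    except KeyError:
        raise ValidationError(
            f"unknown namespace {namespace!r}; expected one of {sorted(set(NAMESPACE_ALIASES))}"
        ) from None


@dataclass
class OntologyTerm:
    """One ontology term: a node of the ``is_a`` DAG.

    Only ``is_a`` parents are recorded; other relationship types
    (``part_of``, ``regulates``, …) are outside the backbone this package
    propagates over.
    """

    term_id: str
    name: str = ""
    namespace: str = ""
    parent_ids: list[str] = field(default_factory=list)
    alt_ids: list[str] = field(default_factory=list)
    is_obsolete: bool = False


@dataclass
class Ontology:
    """A set of terms plus the alternate-id table.

    The ``is_a`` relation restricted to ids present in :attr:`terms` is
    guaranteed acyclic by :func:`read_obo`.
    """

    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    alt_id_map: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def resolve(self, term_id: str) -> str | None:
        """Return the canonical id for ``term_id`` (following alt_ids), or
        ``None`` when the id is unknown or points at an obsolete term."""
        tid = term_id if term_id in self.terms else self.alt_id_map.get(term_id)
        if tid is None or self.terms[tid].is_obsolete:
            return None
        return tid

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All ``is_a`` ancestors of ``term_id`` (excluding itself)."""
        cache = self.__dict__.setdefault("_ancestor_cache", {})
        if term_id in cache:
            return cache[term_id]
        out: set[str] = set()
        stack = [p for p in self.terms[term_id].parent_ids if p in self.terms]
        while stack:
            pid = stack.pop()
            if pid in out:
                continue
            out.add(pid)
            if pid in cache:
                out |= cache[pid]
            else:
                stack.extend(p for p in self.terms[pid].parent_ids if p in self.terms)
        result = frozenset(out)
        cache[term_id] = result
        return result


@dataclass
class AnnotationRecord:
    """A single gene→term association.

    ``negated`` mirrors the GAF ``NOT`` qualifier: the gene is asserted *not*
    to have the term, and such records must never enter a term index.
    """

    gene_id: str
    term_id: str
    aspect: str
    evidence_code: str = ""
    negated: bool = False

    def key(self) -> tuple[str, str, str, bool]:
        return (self.gene_id, self.term_id, self.aspect, self.negated)


@dataclass
class AnnotationSet:
    """An ordered list of annotation records plus parser bookkeeping."""

    records: list[AnnotationRecord] = field(default_factory=list)
    skipped_rows: int = 0

    def __iter__(self) -> Iterator[AnnotationRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def content_keys(self) -> set[tuple[str, str, str, bool]]:
        """Set of (gene, term, aspect, negated) tuples — the round-trip identity."""
        return {r.key() for r in self.records}


@dataclass
class QueryInput:
    """The user's query: ordered unique ids, optional per-gene values, and an
    optional explicit background universe."""

    query_ids: list[str]
    values: dict[str, float] | None = None
    background_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.query_ids:
            raise ValidationError("query list is empty")

    @property
    def ids_outside_background(self) -> set[str]:
        """Query ids absent from the user-supplied background (empty when no
        background was given)."""
        if self.background_ids is None:
            return set()
        return set(self.query_ids) - set(self.background_ids)


# ---------------------------------------------------------------------------
# OBO


def _check_acyclic(terms: Mapping[str, OntologyTerm]) -> None:
    # Kahn's algorithm over is_a edges restricted to resolvable ids.
    indeg = {tid: 0 for tid in terms}
    children: dict[str, list[str]] = {tid: [] for tid in terms}
    for tid, term in terms.items():
        for pid in term.parent_ids:
            if pid in terms:
                indeg[tid] += 1
                children[pid].append(tid)
    queue = [tid for tid, d in indeg.items() if d == 0]
    seen = 0
    while queue:
        nid = queue.pop()
        seen += 1
        for c in children[nid]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if seen != len(terms):
        member = min(tid for tid, d in indeg.items() if d > 0)
        raise ValidationError(f"is_a relation contains a cycle involving {member}")


def read_obo(path: str | Path) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    Only ``[Term]`` stanzas are read; ``is_a`` lines define parents,
    ``alt_id`` lines populate the alternate-id map, and terms marked
    ``is_obsolete: true`` are kept (so alt ids still resolve) but stripped of
    parents and excluded from indexing downstream.

    Raises
    ------
    ValidationError
        If the ``is_a`` graph over resolvable ids contains a cycle.
    OSError
        If the file cannot be read.
    """
    terms: dict[str, OntologyTerm] = {}
    alt_id_map: dict[str, str] = {}
    current: OntologyTerm | None = None
    in_term_stanza = False

    def _flush() -> None:
        nonlocal current
        if current is not None and current.term_id:
            if current.is_obsolete:
                current.parent_ids = []
            terms[current.term_id] = current
            for alt in current.alt_ids:
                alt_id_map[alt] = current.term_id
        current = None

    with open(path, encoding="utf-8", newline=None) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                _flush()
                in_term_stanza = line == "[Term]"
                if in_term_stanza:
                    current = OntologyTerm(term_id="")
                continue
            if not in_term_stanza or current is None or not line or line.startswith("!"):
                continue
            if ":" not in line:
                continue
            tag, _, value = line.partition(":")
            value = value.split("!")[0].strip()
            tag = tag.strip()
            if tag == "id":
                current.term_id = value
            elif tag == "name":
                current.name = value
            elif tag == "namespace":
                current.namespace = value
            elif tag == "is_a":
                current.parent_ids.append(value)
            elif tag == "alt_id":
                current.alt_ids.append(value)
            elif tag == "is_obsolete":
                current.is_obsolete = value.lower() == "true"
    _flush()

    _check_acyclic(terms)
    return Ontology(terms=terms, alt_id_map=alt_id_map)


def write_obo(ontology: Ontology, path: str | Path) -> None:
    """Serialize an :class:`Ontology` back to OBO flat format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for tid in sorted(ontology.terms):
            t = ontology.terms[tid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {t.term_id}\n")
            if t.name:
                fh.write(f"name: {t.name}\n")
            if t.namespace:
                fh.write(f"namespace: {t.namespace}\n")
            for alt in t.alt_ids:
                fh.write(f"alt_id: {alt}\n")
            for pid in t.parent_ids:
                fh.write(f"is_a: {pid}\n")
            if t.is_obsolete:
                fh.write("is_obsolete: true\n")


# ---------------------------------------------------------------------------
# GAF

_GAF_MIN_COLUMNS = 15


def read_gaf(path: str | Path) -> AnnotationSet:
    """Parse a GAF 2.1/2.2 file.

    Columns used (1-based): 2 = object id, 4 = qualifier (``NOT`` → negated),
    5 = term id, 7 = evidence code, 9 = aspect.  Comment lines start with
    ``!``.  Rows with fewer than 15 columns are skipped with a logged count;
    a file with zero usable rows is a validation error.
    """
    records: list[AnnotationRecord] = []
    skipped = 0
    with open(path, encoding="utf-8", newline=None) as fh:
        for raw in fh:
            if raw.startswith("!") or not raw.strip():
                continue
            fields = raw.rstrip("\r\n").split("\t")
            if len(fields) < _GAF_MIN_COLUMNS:
                skipped += 1
                continue
            gene_id, qualifier, term_id = fields[1], fields[3], fields[4]
            evidence, aspect = fields[6], fields[8]
            if not gene_id or not term_id:
                skipped += 1
                continue
            negated = "NOT" in qualifier.split("|")
            records.append(
                AnnotationRecord(
                    gene_id=gene_id,
                    term_id=term_id,
                    aspect=aspect,
                    evidence_code=evidence,
                    negated=negated,
                )
            )
    if skipped:
        log.warning("read_gaf: skipped %d malformed row(s) in %s", skipped, path)
    if not records:
        raise ValidationError(f"GAF file {path} contains no usable annotation rows")
    return AnnotationSet(records=records, skipped_rows=skipped)


def write_gaf(annotations: AnnotationSet, path: str | Path, db: str = "oranet") -> None:
    """Write an :class:`AnnotationSet` as GAF 2.2 lines (17 columns)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for r in annotations:
            qualifier = "NOT|involved_in" if r.negated else "involved_in"
            cols = [
                db, r.gene_id, r.gene_id, qualifier, r.term_id,
                "REF:0000000", r.evidence_code or "IEA", "", r.aspect,
                "", "", "protein", "taxon:0000", "20180101", db, "", "",
            ]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# KEGG mapping


def read_kegg_mapping(
    gene_pathway_path: str | Path, pathway_names_path: str | Path
) -> tuple[AnnotationSet, Ontology]:
    """Read a two-column (gene_id, pathway_id) membership table plus a
    (pathway_id, name) table.

    Returns annotation records with aspect ``"pathway"`` and a flat (parent-
    free) ontology of pathway terms.  A pathway id missing from the names
    table yields a term named after its own id, with a warning.
    """
    names: dict[str, str] = {}
    with open(pathway_names_path, encoding="utf-8", newline=None) as fh:
        for raw in fh:
            fields = raw.rstrip("\r\n").split("\t")
            if len(fields) >= 2 and fields[0]:
                names[fields[0]] = fields[1]

    records: list[AnnotationRecord] = []
    terms: dict[str, OntologyTerm] = {}
    unnamed = 0
    with open(gene_pathway_path, encoding="utf-8", newline=None) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\r\n").split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                continue
            gene_id, pathway_id = fields[0], fields[1]
            records.append(AnnotationRecord(gene_id=gene_id, term_id=pathway_id, aspect="pathway"))
            if pathway_id not in terms:
                name = names.get(pathway_id)
                if name is None:
                    name = pathway_id
                    unnamed += 1
                terms[pathway_id] = OntologyTerm(
                    term_id=pathway_id, name=name, namespace="pathway"
                )
    if unnamed:
        log.warning(
            "read_kegg_mapping: %d pathway id(s) missing from names table; named by id", unnamed
        )
    if not records:
        raise ValidationError(f"KEGG mapping file {gene_pathway_path} is empty")
    return AnnotationSet(records=records), Ontology(terms=terms)


# ---------------------------------------------------------------------------
# Query file


def read_query_file(path: str | Path) -> QueryInput:
    """Read the 1–3 column tab-separated query file.

    Column 1 holds query ids, column 2 optional numeric values (aligned with
    column 1 by row), column 3 an independent-length background id list.
    Duplicate query ids are collapsed to their first occurrence with a
    warning; a non-numeric value is a validation error naming the row.
    """
    query_ids: list[str] = []
    values: dict[str, float] = {}
    background: list[str] = []
    seen_query: set[str] = set()
    seen_background: set[str] = set()
    duplicates = 0
    any_value_column = False

    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            qid = fields[0].strip()
            if qid:
                if qid in seen_query:
                    duplicates += 1
                else:
                    seen_query.add(qid)
                    query_ids.append(qid)
                    if len(fields) >= 2 and fields[1].strip():
                        any_value_column = True
                        token = fields[1].strip()
                        try:
                            values[qid] = float(token)
                        except ValueError:
                            raise ValidationError(
                                f"non-numeric value {token!r} in column 2 at row {lineno}"
                            ) from None
            elif len(fields) >= 2 and fields[1].strip():
                raise ValidationError(
                    f"value without identifier in column 2 at row {lineno}"
                )
            if len(fields) >= 3 and fields[2].strip():
                bid = fields[2].strip()
                if bid not in seen_background:
                    seen_background.add(bid)
                    background.append(bid)

    if duplicates:
        log.warning(
            "read_query_file: collapsed %d duplicate query id(s) in %s (first value kept)",
            duplicates, path,
        )
    if not query_ids:
        raise ValidationError(f"query file {path} has an empty identifier column")
    return QueryInput(
        query_ids=query_ids,
        values=values if any_value_column else None,
        background_ids=background if background else None,
    )


def write_query_file(query: QueryInput, path: str | Path) -> None:
    """Serialize a :class:`QueryInput` back to the tabular query format, such
    that :func:`read_query_file` reproduces it exactly."""
    bg = query.background_ids or []
    n = max(len(query.query_ids), len(bg))
    with open(path, "w", encoding="utf-8") as fh:
        for i in range(n):
            qid = query.query_ids[i] if i < len(query.query_ids) else ""
            val = ""
            if query.values is not None and qid and qid in query.values:
                val = repr(query.values[qid])
            bid = bg[i] if i < len(bg) else ""
            if bg:
                fh.write(f"{qid}\t{val}\t{bid}\n")
            elif query.values is not None:
                fh.write(f"{qid}\t{val}\n")
            else:
                fh.write(f"{qid}\n")
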