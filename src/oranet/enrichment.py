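"""The statistical core: hypergeometric over-representation testing.

Model
-----
For a term annotated to ``m`` of the ``N`` background genes, and a query of
effective size ``k`` (query ∩ background) containing ``x`` genes of the term,
the null hypothesis is that the query is an unordered uniform draw of ``k``
genes from the background.  The one-sided over-representation p-value is the
hypergeometric upper tail

    P(X >= x) = sum_{i=x}^{min(m,k)} C(m,i) C(N-m, k-i) / C(N,k).

Two numerical routes are provided: a log-space evaluation with compensated
summation (the default, safe up to N ~ 1e6) and an exact rational evaluation
for moderate N, used to cross-check the floating-point path.

Multiple testing is handled either by Benjamini–Hochberg step-up FDR (the
default) or by a modified Bonferroni correction whose multiplier is the
number of terms actually represented in the query (x >= 1), not the number
of terms in the index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation_io import QueryInput
from .exceptions import DomainError, ValidationError
from .term_index import TermGeneIndex

CORRECTION_METHODS = ("fdr_bh", "bonferroni")


# ---------------------------------------------------------------------------
# Counts


@dataclass(frozen=True)
class ContingencyCounts:
    """The four counts behind one term's test.

    N: background size; m: background genes annotated to the term;
    k: effective query size (query ∩ background); x: query genes on the term.
    """

    N: int
    m: int
    k: int
    x: int

    def validate(self) -> None:
        if not 0 <= self.m <= self.N:
            raise DomainError(f"required 0 <= m <= N, got m={self.m}, N={self.N}")
        if not 0 <= self.k <= self.N:
            raise DomainError(f"required 0 <= k <= N, got k={self.k}, N={self.N}")
        if not 0 <= self.x <= min(self.m, self.k):
            raise DomainError(
                f"required 0 <= x <= min(m, k), got x={self.x}, m={self.m}, k={self.k}"
            )


# ---------------------------------------------------------------------------
# Hypergeometric upper tail


def _log_binom(n: int, r: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(r + 1) - math.lgamma(n - r + 1)


def hypergeom_upper_tail(x: int, k: int, m: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, m, k), in log space.

    Each probability-mass term is evaluated through log-gamma and the terms
    are added with compensated (Neumaier) summation, so the tail is accurate
    to ~1e-14 relative error even for N up to about 1e6.

    Raises :class:`DomainError` naming the violated inequality when the
    counts are outside the hypergeometric domain.
    """
    ContingencyCounts(N=N, m=m, k=k, x=x).validate()
    if x == 0:
        return 1.0
    hi = min(m, k)
    log_denom = _log_binom(N, k)
    # Neumaier compensated summation of exp(logpmf) terms.
    total = 0.0
    comp = 0.0
    for i in range(x, hi + 1):
        if k - i > N - m:
            continue
        term = math.exp(_log_binom(m, i) + _log_binom(N - m, k - i) - log_denom)
        t = total + term
        if abs(total) >= abs(term):
            comp += (total - t) + term
        else:
            comp += (term - t) + total
        total = t
    return min(1.0, total + comp)


def hypergeom_upper_tail_exact(x: int, k: int, m: int, N: int) -> Fraction:
    """Exact rational P(X >= x); intended for moderate N (say N <= 1000)."""
    ContingencyCounts(N=N, m=m, k=k, x=x).validate()
    if x == 0:
        return Fraction(1)
    hi = min(m, k)
    num = 0
    for i in range(x, hi + 1):
        if k - i > N - m:
            continue
        num += math.comb(m, i) * math.comb(N - m, k - i)
    return Fraction(num, math.comb(N, k))


# ---------------------------------------------------------------------------
# Multiple-testing corrections


def adjust_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order.

    q_(i) = min_{j >= i} ( p_(j) * M / j ), capped at 1, where p_(1) <= ... <=
    p_(M) is the sorted input.  An empty input yields an empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    M = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * M / np.arange(1, M + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(M)
    out[order] = q_sorted
    return out.tolist()


def adjust_bonferroni(p_values: Sequence[float], M_effective: int) -> list[float]:
    """Modified Bonferroni: multiply each p by ``M_effective``, cap at 1.

    ``M_effective`` is the number of terms represented in the query (x >= 1),
    not the total number of indexed terms.
    """
    if M_effective < 1:
        raise DomainError("M_effective must be >= 1")
    return [min(1.0, p * M_effective) for p in p_values]


# ---------------------------------------------------------------------------
# Results


@dataclass
class EnrichmentResult:
    """One term's enrichment outcome."""

    term_id: str
    term_name: str
    counts: ContingencyCounts
    p_value: float
    p_adjusted: float
    correction_method: str
    member_genes: frozenset[str]
    significant: bool


@dataclass
class EnrichmentReport:
    """Results container for one enrichment fit.

    Results are sorted ascending by p-value with lexicographic term-id
    tie-break, so output is deterministic.  ``unmatched_query_ids`` are query
    ids that fell outside the background universe and therefore did not
    contribute to ``k``.
    """

    results: list[EnrichmentResult]
    alpha: float
    namespace: str
    correction: str
    N: int
    k: int
    parameters: dict = field(default_factory=dict)
    unmatched_query_ids: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.results)

    @property
    def significant_results(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.significant]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view, one row per tested term."""
        rows = [
            {
                "term_id": r.term_id,
                "name": r.term_name,
                "namespace": self.namespace,
                "x": r.counts.x,
                "k": r.counts.k,
                "m": r.counts.m,
                "N": r.counts.N,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "method": r.correction_method,
                "member_genes": ";".join(sorted(r.member_genes)),
            }
            for r in self.results
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "term_id", "name", "namespace", "x", "k", "m", "N",
                "p_value", "p_adjusted", "method", "member_genes",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_xlsx(self, path: str | Path, sheet_name: str | None = None) -> None:
        self.to_frame().to_excel(path, sheet_name=sheet_name or self.namespace[:31], index=False)

    def summary(self) -> str:
        """Human-readable summary table in the style of statistical model
        results objects."""
        lines = [
            "Over-representation analysis",
            "=" * 72,
            f"namespace:       {self.namespace}",
            f"background N:    {self.N}",
            f"effective k:     {self.k}",
            f"terms tested:    {len(self.results)}",
            f"significant:     {len(self.significant_results)} at alpha={self.alpha:g} ({self.correction})",
        ]
        if self.unmatched_query_ids:
            lines.append(f"unmatched ids:   {len(self.unmatched_query_ids)} (outside background)")
        lines.append("-" * 72)
        df = self.to_frame()[["term_id", "name", "x", "m", "p_value", "p_adjusted"]]
        with pd.option_context("display.max_rows", 40, "display.width", 120):
            lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# The test proper


def enrich(
    query: QueryInput,
    index: TermGeneIndex,
    alpha: float = 0.05,
    correction: str = "fdr_bh",
) -> EnrichmentReport:
    """Test every represented term (x >= 1) for over-representation.

    ``k`` is the effective query size |query ∩ background|; query ids outside
    the background are reported in ``unmatched_query_ids`` and excluded from
    the test.  ``significant`` is ``p_adjusted <= alpha``.
    """
    if correction not in CORRECTION_METHODS:
        raise ValidationError(f"unknown correction {correction!r}; expected one of {CORRECTION_METHODS}")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")

    qset = set(query.query_ids)
    effective = qset & index.background
    unmatched = frozenset(qset - index.background)
    k = len(effective)
    if k == 0:
        raise ValidationError("no query id found in background")
    N = index.N

    rows: list[tuple[str, ContingencyCounts, float, frozenset[str]]] = []
    for tid in sorted(index.term_to_genes):
        genes = index.term_to_genes[tid]
        members = frozenset(genes & effective)
        x = len(members)
        if x == 0:
            continue
        counts = ContingencyCounts(N=N, m=len(genes), k=k, x=x)
        rows.append((tid, counts, hypergeom_upper_tail(x, k, counts.m, N), members))

    if not rows:
        raise ValidationError("no term is represented in the query (all x = 0)")

    p_raw = [r[2] for r in rows]
    if correction == "fdr_bh":
        p_adj = adjust_bh(p_raw)
    else:
        p_adj = adjust_bonferroni(p_raw, M_effective=len(rows))

    results = [
        EnrichmentResult(
            term_id=tid,
            term_name=index.term_names.get(tid, ""),
            counts=counts,
            p_value=p,
            p_adjusted=q,
            correction_method=correction,
            member_genes=members,
            significant=q <= alpha,
        )
        for (tid, counts, p, members), q in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))

    return EnrichmentReport(
        results=results,
        alpha=alpha,
        namespace=index.namespace,
        correction=correction,
        N=N,
        k=k,
        unmatched_query_ids=unmatched,
    )


# ---------------------------------------------------------------------------
# Model-style front end


class OverRepresentationAnalysis:
    """Model object: a query list analysed against a term index.

    Construct from in-memory objects, or from files via :meth:`from_files`;
    ``fit`` runs the hypergeometric test with the chosen correction and
    returns an :class:`EnrichmentReport`.

    Examples
    --------
    >>> model = OverRepresentationAnalysis(query, index)   # doctest: +SKIP
    >>> report = model.fit(alpha=0.05, correction="fdr_bh")  # doctest: +SKIP
    >>> print(report.summary())                              # doctest: +SKIP
    """

    def __init__(self, query: QueryInput, index: TermGeneIndex):
        self.query = query
        self.index = index

    @classmethod
    def from_files(
        cls,
        query_path: str | Path,
        *,
        obo_path: str | Path | None = None,
        gaf_path: str | Path | None = None,
        kegg_map_path: str | Path | None = None,
        kegg_names_path: str | Path | None = None,
        namespace: str = "biological_process",
        propagate: bool = False,
        evidence_filter: set[str] | None = None,
        min_term_size: int = 1,
    ) -> "OverRepresentationAnalysis":
        """Build the model from a query file plus either (OBO + GAF) or a
        KEGG gene→pathway mapping with its names table."""
        from .annotation_io import read_gaf, read_kegg_mapping, read_obo, read_query_file
        from .term_index import build_term_index

        query = read_query_file(query_path)
        if kegg_map_path is not None:
            if kegg_names_path is None:
                raise ValidationError("KEGG analysis requires both the mapping and names files")
            annotations, ontology = read_kegg_mapping(kegg_map_path, kegg_names_path)
            namespace = "pathway"
        else:
            if obo_path is None or gaf_path is None:
                raise ValidationError("GO analysis requires both an OBO and a GAF file")
            ontology = read_obo(obo_path)
            annotations = read_gaf(gaf_path)
        index = build_term_index(
            annotations,
            ontology,
            namespace=namespace,
            background_ids=query.background_ids,
            propagate=propagate,
            evidence_filter=evidence_filter,
            min_term_size=min_term_size,
        )
        return cls(query, index)

    def fit(self, alpha: float = 0.05, correction: str = "fdr_bh") -> EnrichmentReport:
        report = enrich(self.query, self.index, alpha=alpha, correction=correction)
        report.parameters = {"alpha": alpha, "correction": correction}
        return report
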