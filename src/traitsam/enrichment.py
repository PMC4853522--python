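"""Singular enrichment analysis (SEA) of gene lists against a GO background.

A query list (typically the significant probes for one trait and direction)
is tested term-by-term for over-representation relative to a reference gene
universe using the one-sided hypergeometric (Fisher exact, enrichment
direction) test, followed by Benjamini-Hochberg control within each GO
namespace.  The annotation is taken as already propagated to ancestor terms;
an optional propagation step over a parent-child table is available for
annotations that are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("traitsam")

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: smallest reportable p-value; the exact tail can underflow double precision
#: for extreme overlaps and p is defined to lie in (0, 1]
_P_FLOOR = 5e-324


class EnrichmentError(ValueError):
    """Raised for inconsistent counts or unusable annotation/query inputs."""


@dataclass
class GoAnnotation:
    """Gene -> GO-term annotation with term metadata and a gene universe.

    Parameters
    ----------
    gene_to_terms
        Mapping from gene id to the set of term ids annotated to it.
    term_namespace
        Term id -> namespace; unknown terms default to ``biological_process``.
    term_label
        Term id -> human-readable label (optional, may be sparse).
    universe
        The reference background; every annotated gene must be a member.
    """

    gene_to_terms: dict[str, frozenset[str]]
    term_namespace: dict[str, str] = field(default_factory=dict)
    term_label: dict[str, str] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set(self.gene_to_terms)
        stray = set(self.gene_to_terms) - self.universe
        if stray:
            raise EnrichmentError(
                f"{len(stray)} annotated genes outside the universe "
                f"(e.g. {sorted(stray)[0]!r})"
            )
        for gene, terms in self.gene_to_terms.items():
            if not terms:
                raise EnrichmentError(f"gene {gene!r} has an empty term set")

    def namespace_of(self, term: str) -> str:
        return self.term_namespace.get(term, "biological_process")

    def term_to_genes(self) -> dict[str, set[str]]:
        """Invert the annotation relation."""
        out: dict[str, set[str]] = {}
        for gene, terms in self.gene_to_terms.items():
            for t in terms:
                out.setdefault(t, set()).add(gene)
        return out

    def propagate(self, parents: dict[str, set[str]]) -> "GoAnnotation":
        """Return a copy with annotations propagated to ancestor terms.

        ``parents`` maps each term to its direct parent terms; ancestors are
        accumulated transitively.  Off by default in :func:`run_sea`.
        """
        closure: dict[str, set[str]] = {}

        def ancestors(t: str) -> set[str]:
            if t not in closure:
                acc: set[str] = set()
                for p in parents.get(t, ()):  # cycles are a format error upstream
                    acc.add(p)
                    acc |= ancestors(p)
                closure[t] = acc
            return closure[t]

        g2t = {
            g: frozenset(set(ts) | set().union(*(ancestors(t) for t in ts)))
            for g, ts in self.gene_to_terms.items()
        }
        return GoAnnotation(g2t, dict(self.term_namespace), dict(self.term_label),
                            set(self.universe))


@dataclass
class EnrichmentResult:
    """Hypergeometric test result for a single term.

    ``M`` universe size, ``K`` universe genes carrying the term, ``n`` query
    size within the universe, ``x`` overlap.  ``ratio`` is the enrichment
    ratio (x/n)/(K/M); ``fdr`` is the Benjamini-Hochberg adjusted p within
    the term's namespace.
    """

    term: str
    namespace: str
    label: str
    M: int
    K: int
    n: int
    x: int
    ratio: float
    p: float
    fdr: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.K, self.n)):
            raise EnrichmentError(
                f"term {self.term}: overlap x={self.x} outside [0, min(K,n)]"
            )


def hypergeometric_pvalue(M: int, K: int, n: int, x: int) -> float:
    """Upper-tail P(X >= x) for X ~ Hypergeometric(M, K, n).

    Exact, computed by scipy's survival function (log-gamma based, stable for
    large counts).  Returns a value in (0, 1].
    """
    for name, v in (("M", M), ("K", K), ("n", n), ("x", x)):
        if int(v) != v or v < 0:
            raise EnrichmentError(f"{name}={v} is not a non-negative integer")
    if K > M or n > M:
        raise EnrichmentError(f"inconsistent counts: K={K}, n={n} exceed M={M}")
    if x > min(K, n):
        raise EnrichmentError(f"overlap x={x} exceeds min(K={K}, n={n})")
    if x == 0:
        return 1.0
    p = float(stats.hypergeom.sf(x - 1, M, K, n))
    return min(1.0, max(p, _P_FLOOR))


def run_sea(
    query: list[str],
    annotation: GoAnnotation,
    background: list[str] | None = None,
    alpha_fdr: float = 0.05,
    min_term_size: int = 2,
    method: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Singular enrichment analysis of ``query`` against a reference background.

    One hypergeometric test per term with at least ``min_term_size`` carriers
    in the universe and a non-empty overlap with the query; p-values are
    adjusted per namespace (``fdr_bh`` default, ``fdr_by`` for the
    Benjamini-Yekutieli alternative).  Results are sorted by p-value.
    """
    if not annotation.gene_to_terms:
        raise EnrichmentError("empty annotation")
    universe = set(background) if background is not None else set(annotation.universe)
    if not universe:
        raise EnrichmentError("empty background universe")

    query_unique = list(dict.fromkeys(query))
    in_universe = [g for g in query_unique if g in universe]
    dropped = len(query_unique) - len(in_universe)
    if dropped:
        logger.info("run_sea: dropped %d query genes outside the background", dropped)
    if not in_universe:
        raise EnrichmentError("query is empty after background intersection")

    M = len(universe)
    n = len(in_universe)
    qset = set(in_universe)

    t2g = annotation.term_to_genes()
    rows: list[EnrichmentResult] = []
    for term in sorted(t2g):
        carriers = t2g[term] & universe
        K = len(carriers)
        if K < min_term_size:
            continue
        x = len(carriers & qset)
        if x < 1:
            continue
        p = hypergeometric_pvalue(M, K, n, x)
        ratio = (x / n) / (K / M)
        rows.append(EnrichmentResult(
            term=term,
            namespace=annotation.namespace_of(term),
            label=annotation.term_label.get(term, ""),
            M=M, K=K, n=n, x=x, ratio=ratio, p=p, fdr=1.0, significant=False,
        ))

    if not rows:
        logger.info("run_sea: no testable terms for this query")
        return []

    # BH within each namespace, as the three GO ontologies are disjoint tests
    for ns in {r.namespace for r in rows}:
        group = [r for r in rows if r.namespace == ns]
        _, adj, _, _ = multipletests([r.p for r in group], method=method)
        for r, f in zip(group, adj):
            r.fdr = float(min(1.0, max(f, _P_FLOOR)))
            r.significant = r.fdr <= alpha_fdr

    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def sea_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate :func:`run_sea` output (one row per tested term)."""
    return pd.DataFrame(
        [
            {
                "term": r.term, "namespace": r.namespace, "label": r.label,
                "x": r.x, "n": r.n, "K": r.K, "M": r.M,
                "ratio": r.ratio, "p": r.p, "fdr": r.fdr,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=["term", "namespace", "label", "x", "n", "K", "M",
                 "ratio", "p", "fdr", "significant"],
    )
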