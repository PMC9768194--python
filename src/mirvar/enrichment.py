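"""Over-representation analysis of target gene lists and term diffing.

The statistic is the one-sided hypergeometric upper tail (Fisher exact
enrichment): with a universe of N genes of which K carry a term, the
probability that a query of n genes contains >= k term genes by chance.
Raw p <= alpha (default 0.05) is the primary significance rule;
Benjamini-Hochberg adjusted significance is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import hypergeom

__all__ = [
    "GeneSetAnnotation",
    "EnrichmentResult",
    "TermDiff",
    "hypergeometric_tail",
    "run_ora",
    "diff_terms",
]


class GeneSetAnnotation:
    """term id -> (term name, gene set), plus the gene universe."""

    def __init__(self, terms: Mapping[str, tuple[str, Iterable[str]]],
                 universe: Optional[Iterable[str]] = None):
        cleaned = {}
        genes_seen: set[str] = set()
        for tid, (name, genes) in terms.items():
            gs = frozenset(genes)
            if universe is not None:
                gs = gs & frozenset(universe)
            if gs:
                cleaned[tid] = (name, gs)
                genes_seen |= gs
        self.terms: dict[str, tuple[str, frozenset]] = cleaned
        self.universe: frozenset = frozenset(universe) if universe is not None \
            else frozenset(genes_seen)
        for tid, (_, gs) in self.terms.items():
            if not gs <= self.universe:
                raise ValueError(f"term {tid} has genes outside the universe")

    @classmethod
    def from_tsv(cls, term_gene_path, term_name_path=None,
                 universe: Optional[Iterable[str]] = None) -> "GeneSetAnnotation":
        """Two-column TSV term_id<TAB>gene_id; optional term-name TSV
        term_id<TAB>name."""
        import pandas as pd

        df = pd.read_csv(term_gene_path, sep="\t", header=None,
                         names=["term", "gene"], dtype=str, comment="#")
        names = {}
        if term_name_path is not None:
            ndf = pd.read_csv(term_name_path, sep="\t", header=None,
                              names=["term", "name"], dtype=str, comment="#")
            names = dict(zip(ndf["term"], ndf["name"]))
        terms: dict[str, tuple[str, set]] = {}
        for term, gene in zip(df["term"], df["gene"]):
            terms.setdefault(term, (names.get(term, term), set()))[1].add(gene)
        return cls(terms, universe)

    def __len__(self) -> int:
        return len(self.terms)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric configuration K={K} n={n} N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    k: int           # query genes carrying the term
    K: int           # universe genes carrying the term
    n: int           # in-universe query size
    N: int           # universe size
    p: float
    p_bh: float
    significant: bool      # raw p <= alpha
    significant_bh: bool

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError("inconsistent counts")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p out of (0,1]: {self.p}")


def run_ora(query: Iterable[str], annotation: GeneSetAnnotation,
            alpha: float = 0.05) -> list[EnrichmentResult]:
    """One result per annotated term, sorted by (p, term id)."""
    from statsmodels.stats.multitest import multipletests

    query = frozenset(query)
    in_univ = query & annotation.universe
    if not in_univ:
        raise ValueError(
            f"query empty after universe intersection "
            f"({len(query)} ids discarded)"
        )
    N = len(annotation.universe)
    n = len(in_univ)
    rows = []
    for tid in sorted(annotation.terms):
        name, genes = annotation.terms[tid]
        K = len(genes)
        k = len(in_univ & genes)
        p = hypergeometric_tail(k, K, n, N)
        rows.append((tid, name, k, K, p))
    pvals = [r[4] for r in rows]
    _, p_bh, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    results = [
        EnrichmentResult(tid, name, k, K, n, N, p, float(pb),
                         significant=p <= alpha, significant_bh=pb <= alpha)
        for (tid, name, k, K, p), pb in zip(rows, p_bh)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


@dataclass
class TermDiff:
    gained: frozenset   # significant for alt only
    lost: frozenset     # significant for ref only
    shared: frozenset   # significant for both

    def to_dict(self) -> dict:
        return {
            "gained": sorted(self.gained),
            "lost": sorted(self.lost),
            "shared": sorted(self.shared),
        }


def diff_terms(ref_results: Sequence[EnrichmentResult],
               alt_results: Sequence[EnrichmentResult]) -> TermDiff:
    """Partition significant terms into gained/lost/shared between the
    reference-seed and alternative-seed analyses."""
    ref_terms = {r.term_id for r in ref_results}
    alt_terms = {r.term_id for r in alt_results}
    if ref_terms != alt_terms:
        raise ValueError("result lists come from different annotations")
    ref_sig = {r.term_id for r in ref_results if r.significant}
    alt_sig = {r.term_id for r in alt_results if r.significant}
    return TermDiff(
        gained=frozenset(alt_sig - ref_sig),
        lost=frozenset(ref_sig - alt_sig),
        shared=frozenset(ref_sig & alt_sig),
    )
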