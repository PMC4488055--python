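"""Hypergeometric over-representation analysis with Bonferroni correction.

Supports the dual-reference scheme: the same query gene set can be tested
against the entire annotation universe or against a restricted universe
(e.g. all up-regulated genes), which changes N, K and n and hence every
p-value.  Correction is Bonferroni over the terms actually tested (terms
with at least one universe gene), the only multiplicity scheme used here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

__all__ = ["AnnotationSet", "hypergeom_tail", "enrich",
           "read_annotation", "write_annotation"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationSet:
    """Flat term -> gene-set annotation over a gene universe."""

    terms: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("annotation has no terms")
        stray = set().union(*self.terms.values()) - self.universe
        if stray:
            raise ValueError(
                f"{len(stray)} annotated gene(s) outside the universe, e.g. "
                f"{sorted(stray)[:5]}"
            )

    def restricted_to(self, genes: Iterable[str]) -> "AnnotationSet":
        """The same annotation over a restricted universe (dual-reference)."""
        universe = self.universe & frozenset(genes)
        if not universe:
            raise ValueError("restricted universe is empty")
        terms = {
            term: frozenset(members & universe)
            for term, members in self.terms.items()
        }
        return AnnotationSet(terms=terms, universe=universe)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: term size, n: query size, k: overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: N={N}, K={K}, n={n}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    # survival function at k-1 gives P(X >= k); scipy evaluates stably
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(query: Iterable[str], annotation: AnnotationSet) -> pd.DataFrame:
    """Over-representation of ``query`` in every annotation term.

    Genes outside the universe are dropped (count logged).  One row per term
    with K >= 1 universe genes; the Bonferroni multiplier is the number of
    rows tested.  Sorted ascending by corrected p, ties by term id.
    """
    query = set(query)
    effective = query & annotation.universe
    dropped = len(query) - len(effective)
    if dropped:
        logger.info("%d query gene(s) outside the universe dropped", dropped)
    if not effective:
        raise ValueError("no query gene lies in the annotation universe")

    N = len(annotation.universe)
    n = len(effective)
    rows = []
    for term, members in annotation.terms.items():
        K = len(members)
        if K == 0:
            continue
        k = len(effective & members)
        rows.append((term, k, n, K, N, hypergeom_tail(N, K, n, k)))
    n_tested = len(rows)
    df = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "p_raw"]
    )
    df["p_bonferroni"] = (df["p_raw"] * n_tested).clip(upper=1.0)
    return df.sort_values(
        ["p_bonferroni", "term"], kind="mergesort"
    ).reset_index(drop=True)


def read_annotation(path, universe: Iterable[str] | None = None) -> AnnotationSet:
    """Read a 2-column TSV (term, gene).

    The universe defaults to all annotated genes; pass ``universe`` to widen
    or restrict it explicitly.
    """
    terms: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns (term, gene)"
                )
            terms.setdefault(fields[0], set()).add(fields[1])
    annotated = set().union(*terms.values()) if terms else set()
    full_universe = frozenset(universe) if universe is not None else frozenset(annotated)
    return AnnotationSet(
        terms={t: frozenset(g & full_universe) for t, g in terms.items()},
        universe=full_universe,
    )


def write_annotation(annotation: AnnotationSet, path,
                     header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("#term\tgene\n")
        for term in sorted(annotation.terms):
            for gene in sorted(annotation.terms[term]):
                fh.write(f"{term}\t{gene}\n")
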