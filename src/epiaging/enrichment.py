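"""Hypergeometric gene-set enrichment of shortest-path gene lists.

Query genes are the union of gene symbols annotated to the CpG sites on
the aging->disease shortest paths.  For a gene set of size M in a
background universe of N genes and a query of size n, the enrichment
p-value is the hypergeometric upper tail

    P(X >= k) = 1 - sum_{j < k} C(M, j) C(N-M, n-j) / C(N, n),

evaluated with log-space binomial coefficients; the per-collection
p-values are Benjamini-Hochberg adjusted and called at FDR < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .diffnet import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene-symbol sets over a background universe."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        if self.universe is None:
            uni = set()
            for members in self.sets.values():
                uni.update(members)
            self.universe = sorted(uni)

    def restricted(self, universe) -> "GeneSetCollection":
        uni = sorted(set(universe))
        uset = set(uni)
        return GeneSetCollection(
            sets={name: sorted(set(m) & uset) for name, m in self.sets.items()},
            descriptions=dict(self.descriptions),
            universe=uni,
        )


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning("%s: line %d: %d duplicate genes collapsed", path, lineno, len(genes) - len(unique))
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection | dict, path) -> None:
    """Write sets in GMT format (name, description, tab-separated genes)."""
    sets = collection.sets if isinstance(collection, GeneSetCollection) else collection
    descriptions = (
        collection.descriptions if isinstance(collection, GeneSetCollection) else {}
    )
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def _log_comb(n, k) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(k: int, M: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, M marked, n drawn).

    Computed as a log-space sum over the upper tail (numerically stable;
    equal to 1 - sum_{j<k} of the pmf).
    """
    if not (0 <= k <= min(M, n)):
        raise ValueError(f"k={k} outside [0, min(M={M}, n={n})]")
    if M > N or n > N or min(M, n, N) < 0:
        raise ValueError(f"inconsistent counts k={k}, M={M}, n={n}, N={N}")
    if k == 0:
        return 1.0
    j = np.arange(k, min(M, n) + 1)
    j = j[n - j <= N - M]  # support
    if j.size == 0:
        return 0.0
    log_terms = _log_comb(M, j) + _log_comb(N - M, n - j) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def map_paths_to_genes(
    paths: dict[tuple[str, str], list[str]] | list[list[str]],
    annotation: pd.DataFrame,
) -> list[str]:
    """Union of genes annotated to the CpG sites on the given paths.

    ``annotation`` has columns ``cpg_id`` and ``gene``.  Unannotated path
    nodes are dropped with a warning; the result is deduplicated and sorted.
    """
    lookup: dict[str, set[str]] = {}
    for cpg, gene in zip(annotation["cpg_id"], annotation["gene"]):
        lookup.setdefault(cpg, set()).add(gene)
    seqs = paths.values() if isinstance(paths, dict) else paths
    genes: set[str] = set()
    uncovered = 0
    for path in seqs:
        for node in path:
            if node in lookup:
                genes.update(lookup[node])
            else:
                uncovered += 1
    if uncovered:
        logger.warning("%d path nodes lack a gene annotation", uncovered)
    if not genes:
        logger.warning("empty gene list: enrichment will be skipped")
    return sorted(genes)


@dataclass
class EnrichmentResult:
    """Per-set overlap counts, hypergeometric p and BH q."""

    table: pd.DataFrame  # set, k, M, n, N, p, q, significant, overlap_genes

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def enrich(
    query_genes: list[str],
    collection: GeneSetCollection,
    fdr_threshold: float = 0.05,
) -> EnrichmentResult:
    """Hypergeometric test of the query against every set, BH-adjusted.

    Query genes outside the universe are dropped (logged); results are
    sorted by p ascending with ties broken by set name.
    """
    if not collection.sets:
        raise ValueError("empty gene-set collection")
    universe = set(collection.universe)
    N = len(universe)
    query = sorted(set(query_genes) & universe)
    dropped = len(set(query_genes)) - len(query)
    if dropped:
        logger.info("%d query genes outside the universe dropped", dropped)
    n = len(query)
    qset = set(query)

    rows = []
    for name in sorted(collection.sets):
        members = set(collection.sets[name]) & universe
        M = len(members)
        overlap = sorted(members & qset)
        k = len(overlap)
        p = hypergeom_upper_tail(k, M, n, N) if M and n else 1.0
        rows.append({"set": name, "k": k, "M": M, "n": n, "N": N, "p": p,
                     "overlap_genes": ";".join(overlap)})
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = table["q"] < fdr_threshold
    table = table.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    return EnrichmentResult(table=table)
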