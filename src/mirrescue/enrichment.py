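"""Over-representation and rank-based enrichment on user-supplied sets.

`ora` tests a query gene list against a GMT collection with the exact
hypergeometric upper tail (optionally the EASE variant that scores the
overlap minus one); `gsea_es` computes the weighted Kolmogorov-Smirnov
running-sum enrichment score over a ranked list with a seeded gene-set
permutation p-value; `mirna_group_ora` applies the hypergeometric
machinery to miRNA family/cluster annotations. All collections are
BH-adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets \
                else set()
        if not self.universe:
            raise EnrichmentError("empty universe")
        self.sets = {n: s & self.universe for n, s in self.sets.items()}
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            log.warning("dropping empty gene sets: %s", empty)
            self.sets = {n: s for n, s in self.sets.items() if s}


def ora(query_set, collection: GeneSetCollection,
        ease: bool = False) -> pd.DataFrame:
    """Hypergeometric over-representation per set, BH over the collection.

    With ``ease=True`` the DAVID-style conservative score is used
    (upper tail of overlap - 1 for nonzero overlaps).
    """
    universe = collection.universe
    query = set(query_set)
    outside = query - universe
    if outside:
        log.warning("dropping %d query genes outside the universe",
                    len(outside))
        query &= universe
    M, n = len(universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(query & members)
        k_eff = max(k - 1, 0) if ease and k > 0 else k
        p = float(hypergeom.sf(k_eff - 1, M, K, n))
        rows.append({"set": name, "size": K, "overlap": k, "p": p,
                     "members": ",".join(sorted(query & members))})
    df = pd.DataFrame(rows, columns=["set", "size", "overlap", "p",
                                     "members"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = []
    return df[["set", "size", "overlap", "p", "q", "members"]]


def gsea_es(ranked_genes, scores, gene_set, weight: float = 1.0,
            n_perm: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Weighted KS enrichment score and gene-set-permutation p-value.

    ``ranked_genes`` is the full list ordered by the ranking metric,
    ``scores`` the corresponding metric values. Hits advance the
    running sum by |score|^weight normalized to the set total, misses
    decrease it by 1/(N - Nh); the ES is the maximum deviation from
    zero (signed). The null is size-matched random gene sets drawn from
    the ranked list with a seeded generator.
    """
    genes = list(ranked_genes)
    if len(set(genes)) != len(genes):
        raise EnrichmentError("ranked list contains duplicate genes")
    scores = np.asarray(scores, float)
    if scores.size != len(genes):
        raise EnrichmentError("scores and ranked list differ in length")
    inset = np.array([g in set(gene_set) for g in genes])
    nh = int(inset.sum())
    if nh == 0 or nh == len(genes):
        raise EnrichmentError("gene set must overlap the list strictly")

    def es_for(mask: np.ndarray) -> float:
        w = np.abs(scores) ** weight
        nr = w[mask].sum()
        if nr == 0:
            raise EnrichmentError("zero total weight in set")
        step = np.where(mask, w / nr, -1.0 / (len(genes) - mask.sum()))
        running = np.cumsum(step)
        return float(running[np.argmax(np.abs(running))])

    es = es_for(inset)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = np.zeros(len(genes), dtype=bool)
        perm[rng.choice(len(genes), size=nh, replace=False)] = True
        if abs(es_for(perm)) >= abs(es):
            hits += 1
    p = (1.0 + hits) / (n_perm + 1.0)
    return es, p


def mirna_group_ora(query_mirnas, annotation: pd.DataFrame,
                    categories: tuple[str, ...] = ("family", "cluster")
                    ) -> pd.DataFrame:
    """Hypergeometric enrichment of miRNA families/clusters, BH FDR.

    ``annotation`` maps miRNA -> category labels with columns
    ('mirna', 'family', 'cluster', ...); the universe is every
    annotated miRNA. Query miRNAs absent from the annotation are
    dropped with a warning; an empty query after dropping is an error.
    """
    if "mirna" not in annotation.columns:
        raise EnrichmentError("annotation needs a 'mirna' column")
    universe = set(annotation["mirna"])
    query = set(query_mirnas)
    dropped = query - universe
    if dropped:
        log.warning("dropping %d unannotated query miRNAs", len(dropped))
        query &= universe
    if not query:
        raise EnrichmentError("no query miRNAs remain after dropping")
    M, n = len(universe), len(query)
    rows = []
    for cat in categories:
        if cat not in annotation.columns:
            continue
        for term, sub in annotation.dropna(subset=[cat]).groupby(cat):
            members = set(sub["mirna"])
            k = len(query & members)
            p = float(hypergeom.sf(k - 1, M, len(members), n))
            rows.append({"category": cat, "term": term,
                         "size": len(members), "overlap": k, "p": p,
                         "members": ",".join(sorted(query & members))})
    df = pd.DataFrame(rows, columns=["category", "term", "size", "overlap",
                                     "p", "members"])
    if len(df):
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["fdr"] = []
    return df[["category", "term", "size", "overlap", "p", "fdr",
               "members"]]
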