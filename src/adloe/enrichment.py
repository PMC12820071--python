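"""Hypergeometric over-representation of shared-risk genes.

Shared-risk SNPs are mapped to genes through the positional / eQTL /
chromatin-interaction annotation lists carried on each SNP, and the
resulting gene set is tested against named collections (GMT format)
with one-sided hypergeometric tests and Benjamini-Hochberg adjustment.
A set is reported as significant only when its adjusted p-value is
<= 0.05 AND it overlaps the query in more than one gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "map_shared_snps_to_genes",
    "hypergeom_test",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe.

    By default the universe is the union of all genes in the collection
    (a curated protein-coding universe can be supplied instead).
    """

    sets: dict                      # name -> set of gene symbols
    universe: set | None = None

    def __post_init__(self):
        if not self.sets:
            raise ValueError("empty gene-set collection")
        union = set().union(*self.sets.values())
        if self.universe is None:
            self.universe = union
        else:
            self.universe = set(self.universe)
            stray = union - self.universe
            if stray:
                raise ValueError(f"set genes outside the universe: "
                                 f"{sorted(stray)[:5]}...")
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set: {name!r}")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> gene...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return GeneSetCollection(sets=sets)


def map_shared_snps_to_genes(shared: pd.DataFrame,
                             annotation: pd.DataFrame) -> set:
    """Union of the mapped-gene lists over the shared-risk SNPs.

    Annotation carries per-SNP ``mapped_genes`` as a list or a
    semicolon-joined string; SNPs without annotation are skipped with a
    warning.
    """
    ann = annotation.set_index("snp_id")["mapped_genes"]
    genes: set = set()
    missing = []
    for snp in shared["snp_id"]:
        if snp not in ann.index:
            missing.append(snp)
            continue
        entry = ann.loc[snp]
        if isinstance(entry, str):
            entry = [g for g in entry.split(";") if g]
        genes.update(entry)
    if missing:
        warnings.warn(f"{len(missing)} shared SNPs lack gene annotation; "
                      "skipped")
    return genes


def hypergeom_test(query: set, collection: GeneSetCollection,
                   alpha: float = 0.05) -> pd.DataFrame:
    """One-sided enrichment of ``query`` in every set of the collection.

    p = P(X >= k) for X ~ Hypergeometric(N, K, n) with N the universe
    size, K the set size, n the (in-universe) query size and k the
    overlap.  BH adjustment runs across all sets; the ``significant``
    flag additionally requires k > 1.  Query genes outside the universe
    are dropped and counted in the ``n_dropped`` attribute.
    """
    query = set(query)
    in_universe = query & collection.universe
    n_dropped = len(query) - len(in_universe)
    N = len(collection.universe)
    n = len(in_universe)
    rows = []
    for name, genes in collection.sets.items():
        overlap = sorted(in_universe & genes)
        k, K = len(overlap), len(genes)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"set_name": name, "overlap": k, "set_size": K,
                     "query_size": n, "p_value": min(p, 1.0),
                     "overlapping_genes": ";".join(overlap)})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["significant"] = (table["p_adjusted"] <= alpha) \
        & (table["overlap"] > 1)
    table.attrs["n_dropped"] = n_dropped
    return table.sort_values("p_value", kind="mergesort") \
        .reset_index(drop=True)
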