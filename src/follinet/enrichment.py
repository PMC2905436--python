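"""Gene-set (pathway) enrichment and pathway-overlap statistics.

Gene lists (signatures or modules) are tested against a GMT collection
with the one-sided hypergeometric test (Fisher exact enrichment):
p = P(X >= observed overlap) for X ~ Hypergeom(universe, set, list),
with Benjamini-Hochberg adjustment across the sets of one scan.  A
module x pathway cross-tab of raw overlap counts and a Fisher test on
the overlap of two treatments' affected-pathway name lists complete the
module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_enrich",
    "enrich_all",
    "crosstab_counts",
    "pathway_overlap_test",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are tested against."""

    sets: dict[str, set[str]]
    universe: set[str] | None = None

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        if self.universe is not None:
            for name, members in self.sets.items():
                extra = members - self.universe
                if extra:
                    raise ValueError(
                        f"gene set {name!r} has members outside the universe: "
                        f"{sorted(extra)[:5]}"
                    )

    @property
    def all_set_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <TAB> description <TAB> member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need name, "
                    f"description and at least one gene; got {len(fields)} fields)"
                )
            name, _desc, *genes = fields
            members = {g for g in genes if g}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t-\t{genes}\n")


def hypergeom_enrich(
    gene_list: set[str], gene_set: set[str], universe: set[str]
) -> dict:
    """One-sided hypergeometric enrichment of a list-set overlap.

    p = P(X >= k) for X ~ Hypergeom(M=|universe|, n=|set|, N=|list|)
    where k is the observed overlap.
    """
    offenders = (gene_list | gene_set) - universe
    if offenders:
        raise ValueError(
            f"genes outside the universe: {sorted(offenders)[:10]}"
        )
    M, n, N = len(universe), len(gene_set), len(gene_list)
    k = len(gene_list & gene_set)
    p = float(stats.hypergeom.sf(k - 1, M, n, N))
    return {
        "overlap": k,
        "list_size": N,
        "set_size": n,
        "universe_size": M,
        "p_value": min(p, 1.0),
    }


def enrich_all(
    gene_list: set[str],
    collection: GeneSetCollection,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric scan of a gene list over every set in the collection.

    The universe defaults to the collection's pinned universe, else the
    union of all set members and the list.  q-values are BH-adjusted
    across the tested sets; rows come back sorted by p.
    """
    if not gene_list:
        raise ValueError("gene list is empty")
    if universe is None:
        universe = collection.universe or (collection.all_set_genes | set(gene_list))
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        if not members:
            continue
        row = hypergeom_enrich(gene_list & universe, members, universe)
        row["set"] = name
        rows.append(row)
    table = pd.DataFrame(rows)
    _, q, _, _ = multipletests(table["p_value"].to_numpy(), method="fdr_bh")
    table["q_value"] = q
    cols = ["set", "overlap", "list_size", "set_size", "universe_size", "p_value", "q_value"]
    return table[cols].sort_values(["p_value", "set"]).reset_index(drop=True)


def crosstab_counts(
    lists: dict[str, set[str]], collection: GeneSetCollection
) -> pd.DataFrame:
    """Pathway x list table of raw overlap counts, plus a union total column."""
    union: set[str] = set()
    for genes in lists.values():
        union |= genes
    data = {}
    for name in lists:
        data[name] = [len(lists[name] & collection.sets[s]) for s in sorted(collection.sets)]
    data["total"] = [len(union & collection.sets[s]) for s in sorted(collection.sets)]
    return pd.DataFrame(data, index=sorted(collection.sets))


def pathway_overlap_test(
    pathways_a: set[str], pathways_b: set[str], pathway_universe: int
) -> float:
    """Fisher/hypergeometric test on the overlap of two pathway name lists.

    Upper-tail p for the observed number of shared pathway names given
    the two list sizes and the total number of pathways eligible.
    """
    if pathway_universe < len(pathways_a | pathways_b):
        raise ValueError(
            f"pathway universe ({pathway_universe}) smaller than the union "
            f"of the two lists ({len(pathways_a | pathways_b)})"
        )
    k = len(pathways_a & pathways_b)
    p = float(stats.hypergeom.sf(k - 1, pathway_universe, len(pathways_a), len(pathways_b)))
    return min(p, 1.0)
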