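"""Intramodular connectivity (k.in) and hub-gene selection.

k.in of a gene is the sum of its adjacency weights to all other genes in
its own module; the most intramodularly connected genes ("hubs") are
selected per module as a top fraction of the module (default 10%, with
per-module overrides such as 20% for a module whose strongest hubs lack
annotation).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .modules import GREY, ModuleAssignment

__all__ = ["intramodular_connectivity", "select_hubs"]


def intramodular_connectivity(
    adj: pd.DataFrame, assignment: ModuleAssignment
) -> pd.DataFrame:
    """Per-gene hub table: module, total connectivity, k.in, within-module rank.

    Grey (unassigned) genes keep k_in = 0 and rank 0.  Ranks are dense
    within each module, 1 = highest k_in, ties broken by gene ID.
    """
    genes = list(adj.index)
    missing = [g for g in genes if g not in assignment.label_of]
    if missing:
        raise KeyError(f"gene {missing[0]!r} missing from the module assignment")
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k_total = a.sum(axis=1)
    colors = np.array([assignment.label_of[g] for g in genes])
    k_in = np.zeros(len(genes))
    for color in set(colors):
        if color == GREY:
            continue
        idx = np.flatnonzero(colors == color)
        k_in[idx] = a[np.ix_(idx, idx)].sum(axis=1)
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "module": colors,
            "k_total": k_total,
            "k_in": k_in,
        }
    )
    table["rank"] = 0
    for color in set(colors):
        if color == GREY:
            continue
        sub = table[table["module"] == color]
        order = sub.sort_values(["k_in", "gene_id"], ascending=[False, True])
        table.loc[order.index, "rank"] = np.arange(1, len(order) + 1)
    table["selected"] = False
    table = table.set_index("gene_id", drop=False)
    table.index.name = None
    return table


def select_hubs(
    table: pd.DataFrame,
    fraction_default: float = 0.10,
    fraction_overrides: dict[str, float] | None = None,
    modules_of_interest: list[str] | None = None,
    annotated: dict[str, bool] | None = None,
    annotated_only: bool = False,
) -> pd.DataFrame:
    """Flag the top fraction of each module of interest by k.in.

    Selects ceil(fraction x module size) genes per module (rank order,
    ties by gene ID).  With ``annotated_only`` the selection is drawn
    from annotated genes only, still counting the quota against the full
    module size.  Grey genes are never selected.
    """
    overrides = fraction_overrides or {}
    out = table.copy()
    out["selected"] = False
    if annotated is not None:
        out["annotated"] = [bool(annotated.get(g, False)) for g in out["gene_id"]]
    known = set(out["module"]) - {GREY}
    targets = sorted(known) if modules_of_interest is None else list(modules_of_interest)
    for color in targets:
        if color not in known:
            raise KeyError(f"unknown module colour {color!r}")
        frac = overrides.get(color, fraction_default)
        if not 0 < frac <= 1:
            raise ValueError(f"selection fraction for {color!r} must lie in (0, 1]")
        sub = out[out["module"] == color]
        n_pick = math.ceil(frac * len(sub))
        pool = sub
        if annotated_only and "annotated" in out.columns:
            pool = sub[sub["annotated"]]
        picked = pool.sort_values(["k_in", "gene_id"], ascending=[False, True]).head(n_pick)
        out.loc[picked.index, "selected"] = True
    return out
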