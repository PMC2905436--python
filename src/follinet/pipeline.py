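"""End-to-end pipeline: DE filter -> network -> modules -> hubs -> enrichment.

`run_pipeline` executes the whole analysis from a single
`PipelineConfig` and writes every artifact (signatures, network edge
list, module assignment, hub table, enrichment tables, run report) to
the output directory.  All randomness flows from the single configured
seed, so identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de, enrichment, hubs, io, network
from .modules import GREY, dendrogram_to_newick, detect_modules

logger = logging.getLogger("follinet")

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    expression: str = ""
    design: str = ""
    gmt: str | None = None
    out_dir: str = "follinet_out"
    # DE criteria
    fc_up: float = 1.2
    fc_down: float = 0.83
    p_max: float = 0.05
    min_abs_diff: float = 10.0
    equal_var: bool = False
    log2_input: bool = False
    control_label: str = "control"
    residualize_before_de: bool = False
    batch_cols: list[str] = field(default_factory=lambda: ["batch"])
    # network
    beta: int | str = "auto"
    beta_grid: list[int] = field(default_factory=lambda: list(range(1, 21)))
    r2_threshold: float = 0.75
    n_bins: int = 10
    edge_min_weight: float = 0.1
    # modules
    min_module_size: int = 20
    deep_split: int = 2
    cut_height_fraction: float = 0.99
    # hubs
    hub_fraction: float = 0.10
    hub_fraction_overrides: dict = field(default_factory=dict)
    modules_of_interest: list[str] | None = None
    # misc
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


def _stage(name):
    logger.info("stage: %s", name)
    return time.time()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the run report dictionary."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": []}

    t0 = _stage("read inputs")
    expr = io.read_expression(config.expression)
    design = io.read_design(config.design)
    criteria = de.SignatureCriteria(
        fc_up=config.fc_up, fc_down=config.fc_down, p_max=config.p_max,
        min_abs_diff=config.min_abs_diff, log2_input=config.log2_input,
    )

    de_input = expr
    if config.residualize_before_de:
        de_input = de.residualize_batches(expr, design, config.batch_cols)

    _stage("signatures")
    treatments = sorted(set(design["treatment"]) - {config.control_label})
    signatures = []
    for trt in treatments:
        sig = de.compute_signature(
            de_input, design, trt, criteria,
            control_label=config.control_label, equal_var=config.equal_var,
        )
        io.write_tsv(sig.records, out / f"signature_{trt}.tsv")
        signatures.append(sig)
    union = sorted(de.union_signatures(signatures))
    report["signature_sizes"] = {s.treatment: s.size for s in signatures}
    report["union_size"] = len(union)
    if len(signatures) >= 2:
        overlaps = de.signature_overlap_counts(signatures)
        io.write_tsv(overlaps, out / "signature_overlaps.tsv", index=True)

    _stage("residualize batches")
    batch_ok = all(c in design.columns for c in config.batch_cols)
    net_input = expr.loc[union]
    if batch_ok and any(design[c].nunique() > 1 for c in config.batch_cols if c in design):
        net_input = de.residualize_batches(net_input, design, config.batch_cols)

    _stage("network")
    cor = network.correlation_matrix(net_input)
    if config.beta == "auto":
        beta, fits, warned = network.pick_beta(
            cor, beta_grid=config.beta_grid, r2_threshold=config.r2_threshold,
            n_bins=config.n_bins, is_correlation=True,
        )
        report["beta_fit_table"] = {
            str(b): {"slope": f.slope, "r2_plain": f.r2_plain,
                     "r2_truncated": f.r2_truncated}
            for b, f in fits.items()
        }
        report["beta_warning"] = warned
    else:
        beta = int(config.beta)
    report["beta"] = beta
    adj = network.adjacency(cor, beta)
    tom_m = network.tom(adj)

    _stage("modules")
    assignment, Z = detect_modules(
        tom_m, min_size=config.min_module_size, deep_split=config.deep_split,
        cut_height_fraction=config.cut_height_fraction,
    )
    module_table = pd.DataFrame(
        {
            "gene_id": list(tom_m.index),
            "module_color": [assignment.label_of[g] for g in tom_m.index],
        }
    )
    module_table["module_size"] = [
        assignment.module_sizes.get(c, 0) for c in module_table["module_color"]
    ]
    io.write_tsv(module_table, out / "modules.tsv")
    (out / "dendrogram.nwk").write_text(dendrogram_to_newick(Z, list(tom_m.index)))
    report["module_sizes"] = dict(assignment.module_sizes)
    report["grey_count"] = assignment.grey_count
    report["n_modules"] = assignment.n_modules

    _stage("edges")
    _write_edges(adj, tom_m, out / "edges.tsv", config.edge_min_weight)

    _stage("hubs")
    hub_table = hubs.intramodular_connectivity(adj, assignment)
    hub_table = hubs.select_hubs(
        hub_table, fraction_default=config.hub_fraction,
        fraction_overrides=config.hub_fraction_overrides or None,
        modules_of_interest=config.modules_of_interest,
    )
    io.write_tsv(hub_table.reset_index(drop=True), out / "hubs.tsv")
    report["hub_genes"] = sorted(hub_table.loc[hub_table["selected"], "gene_id"])

    if config.gmt:
        _stage("enrichment")
        collection = enrichment.read_gmt(config.gmt)
        universe = set(expr.index)
        lists: dict[str, set[str]] = {s.treatment: s.genes for s in signatures}
        for color in assignment.module_sizes:
            lists[color] = {
                g for g, c in assignment.label_of.items() if c == color
            }
        crosstab = enrichment.crosstab_counts(lists, collection)
        io.write_tsv(crosstab, out / "pathway_crosstab.tsv", index=True)
        enriched_paths: dict[str, set[str]] = {}
        for name, genes in sorted(lists.items()):
            if not genes:
                continue
            table = enrichment.enrich_all(genes, collection, universe=universe)
            io.write_tsv(table, out / f"enrichment_{name}.tsv")
            enriched_paths[name] = set(
                table.loc[table["overlap"] > 0, "set"]
            )
        # pairwise pathway-overlap Fisher tests between treatment signatures
        n_paths = len(collection.sets)
        overlap_rows = []
        trts = [s.treatment for s in signatures if s.treatment in enriched_paths]
        for i, a in enumerate(trts):
            for b in trts[i + 1:]:
                p = enrichment.pathway_overlap_test(
                    enriched_paths[a], enriched_paths[b], n_paths
                )
                overlap_rows.append(
                    {"a": a, "b": b,
                     "overlap": len(enriched_paths[a] & enriched_paths[b]),
                     "n_a": len(enriched_paths[a]), "n_b": len(enriched_paths[b]),
                     "universe": n_paths, "p_value": p}
                )
        if overlap_rows:
            io.write_tsv(pd.DataFrame(overlap_rows), out / "pathway_overlap_tests.tsv")
            report["pathway_overlap_tests"] = len(overlap_rows)

    report["files"] = sorted(p.name for p in out.iterdir())
    io.write_report(report, out / "report.json")
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return report


def _write_edges(adj: pd.DataFrame, tom_m: pd.DataFrame, path, min_weight: float) -> None:
    a = adj.to_numpy()
    t = tom_m.to_numpy()
    genes = list(adj.index)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = a[iu, ju] >= min_weight
    df = pd.DataFrame(
        {
            "gene_a": [genes[i] for i in iu[keep]],
            "gene_b": [genes[j] for j in ju[keep]],
            "adjacency": a[iu, ju][keep],
            "tom": t[iu, ju][keep],
        }
    )
    io.write_tsv(df, path)


def write_report(report: dict, path) -> None:
    io.write_report(report, path)
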