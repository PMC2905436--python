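"""Synthetic expression matrices with planted co-expression modules.

The generator emulates a growth-factor perturbation microarray study:
a handful of treatments with 2-3 replicates each plus a pool of control
samples, genes organised into correlated modules driven by per-module
latent factors, treatment-specific differential expression with small
fold changes, additive batch offsets, and Gaussian intensity noise on a
linear (RMA-like) scale.

Every draw is governed by a single seed so downstream stages can be
tested against the returned ground truth without any external data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Treatment",
    "SimulationConfig",
    "GroundTruth",
    "study_config",
    "generate_design",
    "generate_expression",
    "write_ground_truth",
    "read_ground_truth",
]

#: intensities are clipped at this floor to stay strictly positive
INTENSITY_FLOOR = 1e-3


class ConfigurationError(ValueError):
    """A simulation config violates one of its invariants."""


@dataclass(frozen=True)
class Treatment:
    """One perturbation arm: name, replicate count, planted DE effect."""

    name: str
    n_replicates: int = 3
    affected_gene_count: int = 0
    effect_multiplier: float = 1.5


@dataclass
class SimulationConfig:
    """Parameters of the planted-structure expression simulator.

    ``sum(module_sizes) + background_genes`` must equal ``n_genes``;
    ``module_cohesion`` is the target within-module Pearson correlation.
    """

    n_genes: int = 2000
    module_sizes: Sequence[int] = field(default_factory=lambda: [100, 80, 60, 40, 20])
    background_genes: int = 1700
    treatments: Sequence[Treatment] = field(
        default_factory=lambda: [Treatment("TRT", 3, 50, 1.5)]
    )
    n_controls: int = 3
    batch_labels: Sequence[str] | None = None
    baseline_mean: float = 100.0
    noise_sd: float = 10.0
    batch_sd: float = 5.0
    module_cohesion: float = 0.8
    de_mode: str = "module"  # "module": responsive genes drawn module-wise; "random": anywhere
    de_direction: str = "up"  # "up" or "both" (random per-gene up/down regulation)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if any(m < 1 for m in self.module_sizes):
            raise ConfigurationError("every module size must be >= 1")
        if self.background_genes < 0:
            raise ConfigurationError("background_genes must be >= 0")
        if sum(self.module_sizes) + self.background_genes != self.n_genes:
            raise ConfigurationError(
                "sum(module_sizes) + background_genes != n_genes "
                f"({sum(self.module_sizes)} + {self.background_genes} != {self.n_genes})"
            )
        if not self.treatments:
            raise ConfigurationError("at least one treatment is required")
        for t in self.treatments:
            if t.n_replicates < 1:
                raise ConfigurationError(f"treatment {t.name}: n_replicates must be >= 1")
            if t.effect_multiplier <= 0:
                raise ConfigurationError(f"treatment {t.name}: effect_multiplier must be > 0")
            if not 0 <= t.affected_gene_count <= self.n_genes:
                raise ConfigurationError(f"treatment {t.name}: affected_gene_count out of range")
        if self.n_controls < 1:
            raise ConfigurationError("n_controls must be >= 1")
        if not 0.0 <= self.module_cohesion <= 1.0:
            raise ConfigurationError("module_cohesion must lie in [0, 1]")
        if self.noise_sd < 0 or self.batch_sd < 0:
            raise ConfigurationError("noise_sd and batch_sd must be >= 0")
        if self.de_mode not in ("module", "random"):
            raise ConfigurationError("de_mode must be 'module' or 'random'")
        if self.de_direction not in ("up", "both"):
            raise ConfigurationError("de_direction must be 'up' or 'both'")
        n_samples = self.n_controls + sum(t.n_replicates for t in self.treatments)
        if self.batch_labels is not None and len(self.batch_labels) != n_samples:
            raise ConfigurationError(
                f"batch_labels has {len(self.batch_labels)} entries for {n_samples} samples"
            )

    @property
    def n_samples(self) -> int:
        return self.n_controls + sum(t.n_replicates for t in self.treatments)


@dataclass
class GroundTruth:
    """Planted structure: module labels, DE genes per treatment, hub ranks.

    ``module_of`` maps every gene ID to a planted module index or ``None``
    (background); ``hub_rank`` is the within-module loading rank (0 = the
    most strongly loaded gene, the planted hub).
    """

    module_of: dict[str, int | None]
    de_genes: dict[str, set[str]]
    hub_rank: dict[str, int | None]


def study_config(seed: int = 0, n_genes: int = 2000) -> SimulationConfig:
    """A desk-scale config mirroring the study's shape.

    Eight growth-factor arms with three replicates each (GDNF with two)
    plus 15 controls give 38 samples; 16 modules with sizes drawn between
    20 and 194; roughly 10% of genes differentially expressed per strong
    treatment with a modest (x1.5) effect.
    """
    rng = np.random.default_rng(seed)
    sizes = [int(s) for s in rng.integers(20, 195, size=16)]
    cap = int(0.85 * n_genes)  # leave a background pool of unassigned genes
    if sum(sizes) > cap:
        scale = cap / sum(sizes)
        sizes = [max(20, int(round(s * scale))) for s in sizes]
    while sum(sizes) > cap and len(sizes) > 1:
        sizes.pop()  # desk scales below ~400 genes carry fewer modules
    names = ["AMH", "FGF2", "BMP4", "GDNF", "FGF7", "KITLG", "LIF", "PDGF"]
    n_de = max(1, n_genes // 10)
    treatments = [
        Treatment(n, 2 if n == "GDNF" else 3, n_de, 1.5) for n in names
    ]
    return SimulationConfig(
        n_genes=n_genes,
        module_sizes=sizes,
        background_genes=n_genes - sum(sizes),
        treatments=treatments,
        n_controls=15,
        baseline_mean=100.0,
        noise_sd=10.0,
        batch_sd=5.0,
        module_cohesion=0.8,
        de_mode="module",
        de_direction="both",
        seed=seed,
    )


def _default_batches(n_samples: int, rng: np.random.Generator) -> list[str]:
    # three nuisance batches standing in for culture / RNA / array dates
    return [f"batch{(i % 3) + 1}" for i in range(n_samples)]


def generate_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample design table: one row per array.

    Columns: ``sample_id``, ``treatment`` ("control" or a treatment
    name), ``batch``, ``replicate``.  Controls come first, then each
    treatment arm in config order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for r in range(config.n_controls):
        rows.append(("control", r))
    for t in config.treatments:
        for r in range(t.n_replicates):
            rows.append((t.name, r))
    batches = (
        list(config.batch_labels)
        if config.batch_labels is not None
        else _default_batches(len(rows), rng)
    )
    return pd.DataFrame(
        {
            "sample_id": [f"s{i:03d}_{trt}_{r}" for i, (trt, r) in enumerate(rows)],
            "treatment": [trt for trt, _ in rows],
            "batch": batches,
            "replicate": [r for _, r in rows],
        }
    )


def generate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a genes x samples intensity matrix with planted structure.

    Gene g in module b follows

        x_gs = baseline_g + noise_sd * (sqrt(c_g) f_bs + sqrt(1-c_g) e_gs)
               + batch_s + de_gs

    with f_bs a per-module per-sample latent factor, c_g a gene-level
    cohesion (c_g = 1 - (1-c) v_g, v_g ~ U(1, 1.5), so cohesion 1 gives
    exactly unit within-module correlation), e and the background noise
    standard normal, batch_s an additive per-batch offset, and de_gs =
    baseline_g (m-1) in treated samples of an affected gene (a
    multiplicative shift of the treated-group mean, matching fold-change
    criteria on the linear scale).  Intensities are clipped at a small
    positive floor.

    Returns ``(expression, design, truth)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = generate_design(config)
    n_g, n_s = config.n_genes, config.n_samples
    genes = [f"g{i:05d}" for i in range(n_g)]

    baseline = config.baseline_mean * np.exp(rng.normal(0.0, 0.3, size=n_g))

    # planted module memberships: modules fill the front of the gene list
    module_of: dict[str, int | None] = {g: None for g in genes}
    hub_rank: dict[str, int | None] = {g: None for g in genes}
    start = 0
    module_members: list[np.ndarray] = []
    for b, size in enumerate(config.module_sizes):
        idx = np.arange(start, start + size)
        module_members.append(idx)
        for g in idx:
            module_of[genes[g]] = b
        start += size

    c = config.module_cohesion
    # the latent amplitude matches noise_sd so within-module correlation is
    # governed by c alone; with noise_sd = 0 a unit amplitude keeps the
    # shared factor alive (correlation exactly 1 at full cohesion)
    amp = config.noise_sd if config.noise_sd > 0 else 1.0
    signal = config.noise_sd * rng.normal(0.0, 1.0, size=(n_g, n_s))
    for b, idx in enumerate(module_members):
        f = rng.normal(0.0, 1.0, size=n_s)  # shared latent factor
        if c == 1.0:
            c_g = np.ones(idx.size)
        else:
            # loading spread: hubs sit near the nominal cohesion, peripheral
            # genes well below it, so planted hub ranks are recoverable
            v = rng.uniform(1.0, 3.0, size=idx.size)
            c_g = np.clip(1.0 - (1.0 - c) * v, 0.0, 1.0)
        signal[idx] = amp * (
            np.sqrt(c_g)[:, None] * f
        ) + np.sqrt(1.0 - c_g)[:, None] * signal[idx]
        order = np.argsort(-c_g, kind="stable")
        for rank, j in enumerate(order):
            hub_rank[genes[idx[j]]] = rank

    x = baseline[:, None] + signal

    # additive batch offsets shared by all genes on a batch's arrays
    levels = sorted(set(design["batch"]))
    offsets = {lv: rng.normal(0.0, config.batch_sd) for lv in levels}
    x += np.array([offsets[b] for b in design["batch"]])[None, :]

    # treatment effects: multiplicative shift of the treated-group mean.
    # In "module" mode each planted module responds to one treatment
    # (round-robin), so co-response reinforces the planted correlation the
    # way shared regulation does in a real perturbation panel; the quota
    # (affected_gene_count) is drawn from the responsive modules first and
    # spills over into the remaining genes.
    de_genes: dict[str, set[str]] = {}
    treated_cols = {
        t.name: np.flatnonzero(design["treatment"].to_numpy() == t.name)
        for t in config.treatments
    }
    n_trt = len(config.treatments)
    n_mod = len(module_members)
    # coherent response direction per (module, treatment): a module is a
    # co-regulated unit, so its members move the same way under a treatment
    module_sign = {
        (j, i): bool(rng.choice([True, False]))
        for j in range(n_mod) for i in range(n_trt)
    }
    module_of_idx = np.full(n_g, -1, dtype=int)
    for j, idx in enumerate(module_members):
        module_of_idx[idx] = j
    for i, t in enumerate(config.treatments):
        if config.de_mode == "module" and n_mod:
            pool = np.concatenate(
                [idx for j, idx in enumerate(module_members) if j % n_trt == i]
                or [np.array([], int)]
            )
            if pool.size >= t.affected_gene_count:
                affected = rng.choice(pool, size=t.affected_gene_count, replace=False)
            else:
                others = np.setdiff1d(np.arange(n_g), pool)
                extra = rng.choice(
                    others, size=t.affected_gene_count - pool.size, replace=False
                )
                affected = np.concatenate([pool, extra])
        else:
            affected = rng.choice(n_g, size=t.affected_gene_count, replace=False)
        de_genes[t.name] = {genes[i] for i in affected}
        if t.effect_multiplier != 1.0 and affected.size:
            m = t.effect_multiplier
            if config.de_direction == "both":
                is_up = np.array(
                    [
                        module_sign[(module_of_idx[g], i)]
                        if module_of_idx[g] >= 0
                        else bool(rng.choice([True, False]))
                        for g in affected
                    ]
                )
            else:
                is_up = np.ones(affected.size, dtype=bool)
            shift = np.where(
                is_up,
                baseline[affected] * (m - 1.0),
                baseline[affected] * (1.0 / m - 1.0),
            )
            x[np.ix_(affected, treated_cols[t.name])] += shift[:, None]

    x = np.maximum(x, INTENSITY_FLOOR)
    expr = pd.DataFrame(x, index=pd.Index(genes, name="gene_id"),
                        columns=design["sample_id"].tolist())
    return expr, design, GroundTruth(module_of, de_genes, hub_rank)


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "module_of": truth.module_of,
        "de_genes": {k: sorted(v) for k, v in truth.de_genes.items()},
        "hub_rank": truth.hub_rank,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        module_of=payload["module_of"],
        de_genes={k: set(v) for k, v in payload["de_genes"].items()},
        hub_rank=payload["hub_rank"],
    )


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["module_sizes"] = list(d["module_sizes"])
    d["treatments"] = [dataclasses.asdict(t) if not isinstance(t, dict) else t
                       for t in config.treatments]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["treatments"] = [Treatment(**t) for t in d.get("treatments", [])]
    return SimulationConfig(**d)
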