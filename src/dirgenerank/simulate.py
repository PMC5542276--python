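"""Seeded synthetic cohorts with planted modulator -> dependent structure.

The generator emulates the statistical situation the pipeline is built for:
a handful of driver genes modulate blocks of dependent genes whose
association with prognosis is *conditional* — a dependent gene tracks a
prognostic latent factor only in the samples where its driver is highly
expressed, so its marginal information about the phenotype is diluted while
its driver-conditioned information is strong.

Structure, for driver k with latent factor z_k (both standard normal across
samples):

* dependent gene g of driver k:  x_g = s * 1[driver_k high] * z_k + noise,
  with s = ``interaction_strength`` and "high" meaning above the driver's
  median;
* log relative hazard: eta = hazard_beta * sum_k driver_k
  + interaction_strength * sum_k z_k — drivers carry ``hazard_beta`` per
  standard deviation, and each latent factor carries
  ``interaction_strength``, which therefore sets how strongly a dependent
  gene is tied to the phenotype inside its driver-high stratum;
* survival: exponential with rate baseline_hazard * exp(eta); a fraction
  ``censor_rate`` of patients is censored uniformly before their death time;
* PPI scaffold: the true driver-dependent pairs plus random decoy pairs.

All other genes are independent standard normals.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import ClinicalTable, ExpressionMatrix, PPIEdgeList

__all__ = ["SimConfig", "SimTruth", "generate_cohort", "generate_null_cohort", "write_cohort"]

#: default baseline hazard (per day): median survival of a baseline patient
#: equals the 1200-day phenotype cutoff, so labels are roughly balanced
DEFAULT_BASELINE_HAZARD = math.log(2) / 1200.0


@dataclass
class SimConfig:
    n_samples: int = 400
    n_genes: int = 300
    n_drivers: int = 3
    dependents_per_driver: int = 8
    interaction_strength: float = 1.5
    hazard_beta: float = 0.8
    baseline_hazard: float = DEFAULT_BASELINE_HAZARD
    censor_rate: float = 0.2
    decoy_ppi_edges: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drivers * (1 + self.dependents_per_driver) > self.n_genes:
            raise ValueError("drivers and dependents exceed n_genes")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.n_samples < 2 or self.baseline_hazard <= 0:
            raise ValueError("infeasible config")


@dataclass
class SimTruth:
    drivers: list[str]
    dependents: dict[str, list[str]]  # driver -> its dependent genes
    true_edges: list[tuple[str, str]] = field(default_factory=list)  # driver -> dependent

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _survival(rng, eta: np.ndarray, baseline_hazard: float, censor_rate: float):
    t_death = rng.exponential(1.0 / (baseline_hazard * np.exp(eta)))
    censored = rng.random(eta.size) < censor_rate
    u = rng.random(eta.size)
    days = np.where(censored, u * t_death, t_death)
    return days, ~censored


def generate_cohort(cfg: SimConfig):
    """Simulate one cohort; returns (expression, clinical, ppi, truth)."""
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    samples = [f"S{i:04d}" for i in range(1, cfg.n_samples + 1)]

    values = rng.standard_normal((cfg.n_genes, cfg.n_samples))
    drivers = genes[: cfg.n_drivers]
    dependents: dict[str, list[str]] = {}
    eta = np.zeros(cfg.n_samples)
    next_row = cfg.n_drivers
    for k, drv in enumerate(drivers):
        drv_expr = values[k]
        high = drv_expr > np.median(drv_expr)
        z = rng.standard_normal(cfg.n_samples)
        deps = genes[next_row : next_row + cfg.dependents_per_driver]
        for row in range(next_row, next_row + cfg.dependents_per_driver):
            noise = rng.standard_normal(cfg.n_samples)
            values[row] = cfg.interaction_strength * high * z + noise
        next_row += cfg.dependents_per_driver
        dependents[drv] = deps
        eta += cfg.hazard_beta * drv_expr + cfg.interaction_strength * z

    days, dead = _survival(rng, eta, cfg.baseline_hazard, cfg.censor_rate)

    true_edges = [(drv, dep) for drv, deps in dependents.items() for dep in deps]
    truth_pairs = {tuple(sorted(e)) for e in true_edges}
    max_decoys = cfg.n_genes * (cfg.n_genes - 1) // 2 - len(truth_pairs)
    if cfg.decoy_ppi_edges > max_decoys:
        raise ValueError("decoy_ppi_edges exceeds the number of available gene pairs")
    decoys: set = set()
    while len(decoys) < cfg.decoy_ppi_edges:
        i, j = rng.integers(0, cfg.n_genes, size=2)
        if i == j:
            continue
        pair = tuple(sorted((genes[i], genes[j])))
        if pair in truth_pairs or pair in decoys:
            continue
        decoys.add(pair)
    pairs = sorted(truth_pairs) + sorted(decoys)

    expr = ExpressionMatrix(genes, samples, values)
    clin = ClinicalTable(list(samples), days, dead)
    ppi = PPIEdgeList(pairs)
    truth = SimTruth(drivers, dependents, true_edges)
    return expr, clin, ppi, truth


def generate_null_cohort(
    n_samples: int,
    n_genes: int,
    seed: int = 0,
    n_ppi_edges: int | None = None,
    baseline_hazard: float = DEFAULT_BASELINE_HAZARD,
    censor_rate: float = 0.2,
):
    """Cohort with no structure: expression, survival and PPI all independent."""
    if n_samples < 2 or n_genes < 2:
        raise ValueError("need at least 2 samples and 2 genes")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    samples = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    values = rng.standard_normal((n_genes, n_samples))
    days, dead = _survival(rng, np.zeros(n_samples), baseline_hazard, censor_rate)
    if n_ppi_edges is None:
        n_ppi_edges = n_genes
    n_ppi_edges = min(n_ppi_edges, n_genes * (n_genes - 1) // 2)
    pairs: set = set()
    while len(pairs) < n_ppi_edges:
        i, j = rng.integers(0, n_genes, size=2)
        if i != j:
            pairs.add(tuple(sorted((genes[i], genes[j]))))
    return (
        ExpressionMatrix(genes, samples, values),
        ClinicalTable(list(samples), days, dead),
        PPIEdgeList(sorted(pairs)),
    )


def write_cohort(outdir, expr: ExpressionMatrix, clin: ClinicalTable,
                 ppi: PPIEdgeList, truth: SimTruth | None = None) -> None:
    """Write a cohort in the TSV formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr.to_frame().rename_axis("gene_id").to_csv(outdir / "expression.tsv", sep="\t")
    clin.to_frame().rename_axis("sample_id").to_csv(outdir / "clinical.tsv", sep="\t")
    with open(outdir / "ppi.tsv", "w") as fh:
        for a, b in ppi.pairs:
            fh.write(f"{a}\t{b}\n")
    if truth is not None:
        truth.to_json(outdir / "truth.json")
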