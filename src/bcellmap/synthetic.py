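"""Synthetic paired proteome/transcriptome studies with planted structure.

The generator emulates the study design the pipeline targets: five
maturation-ordered B-cell populations (naive, CB, CC, memory, PC) with
five LFQ proteomics replicates each, and a paired four-population
(no-PC) transcriptome with six replicates.  Planted features:

* **population-specific proteins** — detected in exactly one population,
  zero elsewhere (the "exclusive proteome" of each subset);
* **differential proteins** — a log2-scale mean shift in one population
  (or in a planted pair of populations, to mimic the germinal-center
  CB~CC / naive~memory similarity structure);
* **intensity-dependent dropout** — low-abundance values are more likely
  to be reported as 0 (missing-not-at-random detection limits);
* **reduced PC depth** — the plasma-cell proteome is thinned to a
  fraction of the other populations' detected proteomes, mirroring the
  much lower protein yield of sorted PC samples.

Every draw flows from one root seed, so identical parameters give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_io import (
    CHROMOSOMES,
    ExpressionMatrix,
    IdMap,
    IntensityMatrix,
    SampleDesign,
    write_expression_matrix,
    write_id_map,
    write_long_intensities,
)

__all__ = [
    "SimulationParams",
    "TruthManifest",
    "simulate_paired_study",
    "inject_dropout",
    "write_study",
    "default_proteome_design",
    "default_transcriptome_design",
]

LN2 = float(np.log(2.0))

#: Maturation-ordered populations; PC is proteome-only.
PROTEOME_POPULATIONS = ("naive", "CB", "CC", "memory", "PC")
TRANSCRIPTOME_POPULATIONS = ("naive", "CB", "CC", "memory")


def default_proteome_design() -> SampleDesign:
    return SampleDesign(PROTEOME_POPULATIONS, {p: 5 for p in PROTEOME_POPULATIONS})


def default_transcriptome_design() -> SampleDesign:
    return SampleDesign(TRANSCRIPTOME_POPULATIONS, {p: 6 for p in TRANSCRIPTOME_POPULATIONS})


@dataclass
class SimulationParams:
    """Knobs of the paired-omics generator.

    Abundances are log-normal: each protein draws a natural-log baseline
    mean from ``Normal(baseline_log_mean, baseline_log_sd)``; replicate
    values scatter around it with ``replicate_log_sd``.  Differential
    proteins add ``effect_size_log2 * ln 2`` to the up-population's log
    mean.  Dropout zeroes a nonzero value with probability
    ``logistic(slope * (ln midpoint - ln value))``.  The default
    population-specific fractions follow the magnitudes of the exclusive
    proteomes of the five subsets (from ~0.4% for naive up to ~6% for
    PC); ``up_population_weights`` defaults to the observed skew of
    maximal expression toward germinal-center cells.
    """

    design_proteome: SampleDesign = field(default_factory=default_proteome_design)
    design_transcriptome: SampleDesign = field(default_factory=default_transcriptome_design)
    n_proteins: int = 400
    fraction_population_specific: Mapping[str, float] = field(
        default_factory=lambda: {"naive": 0.004, "CB": 0.01, "CC": 0.02, "memory": 0.02, "PC": 0.06}
    )
    fraction_differential: float = 0.25
    effect_size_log2: float = 2.0
    effect_mode: str = "single"  # "single" or "paired" (CB~CC / naive~memory)
    up_population_weights: Mapping[str, float] = field(
        default_factory=lambda: {"naive": 0.03, "CB": 0.48, "CC": 0.36, "memory": 0.13}
    )
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 1.2
    replicate_log_sd: float = 0.35
    apply_dropout: bool = True
    dropout_midpoint: float = 150.0
    dropout_slope: float = 1.0
    pc_depth_factor: float = 0.15
    transcript_base_mean: float = 7.0
    transcript_base_sd: float = 1.5
    transcript_replicate_sd: float = 0.4
    protein_transcript_correlation: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        fracs = dict(self.fraction_population_specific)
        unknown = set(fracs) - set(self.design_proteome.populations)
        if unknown:
            raise ValueError(f"fractions for unknown populations: {sorted(unknown)}")
        if any(not (0 <= f <= 1) for f in fracs.values()) or not (0 <= self.fraction_differential <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if sum(fracs.values()) + self.fraction_differential > 1.0 + 1e-12:
            raise ValueError("planted fractions sum to more than 1")
        if self.effect_size_log2 < 0:
            raise ValueError("effect_size_log2 must be >= 0")
        if not (0 < self.pc_depth_factor <= 1):
            raise ValueError("pc_depth_factor must be in (0, 1]")
        if self.effect_mode not in {"single", "paired"}:
            raise ValueError("effect_mode must be 'single' or 'paired'")
        if self.apply_dropout and self.dropout_midpoint <= 0:
            raise ValueError("dropout_midpoint must be > 0")
        if not (-1 <= self.protein_transcript_correlation <= 1):
            raise ValueError("correlation must be in [-1, 1]")


@dataclass
class TruthManifest:
    """Ground truth of one simulated study.

    ``population_specific[pid]`` is the planted population or ``None``;
    ``differential[pid]`` flags a planted mean shift whose up
    population(s) and log2 size are in ``up_population`` /
    ``true_log2_effect``.  ``gene_of`` links each protein to its
    transcript.
    """

    population_specific: dict[str, str | None]
    differential: dict[str, bool]
    up_population: dict[str, list[str]]
    true_log2_effect: dict[str, float]
    gene_of: dict[str, str]
    protein_transcript_correlation: float
    dropout: dict
    seed: int

    def differential_ids(self) -> list[str]:
        return [p for p, d in self.differential.items() if d]

    def specific_ids(self, population: str) -> list[str]:
        return sorted(p for p, s in self.population_specific.items() if s == population)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def inject_dropout(
    matrix: IntensityMatrix, midpoint: float, slope: float, seed: int
) -> IntensityMatrix:
    """Zero nonzero entries with intensity-dependent probability.

    Each nonzero value ``v`` is independently set to 0 with probability
    ``logistic(slope * (ln midpoint - ln v))``: values far below the
    detection midpoint are almost surely lost, values far above almost
    surely kept.  Zeros stay zero.
    """
    if midpoint <= 0:
        raise ValueError("midpoint must be > 0")
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    nz = values > 0
    p_drop = expit(slope * (np.log(midpoint) - np.log(values, where=nz, out=np.zeros_like(values))))
    drop = nz & (rng.random(values.shape) < p_drop)
    values[drop] = 0.0
    return matrix.replace(values=values)


def simulate_paired_study(
    params: SimulationParams,
) -> tuple[IntensityMatrix, ExpressionMatrix, IdMap, TruthManifest]:
    """Generate a paired proteome + transcriptome study with known truth."""
    rng = np.random.default_rng(params.seed)
    n = params.n_proteins
    design_p = params.design_proteome
    design_t = params.design_transcriptome
    pops_p = design_p.populations
    pops_t = design_t.populations

    protein_ids = [f"P{i:05d}" for i in range(n)]
    gene_ids = [f"G{i:05d}" for i in range(n)]

    # --- planted memberships --------------------------------------------
    order = rng.permutation(n)
    cursor = 0
    specific_of: dict[str, str | None] = {p: None for p in protein_ids}
    for pop in pops_p:
        k = int(round(params.fraction_population_specific.get(pop, 0.0) * n))
        for idx in order[cursor : cursor + k]:
            specific_of[protein_ids[idx]] = pop
        cursor += k
    n_diff = int(round(params.fraction_differential * n))
    diff_idx = order[cursor : cursor + n_diff]
    differential = {p: False for p in protein_ids}
    up_population: dict[str, list[str]] = {p: [] for p in protein_ids}
    effect: dict[str, float] = {p: 0.0 for p in protein_ids}

    up_pops = [p for p in pops_t if p in pops_p]
    weights = np.array([params.up_population_weights.get(p, 0.0) for p in up_pops], dtype=float)
    if weights.sum() <= 0:
        weights = np.ones(len(up_pops))
    weights = weights / weights.sum()
    for idx in diff_idx:
        pid = protein_ids[idx]
        differential[pid] = True
        effect[pid] = params.effect_size_log2
        if params.effect_mode == "paired":
            pair = ("CB", "CC") if rng.random() < 0.5 else ("naive", "memory")
            up_population[pid] = [p for p in pair if p in pops_p]
        else:
            up_population[pid] = [str(rng.choice(up_pops, p=weights))]

    # --- protein intensities --------------------------------------------
    base_mu = rng.normal(params.baseline_log_mean, params.baseline_log_sd, size=n)
    log_mu = np.tile(base_mu[:, None], (1, len(pops_p)))  # protein x population
    pop_col = {p: j for j, p in enumerate(pops_p)}
    for i, pid in enumerate(protein_ids):
        for up in up_population[pid]:
            log_mu[i, pop_col[up]] += effect[pid] * LN2

    values = np.zeros((n, design_p.n_samples))
    for j, pop in enumerate(pops_p):
        cols = design_p.columns_for(pop)
        reps = design_p.replicates[pop]
        noise = rng.normal(0.0, params.replicate_log_sd, size=(n, reps))
        values[:, cols] = np.exp(log_mu[:, [j]] + noise)

    # population-specific proteins are absent everywhere else
    for i, pid in enumerate(protein_ids):
        home = specific_of[pid]
        if home is not None:
            for pop in pops_p:
                if pop != home:
                    values[i, design_p.columns_for(pop)] = 0.0

    # PC depth thinning: whole-protein loss from the PC proteome, sparing
    # planted PC-specific proteins so exclusive sets stay recoverable.
    if "PC" in pops_p and params.pc_depth_factor < 1.0:
        keep = rng.random(n) < params.pc_depth_factor
        for i, pid in enumerate(protein_ids):
            if specific_of[pid] == "PC":
                continue
            if not keep[i]:
                values[i, design_p.columns_for("PC")] = 0.0

    proteome = IntensityMatrix(protein_ids=protein_ids, design=design_p, values=values)
    if params.apply_dropout:
        proteome = inject_dropout(
            proteome,
            params.dropout_midpoint,
            params.dropout_slope,
            seed=int(rng.integers(2**31 - 1)),
        )

    # --- paired transcriptome -------------------------------------------
    rho = params.protein_transcript_correlation
    z_protein = (base_mu - params.baseline_log_mean) / params.baseline_log_sd
    eps = rng.normal(size=n)
    t_base = params.transcript_base_mean + params.transcript_base_sd * (
        rho * z_protein + np.sqrt(max(0.0, 1 - rho**2)) * eps
    )
    t_mu = np.tile(t_base[:, None], (1, len(pops_t)))
    tcol = {p: j for j, p in enumerate(pops_t)}
    for i, pid in enumerate(protein_ids):
        for up in up_population[pid]:
            if up in tcol:
                t_mu[i, tcol[up]] += effect[pid]  # already log2 units
    t_values = np.zeros((n, design_t.n_samples))
    for j, pop in enumerate(pops_t):
        cols = design_t.columns_for(pop)
        reps = design_t.replicates[pop]
        t_values[:, cols] = t_mu[:, [j]] + rng.normal(
            0.0, params.transcript_replicate_sd, size=(n, reps)
        )
    transcriptome = ExpressionMatrix(gene_ids=gene_ids, design=design_t, values=t_values)

    # --- ID map -----------------------------------------------------------
    chroms = rng.choice(np.array(CHROMOSOMES), size=n)
    pe = rng.choice(np.array(["PE1", "PE2", "PE5"]), size=n, p=[0.988, 0.002, 0.010])
    idmap = IdMap(
        records=pd.DataFrame(
            {"protein_id": protein_ids, "gene_id": gene_ids, "chromosome": chroms, "pe_class": pe}
        )
    )

    manifest = TruthManifest(
        population_specific=specific_of,
        differential=differential,
        up_population=up_population,
        true_log2_effect=effect,
        gene_of=dict(zip(protein_ids, gene_ids)),
        protein_transcript_correlation=rho,
        dropout={
            "applied": params.apply_dropout,
            "midpoint": params.dropout_midpoint,
            "slope": params.dropout_slope,
            "pc_depth_factor": params.pc_depth_factor,
        },
        seed=params.seed,
    )
    return proteome, transcriptome, idmap, manifest


def write_study(
    out_dir: str | Path,
    proteome: IntensityMatrix,
    transcriptome: ExpressionMatrix,
    idmap: IdMap,
    manifest: TruthManifest,
) -> dict[str, Path]:
    """Write the four study files plus the ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": out / "intensities.tsv",
        "expression": out / "expression.tsv",
        "id_map": out / "id_map.tsv",
        "truth_manifest": out / "truth_manifest.json",
    }
    write_long_intensities(proteome, paths["intensities"])
    write_expression_matrix(transcriptome, paths["expression"])
    write_id_map(idmap, paths["id_map"])
    manifest.to_json(paths["truth_manifest"])
    return paths
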