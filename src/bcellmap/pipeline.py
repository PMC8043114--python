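"""End-to-end orchestration: config, stage sequencing, logging, manifest.

Stages run in a fixed order — synthetic/ingest, qualitative,
quantitative, transcriptome, integration, enrichment — each writing its
TSV/JSON artifacts into the output directory.  All randomness flows
from one root seed split per stage, so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core_io import (
    GeneSetCollection,
    IdMap,
    IntensityMatrix,
    ScreenParams,
    read_expression_matrix,
    read_gene_sets,
    read_id_map,
    read_long_intensities,
    subset_populations,
    write_gene_sets,
)
from .enrichment import ora_test
from .integration import (
    export_tracks,
    full_replicate_means,
    match_ids,
    pt_ratios,
    ratio_clusters,
    ratio_population_dendrogram,
)
from .qualitative import (
    binary_cluster,
    consensus_presence,
    exclusive_proteins,
    membership_summary,
)
from .quantitative import (
    chromosome_profiles,
    differential_screen,
    drop_all_absent,
    extremal_summary,
    hierarchical_heatmap_order,
    passes_filters,
    pca_scores,
    propagate_zeros,
    som_clusters,
)
from .synthetic import SimulationParams, simulate_paired_study, write_study
from .transcriptome import cross_omics_overlap, gene_screen

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = ("qualitative", "quantitative", "transcriptome", "integration", "enrichment")


@dataclass
class PipelineConfig:
    """Declarative run description (YAML-loadable).

    Either ``synthetic`` is true and ``simulation`` holds generator
    parameters, or the four input paths must point to existing files.
    ``stages`` toggles individual stages; the quantitative screen is
    restricted to the populations shared with the transcriptome design
    when a depth-limited population (PC) is present.
    """

    out_dir: str = "bcellmap_out"
    synthetic: bool = True
    simulation: SimulationParams = field(default_factory=SimulationParams)
    screen: ScreenParams = field(default_factory=ScreenParams)
    intensities_path: str | None = None
    expression_path: str | None = None
    id_map_path: str | None = None
    gene_sets_path: str | None = None
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in ALL_STAGES})
    quantitative_populations: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for s in ALL_STAGES:
            self.stages.setdefault(s, True)
        if not self.synthetic:
            for name in ("intensities_path", "id_map_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} must point to an existing file when synthetic is false")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            raw["simulation"] = SimulationParams(**raw["simulation"])
        if "screen" in raw and isinstance(raw["screen"], dict):
            raw["screen"] = ScreenParams(**raw["screen"])
        return cls(**raw)


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def __call__(self, msg: str) -> None:
        stamp = time.strftime("%Y-%m-%d %H:%M:%S")
        self.lines.append(f"{stamp}  {msg}")
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(self.lines[-1] + "\n")


def _stage_seeds(root_seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(root_seed).generate_state(len(ALL_STAGES) + 1)
    names = ("synthetic",) + ALL_STAGES
    return {n: int(s % (2**31 - 1)) for n, s in zip(names, state)}


def _synthetic_gene_sets(manifest, protein_ids, seed: int) -> GeneSetCollection:
    """Demo gene-set collection: planted sets plus random draws."""
    rng = np.random.default_rng(seed)
    sets: dict[str, frozenset[str]] = {}
    diff = manifest.differential_ids()
    if diff:
        sets["planted_differential"] = frozenset(diff)
    for pop in sorted({v for v in manifest.population_specific.values() if v}):
        members = manifest.specific_ids(pop)
        if members:
            sets[f"planted_specific_{pop}"] = frozenset(members)
    for i in range(5):
        size = int(rng.integers(10, 40))
        sets[f"random_set_{i}"] = frozenset(rng.choice(protein_ids, size=size, replace=False))
    return GeneSetCollection(sets=sets, descriptions={n: "synthetic" for n in sets})


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.txt"
    log_path.write_text("", encoding="utf-8")
    log = _Log(log_path)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "screen_params": dataclasses.asdict(config.screen),
        "stages_run": [],
        "outputs": {},
    }
    current_stage = "setup"
    try:
        # ------------------------------------------------------ ingest
        current_stage = "synthetic" if config.synthetic else "ingest"
        gene_sets: GeneSetCollection | None = None
        truth = None
        if config.synthetic:
            sim = dataclasses.replace(config.simulation, seed=seeds["synthetic"])
            proteome, transcriptome, idmap, truth = simulate_paired_study(sim)
            paths = write_study(out / "synthetic", proteome, transcriptome, idmap, truth)
            manifest["outputs"]["synthetic"] = sorted(str(p) for p in paths.values())
            manifest["simulation_params"] = {
                k: v for k, v in dataclasses.asdict(sim).items()
                if not k.startswith("design_")
            }
            log(f"synthetic: generated {proteome.n_proteins} proteins, seed {sim.seed}")
        else:
            from .synthetic import default_proteome_design, default_transcriptome_design

            proteome = read_long_intensities(config.intensities_path, default_proteome_design())
            transcriptome = (
                read_expression_matrix(config.expression_path, default_transcriptome_design())
                if config.expression_path
                else None
            )
            idmap = read_id_map(config.id_map_path)
            log(f"ingest: read {proteome.n_proteins} proteins")
        if config.gene_sets_path:
            gene_sets = read_gene_sets(config.gene_sets_path)
        elif config.synthetic and truth is not None:
            gene_sets = _synthetic_gene_sets(truth, proteome.protein_ids, seeds["enrichment"])
            write_gene_sets(gene_sets, out / "synthetic" / "gene_sets.gmt")

        # -------------------------------------------------- qualitative
        presence = None
        if config.stages["qualitative"]:
            current_stage = "qualitative"
            presence = consensus_presence(proteome)
            presence.write(out / "presence_matrix.tsv")
            summary = membership_summary(presence)
            summary.write(out / "membership_summary.tsv")
            for pop in presence.populations:
                ids = exclusive_proteins(presence, pop)
                (out / f"exclusive_{pop}.txt").write_text(
                    "\n".join(ids) + ("\n" if ids else ""), encoding="utf-8"
                )
            if len(presence.populations) >= 2:
                binary_cluster(presence).to_json(out / "dendrogram.json")
            manifest["outputs"]["qualitative"] = [
                "presence_matrix.tsv", "membership_summary.tsv", "dendrogram.json",
            ] + [f"exclusive_{p}.txt" for p in presence.populations]
            manifest["stages_run"].append("qualitative")
            log(f"qualitative: {presence.n_proteins} proteins with consensus presence")

        # ------------------------------------------------- quantitative
        table = None
        if config.stages["quantitative"]:
            current_stage = "quantitative"
            quant_pops = config.quantitative_populations
            if quant_pops is None:
                quant_pops = [p for p in proteome.design.populations if p != "PC"]
            quant = subset_populations(proteome, quant_pops)
            quant = drop_all_absent(propagate_zeros(quant))
            screen = config.screen.replace(seed=seeds["quantitative"])
            table = differential_screen(quant, screen)
            table.write(out / "differential_table.tsv")
            passes_filters(table, screen).to_csv(
                out / "screen_filters.tsv", sep="\t", index=False
            )
            zf = table.z_frame()
            zf.rename_axis("protein_id").to_csv(out / "z_matrix.tsv", sep="\t")
            ex = extremal_summary(table)
            ex.to_frame().to_csv(out / "extremal_summary.tsv", sep="\t", index=False)
            pca = pca_scores(zf.T)
            pca.write(out / "pca_scores.tsv")
            sig = zf[np.asarray(table.significant)]
            if len(sig) >= screen.som_rows * screen.som_cols:
                som_clusters(sig, screen).write(out / "som_clusters.tsv")
            chromosome_profiles(table, idmap).write(out / "chromosome_profiles.tsv")
            if len(zf) >= 2:
                hierarchical_heatmap_order(zf, axis="columns").to_json(
                    out / "heatmap_population_order.json"
                )
            manifest["outputs"]["quantitative"] = [
                "differential_table.tsv", "screen_filters.tsv", "z_matrix.tsv",
                "extremal_summary.tsv", "pca_scores.tsv", "som_clusters.tsv",
                "chromosome_profiles.tsv", "heatmap_population_order.json",
            ]
            manifest["stages_run"].append("quantitative")
            log(
                f"quantitative: {table.n_proteins} proteins screened, "
                f"{int(np.sum(table.significant))} significant at "
                f"p<={screen.anova_alpha}"
            )

        # ------------------------------------------------ transcriptome
        gene_table = None
        if config.stages["transcriptome"] and transcriptome is not None:
            current_stage = "transcriptome"
            screen = config.screen.replace(seed=seeds["transcriptome"])
            gene_table = gene_screen(transcriptome, screen)
            gene_table.write(out / "gene_differential_table.tsv")
            if table is not None:
                overlap = cross_omics_overlap(gene_table, table, idmap)
                with open(out / "cross_omics_overlap.json", "w", encoding="utf-8") as fh:
                    json.dump(overlap.to_dict(), fh, indent=1)
            manifest["outputs"]["transcriptome"] = [
                "gene_differential_table.tsv", "cross_omics_overlap.json",
            ]
            manifest["stages_run"].append("transcriptome")
            log(
                f"transcriptome: {gene_table.n_genes} genes, "
                f"{len(gene_table.significant_ids())} Bonferroni-significant"
            )

        # -------------------------------------------------- integration
        if config.stages["integration"] and transcriptome is not None:
            current_stage = "integration"
            screen = config.screen.replace(seed=seeds["integration"])
            shared = [p for p in proteome.design.populations
                      if p in transcriptome.design.populations]
            protein_means = full_replicate_means(
                subset_populations(proteome, shared), "proteome"
            )
            transcript_means = full_replicate_means(transcriptome, "transcriptome")
            paired = pt_ratios(match_ids(protein_means, transcript_means, idmap))
            paired.write(out / "paired_table.tsv")
            try:
                clusters = ratio_clusters(paired, screen)
                clusters.write(out / "ratio_clusters.tsv")
            except ValueError as exc:
                log(f"integration: ratio clustering skipped ({exc})")
            ratio_population_dendrogram(paired).to_json(out / "ratio_dendrogram.json")
            export_tracks(protein_means, transcript_means, paired, idmap, out)
            manifest["outputs"]["integration"] = [
                "paired_table.tsv", "ratio_clusters.tsv", "ratio_dendrogram.json",
                "tracks_proteome.tsv", "tracks_transcriptome.tsv", "tracks_ratio.tsv",
            ]
            manifest["stages_run"].append("integration")
            log(f"integration: {len(paired)} matched protein/transcript pairs")

        # --------------------------------------------------- enrichment
        if config.stages["enrichment"] and gene_sets is not None and presence is not None:
            current_stage = "enrichment"
            universe = set(presence.protein_ids)
            for pop in presence.populations:
                query = set(exclusive_proteins(presence, pop)) & universe
                if not query:
                    continue
                result = ora_test(query, universe, gene_sets)
                result.write(out / f"enrichment_exclusive_{pop}.tsv")
            if table is not None:
                query = {
                    p for p, s in zip(table.protein_ids, table.significant) if s
                } & universe
                if query:
                    ora_test(query, universe, gene_sets).write(
                        out / "enrichment_differential.tsv"
                    )
            manifest["stages_run"].append("enrichment")
            log("enrichment: over-representation tests written")

    except Exception as exc:
        log(f"FAILED at stage {current_stage}: {exc}")
        manifest["failed_stage"] = current_stage
        manifest["error"] = "".join(traceback.format_exception_only(exc)).strip()
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    log("done")
    return out
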