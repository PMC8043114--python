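"""Proteome-transcriptome integration: matched means, P/T ratios, clusters.

For every ID detected in all replicates, replicate means are taken per
population; proteins and transcripts are matched through the ID map;
and the per-population log10 protein/transcript ratio (a
translation-efficiency-like summary) is computed on raw-scale means.
Ratio profiles are z-scored per ID and clustered with DBSCAN; an
epsilon sweep over the k-distance curve reports the neighborhood radii
that yield a requested cluster count.  Plot-ready Circos-style track
tables are exported per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .cluster import DendrogramResult, average_linkage_tree
from .core_io import ExpressionMatrix, IdMap, IntensityMatrix, ScreenParams
from .quantitative import ClusterAssignment

__all__ = [
    "PairedOmicsTable",
    "full_replicate_means",
    "match_ids",
    "pt_ratios",
    "ratio_z_matrix",
    "ratio_clusters",
    "sweep_epsilon",
    "ratio_population_dendrogram",
    "export_tracks",
]

TRACK_LAYERS = ("proteome", "transcriptome", "ratio")


@dataclass
class PairedOmicsTable:
    """Matched protein/transcript mean profiles and log10 P/T ratios.

    ``frame`` is keyed by protein_id with the linked gene_id, a
    ``multiplicity`` flag (``one-to-one`` or ``collapsed``), and
    ``protein_mean_<pop>`` / ``transcript_mean_<pop>`` columns over the
    shared populations.  ``pt_ratios`` adds ``log10_ratio_<pop>``
    columns (NaN where either mean is missing or non-positive).
    """

    frame: pd.DataFrame
    populations: tuple[str, ...]
    n_unmatched_proteins: int = 0
    n_unmatched_genes: int = 0
    n_undefined_ratios: int = 0

    def __len__(self) -> int:
        return len(self.frame)

    def has_ratios(self) -> bool:
        return any(c.startswith("log10_ratio_") for c in self.frame.columns)

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def full_replicate_means(
    matrix: IntensityMatrix | ExpressionMatrix, mode: str
) -> pd.DataFrame:
    """Per-population means of IDs detected in all replicates.

    ``mode='proteome'``: an ID is kept when at least one population has
    it detected (> 0) in every replicate; a population's mean is defined
    (non-NaN) only when all of that population's replicates are nonzero.
    ``mode='transcriptome'``: an ID is kept only when present in every
    replicate of every population.
    """
    if mode not in {"proteome", "transcriptome"}:
        raise ValueError("mode must be 'proteome' or 'transcriptome'")
    ids = matrix.protein_ids if isinstance(matrix, IntensityMatrix) else matrix.gene_ids
    pops = matrix.design.populations
    means = np.column_stack([matrix.population_values(p).mean(axis=1) for p in pops])
    complete = np.column_stack(
        [(matrix.population_values(p) > 0).all(axis=1) for p in pops]
    )
    values = np.where(complete, means, np.nan)
    if mode == "proteome":
        keep = complete.any(axis=1)
    else:
        keep = complete.all(axis=1)
    return pd.DataFrame(values[keep], index=[i for i, k in zip(ids, keep) if k], columns=list(pops))


def match_ids(
    protein_means: pd.DataFrame, transcript_means: pd.DataFrame, idmap: IdMap
) -> PairedOmicsTable:
    """Join protein and transcript mean tables through the ID map.

    Many-to-many mappings are collapsed to one row per protein by
    keeping the candidate with the highest grand-mean expression, with
    the ``multiplicity`` flag set to ``collapsed``.
    """
    if protein_means.empty or transcript_means.empty:
        raise ValueError("both mean tables must be non-empty")
    pops = tuple(p for p in protein_means.columns if p in set(transcript_means.columns))
    if not pops:
        raise ValueError("no shared populations between the two tables")
    rec = idmap.records
    rec = rec[rec["protein_id"].isin(protein_means.index) & rec["gene_id"].isin(transcript_means.index)]

    t_grand = transcript_means[list(pops)].mean(axis=1)
    p_grand = protein_means[list(pops)].mean(axis=1)

    rows = []
    # collapse transcripts per protein: highest transcript grand mean wins
    chosen: dict[str, tuple[str, bool]] = {}
    for pid, sub in rec.groupby("protein_id", sort=False):
        genes = sub["gene_id"].tolist()
        best = max(genes, key=lambda g: (t_grand[g], g))
        chosen[pid] = (best, len(genes) > 1)
    # collapse proteins per gene: highest protein grand mean wins
    by_gene: dict[str, list[str]] = {}
    for pid, (g, _) in chosen.items():
        by_gene.setdefault(g, []).append(pid)
    for g, pids in by_gene.items():
        best_pid = max(pids, key=lambda p: (p_grand[p], p))
        collapsed = len(pids) > 1 or chosen[best_pid][1]
        row = {
            "protein_id": best_pid,
            "gene_id": g,
            "multiplicity": "collapsed" if collapsed else "one-to-one",
        }
        for p in pops:
            row[f"protein_mean_{p}"] = protein_means.at[best_pid, p]
            row[f"transcript_mean_{p}"] = transcript_means.at[g, p]
        rows.append(row)
    frame = pd.DataFrame(rows).sort_values("protein_id").reset_index(drop=True)
    matched_proteins = set(frame["protein_id"]) if rows else set()
    matched_genes = set(frame["gene_id"]) if rows else set()
    return PairedOmicsTable(
        frame=frame,
        populations=pops,
        n_unmatched_proteins=len(set(protein_means.index) - matched_proteins),
        n_unmatched_genes=len(set(transcript_means.index) - matched_genes),
    )


def pt_ratios(paired: PairedOmicsTable) -> PairedOmicsTable:
    """log10(protein mean / transcript mean) per population.

    The direct ratio of raw-scale means is taken and then logged; pairs
    where either mean is missing or <= 0 yield NaN and are excluded from
    downstream clustering (counted in ``n_undefined_ratios``).
    """
    frame = paired.frame.copy()
    n_undef = 0
    for p in paired.populations:
        pm = frame[f"protein_mean_{p}"].to_numpy(dtype=float)
        tm = frame[f"transcript_mean_{p}"].to_numpy(dtype=float)
        ok = np.isfinite(pm) & np.isfinite(tm) & (pm > 0) & (tm > 0)
        ratio = np.full(len(frame), np.nan)
        ratio[ok] = np.log10(pm[ok] / tm[ok])
        n_undef += int((~ok).sum())
        frame[f"log10_ratio_{p}"] = ratio
    return PairedOmicsTable(
        frame=frame,
        populations=paired.populations,
        n_unmatched_proteins=paired.n_unmatched_proteins,
        n_unmatched_genes=paired.n_unmatched_genes,
        n_undefined_ratios=n_undef,
    )


def ratio_z_matrix(paired: PairedOmicsTable) -> pd.DataFrame:
    """Complete ratio profiles, z-scored per ID (sample SD, ddof=1).

    IDs with any undefined ratio are excluded first; constant rows get
    all-zero z-profiles.
    """
    if not paired.has_ratios():
        paired = pt_ratios(paired)
    cols = [f"log10_ratio_{p}" for p in paired.populations]
    sub = paired.frame.set_index("protein_id")[cols].dropna()
    x = sub.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=sub.index, columns=list(paired.populations))


def ratio_clusters(paired: PairedOmicsTable, params: ScreenParams) -> ClusterAssignment:
    """DBSCAN on z-scored P/T ratio profiles; -1 labels noise."""
    z = ratio_z_matrix(paired)
    if len(z) < params.dbscan_min_points:
        raise ValueError("fewer complete ratio profiles than dbscan_min_points")
    labels = DBSCAN(eps=params.dbscan_eps, min_samples=params.dbscan_min_points).fit_predict(
        z.to_numpy()
    )
    import warnings

    if (labels == -1).all():
        warnings.warn("all ratio profiles labeled as noise; epsilon may be too small")
    return ClusterAssignment(
        item_ids=[str(i) for i in z.index],
        labels=labels,
        method="dbscan",
        params={"eps": params.dbscan_eps, "min_points": params.dbscan_min_points},
        seed=params.seed,
    )


def sweep_epsilon(
    paired: PairedOmicsTable,
    params: ScreenParams,
    target_clusters: int = 4,
    n_candidates: int = 50,
) -> list[float]:
    """Epsilon values (from the k-distance curve) giving the target cluster count.

    Candidate radii are quantiles of the distance to the
    ``min_points``-th nearest neighbor; each is tried with DBSCAN and
    those producing exactly ``target_clusters`` clusters (noise aside)
    are returned sorted.
    """
    z = ratio_z_matrix(paired).to_numpy()
    if len(z) <= params.dbscan_min_points:
        raise ValueError("not enough complete ratio profiles to sweep")
    from sklearn.neighbors import NearestNeighbors

    k = params.dbscan_min_points
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(z))).fit(z)
    kdist = np.sort(nn.kneighbors(z)[0][:, -1])
    qs = np.linspace(0.02, 0.98, n_candidates)
    candidates = sorted(set(float(np.quantile(kdist, q)) for q in qs))
    hits = []
    for eps in candidates:
        if eps <= 0:
            continue
        labels = DBSCAN(eps=eps, min_samples=k).fit_predict(z)
        if len(set(labels) - {-1}) == target_clusters:
            hits.append(eps)
    return hits


def ratio_population_dendrogram(paired: PairedOmicsTable) -> DendrogramResult:
    """Cluster populations on z-scored ratio profiles (Euclidean, average)."""
    z = ratio_z_matrix(paired)
    return average_linkage_tree(z.to_numpy().T, list(z.columns))


def export_tracks(
    protein_means: pd.DataFrame,
    transcript_means: pd.DataFrame,
    paired: PairedOmicsTable,
    idmap: IdMap,
    out_dir: str | Path,
) -> dict[str, pd.DataFrame]:
    """Write Circos-style per-chromosome line-track tables.

    Three layers: log10 protein mean, log10 transcript mean (values as
    given; the transcriptome is already log-scale so it is exported
    unchanged), and the log10 P/T ratio.  Position is a deterministic
    ordinal within each chromosome (alphabetical by ID).  IDs without a
    chromosome are skipped and counted in the returned frames' attrs.
    """
    if not paired.has_ratios():
        paired = pt_ratios(paired)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = idmap.records
    chrom_of_protein = dict(zip(rec["protein_id"], rec["chromosome"]))
    chrom_of_gene = dict(zip(rec["gene_id"], rec["chromosome"]))

    def build(ids, chrom_of, value_fn, populations) -> pd.DataFrame:
        placed = sorted((chrom_of[i], i) for i in ids if i in chrom_of)
        skipped = sum(1 for i in ids if i not in chrom_of)
        rows = []
        pos = 0
        last_chrom = None
        for chrom, ident in placed:
            pos = pos + 1 if chrom == last_chrom else 1
            last_chrom = chrom
            for p in populations:
                v = value_fn(ident, p)
                if v is not None and np.isfinite(v):
                    rows.append((chrom, pos, ident, p, v))
        df = pd.DataFrame(rows, columns=["chromosome", "position", "id", "population", "value"])
        df.attrs["skipped_no_chromosome"] = skipped
        return df

    def protein_value(pid, pop):
        v = protein_means.at[pid, pop]
        return float(np.log10(v)) if np.isfinite(v) and v > 0 else None

    def transcript_value(gid, pop):
        v = transcript_means.at[gid, pop]
        return float(v) if np.isfinite(v) else None

    ratio_frame = paired.frame.set_index("protein_id")

    def ratio_value(pid, pop):
        v = ratio_frame.at[pid, f"log10_ratio_{pop}"]
        return float(v) if np.isfinite(v) else None

    shared = paired.populations
    tracks = {
        "proteome": build(list(protein_means.index), chrom_of_protein, protein_value, shared),
        "transcriptome": build(list(transcript_means.index), chrom_of_gene, transcript_value, shared),
        "ratio": build(list(ratio_frame.index), chrom_of_protein, ratio_value, shared),
    }
    for layer, df in tracks.items():
        df.to_csv(out / f"tracks_{layer}.tsv", sep="\t", index=False, encoding="utf-8")
    return tracks
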