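"""Domain types and tab-delimited I/O shared by every pipeline stage.

The pipeline's canonical in-memory containers are thin dataclasses around
numpy arrays with an explicit :class:`SampleDesign` describing the
population x replicate layout.  Throughout the package an intensity of
exactly ``0`` means "not detected": absence carries quantitative meaning
(zero expression) and is never represented as NaN.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PE_CLASSES",
    "CHROMOSOMES",
    "SampleDesign",
    "IntensityMatrix",
    "ExpressionMatrix",
    "IdMap",
    "GeneSetCollection",
    "ScreenParams",
    "read_long_intensities",
    "write_long_intensities",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_id_map",
    "write_id_map",
    "read_gene_sets",
    "write_gene_sets",
]

#: Human Proteome Project protein-evidence tiers ("missing protein" classes).
PE_CLASSES = frozenset({"PE1", "PE2", "PE3", "PE4", "PE5"})

#: Default chromosome vocabulary: 22 autosomes plus the sex chromosomes.
CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")


@dataclass(frozen=True)
class SampleDesign:
    """Ordered populations and the replicate count of each.

    Parameters
    ----------
    populations
        Population labels in biological (maturation) order.
    replicates
        Mapping of population label to its replicate count (>= 2 each).
    """

    populations: tuple[str, ...]
    replicates: Mapping[str, int]

    def __post_init__(self) -> None:
        pops = tuple(self.populations)
        object.__setattr__(self, "populations", pops)
        object.__setattr__(self, "replicates", dict(self.replicates))
        if len(pops) == 0:
            raise ValueError("design needs at least one population")
        if len(set(pops)) != len(pops):
            raise ValueError("population labels must be unique")
        if any(not p for p in pops):
            raise ValueError("population labels must be non-empty")
        for p in pops:
            n = self.replicates.get(p)
            if n is None:
                raise ValueError(f"no replicate count for population {p!r}")
            if not isinstance(n, (int, np.integer)) or n < 2:
                raise ValueError(f"population {p!r} needs >= 2 replicates, got {n!r}")
        extra = set(self.replicates) - set(pops)
        if extra:
            raise ValueError(f"replicate counts for unknown populations: {sorted(extra)}")

    @property
    def n_samples(self) -> int:
        return sum(self.replicates[p] for p in self.populations)

    def sample_index(self) -> list[tuple[str, int]]:
        """(population, replicate) pairs in column order; replicates 1-based."""
        return [(p, r) for p in self.populations for r in range(1, self.replicates[p] + 1)]

    def sample_labels(self) -> list[str]:
        return [f"{p}_{r}" for p, r in self.sample_index()]

    def columns_for(self, population: str) -> slice:
        """Column slice of one population's replicates."""
        if population not in self.replicates:
            raise KeyError(f"unknown population {population!r}")
        start = 0
        for p in self.populations:
            n = self.replicates[p]
            if p == population:
                return slice(start, start + n)
            start += n
        raise AssertionError("unreachable")


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} {dup!r}")
    return ids


@dataclass
class IntensityMatrix:
    """Protein x sample grid of non-negative normalized LFQ abundances.

    ``values[i, j]`` is the abundance of ``protein_ids[i]`` in the j-th
    sample of ``design.sample_index()``; 0 encodes "not detected".
    """

    protein_ids: list[str]
    design: SampleDesign
    values: np.ndarray

    def __post_init__(self) -> None:
        self.protein_ids = _check_ids(self.protein_ids, "protein_id")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.protein_ids), self.design.n_samples):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {self.design.n_samples} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensities must be finite")
        if (self.values < 0).any():
            raise ValueError("intensities must be >= 0")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def population_values(self, population: str) -> np.ndarray:
        """View of one population's replicate columns (proteins x replicates)."""
        return self.values[:, self.design.columns_for(population)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.design.sample_labels())

    def replace(self, *, protein_ids: list[str] | None = None, values: np.ndarray | None = None) -> "IntensityMatrix":
        return IntensityMatrix(
            protein_ids=list(self.protein_ids if protein_ids is None else protein_ids),
            design=self.design,
            values=(self.values if values is None else values).copy(),
        )


@dataclass
class ExpressionMatrix:
    """Gene x sample grid of log2-scale expression (microarray units)."""

    gene_ids: list[str]
    design: SampleDesign
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene_id")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.gene_ids), self.design.n_samples):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {self.design.n_samples} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def population_values(self, population: str) -> np.ndarray:
        return self.values[:, self.design.columns_for(population)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.design.sample_labels())


@dataclass
class IdMap:
    """Protein accession <-> gene ID <-> chromosome (+ optional PE class) map."""

    records: pd.DataFrame
    chromosome_vocabulary: tuple[str, ...] = CHROMOSOMES

    def __post_init__(self) -> None:
        required = ["protein_id", "gene_id", "chromosome", "pe_class"]
        df = self.records
        if "pe_class" not in df.columns:
            df = df.assign(pe_class="")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"IdMap missing columns: {missing}")
        df = df[required].astype(str).replace({"pe_class": {"nan": "", "None": ""}})
        df = df.drop_duplicates()
        if df.duplicated(subset=["protein_id", "gene_id"]).any():
            pair = df[df.duplicated(subset=["protein_id", "gene_id"])].iloc[0]
            raise ValueError(
                f"conflicting duplicate mapping for ({pair.protein_id!r}, {pair.gene_id!r})"
            )
        bad_pe = sorted(set(df["pe_class"]) - PE_CLASSES - {""})
        if bad_pe:
            raise ValueError(f"invalid pe_class values: {bad_pe}")
        vocab = set(self.chromosome_vocabulary)
        bad_chrom = sorted(set(df["chromosome"]) - vocab)
        if bad_chrom:
            raise ValueError(f"chromosome labels outside declared vocabulary: {bad_chrom}")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def genes_for(self, protein_id: str) -> list[str]:
        r = self.records
        return r.loc[r["protein_id"] == protein_id, "gene_id"].tolist()

    def protein_to_chromosomes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pid, chrom in zip(self.records["protein_id"], self.records["chromosome"]):
            out.setdefault(pid, [])
            if chrom not in out[pid]:
                out[pid].append(chrom)
        return out


@dataclass
class GeneSetCollection:
    """Named gene/protein sets (GMT semantics)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = {n: frozenset(m) for n, m in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class ScreenParams:
    """Thresholds and tuning knobs for the statistical stages.

    ``anova_alpha`` gates the protein screen's ``significant`` flag
    (raw ANOVA p <= alpha); ``q_alpha`` and ``min_max_fold_change`` are
    the stricter filters computed alongside.  ``pseudo_offset`` is added
    before the log2 transform of intensities.  The clustering knobs cover
    the density-based ratio clustering (``dbscan_*``) and the
    self-organizing map (``som_*``; the default 5 x 1 grid yields five
    profile clusters).
    """

    anova_alpha: float = 0.05
    q_alpha: float = 0.05
    min_max_fold_change: float = 2.0
    pairwise_alpha: float = 0.05
    bonferroni_alpha: float = 0.05
    pseudo_offset: float = 1.0
    dbscan_eps: float = 1.0
    dbscan_min_points: int = 5
    som_rows: int = 5
    som_cols: int = 1
    som_epochs: int = 500
    som_learning_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("anova_alpha", "q_alpha", "pairwise_alpha", "bonferroni_alpha"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {a}")
        if self.min_max_fold_change < 1.0:
            raise ValueError("min_max_fold_change must be >= 1")
        if self.pseudo_offset <= 0:
            raise ValueError("pseudo_offset must be > 0")
        if self.dbscan_eps <= 0 or self.dbscan_min_points < 1:
            raise ValueError("invalid density-clustering parameters")
        if self.som_rows < 1 or self.som_cols < 1 or self.som_epochs < 1:
            raise ValueError("invalid SOM parameters")
        if not (0 < self.som_learning_rate <= 1):
            raise ValueError("som_learning_rate must be in (0, 1]")

    def replace(self, **kwargs) -> "ScreenParams":
        return dataclasses.replace(self, **kwargs)


def subset_populations(matrix: IntensityMatrix, populations: Sequence[str]) -> IntensityMatrix:
    """Restrict an intensity matrix to a subset of populations (in given order)."""
    design = matrix.design
    missing = [p for p in populations if p not in design.populations]
    if missing:
        raise ValueError(f"unknown populations: {missing}")
    new_design = SampleDesign(tuple(populations), {p: design.replicates[p] for p in populations})
    cols = np.concatenate([np.arange(matrix.values.shape[1])[design.columns_for(p)] for p in populations])
    return IntensityMatrix(
        protein_ids=list(matrix.protein_ids),
        design=new_design,
        values=matrix.values[:, cols].copy(),
    )


# ---------------------------------------------------------------------------
# Readers / writers.  All files are UTF-8 TSV with '.' decimal separator.
# ---------------------------------------------------------------------------

def read_long_intensities(path: str | Path, design: SampleDesign) -> IntensityMatrix:
    """Read a long-format (tidy) protein intensity table.

    The file must have columns ``protein_id  population  replicate
    intensity``.  (protein, sample) pairs absent from the file are filled
    with 0 ("not detected").  Protein row order is first-appearance order.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t",
        dtype={"protein_id": str, "population": str},
        float_precision="round_trip",
    )
    required = {"protein_id", "population", "replicate", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    if intensity.isna().any():
        line = int(df.index[intensity.isna()][0]) + 2  # +1 header, +1 1-based
        raise ValueError(f"{path}: non-numeric intensity at line {line}")
    if (intensity < 0).any():
        line = int(df.index[intensity < 0][0]) + 2
        raise ValueError(f"{path}: negative intensity at line {line}")

    unknown = set(df["population"]) - set(design.populations)
    if unknown:
        raise ValueError(f"{path}: unknown population label(s) {sorted(unknown)}")
    replicate = pd.to_numeric(df["replicate"], errors="coerce")
    if replicate.isna().any() or (replicate != replicate.astype(int)).any():
        raise ValueError(f"{path}: replicate column must be integer")
    df = df.assign(replicate=replicate.astype(int), intensity=intensity.astype(float))
    for pop, sub in df.groupby("population", sort=False):
        n = design.replicates[str(pop)]
        bad = sub.loc[(sub["replicate"] < 1) | (sub["replicate"] > n)]
        if len(bad):
            r = bad.iloc[0]
            raise ValueError(f"{path}: replicate {r.replicate} outside 1..{n} for population {pop!r}")

    dup = df.duplicated(subset=["protein_id", "population", "replicate"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate entry for ({r.protein_id!r}, {r.population!r}, replicate {r.replicate})"
        )

    protein_ids = list(dict.fromkeys(df["protein_id"]))
    row_of = {p: i for i, p in enumerate(protein_ids)}
    col_of = {pr: j for j, pr in enumerate(design.sample_index())}
    values = np.zeros((len(protein_ids), design.n_samples))
    rows = df["protein_id"].map(row_of).to_numpy(dtype=int)
    cols = np.array(
        [col_of[(p, r)] for p, r in zip(df["population"], df["replicate"])], dtype=int
    )
    values[rows, cols] = df["intensity"].to_numpy()
    return IntensityMatrix(protein_ids=protein_ids, design=design, values=values)


def write_long_intensities(matrix: IntensityMatrix, path: str | Path) -> None:
    """Write every (protein, sample) cell, zeros included, as tidy TSV."""
    idx = matrix.design.sample_index()
    rows = []
    for i, pid in enumerate(matrix.protein_ids):
        for j, (pop, rep) in enumerate(idx):
            rows.append((pid, pop, rep, matrix.values[i, j]))
    out = pd.DataFrame(rows, columns=["protein_id", "population", "replicate", "intensity"])
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_expression_matrix(path: str | Path, design: SampleDesign) -> ExpressionMatrix:
    """Read a wide expression matrix: gene_id column + ``<pop>_<rep>`` columns."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, float_precision="round_trip")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: first column must be gene_id")
    expected = design.sample_labels()
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sample columns {missing}")
    values = df[expected].to_numpy(dtype=float)
    return ExpressionMatrix(gene_ids=df["gene_id"].tolist(), design=design, values=values)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().rename_axis("gene_id").to_csv(path, sep="\t", encoding="utf-8")


def read_id_map(path: str | Path, chromosome_vocabulary: tuple[str, ...] = CHROMOSOMES) -> IdMap:
    """Read a protein/gene/chromosome/PE-class map; duplicate rows collapse."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return IdMap(records=df, chromosome_vocabulary=chromosome_vocabulary)


def write_id_map(idmap: IdMap, path: str | Path) -> None:
    idmap.records.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file (name, description, tab-separated members)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")
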