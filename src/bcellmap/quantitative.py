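"""The quantitative differential screen and its downstream summaries.

The screen follows the study's zero-handling conventions: within each
population, a single missing replicate zeroes the whole population for
that protein (``propagate_zeros``); proteins absent everywhere are
removed (``drop_all_absent``); the remaining zeros mean true absence
and enter the statistics as zero expression.  Per protein the screen
runs a one-way fixed-effects ANOVA on log2(intensity + offset) across
populations, Benjamini-Hochberg adjustment across proteins, all-pairs
Welch t-tests, and the max fold change of raw population means.  The
summaries — z-score profiles, argmax/argmin distributions, grouped and
per-chromosome mean profiles, heatmap dendrograms, PCA and SOM
clustering — mirror the figures such screens feed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cluster import DendrogramResult, average_linkage_tree
from .core_io import IdMap, IntensityMatrix, ScreenParams
from .som import SelfOrganizingMap

__all__ = [
    "DifferentialTable",
    "ClusterAssignment",
    "ExtremalSummary",
    "ChromosomeProfiles",
    "PCAResult",
    "propagate_zeros",
    "drop_all_absent",
    "differential_screen",
    "zscore_profiles",
    "extremal_summary",
    "group_mean_profiles",
    "chromosome_profiles",
    "hierarchical_heatmap_order",
    "pca_scores",
    "som_clusters",
]


@dataclass
class DifferentialTable:
    """Per-protein results of the differential screen.

    ``means`` are raw-scale population means (protein x population);
    ``anova_p`` / ``bh_q`` the ANOVA p-value and its BH adjustment;
    ``max_fold_change`` the largest pairwise ratio of population means
    (larger mean in the numerator; ``inf`` when the smaller mean is 0,
    with ``mfc_undefined`` set).  ``pairwise_p`` maps population pairs
    to Welch t-test p-values.  ``significant`` is the raw-p screen flag;
    ``untestable`` marks proteins with zero residual variance.
    """

    protein_ids: list[str]
    populations: tuple[str, ...]
    means: np.ndarray
    anova_p: np.ndarray
    bh_q: np.ndarray
    max_fold_change: np.ndarray
    mfc_undefined: np.ndarray
    pairwise_p: dict[tuple[str, str], np.ndarray]
    significant: np.ndarray
    untestable: np.ndarray
    z_profile: np.ndarray | None = None
    argmax_population: list[str] | None = None
    argmin_population: list[str] | None = None
    argmax_tie: np.ndarray | None = None
    argmin_tie: np.ndarray | None = None

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def mean_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.means, index=self.protein_ids, columns=list(self.populations))

    def z_frame(self) -> pd.DataFrame:
        if self.z_profile is None:
            raise ValueError("z profiles not computed; call zscore_profiles first")
        return pd.DataFrame(self.z_profile, index=self.protein_ids, columns=list(self.populations))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"protein_id": self.protein_ids})
        for j, p in enumerate(self.populations):
            df[f"mean_{p}"] = self.means[:, j]
        df["anova_p"] = self.anova_p
        df["bh_q"] = self.bh_q
        df["max_fold_change"] = self.max_fold_change
        df["mfc_undefined"] = self.mfc_undefined
        df["significant"] = self.significant
        df["untestable"] = self.untestable
        for (a, b), pvals in self.pairwise_p.items():
            df[f"p_{a}_vs_{b}"] = pvals
        if self.z_profile is not None:
            for j, p in enumerate(self.populations):
                df[f"z_{p}"] = self.z_profile[:, j]
        if self.argmax_population is not None:
            df["argmax_population"] = self.argmax_population
            df["argmin_population"] = self.argmin_population
            df["argmax_tie"] = self.argmax_tie
            df["argmin_tie"] = self.argmin_tie
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, encoding="utf-8")


@dataclass
class ClusterAssignment:
    """Cluster labels for a set of items; -1 is noise (density methods only)."""

    item_ids: list[str]
    labels: np.ndarray
    method: str
    params: dict
    seed: int
    prototypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.item_ids):
            raise ValueError("labels must cover all items")
        if (self.labels < 0).any() and self.method != "dbscan":
            raise ValueError("noise labels only allowed for density-based clustering")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"item_id": self.item_ids, "cluster": self.labels})

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, encoding="utf-8")


def propagate_zeros(matrix: IntensityMatrix) -> IntensityMatrix:
    """Zero a whole population when any of its replicates is 0.

    Absence in one replicate is taken as absence in the population; the
    zero has quantitative meaning and the protein is kept.  Idempotent.
    """
    values = matrix.values.copy()
    for pop in matrix.design.populations:
        cols = matrix.design.columns_for(pop)
        block = values[:, cols]
        block[(block == 0).any(axis=1)] = 0.0
        values[:, cols] = block
    return matrix.replace(values=values)


def drop_all_absent(matrix: IntensityMatrix) -> IntensityMatrix:
    """Remove proteins absent (all-zero) across every population."""
    keep = (matrix.values > 0).any(axis=1)
    return matrix.replace(
        protein_ids=[p for p, k in zip(matrix.protein_ids, keep) if k],
        values=matrix.values[keep],
    )


def _oneway_anova(y: np.ndarray, design, populations) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-way fixed-effects ANOVA per row. Returns (F, p, untestable)."""
    k = len(populations)
    n_total = y.shape[1]
    groups = [y[:, design.columns_for(p)] for p in populations]
    ns = np.array([g.shape[1] for g in groups])
    gmeans = np.column_stack([g.mean(axis=1) for g in groups])
    grand = y.mean(axis=1)
    ssb = (ns[None, :] * (gmeans - grand[:, None]) ** 2).sum(axis=1)
    ssw = sum(((g - gm[:, None]) ** 2).sum(axis=1) for g, gm in zip(groups, gmeans.T))
    dfb, dfw = k - 1, n_total - k
    if dfw <= 0:
        raise ValueError("no residual degrees of freedom in design")
    untestable = ssw <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = np.ones_like(f)
    ok = ~untestable
    p[ok] = stats.f.sf(f[ok], dfb, dfw)
    f[untestable] = np.nan
    return f, p, untestable


def differential_screen(
    matrix: IntensityMatrix,
    params: ScreenParams,
    *,
    equal_var: bool = False,
    log_transform: bool = True,
) -> DifferentialTable:
    """ANOVA + BH + pairwise t-tests + max fold change, per protein.

    Expects a zero-propagated matrix with all-absent proteins dropped.
    Tests run on ``log2(intensity + pseudo_offset)`` (or raw intensities
    with ``log_transform=False``); fold changes use raw population
    means.  ``equal_var=True`` switches the pairwise follow-ups from
    Welch to pooled-variance t-tests.
    """
    design = matrix.design
    pops = design.populations
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    y = np.log2(matrix.values + params.pseudo_offset) if log_transform else matrix.values
    _, anova_p, untestable = _oneway_anova(y, design, pops)
    bh_q = multipletests(anova_p, method="fdr_bh")[1]

    raw_means = np.column_stack(
        [matrix.population_values(p).mean(axis=1) for p in pops]
    )

    # max fold change: larger mean over smaller, per pair; 0-vs-positive -> inf
    n = matrix.n_proteins
    mfc = np.full(n, 1.0)
    mfc_undef = np.zeros(n, dtype=bool)
    for a, b in combinations(range(len(pops)), 2):
        hi = np.maximum(raw_means[:, a], raw_means[:, b])
        lo = np.minimum(raw_means[:, a], raw_means[:, b])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(lo > 0, hi / np.where(lo > 0, lo, 1.0), np.where(hi > 0, np.inf, np.nan))
        both_zero = np.isnan(ratio)
        ratio[both_zero] = 1.0  # uninformative pair
        mfc = np.maximum(mfc, ratio)
    mfc_undef = np.isinf(mfc)

    pairwise_p: dict[tuple[str, str], np.ndarray] = {}
    for pa, pb in combinations(pops, 2):
        ya, yb = y[:, design.columns_for(pa)], y[:, design.columns_for(pb)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(ya, yb, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
        p[~np.isfinite(p)] = 1.0  # zero-variance degenerate pairs
        pairwise_p[(pa, pb)] = p

    significant = (anova_p <= params.anova_alpha) & ~untestable
    table = DifferentialTable(
        protein_ids=list(matrix.protein_ids),
        populations=pops,
        means=raw_means,
        anova_p=anova_p,
        bh_q=bh_q,
        max_fold_change=mfc,
        mfc_undefined=mfc_undef,
        pairwise_p=pairwise_p,
        significant=significant,
        untestable=untestable,
    )
    return zscore_profiles(table)


def passes_filters(table: DifferentialTable, params: ScreenParams) -> pd.DataFrame:
    """Boolean filter variants: raw p, BH q, and max-fold-change gates."""
    return pd.DataFrame(
        {
            "protein_id": table.protein_ids,
            "pass_p": table.anova_p <= params.anova_alpha,
            "pass_q": table.bh_q <= params.q_alpha,
            "pass_mfc": table.max_fold_change >= params.min_max_fold_change,
        }
    )


def zscore_profiles(table: DifferentialTable) -> DifferentialTable:
    """Standardize each protein's population-mean profile to z-scores.

    z = (mean - row mean) / row sample SD (ddof = 1); constant rows get
    all zeros.  Absent populations enter with mean 0.  Also assigns the
    argmax/argmin population of each profile, breaking ties by the fixed
    maturation order with an explicit tie flag.
    """
    m = table.means
    row_mean = m.mean(axis=1, keepdims=True)
    row_sd = m.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (m - row_mean) / row_sd
    z[np.broadcast_to(row_sd == 0, z.shape)] = 0.0
    table.z_profile = z

    argmax = m.argmax(axis=1)  # numpy argmax/argmin take the first index on ties
    argmin = m.argmin(axis=1)
    table.argmax_population = [table.populations[i] for i in argmax]
    table.argmin_population = [table.populations[i] for i in argmin]
    table.argmax_tie = (m == m.max(axis=1, keepdims=True)).sum(axis=1) > 1
    table.argmin_tie = (m == m.min(axis=1, keepdims=True)).sum(axis=1) > 1
    return table


@dataclass
class ExtremalSummary:
    """Counts of proteins maximally / minimally expressed per population."""

    argmax_counts: dict[str, int]
    argmin_counts: dict[str, int]
    n_proteins: int
    n_argmax_ties: int
    n_argmin_ties: int

    def to_frame(self) -> pd.DataFrame:
        pops = list(self.argmax_counts)
        return pd.DataFrame(
            {
                "population": pops,
                "argmax_count": [self.argmax_counts[p] for p in pops],
                "argmin_count": [self.argmin_counts[p] for p in pops],
            }
        )


def extremal_summary(table: DifferentialTable) -> ExtremalSummary:
    """Per-population counts of argmax/argmin proteins (a partition)."""
    if table.argmax_population is None:
        table = zscore_profiles(table)
    pops = table.populations
    argmax_counts = {p: 0 for p in pops}
    argmin_counts = {p: 0 for p in pops}
    for p in table.argmax_population:  # type: ignore[union-attr]
        argmax_counts[p] += 1
    for p in table.argmin_population:  # type: ignore[union-attr]
        argmin_counts[p] += 1
    return ExtremalSummary(
        argmax_counts=argmax_counts,
        argmin_counts=argmin_counts,
        n_proteins=table.n_proteins,
        n_argmax_ties=int(np.sum(table.argmax_tie)),
        n_argmin_ties=int(np.sum(table.argmin_tie)),
    )


def group_mean_profiles(
    matrix: IntensityMatrix, grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Mean population profile of each protein group (e.g. protein family).

    For every group and population: the mean over member proteins of the
    population replicate-mean.  Proteins without a group are ignored;
    groups with no protein in the matrix are dropped with a warning.
    Returns a frame indexed by group with population columns and
    ``group_size``.
    """
    pops = matrix.design.populations
    pop_means = np.column_stack([matrix.population_values(p).mean(axis=1) for p in pops])
    df = pd.DataFrame(pop_means, index=matrix.protein_ids, columns=list(pops))
    df["group"] = [grouping.get(pid) for pid in matrix.protein_ids]
    present = df.dropna(subset=["group"])
    empty = set(grouping.values()) - set(present["group"])
    if empty:
        warnings.warn(f"groups with no matched proteins dropped: {sorted(empty)}")
    agg = present.groupby("group").agg({p: "mean" for p in pops})
    agg["group_size"] = present.groupby("group").size()
    return agg


@dataclass
class ChromosomeProfiles:
    """Per-chromosome mean z-profiles of the screened proteins."""

    frame: pd.DataFrame  # chromosome x (population z means + protein_count)
    unmapped: int
    multi_mapped: list[str]

    def write(self, path: str | Path) -> None:
        self.frame.rename_axis("chromosome").to_csv(path, sep="\t", encoding="utf-8")


def chromosome_profiles(table: DifferentialTable, idmap: IdMap) -> ChromosomeProfiles:
    """Mean z-profile and protein count per chromosome.

    Proteins with no chromosome mapping are counted as unmapped;
    proteins mapping to several chromosomes contribute once per
    chromosome and are flagged.
    """
    if table.z_profile is None:
        table = zscore_profiles(table)
    chrom_of = idmap.protein_to_chromosomes()
    rows = []
    unmapped = 0
    multi = []
    for i, pid in enumerate(table.protein_ids):
        chroms = chrom_of.get(pid, [])
        if not chroms:
            unmapped += 1
            continue
        if len(chroms) > 1:
            multi.append(pid)
        for c in chroms:
            rows.append((c, *table.z_profile[i]))
    if not rows:
        raise ValueError("idmap maps none of the table's proteins")
    df = pd.DataFrame(rows, columns=["chromosome", *table.populations])
    agg = df.groupby("chromosome").mean()
    agg["protein_count"] = df.groupby("chromosome").size()
    return ChromosomeProfiles(frame=agg, unmapped=unmapped, multi_mapped=sorted(multi))


def hierarchical_heatmap_order(z_matrix: pd.DataFrame, axis: str = "rows") -> DendrogramResult:
    """Heatmap ordering: average-linkage Euclidean clustering of one axis.

    ``axis='rows'`` clusters proteins, ``axis='columns'`` clusters
    samples/populations.
    """
    if axis not in {"rows", "columns"}:
        raise ValueError("axis must be 'rows' or 'columns'")
    if axis == "columns":
        z_matrix = z_matrix.T
    return average_linkage_tree(z_matrix.to_numpy(dtype=float), [str(i) for i in z_matrix.index])


@dataclass
class PCAResult:
    scores: pd.DataFrame  # sample x component
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # component x feature

    def write(self, path: str | Path) -> None:
        self.scores.rename_axis("sample").to_csv(path, sep="\t", encoding="utf-8")


def pca_scores(sample_matrix: pd.DataFrame) -> PCAResult:
    """PCA of samples in profile space (rows = samples, columns = features).

    Columns are centered; all ``min(n_samples, n_features)`` components
    are returned, so explained-variance fractions sum to 1.  The sign of
    each component is fixed by making its largest-magnitude loading
    positive.
    """
    x = sample_matrix.to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u * s
    total = (s**2).sum()
    evr = (s**2) / total if total > 0 else np.zeros_like(s)
    return PCAResult(
        scores=pd.DataFrame(
            scores, index=sample_matrix.index, columns=[f"PC{j+1}" for j in range(len(s))]
        ),
        explained_variance_ratio=evr,
        loadings=vt,
    )


def som_clusters(z_matrix: pd.DataFrame, params: ScreenParams) -> ClusterAssignment:
    """Cluster protein z-profiles with a self-organizing map.

    The default 5 x 1 grid quantizes the profiles into five clusters;
    each protein is assigned its best-matching unit.
    """
    n_units = params.som_rows * params.som_cols
    if n_units > len(z_matrix):
        raise ValueError(f"SOM grid ({n_units} units) larger than protein count ({len(z_matrix)})")
    som = SelfOrganizingMap(
        rows=params.som_rows,
        cols=params.som_cols,
        epochs=params.som_epochs,
        learning_rate=params.som_learning_rate,
        random_state=params.seed,
    )
    som.fit(z_matrix.to_numpy(dtype=float))
    return ClusterAssignment(
        item_ids=[str(i) for i in z_matrix.index],
        labels=som.labels_,
        method="som",
        params={
            "rows": params.som_rows,
            "cols": params.som_cols,
            "epochs": params.som_epochs,
            "learning_rate": params.som_learning_rate,
        },
        seed=params.seed,
        prototypes=som.prototypes_,
    )
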