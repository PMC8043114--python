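"""Per-gene differential analysis of the four-population transcriptome.

Each gene gets a one-way ANOVA across populations on the (already
log-scale) expression values, a Bonferroni correction across genes, and
— for genes passing the Bonferroni cutoff — a Tukey HSD follow-up over
all population pairs using the studentized-range distribution
(Tukey-Kramer for unbalanced groups).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range

from .core_io import ExpressionMatrix, IdMap, ScreenParams
from .quantitative import DifferentialTable, _oneway_anova

__all__ = ["GeneDifferentialTable", "gene_screen", "cross_omics_overlap", "OverlapReport"]


@dataclass
class GeneDifferentialTable:
    """Per-gene ANOVA + Bonferroni + Tukey HSD results.

    ``tukey_p`` maps population pairs to HSD p-values (NaN for genes the
    follow-up was not run on); ``distinguishable`` flags pairs with
    Tukey p below the cutoff.
    """

    gene_ids: list[str]
    populations: tuple[str, ...]
    means: np.ndarray
    anova_p: np.ndarray
    bonferroni_p: np.ndarray
    tukey_p: dict[tuple[str, str], np.ndarray]
    distinguishable: dict[tuple[str, str], np.ndarray]
    significant: np.ndarray
    untestable: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def significant_ids(self) -> list[str]:
        return [g for g, s in zip(self.gene_ids, self.significant) if s]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene_id": self.gene_ids})
        for j, p in enumerate(self.populations):
            df[f"mean_{p}"] = self.means[:, j]
        df["anova_p"] = self.anova_p
        df["bonferroni_p"] = self.bonferroni_p
        df["significant"] = self.significant
        df["untestable"] = self.untestable
        for (a, b), pv in self.tukey_p.items():
            df[f"tukey_p_{a}_vs_{b}"] = pv
            df[f"distinct_{a}_vs_{b}"] = self.distinguishable[(a, b)]
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, encoding="utf-8")


def gene_screen(matrix: ExpressionMatrix, params: ScreenParams) -> GeneDifferentialTable:
    """ANOVA + Bonferroni across genes, Tukey HSD for the survivors.

    Expression values are used as given (log2 microarray scale).  Genes
    with ``bonferroni_p < bonferroni_alpha`` get the all-pairs Tukey HSD
    follow-up; a pair is *distinguishable* when its HSD p-value is below
    ``pairwise_alpha``.
    """
    design = matrix.design
    pops = design.populations
    y = matrix.values
    _, anova_p, untestable = _oneway_anova(y, design, pops)
    n_genes = matrix.n_genes
    bonferroni_p = np.minimum(1.0, anova_p * n_genes)
    significant = (bonferroni_p < params.bonferroni_alpha) & ~untestable

    groups = [y[:, design.columns_for(p)] for p in pops]
    ns = np.array([g.shape[1] for g in groups])
    gmeans = np.column_stack([g.mean(axis=1) for g in groups])
    ssw = sum(((g - gm[:, None]) ** 2).sum(axis=1) for g, gm in zip(groups, gmeans.T))
    dfw = y.shape[1] - len(pops)
    msw = ssw / dfw
    k = len(pops)

    tukey_p: dict[tuple[str, str], np.ndarray] = {}
    distinguishable: dict[tuple[str, str], np.ndarray] = {}
    run = significant
    for (ia, pa), (ib, pb) in combinations(enumerate(pops), 2):
        pvals = np.full(n_genes, np.nan)
        if run.any():
            diff = np.abs(gmeans[run, ia] - gmeans[run, ib])
            # Tukey-Kramer standard error; reduces to sqrt(MSW/n) when balanced
            se = np.sqrt(msw[run] / 2.0 * (1.0 / ns[ia] + 1.0 / ns[ib]))
            with np.errstate(divide="ignore", invalid="ignore"):
                q = np.where(se > 0, diff / se, np.inf)
            pvals[run] = studentized_range.sf(q, k, dfw)
        tukey_p[(pa, pb)] = pvals
        with np.errstate(invalid="ignore"):
            distinguishable[(pa, pb)] = pvals < params.pairwise_alpha

    return GeneDifferentialTable(
        gene_ids=list(matrix.gene_ids),
        populations=pops,
        means=gmeans,
        anova_p=anova_p,
        bonferroni_p=bonferroni_p,
        tukey_p=tukey_p,
        distinguishable=distinguishable,
        significant=significant,
        untestable=untestable,
    )


@dataclass
class OverlapReport:
    """Cross-omics agreement between gene and protein screens."""

    n_significant_genes: int
    n_significant_proteins: int
    n_mapped_pairs: int
    n_both_significant: int
    both_significant_pairs: list[tuple[str, str]]
    fraction_of_genes: float

    def to_dict(self) -> dict:
        return {
            "n_significant_genes": self.n_significant_genes,
            "n_significant_proteins": self.n_significant_proteins,
            "n_mapped_pairs": self.n_mapped_pairs,
            "n_both_significant": self.n_both_significant,
            "fraction_of_genes": self.fraction_of_genes,
        }


def cross_omics_overlap(
    genes: GeneDifferentialTable, proteins: DifferentialTable, idmap: IdMap
) -> OverlapReport:
    """How many significant transcripts map to a significant protein.

    Counts (gene, protein) pairs in the ID map where both screens call
    significance, and the fraction of significant genes this represents.
    """
    sig_genes = set(genes.significant_ids())
    sig_proteins = {
        p for p, s in zip(proteins.protein_ids, proteins.significant) if s
    }
    pairs = list(zip(idmap.records["gene_id"], idmap.records["protein_id"]))
    mapped = [(g, p) for g, p in pairs if g in set(genes.gene_ids) and p in set(proteins.protein_ids)]
    both = sorted({(g, p) for g, p in mapped if g in sig_genes and p in sig_proteins})
    n_sig_genes = len(sig_genes)
    return OverlapReport(
        n_significant_genes=n_sig_genes,
        n_significant_proteins=len(sig_proteins),
        n_mapped_pairs=len(mapped),
        n_both_significant=len(both),
        both_significant_pairs=both,
        fraction_of_genes=(len({g for g, _ in both}) / n_sig_genes) if n_sig_genes else 0.0,
    )
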