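"""Over-representation analysis of ID lists against gene-set collections.

One-sided hypergeometric tail test per set: given a universe of N IDs,
a query of n, and a set covering K universe members, the p-value is
P[X >= k] for the observed overlap k under sampling without
replacement.  BH correction is applied across the tested sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core_io import GeneSetCollection

__all__ = ["EnrichmentResult", "ora_test"]


@dataclass
class EnrichmentResult:
    """Per-set ORA statistics plus the sets skipped by size bounds."""

    frame: pd.DataFrame
    universe_size: int
    query_size: int
    skipped_sets: list[str]

    def __len__(self) -> int:
        return len(self.frame)

    def significant(self, q_alpha: float = 0.05) -> pd.DataFrame:
        return self.frame[self.frame["bh_q"] <= q_alpha]

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def ora_test(
    query: set[str],
    universe: set[str],
    sets: GeneSetCollection,
    min_set_size: int = 1,
    max_set_size: int | None = None,
) -> EnrichmentResult:
    """Hypergeometric over-representation test of ``query`` against ``sets``.

    Sets are intersected with the universe first; sets whose effective
    size falls outside ``[min_set_size, max_set_size]`` are skipped and
    reported.  The query must be a subset of the universe.
    """
    if not universe:
        raise ValueError("universe is empty")
    stray = sorted(set(query) - set(universe))
    if stray:
        raise ValueError(f"query IDs outside the universe: {stray[:10]}")
    universe = set(universe)
    query = set(query)
    n_universe, n_query = len(universe), len(query)

    rows = []
    skipped = []
    for name, members in sets.items():
        eff = members & universe
        size = len(eff)
        if size < min_set_size or (max_set_size is not None and size > max_set_size):
            skipped.append(name)
            continue
        overlap = query & eff
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, n_universe, size, n_query))
        p = min(p, 1.0)
        rows.append(
            {
                "set_name": name,
                "set_size": size,
                "query_size": n_query,
                "universe_size": n_universe,
                "overlap": k,
                "p_value": p,
                "overlap_ids": ";".join(sorted(overlap)),
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["bh_q"] = multipletests(frame["p_value"].to_numpy(), method="fdr_bh")[1]
        frame = frame.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        frame["bh_q"] = []
    return EnrichmentResult(
        frame=frame,
        universe_size=n_universe,
        query_size=n_query,
        skipped_sets=sorted(skipped),
    )
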