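"""Predicted-target interpretation: score-threshold filtering, hypergeometric
pathway over-representation with BH correction, and expressed-target overlap
counts against cell-type gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .censored import bh_adjust

__all__ = [
    "GeneSetCollection",
    "filter_targets",
    "hypergeom_enrichment",
    "expressed_overlap",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are drawn from."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.universe = {_norm(g) for g in self.universe}
        self.sets = {name: {_norm(g) for g in s} for name, s in self.sets.items()}
        for name, s in self.sets.items():
            if not s <= self.universe:
                raise ValueError(f"gene set {name!r} is not contained in the universe")


def _norm(gene: str) -> str:
    return str(gene).strip().upper()


def filter_targets(
    records: pd.DataFrame,
    context_max: float = -0.3,
    aggregate_min: float = 0.3,
) -> set[str]:
    """Genes whose cumulative weighted context score is strictly below
    ``context_max`` and whose aggregate score is at least ``aggregate_min``.

    ``records`` needs columns ``gene``, ``context_score``, ``aggregate_score``.
    """
    keep = (records["context_score"] < context_max) & (
        records["aggregate_score"] >= aggregate_min
    )
    return {_norm(g) for g in records.loc[keep, "gene"]}


def hypergeom_enrichment(
    targets: set[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each gene set.

    With universe size N, set size K, target-list size n and overlap k, the
    p-value is P(X >= k) for X hypergeometric(N, K, n); p-values are
    BH-adjusted across sets.
    """
    if not collection.universe:
        raise ValueError("empty universe")
    targets = {_norm(g) for g in targets}
    if not targets <= collection.universe:
        raise ValueError("target set must be contained in the universe")
    N = len(collection.universe)
    n = len(targets)
    rows = []
    for name, s in collection.sets.items():
        K = len(s)
        k = len(targets & s)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "n_targets": n, "universe": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out.sort_values("p").reset_index(drop=True)


def expressed_overlap(
    targets: set[str],
    expressed: dict[str, set[str]],
    curated_sets: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Count predicted targets expressed in each cell type, in all cell
    types, and (optionally) cross-tabbed against curated gene sets.

    Gene identifiers are matched case-insensitively after whitespace
    stripping.  Returns one row per count with columns ``category`` and
    ``count`` plus ``n_targets`` for reference.
    """
    targets = {_norm(g) for g in targets}
    expressed = {ct: {_norm(g) for g in s} for ct, s in expressed.items()}
    rows = [{"category": "targets", "count": len(targets)}]
    both: set[str] | None = None
    for ct, s in expressed.items():
        inter = targets & s
        rows.append({"category": f"expressed_{ct}", "count": len(inter)})
        both = inter if both is None else (both & inter)
    if expressed:
        rows.append({"category": "expressed_all", "count": len(both or set())})
    if curated_sets:
        for name, s in curated_sets.items():
            s = {_norm(g) for g in s}
            rows.append({"category": f"targets_in_{name}", "count": len(targets & s)})
            for ct, e in expressed.items():
                rows.append(
                    {
                        "category": f"targets_in_{name}_expressed_{ct}",
                        "count": len(targets & s & e),
                    }
                )
    out = pd.DataFrame(rows)
    out["n_targets"] = len(targets)
    return out
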