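"""Gene-set overrepresentation with a direction-based activation score.

A generic stand-in for proprietary pathway software: one-sided hypergeometric
(Fisher) overrepresentation of a gene list against user-supplied sets, plus
an activation z-score summarizing directional consistency of the overlapping
genes, z = (n_up - n_down) / sqrt(n). Sets pass at activation z >= 1 and
p < 0.05 by default. The universe defaults to the genes analyzed by the
screen, matching the screening frame rather than the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EnrichmentResult", "fisher_ora", "activation_z", "enrich_table"]


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: tuple
    p_value: float
    activation_z: float
    passes: bool


def fisher_ora(gene_list, gene_set, universe) -> float:
    """One-sided hypergeometric upper tail P(X >= |list ∩ set|).

    Drawing |list| genes from a universe containing |set| marked genes.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    lst = set(gene_list)
    st = set(gene_set) & uni  # membership outside the universe is ignored
    if not lst <= uni:
        extra = sorted(lst - uni)[:5]
        raise ValueError(f"gene list not a subset of the universe (e.g. {extra})")
    k = len(lst & st)
    # survival function at k-1 gives P(X >= k)
    return float(stats.hypergeom.sf(k - 1, len(uni), len(st), len(lst)))


def activation_z(directions) -> float:
    """Direction-consistency score (n_up - n_down) / sqrt(n) for ±1 labels."""
    d = np.asarray(directions, dtype=float)
    if d.size == 0:
        raise ValueError("no directions")
    if not np.all(np.isin(d, (-1.0, 1.0))):
        raise ValueError("directions must be +1 or -1")
    return float((d == 1).sum() - (d == -1).sum()) / float(np.sqrt(d.size))


def enrich_table(gene_directions: dict, gene_sets: dict, universe,
                 z_min: float = 1.0, alpha: float = 0.05) -> pd.DataFrame:
    """Overrepresentation table: one row per set, sorted by p-value.

    ``gene_directions`` maps each list gene to ±1; ``passes`` applies both
    the activation z and p thresholds.
    """
    if not gene_sets:
        raise ValueError("no gene sets")
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    lst = list(gene_directions)
    rows = []
    for name, members in gene_sets.items():
        overlap = sorted(set(lst) & set(members) & uni)
        p = fisher_ora(lst, members, uni)
        if overlap:
            z = activation_z([gene_directions[g] for g in overlap])
        else:
            z = 0.0
        rows.append({
            "set": name,
            "n_set": len(set(members) & uni),
            "n_overlap": len(overlap),
            "overlap": ",".join(overlap),
            "p": p,
            "activation_z": z,
            "passes": bool(z >= z_min and p < alpha),
        })
    return (pd.DataFrame(rows)
            .sort_values("p", kind="stable")
            .reset_index(drop=True))
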