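"""Gene-set over-representation of screen hit lists.

One-sided Fisher exact test of each gene set against the hit list,
conditioned on the tested-gene universe (the genes that survived the
missingness filter), with Benjamini-Hochberg correction across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import read_gmt
from .multitest import bh_qvalues

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets intersected with a tested-gene universe; sets empty
    after intersection are dropped with a warning."""

    sets: dict[str, set]
    descriptions: dict[str, str]
    universe: set

    @classmethod
    def from_gmt(cls, path, universe) -> "GeneSetCollection":
        raw = read_gmt(path)
        return cls.from_dict(
            {name: rec["genes"] for name, rec in raw.items()},
            universe,
            descriptions={name: rec["description"] for name, rec in raw.items()},
        )

    @classmethod
    def from_dict(cls, sets: dict, universe, descriptions=None) -> "GeneSetCollection":
        universe = set(universe)
        kept, desc = {}, {}
        for name, genes in sets.items():
            members = set(genes) & universe
            if not members:
                logger.warning("gene set %r empty after universe intersection; dropped", name)
                continue
            kept[name] = members
            desc[name] = (descriptions or {}).get(name, "")
        return cls(sets=kept, descriptions=desc, universe=universe)


def enrich(hits, collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of ``hits`` in each set.

    hits must be a subset of the collection's universe. Returns a table
    sorted by p with columns (set, set_size, overlap, odds_ratio, p, p_bh).
    """
    hits = set(hits)
    stray = hits - collection.universe
    if stray:
        raise ValueError(f"hits not in universe: {sorted(stray)[:5]}")
    if not hits:
        logger.warning("empty hit list; enrichment result is empty")
        return pd.DataFrame(
            columns=["set", "description", "set_size", "overlap", "odds_ratio", "p", "p_bh"]
        ).set_index("set")
    n_univ = len(collection.universe)
    rows = []
    for name, members in collection.sets.items():
        k = len(hits & members)
        table = [
            [k, len(hits) - k],
            [len(members) - k, n_univ - len(members) - len(hits) + k],
        ]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "set": name,
                "description": collection.descriptions.get(name, ""),
                "set_size": len(members),
                "overlap": k,
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_qvalues(out["p"].to_numpy())
    return out.sort_values("p", kind="stable").set_index("set")
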