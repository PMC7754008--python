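"""Hub-gene and hub-lncRNA selection, Venn intersection, and pathway ORA.

Hub partners of an anchor gene are the features most strongly correlated
with it (ranked by |r|, Fig-4 style); hub lncRNAs are differential lncRNAs
whose signed correlation with the anchor exceeds a cutoff (default
r > 0.5), ranked two ways — ascending differential p-value and descending
baseMean — with the top-k lists intersected (the Venn selection).

Pathway over-representation is an upper-tail hypergeometric test of the
query set against each supplied gene set, BH-adjusted across pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PathwaySet
from .sponge import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class HubRanking:
    anchor_id: str
    partners: pd.DataFrame  # columns: feature_id, r; ordered by |r| desc
    k_top: int


@dataclass
class VennSelection:
    list_by_p: list[str]
    list_by_basemean: list[str]

    @property
    def intersection(self) -> set[str]:
        return set(self.list_by_p) & set(self.list_by_basemean)


def _anchor_correlations(anchor_id: str, expr: pd.DataFrame,
                         candidate_ids: list[str]) -> pd.Series:
    if anchor_id not in expr.index:
        raise KeyError(f"anchor {anchor_id!r} not in expression matrix")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = expr.loc[anchor_id].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("anchor has constant expression")
    cands = [c for c in candidate_ids if c != anchor_id and c in expr.index]
    y = expr.loc[cands].to_numpy(dtype=float)
    xc = x - x.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum()) * np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = yc @ xc / denom
    return pd.Series(np.where(np.isfinite(r), r, 0.0), index=cands, name="r")


def rank_correlated_partners(
    anchor_id: str,
    expr: pd.DataFrame,
    candidate_ids: list[str],
    k_top: int = 20,
) -> HubRanking:
    """Top-k candidates by |Pearson r| with the anchor, ties by id."""
    r = _anchor_correlations(anchor_id, expr, candidate_ids)
    order = sorted(r.index, key=lambda f: (-abs(r[f]), f))[:k_top]
    partners = pd.DataFrame({"feature_id": order, "r": [r[f] for f in order]})
    return HubRanking(anchor_id=anchor_id, partners=partners, k_top=k_top)


def select_hub_lncrnas(
    anchor_gene: str,
    de_lnc: pd.DataFrame,
    expr: pd.DataFrame,
    r_cutoff: float = 0.5,
    k_top: int = 20,
    de_p_threshold: float = 0.05,
) -> VennSelection:
    """Venn selection of hub lncRNAs tied to one anchor gene.

    Differential lncRNAs (raw p below ``de_p_threshold``) with signed
    correlation to the anchor above ``r_cutoff`` are ranked by ascending
    differential p-value and by descending baseMean; the two top-k lists
    and their intersection form the selection.
    """
    de_ids = de_lnc.index[de_lnc["p_value"] < de_p_threshold].tolist()
    r = _anchor_correlations(anchor_gene, expr, de_ids)
    passing = [f for f in r.index if r[f] > r_cutoff]
    if not passing:
        logger.warning("no lncRNA passes r > %g with anchor %s", r_cutoff, anchor_gene)
        return VennSelection(list_by_p=[], list_by_basemean=[])
    sub = de_lnc.loc[passing]
    by_p = sorted(passing, key=lambda f: (sub.loc[f, "p_value"], f))[:k_top]
    by_bm = sorted(passing, key=lambda f: (-sub.loc[f, "base_mean"], f))[:k_top]
    return VennSelection(list_by_p=by_p, list_by_basemean=by_bm)


def intersect_lists(lists: list[list[str]]) -> tuple[set[str], list[int]]:
    """Set intersection of two or more id lists, plus per-list exclusive
    counts (ids appearing in that list only) for the Venn rendering."""
    if len(lists) < 2:
        raise ValueError("need at least 2 lists")
    sets = [set(lst) for lst in lists]
    inter = set.intersection(*sets)
    exclusive = []
    for i, s in enumerate(sets):
        others = set().union(*(t for j, t in enumerate(sets) if j != i))
        exclusive.append(len(s - others))
    return inter, exclusive


def ora_enrichment(
    query: set[str],
    pathways: list[PathwaySet],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each pathway.

    Pathways are intersected with the universe first; p is the upper tail
    P(X >= overlap) with population |universe|, successes |pathway|,
    draws |query|.  Returns a table sorted by ascending p with BH-adjusted
    p across all pathways.
    """
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    n = len(universe)
    for ps in pathways:
        members = ps.members & universe
        if not members:
            continue
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, n, len(members), len(query)))
        rows.append({"pathway": ps.name, "overlap": k, "pathway_size": len(members),
                     "query_size": len(query), "p_value": min(max(p, 0.0), 1.0)})
    table = pd.DataFrame(rows, columns=["pathway", "overlap", "pathway_size",
                                        "query_size", "p_value"])
    if len(table):
        table["adj_p"] = bh_adjust(table["p_value"].to_numpy())
        table = table.sort_values(by=["p_value", "pathway"],
                                  kind="mergesort").reset_index(drop=True)
    else:
        table["adj_p"] = pd.Series(dtype=float)
    return table
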