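"""ceRNA sponge-pair inference.

For every candidate lncRNA-gene pair the module computes two p-values and
combines them:

* ``P1`` — significance of the number of miRNAs the pair shares, as the
  upper tail of the hypergeometric distribution (the one-tailed Fisher
  exact test on the 2x2 membership table);
* ``P2`` — significance of the Pearson correlation of the pair's
  expression across all samples;
* combined via Fisher's sum-of-logs method (chi-square with 4 df), then
  Benjamini-Hochberg adjusted across every enumerated pair.

A pair passes when its FDR is at most 5%, it shares at least ten distinct
miRNAs, and the pair correlation exceeds r = 0.25 — with candidate
lncRNAs, genes and the miRNA universe all pre-filtered to differential
features (raw p < 0.05).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CeRNANetwork, TargetMap

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class SpongeThresholds:
    """Hard filters of the pair-calling step (defaults as published)."""

    min_shared: int = 10       # inclusive: k >= 10
    min_r: float = 0.25        # exclusive: r > 0.25
    fdr: float = 0.05          # inclusive: FDR <= 0.05
    de_p: float = 0.05         # exclusive: feature DE p < 0.05


def shared_mirna_test(
    mirnas_of_lnc: set[str], mirnas_of_gene: set[str], universe: set[str]
) -> tuple[int, float]:
    """Upper-tail hypergeometric test on the shared-miRNA count.

    Population = the miRNA universe, successes = miRNAs of one member,
    draws = miRNAs of the other; the upper tail P(X >= k) is symmetric in
    the two sets so the margin assignment is immaterial.
    """
    if not universe:
        raise ValueError("empty miRNA universe")
    s1 = mirnas_of_lnc & universe
    s2 = mirnas_of_gene & universe
    k = len(s1 & s2)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(s1), len(s2)))
    return k, min(max(p, 0.0), 1.0)


def correlation_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with its two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no defined correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fisher_combine(p1: float, p2: float) -> float:
    """Fisher's sum-of-logs combination of two independent p-values.

    X = -2(ln p1 + ln p2) is chi-square with 4 df under the null; the
    survival function has the closed form exp(-X/2) * (1 + X/2).
    """
    ps = []
    for p in (p1, p2):
        if not (0 <= p <= 1):
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p <= 0:
            warnings.warn("p-value of 0 clamped for Fisher combination", stacklevel=2)
            p = _P_FLOOR
        ps.append(p)
    x = -2.0 * (np.log(ps[0]) + np.log(ps[1]))
    return float(stats.chi2.sf(x, df=4))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def pair_passes(fdr: float, k: int, corr_r: float,
                thresholds: SpongeThresholds = SpongeThresholds()) -> bool:
    """The published pair filter: FDR <= 5% (inclusive), shared miRNAs
    k >= 10 (inclusive), pair correlation r > 0.25 (strict)."""
    return bool(fdr <= thresholds.fdr
                and k >= thresholds.min_shared
                and corr_r > thresholds.min_r)


def _de_ids(table: pd.DataFrame, p_threshold: float) -> list[str]:
    return table.index[table["p_value"] < p_threshold].tolist()


def call_sponge_pairs(
    de_lnc: pd.DataFrame,
    de_mrna: pd.DataFrame,
    de_mirna: pd.DataFrame,
    expr: pd.DataFrame,
    targets: TargetMap,
    thresholds: SpongeThresholds = SpongeThresholds(),
    universe: str = "de",
    seed_families: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Enumerate and score all differential lncRNA x gene candidate pairs.

    Parameters
    ----------
    de_lnc, de_mrna, de_mirna
        Differential tables indexed by feature id with a ``p_value`` column.
    expr
        log2(normalized + 1) expression, features x samples, covering all
        candidate lncRNAs and genes across both groups.
    targets
        miRNA -> target interaction map.
    universe
        ``"de"`` restricts the miRNA universe to differential miRNAs that
        appear in the target map (default); ``"all"`` uses every target-map
        miRNA.
    seed_families
        Optional miRNA id -> seed-family map; members of one family are
        collapsed before counting shared miRNAs.

    Returns
    -------
    DataFrame with one row per enumerated pair, sorted by (fdr, -k, ids),
    columns: lncrna_id, gene_id, shared_mirnas, k, p_shared, corr_r,
    p_corr, p_combined, fdr, passes.
    """
    if universe == "de":
        uni = set(_de_ids(de_mirna, thresholds.de_p)) & targets.universe
    elif universe == "all":
        uni = targets.universe
    else:
        raise ValueError(f"unknown universe mode {universe!r}")

    lnc_ids = [f for f in _de_ids(de_lnc, thresholds.de_p) if f in expr.index]
    gene_ids = [f for f in _de_ids(de_mrna, thresholds.de_p) if f in expr.index]
    if not lnc_ids or not gene_ids or not uni:
        logger.warning(
            "empty candidate set (%d lncRNAs, %d genes, %d universe miRNAs)",
            len(lnc_ids), len(gene_ids), len(uni),
        )
        return pd.DataFrame(
            columns=["lncrna_id", "gene_id", "shared_mirnas", "k", "p_shared",
                     "corr_r", "p_corr", "p_combined", "fdr", "passes"]
        )

    def collapse(mirnas: set[str]) -> set[str]:
        if seed_families is None:
            return mirnas
        return {seed_families.get(m, m) for m in mirnas}

    family_universe = collapse(uni)
    rows = []
    for lnc in lnc_ids:
        m_lnc = collapse(targets.mirnas_of(lnc) & uni)
        x = expr.loc[lnc].to_numpy(dtype=float)
        for gene in gene_ids:
            m_gene = collapse(targets.mirnas_of(gene) & uni)
            shared = sorted(m_lnc & m_gene)
            k, p_shared = shared_mirna_test(m_lnc, m_gene, family_universe)
            y = expr.loc[gene].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p_corr = 0.0, 1.0
            else:
                r, p_corr = correlation_test(x, y)
            p_comb = fisher_combine(max(p_shared, _P_FLOOR), max(p_corr, _P_FLOOR))
            rows.append({
                "lncrna_id": lnc, "gene_id": gene,
                "shared_mirnas": ",".join(shared), "k": k,
                "p_shared": p_shared, "corr_r": r, "p_corr": p_corr,
                "p_combined": max(p_comb, _P_FLOOR),
            })
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p_combined"].to_numpy())
    table["passes"] = [
        pair_passes(f, k, r, thresholds)
        for f, k, r in zip(table["fdr"], table["k"], table["corr_r"])
    ]
    table = table.sort_values(
        by=["fdr", "k", "lncrna_id", "gene_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    logger.info("scored %d pairs, %d passing", len(table), int(table["passes"].sum()))
    return table


def rank_mediators(
    pair: pd.Series,
    de_mirna: pd.DataFrame,
    expr: pd.DataFrame,
    k_top: int = 20,
    rank_key: str = "p_value",
) -> pd.DataFrame:
    """Order a passing pair's shared miRNAs and keep the top ``k_top``.

    ``rank_key="p_value"`` sorts by the miRNA's differential p ascending;
    ``rank_key="corr_r"`` sorts by the magnitude of the miRNA's mean
    correlation to the two pair members, descending.  Ties break
    lexicographically by id.
    """
    if rank_key not in ("p_value", "corr_r"):
        raise ValueError(f"unknown rank key {rank_key!r}")
    shared = [m for m in str(pair["shared_mirnas"]).split(",") if m]
    x_lnc = expr.loc[pair["lncrna_id"]].to_numpy(dtype=float)
    x_gene = expr.loc[pair["gene_id"]].to_numpy(dtype=float)
    rows = []
    for m in shared:
        de_p = float(de_mirna.loc[m, "p_value"]) if m in de_mirna.index else float("nan")
        if m in expr.index:
            xm = expr.loc[m].to_numpy(dtype=float)
            r_lnc = _safe_r(xm, x_lnc)
            r_gene = _safe_r(xm, x_gene)
        else:
            r_lnc = r_gene = float("nan")
        rows.append({"mirna_id": m, "de_p": de_p, "r_lnc": r_lnc, "r_gene": r_gene})
    med = pd.DataFrame(rows, columns=["mirna_id", "de_p", "r_lnc", "r_gene"])
    if med.empty:
        return med
    if rank_key == "p_value":
        med["_key"] = med["de_p"]
        ascending = True
    else:
        med["_key"] = -med[["r_lnc", "r_gene"]].abs().mean(axis=1)
        ascending = True
    med = med.sort_values(by=["_key", "mirna_id"], ascending=[ascending, True],
                          kind="mergesort").drop(columns="_key")
    return med.head(k_top).reset_index(drop=True)


def _safe_r(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def assemble_network(
    pairs: pd.DataFrame, mediators: dict[tuple[str, str], pd.DataFrame]
) -> CeRNANetwork:
    """Build the triplet network from passing pairs and their top mediators."""
    net = CeRNANetwork()
    for _, pair in pairs[pairs["passes"]].iterrows():
        key = (pair["lncrna_id"], pair["gene_id"])
        med = mediators.get(key)
        if med is None:
            continue
        for _, m in med.iterrows():
            net.triplets.append({
                "lncrna": pair["lncrna_id"],
                "mirna": m["mirna_id"],
                "mrna": pair["gene_id"],
                "mirna_de_p": float(m["de_p"]),
                "r_lnc": float(m["r_lnc"]),
                "r_mrna": float(m["r_gene"]),
            })
    return net
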