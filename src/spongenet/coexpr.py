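"""Weighted co-expression network core: adjacency, TOM, modules, eigengenes.

The chain mirrors the standard weighted gene co-expression analysis recipe:
Pearson correlation of log-scale expression; soft-thresholding of the
correlation (unsigned, a_ij = |r_ij|^beta, with a signed variant) at a
power chosen by scale-free topology fit; transformation to the topological
overlap matrix

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu;

average-linkage hierarchical clustering of 1 - TOM with a static cut
(dynamic hybrid tree cutting is deliberately out of scope; cut height and
minimum module size are exposed instead); size-ordered colour naming with
"grey" for unassigned genes; module eigengenes as the first principal
component of the gene-standardized module expression; and point-biserial
module-trait correlation against the binary condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

# WGCNA's conventional size-ordered palette; "grey" is reserved for
# unassigned genes.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)
UNASSIGNED = "grey"


def correlation_matrix(expr: pd.DataFrame, drop_constant: bool = True) -> pd.DataFrame:
    """Pearson correlation between all gene pairs (genes x samples input)."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    values = expr.to_numpy(dtype=float)
    constant = values.std(axis=1) == 0
    if constant.any():
        if not drop_constant:
            raise ValueError("zero-variance genes present")
        logger.warning("dropping %d zero-variance genes", int(constant.sum()))
        expr = expr.loc[~constant]
        values = expr.to_numpy(dtype=float)
    corr = np.corrcoef(values)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=expr.index, columns=expr.index)


def adjacency(corr: pd.DataFrame, beta: int = 6, signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded adjacency: |r|^beta (unsigned) or ((1+r)/2)^beta."""
    if beta < 1:
        raise ValueError("soft-threshold power must be >= 1")
    r = corr.to_numpy(dtype=float)
    a = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=corr.index, columns=corr.columns)


def scale_free_fit(adj: pd.DataFrame, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index for one adjacency matrix.

    Connectivities are binned; the fit is the squared correlation between
    log10(mean connectivity per bin) and log10(bin frequency), negated when
    the log-log slope is positive (the signed convention, so only
    decreasing degree distributions score well).
    """
    a = adj.to_numpy(dtype=float)
    k = a.sum(axis=0) - np.diag(a)
    return scale_free_fit_from_connectivity(k, n_bins=n_bins)


def scale_free_fit_from_connectivity(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free fit from a vector of node connectivities."""
    k = np.asarray(k, dtype=float)
    if np.ptp(k) == 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins).astype(float)
    mean_k = np.array([k[which == b].mean() if freq[b] else np.nan for b in range(n_bins)])
    ok = (freq > 0) & (mean_k > 0)
    if ok.sum() < 3:
        return float("nan")
    log_k = np.log10(mean_k[ok])
    log_p = np.log10(freq[ok] / freq[ok].sum())
    slope, _, r, _, _ = stats.linregress(log_k, log_p)
    return float(-np.sign(slope) * r**2)


def pick_soft_threshold(
    corr: pd.DataFrame,
    powers: range = range(1, 21),
    r2_target: float = 0.8,
    signed: bool = False,
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose signed scale-free fit reaches ``r2_target``.

    Falls back to the argmax power (with a warning) when no power reaches
    the target, and to beta = 6 when every fit is degenerate.
    """
    if corr.shape[0] < 20:
        raise ValueError("soft-threshold selection needs at least 20 genes")
    rows = []
    for beta in powers:
        adj = adjacency(corr, beta=beta, signed=signed)
        fit = scale_free_fit(adj)
        k = adj.to_numpy().sum(axis=0) - 1.0
        rows.append({"power": beta, "sft_r2": fit,
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    table = pd.DataFrame(rows)
    fits = table["sft_r2"]
    if fits.isna().all():
        logger.warning("degenerate connectivity at every power; falling back to beta=6")
        return 6, table
    reached = table[fits >= r2_target]
    if len(reached):
        beta = int(reached["power"].iloc[0])
    else:
        beta = int(table.loc[fits.idxmax(), "power"])
        logger.warning("no power reached scale-free fit %.2f; using argmax beta=%d",
                       r2_target, beta)
    return beta, table


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency with unit diagonal."""
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    # l_ij over u != i, j: (A @ A) includes u = i and u = j, each a_ij * 1
    l = a @ a - 2.0 * a  # valid because diag(a) == 1
    k = a.sum(axis=0) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.995,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static branch cut.

    Clusters smaller than ``min_module_size`` fall into "grey"; surviving
    modules are colour-named in decreasing size order.
    """
    genes = tom.index
    n = len(genes)
    if n < min_module_size:
        return pd.Series([UNASSIGNED] * n, index=genes, name="module")
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].index
    # name modules by decreasing size, ties by first occurrence
    ordered = sorted(keep, key=lambda c: (-sizes[c], list(raw).index(c)))
    names: dict[int, str] = {}
    for i, c in enumerate(ordered):
        names[c] = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module_{i + 1}"
    labels = [names.get(c, UNASSIGNED) for c in raw]
    out = pd.Series(labels, index=genes, name="module")
    logger.info("detected %d modules (+%d grey genes) at cut %.3f, min size %d",
                len(ordered), int((out == UNASSIGNED).sum()), cut_height, min_module_size)
    return out


@dataclass
class ModulePartition:
    """Module labels, eigengenes, and their correlation to the condition."""

    labels: pd.Series                 # gene -> colour
    eigengenes: pd.DataFrame          # modules x samples, unit variance
    variance_explained: pd.Series     # module -> fraction in [0, 1]
    trait_correlations: pd.DataFrame | None = None  # module -> (r, p)


def module_eigengene(
    expr: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component of each module's standardized expression.

    Each eigengene is unit-variance (ddof=1) and sign-oriented so its mean
    correlation with the module's genes is positive.  Returns (eigengenes,
    variance_explained).
    """
    modules = [m for m in labels.unique() if m != UNASSIGNED]
    me_rows, ve = {}, {}
    for mod in modules:
        genes = labels.index[labels == mod]
        if len(genes) < 2:
            raise ValueError(f"module {mod!r} has fewer than 2 genes")
        x = expr.loc[genes].to_numpy(dtype=float)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        if (sd == 0).any():
            raise ValueError(f"zero-variance gene in module {mod!r}")
        z = (x - x.mean(axis=1, keepdims=True)) / sd
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        me = me / me.std(ddof=1)
        # orient: average correlation with module genes positive
        if np.mean([np.corrcoef(me, row)[0, 1] for row in z]) < 0:
            me = -me
        me_rows[mod] = me
        ve[mod] = float(s[0] ** 2 / (s**2).sum())
    eigengenes = pd.DataFrame(me_rows, index=expr.columns).T
    return eigengenes, pd.Series(ve, name="variance_explained")


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait: pd.Series
) -> pd.DataFrame:
    """Point-biserial correlation of each eigengene with the 0/1 condition."""
    t = trait.loc[eigengenes.columns].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("trait is constant across samples")
    rows = {}
    for mod in eigengenes.index:
        r, p = stats.pearsonr(eigengenes.loc[mod].to_numpy(dtype=float), t)
        rows[mod] = {"r": float(r), "p": float(p)}
    return pd.DataFrame(rows).T[["r", "p"]]


def run_wgcna(
    expr: pd.DataFrame,
    trait: pd.Series,
    beta: int | None = None,
    signed: bool = False,
    min_module_size: int = 30,
    cut_height: float = 0.995,
    r2_target: float = 0.8,
) -> tuple[ModulePartition, pd.DataFrame | None]:
    """Full chain: correlation -> power -> adjacency -> TOM -> modules -> ME.

    When ``beta`` is None the power is chosen by scale-free fit; the fit
    table is returned alongside the partition (None when beta was given).
    """
    corr = correlation_matrix(expr)
    fit_table = None
    if beta is None:
        beta, fit_table = pick_soft_threshold(corr, r2_target=r2_target, signed=signed)
    adj = adjacency(corr, beta=beta, signed=signed)
    tom = tom_similarity(adj)
    labels = detect_modules(tom, min_module_size=min_module_size, cut_height=cut_height)
    expr = expr.loc[corr.index]  # constant genes may have been dropped
    if (labels != UNASSIGNED).any():
        eigengenes, ve = module_eigengene(expr, labels)
        trait_corr = module_trait_correlation(eigengenes, trait)
    else:
        eigengenes = pd.DataFrame(columns=expr.columns)
        ve = pd.Series(dtype=float, name="variance_explained")
        trait_corr = pd.DataFrame(columns=["r", "p"])
    part = ModulePartition(labels=labels, eigengenes=eigengenes,
                           variance_explained=ve, trait_correlations=trait_corr)
    return part, fit_table
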