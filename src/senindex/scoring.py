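"""Per-cell gene-signature scoring.

Two scorers, covering the two mechanisms the pipeline needs:

* :func:`module_score` — signature mean expression minus the mean of control
  genes drawn from expression-matched bins. The control pool corrects for
  the fact that highly expressed genes score high on any average; drawing
  controls from each signature gene's own expression bin makes the null
  score zero in expectation.

* :func:`ssgsea_score` — a single-sample, rank-based enrichment score. Per
  cell, genes are ranked by expression; walking the ranked list from the
  top, an in-set running sum (weighted by rank^alpha) is compared with a
  uniform out-of-set running sum, and the score is the sum of their
  differences over all list positions. Being a function of ranks only, it
  is invariant to monotone transforms of a cell's expression vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .io import GeneSet, NormalizedMatrix, SignatureRegistry

logger = logging.getLogger(__name__)

__all__ = ["ModuleScoreParams", "SsgseaParams", "module_score", "ssgsea_score",
           "ssgsea_score_sets", "score_panel"]


@dataclass
class ModuleScoreParams:
    n_bins: int = 25
    n_ctrl_per_gene: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.n_ctrl_per_gene < 1:
            raise ValueError("n_bins and n_ctrl_per_gene must be >= 1")


@dataclass
class SsgseaParams:
    weight_exponent: float = 0.25
    normalize_across_cells: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight_exponent) or self.weight_exponent < 0:
            raise ValueError("weight_exponent must be finite and >= 0")


def _bin_assignments(gene_means: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-size expression bins: genes sorted by mean, split into n_bins
    contiguous groups (cut_number-style)."""
    n = len(gene_means)
    order = np.argsort(gene_means, kind="stable")
    bins = np.empty(n, dtype=np.int64)
    # sizes differ by at most one
    splits = np.array_split(np.arange(n), min(n_bins, n))
    for b, idx in enumerate(splits):
        bins[order[idx]] = b
    return bins


def module_score(
    nm: NormalizedMatrix, sig: GeneSet, p: ModuleScoreParams | None = None
) -> np.ndarray:
    """Binned-control module score per cell.

    For each signature gene, controls are drawn from its expression bin
    (excluding signature genes); when the requested number of draws meets or
    exceeds the pool size the entire pool is used, which makes small-panel
    scores exactly mean(signature) - mean(complement). The score is the
    per-cell mean over signature genes minus the mean over the pooled
    control draws. Deterministic given ``p.seed``.
    """
    p = p or ModuleScoreParams()
    sig = sig.intersect(nm.gene_ids)
    sig_idx = np.array([nm.gene_ids.get_loc(g) for g in sig.genes])
    if len(sig_idx) == nm.n_genes:
        raise ValueError(
            f"signature {sig.name!r} covers the whole panel; no control genes remain"
        )

    gene_means = np.asarray(nm.X.mean(axis=0)).ravel()
    # keep bins populated on small panels: average bin size >= 10 genes
    eff_bins = min(p.n_bins, max(1, nm.n_genes // 10))
    if eff_bins < p.n_bins:
        logger.warning(
            "panel of %d genes too small for %d bins; using %d",
            nm.n_genes, p.n_bins, eff_bins,
        )
    bins = _bin_assignments(gene_means, eff_bins)
    in_sig = np.zeros(nm.n_genes, dtype=bool)
    in_sig[sig_idx] = True

    rng = np.random.default_rng(p.seed)
    ctrl_idx_parts: list[np.ndarray] = []
    for j in sig_idx:
        pool = np.flatnonzero((bins == bins[j]) & ~in_sig)
        if pool.size == 0:
            raise ValueError(
                f"signature gene {nm.gene_ids[j]!r}: its expression bin has no "
                "control genes outside the signature"
            )
        if p.n_ctrl_per_gene >= pool.size:
            ctrl_idx_parts.append(pool)
        else:
            ctrl_idx_parts.append(rng.choice(pool, size=p.n_ctrl_per_gene, replace=True))
    ctrl_idx = np.concatenate(ctrl_idx_parts)

    sig_mean = np.asarray(nm.X[:, sig_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(nm.X[:, ctrl_idx].mean(axis=1)).ravel()
    return sig_mean - ctrl_mean


def _ssgsea_raw(expr: np.ndarray, in_set: np.ndarray, alpha: float) -> np.ndarray:
    """Raw ssGSEA running-sum scores for one gene set.

    expr: cells x genes dense array; in_set: boolean per gene.
    Ranks are ascending with average ties (top gene has rank G); the walk is
    in descending expression order, stable in gene index within ties.
    """
    n_cells, n_genes = expr.shape
    n_in = int(in_set.sum())
    n_out = n_genes - n_in
    if n_in == 0 or n_out == 0:
        raise ValueError("gene set must be a proper non-empty subset of the panel")

    ranks = rankdata(expr, axis=1, method="average")
    weights = np.abs(ranks) ** alpha
    # walk order: descending expression, gene index breaks ties
    order = np.argsort(-expr, axis=1, kind="stable")

    rows = np.arange(n_cells)[:, None]
    w_ord = weights[rows, order]
    in_ord = in_set[order]

    w_in = np.where(in_ord, w_ord, 0.0)
    denom = w_in.sum(axis=1, keepdims=True)
    ecdf_in = np.cumsum(w_in, axis=1) / denom
    ecdf_out = np.cumsum(np.where(in_ord, 0.0, 1.0), axis=1) / n_out
    return (ecdf_in - ecdf_out).sum(axis=1)


def ssgsea_score(
    nm: NormalizedMatrix, gs: GeneSet, p: SsgseaParams | None = None
) -> np.ndarray:
    """Single-sample GSEA score of one gene set per cell.

    When ``p.normalize_across_cells`` is set, raw scores are divided by the
    (max - min) over the scores computed in this call.
    """
    p = p or SsgseaParams()
    gs = gs.intersect(nm.gene_ids)
    in_set = np.asarray(nm.gene_ids.isin(gs.genes))
    raw = _ssgsea_raw(nm.dense(), in_set, p.weight_exponent)
    if p.normalize_across_cells:
        span = raw.max() - raw.min()
        if span > 0:
            raw = raw / span
    return raw


def ssgsea_score_sets(
    nm: NormalizedMatrix, sets: list[GeneSet], p: SsgseaParams | None = None
) -> pd.DataFrame:
    """ssGSEA scores for several gene sets; range normalization is global
    over the whole score matrix of the call, as in multi-set GSVA runs."""
    p = p or SsgseaParams()
    expr = nm.dense()
    cols = {}
    for gs in sets:
        gsx = gs.intersect(nm.gene_ids)
        in_set = np.asarray(nm.gene_ids.isin(gsx.genes))
        cols[gs.name] = _ssgsea_raw(expr, in_set, p.weight_exponent)
    df = pd.DataFrame(cols, index=nm.cell_ids)
    if p.normalize_across_cells and df.size:
        span = df.to_numpy().max() - df.to_numpy().min()
        if span > 0:
            df = df / span
    return df


def score_panel(
    nm: NormalizedMatrix,
    registry: SignatureRegistry | None = None,
    gmt_sets: list[GeneSet] | None = None,
    module_params: ModuleScoreParams | None = None,
    ssgsea_params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """Batch scoring: module scores for registry signatures, ssGSEA for GMT
    sets. One column per signature, one row per cell."""
    out = pd.DataFrame(index=nm.cell_ids)
    registry = registry or {}
    gmt_sets = gmt_sets or []
    if not registry and not gmt_sets:
        logger.warning("score_panel called with no signatures; empty table returned")
        return out
    for name, gs in registry.items():
        out[name] = module_score(nm, gs, module_params)
    if gmt_sets:
        ss = ssgsea_score_sets(nm, gmt_sets, ssgsea_params)
        for c in ss.columns:
            out[c] = ss[c].to_numpy()
    return out
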