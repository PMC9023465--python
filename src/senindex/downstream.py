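"""Downstream analyses on SIT labels.

* Wilcoxon rank-sum differential expression between senescent and
  non-senescent cells, with Benjamini-Hochberg FDR and a minimum-detection
  filter (a gene must be expressed in at least 30% of cells of one group).
* A pro-survival correlation screen: Pearson correlation of each candidate
  survival gene with the three composite senescence scores; genes pass at
  r > 0.4 against all three and BH-FDR < 0.05 within each score family.
* Stratification of senescent cells by Bcl2 (median split) and Mcl1
  (lower-quartile split: Mcl1+ covers the upper three quartile intervals),
  the grouping behind senolytic-target comparisons.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSet, NormalizedMatrix, builtin_signatures

logger = logging.getLogger(__name__)

__all__ = ["bh_adjust", "wilcoxon_de", "exact_rank_sum_p",
           "survival_correlation_screen", "default_survival_panel",
           "stratify_bcl2_mcl1"]

_LFC_PSEUDOCOUNT = 1e-9


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Wilcoxon rank-sum p-value by exhaustive enumeration.

    Enumerates all C(n1+n2, n1) assignments of the pooled (average-tie)
    ranks to group 1 and counts assignments whose rank-sum deviates from the
    null mean at least as much as the observed one. Handles ties exactly;
    intended for small groups (n1, n2 <= 10).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    obs = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    dev = abs(obs - mu)
    total = 0
    hits = 0
    for comb in combinations(range(n1 + n2), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def _rank_sum_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 10) -> float:
    """Two-sided rank-sum p: exact enumeration for small groups, otherwise
    the tie-corrected normal approximation (with continuity correction)."""
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        return exact_rank_sum_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def wilcoxon_de(
    nm: NormalizedMatrix,
    group_labels: np.ndarray,
    min_pct: float = 0.30,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE of group True vs group False.

    Genes are tested only if detected in at least ``min_pct`` of the cells
    of at least one group. Log fold change is the natural log of the ratio
    of group means of expm1(normalized expression), with a small
    pseudocount. BH adjustment is applied across the tested genes only.

    Returns one row per tested gene: gene, log_fc, pct_group1, pct_group2,
    p_value, fdr, significant.
    """
    group_labels = np.asarray(group_labels, dtype=bool)
    if group_labels.size != nm.n_cells:
        raise ValueError("group_labels length must equal the number of cells")
    n1, n2 = int(group_labels.sum()), int((~group_labels).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")

    X = nm.dense()
    g1, g2 = X[group_labels], X[~group_labels]
    pct1 = (g1 > 0).mean(axis=0)
    pct2 = (g2 > 0).mean(axis=0)
    testable = (pct1 >= min_pct) | (pct2 >= min_pct)
    if not testable.any():
        logger.warning("no gene passes the %.0f%% detection filter", 100 * min_pct)
        return pd.DataFrame(
            columns=["gene", "log_fc", "pct_group1", "pct_group2",
                     "p_value", "fdr", "significant"]
        )

    idx = np.flatnonzero(testable)
    pvals = np.empty(idx.size)
    lfc = np.empty(idx.size)
    for i, j in enumerate(idx):
        a, b = g1[:, j], g2[:, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[i] = 1.0
        else:
            pvals[i] = _rank_sum_p(a, b)
        m1 = np.expm1(a).mean() + _LFC_PSEUDOCOUNT
        m2 = np.expm1(b).mean() + _LFC_PSEUDOCOUNT
        lfc[i] = np.log(m1 / m2)
    fdr = bh_adjust(pvals)
    out = pd.DataFrame({
        "gene": nm.gene_ids[idx],
        "log_fc": lfc,
        "pct_group1": pct1[idx],
        "pct_group2": pct2[idx],
        "p_value": pvals,
        "fdr": fdr,
    })
    out["significant"] = out["fdr"] < fdr_cut
    return out.reset_index(drop=True)


def default_survival_panel() -> GeneSet:
    """Default pro-survival candidate panel: the union of the apoptosis,
    necroptosis, ferroptosis, parthanatos and pyroptosis signature lists.
    The screen is config-sensitive; supply a curated panel to override."""
    reg = builtin_signatures()
    genes: list[str] = []
    for name in ("anti_apoptosis", "pro_apoptosis", "necroptosis",
                 "ferroptosis", "parthanatos", "pyroptosis"):
        for g in reg[name].genes:
            if g not in genes:
                genes.append(g)
    return GeneSet("survival_panel", genes, source="builtin")


def survival_correlation_screen(
    nm: NormalizedMatrix,
    scores: pd.DataFrame,
    survival_genes: GeneSet | None = None,
    r_threshold: float = 0.4,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pearson-correlation screen of survival genes against the three
    composite senescence scores.

    ``scores`` must carry columns score_K, score_R, score_WP aligned to the
    cells of ``nm``. Two-sided t-test p-values are BH-adjusted within each
    score family. A gene passes iff r > r_threshold for all three scores
    and every FDR < fdr_threshold. Zero-variance genes report NaN and never
    pass.
    """
    survival_genes = survival_genes or default_survival_panel()
    panel = survival_genes.intersect(nm.gene_ids)
    if len(scores) != nm.n_cells:
        raise ValueError("score table must align with the expression matrix cells")

    keys = ("K", "R", "WP")
    rows = {g: {} for g in panel.genes}
    pvals = {k: [] for k in keys}
    for g in panel.genes:
        expr = nm.gene_vector(g)
        constant = np.all(expr == expr[0])
        for k in keys:
            s = scores[f"score_{k}"].to_numpy(dtype=float)
            if constant or np.all(s == s[0]):
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(expr, s)
            rows[g][f"r_{k}"] = r
            pvals[k].append(p)

    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    for k in keys:
        p = np.asarray(pvals[k], dtype=float)
        fdr = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            fdr[ok] = bh_adjust(p[ok])
        out[f"fdr_{k}"] = fdr
    r_cols = [f"r_{k}" for k in keys]
    f_cols = [f"fdr_{k}" for k in keys]
    out["passes"] = (
        out[r_cols].notna().all(axis=1)
        & (out[r_cols].min(axis=1) > r_threshold)
        & (out[f_cols].max(axis=1) < fdr_threshold)
    )
    return out.reset_index()


def stratify_bcl2_mcl1(
    nm: NormalizedMatrix,
    sit_labels: np.ndarray,
    bcl2_gene: str = "Bcl2",
    mcl1_gene: str = "Mcl1",
    mcl1_positive_quartiles: str = "upper",
) -> pd.DataFrame:
    """Classify senescent cells by Bcl2 and Mcl1 expression.

    Bcl2+ means expression strictly above the median over senescent cells.
    Mcl1+ covers three of the four quartile intervals: "upper" (default)
    calls cells above Q1 positive; "lower" calls cells at or below Q3
    positive. Thresholds are computed over senescent cells only and
    recorded in the output attrs.

    Returns a table over senescent cells: cell_id, bcl2_class, mcl1_class,
    joint_class.
    """
    sit_labels = np.asarray(sit_labels, dtype=bool)
    if sit_labels.size != nm.n_cells:
        raise ValueError("sit_labels length must equal the number of cells")
    for g in (bcl2_gene, mcl1_gene):
        if g not in nm.gene_ids:
            raise ValueError(f"required gene {g!r} absent from the expression panel")
    if not sit_labels.any():
        raise ValueError("no senescent cells to stratify")

    sen = nm.subset_cells(sit_labels)
    bcl2 = sen.gene_vector(bcl2_gene)
    mcl1 = sen.gene_vector(mcl1_gene)

    bcl2_cut = float(np.median(bcl2))
    bcl2_pos = bcl2 > bcl2_cut
    if mcl1_positive_quartiles == "upper":
        mcl1_cut = float(np.quantile(mcl1, 0.25))
        mcl1_pos = mcl1 > mcl1_cut
    elif mcl1_positive_quartiles == "lower":
        mcl1_cut = float(np.quantile(mcl1, 0.75))
        mcl1_pos = mcl1 <= mcl1_cut
    else:
        raise ValueError("mcl1_positive_quartiles must be 'upper' or 'lower'")
    if np.all(mcl1 == mcl1[0]):
        logger.warning("Mcl1 expression constant over senescent cells; "
                       "all cells classify negative under the strict rule")

    out = pd.DataFrame({
        "cell_id": sen.cell_ids,
        "bcl2_class": np.where(bcl2_pos, "pos", "neg"),
        "mcl1_class": np.where(mcl1_pos, "pos", "neg"),
    })
    out["joint_class"] = (
        "Bcl2" + np.where(bcl2_pos, "+", "-") + "Mcl1" + np.where(mcl1_pos, "+", "-")
    )
    out.attrs["bcl2_threshold"] = bcl2_cut
    out.attrs["mcl1_threshold"] = mcl1_cut
    out.attrs["mcl1_positive_quartiles"] = mcl1_positive_quartiles
    return out
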