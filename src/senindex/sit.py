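"""The Senescence Index Tool (SIT).

Senescent tumor cells share two transcriptional features: overexpression of
canonical senescence markers (Cdkn2a/p16, Cdkn2b/p15, Cdkn1a/p21,
Cdkn1b/p27, Serpine1/PAI-1) and cell-cycle arrest. SIT composes both:

1. a binned-control module score of the senescence marker signature;
2. per-cell ssGSEA against three cell-cycle collections (KEGG, Reactome,
   WikiPathways), inverted so that low cell-cycle activity scores high::

       arrest_i = -ssgsea_i,            i in {K, R, WP}

3. composite senescence scores, each term min-max normalized to [0, 1]
   across the scored population::

       score_i = minmax(arrest_i) + minmax(senescence_signature)

4. a cell is called senescent iff its score is in the fourth (highest)
   quartile of score_K AND score_R AND score_WP.

The quartile cut uses the type-7 (linear interpolation) quantile, and a
score equal to Q3 counts as fourth quartile, so each marginal passes at
least 25% of cells; the three-way intersection is what makes the final
labeled fraction conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSet, NormalizedMatrix, builtin_signatures
from .scoring import ModuleScoreParams, SsgseaParams, module_score, ssgsea_score_sets

logger = logging.getLogger(__name__)

__all__ = ["SitParams", "minmax_normalize", "arrest_signature",
           "senescence_score", "classify_senescent", "run_sit"]

SCORE_KEYS = ("K", "R", "WP")


@dataclass
class SitParams:
    """Scoring knobs for one SIT run; seeds fan out from ``seed``."""

    seed: int = 0
    n_bins: int = 25
    n_ctrl_per_gene: int = 100
    weight_exponent: float = 0.25
    per_sample: bool = False
    senescence_signature: GeneSet | None = None

    def module_params(self) -> ModuleScoreParams:
        return ModuleScoreParams(self.n_bins, self.n_ctrl_per_gene, self.seed)

    def ssgsea_params(self) -> SsgseaParams:
        return SsgseaParams(self.weight_exponent, True)


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); a constant vector maps to all zeros."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot min-max normalize an empty vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    span = x.max() - x.min()
    if span == 0:
        return np.zeros_like(x)
    return (x - x.min()) / span


def arrest_signature(ssgsea_scores: np.ndarray) -> np.ndarray:
    """Invert a cell-cycle ssGSEA score into a cell-cycle *arrest* score."""
    return -np.asarray(ssgsea_scores, dtype=float)


def senescence_score(arrest: np.ndarray, sen_sig: np.ndarray) -> np.ndarray:
    """Composite score: minmax(arrest) + minmax(senescence signature)."""
    arrest = np.asarray(arrest, dtype=float)
    sen_sig = np.asarray(sen_sig, dtype=float)
    if arrest.shape != sen_sig.shape:
        raise ValueError(
            f"length mismatch: arrest {arrest.shape} vs senescence {sen_sig.shape}"
        )
    return minmax_normalize(arrest) + minmax_normalize(sen_sig)


def classify_senescent(
    score_K: np.ndarray, score_R: np.ndarray, score_WP: np.ndarray
) -> tuple[np.ndarray, dict[str, float]]:
    """Label cells in the fourth quartile of all three composite scores.

    Returns (labels, cutpoints) where cutpoints maps score name to its Q3
    (type-7 quantile). A score exactly at Q3 counts as fourth quartile.
    """
    scores = {"K": np.asarray(score_K, float),
              "R": np.asarray(score_R, float),
              "WP": np.asarray(score_WP, float)}
    n = scores["K"].size
    if any(s.size != n for s in scores.values()):
        raise ValueError("score vectors must cover identical cells")
    if n < 4:
        raise ValueError(f"need at least 4 cells to form quartiles, got {n}")
    cutpoints = {k: float(np.quantile(v, 0.75)) for k, v in scores.items()}
    labels = np.ones(n, dtype=bool)
    for k, v in scores.items():
        labels &= v >= cutpoints[k]
    return labels, cutpoints


def _run_sit_single(
    nm: NormalizedMatrix,
    cellcycle_sets: dict[str, GeneSet],
    params: SitParams,
) -> tuple[pd.DataFrame, dict]:
    sig = params.senescence_signature or builtin_signatures()["senescence_core"]
    try:
        sen = module_score(nm, sig, params.module_params())
    except ValueError as exc:
        raise ValueError(f"SIT stage (a) senescence signature: {exc}") from exc

    try:
        named = [GeneSet(k, cellcycle_sets[k].genes, cellcycle_sets[k].source)
                 for k in SCORE_KEYS]
        ss = ssgsea_score_sets(nm, named, params.ssgsea_params())
    except (ValueError, KeyError) as exc:
        raise ValueError(f"SIT stage (b) cell-cycle ssGSEA: {exc}") from exc

    table = pd.DataFrame(index=nm.cell_ids)
    table["senescence_signature"] = sen
    for k in SCORE_KEYS:
        table[f"ssgsva_{k}"] = ss[k].to_numpy()
        table[f"arrest_{k}"] = arrest_signature(table[f"ssgsva_{k}"].to_numpy())
        table[f"score_{k}"] = senescence_score(
            table[f"arrest_{k}"].to_numpy(), sen
        )
    labels, cutpoints = classify_senescent(
        *(table[f"score_{k}"].to_numpy() for k in SCORE_KEYS)
    )
    table["sit_label"] = labels

    sig_used = sig.intersect(nm.gene_ids)
    audit = {
        "n_cells": int(nm.n_cells),
        "n_genes": int(nm.n_genes),
        "seed": int(params.seed),
        "quartile_cutpoints": cutpoints,
        "quantile_type": 7,
        "senescence_signature_genes": list(sig_used.genes),
        "cellcycle_set_sizes": {
            k: len(cellcycle_sets[k].intersect(nm.gene_ids)) for k in SCORE_KEYS
        },
        "n_senescent": int(labels.sum()),
        "labeled_fraction": float(labels.mean()),
    }
    return table, audit


def run_sit(
    nm: NormalizedMatrix,
    cellcycle_sets: dict[str, GeneSet],
    params: SitParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full four-step SIT on a post-QC normalized matrix.

    ``cellcycle_sets`` maps the keys "K", "R", "WP" to the corresponding
    cell-cycle gene sets (supplied as GMT inputs). With
    ``params.per_sample`` the scoring and quartile split are repeated
    within each ``sample`` group of the cell metadata; by default all cells
    are scored and split jointly (the merged-population convention).

    Returns the per-cell score table (senescence_signature, ssgsva/arrest/
    score for K, R, WP, and the boolean ``sit_label``) plus a JSON-ready
    audit dict with cutpoints, seeds and gene-set intersections.
    """
    params = params or SitParams()
    missing = [k for k in SCORE_KEYS if k not in cellcycle_sets]
    if missing:
        raise ValueError(f"missing cell-cycle gene sets: {missing}")

    if not params.per_sample:
        return _run_sit_single(nm, cellcycle_sets, params)

    if "sample" not in nm.cells.columns:
        raise ValueError("per_sample=True requires a 'sample' column in cell metadata")
    tables, audits = [], {}
    for sample, idx in nm.cells.groupby("sample", sort=True).groups.items():
        mask = np.asarray(nm.cell_ids.isin(idx))
        t, a = _run_sit_single(nm.subset_cells(mask), cellcycle_sets, params)
        tables.append(t)
        audits[str(sample)] = a
    table = pd.concat(tables).loc[nm.cell_ids]
    audit = {"per_sample": True, "samples": audits,
             "n_senescent": int(table["sit_label"].sum()),
             "labeled_fraction": float(table["sit_label"].mean())}
    return table, audit
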