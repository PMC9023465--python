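"""Cell- and gene-level quality control and epithelial gating.

Filters mirror standard droplet scRNA-seq practice for tumor epithelium:
cells with a high mitochondrial fraction (dying) or too few detected genes
(empty droplets/debris) are removed, non-protein-coding genes are dropped,
and contaminating immune cells are gated out as Ptprc+ / Epcam−.

Mitochondrial fractions and detected-gene counts are always computed on the
full original gene panel, before any protein-coding subsetting, so QC sees
total RNA content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import CountMatrix, NormalizedMatrix, SignatureRegistry

logger = logging.getLogger(__name__)

__all__ = ["QCReport", "filter_cells", "filter_genes_protein_coding",
           "gate_epithelial", "annotate_compartment"]

COMPARTMENT_ORDER = ("luminal", "basal", "seminal_vesicle")


@dataclass
class QCReport:
    """Bookkeeping for one QC stage; counts reconcile with matrix shapes."""

    n_cells_in: int = 0
    n_cells_out: int = 0
    removed_by_mito: int = 0
    removed_by_min_genes: int = 0
    removed_by_gating: int = 0
    n_genes_in: int = 0
    n_genes_out: int = 0
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def filter_cells(
    cm: CountMatrix,
    max_mito_frac: float = 0.25,
    min_genes: int = 100,
    reference: CountMatrix | None = None,
) -> tuple[CountMatrix, QCReport]:
    """Keep cells with mito fraction <= *max_mito_frac* and >= *min_genes*
    detected genes.

    Boundary cells (exactly 25% mito, exactly 100 genes) are retained: the
    removal rules are strict ("more than" / "fewer than"). When *reference*
    is given (the pre-gene-filtering matrix), mito fractions and detected
    genes are computed on its full panel so QC sees total RNA content.
    """
    src = cm if reference is None else reference.subset_cells(
        np.asarray(reference.cell_ids.isin(cm.cell_ids))
    )
    if src.n_cells != cm.n_cells or not (src.cell_ids == cm.cell_ids).all():
        raise ValueError("reference matrix does not cover the same cells")
    totals = np.asarray(src.X.sum(axis=1)).ravel().astype(float)
    mito_mask = src.genes["is_mito"].to_numpy()
    mito_counts = np.asarray(src.X[:, mito_mask].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1.0), 0.0)
    n_detected = np.asarray((src.X > 0).sum(axis=1)).ravel()

    fail_mito = mito_frac > max_mito_frac
    fail_genes = n_detected < min_genes
    keep = ~(fail_mito | fail_genes)

    report = QCReport(
        n_cells_in=cm.n_cells,
        n_cells_out=int(keep.sum()),
        removed_by_mito=int(fail_mito.sum()),
        removed_by_min_genes=int(fail_genes.sum()),
        n_genes_in=cm.n_genes,
        n_genes_out=cm.n_genes,
    )
    if not keep.any():
        raise ValueError(f"all {cm.n_cells} cells removed by QC filters: {report.to_dict()}")
    return cm.subset_cells(keep), report


def filter_genes_protein_coding(cm: CountMatrix) -> CountMatrix:
    """Restrict the panel to protein-coding genes; cells are untouched.

    Genes with a missing biotype are treated as non-coding (with a warning).
    """
    biotype = cm.genes["biotype"]
    n_missing = int(biotype.isna().sum())
    if n_missing:
        logger.warning("%d gene(s) lack a biotype annotation; treated as non-coding", n_missing)
    keep = (biotype == "protein_coding").fillna(False).to_numpy()
    if not keep.any():
        raise ValueError("no protein-coding genes remain after biotype filtering")
    return cm.subset_genes(keep)


def gate_epithelial(
    nm: NormalizedMatrix,
    epcam_gene: str = "Epcam",
    ptprc_gene: str = "Ptprc",
) -> tuple[NormalizedMatrix, QCReport]:
    """Remove immune contaminants: cells with any Ptprc (CD45) detection and
    no Epcam detection. Positivity is detection-based (expression > 0)."""
    report = QCReport(
        n_cells_in=nm.n_cells, n_cells_out=nm.n_cells,
        n_genes_in=nm.n_genes, n_genes_out=nm.n_genes,
    )
    missing = [g for g in (epcam_gene, ptprc_gene) if g not in nm.gene_ids]
    if missing:
        msg = f"gating genes absent from panel: {missing}; epithelial gate skipped"
        logger.warning(msg)
        report.notes.append(msg)
        return nm, report

    epcam = nm.gene_vector(epcam_gene)
    ptprc = nm.gene_vector(ptprc_gene)
    remove = (ptprc > 0) & (epcam == 0)
    report.removed_by_gating = int(remove.sum())
    report.n_cells_out = int((~remove).sum())
    return nm.subset_cells(~remove), report


def annotate_compartment(
    nm: NormalizedMatrix, markers: SignatureRegistry
) -> tuple[np.ndarray, np.ndarray]:
    """Label each cell with its epithelial compartment by highest mean
    marker expression.

    Compartments considered are ``luminal``, ``basal`` and
    ``seminal_vesicle`` in that fixed order; ties resolve to the earliest
    compartment and are flagged.

    Returns (labels, tie_flags), both length n_cells.
    """
    means = {}
    for comp in COMPARTMENT_ORDER:
        if comp not in markers:
            logger.warning("no marker set for compartment %s; excluded", comp)
            continue
        try:
            gs = markers[comp].intersect(nm.gene_ids)
        except ValueError:
            logger.warning("compartment %s has no markers in panel; excluded", comp)
            continue
        cols = [nm.gene_ids.get_loc(g) for g in gs.genes]
        means[comp] = np.asarray(nm.X[:, cols].mean(axis=1)).ravel()
    if not means:
        raise ValueError("no compartment has markers present in the panel")

    comps = [c for c in COMPARTMENT_ORDER if c in means]
    score = np.vstack([means[c] for c in comps])  # compartments x cells
    best = np.argmax(score, axis=0)  # argmax takes the first max -> tie rule
    is_tie = (score == score[best, np.arange(score.shape[1])]).sum(axis=0) > 1
    labels = np.array([comps[i] for i in best], dtype=object)
    return labels, is_tie
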