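#!/usr/bin/env python
"""Quality control of the simulated tumor.

Applies the cell filters (mito fraction <= 25%, >= 100 detected genes), the
protein-coding restriction, library-size normalization and the Ptprc+/
Epcam- epithelial gate, then annotates epithelial compartments. Writes the
post-QC matrix and a QC report under results/qc/.
"""

import json
from pathlib import Path

import pandas as pd

from senindex import (annotate_compartment, builtin_signatures, filter_cells,
                      filter_genes_protein_coding, gate_epithelial, normalize,
                      read_10x_triplet, read_gene_annotation,
                      write_10x_triplet)

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    cm = read_10x_triplet(BASE / "data")
    ann = read_gene_annotation(BASE / "data" / "annotation.tsv")
    cm.genes["biotype"] = ann.loc[cm.gene_ids, "biotype"].to_numpy()
    cm.genes["is_mito"] = ann.loc[cm.gene_ids, "is_mito"].to_numpy()

    cm_f, rep = filter_cells(cm)
    cm_f = filter_genes_protein_coding(cm_f)
    nm = normalize(cm_f)
    nm, rep_gate = gate_epithelial(nm)
    labels, ties = annotate_compartment(nm, builtin_signatures())

    out = BASE / "qc"
    out.mkdir(parents=True, exist_ok=True)
    keep = cm_f.cell_ids.isin(nm.cell_ids)
    write_10x_triplet(cm_f.subset_cells(keep), out)
    cm_f.genes.reset_index().to_csv(out / "annotation.tsv", sep="\t", index=False)
    pd.DataFrame({"cell_id": nm.cell_ids, "compartment": labels,
                  "tie": ties}).to_csv(out / "compartments.tsv", sep="\t",
                                       index=False)
    report = {"cells": rep.to_dict(), "gating": rep_gate.to_dict()}
    (out / "qc.json").write_text(json.dumps(report, indent=2))

    print(f"cells: {rep.n_cells_in} -> {nm.n_cells} "
          f"(mito {rep.removed_by_mito}, min-genes {rep.removed_by_min_genes}, "
          f"gating {rep_gate.removed_by_gating})")
    print(f"genes: {cm.n_genes} -> {nm.n_genes} after protein-coding filter")
    print("compartments:", pd.Series(labels).value_counts().to_dict())


if __name__ == "__main__":
    main()
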