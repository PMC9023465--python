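#!/usr/bin/env python
"""Generate the synthetic tumor used by the downstream analysis scripts.

Draws the default study conditions — 2000 cells, 20% planted senescent,
|lfc|=2 effects on senescence markers, SASP and cell-cycle genes — and
writes a 10x-style triplet plus the planted truth under results/data/.
"""

from pathlib import Path

from senindex import SimConfig, simulate_tumor, write_10x_triplet

SEED = 11
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main():
    cfg = SimConfig(seed=SEED)
    cm, truth = simulate_tumor(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    write_10x_triplet(cm, OUT)
    cm.genes.reset_index().to_csv(OUT / "annotation.tsv", sep="\t", index=False)
    truth.truth_frame().assign(cell_id=cm.cell_ids).to_csv(
        OUT / "truth.tsv", sep="\t", index=False)
    n_roles = truth.gene_role.value_counts()
    print(f"wrote {cm.n_cells} cells x {cm.n_genes} genes to {OUT}")
    print(f"planted senescent cells: {truth.is_senescent.sum()}")
    print("gene roles:", dict(n_roles))


if __name__ == "__main__":
    main()
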