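#!/usr/bin/env python
"""Downstream analyses on the SIT labels.

Runs the Wilcoxon DE of senescent vs non-senescent cells, the pro-survival
correlation screen against S_K/S_R/S_WP, and the Bcl2/Mcl1 stratification
of senescent cells. Writes de.tsv, screen.tsv and stratification.tsv under
results/downstream/.
"""

from pathlib import Path

import pandas as pd

from senindex import (normalize, read_10x_triplet, stratify_bcl2_mcl1,
                      survival_correlation_screen, wilcoxon_de)

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    cm = read_10x_triplet(BASE / "qc")
    nm = normalize(cm)
    scores = pd.read_csv(BASE / "sit" / "sit_scores.tsv", sep="\t"
                         ).set_index("cell_id").loc[nm.cell_ids]
    labels = scores["sit_label"].to_numpy(bool)

    out = BASE / "downstream"
    out.mkdir(parents=True, exist_ok=True)

    de = wilcoxon_de(nm, labels)
    de.to_csv(out / "de.tsv", sep="\t", index=False, float_format="%.10g")
    up = de[de["significant"] & (de["log_fc"] > 0)]
    print(f"DE: {len(de)} genes tested, {de['significant'].sum()} at FDR<0.05 "
          f"({len(up)} up in senescent cells)")

    screen = survival_correlation_screen(nm, scores)
    screen.to_csv(out / "screen.tsv", sep="\t", index=False,
                  float_format="%.10g")
    top = screen.sort_values("r_K", ascending=False).head(3)
    print("screen top correlates with S_K:",
          [(g, round(r, 3)) for g, r in zip(top["gene"], top["r_K"])])

    strat = stratify_bcl2_mcl1(nm, labels)
    strat.to_csv(out / "stratification.tsv", sep="\t", index=False)
    print("stratification of senescent cells:",
          strat["joint_class"].value_counts().to_dict())
    print(f"Bcl2-negative fraction: "
          f"{(strat['bcl2_class'] == 'neg').mean():.3f}")


if __name__ == "__main__":
    main()
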