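#!/usr/bin/env python
"""Predict the protein variant catalog of the designed slippery gene.

Finding: the unedited transcript yields the 807-aa truncated product from a
2,424-nt ORF; a +1 slippage edit restores the downstream frame and yields
the 1,129-aa full-length protein. Writes results/variants.tsv.
"""

import pandas as pd

from slipscan import GeneDesign, design_gene, designed_run, predict_variants
from slipscan.seq_core import write_tsv_report


def main() -> None:
    design = GeneDesign(seed=7)
    gene = design_gene(design)
    rows = []
    for v in predict_variants(gene, designed_run(design), (-2, -1, 1, 2)):
        rows.append(
            {
                "k": v.produced_by_k,
                "length_aa": v.length_aa,
                "mw_kda": v.mw_kda,
                "restored": v.full_length_restored,
            }
        )
        print(
            f"k={v.produced_by_k:+d}: {v.length_aa} aa, {v.mw_kda:.1f} kDa"
            + ("  (reads past the premature stop)" if v.full_length_restored else "")
        )
    write_tsv_report(pd.DataFrame(rows), "results/variants.tsv",
                     ["analysis/02_predict_variants.py"])


if __name__ == "__main__":
    main()
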