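#!/usr/bin/env python
"""Scan the study inputs for slippery sites.

Scans (i) the printed 56-nt synthetic RNA used as the reverse-transcription
control and (ii) a designed gene with the natural tssM1-like architecture,
and writes the called sites to results/sites.tsv.

Finding: the 56-nt control carries a single 11-A run; the designed gene
shows one slippery site — an 11-A run ending 28 nt upstream of the premature
amber stop — whose +1 edit restores the downstream reading frame.
"""

import pandas as pd

from slipscan import Cds, GeneDesign, call_slippery_sites, design_gene, find_runs
from slipscan.seq_core import write_tsv_report

SYNTHETIC_RNA_56NT = "GCCGGCUAUUAUGAGGCGUUUAAAAAAAAAAAUGGGUCCGGGGCUGAUGCUGUUAG"


def main() -> None:
    rna = Cds("synthetic_56nt", SYNTHETIC_RNA_56NT, alphabet="RNA", source="synthetic")
    (run,) = find_runs(rna, base="A", min_length=8)
    print(f"{rna.id}: {len(rna)} nt, one A-run of length {run.length} at nt {run.start}")

    gene = design_gene(GeneDesign(seed=7))
    rows = []
    for site in call_slippery_sites(gene):
        rows.append(
            {
                "seq_id": site.run.seq_id,
                "base": site.run.base,
                "run_start": site.run.start,
                "run_len": site.run.length,
                "stop_start": site.premature_stop_start,
                "distance": site.distance,
                "restoring_edits": ",".join(map(str, sorted(site.restoring_edits))),
            }
        )
        print(
            f"{gene.id}: {site.run.length}-A run at nt {site.run.start}, "
            f"{site.distance} nt upstream of the stop at nt {site.premature_stop_start}; "
            f"restoring edits: {sorted(site.restoring_edits)}"
        )
    write_tsv_report(pd.DataFrame(rows), "results/sites.tsv", ["analysis/01_scan_slippery_site.py"])


if __name__ == "__main__":
    main()
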