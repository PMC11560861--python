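"""Per-cell quality control: IQR gene fence, mitochondrial cap, doublets.

Runs the filters on a small hand-built metrics table. With gene counts
[100, 200, 300, 400, 1000] the interpolated quartiles give a keep window
of [0, 600], so only the 1000-gene cell fails the fence; a cell at
exactly 10% mitochondrial RNA is kept (removal is strictly greater
than), and flagged doublets fail regardless.
"""

import pandas as pd

from clonetrace import combine_qc

metrics = pd.DataFrame(
    {
        "cell_id": ["c1", "c2", "c3", "c4", "c5"],
        "n_genes": [100, 200, 300, 400, 1000],
        "mito_fraction": [0.10, 0.11, 0.02, 0.0, 0.05],
        "doublet": [False, False, True, False, False],
    }
)
out = combine_qc(metrics)
print(out[["cell_id", "n_genes", "mito_fraction", "doublet",
           "iqr_pass", "mito_pass", "qc_pass"]].to_string(index=False))
print(f"\n{int(out['qc_pass'].sum())} of {len(out)} cells pass QC")
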