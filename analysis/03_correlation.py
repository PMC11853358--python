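#!/usr/bin/env python
"""Dynamic cross-correlation matrices of Cα fluctuations for both systems.

Writes the full DCCM and a display copy with |C| < 0.3 blanked (the masked
copy is presentation-only; downstream network weights use the full matrix).
"""

import numpy as np

from common import load, outdir

from ppidyn.correlation import dccm, mask_for_display, write_dccm_tsv
from ppidyn.structio import select


def main() -> None:
    out = outdir("correlation")
    for tag in ("wt", "mut"):
        ds = load(tag)
        ca = select(ds["model"], "name CA")
        mat = dccm(ds["trajectory"], ca, fit_reference="mean")
        write_dccm_tsv(mat, out / f"{tag}_dccm.tsv")
        write_dccm_tsv(mask_for_display(mat, 0.3), out / f"{tag}_dccm_masked030.tsv")
        off = ~np.eye(mat.n, dtype=bool)
        print(f"[{tag}] mean |C| off-diagonal: {np.nanmean(np.abs(mat.C[off])):.3f}")


if __name__ == "__main__":
    main()
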