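#!/usr/bin/env python
"""Per-frame RMSD and per-residue RMSF of both systems (Cα, fitted).

Expected finding: the wild-type-like complex fluctuates in a narrower basin,
so both its mean RMSD and its RMSF profile sit below the mutant-like arm.
"""

import numpy as np

from common import load, outdir

from ppidyn.fitmetrics import rmsd_series, rmsf, write_rmsd_tsv, write_rmsf_tsv
from ppidyn.structio import select


def main() -> None:
    out = outdir("fluctuations")
    for tag in ("wt", "mut"):
        ds = load(tag)
        ca = select(ds["model"], "name CA")
        rmsd = rmsd_series(ds["trajectory"], ca, reference_frame=0, fit=True)
        write_rmsd_tsv(rmsd, out / f"{tag}_rmsd.tsv")
        vals = rmsf(ds["trajectory"], ca, reference="initial", fit=True)
        resnums = [ds["model"].atoms[i].residue_number for i in ca]
        write_rmsf_tsv(resnums, vals, out / f"{tag}_rmsf.tsv", convention="initial")
        print(f"[{tag}] RMSD {rmsd.mean():.2f} ± {rmsd.std():.2f} Å, "
              f"mean RMSF {np.mean(vals):.2f} Å")


if __name__ == "__main__":
    main()
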