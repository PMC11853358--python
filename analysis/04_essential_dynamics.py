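#!/usr/bin/env python
"""Essential dynamics: per-system PCA, shared-space projections, RMSIP and
overlap, free-energy landscapes, k-means representative clusters, porcupine
PDBs.

Expected finding: the mutant-like system concentrates its motion in one
dominant component (high PC1 fraction, steep eigenvalue decay), the wild-type
arm spreads variance over many components; the two essential subspaces differ
(RMSIP well below 1).
"""

import numpy as np

from common import HUB, load, outdir

from ppidyn.essential import (
    fel_from_projection,
    fit_pca,
    kmeans_representatives,
    overlap_matrix,
    porcupine,
    project,
    rmsip,
    variance_fractions,
    write_eigen_tsv,
    write_fel_tsv,
    write_projection_tsv,
)
from ppidyn.structio import select


def main() -> None:
    out = outdir("essential")
    ds = {tag: load(tag) for tag in ("wt", "mut")}
    sel = {tag: select(d["model"], "name CA") for tag, d in ds.items()}
    models = {}
    for tag in ("wt", "mut"):
        pca = fit_pca(ds[tag]["trajectory"], sel[tag])
        models[tag] = pca
        fr = variance_fractions(pca)
        write_eigen_tsv(pca, out / f"{tag}_eigen.tsv")
        proj = project(pca, ds[tag]["trajectory"], components=(0, 1), selection=sel[tag])
        write_projection_tsv(proj, out / f"{tag}_projection.tsv")
        grid = fel_from_projection(proj, bins=100, temperature=310.0)
        write_fel_tsv(grid, out / f"{tag}_fel.tsv")
        clusters = kmeans_representatives(proj, k=5, seed=0)
        with open(out / f"{tag}_clusters.tsv", "w") as fh:
            fh.write("cluster\toccupancy_pct\tmedoid_frame\n")
            for i, (o, f) in enumerate(zip(clusters.occupancy_percent, clusters.medoid_frames)):
                fh.write(f"{i + 1}\t{o:.2f}\t{f}\n")
        porcupine(pca, 0, scale=3.0, topology=ds[tag]["model"], selection=sel[tag],
                  path=out / f"{tag}_porcupine_pc1.pdb")
        print(f"[{tag}] PC1/PC2 variance: {100 * fr[0]:.1f}% / {100 * fr[1]:.1f}%, "
              f"top cluster {clusters.occupancy_percent[0]:.1f}%")

    # shared space: pooled fit over both systems' analysis frames
    shared = fit_pca(
        [ds["wt"]["trajectory"], ds["mut"]["trajectory"]], [sel["wt"], sel["mut"]]
    )
    write_eigen_tsv(shared, out / "shared_eigen.tsv")
    val = rmsip(models["wt"], models["mut"], k=10)
    ov = overlap_matrix(models["wt"], models["mut"], k=10)
    np.savetxt(out / "overlap_matrix.tsv", ov, delimiter="\t", fmt="%.6f")
    print(f"RMSIP (first 10 PCs): {val:.2f}; mean overlap {ov.mean():.3f}")


if __name__ == "__main__":
    main()
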