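"""Essential dynamics: Cartesian PCA, subspace comparison, FELs, clusters.

The essential model is the eigensystem of the 3N×3N covariance matrix of
superposed Cartesian coordinates. Each principal component PC_i is a linear
combination Σ_j α_ij x_j of the fitted coordinates; the leading components
carry the dominant collective motions. Two systems become directly comparable
by fitting one model on their pooled frames ("shared PCA space") or by
projecting one system onto the other's modes.

Free-energy landscapes convert binned populations over two reaction
coordinates into relative free energies, G_i = −k_B T ln(N_i / N_max), so the
most populated bin sits at G = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from ppidyn.fitmetrics import superpose_frames
from ppidyn.structio import StructureModel, TrajectoryEnsemble, write_trajectory_pdb

__all__ = [
    "BOLTZMANN_KCAL",
    "EssentialModel",
    "ProjectionSeries",
    "FELGrid",
    "ClusterSummary",
    "fit_pca",
    "variance_fractions",
    "project",
    "rmsip",
    "overlap_matrix",
    "porcupine",
    "fel",
    "fel_from_projection",
    "kmeans_representatives",
]

#: Boltzmann constant in kcal·mol⁻¹·K⁻¹
BOLTZMANN_KCAL = 0.0019872041


@dataclass
class EssentialModel:
    """PCA eigensystem over a Cartesian selection.

    ``eigenvectors`` has orthonormal columns (3N × m); ``eigenvalues`` (Å²)
    are sorted descending. The sign of each column is fixed so its
    largest-magnitude loading is positive, making projections reproducible.
    """

    mean_coordinates: np.ndarray  # N × 3 Å
    eigenvectors: np.ndarray  # 3N × m
    eigenvalues: np.ndarray  # m, descending, Å²
    selection_labels: list[str]

    @property
    def n_atoms(self) -> int:
        return self.mean_coordinates.shape[0]

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]


@dataclass
class ProjectionSeries:
    """Per-frame scores (Å) on a set of requested components."""

    scores: np.ndarray  # F × k
    component_indices: list[int]

    def __post_init__(self) -> None:
        if self.scores.shape[1] != len(self.component_indices):
            raise ValueError("score column count must match requested components")


@dataclass
class FELGrid:
    """A binned 2-D free-energy surface (kcal/mol). Empty bins are NaN."""

    edges_a: np.ndarray
    edges_b: np.ndarray
    G: np.ndarray
    counts: np.ndarray
    temperature: float
    axis_labels: tuple[str, str] = ("coord_a", "coord_b")

    @property
    def centers_a(self) -> np.ndarray:
        return 0.5 * (self.edges_a[:-1] + self.edges_a[1:])

    @property
    def centers_b(self) -> np.ndarray:
        return 0.5 * (self.edges_b[:-1] + self.edges_b[1:])


@dataclass
class ClusterSummary:
    """k-means clusters of PC-space projections with medoid frames."""

    centroids: np.ndarray  # k × d
    occupancy_percent: np.ndarray  # k, sums to 100
    medoid_frames: np.ndarray  # k frame indices
    labels: np.ndarray  # per-frame cluster id


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    out = vecs.copy()
    for j in range(out.shape[1]):
        k = np.argmax(np.abs(out[:, j]))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _collect_fitted(
    trajs: Sequence[TrajectoryEnsemble],
    selection: np.ndarray,
    reference: np.ndarray,
    fit: bool,
) -> np.ndarray:
    blocks = []
    for t, sel in zip(trajs, selection):
        frames = t.analysis_frames[:, sel, :]
        blocks.append(superpose_frames(frames, reference) if fit else frames)
    return np.concatenate(blocks, axis=0)


def fit_pca(
    trajs: TrajectoryEnsemble | Sequence[TrajectoryEnsemble],
    selection: np.ndarray,
    reference: np.ndarray | None = None,
    fit: bool = True,
) -> EssentialModel:
    """Fit the essential model on pooled, superposed frames.

    Passing both systems' trajectories yields the shared PCA space: one
    eigensystem over the pooled post-equilibration frames, each superposed to
    a single common reference (by default the first analysis frame of the
    first trajectory). ``fit=False`` skips the superposition for inputs whose
    rigid-body motion is already removed (or deliberately planted).

    ``selection`` is one index array applied to every trajectory, or a list
    of per-trajectory index arrays of equal length (for systems whose
    topologies differ outside the analysed selection).
    """
    if isinstance(trajs, TrajectoryEnsemble):
        trajs = [trajs]
    if isinstance(selection, (list, tuple)):
        sels = [np.asarray(s, dtype=int) for s in selection]
        if len(sels) != len(trajs):
            raise ValueError("need one selection per trajectory")
    else:
        sels = [np.asarray(selection, dtype=int)] * len(trajs)
    n_sel = sels[0].size
    if n_sel == 0:
        raise ValueError("empty selection")
    for t, sel in zip(trajs, sels):
        if sel.size != n_sel:
            raise ValueError("per-trajectory selections must have equal atom counts")
        if t.topology.n_atoms <= sel.max():
            raise ValueError("selection exceeds trajectory atom count")
    if reference is None:
        reference = trajs[0].analysis_frames[0, sels[0], :]
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (n_sel, 3):
        raise ValueError("reference shape must match the selection")
    fitted = _collect_fitted(trajs, sels, reference, fit)  # F × N × 3
    n_frames = fitted.shape[0]
    if n_frames <= 3 * n_sel:
        warnings.warn(
            f"only {n_frames} frames for {3 * n_sel} Cartesian dimensions; "
            "covariance is rank-deficient",
            stacklevel=2,
        )
    mean = fitted.mean(axis=0)
    x = (fitted - mean).reshape(n_frames, -1)  # F × 3N
    cov = (x.T @ x) / n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])
    labels = [
        f"{trajs[0].topology.atoms[i].chain_id}:{trajs[0].topology.atoms[i].residue_number}"
        for i in sels[0]
    ]
    return EssentialModel(
        mean_coordinates=mean,
        eigenvectors=evecs,
        eigenvalues=evals,
        selection_labels=labels,
    )


def variance_fractions(model: EssentialModel) -> np.ndarray:
    """Fraction of total variance per component: λ_i / Σλ."""
    total = model.eigenvalues.sum()
    if total <= 0:
        raise ValueError("model has no positive eigenvalues")
    return model.eigenvalues / total


def project(
    model: EssentialModel,
    traj: TrajectoryEnsemble | np.ndarray,
    components: Sequence[int] = (0, 1),
    selection: np.ndarray | None = None,
    fit: bool = True,
) -> ProjectionSeries:
    """Project frames onto model components: score = (fitted − mean)·α.

    ``traj`` may be a TrajectoryEnsemble (with ``selection`` resolving the
    model's atoms) or an already-selected F × N × 3 coordinate block; frames
    are superposed to the model mean before projecting unless ``fit=False``.
    """
    if isinstance(traj, TrajectoryEnsemble):
        if selection is None:
            raise ValueError("selection required when projecting a TrajectoryEnsemble")
        frames = traj.analysis_frames[:, np.asarray(selection, dtype=int), :]
    else:
        frames = np.asarray(traj, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
    if frames.shape[1] != model.n_atoms:
        raise ValueError(
            f"atom count mismatch: model has {model.n_atoms}, frames have {frames.shape[1]}"
        )
    comps = list(components)
    if any(c < 0 or c >= model.n_components for c in comps):
        raise ValueError("component index out of range")
    fitted = superpose_frames(frames, model.mean_coordinates) if fit else frames
    x = (fitted - model.mean_coordinates).reshape(fitted.shape[0], -1)
    scores = x @ model.eigenvectors[:, comps]
    return ProjectionSeries(scores=scores, component_indices=comps)


def rmsip(model_a: EssentialModel, model_b: EssentialModel, k: int = 10) -> float:
    """Root mean square inner product of the first ``k`` components.

    RMSIP = sqrt( (1/k) Σ_i Σ_j (α_i^A · α_j^B)² ) ∈ [0, 1]; 1 means the two
    k-dimensional essential subspaces coincide.
    """
    ov = overlap_matrix(model_a, model_b, k)
    return float(np.sqrt(ov.sum() / k))


def overlap_matrix(model_a: EssentialModel, model_b: EssentialModel, k: int = 10) -> np.ndarray:
    """k×k grid of squared inner products between leading components."""
    if model_a.eigenvectors.shape[0] != model_b.eigenvectors.shape[0]:
        raise ValueError("models span different coordinate dimensions")
    if model_a.n_components < k or model_b.n_components < k:
        raise ValueError(f"both models need at least k={k} components")
    a = model_a.eigenvectors[:, :k]
    b = model_b.eigenvectors[:, :k]
    return (a.T @ b) ** 2


def porcupine(
    model: EssentialModel,
    component: int = 0,
    scale: float = 1.0,
    topology: StructureModel | None = None,
    selection: np.ndarray | None = None,
    path: str | Path | None = None,
) -> np.ndarray:
    """Per-atom displacement vectors of one component, anchored on the mean.

    Returns an N×3 array (``scale`` × the per-atom eigenvector slice).  When
    ``topology``/``selection``/``path`` are given, a two-model PDB (mean and
    mean+displacement) is written for arrow rendering in a viewer.
    """
    if not 0 <= component < model.n_components:
        raise ValueError("component index out of range")
    vecs = model.eigenvectors[:, component].reshape(-1, 3) * scale
    if path is not None:
        if topology is None or selection is None:
            raise ValueError("topology and selection are required to write a porcupine PDB")
        sub = topology.subset(list(np.asarray(selection, dtype=int)))
        frames = np.stack([model.mean_coordinates, model.mean_coordinates + vecs])
        write_trajectory_pdb(TrajectoryEnsemble(sub, frames), path)
    return vecs


def fel(
    coord_a: np.ndarray,
    coord_b: np.ndarray,
    bins: int | tuple[int, int] = 100,
    temperature: float = 310.0,
    axis_labels: tuple[str, str] = ("coord_a", "coord_b"),
) -> FELGrid:
    """Free-energy landscape over two reaction-coordinate series.

    G_i = −k_B·T·ln(N_i / N_max); the most populated bin is exactly 0 and
    empty bins are NaN (undefined, not an arbitrary cap).
    """
    a = np.asarray(coord_a, dtype=float).ravel()
    b = np.asarray(coord_b, dtype=float).ravel()
    if a.size == 0 or a.size != b.size:
        raise ValueError("reaction-coordinate series must be nonempty and equal length")
    if isinstance(bins, int):
        bins = (bins, bins)
    if bins[0] < 2 or bins[1] < 2:
        raise ValueError("at least 2 bins per axis")
    counts, ea, eb = np.histogram2d(a, b, bins=bins)
    n_max = counts.max()
    with np.errstate(divide="ignore"):
        G = np.where(counts > 0, -BOLTZMANN_KCAL * temperature * np.log(counts / n_max), np.nan)
    return FELGrid(
        edges_a=ea, edges_b=eb, G=G, counts=counts.astype(int),
        temperature=temperature, axis_labels=axis_labels,
    )


def fel_from_projection(
    proj: ProjectionSeries,
    bins: int | tuple[int, int] = 100,
    temperature: float = 310.0,
) -> FELGrid:
    """FEL over the first two columns of a projection series (PC1 vs PC2)."""
    if proj.scores.shape[1] < 2:
        raise ValueError("projection must carry at least two components")
    i, j = proj.component_indices[:2]
    return fel(
        proj.scores[:, 0], proj.scores[:, 1], bins=bins, temperature=temperature,
        axis_labels=(f"PC{i + 1}", f"PC{j + 1}"),
    )


def kmeans_representatives(
    proj: ProjectionSeries,
    k: int = 5,
    seed: int = 0,
    restarts: int = 50,
) -> ClusterSummary:
    """k-means over projection scores with medoid (nearest-to-centroid) frames.

    Deterministic for a given seed: k-means++ initialisation with ``restarts``
    re-initialisations, best inertia kept.
    """
    x = proj.scores
    if x.shape[0] < k:
        raise ValueError(f"k={k} exceeds the {x.shape[0]} available frames")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(x)
    # order clusters by occupancy (largest first) for stable reporting
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels]
    centroids = km.cluster_centers_[order]
    sizes = sizes[order]
    occupancy = 100.0 * sizes / x.shape[0]
    medoids = np.empty(k, dtype=int)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        d = np.linalg.norm(x[members] - centroids[c], axis=1)
        medoids[c] = members[np.argmin(d)]
    return ClusterSummary(
        centroids=centroids,
        occupancy_percent=occupancy,
        medoid_frames=medoids,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_eigen_tsv(model: EssentialModel, path: str | Path) -> None:
    fr = variance_fractions(model)
    with open(path, "w") as fh:
        fh.write("component\teigenvalue_A2\tvariance_fraction\n")
        for i, (ev, f) in enumerate(zip(model.eigenvalues, fr), start=1):
            fh.write(f"{i}\t{ev:.8g}\t{f:.8g}\n")


def write_projection_tsv(proj: ProjectionSeries, path: str | Path) -> None:
    cols = [f"PC{i + 1}" for i in proj.component_indices]
    with open(path, "w") as fh:
        fh.write("frame\t" + "\t".join(cols) + "\n")
        for f in range(proj.scores.shape[0]):
            fh.write(f"{f}\t" + "\t".join(f"{v:.6f}" for v in proj.scores[f]) + "\n")


def write_fel_tsv(grid: FELGrid, path: str | Path) -> None:
    """Long format: binA_center, binB_center, G, count."""
    ca, cb = grid.centers_a, grid.centers_b
    with open(path, "w") as fh:
        fh.write(f"# T={grid.temperature} K, axes={grid.axis_labels[0]},{grid.axis_labels[1]}\n")
        fh.write("binA_center\tbinB_center\tG_kcal_mol\tcount\n")
        for i in range(ca.size):
            for j in range(cb.size):
                g = grid.G[i, j]
                gtxt = "nan" if np.isnan(g) else f"{g:.6f}"
                fh.write(f"{ca[i]:.6f}\t{cb[j]:.6f}\t{gtxt}\t{int(grid.counts[i, j])}\n")
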