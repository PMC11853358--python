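"""Rigid-body superposition (Kabsch) and deviation/fluctuation metrics.

RMSD series are measured against a chosen reference frame; RMSF supports both
the "relative to initial positions" convention and the conventional
mean-reference form (one flag apart — outputs should record which was used).
Fitting is unweighted least squares over the fit selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ppidyn.structio import TrajectoryEnsemble

__all__ = ["SuperpositionResult", "superpose", "apply_transform", "rmsd_series", "rmsf"]


@dataclass(frozen=True)
class SuperpositionResult:
    """A proper rotation + translation minimising least-squares deviation."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float  # Å


def _check_coords(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"{name} must be N×3")
    return x


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference`` (Kabsch).

    Returns the transform ``x → R @ (x − mobile_mean) + reference_mean`` and
    the post-fit RMSD. Reflections are excluded (determinant forced to +1).
    """
    mobile = _check_coords(mobile, "mobile")
    reference = _check_coords(reference, "reference")
    if mobile.shape != reference.shape:
        raise ValueError(f"coordinate shape mismatch: {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 atoms")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    p = mobile - mu_m
    q = reference - mu_r
    # rank of the reference cloud decides whether the rotation is well defined
    if np.linalg.matrix_rank(q, tol=1e-8 * max(1.0, np.abs(q).max())) < 2:
        raise ValueError("degenerate (collinear) reference coordinates: rank-deficient fit")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    fitted = (rot @ p.T).T + mu_r
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    translation = mu_r - rot @ mu_m
    return SuperpositionResult(rotation=rot, translation=translation, rmsd=rmsd)


def apply_transform(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    """Apply a fitted transform to an arbitrary coordinate set."""
    coords = _check_coords(coords, "coords")
    return (result.rotation @ coords.T).T + result.translation


def _raw_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose_frames(
    frames: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Superpose every frame onto ``reference`` using ``fit_indices`` atoms.

    The transform is fitted on the fit selection but applied to all atoms
    (fit on Cα, measure anywhere).
    """
    frames = np.asarray(frames, dtype=float)
    out = np.empty_like(frames)
    ref = reference if fit_indices is None else reference[fit_indices]
    for f in range(frames.shape[0]):
        mob = frames[f] if fit_indices is None else frames[f][fit_indices]
        res = superpose(mob, ref)
        out[f] = apply_transform(frames[f], res)
    return out


def rmsd_series(
    traj: TrajectoryEnsemble,
    selection: np.ndarray,
    reference_frame: int = 0,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Å) of the selected atoms against a reference frame.

    With ``fit`` on, each frame is first rigid-body superposed (on the same
    selection) onto the reference; with it off the raw deviation is reported.
    Covers all frames, including any equilibration segment, so the series can
    be used to choose the equilibration cut.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    coords = traj.frames[:, selection, :]
    ref = coords[reference_frame]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        if fit:
            out[f] = superpose(coords[f], ref).rmsd
        else:
            out[f] = _raw_rmsd(coords[f], ref)
    return out


def rmsf(
    traj: TrajectoryEnsemble,
    selection: np.ndarray,
    reference: str = "initial",
    fit: bool = True,
) -> np.ndarray:
    """Per-atom RMSF (Å) over the analysis frames.

    ``reference='initial'`` measures fluctuation about each atom's position in
    the first analysis frame; ``reference='mean'`` about its trajectory mean.
    With ``fit`` on, frames are superposed (on the selection) to the reference
    frame first, removing global rigid-body motion.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    if reference not in ("initial", "mean"):
        raise ValueError("reference must be 'initial' or 'mean'")
    frames = traj.analysis_frames[:, selection, :]
    if fit:
        frames = superpose_frames(frames, frames[0])
    ref = frames[0] if reference == "initial" else frames.mean(axis=0)
    dev2 = np.sum((frames - ref) ** 2, axis=2)  # F × N
    return np.sqrt(dev2.mean(axis=0))


def write_rmsd_tsv(values: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("frame\trmsd_A\n")
        for i, v in enumerate(values):
            fh.write(f"{i}\t{v:.6f}\n")


def write_rmsf_tsv(resnums, values: np.ndarray, path, convention: str = "initial") -> None:
    with open(path, "w") as fh:
        fh.write(f"# reference_convention={convention}\n")
        fh.write("resnum\trmsf_A\n")
        for rn, v in zip(resnums, values):
            fh.write(f"{rn}\t{v:.6f}\n")
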