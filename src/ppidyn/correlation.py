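"""Dynamic cross-correlation matrix (DCCM) of Cα fluctuation vectors.

The matrix element for atoms i, j is the normalised covariance of their 3-D
displacement vectors,

    C_ij = ⟨Δr_i · Δr_j⟩ / sqrt(⟨Δr_i²⟩ ⟨Δr_j²⟩),

with Δr the displacement from the reference (trajectory mean by default)
after frame-wise rigid-body superposition. Values lie in [−1, 1]; +1 is fully
correlated motion, −1 fully anti-correlated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ppidyn.fitmetrics import superpose_frames
from ppidyn.structio import TrajectoryEnsemble

__all__ = ["CorrelationMatrix", "dccm", "mask_for_display", "write_dccm_tsv", "read_dccm_tsv"]


@dataclass
class CorrelationMatrix:
    """Normalised cross-correlations ``C`` plus the raw covariances ``c`` (Å²).

    ``defined`` marks rows/columns with nonzero variance; undefined entries of
    ``C`` are NaN (reported as missing, never as 0).
    """

    residue_labels: list[str]
    C: np.ndarray
    c: np.ndarray
    defined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.residue_labels)
        if self.C.shape != (n, n) or self.c.shape != (n, n):
            raise ValueError("matrix shape must match the number of residue labels")
        if self.defined is None:
            self.defined = ~np.isnan(np.diag(self.C))

    @property
    def n(self) -> int:
        return len(self.residue_labels)


def dccm(
    traj: TrajectoryEnsemble,
    selection: np.ndarray,
    fit_reference: str = "mean",
    fit: bool = True,
) -> CorrelationMatrix:
    """Compute the DCCM over the analysis frames of a trajectory.

    ``fit_reference`` chooses both the superposition target and the
    fluctuation reference: ``'mean'`` (iterated: fit to frame 0, take the mean
    structure, fluctuations about the mean) or ``'initial'`` (fluctuations
    about the first analysis frame).
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    frames = traj.analysis_frames[:, selection, :]
    if frames.shape[0] < 2:
        raise ValueError("DCCM requires at least 2 analysis frames")
    if fit_reference not in ("mean", "initial"):
        raise ValueError("fit_reference must be 'mean' or 'initial'")
    if fit:
        frames = superpose_frames(frames, frames[0])
    ref = frames.mean(axis=0) if fit_reference == "mean" else frames[0]
    dr = frames - ref  # F × N × 3
    # covariance of 3-D displacement vectors: c_ij = ⟨Δr_i · Δr_j⟩
    c = np.einsum("fid,fjd->ij", dr, dr) / dr.shape[0]
    var = np.diag(c).copy()
    # zero-variance detection must tolerate float cancellation noise
    defined = var > 1e-12 * max(1.0, float(var.max(initial=0.0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(var, var))
        C = np.where(denom > 0, c / denom, np.nan)
    C[~defined, :] = np.nan
    C[:, ~defined] = np.nan
    # numerical guard: clip tiny excursions outside [-1, 1]
    C = np.where(np.isnan(C), C, np.clip(C, -1.0, 1.0))
    idx = np.where(defined)[0]
    C[idx, idx] = 1.0
    labels = [
        f"{traj.topology.atoms[i].chain_id}:{traj.topology.atoms[i].residue_number}"
        for i in selection
    ]
    return CorrelationMatrix(residue_labels=labels, C=C, c=c, defined=defined)


def mask_for_display(matrix: CorrelationMatrix, threshold: float) -> CorrelationMatrix:
    """Return a display copy with entries of |C| < threshold blanked (NaN).

    The computation-facing matrix is untouched; the mask exists only to
    de-clutter heat-map style output.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    C = matrix.C.copy()
    with np.errstate(invalid="ignore"):
        C[np.abs(C) < threshold] = np.nan
    return CorrelationMatrix(
        residue_labels=list(matrix.residue_labels),
        C=C,
        c=matrix.c.copy(),
        defined=matrix.defined.copy(),
    )


def write_dccm_tsv(matrix: CorrelationMatrix, path: str | Path) -> None:
    """TSV with residue labels as the header row and first column."""
    with open(path, "w") as fh:
        fh.write("residue\t" + "\t".join(matrix.residue_labels) + "\n")
        for i, lab in enumerate(matrix.residue_labels):
            row = "\t".join(
                "nan" if np.isnan(v) else f"{v:.6f}" for v in matrix.C[i]
            )
            fh.write(f"{lab}\t{row}\n")


def read_dccm_tsv(path: str | Path) -> CorrelationMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        labels = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    C = np.asarray(rows)
    if labels != header:
        raise ValueError("row labels do not match header labels")
    return CorrelationMatrix(residue_labels=labels, C=C, c=np.full_like(C, np.nan))
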