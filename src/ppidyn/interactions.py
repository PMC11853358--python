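"""Geometric interaction detection and occupancy statistics.

Per-frame criteria (all distances in Å, heavy-atom based; hydrogen-aware
angle criteria are applied only when hydrogens are present):

* contact            — minimum inter-residue heavy-atom distance ≤ 4.5
* hydrogen bond      — donor–acceptor ≤ 3.5 (and D–H···A ≥ 135° with H)
* salt bridge        — anion carboxylate O to cation N ≤ 4.0
* hydrophobic        — apolar side-chain carbon pair ≤ 4.5

Occupancy is the exact fraction of analysis frames satisfying the criterion
(integer frame counting, no smoothing); an interaction is "stable" when its
occupancy reaches the configured threshold (default 0.70).

SASA uses Shrake–Rupley quadrature with a deterministic golden-spiral point
set; the buried interface area between chain groups A and B is
(SASA_A + SASA_B − SASA_AB) / 2 per frame (half-buried-surface convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ppidyn.structio import StructureModel, TrajectoryEnsemble

__all__ = [
    "InteractionRecord",
    "SasaResult",
    "InterfaceSeries",
    "DEFAULT_RADII",
    "sasa",
    "interface_area",
    "contact_occupancy",
    "hydrogen_bonds",
    "salt_bridges",
    "classify_interface",
]

#: Bondi-like van der Waals radii (Å) by element; overridable per atom via the
#: force-field parameter table (``intrinsic_radius``).
DEFAULT_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

# donor / acceptor heavy atoms per residue template (backbone N/O included)
_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_ACCEPTORS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"}, "CYS": {"SG"},
}
_ANION_ATOMS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
}
_CATION_ATOMS: dict[str, set[str]] = {
    # ARG: terminal guanidinium nitrogens only; NE is treated as an H-bond
    # donor, not a salt-bridge cation centre
    "LYS": {"NZ"}, "ARG": {"NH1", "NH2"},
}
_CATION_ATOMS_PROTONATED_HIS = {"HIS": {"ND1", "NE2"}}


@dataclass(frozen=True)
class InteractionRecord:
    """One residue–residue interaction with its exact frame occupancy."""

    chain_a: str
    resnum_a: int
    resname_a: str
    chain_b: str
    resnum_b: int
    resname_b: str
    interaction_type: str  # contact | hbond | saltbridge | hydrophobic
    count: int  # frames satisfying the criterion
    n_frames: int
    stable_threshold: float = 0.70

    @property
    def occupancy(self) -> float:
        return self.count / self.n_frames

    @property
    def occupancy_exact(self) -> Fraction:
        return Fraction(self.count, self.n_frames)

    @property
    def stable(self) -> bool:
        return self.occupancy >= self.stable_threshold


@dataclass
class SasaResult:
    """Per-atom solvent-accessible surface areas (Å²)."""

    per_atom: np.ndarray
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


@dataclass
class InterfaceSeries:
    """Per-frame buried interface area (Å²) between two chain groups."""

    areas: np.ndarray
    frame_indices: np.ndarray
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    convention: str = "half-buried-SASA"

    def histogram(self, bins: int = 40) -> tuple[np.ndarray, np.ndarray]:
        """(bin_edges, probabilities); probabilities sum to 1."""
        counts, edges = np.histogram(self.areas, bins=bins)
        return edges, counts / counts.sum()

    def mode(self, bins: int = 40) -> float:
        """Center of the most populated histogram bin (the distribution peak)."""
        edges, probs = self.histogram(bins)
        i = int(np.argmax(probs))
        return float(0.5 * (edges[i] + edges[i + 1]))


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def atom_radii(model: StructureModel) -> np.ndarray:
    """Per-atom radii: the parameter-table radius when present, else the
    element-default table. Raises for atoms with neither."""
    radii = np.empty(model.n_atoms)
    for i, a in enumerate(model.atoms):
        if a.intrinsic_radius is not None:
            radii[i] = a.intrinsic_radius
            continue
        el = (a.element or a.atom_name.strip()[:1]).upper()
        if el not in DEFAULT_RADII:
            raise ValueError(
                f"no radius for atom {a.chain_id}:{a.residue_number}:{a.atom_name} "
                f"(element {el!r})"
            )
        radii[i] = DEFAULT_RADII[el]
    return radii


def sasa(
    model: StructureModel,
    coordinates: np.ndarray | None = None,
    probe: float = 1.4,
    points: int = 960,
    radii: np.ndarray | None = None,
) -> SasaResult:
    """Shrake–Rupley SASA of one conformation.

    Each atom is expanded by the probe radius; the exposed fraction of a
    deterministic ``points``-point sphere quadrature gives its area
    contribution 4π(r+probe)² × exposed/points.
    """
    xyz = np.asarray(coordinates if coordinates is not None else model.coordinates, dtype=float)
    if xyz.shape != (model.n_atoms, 3):
        raise ValueError("coordinates must be A×3 matching the model")
    r = (radii if radii is not None else atom_radii(model)) + probe
    unit = _sphere_points(points)
    tree = cKDTree(xyz)
    out = np.zeros(model.n_atoms)
    rmax = r.max()
    for i in range(model.n_atoms):
        neigh = [j for j in tree.query_ball_point(xyz[i], r[i] + rmax) if j != i]
        pts = xyz[i] + r[i] * unit
        if neigh:
            nb = np.asarray(neigh, dtype=int)
            d2 = np.sum((pts[:, None, :] - xyz[nb][None, :, :]) ** 2, axis=2)
            buried = (d2 < (r[nb] ** 2)[None, :]).any(axis=1)
            exposed = np.count_nonzero(~buried)
        else:
            exposed = points
        out[i] = 4.0 * np.pi * r[i] ** 2 * exposed / points
    return SasaResult(per_atom=out, probe_radius=probe, n_points=points)


def _group_indices(model: StructureModel, chains: Iterable[str]) -> np.ndarray:
    chains = set(chains)
    idx = [i for i, a in enumerate(model.atoms) if a.chain_id in chains]
    if not idx:
        raise ValueError(f"no atoms in chain group {sorted(chains)}")
    return np.asarray(idx, dtype=int)


def interface_area(
    traj: TrajectoryEnsemble,
    group_a: Sequence[str],
    group_b: Sequence[str],
    probe: float = 1.4,
    points: int = 960,
    stride: int = 1,
) -> InterfaceSeries:
    """Per-frame buried interface area between two disjoint chain groups.

    area = (SASA(A alone) + SASA(B alone) − SASA(A∪B)) / 2 — nonnegative, zero
    for separated chains. ``stride`` subsamples analysis frames (SASA is the
    costly step of the pipeline).
    """
    if set(group_a) & set(group_b):
        raise ValueError("chain groups must be disjoint")
    model = traj.topology
    ia = _group_indices(model, group_a)
    ib = _group_indices(model, group_b)
    iab = np.concatenate([ia, ib])
    sub_a = model.subset(list(ia))
    sub_b = model.subset(list(ib))
    sub_ab = model.subset(list(iab))
    radii = atom_radii(model)
    frame_idx = np.arange(traj.analysis_start, traj.n_frames, stride)
    areas = np.empty(frame_idx.size)
    for k, f in enumerate(frame_idx):
        xyz = traj.frames[f]
        s_a = sasa(sub_a, xyz[ia], probe, points, radii=radii[ia]).total
        s_b = sasa(sub_b, xyz[ib], probe, points, radii=radii[ib]).total
        s_ab = sasa(sub_ab, xyz[iab], probe, points, radii=radii[iab]).total
        areas[k] = max(0.0, 0.5 * (s_a + s_b - s_ab))
    return InterfaceSeries(
        areas=areas, frame_indices=frame_idx,
        group_a=tuple(group_a), group_b=tuple(group_b),
    )


# ---------------------------------------------------------------------------
# occupancy machinery
# ---------------------------------------------------------------------------

def _residue_table(model: StructureModel):
    keys = []
    resname = {}
    atoms_of = {}
    for i, a in enumerate(model.atoms):
        k = (a.chain_id, a.residue_number)
        if k not in atoms_of:
            atoms_of[k] = []
            keys.append(k)
            resname[k] = a.residue_name
        atoms_of[k].append(i)
    return keys, resname, {k: np.asarray(v, dtype=int) for k, v in atoms_of.items()}


def _pair_occupancy_counts(
    traj: TrajectoryEnsemble,
    atoms_a: dict,
    atoms_b: dict,
    cutoff: float,
) -> dict[tuple, int]:
    """Frames in which min distance between the two atom sets ≤ cutoff,
    counted for every (key_a, key_b) pair with at least one hit."""
    counts: dict[tuple, int] = {}
    frames = traj.analysis_frames
    keys_a = list(atoms_a)
    keys_b = list(atoms_b)
    ia = [atoms_a[k] for k in keys_a]
    ib = [atoms_b[k] for k in keys_b]
    flat_a = np.concatenate(ia)
    flat_b = np.concatenate(ib)
    own_a = np.concatenate([np.full(len(v), i) for i, v in enumerate(ia)])
    own_b = np.concatenate([np.full(len(v), i) for i, v in enumerate(ib)])
    for f in range(frames.shape[0]):
        ta = cKDTree(frames[f][flat_a])
        tb = cKDTree(frames[f][flat_b])
        hit: set[tuple[int, int]] = set()
        pairs = ta.query_ball_tree(tb, cutoff)
        for qa, lst in enumerate(pairs):
            for qb in lst:
                hit.add((own_a[qa], own_b[qb]))
        for ka, kb in hit:
            key = (keys_a[ka], keys_b[kb])
            counts[key] = counts.get(key, 0) + 1
    return counts


def contact_occupancy(
    traj: TrajectoryEnsemble,
    group_a: Sequence[str] | None = None,
    group_b: Sequence[str] | None = None,
    cutoff: float = 4.5,
    mode: str = "heavy-any",
    stable_threshold: float = 0.70,
    pairs: Sequence[tuple[tuple[str, int], tuple[str, int]]] | None = None,
) -> list[InteractionRecord]:
    """Residue-pair contact occupancy by exact frame counting.

    A pair is in contact in a frame when the minimum pairwise distance between
    its atoms (all heavy atoms, or Cα only with ``mode='ca'``) is ≤ cutoff.
    With chain groups given, only inter-group pairs are reported; with
    ``pairs`` given, only those residue pairs.
    """
    if mode not in ("heavy-any", "ca"):
        raise ValueError("mode must be 'heavy-any' or 'ca'")
    model = traj.topology
    keys, resname, atoms_of = _residue_table(model)

    def _filter(idx: np.ndarray) -> np.ndarray:
        sel = [
            i for i in idx
            if (mode == "heavy-any" and not model.atoms[i].is_hydrogen)
            or (mode == "ca" and model.atoms[i].atom_name == "CA")
        ]
        return np.asarray(sel, dtype=int)

    atoms_of = {k: _filter(v) for k, v in atoms_of.items()}
    atoms_of = {k: v for k, v in atoms_of.items() if v.size}

    if pairs is not None:
        side_a = {p[0]: atoms_of[p[0]] for p in pairs}
        side_b = {p[1]: atoms_of[p[1]] for p in pairs}
        wanted = {(p[0], p[1]) for p in pairs}
    elif group_a is not None and group_b is not None:
        ca_, cb_ = set(group_a), set(group_b)
        side_a = {k: v for k, v in atoms_of.items() if k[0] in ca_}
        side_b = {k: v for k, v in atoms_of.items() if k[0] in cb_}
        wanted = None
    else:
        side_a = atoms_of
        side_b = atoms_of
        wanted = None

    counts = _pair_occupancy_counts(traj, side_a, side_b, cutoff)
    n = traj.n_analysis_frames
    records = []
    seen = set()
    for (ka, kb), c in sorted(counts.items()):
        if ka == kb:
            continue
        if wanted is not None and (ka, kb) not in wanted:
            continue
        if wanted is None and (kb, ka) in seen:
            continue
        seen.add((ka, kb))
        records.append(
            InteractionRecord(
                chain_a=ka[0], resnum_a=ka[1], resname_a=resname[ka],
                chain_b=kb[0], resnum_b=kb[1], resname_b=resname[kb],
                interaction_type="contact", count=c, n_frames=n,
                stable_threshold=stable_threshold,
            )
        )
    if wanted is not None:
        have = {(r.chain_a, r.resnum_a, r.chain_b, r.resnum_b) for r in records}
        for (ka, kb) in wanted:
            if (ka[0], ka[1], kb[0], kb[1]) not in have:
                records.append(
                    InteractionRecord(
                        chain_a=ka[0], resnum_a=ka[1], resname_a=resname[ka],
                        chain_b=kb[0], resnum_b=kb[1], resname_b=resname[kb],
                        interaction_type="contact", count=0, n_frames=n,
                        stable_threshold=stable_threshold,
                    )
                )
    return records


def _typed_pair_records(
    traj: TrajectoryEnsemble,
    atoms_a: dict,
    atoms_b: dict,
    resname: dict,
    cutoff: float,
    itype: str,
    stable_threshold: float,
) -> list[InteractionRecord]:
    if not atoms_a or not atoms_b:
        return []
    counts = _pair_occupancy_counts(traj, atoms_a, atoms_b, cutoff)
    n = traj.n_analysis_frames
    out = []
    seen = set()
    for (ka, kb), c in sorted(counts.items()):
        if ka == kb or (kb, ka) in seen:
            continue
        seen.add((ka, kb))
        out.append(
            InteractionRecord(
                chain_a=ka[0], resnum_a=ka[1], resname_a=resname[ka],
                chain_b=kb[0], resnum_b=kb[1], resname_b=resname[kb],
                interaction_type=itype, count=c, n_frames=n,
                stable_threshold=stable_threshold,
            )
        )
    return out


def _template_atoms(model: StructureModel, table: dict[str, set[str]], extra_backbone: str | None):
    """Residue → atom-index array for template-listed heavy atoms."""
    out: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(model.atoms):
        names = table.get(a.residue_name, set())
        if a.atom_name in names or (extra_backbone and a.atom_name == extra_backbone):
            out.setdefault((a.chain_id, a.residue_number), []).append(i)
    return {k: np.asarray(v, dtype=int) for k, v in out.items()}


def _has_hydrogens(model: StructureModel) -> bool:
    return any(a.is_hydrogen for a in model.atoms)


def hydrogen_bonds(
    traj: TrajectoryEnsemble,
    d_max: float = 3.5,
    angle_min: float = 135.0,
    stable_threshold: float = 0.70,
    include_backbone: bool = True,
) -> list[InteractionRecord]:
    """Hydrogen-bond occupancy between donor and acceptor residues.

    With hydrogens present: D–A ≤ d_max and D–H···A angle ≥ angle_min.
    Without hydrogens (the mode used for heavy-atom-only models): the distance
    criterion alone. The geometric mode should be recorded alongside output.
    """
    model = traj.topology
    _, resname, _ = _residue_table(model)
    bb_d = "N" if include_backbone else None
    bb_a = "O" if include_backbone else None
    donors = _template_atoms(model, _DONORS, bb_d)
    acceptors = _template_atoms(model, _ACCEPTORS, bb_a)
    if _has_hydrogens(model):
        return _hbonds_with_hydrogens(
            traj, donors, acceptors, resname, d_max, angle_min, stable_threshold
        )
    recs = _typed_pair_records(
        traj, donors, acceptors, resname, d_max, "hbond", stable_threshold
    )
    return recs


def _hbonds_with_hydrogens(traj, donors, acceptors, resname, d_max, angle_min, stable_threshold):
    model = traj.topology
    frames = traj.analysis_frames
    n = frames.shape[0]
    # attach hydrogens to donor heavy atoms by proximity in frame 0
    h_idx = np.asarray([i for i, a in enumerate(model.atoms) if a.is_hydrogen], dtype=int)
    counts: dict[tuple, int] = {}
    don_items = [(k, i) for k, v in donors.items() for i in v]
    acc_items = [(k, i) for k, v in acceptors.items() for i in v]
    if not don_items or not acc_items:
        return []
    d_at = np.asarray([i for _, i in don_items])
    a_at = np.asarray([i for _, i in acc_items])
    x0 = frames[0]
    attached: dict[int, np.ndarray] = {}
    if h_idx.size:
        tree_h = cKDTree(x0[h_idx])
        for di in d_at:
            near = tree_h.query_ball_point(x0[di], 1.25)
            attached[di] = h_idx[np.asarray(near, dtype=int)] if near else np.empty(0, int)
    for f in range(n):
        xyz = frames[f]
        ta = cKDTree(xyz[a_at])
        hit: set[tuple] = set()
        for (dk, di) in don_items:
            for qa in ta.query_ball_point(xyz[di], d_max):
                ak, ai = acc_items[qa]
                if ak == dk:
                    continue
                hs = attached.get(di, np.empty(0, int))
                if hs.size:
                    ok = False
                    for hi in hs:
                        v1 = xyz[di] - xyz[hi]
                        v2 = xyz[ai] - xyz[hi]
                        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= angle_min:
                            ok = True
                            break
                    if not ok:
                        continue
                hit.add((dk, ak))
        for pair in hit:
            counts[pair] = counts.get(pair, 0) + 1
    out = []
    seen = set()
    for (ka, kb), c in sorted(counts.items()):
        if (kb, ka) in seen:
            continue
        seen.add((ka, kb))
        out.append(
            InteractionRecord(
                chain_a=ka[0], resnum_a=ka[1], resname_a=resname[ka],
                chain_b=kb[0], resnum_b=kb[1], resname_b=resname[kb],
                interaction_type="hbond", count=c, n_frames=n,
                stable_threshold=stable_threshold,
            )
        )
    return out


def salt_bridges(
    traj: TrajectoryEnsemble,
    d_max: float = 4.0,
    stable_threshold: float = 0.70,
    protonated_his: bool = False,
) -> list[InteractionRecord]:
    """Salt-bridge occupancy: any anion carboxylate O within ``d_max`` of a
    cation amine/guanidinium N counts the frame."""
    model = traj.topology
    _, resname, _ = _residue_table(model)
    cation_table = dict(_CATION_ATOMS)
    if protonated_his:
        cation_table.update(_CATION_ATOMS_PROTONATED_HIS)
    anions = _template_atoms(model, _ANION_ATOMS, None)
    cations = _template_atoms(model, cation_table, None)
    return _typed_pair_records(
        traj, anions, cations, resname, d_max, "saltbridge", stable_threshold
    )


def _apolar_sidechain_carbons(model: StructureModel) -> dict[tuple[str, int], np.ndarray]:
    out: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(model.atoms):
        el = (a.element or a.atom_name[:1]).upper()
        if el == "C" and a.atom_name not in _BACKBONE_NAMES:
            out.setdefault((a.chain_id, a.residue_number), []).append(i)
    return {k: np.asarray(v, dtype=int) for k, v in out.items()}


def classify_interface(
    traj: TrajectoryEnsemble,
    group_a: Sequence[str],
    group_b: Sequence[str],
    hbond_d_max: float = 3.5,
    saltbridge_d_max: float = 4.0,
    hydrophobic_d_max: float = 4.5,
    stable_threshold: float = 0.70,
) -> list[InteractionRecord]:
    """Typed interface interaction table (hbond / saltbridge / hydrophobic).

    Each inter-group residue pair appears once per interaction type with its
    occupancy; a pair may legitimately carry more than one type (e.g. both a
    hydrogen bond and a salt bridge under their respective criteria).
    """
    ca_, cb_ = set(group_a), set(group_b)
    if ca_ & cb_:
        raise ValueError("chain groups must be disjoint")

    def _cross(records: list[InteractionRecord]) -> list[InteractionRecord]:
        out = []
        for r in records:
            if (r.chain_a in ca_ and r.chain_b in cb_) or (r.chain_a in cb_ and r.chain_b in ca_):
                out.append(r)
        return out

    model = traj.topology
    _, resname, _ = _residue_table(model)
    apolar = _apolar_sidechain_carbons(model)
    hydrophobic = _typed_pair_records(
        traj, apolar, apolar, resname, hydrophobic_d_max, "hydrophobic", stable_threshold
    )
    records = (
        _cross(hydrogen_bonds(traj, hbond_d_max, stable_threshold=stable_threshold))
        + _cross(salt_bridges(traj, saltbridge_d_max, stable_threshold=stable_threshold))
        + _cross(hydrophobic)
    )
    return records


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_interactions_tsv(records: list[InteractionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chainA\tresA\tresnameA\tchainB\tresB\tresnameB\ttype\toccupancy\tstable\n")
        for r in records:
            fh.write(
                f"{r.chain_a}\t{r.resnum_a}\t{r.resname_a}\t{r.chain_b}\t{r.resnum_b}\t"
                f"{r.resname_b}\t{r.interaction_type}\t{r.occupancy:.6f}\t{int(r.stable)}\n"
            )


def write_interface_tsv(series: InterfaceSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# convention={series.convention} groupA={','.join(series.group_a)} "
                 f"groupB={','.join(series.group_b)}\n")
        fh.write("frame\tarea_A2\n")
        for f, a in zip(series.frame_indices, series.areas):
            fh.write(f"{f}\t{a:.4f}\n")
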