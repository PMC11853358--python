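"""Structure/trajectory data model, PDB/DCD/XTC readers and writers, selections.

Coordinates are carried internally in Å everywhere (XTC, which stores nm, is
converted on read).  Author residue numbering and chain identifiers from the
input file are preserved end-to-end so that outputs can name residues the way
the source structure does (e.g. D27, R151, C459), including non-contiguous
numbering.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "StructureModel",
    "TrajectoryEnsemble",
    "PDBParseError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory_pdb",
    "write_trajectory_xtc",
    "read_parameter_table",
    "write_parameter_table",
    "select",
]

_HYDROGEN_RE = re.compile(r"^\d*H")


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be parsed; names the offending line."""


class SelectionError(ValueError):
    """Raised for an unparseable selection expression; reports the position."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, coordinates (Å) and optional force-field terms.

    ``partial_charge`` is in elementary charges, ``intrinsic_radius`` and
    ``lj_rmin_half`` in Å, ``lj_epsilon`` in kcal/mol.
    """

    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coordinates: np.ndarray
    partial_charge: float | None = None
    intrinsic_radius: float | None = None
    lj_epsilon: float | None = None
    lj_rmin_half: float | None = None

    def __post_init__(self) -> None:
        xyz = np.asarray(self.coordinates, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError(f"atom {self.atom_name}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coordinates", xyz)
        if self.intrinsic_radius is not None and self.intrinsic_radius <= 0:
            raise ValueError(f"atom {self.atom_name}: intrinsic radius must be > 0")

    @property
    def is_hydrogen(self) -> bool:
        if self.element:
            return self.element.upper() == "H"
        return bool(_HYDROGEN_RE.match(self.atom_name.strip()))


@dataclass
class StructureModel:
    """An ordered list of atoms partitioned into chains.

    Atom order is stable: every derived output (selections, matrices,
    trajectories) indexes into this order.
    """

    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.atom_name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in model")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    @property
    def chain_partition(self) -> dict[str, np.ndarray]:
        part: dict[str, list[int]] = {}
        for i, a in enumerate(self.atoms):
            part.setdefault(a.chain_id, []).append(i)
        return {c: np.asarray(ix, dtype=int) for c, ix in part.items()}

    def residues(self, indices: Sequence[int] | None = None) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, resnum, resname) keys covering ``indices``."""
        idx = range(len(self.atoms)) if indices is None else indices
        out: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for i in idx:
            a = self.atoms[i]
            if (a.chain_id, a.residue_number) not in seen:
                seen.add((a.chain_id, a.residue_number))
                out.append((a.chain_id, a.residue_number, a.residue_name))
        return out

    def residue_atom_indices(self) -> dict[tuple[str, int], np.ndarray]:
        out: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault((a.chain_id, a.residue_number), []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}

    def with_coordinates(self, xyz: np.ndarray) -> "StructureModel":
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"expected coordinates of shape ({len(self.atoms)}, 3), got {xyz.shape}")
        return StructureModel([replace(a, coordinates=xyz[i]) for i, a in enumerate(self.atoms)])

    def subset(self, indices: Sequence[int]) -> "StructureModel":
        return StructureModel([self.atoms[i] for i in indices])


@dataclass
class TrajectoryEnsemble:
    """A topology plus an F × A × 3 coordinate block in Å.

    ``analysis_start`` marks the first frame used by every analysis stage —
    the equilibration discard (production runs typically equilibrate over an
    initial segment that is excluded from statistics).
    """

    topology: StructureModel
    frames: np.ndarray
    frame_times: np.ndarray | None = None
    analysis_start: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, A, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count mismatch: topology has {self.topology.n_atoms}, "
                f"frames have {self.frames.shape[1]}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if not (0 <= self.analysis_start < self.frames.shape[0]):
            raise ValueError("analysis_start must be a valid frame index")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    @property
    def analysis_frames(self) -> np.ndarray:
        return self.frames[self.analysis_start:]

    @property
    def n_analysis_frames(self) -> int:
        return self.n_frames - self.analysis_start


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, str, float]:
    """Parse an ATOM/HETATM fixed-column record → (record, altloc, occupancy)."""
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if not name:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: empty atom name")
    rec = AtomRecord(
        atom_name=name,
        element=element,
        residue_name=resname,
        residue_number=resnum,
        chain_id=chain,
        coordinates=np.array([x, y, z]),
    )
    return rec, altloc, occupancy


def _read_pdb_models(text: str) -> list[list[tuple[AtomRecord, str, float]]]:
    models: list[list[tuple[AtomRecord, str, float]]] = []
    current: list[tuple[AtomRecord, str, float]] = []
    in_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec6 = line[:6]
        if rec6 == "MODEL ":
            if current:
                models.append(current)
                current = []
            in_model = True
        elif rec6 == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif rec6 in ("ATOM  ", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
    if current or not models:
        models.append(current)
    del in_model
    return [m for m in models if m] or [[]]


def _resolve_altloc(parsed: list[tuple[AtomRecord, str, float]]) -> list[AtomRecord]:
    """Keep one conformer per atom: the highest-occupancy altloc (ties: first)."""
    best: dict[tuple[str, int, str], tuple[float, int, AtomRecord]] = {}
    order: list[tuple[str, int, str]] = []
    for i, (rec, altloc, occ) in enumerate(parsed):
        key = (rec.chain_id, rec.residue_number, rec.atom_name)
        if key not in best:
            best[key] = (occ, i, rec)
            order.append(key)
        elif altloc and occ > best[key][0]:
            best[key] = (occ, best[key][1], rec)
    return [best[k][2] for k in order]


def read_structure(path: str | Path, format: str = "pdb") -> StructureModel:
    """Read a structure file into a :class:`StructureModel`.

    Altloc groups are resolved to the highest-occupancy conformer; author
    residue numbering and chain identifiers are preserved.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format: {format!r}")
    text = Path(path).read_text()
    models = _read_pdb_models(text)
    atoms = _resolve_altloc(models[0])
    if not atoms:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    return StructureModel(atoms)


def _format_atom_line(i: int, a: AtomRecord) -> str:
    name = a.atom_name
    # PDB convention: 1-3 char names start in column 14 unless 4 chars long
    name_field = f" {name:<3s}" if len(name) < 4 else name
    x, y, z = a.coordinates
    return (
        f"ATOM  {i:5d} {name_field}{'':1s}{a.residue_name:>3s} {a.chain_id:1s}"
        f"{a.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {a.element:>2s}"
    )


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a single-model PDB file (atom order, numbering, chains preserved)."""
    lines = []
    serial = 0
    prev_chain = None
    for a in model.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        serial += 1
        lines.append(_format_atom_line(serial, a))
        prev_chain = a.chain_id
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory_pdb(traj: TrajectoryEnsemble, path: str | Path) -> None:
    """Write a multi-model PDB trajectory."""
    buf = io.StringIO()
    for f in range(traj.n_frames):
        buf.write(f"MODEL     {f + 1:4d}\n")
        serial = 0
        for a, xyz in zip(traj.topology.atoms, traj.frames[f]):
            serial += 1
            buf.write(_format_atom_line(serial, replace(a, coordinates=xyz)) + "\n")
        buf.write("ENDMDL\n")
    buf.write("END\n")
    Path(path).write_text(buf.getvalue())


def write_trajectory_xtc(traj: TrajectoryEnsemble, path: str | Path) -> None:
    """Write an XTC trajectory (nm on disk, converted from the Å in memory)."""
    import MDAnalysis as mda

    n = traj.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    with mda.Writer(str(path), n_atoms=n) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.frames[f]  # MDAnalysis holds Å; XTC writer emits nm
            w.write(u.atoms)


def read_trajectory(
    path: str | Path,
    topology: StructureModel,
    format: str | None = None,
    analysis_start: int = 0,
) -> TrajectoryEnsemble:
    """Read a coordinate trajectory against a topology.

    Multi-model PDB is parsed natively; DCD and XTC go through MDAnalysis
    (which yields Å for both formats, converting XTC's stored nm).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        models = _read_pdb_models(path.read_text())
        frames = []
        for m in models:
            atoms = _resolve_altloc(m)
            if len(atoms) != topology.n_atoms:
                raise ValueError(
                    f"atom-count mismatch: expected {topology.n_atoms}, found {len(atoms)}"
                )
            frames.append([a.coordinates for a in atoms])
        return TrajectoryEnsemble(topology, np.asarray(frames), analysis_start=analysis_start)
    if fmt in ("dcd", "xtc"):
        import MDAnalysis as mda

        u = mda.Universe.empty(topology.n_atoms, trajectory=True)
        try:
            u.load_new(str(path))
        except (ValueError, IOError, EOFError) as exc:
            raise ValueError(
                f"cannot read {fmt.upper()} trajectory with expected atom count "
                f"{topology.n_atoms}: {exc}"
            ) from exc
        if u.trajectory.n_atoms != topology.n_atoms:
            raise ValueError(
                f"atom-count mismatch: expected {topology.n_atoms}, "
                f"found {u.trajectory.n_atoms}"
            )
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
        return TrajectoryEnsemble(topology, frames, analysis_start=analysis_start)
    raise ValueError(f"unsupported trajectory format: {fmt!r}")


# ---------------------------------------------------------------------------
# Force-field parameter table
# ---------------------------------------------------------------------------

_PARAM_COLUMNS = ["chain", "resnum", "atom", "charge", "radius", "eps", "rmin_half"]


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    """Read the whitespace-delimited per-atom parameter table.

    Columns: ``chain resnum atom charge radius eps rmin_half`` (charge in e,
    radius and r_min/2 in Å, ε in kcal/mol).
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    missing = [c for c in _PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"parameter table missing columns: {missing}")
    df["chain"] = df["chain"].astype(str)
    df["resnum"] = df["resnum"].astype(int)
    return df[_PARAM_COLUMNS]


def write_parameter_table(df: pd.DataFrame, path: str | Path) -> None:
    df[_PARAM_COLUMNS].to_csv(path, sep="\t", index=False)


def apply_parameters(model: StructureModel, table: pd.DataFrame) -> StructureModel:
    """Return a copy of ``model`` with per-atom force-field terms filled in."""
    lut = {
        (str(r.chain), int(r.resnum), str(r.atom)): r
        for r in table.itertuples(index=False)
    }
    atoms = []
    for a in model.atoms:
        row = lut.get((a.chain_id, a.residue_number, a.atom_name))
        if row is None:
            atoms.append(a)
        else:
            atoms.append(
                replace(
                    a,
                    partial_charge=float(row.charge),
                    intrinsic_radius=float(row.radius),
                    lj_epsilon=float(row.eps),
                    lj_rmin_half=float(row.rmin_half),
                )
            )
    return StructureModel(atoms)


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------
# Grammar:  expr := term ('or' term)* ; term := factor ('and' factor)* ;
# factor := 'not' factor | '(' expr ')' | primitive
# primitives: all | heavy | hydrogen | name N1 N2.. | chain C1 C2.. |
#             resname R1 R2.. | resid A-B C ...

_TOKEN_RE = re.compile(r"\s*([()]|[^\s()]+)")


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if not m:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _SelParser:
    def __init__(self, model: StructureModel, expr: str):
        self.model = model
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.i = 0

    def _peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _pos(self) -> int:
        return self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.expr)

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise SelectionError(f"unexpected end of selection at position {len(self.expr)}")
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self._expr()
        if self._peek() is not None:
            raise SelectionError(
                f"unexpected token {self._peek()!r} at position {self._pos()}"
            )
        return mask

    def _expr(self) -> np.ndarray:
        mask = self._term()
        while self._peek() == "or":
            self._next()
            mask = mask | self._term()
        return mask

    def _term(self) -> np.ndarray:
        mask = self._factor()
        while self._peek() == "and":
            self._next()
            mask = mask & self._factor()
        return mask

    def _factor(self) -> np.ndarray:
        tok = self._peek()
        if tok == "not":
            self._next()
            return ~self._factor()
        if tok == "(":
            self._next()
            mask = self._expr()
            if self._peek() != ")":
                raise SelectionError(f"expected ')' at position {self._pos()}")
            self._next()
            return mask
        return self._primitive()

    def _values(self) -> list[str]:
        vals = []
        stop = {"and", "or", "not", "(", ")"}
        while self._peek() is not None and self._peek() not in stop:
            vals.append(self._next())
        if not vals:
            raise SelectionError(f"expected value at position {self._pos()}")
        return vals

    def _primitive(self) -> np.ndarray:
        atoms = self.model.atoms
        pos = self._pos()
        tok = self._next()
        if tok == "all":
            return np.ones(len(atoms), dtype=bool)
        if tok == "heavy":
            return np.array([not a.is_hydrogen for a in atoms])
        if tok == "hydrogen":
            return np.array([a.is_hydrogen for a in atoms])
        if tok == "name":
            names = set(self._values())
            return np.array([a.atom_name in names for a in atoms])
        if tok == "chain":
            chains = set(self._values())
            return np.array([a.chain_id in chains for a in atoms])
        if tok == "resname":
            rn = set(self._values())
            return np.array([a.residue_name in rn for a in atoms])
        if tok == "resid":
            ranges: list[tuple[int, int]] = []
            for v in self._values():
                try:
                    if "-" in v[1:]:
                        lo, hi = v.split("-", 1) if not v.startswith("-") else (v, v)
                        ranges.append((int(lo), int(hi)))
                    else:
                        ranges.append((int(v), int(v)))
                except ValueError as exc:
                    raise SelectionError(f"bad resid value {v!r} at position {pos}") from exc
            return np.array(
                [any(lo <= a.residue_number <= hi for lo, hi in ranges) for a in atoms]
            )
        raise SelectionError(f"unknown selection keyword {tok!r} at position {pos}")


def select(model: StructureModel, expr: str) -> np.ndarray:
    """Resolve a selection expression to an ordered atom index array.

    The returned indices follow topology order, so selection is deterministic
    and idempotent.
    """
    if not expr or not expr.strip():
        raise SelectionError("empty selection expression")
    mask = _SelParser(model, expr.strip()).parse()
    return np.flatnonzero(mask)
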