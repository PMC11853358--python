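"""Synthetic two-chain complexes and stochastic trajectories with planted truth.

Production MD trajectories are rarely deposited, so every pipeline stage here
is validated against generated ensembles whose statistical structure is fully
known in advance:

* **Geometry** — two Cα-bead chains laid out on parallel lines across an
  interface gap; author residue numbering may be non-contiguous (segments),
  as in real PDB entries. Residues participating in planted interactions get
  typed side-chain pseudo-atoms (carboxylate O, amine/guanidinium N, donor
  N / acceptor OH, apolar carbons).
* **Fluctuations** — residue displacements are Gaussian with a planted block
  covariance: residues in a block share a latent 3-vector (variance ρσ²) on
  top of independent noise ((1−ρ)σ²), so the planted pairwise correlation
  within a block is exactly ρ.
* **Collective modes** — optional global modes (an interface "breathing"
  translation, a sine-shaped internal wave) with Gaussian amplitudes, plus a
  deterministic approach/departure drift of one chain along the interface
  normal.
* **Interaction schedules** — each planted residue pair is ON in exactly
  k = occupancy × F frames (a seeded permutation chooses which); on ON frames
  the follower atom is placed at the bound distance from its anchor, on OFF
  frames well outside every criterion, so downstream occupancies are exact
  rationals by construction.
* **Community structure** — contact schedules densify residue blocks into
  graph communities; a designated hub residue bridges the interface in the
  "wt-like" scenario and loses its contacts in the "mutant-like" one.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from ppidyn.structio import AtomRecord, StructureModel, TrajectoryEnsemble

__all__ = [
    "Segment",
    "Block",
    "Mode",
    "Schedule",
    "SyntheticSpec",
    "PlantedTruth",
    "make_complex",
    "simulate_trajectory",
    "make_scenario_pair",
    "make_two_block_spec",
]

_X = np.array([1.0, 0.0, 0.0])

# bound / unbound anchor–follower distances per interaction kind (Å).
# ON distances sit inside each criterion; the salt-bridge ON distance (3.8,
# within the 4.0 N–O criterion but outside the 3.5 H-bond one) keeps pairs
# that carry both a salt-bridge and an H-bond schedule independently exact.
_D_ON = {"saltbridge": 3.8, "hbond": 2.9, "contact": 3.8, "hydrophobic": 4.0}
_D_OFF = 8.0
_OFF_KICK = np.array([0.0, 0.0, 2.0])  # lifts unbound followers off the chain plane
_ANCHOR_OFFSET = 2.5

_RADII = {"C": 1.7, "N": 1.55, "O": 1.5}
_CHARGES = {"OD1": -0.5, "OD2": -0.5, "OE1": -0.5, "OE2": -0.5,
            "NZ": 1.0, "NH1": 0.5, "NH2": 0.5}


@dataclass(frozen=True)
class Segment:
    """A contiguous stretch of author numbering placed along the chain line."""

    first: int
    last: int
    x_start: float
    y: float = 0.0
    z: float = 0.0


@dataclass(frozen=True)
class Block:
    """A correlation block: members share a latent displacement (corr = rho)."""

    name: str
    members: tuple[tuple[str, int, int], ...]  # (chain, lo, hi) residue ranges
    rho: float = 0.55
    amplitude: float = 0.35  # per-axis displacement sd, Å

    def contains(self, chain: str, resnum: int) -> bool:
        return any(c == chain and lo <= resnum <= hi for c, lo, hi in self.members)


@dataclass(frozen=True)
class Mode:
    """A planted collective mode with Gaussian amplitude (sd in Å).

    kinds: ``breathing`` — chains translate against each other along the
    interface normal; ``wave`` — sine-shaped displacement along z with
    wavelength ``wavelength`` (Å) in x. ``normalize`` rescales the mode
    vector to unit norm so its PCA eigenvalue equals sigma².
    """

    kind: str
    sigma: float
    wavelength: float = 80.0
    normalize: bool = False


@dataclass(frozen=True)
class Schedule:
    """A planted interaction with an exact target occupancy (= count/frames)."""

    res_a: tuple[str, int]
    res_b: tuple[str, int]
    kind: str  # saltbridge | hbond | contact | hydrophobic
    occupancy: float

    def count(self, frames: int) -> int:
        k = self.occupancy * frames
        if abs(k - round(k)) > 1e-9:
            raise ValueError(
                f"occupancy {self.occupancy} is not representable as k/{frames} "
                f"for pair {self.res_a}-{self.res_b}"
            )
        return int(round(k))


@dataclass
class SyntheticSpec:
    """Full description of a synthetic two-chain dataset."""

    chains: dict[str, list[Segment]]
    frames: int = 500
    seed: int = 0
    spacing: float = 3.8
    blocks: list[Block] = field(default_factory=list)
    modes: list[Mode] = field(default_factory=list)
    drift: float = 0.0  # total gap change over the run (+ = departing), Å
    drift_chain: str = "P"
    schedules: list[Schedule] = field(default_factory=list)
    resnames: dict[tuple[str, int], str] = field(default_factory=dict)
    hub: tuple[str, int] | None = None

    def residue_list(self) -> list[tuple[str, int]]:
        out = []
        for cid, segs in self.chains.items():
            for s in segs:
                out.extend((cid, r) for r in range(s.first, s.last + 1))
        return out


@dataclass
class PlantedTruth:
    """Ground truth emitted with every dataset: enough to score every stage."""

    occupancies: dict[tuple[tuple[str, int], tuple[str, int], str], Fraction]
    block_of: dict[tuple[str, int], str]
    block_rho: dict[str, float]
    mode_sigmas: dict[str, float]
    hub: tuple[str, int] | None
    drift: float

    def to_text(self) -> str:
        lines = ["# planted truth"]
        lines.append(f"drift: {self.drift}")
        lines.append(f"hub: {self.hub}")
        for name, s in self.mode_sigmas.items():
            lines.append(f"mode_sigma {name}: {s}")
        for (a, b, kind), occ in sorted(self.occupancies.items()):
            lines.append(f"occupancy {a[0]}:{a[1]} {b[0]}:{b[1]} {kind}: {occ}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# complex construction
# ---------------------------------------------------------------------------

def _base_ca_positions(spec: SyntheticSpec) -> dict[tuple[str, int], np.ndarray]:
    pos = {}
    for cid, segs in spec.chains.items():
        for s in segs:
            for i, r in enumerate(range(s.first, s.last + 1)):
                pos[(cid, r)] = np.array([s.x_start + i * spec.spacing, s.y, s.z])
    return pos


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


def _required_resnames(spec: SyntheticSpec) -> dict[tuple[str, int], str]:
    """Residue names implied by the planted interaction types."""
    names = dict(spec.resnames)

    def _want(key, default):
        names.setdefault(key, default)

    for s in spec.schedules:
        if s.kind == "saltbridge":
            _want(s.res_a, "ASP")
            _want(s.res_b, "LYS")
        elif s.kind == "hbond":
            if names.get(s.res_a) in ("ASP", "GLU"):
                _want(s.res_b, "ARG")
            else:
                _want(s.res_a, "PHE")
                _want(s.res_b, "TYR")
        elif s.kind == "hydrophobic":
            _want(s.res_a, "LEU")
            _want(s.res_b, "ILE")
    return names


def make_complex(spec: SyntheticSpec) -> tuple[StructureModel, pd.DataFrame]:
    """Build the bead model and its per-atom force-field parameter table.

    Deterministic given the spec: same spec (and seed) → byte-identical PDB.
    """
    for s in spec.schedules:
        s.count(spec.frames)  # validate representability up front
    ca = _base_ca_positions(spec)
    names = _required_resnames(spec)
    atoms_of: dict[tuple[str, int], list[AtomRecord]] = {}
    for key in spec.residue_list():
        resname = names.get(key, "GLY")
        atoms_of[key] = [
            AtomRecord("CA", "C", resname, key[1], key[0], ca[key])
        ]

    def _ensure(key, atom_name, element, position) -> None:
        if not any(a.atom_name == atom_name for a in atoms_of[key]):
            atoms_of[key].append(
                AtomRecord(atom_name, element, names.get(key, "GLY"), key[1], key[0], position)
            )

    q_counter: dict[tuple[str, int], int] = {}

    def _next_q(key) -> str:
        q_counter[key] = q_counter.get(key, 0) + 1
        return f"Q{q_counter[key]}"

    for s in spec.schedules:
        if s.res_a not in ca or s.res_b not in ca:
            raise ValueError(f"schedule references unknown residue {s.res_a} or {s.res_b}")
        u = _unit(ca[s.res_b] - ca[s.res_a])
        # secondary atoms are offset away from the partner side so they never
        # produce accidental criterion hits of their own
        a_sec = -_X if u[0] >= 0 else _X  # anchor secondary: away from follower
        f_sec = -a_sec  # follower secondary: away from anchor
        # contact pseudo-atoms hug their own backbone so the anchor keeps a
        # safe margin to the partner residue's Cα under fluctuation noise
        offset = 0.5 if s.kind == "contact" else _ANCHOR_OFFSET
        anchor_pos = ca[s.res_a] + offset * u
        d_on = _D_ON[s.kind]
        if s.kind == "saltbridge":
            _ensure(s.res_a, "OD1" if names[s.res_a] == "ASP" else "OE1", "O", anchor_pos)
            _ensure(s.res_a, "OD2" if names[s.res_a] == "ASP" else "OE2", "O", anchor_pos + a_sec)
            if names[s.res_b] == "ARG":
                _ensure(s.res_b, "NH1", "N", anchor_pos + d_on * u)
                _ensure(s.res_b, "NH2", "N", anchor_pos + d_on * u + f_sec)
            else:
                _ensure(s.res_b, "NZ", "N", anchor_pos + d_on * u)
        elif s.kind == "hbond":
            if names.get(s.res_a) in ("ASP", "GLU"):
                _ensure(s.res_a, "OE1" if names[s.res_a] == "GLU" else "OD1", "O", anchor_pos)
                _ensure(s.res_b, "NE", "N", anchor_pos + d_on * u)
            else:
                _ensure(s.res_a, "N", "N", anchor_pos)
                _ensure(s.res_b, "OH", "O", anchor_pos + d_on * u)
        elif s.kind == "hydrophobic":
            _ensure(s.res_a, "CD1", "C", anchor_pos)
            _ensure(s.res_b, "CD1", "C", anchor_pos + d_on * u)
        elif s.kind == "contact":
            _ensure(s.res_a, _next_q(s.res_a), "C", anchor_pos)
            _ensure(s.res_b, _next_q(s.res_b), "C", anchor_pos + d_on * u)
        else:
            raise ValueError(f"unknown schedule kind {s.kind!r}")

    atoms: list[AtomRecord] = []
    for key in spec.residue_list():
        atoms.extend(atoms_of[key])
    model = StructureModel(atoms)

    rows = []
    for a in model.atoms:
        rows.append(
            {
                "chain": a.chain_id,
                "resnum": a.residue_number,
                "atom": a.atom_name,
                "charge": _CHARGES.get(a.atom_name, 0.0),
                "radius": _RADII.get(a.element, 1.7),
                # dispersion lives on the backbone beads only; the planted
                # side-group pseudo-atoms carry charge (and GB radii) but no
                # LJ well, so scheduled approaches cannot create steric spikes
                "eps": 0.1 if a.atom_name == "CA" else 0.0,
                "rmin_half": 2.0 if a.element == "C" else 1.5,
            }
        )
    return model, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def _block_of_residue(spec: SyntheticSpec) -> dict[tuple[str, int], str]:
    out = {}
    for key in spec.residue_list():
        for b in spec.blocks:
            if b.contains(*key):
                out[key] = b.name
                break
        else:
            out[key] = f"_solo_{key[0]}_{key[1]}"
    return out


def _mode_vector(mode: Mode, model: StructureModel, base: np.ndarray, chain_ids: list[str]) -> np.ndarray:
    n = model.n_atoms
    w = np.zeros((n, 3))
    if mode.kind == "breathing":
        # first chain moves +y, every other chain −y (relative approach axis)
        first = chain_ids[0]
        for i, a in enumerate(model.atoms):
            w[i, 1] = 0.5 if a.chain_id == first else -0.5
    elif mode.kind == "wave":
        w[:, 2] = np.sin(2.0 * np.pi * base[:, 0] / mode.wavelength)
    else:
        raise ValueError(f"unknown mode kind {mode.kind!r}")
    if mode.normalize:
        w /= np.linalg.norm(w)
    return w


def simulate_trajectory(
    model: StructureModel,
    spec: SyntheticSpec,
) -> tuple[TrajectoryEnsemble, PlantedTruth]:
    """Generate the stochastic trajectory and its ground truth.

    Displacement order of operations per frame: block/residue Gaussian noise →
    collective modes → chain drift → interaction schedules (followers placed
    relative to their anchor's instantaneous position, so each planted
    occupancy is hit exactly).
    """
    rng = np.random.default_rng(spec.seed)
    F = spec.frames
    n = model.n_atoms
    base = model.coordinates
    chain_ids = model.chain_ids

    res_keys = []
    res_of_atom = np.empty(n, dtype=int)
    index_of = {}
    for i, a in enumerate(model.atoms):
        k = (a.chain_id, a.residue_number)
        if k not in index_of:
            index_of[k] = len(res_keys)
            res_keys.append(k)
        res_of_atom[i] = index_of[k]
    n_res = len(res_keys)

    block_of = _block_of_residue(spec)
    block_names = sorted({block_of[k] for k in res_keys})
    block_idx = {name: i for i, name in enumerate(block_names)}
    rho_of = {b.name: b.rho for b in spec.blocks}
    amp_of = {b.name: b.amplitude for b in spec.blocks}

    # residue-level displacements: shared block latent + independent noise
    disp_res = np.zeros((F, n_res, 3))
    shared = {}
    for name in block_names:
        rho = rho_of.get(name, 0.0)
        amp = amp_of.get(name, spec.blocks[0].amplitude if spec.blocks else 0.0)
        shared[name] = rng.normal(0.0, amp * np.sqrt(rho), size=(F, 3)) if amp > 0 else np.zeros((F, 3))
    for ri, key in enumerate(res_keys):
        name = block_of[key]
        rho = rho_of.get(name, 0.0)
        amp = amp_of.get(name, spec.blocks[0].amplitude if spec.blocks else 0.0)
        indep = rng.normal(0.0, amp * np.sqrt(1.0 - rho), size=(F, 3)) if amp > 0 else 0.0
        disp_res[:, ri, :] = shared[name] + indep

    frames = base[None, :, :] + disp_res[:, res_of_atom, :]

    mode_sigmas = {}
    for m in spec.modes:
        w = _mode_vector(m, model, base, chain_ids)
        a_t = rng.normal(0.0, m.sigma, size=F)
        frames += a_t[:, None, None] * w[None, :, :]
        mode_sigmas[m.kind] = m.sigma

    if spec.drift != 0.0 and F > 1:
        drift_atoms = np.array([a.chain_id == spec.drift_chain for a in model.atoms])
        t = np.arange(F) / (F - 1)
        frames[:, drift_atoms, 1] += spec.drift * t[:, None]

    # planted interaction schedules
    atom_index = {
        (a.chain_id, a.residue_number, a.atom_name): i for i, a in enumerate(model.atoms)
    }
    names = _required_resnames(spec)
    ca = _base_ca_positions(spec)
    occupancies = {}
    q_counter: dict[tuple[str, int], int] = {}

    def _next_q(key) -> str:
        q_counter[key] = q_counter.get(key, 0) + 1
        return f"Q{q_counter[key]}"

    for s in spec.schedules:
        u = _unit(ca[s.res_b] - ca[s.res_a])
        f_sec = _X if u[0] >= 0 else -_X
        if s.kind == "saltbridge":
            anchor = "OD1" if names[s.res_a] == "ASP" else "OE1"
            follower = "NH1" if names[s.res_b] == "ARG" else "NZ"
            secondary = [("NH2", f_sec)] if names[s.res_b] == "ARG" else []
        elif s.kind == "hbond":
            if names.get(s.res_a) in ("ASP", "GLU"):
                anchor = "OE1" if names[s.res_a] == "GLU" else "OD1"
                follower = "NE"
            else:
                anchor, follower = "N", "OH"
            secondary = []
        elif s.kind == "hydrophobic":
            anchor, follower, secondary = "CD1", "CD1", []
        else:  # contact
            anchor, follower, secondary = _next_q(s.res_a), _next_q(s.res_b), []
        ja = atom_index[(s.res_a[0], s.res_a[1], anchor)]
        jf = atom_index[(s.res_b[0], s.res_b[1], follower)]
        k = s.count(F)
        on = np.zeros(F, dtype=bool)
        on[rng.permutation(F)[:k]] = True
        d = np.where(on, _D_ON[s.kind], _D_OFF)
        frames[:, jf, :] = frames[:, ja, :] + d[:, None] * u[None, :] \
            + np.where(on, 0.0, 1.0)[:, None] * _OFF_KICK[None, :]
        for sec_name, off in secondary:
            js = atom_index[(s.res_b[0], s.res_b[1], sec_name)]
            frames[:, js, :] = frames[:, jf, :] + off[None, :]
        occupancies[(s.res_a, s.res_b, s.kind)] = Fraction(k, F)

    truth = PlantedTruth(
        occupancies=occupancies,
        block_of=block_of,
        block_rho={b.name: b.rho for b in spec.blocks},
        mode_sigmas=mode_sigmas,
        hub=spec.hub,
        drift=spec.drift,
    )
    return TrajectoryEnsemble(model, frames), truth


def generate(spec: SyntheticSpec) -> tuple[StructureModel, pd.DataFrame, TrajectoryEnsemble, PlantedTruth]:
    """Convenience: build the complex and simulate its trajectory."""
    model, params = make_complex(spec)
    traj, truth = simulate_trajectory(model, spec)
    return model, params, traj, truth


# ---------------------------------------------------------------------------
# study scenarios
# ---------------------------------------------------------------------------

def _densify(
    blocks: list[Block],
    occ: float = 1.0,
    step: int = 2,
    spans: tuple[int, ...] = (2,),
) -> list[Schedule]:
    """Intra-block (i, i+span) contact schedules that turn blocks into graph
    communities (the backbone path alone has no modular structure)."""
    out = []
    for b in blocks:
        for chain, lo, hi in b.members:
            for span in spans:
                for i in range(lo, hi - span + 1, step):
                    out.append(Schedule((chain, i), (chain, i + span), "contact", occ))
    return out


_GAP = 7.5
_M_SEGS = [Segment(1, 91, 3.8, 0.0, 0.0)]
_P_SEGS = [
    Segment(145, 170, 281.2, _GAP, 0.0),   # pairs with the ligand's 74–91 stretch
    Segment(230, 250, 76.0, _GAP, 0.0),    # pairs with the ligand's 20–40 stretch
    Segment(450, 470, 273.6, _GAP, 7.0),   # hub segment, offset in z
]

_WT_BLOCKS = [
    Block("M1", (("M", 1, 45),)),
    Block("M2", (("M", 46, 78),)),
    Block("M3", (("M", 85, 91),)),
    Block("IFACE", (("M", 79, 84), ("P", 150, 155), ("P", 457, 461)), rho=0.65),
    Block("P1a", (("P", 145, 149),)),
    Block("P1b", (("P", 156, 170),)),
    Block("P2", (("P", 230, 250),)),
    Block("P3a", (("P", 450, 456),)),
    Block("P3b", (("P", 462, 470),)),
]

_MUT_BLOCKS = [
    Block("M1", (("M", 1, 45),)),
    Block("M2", (("M", 46, 91),)),
    Block("P1", (("P", 145, 170),)),
    Block("P2", (("P", 230, 250),)),
    Block("P3", (("P", 450, 470),)),
]

# polar/hydrophobic interface schedules: (res_a, res_b, kind, wt occ, mut occ)
# occupancy contrasts follow the wild-type vs mutant pattern of destabilised
# interfaces (all values exact k/500)
_IFACE_SCHEDULES = [
    (("M", 82), ("P", 151), "saltbridge", 389 / 500, 17 / 500),
    (("M", 82), ("P", 151), "hbond", 170 / 500, 6 / 500),
    (("M", 81), ("P", 152), "hbond", 316 / 500, 13 / 500),
    (("M", 27), ("P", 237), "saltbridge", 270 / 500, 122 / 500),
    (("M", 28), ("P", 235), "saltbridge", 230 / 500, 99 / 500),
    (("M", 28), ("P", 239), "saltbridge", 180 / 500, 47 / 500),
    (("M", 30), ("P", 240), "hydrophobic", 450 / 500, 200 / 500),
    (("M", 85), ("P", 156), "hydrophobic", 425 / 500, 150 / 500),
    (("M", 20), ("P", 230), "contact", 375 / 500, 150 / 500),
]

_HUB = ("P", 459)
_HUB_CONTACTS = [("M", 80), ("M", 81), ("M", 82), ("M", 83), ("P", 151), ("P", 152)]

_RESNAMES = {
    ("M", 27): "ASP", ("M", 28): "ASP", ("M", 81): "PHE", ("M", 82): "GLU",
    ("P", 151): "ARG", ("P", 152): "TYR", ("P", 235): "ARG", ("P", 237): "LYS",
    ("P", 239): "LYS", ("P", 459): "CYS",
}


def scenario_spec(style: str, seed: int, frames: int = 500) -> SyntheticSpec:
    """The spec for one comparison arm.

    ``wt-like``: narrow basin (small breathing mode), approaching drift, high
    interface occupancies, an interface correlation block, and a hub residue
    whose contacts stitch the two chains together. ``mutant-like``: one
    dominant large-amplitude internal mode, departing drift, low occupancies,
    hub contacts removed. These are the only planted contrasts.
    """
    if style == "wt-like":
        blocks = _WT_BLOCKS
        modes = [Mode("breathing", sigma=0.6)]
        drift = -0.4
        schedules = [Schedule(a, b, kind, wt) for a, b, kind, wt, _ in _IFACE_SCHEDULES]
        schedules += [Schedule(_HUB, other, "contact", 1.0) for other in _HUB_CONTACTS]
        hub = _HUB
    elif style == "mutant-like":
        blocks = _MUT_BLOCKS
        modes = [Mode("breathing", sigma=0.2), Mode("wave", sigma=1.5)]
        drift = 0.8
        schedules = [Schedule(a, b, kind, mut) for a, b, kind, _, mut in _IFACE_SCHEDULES]
        hub = _HUB
    else:
        raise ValueError("style must be 'wt-like' or 'mutant-like'")
    schedules += _densify(blocks)
    return SyntheticSpec(
        chains={"M": list(_M_SEGS), "P": list(_P_SEGS)},
        frames=frames,
        seed=seed,
        blocks=list(blocks),
        modes=modes,
        drift=drift,
        schedules=schedules,
        resnames=dict(_RESNAMES),
        hub=hub,
    )


def make_scenario_pair(seed: int, frames: int = 500) -> dict[str, dict]:
    """Matched wt-like / mutant-like datasets with their planted truths."""
    out = {}
    for style, sub in (("wt-like", 0), ("mutant-like", 1)):
        spec = scenario_spec(style, seed=2 * seed + sub, frames=frames)
        model, params, traj, truth = generate(spec)
        out["wt" if sub == 0 else "mut"] = {
            "spec": spec, "model": model, "params": params,
            "trajectory": traj, "truth": truth,
        }
    return out


def make_two_block_spec(
    seed: int,
    n_per_block: int = 12,
    frames: int = 2000,
    rho: float = 0.8,
) -> SyntheticSpec:
    """A minimal planted-bipartition system: one chain, two correlation blocks
    densified into communities, a single cross-block (backbone) contact."""
    n = 2 * n_per_block
    blocks = [
        Block("A", (("M", 1, n_per_block),), rho=rho),
        Block("B", (("M", n_per_block + 1, n),), rho=rho),
    ]
    return SyntheticSpec(
        chains={"M": [Segment(1, n, 3.8, 0.0, 0.0)]},
        frames=frames,
        seed=seed,
        blocks=blocks,
        schedules=_densify(blocks, step=1, spans=(2, 3, 4)),
    )
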