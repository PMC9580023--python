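"""Construction and dialcohol modification of Iβ cellulose nanocrystals.

A nanocrystal is an ``nx × ny`` grid of cellulose chains on the primitive
cross-section vectors u = (a+b)/2 and v = (a−b)/2 of the centered Iβ lattice
(the 110 / 1−10 chain-to-chain directions), each chain ``n_units`` glucose
units long with the chain axis along c.  Chains on the odd sublattice are the
"center" chains of the conventional cell and are staggered by c/4 along the
axis.  The 7 × 7 grid is therefore a diamond whose two tips along the (200)
stacking direction stand alone in their sheet — these are the two chains
whose C2-C3 bonds all point into the solvent, while the chains on the
110/1−10 faces expose every second C2-C3 bond.

The dialcohol modification cleaves the C2-C3 bond of a glucose unit
(periodate oxidation followed by borohydride reduction) and adds one
hydrogen to each of C2 and C3; hydroxyls are retained.  Pattern A modifies
every second unit along a chain, pattern B all units.  The standard recipes
label the result by their nominal degree of modification (0, 25, 40, 100 %).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from . import ibeta
from .frames import Frame

logger = logging.getLogger(__name__)

RESNAME_NATIVE = "BGC"   # β-D-glucose unit
RESNAME_MODIFIED = "DAC"  # dialcohol (ring-opened) unit


class ModificationPattern(Enum):
    """A: every second C2-C3 bond cleaved; B: all C2-C3 bonds cleaved."""

    A = "alternating"
    B = "full"


@dataclass(frozen=True)
class DomRecipe:
    """Per-layer pattern assignment for a nominal DoM label (percent)."""

    label: int
    layers: dict = field(default_factory=dict)   # layer -> pattern for sides
    # top/bottom chains of a treated layer always get pattern B


@dataclass
class GlucoseUnit:
    """View of one glucose unit: named atom positions (nm) and its state."""

    chain_id: int
    unit_index: int
    atoms: dict
    modified: bool


@dataclass
class ChainInfo:
    chain_id: int
    grid: tuple            # (i, j) on the u/v grid
    layer: int             # 1 = outermost ring
    role: str              # "side" or "top-bottom"


class Nanocrystal:
    """Atom-array representation of a built nanocrystal.

    Atoms are stored chain-by-chain, unit-by-unit, as parallel arrays:
    ``names`` (atom names), ``chain_index``, ``unit_index`` and ``positions``
    (nm).  ``modified`` is an (n_chains, n_units) boolean table.  The lattice
    frame (axis vectors as built, possibly rotated later) travels with the
    object so that dimensions are measured in the crystal frame regardless of
    rigid motions.
    """

    def __init__(self, nx, ny, n_units, names, chain_index, unit_index,
                 positions, modified, axes):
        self.nx = int(nx)
        self.ny = int(ny)
        self.n_units = int(n_units)
        self.names = np.asarray(names, dtype=object)
        self.chain_index = np.asarray(chain_index, dtype=np.int32)
        self.unit_index = np.asarray(unit_index, dtype=np.int32)
        self.positions = np.asarray(positions, dtype=float)
        self.modified = np.asarray(modified, dtype=bool)
        self.axes = {k: np.asarray(v, dtype=float) for k, v in axes.items()}

    # ------------------------------------------------------------------
    @property
    def n_chains(self) -> int:
        return self.nx * self.ny

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_glucose(self) -> int:
        return self.n_chains * self.n_units

    def grid_of(self, chain_id: int):
        return divmod(chain_id, self.ny)

    def copy(self) -> "Nanocrystal":
        return Nanocrystal(self.nx, self.ny, self.n_units, self.names.copy(),
                           self.chain_index.copy(), self.unit_index.copy(),
                           self.positions.copy(), self.modified.copy(),
                           {k: v.copy() for k, v in self.axes.items()})

    def translate(self, shift) -> "Nanocrystal":
        out = self.copy()
        out.positions = out.positions + np.asarray(shift, dtype=float)
        return out

    def rotate(self, R) -> "Nanocrystal":
        R = np.asarray(R, dtype=float)
        out = self.copy()
        out.positions = out.positions @ R.T
        out.axes = {k: R @ v for k, v in out.axes.items()}
        return out

    def unit(self, chain_id: int, unit_index: int) -> GlucoseUnit:
        mask = (self.chain_index == chain_id) & (self.unit_index == unit_index)
        atoms = {n: p for n, p in zip(self.names[mask], self.positions[mask])}
        return GlucoseUnit(chain_id, unit_index, atoms,
                           bool(self.modified[chain_id, unit_index]))

    def elements(self) -> np.ndarray:
        return np.array([n[0] for n in self.names], dtype=object)

    # ------------------------------------------------------------------
    def bonds(self):
        """Heavy+hydrogen bond list as global atom-index pairs.  The C2-C3
        bond is present only for unmodified units."""
        index = {}
        for gi, (ci, ui, nm) in enumerate(zip(self.chain_index,
                                              self.unit_index, self.names)):
            index[(int(ci), int(ui), nm)] = gi
        pairs = []

        def add(ci, ui, a, b, uj=None):
            key_a = (ci, ui, a)
            key_b = (ci, ui if uj is None else uj, b)
            if key_a in index and key_b in index:
                pairs.append((index[key_a], index[key_b]))

        for ci in range(self.n_chains):
            for ui in range(self.n_units):
                for a, b in ibeta.RING_BONDS:
                    add(ci, ui, a, b)
                if not self.modified[ci, ui]:
                    add(ci, ui, *ibeta.C2C3_BOND)
                for a, b in ibeta.HYDROGEN_BONDS_INTRA:
                    add(ci, ui, a, b)
                for a, b in (("C2", "H2B"), ("C3", "H3B"),
                             ("C1", "O1"), ("O1", "HO1"), ("O4", "HO4")):
                    add(ci, ui, a, b)
                if ui + 1 < self.n_units:
                    add(ci, ui, "O4", "C1", uj=ui + 1)
        return pairs

    def to_frame(self) -> Frame:
        resnames = np.where(self.modified[self.chain_index, self.unit_index],
                            RESNAME_MODIFIED, RESNAME_NATIVE).astype(object)
        return Frame(
            names=self.names.copy(),
            elements=self.elements(),
            resnames=resnames,
            resids=self.unit_index.astype(int) + 1,
            chain_ids=self.chain_index.astype(int).copy(),
            positions=self.positions.copy(),
            box=np.ptp(self.positions, axis=0) + 1.0,
        )


# ---------------------------------------------------------------------------
def build_cnc(nx: int, ny: int, n_units: int) -> Nanocrystal:
    """Build an unmodified nx × ny chain crystal, each chain ``n_units``
    glucose units (must be even: the c repeat is one cellobiose).

    >>> build_cnc(7, 7, 40).n_chains
    49
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be positive")
    if n_units < 1 or n_units % 2:
        raise ValueError(
            "n_units must be a positive even number: the Iβ c-axis repeat is "
            "one cellobiose (two glucose units)")
    cell = ibeta.default_unit_cell()
    R, t = cell.step_rot, cell.step_trans

    # one chain in the lattice frame
    atom_names, atom_unit, coords = [], [], []
    residues = []
    tpl_names = [n for n in sorted(cell.template) if n != "O1"]
    X = {k: v.copy() for k, v in cell.template.items()}
    for k in range(n_units):
        residues.append({k2: v.copy() for k2, v in X.items()})
        X = {k2: R @ v + t for k2, v in X.items()}
    o1, ho1, ho4 = ibeta.cap_positions(cell, residues[0], residues[-1])
    for k, resd in enumerate(residues):
        names_k = list(tpl_names)
        if k == 0:
            resd["HO1"] = ho1
            names_k = ["O1", "HO1"] + names_k
        if k == n_units - 1:
            resd["HO4"] = ho4
            names_k = names_k + ["HO4"]
        for nm in names_k:
            atom_names.append(nm)
            atom_unit.append(k)
            coords.append(resd[nm])
    chain_pos = np.array(coords)
    chain_names = np.array(atom_names, dtype=object)
    chain_unit = np.array(atom_unit, dtype=np.int32)

    u2, v2 = cell.u_vec, cell.v_vec
    stagger = cell.c / 4.0
    all_pos, all_names, all_unit, all_chain = [], [], [], []
    cid = 0
    for i in range(nx):
        for j in range(ny):
            shift = i * u2 + j * v2
            if (i + j) % 2:
                shift = shift + np.array([0.0, 0.0, stagger])
            all_pos.append(chain_pos + shift)
            all_names.append(chain_names)
            all_unit.append(chain_unit)
            all_chain.append(np.full(len(chain_names), cid, dtype=np.int32))
            cid += 1
    axes = {"a": cell.a_vec, "b": cell.b_vec, "c": cell.c_vec,
            "u": u2, "v": v2}
    return Nanocrystal(nx, ny, n_units,
                       np.concatenate(all_names), np.concatenate(all_chain),
                       np.concatenate(all_unit), np.vstack(all_pos),
                       np.zeros((nx * ny, n_units), dtype=bool), axes)


def classify_chains(crystal: Nanocrystal) -> list[ChainInfo]:
    """Label every chain with its ring layer (1 = perimeter) and its role.

    Within each ring the chains at the strict extremes of the (200) stacking
    coordinate i+j (the diamond tips) are "top-bottom"; the rest, lying on
    the 110/1−10 faces, are "side".  For the 7×7 grid this gives the 22+2
    split of the outermost layer.
    """
    nx, ny = crystal.nx, crystal.ny
    out = []
    rings: dict[int, list] = {}
    for cid in range(crystal.n_chains):
        i, j = crystal.grid_of(cid)
        layer = min(i, j, nx - 1 - i, ny - 1 - j) + 1
        rings.setdefault(layer, []).append((cid, i + j))
    for layer, members in rings.items():
        stack = [s for _, s in members]
        lo, hi = min(stack), max(stack)
        for cid, s in members:
            if len(members) > 2 and (s == lo or s == hi) and stack.count(s) == 1:
                role = "top-bottom"
            else:
                role = "side"
            i, j = crystal.grid_of(cid)
            out.append(ChainInfo(cid, (i, j), layer, role))
    out.sort(key=lambda c: c.chain_id)
    return out


def apply_dialcohol_modification(crystal: Nanocrystal, chain_selection,
                                 pattern: ModificationPattern,
                                 phase: int = 0) -> Nanocrystal:
    """Cleave C2-C3 bonds in the selected chains and add the two hydrogens.

    Pattern A converts units with ``unit_index % 2 == phase``; pattern B all
    units.  Already-modified units are left untouched (idempotent).  Returns
    a new crystal; the input is not mutated.
    """
    chain_selection = sorted(set(int(c) for c in chain_selection))
    if not chain_selection:
        warnings.warn("empty chain selection: crystal returned unchanged")
        return crystal.copy()
    for cid in chain_selection:
        if not (0 <= cid < crystal.n_chains):
            raise ValueError(f"unknown chain id {cid}")
    if not isinstance(pattern, ModificationPattern):
        raise ValueError(f"invalid pattern {pattern!r}")
    if phase not in (0, 1):
        raise ValueError("phase must be 0 or 1")

    out = crystal.copy()
    targets = []
    for cid in chain_selection:
        for ui in range(out.n_units):
            if pattern is ModificationPattern.A and ui % 2 != phase:
                continue
            if out.modified[cid, ui]:
                continue
            targets.append((cid, ui))
            out.modified[cid, ui] = True
    if not targets:
        return out

    # insert H2B/H3B for each newly modified unit, preserving atom grouping
    names = list(out.names)
    chain_idx = list(out.chain_index)
    unit_idx = list(out.unit_index)
    pos = list(out.positions)

    lookup = {}
    for gi, (ci, ui, nm) in enumerate(zip(out.chain_index, out.unit_index,
                                          out.names)):
        lookup[(int(ci), int(ui), nm)] = gi

    insertions = []   # (global insert position, name, xyz, ci, ui)
    for ci, ui in targets:
        get = lambda nm: out.positions[lookup[(ci, ui, nm)]]
        h2b = ibeta.tetrahedral_completion(
            get("C2"), [get("C1"), get("O2"), get("H2")], ibeta.L_CH)
        h3b = ibeta.tetrahedral_completion(
            get("C3"), [get("C4"), get("O3"), get("H3")], ibeta.L_CH)
        insertions.append((lookup[(ci, ui, "H2")] + 1, "H2B", h2b, ci, ui))
        insertions.append((lookup[(ci, ui, "H3")] + 1, "H3B", h3b, ci, ui))
    for at, nm, xyz, ci, ui in sorted(insertions, key=lambda x: -x[0]):
        names.insert(at, nm)
        chain_idx.insert(at, ci)
        unit_idx.insert(at, ui)
        pos.insert(at, xyz)

    out.names = np.array(names, dtype=object)
    out.chain_index = np.array(chain_idx, dtype=np.int32)
    out.unit_index = np.array(unit_idx, dtype=np.int32)
    out.positions = np.array(pos, dtype=float)
    return out


STANDARD_DOM_LABELS = (0, 25, 40, 100)


def make_standard_dom(nx: int, ny: int, n_units: int, label: int,
                      phase: int = 0, surface_all_b: bool = False) -> Nanocrystal:
    """Build a crystal with one of the standard core–shell recipes.

    label 0   — native crystal, nothing modified;
    label 25  — outermost layer: side chains pattern A, the two stacking-tip
                chains pattern B;
    label 40  — same treatment applied to layers 1 and 2;
    label 100 — pattern B everywhere.

    ``surface_all_b`` is the control variant in which every C2-C3 bond of the
    outermost layer is cleaved (pattern B) with layer 2 untouched; it is only
    meaningful together with ``label=40`` nominal coverage studies and is
    accepted with any nonzero label.

    The labels are the recipes' nominal names; the realized fraction is
    whatever :func:`compute_dom` reports (e.g. 520/1960 ≈ 26.5 % for the
    7×7×40 "25 %" recipe).
    """
    if label not in STANDARD_DOM_LABELS:
        raise ValueError(
            f"unsupported DoM label {label!r}; supported: {STANDARD_DOM_LABELS}")
    crystal = build_cnc(nx, ny, n_units)
    if label == 0:
        return crystal
    if label == 100:
        return apply_dialcohol_modification(
            crystal, range(crystal.n_chains), ModificationPattern.B)
    info = classify_chains(crystal)
    if surface_all_b:
        layer1 = [c.chain_id for c in info if c.layer == 1]
        return apply_dialcohol_modification(crystal, layer1,
                                            ModificationPattern.B)
    n_layers = 1 if label == 25 else 2
    out = crystal
    for layer in range(1, n_layers + 1):
        sides = [c.chain_id for c in info if c.layer == layer and c.role == "side"]
        tips = [c.chain_id for c in info if c.layer == layer and c.role == "top-bottom"]
        if sides:
            out = apply_dialcohol_modification(out, sides,
                                               ModificationPattern.A, phase)
        if tips:
            out = apply_dialcohol_modification(out, tips, ModificationPattern.B)
    return out


def compute_dom(crystal: Nanocrystal) -> float:
    """Fraction of glucose units in the dialcohol form."""
    if crystal.n_glucose == 0:
        raise ValueError("empty crystal")
    return float(crystal.modified.mean())


def measure_dimensions(crystal: Nanocrystal) -> tuple[float, float, float]:
    """(width, height, length) in nm, rounded to 0.1 nm.

    Width and height are heavy-atom extents across the two cross-section
    faces (perpendicular widths of the u/v parallelogram); the length is the
    crystallographic repeat length along the chain axis — the extent of the
    per-unit ring centers plus one c/2 repeat, which equals n_units·c/2 for
    an ideal chain and is robust to terminal decoration and thermal jitter.
    All three are measured in the crystal's own lattice frame, so they are
    invariant under rigid motions of the crystal.
    """
    u2, v2, c2 = crystal.axes["u"], crystal.axes["v"], crystal.axes["c"]
    chat = c2 / np.linalg.norm(c2)
    n_u = np.cross(v2, chat)
    n_u /= np.linalg.norm(n_u)
    n_v = np.cross(u2, chat)
    n_v /= np.linalg.norm(n_v)

    heavy = np.array([not n.startswith("H") for n in crystal.names])
    pts = crystal.positions[heavy]
    width = float(np.ptp(pts @ n_u))
    height = float(np.ptp(pts @ n_v))

    ring = ("C1", "C2", "C3", "C4", "C5", "O5")
    ring_mask = np.isin(crystal.names.astype(str), ring)
    rp = crystal.positions[ring_mask]
    keys = (crystal.chain_index[ring_mask].astype(np.int64) * crystal.n_units
            + crystal.unit_index[ring_mask])
    order = np.argsort(keys, kind="stable")
    rp = rp[order]
    centers = rp.reshape(-1, 6, 3).mean(axis=1)         # (n_chains*n_units, 3)
    proj = (centers @ chat).reshape(crystal.n_chains, crystal.n_units)
    rise = np.linalg.norm(c2) / 2.0
    # chain length, not envelope: the c/4 stagger between the two sublattices
    # is sub-repeat detail, the crystal is as long as its chains
    length = float(np.ptp(proj, axis=1).max()) + rise
    return (round(width, 1), round(height, 1), round(length, 1))
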