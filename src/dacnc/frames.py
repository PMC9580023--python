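"""Lightweight coordinate-frame container shared by all analyses.

A :class:`Frame` is a flat set of atoms with names, elements, residue and
chain bookkeeping, positions in nm, and an optional rectangular bounding box
(nm).  Frames come from built crystals, from structure files, or from the
synthetic-data generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WATER_RESNAMES = ("SOL", "HOH", "WAT", "TIP3")


@dataclass
class Frame:
    names: np.ndarray        # atom names
    elements: np.ndarray     # element symbols
    resnames: np.ndarray
    resids: np.ndarray       # 1-based within a chain
    chain_ids: np.ndarray    # integer chain partition labels
    positions: np.ndarray    # (N, 3) nm
    box: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.positions)
        for attr in ("names", "elements", "resnames", "resids", "chain_ids"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length mismatch with positions")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def bounding_volume(self) -> float:
        """Volume (nm³) of the frame's box, or of the axis-aligned bounding
        box of its atoms when no box is recorded."""
        if self.box is not None:
            return float(np.prod(self.box))
        return float(np.prod(np.ptp(self.positions, axis=0)))

    def is_water(self) -> np.ndarray:
        return np.isin(self.resnames.astype(str), WATER_RESNAMES)

    def is_cellulose(self) -> np.ndarray:
        return np.isin(self.resnames.astype(str), ("BGC", "DAC"))

    def n_glucose(self) -> int:
        """Number of glucose units (cellulose residues) in the frame."""
        cel = self.is_cellulose()
        keys = set(zip(self.chain_ids[cel].tolist(), self.resids[cel].tolist()))
        return len(keys)

    def select(self, mask) -> "Frame":
        mask = np.asarray(mask, dtype=bool)
        return Frame(self.names[mask], self.elements[mask],
                     self.resnames[mask], self.resids[mask],
                     self.chain_ids[mask], self.positions[mask],
                     None if self.box is None else self.box.copy())

    def translated(self, shift) -> "Frame":
        out = self.select(np.ones(self.n_atoms, dtype=bool))
        out.positions = out.positions + np.asarray(shift, dtype=float)
        return out

    def rotated(self, R) -> "Frame":
        out = self.select(np.ones(self.n_atoms, dtype=bool))
        out.positions = out.positions @ np.asarray(R, dtype=float).T
        out.box = None   # an axis-aligned box does not survive rotation
        return out


def guess_element(name: str) -> str:
    name = name.strip()
    if not name:
        raise ValueError("empty atom name")
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    two = name[:2].capitalize()
    if two in ("Cl", "Na", "Mg", "Ca", "Fe", "Zn", "Br"):
        return two
    return name[0].upper()
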