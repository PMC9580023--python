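"""Structure file round-trip: package-own PDB/GRO writers, MDAnalysis readers.

Writing is done directly (fixed-column formats) because the writer must
control details the analyses rely on: distinct residue names for native
(BGC) and dialcohol (DAC) units, CONECT records that omit the cleaved C2-C3
bond, chain identifiers cycling A–Z then 0–9, and per-chain residue
numbering restarting at 1 so that the chain partition survives a GRO
round-trip (a new chain starts wherever the residue number drops).
Reading goes through MDAnalysis and is converted to :class:`~dacnc.frames.Frame`.
"""

from __future__ import annotations

import os
import warnings

import numpy as np

from .frames import Frame, guess_element

CHAIN_SYMBOLS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"


def _chain_symbol(i: int) -> str:
    return CHAIN_SYMBOLS[i % len(CHAIN_SYMBOLS)]


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------
def write_structure(obj, path, fmt: str | None = None, conect: bool | None = None):
    """Write a Nanocrystal or Frame to PDB or GRO (format from extension when
    ``fmt`` is None).  ``conect`` controls PDB connectivity records; default:
    written when the object knows its bonds (crystals), omitted for frames."""
    path = os.fspath(path)
    if fmt is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        fmt = ext
    fmt = fmt.lower()
    if fmt not in ("pdb", "gro"):
        raise ValueError(f"unknown structure format {fmt!r} (use pdb or gro)")

    bonds = None
    if hasattr(obj, "to_frame"):          # Nanocrystal
        if conect is None or conect:
            bonds = obj.bonds()
        frame = obj.to_frame()
    else:
        frame = obj
        if conect:
            raise ValueError("CONECT requested but the object has no bond list")
    if fmt == "pdb":
        _write_pdb(frame, path, bonds)
    else:
        _write_gro(frame, path)


def _write_pdb(frame: Frame, path: str, bonds):
    lines = []
    chain_prev = None
    resid_offset = 0
    for i in range(frame.n_atoms):
        cid = frame.chain_ids[i]
        if chain_prev is not None and cid != chain_prev:
            lines.append("TER")
        chain_prev = cid
        name = str(frame.names[i])
        pdb_name = name if len(name) == 4 else f" {name:<3s}"
        x, y, z = frame.positions[i] * 10.0   # nm -> Å
        lines.append(
            f"ATOM  {(i + 1) % 100000:5d} {pdb_name:<4s}{str(frame.resnames[i]):>4s} "
            f"{_chain_symbol(int(cid))}{int(frame.resids[i]) % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{str(frame.elements[i]):>2s}")
    lines.append("TER")
    if bonds:
        neigh: dict[int, list[int]] = {}
        for a, b in bonds:
            neigh.setdefault(a, []).append(b)
            neigh.setdefault(b, []).append(a)
        for a in sorted(neigh):
            partners = sorted(neigh[a])
            for k in range(0, len(partners), 4):
                chunk = partners[k:k + 4]
                lines.append("CONECT" + f"{a + 1:5d}"
                             + "".join(f"{p + 1:5d}" for p in chunk))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _write_gro(frame: Frame, path: str):
    lines = ["dacnc structure", f"{frame.n_atoms:5d}"]
    for i in range(frame.n_atoms):
        x, y, z = frame.positions[i]
        lines.append(
            f"{int(frame.resids[i]) % 100000:5d}{str(frame.resnames[i]):<5s}"
            f"{str(frame.names[i]):>5s}{(i + 1) % 100000:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}")
    box = frame.box
    if box is None:
        box = np.ptp(frame.positions, axis=0) + 1.0
    lines.append(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------
def read_structure(path):
    """Read a single-frame PDB/GRO file into a :class:`Frame` (positions nm).

    Multi-model PDB files are read with :func:`read_trajectory`; this
    function returns their first frame.
    """
    frames = read_trajectory(path)
    return frames[0]


def read_trajectory(path) -> list[Frame]:
    """Read a (possibly multi-model) PDB or GRO file as a list of Frames."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext not in ("pdb", "gro"):
        raise ValueError(f"unknown structure format {ext!r} (use pdb or gro)")
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            uni = mda.Universe(path)
        except Exception as exc:
            line = _find_bad_line(path, ext)
            raise ValueError(
                f"malformed {ext.upper()} file {path!r}"
                + (f" at line {line}" if line else "")
                + f": {exc}") from exc
        names = np.array([a.name for a in uni.atoms], dtype=object)
        try:
            elements = np.array([a.element for a in uni.atoms], dtype=object)
        except Exception:
            elements = np.array([guess_element(n) for n in names], dtype=object)
        resnames = np.array([a.resname for a in uni.atoms], dtype=object)
        resids = np.array([a.resid for a in uni.atoms], dtype=int)
        try:
            chainletters = np.array([a.chainID for a in uni.atoms], dtype=object)
        except Exception:
            chainletters = None
        chain_ids = _infer_chains(resids, chainletters)
        out = []
        for ts in uni.trajectory:
            box = None
            if ts.dimensions is not None and ts.dimensions[:3].any():
                box = ts.dimensions[:3] / 10.0
            out.append(Frame(names.copy(), elements.copy(), resnames.copy(),
                             resids.copy(), chain_ids.copy(),
                             ts.positions / 10.0, box))
    if not out:
        raise ValueError(f"no coordinate frames found in {path!r}")
    return out


def _infer_chains(resids, chainletters) -> np.ndarray:
    """Chain partition: a new chain starts when the chain letter changes or
    the residue number decreases (our writers restart resids per chain)."""
    n = len(resids)
    chains = np.zeros(n, dtype=int)
    current = 0
    for i in range(1, n):
        new = resids[i] < resids[i - 1]
        if chainletters is not None and chainletters[i] != chainletters[i - 1]:
            new = True
        if new:
            current += 1
        chains[i] = current
    return chains


def _find_bad_line(path, ext):
    """Best-effort scan for the first syntactically broken record."""
    try:
        with open(path, errors="replace") as fh:
            lines = fh.readlines()
    except OSError:
        return None
    if ext == "pdb":
        for no, line in enumerate(lines, 1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except (ValueError, IndexError):
                    return no
    else:
        try:
            natoms = int(lines[1])
        except (ValueError, IndexError):
            return 2
        for no in range(3, min(3 + natoms, len(lines) + 1)):
            line = lines[no - 1]
            try:
                float(line[20:28]); float(line[28:36]); float(line[36:44])
            except (ValueError, IndexError):
                return no
    return None
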