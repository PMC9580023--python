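"""Ground-truth fixtures: thermal jitter, water shells, stick-slip traces.

None of these generators attempt physical realism beyond what the analyses
measure geometrically.  They exist so every analysis stage can be exercised
against known ground truth without molecular dynamics:

* :func:`jitter_crystal` emulates thermal disorder with i.i.d. Gaussian
  displacements.  Atoms of dialcohol-modified units receive a larger
  amplitude (``modified_scale`` × σ): the ring-opened chains are flexible and
  form the disordered shell, while the native core stays crystalline — the
  package's stand-in for the equilibrated core–shell structure.
* :func:`place_water_shell` surrounds the crystal with a Poisson gas of
  rigid 3-site waters confined to a shell, respecting only a hard solute
  clearance.  Adequate for geometric hydrogen-bond and shell-selection
  tests; no energetics implied.
* :func:`synth_force_trace` produces a sawtooth stick-slip stress trace
  with programmed peak heights, pre-peak slope, event count and integral,
  plus Gaussian noise, and returns the exact ground truth alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .frames import Frame
from .shear_analysis import (DEFAULT_CONTACT_AREA, KJ_PER_MOL_NM_IN_PN,
                             ForceCurve, ShearRunMetadata)

WATER_OH = 0.09572        # nm
WATER_ANGLE = 104.52      # degrees
SOLUTE_CLEARANCE = 0.25   # nm, minimum water-O to solute heavy atom distance


# ---------------------------------------------------------------------------
def jitter_crystal(crystal, sigma: float, seed: int = 0,
                   modified_scale: float = 5.0) -> Frame:
    """Gaussian-jittered frame of a built crystal.

    ``sigma`` (nm) applies to atoms of native units; atoms of modified units
    get ``modified_scale``·σ.  σ = 0 returns the exact coordinates; equal
    seeds give identical frames.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    frame = crystal.to_frame()
    if sigma == 0:
        return frame
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=frame.positions.shape)
    is_mod = frame.resnames.astype(str) == "DAC"
    scale = np.where(is_mod, modified_scale, 1.0)[:, None]
    frame.positions = frame.positions + noise * scale
    return frame


# ---------------------------------------------------------------------------
def place_water_shell(crystal, thickness: float = 0.6, density: float = 33.0,
                      seed: int = 0, max_attempts: int = 5_000_000) -> Frame:
    """Crystal frame plus a shell of waters around it.

    Water oxygens follow a Poisson point process with intensity ``density``
    (nm⁻³) over the accessible region: within ``thickness`` of any solute
    heavy atom but no closer than 0.25 nm to one.  Orientations are uniform.
    """
    if thickness < 0:
        raise ValueError("thickness must be non-negative")
    if density < 0:
        raise ValueError("density must be non-negative")
    solute = crystal.to_frame()
    if thickness == 0 or density == 0:
        return solute
    rng = np.random.default_rng(seed)
    heavy = np.array([not str(n).startswith("H") for n in solute.names])
    hpos = solute.positions[heavy]
    lo = hpos.min(axis=0) - thickness
    hi = hpos.max(axis=0) + thickness
    vol = float(np.prod(hi - lo))
    n_try = rng.poisson(density * vol)
    if n_try > max_attempts:
        raise ValueError(
            f"requested density needs {n_try} candidate points "
            f"(> {max_attempts}); reduce density or thickness")
    pts = rng.uniform(lo, hi, size=(n_try, 3))
    tree = cKDTree(hpos)
    dmin, _ = tree.query(pts)
    keep = pts[(dmin >= SOLUTE_CLEARANCE) & (dmin <= thickness)]

    n_w = len(keep)
    names, elements, resnames, resids, chains, pos = [], [], [], [], [], []
    half = np.deg2rad(WATER_ANGLE / 2.0)
    h1 = WATER_OH * np.array([np.sin(half), 0.0, np.cos(half)])
    h2 = WATER_OH * np.array([-np.sin(half), 0.0, np.cos(half)])
    rots = Rotation.random(n_w, random_state=np.random.RandomState(seed + 1)) \
        if n_w else None
    water_chain = int(solute.chain_ids.max()) + 1 if solute.n_atoms else 0
    for w in range(n_w):
        R = rots[w].as_matrix()
        o = keep[w]
        for nm, el, xyz in (("OW", "O", o), ("HW1", "H", o + R @ h1),
                            ("HW2", "H", o + R @ h2)):
            names.append(nm)
            elements.append(el)
            resnames.append("SOL")
            resids.append(w + 1)
            chains.append(water_chain)
            pos.append(xyz)
    if not n_w:
        return solute
    return Frame(
        names=np.concatenate([solute.names, np.array(names, dtype=object)]),
        elements=np.concatenate([solute.elements, np.array(elements, dtype=object)]),
        resnames=np.concatenate([solute.resnames, np.array(resnames, dtype=object)]),
        resids=np.concatenate([solute.resids, np.array(resids, dtype=int)]),
        chain_ids=np.concatenate([solute.chain_ids, np.array(chains, dtype=int)]),
        positions=np.vstack([solute.positions, np.array(pos)]),
        box=(hi - lo) + 2.0 * thickness,
    )


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class SyntheticTraceParams:
    """Programmed stick-slip trace.  Defaults emulate the qualitative shape
    of an axial, one-water-layer, room-temperature shear of native crystals:
    four stick-slip teeth with decreasing peaks."""

    n_events: int = 4
    peak_heights: tuple = (120.0, 100.0, 90.0, 80.0)   # MPa
    slope: float = 300.0            # MPa nm⁻¹, elastic loading slope
    drop_width: float = 0.05        # nm, width of each slip drop
    residual_fraction: float = 0.3  # stress level right after a slip
    tail: float = 0.5               # nm of zero stress after the last slip
    noise_sigma: float = 1.0        # MPa
    spacing: float = 0.002          # nm sample spacing
    area: float = DEFAULT_CONTACT_AREA   # nm²
    seed: int = 0

    def __post_init__(self):
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if self.n_events and len(self.peak_heights) != self.n_events:
            raise ValueError("one peak height per event required")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.spacing <= 0 or self.slope <= 0 or self.drop_width <= 0:
            raise ValueError("spacing, slope and drop_width must be positive")
        if not 0 <= self.residual_fraction < 1:
            raise ValueError("residual_fraction must be in [0, 1)")


@dataclass(frozen=True)
class TraceGroundTruth:
    tau_max: float          # MPa
    d_at_max: float         # nm
    stiffness: float        # MPa nm⁻¹
    n_events: int
    energy: float           # kJ mol⁻¹, integral of the noise-free force
    params: SyntheticTraceParams = field(repr=False, default=None)


def _trace_nodes(p: SyntheticTraceParams):
    """Piecewise-linear (d, τ) nodes of the noise-free trace."""
    nodes = [(0.0, 0.0)]
    d = 0.0
    tau = 0.0
    if p.n_events == 0:
        ramp = 1.0
        nodes.append((ramp, p.slope * ramp))
        return np.array(nodes)
    for k, peak in enumerate(p.peak_heights):
        d += (peak - tau) / p.slope
        nodes.append((d, peak))
        tau = 0.0 if k == p.n_events - 1 else p.residual_fraction * peak
        d += p.drop_width
        nodes.append((d, tau))
    nodes.append((d + p.tail, 0.0))
    return np.array(nodes)


def synth_force_trace(params: SyntheticTraceParams | None = None
                      ) -> tuple[ForceCurve, TraceGroundTruth]:
    """Sampled stick-slip force trace plus its exact ground truth.

    The noise-free trace hits the programmed peaks, slope and event count by
    construction; ``energy`` is the exact piecewise-linear integral of the
    noise-free force over the full displacement range.  Noise is Gaussian
    per sample and deterministic per seed.
    """
    p = params or SyntheticTraceParams()
    nodes = _trace_nodes(p)
    d_end = nodes[-1, 0]
    d = np.arange(0.0, d_end + p.spacing * 0.5, p.spacing)
    tau = np.interp(d, nodes[:, 0], nodes[:, 1])
    rng = np.random.default_rng(p.seed)
    tau_noisy = tau + rng.normal(0.0, p.noise_sigma, size=tau.shape) \
        if p.noise_sigma > 0 else tau

    to_force = p.area / KJ_PER_MOL_NM_IN_PN     # MPa -> kJ/mol/nm
    meta = ShearRunMetadata(area=p.area)
    curve = ForceCurve(d, tau_noisy * to_force, meta)

    if p.n_events:
        i = int(np.argmax(nodes[:, 1]))
        tmax, d_at = float(nodes[i, 1]), float(nodes[i, 0])
    else:
        tmax, d_at = float(nodes[-1, 1]), float(nodes[-1, 0])
    energy = float(np.trapezoid(nodes[:, 1] * to_force, nodes[:, 0]))
    truth = TraceGroundTruth(tmax, d_at, p.slope, p.n_events, energy, p)
    return curve, truth
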