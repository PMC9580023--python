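"""Post-processing of steered-pull force/displacement traces.

A steered shear run drags one nanocrystal past another with a moving
harmonic restraint (pull rate v, spring constant k); its output is a pull
force versus time or displacement.  This module turns such traces into
engineering stress τ(d) = F(d)/A with a constant nominal contact area A
(default 65.5 nm², the solvent-accessible contact area of the unmodified
crystal pair), and extracts the observables used to compare runs: the peak
shear stress τ_max, the interfacial stiffness Δτ/Δd before the first slip,
the stick-slip event sequence, and the force-curve integral as an
interaction-energy estimate.

Forces are carried in the engine-native unit kJ mol⁻¹ nm⁻¹ or in pN; the
conversion constant is 1 kJ mol⁻¹ nm⁻¹ = 1.66054 pN, and pN/nm² = MPa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

logger = logging.getLogger(__name__)

#: 1 kJ mol⁻¹ nm⁻¹ in pN  (1000 / N_A / 1e-9 / 1e-12)
KJ_PER_MOL_NM_IN_PN = 1.0e3 / 6.02214076e23 / 1.0e-9 / 1.0e-12

FORCE_UNITS = ("kJ/mol/nm", "pN")

DEFAULT_CONTACT_AREA = 65.5   # nm², SASA-based nominal contact area


@dataclass(frozen=True)
class ShearRunMetadata:
    direction: str = "axial"            # "axial" | "transverse"
    separation: float | None = 0.3      # surface-to-surface distance (nm)
    temperature: float = 25.0           # °C
    pull_rate: float = 1.0              # nm ns⁻¹
    spring_constant: float = 10_000.0   # kJ mol⁻¹ nm⁻²
    area: float | None = DEFAULT_CONTACT_AREA   # nm²
    force_unit: str = "kJ/mol/nm"

    def __post_init__(self):
        if self.direction not in ("axial", "transverse"):
            raise ValueError("direction must be 'axial' or 'transverse'")
        if self.pull_rate <= 0 or self.spring_constant <= 0:
            raise ValueError("pull rate and spring constant must be positive")
        if self.area is not None and self.area <= 0:
            raise ValueError("contact area must be positive")
        if self.force_unit not in FORCE_UNITS:
            raise ValueError(f"force unit must be one of {FORCE_UNITS}")

    @property
    def label(self) -> str:
        """Short run label in the Ax/Tr_separation@temperature style."""
        tag = "Ax" if self.direction == "axial" else "Tr"
        sep = "free" if self.separation is None else f"{self.separation * 10:.0f}"
        return f"{tag}_{sep}@{self.temperature:.0f}"


@dataclass
class ForceCurve:
    displacement: np.ndarray            # nm, strictly increasing
    force: np.ndarray                   # metadata.force_unit
    metadata: ShearRunMetadata = field(default_factory=ShearRunMetadata)

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.shape != self.force.shape:
            raise ValueError("displacement and force must have equal length")
        if len(self.displacement) == 0:
            raise ValueError("empty force curve")
        if np.any(np.diff(self.displacement) <= 0):
            raise ValueError("displacement must be strictly increasing")

    def force_pn(self) -> np.ndarray:
        if self.metadata.force_unit == "pN":
            return self.force
        return self.force * KJ_PER_MOL_NM_IN_PN


@dataclass
class StressCurve:
    displacement: np.ndarray   # nm
    stress: np.ndarray         # MPa
    metadata: ShearRunMetadata = field(default_factory=ShearRunMetadata)


class StickSlipEvent(NamedTuple):
    d_peak: float        # nm
    tau_peak: float      # MPa
    drop: float          # MPa, stress release after the peak


# ---------------------------------------------------------------------------
# ingest
# ---------------------------------------------------------------------------
def read_pull_curve(path, dialect: str = "xvg",
                    metadata: ShearRunMetadata | None = None,
                    abscissa: str = "time") -> ForceCurve:
    """Read a two-column pull trace (XVG dialect: lines starting with '@' or
    '#' are comments; CSV: comma-separated, optional header line).

    With ``abscissa="time"`` (the engine's native force-vs-time output) the
    first column is converted to displacement d = v·t using the metadata
    pull rate.  Duplicate abscissa values are collapsed by averaging.
    """
    if dialect not in ("xvg", "csv"):
        raise ValueError("dialect must be 'xvg' or 'csv'")
    if abscissa not in ("time", "displacement"):
        raise ValueError("abscissa must be 'time' or 'displacement'")
    metadata = metadata or ShearRunMetadata()
    xs, ys = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if dialect == "xvg" and line.startswith(("@", "#")):
                continue
            parts = line.split(",") if dialect == "csv" else line.split()
            if dialect == "csv" and lineno == 1:
                try:
                    [float(p) for p in parts[:2]]
                except ValueError:
                    continue    # header line
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric data {line!r}") from None
    if not xs:
        raise ValueError(f"{path}: no data rows")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if abscissa == "time":
        x = x * metadata.pull_rate
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    ux, inverse = np.unique(x, return_inverse=True)
    if len(ux) < len(x):
        sums = np.zeros(len(ux))
        cnts = np.zeros(len(ux))
        np.add.at(sums, inverse, y)
        np.add.at(cnts, inverse, 1.0)
        x, y = ux, sums / cnts
    return ForceCurve(x, y, metadata)


def write_pull_curve_csv(curve: ForceCurve, path):
    import pandas as pd
    pd.DataFrame({"displacement_nm": curve.displacement,
                  f"force_{curve.metadata.force_unit.replace('/', '_')}":
                      curve.force}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------
def stress_curve(curve: ForceCurve) -> StressCurve:
    """Engineering stress τ(d) = F(d)/A in MPa (A constant over the curve)."""
    area = curve.metadata.area
    if area is None:
        raise ValueError("metadata.area is not set; engineering stress "
                         "requires the nominal contact area")
    tau = curve.force_pn() / area
    return StressCurve(curve.displacement.copy(), tau, curve.metadata)


def tau_max(curve: StressCurve) -> tuple[float, float]:
    """(τ_max, displacement at the maximum); ties go to the smallest d."""
    i = int(np.argmax(curve.stress))
    return float(curve.stress[i]), float(curve.displacement[i])


def stick_slip_events(curve: StressCurve,
                      min_prominence: float | None = None) -> list[StickSlipEvent]:
    """Ordered stick-slip events: stress maxima with prominence at least
    ``min_prominence`` (default: 10 % of the stress range), each paired with
    the stress release down to the following minimum."""
    tau = curve.stress
    if min_prominence is None:
        rng = float(np.ptp(tau))
        min_prominence = 0.1 * rng if rng > 0 else np.inf
    if not np.isfinite(min_prominence):
        return []
    idx, _ = _scipy_find_peaks(tau, prominence=min_prominence)
    events = []
    for k, i in enumerate(idx):
        j_end = idx[k + 1] if k + 1 < len(idx) else len(tau)
        valley = float(tau[i:j_end].min())
        events.append(StickSlipEvent(float(curve.displacement[i]),
                                     float(tau[i]), float(tau[i] - valley)))
    return events


def interfacial_stiffness(curve: StressCurve,
                          min_prominence: float | None = None) -> float:
    """Δτ/Δd (MPa nm⁻¹): least-squares slope of τ versus d from the start of
    the curve to the first detected stick-slip peak.  When no peak is found
    the fit window falls back to the first 10 % of the displacement range
    (logged)."""
    events = stick_slip_events(curve, min_prominence)
    d = curve.displacement
    if events:
        d_end = events[0].d_peak
    else:
        d_end = d[0] + 0.1 * (d[-1] - d[0])
        logger.info("no stick-slip peak found; stiffness fitted on the "
                    "first 10%% of the displacement range")
    mask = d <= d_end
    if mask.sum() < 2:
        mask = np.zeros_like(mask)
        mask[:max(3, 2)] = True
    x, y = d[mask], curve.stress[mask]
    slope = np.polyfit(x, y, 1)[0] if len(x) > 1 else 0.0
    return float(slope)


def interaction_energy(curve: ForceCurve, d_range=None) -> float:
    """Trapezoidal integral of the force over ``d_range`` (default: the
    whole curve), in kJ mol⁻¹ when the force unit is kJ mol⁻¹ nm⁻¹ (pN·nm
    otherwise).  Additive over adjacent ranges; endpoints are interpolated
    so a split at any interior point sums exactly to the whole."""
    d = curve.displacement
    f = curve.force
    if d_range is None:
        d_range = (d[0], d[-1])
    lo, hi = float(d_range[0]), float(d_range[1])
    if hi < lo:
        raise ValueError(f"inverted range {d_range!r}")
    if lo < d[0] - 1e-12 or hi > d[-1] + 1e-12:
        raise ValueError("d_range outside the curve span")
    inner = (d > lo) & (d < hi)
    xs = np.concatenate([[lo], d[inner], [hi]])
    ys = np.concatenate([[np.interp(lo, d, f)], f[inner], [np.interp(hi, d, f)]])
    return float(np.trapezoid(ys, xs))


def shear_summary(curve: ForceCurve, min_prominence: float | None = None) -> dict:
    """One-stop summary: stress curve observables plus the energy integral."""
    sc = stress_curve(curve)
    tmax, d_at = tau_max(sc)
    events = stick_slip_events(sc, min_prominence)
    return {
        "label": curve.metadata.label,
        "tau_max_MPa": tmax,
        "d_at_max_nm": d_at,
        "stiffness_MPa_per_nm": interfacial_stiffness(sc, min_prominence),
        "n_events": len(events),
        "events": [e._asdict() for e in events],
        "energy_kJ_per_mol": interaction_energy(curve),
        "area_nm2": curve.metadata.area,
    }
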