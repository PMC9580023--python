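# Methods

## The crystal model

The builder produces finite Iβ cellulose nanocrystals from three
ingredients: the published monoclinic cell constants of the native Iβ
allomorph (a = 7.784 Å, b = 8.201 Å, c = 10.380 Å, γ = 96.5°; two chains
per cell, one cellobiose repeat along c), an idealized glucose residue, and
an exact 2₁ screw.

The residue is synthetic, not experimental: a β-D-glucopyranose built as an
ideal ⁴C₁ chair (C–C 1.52 Å, C–O 1.43 Å, C–H 1.10 Å, O–H 0.97 Å, ring
pucker half-amplitude 0.26 Å) with all oxygen substituents equatorial and
the hydroxymethyl group in the tg rotamer.  The two glycosidic torsions
Φ = C4-O4-C1-O5 and Ψ = C5-C4-O4-C1 are not free: they are solved (two
equations, two unknowns) so that consecutive residues are related by an
exact two-fold screw with rise c/2 = 5.19 Å — the defining property of the
cellulose chain in the crystal.  With a glycosidic bridge angle of 115°
the solution lands at (Φ, Ψ) = (−87.5°, −153.0°), in the range observed
for crystalline cellulose.  The bridge angle and pucker were fixed by a
clash / hydrogen-bond-distance scan of the assembled dimer; the known cost
of the idealization is an intrachain O3···O5′ distance of ≈ 2.4 Å versus
≈ 2.75 Å in the experimental structure.

Hydroxyl hydrogens are oriented along the dominant crystalline network:
O3-H → O5 of the next residue and O2-H → O6 of the previous residue within
a chain, O6-H → O3 of the in-sheet neighbour chain.  Each azimuth about its
C–O axis is the closed-form optimum pointing at that acceptor.  Chain ends
are capped with O1-H (reducing end) and O4-H (non-reducing end).

Chains sit on the primitive cross-section vectors u = (a+b)/2 and
v = (a−b)/2 of the centered chain lattice (|u| ≈ 0.53 nm, |v| ≈ 0.60 nm,
the 110 / 1−10 chain-to-chain directions).  An nx × ny grid is therefore a
diamond whose faces are the 110/1−10 planes; chains on the odd sublattice
are the conventional cell's center chains and are staggered by c/4.  This
arrangement is what makes the surface chemistry come out right: the two
grid corners along the (200) stacking direction stand alone in their sheet
with every C2–C3 bond facing the solvent, while chains on the faces expose
every second C2–C3 bond.  For the 7 × 7 grid the outermost ring splits into
22 "side" chains and 2 "top/bottom" chains.

### Dialcohol modification

Modifying a glucose unit removes the C2–C3 bond from the connectivity and
adds one hydrogen to each of C2 and C3 at the ideal sp³ completion of the
three remaining bonds; hydroxyls are retained and no relaxation is
performed (ring-opening relaxation is an MD engine's job, out of scope
here).  Pattern A modifies every second unit (phase selectable), pattern B
all units.  The standard recipes treat the outermost ring (label 25: sides
A, tips B), the two outermost rings (label 40), or everything (label 100).
The labels are nominal names; `compute_dom` reports the realized fraction
(e.g. 520/1960 ≈ 26.5 % for the 7×7×40 label-25 recipe).  A control
variant modifies every C2–C3 bond of the outermost ring only.

### Reported dimensions

`measure_dimensions` reports, in the crystal's own lattice frame (hence
invariant under rigid motion, rounded to 0.1 nm):

* width / height — heavy-atom extents across the two cross-section faces
  (perpendicular widths of the u/v parallelogram).  Hydrogens are excluded
  because the reference dimensions such models are compared against come
  from heavy-atom (diffraction) structures.
* length — the crystallographic repeat length of a chain: the extent of
  the per-unit ring centers along the axis plus one c/2 repeat.  This
  equals n_units·c/2 for an ideal chain, is robust to terminal decoration
  and thermal jitter, and deliberately excludes the c/4 sublattice stagger
  (the crystal is as long as its chains).  A raw atomic-extent measurement
  would add ≈ 0.2 nm of terminal-atom overhang.

The standard 7 × 7 × 40 build measures 3.6 × 4.1 × 20.8 nm.

## Structure analyses

**Interchain RDF → S(q).**  For the atom-pair classes C–O, C–H and O–H,
g(r) is accumulated over pairs whose atoms belong to different chains;
same-chain pairs carry conformational rather than packing information and
are excluded.  Normalization uses the partner-species count over the
frame's bounding volume — the analysis targets one finite crystal, not a
periodic liquid, so g(r) decays at large r instead of plateauing at 1.
The transform S(q) = 1 + 4πρ ∫₀^rmax r²(g−1) sinc(qr) w(r) dr uses
r_max = 3 nm, Δr = 0.02 nm, a Lorch window by default (w = sinc(πr/r_max)),
and a q grid 0.5–30 nm⁻¹ with Δq = 0.05 nm⁻¹.  The class transforms are
combined as an unweighted mean by default; passing X-ray form-factor
weights suppresses the hydrogen classes and strengthens the 110/1−10
reflection without moving peak positions (that insensitivity is a unit
test).  Peak positions are refined by local quadratic interpolation.  The
small-angle region below ≈ 8 nm⁻¹ is dominated by the finite particle size;
reflections should be read in the 10–20 nm⁻¹ fingerprint window, where the
native crystal shows (200) at 16.3 nm⁻¹ and the merged (110/1−10) at
13.3 nm⁻¹.

**Hydrogen bonds.**  Geometric criteria, donor–acceptor distance ≤ 0.35 nm
and hydrogen–donor–acceptor angle ≤ 30° (the common pair-counting
convention of MD analysis tools); both configurable.  Donors are
identified structurally (any H within 0.115 nm of a group oxygen).  For
the cellulose–cellulose count the default excludes pairs within one
glucose unit, making the quantity "glucose-to-glucose" bonds per unit.
The static, defect-free crystal engages all three hydroxyl donors of the
crystalline network and measures 2.69 bonds per glucose on the 7×7×40
build; thermal ensembles average nearer 2, and the package's jitter
stand-in reproduces that decline (1.51 at σ = 0.02 nm).

**Torsions, water shell, SASA.**  Φ/Ψ are computed per glycosidic linkage
(5° histogram bins, circular mode); the built native crystal is unimodal at
(−87.5°, −153.0°).  The water shell selects whole water molecules with any
atom within the cutoff (default 0.6 nm) of the solute.  SASA is
Shrake–Rupley with Bondi radii, probe 0.14 nm and 960 golden-spiral points
per sphere (exact for an isolated sphere; coincident duplicate atoms are
counted once).

## Shear-trace post-processing

Traces are ingested from the two-column XVG dialect (force vs time,
converted through the pull rate, default 1 nm ns⁻¹) or CSV (force vs
displacement); duplicate abscissae are averaged.  Engineering stress uses a
constant nominal contact area, default 65.5 nm² (the solvent-accessible
contact area of the unmodified crystal pair; configurable).  1 kJ mol⁻¹
nm⁻¹ = 1.66054 pN and pN nm⁻² = MPa.  τ_max is the global maximum (ties to
smallest d).  Stick-slip events are stress maxima with prominence ≥ 10 %
of the stress range (configurable), each paired with the release down to
the following minimum.  Interfacial stiffness is the least-squares slope
from the start of the curve to the first event; with no event the window
falls back to the first 10 % of the displacement range (logged).  The
interaction energy is the trapezoidal integral of force over displacement
with interpolated endpoints, so it is exactly additive over adjacent
ranges.  The integral is a pragmatic estimate, not a free energy.

## Synthetic data: what it emulates and what it does not

The generators exist to give every analysis a known ground truth; they are
statistical stand-ins, not physics.

* **Thermal jitter** draws i.i.d. Gaussian displacements (default
  σ = 0.02 nm for native units).  Atoms of modified units receive 5 × σ:
  ring-opened dialcohol chains are flexible and form the disordered shell,
  so the stand-in must disorder them more than the native core — without
  this, modification would not move any atom and the loss of the (200)
  reflection with increasing DoM could not be reproduced.  Under this
  emulation the (200) prominence falls monotonically through the DoM
  series 0 → 25 → 40 → 100 and vanishes at 100 %.  What jitter does not
  emulate: correlated phonons, chain slippage, solvent swelling, or any
  relaxation of the modified geometry — so passing tests demonstrate the
  *analyses* respond correctly to disorder, not that the model predicts
  thermal structure.
* **Water shells** are a Poisson point process (default 33 nm⁻³ ≈ bulk
  density) of rigid 3-site waters with uniform orientations, confined
  between 0.25 nm clearance from solute heavy atoms and the shell
  thickness.  Waters may overlap each other; geometry suffices for shell
  selection and hydrogen-bond machinery tests, nothing energetic.
* **Stick-slip traces** are piecewise-linear sawtooths (defaults: four
  teeth with peaks 120/100/90/80 MPa, loading slope 300 MPa nm⁻¹, slip
  width 0.05 nm, residual 30 % of the peak, Gaussian noise σ = 1 MPa,
  spacing 0.002 nm), chosen to resemble the qualitative shape of an axial,
  one-water-layer, room-temperature shear of native crystals.  All
  observables are computable exactly from the node list before noise, and
  the generator returns them alongside the trace.  Over 100 seeds the
  pipeline recovers τ_max, stiffness and energy with ≲ 0.5 % median
  relative error and the event count exactly.

## Numerical and degenerate-input choices

Ties in τ_max go to the smallest displacement.  An empty modification
selection warns and returns the crystal unchanged; re-modifying a modified
unit is a no-op.  Torsion linkages with missing named atoms are skipped
and logged.  Frames without water warn and return an empty shell.  The
two-atom S(q) reduces to the Debye closed form 1 + sin(qd)/(qd) in the
dilute limit; the interchain RDF equals an O(N²) pair loop to 1e-10
relative on small crystals (both are tests).  GRO files carry no chain
field, so the writers restart residue numbering per chain and the readers
start a new chain wherever the residue number drops; PDB chain letters
cycle A–Z then 0–9.

## Known limitations

Idealized geometry (exact chair, single chain conformation for both
sublattices, compressed O3···O5′ contact); no force-field topology export;
hydrogen positions are a single fully-ordered network while real Iβ
hydroxyls are partially disordered; the structure factor is an
orientationally averaged pair-correlation transform, not a Debye
full-scattering calculation; jitter-based disorder is uncorrelated.  These
are acceptable for the package's purpose — testing builders and analysis
pipelines at desk scale — and are the first things to revisit if the
models are used as MD starting structures.
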