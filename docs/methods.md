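# Methods

## The system and the measures

A Fab consists of a heavy-chain V_H + C_H1 and a light-chain V_L + C_L; the
variable and constant modules are linked by short "switch" (hinge) stretches.
`fabdyn` treats the Fab as four rigid-ish domains plus the switches and
quantifies three families of internal coordinates.

**COM torsions.** The elbow torsion is the dihedral of four centers of mass:
COM(V_H ∪ V_L), COM(switch heavy), COM(switch light), COM(C_H1 ∪ C_L) — the
switch COMs form the central axis. The C_H1–C_L interface torsion is the
dihedral of COM(C_H1 C-terminal loops), COM(C_H1), COM(C_L), COM(C_L
C-terminal loops). COMs are mass-weighted by default (the MD convention;
a geometric option exists because either reading is defensible), hydrogens
included when present — at these length scales the difference is negligible
but the choice must be fixed. Which residues constitute the C-terminal
loops and the switches is a per-structure user decision made explicit in the
partition config; the packaged template carries Chothia-style defaults for a
standard Fab as a starting point only.

**Torsion convention.** IUPAC: looking along the central bond (point 2 →
point 3), a clockwise rotation of the far bond is positive; implemented in
the atan2 form; range (−180°, +180°]. Consequences covered by tests: the
dihedral is invariant under reversing the four points (cis/trans assignments
are direction-free) and changes sign under mirror reflection.

**ABangle-style V_H–V_L measures.** A plane frame (origin + two in-plane
principal axes) is fitted once to each domain of a packaged *idealized* Fv
core — eight pseudo-Cα positions per domain arranged as a thin oblique
plate — and carried onto each structure by least-squares superposition of
the core onto the observed core Cα positions (≥ 3 must resolve). The
interdomain vector C points from the light-domain origin to the heavy-domain
origin, so a positive rotation of the V_H frame about C increases HL by
exactly that amount; dc = |C|; HC1/HC2 (LC1/LC2) are the angles of the
heavy (light) in-plane axes to C, reported in [0°, 180°]; HL is the torsion
of the two first in-plane axes about C, in (−180°, 180°]. The packaged core
is NOT the consensus dataset of the original ABangle tool (which is not
redistributed here): absolute values are not comparable with published
ABangle numbers; differences, shifts and widths are. A user-supplied
reference core file restores comparability with any other convention.

**PCA sign disambiguation.** Principal-axis signs are arbitrary; each axis
is flipped toward a reference direction (the canonical frame's axis when
transforming, the fixed +x, +y, +z sequence on exact ties). A cloud is
accepted as plate-like only if the ratio of its 2nd to 3rd singular value
exceeds 10; collinear clouds are rejected. The thresholds are explicit so
the degenerate behaviour is testable.

**Classical elbow angle.** The pseudo-two-fold axes relating V_H→V_L and
C_H1→C_L are taken from the rotation part of the least-squares
superposition of paired heavy-side Cα cores onto light-side cores (explicit
residue pairings in the partition config; rotations under 5° are rejected
as axis-undefined). Convention, fixed here because the literature leaves it
under-specified: the V axis is oriented toward the constant module
(non-negative dot product with the V-COM → C-COM direction), the C axis
toward the variable module; the elbow is the angle between the oriented
axes, replaced by 360° minus it when the dihedral (V axis, V-COM → C-COM,
C axis) is negative. A fully extended Fab reads 180°, and values above 180°
(reported for λ-light-chain Fabs) are representable. Constructed fixtures
with analytically prescribed axes pin the convention in the tests.

## Timescale assignment

Angle series are unwrapped (successive differences mapped into
(−180°, +180°] and re-accumulated) so wells straddling ±180° stay single
wells, demeaned, and Fourier transformed. The periodogram is one-sided and
normalized so the bin powers sum exactly to the series variance; no window
function is applied, which keeps that Parseval bookkeeping exact at the
price of spectral leakage for off-grid lines — acceptable because the
quantities of interest are band-integrated fractions, not line shapes.
Variance is assigned to three period bands: faster than 0.1 ns, 0.1–10 ns
(the 0.1–10 GHz regime of collective Fab interdomain motion), slower than
10 ns. The zero-frequency component belongs to the slow band, so the three
hard-mask band filters sum exactly to the original series. Band edges are
configurable (some presentations draw the fast edge at 1 ns instead; the
0.1/10 ns default follows the frequency-domain statement of the regime).
No detrending beyond mean removal is applied — drift is real slow-band
signal here. Smooth (non-hard-mask) filters and multitaper/Welch estimators
are deliberately out of scope.

## Free energy, force constants, frequencies

Boltzmann inversion: histogram (default 0.5° bins) → per-bin probability →
G = −k_B·T·ln p, minimum shifted to zero, empty bins dropped; needs ≥ 100
samples and at least two occupied bins. The harmonic fit is a weighted
least-squares parabola G = ½k(θ−θ₀)² over the bins within 2·k_B·T of the
minimum (the harmonic-approximation regime; configurable), weights = bin
counts, θ in radians internally so k is in kcal·mol⁻¹·rad⁻² (degrees are a
display unit only — the frequency formula needs SI-compatible curvature).
Negative curvature raises an error; r² < 0.9 flags a fit not to be trusted
(bimodal distributions land here). For a Gaussian well the identity
k = k_B·T/σ² ties the fit to the sample width; with k_B·T(300 K) =
0.59616 kcal/mol, σ = 5.0° corresponds to k = 78.3 kcal·mol⁻¹·rad⁻².

The characteristic frequency is the undamped two-body oscillator value
f = (1/2π)·√(k/I) with I the *reduced* torsional inertia
I_a·I_b/(I_a + I_b), each I_g = Σ m·d² about the torsion's central COM–COM
axis — the classical-mechanics choice for two rigid bodies counter-rotating
about a shared axis; which bodies and which axis is an assumption made
explicit here. Conversions are pinned named constants
(1 kcal/mol = 6.947695×10⁻²¹ J per molecule; 1 amu·Å² =
1.66053907×10⁻⁴⁷ kg·m²); k = 10 kcal·mol⁻¹·rad⁻² with I = 10⁷ amu·Å² gives
3.26 GHz. No friction/damping is modelled, and no 2-D free-energy surfaces.

## Synthetic ground truth — what it does and does not show

`simulate_ou` draws a stationary Ornstein–Uhlenbeck process by exact
discretization (θ_{t+dt} = θ₀ + (θ_t−θ₀)e^{−dt/τ} + σ√(1−e^{−2dt/τ})·z), so
the stationary variance k_B·T/k is exact at any sampling interval and
parameter-recovery tests carry no integrator bias. `simulate_harmonic` is
the deterministic cosine at the analytic frequency. `build_toy_fab`
assembles four bead clusters (plus switch and loop beads) whose COMs and
core positions realize prescribed elbow/interface torsions and V_H–V_L pose
*exactly*; `animate_toy_fab` rotates the constant module about the hinge
axis so the measured elbow series equals an input series to machine
precision (≤ 0.05° after a round trip through 3-decimal PDB coordinates).
Beads default to 24 × 500 amu per domain (~12 kDa, a realistic
immunoglobulin-domain mass), which puts hinge inertias near 10⁷ amu·Å² and
frequencies in the GHz regime.

These generators validate the *machinery*: geometry definitions, spectral
bookkeeping, Boltzmann inversion, comparison statistics. They do not
emulate anharmonicity, multi-well kinetics, CDR-loop coupling, solvent
friction or force-field physics, so passing tests say nothing about whether
a particular real Fab's well is parabolic — that is what the r² flag and
the band fractions are for when real trajectories are analysed.

## Study conditions and problem sizes

Statistical checks run at 1 ps sampling with correlation time 100 ps
(sub-ns, the regime of Fab interface fluctuations) and n = 10⁶ samples —
a 1 µs record, the per-run scale of the MD studies this pipeline serves —
giving ~5,000 effective samples, i.e. ~1% s.e. on σ and ~2% on k.
Two-ensemble comparisons use τ = 20 ps so the σ-ratio tolerance of 0.02 is
a ≥3 s.e. bound. The analysis drivers under `analysis/` use n = 10⁵ and a
500-frame structural trajectory so the whole narrative runs in seconds.
Tolerances on stochastic assertions are set at ≥3 standard errors derived
from these conditions; exact geometric round trips are asserted at 10⁻⁶ °
(construction) and 10⁻⁹ ° (invariance).

## Known limitations

* Absolute ABangle-style values depend on the packaged idealized core (see
  above); only relative statements transfer across conventions.
* The classical-elbow orientation rule can be sensitive when a pseudo-dyad
  is nearly perpendicular to the V→C direction with a near-zero tie-break;
  real Fab dyads are far from this regime.
* Binary trajectory formats are not read; trajectories must be multi-model
  PDB (the format round-trips bit-exactly at 3-decimal precision).
* Residue-range configs, not sequence annotation, define the domains: the
  user owns the numbering correctness, including insertion codes (which
  sort within their parent residue number).
* `free_energy_profile` unwraps periodic series; a genuinely multimodal
  circular distribution with occupancy on both sides of the wrap point can
  still split — inspect histograms when r² is poor.
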