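# Methods

## The model

`inclusim` studies how a small guest molecule binds inside a
truncated-cone host (the β-cyclodextrin geometry) surrounded by a
continuum solvent.  The complexation energy is the sum of an
intermolecular and an intramolecular part,

    E = Einter + Eintra,

with the intermolecular part summed over all host–guest atom pairs i, j
at distance R_ij:

    Einter = Σ_ij [ A_ij/R_ij¹² − B_ij/R_ij⁶ + q_i q_j / (ε R_ij) ]
           + Σ_{H-bond pairs} [ C_ij/R_ij¹² − D_ij/R_ij¹⁰ ]

and the intramolecular part over the guest's bonded terms:

    Eintra = Σ_bonds k_r (r − r_eq)² + Σ_angles k_θ (θ − θ_eq)²
           + Σ_dihedrals V_n/2 · [1 + cos(n φ − γ)].

Conventions and assumptions:

* **Units** — Å, elementary charges, amu, kcal/mol, fs internally; ps in
  reports.  Coulomb constant 332.0637 kcal·Å/(mol·e²), k_B =
  1.9872041·10⁻³ kcal/(mol·K).
* **Continuum solvent** — water enters only through ε = 80 dividing the
  Coulomb term (ε = 26 models ethanol).  The electrostatic component is
  therefore exactly linear in 1/ε.  Hydrophobic and discrete-water
  effects are outside the model.
* **No cutoffs** — the system is one host–guest pair, so all pairs are
  summed.  Intermolecular pairs are host–guest only; guest–guest
  non-bonded terms are not evaluated (Eintra is the bonded part).
* **12-10 hydrogen bonds** — pairs of a flagged donor hydrogen and a
  flagged acceptor use the C/R¹² − D/R¹⁰ term *instead of* the 12-6
  term, the classic AMBER-84 convention.
* **Combining rule** — per-type A, B combine geometrically
  (A_ij = √(A_i A_j)), with explicit pair overrides allowed in the
  parameter table.
* **Rigid host** — the host stays at its input geometry, so its internal
  energy is an additive constant and is never evaluated; reported Eintra
  is the guest's.

The host-fixed frame puts the origin at the host centre of mass and Z
along the cavity axis, +Z toward the wider rim.  The axis is the
inertia-tensor eigenvector whose eigenvalue is farthest from the other
two: an axisymmetric body has two degenerate moments, and the unique one
belongs to the symmetry axis.  (Selecting the *smallest* moment instead
fails for oblate hosts, where the symmetry axis carries the largest
moment.)  The rim sign is detected from the mass-weighted correlation
between axial position and radial spread.

## The position × orientation scan

The guest centre of mass visits a cubic lattice (reproduction scale:
−5 ≤ X, Y, Z ≤ 5 Å at 0.1 Å; desk scale: 0.5 Å).  At each point the
energy is evaluated over a fixed orientation set and the minimum is
recorded.  Orientations come from a regular intrinsic Z-Y-Z Euler
lattice with counts (2n, n, 2n); the reproduction target of ~23 000
yields 36×18×36 = 23 328.  The β grid spans [0, π] *inclusive*, so even
a coarse lattice contains the axis-aligned orientations a slender guest
needs to thread a narrow cavity; the duplicate orientations this
produces at the poles are accepted.  A seeded uniform-random scheme is
also available.

Products:

* **Penetration potential W(Z)** — the minimum *intermolecular* energy
  over each plane Z = const, with the (LJ, electrostatic, H-bond)
  decomposition of each plane's minimizer.  For an attractive host W is
  a potential well: deeper inside the cavity than outside.
* **Boltzmann PES** — at each point the orientation-averaged energy
  ⟨E⟩ = Σ E_k e^(−E_k/k_BT) / Σ e^(−E_k/k_BT) (energy expectation under
  Boltzmann weights, computed shift-safely; T = 293 K by default).  This
  lies between the per-point minimum and the arithmetic mean by
  construction.  The map is reduced to four Z-slabs of equal width
  tiling the host's Z extent (≈ 2 Å for the 8 Å toy host, ≈ 2.5 Å for a
  cyclodextrin-sized host), each slab reporting the per-(X,Y) minimum of
  ⟨E⟩.
* **Global minimum** — the lattice-and-orientation-set minimizer E_min
  with its pose and full decomposition; ties break lexicographically by
  (Z, X, Y, orientation index).
* **Inclusion classification** — a guest atom is *inside* when its Z
  lies within the host's extent and its radial distance is below the
  cavity radius at that Z (linear fit of site radius vs Z); a complex is
  an inclusion complex when the inside fraction is positive.

Pair distances are clamped at 0.1 Å during scans and energies above
10⁶ kcal/mol mark steric clashes (∞ if no orientation is clash-free).

## Rigid-body dynamics

The guest moves as a rigid body in the fixed host's field: the centre of
mass follows the net intermolecular force, the orientation — a unit
quaternion, avoiding the Euler-angle singularity — follows the net
torque about the COM.  Integration is leap-frog with dt = 1 fs;
configuration and energies are registered every 100 steps (0.1 ps).

Constant temperature (293 K) is enforced by an isokinetic constraint in
the style of the Brown–Clarke leap-frog: after each velocity update the
translational velocity and the angular momentum are rescaled by scalar
factors so that the translational and rotational kinetic energies sit
*separately* and exactly at their equipartition targets (3/2)k_BT.
Because re-expressing the angular momentum in the rotated body frame
shifts the rotational KE by a few 10⁻⁶, the rotational constraint is
re-applied to the stored end-of-step momentum, making both reservoirs
exact at every stored state.  With the thermostat off the scheme reduces
to plain (energy-conserving, time-reversible) leap-frog; energy
conservation should be assessed with time-synchronized velocities
(v(t) = v(t−dt/2) + a·dt/2), since the staggered sum oscillates at the
half-step offset.

Initial conditions follow the four canonical approach classes: COM on
the cavity axis 1 Å beyond the narrow or the wide rim, with either the
"radical" (polar tail) end or the "phenyl" (head) end pointing toward
the cavity, a seeded random azimuth about the axis, and random velocity
directions with magnitudes set exactly to the equipartition targets.
The default protocol runs three seeded trajectories per class — twelve
in total.

A trajectory ends when the guest has truly departed: COM outside a
cylinder of (max host radius + 2 Å) over the host Z extent ± 2 Å *and*
Einter above −k_BT, sustained for 50 consecutive sampled frames; a
`max_steps` cap (default 2·10⁵ desk scale, 6·10⁵ in the acceptance
script, i.e. 0.6 ns) flags non-terminated runs.  The *residence time* is
the total sampled time with Einter below −k_BT.

The inner loop also exists as a numba-compiled kernel that advances one
sampling interval at a time; it mirrors the reference `step()` exactly
and is cross-checked against it in the tests.  Quaternions are
renormalized every step (norm drift < 10⁻⁸ over 10⁶ steps).

## Observables

* **Position probability density** — COM samples histogrammed into cubic
  voxels (0.5 Å default) with half-open bins; probabilities normalize by
  the total sample count, with out-of-grid samples in a reported
  overflow bin.  XY and XZ marginals and per-disposition subsets
  (radical-first / phenyl-first / narrow-rim / wide-rim) are available;
  subset densities mix back to the full density with count weights.
* **Binding free energy** — F = −k_BT ln Σ_i e^(−W_i/k_BT) over the
  registered complex energies W_i of one trajectory (log-sum-exp).  With
  one frame F = W₁; N identical frames give W − k_BT ln N; F never
  exceeds min W_i.  F is computed per trajectory and averaged
  (unweighted) to F_mean, since a per-trajectory spread is the natural
  report of the protocol.  W_i is the frame's total energy E.
* **Summary** — E_mean is the frame-weighted mean of totals across all
  trajectories (components sum to it exactly); t_mean is the unweighted
  mean residence time.

## The synthetic system

Because real cyclodextrin coordinate and charge sets are external data,
the default study system is generated:

* **Toy host** — 4 rings × 10 LJ sites between rim radii 3.0 Å (narrow)
  and 3.9 Å (wide), height 8 Å: a βCD-like truncated cone (cavity
  diameter ~6–8 Å).  Rim rings carry ±0.05 e (net neutral) and two
  wide-rim sites are hydrogen-bond acceptors.  Site well depth
  0.135 kcal/mol was fixed once so that the cavity minimum is
  approximately −10 kcal/mol for the default guest — the energy scale of
  small-molecule cyclodextrin complexation (measured: Einter_min ≈
  −16.7, Emin ≈ −11.1).
* **Toy guest** — a 10-site rod along body Z (9.9 Å, eugenol-like
  length), shallow planar zig-zag so every dihedral is defined, a polar
  donor-H tip carrying ±0.25 e, and a 3-fold torsion with phase γ = π so
  the rigid reference conformation carries a positive internal energy
  (Eintra = 5.67 kcal/mol), as a bound, conformationally strained guest
  would.  Bond/angle equilibria are generated consistent with the
  geometry, so stretch and bend vanish at reference.
* **Harmonic probe** — a single particle in ½k|r|² with closed-form
  energy, force and period, used as the integrator oracle.
* **Best-effort molecular assets** — `packaged_bcd_eugenol()` builds a
  β-cyclodextrin (C₄₂H₇₀O₃₅, no stereochemistry) and a eugenol from
  connectivity at run time with RDKit (ETKDG embedding, Gasteiger
  charges, generic element-based LJ table).  These are synthetic
  reconstructions for pipeline exercise, not literature structures, and
  support no quantitative claims.

What the toys do *not* emulate: atomic-resolution cavity corrugation,
host flexibility, discrete water, real charge distributions.  Passing
tests demonstrate correctness of the machinery (energies, minima,
constraints, bookkeeping), not chemical accuracy for any real complex.

## Numerical choices and limitations

* Scan clash floor 0.1 Å; clash energy threshold 10⁶ kcal/mol.
* Boltzmann averages use max-shifted exponentials; F uses
  `scipy.special.logsumexp`.
* Degenerate (singular-inertia) bodies — single sites, strict linear
  rods — propagate translation only.
* Desk-scale defaults (0.5 Å grid, 256 orientations, 0.2–0.6 ns caps)
  are chosen so a full study runs in minutes on one core; the
  reproduction-scale settings (0.1 Å, 23 328 orientations) are available
  through the same configuration surface and run for hours.
* In the toy system the −16.7 kcal/mol well plus isokinetic dynamics
  keeps most trajectories bound beyond the cap, so t_mean is
  right-censored at the cap; escapes, when they occur, happen on the
  ~100 ps scale.
* The rigid-guest treatment makes Eintra constant along a trajectory;
  torsional flexibility during dynamics is not modelled.
* Lattice minima are reported as-is; no continuous local minimization is
  applied.
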