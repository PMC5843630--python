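# Methods

`ipswater` is a self-contained test bench for isotropic-periodic-sum (IPS)
electrostatics in rigid SPC/E water. It exists to answer one question in a
controlled setting: *how does the choice of cut-off scheme — atom-based vs
group-based — interact with the cut-off boundary conditions of the IPS
family of truncated Coulomb potentials?* Everything in the package serves
that comparison: the potentials themselves, a direct Ewald reference, a
small MD engine, and the observables that are known to expose truncation
artefacts.

## The IPS pair potentials

The total electrostatic pair interaction is modelled as

    u(r) = 1/r + phi(r; r_c)   for r <= r_c,      u(r) = 0 beyond,

multiplied by `coulomb_factor * q_i * q_j` (units: kJ/mol, nm, ps, e;
`coulomb_factor = 138.935458 kJ mol^-1 nm e^-2`). The image term `phi` is an
even polynomial in the reduced distance `s = r/r_c`, scaled by `1/r_c`:

    phi(r) = (1/r_c) * sum_k c_k s^(2k).

The family members are distinguished solely by which derivative orders of
`u` are forced to vanish at `r = r_c`:

| method   | vanishing orders | basis degree | extra condition |
|----------|------------------|--------------|-----------------|
| IPSn     | 0, 1             | 2            | —               |
| IPSp     | 0–3              | 6            | —               |
| LIPS-5th | 0–5              | 10           | —               |
| LIPS-SW  | 0–5              | 12           | c_1 = 1/2       |

The coefficients are obtained by solving the linear system these conditions
impose (`solve_ips_coefficients`), using the lowest-degree even-polynomial
basis consistent with the conditions. Two consequences worth knowing:

* **IPSn reduces to the conducting reaction field.** With orders {0, 1} the
  solver returns `c = (-3/2, 1/2)`, i.e.
  `u = 1/r + r^2/(2 r_c^3) - 3/(2 r_c)` — a useful closed-form anchor that
  the tests assert exactly.
* **LIPS-SW is provisional.** Its published form is a periodic
  reaction-field construction whose exact polynomial we do not transcribe
  here. We realise it as the LIPS member with orders 0–5 vanishing plus one
  extra basis degree fixed by a reaction-field-like curvature condition at
  the origin: the reduced `s^2` coefficient is pinned to 1/2, the conducting
  reaction-field value. This gives a well-defined member of the family with
  the advertised boundary smoothness; anyone holding the published
  coefficients can construct `IpsPotential` directly with them, and the
  whole downstream pipeline is unchanged.

`verify_boundary` reports |d^k u/dr^k(r_c)| for k = 0..6 analytically
(term-wise differentiation); finite differences are reserved for the test
oracles because stencils above 3rd order lose too many digits at useful
step sizes.

## Tabulated interactions

Simulations consume potentials through sampled tables in the GROMACS xvg
convention — columns `r, f, -f', g, -g', h, -h'` with
`V = qq*ke*f + C6*g + C12*h`, `g = -r^-6`, `h = r^-12`. Grid: start
0.002 nm, default spacing 0.0005 nm (a warning fires above 0.002 nm).
Evaluation uses cubic Hermite interpolation of (value, derivative) pairs, so
the interpolated force is the *exact* negative gradient of the interpolated
energy — a prerequisite for NVE energy conservation with tabulated forces.

Two deliberate numerical choices:

* **The LJ columns are truncated *and energy-shifted* to zero at the LJ
  cut-off.** The shift leaves forces untouched. At the production-scale LJ
  cut-off (4 sigma = 1.2664 nm) the shift is ~1e-3 kJ/mol and irrelevant;
  at the desk-scale cut-offs this package actually runs (0.45–0.9 nm,
  bounded by half the box edge of 48–216-molecule boxes) the unshifted
  energy jump at the boundary (~0.05–0.3 kJ/mol per crossing event) turns
  NVE total energy into a random walk of ~0.2–2 kJ/mol per molecule over a
  few ps, swamping every conservation diagnostic. Every method *and* the
  Ewald baseline use the same shifted LJ table, so method comparisons are
  unaffected.
* **The electrostatic columns are exactly zero beyond r_c**, and with a
  pseudo cut-off radius `r_c* > r_c` the grid extends to `r_c*` with
  explicit zero rows. A group-based pair list built at `r_c*` over such a
  table reproduces atom-based truncation at `r_c` to summation rounding,
  provided `r_c* - r_c` exceeds the molecular diameter (~0.2 nm for water),
  so that no atom pair inside `r_c` can belong to a group pair beyond
  `r_c*`.

## Cut-off schemes

One rigid water = one charge group (net charge zero); the group reference
point is the geometric centre of its three sites. Atom-based lists include
an atom pair iff its minimum-image distance is <= r_c (closed ball);
group-based lists include *all nine* atom pairs of a molecule pair iff the
centres are within r_c — all-or-nothing, so no molecular dipole is ever
split by the boundary. Pair lists are rebuilt every step (no Verlet skin,
no twin-range). Three interchangeable search algorithms (compiled O(N^2),
numpy O(N^2), cell list) produce identical lists and are cross-checked in
the tests; the compiled force loop is likewise mirrored by a vectorised
numpy reference path.

## Ewald reference

The accuracy baseline is a direct Ewald sum (real + reciprocal + self +
intramolecular-exclusion terms), exact at these system sizes and free of
mesh-interpolation error: real-space cut-off fixed at half the minimum box
edge, splitting parameter from `erfc(alpha r_cut) = eps`, reciprocal shells
grown until the standard estimate falls below `eps`, where `eps` is
calibrated so the user-facing tolerance is roughly a per-pair energy error
in kJ/mol. Conventions: tin-foil boundary (no surface-dipole term);
intramolecular pairs of each rigid water excluded, with their
reciprocal-space contribution subtracted via an erf correction. The
rock-salt Madelung constant is recovered to ~1e-5 against an independent
Evjen direct sum, and forces equal central-difference energy gradients to
1e-6 relative.

## MD engine

Velocity Verlet at 2 fs with SHAKE/RATTLE rigid-water constraints and a
single-chain Nose-Hoover thermostat (tau = 0.04 ps, updated every step,
`Q = g kB T tau^2`, degrees of freedom `g = 6 N_mol - 3`). SHAKE solves the
three coupled constraints of each molecule by a batched 3x3 Newton update
along the pre-drift bond directions (relative tolerance 1e-6, typically 2–3
iterations); RATTLE is a single exact 3x3 solve because velocity
constraints are linear. Initial velocities are Maxwell-Boltzmann draws with
centre-of-mass motion removed, constraint-projected, and rescaled to the
target temperature; trajectories are bit-reproducible for a fixed seed.

## System builder

Initial structures are jittered cubic lattices of randomly oriented rigid
waters. The bulk box edge follows exactly from `L^3 = n m_w / rho`, so the
stated state point (0.997 g/cm^3, 298.15 K) is reproduced by construction;
the builder guarantees no intermolecular O–O pair closer than 0.25 nm. Slabs
place the same lattice in a central sub-volume of an elongated box, with the
liquid thickness implied by the bulk density. A lattice start is not a
liquid: 1–20 ps of NVT equilibration (system-size dependent) burns in the
structure, and every reported average in this package is taken after such a
burn-in. What the generator deliberately does *not* emulate: pre-equilibrated
hydrogen-bond networks, interface roughness, or long-wavelength density
fluctuations of systems thousands of molecules large.

## Observables

* **Self-diffusion** from the Einstein relation: particle-averaged oxygen
  MSD on minimum-image-unwrapped positions, multiple time origins (origin
  stride = window/10), least-squares slope over the fit window divided
  by 6; a log-log exponent far from 1 flags a non-diffusive regime.
* **g_OO(r)** with the normalisation `V / (4 pi r^2 dr N (N-1))` applied to
  the ordered-pair shell counts.
* **Kirkwood factor G_k(r)**: cumulative dipole-dipole correlation within
  r, self term included (`G_k(0+) = 1`); reported at bin upper edges.
* **h_OO(r) = 3 g_OO(r) <cos theta(r)>** with the shell-wise mean of
  `u_i . u_j` normalised per reference molecule; empty shells contribute 0,
  which makes `h_OO <= 3 g_OO` an identity only in fully-occupied bins (the
  dense/thermodynamic limit).
* **Slab profiles**: frame-averaged mass and charge densities along the
  surface normal (default dz = 0.02 nm), and the electrostatic potential
  `psi(z)` by double trapezoid integration of the Poisson equation,
  anchored to zero at the lowest-mass-density (vacuum) bin. psi is reported
  in kJ/(mol e); multiply by 0.01036 for volts.

Molecular distances in the dipole observables are measured O-to-O; dipoles
are unit H–H-bisector vectors. Default radial bin width 0.002 nm. Every
binned estimator has an O(N^2) brute-force oracle in the test suite.

## Desk-scale study conditions

Production-scale studies of these systems run 6192-molecule bulk boxes
(r_c = 1.2–2.8 nm) and ~11,000-molecule slabs for nanoseconds. This package's standing conditions
are desk analogues chosen once: bulk boxes of 48–216 molecules (box edges
1.13–1.86 nm), electrostatic cut-offs bounded by half the box edge
(0.45–0.9 nm), LJ cut-off = min(4 sigma, r_c), 2 fs steps, a few ps of
equilibration and 16–50 ps of sampling. The comparison experiments use 216
molecules with r_c = 0.9 nm — the largest cut-off a desk box affords — and
identical seeds across methods so that differences are attributable to the
potential alone.

What these conditions can and cannot show: the boundary-condition physics
(which derivative orders vanish at r_c, and what that does to energies,
diffusion, and dipole correlations under a group-based cut-off) transfers
cleanly, and the Ewald-referenced SPC/E observables land in the literature
range (potential energy ≈ −46 kJ/mol per molecule, D ≈ 2.6e-9 m^2/s at
298 K). What does *not* transfer is convergence with r_c: at production scale the
extended-family potentials only converge to the lattice-sum
baseline at r_c ≳ 1.8 nm, which no desk-scale box can reach, so
desk-scale runs of those methods can sit a few kJ/mol from the Ewald
reference while exhibiting exactly the right boundary behaviour.

A second desk-scale limitation is deliberate and instructive: a *plain*
group-based cut-off makes the total energy discontinuous whenever a group
pair crosses r_c (the interaction switches on/off at atom-pair distances
where the tabulated energy is not zero). The jump scales like the leading
non-vanishing boundary derivative, i.e. it is catastrophic for IPSn
(~kJ/mol per event), small for LIPS-5th/LIPS-SW, and tiny at production
r_c; at desk r_c even the LIPS members random-walk more than 0.01 kJ/mol
per molecule over 20 ps. NVE conservation at desk scale therefore holds for
atom-based truncation and for group-based truncation with a pseudo cut-off
(numerically identical to atom-based), while plain group-based NVE drift is
itself a *measurement* of the boundary-condition quality — the test suite
asserts the former and measures the latter, and the IPSn-group drift is
orders of magnitude above the rest, which is the package's whole point in
miniature.

## Numerical choices, ties, degenerate inputs

* Distances exactly at r_c are *included* in pair lists (closed ball) —
  measure-zero physically, but required for exact oracle equality.
* The boundary-condition solver uses `lstsq` and rejects systems whose
  residual exceeds 1e-9, naming the conflicting conditions.
* Pair distances below the table start (0.002 nm) raise an overlap error.
* Zero-molecule recipes and zero-step simulations return valid empty/
  identity results.
* Block error bars use 5 equal blocks; the choice of five blocks is this
  package's own convention.

## Known limitations

* LIPS-SW coefficients are this package's boundary-condition realisation,
  not the published polynomial (see above).
* The Nose-Hoover chain length and velocity-constraint variant are not
  specified in the source material; single chain + RATTLE is assumed.
* No barostat, no twin-range lists, no mesh Ewald: out of scope.
* Production-scale runs (thousands of molecules, ns sampling) are supported
  by the same code paths but are hours-long; the `production` profile exists
  and warns rather than pretending otherwise.
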