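# Methods

## Model

The package treats a ring homooligomer as a Cα-level elastic network at
its reference (crystal-like) geometry. The potential is a sum of Hookean
pair terms over all Cα pairs closer than a cutoff in the reference,

    V = Σ_{|r⁰_ij| < R_c} (K/2) (|r_ij| − |r⁰_ij|)²,

with a strict inequality at the cutoff. Normal modes are eigenpairs of
the mass-weighted Hessian of V at the reference; the thermal covariance
is the pseudo-inverse relation C = k_B T H⁺ restricted to the non-rigid
modes. Assumptions inherited from the model class: harmonic dynamics
about a single minimum, uniform spring strength, Cα-only resolution, no
solvent. Node masses are uniform (unit) — with identical masses a
mass-weighted and an unweighted treatment differ only by a global scale,
so mode frequencies √λ are quoted in the arbitrary unit √(K/m).

## Symmetry coordinates and irrep labels

For C_n the complex irreps T_k (k = 1..n) have characters
ω^((k−1)m), ω = e^(2πi/n). The projection-operator basis

    U_j^(k) = n^(−1/2) Σ_m conj(T_k(R^m)) R^m e_j

is built with R acting both as a block permutation of subunits
(m → m+1) and as a rotation of every displacement 3-vector by 2π/n about
the symmetry axis; both parts are required for equivariance and are
tested explicitly. Conjugate irreps are combined into real subspaces,
and the package labels those subspaces by the physical wavenumber p:

- Γ_0 = T_1 — totally symmetric, dimension 3·N_subunit, 0 nodes;
- Γ_p = T_(p+1) ⊕ T_(n−p+1) for 0 < 2p < n — dimension 6·N_subunit,
  doubly degenerate modes, 2p nodes;
- Γ_(n/2) = T_(n/2+1) for even n — dimension 3·N_subunit, n nodes.

The real basis of a paired subspace takes √2·Re U and −√2·Im U of
T_(p+1), real parts first; the construction is orthonormal analytically,
which the tests confirm to 1e−10. Labelling by wavenumber keeps the node
law exact (a pure Γ_p mode has 2p nodes) with the totally symmetric
"breathing" subspace at p = 0.

A mode is classified by its squared projection onto each Γ_p (the
weights sum to 1 by completeness); it is called pure above weight 0.99,
and labels within 0.01 of the maximum tie-break to the lower p.

## Canonical frame and symmetrization

All ring math happens in one frame: center of mass at the origin,
symmetry axis = +z (the thinnest principal axis of the subunit-COM
cloud), subunits indexed counterclockwise from +z, subunit-0 COM at
angle 0, angles in degrees in [0, 360). The axis sign is chosen to make
the subunit indexing counterclockwise, with a lexicographic tie-break
when the ordering signal is degenerate.

A reference with exact C_n symmetry is produced geometrically: each
subunit block is rotated into the subunit-0 frame, the n images are
averaged, and the ring is regenerated from the average. This is the
orthogonal projection onto the symmetric subspace — idempotent, residual
at machine precision — and replaces force-field minimization under a
symmetry restraint. Sub-Å input asymmetry therefore moves the reference
slightly relative to an energy-minimized one; ENM mode structure is
insensitive to this, but printed frequencies can shift by a few percent,
which is why frequency comparisons to literature values are made loosely
(±15%) while mode ordering, degeneracy and irrep labels are the strict
checks.

## Angular correlation C(θ)

C(θ) correlates the displacement of the atoms within ±4° of the
subunit-0 COM direction with the atoms within ±4° of angle θ, rotating
the reference displacements by θ first:

    C(θ) = (R_z(θ) s₀) · s(θ) / (|s₀| |s(θ)|),

where s₀ and s(θ) are the summed displacement vectors of the two
windows. The normalization by the two window norms is this package's
convention; it makes C(0) = 1 exactly and bounds |C| ≤ 1 by
Cauchy–Schwarz. Both window half-widths default to 4° and are
configurable. The θ grid is 1°; grid points with an empty window are
gaps (NaN), not zeros. On sparse bead models the reference window can be
empty; an opt-in `widen_to_nearest` grows the allowance just enough to
reach the nearest atom (the CLI uses it, the library default raises).

The RMS of C over the grid — excluding the self window at θ = 0 — is the
cooperativity score; 0.5 is the conventional threshold for calling a
mode cooperative. Wave nodes are read from C(θ) as sign changes with
linear interpolation, and from the per-subunit standing-wave profile as
the zeros of a least-squares fit of A·cos(pθ + φ) to the per-subunit
amplitudes (signed projections of each subunit's summed displacement
onto the dominant collective direction). For a pure Γ_p mode the fit
yields exactly 2p node angles; mixed modes fall back to cyclic sign
counting with amplitudes below 1e−6 of the maximum treated as zeros. The
2p sign-change law for C(θ) itself holds at subunit resolution: windows
that contain no or very few atoms can add sub-subunit wiggles, so dense
models (many atoms per subunit, as in real proteins) show exactly 2p
crossings while very sparse toys may show more.

A node "matches" a subunit interface when its cyclic distance to the
nearest interface angle (midpoint between adjacent subunit-COM angles)
is at most 4°, the same tolerance as the window.

## Ensemble analyses

PCA diagonalizes the maximum-likelihood Cartesian covariance (divide by
F) of globally superposed frames; global superposition iterates
mean-structure refinement to convergence, which makes it idempotent.
Per-subunit superposition — used for intra-subunit RMSF and the internal
term of the fluctuation decomposition — fits each subunit of each frame
onto that subunit's average structure, removing the subunit's rigid
motion as in the standard intra-subunit fluctuation analysis.

The per-subunit fluctuation along a chosen axis (default z) splits as

    total = internal + translational + rotational,

with total the sum over the subunit's atoms of the per-atom variance,
internal the same after per-subunit superposition, translational
N_subunit times the variance of the subunit-COM coordinate, and
rotational defined by subtraction. The rotational term can come out
slightly negative under finite sampling and is reported as computed,
never clamped.

Mode/principal-mode overlap is the absolute inner product; for
degenerate pairs the subspace overlap (RMS of the singular values of the
cross-Gram matrix) is the meaningful quantity, since PCA sees only
variances and freely mixes a degenerate pair.

## Synthetic data

The generator emulates the two features of ring oligomers that drive
the symmetry phenomenology: exact C_n geometry and stiff-core /
soft-interface elasticity. Subunits are bead clusters (uniform random
placement within a 4 Å cube at the ring radius, re-drawn until beads are
over 1 Å apart and the network is well-conditioned), replicated by exact
rotations, with intra-subunit springs stiffened by `core_stiffness`
(default 10). The default radius puts adjacent subunit centers 6 Å
apart so that, under the default 12 Å cutoff, next-nearest subunits also
interact — like real rings, where the cutoff spans several subunits —
keeping exactly six zero modes.

Trajectories are independent draws from the harmonic Boltzmann
distribution: frame = reference + Σ_k a_k u_k with
a_k ~ N(0, k_B T/λ_k), over all non-rigid modes or a chosen Γ_p/index
subset. Defaults: T = 328 K (the growth temperature of the thermophilic
ring protein that motivates the package), K = 1 kcal mol⁻¹ Å⁻²,
R_c = 12 Å, k_B = 0.0019872 kcal mol⁻¹ K⁻¹. Because frames are
independent and exactly Gaussian, static covariances are reproduced
without kinetic artifacts; conversely the generator says nothing about
time scales, anharmonicity, solvent damping, or ligand events — passing
tests validate the analysis machinery, not those aspects of real data.
Pseudo-symmetry is emulated by adding i.i.d. Gaussian noise (σ in Å) to
the reference and recomputing the network and modes on the distorted
structure.

## Numerical choices

- Rigid-body modes: eigenvalues below 1e−8·λ_max; exactly six are
  required, otherwise the network is rejected as ill-conditioned. The
  generator additionally demands the softest genuine mode clear that
  threshold with a 10× margin.
- Degenerate pairs: relative eigenvalue gap below 1e−6.
- Block-diagonalization leakage: off-block Frobenius mass above
  1e−8·‖H‖ raises "structure not C_n-symmetric".
- Symmetrization residual tolerance 1e−10 Å; toy rings are exact to
  ~1e−14.
- PDB dialect: first MODEL, altloc blank or 'A', hydrogens dropped,
  author residue numbering with insertion codes appended.
- Covariances are maximum-likelihood (divide by F); at the frame counts
  used the difference from F−1 is negligible.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
rings: n ∈ {3, 5, 6, 11, 12} with 2–5 beads per subunit for the spectral
checks, a 12×10-bead ring (360 degrees of freedom) for the node-law and
ensemble checks, 20,000 frames for PCA subspace recovery, 50,000 frames
for per-mode equipartition, and five independent rings × 4,000 frames
for the paired pseudo-symmetry comparison. The cooperativity loss under
pseudo-symmetry is a mean effect across rings — individual toy rings can
buck the trend, so both the test and the acceptance script average over
independent replicates.

## Known limitations

- Quantities tied to the TRAP crystal structures (lowest-mode
  frequencies 0.259/0.246, node–interface matching of the real 11-mer vs
  12-mer, the 0.26 Å monomer RMSD) require `data/1C9S.pdb` and
  `data/2EXS.pdb`; coordinate files are not redistributed, so those
  checks report a clear failure message until the files are supplied.
- Frequencies are in the ENM's arbitrary unit; only ratios, ordering and
  degeneracy are physically meaningful.
- The angular correlation normalization is a documented convention (the
  window-sum form above), chosen for its exact C(0) = 1 and |C| ≤ 1
  properties.
- Dihedral (D_n) rings, rings of dimer units, and non-cyclic point
  groups are out of scope.
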