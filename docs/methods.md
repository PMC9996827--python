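# Methods

`rborient` models specular neutron reflection (NR) from a monolayer of
identically oriented, rigid protein molecules adsorbed at an air/water
or oil/water interface, and infers the orientation, interfacial
penetration and surface excess of the protein from multi-contrast
reflectivity data.

## The rigid-body slab model

A residue-level structure is coarse-grained to one bead per residue at
the heavy-atom centroid (switchable to C-alpha).  The bead cloud is put
into a canonical reference frame — centroid at the origin, principal
axes sorted by extent and aligned to (y, x, z) = (major, semi-major,
minor) — which defines the (theta, phi) = (0, 0) orientation.  Axis
signs are fixed by requiring the bead farthest out along y (then x) to
sit on the positive side, so the reference state is reproducible.

Orientation is parametrized by two active, right-handed Euler angles in
the XY convention: theta about x, then phi about y (composite matrix
R_y(phi) R_x(theta)).  NR is insensitive to rotations about the surface
normal z, so two angles cover every distinguishable orientation.  A ZY
convention is available for symmetry analyses.

After rotation, a box spanning the protein's coordinate extents is cut
along z into `n_slices` equal slabs (default 50).  Each residue's whole
volume `V_i` and effective scattering length

    b_i(H) = H * b_i^h + (1 - H) * b_i^d

(`H` the volume fraction of light water; labile hydrogens fully
exchanged by default, with a global exchange-fraction dial for
sensitivity checks) are binned into the slice containing its
representative z.  Per slice, the protein SLD is `sum b / sum V` and the
protein box fraction is `rho_slice = V_slice / (A d)`, with the box
cross-section A padded by 2 A per side against degenerate projections.

The layer hydration is tied to the surface excess Gamma (mg/m^2)
through the protein's molecular-weight-dependent mass density
rho(M) = 1.410 + 0.145 exp(-M / 13 kDa) g/cm^3:

    rho_total = 10 * Gamma / (D_prot * extent)      (dimensionless)
    rho_norm  = rho_total / rho_box

and each slice's total SLD mixes protein and bulk:

    SLD_slice = rho_norm rho_slice SLD_prot + (1 - rho_norm rho_slice) SLD_bulk.

`rho_norm` may exceed 1 (denser than one box per molecule), but any
slice occupancy `rho_norm * rho_slice > 1` raises a `PackingError`
naming the slice rather than silently truncating.

The interface plane sits at `z_interface = min_z(protein) + z_pen`;
`z_pen = 0` leaves the protein entirely in the solvent.  Slices below
the interface take the substrate SLD as bulk, slices above the solvent
SLD, and the straddling slice mixes the two by its z-extent fractions.
The penetrated fraction `P_f` is the fraction of residues below the
interface.

Reflectivity is computed by the characteristic-matrix (Abeles)
recursion over the slab stack between the semi-infinite substrate
(fronting) and solvent (backing), with optional Gaussian Q-resolution
smearing (default off) and optional absorption terms (default 0).  The
kernel is verified against the closed-form Fresnel solution of a bare
interface to |dR| < 1e-8, including total reflection below
q_c = sqrt(16 pi dRho), and against an independently coded Parratt
recursion.

Multi-contrast data are fitted simultaneously: orientation, z_pen and
Gamma are shared across the isotopic contrasts of one condition, while
intensity scale and flat background may optionally be freed per
contrast (fixed at 1 and 0 by default).  The goodness of fit is the
plain summed chi^2 with dR weights.

### A gauge degeneracy of the XY parametrization

The projection of any point onto z satisfies
`z(theta + 180, 180 - phi) = z(theta, phi)` identically, so these two
parameter points produce the *same* SLD profile for any structure: the
XY angle chart double-covers profile space.  This is distinct from the
physically motivated near-degeneracy (theta + 180, phi + 180), which
flips the molecule and produces a similar profile only insofar as the
mass distribution is mirror-symmetric.  All recovery scoring and
credible-region checks treat the four profile-equivalent images of a
state as one physical solution.

## Optimization

The orientation posterior under percent-level noise is of order one
degree wide in a 360-degree domain, so a single stochastic global
search is unreliable.  `best_fit` therefore chains three deterministic
stages: differential evolution over the full parameter box (which pins
Gamma and z_pen), a 5-degree (theta, phi) grid scan at those nuisance
values, and Nelder-Mead simplex refinement (with restarts) from the
best grid candidates.  Simplex rather than gradient polish is used
because whole-residue binning makes chi^2 piecewise smooth with small
steps whenever a residue crosses a slice edge.

## MCMC

The posterior is proportional to exp(-chi^2 / 2) under uniform priors
inside the bounds.  The sampler is a delayed-rejection adaptive
Metropolis (DRAM): a symmetric Gaussian random walk whose covariance
adapts every 1000 steps to `2.4^2/d * cov(history)` (Haario scaling),
with one delayed-rejection stage at 0.2 times the proposal scale.  The
angle coordinates are periodic: proposals wrap across +-180 (a step of
-3 from -179 lands at +178), which removes the reflecting barrier at
the seam; z_pen and Gamma proposals are reflected at their bounds.
Internally the walk is left unwrapped so covariance adaptation never
sees the seam; stored chains are wrapped to [-180, 180).  Production
settings default to 2,000,000 steps with 200,000 burn-in and 5
independent repeats (differing only in seeds spawned from one master
seed); tests and the worked examples scale this down.  For multimodal
posteriors whose modes do not mix, `combine_chains` concatenates
chains started at each mode and records the provenance of every
segment.

## Posterior summaries

Orientation densities are estimated on a 1-degree periodic grid by
diffusing the sample histogram under the heat equation — a wrapped-
Gaussian convolution via FFT, which is exactly periodic and
mass-conserving — with a per-axis plug-in bandwidth (circular standard
deviation times n^(-1/6), floored at one grid cell).  This is a
fixed-bandwidth diffusion estimate; a fully adaptive-bandwidth
diffusion solver is a known refinement that is not implemented here.
Highest-posterior-density regions at 25/65/95% are super-level sets
found by sorting grid cells by density (ties broken by cell index) and
accumulating mass; regions are nested by construction and their
enclosed mass is within one cell of nominal.  Gamma and z_pen
marginals, being roughly Gaussian, are summarised as mean +- standard
deviation.  Credible bands for SLD profiles and reflectivity curves
are pointwise interpolated percentiles over (by default) 3000 posterior
draws; draws on which the forward model fails are dropped with a
warning, never silently replaced.

## Footprints

The molecular footprint of an oriented protein is the area of its
residues projected on the interfacial plane: the convex hull, and a
concave alpha-shape (Delaunay triangles with circumradius < alpha,
default alpha twice the median nearest-neighbour spacing of the
projection; a fragmenting alpha raises an error with the fragment
count).  Projected bead centres are used without inflation by residue
radii (an optional buffer exists).  These geometric areas are compared
with the area per molecule implied by the measured surface excess,
APM = MWT / (N_A Gamma), about 1.01e4 A^2 for a 146 kDa protein at
2.40 mg/m^2.

## Synthetic data

The generator builds bead proteins (sphere, ellipsoid, cylinder, or a
three-lobed mAb-like Y with one arm biased to heavy residues so its
2-fold symmetry is broken) by rejection sampling with a 4 A minimum
bead separation, drawing residue identities from the real parameter
table so Gamma/hydration bookkeeping runs at realistic magnitudes.
Default experiment conditions mirror the standard contrast-variation
design: NRW, protein-matched water (SLD 2.56e-6 A^-2) and D2O over an
air substrate (oil variants swap the substrate SLD to 5.65e-6 A^-2),
Q in 0.012-0.4 A^-1, with multiplicative Gaussian noise
(sigma_rel = 1% by default) plus a 1e-7 additive background floor.
What the generator does *not* emulate: instrument-specific resolution
functions, the finite oil-film thickness, inter-protein structure
factors, orientation mixtures, and conformational flexibility — so
passing recovery tests demonstrate the estimator's correctness under
the model's own assumptions, not robustness to real-data systematics.

## Numerical choices and limitations

- Residue parameters: element coherent scattering lengths (fm):
  H -3.739, D 6.671, C 6.646, N 9.360, O 5.803, S 2.847; residue
  volumes from the standard empirical tabulation; exchangeable-H counts
  for side chains in their pH ~7 charge states.  Pure-water densities
  0.998 / 1.105 g/cm^3 (20 C) reproduce SLD endpoints 6.35e-6 and
  -0.56e-6 A^-2 within 1%.
- Residue-to-slice binning uses half-open intervals [lo, hi), top slice
  closed; empty slices store SLD_prot = 0 with V = 0.
- Under whole-residue binning the pointwise occupancy profile does not
  converge as slices shrink (a finite residue volume in an ever-thinner
  slab diverges); the cumulative volume distribution does, and the
  default 50 slices is the regime the model is designed for.  Profile-
  space comparisons between states therefore smooth both profiles with
  a fixed 3 A Gaussian — structure below ~16 A (2 pi / Q_max) is
  invisible to the data, while slice-edge jitter otherwise dominates
  the raw RMS.
- Unknown residue codes in input structures raise an error by default
  (silent substitution would corrupt the SLD); multi-model PDB files
  use model 1; first altloc wins; hydrogens are ignored.
- The sampler's DR acceptance uses Gaussian stage-one densities with
  wrapped differences; this is exact for the reflected dimensions and
  the standard approximation for folded kernels.
- Scaled-down problem sizes in the shipped tests: a 300-bead synthetic
  protein, 60-point Q grids, 5e4-step chains for recovery and 1.5e4 for
  the contrast-variation comparison.
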