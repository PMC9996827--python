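# rborient

Rigid-body orientation modelling of interfacially adsorbed proteins for
specular neutron reflectometry (NR).

Proteins — monoclonal antibodies in particular — adsorb to the
air/water and oil/water interfaces they meet during manufacturing,
filling and storage, and the orientation they adopt there controls how
the adsorbed layer packs, penetrates the interface and (potentially)
destabilises.  Specular NR measures the reflectivity R(Q) normal to the
interface and so encodes the depth profile of scattering length density
(SLD), but a slab-model fit of R(Q) says little about *which way up*
the molecule sits.  `rborient` closes that gap: it takes a residue-level
structure, treats it as a rigid body, and fits its orientation,
interfacial penetration and surface excess directly to multi-contrast
reflectivity data, with full Bayesian uncertainty on the orientation.

It is written for scattering scientists analysing protein adsorption at
liquid interfaces (and for methods work on such analyses): the library
is the primary interface, with a thin `rborient` command-line wrapper.

## The model

A structure is coarse-grained to one bead per residue (volume `V_i`,
solvent-exchange-aware scattering length
`b_i(H) = H b_i^h + (1-H) b_i^d`).  The canonicalized bead cloud is
rotated by two Euler angles (theta about x, then phi about y; rotations
about the surface normal z are invisible to NR), boxed, and cut along z
into 50 equal slices.  Per slice, the protein SLD and volume fraction
combine with the bulk (solvent above the interface at
`min_z + z_pen`, substrate below) into a hydrated slab profile:

    SLD_slice = rho_norm rho_slice SLD_prot + (1 - rho_norm rho_slice) SLD_bulk,
    rho_norm  = rho_total / rho_box,
    rho_total = 10 Gamma / (D_prot extent),

with the surface excess Gamma (mg/m^2) and the molecular-weight-
dependent protein density D_prot tying hydration to the measured
adsorbed amount.  Reflectivity follows from the optical-matrix (Abeles)
recursion, co-refined across isotopic contrasts (e.g. NRW,
protein-matched water, D2O).  A best fit comes from differential
evolution plus grid-seeded simplex refinement; posteriors come from a
delayed-rejection adaptive Metropolis sampler with periodic boundaries
in the angles, summarised as toroidal kernel densities,
highest-posterior-density regions (25/65/95%), mean +- sd intervals for
Gamma and z_pen, and credible bands for profiles and curves.  Footprint
areas (convex hull, concave alpha-shape, and `APM = MWT / (N_A Gamma)`)
connect orientation to packing.  See `docs/methods.md` for the full
account, including an exact two-fold gauge degeneracy of the
angle parametrization.

## Worked example

Simulate a noisy three-contrast experiment on a 300-bead mAb-like
synthetic protein adsorbed at a known state — theta = 30, phi = 45,
z_pen = 10 A, Gamma = 2.0 mg/m^2, 1% relative noise — then recover that
state:

```python
import rborient as rb
from rborient.synthetic import (SyntheticSpec, GroundTruth, default_contrasts,
                                make_bead_protein, simulate_experiment,
                                recovery_score)
from rborient.slabs import AdsorptionState, Orientation
from rborient.posterior import kde_torus, hpd_regions, univariate_interval

model = make_bead_protein(SyntheticSpec(shape="y", n_beads=300,
                                        extents=(90, 60, 40), seed=7))
truth = AdsorptionState(orientation=Orientation(30, 45), z_pen=10.0, gamma=2.0)
contrasts = default_contrasts()          # NRW, CM-protein, D2O over air
curves, _ = simulate_experiment(model, GroundTruth(state=truth,
                                contrasts=contrasts, sigma_rel=0.01), seed=1)

problem = rb.FitProblem(model=model, datasets=list(zip(contrasts, curves)))
states, params, chi2 = rb.best_fit(problem, seed=3)
chain = rb.run_mcmc(problem, rb.SamplerConfig(n_steps=50_000, n_burn=5_000,
                                              seed=5), x0=params)[0]
post = chain.posterior
regions = hpd_regions(kde_torus(post[:, :2]))
g_mean, g_std = univariate_interval(post[:, 3])
```

Output (about four minutes on one CPU):

```
best fit: theta=-151.0 phi=135.8 z_pen=9.5 A  Gamma=1.997 mg/m^2  chi2/pt=0.66
profile RMS error: 2.3% of dynamic range
acceptance rate 0.65; Gamma = 1.999 +- 0.002 mg/m^2
95% HPDR area: 28.0 deg^2
```

What the numbers mean: the fitted angles (-151.0, 135.8) look nothing
like the truth (30, 45) but are its *exact* profile-equivalent image
under the (theta+180, 180-phi) gauge map — NR cannot tell the two
apart — and indeed the fitted SLD profile agrees with the generating
profile to 2.3% RMS of its dynamic range.  chi^2 per point near 1
means the fit is at the noise floor.  The 95% credible orientation
region covers just 28 deg^2 of the 360x360 deg^2 torus and contains the
truth's image; Gamma is recovered to three decimals because NR is
extremely sensitive to the adsorbed amount.  Dropping to a single
contrast widens the 95% region several-fold, which is the quantitative
case for contrast variation.

The same workflow is scriptable from a shell via YAML configs:

```sh
rborient simulate --config run.yaml      # datasets + manifest
rborient fit      --config run.yaml      # best-fit state, profiles, P_f
rborient mcmc     --config run.yaml      # chains, KDE, HPDRs, bands
rborient footprint --config run.yaml     # APM over an angle grid
```

Every output directory carries a `provenance.json` (config hash, seed,
package version); reruns with the same seed are bit-identical.

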