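# Methods

`piliagg` simulates suspensions of spherical bacterial cells that stick to
each other through discrete adhesive surface sites ("adhesins", a coarse
proxy for type-IV pili frozen in the extended state), and quantifies the
multicellular aggregates they form with an image-autocorrelation statistic.
This note records the model, the conventions, and the judgement calls.

## Cell model

A cell is a rigid body composed of

* one **body sphere** `B` of radius `sigma_B = 5`, and
* `n` **adhesin spheres** `P` of radius `sigma_P = 1` (the unit of length),
  default `n = 19`, whose centers lie on the contact sphere of radius
  `sigma_B + sigma_P = 6` (adhesin spheres tangent to the body surface).

Two placement patterns:

* **localized** — a hexagonally close-packed patch on one side of the body
  (closed shells 1/6/12 for n = 19).  The patch is built as a planar
  hexagonal lattice wrapped onto the contact sphere by an
  azimuthal-equidistant map; the lattice spacing is the smallest (found by
  bisection) at which no two adhesin spheres overlap, i.e. "closely packed"
  is realized as *tangent* spheres.  A spherical cap was chosen over a flat
  plate because it keeps every adhesin at the body-contact distance, where
  the body-adhesin repulsion is exactly at its zero-force point.
* **dispersed** — near-uniform coverage of the whole sphere: a Fibonacci
  spiral point set refined by deterministic pairwise-repulsion relaxation on
  the sphere (200 tangent-projected gradient steps).  No RNG is involved, so
  the template is bit-reproducible.

Energy scale: `kBT = 1`.  Inter-cell atom pairs interact as

* `B-B` and `B-P`: purely repulsive truncated-and-shifted Lennard-Jones
  (WCA) `E(r) = eps + 4 eps [ (s/r)^12 - (s/r)^6 ]` for
  `r < 2^(1/6) s`, `s = sigma_X + sigma_Y`, `eps = 1`;
* `P-P`: soft cosine well `E(r) = A [1 + cos(pi r / r_c)]` for `r < r_c`,
  with `r_c = sigma_P = 1` and binding strength `A = -8` (adhesive strains)
  or `A = 0` (non-adhesive control).  The well is deepest (`2A = -16 kBT`)
  at complete overlap, so bound adhesins sit essentially coincident; with
  arms of 6 on each side, a bound cell pair rests at center distance ~12,
  just outside the 11.2 body-body repulsion cutoff.  Same-cell pairs never
  interact (the body is rigid).

Both potentials and their first derivatives vanish continuously at their
cutoffs.  Per-atom-pair force magnitudes are capped at a configurable bound
(default 1e3) purely as numerical insurance against pathological initial
overlaps; in equilibrated configurations the cap is never active.

## Dynamics

Langevin dynamics with a BAOAB splitting (half kick, half drift, exact
Ornstein-Uhlenbeck velocity refresh, half drift, half kick), `dt = 0.05 tau`.
Orientations are unit quaternions advanced by the exponential map of the
world-frame angular velocity and renormalized every half drift; adhesin
world positions are always regenerated from the quaternion, so rigid
geometry is exact by construction rather than maintained by constraints.

**Time unit and drag.**  `tau` is defined as the time a free adhesin-sized
sphere takes to diffuse one unit length, read as `<|dr|^2> = sigma_P^2` at
`t = tau` in 3D, i.e. `D_P = sigma_P^2 / (6 tau)` and adhesin drag
`zeta_P = kBT / D_P = 6`.  Per-atom drag scales with radius
(Stokes-like), so `zeta_B = 30`, and a cell's translational drag is the sum
over constituents: `zeta = zeta_B + 19 zeta_P = 144` (mass 20 with unit
atom masses, `gamma_t = 7.2 / tau`).  Rotational drag comes from the
adhesins' arms, `zeta_r = zeta_P * sum r_k^2 = 4104`, about an isotropic
orientation-averaged inertia `I = (2/3) sum m r_k^2 = 456`
(`gamma_r = 9.0 / tau`).  The isotropic-inertia approximation ignores the
patch anisotropy of localized templates; it cannot affect equilibrium
distributions, only O(1) factors in rotational timescales.  Drag is a
property of the medium: it is derived at the reference `kBT = 1` so that
zero-temperature test runs retain finite friction.

The fluctuation-dissipation contract is enforced exactly through the OU
coefficients (`c = exp(-gamma dt)`, noise variance `kBT (1 - c^2) / m` per
Cartesian component).  Verified properties: kinetic energy per DOF =
0.5 +/- 5% (translational and rotational), velocity decay `v0 exp(-gamma t)`
exact at `kBT = 0`, free-cell diffusion within 10% of `kBT / zeta` (the
BAOAB finite-`dt` correction factor is 1.011 at `gamma dt = 0.36`), total
energy drift < 0.1% over 1e4 steps with the thermostat off at `dt/10`, and
momentum conservation to 1e-9 without the thermostat.

Noise comes from an explicit xorshift64* stream (SplitMix64-seeded) with
Marsaglia-polar normal deviates, advanced only inside the compiled kernel:
a phase sequence is bit-reproducible from its seed, independent of global
RNG state.

**Neighbor search.**  A Verlet pair list over cell centers (interaction
reach 13, skin 4, rebuilt when any cell has moved half the skin), then
per-pair atom loops with per-class distance gates.  An independent all-pairs
numpy evaluation is kept as an oracle; the two paths agree to 1e-10 in
tests, so list bookkeeping is correctness-checked, not trusted.

**Plate compression.**  To mimic cells settling under an agar pad before
imaging, the final configurations are squeezed along z between two
infinite one-sided walls that move toward each other at constant speed until
a fixed final gap (50).  Each wall repels every atom (bodies and adhesins)
through the same truncated-shifted LJ form in the wall-normal coordinate —
applying walls to all atoms, not only bodies, avoids adhesins poking
through the wall.  The x-y box remains periodic and fixed.

## Simulation presets

| parameter | `full` preset | `desk` preset (default) |
|---|---|---|
| cells | 512 | 64 |
| box | 500^3 periodic | 200^3 periodic |
| number density | 4.1e-6 | 8.0e-6 (1.95x) |
| equilibration | 8e8 tau | 2e5 tau |
| recording | 300 frames / 1.5e8 tau | 3 frames / 1.5e4 tau |
| frames quantified | every recorded frame | final frame |
| compression | 2e7 tau, 500 -> 50 | 1e4 tau, 200 -> 50 |
| replicates | 5 | 5 |

The `full` preset pins the full-scale reference protocol; at ~1.6e10 steps
per replicate it is far beyond a single workstation, so all tests and the
acceptance script use the `desk` preset.  Desk problem sizes were chosen as
the package's own scaling: 64 cells keep the density within 2x of full
scale in a box still ~15 interaction diameters wide; 2e5 tau gives each
cell several diffusive encounter times (mean free path ~50, cell diffusion
length ~90 over the run), enough for the adhesion-pattern contrast to
develop; the compression speed (7.5e-3 per tau) stays ~30x below thermal
speeds, i.e. quasi-static.  The desk protocol compresses and
quantifies the final recorded configuration of each replicate (the
full-scale protocol compresses every recorded configuration;
`n_compress_frames` extends the desk average over the last K recorded
frames when more smoothing per replicate is wanted).  Replicate k of every strain uses seed
`base_seed + k`, giving paired seed sets across strains.

## From configurations to aggregate sizes

1. **Projection.**  The compressed configuration is projected onto the x-y
   plane: each body drawn as a filled disk of radius `sigma_B`; a pixel
   (1 length unit, centers at half-integers) is foreground iff its center
   lies in a disk under the periodic metric.  Pixel-center rasterization was
   chosen over anti-aliasing because it admits an exact lattice-enumeration
   oracle.
2. **Autocorrelation.**  `C(r) = <phi(0) phi(r)> / <phi^2>` over all pixel
   pairs, by FFT: circular correlation for periodic projections; zero-padded
   correlation with per-lag valid-pair normalization for micrographs.  Lags
   are binned into unit-pixel radial shells (bin = rounded lag magnitude)
   with pair-count weighting; `C(0) = 1` identically for binary fields.
3. **Fit.**  Weighted least squares of `C(r) = C_inf + (1 - C_inf)
   exp(-r/a)` over `r in [0, min(L/4, 150 px)]`, excluding bins with fewer
   than 100 pairs; weights ~ sqrt(pair count) (heteroscedastic bin noise);
   initial guesses from the large-r plateau and the 1/e crossing; bounds
   `0 <= C_inf <= 0.999`, `0.1 <= a <= 4 r_max`.  Non-convergence or a
   bound-pinned parameter is flagged in the result, never silently passed.
   The fit range and weighting are surfaced in the result metadata because
   they are analysis choices, not measurements.
4. **Report.**  Aggregate size = `2a`.  For binary fields
   `C(r -> inf) -> <phi>`, so fitted `C_inf` should approximate the
   foreground area fraction — a built-in sanity check asserted in tests.

A particle-space cross-check, independent of imaging: cells are clustered
by union-find over inter-cell adhesin pairs closer than `r_c` (minimum
image).  The non-adhesive strain must decompose into singletons, and the
image-based ranking of strains must agree with mean contact-cluster sizes.

## Synthetic data

All validation inputs are generated, with ground truth:

* `bernoulli` — iid occupancy at a target fraction; its exact correlation
  (`C(0)=1`, `C(r>0)=p`) pins the normalization.
* `smoothed_noise` — thresholded Gaussian-filtered periodic white noise;
  the measured correlation length is monotone in the kernel scale, which is
  asserted as a ladder.  Its correlation function is *not* exactly
  offset-exponential, so exact fit-recovery claims are made only on
  `make_exponential_profile` (model-exact profiles with optional noise);
  smoothed noise is used for monotonicity and area-fraction checks only.
* `disks` — uniform or parent-clustered disk placements (small vs large
  aggregates) rasterized by the same projection code.
* `micrograph` — phase-contrast emulation: dark disks (diameter ~15 px,
  i.e. ~1 um cocci at 100x / 0.065 um per px) with bright halo rims on a
  bright background, multiplicative illumination gradient (+/-15%),
  additive Gaussian noise (sd 0.02 on a unit intensity scale, SNR ~22
  against the 0.45 cell-background contrast — a well-exposed sCMOS
  acquisition), and 0.2% salt-and-pepper outliers, paired with the
  noise-free mask as ground truth.

What passing on these fixtures does **not** show: real micrographs have
out-of-focus light, cell-shape variation, rafts and debris, and correlated
(not iid) noise; the segmentation defaults (block 51 px, offset 2% of
dynamic range, opening 1 px, closing 2 px) are standard starting points a
user should revisit per dataset, and the IoU acceptance on fixtures
calibrates the pipeline's mechanics, not any particular microscope.

## Numerical choices and degenerate inputs

* Zero separation: repulsive kinds raise (or cap, during dynamics); the
  cosine well is finite with zero force at `r = 0`.
* Initial placement: rejection sampling with minimum center distance
  `2 sigma_B`; a packing failure after bounded attempts raises an
  infeasible-density error.  Residual body-adhesin overlaps at t = 0 relax
  within a few damped steps under the force cap.
* Minimum image maps components into `(-L/2, L/2]` (upper boundary
  inclusive); the hot path uses round-to-nearest, which differs only on a
  measure-zero set.
* All-zero images raise on autocorrelation (undefined normalization); flat
  profiles (`C == 1`) flag the fit as degenerate (`a` unidentifiable).
* Constant micrographs segment to all-background (offset > 0), by design.
* Quaternion drift uses a 4th-order small-angle expansion below half-angle
  0.05 rad (relative error < 1e-10 there) and exact trig above.

## Known limitations

* Pili are static adhesive sites: no extension/retraction, no twitching, no
  DNA uptake — appropriate for a retraction-motor-deficient background, and
  deliberately so.
* No hydrodynamic interactions, growth, or division; drag is per-atom
  Stokes-like, not a faithful mobility tensor.
* Desk-scale runs reach the aggregation regime but not full coarsening;
  absolute `2a` values are therefore smaller than a full-scale run would
  give, and only the *ordering* of strains (dispersed > localized >
  non-adhesive) is treated as the reproducible claim, assessed over 5
  paired replicate seeds.
* With `A = 0` the adhesin spheres have no interaction at all, so at any
  snapshot instant a grazing inter-cell adhesin pair can momentarily sit
  closer than `r_c`; the contact-cluster count of the non-adhesive control
  is therefore `n_cells` only up to an occasional single grazing pair
  (singleton fraction >= 98% in desk runs), not identically.
* The `full` preset is provided and schedule-checked but not exercised
  end-to-end by tests.
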