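# Methods

## Scope and coordinates

`ovomag` models the on-axis capture of a nanoparticle-labeled egg by a
cylindrical permanent magnet, and the analyses that surround such
experiments. The axial coordinate `z` is the distance from the magnet's
near pole face, positive away from the magnet; all internal quantities are
SI (m, kg, s, T), while file interfaces use mm/mT (field scans) and
mm, mm/s, mm/s² (kinematics tables), the units bench data are recorded in.
Off-axis fields, magnet arrays, 2-D/3-D trajectories, fluid meniscus
effects and multi-egg interactions are out of scope.

## Field model

The on-axis flux density of an axially magnetized cylinder is the standard
solenoid-equivalent solution `B(z) = (Br/2)[(z+L)/√((z+L)²+R²) −
z/√(z²+R²)]`, strictly decreasing and positive for `Br > 0`, with analytic
gradient. The tests hold it against an independent Biot–Savart integration
of the equivalent surface-current loop stack (agreement < 0.1% over
0.1–20 mm, actually ~1e-7) and against the dipole asymptote
`μ₀m/(2πz'³)`, `m = Br·πR²L/μ₀`, beyond ten magnet radii.

Remanence calibration is least squares on field values. Since `B` is
linear in `Br`, the estimator is the closed-form projection
`Br = Σw f B_meas / Σw f²` with `f(z)` the unit-remanence geometric factor;
weights are inverse variances when per-point standard deviations are
supplied, otherwise uniform. Fitting on field values rather than
log-fields keeps the noise model additive, matching how Hall probes err.
When no scan exists, `Br` defaults to 1.3 T (typical sintered NdFeB) and is
flagged as assumed.

The three characterization magnets are S-02-02 (2 mm ø × 2 mm),
S-02-05 (2 mm ø × 5 mm) and S-03-06 (3 mm ø × 6 mm).

## Particle load and magnetization

A 150 µm egg (density 1030 kg/m³) carries `n` beads of 0.365 µm diameter on
its zona surface. The count equivalent to covering an area fraction `c` is
`n = round(c · φ · 4πR_egg² / (πr_p²))` with hexagonal packing
`φ = π/(2√3) ≈ 0.9069` by default. The default study load is `c = 0.25`,
the coverage measured after a 30-minute incubation at which most eggs
respond; it gives `n ≈ 1.5×10⁵`.

Per-particle magnetization is the continuous piecewise model
`m(B) = min(χV_p B/μ₀, m_s)`: linear (superparamagnetic susceptibility
regime) below the crossover `B* = μ₀m_s/(χV_p)` and saturated above. The
piecewise form was chosen over a Langevin curve because its breakpoint is
analytically checkable; a Langevin option could sit behind the same
contract. Defaults `χ = 1.4` (SI volume susceptibility) and
`m_s = 1×10⁻¹⁵ A·m²` correspond to ~30% w/w magnetite
(σ_s ≈ 92 A·m²/kg, ρ ≈ 5200 kg/m³) in a 1400 kg/m³ polymer bead of this
size. These magnetic parameters are assumed, not measured, and are
configurable; with them `B* ≈ 35 mT`, so the linear→saturated transition
falls 2–3 mm from the small magnet's face — inside the travel range, which
is what produces the late, abrupt rise of the acceleration.

The total pull is `F(z) = n·m(B(z))·|dB/dz|`, i.e. identical point dipoles
at the egg centre; inter-particle dipolar interactions and the spatial
spread of beads over the zona are ignored (the egg radius is small against
the field's length scale except at contact).

## Capture dynamics

Forces on the egg along the axis: magnetic pull `F(z)`; Stokes drag
`γv` with `γ = 3πηd` times an optional wall factor (default 1.0 — wall
corrections for a sphere on a plane are O(1) and unknown for a rough zona);
Coulomb friction `μ_k W` against the dish with stiction threshold `μ_s W`,
where `W = (ρ_egg−ρ_medium)Vg` is the immersed weight. Defaults: PBS
(η = 1.0 mPa·s, ρ = 1005 kg/m³), `μ_s = μ_k = 0.1`. A neutrally buoyant or
floating egg (`W ≤ 0`) has no frictional contact; the simulator then drops
the friction terms and the effective range is undefined (raised as an
error), since there is no threshold to cross.

The full dynamics `m_egg dv/dt = F(z) − γv − μ_k W` are integrated with
LSODA (rtol 1e-9) and a terminal event at contact `z = R_egg` (particles sit
on the zona, so contact is face-to-centre distance of one egg radius). A
quasi-static mode drops inertia (`v = (F−μ_k W)/γ`); the Stokes relaxation
time `m_egg/γ ≈ 1.3 ms` is orders below capture times, and the two agree to
≲0.02% on the characterization scenario. Sliding (not rolling) contact with
constant kinetic friction is assumed throughout the motion.

Cumulative magnetic work, drag dissipation and friction dissipation are
integrated as additional ODE states, so the energy audit
(work ≥ drag + friction at every step, remainder = kinetic energy) holds to
solver precision rather than to quadrature error.

Output trajectories are sampled **uniformly in position** (1000 samples by
default), because a release near the effective range produces a long creep
followed by a second-scale sprint; time-uniform samples would alias the
sprint entirely. Time stamps are recovered by inverting the monotone `z(t)`
on the solver mesh.

**Effective range** is the largest root of `F(z) = μ_s W`, found by a
coarse scan plus Brent refinement on the decaying branch (the force curve
is monotone beyond contact; a sub-µm non-monotonicity of `|dB/dz|` exists
only inside the contact radius). Zero friction raises an unbounded-range
signal; a threshold above the contact force raises a never-moves signal.

### The two named scenarios

* **Characterization scenario** (`characterize_magnet`): release at
  0.99 × effective range — the "barely attracted" placement of the bench
  protocol. It yields the headline orderings (effective range 5.56 / 6.45 /
  8.73 mm and capture time 80 / 102 / 137 s across the three magnets at the
  default load, both strictly increasing with magnet size) and the
  acceleration signature: |a| stays below 1% of its peak over the first
  half of the travel, and the peak falls within the final 5% of the
  approach.
* **Video scenario** (`default_scenario`): release where the quasi-static
  speed equals 1 mm/s. This start is slow on the scale of the capture yet
  sits above the 3σ speed-noise floor of a 30 Hz camera with 5 µm
  localization noise (≈0.6 mm/s), so motion onset is detectable in a single
  frame. It is the scenario filmed by the synthetic video generator and
  used for closed-loop tracking validation.

With the default friction (`μ_s W ≈ 4×10⁻¹⁴ N` for a 150 µm egg only
25 kg/m³ denser than PBS) the computed effective ranges are several
millimetres — larger than the millimetre-scale reaches seen on real dishes,
where surface adhesion adds a resistive force well above `μ_s W`. The
orderings and signatures, not the absolute ranges, are the validated
content; all thresholds are configurable through `FrictionSpec` and
`EggBody`.

## Trajectory analysis

* **Smoothing**: least-squares polynomial of `x` over `t`
  (`numpy.polynomial`, fitted in a scaled domain for conditioning). With
  `degree="auto"` the degree in [3, 8] minimizing the small-sample
  corrected AIC is chosen. Polynomials cannot follow the contact corner
  (the last frame or two of a capture); the smoothing window should end at
  contact, and the tests fit the approach phase accordingly.
* **Differentiation**: analytic derivatives of the fitted polynomial, and
  independently raw second-order finite differences using the exact
  3-point stencils for nonuniform steps (camera frames may drop), with
  one-sided second-order endpoints. Both stencils are exact on quadratics.
* **Onset detection**: motion onset is the first time the finite-difference
  speed (3-point median filtered, so a single noisy dip cannot delay it)
  exceeds a noise floor for ≥3 consecutive samples. The default floor is
  3× a robust speed-noise scale, `σ_v = √2 σ_x/Δt`, with `σ_x` estimated
  from the median absolute second difference of `x` (noise contributes
  √6 σ_x to second differences while smooth motion contributes only
  O(Δt²), so the estimate needs no prior segmentation into
  stationary/moving parts). The estimator assumes near-uniform sampling;
  for noiseless simulator output pass `noise_floor=0`.
* **Capture metrics**: observed effective range = position at onset;
  observed capture time = remaining track duration. On synthetic 30 Hz
  videos with 5 µm noise the median recovery error over 20 seeds is ~3%
  (capture time) and ~1% (range); single seeds scatter by about one frame
  interval, which on the ~0.6 s video capture can reach ~14%.

## Coverage quantification

Egg segmentation: Otsu threshold on the full image (the egg is darker than
the background), largest connected component, holes filled, with a
plausibility window of 100–200 µm equivalent diameter. The ZP band is the
annulus within 19 µm of the disc boundary (the measured zona thickness;
configurable), computed from the Euclidean distance transform — exact for
widths where structuring-element erosion becomes expensive. Particle
pixels are those below a second Otsu threshold computed within the band.

Otsu always splits a histogram, even pure noise, so the band threshold is
guarded by a separability test: splitting Gaussian noise at its mean gives
a between-class gap of ~1.6σ against a within-class spread of ~0.6σ
(ratio ~2.7), while genuine egg/particle bimodality scores far higher; a
ratio below 4 declares the band unimodal, and the band is then classified
as particle-free or fully covered by comparing its median intensity with
the particle-free egg interior. All decisions are histogram-shape and
median based, so coverage is invariant to affine intensity rescaling.
Coverage is the particle-pixel percentage of the 2-D projected band (a
whole-disc variant is exposed as a flag); it is not a 3-D surface
estimate.

## Synthetic data

Every generator takes an explicit seed and creates its own
`numpy.random.Generator` — no process-global state, so outputs are byte
identical across runs and test orderings, and each generator's output
satisfies the consuming module's preconditions by construction.

* **Field scans**: model field plus i.i.d. Gaussian noise (default 2 mT,
  the scale of a bench Hall probe).
* **Capture videos**: the simulated trajectory interpolated onto camera
  frames (default 30 Hz), preceded by a stationary lead-in (default 1 s, so
  onset detection has a pre-motion segment), plus i.i.d. Gaussian
  localization noise (default 5 µm, sub-pixel tracking at a stereomicroscope
  scale).
* **Count tables**: independent binomial draws at specified per-label
  probabilities, at the tens-of-eggs-per-replicate scale of the real
  experiments.
* **Micrographs**: bright background (grey 200), darker egg disc (120),
  darkest dots (40), Gaussian pixel noise (default σ = 3). Dot centres are
  drawn uniformly over the band annulus **with overlaps allowed** (a
  boolean/Poisson germ-grain model): projected particle aggregates do
  overlap in real images, and sequential *non-overlapping* placement of
  equal discs jams at ~0.55 area fraction, below coverage levels the
  estimator must be exercised at. The realized covered fraction is tracked
  exactly on pixels and placement stops once the target is reached, so the
  realized value overshoots by at most one dot area and is returned with
  the image. Unreachable targets (≥1, or dots larger than the band) raise
  an infeasibility error. No optical PSF, cumulus cells or photorealistic
  texture are modeled — passing closed-loop tests shows the thresholding
  logic is correct on images with the assumed three-level structure, not
  that it is robust to real optics.

## What the tests do and do not show

The suite validates internal consistency (simulator ↔ tracking pipeline,
generator ↔ estimator closed loops), agreement with independent numerical
oracles (Biot–Savart, closed-form constant-force solution, grid search,
score-test inversion, hand-expanded chi-square), statistical calibration
(type-I error 4.5–6.5% at nominal 5%; Wilson coverage ≥93% at nominal 95%)
and the qualitative orderings and signatures reported for the real system.
It does not validate the assumed magnetic and frictional parameter values
against measurements — none are published for this system — nor the
segmentation against real micrographs.

## Statistical choices

Pearson chi-square without continuity correction is the default (the
correction is exposed as a flag); p-values are two-sided on 1 df. No
multiple-testing adjustment is applied across tables, mirroring
per-comparison practice. The in-vivo binomial GLM with a litter random
effect that would refine the implantation/offspring comparison requires
per-litter data that are not published; the package implements the
chi-square comparison on the printed totals only. Wilson score intervals
are used for proportions because they behave at the 0/n and n/n boundaries.
The reversibility monotonicity flag tolerates local increases only when
successive Wilson intervals overlap, so sampling noise on a genuinely
decreasing course does not flip it (flag correct in ≥95% of simulated
courses at n = 40 per point).

## Numerical choices

ODE: LSODA, rtol 1e-9, atol scaled to the release distance, terminal event
at contact. Effective-range root: 4096-point bracket scan + Brent, xtol
1e-12 m, validated against a 1 µm exhaustive grid (agreement < 0.4 µm).
Quasi-static acceleration is reported as `v·|F'(z)|/γ` with a central
difference of the force (h = 0.1 µm). Polynomial fits run in numpy's
scaled domain; coefficients are converted back to the raw time variable.
Degenerate inputs (all-equal scan distances, underdetermined fits,
zero-margin tables, bands wider than the egg) raise errors rather than
returning numbers.
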