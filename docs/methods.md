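# Methods

`aerotree` is a reduced-order model of how structural and functional
alterations of severe-asthmatic airways reshape inhaled-aerosol transport.
It replaces the resolved-CFD stages of an image-based pipeline (LES flow
fields on CT-derived meshes) with analytic in-branch flow plus a Lagrangian
particle model, while keeping the three quantities that organise the
physics: lumen circularity **Cr**, hydraulic diameter **Dh**, and the branch
Stokes number **Stk**. This note records the model, its assumptions, the
defaults, and what the reductions do and do not preserve.

## Airway trees and morphometry

A tree is a rooted set of straight branches; each branch carries proximal
and distal cross-sections reduced to lumen area `Ac` and perimeter `Pe`.
Metrics:

- `Dave = sqrt(4 Ac / π)` — area-equivalent diameter. (Some sources typeset
  this expression without the square root; dimensional analysis and the
  magnitudes of published airway tables require the root, which is what we
  implement.)
- `Cr = π Dave / Pe ∈ (0, 1]` — circularity; 1 for a circle.
- `Dh = 4 Ac / Pe = Cr · Dave` — hydraulic diameter.

Within-branch properties are linearly interpolated between stations (no
within-branch profile is claimed by the data the model emulates; a station
argument exposes the choice of measurement plane). Ellipse perimeters use
the Ramanujan-II approximation (relative error < 1e-9 up to the 5:1 aspect
cap, far below airway-measurement precision); recovering ellipse axes from
`(Ac, Pe)` inverts that formula by monotone root-finding.

## Synthetic phenotypes

The generator emulates CT-derived inputs rather than images: a fixed
34-branch anatomical template (trachea, main and lobar bronchi, named
segmental branches RB1–RB10 / LB1+2–LB10b; 31 named branches after the
first generation), Murray-type parent-to-child diameter ratio 0.79 with
lognormal jitter (σ = 0.05), length-to-diameter ratio 3.0 (σ = 0.10), and a
trachea of Dave 18 mm (chosen so the tracheal Reynolds number at the study
inflow sits mid-band, ~1410).

Branch azimuths are defined in the same turn-plane basis the flow model
uses (φ = 0 along the projection of the grandparent's axis — the direction
the incoming momentum keeps pointing). Anatomically continuing trunks sit
at φ = 0 and side/upper takeoffs at φ = 180; this is the geometric fact
that makes inertial particles overshoot upper-lobe takeoffs. The ellipse
minor axis lies in the same plane, which couples reduced circularity to
increased impaction: at fixed `Dave`, a flatter lumen moves the wall closer
along exactly the direction unrelaxed momentum points.

Phenotype controls and defaults (the study's claims are orderings, not
absolute ventilation values, so the level of the shift is an assumption
stated here):

| phenotype | cr_target | constriction | upper_shift | RMB angle |
|---|---|---|---|---|
| healthy_1 / healthy_2 | 0.96 | 1.0 | 0.33 | 90° / 91° |
| severe_cr | 0.88 | 1.0 | 0.45 | 83° |
| severe_cr_dh | 0.85 | 0.6 | 0.45 | 88° |

Per-branch circularity is drawn N(cr_target, 0.015), clipped at ±0.04;
`constriction_factor` multiplies `Dave` of lower-lobe (RLL/LLL) branches;
optional focal constrictions rescale one named branch and its descendants
to a target `Dave` (a focal stenosis superposed on diffuse narrowing).
Lobar air-volume change allocates `upper_shift` of the total (default
3.33 L, a healthy TLC−FRC) to RUL+LUL (0.47/0.53 within), the rest to
RML/RLL/LLL (0.15/0.45/0.40), so `U/(M+L)|v = upper_shift/(1−upper_shift)`
exactly. Everything is reproducible from the spec seed.

What the generator does **not** emulate: carinal ridge geometry, airway
curvature and non-planar branching, cartilage corrugation, within-branch
diameter profiles from images, intra-lobe ventilation heterogeneity.
Passing tests on these trees demonstrate mechanisms, not subject-specific
dosimetry.

## Flow

The inlet condition is the peak of a sinusoidal breath, `Q_peak = π·TV/T`
(500 mL, 4.8 s → 3.27e-4 m³/s ≈ 20 L/min), treated as steady inspiration.
Each lobe's air-volume change, divided equally among its terminal branches,
prescribes the terminal flow fractions; internal flows follow by mass
conservation. No pressure/resistance network is solved — the flow split is
ventilation-prescribed by construction.

In-branch velocity is elliptic Poiseuille: `u = 2 u_mean (1 − (x/b)² −
(y/a)²)` along the axis, flux exactly `Q`; divergence-free in uniform
branches; tapered branches add the self-similar lateral component so
streamlines contract with the wall. This is the central model reduction:
no secondary (Dean) vortices, no jets, no flow separation, abrupt frame
changes at bifurcations. Air: ρ = 1.12 kg/m³, ν = 1.64e-5 m²/s.

Glottal turbulence is emulated by an Ornstein–Uhlenbeck fluctuation,
applied in the proximal 25% of the trachea (extent configurable): the
standardized OU state (unit rms, correlation time `eddy_length/|u|`)
multiplies `intensity · |u_local|`, so the fluctuation rms is 0.29 of the
local mean speed and vanishes at the wall like real near-wall turbulence.
Defaults 0.29 and 8 mm. Limitation: multiplicative noise still transports
some particles into the slow near-wall region (an Itô-drift-like artifact),
adding tracheal deposition beyond what a resolved eddy field would give;
tests of the pure ventilation-split mechanism and of the size-ordering of
lobar distribution therefore run with the surrogate disabled — those claims
concern the deterministic mechanisms, and the surrogate only disperses
around them (at demonstration-scale ensembles it can even blur the small
2.5-vs-5 μm step).

Wall loads use Poiseuille surrogates, `τ_w = 32 μ Q/(π Dave³)` and
`ΔP = 128 μ L Q/(π Dave⁴)` (so `ΔP = 4 L τ_w / Dave` exactly). They are
reported for ordering claims (rank correlations), not as resolved
wall-stress fields.

## Particles

Equation of motion: Stokes drag plus buoyancy-corrected gravity,
`du_p/dt = (u − u_p)/τ_p + g (ρ_p − ρ_f)/ρ_p`, with
`τ_p = ρ_p d² Cc/(18 μ)` — the standard form of the `U/(Stk·Dave)` drag
prefactor, exactly equivalent when the particle–particle interaction
factor α is 1 (dilute aerosol; the α^3.7 dependence of the branch Stokes
number `Stk = 2 Q ρ_p d² Cc α^3.7/(9 π μ Dave³)` is retained in the
formula and α is configurable, default 1). Slip correction: classical
three-constant Cunningham form, `Cc = 1 + Kn(1.257 + 0.4 e^(−1.1/Kn))`,
`Kn = 2λ/d`, λ = 68 nm. Gravity default is supine (−y, posterior).

Numerics: per step the drag ODE is integrated **exactly** with the fluid
velocity frozen (exponential integrator), and the position uses the exact
integral of that velocity solution, so the stopping distance `τ_p |v−u|` —
the impaction length — is resolved at any step size; a trapezoidal position
update would smear it whenever `dt > τ_p`. Tracers (d = 0) follow
streamlines identically. The step is `min(T/24, max(τ_p/10, T/240))` with
`T` the branch transit time; after 2.5 transits only slow near-wall
particles remain, whose sole capture mechanism is sedimentation, so the
step grows geometrically (×1.06, capped at T/8) until a residence cap of
`max(120 T, 0.3 s)` — 0.3 s is the time a 10 μm particle needs to settle
across a ~1 mm airway, so gravitational capture is not truncated, and the
generous transit multiple keeps the abandoned (`in_domain`) fraction below
~1%, small enough not to distort lobar statistics.

Walls absorb perfectly (no rebound or resuspension). Deposition is
detected by the lumen test `(x/b)² + (y/a)² ≥ 1` with linear backtracking
to the crossing point.

At a bifurcation the parent outlet disc (normalized coordinates) is cut
perpendicular to the projected daughter-separation direction into sectors
with areas proportional to daughter flows, and each sector is remapped
onto the daughter inlet by a measure-preserving quantile map (carina side
to carina side). Uniform arrivals stay uniform, so the tracer-limit count
split equals the flow split with binomial statistics — the property the
lobar-distribution analyses rest on. The lab-frame velocity is preserved
across the hand-off; its component perpendicular to the daughter axis is
the impaction mechanism. The carinal ridge itself is not resolved:
near-carina particles enter the daughter near its wall and deposit only if
their stopping distance reaches it.

Release protocol (study conditions): 10,000 particles per release,
uniform over a cylinder of radius 10 mm and depth 4 mm at the tracheal
inlet (the disc is stretched to the lumen's ellipticity at equal area, and
clipped with a warning if it does not fit), initial velocity equal to the
local fluid velocity, 9 independent releases per size, sizes 2.5/5/10 μm,
ρ_p = 1000 kg/m³. Fates: *deposited*, *advected* (exits a terminal branch;
lobe recorded), *in_domain* (residence cap). Per-lobe *distribution*
counts first entry into any branch of the lobe. Integer conservation
(released = deposited + advected + in_domain) holds exactly on every run.

## Reported quantities

- FEV1/FVC as integer percent (round half-up, matching clinical tables).
- `U/(M+L)|v` and `U/(M+L)|dist` — upper-to-(middle+lower) ratios of
  air-volume change and of particle distribution counts.
- Deposition efficiency per branch (deposited/entering) against the
  parent branch's Stokes number, ensemble mean ± sd.
- The constriction-coupling table: per-branch `Dave`, `Dh`, `τ_w`, `ΔP`,
  deposition; Spearman rank correlations of `1/Dh` with `τ_w`, `ΔP` and
  deposition *efficiency*. Rank correlation is used because the claims are
  orderings; efficiency (rather than share of released particles) is used
  because absolute per-branch counts are dominated by how many particles
  reach a branch, not by its constriction. Zero-variance inputs yield NaN
  (undefined), never zero.

## Problem sizes used in checks

The verification suite exercises the full study protocol where the claim
is quantitative (tracer-limit lobar split and the constricted-branch
efficiency use 9 × 10,000 particles) and reduced ensembles (3–5 releases of
4,000–20,000) for ordering claims, sized so that the assertion in question
is resolved at ≥ 3 standard errors where practical; each fixture states its
counts. The circularity–deposition comparison is run as a controlled
experiment — two generators identical in seed, geometry and ventilation,
differing only in target circularity — because that isolation (matched
Stokes number, matched angle) is exactly what the matched-Stk framing of
the underlying claim is for.

## Known limitations

- No secondary flows, jets or separation: deposition efficiencies in
  strongly constricted branches are underestimated relative to resolved
  LES, which concentrates a jet onto the carina. In this model a focally
  constricted ~3 mm lower-lobe branch captures roughly three quarters of
  entering 10 μm particles (its daughters included) rather than
  essentially all of them.
- The turbulence surrogate reproduces the printed intensity and eddy
  scale but not eddy structure; its dispersion near walls is artifact-prone
  (see above).
- Uniform intra-lobe ventilation: lobar ratios are exact by construction,
  intra-lobar heterogeneity is absent.
- Expiration, hygroscopic growth, two-way coupling and particle–particle
  collisions are out of scope; walls are perfectly absorbing.
- Statistical claims across subjects are out of scope (the emulated cohort
  is two healthy + two severe phenotypes).
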