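# Model and methods

`learnwalks` simulates the pre-foraging learning walks of ants as the
interplay of three navigation systems and a single fusion rule. This note
describes the model, its numerical choices, the synthetic environment, and
what the package's tests do and do not establish about real behaviour.

## The model

An agent moves in the x–y plane with fixed step length U, the nest at the
origin. At every step it forms three estimates of the nest direction and
three familiarity scores in [0, 1]:

- **Vision (mushroom body).** The panorama at the current position is
  rendered as a binary skyline image, mapped onto a unit disk (azimuth →
  polar angle, elevation → radius) and encoded as the 81 Zernike-moment
  amplitudes A_i up to order n_max = 16 — a heading-invariant descriptor.
  The amplitudes drive a VPN→KC→MBON network: each of the 4000 Kenyon
  cells reads a small random subset of the 81 amplitude channels and fires
  when its mean (L1-normalised) input exceeds θ_KC = 0.04, giving ~5%
  sparse activity. The MBON response C_MBON sums the KC→MBON weights of
  active cells; learning depresses those weights by λ_vis per exposure
  (floored at 0), so familiar views yield low responses. The normalised
  novelty (response per active cell) is tracked per step; visual
  familiarity is ω_v = 1 − novelty. During a pirouette-like scan the agent
  learns the current view and re-estimates the visual nest direction θ_v
  as the heading, out of 8 probes, with the steepest novelty decrease.
- **Olfaction.** A normalised Gaussian plume of nest odour,
  C(x, y) = exp(−(x²+y²)/2σ²), gives ω_olf = C directly and a homing
  direction along the analytic gradient, θ_olf = atan2(−y, −x). A
  wind-stretched (anisotropic) variant of the field is provided but not
  used in the nominal conditions.
- **Path integration (PI).** The outbound displacement is accumulated
  per step with i.i.d. Gaussian error (sd 10⁻⁴ m per component, 1% of U);
  θ_PI is the direction of the negated accumulated vector. The PI weight
  is the slack left by the other senses: ω_PI = max(1 − ω_v − ω_olf, 0).

The **Homing Vector** is the weighted sum of the three unit direction
vectors. The **Learning Vector** rotates it by an offset φ ∈ [0, π] that
encodes the exploration/homing trade-off: each modality maps its
familiarity onto an offset contribution (familiar → bold → large
deviation), mixed with the same weights and gated by the binary
exploration state A_c:

- visual: a piecewise-linear ramp on the novelty trace through
  (mean − sd, π) and (mean + sd, 0) over a sliding window;
- olfactory: C·π;
- PI: the ratio r/d_k of the current home-vector length to the walk's
  expected maximum range d_k (d_1 = 0.184 m, growing ×3.8, ×2, ×2).

φ = A_c·(ω_v F_v + ω_olf F_olf + ω_PI F_PI), clamped to [0, π]. While
exploring (A_c = 1) the agent moves along the Learning Vector (or, with
probability p_rand, along a von Mises heading around its current
direction); after the walk's step budget np_j = np_1·r^(j−1) is spent,
A_c = 0 and the agent homes until it re-enters the nest radius. Scans
occur every ⌈np_j / n_j⌉ steps during exploration.

## Numerical and design choices

- **Zernike evaluation.** For panoramas the amplitudes are computed by
  quadrature directly on the (elevation, azimuth) grid — the panorama is
  already a polar sampling of the disk — which makes the amplitudes of a
  cyclically shifted panorama exactly equal (the azimuth sum is a DFT).
  A raster-based route (disk image + pixel-grid basis) exists for generic
  images and agrees with rotation oracles to <10⁻³ on smooth images.
- **Renderer.** One ray per pixel (default 90×25, elevations −10°…60°,
  eye 5 mm above ground) against the triangle mesh, with azimuth/elevation
  culling compiled by numba; object = 1, sky = 0, ground = 0.5. Verified
  pixel-exact against a brute-force ray–triangle oracle.
- **Feature scaling and sparsity.** Amplitudes are L1-normalised per
  presentation, so θ_KC = 0.04 ≈ 3× the mean channel and gates sparsely;
  with KC fan-in 2 the activity is ~5%, the regime in which the network
  actually separates places. (Min–max scaling, selectable via
  `mb.feature_norm`, makes the code ~90% dense and the familiarity field
  spatially flat.) A view that activates no KC carries no familiarity
  evidence and scores fully novel.
- **Direction comparisons** use the normalised (per-active-cell) MBON
  response: the raw sum varies ~2× with how many cells a scene drives,
  which would swamp the familiarity signal.
- **Rate transfer.** A sigmoid firing-rate transfer (`neuron_rate`) is
  provided as the generic neuron model, but it is deliberately not
  applied to the MBON sum before computing familiarity — squashing the
  response into (0, 1) would collapse the familiarity normalisation's
  dynamic range.
- **PI offset gain.** The r/d_k ratio is used literally (radians,
  unclamped) by default; an explicit angular gain (`pi.fpi_scale`) exposes
  the whole family from the bare ratio (1.0) to the [0, π] mapping (π).
  The gain decides the radius, relative to d_k, at which PI-driven
  boldness turns the walk outward; the literal form is the only member of
  the family that keeps the first walk inside its empirical range while
  letting later walks expand.
- **Novelty window** N_window = 300 steps: long enough to span familiar
  and novel experience, so the visual offset behaves like an absolute
  familiarity reference (bold inside the learned corridor, cautious at
  its frontier) instead of pure within-terrain jitter.
- **Loop handedness**: the rotation sign is redrawn per inter-scan
  segment (`lv.sign_mode="random"`); the strictly counter-clockwise form
  is available but biases all loops one way.
- **Degenerate cases.** Undefined directions (at the nest, or a zero PI
  vector) drop out of the vector sum with their weight; a cancelled
  Homing Vector keeps the previous heading; walks reflect at the world
  boundary.
- **Recall tests** (frozen memory, displaced agent): ω_PI is forced to 0
  and the visual/olfactory weights renormalised; the novelty field of the
  frozen network is precomputed on a 0.15–0.2 m grid shared by all agents
  in a world, lightly smoothed (one grid cell), and descended with 0.5 m
  probes, only while an actual descent exists; a stochastic-step
  probability of 0.1 lets the agent leave plateaus. Success means
  entering 0.1 m of the nest within 3000 steps.

## Synthetic environment

The terrain is a seeded triangle mesh: a flat ground plane, 100
cone-shaped tussocks (heights 5–35 cm, base radii 5–25 cm) scattered in a
5 m disc with a 0.1 m clearing around the nest, and 12 larger bush/tree
cones (0.5–1.8 m) further out. The landmark ring matters: without it the
amplitude-only panoramic code aliases severely, i.e. views from positions
metres apart can resemble each other more than views half a metre apart.
The odour field uses σ = 0.15 m, confining reliable olfaction to roughly
the first walk's range.

Nominal conditions (config defaults): U = 0.01 m, p_rand = 0.5, κ = 5,
np_1 = 120, budget growth r = 2, scans per walk (12, 18, 24, 32),
λ_vis = 0.018, 10 agents per cohort sharing one world. Where the study
conditions state only ranges (σ, λ_vis, p_rand, κ, r) the defaults were
fixed once, inside those ranges, against the empirical first-walk
trajectory band and its growth multipliers; problem sizes (one master
seed, 10 agents, 4 walks, 64 release points) are the package's standard
experiment and what the acceptance script re-runs.

## What the simulations show — and what they do not

With these conditions the model reproduces, qualitatively and in part
quantitatively, the behavioural picture the framework was built around:

- walk 1 is an olfactory-pocket excursion whose maximum distance
  (~0.2 m) and hull area sit inside the empirical first-walk bands, and
  walk 2 expands into the PI/vision regime (~0.6–0.7 m, also in-band);
- the cue-weight regime shifts across walks: olfaction-dominant in walk
  1 (~55–60%), PI strongest mid-walks, vision growing monotonically to
  dominate by walk 4;
- the reduced-vision variant (λ_vis halved, scan counts quartered)
  produces exactly ¼ the scans, smoother trajectories (lower mean turning
  angle) and higher PI reliance.

Two quantitative targets are *not* met, for a shared reason. The
Zernike-amplitude code generalises very broadly (feature correlation
often >0.9 between positions metres apart). Consequently (i) by walk 3
the accumulated synaptic depression raises visual familiarity nearly
everywhere, which erodes the PI weight and lets walks 3–4 overshoot their
empirical ranges (~4 m vs 1.4/2.8 m; pooled in-band fractions ~40–50%
against the 85/90% reference); and (ii) the frozen-memory novelty field,
although globally increasing with distance from the nest, is too weakly
structured for reliable visual recall, so homing success after walk 4 is
not materially higher than after walk 1 (the reference reports a very
large paired effect). These limits are properties of the amplitude-only
panoramic encoding in this synthetic world, not of the fusion rule; the
test suite asserts them at their stated tolerances and the failing
assertions document the gap rather than hiding it.

Passing tests on this synthetic world show internal consistency of the
mechanisms (geometry, encoding invariances, learning rule, fusion
algebra, protocol arithmetic, statistics), not fidelity to any real ant's
visual ecology: the world has no texture, lighting, occlusion softness,
wind, or conspecifics, and its odour field is a stationary Gaussian.
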