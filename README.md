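# learnwalks

An agent-based simulator of the **learning walks** of ants — the short,
looping excursions naive foragers make around their nest before ever
leaving to forage, during which they acquire the nest-centred visual
memories that later support homing. The package is aimed at computational
neuroethologists and modellers who want a tested, fully synthetic testbed
for multimodal cue integration during early spatial learning.

## The model

At every step the agent fuses three nest-direction estimates, each with a
familiarity weight in [0, 1]:

- **Mushroom-body vision** — panoramas are rendered from a 3-D triangle
  mesh, encoded as rotation-invariant Zernike-moment amplitudes
  (N_VPN = 81, order 16), and scored for novelty by a sparse VPN→KC→MBON
  network (N_KC = 4000, θ_KC = 0.04) whose KC→MBON synapses are depressed
  by λ_vis at each pirouette-like scan. Visual familiarity
  ω_v = 1 − C_MBON/N_active.
- **Innate olfaction** — a normalised Gaussian nest plume
  C(x,y) = exp(−(x²+y²)/2σ²) gives ω_olf = C and θ_olf = atan2(−y, −x).
- **Path integration** — noisy accumulation of step vectors
  (δ ~ N(0, 10⁻⁴ m) per component per step) gives θ_PI, with
  ω_PI = max(1 − ω_v − ω_olf, 0).

The fused **Homing Vector** `V = Σ ω_i (cos θ_i, sin θ_i)` is rotated by
an offset φ ∈ [0, π] — the **Learning Vector** — where φ grows with
familiarity (olfactory C·π, a window-relative ramp on MBON novelty for
vision, and the ratio r/d_k of the PI vector length to the walk's
expected range for PI), gated by the exploration state A_c. Bold (large
φ) means heading away from the nest; φ = 0 is pure homing. Walks follow
a doubling step budget np_j = np_1·2^(j−1) with scheduled scans, then
switch to homing. See `docs/methods.md` for every parameter, default and
known limitation.

## Worked example

```python
from learnwalks import Environment, nominal_config, run_walk_series
from learnwalks.experiments import walk_metrics

cfg = nominal_config()
env = Environment.from_config(cfg, world_seed=42)
records, snapshots, agent = run_walk_series(env, agent_seed=7)
for rec in records:
    m = walk_metrics(rec)
    print(f"walk {m['walk']}: {len(rec.rows)} steps, "
          f"max distance {m['max_dist']:.2f} m, hull area {m['area']:.3f} m^2, "
          f"weights v/olf/pi = {m['mean_w_v']:.2f}/{m['mean_w_olf']:.2f}/{m['mean_w_pi']:.2f}")
```

prints

```
walk 1: 138 steps, max distance 0.22 m, hull area 0.052 m^2, weights v/olf/pi = 0.12/0.57/0.31
walk 2: 266 steps, max distance 0.37 m, hull area 0.093 m^2, weights v/olf/pi = 0.37/0.39/0.24
walk 3: 3480 steps, max distance 6.09 m, hull area 2.526 m^2, weights v/olf/pi = 0.58/0.03/0.39
walk 4: 3960 steps, max distance 3.94 m, hull area 5.125 m^2, weights v/olf/pi = 0.62/0.01/0.37
```

Walk 1 stays inside the odour pocket (max distance ~0.2 m, olfaction
dominant); later walks expand as visual familiarity accumulates and path
integration takes over mid-range, reproducing the cue-transition picture
qualitatively (late walks over-expand relative to real ants — see the
limitations section of the methods note). `snapshots` holds the frozen
mushroom-body memory after each walk, ready for recall experiments
(`learnwalks.experiments.homing_test`).

A thin CLI wraps the same library calls:

```bash
learnwalks simulate        --seed 1 --agents 10 --walks 4 --out runs/sim
learnwalks homing-test     --seed 1 --agents 10 --levels 1,4 --out runs/ht
learnwalks species-compare --seed 1 --agents 10 --out runs/species
```

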