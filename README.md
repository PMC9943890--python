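# colonyrot

Coherent angular motion (CAM) — the persistent, synchronized rotation
of all cells in a cluster about its centroid — occurs spontaneously
in freely expanding epithelial cell colonies, without any
micropatterned confinement.  `colonyrot` packages the computational
side of that finding for two audiences:

* **modellers**: a 2D wet active-nematic continuum simulator
  (Q-tensor dynamics + D2Q9 lattice-Boltzmann flow + Cahn–Hilliard
  phase field) of a tissue droplet that spontaneously starts rotating
  once it is large enough, with a randomly selected but persistent
  sense of rotation;
* **experimentalists**: the trajectory-kinematics and colony-growth
  analysis pipeline for time-lapse tracking data — radial/angular
  velocity decomposition about the cluster centroid, inner/outer
  region statistics, angular velocity versus cluster area, and
  exponential growth fits — plus seeded synthetic-data generators so
  the whole pipeline is testable without microscopy data.

## The model and the statistics

The colony is a droplet of concentration `phi` (1 = tissue) coupled
to a nematic order tensor `Q = S(nn − I/2)` and a velocity field `u`:

    ∂t Q + u·∇Q − W(Q, ∇u)      = γ H,        H = −δF/δQ
    ρ (∂t + u·∇) u              = ∇·Π,        Π = Π_viscous + Π_elastic + ζφQ
    ∂t φ + u·∇φ                 = Γ_φ ∇² μ,    μ = δF/δφ

with free energy
`F = ∫ (C/2)(1 + Tr Q²/2)² + (B/2)φ²(1−φ)² + K_φ|∇φ|² + (K/2)|∇Q|²`.
The isotropic state is the bulk minimum (`C > 0`), so order — and
hence rotation — exists only where extensile activity (`ζ < 0`)
creates it.  Small droplets stay quiescent; intermediate ones develop
a spiral flow that rotates the colony rigidly with a random but
persistent sign; large ones decay into turbulent-like motion.

On the analysis side, cell counts follow `N(t) = N0·2^(t/t_d)`
(duplication time `t_d`), confluence follows `A_s(t) = A_s0·2^(t/τ)`
after master-curve alignment, the free-expansion regime ends at the
critical area `A_c = 4π τ² v_ρ²`, and per-cell polar kinematics
(`V_ρ` in µm/min, `ω` in rad/h about the cluster centroid) quantify
the coherence of rotation.

## Worked example

Generate a synthetic rotating cluster, analyse it, and fit growth
curves:

```sh
colonyrot synth rotating --seed 5 --out rot.csv
colonyrot analyze-tracks --in rot.csv --interval 2 --split-radius 46
```

prints (abridged):

```json
{
  "clusters": [
    {
      "cluster_id": 0,
      "n_cells": 52,
      "mean_radius_um": 58.33,
      "aspect_ratio": 0.830,
      "n_inner": 14,
      "n_outer": 38,
      "omega_mean_rad_h": 0.0496,
      "v_rho_mean_um_min": 0.0398
    }
  ]
}
```

— a 52-cell cluster whose recovered angular velocity (0.0496 rad/h)
and radial drift (0.0398 µm/min) match the generator's ground truth
(0.05 rad/h, 0.04 µm/min) within the tracking noise.  The sidecar
`rot.truth.json` carries that ground truth.

Simulating a rotating droplet (reduced 64×64 smoke configuration;
the physical box is 300×300):

```sh
colonyrot simulate --config cfg.toml --out run.h5 --csv obs.csv
```

writes the final field snapshot (HDF5: `phi`, `Qxx`, `Qxy`, `ux`,
`uy`) and the observable series (step, colony area, angular velocity
`omega`, mean speed, nematic order `S_mean`, free energy).  From
Python:

```python
from colonyrot import simulate as sim

params = sim.ModelParams(nx=128, ny=128, radius=20, seed=2)
obs = sim.run(params, n_steps=20000, sample_every=2000)
print(obs.to_dataframe()[["step", "omega", "S_mean"]].tail(3))
```

```
     step     omega    S_mean
8   16000 -0.000273  0.541007
9   18000 -0.000252  0.536087
10  20000 -0.000178  0.516032
```

The droplet has ordered (`S ≈ 0.53`) and rotates clockwise at a
plateau `|ω| ≈ 2e-4` (lattice units) with a persistent sign; rerun
with other seeds and the sign flips at random.

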