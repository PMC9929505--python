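# bitemech

Lever-and-muscle mechanics of arthropod biting: how hard can a mandible
bite, and how does that force change with how far the jaws are open?

`bitemech` implements a first-principles biomechanical model of the
musculoskeletal bite apparatus of arthropods with hinged (single-axis)
mandible joints — leaf-cutter ants are the worked reference system — and
the analysis tooling around it:

* **Forward prediction** of bite force across mandibular opening angles
  from morphology (levers, rotation axis, apodeme) and muscle physiology.
* **Physiology extraction**: fitting the muscle force–length parameters
  (σ_max, L_opt, β) to in-vivo bite-force measurements through the full
  forward model, statsmodels-style (`ForceLengthModel` → `fit()` →
  `ForceLengthResults` with CIs and `summary()`).
* **Sensor corrections** for one-dimensional force transducers
  (projection angle α and plate moment-arm factor Γ) and rescaling of
  non-distal bites to the distal tooth tip.
* **Joint-axis estimation** from multi-pose 3-D landmarks (constant-angle
  criterion of rigid-body rotation) and apodeme displacement-axis PCA.
* **CT fibre morphometry**: rank-matching of fibre seeds to apodeme
  surface points, filament growth through a muscle mask, attachment
  classification, fibre lengths and pennation angles.
* **Synthetic generators** for all of the above, with ground truth, so
  the whole pipeline is testable without any imaging or force data.

## The model

For a mandible rotating about a fixed unit axis **R̂** through the joint
centre, with inlever **L**ᵢ (joint → apodeme attachment), outlever **L**ₒ
(joint → bite point) and apodeme main axis **Â** (the pull direction of
the closer muscle), the bite force magnitude at opening angle θ is

    |F_b|(θ) = σ(θ) · A_phys · cos φ(θ) · MA(θ)

with

* mechanical advantage `MA(θ) = sin γ(θ) · |R̂×Lᵢ| · |R̂×Â| / |R̂×Lₒ|`,
  where the apodeme angle follows the linear law `γ(θ) = θ₀ − θ + γ₀`;
* apodeme displacement `Δ(θ) = [cos γ₀ − cos γ(θ)] · |R̂×Lᵢ| · |R̂×Â|`;
* pennation `φ(θ) = arctan[ sin φ₀ / (cos φ₀ − Δ/L_t,0) ]`;
* fibre length from the fibre-triangle relation (with the constant
  filament length L_fil subtracted for filament-attached fibres);
* Gaussian force–length stress `σ = σ_max · exp[−β (1 − L_f/L_opt)²]`;
* physiological cross-section `A_phys = V_m / L_opt`.

A minimal model for ecologists needing only calliper measurements,
`F_max ≈ 8.25 kPa µm⁻¹ · H_w H_l S_l` (head width × head length ×
sarcomere length), and the classical allometric bounds on weight-specific
force (`c · m^(−1/3)`) are included.

## Worked example

```python
import numpy as np
from bitemech import ForceLengthModel, fit_force_length
from bitemech.synthetic import (
    make_reference_apparatus, SyntheticSpec, simulate_bite_measurements,
)

app = make_reference_apparatus()          # leaf-cutter ant major, one side
theta = np.linspace(35, 105, 8)
print(np.round(app.bite_force(theta), 3))
# [1.028 1.133 1.101 0.936 0.704 0.476 0.299 0.178]

meas = simulate_bite_measurements(app, SyntheticSpec(seed=7))  # n=138, 5% noise
res = fit_force_length(meas, app, l_opt_bounds=(0.85, 1.47))
print(res.summary())
# Force-length fit (bounded nonlinear least squares)
#   n_obs = 138   converged = True   RMS residual = 0.03213 N
#   param         estimate     std err      [0.025      0.975]  unit
#   --------------------------------------------------------------
#   sigma_max       1.1537      0.0061      1.1416      1.1658  MPa
#   l_opt           0.9433      0.0110      0.9215      0.9650  mm
#   beta            6.2384      0.4784      5.2924      7.1845
```

The force curve peaks near 1.1 N at ~48° — small opening angles, where
leaf-cutter ants actually cut — and falls roughly five-fold by 100°. The
fit recovers the generating physiology (σ_max = 1.16 MPa, L_opt =
0.92 mm, β = 5.34) from noisy simulated measurements, with β the most
uncertain parameter, as expected when the data cover mostly one flank of
the force–length curve.

The same operations are available from the shell:

```sh
bitemech simulate apparatus --out sim/
bitemech predict --config sim/apparatus.json --theta-grid 35:105:1 --terms --out curve.csv
bitemech simulate bites --seed 7 --out sim/
bitemech fit --measurements sim/bites.csv --config sim/apparatus.json \
             --fibre-range 0.85,1.47 --out fit.json
```

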