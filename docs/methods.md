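# Methods

## Model and assumptions

The package models a chewing-biting mouthpart as a rigid lever system
driven by a pennate muscle through a tendon-like apodeme:

1. **Hinge joint.** Mandible kinematics are fully described by rotation
   about a single fixed axis R̂. Joints with more degrees of freedom
   (some hymenopterans) are out of scope.
2. **Rigid skeleton.** Head capsule, mandible and apodeme are rigid;
   cuticular filaments connecting some fibres to the apodeme are treated
   as inextensible (their strain across the opening range is on the order
   of a percent).
3. **Pure apodeme translation.** The apodeme displaces along its main
   axis Â, which is taken as the direction of the net muscle force. The
   lateral component of the attachment-point path (a circular arc) is
   accommodated by rotation of the soft apodeme ligament, not by lateral
   apodeme motion. Only displacement components in the rotation plane
   contribute to rotation, hence the recurring projection factor |R̂×Â|.
4. **Quasistatic maximal activation.** No force–velocity effects,
   activation dynamics or passive-elastic stress; the model predicts the
   envelope of maximal isometric bite forces.

Under these assumptions the bite force factorizes into stress × area ×
pennation projection × mechanical advantage; every θ-dependence enters
through the linear apodeme-angle law γ(θ) = θ₀ − θ + γ₀ and the
displacement Δ(θ) derived from it. Two exact internal identities tie the
pieces together and are enforced by the test suite: the virtual-work
relation dΔ/dθ = −|L_i,eff| (displacement and effective inlever are not
independent), and conservation of the fibre-triangle height
(L_f + L_fil)·sin φ, which links the pennation relation to the
fibre-length relations.

## Parameters

| Parameter | Unit | Reference value | Meaning |
|---|---|---|---|
| θ₀, γ₀ | deg | 51, 90 | reference opening angle and apodeme angle there (γ=90° ⇔ MA maximal) |
| \|R̂×L_i\|·\|R̂×Â\| | mm | 0.6454 | projected inlever × in-plane force fraction |
| \|R̂×L_o,d\| | mm | 2.2254 | projected distal outlever (effective outlever at all θ) |
| φ₀ | deg | 36.38 | pennation at the reference pose |
| L_f,0 / L_d,0 | mm | 0.988 / 1.633 | reference fibre lengths (filament / direct population) |
| L_fil | mm | 0.60 | filament length, constant |
| fraction direct | – | 0.15 | number fraction of directly attached fibres |
| V_m | mm³ | 3.956 | muscle volume per side |
| σ_max | MPa | 1.16 | peak isometric stress |
| L_opt | mm | 0.92 | optimal fibre length (filament population) |
| β | – | 5.34 | Gaussian force–length width parameter |
| admissible θ | deg | 35–105 | configurable evaluation range |

Angles are degrees at every interface and radians internally; lengths mm,
stresses MPa, forces N, sarcomere lengths µm. The minimal model keeps its
literature constants (MA ≈ 0.55, cos φ ≈ 1, A_phys ≈ 0.3·H_w·H_l,
σ_max ≈ 50·S_l kPa for S_l in 3–17 µm, giving the combined prefactor
8.25 kPa µm⁻¹).

### The reference apparatus

No raw morphology is shipped; `make_reference_apparatus()` back-solves a
complete single-side apparatus from published summary statistics of
*Atta cephalotes* majors. Lever magnitudes follow exactly from the
MA peak (0.29 at 51°) and the 0.7 mm displacement range. The
per-population pairs (φ₀, reference length) are over-determined: four
printed targets (pennation 41°→27° across the range, fibre lengths at
both range ends) constrain two free parameters per population, and the
printed values are mutually inconsistent at the ~5 % level under the
height-conservation constraint. They are therefore fitted by weighted
least squares (length residuals weighted 10 mm⁻¹ against 1 deg⁻¹),
reproducing pennation to 0.7°, fibre lengths to 0.04 mm and the
length-change ratios to ~0.04. A unit test checks every printed target at
these tolerances.

The resulting force curve peaks at ≈1.14 N near 48° and falls about
five-fold by 100°. This is the *fitted-curve* peak; the largest single
measured force reported in vivo (1.4 N) sits above the curve, inside the
measurement scatter. The apparatus' all-optimal bound
σ_max·A_phys·cos φ_min·MA_max ≈ 1.28 N brackets the curve peak from
above, consistent with the published observation that synchronizing all
determinants would raise the peak by only ~15 %.

### Mixed fibre populations

Stress, pennation and fibre length are evaluated per population; the
physiological cross-section A_phys = V_m/L_opt is pooled and partitioned
by number fraction (an area-resolved alternative is available via
`pooled_a_phys=False`). Direct fibres share σ_max and β with the
filament-attached majority; their optimal length is tied by the
*equivalent-stretch* rule L_opt,pop = L_opt,ref · (L_pop,0 / L_ref,0)
evaluated at the reference pose, i.e. both populations are optimal at the
same relative stretch. Evaluated on the reference apparatus this puts the
direct optimum at 1.52 mm; an in-vivo fit that averages fibre lengths
over a scan series instead would shift this by a few percent.

## Fitting

`ForceLengthModel` treats the morphology as known and (σ_max, L_opt, β)
as free, minimizing the sum of squared force residuals with scipy's
bounded trust-region least squares. Because the Gaussian force–length
surface is multimodal when the data cover mainly one flank, the optimizer
is multi-started from a 3×3×3 grid spanning the parameter box (at 15 %,
50 % and 85 % of each interval); the lowest final objective wins and ties
break towards the smallest β. Bounds: σ_max ∈ (10⁻³, 10) MPa,
β ∈ (10⁻², 50), and L_opt inside the caller-supplied range of observed
fibre lengths (0.85–1.47 mm for the reference muscle) — the physical
constraint that the optimum must be visited within the working range.
Fewer than three distinct angles raise an error; a span under 20°
triggers an identifiability warning. Confidence intervals are linearized
(Jacobian-based, t quantile) by default, with a seeded residual-bootstrap
alternative; on well-conditioned synthetic data the two agree within
~30 %, and β is always the widest interval. An opt-in global
mean − 3·SD low-tail pre-filter is provided but never applied silently,
since outlier screening rules are study-specific.

## Synthetic data

The generators emulate the study designs, not the imaging physics:

* `simulate_bite_measurements` — n = 138 measurements, θ uniform in
  50–105°, multiplicative Gaussian noise with σ = 5 % truncated at zero.
  These defaults mirror the in-vivo experiment; the residual model is a
  package choice (the study does not state one). Real measurements
  additionally carry angle-dependent correction error (projection
  corrections grow sharply below 65°) and passive joint/muscle forces at
  large gapes — neither is simulated, so recovery results bound the
  method's statistical error, not its systematic error on real animals.
* `make_pose_series` — rigid rotations of a base landmark set about a
  known axis. Landmark noise is isotropic Gaussian whose total
  displacement RMS equals the stated fraction of the vector norm
  (per-coordinate σ = noise·|v|/√3). The base vectors are chosen
  anatomically: apodeme attachment postero-medial, distal tooth
  antero-lateral, proximal tooth near-lateral — three genuinely distinct
  directions, as the constant-angle axis criterion requires (a proximal
  tooth vector nearly parallel to the distal one carries no independent
  information and degrades the estimate).
* `make_apodeme_com_track` / `make_attachment_path` — the apodeme centre
  of mass translates, so PCA on its track recovers Δ(θ) exactly; the
  attachment point moves on a circular arc, whose longitudinal projection
  onto the apodeme axis also equals Δ/|R̂×Â| exactly, but a straight-line
  PCA fit to the arc itself carries a curvature bias of a few percent of
  the displacement range over the full 70° span (amplitude
  ≈ (1 − sin γ_mid)·r). Tests assert the two exact identities and bound
  the arc bias.
* `make_fibre_field` — non-crossing pennate fans with a muscle-free
  corridor above the apodeme, so true filament lengths are
  corridor/sin φ; seeds, insertions and the voxel mask come with exact
  ground truth. Real CT fields add curved fibres, segmentation noise and
  partial-volume effects that the generator deliberately omits, which is
  why the synthetic suite demands near-exact recovery (median length
  error 0, pennation error < 1°) — stricter than the 1 ± 18 % / 0 ± 1°
  reported when the same algorithm was validated against manual tracing
  on real scans.

Every generator is a pure function of its arguments and an explicit seed.

## Numerical choices

* Degenerate-projection tolerance 10⁻⁹ mm on |R̂×v|; unit vectors checked
  to 10⁻⁶ and renormalized.
* Pennation uses `atan2`, continuing smoothly past 90° when the
  denominator turns negative — the branch that conserves fibre-triangle
  height. σ(φ₀=0, denominator 0) raises an undefined-orientation error.
* Axis estimation parametrizes R̂ by azimuth/elevation; the objective
  (squared angular deviations about per-vector means, in deg²) is
  evaluated at the 26 integer-lattice directions and Nelder–Mead refines
  the 5 best; the sign is fixed against the dorso-ventral head axis.
  The residual reported is the mean squared deviation per angle.
* Filament growth marches in 0.5-voxel steps with voxel-centre
  coordinates (physical position = (index+0.5)·voxel size) and a 10⁻⁹
  boundary snap so integer-voxel translations of the whole field are
  exactly neutral. Muscle voxels are counted cumulatively (not
  consecutively); once the count reaches the fibre-diameter threshold
  (default 5 px) growth stops and the filament length is the arc length
  at the *first* muscle voxel — the threshold confirms genuine muscle
  entry rather than a stray labelled voxel, and a fibre whose confirmed
  entry lies within 5 px of the apodeme is classified directly attached.
  Rays that exit the mask unconfirmed fall back to the full
  seed–insertion distance and are flagged unreliable.
* Rank matching bins surface ranks j of N_a into seed-rank bins
  ⌊j·N_s/N_a⌋; empty bins fall back to the nearest non-empty bin
  (logged); anterior–posterior sort ties break on the dorso-ventral
  coordinate.
* The sensor correction requires cos α > 0.2; corrections reported for
  real measurements reach ~28 % at small angles, and the floor turns a
  silent blow-up of 1/cos α into an explicit error.
* Problem sizes: the recovery experiment uses 50 replicates of n = 138;
  the axis Monte Carlo 200 draws; the brute-force forward-model
  cross-check 100 random parameter sets. Replicate seeds are spawned from
  the user seed via `numpy.random.SeedSequence`.

## Design choices

* The fitting surface follows the statsmodels Model/Results idiom; the
  remaining modules are plain functions over small frozen dataclasses,
  with `fit_force_length` kept as a functional wrapper.
* Two lateral-axis proxies exist in practice (a head-fixed axis for CT
  work; the eye-centre line for force experiments). The package takes the
  lateral axis as explicit input everywhere and does not decide their
  equivalence.
* A_phys is computed where muscle volume and L_opt meet
  (`BiteApparatus.a_phys`), so A_phys = V_m/L_opt holds by construction
  rather than by a stored-field invariant.
* The CLI is a thin click layer over the library; every subcommand reads
  and writes the documented CSV/JSON/TIFF dialects and exits 0/1/2 for
  success/validation error/numerical failure.

## Known limitations

* Static maximal-activation forces only; no force–velocity, activation or
  passive-force terms, so the model under-predicts measured forces at
  very large opening angles where passive contributions (~tens of mN)
  become visible.
* Single-axis joints only; the axis estimator will average, not detect,
  genuine multi-DOF motion.
* The equivalent-stretch tie makes direct-fibre physiology a deterministic
  function of the filament-fibre fit; with richer data the populations
  could be fitted separately.
* Straight-fibre morphometry: curved fibres are systematically shortened,
  and the rank-matching premise (uniform attachment density, non-crossing
  fibres) is assumed, not checked.
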