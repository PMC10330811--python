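# Methods

This note documents the models implemented in `ceustrack`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not demonstrate.

## Tracking model

One lesion is tracked through a grayscale cine-loop as pure translation: the
box size given on frame 0 is kept for the whole run.  This reflects how
focal liver lesions move under breathing — the tissue translates almost
rigidly in the imaging plane over the second-to-second timescale, while
genuine scale or rotation changes are slow and small compared with the
localization errors that matter here.

Each frame passes through five stages.

### 1. Motion measurement (Lucas–Kanade flow)

Intensity constancy linearized to first order gives, per pixel,
`I_t + ∇I · u̇ = 0`.  Stacking the constraint over an observation window
yields `U u̇ = V` with rows `[I_x, I_y]` and `V = −I_t`, solved by the
normal equations `u̇ = (UᵀU)⁻¹UᵀV`.  Numerics:

* frames are Gaussian-smoothed (σ = 1 px) before differentiation; spatial
  gradients are central differences averaged over the two frames, and
  `I_t` is the plain frame difference (Δt = 1 frame);
* a window whose normal matrix has smallest eigenvalue below
  `τ_eig = 10⁻⁶` is degenerate (flat shadow, uniform tissue) and returns a
  flagged zero flow;
* a rank-1 normal matrix (1-D texture — the aperture problem) returns the
  minimum-norm least-squares solution with an `aperture` flag; such
  windows are excluded from ROI aggregation because their
  gradient-orthogonal component is unobservable;
* the ROI is tiled into a 4×4 grid of 15×15 windows (defaults; the
  brightness-constancy and smoothness assumptions hold locally, not
  globally) and the per-window flows are combined component-wise by a
  conditioning-weighted mean after trimming the lowest and highest 25%.
  Estimates larger than half the window are flagged unreliable: single-
  scale LK cannot measure them, and large motions are the Kalman filter's
  job, not the flow's.

### 2. Constant-velocity Kalman filter

State `x = [u_x, u_y, v_x, v_y]` (px, px/frame), standard predict/update
recursion with position-only measurements `z = previous center + u̇`.
Parameter choices:

* **Process noise.** `Q` is the discrete white-acceleration covariance
  with acceleration variance `q = 0.25 px²/frame⁴` per axis.  Breathing
  motion is smooth but not constant-velocity; a white-acceleration model
  makes the position uncertainty grow realistically (several pixels over a
  10-frame measurement gap) instead of the near-frozen covariance a small
  diagonal position-noise `Q` produces.  This matters at shadow exit: the
  prediction can be tens of pixels off when a shadow spans a breathing
  turning point, and the re-localization search must know that.
* **Measurement noise.** `R = 4 px² · I` for flow measurements (sub-pixel
  accuracy per window, but aggregated over a deforming ROI), and
  `R = 1 px² · I` for the matched template center, which re-updates the
  filter after matching (the matcher is the more trustworthy sensor; the
  loop closure is configurable).
* **Initialization.** Position = the frame-0 box center with variance
  1 px²; velocity = 0 with variance 10 px²/frame² — known start, unknown
  motion.
* Covariances are symmetrized after every step and negative eigenvalues
  from round-off are clipped at zero.
* A missing measurement (degenerate flow, shadow frame, or the frame
  immediately after a shadow, where intensity constancy is known to be
  violated) triggers a predict-only step.

### 3. Gaussian temporal motion attention

`Att(l_i) = exp(−d_i²/2σ²)` with `d_i` the Euclidean distance from the
candidate center `l_i` to the filtered position `l_c`; candidates with
`Att < 10⁻⁴` are invalid.  σ is the sample standard deviation of the
per-frame moving distance over the last 10 frames, widened by the filter's
own position standard deviation (`√λ_max` of the position block of `P`) and
then clamped to [3, 9] px.  The widening term is what re-opens the gate
after a shadow: displacement history alone says the target has been moving
smoothly, but the covariance knows ten frames passed without a measurement.
Too small a σ makes the gate reject legitimate corrections; too large
makes it vacuous — hence the clamp.

**Fusion.** The attention acts as a hard validity gate: the predicted
location is the argmax of the raw score map over the cells with
`Att ≥ 10⁻⁴`, ties broken by distance to `l_c`, then row-major order.  An
element-wise product of the min-max-normalized score map with the attention
(available as `fusion="multiplicative"`) was evaluated and rejected as the
default: with σ clamped at 3 px the Gaussian decays across a few pixels
while NCC scores vary on the scale of the whole search window, so the
product's argmax essentially returns `l_c` itself; the matcher then never
corrects the filter and the position error integrates without bound
(mean IoU 0.36 vs 0.88 on a 60-frame benchmark).  The gate keeps the two
sources in their proper roles — the prior restricts, the likelihood
decides.

### 4. Matching

The NCC backend correlates raw patches with zero-mean unit-norm windows
(scores in [−1, 1]; a flat template is flagged and leaves the position at
the prediction).  The template patch is the box plus an 8 px context
margin; the search window extends 32 px beyond the template (clipped to
the frame with offset bookkeeping, so border approaches cannot crash).
The learned backend embeds both patches with the 5-layer network
(conv 11×11/s2 + pool, conv 5×5 + pool, conv 3×3 ×3; channels
16, 32, 64, 128, 64; stride 8, receptive-field offset 40 px) and takes the
plain inner-product correlation, bicubically upsampled to pixel
resolution so the attention and score grids share image coordinates.  The
score-cell-to-image mapping is exact by construction and is verified by
planted-patch tests.

### 5. Template update

`T̂ = (1−γ) T̂⁻ + γZ` every 5 frames (matching ~15 fps loops), where `Z` is
the patch at the accepted location of the current frame.  For the NCC
backend the update operates on raw normalized patches, for the learned
backend on feature maps — the same convex combination either way.  γ is
fixed at 0.7 by default; the adaptive mode sets γ to the relative ROI
intensity growth since the last update, `|I − I_ref|/max(I_ref, ε)`,
clamped to [0.1, 0.9] so the template neither freezes nor is replaced
wholesale.  The tracked ROI's mean intensity is recorded every frame (the
tracker's own TIC); a frame whose intensity falls below
η = 0.35 × median(last 25 samples) is abnormal: no matching, no update,
predict-only output.  The relative default adapts across machines and gain
settings; an absolute η is available.  The 25-sample window makes the
median robust to the 10-frame shadows themselves; the factor 0.35 sits
between the ~10× attenuation of a dense shadow and normal enhancement
fluctuations.

## Synthetic scenes

The generator renders what makes CEUS tracking hard, with exact ground
truth:

* **Enhancement.** Lesion and background follow separate log-normal bolus
  time-intensity curves `I(t) = b + (p−b)·exp(−ln²(t/t_p)/2s²)` with
  independent wash-in/wash-out shape rates — the standard bolus-kinetics
  form.  In the reference scene the lesion starts hypoechoic (scene clock
  t₀ = 0.5 s), crosses the background intensity near frame 10, and
  hyperenhances to ~6× its baseline: the contrast inversion plus an
  inconspicuous transition regime that defeats any frozen template.
* **Texture.** Multiplicative smooth speckle that translates rigidly with
  the scene and slowly decorrelates (two fields cross-faded over the run),
  emulating perfusion-driven appearance change in real tissue.
* **Motion.** Per-axis breathing sinusoid (reference: 15 px lateral, 5 px
  axial, period 40 frames) plus optional linear drift; the analytic
  trajectory is the ground truth to machine precision.
* **Distractors.** Blobs at fixed offsets from the lesion, moving with the
  tissue; the reference scene has one with the lesion's own TIC and radius
  ~59 px away — a true look-alike.
* **Shadows.** Whole-frame multiplicative attenuation (reference: ×0.1,
  frames 70–79 and 140–149).
* **Noise.** Additive Gaussian (σ = 0.02), clipped to [0, 1].

Frames default to 256×192 — a scaled-down acquisition that keeps the full
200-frame benchmark under ~10 s per tracker run; full-size scenes are one
`SceneSpec` field away.  Everything is deterministic given the scene seed.

What the generator does **not** emulate: physically realistic speckle
statistics and microbubble kinetics, out-of-plane motion, probe-pressure
deformation, scanner post-processing, or annotation noise (ground truth is
exact).  Passing the synthetic benchmark therefore shows the pipeline's
mechanisms work as designed — shadow suspension, re-localization, template
adaptation, distractor rejection — not that clinical-grade accuracy is
achieved on patient data.

## Training the learned backbone

Training pairs are (template, search, true-offset) triples cut from short
synthetic scenes; labels on the score map are +1 within 16 px of the true
center, −1 elsewhere, with the classes weighted equally (an all-zero score
map then costs exactly log 2).  The raw feature correlations carry a large
DC offset, so the loss sees `a·(s − mean(s)) + b` with learnable scalars —
the usual adjust head; both operations are monotone, so inference argmax is
unaffected.  SGD with momentum 0.9 and weight decay 5·10⁻⁴ is the default
optimizer (Adam is selectable), batch size 8.  The configured default
learning rate of 10⁻⁷ is deliberately conservative; desk-scale smoke runs
on 64 synthetic pairs use 0.05, which moves the one-epoch loss visibly
(≈0.72 → 0.65).  Checkpoints are single `.npz` archives with a version tag
and the layer schedule; loss curves are persisted as CSV.

## Evaluation conventions

Metrics use only labeled frames.  Boxes are half-open rectangles in
continuous coordinates (shared edges have zero overlap).  The combined
RMSE reported alongside the per-direction values is
`√(RMSE_x² + RMSE_y²)` — a repository convention, stated because the
per-direction definition does not prescribe one.  FPS is wall-clock and
reported only; it is hardware-dependent and never asserted.  Ablation
orderings are compared on the dense generator ground truth (all 200
frames) — sparse 20-frame means tie at noise level between variants that
both succeed or both fail — while "lost the target" (IoU < 0.1) is judged
on the sparse labels, as an annotator would.

## Known limitations

* Single-scale LK bounds measurable inter-frame motion to about half the
  window (7 px by default); faster motion relies entirely on the
  constant-velocity prior.
* A shadow spanning a breathing turning point still costs accuracy: with
  no measurements the filter extrapolates straight while the target
  reverses (up to ~20 px transient error in the reference scene); the
  widened attention gate recovers the target at shadow exit, but those
  frames keep their error.  Motion models beyond constant velocity are
  out of scope.
* The NCC matcher has integer-pixel resolution; sub-pixel localization
  would need score-map interpolation around the peak.
* The abnormal detector keys on global ROI intensity; a shadow that
  covers only the distractor, or a lesion washing out to near-background
  intensity very fast, can fool it in either direction.
* The learned backbone is a desk-scale implementation intended for the
  training-contract tests; no claim is made that one epoch on synthetic
  pairs yields features competitive with the NCC default.
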