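# Methods

## The model

`pfgmco` trains one classification model **per site** (client) of a
federation, for each of three imaging modalities — a structural volume
(sMRI-like) and two half-resolution functional maps (ALFF-like and
ReHo-like) — plus a per-site fusion classifier, without any raw data or
label ever leaving a site.

Each modality model has three parts: an encoder `E` (volume → feature
vector of length `d_feat`), a linear classifier head (`d_feat → 2`), and a
linear gradient-matching (GM) head (`d_feat → 2`, parameter count
`2·d_feat + 2`).  One training round, executed once per epoch, is:

1. **Local update.**  One epoch of minibatch cross-entropy steps on the
   site's own data at the local rate `alpha`.  The GM head is fitted on the
   same batches; its loss does not backpropagate into the encoder.
2. **Federated adaptive aggregation.**  Every site broadcasts its
   parameters through the Gaussian mechanism `G(P) = P + N(0, sigma2)`.
   For each recipient *i*, every peer *j* loads *i*'s noised model, encodes
   *j*'s own volumes with it, and returns the noised mean cross-entropy
   gradient of the noised GM head on those features.  The pair loss
   `L_ij = 1 − cos(g_i, G(g_j))` (g_i from *i*'s own clean model and data)
   measures distribution dissimilarity; weights are either the printed
   normalization `λ_ij = L_ij / Σ L_ij` (`as_printed`) or the complement
   `λ_ij ∝ (2 − L_ij)` (`similarity`, the default — it matches the stated
   intent that similar sites contribute more, whereas the printed formula
   rewards dissimilarity; both are exposed because the printed formulation is internally
   inconsistent on this point).  Aggregation is
   `θ' = (1−ζ)·θ + ζ·Σ λ_j G(θ_j)` (`convex`, default) or the literal
   additive form `θ' = θ + ζ·Σ λ_j G(θ_j)` (`additive_as_printed`, whose
   norm grows without bound; provided for fidelity).
3. **Federated optimization.**  One epoch at the federated rate `eta` on
   the composite loss `L_cls + β·L_GM + γ·L_con`.  `L_GM` repeats the
   gradient-matching construction at the post-aggregation parameters, with
   peer gradients exchanged once per round; `L_con` is a model-contrastive
   term comparing the current encoder's features against the frozen
   locally-updated encoder (positive) and the previous round's encoder
   (negative) on the same inputs.  Two contrastive variants exist: the
   printed form with `(1−cos)/τ` distances in the denominator (default)
   and the standard MOON form; the printed numerator/denominator asymmetry
   is preserved, not repaired.
4. **Fusion.**  With all three modalities present, per-site features are
   combined by multimodal compact bilinear pooling — count sketch followed
   by FFT circular convolution, `MCB(a,b) = IFFT(FFT(Φa) ⊙ FFT(Φb))` —
   hierarchically: functional channels first, then structural × functional.
   A three-layer MLP (`d_fused → 128 → 2`) is trained on the fused features
   while the single-modality models stay frozen.  Sketch hashes are drawn
   once per site and persisted with checkpoints.

Baselines implemented for comparison: `local` (no communication),
`centralized` (pooled data, one model), `fedavg` (sample-size-weighted
parameter averaging each round).  All strategies share one common model
initialization per modality; without a common starting point parameter
averaging is meaningless.

## Composite-loss gradients

The package computes gradients in closed form rather than with an autodiff
framework.  The classification term backpropagates through encoder and
classifier (hand-written layer backward passes, each validated against
central finite differences).  The contrastive term's gradient w.r.t. the
current features is analytic; `f_local` and `f_pre` come from frozen
snapshots and are constants.  The GM term is differentiated w.r.t. the GM
head only, using the exact cross-entropy Hessian of the linear head
(`kron(diag(p) − p pᵀ, φφᵀ)` averaged over the batch); encoder features are
treated as constants for this term, and peer gradients are refreshed once
per round (the aggregation cadence), not per minibatch.

## Privacy

Every message leaving a site — parameter vectors in both exchanges and
returned GM gradients — passes through the sender's Gaussian mechanism with
variance `sigma2` (working default 0.001; `sigma2 = 0` is exact sharing).
Noise is i.i.d. per element and redrawn per exchange.  No clipping,
sensitivity calibration, or formal (ε, δ) accounting is performed: the
mechanism is additive noise with a privacy/utility trade-off controlled by
`sigma2` alone.

## Parameters and defaults

| parameter | default (desk) | full-scale profile | meaning |
|---|---|---|---|
| `epochs` (L) | 10 | 80 | training rounds; aggregation once per round |
| `alpha` | 0.05 | 0.01 | local learning rate |
| `eta` | 0.02 | 0.001 | federated (fine-tune) learning rate |
| `zeta` | 0.3 | — | aggregation strength |
| `beta`, `gamma` | 1.0 | — | weights of GM / contrastive terms |
| `tau` | 0.5 | — | contrastive temperature |
| `sigma2` | 0.001 | 0.001 | Gaussian-mechanism variance |
| `batch_size` | 8 | 8 | minibatch size |
| `d_feat` | 32 | 1024 | encoder feature width |
| backbone | `tiny_cnn_3d` | `resnet10_3d` | encoder variant |
| optimizer | SGD | AdamW (wd 0.95) | plain steps for closed-form tests |

Free choices and their rationale:

* **ζ = 0.3, convex.**  The printed formulation introduces ζ only as a
  regularization term, with no value given.  The convex reading is the only
  bounded one.  ζ trades knowledge transfer against resilience: it must be
  large enough that compatible peers' knowledge actually transfers (tiny ζ
  reduces the method to local training) yet small enough that the
  self-anchored model survives low-quality or adversarial donor mass;
  ζ = 0.3 with similarity weighting balances both at desk scale.
* **η (desk) = 0.02.**  The federated epoch both personalizes the
  aggregated model and repairs low-quality donor mass; rates far below
  `alpha` cannot do either within one epoch at 10 rounds, while rates at
  `alpha` overfit the 60-subject local split.
* **β, γ fixed at 1.**  Nominally learnable scale factors, but
  unconstrained learnable loss weights collapse to zero; fixed scalars with
  an optional softplus-learnable variant were considered and the fixed form
  kept for the tested surface.
* **GM head = single linear layer.**  The exchanged gradient stays
  low-dimensional and its cosine geometry well conditioned; the printed
  formulation leaves this module's architecture open.
* **Gradient clipping (global norm 5)** stabilizes plain SGD under strong
  site gains; **float32** is the engine's compute precision (float64 for
  gradient-validation paths).
* **3D-ResNet-10 feature width**: the standard backbone pools to 512
  channels; a final linear projection provides the stated 1024 features.

## The synthetic federation

Real multisite cohorts of this kind are access-restricted, so experiments
run on generated data engineered to preserve exactly the two properties the
method targets:

* **Shared class signal** — a spherical "lesion" (radius 4 voxels at 16³,
  centred) whose mean intensity is elevated by `effect_size = 1.0` in
  patients, planted on a smooth unit-variance Gaussian random field
  (smoothing σ = 2 voxels).  The two functional channels repeat the lesion
  at half resolution with independently drawn per-channel effect sizes
  (0.6–1.0 × structural), so modalities are complementary rather than
  copies.  A matched-filter oracle (mean intensity inside the true lesion
  mask) reaches ≈ 77% accuracy — the signal is learnable but not
  saturating at 60 training subjects per site, the data-limited regime in
  which federation has something to offer.
* **Site-specific non-biological variability** — each client draws once a
  gain ∈ (0.7, 1.3), offset ∈ (−0.5, 0.5) and voxel-noise SD ∈
  (0.05, 0.2), applied to every volume.  One of five clients additionally
  acquires with **inverted contrast polarity** (negative gain), emulating
  protocol families with flipped tissue contrast.  This matters: plain
  gain/offset shifts turned out to be almost free invariances for pooled
  3D-CNN training at this scale, leaving naive parameter averaging
  unharmed; polarity inversion is the affine site effect that actually
  produces the averaging-hostile regime reported for the real cohort
  (federated averaging below local training).  The default fraction (0.2)
  keeps a majority clique of compatible sites whose pooled knowledge the
  adaptive weights can exploit.

What the generator does **not** emulate: anatomical structure, realistic
intensity histograms, within-client site mixtures, class-conditional
covariate differences (age/sex confounds), or any temporal fMRI dynamics.
Passing tests therefore demonstrate that the algorithmic machinery behaves
as designed under controlled domain shift — not that any particular
accuracy would be obtained on real neuroimaging data.

Labels are allocated near-exactly at the configured class balance.  The
generator is bitwise deterministic given its seed.

## Experiments the test suite runs

At desk scale (5 clients × 80 subjects, 16³/8³ volumes, `d_feat = 32`,
10 rounds, sMRI modality, 3 seeds), shared across the acceptance tests:

* strategy comparison: personalized strategy vs `fedavg` vs `local`;
* ablation: full method vs adaptive-aggregation-only;
* dishonest federation: all incoming donor messages replaced by
  plausible-scale random noise (scale-matched so fakes are not trivially
  detectable by magnitude), comparing each strategy's degradation;
* occlusion sensitivity: a locally trained model's occlusion map must place
  the planted-lesion patch in the top decile of accuracy drops;
* the σ² privacy/utility direction (more noise, no better accuracy) is
  checked at a reduced scale (3 clients × 24) to stay within CPU-minutes.

## Numerical choices and degenerate inputs

* Cosines reject zero-norm vectors (degenerate-gradient / feature errors).
* Accuracy thresholds at probability 0.5 with argmax index-order
  tie-breaking; AUC counts ties as half (rank statistic).
* `MaxPool3d`/`AvgPool3d` require even spatial extents; the tiny CNN
  requires axes divisible by 4.  Volumes are consumed as stored — shape
  mismatches are errors, never resampled.
* Manifest validation reports **all** violations at once; fold assignment
  stratifies by label within client and degrades with a warning when a
  client-class stratum is smaller than k.
* The inverse FFT's imaginary residue in MCB is checked (< 1e-6 relative)
  before the real part is returned.
* A single-client federation degenerates exactly to local training (no
  peers → no aggregation, no GM or contrastive terms).

## Known limitations

* The desk-scale backbone is intentionally small; absolute accuracies are
  not comparable to full-scale 3D-ResNet results on real cohorts.
* With all donors dishonest, the adaptive weights cannot gate fakes (they
  normalize to one over whatever arrives); robustness rests on the convex
  self-anchor and the post-aggregation fine-tune.
* The cohort roster packaged with the library carries a known internal
  inconsistency of its published description: the accompanying text reports 1028 patients / 1225
  controls while the per-client table totals 1068 controls / 1225 patients
  across 2293 subjects; the roster follows the per-client table and the
  2293 total.
* Gradient matching probes similarity through a linear head's gradients;
  sites whose differences are invisible to that head (e.g., identical
  first-order statistics) receive near-uniform weights.
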