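# Methods

`actionrep` implements, end to end and on fully synthetic data, a classic
computational-neuroscience analysis: does making a hierarchical video model
more invariant to 3D viewpoint make its representation of actions both more
useful for viewpoint-invariant recognition and more similar to neural
population responses? The package provides four spatiotemporal convolutional
model variants, a viewpoint match/mismatch decoding protocol, and
representational similarity analysis (RSA) against multi-subject neural-style
recordings with bootstrap uncertainty, a noise ceiling and a noise floor.

## Models

All four models map a grayscale clip (H × W pixels × T frames, values in
[0, 1]) to a fixed-length feature vector.

### Fixed-template models (purely convolutional / unstructured / structured)

The shared stack is:

1. **Scale pyramid.** The clip plus spatially rescaled copies (default
   factors 1, ½, ¼; anti-aliased, temporal length unchanged).
2. **Conv1 — moving Gabor bank.** Each template is a Gabor receptive field

       G(x, y, t) = f(t) · exp(−(x′² + y′ₜ²)/(2σ²)) · cos(2π y′ₜ / λ)

   where (x′, y′) are coordinates rotated by the preferred orientation θ and
   y′ₜ = y′ − ρ·(t − (T−1)/2), i.e. the Gabor drifts at speed ρ px/frame
   orthogonal to its orientation, with the drift trajectory centred on the
   middle frame. The temporal kernel is the biphasic motion-energy form

       f(t) = (kt)ⁿ e^(−kt) [1/n! − (kt)²/(n+2)!],   n = 3,

   which vanishes at t = 0 and changes sign once at kt = √((n+1)(n+2)). A
   variant with prefactor (kt)² and Gaussian decay e^(−(kt)²) is available
   behind the `form` flag. The rate k defaults to 2n/T so the excitatory
   lobe peaks near the temporal midpoint; σ = 0.6·S and λ = 2√2·σ with S the
   spatial template size. The full bank is 8 orientations × 3 speeds (linear
   grid 4/3 … 4 px/frame) × 3 size classes (7×7×3, 9×9×4, 11×11×5) = 72
   templates.
3. **Template matching.** Convolution is valid (no padding) normalized
   cross-correlation: templates are mean-subtracted and ℓ2-normalized, and
   every input patch is ℓ2-normalized, so a response of 1 is an exact
   contrast-invariant match (a raw dot-product mode exists). A periodic
   (`wrap`) boundary mode supports the exact translation-invariance test
   harness. Responses are not rectified; max pooling operates on the signed
   matches.
4. **Pool1.** Spatial max pooling (default 4×4 window, stride 2, one time
   unit per channel), then max across adjacent scale pairs ({1, ½}, {½, ¼}
   → 2 scale channels); the finer response map is resampled onto the
   coarser grid before the elementwise max.
5. **Conv2 — sampled templates.** Templates are patches of Pool1 responses
   to the *embedding set* (clips of the non-test actors), drawn uniformly
   over clips, scale channels and positions, spanning the full Conv1 channel
   depth; each records its source actor, action, viewpoint, size class and
   scale channel. The same sampled bank is reused by all three fixed models.
   Mixed-size outputs are centre-cropped to the common extent (benign under
   global spatial pooling).
6. **Pool2 — the experimental manipulation.** Max over the whole spatial
   extent and one temporal unit, then over channels according to the wiring:
   * *per-channel* (purely convolutional): one unit per template, pooling
     that template's maps across the remaining scale channels;
   * *structured*: one unit per (actor, action, size class, scale channel),
     pooling that actor/action pair's templates across **all viewpoints** —
     3D orientation is discarded the way spatial pooling discards position;
   * *unstructured*: a seeded uniform random partition with exactly the
     structured partition's group-size multiset (the control).
   The residual time axis is collapsed by a global max so the signature
   length equals the number of Pool2 units.

The full-scale configuration uses 512 Conv2 templates; with 60 even groups
the random-partition wiring yields group sizes 8 and 9 only. Structured
wiring with 3 sizes × 2 scale channels yields 6 units per actor/action pair.
Both unit-count conventions are exposed (`make_pool_groups`,
`random_even_groups`) rather than hard-coded.

### Learned-template model

A trainable network with the same coarse layout — two
Convolution–BatchNorm–MaxPool–BatchNorm modules, two Linear–ReLU–BatchNorm
modules (256 and 128 units at full scale) and a log-soft-max head — trained
by mini-batch SGD (batch 10) on the cross-entropy between predicted and true
action labels of the embedding set. Default learning rate 0.01 and 30
epochs, no momentum or weight decay (all configurable); the desk-scale
preset uses lr 0.05. At feature-extraction time the linear layers and the
head are discarded and the flattened output of the last pooling /
normalization stage is the feature vector, with batch-norm statistics
frozen. All layers are implemented in numpy with analytic gradients,
verified against central finite differences in the test suite; the literal
Conv–BN–Pool–BN ordering is used.

## Decoding protocol

A Gaussian-kernel regularized least squares classifier with one-vs-all ±1
coding and arg-max decoding (ties to the lowest class id). Features are
z-scored per dimension on the training set. The kernel aperture (median
pairwise-distance heuristic × {¼, ½, 1, 2, 4}) and ridge strength (10⁻⁶ …
10², 9 log-spaced points) are selected by leave-one-out classification error
computed in closed form from the hat matrix H = K(K + nλI)⁻¹:

    f_i^loo = (f_i − H_ii y_i) / (1 − H_ii),

ties broken toward larger λ, then larger aperture. Accuracy is per-class
recall averaged with equal class weight.

Experiments use leave-one-actor-out splits: for each test actor, templates
are sampled (or learned) from the remaining actors' clips (the embedding
set), the classifier is trained on embedding actors' clips at one viewpoint
and tested on the held-out actor's clips at the same (*match*) or opposite
(*mismatch*, the invariance test) viewpoint, averaging over the two training
viewpoints (0° and 90°). Test clips never appear in the training or
embedding sets, which is asserted on every split. Reported: mean and
standard error (sample SD/√n) over splits. Model comparisons use a group
one-way ANOVA (fixed- vs learned-template groups) and all pairwise paired
t-tests with Bonferroni correction at family α = 0.05, with an exact fast
path for zero-variance differences.

## RSA

Dissimilarity between two stimuli is 1 − Pearson correlation of their
representation vectors, min-max normalized to [0, 1] over the off-diagonal
(Pearson inside the matrix, Spearman between matrices). Agreement between
two matrices is the Spearman correlation of their strictly lower triangles
(average-rank ties). Uncertainty: 50 bootstrap rounds, each subsampling 30
stimuli without replacement (a with-replacement mode exists behind a flag).
The noise ceiling is the maximum, over subjects and 100 bootstrap rounds, of
each subject's matrix against the mean of the others'; the noise floor is
the maximum over 100 rounds and all models of each model against a
row/column-scrambled neural matrix (one unconstrained symmetric permutation
per round). Scores are reported as (raw − floor)/(ceiling − floor),
unclamped with an out-of-range flag — the max-based floor and ceiling are
conservative, so well-matching models can exceed 1. The headline neural
matrix uses subject-averaged responses; per-subject matrices feed only the
ceiling. Model error bars are bootstrap-sample SDs. The categorical oracle
(dissimilarity 0 within an action, 1 across) is scored on the same floor and
ceiling.

## Synthetic data

**Videos.** Parametric articulated stick figures: per-actor limb
proportions, widths and body intensity are drawn once per actor id from a
seeded generator; actions are periodic joint-angle programs (drink, eat,
jump, run, walk — arm raise-and-hold, alternating bilateral arm cycling,
whole-body vertical motion with crouch, fast and slow alternating gait).
Viewpoint is a 3D yaw of the figure before orthographic projection with a
fixed 20° camera tilt (constant across conditions; without the tilt,
sagittal limb motion would vanish at the frontal view, which no real camera
geometry produces). The background (dim fixed gradient) is identical in
every condition, two static distractor blobs ride on the figure regardless
of action (the held-object confound control), and each clip starts at a
uniformly random phase of the action cycle. Full-scale geometry is
128×76 px × 60 frames; the default desk-scale rendering is 64×38 × 30
frames (2 s at 15 fps).

**Neural responses.** Each stimulus's latent vector concatenates orthonormal
one-hot embeddings of its action, viewpoint and actor, scaled by the
respective geometry weights; a fixed semi-orthogonal projection embeds the
latents isometrically into sensor space (Gaussian fallback when sensors <
latent dimension) and each of the ≥ 2 subjects adds i.i.d. Gaussian noise.
The planted geometry is therefore analytically known: with purely
categorical action weights, between-action dissimilarities are equal by
construction and the categorical oracle is the true generator. Defaults: 8
subjects, 306 sensors, weights (action 1.0, viewpoint 0.25, actor 0.25),
noise SD 0.75.

What the generator does *not* emulate: photorealistic appearance, optical
flow statistics of natural video, temporal neural dynamics (one
time-window-averaged vector per stimulus/subject), sensor covariance or
subject-specific gain. Passing tests therefore show that the pipeline's
inferential machinery behaves correctly on data with known structure — not
that the models explain real recordings.

## Desk-scale study conditions

The pipeline's default configuration — used by the ordering tests and the
acceptance script — is 3 actors × 5 actions × 5 viewpoints × 3 clips at
40×28 px × 16 frames (2 s at 8 fps), an 8-orientation single-speed single
size-class Gabor bank over a 2-scale pyramid (one scale channel), 80 sampled
3×3×3 Conv2 templates, the reduced learned architecture (8 and 24 filters,
24-dimensional features, 30 epochs at lr 0.05), decoding restricted to the
0°/90° viewpoints, a fresh 60-stimulus RSA set at those two viewpoints, and
neural geometry (1.0, 0.15, 0.15) with noise SD 0.6. Five pipeline seeds are
aggregated. Under these conditions the expected ordering holds on 5-seed
means — mismatch accuracy and normalized RSA are highest for the learned
model, and structured pooling beats both the unstructured control and the
purely convolutional model — but the structured-vs-convolutional margins are
small relative to seed-to-seed variability; at this scale that contrast
should be read as directional, not as a calibrated effect size. Runs are
fully deterministic given the configuration seed (every stage derives its
own stream from it), so all reported numbers are exactly reproducible.

## Numerical choices and edge cases

- Zero-norm input patches respond 0 under normalized matching; flat sampled
  patches are redrawn.
- Constant feature rows make correlation undefined and are rejected with the
  offending stimulus id.
- Degenerate normalization (ceiling ≤ floor) is rejected.
- LOO denominators are floored at 1e−10 with a logged warning when the hat
  matrix approaches singularity.
- Convolutions are valid-mode with 0-based coordinates; the invariance
  harness uses periodic padding and unit pooling regions so circular shifts
  commute exactly with the network.
- Mixed-size template responses are centre-cropped to the smallest common
  extent before stacking.

## Known limitations

- Stick-figure stimuli are far easier than natural video; absolute
  accuracies do not transfer.
- The learned model is trained at desk scale on tens of clips; its
  representation quality varies noticeably across seeds.
- The noise floor/ceiling are maxima over bootstrap rounds, biasing both
  upward; normalized scores are comparable within a run, not across
  different bootstrap settings.
- Only two decode viewpoints are supported by the experiment protocols, by
  design.
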