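# Methods

## The classification model

`rlmdpa` classifies two-class grayscale medical images (the motivating
case is cardiac MR screening for myocarditis) under strong class
imbalance by recasting classification as a sequential decision problem
and training a convolutional action-value (Q) network with two stages:
a gradient-free artificial bee colony (ABC) search that supplies the
initial weights, followed by deep Q-learning with experience replay.

### The imbalanced-classification MDP

Given a labelled set D = {(x_i, y_i)} with a minority class D_H
(label 0, e.g. healthy controls) and a majority class D_S (label 1,
e.g. diseased), each training episode shuffles D and serves one image
per step.  The agent's action a ∈ {0, 1} is the predicted label, and
the reward is class-asymmetric:

    r(a, y) = +1   if a = y and y ∈ D_H      (minority correct)
              −1   if a ≠ y and y ∈ D_H      (minority wrong)
              +λ   if a = y and y ∈ D_S      (majority correct)
              −λ   if a ≠ y and y ∈ D_S      (majority wrong)

with λ ∈ [0, 1].  An episode terminates when the data are exhausted or
immediately on the first misclassified minority sample.  Both devices —
the larger minority reward and the minority-triggered termination —
concentrate learning signal on the rare class.  λ = 1 makes the two
classes symmetric; λ = 0 removes all reward feedback from the majority
class.  λ = 0.3 is the default, the best-performing setting of the
majority-reward sweep.

The return is the discounted reward sum g_t = Σ_k γ^k r_{t+k}
(γ = 0.9 by default), and the optimal greedy policy is
a\*(s) = argmax_a Q\*(s, a).

### The Q-network

The function Q(s, a; θ) is a convolutional network implemented in plain
NumPy with hand-written gradients (no tensor-autodiff framework is
required at this problem scale).  Full-scale architecture: 100×100
single-channel input in [0, 1]; five convolution layers with
128/64/32/16/8 filters, kernel 3, stride 2, padding 1, each followed by
ReLU and a 2×2 ceil-mode max-pool; fully connected layers of 128/64/32
units with dropout 0.4; a linear two-unit output head.

Two numerical choices make the printed layer list realizable.  Pooling
is ceil-mode, and any pool whose input spatial dimension is already 1
is skipped: on 100×100 input the realized spatial sizes are
100→50→25 → 13→7 → 4→2 → 1 → 1, giving a 1×1×8 final feature map.
The architecture validator reports the realized sizes and rejects any
configuration that would collapse to zero.

All learnable parameters — convolution kernels, biases, FC matrices —
are exposed as one flat vector of length D (110,874 at full scale):
conv layers first in network order, each tensor immediately followed by
its bias, every tensor flattened row-major.  Encoding and decoding are
exact inverses (tested bit-for-bit); the 4-D kernel flattening order is
(filter, channel, row, column).  Biases are included in the vector so
the ABC stage optimizes every parameter.

### Stage 1: artificial bee colony pretraining

The ABC search treats a weight vector as a "food source".  With colony
size C (default 100):

* initialization draws every coordinate uniformly in per-dimension
  bounds [s_min, s_max] (default [−1, 1]; the bounds are a package
  default, chosen as the conventional unit box — no canonical value
  exists for network weights);
* the employed phase perturbs one coordinate of each of the first
  ⌈C/2⌉ sources toward a random partner, v_j = s_j + φ(s_j − s_kj),
  keeping the candidate only on strict fitness improvement;
* the onlooker phase repeats the same move ⌈C/2⌉ times on sources
  drawn with probability p_i = fit_i / Σ fit (roulette wheel);
* at most one scout per cycle re-draws a source whose trial counter
  exceeded the limit (default ⌈C/2⌉ × D) uniformly inside the bounds.

φ is drawn from [0, 1] by default with a config switch for the
conventional [−1, 1]; candidates leaving the bounds are clipped.  The
budget is counted in fitness evaluations (default 25,000).  Fitness of
a candidate is 1 / (1 + SSE) over the training samples with hard argmax
labels, i.e. 1 / (1 + #misclassified): it lies in (0, 1] and equals 1
exactly on a perfect fit.  The global best is tracked elitistically, so
the reported best-fitness history is non-decreasing by construction.

Design notes: scout re-draws use the initialization formula (a
neighbor move on a discarded source is ill-defined); fitness may be
evaluated on a seeded subsample to bound per-candidate cost; employed
bees are assigned to the first half of the colony so that the employed
and onlooker counts are each 50% of the colony with C food sources.

### Stage 2: deep Q-learning

Transitions (s, a, r, s′, end) are stored in a bounded FIFO replay
memory (default 50,000) and sampled uniformly in mini-batches of 64.
After every environment step (once the memory holds a full batch) one
stochastic-gradient-descent step is taken on the squared TD loss

    L(θ_k) = Σ_B (y − Q(s, a; θ_k))²,
    y = r                        if end,
        r + γ max_a′ Q(s′, a′; θ_{k−1})  otherwise,

with the targets held fixed (no gradient through θ_{k−1}).  θ_{k−1} is
a snapshot of the weights taken immediately before the update; the
snapshot cadence is configurable (`target_sync`).  The update is plain
SGD with step size l (default 1e−4): the loss formulation above is
literally a fixed-step descent, and anything fancier is deliberately
left out.  Action selection during training is ε-greedy with
multiplicative decay (1.0 → 0.01, factor 0.995 per episode); ε = 0
recovers a purely greedy policy.  Ties in argmax resolve to action 0
(the minority class).

Training runs for E episodes (default 18,000 at full scale).  When a
validation set is supplied, the minority-class F-measure is evaluated
every `eval_every` episodes, training early-stops after `patience`
non-improving evaluations, and the best-scoring checkpoint is returned
— checkpoint selection matters because small-scale Q-learning runs can
drift out of a good policy late in training.  At desk scale, where a
held-out split would be only a handful of images, the model facade can
instead monitor the training set itself (`checkpoint_on_train`).

Prediction is per image: the greedy argmax of the two action values.

## Evaluation

Six metrics from the confusion counts, with the positive class
defaulting to the minority label: accuracy, recall, precision,
F-measure (harmonic mean of recall and precision), specificity, and
G-means = sqrt(recall × specificity).  The square-root form of G-means
is used because it is the geometric mean the imbalanced-classification
literature defines and the one consistent with standard reporting.
Degenerate denominators (no positives predicted, no positives present)
yield 0 with a warning.  Cross-validation is stratified 5-fold with
seeded shuffling; per-fold metrics are aggregated as
min / median / max / mean / std.  Which class counts as "positive" is
configurable; the default (minority) matches the screening framing in
which the rare class is the one whose retrieval matters.

## Synthetic data

The generator emulates a two-class grayscale screening set: every image
is a smooth Gaussian-filtered background texture (base level 0.35,
texture sd 0.08, smoothing sigma 4 px) plus optional pixel noise;
majority-class images additionally contain one bright elliptical patch
(smooth quartic profile, random center/size/orientation, radius ≈ 12%
of the image side by default) whose amplitude is
`lesion_intensity × separability`.  Intensities are clipped to [0, 1].
`separability` = 1 with zero noise makes the classes separable by a
max-pixel threshold; `separability` = 0 makes them identically
distributed.  The default class sizes (245 : 469) mirror the ~0.52
minority:majority ratio of the motivating clinical dataset at one tenth
of its scale.

What the generator does *not* emulate: cardiac anatomy, acquisition
physics and artifacts, multiple images per patient (and hence
patient-level correlation), and multi-modal intensity distributions.
Passing tests on this generator therefore demonstrate that the
algorithmic machinery behaves as specified — not that the pipeline
reaches any particular accuracy on real CMR data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at desk
scale, chosen once as the package's own study conditions: 16×16 images,
a 4/3-filter, 8-unit network (201 parameters), bee-colony budgets of a
few hundred evaluations, and a few hundred training episodes.  At this
scale the 10:1 imbalanced fixture uses a 4 px lesion radius (25% of the
image side) so that the lesion remains resolvable at the coarse
resolution.  The full 100×100 five-layer architecture is exercised by
construction/geometry tests and a forward smoke test.

Other numerical choices: all randomness flows through seeded NumPy
generators (identical seeds give bitwise-identical populations, logs
and weights); uniform replay sampling is with replacement; weight
initialization before pretraining is uniform in the ABC bounds; zero
learning rate is an exact fixed point of the update; empty batches,
NaN inputs, shape mismatches and single-class datasets raise typed
errors rather than propagating silently.

## Known limitations

* Pure SGD on the summed batch loss is sensitive to the learning rate;
  small-scale runs can collapse into an all-majority or all-minority
  policy, which is why checkpoint selection on a monitored F-measure is
  recommended (and used in the examples).
* The ABC stage at desk-scale budgets typically improves the starting
  fitness only modestly; its value at full scale (large budgets, long
  training) is not assessed here.
* Episode termination on minority error makes episode length — and
  hence the replay mixture — depend on the current policy; no
  correction for this nonstationarity is attempted.
* Binary classification only; single-channel images only.
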