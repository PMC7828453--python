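# Methods

This note documents the models implemented in `locomode`, the numerical and
design choices behind them, what the synthetic-data generator emulates, and
the limits of what experiments on that generator can show.

## The improved trainer

Each judgment node is a single-hidden-layer MLP with logistic activations in
both layers: `h_j = f(Σ_i w_ij x_i − θ_j)`, `y_k = f(Σ_j w_jk h_j − θ_k)`.
Thresholds enter with a minus sign, so their gradient terms carry an explicit
(−1). The per-sample objective is the half squared error
`E = ½ Σ_k (y_k − ŷ_k)²` against one-hot targets.

Training is online (per sample), with the instance order reshuffled every
epoch under the run's seed. Two refinements:

* **Adaptive learning rate.** α is updated once per epoch from the mean epoch
  error: ×0.99 when the error grew by more than 4%, ×1.01 when it fell,
  unchanged in the dead band. Comparing per-epoch means rather than
  per-sample errors is a deliberate choice: per-sample comparisons are
  noise-dominated under online updates. α therefore stays within
  [α₀·0.99^T, α₀·1.01^T] after T epochs and is always positive.
* **Forgetting factor.** Each parameter group's update is
  `α·g(t) + β·α·g(t−1)`, where g is the bracketed gradient term of the update
  rule and g(t−1) is the *previous sample's* term (zeros at the first step).
  β is constant; the package default is 0.5, a mid-range momentum-like value
  (no principled setting exists, so it is exposed in the configuration). With β = 0 each step is exactly `−α·∇E`, which the test suite
  verifies against central-difference gradients to 1e−6.

All bracketed terms are evaluated on the forward pass of the pre-update
parameters, then both layers' deltas are applied simultaneously. The default
α₀ is 0.05. Training stops at the epoch budget or when the mean epoch error
falls below `target_error`. The sigmoid is computed with
`scipy.special.expit`, which is stable for large |z|.

## Bee-colony initialization

Randomly initialized networks occasionally fail to converge within a modest
epoch budget — the motivation for choosing initial weights and thresholds by
artificial-bee-colony search over the flattened parameter vector (dimension
D = m(n+1) + l(m+1), box bounds ±1 by default).

Conventions, where the canonical ABC literature leaves choices open:

* the raw objective E (to minimize) is transformed to a selection fitness
  `fit = 1/(1+E)`, so fitness-proportional following and the ≥-tie greedy
  rule both favor low error;
* neighborhood moves perturb exactly one randomly chosen dimension,
  `x_j + φ·(x_j − partner_j)` with φ ~ U[−1, 1], clipped to bounds;
* following (onlooker) bees act on the source they select, guarded by the
  same greedy rule;
* a source stagnant for `limit` trials (default 50) is replaced by a fresh
  uniform draw; the global best is recorded first and can never be lost;
* each of `n_global` rounds restarts the population from scratch; the best
  position over all rounds wins.

Evaluating a candidate by fully training its network is intractable at the
full-scale schedule (200 bees, 10 global × 1000 local searches). Fitness is
therefore the mean half-squared error after a short frozen probe: P epochs of
training (default 1; 0 scores the raw forward error) on a fixed subsample
(default 256 instances) with a frozen seed, making fitness deterministic per
position. That schedule remains expressible through `ABCConfig`;
tests and the acceptance script use desk-scale schedules (colonies of 8–40,
1–2 global × 10–300 local) chosen so every run completes in seconds.

## Decision-tree structures

Both built-in topologies use five judgment nodes. DTS-A: a four-way root over
the similarity categories, then four resolving children. DTS-B: a chain —
static vs rest, Sit vs Stand, stairs peeled off, ramps peeled off, walking
speeds resolved — with hidden sizes (10, 30, 30, 60, 40), the per-node neuron
counts found by structure optimization; DTS-A and the flat network default to
100 hidden neurons.

Each node is trained independently on the training instances that fall under
its subtree, with labels remapped to node-local branch indices; out-of-subtree
instances are excluded (an "others" class exists only where the topology
declares a branch for it, as in DTS-B nodes 3 and 4). Per-node seeds derive
deterministically from the run seed and the node's position in id order, so
training order is immaterial. Inference routes each window from the root by
argmax (ties to the lowest branch index) to a single-mode leaf, evaluating at
most `depth` networks.

## Data pipeline

Windows of 100/150/200 ms are cut non-overlapping by default (stride
configurable), trailing partial windows dropped, and flattened channel-major
(all ax samples, then ay, …) — the order is arbitrary but frozen for
serialization. The 24-dimensional summary representation is (max, min, mean,
population-sd) per channel, in channel-major blocks. Normalization is
per-dimension min–max to [0, 1] fitted on the training split only, clipped on
held-out data; degenerate dimensions map to 0.5 (the sigmoid midpoint).
Splitting is a seeded shuffle at 8:2. The standard-deviation divisor is n
(population), one of two defensible choices, fixed and tested.

## The synthetic generator

Real below-knee recordings of the nine modes are not redistributable, so
experiments run on generated surrogates: per channel, a gravity-projection
baseline plus three harmonics of a stride fundamental (relative strengths
1 : 0.45 : 0.2, per-channel quarter-cycle phase lags), with per-recording
random phase offsets (scale `jitter`) and white Gaussian noise.

The default profiles encode the similarity structure of the sensing problem,
chosen once to make the generator reproduce the qualitative regime of real
gait data rather than any particular accuracy value:

* the three walking speeds share a baseline and differ in cadence
  (1.3 / 1.9 / 2.5 Hz) and amplitude;
* the two ramp modes run at the medium-walking cadence and differ from
  walking mainly by a small opposite-sign shank-tilt gravity component
  (±0.9 m/s² on az) and a slightly raised gz signature — the subtlest
  inter-category boundary;
* the two stair modes are slow-cadence (1.1 Hz) with a strong gx signature,
  mutually similar but well separated from the other categories;
* Sit and Stand are static with *almost* identical gravity orientation
  (baseline differences of 0.06–0.6 m/s² against noise sd 0.25), so
  separating them rewards a focused binary decision — a nine-way classifier
  trained under a modest epoch budget tends to conflate them, while the
  dedicated sit/stand node does not.

Dynamic modes use noise sd 0.6 and jitter 0.5, set so that none of the
classifiers saturates at the study's training budget and structural
differences between them remain visible.

What the generator does **not** emulate: inter-subject variability, gait
asymmetry and stride-to-stride timing irregularity, transitions between
modes, sensor bias drift and calibration error, and any nonstationarity
within a recording. Consequently, passing experiments demonstrate that the
pipeline, the trainer, the tree routing and the bee-colony search behave as
specified and that the hierarchical designs exploit the intended similarity
structure; they do not predict accuracy on human-subject data.

## Study conditions and problem sizes

The package's standard synthetic study simulates 60 s per mode at 100 Hz
(2700 windows at 200 ms), splits 8:2, and trains every network for 30 epochs
at α₀ = 0.05, β = 0.5 — a budget at which the flat nine-way network is still
visibly handicapped by capacity contention while the focused tree nodes
converge; with much larger budgets all three structures saturate on synthetic
data and their ordering dissolves (a simulator artifact: real data keeps the
flat problem hard at any budget). Under these conditions the expected regime
is flat ≈ 75–95%, DTS-A ≈ 94–98%, DTS-B ≈ 92–99% with DTS-B ≥ DTS-A ≥ flat
in the large majority of seeds; the acceptance tests pin one representative
seed. The 100 ms window comparison and the sit/stand node accuracy use the
same conditions.

Degenerate inputs are handled explicitly: windows longer than a recording
yield an empty window set; constant feature dimensions normalize to 0.5; a
tree node with no training instances is an error naming the node; ties in any
argmax resolve to the lowest index.

## Known limitations

* The hidden-size defaults for DTS-B are adopted as fixed constants of the
  structure-optimized design, not re-derived here; re-running the neuron-count sweep on synthetic
  data would find different inflection points.
* The momentum memory follows the previous *sample*, not the previous epoch;
  the sequential reading of the update equations supports this, but the
  alternative is expressible only by retraining code.
* Parameter counting includes thresholds; input dimension 120 corresponds to
  the 200 ms raw-value representation.
* The ROC construction is micro-averaged one-vs-rest and F1 is macro-averaged;
  other conventions would give different numbers on the same predictions.
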