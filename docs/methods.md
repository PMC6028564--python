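# Methods

`rnncluster` implements a random neural-network cluster: a random-subspace
ensemble of small, from-scratch neural networks for case/control
classification of functional brain connectomes, with a feature-frequency
procedure that maps discriminative features back to brain regions. This
note records the model, its assumptions, the parameters that matter, and
the design choices made where the design was genuinely open.

## From time series to features

Each subject is a T x R matrix of ROI time series (default T = 110
timepoints, R = 90 regions — the 90-region AAL parcellation). The pipeline
is:

1. **Connectivity.** Pearson correlation between every pair of region
   series gives an R x R symmetric matrix. A constant series is an error
   (correlation undefined), reported with the region index.
2. **Binarization.** An edge joins regions i and j iff `|r_ij| > t`
   strictly, with threshold t = 0.25 by default; the diagonal is removed.
   Strictness at the boundary is a convention (configurable via the
   threshold itself); the absolute value means strong negative coupling
   counts as connectivity.
3. **Graph indicators.** On the binary graph we compute, per node:
   degree N_i; clustering coefficient C_i = 2e / (N_i (N_i - 1)) with e
   the number of edges among i's neighbours; local efficiency
   E(i) = (1 / (N_i (N_i - 1))) * sum over ordered neighbour pairs of
   1/d, the Latora–Marchiori form, with d measured inside the subgraph
   induced by the neighbours of i; and, per pair, the unweighted
   shortest-path (hop) distance. Nodes with fewer than two neighbours
   get C_i = E(i) = 0 (the denominator would vanish).
4. **Feature vector.** `[degree (R) | clustering (R) | shortest paths,
   upper triangle i<j (R(R-1)/2) | local efficiency (R)]` —
   3R + R(R-1)/2 features, 4275 for R = 90 of which 4005 are pair
   features. The layout map is bijective and versioned; it is emitted as
   sidecar JSON with every feature table.

Numerical conventions worth knowing:

* **Disconnected pairs.** Hop distance is undefined; we store the
  sentinel R (one more than any possible hop count), which keeps
  features finite and ranks "unreachable" beyond "far". Disconnected
  neighbour pairs contribute 0 to local efficiency.
* **Local-efficiency distances.** The textbook formula is ambiguous
  about the graph on which d is measured. The default is the
  neighbour-induced subgraph (standard); a `local_efficiency_distances=
  "global"` switch measures between-neighbour distances in the full
  graph instead.
* Shortest paths are computed on the *binary* graph; no weighted-graph
  variant is implemented.

## The five base networks

All five train on features standardized to zero mean and unit variance on
their own training subsample (sigmoid units saturate otherwise), encode
classes as 1-of-K targets, decide by argmax with ties to the lowest class
index, and are deterministic given `random_state` (PCG64; weights
initialized uniform(-0.5, 0.5)).

* **BP** — one sigmoid hidden layer (default 10 units), linear outputs,
  full-batch gradient descent on the mean halved squared error. Default
  step 0.3, up to 500 epochs.
* **PNN** — Parzen-window classifier; class score is the mean Gaussian
  kernel `exp(-||s - s_ij||^2 / sigma^2)` over the class's stored
  patterns. The shared normalization constant cancels in the argmax. The
  default `sigma=None` resolves to sqrt(d) at fit time: squared distances
  between standardized d-dimensional points concentrate around 2d, so a
  fixed small sigma underflows every kernel to zero as soon as d is more
  than a handful — the sqrt(d) rule keeps distances on the kernel's
  sensitive scale at every member size.
* **Competitive** — winner-take-all prototypes updated by the inner-star
  rule dw = eta (p - w), eta = 0.01, 500 epochs of seeded-order online
  updates. Training is unsupervised; prototypes receive the majority
  label of the training samples they win (a documented bolt-on — the
  winner-take-all layer itself knows nothing of labels), and a prototype
  that wins nothing falls back to the overall majority class.
* **LVQ (LVQ1)** — labelled prototypes initialized at class means; the
  winning prototype moves toward a same-label sample and away from a
  different-label one. With eta = 0 this is exactly the
  nearest-class-mean classifier.
* **Elman** — a simple recurrent network. Static feature vectors carry no
  time axis, so the m features are split into S = 4 contiguous chunks
  (zero-padded to equal length) and presented as a short sequence; the
  hidden state is `h(f) = sigmoid(W2 e(f) + W1 (alpha h(f-1)) + b)` with
  the context decay alpha = 1 fixed (not trained), and a linear readout
  of the final state is trained by backpropagation through time. With
  alpha = 0 the context path is silent and the network is feed-forward.
  Default step 0.5 and up to 1000 epochs: the recurrent pathway needs a
  larger step and more epochs than plain BP to reach the same training
  error (measured on standardized synthetic tables; smaller steps leave
  the loss visibly unconverged at the epoch budget, steps of 1 or more
  destabilize it).

BP and Elman stop early once the per-epoch loss improvement stays below
`tol` (default 1e-6) for 10 consecutive epochs; `tol=0` disables this and
recovers fixed-epoch training. Loss curves are exposed as `loss_curve_`;
at sufficiently small steps they are monotonically non-increasing.

## The random cluster

Given a labelled feature table, `split_train_test` makes a stratified 8:2
split (per-class floor rounding, remainder to the test side; 92 subjects
split 73/19). The ensemble then draws, for each of k members
(default 1000), `n_sub` subjects (default 70) and `m_feat` features
(default 120) without replacement from the training set, and trains one
base network per member. Member seeds are spawned deterministically from
the master seed (`numpy.random.SeedSequence`), so results do not depend
on execution order and a member can be retrained in isolation. A member
whose training raises is excluded from voting and counted in
`n_failed_`.

Prediction is majority vote; a tie goes to the class listed first in
sorted order and is flagged per subject. Members whose individual
held-out accuracy is **strictly** greater than the significance cut
(default 0.6) form the significant set; feature importance is the count,
per feature, of significant members that sampled it (the counts always
sum to `#significant x m_feat` — an identity the tests enforce on random
configurations). The top-m features by count (ties broken by ascending
index) are the significant features; `optimal_feature_count` rebuilds
clusters restricted to the top-m* for each candidate m* (several
repetitions with derived seeds) and picks the highest mean accuracy,
preferring lower variance and then smaller m* on ties — the
"highest and stable" rule.

One caveat is inherited from the procedure itself: significant members
are selected by *test-set* accuracy and the ensemble is then evaluated on
that same test set, which leaks information and flatters the
significant-feature accuracies. The default reproduces this procedure
faithfully; the CLI's `--holdout-frac` option instead carves an inner
validation split from the training set and selects significant members
on it, leaving the test set untouched until the final evaluation.

## Region weights and demographics

A selected nodal feature credits its region once; a selected pair
(shortest-path) feature credits both endpoints. Region weights therefore
sum to `#nodal + 2 x #pair` selected features. Reports rank regions by
descending weight (ties by ascending region index) and filter at an
**inclusive** minimum weight. Region tables use 1-based AAL numbering and
abbreviations; a 90-region label table ships with the package.

Cohort demographics use the two standard table tests: Pearson chi-square
on the 2x2 sex table with 1 df and *no* continuity correction (with
Yates' correction the canonical 5/45-vs-6/36 table gives ~0.76 instead of
the expected 0.528), and a pooled-variance two-sample t-test on age from
summary statistics.

## The synthetic cohorts

`generate_cohort` emulates the *output* of resting-state fMRI
preprocessing, not the scanner: each subject's T x R series is drawn from
a multivariate normal whose correlation matrix is the group target —
`base_rho` (default 0.1) on every off-diagonal pair, plus `delta_rho` on
the planted pairs for the case group. The target is checked for positive
semidefiniteness (smallest eigenvalue above -1e-10) and rejected with the
offending pairs named, unless `repair=True` opts into eigenvalue
clipping. Because Pearson correlation is scale-invariant, `noise_sd` only
sets signal amplitude. Defaults mirror a 92-subject study: 50/42 per
group, R = 90, T = 110 (120 scanner volumes minus 10 discarded).

Planted effects are injected as *correlation* differences, not mean
shifts, because every downstream feature is correlation-derived. When a
connected module of regions is planted (e.g. a triad), the effect spreads
across degree, clustering, local-efficiency and many path features of
those regions — which is what the feature-frequency procedure exploits;
disjoint planted pairs concentrate the signal in very few features and
are a much harder target for subspace voting. `generate_feature_table` is
the fast path for ensemble tests: unit-variance Gaussian features with a
standardized mean difference `effect_size` on planted indices, skipping
time series entirely.

What the generator does **not** emulate: head motion, physiological
noise, site effects, autocorrelated BOLD dynamics, or negative
correlation structure. Passing tests show the machinery is correct and
that the ensemble aggregates as designed on known ground truth; they say
nothing about classification accuracy on real cohorts.

## Problem sizes used in validation

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which the studied effects are visible: ensemble sanity
uses 92 subjects x 20 regions with a planted triad and k = 100 Elman
members, each sampling 70 subjects x 25 features — 10% of the 250
features, the sampling fraction scaled down proportionally from the
120-of-4275 reference geometry. Importance recovery uses 200 direct
features with 10 planted (effect size 2) and k = 200 PNN members
sampling 45 of the 80 training subjects: the frequency ranking depends
on the *contrast* in significance rates between members that did and did
not sample a planted feature, and bagging-style half-sampling of
subjects decorrelates members enough to make that contrast visible,
where near-full subject sampling (the reference 70-of-73 geometry)
leaves most members above the 0.6 cut and the ranking close to sampling
noise. k scales the ensemble only; the counting and voting logic is
identical at any k.

Two regime observations worth recording. First, subspace voting needs
the discriminative signal spread over enough features: when a planted
effect touches only a handful of the sampled features, most members are
pure-noise learners whose correlated votes cap the ensemble near
chance — a planted *module* (triad or larger), whose effect propagates
through degree, clustering, efficiency and path features, is both the
realistic disorder model and the regime where voting aggregates.
Second, with m_feat well above the member sample size (120 features for
70 subjects), every base network overfits its noise dimensions and both
member quality and feature ranking degrade; the scaled studies keep
m_feat below the member sample size.

## Known limitations

* The five networks implement the minimal textbook forms (single hidden
  layer, fixed alpha, LVQ1, plain winner-take-all); no momentum,
  regularization, or adaptive steps.
* Members train on raw sampled features; no within-member feature
  selection or weighting.
* With m_feat greater than the member sample size the base networks
  overfit freely; the ensemble tolerates this but individual member
  accuracies become noisy.
* Vote ties are possible with even k on binary problems; they are
  deterministic (first-sorted class) and flagged, but an odd k avoids
  them entirely.
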