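# Methods

## Problem setting

Given a community of OTUs with (i) an abundance table over samples,
(ii) one representative sequence per OTU (~10³ bp) and (iii) partial
multihot KO annotations, predict the full multilabel KO profile of every
OTU. The working hypothesis is that co-occurrence — correlated abundance
across samples — is informative about shared function, so the graph built
from abundance correlations carries signal that sequence composition alone
does not.

## Network inference

SparCC is the default correlation backend because amplicon abundances are
compositional. The implementation is the single-pass linear approximation:
counts get a pseudocount (default 1.0), are converted to per-sample
fractions, and the log-ratio variance matrix
t_ij = Var_s log(x_is/x_js) is reduced to basis variances ω by solving the
linear system obtained from row sums of
t_ij ≈ ω_i + ω_j − 2ρ_ij√(ω_iω_j) under the assumption that the
correlation cross-terms cancel. Correlations are clipped to [−1, 1] and
symmetrized. An optional refinement excludes the most strongly correlated
pair from the variance system and re-solves (`n_exclusion_iters`, default
0: the single pass is deterministic, fast, and sufficient for the guild
structures studied here; the refinement matters mostly when a few pairs
are near-perfectly correlated). Fewer than 4 OTUs leaves the system
underdetermined and is an error; a Spearman backend exists as a fallback
and for cross-checks. Dirichlet resampling and bootstrap significance
filtering are out of scope.

Edges require ρ strictly above the threshold. Defaults: threshold 0.3,
positive correlations only — "co-occurrence" semantics; both are exposed
because published analyses vary widely in this choice.

## Features

k-mer frequencies on the forward strand only (16S amplicons have fixed
orientation), windows containing non-ACGT characters skipped, rows
normalized by the number of counted windows. Default k = 7 (16384
columns) for real data; the desk-scale studies use k = 3, which already
separates guild prototypes.

Before training, the classifier z-scores each feature column over the
network's nodes (toggleable). Raw k-mer frequencies live at the 4^-k
scale and their discriminative variation is smaller still; standardization
puts all variants of the model on a numerically comparable footing. The
fitted mean/sd are stored with the model and applied at prediction time.

## Embedding and classifier

The embedding is a K-layer neighbor-sampled aggregation (K = 2 by
default, fanouts 25/10 at full scale, 10/5 in the desk-scale studies).
Sampling is uniform *with replacement* to a fixed fanout; an isolated
node samples itself. The aggregator is an elementwise SUM (mean and
max-pool variants realize the corresponding baselines); each layer
computes σ([W₁·h_self] ‖ [W₂·h_agg]) with ReLU σ. The deepest layer
consumes raw features; shallower layers consume the previous layer's
outputs. Each training minibatch draws fresh samples (stochastic
regularization); evaluation uses a fixed seed so predictions are
reproducible.

The classifier head is one hidden ReLU layer (with dropout) and
independent per-class sigmoid outputs. Classes are split at prevalence
τ = 0.5 into majority/minority tasks; each task owns a full
embedding + head stack over the same graph, and one Adam optimizer
minimizes the sum of the two summed binary cross-entropies, so the tasks
are learned separately but simultaneously. Forward and backward passes
are written directly in NumPy (the gradient of the sampled-tree
aggregation is an exercise in bookkeeping, not a reason for a framework
dependency); Adam uses β = (0.9, 0.999), ε = 1e−8, with L2 weight decay
added to the gradients. Degenerate splits (an empty side) fall back to
single-task training with a warning. Loss reduction is a sum over cells;
mean reduction is available and only rescales the effective learning
rate.

Numerical choices: probabilities are clipped to [1e−7, 1 − 1e−7] in the
loss and in reported predictions (sigmoids saturate in float64);
non-finite training loss aborts with the epoch number; binarization
threshold 0.5.

## Evaluation

micro-F1 pools TP/FP/FN over classes. macro-F1 is the harmonic mean of
the class-averaged precision and class-averaged recall; the more common
mean-of-per-class-F1 is available as an option and in the per-class
table (the two differ whenever classes are unbalanced — both are
reported so either convention can be compared). Accuracy is elementwise
cell agreement (subset accuracy optional). ROC-AUC is micro-averaged
over pooled cells via the rank-sum formulation with ties at 1/2.
Zero-denominator precision/recall contributes 0 and is counted in logs.
The support–performance regression is OLS of per-class F1 on
training-set support with a two-sided t-test on the slope.

## Hypothesis tests

Adjacency test: per repeat, equal numbers of adjacent pairs and pairs not
reachable within three steps are drawn without replacement (with
replacement across repeats) among OTUs with at least one annotation, and
the mean Jaccard distance of KO vectors per group is recorded. The
neighborhood test ranks pairs by the Hamming distance of adjacency rows
and contrasts the extremes; ties break by lexicographic pair order, and
graphs beyond a configurable pair budget are subsampled with a seed.

The negative control redraws a *fresh* label permutation for every
repeat. A single fixed shuffle would leave all repeats dependent on the
same accidental alignment, so any static difference — however tiny —
accumulates into spurious significance under a sign test across repeats;
per-repeat permutations make the null exact.

## Synthetic communities

The generator emulates the three properties the method exploits.
Abundance: each guild draws one log-normal latent abundance per sample
(log-sd 1.0 between samples, median 200 counts) and members multiply it
by log-normal noise (log-sd 0.1), giving SparCC-recoverable within-guild
correlation and compositionally induced negative between-guild
correlation. Sequences: one uniform-random prototype per guild, members
mutated by i.i.d. substitutions (default rate 0.1 — members of a guild
are distinct taxa, necessarily more divergent than the ~3% that separates
OTUs; there is no phylogenetic simulator because only k-mer composition
is consumed). Labels: class c covers round(G·0.9·(c+1)^−2) guilds (at
least one), every member OTU inherits the guild's classes, and cells
flip independently with probability 0.05. The 0.9 scale keeps even the
top class absent from some guilds — a function carried by every OTU
would be uninformative and would make the majority task trivial.

What the generator does *not* emulate: sequencing error and chimeras,
phylogenetic signal in sequences, functions shared across guilds by
mechanisms other than co-occurrence, and annotation biases of real KO
databases. Passing tests therefore demonstrate that the implementation
recovers structure it is designed for, not field performance on real
communities.

## Desk-scale study conditions

All studies run on one CPU in seconds to tens of seconds.

* **SparCC recovery:** 4 guilds × 10 OTUs, 50 samples, within-guild
  log-sd 0.1.
* **Hypothesis tests:** 6 guilds × 10 OTUs, label noise 0.05; 200 pairs ×
  100 repeats (adjacency), 100 + 100 extreme pairs (neighborhood);
  100 control shuffles.
* **Ablation study:** 16 guilds × 8 OTUs, 50 samples, 40 classes,
  prevalence exponent 2 with scale 0.9, sequence divergence 0.15, label
  noise 0.05; k = 3, fanouts [10, 5], embedding width 32, hidden width
  32, 100 epochs, five replicate seeds; metrics on a held-out 20% of
  OTUs.

Two of these numbers are deliberate study-design choices rather than
generator defaults. Sequence divergence is raised from 0.10 to 0.15
because at 0.10 the k-mer features alone already solve the desk-scale
task and all model variants tie at ceiling — there is no headroom left
for the factors under study. Sixteen guilds (not the default four) give
the exponent-2 power law several distinct coverage levels
({14, 4, 2, 1} guilds), hence real spread in per-class training support;
with fewer guilds every tail class collapses onto a single guild and the
support–performance relationship is structurally flat.

## Known limitations

* The macro-F1 advantage of the task split over single-task training is
  directional on average across replicates but noisy at this scale;
  individual seed sets can invert it. The sequence-only ablation's
  micro-F1 deficit and both hypothesis-test directions are robust.
* One graph is shared by both task stacks; rebuilding the network per
  label subset is not supported.
* Whether the classifier head should be trained jointly with the
  embedding (as here) or after freezing it is an open design point; joint
  training is the simpler end-to-end choice.
* The LSTM aggregator baseline is intentionally absent (order-dependent,
  large surface); mean and max-pool aggregators cover the
  permutation-invariant alternatives.
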