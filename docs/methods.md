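# Methods

## Decomposition and aggregation

A K-class lesion classification problem is decomposed one-vs-one into
K(K−1)/2 binary classifiers, one per unordered class pair {i, j}, each
emitting confidences (p_i, p_j) that sum to 1. The decision directed acyclic
graph (DDAG) aggregates them by sequential elimination over a maintained
class order: the first two classes of the remaining list are compared through
their pairwise classifier and the loser is removed; after exactly K−1
comparisons the surviving class is the prediction, and the sequence of
comparisons is the evaluation path. Two consequences drive the tests: a
Condorcet winner (a class winning all its pairwise duels) is predicted under
every elimination order, and in cyclic configurations the prediction depends
on the root. The root pair is selected as the pairwise task with the highest
validation balanced accuracy, ties broken toward the lexicographically
smallest pair; the remaining classes follow in index order, which makes the
structure fully determined by the class order.

Tie handling is deliberate and documented rather than inherited from the
literature, which is silent on it: an exact confidence tie eliminates the
class with the larger index, so predictions are deterministic.

The five classical fusion rules (avg, prod, mconf, gmean, max-win) merge m
multiclass probability matrices row-wise and renormalize. Probabilities are
floored at 1e-12 before products so the prod/gmean normalizer cannot vanish.
A max-win row with tied maxima splits that classifier's vote equally among
the tied classes so the fused row still sums to 1.

Because the DDAG emits a decision rather than a probability vector, the
experiment driver uses a documented surrogate — the per-class mean of
pairwise confidences, renormalized — whenever per-sample confidences are
needed to compare the DDAG against fusion rules in the statistical tests.

## Preprocessing

Patch-wise gray-world color constancy assumes a von-Kries (channel-wise
multiplicative) illuminant and an achromatic scene average. The image is
divided into a uniform patch grid (default 4×4; remainder rows/columns are
absorbed by edge patches) and each patch contributes its mean color with
equal weight regardless of its exact pixel count; the per-channel average of
patch means, rescaled so its maximum component is 1, is the illuminant
estimate. Normalizing the maximum to 1 means correction only darkens, which
minimizes clipping. Components are floored at 1e-4 so a degenerate
(all-zero) channel cannot blow up the division; a warning is logged when the
floor engages. Plain p = 1 averaging is used, not a Minkowski
(shades-of-gray) norm.

The full pipeline order is fixed and enforced: gray-world → center crop →
bicubic resize → mean-RGB subtraction. Center cropping rounds fractional
offsets toward the top-left (offset = floor((in − out)/2)). The default
subtraction constant is the published ImageNet per-channel mean (0.485,
0.456, 0.406) on the [0, 1] scale, configurable. Images are held as [0, 1]
floats internally; 8-bit PNG/JPEG is converted at I/O.

## Splitting, balancing, and class weights

Stratified splits size the smaller side per class as
round-half-up(fraction × n_c); this reproduces every self-consistent cell of
the reference per-class count table (e.g. a 20% test split of (1113, 6705,
1099) gives (223, 1341, 220), and a 20% validation split of (779, 4694, 769)
leaves a (623, 3755, 615) training fold). Repeated validation is n
independent stratified shuffle splits (default 3) rather than disjoint-fold
cross-validation — that is what the described protocol literally does.

Class balancing generates max(0, target − observed) augmented images per
class, drawing each operation from {hflip, vflip, rotation, width shift,
height shift}. Operation parameter ranges are a package choice (rotation
uniform in ±90°, shifts uniform in ±10% with reflect padding), configurable;
sources are used round-robin so no image is reused more than necessary.

Class weights are the inverse normalized frequency w_i = (Σ n)/n_i (default
"total" mode); the alternative K/n_i ("classes" mode) differs only by a
constant factor that the learning rate absorbs.

## Training schedule

Each pairwise task trains on the two-class subset with the weighted
cross-entropy L = −w_c log q_c (predictions clipped to [1e-7, 1−1e-7]),
Adam, batch size 32. The learning rate starts at lr0 and is held until the
validation loss fails to improve its running minimum for `plateau_patience`
epochs (default 8); at each such plateau event it is reset from the
polynomial decay lr0·(1 − epoch/total_epochs) at the current epoch. Training
stops early when train accuracy exceeds validation accuracy by more than the
overfit gap (default 10%, plain accuracy, strict inequality), or when the
decayed rate reaches zero. The returned model is the checkpoint with the
best validation balanced accuracy.

The default backbone is a softmax-head linear model (optionally one hidden
ReLU layer) over 16×16 downsampled, standardized RGB pixels — the framework
is backbone-agnostic and this keeps every end-to-end test CPU-cheap while
satisfying the full contract (2-node head, per-epoch scheduled training,
exact snapshot/restore). Deep fine-tuned CNNs plug in through the same
contract but are not part of the test surface.

## Metrics and statistics

Balanced accuracy is the macro-average of per-class recalls; for K = 2 this
is identically (sensitivity + specificity)/2. Specificity is one-vs-rest.
Binary decisions threshold the positive-class confidence at 0.5 (boundary
counts as positive); multiclass decisions use argmax, with the threshold
recorded for reporting. AUROC uses the Mann–Whitney formulation (ties count
half), cross-checked in the tests against an explicit pair-counting oracle.

Two models are compared with a two-sided paired t test; three or more with
Kruskal–Wallis followed by Dunn's rank-based post hoc z tests with tie
correction (no multiplicity adjustment by default, Bonferroni optional).
The comparison unit is the per-sample true-class probability. Group ranks
are formed by ordering groups by mean value (best first) and merging
adjacent groups whose pairwise difference is not significant; each method
also reports the set of methods significantly worse than it. "Not
significantly different" is not transitive, so this merge rule is a
documented convention, not a theorem.

## Synthetic data

The image generator renders one centered blob per image: a radial polygon
with sinusoidal boundary perturbation (irregularity × radius amplitude),
anti-aliased over one pixel, interior Gaussian texture noise, on a
skin-toned background, followed by a per-image channel-wise illuminant tint
drawn from configurable bounds and clipped to [0, 1]. Class identity shows
in radius, boundary irregularity, base color, and texture level; the
`separability` dial linearly interpolates all class parameters toward their
across-class mean, so 0 makes classes statistically identical and 1 keeps
them fully distinct. Per-image seeds derive from the top-level seed by a
counter-based scheme, so datasets are reproducible under reordering.

The probability simulator draws each classifier's row from a Dirichlet with
concentration 1 + fidelity on the true class and 1 elsewhere: fidelity 0 is
chance level, large fidelity approaches an oracle, and accuracy is monotone
in fidelity (verified by simulation).

What the generator does not emulate: hair and ruler artifacts, multi-scale
dermoscopic texture (networks, globules), lesion off-centering, camera
noise models, or realistic inter-class ambiguity structure. Passing
end-to-end tests therefore demonstrate that the pipeline, schedule, and
aggregation logic are correct and well-calibrated — not that any particular
accuracy transfers to real dermoscopy, which additionally requires deep
backbones and real data.

## Problem sizes and numerical choices

End-to-end tests use 50 images per class at 48×48 pixels with the default
backbone and 15–25 epoch budgets, chosen as the smallest configuration at
which fully separable classes are recovered essentially perfectly (pairwise
validation BACC 1.0, DDAG test BACC > 0.9) and chance-level behavior is
distinguishable from it. Statistical calibration checks use 1000 replicates
(3σ binomial bands around α = 0.05). Degenerate inputs are handled
explicitly: zero pair-sums in pairwise conversion yield a 0.5/0.5 tie with a
warning, all-identical groups give an omnibus p of 1, and zero-variance
paired differences raise rather than silently returning a statistic.

## Known limitations

- The DDAG probability surrogate is a convenience for statistical
  comparison, not part of the aggregation theory.
- The plateau-triggered decay follows a literal reading of the schedule
  description (decay recomputed at plateau events, held otherwise); other
  readings (monotone per-epoch decay) exist and would change traces but not
  the interfaces.
- The early-stop gap compares plain accuracies, not balanced accuracies.
- Dunn group ranks depend on the adjacency merge convention when
  significance is non-transitive.
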