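# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not show about real data.

## Stimulus selection

The selection procedure turns a table of per-image affective norms into
seven emotion pools of ten images each.

**Pre-screen.** Images with disgust intensity strictly greater than 4 (on
the [1, 7] scale) are removed once, globally, before any per-emotion
search, so that overly shocking material is never shown to participants. An
intensity of exactly 4 is kept. The pre-screen is idempotent.

**Clustering.** k-means with k = 3 partitions the (valence, arousal) plane
into the three macro-affect groups. Both axes share the [1, 9] scale, so no
standardization is applied. We run Lloyd iterations from k-means++ seeds
with 10 restarts (scikit-learn's `KMeans`, `algorithm="lloyd"`,
`max_iter=300`): a single random-point initialization can place two seeds
in one tight blob and converge to a wrong local optimum with appreciable
probability, whereas k-means++ with restarts recovers well-separated
affect groups for any seed — a property the test suite asserts directly.

**Cluster labelling.** Valence bands are half-open — negative [1, 4),
neutral [4, 6), positive [6, 9] — so every valence value falls in exactly
one band (the published band endpoints overlap at 4 and 6; determinism
requires a convention). A cluster is labelled by the band holding the
majority of its members; ties are broken by the band containing the
cluster's mean valence, then by the fixed order negative < neutral <
positive.

**Per-emotion picks.** Each basic emotion searches the clusters its macro
label maps to (the four negative emotions → negative, happiness →
positive, surprise → all three, reflecting its dual positive/negative
nature), restricted to images carrying the emotion's discrete label, and
takes the top ten by that emotion's intensity, descending. Neutral images
have no intensity rating; they are taken from the neutral cluster among
images tagged with *all six* basic-emotion labels (no single emotion
dominates), ranked by arousal ascending. Intensity and arousal ties are
broken by image id for reproducibility.

**Disjointness and ordering.** Whether one image may serve two emotion
groups is an open design point (surprise searches every cluster, so
collisions are possible). We enforce disjoint groups — 7 × 10 distinct ids
— by filling groups in the fixed order neutral, happy, anger, fear, sad,
disgust, surprise and removing already-selected ids from later candidate
pools. The order is a documented package choice, not an empirical fact.

**Sessions.** A session samples 5 ids per group uniformly (seeded) and
arranges the 35 items so no two consecutive items share a group, via
randomized backtracking with the pruning bound "a group needing more than
⌈remaining/2⌉ slots cannot avoid adjacency". For 5-of-7 sessions the
arrangement always exists; infeasible degenerate inputs raise.

## Landmark normalization

Four anchor landmarks whose positions facial expressions essentially do not
move define the face-intrinsic frame: the outer jaw/temple points (indices
0 and 16 of the standard 68-point scheme), the top of the nose bridge
(27, "nasal center"), and the base of the nose (33, "subnasal center").
These default indices are configurable: the anatomically exact choice is
not standardized, and any four expression-stable points with the required
left/center/right geometry work.

Distances are axis-aligned coordinate differences, not Euclidean norms:
the stated goal is to cancel horizontal and vertical position/scale
independently. Points left of the nasal center divide their x offset by
the left anchor distance, points at or right of it by the right distance —
using two separate horizontal distances balances facial asymmetry. All y
offsets divide by the vertical nasal-to-subnasal distance. Centering at
the nasal center makes the representation translation-free. Image
convention throughout: y grows downward; no flip.

Consequences asserted by the test suite: invariance to translation plus
independent positive axis scalings (to 1e-9), non-invariance to rotation
(a 10° roll changes the output; 3-D pose correction is out of scope), and
bitwise determinism.

**Feature subset.** The FACS manual singles out 22 facial muscles as the
drivers of expression; the corresponding landmark subset is not published,
so the package ships a documented default covering the brows (17, 19, 24,
26), eye corners and lids (36, 37, 39, 42, 44, 45), nose wings (31, 35),
and mouth (48, 50, 51, 52, 54, 56, 57, 58, 62, 66) — 22 points, 44
features — overridable via configuration.

## Dataset construction and rebalancing

Participants select one or more of the seven emotions per image; labels are
encoded as 7-bit vectors in the fixed order anger, disgust, fear, happy,
neutral, sad, surprise. An empty selection is invalid (the acquisition UI
requires at least one choice); an all-zero *prediction* is allowed.

Each emotion's binary task sets class 1 = emotion selected. Class 1 is
normally the minority, since class 0 pools every other selection.
Rebalancing keeps all positives and undersamples negatives, seeded and
without replacement, to `n_pos + floor(n_pos / 2)` — the residual class
difference equals half the minority count, a deliberate partial balance
because the negatives span a wider variety of expressions than the
positives. `floor` resolves odd minority counts. Undersampling is applied
once, before cross-validation; this mirrors the emulated acquisition
pipeline's processing order and means folds share the balanced pool
(a fold-internal variant would avoid that form of leakage, but the
package defaults to the faithful order).

## Classifier ensemble

Per emotion, two families are tuned and compared:

* SVM: cost C log-uniform on [1e-2, 1e3], kernel ∈ {linear, rbf}, width
  gamma log-uniform on [1e-4, 10];
* random forest: 50–500 trees, max depth ∈ {unlimited, 2..20}, minimum
  split size 2–10.

Random search draws `n_iter` configurations per family (default 50;
smaller budgets are used in tests and the acceptance script to keep
runtimes in minutes — on clearly separable data the argmax is insensitive
to the budget) and scores each by stratified five-fold cross-validated
mean F-measure; ties go to the earlier draw. Folds are stratified and
seeded; metrics are computed per held-out fold from its confusion counts
and averaged arithmetically (not pooled). The better family per emotion is
chosen by mean F-measure, ties by G-mean, then SVM; the winning head is
refit on its full balanced task.

Metric conventions: precision and F are 0 when their denominators vanish
(logged); G-mean is the geometric mean of sensitivity and specificity —
the standard imbalance-insensitive definition, which is also why
precision/F/G-mean rather than accuracy are emphasized on the residually
imbalanced tasks.

## Agreement statistics

The success rate of an algorithm against a participant is the fraction of
presentations whose selected and detected emotion sets intersect; it is
order-invariant and monotone in the detected sets. Reports expose per-user
rates and their mean. Per-emotion agreement builds, for each emotion, a
binary confusion over presentations (truth = user selected it, prediction
= algorithm detected it), pooled across users by default (a per-user
average is a one-line variant; pooling is the default because the
per-emotion counts per user are small). Accuracy is computed but omitted
from the default report, matching the imbalance-insensitive trio.

## Synthetic generators

**Ratings.** Images are assigned roles cycling through the seven emotion
targets; 5% are "shock" images whose disgust intensity (4.5–7) exceeds the
pre-screen threshold. Valence/arousal are drawn N(centroid, 0.3²), clipped
to [1, 9], around the macro centroids negative (2.7, 6.9), neutral
(5.0, 3.0), positive (8.0, 6.9). Target emotions get intensity 5–7
(disgust targets 3.2–4.0, just under the screen, so the screen never
starves the disgust pool), all other intensities 1–2.2. Neutral-eligible
images carry all six basic labels, uniformly low intensities, and an extra
arousal reduction. Surprise targets rotate through the three clusters. At
the default 700 images every emotion has ≥ 10 disjoint qualifying
candidates with margin.

**Landmarks.** The canonical neutral face is a hand-constructed 68-point
layout with unit anchor distances. Each basic emotion has a displacement
prototype motivated by its characteristic action units — mouth-corner
raise (happiness), lip-corner depression with inner-brow raise (sadness),
brow lowering and knitting (anger), brow raise with dropped jaw
(surprise), raised-and-knit brows with horizontally stretched mouth
(fear), nose wrinkle with raised upper lip (disgust); neutrality is the
zero field. All four anchors are undisplaced in every prototype. The
overall amplitude constant (1.5) makes a unit `expression_strength` move
expressive landmarks by roughly 0.3–1.4 anchor units, i.e. a full-blown
posed expression.

A sample draws a primary emotion uniformly over the seven states and, with
probability `multi_label_rate` (default 0.25), a second *basic* emotion —
neutrality never co-occurs with an expressed emotion, since a face cannot
be simultaneously neutral and expressive. Points = template +
strength × summed fields + isotropic Gaussian noise (sd `noise_sd`,
default 0.2 template units), then per-axis scale jitter (uniform 80–120
pixels/unit) and translation (uniform 100–500 px). Anchor landmarks
receive a quarter of the landmark noise: they sit on rigid, high-contrast
facial structure that detectors localize far more precisely than
deformable lips or brows, and stable normalization denominators depend on
it. Extreme noise draws that would still collapse an anchor distance are
clamped to a minimum gap of 0.1 units so every generated frame is
normalizable by construction. Jitter values are drawn after the noise from
the same stream, so configurations differing only in jitter ranges
produce identical pre-jitter geometry — the basis of the
jitter-cancellation test.

**What passing tests show — and what they do not.** With
`expression_strength/noise_sd ≥ 5` the seven binary tasks are cleanly
separable and every per-emotion cross-validated mean F-measure reaches
≥ 0.9 (≈ 0.94–1.0 at the regime boundary with ~700 samples); with the
labels permuted, accuracy falls to 0.5 on class-balanced tasks. This
demonstrates that the pipeline — normalization, feature reduction,
rebalancing, search, evaluation — recovers a known signal and does not
hallucinate one. It does not demonstrate performance on real faces: the
generator has a single facial geometry, linear additive expressions,
isotropic noise, no head rotation, no inter-subject variation, and
self-report labels that always match the generated expression. Real
multi-label annotations are noisier and real expressions far subtler, so
real-data metrics will be lower.

**Chance calibration.** The chance level of a binary task is the majority
class fraction, which is 0.6 after the 1.5:1 rebalancing; chance
calibration therefore trims tasks to exact class balance before permuting
labels, making the reference level exactly 0.5.

## Problem sizes and numerical choices

The test suite and acceptance script use 20 simulated subjects (700
samples), random-search budgets of 4–6 draws per family, and 5 folds;
these sizes were chosen so the whole pipeline demonstrates its properties
in a few minutes on one core. Seeds parameterize every stochastic step
(generation, undersampling, fold shuffling, search draws); derived
sub-seeds stay below 2³¹. Degenerate inputs (empty classes, coincident
anchors, empty clusters, infeasible sessions) raise `ValueError` with the
offending entity named rather than being silently repaired.

## Known limitations

* Rotation (head roll) is not corrected; the normalization is deliberately
  axis-aligned.
* Undersampling before cross-validation lets folds share the sampled
  negative pool; metrics are accordingly slightly optimistic.
* The 22-point subset and the four anchor indices are documented defaults,
  not published ground truth; both are configurable.
* The generator's displacement prototypes are caricatures for signal
  recovery, not face statistics; no claim about real-data performance
  follows from synthetic results.
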