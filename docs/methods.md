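# Methods

This note documents the models and procedures implemented in `gericare`,
the parameters that matter, what the synthetic generators emulate, and the
design choices made where the design was genuinely open.

## Vision input and coordinates

The package consumes per-person skeletons of 17 COCO-style keypoints, as
produced by modern pose estimators; pose estimation itself is out of scope
and keypoints enter through pluggable stream readers (JSON or CSV).
Coordinates are image pixels, origin top-left, x rightward, y downward,
0-based; timestamps are POSIX seconds.  A keypoint with confidence below
the detection threshold (default 0.05, the convention of common pose
estimators) is treated as undetected and excluded from all geometry.

Image conditioning ahead of detection uses the simplest member of each
operator family — gamma mapping for brightening (out = 255·(in/255)^(1/γ),
γ > 1 brightens), rectangular crop, box mean filter for denoising, Sobel
3×3 gradient magnitude for edges — with reflective borders everywhere and
all values clipped to [0, 255].  No parameter values are canonical here;
the defaults are conventions exposed in the API.

## Static posture classification

A skeleton is reduced to geometric features: torso angle from vertical of
the mid-shoulder→mid-hip axis (degrees, folded to [0, 90]); hip flexion
angle between torso and thigh, averaged over sides with both landmarks
detected (≈180° standing, ≈90° seated); bounding-box aspect; head height
above mid-hip in torso lengths; detected keypoint fraction; and torso
length (the only scale-dependent feature, used for normalization, never
for classification).  Fewer than 4 detected keypoints, or no detected
shoulder or hip, flags the features unreliable and the classification
unknown rather than raising.

Two classifiers sit behind one model handle:

* **rule fallback** — torso angle ≥ 50° is horizontal, split into
  lying-like vs fallen by whether the keypoint centroid lies inside a
  per-camera bed polygon; otherwise hip flexion ≤ 130° is sitting, else
  upright.  The thresholds sit midway between the well-separated synthetic
  pose geometries and are configurable.
* **trained tree** — the same CART learner as the care-plan module
  (depth ≤ 4 by default here, ≥ 6 samples per leaf) over the feature
  vector plus the bed flag.  Class order is severity-first
  (fallen > lying-like > sitting > upright) so leaf ties can never hide a
  dangerous state.

The bed polygon is the one deliberately position-dependent ingredient: the
geometric distinction between "horizontal in bed" and "horizontal on the
floor" is spatial, not postural.  All other features are invariant to
translation and uniform scaling, which is property-tested.

## Timed verification and wearable fusion

The protocol assesses one frame per 5 s (at 10 FPS this inspects 600
frames per minute and keeps 12), verifies a pose from 3 assessments over
15 s by 2-of-3 majority, and reassesses every minute.  Strict unanimity
was rejected: under keypoint noise it starves minutes of labels.  Severity
bias: two or more fallen assessments verify *fallen on the ground*
regardless of the third.

An upright majority becomes *walking* when the mean motion score exceeds
0.05 torso lengths, else *standing*.  The motion score between two
skeletons is the mean Euclidean displacement of commonly detected
keypoints divided by the mean torso length of the pair; it is symmetric
and undefined below 3 common keypoints.  A lying-like majority is held for
one minute and becomes *sleeping* iff the wristband sleep flag is raised
anywhere in that minute, or the minute's motion stays below 0.02 torso
lengths while the mean heart rate sits at least 10 bpm below the personal
awake baseline (the trailing median of awake-period heart rate; 70 bpm
when no history exists); otherwise *lying in bed*.  Entirely missing
vitals fall back to motion alone and flag the minute low-confidence.
The three thresholds are package defaults exposed in `MonitorConfig`;
sleeping can only arise through this fusion, never from a single frame.

Missing vitals samples are imputed by last-observation-carried-forward
with a staleness bound (default 24 h).  Staleness is counted from the last
*measured* value — carried copies do not extend the horizon — which makes
the fill idempotent and prevents silently stale vitals.

Minutes with no usable verification inherit the previous verified pose for
at most 5 consecutive minutes; a subject absent for a whole minute is a
gap, not an error.  Verified minutes accumulate into a per-day activity
ledger (hours per pose, conservation ≤ 24 h/day enforced).

## Movement-habit change

Daily active hours ActH = walking + sitting + standing.  With
Diff(a, b) = ((a − b)/b)·100 and threshold k_th = 12.5%, the verdict over
days (m−1, m−2, m−3) is *slowed down* iff both consecutive diffs are
≤ −k_th, *increased* iff both are ≥ +k_th, else *unchanged*; a diff exactly
at ±k_th satisfies its inequality.  The printed formula divides by b with
no guard; Diff(a, 0) with a > 0 is taken as +∞ (any activity after an
inactive day is an unbounded relative increase) and Diff(0, 0) as 0, which
preserves the monotone semantics.  The verdict is a pure function of the
three values and scale-invariant, and an exhaustive grid (0–12 h in 0.5 h
steps, 15 625 triples) is checked against an independent transcription of
the decision procedure.

## Care-plan decision support

The patient state has 21 categorical variables (plus demographics with
height restricted to 1.20–2.20 m).  Value sets documented with open tails
("etc.") in the clinical source are closed with representative members so
the schema is checkable.

**Rules.**  Staff-written IF-THEN rules are conjunctions of
(variable, operator, value) conditions mapping to one of four actions.
Evaluation order is severity of action (descending), then priority, then
id — a deliberate choice, since no ordering is canonical: with
severity-first, an emergency rule can never be shadowed by a blander one.
Unmatched states default to *continue current treatment*.  Rules are
validated against the schema at load time.  The shipped 18-rule set is
illustrative (production rulesets are site-specific and private) and is
written so that the tree emulation below is a meaningful demonstration.

**Tree.**  A CART with Gini impurity (1 − Σ p_j²), grown greedily and
pre-pruned to depth ≤ 3 with ≥ 6 samples per leaf — "minimum samples" is
read as per-leaf support, the standard pre-pruning semantics matching the
overfitting motive.  Categorical variables are one-hot binarized
(variable == value) rather than subset-searched, keeping every split
readable at depth 3 and the fit deterministic: features are scanned in
index order, thresholds in increasing order, and only a strictly positive
impurity decrease splits.  Leaf ties resolve to the most severe action.
The tree serializes to JSON and round-trips without changing any
prediction.  On 5 000 rule-labelled synthetic states (4 000 train /
1 000 test) the tree agrees with the rule engine on ~87–89% of held-out
states across seeds.

## Re-identification

Bag of visual words: patches (8×8, mean-subtracted, L2-normalized) are
taken around Harris corners, falling back to a dense grid on weakly
textured images; near-constant patches are skipped, so a flat image yields
no descriptors and an all-zero sentinel histogram.  A K-means vocabulary
(default k = 64, Lloyd's algorithm, seeded) quantizes descriptors to
words; ties in the nearest-centroid assignment go to the lowest index.
The identity classifier is a linear one-vs-rest maximum-margin model over
histograms with at most four classes — three ward patients plus the
open-set "None" class, which has its own training examples *and* an
optional margin threshold below which any prediction is forced to "None".
Vocabulary and model are pure functions of (data, seed, params) and
serialize to JSON.

## Evaluation suite

Confusion matrices use rows = actual, columns = predicted.  Per-class
scores are one-vs-rest: precision = diag/column sum, recall = diag/row
sum, F1 their harmonic mean, with empty denominators scored 0 and flagged.
Macro F1 is the unweighted mean; weighted F1 is Σ (k_i/N)·F1_i — the
weights already sum to one, so no further division by the class count is
applied (a formula printed with such a division is inconsistent with its
own reported value and is treated as a typo).  Computation is at full
precision; report-time rounding is half-up to 4 decimals.  ROC AUC is the
one-vs-rest trapezoidal area, computed via midranks (the Mann–Whitney
form), verified against brute-force pair counting and an independent
library implementation.

## Synthetic data: what it does and does not emulate

The generators stand in for private ward footage and wearable logs:

* **Skeleton streams** — a 6-segment articulated stick figure (stature
  120–168 px in a 640×480 scene, ≈1.5–1.9 m at the default scale) with
  per-pose geometry: vertical torso for standing, limb oscillation plus
  translation (default 40 px/s) for walking, ≈90° hip flexion for sitting,
  horizontal torso inside/outside the bed polygon for lying/fallen, and
  zero voluntary motion for sleeping versus slow lateral fidgeting for
  awake lying.  Isotropic Gaussian keypoint noise (σ as a fraction of
  torso length) and independent per-keypoint dropout emulate jitter and
  blanket occlusion.
* **Vitals** — heart rate = baseline + a 3 bpm circadian sine + N(0, 1.5),
  reduced by 15 bpm with the sleep flag raised inside scripted sleep
  intervals; scripted whole-record dropouts exercise the carry-forward
  imputation.
* **Patient states** — sampled per-variable from priors skewed toward
  clinically stable values (a stable long-term-care ward; uniform sampling
  over the value sets would make severe states absurdly prevalent) and
  labelled by the rule engine, which is the training oracle for the tree.
  Uniform and custom priors are available.
* **Ward images** — 64×64 procedural textures (oriented gratings, checker,
  rings) inside an elliptical silhouette over varying backgrounds; the
  "None" class draws from a pool of other textures.

Every generator is a pure function of (script/params, seed).  What passing
tests on these data show is that the *protocol logic* — sampling,
verification, fusion, ledger accounting, rule evaluation, tree induction,
descriptor quantization, metric arithmetic — is correct and that each
learner recovers planted, well-separated structure.  They do not show
robustness to real pose-estimator failure modes (identity switches,
hallucinated limbs, crowded scenes), real sleep physiology, correlated
clinical variables, or real appearance variation; the published accuracies
of systems measured on live footage are therefore not reproduction targets
here, and the package asserts property floors (tree-rule agreement ≥ 0.85,
noisy posture accuracy ≥ 0.90 with σ = 2% of torso length and 15%
occlusion, clean-pose accuracy = 1.0, per-class re-identification ≥ 0.85)
instead.

## Numerical and degenerate-input choices

Division-by-zero sentinels in the habit diff; undefined motion scores and
AUCs flagged rather than silently zeroed; all-zero histogram sentinel for
descriptorless images; single-class training data rejected for posture and
identity models but valid (single leaf) for the care-plan tree; ledger
conservation enforced at insert time.  Benchmark problem sizes (5 000
states, 250 skeletons per class, 18 images per class) were chosen as the
smallest sizes at which the measured quantities are stable across seeds.

## Known limitations

Single camera, single bed polygon, no cross-camera tracking; the minute
grid is anchored at stream start rather than wall-clock minutes; the
wristband sampling rate is assumed regular-ish but not required; the
shipped ruleset is a demonstration, not clinical guidance; and the
open-set "None" margin threshold is left unset by default because the
synthetic "None" class is trained explicitly.
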