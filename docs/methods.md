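# Methods

`neurocoh` implements a quantitative-EEG pipeline for distinguishing two
clinical brain states that present with visually similar periodic
discharges: focal-onset nonconvulsive status epilepticus (NCSE), whose
functional networks are hypothesized to be *segregated* around an
ictogenic focus, and toxic/metabolic encephalopathy (TME), whose diffuse
cortical involvement produces *integrated*, globally efficient networks.
Because clinical EEG of this kind cannot be redistributed, the package
ships a synthetic cohort generator that encodes exactly this structural
contrast, and the pipeline's validity is established on properties
(estimator bias laws, enumeration oracles, statistical calibration,
parameter recovery) rather than on reproducing any specific patient table.

## Synthetic cohorts

Each subject is a 19-channel recording on the International 10-20 montage,
sampled at 200 Hz (60 s by default). The periodic-discharge source is a
stylized triphasic transient — a dominant sharp wave flanked by two
smaller opposite-polarity Gaussian lobes spanning ~80% of the cycle —
repeated quasi-periodically at the discharge rate (default 2 Hz) with
cycle-to-cycle amplitude jitter (10%) and cumulative inter-discharge
timing jitter (SD 4% of the period). The timing jitter matters: it makes
independently generated trains decohere over tens of seconds, the way
distinct clinical generators do. Each driving source mixes the discharge
train with shared broadband activity (white + 1/f, 55% of source power),
modeling the ongoing cortical signal that is conducted along with the
discharges; without it, coherence between driven channels would collapse
to the noise floor outside the delta band, which real scalp EEG does not
do.

The two archetypes differ only in the coupling topology:

* **integrated** (`tme_like`): one source drives all 19 channels (gain
  jitter 10%) plus independent per-channel sensor noise (white + 1/f);
* **segregated** (`ncse_like`): channels are partitioned into
  `n_communities` (default 3) spatially contiguous electrode
  neighborhoods along a scalp path, each driven by its own source.
  Community discharge rates are spread over ±25% of the nominal rate so
  communities are mutually incoherent; a `leakage` coefficient (default
  0.1) feeds each community the mean of the others.

`snr` (default 3) is the linear source-to-noise amplitude ratio;
`snr = 0` produces pure-noise recordings used to probe the coherence
estimator's bias floor. All randomness descends from one master seed
through per-subject `SeedSequence` derivations, so cohorts are
byte-reproducible and extensible without perturbing existing subjects.

Clinical covariates (age, sex, chronic liver disease, platelets,
magnesium, blood urea nitrogen, creatinine, aspartate transaminase) are
drawn per group from Gaussian (age), Bernoulli (binary) or
moment-matched log-normal (laboratory) distributions whose group
means/SDs default to values typical of published NCSE/TME cohorts; only
the *direction* of the group shifts is load-bearing downstream.

What the generator does **not** emulate: volume conduction and reference
effects, artifacts (EMG, eye blinks), nonstationarity beyond discharge
jitter, and realistic spectral shape of background EEG rhythms (alpha
peaks etc.). Passing tests therefore demonstrate that the pipeline
recovers the network contrast it is designed to detect under controlled
conditions — not that the specific clinical effect sizes would be
reproduced on real patients.

## Epochs and filtering

Ten non-consecutive 2-s epochs per subject (400 samples), pairwise
separated by at least 1 s. Clinically these epochs are selected by visual
review; the default selector spaces them evenly and a hook accepts custom
selection. A 0.1–70 Hz zero-phase acquisition bandpass is applied at load
time (default on). Band-limiting uses 4th-order Butterworth filters run
forward-backward (zero phase, squared magnitude response). The five
analysis bands are delta 0.1–4, theta 4–8, alpha 8–13, beta 13–30 and
gamma 30–50 Hz.

## Coherence networks

Connectivity is Welch-averaged magnitude-squared coherence: Hann window,
0.5-s segments, 50% overlap — K = 7 segments per epoch and a 2-Hz
frequency grid. Band weights average the MSC over bins with
`low <= f < high` (the top band closes its upper edge so the five bands
tile 0–50 Hz); on the 2-Hz grid delta holds bin {2}, theta {4, 6}, alpha
{8, 10, 12}, beta {14–28}, gamma {30–50}. The DC bin is excluded
(detrending makes it degenerate). A subject's per-band network is the
element-wise mean of its ten epoch matrices (per-epoch estimation limits
nonstationarity leakage; concatenation is available as an option via
longer inputs). With K averaged segments the MSC of independent signals
has expectation ≈ 1/K; for overlapping segments the package computes the
overlap-corrected floor (≈ 0.150 for the default estimator vs 1/7 ≈
0.143), which the tests use as the "no coupling" reference.

## Graph measures

All thirteen global measures are computed in-package on the weighted
undirected coherence matrix; `networkx` and enumeration oracles appear
only as cross-checks in the tests.

* Edge lengths: `l = 1/w` (`-log w` optional); all-pairs distances by
  Floyd–Warshall. Disconnected pairs are excluded from the characteristic
  path length and contribute 0 to global efficiency.
* Degree counts edges with `w > tau` (default `tau = 0.5`, which on dense
  coherence matrices produces the partially thresholded topologies that
  clinical toolboxes report); strength sums all weights unthresholded.
  `tau` exists because published average degrees on 19-node coherence
  networks imply an edge-elimination step whose parameters are typically
  not stated; absolute degree magnitudes are therefore configuration-
  dependent and are not treated as reproduction targets.
* Clustering: Onnela geometric-mean triangle intensity per node;
  transitivity pools triangles over triplets; local efficiency is the
  mean global efficiency of each node's neighborhood subgraph (nodes with
  fewer than two neighbors contribute 0).
* Modularity: weighted Newman–Girvan functional, optimized by an
  in-package two-phase Louvain heuristic with 10 seeded restarts
  (resolution γ = 1, ties to first-found). The first restart starts from
  singleton communities (classic Louvain); subsequent restarts start from
  random partitions, and every restart ends with a single-node refinement
  pass on the original graph — singleton starts alone repeatedly converge
  to one suboptimal basin on small graphs, and diversified starts remove
  that failure mode. On ≤ 8 nodes the restarted heuristic attains the
  exhaustive-search optimum in the test suite.
* Assortativity: Pearson correlation of end-node strengths over both
  orientations of suprathreshold edges. On a graph where all end
  strengths are equal (complete unit graph) the correlation is undefined
  and the operation raises; `compute_all` maps this to NaN by default.
* Small-worldness: σ = (C/C_rand)/(L/L_rand) against 10 surrogates built
  by Maslov–Sneppen degree-preserving rewiring (10 attempted swaps per
  edge, 8× attempt budget) of the suprathreshold topology, with the
  original weight multiset shuffled onto the rewired edges. A complete
  graph admits no legal swap, so its surrogates equal the original and
  σ = 1 exactly.

## Group statistics

Each measure × band cell (65 tests) is compared between groups by a
two-sided label-permutation test on the difference of group means (1000
permutations, "+1" smoothing so p ≥ 1/(n_perm+1); Welch-t statistic
available as an option). FDR correction is Benjamini–Hochberg applied
jointly across all 65 tests — the most conservative reading when the
correction family is not otherwise specified. Clinical covariates are
compared with Welch t-tests (continuous) and chi-square tests (binary); a
binary variable constant in the pooled sample returns p = 1 rather than
an error, since no difference is observable.

## Classification

The 22-feature table joins the eight clinical covariates with the 14
graph features that discriminate the archetypes (degree in
delta/alpha/beta/gamma; strength, global efficiency, local efficiency,
clustering, transitivity, modularity in delta; global efficiency in
alpha; assortativity in alpha/beta/gamma). Eight model families (gradient
boosting, logistic regression, random forest, SVM, Gaussian naive Bayes,
shallow MLP, k-NN, decision tree; scikit-learn estimators behind a
standardizing pipeline) are tuned by seeded random search (20 candidates)
with stratified 3-fold CV on a stratified 75% training split, then scored
by stratified 3-fold CV over the full table with the tuned
hyperparameters. "Average of 3-fold CV" is inherently ambiguous about
which data the folds cover; this package tunes on the split and reports
full-data CV, and both choices are configurable. Every reported metric
(PPV, NPV, sensitivity, specificity, accuracy, F1, AUC) is computed by
the package's own confusion-count and ROC operations — the trapezoidal
AUC over the tie-grouped empirical ROC equals the Mann–Whitney U
normalization, which the tests verify against independent pair counting.

Feature influence for the best model is ranked by permutation-sampling
Shapley attribution implemented in-package: for each sampled feature
ordering, features switch one at a time from the background point (the
feature-wise mean) to the explained sample's values, and score increments
are credited to the switched feature. Because each ordering's credits
telescope, additivity (base value + attributions = model score) holds
exactly, not just in expectation; 30 orderings suffice for stable
rankings at this dimensionality.

## Problem sizes and numerical choices

Default study size is 30 subjects per archetype (ten 2-s epochs each),
which recovers the delta-band efficiency/modularity contrast with
FDR-corrected p-values at the permutation floor while keeping a full
pipeline run under a minute on one core. The acceptance script evaluates
direction recovery over five independent cohorts of this size and
permutation calibration over 500 null replicates. Floating-point
tolerances: oracle equality at 1e-9; AUC cross-implementation agreement
at 1e-12; Shapley additivity at 1e-3 (dominated by score-function
rounding). Degenerate inputs (all-zero graphs, single-segment coherence,
empty bands, one-class labels) raise informative errors rather than
returning silent defaults.

## Known limitations

* The generator's archetypes are deliberately stylized; effect sizes are
  far larger than clinical reality, so classifier metrics near 1.0 on
  synthetic cohorts say nothing about clinical accuracy.
* Coherence depends on the reference montage; the package analyzes the
  recorded (common) reference and provides no re-referencing.
* The Louvain heuristic guarantees no global optimum on large graphs;
  restarts make it exact only at the tested sizes.
* Nodal (per-electrode) measures, directed/phase-based connectivity and
  cluster-based edge statistics are out of scope.
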