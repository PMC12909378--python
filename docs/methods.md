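# Methods

This note records the models implemented by `edscreen`, the numerical
conventions chosen where more than one defensible option existed, what the
synthetic-data generator does and does not emulate, and the limits of what
a green test establishes.

## Spectra

A spectrum is a peak list sorted by ascending m/z with an optional
precursor m/z. Cleaning (`spectra.clean_peaks`) applies minimal standard
hygiene: zero-intensity peaks are dropped, peaks beyond the precursor
(m/z > precursor + 0.5 Da, when the precursor is known) are dropped, and
intensities are normalized to the base peak. These defaults are deliberate
and configurable; no noise-floor subtraction is attempted.

Averaging across collision energies normalizes each spectrum first, then
merges pooled peaks by single-linkage in ascending m/z within a tolerance;
a merged peak's m/z is the intensity-weighted mean and its intensity the
plain arithmetic mean over the input spectra (a spectrum lacking the peak
contributes 0). Collision energies are not weighted. Processing in sorted
m/z order makes the merge deterministic and independent of input order.

The quality filter for downstream use requires at least `min_peaks`
(default 5) peaks with relative intensity strictly above
`min_rel_intensity` (default 0.05); "above" is read strictly.

Labels are ternary per assay. When several reports disagree, active wins
over inactive (precautionary principle); inconclusive compounds are
excluded before any network or model sees them.

## Spectral similarity

Both cosines use the same greedy resolution: candidate peak pairs within
the m/z tolerance (inclusive ≤, default 0.2 Da) are sorted by descending
intensity product with ties broken by ascending (m/z_a, m/z_b), then
accepted greedily with each peak used at most once; the score is the sum
of matched intensity products over the product of the two intensity-vector
L2 norms. Intensities are used as-is (no square-root or m/z weighting) —
a declared choice, since published implementations differ. The modified
cosine additionally admits pairs offset by the precursor-mass difference.
Greedy matching can be suboptimal when candidates conflict; the tests
bound it by an exhaustive optimal-assignment oracle on small spectra
rather than asserting optimality.

Externally computed similarity matrices (e.g. from a trained neural
scorer) are only ever *loaded* — validated for symmetry (1e-6), range
[0, 1], and id coverage — never recomputed; training such scorers is out
of scope.

## Networking and voting

An edge requires weight ≥ threshold; optional top-k filtering (default
k=6 when enabled) keeps an edge if *either* endpoint ranks the other in
its k most similar passing neighbors — the union rule preserves symmetry
where a directional reading would not — with ties at the k-th similarity
broken by ascending compound id. Top-k is applied after thresholding.
Weighted voting falls back to the unweighted count when all incident
weights are zero (possible only at threshold 0), which keeps the
equal-weights-equals-majority identity exact.

Leave-one-out evaluation builds the topology once; a node's vote never
uses its own label, so per-node predictions are the leave-one-out
estimates by construction. Note a subtle artifact: under label
permutation the LOO vote is slightly anticorrelated with the node's own
label (an active node's neighbors draw from a pool with one fewer
active), so permuted-label baselines sit marginally below 0.5.

## Modified ROC and FPR at recall

`extended_confusion` classifies connected nodes positive iff probability
≥ threshold (inclusive); unconnected actives/inactives go to NCP/NCN.
The mROC curve sweeps the unique connected probabilities plus one
above-max threshold, anchors at (0, 0), sorts points by mFPR, and extends
horizontally from the terminal point to mFPR = 1 before trapezoidal
integration. This convention puts mROC-AUC on the usual [0, 1] scale
while keeping the unconnected-node penalty: the terminal mTPR — the
connected fraction of actives — caps the area, and a fully disconnected
network scores exactly 0. With no unconnected nodes the metrics reduce to
the classical rates (verified against scikit-learn to 1e-9).

`fpr_at_tpr` is classical: unconnected nodes are predicted negative at
every threshold (they can never be prioritized), and the reported
operating point is the *largest* threshold whose recall meets the target,
i.e. the cheapest workload achieving it. When the target is unreachable
(too many actives unconnected) the maximal-recall point is returned,
flagged unreachable.

## Mondrian conformal prediction

Standard inductive CP with per-class (Mondrian) calibration:
nonconformity is 1 − P̂(true class) from a base model fit on the proper
training part only; p-values use the +1-smoothed, non-randomized rank
with ties counting toward the numerator (conservative). The base model is
pluggable behind a fit/predict-proba contract; the default is a
300-tree random forest with optional class weighting. The ε grid
defaults to {0.15, 0.20, 0.25, 0.30}. The calibration fraction defaults
to 0.2 and is stratified, so both classes are present on both sides.

Because validity holds for any base model, the large-replicate validity
simulation in the test suite uses logistic regression for speed; this
checks the conformal machinery, not forest quality.

## Fingerprint model

Cleaning order: constant bits; near-zero-variance bits (caret
convention — most-common/second-most-common frequency ratio > 19 *and*
distinct-value percentage < 10, both configurable); then iterative
correlated-pair removal at |Pearson r| ≥ 0.9, dropping the member of the
most correlated remaining pair with the larger mean absolute correlation
(ties drop the lexicographically later bit name). For binary bits the
frequency-ratio clause is equivalent to prevalence below 5%, so sparse
fingerprint worlds lose most uninformative bits here — intended, but it
means causal bits must sit above 5% prevalence to survive (see the
generator design below). Cleaning is idempotent.

The classifier is gradient-boosted trees behind the same
fit/predict-proba contract as CP's base model (the specific library is an
implementation detail); randomized search samples from a declared,
overridable grid (depth, learning rate, boosting rounds, L2, class
weight) and scores by mean ROC-AUC over stratified folds (default 5),
refitting the best configuration — ties to the first sampled — on all
data. Deterministic under the seed. Production-scale searches would use
hundreds of trials; the tests use ≤ 8.

## Wastewater prioritization

Fate bands on r = effluent/influent are inclusive: persistent for
0.8 ≤ r ≤ 1.2, transformation product for r ≥ 1.5, other in between or
below; r is relative to the influent. A feature absent from the influent
is a transformation product; a feature fully removed (effluent 0) is
"other". Each approach's decision threshold is derived from its own
training evaluation as the largest threshold achieving the target recall
(default 0.9); features an approach cannot score (no spectrum, no
fingerprint) are *unavailable*, a separate consensus stratum never
conflated with inactive. Consensus counts features by the exact subset of
approaches calling them active, partitioning the feature list.

## Synthetic data: what it emulates, and what not

The generator states a miniature screening-library world: 64 binary bits
per compound, background bits at 3% prevalence, two hidden toxicophore
bits whose prevalence is set so the OR over them hits the target active
fraction (default 16%, the top of the 3–16% range nuclear-receptor
panels show); labels are the OR flipped with probability `label_noise`
(default 5%). Two toxicophores rather than three keep the per-bit
prevalence (8.35%) clear of the 5% near-zero-variance cleaning boundary,
so the causal bits cannot be silently deleted by sampling variance.
Each set bit emits four characteristic fragment peaks from a fixed
per-bit table (seeded hash into 50–500 Da, intensities 0.3–1.0) with
0.01 Da Gaussian jitter, plus one uniform noise peak; compounds sharing
bits therefore share peaks, creating the spectrum↔structure correlation
the networking approach assumes. Precursor m/z is a deterministic
function of the bit pattern, placed above the fragment range. All draws
are indexed by (seed, compound index) or per-bit seeds, so generation is
order-independent and platform-stable.

Not emulated: real fragmentation chemistry, isotope patterns, adduct
diversity, retention behavior, intensity-dependent noise, and the
many-to-one degeneracy of real substructure→fragment relationships. A
green recovery test therefore establishes that the algorithms recover the
structure this world actually contains — not field performance on
LC/HRMS data, which the source datasets (commercial spectral libraries,
trained neural similarity) are needed to assess.

Label noise matters more than it may look: a flipped label is unrankable
by any method, so 5% flips cap fingerprint CV ROC-AUC near 0.89 and
LOO-network mROC-AUC near 0.79 in this world. The recovery suite
accordingly runs the explicitly low-noise configuration
(`label_noise=0.02`), where the measured ceilings are 0.94–0.95 and
0.92–0.98 respectively.

Feature tables are built directly in the interiors of the fate bands
(persistent r ∈ [0.85, 1.15], TP r ∈ [1.6, 2.5], other r ∈ [0.3, 0.7]),
with exactly round(n·fraction) features per stratum, so reclassification
is exact by construction; default strata proportions mirror a realistic
wastewater case (40 persistent and 153 transformation products per 968
usable features).

## Thresholds at recall, at desk scale

The 90%-recall decision threshold is an empirical quantile of the
training actives' scores. With m actives in the evaluation set its true
exceedance concentrates around k/(m+1) where k = ⌈0.9·m⌉ — biased a few
points below the target for small m, with Beta-scale noise. The
end-to-end tests therefore derive thresholds from a 300-compound world
and measure transfer recall on a 1000-compound held-out world; smaller
evaluation sets make the −0.05 recall tolerance a coin flip, which is a
property of quantile estimation, not of the prioritization logic.

## Known limitations

- Greedy peak matching is not optimal assignment; scores can be slightly
  below the true cosine on conflicting candidates.
- The pairwise similarity matrix is dense O(n²); the package targets
  desk-scale compound sets (10²–10⁴), not spectral-library scale.
- Conformal validity is marginal per class, not conditional on feature
  values; efficiency depends entirely on the base model.
- Model serialization uses pickle and is not safe against untrusted
  files.
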