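# edscreen

Toxicity-based prioritization of LC/HRMS features for non-targeted
screening of complex environmental mixtures.

Environmental water samples contain thousands of detectable features —
exact mass, retention time, and often an MS² spectrum — of which only a
tiny fraction can be structurally identified. When the concern is
endocrine-disrupting activity, it pays to decide *which* features deserve
identification effort before any structure is assigned. `edscreen`
implements three complementary frameworks for that decision, evaluates
them under a common set of metrics, and applies them to
influent/effluent wastewater feature tables.

## The three frameworks

**Molecular networking (MN).** Every MS² spectrum is a node; edges connect
pairs whose spectral similarity (greedy or modified cosine at 0.2 Da peak
tolerance, or an externally computed score) passes a threshold, optionally
keeping only each node's six most similar partners. A node's probability
of activity is voted from its direct neighbors, by majority

> p = (number of active neighbors) / (number of neighbors)

or weighted by edge similarity

> p = Σ similarity to active neighbors / Σ similarity to all neighbors.

Because raising the similarity threshold disconnects nodes, evaluation
uses *modified* rates that keep unconnected compounds in the
denominators,

> mTPR = TP / (TP + FN + NCP),  mFPR = FP / (FP + TN + NCN),

where NCP/NCN count network-unconnected positives/negatives; the area
under the (mFPR, mTPR) curve — the mROC-AUC — drives hyperparameter
selection (similarity metric, threshold 0.0–0.9, edge filtering, voting
scheme) via leave-one-out cross-validation.

**Mondrian conformal prediction (CP).** A random-forest base model is
trained on feature vectors of similarities to all training compounds; a
held-out calibration set turns its probabilities into per-class p-values,

> p_c = (#{α_cal(c) ≥ α_query} + 1) / (n_cal(c) + 1),  α = 1 − P̂(true class),

so prediction sets at significance ε carry a per-class error guarantee of
ε under exchangeability — robust to the heavy class imbalance of toxicity
panels (3–16% active).

**Fingerprint classifier (FP).** Binary substructure fingerprints are
cleaned (zero-variance, near-zero-variance, and highly correlated bits
removed) and fed to a gradient-boosted tree classifier tuned by randomized
search under stratified cross-validation.

The frameworks are compared by the false positive rate at fixed recall
(FPR at TPR = 0.5 and 0.9) — the direct measure of wasted identification
workload. For wastewater screening, features are first triaged by their
influent→effluent intensity ratio into *persistent* (within ±20%),
*transformation product* (≥50% increase), or other, then called
active/inactive by each approach at its 90%-recall threshold, and
tabulated by exact agreement (UpSet-style consensus).

A seeded synthetic-data module generates compounds with hidden
toxicophore bits, spectra correlated with their fingerprints, and
influent/effluent feature tables, so the whole pipeline is testable
without any external data.

## Worked example

The end-to-end synthetic demo trains all three approaches, derives
90%-recall thresholds, and prioritizes a 400-feature influent/effluent
table:

```
$ edscreen prioritize --seed 1
{
  "n_features": 400,
  "n_persistent": 17,
  "n_transformation_product": 63,
  "n_of_interest": 80,
  "consensus_all_three": 32,
  "consensus_none": 0,
  "n_unavailable": 6,
  "recall_at_threshold": {
    "MN": 0.9130434782608695,
    "CP": 1.0,
    "FP": 1.0
  },
  "mn_threshold": 0.3,
  "mn_voting": "weighted"
}
```

Of 400 features, 17 are persistent and 63 are transformation products (80
features of interest). All three approaches agree that 32 of them are
potentially active; 6 could not be scored by the fingerprint model
(no predictable fingerprint); every approach meets the 90% recall
constraint on its training evaluation, with the optimized network using a
0.3 similarity threshold and weighted voting.

Other entry points: `edscreen spectra` (read/clean/quality-filter MSP or
MGF files), `edscreen similarity`, `edscreen network`, `edscreen
evaluate`, `edscreen conformal`, `edscreen fpmodel`, and `edscreen synth`
(write a synthetic preset to disk). The library API mirrors the CLI;
see the module docstrings in `src/edscreen/`.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch — the full synthetic wastewater prioritization above — and writes
its results file:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`; the run takes well under a minute on
one CPU.
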