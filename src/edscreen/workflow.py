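"""End-to-end orchestration of the three prioritization approaches.

``train_approaches`` builds, from one synthetic compound world, the three
predictors the package compares:

* **MN** — molecular networking: the similarity threshold is optimized by
  leave-one-out mROC-AUC on the training compounds; a query is scored by
  majority vote over its above-threshold neighbors among the training
  spectra (0 when it connects to nothing).
* **CP** — Mondrian conformal prediction: a random-forest base model on
  similarity-to-training-set feature vectors; a query is scored by its
  active-class p-value.
* **FP** — the fingerprint classifier: gradient-boosted trees on cleaned
  binary fingerprints; a query is scored by its predicted probability.

Each approach carries a training evaluation (scores plus labels on data not
used to fit it) from which a decision threshold at a target recall is
derived; ``wastewater_demo`` then pushes a synthetic influent/effluent
feature table through fate filtering, per-approach calls at 90% recall, and
the consensus count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import conformal as _conformal
from . import fpmodel as _fpmodel
from . import network as _network
from . import prioritize as _prioritize
from . import similarity as _similarity
from . import spectra as _spectra
from . import synthdata as _synthdata
from .network import NodePrediction

__all__ = ["train_approaches", "wastewater_demo", "TrainedApproaches"]

APPROACHES = ("MN", "CP", "FP")

DEFAULT_GRID = tuple(
    _network.NetworkConfig(threshold=t / 10, voting=v)
    for t in range(0, 10) for v in ("majority", "weighted")
)


def _as_predictions(ids: Sequence[str], scores: Sequence[float]) -> list[NodePrediction]:
    return [NodePrediction(i, float(s), True) for i, s in zip(ids, scores)]


@dataclass
class TrainedApproaches:
    """The three fitted predictors plus their training evaluations."""

    train_compounds: list
    test_compounds: list
    matrix: _similarity.SimilarityMatrix
    mn_config: _network.NetworkConfig
    cp_model: _conformal.ConformalModel
    fp_model: _fpmodel.FingerprintModel
    training_eval: dict[str, tuple[list[NodePrediction], dict[str, int]]]
    sim_config: _similarity.SimilarityConfig

    def mn_score(self, spectrum: _spectra.Spectrum | None) -> float | None:
        """Majority-vote probability against the training network."""
        if spectrum is None:
            return None
        cfg = self.mn_config
        n_active = n_total = 0
        score = _similarity.greedy_cosine if \
            self.sim_config.metric == "greedy_cosine" else _similarity.modified_cosine
        for c in self.train_compounds:
            s = score(spectrum, c.spectrum, self.sim_config.mz_tolerance)
            if s >= cfg.threshold:
                n_total += 1
                n_active += self._label(c)
        return n_active / n_total if n_total else 0.0

    def cp_score(self, spectrum: _spectra.Spectrum | None) -> float | None:
        """Active-class conformal p-value from similarity features."""
        if spectrum is None:
            return None
        score = _similarity.greedy_cosine if \
            self.sim_config.metric == "greedy_cosine" else _similarity.modified_cosine
        x = np.array([score(spectrum, c.spectrum, self.sim_config.mz_tolerance)
                      for c in self.train_compounds])
        return _conformal.p_value(self.cp_model, x, 1)

    def fp_score(self, fingerprint) -> float | None:
        if fingerprint is None:
            return None
        fp = _fpmodel.FingerprintMatrix(
            ["query"], np.asarray(fingerprint)[None, :])
        return float(_fpmodel.predict_proba(self.fp_model, fp)[0])

    @staticmethod
    def _label(c) -> int:
        return c.label_binary("synthetic_assay")

    def feature_predictors(self) -> dict[str, Callable]:
        return {
            "MN": lambda f: self.mn_score(f.spectrum),
            "CP": lambda f: self.cp_score(f.spectrum),
            "FP": lambda f: self.fp_score(f.fingerprint),
        }


def train_approaches(
    seed: int = 0,
    n_compounds: int = 150,
    grid: Sequence[_network.NetworkConfig] = DEFAULT_GRID,
    n_trials: int = 8,
    test_fraction: float = 0.25,
) -> TrainedApproaches:
    """Fit MN, CP and FP on one synthetic compound world.

    MN's training evaluation is its leave-one-out prediction on the
    training compounds; CP and FP are evaluated on the held-out test split
    so their recall thresholds are not optimistic.
    """
    cfg = _synthdata.SynthConfig(n_compounds=n_compounds, seed=seed)
    compounds, _ = _synthdata.generate_dataset(cfg)
    train, test = _spectra.stratified_split(
        compounds, test_fraction, "synthetic_assay", seed=seed)
    sim_cfg = _similarity.SimilarityConfig(metric="greedy_cosine")
    matrix = _similarity.pairwise_matrix(train, sim_cfg)
    labels_train = {c.compound_id: c.label_binary("synthetic_assay") for c in train}
    labels_test = {c.compound_id: c.label_binary("synthetic_assay") for c in test}

    ranked = _network.optimize_hyperparams(
        {"greedy_cosine": matrix}, labels_train, grid)
    mn_config, _ = ranked[0]
    mn_eval = _network.loo_predict(matrix, labels_train, mn_config)

    # CP: similarity-to-training-set features
    train_ids = [c.compound_id for c in train]
    X_train = np.array([
        _conformal.similarity_features(c.compound_id, matrix, train_ids)
        for c in train])
    y_train = np.array([labels_train[c.compound_id] for c in train])
    cp_model = _conformal.fit_icp(
        X_train, y_train, calibration_fraction=0.25, seed=seed,
        feature_ids=train_ids)

    fp_train = _fpmodel.FingerprintMatrix(
        train_ids, np.array([c.fingerprint for c in train]))
    cleaned, report = _fpmodel.clean_features(fp_train)
    fp_model = _fpmodel.train_classifier(
        cleaned, y_train, n_trials=n_trials, seed=seed, report=report)

    approaches = TrainedApproaches(
        train_compounds=train, test_compounds=test, matrix=matrix,
        mn_config=mn_config, cp_model=cp_model, fp_model=fp_model,
        training_eval={}, sim_config=sim_cfg)

    test_ids = [c.compound_id for c in test]
    cp_scores = [approaches.cp_score(c.spectrum) for c in test]
    fp_scores = [approaches.fp_score(c.fingerprint) for c in test]
    approaches.training_eval = {
        "MN": (mn_eval, labels_train),
        "CP": (_as_predictions(test_ids, cp_scores), labels_test),
        "FP": (_as_predictions(test_ids, fp_scores), labels_test),
    }
    return approaches


def wastewater_demo(
    seed: int = 0,
    recall_target: float = 0.9,
    n_features: int = 400,
    fraction_persistent: float = 40 / 968,
    fraction_tp: float = 153 / 968,
    fingerprint_missing_rate: float = 0.1,
) -> dict:
    """Synthetic end-to-end run: fate filtering, three-way calls, consensus.

    Feature strata default to the case-study proportions (40 persistent and
    153 transformation products out of 968 features with usable spectra).
    A fraction of features lacks a fingerprint, emulating compounds whose
    fingerprints cannot be predicted from their spectra.
    """
    approaches = train_approaches(seed=seed)
    cfg = _synthdata.SynthConfig(seed=seed + 1)
    features = _synthdata.generate_feature_table(
        n_features, fraction_persistent, fraction_tp, cfg)
    fate = {f.feature_id: _prioritize.classify_fate(f) for f in features}
    of_interest = [f for f in features
                   if fate[f.feature_id] != "other"]

    # attach chemistry: each feature of interest is a fresh compound from
    # the same world; some have no predictable fingerprint
    chem_cfg = _synthdata.SynthConfig(
        n_compounds=len(of_interest), seed=seed + 2)
    chem, _ = _synthdata.generate_dataset(chem_cfg)
    rng = np.random.default_rng([seed, 77])
    for f, c in zip(of_interest, chem):
        f.spectrum = c.spectrum
        f.fingerprint = (None if rng.random() < fingerprint_missing_rate
                         else c.fingerprint)

    _prioritize.prioritize_features(
        of_interest, approaches.feature_predictors(), recall_target,
        approaches.training_eval)
    table = _prioritize.consensus(of_interest, list(APPROACHES))

    def _recall(name: str) -> float:
        preds, labels = approaches.training_eval[name]
        thr = _prioritize.threshold_at_recall(preds, labels, recall_target)
        y = np.array([labels[p.compound_id] for p in preds])
        s = np.array([p.probability if p.connected else 0.0 for p in preds])
        return float(((s >= thr) & (y == 1)).sum() / (y == 1).sum())

    counts = dict(zip(table["membership"], table["count"]))
    summary = {
        "n_features": n_features,
        "n_persistent": sum(v == "persistent" for v in fate.values()),
        "n_transformation_product": sum(
            v == "transformation_product" for v in fate.values()),
        "n_of_interest": len(of_interest),
        "consensus_all_three": int(counts.get("MN&CP&FP", 0)),
        "consensus_none": int(counts.get("(none)", 0)),
        "n_unavailable": int(counts.get("unavailable", 0)),
        "recall_at_threshold": {a: _recall(a) for a in APPROACHES},
        "mn_threshold": approaches.mn_config.threshold,
        "mn_voting": approaches.mn_config.voting,
    }
    return {"summary": summary, "consensus": table, "features": of_interest,
            "approaches": approaches}
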