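"""Wastewater feature-fate classification and multi-approach consensus.

Features detected in paired influent/effluent samples are first triaged by
their intensity ratio r = effluent / influent: *persistent* when the change
stays within +-20% (0.8 <= r <= 1.2), a *transformation product* when the
effluent intensity is at least 50% higher (r >= 1.5), otherwise *other*.
Features of interest are then scored by each prioritization approach
(molecular networking, conformal prediction, fingerprint model); a
feature is called active by an approach when its score reaches the decision
threshold that approach needs to achieve a target recall (typically 90%) on
its training evaluation. Approaches that cannot score a feature — no
usable spectrum, no predictable fingerprint — mark it *unavailable*, which
is tabulated separately from *inactive* in the consensus counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from . import metrics as _metrics
from .network import NodePrediction
from .spectra import Spectrum

__all__ = [
    "FeatureRecord",
    "classify_fate",
    "consensus",
    "prioritize_features",
    "threshold_at_recall",
]

FATES = ("persistent", "transformation_product", "other")
PREDICTION_STATES = ("active", "inactive", "unavailable")


@dataclass
class FeatureRecord:
    """One LC/HRMS feature with influent/effluent intensities."""

    feature_id: str
    precursor_mz: float
    rt: float
    intensity_influent: float
    intensity_effluent: float
    spectrum: Spectrum | None = None
    fingerprint: object | None = None
    predictions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in (self.intensity_influent, self.intensity_effluent):
            if not (v == v and abs(v) != float("inf")) or v < 0:
                raise ValueError(f"{self.feature_id}: invalid intensity {v}")


def classify_fate(f: FeatureRecord) -> str:
    """Persistent / transformation product / other, from the intensity ratio.

    Band boundaries are inclusive. A feature absent from the influent but
    present in the effluent is a transformation product; one removed
    entirely (effluent 0) is 'other'.
    """
    inf, eff = f.intensity_influent, f.intensity_effluent
    if inf == 0 and eff == 0:
        raise ValueError(f"{f.feature_id}: both intensities are zero")
    if inf == 0:
        return "transformation_product"
    r = eff / inf
    if 0.8 <= r <= 1.2:
        return "persistent"
    if r >= 1.5:
        return "transformation_product"
    return "other"


def threshold_at_recall(
    training_preds: Sequence[NodePrediction],
    training_labels: Mapping[str, int],
    recall_target: float,
) -> float:
    """Decision threshold achieving the target recall on a training
    evaluation; raises when the recall is unreachable."""
    point = _metrics.fpr_at_tpr(training_preds, training_labels, recall_target)
    if not point.reachable:
        raise ValueError(
            f"recall {recall_target} unreachable "
            f"(max achievable TPR {point.achieved_tpr:.3f})")
    return point.threshold


def prioritize_features(
    features: Sequence[FeatureRecord],
    predictors: Mapping[str, Callable[[FeatureRecord], float | None]],
    recall_target: float,
    training_eval: Mapping[str, tuple[Sequence[NodePrediction], Mapping[str, int]]],
) -> list[FeatureRecord]:
    """Fill each feature's per-approach active/inactive/unavailable call.

    Each approach's decision threshold is derived from its own training
    evaluation as the largest threshold reaching ``recall_target``; a
    feature is active for that approach iff its score >= the threshold. A
    predictor returning None marks the feature unavailable.
    """
    thresholds = {}
    for name in predictors:
        if name not in training_eval:
            raise KeyError(f"no training evaluation for approach {name!r}")
        preds, labels = training_eval[name]
        try:
            thresholds[name] = threshold_at_recall(preds, labels, recall_target)
        except ValueError as exc:
            raise ValueError(f"approach {name!r}: {exc}") from exc
    for f in features:
        for name, predictor in predictors.items():
            score = predictor(f)
            if score is None:
                f.predictions[name] = "unavailable"
            else:
                f.predictions[name] = (
                    "active" if score >= thresholds[name] else "inactive")
    return list(features)


def consensus(features: Sequence[FeatureRecord],
              approaches: Sequence[str]) -> pd.DataFrame:
    """UpSet-style exact-subset counts of active calls.

    For each subset S of ``approaches``, counts features called active by
    exactly the approaches in S (the empty subset collects features active
    by none). Features with any unavailable prediction form a separate
    'unavailable' stratum; the counts partition the feature list.
    """
    if not approaches:
        raise ValueError("approaches must be nonempty")
    for f in features:
        for a in approaches:
            if f.predictions.get(a, "unavailable") not in PREDICTION_STATES:
                raise ValueError(
                    f"{f.feature_id}: bad prediction {f.predictions.get(a)!r}")
            if a not in f.predictions:
                raise KeyError(f"{f.feature_id}: no prediction for {a!r}")
    rows: dict[str, int] = {}
    n_appr = len(approaches)
    for mask in range(2 ** n_appr):
        member = "&".join(a for k, a in enumerate(approaches) if mask >> k & 1)
        rows[member or "(none)"] = 0
    rows["unavailable"] = 0
    for f in features:
        states = [f.predictions[a] for a in approaches]
        if "unavailable" in states:
            rows["unavailable"] += 1
            continue
        member = "&".join(a for a, s in zip(approaches, states) if s == "active")
        rows[member or "(none)"] += 1
    df = pd.DataFrame(
        {"membership": list(rows), "count": list(rows.values())})
    return df.sort_values("count", ascending=False, kind="stable").reset_index(drop=True)
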