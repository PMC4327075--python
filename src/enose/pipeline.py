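"""End-to-end synthetic study: simulate, featurize, classify.

Reproduces the structure of the healthy-vs-sour-skin proof of concept:
simulate the full design (2 groups x 8 bulbs x 3 sessions/day x 2 days =
96 measurements), apply differential baseline correction, build area
smellprints, split half/half into training and validation, fit LDA on the
training half and report the validation confusion table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import (
    ClassificationReport,
    PcaResult,
    build_smellprints,
    confusion_from_labels,
    confusion_metrics,
    lda_fit,
    lda_predict,
    pca_scores,
    split_train_validation,
)
from .device import CycleConfig, FeatureSelection, characterization_config, default_array
from .features import featurize
from .simulator import (
    ExperimentDesign,
    SensorGasModel,
    healthy_onion_gas,
    onion_model,
    simulate_experiment,
    sour_skin_design,
    sour_skin_gas,
)

__all__ = ["StudyResult", "run_sour_skin_study"]


@dataclass(frozen=True)
class StudyResult:
    """Everything the synthetic disease-detection study produces."""

    labels: np.ndarray  # one label per measurement
    smellprints: np.ndarray  # n x p feature matrix
    train_idx: np.ndarray
    valid_idx: np.ndarray
    report: ClassificationReport  # validation confusion + rates
    pca: PcaResult

    @property
    def validation_accuracy_pct(self) -> float:
        return self.report.correct_rate_pct


def run_sour_skin_study(
    seed: int,
    *,
    design: ExperimentDesign | None = None,
    model: SensorGasModel | None = None,
    cycle: CycleConfig | None = None,
    feature: FeatureSelection = FeatureSelection.AREA,
    train_fraction: float = 0.5,
) -> StudyResult:
    """Run the full synthetic healthy-vs-diseased classification study."""
    design = design or sour_skin_design()
    model = model or onion_model()
    cycle = cycle or characterization_config()
    array = default_array()
    groups = {"healthy": healthy_onion_gas(), "sour_skin": sour_skin_gas()}
    groups = {g: groups[g] for g in design.groups}

    measurements = simulate_experiment(
        groups, design.replicates_per_group, model, cycle, seed, array=array
    )
    labelled = [
        (label, featurize(curves, cycle, correct_baseline=True))
        for label, curves in measurements
    ]
    prints = build_smellprints(labelled, feature)
    X = np.vstack([sp.values for sp in prints])
    y = np.array([sp.label for sp in prints])

    train_idx, valid_idx = split_train_validation(len(y), train_fraction, seed)
    lda = lda_fit(X[train_idx], y[train_idx])
    y_pred = lda_predict(lda, X[valid_idx])
    confusion = confusion_from_labels(y[valid_idx], y_pred, lda.classes)
    return StudyResult(
        labels=y,
        smellprints=X,
        train_idx=train_idx,
        valid_idx=valid_idx,
        report=confusion_metrics(confusion),
        pca=pca_scores(X),
    )
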