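"""End-to-end study pipeline: cohort -> networks -> measures -> statistics
-> classification.

Each stage is a thin composition of the module operations, so the whole
analysis is reproducible from a :class:`~neurocoh.synth.CohortConfig` and
one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bands import DEFAULT_BANDS, BandDefinition
from .classify import ClassifierReport, build_feature_table, evaluate_models
from .coherence import EstimatorConfig, subject_band_networks
from .graph import GraphMetricConfig, compute_all
from .preprocess import extract_epochs
from .stats import GroupComparisonResults, compare_clinical, compare_measures, \
    measures_to_frame
from .synth import CohortConfig, EEGRecording, generate_cohort

__all__ = ["StudyConfig", "StudyResults", "subject_measures",
           "cohort_measures", "run_study"]


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of the full pipeline in one place."""

    cohort: CohortConfig = CohortConfig()
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    estimator: EstimatorConfig = EstimatorConfig()
    graph: GraphMetricConfig = GraphMetricConfig()
    n_epochs: int = 10
    epoch_len: float = 2.0
    min_gap: float = 1.0
    alpha: float = 0.05
    n_perm: int = 1000
    stats_seed: int = 0
    classify: bool = True
    classify_seed: int = 0


@dataclass
class StudyResults:
    """Everything the pipeline computes for one cohort."""

    measures: pd.DataFrame                 # long format, 13 x 5 per subject
    comparisons: GroupComparisonResults
    clinical: pd.DataFrame
    clinical_tests: pd.DataFrame
    classifier_report: ClassifierReport | None = None

    def summary(self) -> str:
        parts = [self.comparisons.summary()]
        if self.classifier_report is not None:
            parts.append("")
            parts.append(self.classifier_report.summary())
        return "\n".join(parts)


def subject_measures(
    rec: EEGRecording,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    estimator: EstimatorConfig = EstimatorConfig(),
    graph: GraphMetricConfig = GraphMetricConfig(),
    n_epochs: int = 10,
    epoch_len: float = 2.0,
    min_gap: float = 1.0,
) -> list:
    """Per-band graph measures for one recording (list of GraphMeasures)."""
    epochs = extract_epochs(rec, n_epochs=n_epochs, epoch_len=epoch_len,
                            min_gap=min_gap)
    nets = subject_band_networks(epochs, bands, estimator)
    return [
        compute_all(net.W, graph, band=name, subject_id=rec.subject_id,
                    group_label=rec.group_label)
        for name, net in nets.items()
    ]


def cohort_measures(
    recordings: list[EEGRecording],
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    estimator: EstimatorConfig = EstimatorConfig(),
    graph: GraphMetricConfig = GraphMetricConfig(),
    n_epochs: int = 10,
    epoch_len: float = 2.0,
    min_gap: float = 1.0,
) -> pd.DataFrame:
    """Long-format measure table for a whole cohort."""
    all_measures = []
    for rec in recordings:
        all_measures.extend(subject_measures(
            rec, bands, estimator, graph, n_epochs, epoch_len, min_gap))
    return measures_to_frame(all_measures)


def run_study(config: StudyConfig = StudyConfig()) -> StudyResults:
    """Run the full pipeline on one synthetic cohort."""
    recordings, clinical = generate_cohort(config.cohort)
    measures = cohort_measures(
        recordings, config.bands, config.estimator, config.graph,
        config.n_epochs, config.epoch_len, config.min_gap,
    )
    comparisons = compare_measures(
        measures, alpha=config.alpha, n_perm=config.n_perm,
        seed=config.stats_seed,
    )
    clinical_tests = compare_clinical(clinical.reset_index())
    report = None
    if config.classify:
        X, y = build_feature_table(clinical, measures)
        report = evaluate_models(X, y, seed=config.classify_seed)
    return StudyResults(
        measures=measures, comparisons=comparisons, clinical=clinical,
        clinical_tests=clinical_tests, classifier_report=report,
    )
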