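"""End-to-end analysis: raw counts → τ matrix → responder report."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import StudyDesign, design_from_counts, validate_counts
from .preprocess import (
    compute_fractions,
    filter_groups,
    impute_detection_limit,
    log_transform_and_average,
)
from .stats import (
    MeanPattern,
    ResponderReport,
    classify_responders,
    compute_changes,
    compute_tau,
    mean_patterns,
    summarize_tau,
)

__all__ = ["AnalysisResult", "analyze_counts"]


@dataclass(frozen=True)
class AnalysisResult:
    """Everything the analysis computes, in one place."""

    design: StudyDesign
    excluded_groups: list[str]
    censored_per_group: pd.Series
    cube: pd.DataFrame
    fractions: pd.DataFrame
    delta: pd.DataFrame
    patterns: MeanPattern
    tau: pd.DataFrame
    summary: pd.DataFrame
    report: ResponderReport


def analyze_counts(table: pd.DataFrame, threshold: float = 0.75,
                   replicate_average: str = "log", fraction_scale: str = "log10",
                   low: float = 0.4, high: float = 0.6, pooling: str = "pooled",
                   leave_one_out: bool = True, phase_order=None) -> AnalysisResult:
    """Run the full responder analysis on a long-format culture-count table.

    Chains validation, the strict >75% prevalence filter, detection-limit
    imputation, log10 transform with replicate averaging, compositional
    fractions, change profiles versus the run-in phase, leave-one-out mean
    patterns, the τ statistic, its report summary, and the percentile-based
    typical/atypical classification.
    """
    df = validate_counts(table)
    df, excluded = filter_groups(df, threshold=threshold)
    df, censored = impute_detection_limit(df)
    design = design_from_counts(df, phase_order=phase_order)
    cube = log_transform_and_average(df, design, replicate_average=replicate_average)
    fractions = compute_fractions(cube, fraction_scale=fraction_scale)
    delta = compute_changes(fractions, reference_phase=design.reference_phase)
    patterns = mean_patterns(delta)
    tau = compute_tau(delta, patterns, leave_one_out=leave_one_out)
    report = classify_responders(tau, low=low, high=high, pooling=pooling)
    return AnalysisResult(
        design=design,
        excluded_groups=excluded,
        censored_per_group=censored,
        cube=cube,
        fractions=fractions,
        delta=delta,
        patterns=patterns,
        tau=tau,
        summary=summarize_tau(tau),
        report=report,
    )
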