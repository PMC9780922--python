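"""From raw CFU counts to compositional fractions.

The preprocessing chain mirrors standard practice for culture-derived
concentration data:

1. **Prevalence filter** — keep only bacterial groups whose share of
   observations strictly above the detection limit exceeds a threshold
   (default 0.75; the comparison is strict, so exactly 75% is excluded).
2. **Detection-limit imputation** — left-censored observations are set to
   the detection limit itself, the simplest single-value substitution for
   censored culture counts.
3. **log10 transform and replicate averaging** — concentrations are
   log10-transformed and replicates averaged on the log scale (a geometric
   mean of CFU), consistent with approximately log-normal measurement noise.
4. **Fractions** — each group's share of the participant × phase total,
   computed by default on the log10 scale.

Steps are exposed both as plain functions and as scikit-learn transformers
(:class:`DetectionLimitImputer`, :class:`PrevalenceFilter`,
:class:`CompositionTransformer`) so the chain composes with
:class:`sklearn.pipeline.Pipeline`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import (
    CompletenessError,
    StudyDesign,
    ValidationError,
    design_from_counts,
    validate_counts,
)

__all__ = [
    "impute_detection_limit",
    "filter_groups",
    "log_transform_and_average",
    "compute_fractions",
    "counts_to_fractions",
    "DetectionLimitImputer",
    "PrevalenceFilter",
    "CompositionTransformer",
]


def impute_detection_limit(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Replace left-censored concentrations by their detection limit.

    Every ``cfu_per_ml`` strictly below its row's ``detection_limit`` is set
    to that limit; values at or above the limit are untouched.  Idempotent.

    Returns
    -------
    (table, censored_per_group)
        The imputed table and a per-group count of replaced observations.
    """
    df = table.copy()
    below = df["cfu_per_ml"] < df["detection_limit"]
    censored = df.loc[below].groupby("group").size().reindex(
        sorted(set(df["group"])), fill_value=0
    )
    censored.name = "n_censored"
    df.loc[below, "cfu_per_ml"] = df.loc[below, "detection_limit"]
    return df, censored


def filter_groups(table: pd.DataFrame, threshold: float = 0.75
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Drop groups with too many observations at or below the detection limit.

    A group is kept iff the proportion of its observations strictly above the
    detection limit is strictly greater than ``threshold``, pooling all
    participants, phases and replicates.  Because imputation maps censored
    values onto the limit itself (never above it), the filter gives identical
    results before or after imputation.

    Returns the filtered table and the list of excluded group ids.
    """
    if not 0 <= threshold <= 1:
        raise ValidationError("filter threshold must be a proportion in [0, 1]")
    above = table["cfu_per_ml"] > table["detection_limit"]
    frac_above = above.groupby(table["group"]).mean()
    keep = frac_above[frac_above > threshold].index
    excluded = sorted(set(table["group"]) - set(keep))
    if len(keep) == 0:
        raise ValidationError(
            "prevalence filter excluded every bacterial group; "
            "no composition can be formed"
        )
    out = table[table["group"].isin(keep)].reset_index(drop=True)
    return out, excluded


def log_transform_and_average(table: pd.DataFrame, design: StudyDesign | None = None,
                              replicate_average: str = "log") -> pd.DataFrame:
    """Build the complete participant × phase × group log10-abundance cube.

    Parameters
    ----------
    table : DataFrame
        Imputed count table (no value below its detection limit).
    design : StudyDesign, optional
        Expected layout; inferred from the table when omitted.
    replicate_average : {"log", "raw"}
        ``"log"`` averages log10 concentrations over replicates (geometric
        mean of CFU, the default); ``"raw"`` averages CFU first and then
        takes log10.

    Returns a DataFrame indexed by ``(participant_id, phase)`` with one
    column per group.  Raises :class:`CompletenessError` if any cell of the
    design has no replicate.
    """
    if replicate_average not in ("log", "raw"):
        raise ValidationError("replicate_average must be 'log' or 'raw'")
    if design is None:
        design = design_from_counts(table)
    if (table["detection_limit"] <= 1).any():
        raise ValidationError(
            "detection limits must exceed 1 CFU/ml so log10 abundances are positive"
        )
    if (table["cfu_per_ml"] < table["detection_limit"]).any():
        raise ValidationError(
            "table contains values below the detection limit; impute first"
        )
    work = table.copy()
    if replicate_average == "log":
        work["y"] = np.log10(work["cfu_per_ml"])
        cell = work.groupby(["participant_id", "phase", "group"])["y"].mean()
    else:
        cell = np.log10(work.groupby(["participant_id", "phase", "group"])["cfu_per_ml"].mean())

    full = pd.MultiIndex.from_product(
        [design.participants, design.phases, design.groups],
        names=["participant_id", "phase", "group"],
    )
    cell = cell.reindex(full)
    if cell.isna().any():
        i, p, b = cell.index[cell.isna().to_numpy()][0]
        raise CompletenessError(
            f"no replicate for participant {i}, phase {p}, group {b}"
        )
    cube = cell.unstack("group").loc[
        pd.MultiIndex.from_product([design.participants, design.phases]),
        list(design.groups),
    ]
    cube.index.names = ["participant_id", "phase"]
    return cube


def compute_fractions(cube: pd.DataFrame, fraction_scale: str = "log10") -> pd.DataFrame:
    """Convert an abundance cube into compositional fractions.

    With ``fraction_scale="log10"`` (default) each group's fraction is its
    log10 abundance divided by the participant × phase total of log10
    abundances; ``"raw"`` uses fractions of the back-transformed CFU
    concentrations instead.  Every row sums to 1.
    """
    if fraction_scale not in ("log10", "raw"):
        raise ValidationError("fraction_scale must be 'log10' or 'raw'")
    values = cube if fraction_scale == "log10" else 10.0 ** cube
    if (values.to_numpy() <= 0).any():
        raise ValidationError("abundance cube must be strictly positive")
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[(totals <= 0).to_numpy()][0]
        raise ValidationError(f"non-positive composition total at {bad}")
    return values.div(totals, axis=0)


def counts_to_fractions(table: pd.DataFrame, threshold: float = 0.75,
                        replicate_average: str = "log",
                        fraction_scale: str = "log10",
                        phase_order=None):
    """Run the full preprocessing chain on a raw count table.

    Returns ``(fractions, info)`` where ``info`` records the excluded groups,
    per-group censoring counts, and the inferred :class:`StudyDesign` of the
    retained groups.
    """
    df = validate_counts(table)
    df, excluded = filter_groups(df, threshold=threshold)
    df, censored = impute_detection_limit(df)
    design = design_from_counts(df, phase_order=phase_order)
    cube = log_transform_and_average(df, design, replicate_average=replicate_average)
    fractions = compute_fractions(cube, fraction_scale=fraction_scale)
    info = {"excluded_groups": excluded, "censored_per_group": censored, "design": design}
    return fractions, info


class DetectionLimitImputer(TransformerMixin, BaseEstimator):
    """Sklearn transformer wrapping :func:`impute_detection_limit`.

    Attributes
    ----------
    censored_per_group_ : pandas.Series
        Number of observations replaced by the detection limit, per group.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = validate_counts(X)
        _, self.censored_per_group_ = impute_detection_limit(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out, _ = impute_detection_limit(validate_counts(X))
        return out


class PrevalenceFilter(TransformerMixin, BaseEstimator):
    """Sklearn transformer wrapping :func:`filter_groups`.

    Parameters
    ----------
    threshold : float, default 0.75
        A group is kept iff its proportion of observations strictly above
        the detection limit strictly exceeds this value.

    Attributes
    ----------
    included_groups_ : list of str
    excluded_groups_ : list of str
    """

    def __init__(self, threshold: float = 0.75):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        X = validate_counts(X)
        kept, self.excluded_groups_ = filter_groups(X, threshold=self.threshold)
        self.included_groups_ = sorted(set(kept["group"]))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = validate_counts(X)
        return X[X["group"].isin(self.included_groups_)].reset_index(drop=True)


class CompositionTransformer(TransformerMixin, BaseEstimator):
    """Counts → compositional fraction matrix, as one sklearn transformer.

    Chains the prevalence filter, detection-limit imputation, log10
    transform with replicate averaging, and fraction computation.

    Parameters
    ----------
    threshold : float, default 0.75
        Prevalence-filter threshold (strict).
    replicate_average : {"log", "raw"}, default "log"
    fraction_scale : {"log10", "raw"}, default "log10"
    phase_order : sequence of str, optional
        Explicit phase ordering (reference first) for non-canonical labels.

    Attributes
    ----------
    design_ : StudyDesign
        Layout of the retained data.
    excluded_groups_ : list of str
    censored_per_group_ : pandas.Series
    """

    def __init__(self, threshold: float = 0.75, replicate_average: str = "log",
                 fraction_scale: str = "log10", phase_order=None):
        self.threshold = threshold
        self.replicate_average = replicate_average
        self.fraction_scale = fraction_scale
        self.phase_order = phase_order

    def fit(self, X: pd.DataFrame, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        fractions, info = counts_to_fractions(
            X,
            threshold=self.threshold,
            replicate_average=self.replicate_average,
            fraction_scale=self.fraction_scale,
            phase_order=self.phase_order,
        )
        self.design_ = info["design"]
        self.excluded_groups_ = info["excluded_groups"]
        self.censored_per_group_ = info["censored_per_group"]
        return fractions

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        df = validate_counts(X)
        df = df[df["group"].isin(self.design_.groups)].reset_index(drop=True)
        df, _ = impute_detection_limit(df)
        design = design_from_counts(df, phase_order=self.phase_order)
        cube = log_transform_and_average(df, design,
                                         replicate_average=self.replicate_average)
        return compute_fractions(cube, fraction_scale=self.fraction_scale)
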