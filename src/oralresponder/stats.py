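"""Change profiles, the τ concordance statistic, and responder classification.

For participant *i*, phase *p* and bacterial group *b*, let ``f[i,p,b]`` be
the group's compositional fraction.  The change profile versus the run-in
reference phase is ``delta[i,p,b] = f[i,p,b] - f[i,ref,b]`` and the cohort
mean pattern is ``mu[p,b] = mean_i delta[i,p,b]``.  The concordance of an
individual with the cohort is the mean squared distance

    tau[i,p] = (1/B) * sum_b (delta[i,p,b] - mu_loo[i,p,b])**2

where ``mu_loo`` is the leave-one-out mean pattern (participant *i* omitted),
which avoids the optimistic bias of comparing a profile against a mean that
contains it.  Small τ means the participant tracks the cohort trend.

Participants are classified from the distribution of τ: *typical* if their
τ is below the 40% percentile in **every** intervention phase, *atypical* if
above the 60% percentile in every phase, *intermediate* otherwise.
Percentiles are pooled over all participant × phase values by default and
use linear interpolation of order statistics (``h = 1 + (n-1)p``).
Inequalities are strict, so ties at a cutpoint fall to intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import ValidationError

__all__ = [
    "MeanPattern",
    "ResponderReport",
    "compute_changes",
    "mean_patterns",
    "compute_tau",
    "summarize_tau",
    "percentile_cutpoints",
    "assign_bands",
    "classify_responders",
    "ResponderClassifier",
]


@dataclass(frozen=True)
class MeanPattern:
    """Cohort mean change pattern and its leave-one-out variants.

    Attributes
    ----------
    mu : DataFrame, phase × group
        Full-cohort mean change profile per phase.
    mu_loo : DataFrame, (participant, phase) × group
        Mean profile with the indexed participant omitted.
    n_participants : int
    """

    mu: pd.DataFrame
    mu_loo: pd.DataFrame
    n_participants: int


@dataclass(frozen=True)
class ResponderReport:
    """Output of :func:`classify_responders`.

    ``labels`` maps each participant to ``"typical"``, ``"atypical"`` or
    ``"intermediate"``; ``bands`` puts every τ value into one of five
    percentile bands (1 = below the 20% cutpoint ... 5 = above the 80%);
    ``cutpoints`` holds the pooled percentile values used.
    """

    labels: pd.Series
    bands: pd.DataFrame
    cutpoints: pd.Series
    tau: pd.DataFrame
    low: float
    high: float
    pooling: str

    @property
    def typical(self) -> list[str]:
        return sorted(self.labels.index[self.labels == "typical"])

    @property
    def atypical(self) -> list[str]:
        return sorted(self.labels.index[self.labels == "atypical"])


def _phases_in_order(index: pd.MultiIndex) -> list[str]:
    return list(dict.fromkeys(index.get_level_values("phase")))


def compute_changes(fractions: pd.DataFrame,
                    reference_phase: str | None = None) -> pd.DataFrame:
    """Change profiles versus the run-in reference phase.

    ``fractions`` is indexed by ``(participant_id, phase)`` with one column
    per group; the reference phase defaults to the first phase appearing in
    the index.  Returns the same layout restricted to non-reference phases.
    Each row sums to 0 because fractions sum to 1.
    """
    phases = _phases_in_order(fractions.index)
    if reference_phase is None:
        reference_phase = phases[0]
    if reference_phase not in phases:
        raise ValidationError(f"reference phase {reference_phase!r} absent from data")
    ref = fractions.xs(reference_phase, level="phase")
    participants = fractions.index.get_level_values("participant_id")
    missing = sorted(set(participants) - set(ref.index))
    if missing:
        raise ValidationError(
            "participant(s) missing the reference phase: " + ", ".join(missing)
        )
    delta = fractions - ref.loc[participants].to_numpy()
    keep = fractions.index.get_level_values("phase") != reference_phase
    return delta.loc[keep]


def mean_patterns(delta: pd.DataFrame) -> MeanPattern:
    """Full and leave-one-out mean change patterns.

    The leave-one-out mean for participant *i* is computed from the identity
    ``mu_loo[i] = (I*mu - delta_i) / (I - 1)``, which equals the mean over
    the other I−1 participants exactly.
    """
    participants = list(dict.fromkeys(delta.index.get_level_values("participant_id")))
    n = len(participants)
    if n < 2:
        raise ValidationError("leave-one-out requires at least two participants")
    mu = delta.groupby(level="phase", sort=False).mean()
    mu_rows = mu.loc[delta.index.get_level_values("phase")].to_numpy()
    loo = (n * mu_rows - delta.to_numpy()) / (n - 1)
    mu_loo = pd.DataFrame(loo, index=delta.index, columns=delta.columns)
    return MeanPattern(mu=mu, mu_loo=mu_loo, n_participants=n)


def compute_tau(delta: pd.DataFrame, patterns: MeanPattern | None = None,
                leave_one_out: bool = True) -> pd.DataFrame:
    """The τ concordance statistic, participant × phase.

    ``tau[i,p]`` is the mean over groups of the squared difference between
    participant *i*'s change profile and the (leave-one-out, by default)
    cohort mean pattern in phase *p*.
    """
    if delta.shape[1] == 0:
        raise ValidationError("no bacterial groups: tau is undefined")
    if patterns is None:
        patterns = mean_patterns(delta)
    if leave_one_out:
        center = patterns.mu_loo.to_numpy()
    else:
        center = patterns.mu.loc[delta.index.get_level_values("phase")].to_numpy()
    sq = (delta.to_numpy() - center) ** 2
    tau_long = pd.Series(sq.mean(axis=1), index=delta.index, name="tau")
    tau = tau_long.unstack("phase")
    participants = list(dict.fromkeys(delta.index.get_level_values("participant_id")))
    return tau.loc[participants, _phases_in_order(delta.index)]


def summarize_tau(tau: pd.DataFrame, rounding: int | None = 3) -> pd.DataFrame:
    """Report-style summary of a τ matrix (phases as rows).

    Rows are the intervention phases plus an ``"all"`` row of per-participant
    means across phases; the ``mean``/``sd`` columns hold the across-
    participant mean and sample (n−1) standard deviation per phase, and — in
    the ``"all"`` row — the mean and sample SD of all participant × phase
    values.  ``rounding`` (default 3 decimals, as conventional for display)
    may be ``None`` for full precision.
    """
    if tau.size == 0:
        raise ValidationError("empty tau matrix")
    out = tau.T.copy()  # phases as rows
    out["mean"] = tau.mean(axis=0)
    out["sd"] = tau.std(axis=0, ddof=1)
    flat = tau.to_numpy().ravel()
    all_row = tau.mean(axis=1)
    all_row["mean"] = flat.mean()
    all_row["sd"] = flat.std(ddof=1)
    out.loc["all"] = all_row
    out.index.name = "phase"
    if rounding is not None:
        out = out.round(rounding)
    return out


def percentile_cutpoints(tau: pd.DataFrame,
                         probs: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
                         pooling: str = "pooled") -> pd.Series | pd.DataFrame:
    """Percentile cutpoints of the τ distribution.

    ``pooling="pooled"`` (default) computes quantiles of all participant ×
    phase values together and returns a Series indexed by probability;
    ``"per_phase"`` returns a DataFrame with one row per phase.  Quantiles
    linearly interpolate order statistics (``h = 1 + (n-1)p``).
    """
    probs = list(probs)
    if sorted(probs) != probs:
        raise ValidationError("probs must be non-decreasing")
    if tau.size == 0:
        raise ValidationError("empty tau matrix")
    if pooling == "pooled":
        q = np.quantile(tau.to_numpy().ravel(), probs, method="linear")
        return pd.Series(q, index=pd.Index(probs, name="prob"), name="cutpoint")
    if pooling == "per_phase":
        rows = {p: np.quantile(tau[p].to_numpy(), probs, method="linear")
                for p in tau.columns}
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=pd.Index(probs, name="prob"))
    raise ValidationError("pooling must be 'pooled' or 'per_phase'")


def assign_bands(tau: pd.DataFrame, cutpoints: Sequence[float]) -> pd.DataFrame:
    """Assign each τ value to a percentile band 1–5.

    Bands are right-closed: a value equal to a cutpoint falls in the lower
    band (band 1: τ ≤ q20, band 2: q20 < τ ≤ q40, ..., band 5: τ > q80).
    """
    cp = np.asarray(cutpoints, dtype=float)
    if (np.diff(cp) < 0).any():
        raise ValidationError("cutpoints must be non-decreasing")
    bands = np.searchsorted(cp, tau.to_numpy(), side="left") + 1
    return pd.DataFrame(bands, index=tau.index, columns=tau.columns)


def classify_responders(tau: pd.DataFrame, low: float = 0.4, high: float = 0.6,
                        pooling: str = "pooled",
                        band_probs: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
                        ) -> ResponderReport:
    """Classify participants as typical / atypical / intermediate responders.

    A participant is *typical* when τ is strictly below the ``low`` percentile
    of the τ distribution in every intervention phase, *atypical* when
    strictly above the ``high`` percentile in every phase, and *intermediate*
    otherwise.  With a degenerate (all-equal) τ distribution the strict
    inequalities never hold and everyone is intermediate.
    """
    if low > high:
        raise ValidationError("low percentile must not exceed high percentile")
    if tau.shape[0] < 2:
        raise ValidationError("classification requires at least two participants")
    if pooling == "pooled":
        q = percentile_cutpoints(tau, [low, high], pooling="pooled")
        q_low = pd.Series(q.iloc[0], index=tau.columns)
        q_high = pd.Series(q.iloc[1], index=tau.columns)
    elif pooling == "per_phase":
        q = percentile_cutpoints(tau, [low, high], pooling="per_phase")
        q_low, q_high = q[low], q[high]
    else:
        raise ValidationError("pooling must be 'pooled' or 'per_phase'")

    is_typical = tau.lt(q_low, axis=1).all(axis=1)
    is_atypical = tau.gt(q_high, axis=1).all(axis=1)
    labels = pd.Series("intermediate", index=tau.index, name="label")
    labels[is_typical] = "typical"
    labels[is_atypical] = "atypical"

    band_cuts = percentile_cutpoints(tau, band_probs, pooling="pooled")
    bands = assign_bands(tau, band_cuts.to_numpy())
    return ResponderReport(labels=labels, bands=bands, cutpoints=band_cuts,
                           tau=tau, low=low, high=high, pooling=pooling)


class ResponderClassifier(BaseEstimator):
    """Cohort-level responder classification from a fraction matrix.

    A scikit-learn-style estimator: ``fit`` takes the compositional fraction
    matrix (``(participant_id, phase)`` MultiIndex rows, one column per
    bacterial group, the reference phase included) and computes change
    profiles, mean patterns, τ, percentile bands and labels for the cohort
    it was fitted on — analogous to a clustering estimator exposing
    ``labels_``.

    Parameters
    ----------
    low, high : float, default 0.4 / 0.6
        Percentiles bounding the typical / atypical calls (strict).
    pooling : {"pooled", "per_phase"}, default "pooled"
        Whether percentile cutpoints pool τ over phases.
    leave_one_out : bool, default True
        Compare each participant against the leave-one-out mean pattern
        (recommended; ``False`` uses the plug-in full mean).
    reference_phase : str, optional
        Run-in phase; defaults to the first phase in the index.
    band_probs : sequence of float
        Percentiles of the five-band display scale.

    Attributes
    ----------
    delta_ : DataFrame
        Change profiles versus the reference phase.
    patterns_ : MeanPattern
    tau_ : DataFrame, participant × phase
    cutpoints_ : Series
    bands_ : DataFrame
    labels_ : Series of {"typical", "atypical", "intermediate"}
    report_ : ResponderReport
    summary_ : DataFrame
        Report-style τ summary with phase means/SDs (3 decimals).
    """

    def __init__(self, low: float = 0.4, high: float = 0.6,
                 pooling: str = "pooled", leave_one_out: bool = True,
                 reference_phase: str | None = None,
                 band_probs: Sequence[float] = (0.2, 0.4, 0.6, 0.8)):
        self.low = low
        self.high = high
        self.pooling = pooling
        self.leave_one_out = leave_one_out
        self.reference_phase = reference_phase
        self.band_probs = band_probs

    def fit(self, X: pd.DataFrame, y=None):
        self.delta_ = compute_changes(X, reference_phase=self.reference_phase)
        self.patterns_ = mean_patterns(self.delta_)
        self.tau_ = compute_tau(self.delta_, self.patterns_,
                                leave_one_out=self.leave_one_out)
        self.report_ = classify_responders(self.tau_, low=self.low,
                                           high=self.high, pooling=self.pooling,
                                           band_probs=self.band_probs)
        self.labels_ = self.report_.labels
        self.bands_ = self.report_.bands
        self.cutpoints_ = self.report_.cutpoints
        self.summary_ = summarize_tau(self.tau_)
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.Series:
        return self.fit(X).labels_
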