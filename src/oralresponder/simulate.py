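"""Synthetic culture-count studies with planted responder behaviour.

The generator emulates a longitudinal dietary-intervention design: a cohort
of participants passes through an ordered series of diet phases (run-in
first), and in each phase the concentration of each cultivable bacterial
group is measured in a few replicates.  Concentrations are generated on the
log10(CFU/ml) scale as

    value[i,p,b,r] = baseline[b] + phase_effect[p,b]
                     + deviation_scale[i] * eta[i,p,b] + eps[i,p,b,r]

with ``eta`` standard-normal participant × phase × group deviations from the
cohort pattern and ``eps`` replicate measurement noise.  ``deviation_scale``
is the planted "typicality dial": participants with a tiny scale track the
cohort mean pattern (typical responders), those with a large scale deviate
in every phase (atypical).  The emitted table stores the raw drawn CFU
concentrations together with each group's detection limit; left-censoring
is applied downstream by the preprocessing imputer, where the study rule
lives.

Draw order is fixed (all ``eta`` first, then all ``eps``) from a single
``numpy.random.default_rng`` stream, so one seed reproduces one table
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import PHASES, StudyDesign, ValidationError

__all__ = ["SimulationConfig", "GroundTruth", "generate_dataset",
           "scenario_presets", "PRESETS"]


def _default_baseline(n_groups: int) -> tuple[float, ...]:
    # plausible culture-technique magnitudes: 10^4 .. 10^8 CFU/ml
    return tuple(np.linspace(4.0, 8.0, n_groups))


def _default_phase_effect(n_phases: int, n_groups: int) -> tuple[tuple[float, ...], ...]:
    """Deterministic diet-shift matrix: zero in the reference phase.

    Some groups trend up across all phases, some down, and an alternating
    component flips direction between phases — the qualitative mix of
    monotone and phase-specific responses seen in diet-shift cohorts.
    """
    b = np.arange(n_groups)
    trend = np.linspace(-0.4, 0.4, n_groups)
    alt = 0.15 * np.cos(np.pi * b)
    rows = [np.zeros(n_groups)]
    for k in range(1, n_phases):
        rows.append(trend * (0.6 + 0.2 * k) + ((-1) ** k) * alt)
    return tuple(tuple(r) for r in rows)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults reproduce the reference design: 11 participants, 5 phases
    (run-in + sucrose, dairy, vegetables, regular diet), ~3 replicates per
    phase, 10 disjunct bacterial groups, log-normal concentration noise and
    a 10^2 CFU/ml detection limit.
    """

    n_participants: int = 11
    n_groups: int = 10
    phases: tuple[str, ...] = PHASES
    replicates: int = 3
    baseline_log10_mean: tuple[float, ...] | None = None
    phase_effect: tuple[tuple[float, ...], ...] | None = None
    deviation_scale: tuple[float, ...] | None = None
    replicate_sd: float = 0.15
    detection_limit: tuple[float, ...] | float = 100.0
    planted_labels: tuple[str, ...] | None = None
    seed: int = 0

    def resolved(self) -> "SimulationConfig":
        """Fill array defaults and validate dimensions."""
        I, B, P = self.n_participants, self.n_groups, len(self.phases)
        if I < 1 or B < 1 or P < 2 or self.replicates < 1:
            raise ValidationError("need ≥1 participant/group/replicate and ≥2 phases")
        baseline = self.baseline_log10_mean or _default_baseline(B)
        effect = self.phase_effect or _default_phase_effect(P, B)
        scale = self.deviation_scale
        if scale is None:
            scale = tuple([0.02, 0.03, 0.07, 0.05, 0.06, 0.15,
                           0.07, 0.18, 0.05, 0.10, 0.20][:I]) if I <= 11 else \
                tuple(np.full(I, 0.08))
        limit = self.detection_limit
        if np.isscalar(limit):
            limit = tuple(float(limit) for _ in range(B))
        cfg = replace(self, baseline_log10_mean=tuple(baseline),
                      phase_effect=tuple(tuple(r) for r in effect),
                      deviation_scale=tuple(scale),
                      detection_limit=tuple(limit))
        if len(cfg.baseline_log10_mean) != B:
            raise ValidationError("baseline_log10_mean length must equal n_groups")
        eff = np.asarray(cfg.phase_effect, dtype=float)
        if eff.shape != (P, B):
            raise ValidationError("phase_effect must be n_phases × n_groups")
        if np.any(eff[0] != 0):
            raise ValidationError("phase_effect must be zero in the reference phase")
        if len(cfg.deviation_scale) != I:
            raise ValidationError("deviation_scale length must equal n_participants")
        if any(s < 0 for s in cfg.deviation_scale) or cfg.replicate_sd < 0:
            raise ValidationError("noise scales must be non-negative")
        if len(cfg.detection_limit) != B or any(d <= 0 for d in cfg.detection_limit):
            raise ValidationError("detection_limit must be positive, one per group")
        return cfg


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a synthetic study, for recovery tests."""

    planted_label: pd.Series  # participant → typical / atypical / intermediate
    deviation_scale: pd.Series
    phase_effect: pd.DataFrame  # phase × group

    def __post_init__(self) -> None:
        scale, label = self.deviation_scale, self.planted_label
        groups = {k: set(scale[label == k]) for k in
                  ("typical", "intermediate", "atypical")}
        if groups["typical"] and groups["intermediate"] and \
                max(groups["typical"]) > min(groups["intermediate"]):
            raise ValidationError("typical scales must not exceed intermediate ones")
        if groups["atypical"] and groups["intermediate"] and \
                min(groups["atypical"]) < max(groups["intermediate"]):
            raise ValidationError("atypical scales must not fall below intermediate ones")


def _derive_labels(scale: np.ndarray) -> np.ndarray:
    """Smallest-scale participants are typical, largest atypical.

    With a constant scale vector (no planted structure) everyone is
    intermediate.
    """
    labels = np.full(len(scale), "intermediate", dtype=object)
    if len(np.unique(scale)) > 1:
        labels[scale == scale.min()] = "typical"
        labels[scale == scale.max()] = "atypical"
    return labels


def generate_dataset(config: SimulationConfig, seed: int | None = None
                     ) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one complete synthetic culture-count table.

    Returns the long-format table (one row per participant × phase ×
    replicate × group, raw CFU/ml plus detection limit) and the planted
    ground truth.  ``seed`` overrides ``config.seed``.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    I, B, P, R = cfg.n_participants, cfg.n_groups, len(cfg.phases), cfg.replicates

    baseline = np.asarray(cfg.baseline_log10_mean)
    effect = np.asarray(cfg.phase_effect)
    scale = np.asarray(cfg.deviation_scale)
    limit = np.asarray(cfg.detection_limit)

    eta = rng.standard_normal((I, P, B))
    eps = rng.standard_normal((I, P, B, R)) * cfg.replicate_sd
    value = (baseline[None, None, :] + effect[None, :, :]
             + scale[:, None, None] * eta)[..., None] + eps
    cfu = 10.0 ** value

    participants = [f"P{i + 1:02d}" for i in range(I)]
    groups = [f"B{b + 1:02d}" for b in range(B)]
    idx = pd.MultiIndex.from_product(
        [participants, list(cfg.phases), groups, range(1, R + 1)],
        names=["participant_id", "phase", "group", "replicate"],
    )
    table = pd.DataFrame(index=idx).reset_index()
    table["cfu_per_ml"] = cfu.transpose(0, 1, 2, 3).reshape(-1)
    table["detection_limit"] = np.tile(np.repeat(limit, R), I * P)
    table = table[["participant_id", "phase", "replicate", "group",
                   "cfu_per_ml", "detection_limit"]]

    labels = (np.asarray(cfg.planted_labels, dtype=object)
              if cfg.planted_labels is not None else _derive_labels(scale))
    if len(labels) != I:
        raise ValidationError("planted_labels length must equal n_participants")
    truth = GroundTruth(
        planted_label=pd.Series(labels, index=participants, name="planted_label"),
        deviation_scale=pd.Series(scale, index=participants, name="deviation_scale"),
        phase_effect=pd.DataFrame(effect, index=list(cfg.phases), columns=groups),
    )
    return table, truth


#: Named study scenarios.
#: - ``reference``: the reference design with a mixed range of deviation
#:   scales (two near-typical, three strongly deviating participants).
#: - ``null``: identical deviation scales — no planted responders.
#: - ``extreme``: well-separated scales (two typical at 0.001, six
#:   intermediate at 0.05, three atypical at 0.5) with low replicate noise,
#:   for parameter-recovery checks.
PRESETS = {
    "reference": SimulationConfig(
        planted_labels=("typical", "typical", "intermediate", "intermediate",
                        "intermediate", "atypical", "intermediate", "atypical",
                        "intermediate", "intermediate", "atypical"),
    ),
    "null": SimulationConfig(
        deviation_scale=tuple([0.08] * 11),
    ),
    "extreme": SimulationConfig(
        deviation_scale=(0.001, 0.001, 0.05, 0.05, 0.05, 0.5,
                         0.05, 0.5, 0.05, 0.05, 0.5),
        replicate_sd=0.05,
    ),
}


def scenario_presets(name: str) -> SimulationConfig:
    """Return a named :class:`SimulationConfig` preset."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
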