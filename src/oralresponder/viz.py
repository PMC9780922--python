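"""Report graphics: sorted mean-change bars, profile overlays, band heat map.

Figures follow the conventions of diet-shift cohort reports: within each
phase the bacterial groups are ranked by the cohort mean change (descending),
so the x-axis of profile plots is the *rank*, not a fixed group identity;
individual participants are thin coloured lines and the cohort mean a
heavier black line; the percentile heat map uses a five-level diverging
scale in which the middle band (τ around the median) is white, strong green
marks close agreement with the mean pattern and strong red marks large
deviations.

Every figure is backed by a CSV written next to it containing exactly the
numbers plotted, and SVG output is byte-deterministic for fixed inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import BoundaryNorm, ListedColormap

from .stats import MeanPattern, ResponderReport

__all__ = ["SortedPattern", "sort_by_mean", "render_reports", "PARTICIPANT_PALETTE"]

log = logging.getLogger(__name__)

#: Fixed participant palette (11 entries, participant order).
PARTICIPANT_PALETTE = (
    "red", "gold", "cyan", "saddlebrown", "green", "purple",
    "limegreen", "orange", "lightskyblue", "blue", "#b57edc",
)

_BAND_COLORS = ListedColormap(
    ["#1a9641", "#a6d96a", "#ffffff", "#f4a582", "#ca0020"], name="tau_bands"
)


@dataclass(frozen=True)
class SortedPattern:
    """Per-phase group ordering by descending mean change.

    ``order[phase]`` is the permutation of group ids; ``mu_sorted`` stacks
    the ordered mean values (phase × rank) and ``individual[phase]`` holds
    each participant's changes permuted into that phase's order.
    """

    order: dict[str, list[str]]
    mu_sorted: pd.DataFrame
    individual: dict[str, pd.DataFrame]


def sort_by_mean(patterns: MeanPattern, delta: pd.DataFrame) -> SortedPattern:
    """Rank groups within each phase by descending cohort mean change.

    Ties are broken lexicographically on the group id; participant profiles
    are permuted consistently with each phase's ordering.
    """
    order: dict[str, list[str]] = {}
    individual: dict[str, pd.DataFrame] = {}
    rows = []
    for phase, mu_row in patterns.mu.iterrows():
        ranked = sorted(mu_row.index, key=lambda g: (-mu_row[g], g))
        order[phase] = ranked
        rows.append(pd.Series(mu_row[ranked].to_numpy(), name=phase))
        ind = delta.xs(phase, level="phase")[ranked]
        ind.columns = pd.RangeIndex(1, len(ranked) + 1, name="rank")
        individual[phase] = ind
    mu_sorted = pd.DataFrame(rows)
    mu_sorted.columns = pd.RangeIndex(1, mu_sorted.shape[1] + 1, name="rank")
    mu_sorted.index.name = "phase"
    return SortedPattern(order=order, mu_sorted=mu_sorted, individual=individual)


def _participant_colors(participants) -> dict[str, str]:
    palette = list(PARTICIPANT_PALETTE)
    while len(palette) < len(participants):
        palette += palette
    return dict(zip(participants, palette))


def _save(fig, out_dir: Path, stem: str, formats) -> list[Path]:
    written = []
    for fmt in formats:
        path = out_dir / f"{stem}.{fmt}"
        kwargs = {"metadata": {"Date": None}} if fmt == "svg" else {}
        fig.savefig(path, format=fmt, **kwargs)
        written.append(path)
    plt.close(fig)
    return written


def render_reports(sorted_pattern: SortedPattern, tau: pd.DataFrame,
                   report: ResponderReport, out_dir: str | Path,
                   cube: pd.DataFrame | None = None,
                   formats: tuple[str, ...] = ("svg", "png")) -> list[Path]:
    """Write the full figure set (plus backing CSVs) to ``out_dir``.

    Produces per-phase bar charts of sorted mean changes, the
    individual-versus-mean profile overlay, the percentile-band heat map,
    and — when atypical responders exist — their profile panels (raw
    log10 concentrations per phase when an abundance ``cube`` is supplied,
    and their mean-change profiles).  Returns the list of files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with matplotlib.rc_context({"svg.hashsalt": "oralresponder"}):
        written = []
        phases = list(sorted_pattern.mu_sorted.index)
        participants = list(tau.index)
        colors = _participant_colors(participants)

        # (a) sorted mean-change bars, one panel per phase
        fig, axes = plt.subplots(len(phases), 1, figsize=(7, 2.2 * len(phases)),
                                 sharex=True, constrained_layout=True)
        for ax, phase in zip(np.atleast_1d(axes), phases):
            mu = sorted_pattern.mu_sorted.loc[phase]
            ax.bar(mu.index, mu.to_numpy(), color="0.4")
            ax.axhline(0.0, color="black", lw=0.8)
            ax.set_ylabel(f"phase {phase}")
        np.atleast_1d(axes)[-1].set_xlabel("group rank (descending mean change)")
        fig.suptitle("Sorted mean fraction changes vs run-in")
        written += _save(fig, out_dir, "mean_changes", formats)
        sorted_pattern.mu_sorted.to_csv(out_dir / "mean_changes.csv")
        written.append(out_dir / "mean_changes.csv")

        # (b) individual profiles with the mean as a heavier black line
        fig, axes = plt.subplots(len(phases), 1, figsize=(7, 2.2 * len(phases)),
                                 sharex=True, constrained_layout=True)
        profile_rows = []
        for ax, phase in zip(np.atleast_1d(axes), phases):
            ind = sorted_pattern.individual[phase]
            for pid, row in ind.iterrows():
                ax.plot(row.index, row.to_numpy(), color=colors[pid], lw=0.9,
                        label=pid)
            ax.plot(sorted_pattern.mu_sorted.columns,
                    sorted_pattern.mu_sorted.loc[phase].to_numpy(),
                    color="black", lw=2.2)
            ax.axhline(0.0, color="0.7", lw=0.6)
            ax.set_ylabel(f"phase {phase}")
            profile_rows.append(ind.assign(phase=phase))
        np.atleast_1d(axes)[0].legend(fontsize=5, ncol=4, frameon=False)
        np.atleast_1d(axes)[-1].set_xlabel("group rank (per-phase ordering)")
        fig.suptitle("Individual vs mean change profiles")
        written += _save(fig, out_dir, "individual_profiles", formats)
        pd.concat(profile_rows).to_csv(out_dir / "individual_profiles.csv")
        written.append(out_dir / "individual_profiles.csv")

        # (c) percentile-band heat map (participants × phases)
        bands = report.bands
        fig, ax = plt.subplots(
            figsize=(1.0 + 0.8 * bands.shape[1], 1.0 + 0.45 * bands.shape[0]),
            constrained_layout=True)
        norm = BoundaryNorm(np.arange(0.5, 6.0, 1.0), _BAND_COLORS.N)
        mesh = ax.pcolormesh(bands.to_numpy(), cmap=_BAND_COLORS, norm=norm,
                             edgecolors="0.8", linewidth=0.5)
        ax.set_xticks(np.arange(bands.shape[1]) + 0.5, bands.columns)
        ax.set_yticks(np.arange(bands.shape[0]) + 0.5, bands.index)
        ax.invert_yaxis()
        ax.set_xlabel("phase")
        cbar = fig.colorbar(mesh, ax=ax, ticks=range(1, 6))
        cbar.set_label("τ percentile band (1 = closest to mean pattern)")
        ax.set_title("Concordance with the cohort mean pattern")
        written += _save(fig, out_dir, "tau_heatmap", formats)
        bands.to_csv(out_dir / "tau_bands.csv")
        tau.to_csv(out_dir / "tau_values.csv")
        written += [out_dir / "tau_bands.csv", out_dir / "tau_values.csv"]

        # (d) atypical-responder panels
        atypical = report.atypical
        if not atypical:
            log.info("no atypical responders; profile panels skipped")
            return written
        n_rows = 2 if cube is not None else 1
        fig, axes = plt.subplots(n_rows, 1, figsize=(7, 3.0 * n_rows),
                                 constrained_layout=True, squeeze=False)
        if cube is not None:
            ax = axes[0][0]
            all_phases = list(dict.fromkeys(cube.index.get_level_values("phase")))
            groups = list(cube.columns)
            for pid in atypical:
                prof = cube.xs(pid, level="participant_id")
                flat = prof.loc[all_phases].to_numpy().ravel()
                ax.plot(np.arange(flat.size), flat, color=colors[pid], lw=0.9,
                        label=pid)
            mean_prof = cube.groupby(level="phase", sort=False).mean()
            ax.plot(np.arange(mean_prof.size),
                    mean_prof.loc[all_phases].to_numpy().ravel(),
                    color="black", lw=2.0, label="cohort mean")
            for k in range(1, len(all_phases)):
                ax.axvline(k * len(groups) - 0.5, color="0.8", lw=0.6)
            ax.set_ylabel("log10 CFU/ml")
            ax.set_title("Atypical responders: concentrations across phases")
            ax.legend(fontsize=6, frameon=False)
        ax = axes[-1][0]
        for phase in phases:
            ind = sorted_pattern.individual[phase]
            offset = phases.index(phase) * (ind.shape[1] + 1)
            for pid in atypical:
                ax.plot(offset + ind.columns.to_numpy(),
                        ind.loc[pid].to_numpy(), color=colors[pid], lw=0.9)
            ax.plot(offset + sorted_pattern.mu_sorted.columns.to_numpy(),
                    sorted_pattern.mu_sorted.loc[phase].to_numpy(),
                    color="black", lw=2.0)
        ax.axhline(0.0, color="0.7", lw=0.6)
        ax.set_ylabel("fraction change")
        ax.set_title("Atypical responders: mean-change profiles per phase")
        written += _save(fig, out_dir, "atypical_profiles", formats)
    return written
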