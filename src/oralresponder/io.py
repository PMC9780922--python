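"""Shared data model and delimited-text I/O.

The package works on long-format culture-count tables: one row per
(participant, phase, replicate, bacterial group) observation carrying the
measured concentration in CFU/ml and the group's detection limit.  All
tabular structures are plain :class:`pandas.DataFrame` objects validated by
the functions here; downstream modules rely on these invariants instead of
re-checking them.

Wide matrices (abundance cubes, fraction matrices, change matrices) use a
``(participant_id, phase)`` row MultiIndex with one column per bacterial
group.  τ matrices are participant × phase.  ``write_table`` serialises any
of them to CSV/TSV such that reading the file back reproduces the object.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "PHASES",
    "FormatError",
    "IntegrityError",
    "ValidationError",
    "CompletenessError",
    "StudyDesign",
    "validate_counts",
    "read_counts",
    "write_table",
    "read_matrix",
    "load_table1_fixture",
    "design_from_counts",
]

#: Mandatory header of a culture-count file (order-free).
REQUIRED_COLUMNS = (
    "participant_id",
    "phase",
    "replicate",
    "group",
    "cfu_per_ml",
    "detection_limit",
)

#: Canonical phase labels: run-in reference first, then the three
#: supplementation phases (sucrose, dairy, vegetables) and the return to the
#: regular diet.
PHASES = ("I", "II", "III", "IV", "V")


class FormatError(ValueError):
    """A file does not conform to the expected delimited-text format."""


class IntegrityError(ValueError):
    """A table violates a uniqueness or referential constraint."""


class ValidationError(ValueError):
    """A value fails a domain check (negative CFU, non-positive limit...)."""


class CompletenessError(ValueError):
    """A required (participant, phase, group) cell has no observation."""


@dataclass(frozen=True)
class StudyDesign:
    """The factorial layout of a longitudinal culture study.

    Parameters
    ----------
    participants : sequence of str
        Participant identifiers.
    phases : sequence of str
        Ordered phase labels; ``phases[0]`` is the run-in reference phase
        against which all change profiles are computed.
    groups : sequence of str
        Labels of the disjunct bacterial groups retained in the analysis.
    replicates_per_phase : int
        Nominal number of replicate culture measurements per phase.
    """

    participants: tuple[str, ...]
    phases: tuple[str, ...]
    groups: tuple[str, ...]
    replicates_per_phase: int = 3

    def __post_init__(self) -> None:
        for name in ("participants", "phases", "groups"):
            values = getattr(self, name)
            object.__setattr__(self, name, tuple(str(v) for v in values))
            values = getattr(self, name)
            if not values:
                raise ValidationError(f"StudyDesign.{name} must be non-empty")
            if len(set(values)) != len(values):
                raise ValidationError(f"StudyDesign.{name} contains duplicates")
        if self.replicates_per_phase < 1:
            raise ValidationError("replicates_per_phase must be positive")

    @property
    def reference_phase(self) -> str:
        return self.phases[0]

    @property
    def intervention_phases(self) -> tuple[str, ...]:
        return self.phases[1:]


def _as_dataframe(table: pd.DataFrame | Iterable[dict]) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table.copy()
    return pd.DataFrame(list(table))


def validate_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format culture-count table.

    Checks the mandatory columns, coerces dtypes, and enforces the domain
    invariants: non-negative concentrations, strictly positive detection
    limits, uniqueness of (participant, phase, replicate, group), and
    presence of every participant in the reference phase ``I`` whenever the
    table uses canonical phase labels.

    Returns a validated copy; raises :class:`FormatError`,
    :class:`ValidationError` or :class:`IntegrityError` otherwise.
    """
    df = _as_dataframe(table)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()

    df["participant_id"] = df["participant_id"].astype(str)
    df["phase"] = df["phase"].astype(str)
    df["group"] = df["group"].astype(str)
    try:
        df["replicate"] = pd.to_numeric(df["replicate"], errors="raise")
        df["cfu_per_ml"] = pd.to_numeric(df["cfu_per_ml"], errors="raise")
        df["detection_limit"] = pd.to_numeric(df["detection_limit"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric value in numeric column: {exc}") from exc

    if (df["replicate"] < 1).any() or (df["replicate"] % 1 != 0).any():
        raise ValidationError("replicate must be a positive integer")
    df["replicate"] = df["replicate"].astype(int)
    if (df["cfu_per_ml"] < 0).any():
        bad = df.loc[df["cfu_per_ml"] < 0].iloc[0]
        raise ValidationError(
            f"negative cfu_per_ml for participant {bad['participant_id']}, "
            f"phase {bad['phase']}, group {bad['group']}"
        )
    if (df["detection_limit"] <= 0).any():
        raise ValidationError("detection_limit must be strictly positive")

    key = ["participant_id", "phase", "replicate", "group"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise IntegrityError(
            f"duplicate observation key (participant, phase, replicate, group): {tuple(first)}"
        )

    phases_present = set(df["phase"])
    if phases_present <= set(PHASES) and "I" in phases_present:
        in_ref = set(df.loc[df["phase"] == "I", "participant_id"])
        missing_ref = sorted(set(df["participant_id"]) - in_ref)
        if missing_ref:
            raise IntegrityError(
                "participant(s) missing the run-in reference phase I: "
                + ", ".join(missing_ref)
            )
    return df.reset_index(drop=True)


def _sniff_delimiter(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return {"csv": ",", "tsv": "\t"}.get(dialect, dialect)
    if path.suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    return ","


def read_counts(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read and validate a culture-count table from a delimited-text file.

    ``dialect`` may be ``"csv"``, ``"tsv"``, or an explicit single-character
    delimiter; by default it is inferred from the file extension (TSV for
    ``.tsv``/``.tab``, CSV otherwise).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path, dialect)
    df = pd.read_csv(path, sep=sep)
    return validate_counts(df)


def write_table(table: pd.DataFrame, path: str | Path, dialect: str | None = None,
                decimals: int | None = None) -> Path:
    """Serialise a table (long counts or wide matrix) to delimited text.

    Wide matrices keep their (Multi)Index; long tables are written without an
    index column.  Reals are written at full precision unless ``decimals``
    requests display rounding (e.g. 3 decimals for a report-style τ table).
    Reading the file back with :func:`read_counts` / :func:`read_matrix`
    reproduces the table.
    """
    if len(table) == 0:
        raise ValidationError("refusing to write an empty table")
    path = Path(path)
    sep = _sniff_delimiter(path, dialect)
    float_format = f"%.{decimals}f" if decimals is not None else None
    keep_index = table.index.nlevels > 1 or table.index.name is not None
    table.to_csv(path, sep=sep, index=keep_index, float_format=float_format)
    return path


def read_matrix(path: str | Path, index_cols: Sequence[str] | None = None,
                dialect: str | None = None) -> pd.DataFrame:
    """Read back a wide matrix written by :func:`write_table`.

    ``index_cols`` names the index column(s); by default any leading columns
    named ``participant_id`` / ``phase`` are used as the index.
    """
    path = Path(path)
    sep = _sniff_delimiter(path, dialect)
    df = pd.read_csv(path, sep=sep)
    if index_cols is None:
        index_cols = [c for c in ("participant_id", "phase") if c in df.columns]
    if index_cols:
        df = df.set_index(list(index_cols))
    return df


def load_table1_fixture() -> pd.DataFrame:
    """Load the packaged published τ table (4 intervention phases × 11 participants).

    Returns a DataFrame indexed by phase (II–V) with columns P1–P11 holding
    the 44 printed three-decimal τ values.  Transpose it to feed the
    participant × phase layout the statistics functions use.
    """
    ref = resources.files("oralresponder.data").joinpath("table1_tau.csv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p).set_index("phase")
    df.index = df.index.astype(str)
    df.columns.name = "participant_id"
    if df.shape != (4, 11) or (df.to_numpy() <= 0).any():
        raise IntegrityError("packaged tau fixture is corrupted")
    return df


def table1_checksum() -> str:
    """SHA-256 of the packaged τ fixture file (integrity pin for tests)."""
    ref = resources.files("oralresponder.data").joinpath("table1_tau.csv")
    return hashlib.sha256(ref.read_bytes()).hexdigest()


def design_from_counts(table: pd.DataFrame,
                       phase_order: Sequence[str] | None = None) -> StudyDesign:
    """Infer a :class:`StudyDesign` from a validated count table.

    Phases are ordered canonically (I–V) when the labels allow it, otherwise
    by ``phase_order`` (mandatory for non-canonical labels, reference first).
    """
    phases_present = list(dict.fromkeys(table["phase"]))
    if phase_order is not None:
        unknown = set(phases_present) - set(phase_order)
        if unknown:
            raise ValidationError(f"phase_order does not cover phase(s): {sorted(unknown)}")
        phases = tuple(p for p in phase_order if p in phases_present)
    elif set(phases_present) <= set(PHASES):
        phases = tuple(p for p in PHASES if p in phases_present)
    else:
        raise ValidationError(
            "non-canonical phase labels require an explicit phase_order "
            "with the reference phase first"
        )
    n_rep = int(table.groupby(["participant_id", "phase", "group"])["replicate"].size().max())
    return StudyDesign(
        participants=tuple(sorted(set(table["participant_id"]))),
        phases=phases,
        groups=tuple(sorted(set(table["group"]))),
        replicates_per_phase=n_rep,
    )
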