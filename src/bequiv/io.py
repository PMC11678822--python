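"""Data model and CSV I/O for 2x2x2 crossover pharmacokinetic studies.

A study is stored long (tidy): one row per observed concentration, keyed by
``(subject, period, time)``.  Formulation is redundant with ``(sequence,
period)`` — sequence "TR" receives Test in period 1 and Reference in period
2, "RT" the reverse — and is validated against it on read.  Concentrations
below the lower limit of quantification (LLOQ) carry an explicit boolean
BLQ flag and an empty concentration cell; no sentinel strings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("bequiv")

#: CSV column order for the study dialect.
CSV_COLUMNS = ["subject", "sequence", "period", "formulation", "time_h", "conc_ng_ml", "blq"]

SEQUENCES = ("TR", "RT")
FORMULATIONS = ("Test", "Reference")

#: Nominal sampling grid used by the pazopanib studies (hours post-dose):
#: pre-dose plus 19 post-dose draws out to 72 h.
DEFAULT_GRID_H = (
    0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 2.75, 3.0, 3.25, 3.5,
    4.0, 4.5, 5.0, 6.0, 8.0, 10.0, 12.0, 24.0, 48.0, 72.0,
)


class SchemaError(ValueError):
    """CSV/config does not match the expected schema."""


class IntegrityError(ValueError):
    """Data contradicts the crossover design or contains duplicates."""


class DataError(ValueError):
    """Structurally valid input that cannot support the requested analysis."""


def formulation_for(sequence: str, period: int) -> str:
    """Formulation implied by the crossover design for a sequence/period cell."""
    if sequence not in SEQUENCES:
        raise IntegrityError(f"unknown sequence {sequence!r}")
    if period not in (1, 2):
        raise IntegrityError(f"period must be 1 or 2, got {period!r}")
    first = "Test" if sequence == "TR" else "Reference"
    second = "Reference" if sequence == "TR" else "Test"
    return first if period == 1 else second


@dataclass(frozen=True)
class ConcentrationRecord:
    """One observed plasma concentration for a subject/period/time cell."""

    subject_id: str
    sequence: str
    period: int
    time_h: float
    conc_ng_ml: float | None
    blq: bool = False

    @property
    def formulation(self) -> str:
        return formulation_for(self.sequence, self.period)

    def __post_init__(self) -> None:
        formulation_for(self.sequence, self.period)  # validates sequence/period
        if self.time_h < 0:
            raise IntegrityError(f"negative time {self.time_h} for subject {self.subject_id}")
        if self.conc_ng_ml is not None:
            if not math.isfinite(self.conc_ng_ml) or self.conc_ng_ml < 0:
                raise IntegrityError(
                    f"concentration must be finite and non-negative, got {self.conc_ng_ml}"
                )


@dataclass(frozen=True)
class StudyConfig:
    """Study-level constants: LLOQ, dose, nominal grid and a label."""

    lloq_ng_ml: float = 50.0
    dose_mg: float = 200.0
    nominal_times_h: tuple[float, ...] = DEFAULT_GRID_H
    label: str = "study"

    def __post_init__(self) -> None:
        grid = tuple(float(t) for t in self.nominal_times_h)
        if len(grid) < 2 or grid[0] != 0.0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise SchemaError("nominal grid must start at 0 and be strictly increasing")
        if self.lloq_ng_ml <= 0 or self.dose_mg <= 0:
            raise SchemaError("lloq_ng_ml and dose_mg must be positive")
        object.__setattr__(self, "nominal_times_h", grid)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise SchemaError(f"config {path} is not a key-value mapping")
        known = {"lloq_ng_ml", "dose_mg", "nominal_times_h", "label"}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class StudyDataset:
    """Long-format crossover study: a record table plus design metadata.

    ``records`` is a DataFrame with the CSV columns; rows are sorted by
    (subject, period, time).  ``conc_ng_ml`` is NaN where BLQ.
    """

    records: pd.DataFrame
    config: StudyConfig = field(default_factory=StudyConfig)

    def __post_init__(self) -> None:
        self.records = _validate_records(self.records, self.config)

    # -- convenience accessors -------------------------------------------------

    @property
    def nominal_times_h(self) -> tuple[float, ...]:
        return self.config.nominal_times_h

    @property
    def lloq_ng_ml(self) -> float:
        return self.config.lloq_ng_ml

    def subjects(self) -> list[str]:
        return sorted(self.records["subject"].unique())

    def profile(self, subject: str, period: int) -> pd.DataFrame:
        """Time-sorted rows for one subject/period; missing pre-dose added as 0."""
        rows = self.records[
            (self.records["subject"] == subject) & (self.records["period"] == period)
        ].sort_values("time_h")
        if rows.empty:
            return rows
        if rows["time_h"].iloc[0] != 0.0:
            logger.warning(
                "subject %s period %d lacks a pre-dose sample; assuming concentration 0",
                subject, period,
            )
            pad = rows.iloc[[0]].copy()
            pad["time_h"] = 0.0
            pad["conc_ng_ml"] = np.nan
            pad["blq"] = True
            rows = pd.concat([pad, rows], ignore_index=True)
        return rows


def completers(dataset: StudyDataset) -> set[str]:
    """Subjects with evaluable data in both periods.

    Only these subjects enter the comparative statistics; a period is
    evaluable when it has at least one quantifiable (non-BLQ) concentration.
    """
    rec = dataset.records
    quant = rec[(~rec["blq"]) & (rec["conc_ng_ml"] > 0)]
    ok = quant.groupby("subject")["period"].nunique()
    return set(ok[ok == 2].index)


def _validate_records(df: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    unknown = [c for c in df.columns if c not in CSV_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown columns: {unknown}")

    df = df.copy()
    df["subject"] = df["subject"].astype(str)
    df["sequence"] = df["sequence"].astype(str)
    df["period"] = df["period"].astype(int)
    df["time_h"] = df["time_h"].astype(float)
    df["conc_ng_ml"] = pd.to_numeric(df["conc_ng_ml"], errors="raise").astype(float)
    if df["blq"].dtype != bool:
        df["blq"] = df["blq"].astype(int).astype(bool)

    bad_seq = set(df["sequence"]) - set(SEQUENCES)
    if bad_seq:
        raise IntegrityError(f"unknown sequences: {sorted(bad_seq)}")
    bad_per = set(df["period"]) - {1, 2}
    if bad_per:
        raise IntegrityError(f"periods outside {{1,2}}: {sorted(bad_per)}")

    expected = [formulation_for(s, p) for s, p in zip(df["sequence"], df["period"])]
    mism = df[np.asarray(expected) != df["formulation"].astype(str).to_numpy()]
    if not mism.empty:
        row = mism.iloc[0]
        raise IntegrityError(
            f"formulation {row['formulation']!r} contradicts sequence {row['sequence']}"
            f" period {row['period']} for subject {row['subject']}"
        )

    seqs = df.groupby("subject")["sequence"].nunique()
    if (seqs > 1).any():
        raise IntegrityError(f"subject {seqs.idxmax()!r} appears in more than one sequence")

    dup = df.duplicated(subset=["subject", "period", "time_h"])
    if dup.any():
        row = df[dup].iloc[0]
        raise IntegrityError(
            f"duplicate observation for subject {row['subject']} period {row['period']}"
            f" at t={row['time_h']} h"
        )

    grid = set(config.nominal_times_h)
    off = set(df["time_h"]) - grid
    if off:
        raise IntegrityError(f"times not on the nominal grid: {sorted(off)[:5]}")

    neg = df["conc_ng_ml"] < 0
    if neg.any():
        raise IntegrityError("negative concentration")
    quantified_blq = df["blq"] & (df["conc_ng_ml"] >= config.lloq_ng_ml)
    if quantified_blq.any():
        raise IntegrityError("BLQ flag set on a concentration at or above the LLOQ")
    # canonical BLQ coding: flag set, value absent (keeps read/write round trips exact)
    df.loc[df["blq"], "conc_ng_ml"] = np.nan

    return df.sort_values(["subject", "period", "time_h"], kind="mergesort").reset_index(drop=True)


def read_study(path: str | Path, config: StudyConfig | None = None) -> StudyDataset:
    """Read a study CSV in the long dialect and validate it against the design.

    Raises :class:`SchemaError` for missing/unknown columns and
    :class:`IntegrityError` for duplicates, off-grid times or
    sequence/period/formulation contradictions.
    """
    df = pd.read_csv(path, dtype={"subject": str})
    return StudyDataset(records=df, config=config or StudyConfig())


def write_study(dataset: StudyDataset, path: str | Path) -> Path:
    """Write the study CSV; BLQ rows get flag ``1`` and an empty concentration cell."""
    df = dataset.records.copy()
    finite = np.isfinite(df["conc_ng_ml"].to_numpy()) | df["blq"].to_numpy()
    if not finite.all():
        raise DataError("refusing to write non-finite concentration")
    df.loc[df["blq"], "conc_ng_ml"] = np.nan
    df["blq"] = df["blq"].astype(int)
    path = Path(path)
    df.to_csv(path, index=False, columns=CSV_COLUMNS)
    return path


def from_records(records: Iterable[ConcentrationRecord], config: StudyConfig | None = None) -> StudyDataset:
    """Build a dataset from record objects (mostly for tests and small examples)."""
    rows = [
        {
            "subject": r.subject_id,
            "sequence": r.sequence,
            "period": r.period,
            "formulation": r.formulation,
            "time_h": r.time_h,
            "conc_ng_ml": np.nan if r.conc_ng_ml is None else r.conc_ng_ml,
            "blq": r.blq,
        }
        for r in records
    ]
    return StudyDataset(records=pd.DataFrame(rows, columns=CSV_COLUMNS), config=config or StudyConfig())


def configure_logging(level: str = "INFO") -> None:
    """Route package logging to stderr at the given level."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())
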