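"""Containers for quantitative phenotype-screen measurements and survival
calling from movement traces.

A screen table is long-format: one row per (gene, batch, replicate) with a
1- or 2-dimensional measurement (e.g. male/female brood size, anterior/
posterior wing area, large/small aggregate counts, day-8/day-22 climbing
speed).  Lifespan assays instead record hourly movement magnitudes per fly;
a fly's lifespan is called as the time point after its last change in
position, and flies still moving in the final frame are right-censored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("unknome")

VIABILITY_CATEGORIES = ("lethal", "semi_lethal", "viable")


@dataclass(frozen=True)
class ScreenSchema:
    """Column mapping for a long-format screen CSV."""

    value_cols: tuple[str, ...]
    gene_col: str = "gene"
    batch_col: str | None = "batch"
    replicate_col: str | None = "replicate"

    def __post_init__(self) -> None:
        if not 1 <= len(self.value_cols) <= 2:
            raise ValueError("screens carry 1- or 2-dimensional measurements")


@dataclass
class ScreenTable:
    """Long-format screen measurements with per-record gene/batch labels."""

    data: pd.DataFrame  # columns: gene, batch, replicate, v1[, v2]
    phenotype_name: str = "phenotype"
    axis_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"gene", "batch", "replicate"}
        if not required <= set(self.data.columns):
            raise ValueError(f"screen table must have columns {sorted(required)}")
        if self.d not in (1, 2):
            raise ValueError("screen table must carry 1 or 2 value columns")
        if not self.axis_labels:
            self.axis_labels = tuple(self.value_columns)
        values = self.data[list(self.value_columns)]
        if not all(np.issubdtype(dt, np.number) for dt in values.dtypes):
            raise ValueError("value columns must be numeric")

    @property
    def value_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c not in ("gene", "batch", "replicate"))

    @property
    def d(self) -> int:
        return len(self.value_columns)

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    def values_matrix(self) -> np.ndarray:
        return self.data[list(self.value_columns)].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def read_screen_table(
    path: str | Path,
    schema: ScreenSchema,
    phenotype_name: str = "phenotype",
) -> ScreenTable:
    """Read and validate a long-format screen CSV against a schema.

    Genes whose values are all missing are dropped with a logged warning;
    a non-numeric value cell is a hard error naming the row.
    """
    df = pd.read_csv(path)
    needed = [schema.gene_col] + list(schema.value_cols)
    if schema.batch_col is not None:
        needed.append(schema.batch_col)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"screen CSV {path} lacks required columns: {missing}")

    for col in schema.value_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
                f"data row {row + 1}"
            )
        df[col] = coerced

    out = pd.DataFrame(
        {
            "gene": df[schema.gene_col].astype(str),
            "batch": (
                df[schema.batch_col].astype(str)
                if schema.batch_col is not None
                else "batch0"
            ),
            "replicate": (
                df[schema.replicate_col].astype(str)
                if schema.replicate_col is not None and schema.replicate_col in df.columns
                else np.arange(len(df)).astype(str)
            ),
        }
    )
    for col in schema.value_cols:
        out[col] = df[col]

    all_missing = out.groupby("gene")[list(schema.value_cols)].apply(
        lambda g: g.isna().all().all()
    )
    dropped = list(all_missing[all_missing].index)
    if dropped:
        logger.warning("dropping %d gene(s) with all-missing values: %s", len(dropped), dropped[:5])
        out = out[~out["gene"].isin(dropped)]
    out = out.dropna(subset=list(schema.value_cols)).reset_index(drop=True)
    return ScreenTable(out, phenotype_name=phenotype_name, axis_labels=tuple(schema.value_cols))


@dataclass(frozen=True)
class MovementTrace:
    """Hourly displacement magnitudes for one fly in one well."""

    fly_id: str
    gene_id: str
    displacements: tuple[float, ...]
    interval_hours: float = 1.0

    def __post_init__(self) -> None:
        if len(self.displacements) == 0:
            raise ValueError(f"trace for fly {self.fly_id} is empty")
        if any(d < 0 for d in self.displacements):
            raise ValueError("displacement magnitudes must be non-negative")
        if self.interval_hours <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def experiment_length_hours(self) -> float:
        return len(self.displacements) * self.interval_hours


@dataclass(frozen=True)
class SurvivalRecord:
    gene_id: str
    fly_id: str
    lifespan_hours: float
    censored: bool = False


@dataclass(frozen=True)
class ViabilityCall:
    gene_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in VIABILITY_CATEGORIES:
            raise ValueError(f"viability category must be one of {VIABILITY_CATEGORIES}")


def classify_viability(
    gene_id: str,
    n_adult_progeny: int,
    majority_viable_adults: bool = True,
) -> ViabilityCall:
    """Classify an RNAi knockdown cross: no adult progeny at all is lethal;
    progeny that emerge but mostly fail to hatch/expand wings/survive is
    semi-lethal; otherwise viable."""
    if n_adult_progeny < 0:
        raise ValueError("progeny count cannot be negative")
    if n_adult_progeny == 0:
        category = "lethal"
    elif not majority_viable_adults:
        category = "semi_lethal"
    else:
        category = "viable"
    return ViabilityCall(gene_id=gene_id, category=category)


def call_death_time(trace: MovementTrace, movement_threshold: float = 0.0) -> SurvivalRecord:
    """Call a fly's lifespan from its movement trace.

    Lifespan is the time point after the last change in position: (index of
    the last frame whose displacement exceeds the threshold) x interval +
    one interval.  A fly still moving in the final frame is censored at the
    experiment length; a fly that never moves gets lifespan 0 (uncensored).
    The default threshold of 0 counts any nonzero displacement as movement.
    """
    if movement_threshold < 0:
        raise ValueError("movement threshold must be >= 0")
    disp = np.asarray(trace.displacements, dtype=float)
    moving = np.flatnonzero(disp > movement_threshold)
    if moving.size == 0:
        return SurvivalRecord(trace.gene_id, trace.fly_id, 0.0, censored=False)
    last = int(moving[-1])
    if last == disp.size - 1:
        return SurvivalRecord(
            trace.gene_id, trace.fly_id, trace.experiment_length_hours, censored=True
        )
    return SurvivalRecord(
        trace.gene_id, trace.fly_id, (last + 1) * trace.interval_hours, censored=False
    )


def summarize_survival(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    """Per-gene median lifespan with dispersion.

    Censored flies contribute at the experiment length (a lower bound on
    their lifespan) and the ``any_censored`` flag is propagated so callers
    can see when a median may be an underestimate.  Even replicate counts
    use the usual midpoint convention.
    """
    rows = [
        {
            "gene": r.gene_id,
            "lifespan_hours": r.lifespan_hours,
            "censored": r.censored,
        }
        for r in records
    ]
    if not rows:
        return pd.DataFrame(
            columns=["gene", "n", "median_lifespan_hours", "mad_hours", "any_censored"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby("gene")
        .agg(
            n=("lifespan_hours", "size"),
            median_lifespan_hours=("lifespan_hours", "median"),
            mad_hours=(
                "lifespan_hours",
                lambda x: float(np.median(np.abs(x - np.median(x)))),
            ),
            any_censored=("censored", "any"),
        )
        .reset_index()
        .sort_values("gene")
        .reset_index(drop=True)
    )
    return out


def read_traces(path: str | Path, interval_hours: float = 1.0) -> list[MovementTrace]:
    """Read a trace matrix CSV: columns fly,gene,h0,h1,... one row per fly."""
    df = pd.read_csv(path, float_precision="round_trip")
    hour_cols = [c for c in df.columns if c not in ("fly", "gene")]
    traces = []
    for row in df.itertuples(index=False):
        disp = tuple(float(getattr(row, c)) for c in hour_cols)
        traces.append(
            MovementTrace(
                fly_id=str(row.fly), gene_id=str(row.gene),
                displacements=disp, interval_hours=interval_hours,
            )
        )
    return traces


def write_traces(traces: Sequence[MovementTrace], path: str | Path) -> None:
    n = max(len(t.displacements) for t in traces)
    rows = []
    for t in traces:
        row = {"fly": t.fly_id, "gene": t.gene_id}
        row.update({f"h{i}": (t.displacements[i] if i < len(t.displacements) else 0.0) for i in range(n)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
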