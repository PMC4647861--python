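"""Observed-data model for ¹⁵N-tyrosine labelling time courses.

The experiment feeds excised flowers with ¹⁵N-tyrosine and harvests tissue at
fixed times after feeding start (t = 0 h).  Four quantities are tracked per
genotype and biological replicate:

``pool_phe``
    total free phenylalanine pool size, nmol·gFW⁻¹;
``frac_phe``
    ¹⁵N fractional abundance of the phenylalanine pool, in [0, 1];
``frac_tyr``
    ¹⁵N fractional abundance of the tyrosine pool, in [0, 1];
``emission_total``
    cumulative phenylalanine-derived volatile emission since feeding start,
    nmol·gFW⁻¹.

Data travel as a tidy long-format TSV with header
``genotype  replicate  time_h  variable  value``.  Rows with ``time_h = 0``
are the measured intercepts that the downstream fixed-intercept regression
treats as known constants; they are stored as data, never extrapolated.
Fractions are proportions: any ``frac_*`` value above 1 is rejected rather
than silently rescaled from percent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

SCHEMA_COLUMNS = ("genotype", "replicate", "time_h", "variable", "value")

VARIABLES = ("pool_phe", "frac_phe", "frac_tyr", "emission_total")
FRACTION_VARIABLES = frozenset({"frac_phe", "frac_tyr"})

#: significant digits used when writing values; the read/write round trip is
#: exact at this precision
_FLOAT_FORMAT = "{:.12g}"


class ValidationError(ValueError):
    """Base class for dataset validation failures."""


class MissingColumnError(ValidationError):
    """The table lacks one of the required long-format columns."""


class NonNumericValueError(ValidationError):
    """A time or value field could not be parsed as a number."""


class UnknownVariableError(ValidationError):
    """A row names a variable outside the recognised set."""


class FractionRangeError(ValidationError):
    """A fractional-abundance value lies outside [0, 1]."""


class NegativeValueError(ValidationError):
    """A pool or emission value is negative."""


class TimeDomainError(ValidationError):
    """A time is negative or non-finite."""


class DuplicateObservationError(ValidationError):
    """Two rows share (genotype, replicate, variable, time)."""


class ShortSeriesError(ValidationError):
    """A series has fewer than two distinct post-intercept time points."""


class UnknownSeriesError(KeyError):
    """Lookup of a (genotype, replicate, variable) triple that is absent."""


class MissingInterceptError(ValidationError):
    """A series used for slope fitting has no t = 0 intercept row."""


@dataclass(frozen=True)
class Observation:
    """A single measurement row."""

    genotype: str
    replicate: str
    time: float
    variable: str
    value: float


@dataclass
class AnalysisConfig:
    """Settings shared across the pipeline stages.

    ``grid_step`` defaults to 0.1 h, i.e. flux estimates every 6 min over the
    6-h feeding window.  ``rnai_emission_fractions`` maps a genotype name to
    the fractions of control total emission observed for its lines; the
    genotype's consumption rate is then the control rate scaled by the mean
    fraction instead of being fitted from its own emission series.
    """

    grid_start: float = 0.0
    grid_end: float = 6.0
    grid_step: float = 0.1
    alpha: float = 0.05
    bonferroni_m: int | None = None  # None: number of comparisons performed
    pooling: str = "replicate"  # or "pooled"
    control_genotype: str = "control"
    rnai_emission_fractions: dict[str, list[float]] = field(default_factory=dict)
    include_f_tyr_variance: bool = True
    enrichment_balance: str = "product_rule"  # or "enrichment_only"
    strict_emission: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.bonferroni_m is not None and self.bonferroni_m < 1:
            raise ValueError("bonferroni_m must be >= 1")
        if self.pooling not in ("replicate", "pooled"):
            raise ValueError("pooling must be 'replicate' or 'pooled'")
        if self.enrichment_balance not in ("product_rule", "enrichment_only"):
            raise ValueError(
                "enrichment_balance must be 'product_rule' or 'enrichment_only'"
            )
        for genotype, fracs in self.rnai_emission_fractions.items():
            arr = np.atleast_1d(np.asarray(fracs, dtype=float))
            if arr.size == 0 or np.any(arr <= 0) or not np.all(np.isfinite(arr)):
                raise ValueError(
                    f"emission fractions for {genotype!r} must be finite and > 0"
                )

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_end - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


@dataclass
class LabelingDataset:
    """Validated long-format labelling time series.

    ``frame`` is kept in canonical order (genotype, replicate, variable,
    time).  Intercepts are the rows with ``time_h == 0``.
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, metadata: dict | None = None
    ) -> "LabelingDataset":
        return cls(_validate_frame(frame), dict(metadata or {}))

    @classmethod
    def from_observations(
        cls, observations: Sequence[Observation], metadata: dict | None = None
    ) -> "LabelingDataset":
        frame = pd.DataFrame(
            [
                (o.genotype, o.replicate, o.time, o.variable, o.value)
                for o in observations
            ],
            columns=list(SCHEMA_COLUMNS),
        )
        return cls.from_frame(frame, metadata)

    @property
    def observations(self) -> list[Observation]:
        return [
            Observation(r.genotype, r.replicate, r.time_h, r.variable, r.value)
            for r in self.frame.itertuples(index=False)
        ]

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["genotype"]))

    def replicates(self, genotype: str) -> list[str]:
        sub = self.frame[self.frame["genotype"] == genotype]
        if sub.empty:
            raise UnknownSeriesError(genotype)
        return list(dict.fromkeys(sub["replicate"]))

    def intercept(self, genotype: str, replicate: str, variable: str) -> float:
        _, _, intercept = extract_series(self, genotype, replicate, variable)
        return intercept


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCHEMA_COLUMNS if c not in frame.columns]
    if missing:
        raise MissingColumnError(f"missing column(s): {missing}")
    frame = frame.loc[:, list(SCHEMA_COLUMNS)].copy()
    frame["genotype"] = frame["genotype"].astype(str)
    frame["replicate"] = frame["replicate"].astype(str)
    frame["variable"] = frame["variable"].astype(str)
    for col in ("time_h", "value"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any() or frame[col].isna().any():
            raise NonNumericValueError(
                f"non-numeric or missing {col} at row(s) "
                f"{list(frame.index[coerced.isna()])[:5]}"
            )
        frame[col] = coerced.astype(float)

    unknown = sorted(set(frame["variable"]) - set(VARIABLES))
    if unknown:
        raise UnknownVariableError(f"unknown variable(s): {unknown}")

    t = frame["time_h"].to_numpy()
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise TimeDomainError("time_h must be finite and >= 0")

    frac = frame["variable"].isin(FRACTION_VARIABLES)
    v = frame["value"].to_numpy()
    if np.any((v[frac.to_numpy()] < 0) | (v[frac.to_numpy()] > 1)):
        raise FractionRangeError(
            "fractional abundances must lie in [0, 1]; percent inputs are "
            "not rescaled"
        )
    if np.any(v[~frac.to_numpy()] < 0):
        raise NegativeValueError("pool and emission values must be >= 0")

    keys = ["genotype", "replicate", "variable", "time_h"]
    if frame.duplicated(subset=keys).any():
        dupes = frame[frame.duplicated(subset=keys, keep=False)]
        raise DuplicateObservationError(
            f"duplicate (genotype, replicate, variable, time) rows:\n"
            f"{dupes.head().to_string(index=False)}"
        )

    frame = frame.sort_values(keys[:3] + ["time_h"], kind="mergesort").reset_index(
        drop=True
    )

    # each series needs >=2 distinct times (intercept + at least one later point)
    sizes = frame.groupby(keys[:3], sort=False)["time_h"].nunique()
    short = sizes[sizes < 2]
    if not short.empty:
        raise ShortSeriesError(
            f"series with fewer than 2 distinct time points: "
            f"{list(short.index[:5])}"
        )
    return frame


def read_dataset(
    path: str | Path, config: AnalysisConfig | None = None
) -> LabelingDataset:
    """Read and validate a long-format labelling TSV.

    Raises a named :class:`ValidationError` subclass for each kind of schema
    violation (missing column, non-numeric value, fraction outside [0, 1],
    duplicated observation, ...).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise MissingColumnError(f"{path} is empty") from exc
    dataset = LabelingDataset.from_frame(frame)
    dataset.metadata.update({"source": str(path), "units": _UNITS})
    return dataset


_UNITS = {
    "time_h": "hours since feeding start",
    "pool_phe": "nmol/gFW",
    "emission_total": "nmol/gFW (cumulative)",
    "frac_phe": "fraction in [0, 1]",
    "frac_tyr": "fraction in [0, 1]",
}


def format_dataset(dataset: LabelingDataset) -> str:
    """Render the canonical TSV text for a dataset."""
    buf = io.StringIO()
    buf.write("\t".join(SCHEMA_COLUMNS) + "\n")
    for row in dataset.frame.itertuples(index=False):
        buf.write(
            "\t".join(
                (
                    row.genotype,
                    row.replicate,
                    _FLOAT_FORMAT.format(row.time_h),
                    row.variable,
                    _FLOAT_FORMAT.format(row.value),
                )
            )
            + "\n"
        )
    return buf.getvalue()


def write_dataset(dataset: LabelingDataset, path: str | Path) -> Path:
    """Write the dataset as a canonically ordered, fixed-format TSV.

    Row order and number formatting are deterministic, so writing the same
    dataset twice yields byte-identical files and
    ``write_dataset(read_dataset(f))`` reproduces a canonically formatted
    ``f`` exactly.
    """
    path = Path(path)
    path.write_text(format_dataset(dataset))
    return path


def extract_series(
    dataset: LabelingDataset, genotype: str, replicate: str, variable: str
) -> tuple[np.ndarray, np.ndarray, float]:
    """Return ``(times, values, intercept)`` for one measured series.

    ``times``/``values`` hold the post-feeding points (t > 0), strictly
    increasing in time; ``intercept`` is the stored t = 0 measurement.
    """
    frame = dataset.frame
    mask = (
        (frame["genotype"] == genotype)
        & (frame["replicate"] == replicate)
        & (frame["variable"] == variable)
    )
    sub = frame[mask]
    if sub.empty:
        raise UnknownSeriesError((genotype, replicate, variable))
    sub = sub.sort_values("time_h")
    t = sub["time_h"].to_numpy(dtype=float)
    v = sub["value"].to_numpy(dtype=float)
    at_zero = t == 0.0
    if not at_zero.any():
        raise MissingInterceptError(
            f"no t=0 intercept for {(genotype, replicate, variable)}"
        )
    intercept = float(v[at_zero][0])
    return t[~at_zero], v[~at_zero], intercept
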