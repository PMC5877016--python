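"""Grey-series primitives: the data model and the generating transforms.

Grey multivariate models never operate on a raw series x⁰ directly.  The
modelling sequence is obtained by the first-order accumulated generating
operation (1-AGO), the running cumulative sum x¹(k) = Σ_{j≤k} x⁰(j), which
damps noise and exposes quasi-exponential structure in short series.  The
background series z¹(k) = 0.5·(x¹(k) + x¹(k−1)) — the nearest-neighbour mean
of consecutive accumulated values — stands in for the one-step integral of x¹
when the continuous whitening equation is discretized.  This module provides
those transforms, series validation, normalization ("initialization"), a
mean-substitution utility for gappy inputs, CSV I/O, and the packaged
China 1996–2015 pollutant/GDP dataset used throughout the docs and tests.

Indexing note: the grey-modelling literature writes k = 1..n; arrays here are
0-based internally, and all user-facing epochs are calendar integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    InsufficientDataError,
    InvalidSeriesError,
    MissingDataError,
)

__all__ = [
    "RawSeries",
    "InitializedSeries",
    "AccumulatedSeries",
    "BackgroundSeries",
    "PreparedDataset",
    "initialize",
    "accumulate",
    "inverse_accumulate",
    "background",
    "mean_substitute",
    "prepare",
    "load_fixture",
    "read_csv",
    "write_csv",
    "FIXTURE_COLUMNS",
]

#: Minimum observations for a meaningful grey fit.
MIN_LENGTH = 4


def _as_float_array(values: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidSeriesError(f"expected a 1-D sequence, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class RawSeries:
    """A named, equally spaced observation sequence.

    Parameters
    ----------
    name : str
        Label used in reports and error messages.
    epochs : sequence of int
        Strictly increasing, constant-step integer epochs (calendar years in
        the packaged dataset).
    values : sequence of float
        Observations, same length as ``epochs``; must be finite.
    unit : str
        Free-text unit label.
    """

    name: str
    epochs: np.ndarray
    values: np.ndarray
    unit: str = ""

    def __post_init__(self):
        object.__setattr__(self, "epochs", np.asarray(self.epochs, dtype=int))
        object.__setattr__(self, "values", _as_float_array(self.values))
        if len(self.epochs) != len(self.values):
            raise InvalidSeriesError(
                f"series {self.name!r}: {len(self.epochs)} epochs vs "
                f"{len(self.values)} values"
            )
        if len(self.values) < MIN_LENGTH:
            raise InvalidSeriesError(
                f"series {self.name!r}: need at least {MIN_LENGTH} observations, "
                f"got {len(self.values)}"
            )
        steps = np.diff(self.epochs)
        if not (steps > 0).all() or len(set(steps.tolist())) > 1:
            raise InvalidSeriesError(
                f"series {self.name!r}: epochs must be strictly increasing with a "
                "constant step"
            )
        if not np.isfinite(self.values).all():
            raise InvalidSeriesError(f"series {self.name!r}: non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    def require_positive(self) -> "RawSeries":
        """Raise unless every value is > 0 (needed for fractional exponents)."""
        if not (self.values > 0).all():
            k = int(np.argmin(self.values > 0))
            raise InvalidSeriesError(
                f"series {self.name!r}: non-positive value {self.values[k]} at "
                f"epoch {self.epochs[k]}"
            )
        return self


@dataclass(frozen=True)
class InitializedSeries:
    """A series rescaled by a base value so different units become comparable.

    ``ratios[k] * base`` reconstructs the raw value.  Under the default
    "first" mode the base is the first observation, so ratios start at 1
    exactly (this is the convention in the packaged dataset's source tables).
    """

    name: str
    epochs: np.ndarray
    base: float
    ratios: np.ndarray
    unit: str = ""
    mode: str = "first"

    @property
    def values(self) -> np.ndarray:
        """The normalized series (alias for ``ratios``)."""
        return self.ratios

    def __len__(self) -> int:
        return len(self.ratios)


@dataclass(frozen=True)
class AccumulatedSeries:
    """1-AGO of a source series: values[k] = sum of the source up to k."""

    values: np.ndarray
    source_name: str = ""

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class BackgroundSeries:
    """Nearest-neighbour means of an accumulated series, defined for k = 2..n.

    ``values[j]`` holds z(k) for k = j+2 in 1-based terms, i.e. the array has
    length n-1.
    """

    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def initialize(series: RawSeries, mode: str = "first") -> InitializedSeries:
    """Normalize a raw series to dimensionless ratios.

    Modes: ``"first"`` divides by the first observation (ratios start at 1),
    ``"mean"`` divides by the series mean, ``"none"`` leaves values unchanged.
    """
    if mode == "first":
        base = float(series.values[0])
        if base <= 0:
            raise InvalidSeriesError(
                f"series {series.name!r}: first value {base} is not a valid "
                "initialization base (must be > 0)"
            )
    elif mode == "mean":
        base = float(series.values.mean())
        if base <= 0:
            raise InvalidSeriesError(
                f"series {series.name!r}: mean {base} is not a valid base"
            )
    elif mode == "none":
        base = 1.0
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return InitializedSeries(
        name=series.name,
        epochs=series.epochs,
        base=base,
        ratios=series.values / base,
        unit=series.unit,
        mode=mode,
    )


def accumulate(series) -> AccumulatedSeries:
    """First-order accumulated generating operation (running cumulative sum)."""
    if isinstance(series, (RawSeries, InitializedSeries)):
        values, name = series.values, series.name
    elif isinstance(series, AccumulatedSeries):
        values, name = series.values, series.source_name
    else:
        values, name = _as_float_array(series), ""
    if len(values) == 0:
        raise InsufficientDataError("cannot accumulate an empty sequence")
    return AccumulatedSeries(values=np.cumsum(values), source_name=name)


def inverse_accumulate(acc) -> np.ndarray:
    """Inverse AGO: first element preserved, first differences thereafter."""
    values = acc.values if isinstance(acc, AccumulatedSeries) else _as_float_array(acc)
    if len(values) == 0:
        raise InsufficientDataError("cannot difference an empty sequence")
    return np.concatenate([values[:1], np.diff(values)])


def background(acc) -> BackgroundSeries:
    """Background (nearest-neighbour mean) series of an accumulated series.

    z(k) = 0.5*(x¹(k) + x¹(k-1)) for k = 2..n, equivalently
    x¹(k-1) + 0.5*x⁰(k).
    """
    values = acc.values if isinstance(acc, AccumulatedSeries) else _as_float_array(acc)
    if len(values) < 2:
        raise InsufficientDataError("background series needs at least 2 points")
    return BackgroundSeries(values=0.5 * (values[1:] + values[:-1]))


def mean_substitute(
    values: Sequence[float],
    missing: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace missing entries by the mean of the observed ones.

    Missing entries are NaNs, or entries equal to ``missing`` if given.
    Returns ``(filled, was_filled)`` where ``was_filled`` is a boolean
    provenance mask.
    """
    arr = np.asarray(values, dtype=float)
    mask = np.isnan(arr) if missing is None else (arr == missing) | np.isnan(arr)
    if mask.all():
        raise MissingDataError("all values are missing; nothing to average")
    filled = arr.copy()
    filled[mask] = arr[~mask].mean()
    return filled, mask


@dataclass(frozen=True)
class PreparedDataset:
    """System + driving series with their grey generating sequences.

    Fields (n observations, N = 1 + number of drivers):

    - ``y0``: initialized system series (length n)
    - ``y1``: its 1-AGO (length n)
    - ``z``:  its background values for k = 2..n (length n-1)
    - ``X0``: initialized driver values, shape (n, N-1)
    - ``X1``: accumulated drivers, shape (n, N-1)
    """

    system: InitializedSeries
    drivers: tuple[InitializedSeries, ...]
    y1: AccumulatedSeries = field(repr=False, default=None)
    z: BackgroundSeries = field(repr=False, default=None)
    driver_acc: tuple[AccumulatedSeries, ...] = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return len(self.system)

    @property
    def N(self) -> int:
        return 1 + len(self.drivers)

    @property
    def epochs(self) -> np.ndarray:
        return self.system.epochs

    @property
    def y0(self) -> np.ndarray:
        return self.system.values

    @property
    def X0(self) -> np.ndarray:
        return np.column_stack([d.values for d in self.drivers])

    @property
    def X1(self) -> np.ndarray:
        return np.column_stack([a.values for a in self.driver_acc])

    @property
    def driver_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.drivers)


def prepare(
    system: RawSeries,
    drivers: Iterable[RawSeries] | RawSeries,
    normalization: str = "first",
) -> PreparedDataset:
    """Initialize, accumulate and background-generate a modelling dataset.

    All series must be positive (fractional driver exponents require positive
    accumulated values) and share epochs.
    """
    if isinstance(drivers, RawSeries):
        drivers = [drivers]
    drivers = list(drivers)
    if not drivers:
        raise InvalidSeriesError("at least one driving series is required")
    system.require_positive()
    for d in drivers:
        d.require_positive()
        if not np.array_equal(d.epochs, system.epochs):
            raise InvalidSeriesError(
                f"driver {d.name!r} epochs do not match system {system.name!r}"
            )
    sys_init = initialize(system, normalization)
    drv_init = tuple(initialize(d, normalization) for d in drivers)
    y1 = accumulate(sys_init)
    return PreparedDataset(
        system=sys_init,
        drivers=drv_init,
        y1=y1,
        z=background(y1),
        driver_acc=tuple(accumulate(d) for d in drv_init),
    )


# ---------------------------------------------------------------------------
# CSV I/O and the packaged dataset
# ---------------------------------------------------------------------------

#: Column names of the packaged China 1996-2015 dataset.
FIXTURE_COLUMNS = ("GDP", "WDPC", "SO2", "Dust")

_FIXTURE_UNITS = {
    "GDP": "yuan per capita",
    "WDPC": "t per capita",
    "SO2": "t per capita",
    "Dust": "t per capita",
}

_EPOCH_COLUMN = "Year"


def read_csv(path: str | Path, epoch_column: str = _EPOCH_COLUMN) -> dict[str, RawSeries]:
    """Read a table of series from CSV: one integer epoch column + one column
    per series (dot decimal separator, UTF-8)."""
    frame = pd.read_csv(path)
    if epoch_column not in frame.columns:
        raise InvalidSeriesError(
            f"{path}: epoch column {epoch_column!r} not found "
            f"(columns: {list(frame.columns)})"
        )
    epochs = frame[epoch_column].to_numpy(dtype=int)
    out: dict[str, RawSeries] = {}
    for col in frame.columns:
        if col == epoch_column:
            continue
        out[col] = RawSeries(name=col, epochs=epochs, values=frame[col].to_numpy(float))
    if not out:
        raise InvalidSeriesError(f"{path}: no value columns")
    return out


def write_csv(
    table: Mapping[str, RawSeries] | Sequence[RawSeries],
    path: str | Path,
    epoch_column: str = _EPOCH_COLUMN,
) -> None:
    """Write series to CSV, round-trip stable at 15 significant digits."""
    series = list(table.values()) if isinstance(table, Mapping) else list(table)
    epochs = series[0].epochs
    for s in series[1:]:
        if not np.array_equal(s.epochs, epochs):
            raise InvalidSeriesError("all series must share epochs to share a table")
    frame = pd.DataFrame({epoch_column: epochs})
    for s in series:
        frame[s.name] = s.values
    frame.to_csv(path, index=False, float_format="%.15g")


def fixture_path() -> Path:
    """Path of the packaged China 1996-2015 pollutant/GDP CSV."""
    return Path(__file__).parent / "data" / "china_pollutants_1996_2015.csv"


def load_fixture() -> dict[str, RawSeries]:
    """Load the packaged dataset: China 1996-2015 annual GDP per capita and
    per-capita wastewater discharge (WDPC), SO2 and dust emissions.

    Returns a dict keyed by column name (``GDP``, ``WDPC``, ``SO2``, ``Dust``).
    """
    table = read_csv(fixture_path())
    return {
        name: RawSeries(s.name, s.epochs, s.values, _FIXTURE_UNITS.get(name, ""))
        for name, s in table.items()
    }
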