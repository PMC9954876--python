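"""Containers for beat-to-beat and synthetic time series.

A :class:`Series` is an ordered, finite, real-valued record: RR intervals in
milliseconds for physiological data, arbitrary units for synthetic benchmark
signals.  Estimator parameters shared by all entropy methods live in
:class:`EntropyParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Series", "EntropyParams", "read_rri", "write_rri"]

#: Recognised physical units for a Series.
UNITS = ("ms", "a.u.")


@dataclass(frozen=True)
class Series:
    """An ordered real-valued sample record.

    Parameters
    ----------
    values : array-like of float
        The samples, in temporal order.  At least two samples, all finite.
    units : {"ms", "a.u."}
        Physical units: milliseconds for RR-interval data, arbitrary units
        for synthetic signals.
    label : str
        Free-text identifier used in exported tables.
    seed : int, optional
        Seed the series was generated from, if synthetic.
    """

    values: np.ndarray
    units: str = "a.u."
    label: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("Series values must be one-dimensional")
        if values.size < 2:
            raise ValueError("Series must contain at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("Series values must all be finite")
        if self.units not in UNITS:
            raise ValueError(f"units must be one of {UNITS!r}, got {self.units!r}")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        """Number of samples N."""
        return self.values.size

    def sd(self) -> float:
        """Population standard deviation (divide by N) of the samples."""
        return float(np.std(self.values))

    def with_values(self, values: Iterable[float], label: str | None = None) -> "Series":
        """Return a copy carrying new sample values (units/seed preserved)."""
        return replace(
            self,
            values=np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float),
            label=self.label if label is None else label,
        )


@dataclass(frozen=True)
class EntropyParams:
    """Parameters shared by the Sample, Fuzzy and Distribution estimators.

    Attributes
    ----------
    m : int
        Embedding dimension (length of the template vectors), >= 1.
    r_fraction : float
        Similarity tolerance as a fraction of the series' standard
        deviation; the absolute tolerance actually applied is
        ``r_fraction * SD(series)``.
    fuzzy_n : float
        Exponent of the exponential fuzzy membership function.
    n_bins : int
        Number M of equispaced bins of the empirical distance distribution
        used by the Distribution entropy.
    fuzzy_membership : {"exp_dn_over_r", "exp_d_over_r_n"}
        Functional form of the fuzzy similarity degree:
        ``exp(-d**n / r)`` (default, the quadratic-exponential family) or
        ``exp(-(d / r)**n)``.
    """

    m: int = 2
    r_fraction: float = 0.20
    fuzzy_n: float = 2.0
    n_bins: int = 512
    fuzzy_membership: str = "exp_dn_over_r"

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 1:
            raise ValueError("m must be a positive integer")
        if not self.r_fraction > 0:
            raise ValueError("r_fraction must be > 0")
        if not self.fuzzy_n > 0:
            raise ValueError("fuzzy_n must be > 0")
        if int(self.n_bins) != self.n_bins or self.n_bins < 2:
            raise ValueError("n_bins must be an integer >= 2")
        if self.fuzzy_membership not in ("exp_dn_over_r", "exp_d_over_r_n"):
            raise ValueError("unknown fuzzy_membership form")


def read_rri(path: str | Path, label: str | None = None) -> Series:
    """Read an RR-interval series from a plain-text file.

    One RR interval per line, in milliseconds; blank lines and lines
    beginning with ``#`` are ignored.
    """
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            values.append(float(line))
    return Series(np.asarray(values), units="ms", label=label or path.stem)


def write_rri(series: Series | Sequence[float], path: str | Path, header: str | None = None) -> None:
    """Write an RR-interval series as plain text, one value per line."""
    values = series.values if isinstance(series, Series) else np.asarray(series, float)
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for v in values:
            fh.write(f"{v:.6f}\n")
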