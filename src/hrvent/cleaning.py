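"""RR-interval cleaning and segment selection.

Premature (ectopic) beats show up as RR intervals far from their local
surroundings.  In place of manual visual editing, a beat is *removed* (not
interpolated) when it deviates by more than a configurable fraction from
the running median of a short centred window.  The entropy analysis then
runs on a fixed-length window of consecutive cleaned beats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import Series

__all__ = ["CleaningReport", "clean_rri", "select_segment"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CleaningReport:
    """Outcome of an RRI cleaning pass."""

    n_input: int
    n_removed: int
    removed_indices: tuple
    max_rel_dev: float
    window: int
    low_quality: bool = False  # more than 10% of beats removed


def clean_rri(
    series: Series, max_rel_dev: float = 0.25, window: int = 5
) -> tuple[Series, CleaningReport]:
    """Remove beats deviating from the running median of their window.

    A beat ``x_i`` is removed when ``|x_i - med_i| / med_i > max_rel_dev``,
    with ``med_i`` the median of the centred ``window``-beat neighbourhood
    (shrunk at the edges).  Removed beats are dropped outright.  If more
    than 10% of beats are removed the series is flagged low-quality and a
    warning is logged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = series.values
    if x.size < window:
        raise ValueError(f"series shorter than the cleaning window ({window})")
    if np.any(x <= 0):
        raise ValueError(
            "clean_rri expects RR intervals in ms (all positive); "
            "a relative deviation from the running median is undefined otherwise"
        )
    med = (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    rel_dev = np.abs(x - med) / med
    removed = np.flatnonzero(rel_dev > max_rel_dev)
    kept = np.delete(x, removed)
    low_quality = removed.size > 0.10 * x.size
    if low_quality:
        logger.warning(
            "low-quality series %s: removed %d of %d beats",
            series.label, removed.size, x.size,
        )
    report = CleaningReport(
        n_input=x.size, n_removed=int(removed.size),
        removed_indices=tuple(int(i) for i in removed),
        max_rel_dev=max_rel_dev, window=window, low_quality=low_quality,
    )
    return series.with_values(kept), report


def select_segment(
    series: Series, length: int = 512, policy: str = "first"
) -> Series:
    """Select a contiguous ``length``-beat analysis window.

    ``policy="first"`` takes the first ``length`` beats, ``"middle"``
    centres the window (start index ``floor((N - length) / 2)``).
    """
    if policy not in ("first", "middle"):
        raise ValueError("policy must be 'first' or 'middle'")
    x = series.values
    if x.size < length:
        raise ValueError(
            f"series has {x.size} beats, fewer than the requested {length}"
        )
    start = 0 if policy == "first" else (x.size - length) // 2
    return series.with_values(x[start : start + length])
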