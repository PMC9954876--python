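"""Sample, Fuzzy and Distribution entropy of a single series.

The three estimators share the same geometric machinery: a series
``x_0 … x_{N-1}`` is embedded as template vectors

    X_i = [x_i, x_{i+delay}, …, x_{i+(m-1)·delay}],   i = 0 … N − m·delay − 1,

and all pairwise Chebyshev (infinity-norm) distances between templates are
computed.  Sample entropy (SampEn) counts pairs closer than a hard tolerance
``r`` at dimensions ``m`` and ``m+1`` and reports the negative log of the
ratio of counts; Fuzzy entropy (FuzzyEn) replaces the hard count with a
graded exponential similarity degree; Distribution entropy (DistEn) ignores
any tolerance and takes the normalized Shannon entropy of the empirical
distribution of the dimension-``m`` distances over ``M`` equispaced bins.

The same number of template vectors, ``N − m·delay``, is used at both
dimensions ``m`` and ``m+1`` so that the two SampEn pair counts run over
identical index sets and their normalizations cancel.  The embedding delay
defaults to 1 and is raised to the scale ``tau`` by the multiscale module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .series import EntropyParams, Series

__all__ = [
    "TemplateVectorSet",
    "PairDistanceSet",
    "EPDF",
    "EntropyEstimate",
    "embed",
    "pairwise_chebyshev",
    "empirical_pdf",
    "sample_entropy",
    "fuzzy_entropy",
    "distribution_entropy",
]


@dataclass(frozen=True)
class TemplateVectorSet:
    """Delay-embedded template vectors of one series."""

    vectors: np.ndarray  # shape (n_vectors, m)
    m: int
    delay: int
    source_length: int

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class PairDistanceSet:
    """Chebyshev distances for every unordered template pair i < j."""

    distances: np.ndarray  # length n_vectors * (n_vectors - 1) / 2
    n_vectors: int


@dataclass(frozen=True)
class EPDF:
    """Empirical probability distribution of pairwise distances."""

    bin_edges: np.ndarray  # M + 1 edges spanning the observed distance range
    probabilities: np.ndarray  # M relative frequencies, summing to 1


@dataclass(frozen=True)
class EntropyEstimate:
    """One entropy value with the settings that produced it.

    ``value`` is NaN and ``defined`` False when SampEn has no matching pairs
    at one of the two dimensions; ``undefined_reason`` then names the empty
    count.  Downstream summaries must skip undefined estimates rather than
    average a sentinel.
    """

    method: str  # "sampen" | "fuzzyen" | "disten"
    value: float
    defined: bool
    m: int
    delay: int
    r_used: float  # absolute tolerance actually applied (NaN for disten)
    n_pairs_m: int
    n_pairs_m1: int
    label: str = ""
    undefined_reason: str | None = None


def _min_length(m: int, delay: int) -> int:
    # need at least 2 template vectors: N - m*delay >= 2
    return m * delay + 2


def _template_matrix(x: np.ndarray, m: int, delay: int, count: int) -> np.ndarray:
    idx = np.arange(count)[:, None] + delay * np.arange(m)[None, :]
    return x[idx]


def embed(series: Series | np.ndarray, m: int, delay: int = 1) -> TemplateVectorSet:
    """Delay-embed a series into ``N − m·delay`` template vectors.

    Vector ``i`` (0-based) is ``[x_i, x_{i+delay}, …, x_{i+(m-1)·delay}]``.
    The count deliberately stops at ``N − m·delay`` — one vector short of
    the maximum for dimension ``m`` — so the same index set serves both
    dimensions ``m`` and ``m + 1`` of the conditional-probability
    estimators.
    """
    x = series.values if isinstance(series, Series) else np.asarray(series, float)
    n = x.size
    if m < 1 or int(m) != m:
        raise ValueError("embedding dimension m must be a positive integer")
    if delay < 1 or int(delay) != delay:
        raise ValueError("delay must be a positive integer")
    count = n - m * delay
    if count < 2:
        raise ValueError(
            f"series of length {n} too short for (m={m}, delay={delay}); "
            f"need N >= {_min_length(m, delay)}"
        )
    return TemplateVectorSet(
        vectors=_template_matrix(x, m, delay, count), m=m, delay=delay, source_length=n
    )


def pairwise_chebyshev(tvs: TemplateVectorSet) -> PairDistanceSet:
    """Infinity-norm distance for every unordered vector pair ``i < j``."""
    if tvs.n_vectors < 2:
        raise ValueError("need at least 2 template vectors")
    return PairDistanceSet(
        distances=pdist(tvs.vectors, metric="chebyshev"), n_vectors=tvs.n_vectors
    )


def empirical_pdf(pds: PairDistanceSet | np.ndarray, n_bins: int) -> EPDF:
    """Histogram the pairwise distances on ``n_bins`` equispaced bins.

    The bins span ``[min(d), max(d)]`` with the rightmost edge inclusive and
    probabilities equal to relative frequencies.  When every distance is
    identical the range is degenerate and all mass is assigned to the first
    bin (the resulting distribution has zero Shannon entropy either way).
    """
    d = pds.distances if isinstance(pds, PairDistanceSet) else np.asarray(pds, float)
    if d.size == 0:
        raise ValueError("empty distance set")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = float(d.min()), float(d.max())
    if lo == hi:
        edges = np.full(n_bins + 1, lo)
        probs = np.zeros(n_bins)
        probs[0] = 1.0
        return EPDF(bin_edges=edges, probabilities=probs)
    counts, edges = np.histogram(d, bins=n_bins, range=(lo, hi))
    return EPDF(bin_edges=edges, probabilities=counts / d.size)


def _distance_pair(x: np.ndarray, m: int, delay: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Distances at dimensions m and m+1 over the shared index set."""
    count = x.size - m * delay
    if count < 2:
        raise ValueError(
            f"series of length {x.size} too short for (m={m}, delay={delay}); "
            f"need N >= {_min_length(m, delay)}"
        )
    dm = pdist(_template_matrix(x, m, delay, count), metric="chebyshev")
    dm1 = pdist(_template_matrix(x, m + 1, delay, count), metric="chebyshev")
    return dm, dm1, count


def _as_array_and_label(series: Series | np.ndarray) -> tuple[np.ndarray, str]:
    if isinstance(series, Series):
        return series.values, series.label
    return np.asarray(series, float), ""


def sample_entropy(
    series: Series | np.ndarray,
    params: EntropyParams | None = None,
    delay: int = 1,
) -> EntropyEstimate:
    """Sample entropy: ``−ln[n_p(m+1, r) / n_p(m, r)]``.

    ``n_p(m, r)`` counts unordered template pairs with Chebyshev distance
    strictly below ``r = r_fraction · SD(series)``; self-pairs are excluded.
    When either count is zero the estimate is flagged undefined.
    """
    from .estimators import SampleEntropy

    params = params or EntropyParams()
    return SampleEntropy(
        m=params.m, r_fraction=params.r_fraction, delay=delay
    ).estimate(series)


def fuzzy_entropy(
    series: Series | np.ndarray,
    params: EntropyParams | None = None,
    delay: int = 1,
) -> EntropyEstimate:
    """Fuzzy entropy: ``ln φ^m − ln φ^{m+1}`` with exponential similarity.

    ``φ^m`` is the mean, over all ordered template pairs ``j ≠ i``, of the
    similarity degree ``exp(−d^n / r)`` (global variant, no local trend
    removal).  Memberships are strictly positive, so the estimate is always
    defined and non-negative.
    """
    from .estimators import FuzzyEntropy

    params = params or EntropyParams()
    return FuzzyEntropy(
        m=params.m,
        r_fraction=params.r_fraction,
        n=params.fuzzy_n,
        membership=params.fuzzy_membership,
        delay=delay,
    ).estimate(series)


def distribution_entropy(
    series: Series | np.ndarray,
    params: EntropyParams | None = None,
    delay: int = 1,
) -> EntropyEstimate:
    """Distribution entropy: normalized Shannon entropy of the distance ePDF.

    Uses the dimension-``m`` distances only — no tolerance and no ``m+1``
    space — binned on ``M`` equispaced bins; the Shannon entropy in bits is
    divided by ``log2(M)`` so the value lies in ``[0, 1]``.
    """
    from .estimators import DistributionEntropy

    params = params or EntropyParams()
    return DistributionEntropy(m=params.m, n_bins=params.n_bins, delay=delay).estimate(
        series
    )


def estimates_to_frame(estimates: Sequence[EntropyEstimate]):
    """Tabulate estimates (one row each) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "series_label": [e.label for e in estimates],
            "method": [e.method for e in estimates],
            "m": [e.m for e in estimates],
            "delay": [e.delay for e in estimates],
            "r_used": [e.r_used for e in estimates],
            "value": [e.value for e in estimates],
            "defined": [e.defined for e in estimates],
        }
    )


def epdf_to_frame(epdf: EPDF):
    """Tabulate an ePDF as (bin_left, bin_right, probability) rows."""
    import pandas as pd

    return pd.DataFrame(
        {
            "bin_left": epdf.bin_edges[:-1],
            "bin_right": epdf.bin_edges[1:],
            "probability": epdf.probabilities,
        }
    )
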