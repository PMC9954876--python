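"""Scikit-learn style entropy estimators.

Each estimator maps fixed-length series (rows of a 2-D array) to one entropy
value per series via :meth:`transform`, and exposes the richer
:meth:`estimate` returning an :class:`~hrvent.entropy.EntropyEstimate` with
full metadata for a single series.  The classes are stateless transformers:
``fit`` only records the input width, so they compose with sklearn pipelines
and model selection out of the box.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .entropy import (
    EntropyEstimate,
    _as_array_and_label,
    _distance_pair,
    embed,
    empirical_pdf,
    pairwise_chebyshev,
)
from .series import Series

__all__ = ["SampleEntropy", "FuzzyEntropy", "DistributionEntropy"]


def _match_count(d: np.ndarray, r: float) -> int:
    # strict inequality per the estimator definition; the r == 0 branch is
    # the degenerate zero-variance limit where only exact coincidences match
    if r > 0:
        return int(np.count_nonzero(d < r))
    return int(np.count_nonzero(d == 0))


def _membership(d: np.ndarray, r: float, n: float, form: str) -> np.ndarray:
    if r == 0:
        return (d == 0).astype(float)
    if form == "exp_dn_over_r":
        return np.exp(-(d**n) / r)
    if form == "exp_d_over_r_n":
        return np.exp(-((d / r) ** n))
    raise ValueError(f"unknown membership form {form!r}")


class _SeriesEntropyBase(TransformerMixin, BaseEstimator):
    """Common array plumbing: rows of X are independent series."""

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2:
            raise ValueError("X must be a 2-D array of series (one per row)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Entropy of each row; NaN where the estimate is undefined."""
        X = self._validate(X)
        return np.array([[self.estimate(row).value] for row in X])

    def estimate(self, series) -> EntropyEstimate:  # pragma: no cover - abstract
        raise NotImplementedError


class SampleEntropy(_SeriesEntropyBase):
    """Sample entropy (SampEn).

    Counts unordered pairs of delay-embedded template vectors whose
    Chebyshev distance is strictly below ``r = r_fraction * SD`` at
    dimensions ``m`` and ``m + 1`` (same template index set at both) and
    returns ``-ln[n_p(m+1, r) / n_p(m, r)]``.

    Parameters
    ----------
    m : int, default 2
        Embedding dimension.
    r_fraction : float, default 0.20
        Tolerance as a fraction of the standard deviation of the series
        being analysed.
    delay : int, default 1
        Lag between consecutive samples of a template vector (set to the
        scale ``tau`` by the multiscale profile).
    """

    def __init__(self, m: int = 2, r_fraction: float = 0.20, delay: int = 1):
        self.m = m
        self.r_fraction = r_fraction
        self.delay = delay

    def estimate(self, series: Series | np.ndarray) -> EntropyEstimate:
        x, label = _as_array_and_label(series)
        r = self.r_fraction * float(np.std(x))
        dm, dm1, _ = _distance_pair(x, self.m, self.delay)
        n_m = _match_count(dm, r)
        n_m1 = _match_count(dm1, r)
        if n_m == 0 or n_m1 == 0:
            which = "n_p(m)" if n_m == 0 else "n_p(m+1)"
            return EntropyEstimate(
                method="sampen", value=float("nan"), defined=False,
                m=self.m, delay=self.delay, r_used=r,
                n_pairs_m=n_m, n_pairs_m1=n_m1, label=label,
                undefined_reason=f"no template matches: {which} = 0",
            )
        value = math.log(n_m) - math.log(n_m1)
        return EntropyEstimate(
            method="sampen", value=value, defined=True,
            m=self.m, delay=self.delay, r_used=r,
            n_pairs_m=n_m, n_pairs_m1=n_m1, label=label,
        )


class FuzzyEntropy(_SeriesEntropyBase):
    """Fuzzy entropy (FuzzyEn), global variant without local trend removal.

    The similarity degree of a template pair is ``exp(-d**n / r)`` (or
    ``exp(-(d/r)**n)`` with ``membership="exp_d_over_r_n"``); ``phi^m`` is
    its mean over all ordered pairs ``j != i`` and the entropy is
    ``ln phi^m - ln phi^{m+1}``.  Memberships are strictly positive, so the
    estimate is always defined for ``r > 0``.
    """

    def __init__(
        self,
        m: int = 2,
        r_fraction: float = 0.20,
        n: float = 2.0,
        membership: str = "exp_dn_over_r",
        delay: int = 1,
    ):
        self.m = m
        self.r_fraction = r_fraction
        self.n = n
        self.membership = membership
        self.delay = delay

    def estimate(self, series: Series | np.ndarray) -> EntropyEstimate:
        x, label = _as_array_and_label(series)
        r = self.r_fraction * float(np.std(x))
        dm, dm1, _ = _distance_pair(x, self.m, self.delay)
        # unordered-pair mean equals the normalized double sum over ordered
        # pairs because the membership is symmetric in (i, j)
        phi_m = float(_membership(dm, r, self.n, self.membership).mean())
        phi_m1 = float(_membership(dm1, r, self.n, self.membership).mean())
        if phi_m == 0 or phi_m1 == 0:
            return EntropyEstimate(
                method="fuzzyen", value=float("nan"), defined=False,
                m=self.m, delay=self.delay, r_used=r,
                n_pairs_m=dm.size, n_pairs_m1=dm1.size, label=label,
                undefined_reason="zero similarity degree",
            )
        value = math.log(phi_m) - math.log(phi_m1)
        return EntropyEstimate(
            method="fuzzyen", value=value, defined=True,
            m=self.m, delay=self.delay, r_used=r,
            n_pairs_m=dm.size, n_pairs_m1=dm1.size, label=label,
        )


class DistributionEntropy(_SeriesEntropyBase):
    """Distribution entropy (DistEn).

    Normalized Shannon entropy of the empirical probability distribution of
    the dimension-``m`` pairwise template distances over ``n_bins``
    equispaced bins; no tolerance and no ``m + 1`` space are involved and
    the value lies in ``[0, 1]``.
    """

    def __init__(self, m: int = 2, n_bins: int = 512, delay: int = 1):
        self.m = m
        self.n_bins = n_bins
        self.delay = delay

    def epdf(self, series: Series | np.ndarray):
        """Empirical distance distribution used by :meth:`estimate`."""
        tvs = embed(series, self.m, self.delay)
        return empirical_pdf(pairwise_chebyshev(tvs), self.n_bins)

    def estimate(self, series: Series | np.ndarray) -> EntropyEstimate:
        x, label = _as_array_and_label(series)
        tvs = embed(x, self.m, self.delay)
        pds = pairwise_chebyshev(tvs)
        epdf = empirical_pdf(pds, self.n_bins)
        p = epdf.probabilities
        p = p[p > 0]
        shen = float(-(p * np.log2(p)).sum())
        value = shen / math.log2(self.n_bins)
        return EntropyEstimate(
            method="disten", value=value, defined=True,
            m=self.m, delay=self.delay, r_used=float("nan"),
            n_pairs_m=pds.distances.size, n_pairs_m1=0, label=label,
        )
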