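"""Scale-wise nonparametric cohort comparisons.

Posture contrasts (supine vs sitting within a group) are paired and use the
Wilcoxon signed-rank test; group contrasts (AB vs SCI within a posture) are
unpaired and use the Wilcoxon rank-sum (Mann-Whitney) test.  Each scale is
tested separately; only the scale-1 a-posteriori contrasts are adjusted for
multiple comparisons with the Benjamini-Hochberg false-discovery-rate
step-up, matching the convention that per-scale null hypotheses are
distinct while the scale-1 contrasts form one family.

The signed-rank null is enumerated exactly (including midrank ties) up to
n = 25 non-zero differences via an integer dynamic program over doubled
midranks; beyond that the tie-corrected normal approximation is used.  The
rank-sum test delegates to scipy with the analogous exact/asymptotic
switch.  The omnibus longitudinal model (a linear mixed-effects fit) is
deliberately out of scope: :func:`cohort_estimates` exports the tidy
long-format table such a model needs, so it can be fitted in any general
statistics package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .multiscale import FilterSpec, MultiscaleEntropy
from .series import EntropyParams, Series

__all__ = [
    "CohortRecord",
    "TestResult",
    "ComparisonResult",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "bh_fdr",
    "cohort_estimates",
    "compare_cohort",
]

#: switch to the normal approximation above these exact-enumeration sizes
EXACT_SIGNED_RANK_MAX_N = 25
EXACT_RANK_SUM_MAX_MIN_N = 10


@dataclass(frozen=True)
class CohortRecord:
    """One subject-posture RRI recording."""

    subject_id: str
    group: str  # "AB" | "SCI"
    posture: str  # "supine" | "sitting"
    series: Series

    def __post_init__(self) -> None:
        if self.group not in ("AB", "SCI"):
            raise ValueError("group must be 'AB' or 'SCI'")
        if self.posture not in ("supine", "sitting"):
            raise ValueError("posture must be 'supine' or 'sitting'")


@dataclass(frozen=True)
class TestResult:
    """Two-sided p-value with the statistic and evaluation route."""

    p: float
    statistic: float
    n: int
    defined: bool = True
    route: str = "exact"
    reason: str | None = None


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p of W+ by DP over the 2^n sign assignments.

    Midranks are doubled so tied (half-integer) ranks become integers; the
    DP array counts sign assignments reaching each doubled rank sum.
    """
    scaled = np.rint(2 * ranks).astype(int)
    total = int(scaled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for s in scaled:
        counts[s:] = counts[s:] + counts[:-s] if s > 0 else counts[s:] * 2
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    lo = counts[: w2 + 1].sum()
    hi = counts[w2:].sum()
    return float(min(1.0, 2 * min(lo, hi)))


def wilcoxon_signed_rank(paired_diffs: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped.  All-zero input yields an undefined
    result (flagged, not a sentinel p).  Exact enumeration (handling
    midrank ties) is used for up to 25 non-zero differences, the
    tie-corrected normal approximation beyond.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(
            p=float("nan"), statistic=float("nan"), n=0, defined=False,
            route="none", reason="all differences are zero",
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_SIGNED_RANK_MAX_N:
        p = _signed_rank_exact_p(ranks, w_plus)
        return TestResult(p=p, statistic=w_plus, n=n, route="exact")
    res = sps.wilcoxon(d, alternative="two-sided", method="approx", correction=False)
    return TestResult(p=float(res.pvalue), statistic=w_plus, n=n, route="approx")


def wilcoxon_rank_sum(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when the smaller group has at most 10 observations
    and the pooled sample is tie-free; tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and min(a.size, b.size) <= EXACT_RANK_SUM_MAX_MIN_N
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        p=float(res.pvalue), statistic=float(res.statistic),
        n=a.size + b.size, route="exact" if exact else "approx",
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries (undefined tests) are passed through unadjusted and do not
    count toward the number of hypotheses.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


@dataclass(frozen=True)
class ComparisonResult:
    """Cohort comparison output.

    ``estimates`` is the tidy long-format table (subject, group, posture,
    method, m, tau, value, defined) suitable as input to an external
    longitudinal model; ``contrasts`` holds one row per contrast and scale
    with raw and (scale-1 only) FDR-adjusted p-values and group summaries.
    """

    method: str
    params: EntropyParams
    estimates: pd.DataFrame
    contrasts: pd.DataFrame


def cohort_estimates(
    records: Sequence[CohortRecord],
    method: str = "sampen",
    params: EntropyParams | None = None,
    scales: Sequence[int] = (1,),
    filter: FilterSpec | None = None,
    r_mode: str = "per_scale",
) -> pd.DataFrame:
    """Per-record, per-scale entropy estimates as a tidy long table."""
    params = params or EntropyParams()
    spec = filter or FilterSpec()
    est = MultiscaleEntropy(
        method=method, m=params.m, r_fraction=params.r_fraction,
        scales=tuple(scales), filter_kind=spec.kind, order=spec.order,
        r_mode=r_mode, fuzzy_n=params.fuzzy_n,
        fuzzy_membership=params.fuzzy_membership, n_bins=params.n_bins,
    )
    rows = []
    for rec in records:
        prof = est.profile(rec.series)
        for tau, e in zip(prof.scales, prof.estimates):
            rows.append(
                {
                    "subject_id": rec.subject_id, "group": rec.group,
                    "posture": rec.posture, "method": method, "m": params.m,
                    "tau": tau, "value": e.value, "defined": e.defined,
                }
            )
    return pd.DataFrame(rows)


def _summary(values: np.ndarray) -> dict:
    n = values.size
    return {
        "mean": float(values.mean()) if n else float("nan"),
        "sem": float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "n": n,
    }


def compare_cohort(
    records: Sequence[CohortRecord],
    method: str = "sampen",
    params: EntropyParams | None = None,
    scales: Sequence[int] = (1,),
    filter: FilterSpec | None = None,
    r_mode: str = "per_scale",
) -> ComparisonResult:
    """Posture (paired) and group (unpaired) contrasts at each scale.

    Posture contrasts use only subjects with both recordings; group
    contrasts pool all recordings of the posture.  Undefined entropy
    estimates are excluded listwise per contrast with the exclusion count
    reported.  Scale-1 contrasts are BH-FDR adjusted as one family of
    a-posteriori comparisons; per-scale contrasts at tau >= 2 test distinct
    null hypotheses and are reported unadjusted.
    """
    params = params or EntropyParams()
    recs = list(records)
    seen = {(r.subject_id, r.posture) for r in recs}
    if len(seen) != len(recs):
        raise ValueError("duplicate (subject, posture) records")
    for group in ("AB", "SCI"):
        for posture in ("supine", "sitting"):
            n_cell = sum(1 for r in recs if r.group == group and r.posture == posture)
            if n_cell < 5:
                raise ValueError(
                    f"cell {group}/{posture} has {n_cell} subjects; need >= 5"
                )

    est = cohort_estimates(recs, method, params, scales, filter, r_mode)
    rows = []
    for tau, sub in est.groupby("tau"):
        ok = sub[sub["defined"]]
        n_undef = int(len(sub) - len(ok))
        # paired posture contrasts within each group
        for group in ("AB", "SCI"):
            wide = (
                ok[ok["group"] == group]
                .pivot(index="subject_id", columns="posture", values="value")
                .dropna()
            )
            if {"supine", "sitting"} <= set(wide.columns) and len(wide) > 0:
                diffs = (wide["supine"] - wide["sitting"]).to_numpy()
                res = wilcoxon_signed_rank(diffs)
                rows.append(
                    {
                        "contrast": "posture_within_group", "level": group,
                        "method": method, "m": params.m, "tau": tau,
                        "n": len(wide), "statistic": res.statistic,
                        "p_raw": res.p, "route": res.route,
                        "n_excluded_undefined": n_undef,
                        "mean_a": float(wide["supine"].mean()),
                        "mean_b": float(wide["sitting"].mean()),
                    }
                )
        # unpaired group contrasts within each posture
        for posture in ("supine", "sitting"):
            cell = ok[ok["posture"] == posture]
            a = cell.loc[cell["group"] == "AB", "value"].to_numpy()
            b = cell.loc[cell["group"] == "SCI", "value"].to_numpy()
            if a.size and b.size:
                res = wilcoxon_rank_sum(a, b)
                rows.append(
                    {
                        "contrast": "group_within_posture", "level": posture,
                        "method": method, "m": params.m, "tau": tau,
                        "n": res.n, "statistic": res.statistic,
                        "p_raw": res.p, "route": res.route,
                        "n_excluded_undefined": n_undef,
                        "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                    }
                )
    contrasts = pd.DataFrame(rows)
    contrasts["p_adjusted"] = np.nan
    tau1 = contrasts["tau"] == 1
    if tau1.any():
        contrasts.loc[tau1, "p_adjusted"] = bh_fdr(contrasts.loc[tau1, "p_raw"])
    return ComparisonResult(
        method=method, params=params, estimates=est, contrasts=contrasts
    )
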