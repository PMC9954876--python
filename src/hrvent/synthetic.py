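"""Synthetic benchmark signals and a synthetic RRI cohort.

Two families are provided:

* the five-process benchmark bank — Gaussian white, pink (1/f) and brown
  (random-walk) noises plus chaotic (omega = 4) and periodic (omega = 3.5)
  logistic-map series, 30 series of 512 samples per process by default —
  used to characterise how the entropy estimators rank randomness and
  complexity;

* a synthetic RR-interval cohort standing in for restricted clinical
  recordings.  Heart-period fluctuations are modelled as a mixture of an
  uncorrelated (vagal, white-noise-like) and a strongly correlated
  (sympathetic, Brown-noise-like) component around a constant mean RR
  interval.  Posture presets shift the sympathetic/vagal amplitude ratio
  upward when sitting; the spinal-cord-injury (SCI) preset swaps part of
  the vagal white component for a standardized chaotic logistic component
  at equal total variance, flattening the distance distribution (higher
  DistEn) while leaving second-order statistics matched with the
  able-bodied (AB) preset.  The cohort is an explicitly synthetic
  stand-in tuned only to reproduce directional contrasts, not absolute
  physiological entropy values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import Series

__all__ = [
    "SyntheticSpec",
    "gen_noise",
    "gen_logistic",
    "gen_bank",
    "gen_synthetic_rri",
    "gen_cohort",
    "COHORT_PRESETS",
    "PROCESSES",
]

PROCESSES = ("white", "pink", "brown", "logistic_chaotic", "logistic_periodic")

#: omega of the logistic recursion for the chaotic / periodic benchmark series
LOGISTIC_OMEGA = {"logistic_chaotic": 4.0, "logistic_periodic": 3.5}


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of one benchmark-bank process."""

    process: str
    n_samples: int = 512
    n_series: int = 30
    seed: int = 0
    process_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.process not in PROCESSES + ("rri_cohort",):
            raise ValueError(f"unknown process {self.process!r}")
        if self.n_samples < 64:
            raise ValueError("n_samples must be >= 64")
        if self.n_series < 1:
            raise ValueError("n_series must be >= 1")


def gen_noise(kind: str, n: int, seed: int) -> Series:
    """Gaussian white, pink (1/f power) or brown (random walk) noise.

    White noise is i.i.d. standard Gaussian.  Pink noise is synthesised in
    the frequency domain: the spectrum of a white series is shaped by a
    ``1/sqrt(f)`` amplitude profile (so power falls as 1/f) and transformed
    back, with the mean removed.  Brown noise is the cumulative sum of a
    white series.  Pink and brown series are rescaled by a deterministic
    (realization-independent) factor so their expected variance is of order
    one, making amplitudes comparable with the unit-variance white noise.
    All are deterministic given ``seed``.
    """
    if n < 64:
        raise ValueError("n must be >= 64")
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(n)
    if kind == "white":
        x = w
    elif kind == "pink":
        spec = np.fft.rfft(w)
        f = np.fft.rfftfreq(n)
        shape = np.zeros_like(f)
        shape[1:] = 1.0 / np.sqrt(f[1:])
        x = np.fft.irfft(spec * shape, n)
        x = x - x.mean()
        # expected variance of the shaped series (Parseval, real FFT):
        # each interior rfft bin carries 2*shape^2/n, the Nyquist bin 1*...
        gains2 = 2.0 * shape**2
        if n % 2 == 0:
            gains2[-1] = shape[-1] ** 2
        x = x / np.sqrt(gains2.sum() / n)
    elif kind == "brown":
        # index-averaged variance of a random walk is ~(n+1)/2
        x = np.cumsum(w) / np.sqrt((n + 1) / 2.0)
    else:
        raise ValueError(f"unknown noise kind {kind!r}")
    return Series(x, units="a.u.", label=f"{kind}", seed=seed)


def gen_logistic(
    omega: float, n: int, seed: int, transient: int = 1000
) -> Series:
    """Logistic recursion ``x(k+1) = omega * x(k) * (1 - x(k))``.

    The initial condition is drawn uniformly in (0.1, 0.9) from ``seed``
    and ``transient`` iterations are discarded so the orbit has settled on
    its attractor (4-cycle at omega = 3.5, chaotic at omega = 4).
    """
    if not 0 < omega <= 4:
        raise ValueError("omega must lie in (0, 4]")
    if transient < 0:
        raise ValueError("transient must be >= 0")
    rng = np.random.default_rng(seed)
    x0 = float(rng.uniform(0.1, 0.9))
    if x0 in (0.0, 1.0):
        raise ValueError("degenerate initial condition")
    out = np.empty(n)
    x = x0
    for _ in range(transient):
        x = omega * x * (1.0 - x)
    for k in range(n):
        x = omega * x * (1.0 - x)
        out[k] = x
    label = f"logistic_w{omega:g}"
    return Series(out, units="a.u.", label=label, seed=seed)


def gen_bank(spec: SyntheticSpec) -> list[Series]:
    """Generate ``n_series`` independent series of one benchmark process.

    The series ``i`` uses seed ``spec.seed + i`` so banks are reproducible
    and individual members can be regenerated in isolation.
    """
    out = []
    for i in range(spec.n_series):
        seed_i = spec.seed + i
        if spec.process in LOGISTIC_OMEGA:
            omega = spec.process_params.get("omega", LOGISTIC_OMEGA[spec.process])
            transient = spec.process_params.get("transient", 1000)
            s = gen_logistic(omega, spec.n_samples, seed_i, transient=transient)
        else:
            s = gen_noise(spec.process, spec.n_samples, seed_i)
        out.append(
            Series(s.values, units="a.u.", label=f"{spec.process}_{i:02d}", seed=seed_i)
        )
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


#: Mixture amplitudes (fractions of the target SD) for the cohort presets.
#: w = vagal white component, s = sympathetic correlated (1/f^beta)
#: component, c = chaotic component modelling the loss of integrative
#: coordination in SCI.  The presets keep w^2 + s^2 + c^2 = 1 so the total
#: SD is matched across cells; sitting raises s at the expense of w, and
#: the SCI presets swap part of w for c at equal variance.
COHORT_PRESETS: dict[tuple[str, str], dict[str, float]] = {
    ("AB", "supine"): {"w": 0.80, "s": 0.60, "c": 0.00},
    ("AB", "sitting"): {"w": 0.46, "s": 0.888, "c": 0.00},
    ("SCI", "supine"): {"w": 0.39, "s": 0.60, "c": 0.70},
    ("SCI", "sitting"): {"w": 0.2225, "s": 0.888, "c": 0.4025},
}

DEFAULT_MEAN_RRI = 900.0  # ms
DEFAULT_RRI_SD = 45.0  # ms, matched across presets
#: spectral exponent of the sympathetic component (power ~ 1/f^beta); 1/f
#: keeps the postural shift neutral with respect to the distance-
#: distribution entropy, which is the premise the cohort emulates
DEFAULT_SYMP_BETA = 1.0


def _correlated_noise(rng: np.random.Generator, n: int, beta: float) -> np.ndarray:
    """Standardized Gaussian noise with power spectrum ~ 1/f**beta."""
    g = rng.standard_normal(n)
    spec = np.fft.rfft(g)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-beta / 2.0)
    return _standardize(np.fft.irfft(spec * shape, n))


def gen_synthetic_rri(
    group: str,
    posture: str,
    n: int = 512,
    seed: int = 0,
    params: dict | None = None,
) -> Series:
    """One synthetic RR-interval series (ms) for a group/posture cell.

    ``RRI = mean_rri + sd * (w·white + s·correlated + c·chaotic)`` with
    each component standardized to unit sample SD, so the series SD is
    close to ``sd`` in every cell.  The correlated (sympathetic) component
    has a 1/f^beta power spectrum; sitting raises its weight at the
    expense of the white (vagal) one, lowering the series' randomness
    while leaving the distance-distribution entropy essentially unchanged.
    The SCI presets replace part of the white amplitude by the broadband
    chaotic component at equal total variance, flattening the distance
    distribution without altering SD.  Amplitudes are small relative to
    the mean (sd << mean/4), so RR intervals stay positive by
    construction.
    """
    if group not in ("AB", "SCI"):
        raise ValueError("group must be 'AB' or 'SCI'")
    if posture not in ("supine", "sitting"):
        raise ValueError("posture must be 'supine' or 'sitting'")
    if n < 128:
        raise ValueError("n must be >= 128")
    params = dict(params or {})
    weights = dict(COHORT_PRESETS[(group, posture)])
    weights.update({k: params[k] for k in ("w", "s", "c") if k in params})
    mean_rri = params.get("mean_rri", DEFAULT_MEAN_RRI)
    sd = params.get("sd", DEFAULT_RRI_SD)
    beta = params.get("symp_beta", DEFAULT_SYMP_BETA)
    if sd >= mean_rri / 4:
        raise ValueError("sd must be below mean_rri / 4 to keep RRI positive")

    rng = np.random.default_rng(seed)
    white = _standardize(rng.standard_normal(n))
    symp = _correlated_noise(rng, n, beta)
    mix = weights["w"] * white + weights["s"] * symp
    if weights["c"] > 0:
        chaotic = _standardize(
            gen_logistic(4.0, n, seed=int(rng.integers(2**31)), transient=1000).values
        )
        mix = mix + weights["c"] * chaotic
    x = mean_rri + sd * mix
    return Series(x, units="ms", label=f"{group}_{posture}", seed=seed)


def gen_cohort(
    n_ab: int = 34,
    n_sci: int = 14,
    n: int = 512,
    seed: int = 0,
    n_missing_supine_sci: int = 2,
    params: dict | None = None,
) -> list:
    """Synthetic cohort of per-subject, per-posture RRI recordings.

    Returns :class:`~hrvent.stats.CohortRecord` objects.  The default cell
    sizes mirror a typical study layout (34 AB, 14 SCI, with the supine
    recording missing in the last ``n_missing_supine_sci`` SCI subjects).
    Each recording gets its own sub-seed derived from ``seed``.
    """
    from .stats import CohortRecord

    records = []
    k = 0
    for group, n_group in (("AB", n_ab), ("SCI", n_sci)):
        for i in range(n_group):
            subject = f"{group}{i:03d}"
            missing_supine = group == "SCI" and i >= n_group - n_missing_supine_sci
            for posture in ("supine", "sitting"):
                if posture == "supine" and missing_supine:
                    continue
                series = gen_synthetic_rri(
                    group, posture, n=n, seed=seed + 7919 * k, params=params
                )
                records.append(
                    CohortRecord(
                        subject_id=subject, group=group, posture=posture,
                        series=Series(
                            series.values, units="ms",
                            label=f"{subject}_{posture}", seed=series.seed,
                        ),
                    )
                )
                k += 1
    return records
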