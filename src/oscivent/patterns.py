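"""Pressure-controlled ventilation pattern synthesis.

Four breath-by-breath command generators used in the study design:

* ``PCV``  - conventional pressure control: constant driving pressure and
  respiratory rate.
* ``PCS``  - PCV plus a regular sigh every 30 s: a normal-length breath
  whose peak inspiratory pressure is raised to 35 cmH2O.
* ``PVV``  - physiologically variable ventilation: breath-wise driving
  pressures and periods follow a looped pre-recorded breathing series.
  The original diaphragm-EMG-derived recording is not public, so the
  default source is a synthetic stand-in: a seeded lognormal AR(1) series
  (CV ~15 %, lag-1 correlation ~0.6) that preserves the skew,
  autocorrelation and looping of physiological breathing.  A user CSV of
  breath amplitudes/periods can be substituted.
* ``MVV``  - mathematically variable ventilation: independent breath-wise
  tidal volumes drawn from a right-skewed discrete distribution over
  [0.6, 2.0] x V_T_ref with most mass below 1x and a heavy tail of large
  breaths (a configurable surrogate for the published recruitment-
  optimizing distribution), converted to driving pressures; the rate is
  fixed.

Delivery through a subject uses a quasi-static single-compartment model:
``V_T = dP * Crs * (1 - exp(-Ti/tau))`` with ``Crs = 1/H`` and
``tau = (Raw + Rtis) * Crs`` where ``Rtis = G / w_b**alpha`` is the tissue
resistance evaluated at the breathing frequency.  The study's target is a
median delivered V_T of 6 ml/kg at I:E = 1:2; ``calibrate_pressures``
rescales the driving-pressure schedule to hit it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BreathCommand",
    "PatternConfig",
    "VentilationPattern",
    "PatternStats",
    "MVVDistribution",
    "PVVSourceSeries",
    "generate_pattern",
    "deliver_volumes",
    "calibrate_pressures",
    "pattern_stats",
]

MODES = ("PCV", "PCS", "PVV", "MVV")


@dataclass(frozen=True)
class BreathCommand:
    start_time: float  # s
    driving_pressure: float  # cmH2O above PEEP
    inspiratory_time: float  # s
    expiratory_time: float  # s
    is_sigh: bool = False

    def __post_init__(self) -> None:
        if self.driving_pressure <= 0:
            raise ValueError("driving_pressure must be positive")

    @property
    def period(self) -> float:
        return self.inspiratory_time + self.expiratory_time


@dataclass(frozen=True)
class PatternConfig:
    mode: str
    peep: float = 6.0  # cmH2O
    target_median_vt: float = 6.0  # ml/kg
    baseline_rr: float = 40.0  # breaths/min
    sigh_interval: float = 30.0  # s, PCS only
    sigh_pip: float = 35.0  # cmH2O, PCS only
    variability: dict = field(default_factory=dict)  # mode-specific
    seed: int = 0
    duration: float = 3600.0  # s
    pressure_scale: float = 1.0  # set by calibrate_pressures

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")


@dataclass(frozen=True)
class VentilationPattern:
    breaths: tuple[BreathCommand, ...]
    delivered_vt: np.ndarray  # ml/kg per breath
    peep: float
    duration: float

    def __post_init__(self) -> None:
        starts = np.array([b.start_time for b in self.breaths])
        ends = starts + np.array([b.period for b in self.breaths])
        if np.any(np.diff(starts) <= 0) or np.any(ends[:-1] > starts[1:] + 1e-9):
            raise ValueError("breaths must be time-ordered and non-overlapping")
        if np.any(np.asarray(self.delivered_vt) <= 0):
            raise ValueError("delivered tidal volumes must be positive")

    @property
    def driving_pressures(self) -> np.ndarray:
        return np.array([b.driving_pressure for b in self.breaths])

    @property
    def sigh_flags(self) -> np.ndarray:
        return np.array([b.is_sigh for b in self.breaths])


@dataclass(frozen=True)
class PatternStats:
    median_vt: float  # ml/kg
    mean_vt: float  # ml/kg
    vt_cv: float  # %
    minute_ventilation: float  # ml/kg/min
    sigh_count: int
    pip_max: float  # cmH2O
    dp_quantiles: dict  # {q: cmH2O}


class MVVDistribution:
    """Right-skewed discrete tidal-volume distribution, relative to V_T_ref.

    Default support is 0.6-2.0 x V_T_ref in 0.1 steps: a hump centred below
    1x (62 % of mass under 1x) and a ~1/v^2 tail of large recruiting
    breaths carrying 28 % of the mass.  Weights are configurable.
    """

    def __init__(
        self,
        values: np.ndarray | None = None,
        weights: np.ndarray | None = None,
    ) -> None:
        if values is None:
            values = np.round(np.arange(0.6, 2.0 + 1e-9, 0.1), 10)
            hump = np.array([0.08, 0.16, 0.20, 0.18])  # 0.6-0.9
            tail_v = values[5:]  # 1.1-2.0
            tail = tail_v**-2.0
            tail *= 0.28 / tail.sum()
            weights = np.concatenate([hump, [0.10], tail])
        values = np.asarray(values, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if values.shape != weights.shape or np.any(weights < 0):
            raise ValueError("values and weights must match, weights non-negative")
        order = np.argsort(values)
        self.values = values[order]
        self.weights = weights[order] / weights.sum()

    def mean(self) -> float:
        return float(np.sum(self.values * self.weights))

    def var(self) -> float:
        m = self.mean()
        return float(np.sum(self.weights * (self.values - m) ** 2))

    def cv(self) -> float:
        """Coefficient of variation, %."""
        return float(np.sqrt(self.var()) / self.mean() * 100.0)

    def quantile(self, q: float) -> float:
        cum = np.cumsum(self.weights)
        return float(self.values[np.searchsorted(cum, q)])

    def median(self) -> float:
        return self.quantile(0.5)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(self.values, size=n, p=self.weights)


@dataclass(frozen=True)
class PVVSourceSeries:
    """Looped source of breath-wise relative amplitudes and periods (s)."""

    relative_amplitude: np.ndarray
    period_s: np.ndarray

    def __post_init__(self) -> None:
        if len(self.relative_amplitude) != len(self.period_s):
            raise ValueError("amplitude and period series must have equal length")
        if np.any(self.relative_amplitude <= 0) or np.any(self.period_s <= 0):
            raise ValueError("source series entries must be positive")

    def __len__(self) -> int:
        return len(self.relative_amplitude)

    @classmethod
    def synthetic_default(
        cls,
        n_breaths: int = 120,
        amp_cv: float = 0.15,
        period_cv: float = 0.10,
        ar1: float = 0.6,
        seed: int = 20190626,
    ) -> "PVVSourceSeries":
        """Synthetic stand-in for the pre-recorded physiological pattern.

        Lognormal AR(1) amplitude and period series with unit mean; the
        fixed internal seed makes it a fixed 'recording' that every PVV
        pattern loops over.
        """
        rng = np.random.default_rng(seed)

        def lognormal_ar1(cv: float) -> np.ndarray:
            sigma = np.sqrt(np.log1p(cv**2))
            innov_sd = sigma * np.sqrt(1.0 - ar1**2)
            x = np.empty(n_breaths)
            x[0] = rng.normal(0.0, sigma)
            for i in range(1, n_breaths):
                x[i] = ar1 * x[i - 1] + rng.normal(0.0, innov_sd)
            return np.exp(x - sigma**2 / 2.0)

        amp = lognormal_ar1(amp_cv)
        per = lognormal_ar1(period_cv)
        return cls(relative_amplitude=amp, period_s=per)


# ---------------------------------------------------------------------------
# subject response model


def _subject_mechanics(subject) -> tuple[float, float, float, float]:
    """(Crs [l/cmH2O], Raw, G, alpha) from any object carrying .cpm/.weight."""
    cpm = subject.cpm
    return 1.0 / cpm.h, cpm.raw, cpm.g, cpm.alpha


def _time_constant(subject, breath_rate_per_min: float) -> float:
    """tau = (Raw + G/w_b^alpha) * Crs at the breathing frequency."""
    crs, raw, g, alpha = _subject_mechanics(subject)
    w_b = 2.0 * np.pi * breath_rate_per_min / 60.0
    r_tis = g / w_b**alpha
    return (raw + r_tis) * crs


def _vt_ml_per_kg(dp: np.ndarray, ti: np.ndarray, subject, tau: float) -> np.ndarray:
    crs = 1.0 / subject.cpm.h
    vt_l = dp * crs * (1.0 - np.exp(-np.asarray(ti) / tau))
    return vt_l * 1000.0 / subject.weight


def _reference_driving_pressure(config: PatternConfig, subject) -> float:
    """Driving pressure delivering the target V_T for a regular breath."""
    tau = _time_constant(subject, config.baseline_rr)
    period = 60.0 / config.baseline_rr
    ti = period / 3.0  # I:E = 1:2
    crs = 1.0 / subject.cpm.h
    vt_l = config.target_median_vt * subject.weight / 1000.0
    return vt_l / (crs * (1.0 - np.exp(-ti / tau)))


# ---------------------------------------------------------------------------
# generators


def _breath_schedule(config: PatternConfig, subject) -> list[BreathCommand]:
    dp_ref = _reference_driving_pressure(config, subject) * config.pressure_scale
    period_ref = 60.0 / config.baseline_rr
    rng = np.random.default_rng(config.seed)
    breaths: list[BreathCommand] = []

    if config.mode in ("PCV", "PCS"):
        n = int(np.floor(config.duration / period_ref + 1e-9))
        for i in range(n):
            breaths.append(
                BreathCommand(
                    start_time=i * period_ref,
                    driving_pressure=dp_ref,
                    inspiratory_time=period_ref / 3.0,
                    expiratory_time=2.0 * period_ref / 3.0,
                )
            )
        if config.mode == "PCS":
            # one sigh at each multiple of the sigh interval: the first
            # breath starting at or after k * sigh_interval, normal timing,
            # PIP raised to sigh_pip (not rescaled by calibration)
            sigh_dp = config.sigh_pip - config.peep
            if sigh_dp <= 0:
                raise ValueError("sigh PIP must exceed PEEP")
            k = 0
            for i, b in enumerate(breaths):
                if b.start_time >= k * config.sigh_interval - 1e-9:
                    breaths[i] = replace(b, driving_pressure=sigh_dp, is_sigh=True)
                    k += 1
        return breaths

    if config.mode == "PVV":
        scale = float(config.variability.get("scale", 1.0))
        source = config.variability.get("source")
        if source is None:
            source = PVVSourceSeries.synthetic_default()
        t = 0.0
        i = 0
        while True:
            a = source.relative_amplitude[i % len(source)] ** scale
            p = source.period_s[i % len(source)] ** scale * period_ref
            if t + p > config.duration + 1e-9:
                break
            breaths.append(
                BreathCommand(
                    start_time=t,
                    driving_pressure=dp_ref * a,
                    inspiratory_time=p / 3.0,
                    expiratory_time=2.0 * p / 3.0,
                )
            )
            t += p
            i += 1
        return breaths

    # MVV: independent draws of relative V_T, fixed rate
    dist = config.variability.get("distribution")
    if dist is None:
        dist = MVVDistribution()
    n = int(np.floor(config.duration / period_ref + 1e-9))
    rel_vt = dist.sample(rng, n)
    for i in range(n):
        breaths.append(
            BreathCommand(
                start_time=i * period_ref,
                driving_pressure=dp_ref * rel_vt[i],
                inspiratory_time=period_ref / 3.0,
                expiratory_time=2.0 * period_ref / 3.0,
            )
        )
    return breaths


def generate_pattern(config: PatternConfig, subject) -> VentilationPattern:
    """Generate the breath schedule and deliver it through the subject."""
    breaths = tuple(_breath_schedule(config, subject))
    if not breaths:
        raise ValueError("duration too short for a single breath")
    tau = _time_constant(subject, config.baseline_rr)
    dp = np.array([b.driving_pressure for b in breaths])
    ti = np.array([b.inspiratory_time for b in breaths])
    vt = _vt_ml_per_kg(dp, ti, subject, tau)
    return VentilationPattern(
        breaths=breaths, delivered_vt=vt, peep=config.peep, duration=config.duration
    )


def deliver_volumes(pattern: VentilationPattern, subject) -> np.ndarray:
    """Quasi-static single-compartment delivered V_T (ml/kg) per breath."""
    periods = np.array([b.period for b in pattern.breaths])
    rr = 60.0 / float(np.median(periods))
    tau = _time_constant(subject, rr)
    dp = pattern.driving_pressures
    ti = np.array([b.inspiratory_time for b in pattern.breaths])
    return _vt_ml_per_kg(dp, ti, subject, tau)


def calibrate_pressures(
    config: PatternConfig,
    subject,
    target: float | None = None,
    statistic: str = "median",
    tol: float = 0.01,
    max_iter: int = 20,
) -> PatternConfig:
    """Scale the driving-pressure schedule until the V_T statistic hits target.

    Mirrors the hourly bedside check: generate the pattern, compare the
    chosen delivered-V_T statistic with the target and rescale.  For the
    linear subject model the exact rescale converges on the second pass.
    Sigh breaths keep their fixed 35 cmH2O PIP and are not rescaled.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    stat_fn = np.median if statistic == "median" else np.mean
    if target is None:
        target = config.target_median_vt
    cfg = config
    last = np.nan
    for _ in range(max_iter):
        pattern = generate_pattern(cfg, subject)
        last = float(stat_fn(pattern.delivered_vt))
        if abs(last - target) <= tol * target:
            return cfg
        cfg = replace(cfg, pressure_scale=cfg.pressure_scale * target / last)
    raise RuntimeError(
        f"pressure calibration did not converge in {max_iter} iterations; "
        f"last {statistic} V_T = {last:.3f} ml/kg (target {target})"
    )


def pattern_stats(pattern: VentilationPattern) -> PatternStats:
    """Summary statistics of a generated pattern."""
    vt = np.asarray(pattern.delivered_vt, dtype=float)
    if len(vt) == 0:
        raise ValueError("empty pattern")
    dp = pattern.driving_pressures
    qs = (0.05, 0.25, 0.5, 0.75, 0.95)
    return PatternStats(
        median_vt=float(np.median(vt)),
        mean_vt=float(np.mean(vt)),
        vt_cv=float(np.std(vt, ddof=1) / np.mean(vt) * 100.0) if len(vt) > 1 else 0.0,
        minute_ventilation=float(vt.sum() / (pattern.duration / 60.0)),
        sigh_count=int(np.sum(pattern.sigh_flags)),
        pip_max=float(pattern.peep + dp.max()),
        dp_quantiles={q: float(np.quantile(dp, q)) for q in qs},
    )
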