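"""Forced-oscillation (wave-tube) measurement chain.

The wave-tube technique estimates a respiratory load impedance from the
pressure transfer ratio measured across a tube of known acoustic properties.
A small-amplitude pseudorandom multi-sine (0.5-20.75 Hz, 1 cmH2O
peak-to-peak) is driven through the tube into the airway opening; lateral
pressures at the loudspeaker end (P1) and tracheal end (P2) are recorded
during short apnoeic windows, and the complex load impedance follows from
the two-port transmission-line equations.

Everything here works in cmH2O / litre / second units for impedances.
Internal acoustics are computed in CGS and converted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "ForcingSignal",
    "TimeSeriesRecording",
    "WaveTubeSpec",
    "ImpedanceSpectrum",
    "TransferFunction",
    "default_component_grid",
    "make_forcing_signal",
    "tube_coefficients",
    "transfer_function",
    "load_impedance",
    "ensemble_average",
    "subtract_instrument",
    "simulate_measurement",
]

#: dyn/cm^2 per cmH2O
_CMH2O_IN_DYN_CM2 = 980.665
#: convert acoustic impedance dyn.s/cm^5 -> cmH2O.s/l
_CGS_TO_CMH2O_S_L = 1000.0 / _CMH2O_IN_DYN_CM2

#: anti-aliasing corner frequency of the acquisition chain, Hz
ANTIALIAS_CORNER_HZ = 25.0
ANTIALIAS_ORDER = 4


@dataclass(frozen=True)
class WaveTubeSpec:
    """Geometry and gas properties of the measuring wave-tube.

    Defaults describe a 100 cm x 0.375 cm (ID) polyethylene tube filled with
    body-temperature humidified air (37 C, ~100% RH): density 1.10e-3 g/cm3,
    dynamic viscosity 1.86e-4 poise, speed of sound 3.53e4 cm/s.
    """

    length: float = 100.0  # cm
    internal_diameter: float = 0.375  # cm
    gas_density: float = 1.10e-3  # g/cm^3
    gas_viscosity: float = 1.86e-4  # poise
    speed_of_sound: float = 3.53e4  # cm/s

    def __post_init__(self) -> None:
        for name in ("length", "internal_diameter", "gas_density", "speed_of_sound"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.gas_viscosity < 0:
            raise ValueError("gas_viscosity must be non-negative")

    @property
    def radius(self) -> float:
        return self.internal_diameter / 2.0

    @property
    def area(self) -> float:
        return np.pi * self.radius**2


@dataclass(frozen=True)
class ForcingSignal:
    """Pseudorandom multi-sine forcing pressure waveform."""

    samples: np.ndarray  # cmH2O
    sample_rate: float  # Hz
    duration: float  # s
    component_freqs: np.ndarray  # Hz
    component_phases: np.ndarray  # rad
    component_amps: np.ndarray  # cmH2O, per-component sine amplitude
    peak_to_peak: float  # cmH2O


@dataclass(frozen=True)
class TimeSeriesRecording:
    """One 8-s two-channel wave-tube pressure recording."""

    p1: np.ndarray  # cmH2O, loudspeaker end
    p2: np.ndarray  # cmH2O, tracheal end
    sample_rate: float = 256.0
    duration: float = 8.0

    def __post_init__(self) -> None:
        if len(self.p1) != len(self.p2):
            raise ValueError("p1 and p2 must have identical length")
        n = round(self.duration * self.sample_rate)
        if n != len(self.p1):
            raise ValueError(
                f"duration*sample_rate = {self.duration * self.sample_rate} "
                f"does not match trace length {len(self.p1)}"
            )


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance on a discrete frequency grid (cmH2O.s/l)."""

    freqs: np.ndarray  # Hz
    values: np.ndarray  # complex
    n_averaged: int = 1

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        v = np.asarray(self.values, dtype=complex)
        if f.ndim != 1 or v.shape != f.shape:
            raise ValueError("freqs and values must be matching 1-D arrays")
        if len(f) and np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "values", v)

    def same_grid(self, other: "ImpedanceSpectrum", rtol: float = 1e-9) -> bool:
        return self.freqs.shape == other.freqs.shape and np.allclose(
            self.freqs, other.freqs, rtol=rtol, atol=1e-12
        )


#: alias: the endotracheal tube + circuit impedance has the same shape
InstrumentImpedance = ImpedanceSpectrum


@dataclass(frozen=True)
class TransferFunction:
    """Complex P1/P2 ratios at the forcing component frequencies."""

    freqs: np.ndarray
    values: np.ndarray


def default_component_grid(
    band: tuple[float, float] = (0.5, 20.75), step: float = 0.25
) -> np.ndarray:
    """Mutually non-harmonic component frequencies on a 0.25 Hz grid.

    Greedy selection from the lowest grid index upward, rejecting any index
    that is an integer multiple of one already chosen.  For the default band
    this yields the prime multiples of 0.25 Hz from 0.5 to 20.75 Hz
    (23 components), so no component is a harmonic of another and
    inter-modulation products fall off the component set.
    """
    lo, hi = band
    kmin = int(np.ceil(lo / step - 1e-9))
    kmax = int(np.floor(hi / step + 1e-9))
    chosen: list[int] = []
    for k in range(max(kmin, 1), kmax + 1):
        if any(k % c == 0 for c in chosen):
            continue
        chosen.append(k)
    return np.array(chosen, dtype=float) * step


def make_forcing_signal(
    band: tuple[float, float] = (0.5, 20.75),
    sample_rate: float = 256.0,
    duration: float = 8.0,
    peak_to_peak: float = 1.0,
    seed: int = 0,
) -> ForcingSignal:
    """Synthesize the pseudorandom multi-sine forcing pressure.

    Components sit on a 0.25 Hz non-harmonic grid inside ``band``; phases
    are drawn uniformly from a seeded generator and the summed waveform is
    rescaled so that max - min equals ``peak_to_peak`` exactly.
    """
    lo, hi = float(band[0]), float(band[1])
    nyquist = sample_rate / 2.0
    if not (0 < lo <= hi):
        raise ValueError(f"band must satisfy 0 < lo <= hi, got {band}")
    if hi >= nyquist:
        raise ValueError(
            f"band upper edge {hi} Hz exceeds the Nyquist limit {nyquist} Hz "
            f"for sample rate {sample_rate} Hz"
        )
    if duration <= 2.0 / lo:
        raise ValueError(
            f"duration {duration} s too short: need > {2.0 / lo} s "
            f"(two periods of the lowest component)"
        )
    n = duration * sample_rate
    if abs(n - round(n)) > 1e-9:
        raise ValueError("duration * sample_rate must be an integer sample count")
    n = int(round(n))

    freqs = default_component_grid((lo, hi))
    if len(freqs) == 0:
        raise ValueError(f"no grid components inside band {band}")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(freqs))

    t = np.arange(n) / sample_rate
    raw = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
    span = raw.max() - raw.min()
    scale = peak_to_peak / span
    samples = raw * scale
    amps = np.full(len(freqs), scale)
    return ForcingSignal(
        samples=samples,
        sample_rate=sample_rate,
        duration=duration,
        component_freqs=freqs,
        component_phases=phases,
        component_amps=amps,
        peak_to_peak=peak_to_peak,
    )


def tube_coefficients(
    tube: WaveTubeSpec, freqs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Characteristic impedance Z0 and propagation wavenumber gamma.

    Lossy transmission-line model with low-frequency viscothermal
    (Poiseuille-regime) wall losses: per unit length the series impedance is
    ``R' + j w L'`` with ``R' = 8 mu / (pi a^4)`` (Poiseuille resistance)
    and ``L' = rho / A`` (gas inertance), and the shunt admittance is
    ``j w C'`` with ``C' = A / (rho c^2)`` (gas compressibility).  Then
    ``gamma = sqrt(Z' Y')`` (1/cm) and ``Z0 = sqrt(Z'/Y')``, converted to
    cmH2O.s/l.  In the lossless limit ``|Z0| -> rho c / A`` and gamma is
    purely imaginary.
    """
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    a = tube.radius
    area = tube.area
    w = 2.0 * np.pi * f
    r_visc = 8.0 * tube.gas_viscosity / (np.pi * a**4)
    z_series = r_visc + 1j * w * tube.gas_density / area
    y_shunt = 1j * w * area / (tube.gas_density * tube.speed_of_sound**2)
    gamma = np.sqrt(z_series * y_shunt)
    # principal branch gives Re(gamma) >= 0 for passive lines
    gamma = np.where(gamma.real < 0, -gamma, gamma)
    z0 = np.sqrt(z_series / y_shunt) * _CGS_TO_CMH2O_S_L
    return z0, gamma


def transfer_function(
    rec: TimeSeriesRecording, component_freqs: np.ndarray
) -> TransferFunction:
    """Cross-spectral P1/P2 estimate at the forcing component frequencies.

    A single full-length rectangular window is used; components with an
    integer number of periods in the record land exactly on FFT bins, so
    the estimate is leakage-free.  Off-grid components are rejected rather
    than interpolated.
    """
    f = np.asarray(component_freqs, dtype=float)
    n = len(rec.p1)
    bins = f * n / rec.sample_rate
    k = np.round(bins).astype(int)
    if np.any(np.abs(bins - k) > 1e-6):
        bad = f[np.abs(bins - k) > 1e-6]
        raise ValueError(f"component frequencies not on the FFT grid: {bad}")
    if np.any(k >= n // 2 + 1) or np.any(k < 1):
        raise ValueError("component frequencies outside the resolvable FFT range")
    s1 = np.fft.rfft(rec.p1)
    s2 = np.fft.rfft(rec.p2)
    # single-window cross-spectral ratio  S12 / S22 == P1/P2
    values = (s1[k] * np.conj(s2[k])) / (s2[k] * np.conj(s2[k]))
    return TransferFunction(freqs=f, values=values)


def load_impedance(tf: TransferFunction, tube: WaveTubeSpec) -> ImpedanceSpectrum:
    """Invert the two-port line equation for the terminating load.

    ``Zload = Z0 sinh(gamma L) / (P1/P2 - cosh(gamma L))``.  Frequencies at
    which the ratio coincides with cosh(gamma L) (an open-end pole) are
    dropped with a warning; on the physiological grid with realistic loads
    this cannot occur.
    """
    z0, gamma = tube_coefficients(tube, tf.freqs)
    gl = gamma * tube.length
    ch = np.cosh(gl)
    denom = tf.values - ch
    ok = np.abs(denom) > 1e-12 * (1.0 + np.abs(ch))
    if not np.all(ok):
        warnings.warn(
            f"infinite-impedance pole at {tf.freqs[~ok]} Hz; dropping",
            RuntimeWarning,
            stacklevel=2,
        )
    z = z0[ok] * np.sinh(gl[ok]) / denom[ok]
    return ImpedanceSpectrum(freqs=tf.freqs[ok], values=z)


def ensemble_average(spectra: list[ImpedanceSpectrum]) -> ImpedanceSpectrum:
    """Complex per-frequency mean of 2-10 replicate spectra on one grid."""
    if not 2 <= len(spectra) <= 10:
        raise ValueError(f"need 2-10 spectra, got {len(spectra)}")
    first = spectra[0]
    for s in spectra[1:]:
        if not first.same_grid(s):
            raise ValueError("spectra are not on identical frequency grids")
    values = np.mean([s.values for s in spectra], axis=0)
    n = sum(s.n_averaged for s in spectra)
    return ImpedanceSpectrum(freqs=first.freqs.copy(), values=values, n_averaged=n)


def subtract_instrument(
    z: ImpedanceSpectrum, instr: ImpedanceSpectrum
) -> ImpedanceSpectrum:
    """Remove the endotracheal tube + circuit impedance (series subtraction)."""
    if not z.same_grid(instr):
        raise ValueError("instrument impedance not on the spectrum's grid")
    return ImpedanceSpectrum(
        freqs=z.freqs.copy(), values=z.values - instr.values, n_averaged=z.n_averaged
    )


def _antialias_response(freqs: np.ndarray, sample_rate: float) -> np.ndarray:
    """Steady-state complex response of the 25 Hz 4th-order anti-alias filter."""
    sos = sps.butter(
        ANTIALIAS_ORDER, ANTIALIAS_CORNER_HZ, btype="low", output="sos", fs=sample_rate
    )
    try:
        _, h = sps.freqz_sos(sos, worN=freqs, fs=sample_rate)
    except AttributeError:  # older scipy
        _, h = sps.sosfreqz(sos, worN=freqs, fs=sample_rate)
    return h


def simulate_measurement(
    zload: ImpedanceSpectrum,
    tube: WaveTubeSpec,
    forcing: ForcingSignal,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TimeSeriesRecording:
    """Synthesize a P1/P2 recording for a known terminating load.

    The forcing waveform defines the P1 component amplitudes/phases; P2
    components follow from the forward two-port relation
    ``P1/P2 = cosh(gamma L) + (Z0/Zload) sinh(gamma L)``.  The acquisition
    chain's 25 Hz anti-alias filter is applied as its steady-state frequency
    response, identically on both channels (recordings are taken in
    periodic steady state during apnoea), so it cancels exactly in the
    ratio.  Additive white Gaussian sensor noise is seeded.
    """
    if len(zload.freqs) != len(forcing.component_freqs) or not np.allclose(
        zload.freqs, forcing.component_freqs, rtol=1e-9, atol=1e-12
    ):
        raise ValueError("zload must be defined exactly on the forcing component grid")
    f = forcing.component_freqs
    z0, gamma = tube_coefficients(tube, f)
    gl = gamma * tube.length
    tf_fwd = np.cosh(gl) + (z0 / zload.values) * np.sinh(gl)
    h = _antialias_response(f, forcing.sample_rate)

    n = int(round(forcing.duration * forcing.sample_rate))
    t = np.arange(n) / forcing.sample_rate
    # each component is  Im( C * exp(j*2*pi*f*t) )  with C = A*exp(j*phi)
    c1 = forcing.component_amps * np.exp(1j * forcing.component_phases) * h
    c2 = c1 / tf_fwd
    phasor = np.exp(2j * np.pi * f[:, None] * t[None, :])
    p1 = np.imag(c1[:, None] * phasor).sum(axis=0)
    p2 = np.imag(c2[:, None] * phasor).sum(axis=0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p1 = p1 + rng.normal(0.0, noise_sd, size=n)
        p2 = p2 + rng.normal(0.0, noise_sd, size=n)
    return TimeSeriesRecording(
        p1=p1, p2=p2, sample_rate=forcing.sample_rate, duration=forcing.duration
    )
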