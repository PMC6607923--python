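"""Constant-phase model of respiratory input impedance.

The model describes low-frequency respiratory impedance as an airway
resistance (Raw) and inertance (Iaw) in series with a constant-phase tissue
compartment of damping G and elastance H:

    Z(w) = Raw + j*w*Iaw + (G - j*H) / w**alpha,   alpha = (2/pi) atan(H/G)

with w the angular frequency (rad/s).  G captures viscous energy loss in
the respiratory tissues, H their elastic energy storage; their ratio
eta = G/H is the tissue hysteresivity.  The tissue term has a
frequency-independent phase of -alpha*pi/2, hence the name.

Fitting minimizes the magnitude-normalized (relative) complex least-squares
error.  Absolute errors would be dominated by the low-frequency tissue term
when H is two orders of magnitude above Raw, so every frequency's deviation
is weighted by 1/|Zrs|.  The search is a seeded differential-evolution
population stage inside a generous parameter box followed by a
derivative-based trust-region polish, which makes the result deterministic
for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import differential_evolution, least_squares

from .signals_fot import ImpedanceSpectrum

__all__ = [
    "CPMParams",
    "DEFAULT_BOUNDS",
    "cpm_impedance",
    "ConstantPhaseModel",
    "ConstantPhaseResults",
    "fit_cpm",
    "fit_quality",
]


@dataclass(frozen=True)
class CPMParams:
    """Constant-phase model quadruple (cmH2O.s/l, cmH2O.s^2/l, cmH2O/l, cmH2O/l)."""

    raw: float
    iaw: float
    g: float
    h: float

    def __post_init__(self) -> None:
        if self.raw < 0 or self.iaw < 0:
            raise ValueError("Raw and Iaw must be non-negative")
        if self.g <= 0 or self.h <= 0:
            raise ValueError("G and H must be positive")

    @property
    def alpha(self) -> float:
        """Tissue exponent (2/pi)*atan(H/G), strictly inside (0, 1)."""
        return (2.0 / np.pi) * np.arctan2(self.h, self.g)

    @property
    def eta(self) -> float:
        """Hysteresivity G/H."""
        return self.g / self.h

    def as_array(self) -> np.ndarray:
        return np.array([self.raw, self.iaw, self.g, self.h])


#: generous box around all physiological rabbit values
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = (
    (0.0, 100.0),  # Raw
    (0.0, 1.0),  # Iaw
    (1.0, 5000.0),  # G
    (10.0, 20000.0),  # H
)


def cpm_impedance(params: CPMParams, freqs: np.ndarray) -> ImpedanceSpectrum:
    """Evaluate the model on a positive frequency grid (Hz)."""
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive (w**alpha singular at 0)")
    w = 2.0 * np.pi * f
    z = params.raw + 1j * w * params.iaw + (params.g - 1j * params.h) / w**params.alpha
    return ImpedanceSpectrum(freqs=f, values=z)


def _model_values(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vectorized model evaluation; theta is (4,) or (4, S)."""
    raw, iaw, g, h = theta[0], theta[1], theta[2], theta[3]
    alpha = (2.0 / np.pi) * np.arctan2(h, g)
    if np.ndim(raw) == 0:
        return raw + 1j * w * iaw + (g - 1j * h) / w**alpha
    w = w[:, None]
    return raw[None, :] + 1j * w * iaw[None, :] + (
        (g - 1j * h)[None, :] / w ** alpha[None, :]
    )


class ConstantPhaseModel:
    """Constant-phase impedance model bound to a measured spectrum.

    Parameters
    ----------
    spectrum : ImpedanceSpectrum
        Ensemble-averaged, instrument-corrected respiratory input impedance.
        At least 8 frequencies spanning at least one decade are required.
        Frequencies with non-positive real part (non-physical for passive
        tissue) are excluded with a warning.
    """

    def __init__(self, spectrum: ImpedanceSpectrum) -> None:
        freqs = spectrum.freqs
        values = spectrum.values
        ok = values.real > 0
        if not np.all(ok):
            warnings.warn(
                f"{np.sum(~ok)} frequencies with non-positive Re(Zrs) excluded "
                "from the fit",
                RuntimeWarning,
                stacklevel=2,
            )
        freqs, values = freqs[ok], values[ok]
        if len(freqs) < 8:
            raise ValueError(f"need >= 8 valid frequencies, got {len(freqs)}")
        if freqs.max() / freqs.min() < 10.0:
            raise ValueError("frequency grid must span at least one decade")
        self.spectrum = spectrum
        self.freqs = freqs
        self.values = values
        self._w = 2.0 * np.pi * freqs
        self._absz = np.abs(values)

    # -- cost pieces ----------------------------------------------------
    def _resid_vector(self, theta: np.ndarray) -> np.ndarray:
        dz = (_model_values(theta, self._w) - self.values) / self._absz
        return np.concatenate([dz.real, dz.imag])

    def _cost(self, theta: np.ndarray) -> np.ndarray:
        zm = _model_values(theta, self._w)
        if zm.ndim == 1:
            return float(np.sum(np.abs(zm - self.values) ** 2 / self._absz**2))
        return np.sum(
            np.abs(zm - self.values[:, None]) ** 2 / self._absz[:, None] ** 2, axis=0
        )

    # -- fitting --------------------------------------------------------
    def fit(
        self,
        bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS,
        seed: int = 0,
        maxiter: int = 150,
        popsize: int = 12,
    ) -> "ConstantPhaseResults":
        """Global (differential evolution) + local (trust-region) fit.

        Deterministic for a fixed seed.  If the polished solution is worse
        than the population optimum or the global stage stalls in a poor
        basin, the global stage restarts from a shifted seed (up to twice).
        """
        best_x, best_cost = None, np.inf
        restarts = 0
        converged = False
        for attempt in range(3):
            de = differential_evolution(
                self._cost,
                bounds=bounds,
                seed=seed + attempt,
                maxiter=maxiter,
                popsize=popsize,
                tol=1e-8,
                polish=False,
                vectorized=True,
                updating="deferred",
                init="sobol",
            )
            x0 = np.clip(de.x, [b[0] for b in bounds], [b[1] for b in bounds])
            ls = least_squares(
                self._resid_vector,
                x0,
                bounds=([b[0] for b in bounds], [b[1] for b in bounds]),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            cost = self._cost(ls.x)
            cand = min((cost, ls.x), (de.fun, de.x), key=lambda t: t[0])
            if cand[0] < best_cost:
                best_cost, best_x = cand
                jac = ls.jac
            # relative RMS per point below 5% counts as a usable basin
            if best_cost / len(self.freqs) < 0.05**2:
                converged = True
                break
            restarts += 1
        raw, iaw, g, h = best_x
        params = CPMParams(raw=max(raw, 0.0), iaw=max(iaw, 0.0), g=g, h=h)
        zm = _model_values(best_x, self._w)
        per_freq = np.abs(zm - self.values) / self._absz

        # Gauss-Newton covariance of the polished solution (relative residuals)
        m = 2 * len(self.freqs)
        dof = max(m - 4, 1)
        s2 = 2.0 * (best_cost / 2.0) / dof
        try:
            cov = s2 * np.linalg.inv(jac.T @ jac)
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            bse = np.full(4, np.nan)

        return ConstantPhaseResults(
            model=self,
            params=params,
            residual=float(best_cost),
            per_freq_residuals=per_freq,
            n_freqs=len(self.freqs),
            converged=converged,
            restarts=restarts,
            bse=bse,
            seed=seed,
            bounds=bounds,
        )


@dataclass(frozen=True)
class ConstantPhaseResults:
    """Fit results: estimates, uncertainties and diagnostics."""

    model: ConstantPhaseModel
    params: CPMParams
    residual: float  # sum of squared relative deviations
    per_freq_residuals: np.ndarray  # |Zm - Zd| / |Zd| per frequency
    n_freqs: int
    converged: bool
    restarts: int
    bse: np.ndarray  # approximate standard errors (Raw, Iaw, G, H)
    seed: int
    bounds: tuple[tuple[float, float], ...]

    @property
    def alpha(self) -> float:
        return self.params.alpha

    @property
    def eta(self) -> float:
        return self.params.eta

    def predict(self, freqs: np.ndarray | None = None) -> ImpedanceSpectrum:
        f = self.model.freqs if freqs is None else np.asarray(freqs, dtype=float)
        return cpm_impedance(self.params, f)

    def rms_relative_error_pct(self) -> float:
        """Root-mean-square relative deviation of the fit, in percent."""
        return float(np.sqrt(self.residual / self.n_freqs) * 100.0)

    def summary(self) -> str:
        p = self.params
        names = ["Raw", "Iaw", "G", "H"]
        units = ["cmH2O.s/l", "cmH2O.s2/l", "cmH2O/l", "cmH2O/l"]
        vals = p.as_array()
        lines = [
            "Constant-phase model fit",
            "=" * 52,
            f"{'parameter':<10}{'estimate':>12}{'std err':>12}  unit",
            "-" * 52,
        ]
        for nm, v, se, u in zip(names, vals, self.bse, units):
            lines.append(f"{nm:<10}{v:>12.4g}{se:>12.2g}  {u}")
        lines += [
            "-" * 52,
            f"alpha = {self.alpha:.4f}   eta = G/H = {self.eta:.4f}",
            f"n_freqs = {self.n_freqs}   rms rel. error = "
            f"{self.rms_relative_error_pct():.3g}%",
            f"residual = {self.residual:.3g}   converged = {self.converged}   "
            f"restarts = {self.restarts}",
        ]
        return "\n".join(lines)


def fit_cpm(
    z: ImpedanceSpectrum,
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS,
    seed: int = 0,
) -> ConstantPhaseResults:
    """Convenience wrapper: build the model and fit it."""
    return ConstantPhaseModel(z).fit(bounds=bounds, seed=seed)


def fit_quality(
    fit: ConstantPhaseResults | CPMParams, z: ImpedanceSpectrum
) -> float:
    """RMS relative deviation (%) of a fitted model against a spectrum.

    Accepts either a results object or bare parameters; used for QC
    thresholds on measured spectra.
    """
    params = fit.params if hasattr(fit, "params") else fit
    zm = cpm_impedance(params, z.freqs).values
    rel = np.abs(zm - z.values) / np.abs(z.values)
    return float(np.sqrt(np.mean(rel**2)) * 100.0)
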