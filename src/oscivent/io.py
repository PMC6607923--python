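"""Plain-text readers/writers for the package's CSV and JSON interfaces."""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .cohort import SubjectState
from .constant_phase import CPMParams, ConstantPhaseResults
from .patterns import PVVSourceSeries, VentilationPattern
from .signals_fot import ImpedanceSpectrum, TimeSeriesRecording, WaveTubeSpec

__all__ = [
    "read_impedance_csv",
    "write_impedance_csv",
    "read_recording_csv",
    "write_recording_csv",
    "write_pattern_csv",
    "read_source_series_csv",
    "read_measurements_csv",
    "write_measurements_csv",
    "tube_from_json",
    "subject_from_json",
    "fit_to_json",
]


def write_impedance_csv(path, z: ImpedanceSpectrum) -> None:
    pd.DataFrame(
        {
            "frequency_hz": z.freqs,
            "zrs_real": z.values.real,
            "zrs_imag": z.values.imag,
        }
    ).to_csv(path, index=False)


def read_impedance_csv(path) -> ImpedanceSpectrum:
    df = pd.read_csv(path)
    return ImpedanceSpectrum(
        freqs=df["frequency_hz"].to_numpy(dtype=float),
        values=df["zrs_real"].to_numpy(dtype=float)
        + 1j * df["zrs_imag"].to_numpy(dtype=float),
    )


def write_recording_csv(path, rec: TimeSeriesRecording) -> None:
    t = np.arange(len(rec.p1)) / rec.sample_rate
    pd.DataFrame({"time_s": t, "p1_cmh2o": rec.p1, "p2_cmh2o": rec.p2}).to_csv(
        path, index=False
    )


def read_recording_csv(path, sample_rate: float | None = None) -> TimeSeriesRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if sample_rate is None:
        sample_rate = 1.0 / np.median(np.diff(t))
    n = len(t)
    return TimeSeriesRecording(
        p1=df["p1_cmh2o"].to_numpy(dtype=float),
        p2=df["p2_cmh2o"].to_numpy(dtype=float),
        sample_rate=float(sample_rate),
        duration=n / float(sample_rate),
    )


def write_pattern_csv(path, pattern: VentilationPattern) -> None:
    rows = []
    for i, (b, vt) in enumerate(zip(pattern.breaths, pattern.delivered_vt)):
        rows.append(
            dict(
                breath_index=i,
                start_s=b.start_time,
                driving_pressure_cmh2o=b.driving_pressure,
                ti_s=b.inspiratory_time,
                te_s=b.expiratory_time,
                is_sigh=int(b.is_sigh),
                vt_ml_per_kg=vt,
            )
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_source_series_csv(path) -> PVVSourceSeries:
    df = pd.read_csv(path)
    return PVVSourceSeries(
        relative_amplitude=df["relative_amplitude"].to_numpy(dtype=float),
        period_s=df["period_s"].to_numpy(dtype=float),
    )


def read_measurements_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_measurements_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def tube_from_json(path) -> WaveTubeSpec:
    with open(path) as fh:
        return WaveTubeSpec(**json.load(fh))


def subject_from_json(path) -> SubjectState:
    """Subject JSON carries weight plus the constant-phase quadruple."""
    with open(path) as fh:
        data = json.load(fh)
    cpm = CPMParams(**data.pop("cpm"))
    defaults = dict(
        pao2=180.0, paco2=40.0, fio2=0.4, ph=7.4, lactate=1.5,
        map=70.0, hr=260.0, peep=6.0, timepoint="BL",
    )
    defaults.update(data)
    return SubjectState(cpm=cpm, **defaults)


def fit_to_json(path, fit: ConstantPhaseResults) -> None:
    payload = {
        "params": dataclasses.asdict(fit.params),
        "alpha": fit.alpha,
        "eta": fit.eta,
        "residual": fit.residual,
        "rms_relative_error_pct": fit.rms_relative_error_pct(),
        "bse": list(fit.bse),
        "n_freqs": fit.n_freqs,
        "converged": fit.converged,
        "restarts": fit.restarts,
        "seed": fit.seed,
        "bounds": [list(b) for b in fit.bounds],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
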