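"""Virtual rabbit-ARDS cohort generator.

Simulates the eight-group study design (four ventilation modes x two PEEP
levels, n = 7 per group by default): per-subject respiratory mechanics,
arterial blood gases and haemodynamics from healthy baseline (BL), through
a severe-ARDS injury transition (T0, PaO2/FiO2 gated at <= 150 mmHg), and
over five hourly timepoints (T1..T5) of ventilation with the assigned
pattern.

Group-mean trajectories are anchored to printed study values: the
tabulated baseline and post-injury mechanics of every group, the pooled
post-injury oxygenation (63.0 mmHg at PEEP 6 vs 112 mmHg at PEEP 9), and
the five-hour relative changes at moderate PEEP (G +58.8 % / +40.8 % and
H +54.5 % / +50.7 % for the sigh and mathematically-variable groups,
PaCO2 +43.9 % / +46.2 %, pH -4.6 %), with no tissue deterioration in the
physiologically-variable and conventional groups and stabilisation of all
groups at the higher PEEP.  Intermediate timepoints are interpolated
geometrically; anchors not printed anywhere are package defaults
documented in the methods note.

Acid-base state is closed through Henderson-Hasselbalch: pH is derived at
every timepoint from PaCO2 and a bicarbonate pool decremented one-to-one
by the lactate rise above baseline, and the lactate endpoint of each group
is solved from that relation so the pH anchor is met exactly at zero
noise.  Lactate stays flat until T2 and rises from T3, as observed.

Between-subject variation is lognormal (10 % CV, the study's sample-size
assumption); within-subject hourly fluctuation is lognormal with 4 % CV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constant_phase import CPMParams, cpm_impedance, fit_cpm
from .signals_fot import (
    ForcingSignal,
    ImpedanceSpectrum,
    TimeSeriesRecording,
    WaveTubeSpec,
    ensemble_average,
    load_impedance,
    make_forcing_signal,
    simulate_measurement,
    subtract_instrument,
    transfer_function,
)

__all__ = [
    "MODES",
    "TIMEPOINTS",
    "VARIABLES",
    "GroupSpec",
    "CohortConfig",
    "SubjectState",
    "Subject",
    "Cohort",
    "TrajectoryTable",
    "blood_gas_model",
    "make_cohort",
    "injury_transition",
    "timecourse",
    "simulate_cohort",
    "emit_raw_recordings",
    "recover_mechanics",
    "export_tables",
    "default_baseline_subject",
]

MODES = ("PVV", "MVV", "PCV", "PCS")
PEEPS = (6.0, 9.0)
TIMEPOINTS = ("BL", "T0", "T1", "T2", "T3", "T4", "T5")
#: the seven primary study variables
VARIABLES = ("Raw", "G", "H", "PF", "PaCO2", "pH", "Lactate")

_PK = 6.1  # carbonic acid pK
_CO2_SOLUBILITY = 0.03  # mmol/l/mmHg
_HCO3_BASELINE = 24.0  # mmol/l
_SEVERE_ARDS_PF_GATE = 150.0  # mmHg
_IAW_DEFAULT = 0.01  # cmH2O.s^2/l, airway inertance (never tabulated)


def blood_gas_model(paco2: float, bicarbonate: float) -> float:
    """Henderson-Hasselbalch: pH = 6.1 + log10(HCO3 / (0.03 * PaCO2))."""
    paco2 = np.asarray(paco2, dtype=float)
    bicarbonate = np.asarray(bicarbonate, dtype=float)
    if np.any(paco2 <= 0) or np.any(bicarbonate <= 0):
        raise ValueError("PaCO2 and bicarbonate must be positive")
    out = _PK + np.log10(bicarbonate / (_CO2_SOLUBILITY * paco2))
    return float(out) if out.ndim == 0 else out


def _ph_from_gas(paco2, lactate, lactate_bl) -> float:
    """pH with the bicarbonate pool decremented by the lactate rise."""
    hco3 = _HCO3_BASELINE - (lactate - lactate_bl)
    return blood_gas_model(paco2, hco3)


def _lactate_for_ph(ph_target: float, paco2: float, lactate_bl: float) -> float:
    """Invert the acid-base closure for the lactate endpoint."""
    hco3 = 10.0 ** (ph_target - _PK) * _CO2_SOLUBILITY * paco2
    return lactate_bl + (_HCO3_BASELINE - hco3)


# ---------------------------------------------------------------------------
# calibration table

# per-group mechanics anchors (cmH2O.s/l for Raw, cmH2O/l for G and H)
_MECH_BL = {
    ("PVV", 6.0): dict(Raw=9.2, G=80.2, H=252.0),
    ("MVV", 6.0): dict(Raw=8.6, G=87.3, H=269.0),
    ("PCV", 6.0): dict(Raw=8.4, G=91.0, H=267.0),
    ("PCS", 6.0): dict(Raw=9.2, G=82.3, H=257.0),
    ("PVV", 9.0): dict(Raw=9.2, G=76.8, H=246.0),
    ("MVV", 9.0): dict(Raw=8.7, G=86.2, H=255.0),
    ("PCV", 9.0): dict(Raw=8.3, G=88.9, H=274.0),
    ("PCS", 9.0): dict(Raw=8.7, G=91.1, H=277.0),
}
_MECH_T0 = {
    ("PVV", 6.0): dict(Raw=14.5, G=251.0, H=1105.0),
    ("MVV", 6.0): dict(Raw=12.3, G=309.0, H=1162.0),
    ("PCV", 6.0): dict(Raw=12.0, G=348.0, H=1438.0),
    ("PCS", 6.0): dict(Raw=12.0, G=262.0, H=1149.0),
    ("PVV", 9.0): dict(Raw=11.1, G=177.0, H=856.0),
    ("MVV", 9.0): dict(Raw=10.4, G=207.0, H=790.0),
    ("PCV", 9.0): dict(Raw=10.7, G=174.0, H=875.0),
    ("PCS", 9.0): dict(Raw=11.5, G=196.0, H=948.0),
}
# pooled post-injury oxygenation anchors, mmHg, by PEEP
_PF_T0 = {6.0: 63.0, 9.0: 112.0}
# unprinted post-injury gas defaults, by PEEP
_PACO2_T0 = {6.0: 55.0, 9.0: 45.0}
_LACTATE_T0 = {6.0: 2.5, 9.0: 2.0}
# healthy baseline defaults (all groups ventilated identically at BL)
_BL_GAS = dict(PF=450.0, PaCO2=40.0, Lactate=1.5)

# five-hour relative drifts vs T0, percent; moderate-PEEP tissue and gas
# deterioration for PCS/MVV, flat PVV/PCV, stabilisation at high PEEP
_T5_DRIFT_PCT = {
    ("PVV", 6.0): dict(Raw=0.0, G=0.0, H=0.0, PF=0.0, PaCO2=8.0, pH=-1.5),
    ("MVV", 6.0): dict(Raw=0.0, G=40.8, H=50.7, PF=-25.0, PaCO2=46.2, pH=-4.6),
    ("PCV", 6.0): dict(Raw=0.0, G=0.0, H=0.0, PF=0.0, PaCO2=5.0, pH=-1.0),
    ("PCS", 6.0): dict(Raw=0.0, G=58.8, H=54.5, PF=-25.0, PaCO2=43.9, pH=-4.6),
    ("PVV", 9.0): dict(Raw=0.0, G=-10.0, H=-10.0, PF=20.0, PaCO2=0.0, pH=-0.5),
    ("MVV", 9.0): dict(Raw=0.0, G=-10.0, H=-10.0, PF=20.0, PaCO2=0.0, pH=-0.5),
    ("PCV", 9.0): dict(Raw=0.0, G=-10.0, H=-10.0, PF=20.0, PaCO2=0.0, pH=-0.5),
    ("PCS", 9.0): dict(Raw=-15.0, G=-10.0, H=-10.0, PF=20.0, PaCO2=0.0, pH=-0.5),
}

# haemodynamic group means (no printed anchors; the high-PEEP groups run a
# higher MAP, matching the reported ordering)
_MAP_MEAN = {6.0: 62.0, 9.0: 68.0}
_HR_MEAN = 260.0


@dataclass(frozen=True)
class GroupSpec:
    mode: str
    peep: float
    n: int = 7

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.peep not in PEEPS:
            raise ValueError(f"PEEP must be one of {PEEPS}")
        if self.n < 1:
            raise ValueError("n must be >= 1")


class TrajectoryTable:
    """Group x timepoint x variable mean table driving the generator.

    Built from the calibration anchors above; every cell of the seven
    primary variables is defined for all eight groups and seven
    timepoints.  Means can be overridden with a nested mapping
    ``{(mode, peep): {timepoint: {variable: value}}}``.
    """

    def __init__(self, means: dict | None = None) -> None:
        self.means = means if means is not None else self._build_default()
        for grp in self.group_keys():
            for tp in TIMEPOINTS:
                for var in VARIABLES:
                    if var not in self.means[grp][tp]:
                        raise ValueError(f"missing cell {grp}/{tp}/{var}")

    @staticmethod
    def group_keys() -> list[tuple[str, float]]:
        return [(m, p) for p in PEEPS for m in MODES]

    @staticmethod
    def _build_default() -> dict:
        means: dict = {}
        for mode, peep in TrajectoryTable.group_keys():
            grp = (mode, peep)
            cells: dict = {}
            lac_bl = _BL_GAS["Lactate"]
            cells["BL"] = dict(
                **_MECH_BL[grp],
                PF=_BL_GAS["PF"],
                PaCO2=_BL_GAS["PaCO2"],
                Lactate=lac_bl,
                pH=blood_gas_model(_BL_GAS["PaCO2"], _HCO3_BASELINE),
            )
            t0 = dict(
                **_MECH_T0[grp],
                PF=_PF_T0[peep],
                PaCO2=_PACO2_T0[peep],
                Lactate=_LACTATE_T0[peep],
            )
            t0["pH"] = _ph_from_gas(t0["PaCO2"], t0["Lactate"], lac_bl)
            cells["T0"] = t0

            drift = _T5_DRIFT_PCT[grp]
            ratio = {v: 1.0 + drift[v] / 100.0 for v in drift}
            paco2_t5 = t0["PaCO2"] * ratio["PaCO2"]
            ph_t5 = t0["pH"] * ratio["pH"]
            lac_t5 = _lactate_for_ph(ph_t5, paco2_t5, lac_bl)
            if lac_t5 < t0["Lactate"]:
                lac_t5 = t0["Lactate"]  # lactate never falls below T0
            for k in range(1, 6):
                cell = {}
                for var in ("Raw", "G", "H", "PF", "PaCO2"):
                    cell[var] = t0[var] * ratio[var] ** (k / 5.0)
                # flat to T2, geometric rise T2 -> T5
                if k <= 2:
                    cell["Lactate"] = t0["Lactate"]
                else:
                    cell["Lactate"] = t0["Lactate"] * (
                        lac_t5 / t0["Lactate"]
                    ) ** ((k - 2) / 3.0)
                cell["pH"] = _ph_from_gas(cell["PaCO2"], cell["Lactate"], lac_bl)
                cells[f"T{k}"] = cell
            means[grp] = cells
        return means

    @classmethod
    def null_progression(cls) -> "TrajectoryTable":
        """Default anchors but no T0 -> T5 drift in any variable (null cohort)."""
        import copy

        means = copy.deepcopy(cls._build_default())
        for grp in means:
            for k in range(1, 6):
                means[grp][f"T{k}"] = dict(means[grp]["T0"])
        return cls(means=means)

    def mean(self, mode: str, peep: float, timepoint: str, variable: str) -> float:
        return self.means[(mode, peep)][timepoint][variable]

    def injury_factor(self, mode: str, peep: float, variable: str) -> float:
        """Multiplicative T0/BL jump for the mechanics variables."""
        g = self.means[(mode, peep)]
        return g["T0"][variable] / g["BL"][variable]

    def drift_ratio(self, mode: str, peep: float, variable: str, k: int) -> float:
        """Cumulative T0 -> Tk multiplier for an anchored variable."""
        g = self.means[(mode, peep)]
        return g[f"T{k}"][variable] / g["T0"][variable]

    def h_fold_change_mean(self) -> float:
        """Mean across the 8 groups of the tabulated H fold-change at injury."""
        return float(
            np.mean([self.injury_factor(m, p, "H") for m, p in self.group_keys()])
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (mode, peep), cells in self.means.items():
            for tp, cell in cells.items():
                for var, val in cell.items():
                    rows.append(
                        dict(mode=mode, peep=peep, timepoint=tp, variable=var, value=val)
                    )
        return pd.DataFrame(rows)


_DEFAULT_TRAJECTORIES: TrajectoryTable | None = None


def default_trajectories() -> TrajectoryTable:
    global _DEFAULT_TRAJECTORIES
    if _DEFAULT_TRAJECTORIES is None:
        _DEFAULT_TRAJECTORIES = TrajectoryTable()
    return _DEFAULT_TRAJECTORIES


# ---------------------------------------------------------------------------
# cohort configuration and subjects


@dataclass(frozen=True)
class CohortConfig:
    n_per_group: int = 7
    weight_mean: float = 3.13  # kg
    weight_range: tuple[float, float] = (2.67, 3.99)  # kg
    between_cv: float = 0.10  # between-subject CV
    within_cv: float = 0.04  # hourly within-subject CV
    seed: int = 0
    dropout_prob: float = 0.0  # pneumothorax emulation

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.between_cv < 0 or self.within_cv < 0:
            raise ValueError("CVs must be non-negative")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "weight_range" in data:
            data["weight_range"] = tuple(data["weight_range"])
        return cls(**data)


@dataclass(frozen=True)
class SubjectState:
    """One virtual rabbit's state at one timepoint."""

    weight: float  # kg
    cpm: CPMParams
    pao2: float  # mmHg
    paco2: float  # mmHg
    fio2: float  # fraction
    ph: float
    lactate: float  # mmol/l
    map: float  # mmHg
    hr: float  # beats/min
    peep: float  # cmH2O
    timepoint: str

    @property
    def pf(self) -> float:
        """PaO2/FiO2 ratio, mmHg."""
        return self.pao2 / self.fio2

    def primary_values(self) -> dict:
        return {
            "Raw": self.cpm.raw,
            "G": self.cpm.g,
            "H": self.cpm.h,
            "PF": self.pf,
            "PaCO2": self.paco2,
            "pH": self.ph,
            "Lactate": self.lactate,
        }


@dataclass
class Subject:
    sid: str
    mode: str
    peep: float
    weight: float
    rng: np.random.Generator
    between: dict  # persistent per-variable lognormal factors
    config: CohortConfig
    trajectories: TrajectoryTable
    base_bl: dict = field(default_factory=dict)  # BL true values
    base_t0: dict = field(default_factory=dict)  # T0 true values
    states: dict = field(default_factory=dict)  # timepoint -> SubjectState
    dropout_after: str | None = None

    @property
    def current_timepoint(self) -> str | None:
        order = [tp for tp in TIMEPOINTS if tp in self.states]
        return order[-1] if order else None


@dataclass
class Cohort:
    config: CohortConfig
    trajectories: TrajectoryTable
    subjects: list

    def group(self, mode: str, peep: float) -> list:
        return [s for s in self.subjects if s.mode == mode and s.peep == peep]

    def __len__(self) -> int:
        return len(self.subjects)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean lognormal multiplier(s) with the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=size))


def _fio2(timepoint: str) -> float:
    return 0.4 if timepoint == "BL" else 0.9


def _haemodynamics(subject: Subject, timepoint: str) -> tuple[float, float]:
    """AR(1) fluctuation around stable group means; MAP higher at high PEEP."""
    map_mean = 70.0 if timepoint == "BL" else _MAP_MEAN[subject.peep]
    last = None
    for tp in reversed(TIMEPOINTS[: TIMEPOINTS.index(timepoint)]):
        if tp in subject.states:
            last = subject.states[tp]
            break
    noise_on = subject.config.within_cv > 0
    phi, sd_map, sd_hr = 0.7, 3.0, 8.0
    if not noise_on:
        return map_mean, _HR_MEAN
    dev_map = (last.map - (70.0 if last.timepoint == "BL" else _MAP_MEAN[subject.peep])) if last else 0.0
    dev_hr = (last.hr - _HR_MEAN) if last else 0.0
    m = map_mean + phi * dev_map + subject.rng.normal(0.0, sd_map)
    h = _HR_MEAN + phi * dev_hr + subject.rng.normal(0.0, sd_hr)
    return float(m), float(h)


def _make_state(subject: Subject, timepoint: str, true_values: dict) -> SubjectState:
    """Apply within-subject fluctuation and assemble the state."""
    cv = subject.config.within_cv
    e = {v: _lognormal_factor(subject.rng, cv) for v in ("Raw", "G", "H", "PF", "PaCO2", "Lactate")}
    raw = true_values["Raw"] * e["Raw"]
    g = true_values["G"] * e["G"]
    h = true_values["H"] * e["H"]
    pf = true_values["PF"] * e["PF"]
    paco2 = true_values["PaCO2"] * e["PaCO2"]
    lactate = true_values["Lactate"] * e["Lactate"]

    if timepoint == "T0":
        # severity gate: injurious ventilation is repeated until the
        # oxygenation criterion for severe ARDS is met
        tries = 0
        while pf > _SEVERE_ARDS_PF_GATE and tries < 100:
            pf = true_values["PF"] * _lognormal_factor(subject.rng, cv)
            tries += 1
        pf = min(pf, _SEVERE_ARDS_PF_GATE)

    lactate_bl = subject.base_bl.get("Lactate", _BL_GAS["Lactate"])
    if timepoint == "BL":
        ph = blood_gas_model(paco2, _HCO3_BASELINE)
    else:
        ph = _ph_from_gas(paco2, lactate, lactate_bl)
    m, hr = _haemodynamics(subject, timepoint)
    fio2 = _fio2(timepoint)
    return SubjectState(
        weight=subject.weight,
        cpm=CPMParams(raw=raw, iaw=_IAW_DEFAULT, g=g, h=h),
        pao2=pf * fio2,
        paco2=paco2,
        fio2=fio2,
        ph=ph,
        lactate=lactate,
        map=m,
        hr=hr,
        peep=subject.peep,
        timepoint=timepoint,
    )


def make_cohort(
    config: CohortConfig, trajectories: TrajectoryTable | None = None
) -> Cohort:
    """Draw the cohort at baseline with block-randomized group assignment."""
    traj = trajectories if trajectories is not None else default_trajectories()
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    groups = TrajectoryTable.group_keys()

    assignments: list[tuple[str, float]] = []
    for _ in range(config.n_per_group):  # block randomization, one per group per block
        block = [groups[i] for i in rng.permutation(len(groups))]
        assignments.extend(block)

    lo, hi = config.weight_range
    # Beta(2.3, 4.3) rescaled to the printed weight range has mean 3.13 kg
    weights = lo + (hi - lo) * rng.beta(2.3, 4.3, size=len(assignments))

    subjects = []
    child_seeds = root.spawn(len(assignments))
    for i, ((mode, peep), w, ss) in enumerate(zip(assignments, weights, child_seeds)):
        srng = np.random.default_rng(ss)
        between = {
            v: _lognormal_factor(srng, config.between_cv)
            for v in ("Raw", "G", "H", "PF", "PaCO2", "Lactate")
        }
        subj = Subject(
            sid=f"S{i + 1:02d}",
            mode=mode,
            peep=peep,
            weight=float(w),
            rng=srng,
            between=between,
            config=config,
            trajectories=traj,
        )
        if config.dropout_prob > 0 and srng.random() < config.dropout_prob:
            subj.dropout_after = f"T{srng.integers(0, 5)}"  # censored post-injury
        subj.base_bl = {
            v: traj.mean(mode, peep, "BL", v) * between[v]
            for v in ("Raw", "G", "H", "PF", "PaCO2", "Lactate")
        }
        subj.states["BL"] = _make_state(subj, "BL", subj.base_bl)
        subjects.append(subj)
    return Cohort(config=config, trajectories=traj, subjects=subjects)


def injury_transition(subject: Subject, peep: float | None = None) -> SubjectState:
    """Apply the multi-hit lung injury, moving the subject from BL to T0.

    Mechanics jump by the group's tabulated T0/BL factors; oxygenation
    drops to the PEEP-dependent pooled anchor; gases follow the trajectory
    table.  Applying the transition twice is rejected.
    """
    if subject.current_timepoint != "BL":
        raise ValueError(
            f"injury transition requires a subject at BL, "
            f"found {subject.current_timepoint}"
        )
    if peep is None:
        peep = subject.peep
    traj = subject.trajectories
    mode = subject.mode
    base = {}
    for v in ("Raw", "G", "H"):
        base[v] = subject.base_bl[v] * traj.injury_factor(mode, peep, v)
    for v in ("PF", "PaCO2", "Lactate"):
        base[v] = traj.mean(mode, peep, "T0", v) * subject.between[v]
    subject.base_t0 = base
    subject.states["T0"] = _make_state(subject, "T0", base)
    return subject.states["T0"]


def timecourse(subject: Subject, group: GroupSpec | None = None) -> list[SubjectState]:
    """Generate the hourly states T1..T5 from the group's calibrated drifts."""
    if subject.current_timepoint != "T0":
        raise ValueError("timecourse requires a subject at T0")
    if group is None:
        group = GroupSpec(mode=subject.mode, peep=subject.peep)
    if group.mode not in MODES:
        raise ValueError(f"unknown group mode {group.mode!r}")
    traj = subject.trajectories
    out = []
    for k in range(1, 6):
        tp = f"T{k}"
        if subject.dropout_after is not None and tp > subject.dropout_after:
            break
        true_values = {
            v: subject.base_t0[v] * traj.drift_ratio(group.mode, group.peep, v, k)
            for v in ("Raw", "G", "H", "PF", "PaCO2", "Lactate")
        }
        subject.states[tp] = _make_state(subject, tp, true_values)
        out.append(subject.states[tp])
    return out


def simulate_cohort(
    config: CohortConfig, trajectories: TrajectoryTable | None = None
) -> Cohort:
    """Full study simulation: baseline cohort, injury, five-hour timecourse."""
    cohort = make_cohort(config, trajectories)
    for subj in cohort.subjects:
        injury_transition(subj)
        timecourse(subj)
    return cohort


# ---------------------------------------------------------------------------
# raw recordings and tables


def emit_raw_recordings(
    cohort: Cohort,
    tube: WaveTubeSpec | None = None,
    forcing: ForcingSignal | None = None,
    reps: tuple[int, int] = (3, 4),
    noise_sd: float = 0.005,
    seed: int = 0,
    subjects: list | None = None,
    timepoints: tuple[str, ...] | None = None,
) -> dict:
    """Simulate wave-tube P1/P2 recordings for each subject x timepoint.

    Three to four replicate 8-s recordings (count drawn uniformly) are
    generated from each state's true constant-phase parameters through the
    transmission-line forward model with additive sensor noise.
    Returns ``{(subject_id, timepoint): [TimeSeriesRecording, ...]}``.
    """
    tube = tube if tube is not None else WaveTubeSpec()
    forcing = forcing if forcing is not None else make_forcing_signal(seed=seed)
    rng = np.random.default_rng(seed)
    recordings: dict = {}
    for subj in subjects if subjects is not None else cohort.subjects:
        for tp, state in subj.states.items():
            if timepoints is not None and tp not in timepoints:
                continue
            n_rep = int(rng.integers(reps[0], reps[1] + 1))
            z = cpm_impedance(state.cpm, forcing.component_freqs)
            recs = [
                simulate_measurement(
                    z, tube, forcing, noise_sd=noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                for _ in range(n_rep)
            ]
            recordings[(subj.sid, tp)] = recs
    return recordings


def recover_mechanics(
    recordings: list[TimeSeriesRecording],
    tube: WaveTubeSpec | None = None,
    forcing: ForcingSignal | None = None,
    instrument: ImpedanceSpectrum | None = None,
    seed: int = 0,
):
    """Full estimation chain: transfer function -> inversion -> ensemble
    average -> instrument correction -> constant-phase fit."""
    tube = tube if tube is not None else WaveTubeSpec()
    forcing = forcing if forcing is not None else make_forcing_signal(seed=seed)
    spectra = [
        load_impedance(transfer_function(r, forcing.component_freqs), tube)
        for r in recordings
    ]
    z = ensemble_average(spectra) if len(spectra) > 1 else spectra[0]
    if instrument is not None:
        z = subtract_instrument(z, instrument)
    return fit_cpm(z, seed=seed)


def export_tables(
    cohort: Cohort, include_haemodynamics: bool = False
) -> pd.DataFrame:
    """Long-format measurement table: one row per subject x timepoint x variable."""
    rows = []
    for subj in cohort.subjects:
        for tp in TIMEPOINTS:
            if tp not in subj.states:
                continue
            state = subj.states[tp]
            values = state.primary_values()
            if include_haemodynamics:
                values = {**values, "MAP": state.map, "HR": state.hr}
            for var, val in values.items():
                rows.append(
                    dict(
                        subject_id=subj.sid,
                        mode=subj.mode,
                        peep=subj.peep,
                        weight_kg=subj.weight,
                        timepoint=tp,
                        variable=var,
                        value=val,
                    )
                )
    return pd.DataFrame(rows)


def default_baseline_subject(weight: float = 3.13) -> SubjectState:
    """A healthy reference rabbit at the tabulated baseline mechanics."""
    return SubjectState(
        weight=weight,
        cpm=CPMParams(raw=9.2, iaw=_IAW_DEFAULT, g=80.2, h=252.0),
        pao2=_BL_GAS["PF"] * 0.4,
        paco2=_BL_GAS["PaCO2"],
        fio2=0.4,
        ph=blood_gas_model(_BL_GAS["PaCO2"], _HCO3_BASELINE),
        lactate=_BL_GAS["Lactate"],
        map=70.0,
        hr=_HR_MEAN,
        peep=6.0,
        timepoint="BL",
    )
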