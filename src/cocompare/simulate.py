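"""Synthetic study generator with known ground truth.

Emulates a prospective method-comparison study in major cardiac surgery:
25 subjects measured at 8 scheduled timepoints (low cardiac output at
baseline, elevated after cardiopulmonary bypass), a thermodilution
reference recorded as triplicate dilution curves with paired GEDV quality
readings, two pulse-contour test channels (radial and femoral site) each
observed before and after an on-demand auto-calibration, and a fluid bolus
between T4 and T5 to which a configurable fraction of subjects respond.

The device observation model is deliberately simple and fully known:

    test = scale * true + bias + drift * step + N(0, noise_sd)

with the accumulated drift removed (and an independent residual drawn) in
the post-calibration state when ``calibration_reset`` is set. Every
downstream statistic is therefore testable by parameter recovery.

All draws come from one seeded ``numpy.random.Generator`` in a fixed,
documented order, so identical (config, seed) produce byte-identical
datasets.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    DEFAULT_FLUID_INTERVAL,
    DEFAULT_SCHEDULE,
    StudyDataset,
    ThermodilutionSet,
    ValidationError,
    reduce_thermodilution,
)

#: Per-timepoint population mean / SD of the true cardiac output (L/min)
#: and heart rate (beats/min): low at baseline, elevated after bypass,
#: settling around 5.9 L/min overall.
CO_MEAN = (4.3, 6.8, 6.2, 5.9, 5.5, 5.9, 5.8, 5.9)
CO_SD = (1.3, 1.4, 1.3, 1.2, 1.4, 1.4, 1.4, 1.7)
HR_MEAN = (59.0, 78.0, 80.0, 78.0, 80.0, 80.0, 77.0, 71.0)
HR_SD = (14.0, 13.0, 15.0, 12.0, 14.0, 12.0, 11.0, 11.0)


@dataclass(frozen=True)
class DeviceModel:
    """Statistical observation model of one pulse-contour test channel.

    ``subject_sd`` is the SD of a stable per-subject calibration offset:
    an uncalibrated pulse-contour monitor estimates vascular compliance
    from demographics, so much of its error is a patient-level constant.
    Such an offset widens the limits of agreement without degrading
    trending or fluid-response detection, and it is deliberately not
    removed by the auto-calibration reset (which targets drift).
    ``noise_sd`` is white measurement noise per reading.
    """

    method: str
    additive_bias: float = 0.0
    proportional_scale: float = 1.0
    subject_sd: float = 0.0
    noise_sd: float = 0.0
    drift_per_step: float = 0.0
    calibration_reset: bool = True
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.residual_sd < 0 or self.subject_sd < 0:
            raise ValidationError("subject_sd, noise_sd and residual_sd must be >= 0")
        if self.proportional_scale <= 0:
            raise ValidationError("proportional_scale must be > 0")


def default_devices() -> tuple[DeviceModel, DeviceModel]:
    """Radial (pR) and femoral (pF) channels with site-specific additive
    bias. Error budgets are dominated by the per-subject offset so that the
    pooled percentage error lands near 45-50 % at a mean CO of ~6 L/min
    while trending and fluid-response detection stay usable. Drift
    magnitudes are illustrative."""
    return (
        DeviceModel("pR", additive_bias=0.31, proportional_scale=1.0,
                    subject_sd=1.40, noise_sd=0.50, drift_per_step=0.2,
                    calibration_reset=True, residual_sd=0.50),
        DeviceModel("pF", additive_bias=0.56, proportional_scale=1.0,
                    subject_sd=1.30, noise_sd=0.45, drift_per_step=0.15,
                    calibration_reset=True, residual_sd=0.45),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic study; every field has a default
    matching the emulated study design."""

    n_subjects: int = 25
    schedule: tuple[str, ...] = DEFAULT_SCHEDULE
    co_mean: tuple[float, ...] = CO_MEAN
    co_between_sd: tuple[float, ...] = CO_SD
    between_subject_frac: float = 0.8
    hr_mean: tuple[float, ...] = HR_MEAN
    hr_sd: tuple[float, ...] = HR_SD
    devices: tuple[DeviceModel, ...] = field(default_factory=default_devices)
    td_noise_sd: float = 0.3
    td_spread_threshold: float = 0.10
    gedv_mean: float = 1500.0
    gedv_between_sd: float = 200.0
    gedv_cv: float = 0.02
    gedv_outlier_prob: float = 0.0
    fluid_challenge_interval: tuple[str, str] = DEFAULT_FLUID_INTERVAL
    responder_fraction: float = 7.0 / 22.0
    responder_dsv_mean: float = 20.0
    responder_dsv_sd: float = 6.0
    nonresponder_dsv_mean: float = 2.0
    nonresponder_dsv_sd: float = 5.0
    emit_sv: bool = True
    keep_td_sets: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValidationError("responder_fraction must be in [0, 1]")
        T = len(self.schedule)
        for name in ("co_mean", "co_between_sd", "hr_mean", "hr_sd"):
            if len(getattr(self, name)) != T:
                raise ValidationError(f"{name} must have one entry per timepoint ({T})")
        for name in ("co_between_sd", "hr_sd", "td_noise_sd", "gedv_between_sd",
                     "gedv_cv", "responder_dsv_sd", "nonresponder_dsv_sd"):
            v = getattr(self, name)
            if np.any(np.asarray(v) < 0):
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.between_subject_frac <= 1.0:
            raise ValidationError("between_subject_frac must be in [0, 1]")
        if not 0.0 <= self.gedv_outlier_prob <= 1.0:
            raise ValidationError("gedv_outlier_prob must be in [0, 1]")
        lo, hi = self.fluid_challenge_interval
        if (lo not in self.schedule or hi not in self.schedule
                or self.schedule.index(hi) != self.schedule.index(lo) + 1):
            raise ValidationError("fluid_challenge_interval must be adjacent schedule labels")


@dataclass(frozen=True)
class GroundTruth:
    """True per-subject hemodynamics and the device parameters that
    generated a dataset; reproducible from (config, seed)."""

    subjects: tuple[str, ...]
    schedule: tuple[str, ...]
    co_true: np.ndarray       # (n_subjects, n_timepoints), L/min
    sv_true: np.ndarray       # mL
    hr: np.ndarray            # beats/min
    responder: np.ndarray     # bool, per subject
    dsv_pct: np.ndarray       # drawn fluid-induced SV change, %
    devices: tuple[DeviceModel, ...]
    seed: int


def _block(subjects, schedule, method, variable, state, values) -> pd.DataFrame:
    S, T = values.shape
    return pd.DataFrame({
        "subject": np.repeat(subjects, T),
        "timepoint": np.tile(schedule, S),
        "method": method,
        "variable": variable,
        "calibration_state": state,
        "value": values.ravel(),
    })


def simulate_study(config: SimulationConfig) -> tuple[StudyDataset, GroundTruth]:
    """Generate one complete synthetic study.

    Draw order (one seeded stream): subject CO effects, CO jitter, subject
    HR effects, HR jitter, responder uniforms, fluid dSV% normals, GEDV
    subject means, triplicate CO noise, triplicate GEDV noise, outlier
    uniforms, fourth readings for flagged sets (in subject/timepoint
    order), then per device in config order: subject offsets, precal
    noise, postcal residual (only when ``calibration_reset`` is set).
    """
    rng = np.random.default_rng(config.seed)
    S = config.n_subjects
    T = len(config.schedule)
    schedule = np.array(config.schedule)
    subjects = np.array([f"S{i + 1:03d}" for i in range(S)])

    co_mu = np.asarray(config.co_mean)
    co_sd = np.asarray(config.co_between_sd)
    f = config.between_subject_frac
    z_co = rng.standard_normal(S)
    eps_co = rng.standard_normal((S, T))
    co_true = co_mu + np.sqrt(f) * np.outer(z_co, co_sd) + np.sqrt(1 - f) * eps_co * co_sd
    co_true = np.clip(co_true, 0.5, None)

    hr_mu = np.asarray(config.hr_mean)
    hr_sd = np.asarray(config.hr_sd)
    z_hr = rng.standard_normal(S)
    eps_hr = rng.standard_normal((S, T))
    hr = hr_mu + np.sqrt(f) * np.outer(z_hr, hr_sd) + np.sqrt(1 - f) * eps_hr * hr_sd
    hr = np.clip(hr, 40.0, None)

    responder = rng.random(S) < config.responder_fraction
    z_dsv = rng.standard_normal(S)
    dsv = np.where(
        responder,
        config.responder_dsv_mean + config.responder_dsv_sd * z_dsv,
        config.nonresponder_dsv_mean + config.nonresponder_dsv_sd * z_dsv,
    )

    # fluid bolus: true SV between the interval endpoints changes by dsv %
    sv_true = co_true / hr * 1000.0
    i_post = list(config.schedule).index(config.fluid_challenge_interval[1])
    i_pre = i_post - 1
    sv_true[:, i_post] = sv_true[:, i_pre] * (1.0 + dsv / 100.0)
    sv_true[:, i_post] = np.clip(sv_true[:, i_post], 5.0, None)
    co_true[:, i_post] = sv_true[:, i_post] * hr[:, i_post] / 1000.0

    # thermodilution triplicates with paired GEDV quality readings
    gedv_subj = np.clip(
        config.gedv_mean + config.gedv_between_sd * rng.standard_normal(S), 600.0, None
    )
    co_read = co_true[:, :, None] + config.td_noise_sd * rng.standard_normal((S, T, 3))
    co_read = np.clip(co_read, 0.05, None)
    gedv_read = gedv_subj[:, None, None] * (
        1.0 + config.gedv_cv * rng.standard_normal((S, T, 3))
    )
    gedv_read = np.clip(gedv_read, 1.0, None)
    outlier = rng.random((S, T)) < config.gedv_outlier_prob
    if outlier.any():
        # force an unreliable triplicate: last GEDV reading off by 25 %
        gedv_read[outlier, 2] *= 1.25
        co_read[outlier, 2] += 1.5

    spread = (gedv_read.max(axis=2) - gedv_read.min(axis=2)) / gedv_read.mean(axis=2)
    needs_fourth = spread > config.td_spread_threshold
    td_value = co_read.mean(axis=2)
    # mean of identical readings must be exact (noise-free generator contract)
    identical = co_read.max(axis=2) == co_read.min(axis=2)
    td_value[identical] = co_read[:, :, 0][identical]
    td_sets: list[ThermodilutionSet] = []
    for s, t in np.argwhere(needs_fourth):
        co4 = max(float(co_true[s, t] + config.td_noise_sd * rng.standard_normal()), 0.05)
        gedv4 = max(float(gedv_subj[s] * (1.0 + config.gedv_cv * rng.standard_normal())), 1.0)
        readings = tuple(zip(co_read[s, t], gedv_read[s, t])) + ((co4, gedv4),)
        tdset = ThermodilutionSet(subjects[s], schedule[t], readings)
        td_value[s, t] = reduce_thermodilution(tdset, config.td_spread_threshold)
        if config.keep_td_sets:
            td_sets.append(tdset)
    if config.keep_td_sets:
        for s in range(S):
            for t in range(T):
                if not needs_fourth[s, t]:
                    td_sets.append(
                        ThermodilutionSet(
                            subjects[s], schedule[t],
                            tuple(zip(co_read[s, t], gedv_read[s, t])),
                        )
                    )

    blocks = [_block(subjects, schedule, "td", "CO", "na", td_value)]
    if config.emit_sv:
        blocks.append(_block(subjects, schedule, "td", "SV", "na", td_value / hr * 1000.0))

    steps = np.arange(T, dtype=float)
    for dev in config.devices:
        offset = rng.normal(0.0, dev.subject_sd, S)
        base = dev.proportional_scale * co_true + dev.additive_bias + offset[:, None]
        precal = base + dev.drift_per_step * steps + rng.normal(0.0, dev.noise_sd, (S, T))
        precal = np.clip(precal, 0.05, None)
        if dev.calibration_reset:
            postcal = base + rng.normal(0.0, dev.residual_sd, (S, T))
            postcal = np.clip(postcal, 0.05, None)
        else:
            postcal = precal.copy()
        blocks.append(_block(subjects, schedule, dev.method, "CO", "precal", precal))
        blocks.append(_block(subjects, schedule, dev.method, "CO", "postcal", postcal))
        if config.emit_sv:
            blocks.append(_block(subjects, schedule, dev.method, "SV", "precal",
                                 precal / hr * 1000.0))
            blocks.append(_block(subjects, schedule, dev.method, "SV", "postcal",
                                 postcal / hr * 1000.0))

    frame = pd.concat(blocks, ignore_index=True)
    dataset = StudyDataset(
        frame=frame,
        schedule=config.schedule,
        fluid_challenge_interval=config.fluid_challenge_interval,
        thermodilution_sets=td_sets,
    )
    truth = GroundTruth(
        subjects=tuple(subjects),
        schedule=tuple(config.schedule),
        co_true=co_true,
        sv_true=sv_true,
        hr=hr,
        responder=responder,
        dsv_pct=dsv,
        devices=tuple(config.devices),
        seed=config.seed,
    )
    return dataset, truth


# -- ground-truth I/O ------------------------------------------------------


def export_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write per-subject true values and responder flags to CSV."""
    cols: dict[str, object] = {
        "subject": list(truth.subjects),
        "responder": [bool(r) for r in truth.responder],
        "dsv_pct": list(np.asarray(truth.dsv_pct, dtype=float)),
    }
    for j, tp in enumerate(truth.schedule):
        cols[f"co_{tp}"] = list(truth.co_true[:, j]) if len(truth.subjects) else []
        cols[f"sv_{tp}"] = list(truth.sv_true[:, j]) if len(truth.subjects) else []
        cols[f"hr_{tp}"] = list(truth.hr[:, j]) if len(truth.subjects) else []
    pd.DataFrame(cols).to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Read a ground-truth CSV written by :func:`export_ground_truth`.

    Device parameters are not stored in the CSV; the returned truth carries
    an empty device tuple and seed -1.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    schedule = tuple(c[3:] for c in df.columns if c.startswith("co_"))
    def grid(prefix):
        if df.empty:
            return np.empty((0, len(schedule)))
        return df[[f"{prefix}_{tp}" for tp in schedule]].to_numpy(dtype=float)
    return GroundTruth(
        subjects=tuple(df["subject"].astype(str)),
        schedule=schedule,
        co_true=grid("co"),
        sv_true=grid("sv"),
        hr=grid("hr"),
        responder=df["responder"].to_numpy(dtype=bool),
        dsv_pct=df["dsv_pct"].to_numpy(dtype=float),
        devices=(),
        seed=-1,
    )


# -- config file I/O -------------------------------------------------------


def load_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML (or JSON) file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: expected a mapping at top level")
    if "devices" in raw:
        raw["devices"] = tuple(
            d if isinstance(d, DeviceModel) else DeviceModel(**d) for d in raw["devices"]
        )
    for key in ("schedule", "co_mean", "co_between_sd", "hr_mean", "hr_sd",
                "fluid_challenge_interval"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    d = asdict(config)
    d["devices"] = [asdict(dev) for dev in config.devices]
    for key, v in d.items():
        if isinstance(v, tuple):
            d[key] = list(v)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
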