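"""Data model, CSV I/O, thermodilution triplicate reduction, and pair alignment.

The pipeline operates on long-format measurement tables: one row per
(subject, timepoint, method, variable, calibration_state). The reference
method is transpulmonary thermodilution (``td``), recorded as the average of
a triplicate of dilution curves; pulse-contour test channels (e.g. ``pR``
for a radial-artery sensor, ``pF`` femoral) are recorded both before
(``precal``) and after (``postcal``) the device's on-demand auto-calibration.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Measurement schedule of the emulated study: induction (T0) through 16 h
#: after ICU admission (T7), with a fluid bolus between T4 and T5.
DEFAULT_SCHEDULE: tuple[str, ...] = ("T0", "T1", "T2", "T3", "T4", "T5", "T6", "T7")
DEFAULT_FLUID_INTERVAL: tuple[str, str] = ("T4", "T5")

CALIBRATION_STATES = ("precal", "postcal", "na")
VARIABLES = ("CO", "SV")

KEY_COLUMNS = ["subject", "timepoint", "method", "variable", "calibration_state"]
COLUMNS = KEY_COLUMNS + ["value"]


class SchemaError(ValueError):
    """Input table lacks a required column or has an unusable layout."""


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


class UniquenessError(ValidationError):
    """Duplicate (subject, timepoint, method, variable, state) key."""


class EmptyResultError(ValueError):
    """An operation produced no usable data (e.g. disjoint methods)."""


class IncompleteSetError(ValueError):
    """Triplicate thermodilution set needs a fourth reading before reduction."""


class DegenerateStatisticsError(ValueError):
    """A statistic is undefined on the provided data (e.g. all points excluded)."""


@dataclass(frozen=True)
class MeasurementRecord:
    """One observed value for one subject/timepoint/method/variable/state."""

    subject_id: str
    timepoint: str
    method: str
    variable: str
    calibration_state: str
    value: float

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValidationError(
                f"variable must be one of {VARIABLES}, got {self.variable!r}"
            )
        if self.calibration_state not in CALIBRATION_STATES:
            raise ValidationError(
                f"calibration_state must be one of {CALIBRATION_STATES}, "
                f"got {self.calibration_state!r}"
            )
        if not math.isfinite(self.value) or self.value < 0:
            raise ValidationError(
                f"value must be finite and >= 0, got {self.value!r} "
                f"({self.subject_id}/{self.timepoint}/{self.method})"
            )


@dataclass(frozen=True)
class ThermodilutionSet:
    """Triplicate (or quadruplicate) thermodilution readings at one timepoint.

    Each reading pairs a cardiac output (L/min) with the simultaneously
    derived global end-diastolic volume (mL), which serves as the quality
    index for the triplicate: if GEDV spread exceeds 10 % a fourth dilution
    is performed and the extreme reading discarded.
    """

    subject_id: str
    timepoint: str
    readings: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not 3 <= len(self.readings) <= 4:
            raise ValidationError(
                f"thermodilution set needs 3 or 4 readings, got {len(self.readings)}"
            )
        for co, gedv in self.readings:
            if not (co > 0 and gedv > 0):
                raise ValidationError(
                    f"thermodilution readings must be positive, got co={co}, gedv={gedv}"
                )

    @property
    def co(self) -> np.ndarray:
        return np.array([r[0] for r in self.readings], dtype=float)

    @property
    def gedv(self) -> np.ndarray:
        return np.array([r[1] for r in self.readings], dtype=float)


@dataclass(frozen=True)
class PairedSample:
    """Aligned (reference, test) values for one subject-timepoint."""

    subject_id: str
    timepoint: str
    ref_value: float
    test_value: float
    calibration_state: str

    def __post_init__(self) -> None:
        for name, v in (("ref_value", self.ref_value), ("test_value", self.test_value)):
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(
                    f"{name} must be finite and > 0, got {v!r} "
                    f"({self.subject_id}/{self.timepoint})"
                )


class PairList(list):
    """List of PairedSample with alignment bookkeeping (skipped timepoints)."""

    def __init__(self, pairs=(), n_skipped: int = 0):
        super().__init__(pairs)
        self.n_skipped = n_skipped


class StudyDataset:
    """A validated long-format measurement table with its schedule.

    Parameters
    ----------
    records
        Iterable of :class:`MeasurementRecord` (or mappings with the same
        field names). Ignored when ``frame`` is given.
    frame
        Pre-built DataFrame with columns ``subject, timepoint, method,
        variable, calibration_state, value``.
    schedule
        Ordered, unique timepoint labels.
    fluid_challenge_interval
        Pair of adjacent schedule labels bracketing the fluid bolus.
    """

    def __init__(
        self,
        records: Sequence[MeasurementRecord] | None = None,
        *,
        frame: pd.DataFrame | None = None,
        schedule: Sequence[str] = DEFAULT_SCHEDULE,
        fluid_challenge_interval: tuple[str, str] = DEFAULT_FLUID_INTERVAL,
        thermodilution_sets: Sequence[ThermodilutionSet] = (),
        validate: bool = True,
    ):
        self.schedule = tuple(schedule)
        if len(set(self.schedule)) != len(self.schedule):
            raise ValidationError("schedule labels must be unique")
        lo, hi = fluid_challenge_interval
        if lo not in self.schedule or hi not in self.schedule:
            raise ValidationError("fluid challenge interval endpoints must be in schedule")
        if self.schedule.index(hi) != self.schedule.index(lo) + 1:
            raise ValidationError(
                f"fluid challenge interval ({lo}, {hi}) must be adjacent schedule entries"
            )
        self.fluid_challenge_interval = (lo, hi)
        self.thermodilution_sets = list(thermodilution_sets)

        if frame is None:
            rows = []
            for r in records or ():
                if isinstance(r, MeasurementRecord):
                    rows.append(
                        (r.subject_id, r.timepoint, r.method, r.variable,
                         r.calibration_state, r.value)
                    )
                else:
                    rows.append(tuple(r[k] for k in
                                      ("subject_id", "timepoint", "method",
                                       "variable", "calibration_state", "value")))
            frame = pd.DataFrame(rows, columns=COLUMNS)
        else:
            missing = [c for c in COLUMNS if c not in frame.columns]
            if missing:
                raise SchemaError(f"frame is missing columns: {missing}")
            frame = frame[COLUMNS].copy()
        frame["value"] = frame["value"].astype(float)
        for col in KEY_COLUMNS:
            frame[col] = frame[col].astype(str)
        self.frame = frame.reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.frame
        bad_tp = sorted(set(df["timepoint"]) - set(self.schedule))
        if bad_tp:
            raise ValidationError(f"timepoints not in schedule: {bad_tp}")
        bad_state = sorted(set(df["calibration_state"]) - set(CALIBRATION_STATES))
        if bad_state:
            raise ValidationError(f"unknown calibration states: {bad_state}")
        bad_var = sorted(set(df["variable"]) - set(VARIABLES))
        if bad_var:
            raise ValidationError(f"unknown variables: {bad_var}")
        bad = df.index[~np.isfinite(df["value"].to_numpy()) | (df["value"].to_numpy() < 0)]
        if len(bad):
            raise ValidationError(
                f"values must be finite and >= 0; offending rows (0-based): {list(bad[:10])}"
            )
        dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
        if dup.any():
            keys = df.loc[dup, KEY_COLUMNS].drop_duplicates().head(5)
            raise UniquenessError(
                "duplicate (subject, timepoint, method, variable, calibration_state) "
                f"keys, e.g.:\n{keys.to_string(index=False)}"
            )

    # -- convenience -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    def records(self) -> Iterator[MeasurementRecord]:
        for row in self.frame.itertuples(index=False):
            yield MeasurementRecord(row.subject, row.timepoint, row.method,
                                    row.variable, row.calibration_state, row.value)

    def subjects(self) -> list[str]:
        return sorted(self.frame["subject"].unique())

    def methods(self) -> list[str]:
        return sorted(self.frame["method"].unique())

    def timepoint_position(self, timepoint: str) -> int:
        return self.schedule.index(timepoint)

    def to_csv(self, path: str | Path) -> None:
        self.frame[COLUMNS].to_csv(path, index=False)


def read_measurements(
    path: str | Path,
    schema_config: str | Path | dict | None = None,
    *,
    schedule: Sequence[str] = DEFAULT_SCHEDULE,
    fluid_challenge_interval: tuple[str, str] = DEFAULT_FLUID_INTERVAL,
) -> StudyDataset:
    """Read a long-format measurement CSV into a validated :class:`StudyDataset`.

    ``schema_config`` optionally remaps column names: a dict (or path to a
    JSON file holding one) from canonical names (``subject``, ``timepoint``,
    ``method``, ``variable``, ``calibration_state``, ``value``) to the names
    used in the file.

    Raises :class:`SchemaError` for missing columns, :class:`ValidationError`
    naming CSV line numbers for unparseable or invalid values, and
    :class:`UniquenessError` for duplicated keys.
    """
    if schema_config is not None and not isinstance(schema_config, dict):
        schema_config = json.loads(Path(schema_config).read_text())
    df = pd.read_csv(path, dtype=str)
    if schema_config:
        rename = {v: k for k, v in schema_config.items()}
        df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[values.isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # header is line 1
        raise ValidationError(f"{path}: non-numeric value at line(s) {lines}")
    # astype(float) (exact strtod) rather than to_numeric, which can be
    # off by one ulp and would break exact write/read round-trips
    df = df.assign(value=df["value"].astype(float))
    neg = df.index[df["value"] < 0]
    if len(neg):
        lines = [int(i) + 2 for i in neg[:10]]
        raise ValidationError(f"{path}: negative value at line(s) {lines}")
    return StudyDataset(
        frame=df,
        schedule=schedule,
        fluid_challenge_interval=fluid_challenge_interval,
    )


def reduce_thermodilution(
    tdset: ThermodilutionSet,
    spread_threshold: float = 0.10,
    *,
    override: bool = False,
) -> float:
    """Reduce a triplicate/quadruplicate thermodilution set to one CO value.

    With three readings whose GEDV relative range ``(max - min)/mean`` is
    within ``spread_threshold``, returns the plain mean CO. A larger spread
    signals an unreliable triplicate: a fourth dilution is required
    (:class:`IncompleteSetError`) unless ``override`` forces the mean. With
    four readings, the GEDV-extreme reading (farthest from the GEDV median,
    ties broken by CO deviation from the CO median, then by larger GEDV and
    CO, so the rule is order-independent) is dropped and the remaining three
    CO values averaged.
    """
    co, gedv = tdset.co, tdset.gedv
    if co.max() == co.min() and len(co) == 3:
        return float(co[0])  # exact: mean of identical readings
    if len(co) == 3:
        spread = (gedv.max() - gedv.min()) / gedv.mean()
        if spread > spread_threshold and not override:
            raise IncompleteSetError(
                f"GEDV spread {spread:.1%} exceeds {spread_threshold:.0%} for "
                f"{tdset.subject_id}/{tdset.timepoint}: supply a 4th reading "
                "or pass override=True"
            )
        return float(co.mean())
    dev_g = np.abs(gedv - np.median(gedv))
    dev_c = np.abs(co - np.median(co))
    # lexicographic argmax over (GEDV deviation, CO deviation, GEDV, CO):
    # value-determined, hence invariant under permutation of the readings
    order = sorted(range(4), key=lambda i: (dev_g[i], dev_c[i], gedv[i], co[i]))
    drop = order[-1]
    keep = [i for i in range(4) if i != drop]
    return float(co[keep].mean())


def align_pairs(
    dataset: StudyDataset,
    ref_method: str,
    test_method: str,
    variable: str = "CO",
    calibration_state: str = "postcal",
    *,
    ref_calibration_state: str = "na",
) -> PairList:
    """Align reference and test values into per-(subject, timepoint) pairs.

    Returns one :class:`PairedSample` per subject-timepoint where both
    methods report the requested variable (the test method in
    ``calibration_state``, the reference in ``ref_calibration_state``).
    Timepoints observed by only one side are skipped; the count is kept on
    the returned :class:`PairList` as ``n_skipped``. Output is ordered by
    subject, then schedule position.
    """
    df = dataset.frame
    ref = df[(df["method"] == ref_method) & (df["variable"] == variable)
             & (df["calibration_state"] == ref_calibration_state)]
    test = df[(df["method"] == test_method) & (df["variable"] == variable)
              & (df["calibration_state"] == calibration_state)]
    merged = ref.merge(test, on=["subject", "timepoint"], suffixes=("_ref", "_test"))
    if merged.empty:
        raise EmptyResultError(
            f"no overlapping ({ref_method}, {test_method}) pairs for "
            f"variable={variable!r}, state={calibration_state!r}"
        )
    n_skipped = (len(ref) - len(merged)) + (len(test) - len(merged))
    if n_skipped:
        logger.info(
            "align_pairs: %d unpaired %s/%s records skipped (%s vs %s)",
            n_skipped, variable, calibration_state, ref_method, test_method,
        )
    pos = {tp: i for i, tp in enumerate(dataset.schedule)}
    merged = merged.assign(_pos=merged["timepoint"].map(pos))
    merged = merged.sort_values(["subject", "_pos"], kind="mergesort")
    pairs = PairList(
        (
            PairedSample(row.subject, row.timepoint, row.value_ref,
                         row.value_test, calibration_state)
            for row in merged.itertuples(index=False)
        ),
        n_skipped=n_skipped,
    )
    return pairs
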