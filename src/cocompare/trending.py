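"""Trending-ability analysis: serial CO changes, four-quadrant concordance,
polar transformation, angular bias and polar concordance.

A device tracks trends well when the change it reports between two
timepoints agrees in direction (four-quadrant analysis) and in proportion
(polar analysis) with the change seen by the reference method. Small
changes carry no direction information — near the origin the sign is noise
— so both analyses support a central exclusion zone, and both rates are
reported with and without it.

In the polar transform each paired change (dref, dtest) becomes an angle to
the line of identity (0 deg and 180 deg mean perfect agreement of the two
changes) and a radius equal to the mean CO change. Changes whose mean is
negative are reflected into the right half-plane so that calibration error
shows up as a small systematic angle (the angular bias) rather than a
bimodal distribution around +-180 deg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .core import DegenerateStatisticsError, PairedSample

logger = logging.getLogger(__name__)

ZONE_RULES = ("mean", "either", "both")


@dataclass(frozen=True)
class DeltaPair:
    """Per-subject change in reference and test values between timepoints.

    ``gap`` is the number of schedule steps spanned; 1 for consecutive
    timepoints, >1 when an intermediate timepoint was missing and the
    interval bridges it.
    """

    subject_id: str
    interval: tuple[str, str]
    delta_ref: float
    delta_test: float
    gap: int = 1


@dataclass(frozen=True)
class FourQuadrantResult:
    concordance_with_exclusion: float | None
    concordance_without_exclusion: float | None
    exclusion_zone: float
    n_total: int
    n_excluded: int
    n_concordant_included: int


@dataclass(frozen=True)
class PolarPoint:
    """Angle (degrees, to the identity line) and radius (mean CO change,
    L/min) of one paired change; ``reflected`` marks points mapped from the
    negative-change half-plane."""

    angle: float
    radius: float
    reflected: bool


@dataclass(frozen=True)
class PolarResult:
    angular_bias: float | None
    polar_concordance_with_exclusion: float | None
    polar_concordance_without_exclusion: float | None
    exclusion_zone: float
    concordance_limit: float
    n_total: int
    n_excluded: int


def compute_deltas(
    pairs: Sequence[PairedSample],
    schedule: Sequence[str],
    pairing_mode: str | None = None,
) -> list[DeltaPair]:
    """Per-subject changes between consecutive observed timepoints.

    ``pairs`` must come from a single calibration state (both interval ends
    use the same state); if ``pairing_mode`` is given it is checked against
    the pairs' state. A missing intermediate timepoint is bridged: the
    interval spans it and records the gap. Subjects observed at fewer than
    two timepoints contribute nothing.
    """
    if pairing_mode is not None:
        states = {p.calibration_state for p in pairs}
        if states - {pairing_mode}:
            raise ValueError(
                f"pairing_mode={pairing_mode!r} but pairs carry states {sorted(states)}"
            )
    pos = {tp: i for i, tp in enumerate(schedule)}
    by_subject: dict[str, list[PairedSample]] = {}
    for p in pairs:
        by_subject.setdefault(p.subject_id, []).append(p)

    deltas: list[DeltaPair] = []
    for subject in sorted(by_subject):
        obs = sorted(by_subject[subject], key=lambda p: pos[p.timepoint])
        if len(obs) < 2:
            logger.info("compute_deltas: subject %s has <2 timepoints, skipped", subject)
            continue
        for a, b in zip(obs, obs[1:]):
            gap = pos[b.timepoint] - pos[a.timepoint]
            if gap > 1:
                logger.info(
                    "compute_deltas: subject %s bridges %s->%s (gap=%d)",
                    subject, a.timepoint, b.timepoint, gap,
                )
            deltas.append(
                DeltaPair(
                    subject_id=subject,
                    interval=(a.timepoint, b.timepoint),
                    delta_ref=b.ref_value - a.ref_value,
                    delta_test=b.test_value - a.test_value,
                    gap=gap,
                )
            )
    return deltas


def _in_zone(d: DeltaPair, zone: float, rule: str) -> bool:
    ar, at = abs(d.delta_ref), abs(d.delta_test)
    if rule == "mean":
        return (ar + at) / 2.0 < zone
    if rule == "either":
        return ar < zone or at < zone
    if rule == "both":
        return ar < zone and at < zone
    raise ValueError(f"unknown zone rule {rule!r}, expected one of {ZONE_RULES}")


def four_quadrant_concordance(
    deltas: Sequence[DeltaPair],
    exclusion_zone: float = 0.75,
    zone_rule: str = "mean",
) -> FourQuadrantResult:
    """Four-quadrant concordance rate, with and without the exclusion zone.

    A pair of changes is concordant when both methods move in the same
    direction (product of deltas > 0). Pairs where either method reports
    exactly zero change lie on an axis and are dropped from the denominator.
    A pair is excluded (with-exclusion rate only) when the mean of the two
    absolute changes is below ``exclusion_zone``; the rule is configurable
    to ``either``/``both``. An undefined rate (empty denominator) is
    returned as ``None``, never as 0.
    """
    if not deltas:
        raise DegenerateStatisticsError("no delta pairs")

    def rate(ds: Sequence[DeltaPair]) -> tuple[float | None, int]:
        judged = [d for d in ds if d.delta_ref * d.delta_test != 0]
        conc = sum(1 for d in judged if d.delta_ref * d.delta_test > 0)
        if not judged:
            return None, conc
        return 100.0 * conc / len(judged), conc

    included = [d for d in deltas if not _in_zone(d, exclusion_zone, zone_rule)]
    with_rate, n_conc = rate(included)
    without_rate, _ = rate(deltas)
    return FourQuadrantResult(
        concordance_with_exclusion=with_rate,
        concordance_without_exclusion=without_rate,
        exclusion_zone=exclusion_zone,
        n_total=len(deltas),
        n_excluded=len(deltas) - len(included),
        n_concordant_included=n_conc,
    )


def to_polar(delta: DeltaPair) -> PolarPoint:
    """Polar transform of one paired change.

    The vector (dref, dtest) is measured as an angle from the positive
    reference axis; points whose mean change is negative are reflected by
    180 deg into the right half-plane. Subtracting 45 deg re-references the
    angle to the line of identity. Radius is |dref + dtest| / 2, the mean CO
    change, in L/min.
    """
    dr, dt = delta.delta_ref, delta.delta_test
    if dr == 0 and dt == 0:
        raise DegenerateStatisticsError(
            f"zero change in both methods for {delta.subject_id} {delta.interval}: "
            "direction undefined; exclude this point"
        )
    theta = math.degrees(math.atan2(dt, dr))
    reflected = (dr + dt) / 2.0 < 0
    if reflected:
        theta += 180.0
    angle = theta - 45.0
    # wrap to (-180, 180]
    angle = angle - 360.0 * math.ceil((angle - 180.0) / 360.0)
    return PolarPoint(angle=angle, radius=abs(dr + dt) / 2.0, reflected=reflected)


def polar_statistics(
    points: Sequence[PolarPoint],
    exclusion_zone: float = 0.5,
    limit: float = 30.0,
) -> PolarResult:
    """Angular bias and polar concordance rate of a set of polar points.

    Points with radius below ``exclusion_zone`` (strict) are excluded from
    the with-exclusion statistics; angular bias (arithmetic mean angle) is
    reported for the with-exclusion set. Concordance counts points with
    |angle| <= ``limit`` (inclusive). Statistics with an empty basis are
    ``None``.
    """
    if not points:
        raise DegenerateStatisticsError("no polar points")
    included = [p for p in points if p.radius >= exclusion_zone]

    def conc(ps: Sequence[PolarPoint]) -> float | None:
        if not ps:
            return None
        return 100.0 * sum(1 for p in ps if abs(p.angle) <= limit) / len(ps)

    bias = sum(p.angle for p in included) / len(included) if included else None
    return PolarResult(
        angular_bias=bias,
        polar_concordance_with_exclusion=conc(included),
        polar_concordance_without_exclusion=conc(points),
        exclusion_zone=exclusion_zone,
        concordance_limit=limit,
        n_total=len(points),
        n_excluded=len(points) - len(included),
    )


def polar_points(deltas: Sequence[DeltaPair]) -> tuple[list[PolarPoint], int]:
    """Polar-transform a delta set, dropping zero-change points.

    Returns the points and the count of dropped (0, 0) pairs.
    """
    pts: list[PolarPoint] = []
    dropped = 0
    for d in deltas:
        if d.delta_ref == 0 and d.delta_test == 0:
            dropped += 1
            logger.info("polar_points: zero change dropped (%s %s)", d.subject_id, d.interval)
            continue
        pts.append(to_polar(d))
    return pts, dropped
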