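"""Fluid-challenge analysis: stroke-volume change, responder classification,
cross-method agreement, and correlation of fluid-induced changes.

A subject is fluid-responsive when a rapid volume bolus raises stroke
volume by more than 10 % (strict). The test device's ability to detect
responsiveness is summarised by (a) the fraction of subjects on which its
responder call agrees with the thermodilution call, and (b) the Spearman
rank correlation between the two methods' percentage SV changes. Pairs of
correlation coefficients (e.g. radial vs femoral site) are compared with
the Fisher z transformation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import DegenerateStatisticsError, StudyDataset

#: Switch point below which the Spearman p-value is computed by exact
#: permutation enumeration rather than the t approximation.
EXACT_PERMUTATION_N = 10


@dataclass(frozen=True)
class FluidChallengeRecord:
    """Stroke volume before and after the bolus for one subject and method."""

    subject_id: str
    sv_pre: float
    sv_post: float
    method: str
    calibration_state: str

    def __post_init__(self) -> None:
        if not self.sv_pre > 0:
            raise DegenerateStatisticsError(
                f"sv_pre must be > 0, got {self.sv_pre} ({self.subject_id})"
            )


@dataclass(frozen=True)
class FluidResponseResult:
    subjects: tuple[str, ...]
    delta_pct_ref: tuple[float, ...]
    delta_pct_test: tuple[float, ...]
    responder_ref: tuple[bool, ...]
    responder_test: tuple[bool, ...]
    n_agree: int
    n_total: int
    spearman_rho: float | None
    spearman_p: float | None
    threshold: float
    pairing_mode: str


def percent_change(pre: float, post: float) -> float:
    """Percentage change from ``pre`` to ``post``; ``pre`` must be positive."""
    if pre <= 0:
        raise DegenerateStatisticsError(f"pre value must be > 0, got {pre}")
    return 100.0 * (post - pre) / pre


def classify_responder(delta_pct: float, threshold: float = 10.0) -> bool:
    """Responder iff the SV change is strictly greater than the threshold."""
    if not math.isfinite(delta_pct):
        raise ValueError(f"delta_pct must be finite, got {delta_pct}")
    return delta_pct > threshold


def responder_agreement(
    ref_flags: Sequence[bool], test_flags: Sequence[bool]
) -> tuple[int, int]:
    """Count positions where the two responder classifications match."""
    if len(ref_flags) != len(test_flags):
        raise ValueError(
            f"flag lists differ in length: {len(ref_flags)} vs {len(test_flags)}"
        )
    n_agree = sum(1 for r, t in zip(ref_flags, test_flags) if bool(r) == bool(t))
    return n_agree, len(ref_flags)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho at small n."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (ry[perms] * rx).mean(axis=1)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_rho(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float | None, float | None]:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value uses the t approximation for n >= 10 and exact
    enumeration of all rank permutations below that. A constant input
    vector leaves the correlation undefined: returns ``(None, None)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be the same length")
    if len(x) < 3:
        raise DegenerateStatisticsError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None, None
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if len(x) < EXACT_PERMUTATION_N:
        p = _exact_spearman_p(x, y, rho)
    return rho, float(p)


def fisher_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two (independent) correlation coefficients via Fisher's z.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided p
    from the standard normal.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise DegenerateStatisticsError(f"|r| must be < 1, got {r}")
        if n <= 3:
            raise DegenerateStatisticsError(f"need n > 3, got {n}")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


PAIRING_MODES = ("postcal-postcal", "postcal-precal")


def extract_challenges(
    dataset: StudyDataset,
    method: str,
    calibration_state_pre: str,
    calibration_state_post: str,
) -> dict[str, FluidChallengeRecord]:
    """Per-subject SV values straddling the dataset's fluid-challenge interval."""
    lo, hi = dataset.fluid_challenge_interval
    df = dataset.frame
    sv = df[(df["method"] == method) & (df["variable"] == "SV")]
    pre = sv[(sv["timepoint"] == lo) & (sv["calibration_state"] == calibration_state_pre)]
    post = sv[(sv["timepoint"] == hi) & (sv["calibration_state"] == calibration_state_post)]
    pre_map = dict(zip(pre["subject"], pre["value"]))
    post_map = dict(zip(post["subject"], post["value"]))
    out = {}
    for subject in sorted(set(pre_map) & set(post_map)):
        out[subject] = FluidChallengeRecord(
            subject_id=subject,
            sv_pre=float(pre_map[subject]),
            sv_post=float(post_map[subject]),
            method=method,
            calibration_state=calibration_state_post,
        )
    return out


def fluid_analysis(
    dataset: StudyDataset,
    ref_method: str = "td",
    test_method: str = "pR",
    threshold: float = 10.0,
    pairing_mode: str = "postcal-postcal",
) -> FluidResponseResult:
    """End-to-end fluid-responsiveness agreement for one test channel.

    The reference SV change uses the thermodilution-derived SV at both ends
    of the challenge interval. For the test device the pre-bolus SV is
    always the auto-calibrated (postcal) value; ``pairing_mode`` selects
    whether the post-bolus SV is the auto-calibrated (``postcal-postcal``)
    or the uncalibrated (``postcal-precal``) value.
    """
    if pairing_mode not in PAIRING_MODES:
        raise ValueError(f"pairing_mode must be one of {PAIRING_MODES}")
    post_state = pairing_mode.split("-")[1]
    ref = extract_challenges(dataset, ref_method, "na", "na")
    test = extract_challenges(dataset, test_method, "postcal", post_state)
    subjects = sorted(set(ref) & set(test))
    if not subjects:
        raise DegenerateStatisticsError(
            f"no subjects with SV on both {ref_method} and {test_method} "
            "across the fluid-challenge interval"
        )
    d_ref = [percent_change(ref[s].sv_pre, ref[s].sv_post) for s in subjects]
    d_test = [percent_change(test[s].sv_pre, test[s].sv_post) for s in subjects]
    flags_ref = [classify_responder(d, threshold) for d in d_ref]
    flags_test = [classify_responder(d, threshold) for d in d_test]
    n_agree, n_total = responder_agreement(flags_ref, flags_test)
    if len(subjects) >= 3:
        rho, p = spearman_rho(d_ref, d_test)
    else:
        rho, p = None, None
    return FluidResponseResult(
        subjects=tuple(subjects),
        delta_pct_ref=tuple(d_ref),
        delta_pct_test=tuple(d_test),
        responder_ref=tuple(flags_ref),
        responder_test=tuple(flags_test),
        n_agree=n_agree,
        n_total=n_total,
        spearman_rho=rho,
        spearman_p=p,
        threshold=threshold,
        pairing_mode=pairing_mode,
    )
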