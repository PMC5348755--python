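"""Bland-Altman agreement with correction for repeated measurements, and
percentage error.

Each subject contributes several paired measurements taken at different
timepoints, over which the true cardiac output genuinely changes. The
repeated-measures correction therefore decomposes the variance of the
paired differences with a one-way random-effects ANOVA over subjects: the
SD entering the limits of agreement is

    sd_diff**2 = between_subject_var + within_subject_var

with ``within_subject_var = MSW`` and
``between_subject_var = max(0, (MSB - MSW) / m0)``, where ``m0`` is the
unbalanced-design average replicate count
``m0 = (N - sum(m_i**2)/N) / (n - 1)``. With one pair per subject this
reduces to (and the implementation falls back to) the ordinary single-
measurement Bland-Altman SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import DegenerateStatisticsError, PairedSample

Z_LOA = 1.96


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement summary between a test and a reference method.

    ``bias`` follows the ``direction`` convention (default
    ``ref_minus_test``: a negative bias means the test method over-reads).
    ``simple_fallback`` is set when every subject contributed a single pair
    so no variance decomposition was possible; ``clamped_between`` when the
    moment estimate of the between-subject component was negative and was
    clamped to zero.
    """

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    within_subject_var: float
    between_subject_var: float
    n_pairs: int
    n_subjects: int
    mean_ref: float
    mean_test: float
    percentage_error: float
    direction: str = "ref_minus_test"
    simple_fallback: bool = False
    clamped_between: bool = False


def percentage_error(sd_diff: float, mean_ref: float, mean_test: float) -> float:
    """Percentage error: 1.96 * SD of the differences over the mean CO of the
    two methods, as a percentage. Values <= 30 % are conventionally taken as
    interchangeable with the reference method."""
    if mean_ref <= 0 or mean_test <= 0:
        raise DegenerateStatisticsError(
            f"method means must be positive, got {mean_ref}, {mean_test}"
        )
    return float(Z_LOA * sd_diff / ((mean_ref + mean_test) / 2.0) * 100.0)


def bland_altman_repeated(
    pairs: Sequence[PairedSample],
    direction: str = "ref_minus_test",
) -> BlandAltmanResult:
    """Bland-Altman analysis corrected for multiple measurements per subject.

    Requires at least two subjects. The bias is the grand mean of the
    differences; the SD of the differences combines the within- and
    between-subject ANOVA components (see module docstring). If every
    subject has exactly one pair the decomposition is undefined and the
    simple Bland-Altman SD is used, flagged via ``simple_fallback``.
    """
    if direction not in ("ref_minus_test", "test_minus_ref"):
        raise ValueError(f"unknown direction {direction!r}")
    if len(pairs) < 2:
        raise DegenerateStatisticsError("need at least 2 pairs")
    subjects = np.array([p.subject_id for p in pairs])
    ref = np.array([p.ref_value for p in pairs], dtype=float)
    test = np.array([p.test_value for p in pairs], dtype=float)
    if len(set(subjects)) < 2:
        raise DegenerateStatisticsError("need pairs from at least 2 subjects")

    d = ref - test if direction == "ref_minus_test" else test - ref
    bias = float(d.mean())
    n_pairs = len(d)

    uniq, inverse, counts = np.unique(subjects, return_inverse=True, return_counts=True)
    n_subj = len(uniq)
    simple_fallback = False
    clamped = False
    if n_pairs == n_subj:
        # one pair per subject: no within-subject replication
        sd = float(d.std(ddof=1))
        within = float("nan")
        between = float("nan")
        simple_fallback = True
    else:
        subj_sum = np.bincount(inverse, weights=d)
        subj_mean = subj_sum / counts
        ssb = float(np.sum(counts * (subj_mean - bias) ** 2))
        ssw = float(np.sum((d - subj_mean[inverse]) ** 2))
        msb = ssb / (n_subj - 1)
        msw = ssw / (n_pairs - n_subj)
        m0 = (n_pairs - np.sum(counts**2) / n_pairs) / (n_subj - 1)
        between = (msb - msw) / m0
        if between < 0:
            between = 0.0
            clamped = True
        within = msw
        sd = float(np.sqrt(within + between))

    mean_ref = float(ref.mean())
    mean_test = float(test.mean())
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - Z_LOA * sd,
        loa_upper=bias + Z_LOA * sd,
        within_subject_var=within,
        between_subject_var=between,
        n_pairs=n_pairs,
        n_subjects=n_subj,
        mean_ref=mean_ref,
        mean_test=mean_test,
        percentage_error=percentage_error(sd, mean_ref, mean_test),
        direction=direction,
        simple_fallback=simple_fallback,
        clamped_between=clamped,
    )
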