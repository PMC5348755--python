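"""Descriptive statistics and Bonferroni-corrected baseline contrasts.

Hemodynamic variables are summarised per timepoint as mean (SD) when
compatible with normality (Shapiro-Wilk at alpha = 0.05) and as median
(25th-75th percentile) otherwise. Each post-baseline timepoint is compared
with baseline by a paired contrast — paired t when the paired differences
pass Shapiro-Wilk, Wilcoxon signed-rank (zeros dropped) otherwise — at a
Bonferroni-corrected level alpha / m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import DegenerateStatisticsError, StudyDataset

logger = logging.getLogger(__name__)

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class DescribeResult:
    n: int
    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    normal: bool | None   # None when Shapiro-Wilk is not applicable (n < 3)
    form: str             # "mean (SD)" or "median (IQR)"

    def formatted(self, digits: int = 1) -> str:
        if self.form == "mean (SD)":
            return f"{self.mean:.{digits}f} ({self.sd:.{digits}f})"
        return f"{self.median:.{digits}f} ({self.q25:.{digits}f}-{self.q75:.{digits}f})"


@dataclass(frozen=True)
class ContrastResult:
    variable: str
    timepoint: str
    test_used: str        # "paired-t" or "wilcoxon"
    p_raw: float
    significant: bool
    n: int
    alpha_corrected: float


def describe(values) -> DescribeResult:
    """Summary statistics with a normality-driven choice of reporting form.

    Percentiles use linear interpolation between order statistics. With
    fewer than 3 values (or zero variance) the Shapiro-Wilk test is not
    applicable and the mean (SD) form is reported.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DegenerateStatisticsError("describe needs at least one value")
    q25, median, q75 = np.percentile(v, [25, 50, 75])
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    normal: bool | None = None
    if v.size >= 3 and v.std() > 0:
        _, p = stats.shapiro(v)
        normal = bool(p > SHAPIRO_ALPHA)
    form = "median (IQR)" if normal is False else "mean (SD)"
    return DescribeResult(
        n=int(v.size),
        mean=float(v.mean()),
        sd=sd,
        median=float(median),
        q25=float(q25),
        q75=float(q75),
        normal=normal,
        form=form,
    )


def _paired_contrast(diff: np.ndarray) -> tuple[str, float]:
    """Choose paired-t vs Wilcoxon on the paired differences and test them."""
    if np.allclose(diff, diff[0]) and diff[0] == 0:
        return "paired-t", 1.0
    normal = True
    if len(diff) >= 3 and diff.std() > 0:
        _, p_sw = stats.shapiro(diff)
        normal = p_sw > SHAPIRO_ALPHA
    if normal:
        if diff.std(ddof=1) == 0:
            # non-zero constant difference: t statistic diverges
            return "paired-t", 0.0
        _, p = stats.ttest_rel(diff, np.zeros_like(diff))
        return "paired-t", float(p)
    nz = diff[diff != 0]
    if nz.size == 0:
        return "wilcoxon", 1.0
    _, p = stats.wilcoxon(nz)
    return "wilcoxon", float(p)


def baseline_contrasts(
    dataset: StudyDataset,
    variable: str = "CO",
    method: str = "td",
    calibration_state: str = "na",
    baseline: str | None = None,
    m: int = 7,
    alpha: float = 0.05,
) -> list[ContrastResult]:
    """Paired contrasts of every post-baseline timepoint against baseline.

    Subjects are paired by id; a timepoint with fewer than 2 paired
    subjects is skipped with a log entry. Significance is flagged at
    ``alpha / m`` (Bonferroni).
    """
    if baseline is None:
        baseline = dataset.schedule[0]
    df = dataset.frame
    sel = df[(df["method"] == method) & (df["variable"] == variable)
             & (df["calibration_state"] == calibration_state)]
    if sel.empty:
        raise DegenerateStatisticsError(
            f"no records for method={method!r}, variable={variable!r}, "
            f"state={calibration_state!r}"
        )
    base = sel[sel["timepoint"] == baseline].set_index("subject")["value"]
    if base.empty:
        raise DegenerateStatisticsError(f"no baseline ({baseline}) records")
    alpha_c = alpha / m
    out: list[ContrastResult] = []
    for tp in dataset.schedule:
        if tp == baseline:
            continue
        cur = sel[sel["timepoint"] == tp].set_index("subject")["value"]
        common = base.index.intersection(cur.index)
        if len(common) < 2:
            logger.info("baseline_contrasts: %s skipped (<2 paired subjects)", tp)
            continue
        diff = (cur.loc[common] - base.loc[common]).to_numpy(dtype=float)
        test_used, p = _paired_contrast(diff)
        out.append(
            ContrastResult(
                variable=variable,
                timepoint=tp,
                test_used=test_used,
                p_raw=p,
                significant=bool(p < alpha_c),
                n=len(common),
                alpha_corrected=alpha_c,
            )
        )
    return out
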