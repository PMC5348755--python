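"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities with longhand loops and textbook
formulas, independent of the vectorized implementation paths they check.
"""

import math


def anova_limits_of_agreement(subject_ids, diffs):
    """One-way random-effects decomposition of paired differences by subject,
    computed with explicit sums of squares.

    Returns (bias, sd_diff, within_var, between_var). Assumes at least one
    subject contributes more than one difference.
    """
    n_total = len(diffs)
    by_subject = {}
    for s, d in zip(subject_ids, diffs):
        by_subject.setdefault(s, []).append(d)
    n_subj = len(by_subject)
    grand = sum(diffs) / n_total

    ssb = 0.0
    ssw = 0.0
    sum_m_sq = 0
    for ds in by_subject.values():
        m = len(ds)
        mean = sum(ds) / m
        ssb += m * (mean - grand) ** 2
        for d in ds:
            ssw += (d - mean) ** 2
        sum_m_sq += m * m

    msb = ssb / (n_subj - 1)
    msw = ssw / (n_total - n_subj)
    m0 = (n_total - sum_m_sq / n_total) / (n_subj - 1)
    between = max(0.0, (msb - msw) / m0)
    sd = math.sqrt(msw + between)
    return grand, sd, msw, between


def simple_sd(diffs):
    """Sample SD (ddof=1) by the two-pass formula."""
    n = len(diffs)
    mean = sum(diffs) / n
    return math.sqrt(sum((d - mean) ** 2 for d in diffs) / (n - 1))


def spearman_rho_longhand(x, y):
    """Spearman rho as the Pearson correlation of average ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    n = len(x)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def place_polar_point(angle_deg, radius):
    """(delta_ref, delta_test) whose polar transform has exactly the given
    angle (degrees, in (-135, 45] + reflection-free range) and radius."""
    theta = math.radians(angle_deg + 45.0)
    s = math.cos(theta) + math.sin(theta)
    if abs(s) < 1e-12:
        raise ValueError("angle maps to zero mean change")
    c = 2.0 * radius / s
    return c * math.cos(theta), c * math.sin(theta)
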