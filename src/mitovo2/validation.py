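"""Agreement statistics between two labelings or two sets of mitoVO2 values.

Start points from two sources are matched one-to-one within a +/-5-sample
tolerance and summarized as an offset histogram with accuracies at offsets
0, 1, 3 and 5 (denominated by the reference count).  Paired per-subject
mitoVO2 values are compared by Bland-Altman analysis — mean bias, its 95%
t-based confidence interval and 1.96-SD limits of agreement — with an
extended, variance-components form of the limits when subjects contribute
repeated (possibly unbalanced) measurements.  Two methods are deemed
comparable when the bias confidence interval lies inside a predefined
+/-0.3 mmHg/s margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["MatchReport", "AgreementReport", "match_starts", "bland_altman",
           "extended_loa", "comparability", "COMPARABILITY_MARGIN"]

COMPARABILITY_MARGIN = 0.3  # mmHg/s


@dataclass
class MatchReport:
    n_ref: int
    n_test: int
    matched: int
    offsets: dict[int, int]            # offset (test - ref) -> count, -5..+5
    unmatched_test: int
    acc0: float
    acc1: float
    acc3: float
    acc5: float
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"n_ref": self.n_ref, "n_test": self.n_test,
                "matched": self.matched,
                "offsets": {str(k): v for k, v in sorted(self.offsets.items())},
                "unmatched_test": self.unmatched_test,
                "acc0": self.acc0, "acc1": self.acc1,
                "acc3": self.acc3, "acc5": self.acc5}


@dataclass
class AgreementReport:
    bias: float
    bias_ci95: tuple[float, float]
    loa: tuple[float, float]
    n_subjects: int
    comparable: bool

    def to_dict(self) -> dict:
        return {"bias": self.bias, "bias_ci95": list(self.bias_ci95),
                "loa": list(self.loa), "n_subjects": self.n_subjects,
                "comparable": self.comparable}


def _check_sorted_unique(a: np.ndarray, name: str) -> None:
    if a.size > 1 and not np.all(np.diff(a) > 0):
        raise ValueError(f"{name} start indices must be sorted and unique")


def match_starts(ref, test, tol: int = 5) -> MatchReport:
    """One-to-one matching of start points within ``tol`` samples.

    Candidate pairs are taken greedily by ascending absolute offset (ties:
    earlier reference, then earlier test point).  Accuracies acc0/1/3/5 are
    the matched fractions at each offset level, relative to the reference
    count.
    """
    ref = np.asarray(ref, dtype=int)
    test = np.asarray(test, dtype=int)
    _check_sorted_unique(ref, "ref")
    _check_sorted_unique(test, "test")
    cand = [(abs(int(t) - int(r)), int(r), int(t))
            for r in ref for t in test if abs(int(t) - int(r)) <= tol]
    cand.sort()
    used_r: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, r, t in cand:
        if r in used_r or t in used_t:
            continue
        used_r.add(r)
        used_t.add(t)
        pairs.append((r, t))
    offsets = {k: 0 for k in range(-tol, tol + 1)}
    for r, t in pairs:
        offsets[t - r] += 1

    def acc(level: int) -> float:
        if ref.size == 0:
            return float("nan")
        return sum(n for k, n in offsets.items() if abs(k) <= level) / ref.size

    return MatchReport(
        n_ref=int(ref.size), n_test=int(test.size), matched=len(pairs),
        offsets=offsets, unmatched_test=int(test.size) - len(pairs),
        acc0=acc(0), acc1=acc(1), acc3=acc(3), acc5=acc(tol),
        pairs=sorted(pairs))


def bland_altman(x, y, margin: float = COMPARABILITY_MARGIN) -> AgreementReport:
    """Classic Bland-Altman agreement between paired per-subject values.

    bias = mean(x - y); its 95% CI from the paired t distribution; limits of
    agreement bias +/- 1.96 * SD of the differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired subjects")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    tcrit = float(stats.t.ppf(0.975, n - 1))
    half = tcrit * sd / np.sqrt(n)
    ci = (bias - half, bias + half)
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    report = AgreementReport(bias=bias, bias_ci95=ci, loa=loa, n_subjects=n,
                             comparable=False)
    report.comparable = comparability(report, margin)
    return report


def extended_loa(per_subject_diffs: list[list[float]]
                 ) -> tuple[float, float]:
    """Limits of agreement for repeated measurements per subject.

    One-way variance components on the differences d_ij (subject i,
    replicate j): the variance of a single difference combines the
    within-subject mean square MSW with the between-subject component
    (MSB - MSW) / n0, where n0 = (N - sum(n_i^2)/N) / (I - 1) corrects for
    unequal replicate counts.  LoA = grand mean +/- 1.96 * sqrt(total
    variance).  With one replicate everywhere the within component has no
    degrees of freedom and the classic single-measurement limits are
    returned with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in per_subject_diffs]
    if len(groups) < 3:
        raise ValueError("need at least 3 subjects")
    if any(g.size < 1 for g in groups):
        raise ValueError("every subject needs at least 1 difference")
    counts = np.array([g.size for g in groups])
    N = int(counts.sum())
    I = len(groups)
    alld = np.concatenate(groups)
    grand = float(alld.mean())
    if np.all(counts == 1):
        warnings.warn("all subjects have a single replicate; falling back to "
                      "the classic limits of agreement", RuntimeWarning,
                      stacklevel=2)
        sd = float(alld.std(ddof=1))
        return (grand - 1.96 * sd, grand + 1.96 * sd)
    means = np.array([g.mean() for g in groups])
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msb = ssb / (I - 1)
    msw = ssw / (N - I)
    n0 = (N - float(np.sum(counts ** 2)) / N) / (I - 1)
    var_between = max((msb - msw) / n0, 0.0)
    var_total = var_between + msw
    half = 1.96 * np.sqrt(var_total)
    return (grand - half, grand + half)


def comparability(report: AgreementReport,
                  margin: float = COMPARABILITY_MARGIN) -> bool:
    """True iff the bias 95% CI lies inside the closed interval
    [-margin, +margin]."""
    lo, hi = report.bias_ci95
    return bool(-margin <= lo and hi <= margin)
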