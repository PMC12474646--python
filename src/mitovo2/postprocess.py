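"""Deterministic cleanup of raw per-sample labels into valid measurements.

The network's raw labels are refined by a fixed rule set so that only a
sustained, artifact-free stop-flow drop counts as a measurement:

R1   1-2 consecutive 'na' flanked by 'measurement' become 'measurement'.
R2   10+ consecutive 'measurement' without a preceding 'start': the first
     becomes 'start'.
R3   Two 'start' labels within 30 samples: the later is discarded.
R4   Measurements that begin below 20 mmHg, or whose minimum never goes
     below 20 mmHg, are excluded.
R5   'na' between a 'start' and its subsequent 'measurement' run is
     relabeled 'measurement'.
QC1  The 'start' is recentered on the highest mitoPO2 among the start
     sample and the next six samples.
QC2  A sharp rise (> 2 mmHg between consecutive samples) within the three
     samples after the start shifts the start past the rise, to the local
     maximum.
QC3  Measurements dropping more than 50 mmHg between the (re)defined start
     and the next sample are removed.
QC4  Segments lasting 10 samples or fewer are removed.

After the QC recentering, the R4 oxygen criteria are re-evaluated on the
final segment.  The full pass is iterated to a fixed point (a QC shift can
re-create an R3 or QC1 condition), so the cleaned label sequence is
idempotent under :func:`apply_rules`; every change is logged with the pass
it occurred in.  Measurement labels left outside any surviving segment are
cleared at the end of each pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LabelSeq, MeasurementSegment, Trace, NA, START, MEASUREMENT

__all__ = ["apply_rules", "RuleAction", "RuleTraceLog",
           "SHARP_RISE_MMHG", "MIN_START_SPACING", "LOW_PO2_MMHG",
           "MAX_FIRST_DROP_MMHG", "MIN_DURATION_SAMPLES"]

SHARP_RISE_MMHG = 2.0     # QC2 rise threshold between consecutive samples
MIN_START_SPACING = 30    # R3: consecutive starts must be > 30 samples apart
LOW_PO2_MMHG = 20.0       # R4 oxygen criteria
MAX_FIRST_DROP_MMHG = 50.0  # QC3 first-second artifact threshold
MIN_DURATION_SAMPLES = 10   # QC4: segments must exceed this many samples
_START_GAP_MAX = 5        # tolerated 'na' gap between a start and its run
_RECENTER_WINDOW = 7      # QC1: start sample plus the next six


@dataclass(frozen=True)
class RuleAction:
    rule: str
    indices: tuple[int, ...]
    action: str
    pass_num: int = 1


@dataclass
class RuleTraceLog:
    actions: list[RuleAction] = field(default_factory=list)

    def add(self, rule: str, indices, action: str, pass_num: int) -> None:
        self.actions.append(RuleAction(rule, tuple(int(i) for i in indices),
                                       action, pass_num))

    def rules_fired(self) -> list[str]:
        return [a.rule for a in self.actions]

    def __len__(self) -> int:
        return len(self.actions)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) inclusive index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]


def _segment_extent(lab: np.ndarray, s: int) -> int:
    """Inclusive end index of the measurement belonging to start ``s``:
    tolerates a short 'na' gap after the start, then follows the consecutive
    'measurement' run."""
    n = lab.size
    j = s + 1
    gap = 0
    while j < n and lab[j] == NA and gap < _START_GAP_MAX:
        j += 1
        gap += 1
    if j >= n or lab[j] != MEASUREMENT:
        return s
    while j + 1 < n and lab[j + 1] == MEASUREMENT:
        j += 1
    return j


def _one_pass(lab: np.ndarray, p: np.ndarray, log: RuleTraceLog,
              pass_num: int) -> np.ndarray:
    lab = lab.copy()
    n = lab.size

    # R1: fill 1-2 sample 'na' holes flanked by measurements
    for a, b in _runs(lab == NA):
        if 1 <= b - a + 1 <= 2 and a > 0 and b < n - 1 \
                and lab[a - 1] == MEASUREMENT and lab[b + 1] == MEASUREMENT:
            lab[a: b + 1] = MEASUREMENT
            log.add("R1", range(a, b + 1), "na->measurement", pass_num)

    # R2: promote the first of a 10+ 'measurement' run with no start
    for a, b in _runs(lab == MEASUREMENT):
        if b - a + 1 >= 10 and (a == 0 or lab[a - 1] != START):
            lab[a] = START
            log.add("R2", [a], "measurement->start", pass_num)

    # R3: discard the later of two starts within 30 samples
    starts = np.flatnonzero(lab == START)
    kept = -10**9
    for s in starts:
        if s - kept <= MIN_START_SPACING:
            new = MEASUREMENT if s + 1 < n and lab[s + 1] == MEASUREMENT else NA
            lab[s] = new
            log.add("R3", [s], "start discarded", pass_num)
        else:
            kept = s

    # R4 (first evaluation): oxygen criteria on the raw segment extent
    for s in np.flatnonzero(lab == START):
        e = _segment_extent(lab, s)
        seg_min = p[s: e + 1].min()
        if p[s] < LOW_PO2_MMHG or seg_min >= LOW_PO2_MMHG:
            lab[s: e + 1] = NA
            why = ("starts below 20 mmHg" if p[s] < LOW_PO2_MMHG
                   else "never reaches below 20 mmHg")
            log.add("R4", range(s, e + 1), f"segment excluded ({why})", pass_num)

    # R5: fill the 'na' gap between a start and its measurement run
    for s in np.flatnonzero(lab == START):
        j = s + 1
        gap = []
        while j < n and lab[j] == NA and len(gap) < _START_GAP_MAX:
            gap.append(j)
            j += 1
        if gap and j < n and lab[j] == MEASUREMENT:
            lab[gap] = MEASUREMENT
            log.add("R5", gap, "na->measurement", pass_num)

    # QC phase, per segment
    for s in list(np.flatnonzero(lab == START)):
        e = _segment_extent(lab, s)
        # QC1/QC2 recentering to a fixed point (the start only moves later)
        while True:
            win_end = min(s + _RECENTER_WINDOW, e + 1)
            s_new = s + int(np.argmax(p[s: win_end]))
            if s_new != s:
                lab[s: s_new] = NA
                lab[s_new] = START
                log.add("QC1", [s, s_new], "start recentered on local max",
                        pass_num)
                s = s_new
                continue
            rise_at = -1
            for t in range(s + 1, min(s + 4, e + 1)):
                if p[t] - p[t - 1] > SHARP_RISE_MMHG:
                    rise_at = t
            if rise_at < 0:
                break
            m = rise_at
            while m + 1 <= e and p[m + 1] >= p[m]:
                m += 1
            lab[s: m] = NA
            lab[m] = START
            log.add("QC2", [s, m], "start shifted past sharp rise", pass_num)
            s = m
        # QC3: first-second cliff
        if s + 1 <= e and p[s] - p[s + 1] > MAX_FIRST_DROP_MMHG:
            lab[s: e + 1] = NA
            log.add("QC3", range(s, e + 1),
                    "segment removed (>50 mmHg first-second drop)", pass_num)
            continue
        # QC4: minimum duration
        if e - s + 1 <= MIN_DURATION_SAMPLES:
            lab[s: e + 1] = NA
            log.add("QC4", range(s, e + 1),
                    "segment removed (duration <= 10 samples)", pass_num)
            continue
        # R4 re-evaluated on the recentered segment
        if p[s] < LOW_PO2_MMHG or p[s: e + 1].min() >= LOW_PO2_MMHG:
            lab[s: e + 1] = NA
            log.add("R4", range(s, e + 1),
                    "segment excluded after recentering", pass_num)

    # clear measurement labels outside surviving segments
    keep = np.zeros(n, dtype=bool)
    for s in np.flatnonzero(lab == START):
        keep[s: _segment_extent(lab, s) + 1] = True
    orphan = (lab == MEASUREMENT) & ~keep
    if orphan.any():
        log.add("cleanup", np.flatnonzero(orphan),
                "orphan measurement labels cleared", pass_num)
        lab[orphan] = NA
    return lab


def apply_rules(labels: LabelSeq, trace: Trace,
                max_passes: int = 6
                ) -> tuple[LabelSeq, list[MeasurementSegment], RuleTraceLog]:
    """Clean a raw label sequence and extract the surviving measurements.

    Returns the cleaned labels, the surviving segments (start plus its
    consecutive measurement samples, inclusive), and a log of every change.
    """
    if len(labels) != len(trace):
        raise ValueError("labels and trace lengths differ")
    p = trace.mitopo2
    lab = labels.codes.copy()
    log = RuleTraceLog()
    for pass_num in range(1, max_passes + 1):
        new = _one_pass(lab, p, log, pass_num)
        if np.array_equal(new, lab):
            lab = new
            break
        lab = new
    segments = [
        MeasurementSegment(int(s), int(e), p[s: e + 1])
        for s in np.flatnonzero(lab == START)
        for e in [_segment_extent(lab, s)]
    ]
    return LabelSeq(lab), segments, log
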