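import numpy as np
import pytest

from mitovo2.io import LabelSeq, Trace, NA, START, MEASUREMENT
from mitovo2.postprocess import apply_rules
from mitovo2.synthetic import CohortConfig, generate_subject


def run(values, codes):
    trace = Trace("t", np.asarray(values, dtype=float))
    return apply_rules(LabelSeq(np.asarray(codes, dtype=np.int8)), trace)


def pad(n, value=60.0):
    """Baseline plateau: n samples at `value`, labeled na."""
    return [value] * n, [NA] * n


def seg_labels(n):
    return [START] + [MEASUREMENT] * (n - 1)


class TestIndividualRules:
    def test_r1_fills_short_na_hole(self):
        # m m na m m within a valid segment: hole filled, run contiguous
        vals = [60.0] * 40 + list(np.linspace(60, 16, 12)) + [60.0] * 40
        codes = [NA] * 40 + seg_labels(12) + [NA] * 40
        codes[40 + 3: 40 + 5] = [NA, NA]
        clean, segs, log = run(vals, codes)
        assert [(s.start_index, s.end_index) for s in segs] == [(40, 51)]
        assert log.rules_fired().count("R1") == 1

    def test_r2_promotes_unled_measurement_run(self):
        vals = [60.0] * 40 + list(np.linspace(60, 16, 12)) + [60.0] * 40
        codes = [NA] * 40 + [MEASUREMENT] * 12 + [NA] * 40
        clean, segs, log = run(vals, codes)
        assert [(s.start_index, s.end_index) for s in segs] == [(40, 51)]
        assert "R2" in log.rules_fired()

    def test_r3_discards_later_of_close_starts(self):
        vals = [60.0] * 100 + list(np.linspace(60, 2, 32)) + [60.0] * 40
        codes = [NA] * 100 + seg_labels(32) + [NA] * 40
        codes[120] = START  # duplicate start 20 samples after the first
        clean, segs, log = run(vals, codes)
        assert [(s.start_index, s.end_index) for s in segs] == [(100, 131)]
        assert log.rules_fired().count("R3") == 1

    def test_r4_drops_low_start(self):
        vals = [18.0] * 40 + list(np.linspace(18, 4, 12)) + [18.0] * 40
        codes = [NA] * 40 + seg_labels(12) + [NA] * 40
        clean, segs, log = run(vals, codes)
        assert segs == []
        assert "R4" in log.rules_fired()
        assert not clean.codes.any()

    def test_r4_drops_shallow_segment(self):
        # declines 60 -> 30: never reaches below 20 mmHg
        vals = [60.0] * 40 + list(np.linspace(60, 30, 16)) + [60.0] * 40
        codes = [NA] * 40 + seg_labels(16) + [NA] * 40
        _, segs, log = run(vals, codes)
        assert segs == []
        assert "R4" in log.rules_fired()

    def test_r5_fills_gap_between_start_and_run(self):
        vals = [60.0] * 40 + list(np.linspace(60, 16, 12)) + [60.0] * 40
        codes = [NA] * 40 + seg_labels(12) + [NA] * 40
        codes[41:44] = [NA] * 3  # too long for R1, filled by R5
        clean, segs, log = run(vals, codes)
        assert [(s.start_index, s.end_index) for s in segs] == [(40, 51)]
        assert log.rules_fired().count("R5") == 1

    def test_qc1_recenters_start_on_local_max(self):
        # start labeled on sample 40 (55 mmHg) but sample 43 holds the
        # 7-neighborhood maximum (58 mmHg)
        vals = [55.0] * 41 + [56.0, 57.0, 58.0] + \
            list(np.linspace(54, 14, 11)) + [55.0] * 40
        codes = [NA] * 40 + seg_labels(14) + [NA] * 41
        clean, segs, log = run(vals, codes)
        assert segs[0].start_index == 43
        assert "QC1" in log.rules_fired()

    def test_qc2_shifts_start_past_sharp_rise(self):
        vals = [70.0] * 40 + [70.0, 50.0, 55.0, 52.0, 48.0, 44.0, 40.0, 36.0,
                              32.0, 28.0, 24.0, 20.0, 16.0, 12.0] + [70.0] * 40
        codes = [NA] * 40 + seg_labels(14) + [NA] * 40
        clean, segs, log = run(vals, codes)
        assert [(s.start_index, s.end_index) for s in segs] == [(42, 53)]
        assert "QC2" in log.rules_fired()

    def test_qc3_drops_cliff_artifact(self):
        vals = [75.0] * 40 + [75.0, 20.0] + list(np.linspace(18, 6, 11)) + \
            [75.0] * 40
        codes = [NA] * 40 + seg_labels(13) + [NA] * 40
        _, segs, log = run(vals, codes)
        assert segs == []
        assert "QC3" in log.rules_fired()

    def test_qc4_drops_short_segment(self):
        vals = [60.0] * 40 + [60.0, 52.0, 44.0, 36.0, 28.0, 20.0, 12.0, 4.0] \
            + [60.0] * 40
        codes = [NA] * 40 + seg_labels(8) + [NA] * 40
        _, segs, log = run(vals, codes)
        assert segs == []
        assert "QC4" in log.rules_fired()


def build_adversarial_fixture():
    """One instance of every violation, with hand-computed survivors.

    Layout (each block preceded by a 40-sample plateau at its start level):
      1 R1   na hole inside run          -> survives [s1, s1+11]
      2 R2   run without start           -> survives [s2, s2+11]
      3 R3   duplicate start at +20      -> survives [s3, s3+31]
      4 R4a  starts at 18 mmHg           -> dropped
      5 R4b  never below 20 mmHg         -> dropped
      6 R5   3-sample na gap after start -> survives [s6, s6+11]
      7 QC1  start 2 early, peak at +2   -> survives recentered [s7, s7+11]
      8 QC2  rise 50->55 after start     -> survives shifted [s8+2, s8+13]
      9 QC3  75->20 first-second cliff   -> dropped
     10 QC4  8-sample segment            -> dropped
    """
    vals: list[float] = []
    codes: list[int] = []
    expected: list[tuple[int, int]] = []

    def block(level, seg_vals, seg_codes, survive=None):
        vals.extend([level] * 40)
        codes.extend([NA] * 40)
        s = len(vals)
        vals.extend(seg_vals)
        codes.extend(seg_codes)
        if survive is not None:
            expected.append((s + survive[0], s + survive[1]))

    decay12 = list(np.linspace(60, 16, 12))  # steps of -4, min 16

    c = seg_labels(12)
    c[3:5] = [NA, NA]
    block(60.0, decay12, c, survive=(0, 11))                       # 1 R1
    block(60.0, decay12, [MEASUREMENT] * 12, survive=(0, 11))      # 2 R2
    c = seg_labels(32)
    c[20] = START
    block(60.0, list(np.linspace(60, 2, 32)), c, survive=(0, 31))  # 3 R3
    block(18.0, list(np.linspace(18, 4, 12)), seg_labels(12))      # 4 R4a
    block(60.0, list(np.linspace(60, 30, 16)), seg_labels(16))     # 5 R4b
    c = seg_labels(12)
    c[1:4] = [NA] * 3
    block(60.0, decay12, c, survive=(0, 11))                       # 6 R5
    # 7 QC1: start labeled 2 samples early on a 58-plateau, decay peaks at 60
    vals.extend([58.0] * 40)
    codes.extend([NA] * 40)
    s7 = len(vals)
    vals.extend(decay12)
    codes.extend([MEASUREMENT] * 12)
    codes[s7 - 2] = START
    codes[s7 - 1] = MEASUREMENT
    expected.append((s7, s7 + 11))
    block(70.0, [70.0, 50.0, 55.0, 52.0, 48.0, 44.0, 40.0, 36.0, 32.0,
                 28.0, 24.0, 20.0, 16.0, 12.0], seg_labels(14),
          survive=(2, 13))                                         # 8 QC2
    block(75.0, [75.0, 20.0] + list(np.linspace(18, 6, 11)),
          seg_labels(13))                                          # 9 QC3
    block(60.0, [60.0, 52.0, 44.0, 36.0, 28.0, 20.0, 12.0, 4.0],
          seg_labels(8))                                           # 10 QC4
    vals.extend([60.0] * 20)
    codes.extend([NA] * 20)
    return np.array(vals), np.array(codes, dtype=np.int8), expected


class TestAdversarialFixture:
    def test_exact_survivors_and_log(self):
        vals, codes, expected = build_adversarial_fixture()
        clean, segs, log = run(vals, codes)
        assert [(s.start_index, s.end_index) for s in segs] == expected
        fired = log.rules_fired()
        for rule in ("R1", "R2", "R3", "R5", "QC1", "QC2", "QC3", "QC4"):
            assert fired.count(rule) == 1, rule
        assert fired.count("R4") == 2  # both exclusion variants

    def test_idempotence(self):
        vals, codes, expected = build_adversarial_fixture()
        trace = Trace("t", vals)
        clean1, segs1, _ = apply_rules(LabelSeq(codes), trace)
        clean2, segs2, log2 = apply_rules(clean1, trace)
        assert clean1 == clean2
        assert [(s.start_index, s.end_index) for s in segs1] == \
            [(s.start_index, s.end_index) for s in segs2]
        assert len(log2) == 0


class TestSurvivorInvariants:
    @pytest.mark.parametrize("seed", [3, 14, 159])
    def test_survivors_satisfy_all_requirements(self, seed):
        """Surviving segments simultaneously satisfy every measurement
        requirement, on noisy generated sessions."""
        trace, labels, _ = generate_subject(
            CohortConfig(measurements_per_subject=6), seed)
        clean, segs, _ = apply_rules(labels, trace)
        p = trace.mitopo2
        starts = [s.start_index for s in segs]
        assert np.all(np.diff(starts) > 30)
        for s in segs:
            i, e = s.start_index, s.end_index
            assert p[i] > 20.0
            assert p[i: e + 1].min() < 20.0
            assert p[i] == p[i: min(i + 7, e + 1)].max()
            assert e - i + 1 > 10
            win = p[i: min(i + 4, e + 1)]
            assert np.all(np.diff(win) <= 2.0)
            assert p[i] - p[i + 1] <= 50.0
        # no measurement labels outside surviving segments
        outside = np.ones(len(trace), dtype=bool)
        for s in segs:
            outside[s.start_index: s.end_index + 1] = False
        assert not (clean.codes[outside] != 0).any()

    @pytest.mark.parametrize("seed", [3, 14, 159])
    def test_idempotence_on_generated_sessions(self, seed):
        trace, labels, _ = generate_subject(
            CohortConfig(measurements_per_subject=6), seed)
        clean1, _, _ = apply_rules(labels, trace)
        clean2, _, _ = apply_rules(clean1, trace)
        assert clean1 == clean2
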