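"""Two-step analysis pipeline: detect start points, then fit mitoVO2.

For every trace: the segmenter labels each sample, the rule engine cleans
the labels into valid measurement segments, each segment is fit with the
decay model, and the subject's mitoVO2 is the mean V_max of the converged
fits.  Given a fixed model checkpoint and inputs the pipeline is fully
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .fitting import FitResult, fit_segment, initial_guess, subject_mitovo2
from .io import LabelSeq, MeasurementSegment, Trace, read_trace, write_results
from .postprocess import RuleTraceLog, apply_rules
from .segmenter import BiLstmSegmenter

log = logging.getLogger(__name__)

__all__ = ["SubjectResult", "analyze_trace", "run_pipeline"]


@dataclass
class SubjectResult:
    subject_id: str
    labels: LabelSeq
    segments: list[MeasurementSegment]
    fits: list[FitResult]
    mitovo2: float | None
    rule_log: RuleTraceLog = field(repr=False, default=None)

    def to_dict(self) -> dict:
        measurements = []
        for seg, fit in zip(self.segments, self.fits):
            params = None
            if fit.params is not None:
                params = {"v0": fit.params.v0, "p50": fit.params.p50,
                          "p0": fit.params.p0, "z": fit.params.z}
            measurements.append({
                "start_index": int(seg.start_index),
                "end_index": int(seg.end_index),
                "params": params,
                "vmax_mmhg_per_s": fit.vmax,
                "converged": fit.converged,
            })
        return {"subject_id": self.subject_id,
                "measurements": measurements,
                "mitovo2_mmhg_per_s": self.mitovo2}


def analyze_trace(model: BiLstmSegmenter, trace: Trace) -> SubjectResult:
    """Run detection, cleanup and fitting on one trace."""
    raw = model.predict(trace)
    clean, segments, rule_log = apply_rules(raw, trace)
    fits = []
    for seg in segments:
        guess = initial_guess(seg, trace, seg.start_index)
        fits.append(fit_segment(seg, guess))
    return SubjectResult(
        subject_id=trace.subject_id, labels=clean, segments=segments,
        fits=fits, mitovo2=subject_mitovo2(fits), rule_log=rule_log)


def run_pipeline(model: BiLstmSegmenter,
                 traces: Sequence[Trace] | str | Path,
                 out_path: str | Path | None = None) -> list[SubjectResult]:
    """Analyze a list of traces (or every ``*.trace.csv`` in a directory);
    optionally write the combined results JSON."""
    if isinstance(traces, (str, Path)):
        paths = sorted(Path(traces).glob("*.trace.csv"))
        loaded: list[Trace] = []
        for p in paths:
            try:
                loaded.append(read_trace(p))
            except Exception as exc:  # unreadable trace: skip, keep going
                log.warning("skipping %s: %s", p, exc)
        traces = loaded
        if not traces:
            log.warning("no readable traces found")
    results = [analyze_trace(model, t) for t in traces]
    if out_path is not None:
        write_results(out_path, [r.to_dict() for r in results])
    return results
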