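"""Synthetic COMET-style measurement sessions with ground-truth labels.

Clinical stop-flow recordings cannot be redistributed, so the pipeline is
developed and validated against generated sessions that reproduce their
structure: a 1-Hz mitoPO2 trace per subject that alternates baseline
plateaus, stop-flow decays driven by the kinetics model, and exponential
reoxygenation back to baseline, with additive white measurement noise.

Each decay carries ground truth: its kinetic parameters, the index of its
first sample (the 'start' label) and the analytic maximal consumption
``v0*p0/(p50+p0)`` (the steepest tangent of a decay started at p0).

An adversarial mode deterministically injects one instance of every label
pathology the post-processing rule engine must handle (label holes, missing
and duplicated starts, low-oxygen starts, shallow and too-short segments,
first-second cliffs, spurious rises after the start).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io import LabelSeq, Trace, NA, START, MEASUREMENT
from .kinetics import KineticParams, simulate_decay

__all__ = ["CohortConfig", "GroundTruthSegment", "generate_subject",
           "generate_cohort", "write_cohort"]


@dataclass(frozen=True)
class GroundTruthSegment:
    params: KineticParams
    start_index: int
    end_index: int
    true_vmax: float  # mmHg/s, analytic steepest slope v0*p0/(p50+p0)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a generated cohort.

    Defaults emulate healthy-volunteer sessions: baseline mitoPO2 around
    60 mmHg, ~1.5 mmHg sensor noise, decays that cross 20 mmHg and last
    longer than 10 s, and consecutive measurements well over 30 s apart.
    """

    n_subjects: int = 20
    measurements_per_subject: int | tuple[int, int] = 8
    baseline_mean: float = 60.0     # mmHg
    baseline_sd: float = 10.0       # mmHg, between-measurement spread
    noise_sd: float = 1.5           # mmHg, i.i.d. Gaussian per sample
    v0_range: tuple[float, float] = (4.0, 14.0)    # mmHg/s
    p50_range: tuple[float, float] = (1.0, 6.0)    # mmHg
    z_range: tuple[float, float] = (0.02, 0.15)    # 1/s
    recovery_tau: float = 10.0      # s, reoxygenation time constant
    baseline_gap: tuple[float, float] = (40.0, 90.0)  # s between measurements
    stop_level: float = 5.0         # mmHg, release pressure once crossed
    max_duration: float = 120.0     # s, device records 120 s per measurement
    min_hold: int = 12              # samples, minimum stop-flow hold
    adversarial: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        n_meas = self.measurements_per_subject
        lo = n_meas if isinstance(n_meas, int) else n_meas[0]
        if self.n_subjects < 1 or lo < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _draw_params(cfg: CohortConfig, rng: np.random.Generator) -> KineticParams:
    p0 = float(np.clip(rng.normal(cfg.baseline_mean, cfg.baseline_sd), 30.0, 100.0))
    return KineticParams(
        v0=float(rng.uniform(*cfg.v0_range)),
        p50=float(rng.uniform(*cfg.p50_range)),
        p0=p0,
        z=float(rng.uniform(*cfg.z_range)),
    )


def _decay_block(cfg: CohortConfig, params: KineticParams) -> np.ndarray:
    """Noise-free stop-flow decay: runs until mitoPO2 crosses the stop level
    (probe held for at least ``min_hold`` samples) or 120 s elapse."""
    _, p = simulate_decay(params, cfg.max_duration, dt=1.0, p_init=params.p0)
    below = np.flatnonzero(p < cfg.stop_level)
    if below.size == 0:
        end = p.size - 1
    else:
        end = max(int(below[0]), cfg.min_hold - 1)
    return p[: end + 1]


def _draw_measurement(cfg: CohortConfig, rng: np.random.Generator
                      ) -> tuple[KineticParams, np.ndarray]:
    """Draw kinetics for one valid measurement: parameter combinations whose
    decay equilibrates above the stop level (influx balancing a weak
    consumption) are not measurable and are redrawn."""
    params, decay = None, None
    for _ in range(50):
        params = _draw_params(cfg, rng)
        decay = _decay_block(cfg, params)
        if decay.min() < cfg.stop_level:
            return params, decay
    warnings.warn(
        "decays never cross the stop level under this configuration; the "
        "segment will fail the minimum-mitoPO2 requirement and be filtered "
        "downstream", RuntimeWarning, stacklevel=3)
    return params, decay


def _recovery_block(p_from: float, level: float, tau: float) -> np.ndarray:
    """Exponential reoxygenation from p_from toward the next baseline level."""
    n = max(int(np.ceil(4.0 * tau)), 1)
    k = np.arange(1, n + 1)
    return level + (p_from - level) * np.exp(-k / tau)


class _SessionBuilder:
    """Accumulates trace blocks plus aligned labels and ground truth."""

    def __init__(self) -> None:
        self.values: list[np.ndarray] = []
        self.labels: list[np.ndarray] = []
        self.truth: list[GroundTruthSegment] = []
        self.n = 0

    def add(self, values: np.ndarray, labels: np.ndarray | None = None) -> int:
        values = np.asarray(values, dtype=float)
        if labels is None:
            labels = np.full(values.size, NA, dtype=np.int8)
        at = self.n
        self.values.append(values)
        self.labels.append(np.asarray(labels, dtype=np.int8))
        self.n += values.size
        return at

    def add_measurement(self, decay: np.ndarray, params: KineticParams) -> int:
        labels = np.full(decay.size, MEASUREMENT, dtype=np.int8)
        labels[0] = START
        at = self.add(decay, labels)
        vmax = params.v0 * params.p0 / (params.p50 + params.p0)
        self.truth.append(GroundTruthSegment(params, at, at + decay.size - 1, vmax))
        return at


def generate_subject(config: CohortConfig, subject_seed: int,
                     subject_id: str = "synthetic"
                     ) -> tuple[Trace, LabelSeq, list[GroundTruthSegment]]:
    """Generate one subject's session: trace, per-sample labels, ground truth."""
    rng = np.random.default_rng(subject_seed)
    n_meas = config.measurements_per_subject
    if not isinstance(n_meas, int):
        n_meas = int(rng.integers(n_meas[0], n_meas[1] + 1))

    drawn = [_draw_measurement(config, rng) for _ in range(n_meas)]
    b = _SessionBuilder()
    for i, (par, decay) in enumerate(drawn):
        gap = int(round(rng.uniform(*config.baseline_gap)))
        b.add(np.full(gap, par.p0))
        b.add_measurement(decay, par)
        next_level = drawn[i + 1][0].p0 if i + 1 < n_meas else par.p0
        b.add(_recovery_block(decay[-1], next_level, config.recovery_tau))
    b.add(np.full(20, drawn[-1][0].p0))  # trailing baseline

    values = np.concatenate(b.values)
    labels = np.concatenate(b.labels)
    truth = list(b.truth)

    if config.adversarial:
        values, labels = _inject_adversarial(values, labels, truth, rng, config)

    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, values.size)
    values = np.clip(values, 0.0, None)
    trace = Trace(subject_id=subject_id, mitopo2=values)
    return trace, LabelSeq(labels), truth


def _inject_adversarial(values: np.ndarray, labels: np.ndarray,
                        truth: list[GroundTruthSegment],
                        rng: np.random.Generator,
                        cfg: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministically corrupt a session so every cleanup rule fires.

    Applies, where enough real segments exist: a 1-2 sample 'na' hole inside
    a measurement run; a deleted 'start'; a duplicate 'start' within 30
    samples; an 'na' gap between a start and its run; a misplaced (early)
    start; a >2 mmHg rise just after a start.  Then appends three invalid
    blocks: a >50 mmHg first-second cliff, a too-short (8-sample) segment and
    a shallow decay that never reaches 20 mmHg, plus one starting below
    20 mmHg.
    """
    labels = labels.copy()
    segs = list(truth)
    if len(segs) >= 1:  # R1: short na hole inside the run
        s = segs[0]
        if s.end_index - s.start_index > 6:
            labels[s.start_index + 3: s.start_index + 5] = NA
    if len(segs) >= 2:  # R2: measurement run with no start
        labels[segs[1].start_index] = MEASUREMENT
    if len(segs) >= 3:  # R3: double start within 30 samples
        s = segs[2]
        dup = min(s.start_index + 20, s.end_index)
        labels[dup] = START
    if len(segs) >= 4:  # R5: na gap between start and its run
        s = segs[3]
        if s.end_index - s.start_index > 6:
            labels[s.start_index + 1: s.start_index + 3] = NA
    if len(segs) >= 5:  # QC1: start placed early, on the plateau
        s = segs[4]
        labels[s.start_index] = MEASUREMENT
        labels[s.start_index - 2] = START
        labels[s.start_index - 1] = MEASUREMENT
    if len(segs) >= 6:  # QC2: sharp rise right after the start
        s = segs[5]
        values = values.copy()
        values[s.start_index + 2] = values[s.start_index + 1] + 4.0

    blocks: list[tuple[np.ndarray, np.ndarray]] = []

    def crafted(vals: np.ndarray) -> None:
        lab = np.full(vals.size, MEASUREMENT, dtype=np.int8)
        lab[0] = START
        blocks.append((np.full(45, vals[0]), np.full(45, NA, dtype=np.int8)))
        blocks.append((vals, lab))

    # QC3: 55-mmHg cliff between start and next sample
    crafted(np.concatenate(([75.0, 20.0], np.linspace(18.0, 10.0, 12))))
    # QC4: 8-sample segment (crosses 20 mmHg but too short)
    crafted(np.linspace(60.0, 12.0, 8))
    # R4: starts below 20 mmHg
    crafted(np.linspace(18.0, 4.0, 14))
    # R4: never reaches below 20 mmHg
    crafted(np.linspace(60.0, 30.0, 16))

    extra_v = np.concatenate([v for v, _ in blocks])
    extra_l = np.concatenate([l for _, l in blocks])
    return np.concatenate([values, extra_v]), np.concatenate([labels, extra_l])


def generate_cohort(config: CohortConfig
                    ) -> list[tuple[Trace, LabelSeq, list[GroundTruthSegment]]]:
    """Generate ``config.n_subjects`` independent subjects, seeded from
    ``config.seed``."""
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=config.n_subjects)
    return [
        generate_subject(config, int(seeds[i]), subject_id=f"subject{i:03d}")
        for i in range(config.n_subjects)
    ]


def write_cohort(out_dir, config: CohortConfig) -> None:
    """Write a cohort as ``*.trace.csv`` / ``*.labels.csv`` / ``*.truth.json``."""
    import json
    from pathlib import Path

    from .io import write_labels, write_trace

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for trace, labels, truth in generate_cohort(config):
        write_trace(out / f"{trace.subject_id}.trace.csv", trace)
        write_labels(out / f"{trace.subject_id}.labels.csv", labels)
        doc = [
            {"start_index": int(g.start_index), "end_index": int(g.end_index),
             "true_vmax": g.true_vmax,
             "params": {"v0": g.params.v0, "p50": g.params.p50,
                        "p0": g.params.p0, "z": g.params.z}}
            for g in truth
        ]
        with open(out / f"{trace.subject_id}.truth.json", "w") as fh:
            json.dump(doc, fh, indent=2)
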