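"""High-level orchestration: library -> personalization -> monitoring.

These functions realize the five workflow steps (model degradations,
synthesize abnormal beats, form the personal training set, train the
personal CNN ensemble, monitor the beat stream) as plain library calls;
the command-line interface in :mod:`cardioabs.cli` is a thin wrapper
around them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .beats import AAMI, EcgRecord, segment_single_beat, segment_trio
from .cnn import CnnConfig, run_ensemble
from .evaluation import (
    ConfusionMatrix5,
    accumulate,
    collapse,
    first_alarm_latency,
    metrics,
)
from .filters import CurationConfig, FilterDesignConfig, FilterLibrary, build_library
from .synthesis import build_training_set


@dataclass
class MonitorResult:
    subject_id: str
    cm5: ConfusionMatrix5
    n_beats: int
    n_abnormal: int
    first_alarm_latencies: list  # one per model; None if never alarmed

    @property
    def cm2(self):
        return collapse(self.cm5)


def monitoring_beats(record: EcgRecord, after_s: float = 300.0,
                     half_window: Optional[int] = None):
    """Beat stream to monitor: everything after the personal-training
    prefix, as (singles, trios, labels) arrays.

    Boundary beats without a trio representation are dropped.
    """
    limit = int(after_s * record.fs)
    xs, xt, labels = [], [], []
    for i, ann in enumerate(record.annotations):
        if ann.r_sample < limit or not 0 < i < record.n_beats - 1:
            continue
        xs.append(segment_single_beat(record, i, half_window).samples)
        xt.append(segment_trio(record, i, half_window).samples)
        labels.append(int(ann.label))
    if not xs:
        return np.empty((0, 128)), np.empty((0, 128)), np.empty(0, dtype=int)
    return np.stack(xs), np.stack(xt), np.array(labels)


def monitor_subject(record: EcgRecord, models, after_s: float = 300.0,
                    half_window: Optional[int] = None) -> MonitorResult:
    """Stream a subject's post-prefix beats through each trained model."""
    from .cnn import predict_batch

    xs, xt, labels = monitoring_beats(record, after_s, half_window)
    cm5 = accumulate(models, xs, xt, labels)
    latencies = [
        first_alarm_latency(labels, predict_batch(m, xs, xt)) for m in models
    ]
    return MonitorResult(
        subject_id=record.subject_id,
        cm5=cm5,
        n_beats=len(labels),
        n_abnormal=int(np.sum(labels != int(AAMI.N))),
        first_alarm_latencies=latencies,
    )


def train_person(
    record: EcgRecord,
    library: FilterLibrary,
    cnn_cfg: Optional[CnnConfig] = None,
    n_runs: int = 10,
    exclude: bool = True,
    half_window: Optional[int] = None,
    duration_s: float = 300.0,
):
    """Personal training set + CNN ensemble for one subject.

    Returns (training_set, [(model, history), ...]).  The subject's own
    filters are excluded from synthesis by default (leave-subject-out).
    ``duration_s`` is the personal-training prefix (real N beats are
    taken from its first span).
    """
    ts = build_training_set(record, library, duration_s=duration_s,
                            half_window=half_window, exclude=exclude)
    if ts.single_class:
        raise ValueError(
            f"training set of {record.subject_id} has a single class "
            "(empty filter library after exclusion?) — cannot train"
        )
    runs = run_ensemble(ts, cnn_cfg, n_runs=n_runs)
    return ts, runs


def run_cohort(
    train_records,
    test_records,
    design_cfg: Optional[FilterDesignConfig] = None,
    curation: Optional[CurationConfig] = None,
    cnn_cfg: Optional[CnnConfig] = None,
    n_runs: int = 10,
    after_s: float = 300.0,
):
    """Full leave-subject-out evaluation over a cohort.

    Builds the filter library from the training records, then for each
    test subject: exclusion, synthesis, ensemble training and
    monitoring.  Returns (library, [MonitorResult, ...], pooled
    DetectionMetrics).
    """
    library = build_library(train_records, design_cfg, curation)
    results = []
    for rec in test_records:
        _, runs = train_person(rec, library, cnn_cfg, n_runs=n_runs)
        models = [m for m, _ in runs]
        results.append(monitor_subject(rec, models, after_s=after_s))
    pooled5 = ConfusionMatrix5.zeros()
    for r in results:
        pooled5 = pooled5 + r.cm5
    pooled_metrics = metrics(collapse(pooled5))
    return library, results, pooled_metrics
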