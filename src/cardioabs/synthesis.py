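"""Personalized training-set assembly from real-N + synthesized-abnormal beats.

For a monitored person the classifier must learn abnormal beats it has
never seen: the curated degradation-filter library (minus any filters
the person's own beats produced) is applied to the person's average
normal beat, and the resulting synthetic beats join the person's real
normal beats from the first five minutes of their record.  The training
set therefore never contains a real abnormal beat — that is the whole
premise of an advance-warning system for healthy subjects.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import islice, cycle
from pathlib import Path
from typing import Optional

import numpy as np

from .beats import (
    AAMI,
    AverageNormalBeat,
    BeatVector,
    EcgRecord,
    segment_single_beat,
    segment_trio,
    select_anb,
)
from .filters import AbsFilter, FilterLibrary, apply_filter, exclude_subject

ABNORMAL_CLASSES = (AAMI.S, AAMI.V, AAMI.Q, AAMI.F)


@dataclass
class TrainingItem:
    single: BeatVector
    trio: BeatVector
    label: AAMI


@dataclass
class TrainingSet:
    """Real-normal + synthetic-abnormal beats for one subject.

    Hard invariant: a real (non-synthetic) beat is always class N, and
    every abnormal-class item is synthetic.
    """

    items: list[TrainingItem]
    subject_id: str
    n_real_normal: int = 0
    n_synthetic_by_class: dict = field(default_factory=dict)
    single_class: bool = False

    def __post_init__(self):
        for it in self.items:
            if it.label == AAMI.N:
                if it.single.is_synthetic or it.trio.is_synthetic:
                    raise ValueError("normal training beats must be real")
            else:
                if not (it.single.is_synthetic and it.trio.is_synthetic):
                    raise ValueError(
                        "abnormal training beats must be synthetic — real "
                        "abnormal beats never enter the training set"
                    )

    def __len__(self) -> int:
        return len(self.items)

    def classes(self) -> set[AAMI]:
        return {it.label for it in self.items}

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(n,128) single channel, (n,128) trio channel, (n,) int labels."""
        xs = np.stack([it.single.samples for it in self.items])
        xt = np.stack([it.trio.samples for it in self.items])
        y = np.array([int(it.label) for it in self.items])
        return xs, xt, y


def synthesize_beat(anb: AverageNormalBeat, f: AbsFilter) -> BeatVector:
    """Apply one degradation filter to the matching-mode ANB."""
    src = anb.single if f.mode == "single" else anb.trio
    if src is None:
        raise ValueError("ANB has no trio representation")
    if src.mode != f.mode:
        raise ValueError(f"mode mismatch: ANB {src.mode} vs filter {f.mode}")
    return BeatVector(
        samples=apply_filter(src.samples, f.h),
        mode=f.mode,
        label=f.source_class,
        subject_id=src.subject_id,
        is_synthetic=True,
        beat_index=-1,
    )


def nearest_synthetic(
    real_abnormal: BeatVector, synthetic: list[BeatVector]
) -> tuple[BeatVector, float]:
    """Closest synthetic beat (Euclidean) to a real abnormal beat."""
    if not synthetic:
        raise ValueError("candidate list is empty")
    if any(s.mode != real_abnormal.mode for s in synthetic):
        raise ValueError("mode mismatch in candidate list")
    d = [float(np.linalg.norm(s.samples - real_abnormal.samples)) for s in synthetic]
    i = int(np.argmin(d))
    return synthetic[i], d[i]


def _as_synthetic(v: BeatVector, label: AAMI) -> BeatVector:
    return BeatVector(
        samples=v.samples.copy(), mode=v.mode, label=label,
        subject_id=v.subject_id, is_synthetic=True, beat_index=-1,
    )


def _real_normal_items(record, limit, half_window):
    out = []
    for i, ann in enumerate(record.annotations):
        if ann.label != AAMI.N or ann.r_sample >= limit:
            continue
        if not 0 < i < record.n_beats - 1:
            continue  # boundary beats have no trio representation
        out.append(
            TrainingItem(
                single=segment_single_beat(record, i, half_window),
                trio=segment_trio(record, i, half_window),
                label=AAMI.N,
            )
        )
    return out


def _thin(seq: list, cap: Optional[int]) -> list:
    """Deterministic, evenly spaced subsample to at most ``cap`` items."""
    if cap is None or len(seq) <= cap:
        return seq
    idx = np.linspace(0, len(seq) - 1, cap).round().astype(int)
    return [seq[i] for i in idx]


def build_training_set(
    subject: EcgRecord,
    library: FilterLibrary,
    duration_s: float = 300.0,
    half_window: Optional[int] = None,
    exclude: bool = True,
    max_synthetic_per_class: Optional[int] = None,
    max_real_normal: Optional[int] = None,
    common_normal_records: Optional[list] = None,
) -> TrainingSet:
    """Assemble the personalized training set for one subject.

    Real part: every N beat (both representations) from the first
    ``duration_s`` seconds of the record.  Synthetic part: the library —
    after removing the subject's own filters — applied to the subject's
    ANB; per abnormal class, single- and trio-mode synthetic beats are
    paired by zipping the two pools (cycling the shorter).  A class
    whose pool is empty in one mode uses the ANB itself for that channel
    (the degradation is all-pass in that representation).  Deterministic.

    Class-balance knobs, all off by default: ``max_synthetic_per_class``
    and ``max_real_normal`` thin their pools by even spacing;
    ``common_normal_records`` merges real N beats from donor records
    (representative common training data) into the real part.
    """
    lib = exclude_subject(library, subject.subject_id) if exclude else library
    anb = select_anb(subject, duration_s, half_window, require_trio=True)

    limit = int(duration_s * subject.fs)
    items = _thin(_real_normal_items(subject, limit, half_window),
                  max_real_normal)
    for donor in common_normal_records or []:
        items.extend(
            _real_normal_items(donor, int(duration_s * donor.fs), half_window)
        )
    n_real = len(items)

    n_by_class: dict[str, int] = {}
    for cls in ABNORMAL_CLASSES:
        singles = [synthesize_beat(anb, f) for f in lib.by_mode("single")
                   if f.source_class == cls]
        trios = [synthesize_beat(anb, f) for f in lib.by_mode("trio")
                 if f.source_class == cls]
        singles = _thin(singles, max_synthetic_per_class)
        trios = _thin(trios, max_synthetic_per_class)
        n_items = max(len(singles), len(trios))
        if n_items == 0:
            continue
        if not singles:
            singles = [_as_synthetic(anb.single, cls)]
        if not trios:
            trios = [_as_synthetic(anb.trio, cls)]
        for s, t in zip(islice(cycle(singles), n_items),
                        islice(cycle(trios), n_items)):
            items.append(TrainingItem(single=s, trio=t, label=cls))
        n_by_class[cls.name] = n_items

    ts = TrainingSet(
        items=items,
        subject_id=subject.subject_id,
        n_real_normal=n_real,
        n_synthetic_by_class=n_by_class,
        single_class=(len(n_by_class) == 0),
    )
    return ts


# -- serialization: paired CSVs, one row per item ---------------------------

def save_training_set(ts: TrainingSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "items.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["label", "is_synthetic"]
            + [f"s{i}" for i in range(128)]
            + [f"t{i}" for i in range(128)]
        )
        for it in ts.items:
            w.writerow(
                [it.label.name, int(it.single.is_synthetic)]
                + [repr(x) for x in it.single.samples.tolist()]
                + [repr(x) for x in it.trio.samples.tolist()]
            )
    meta = directory / "meta.csv"
    with open(meta, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "n_real_normal", "n_synthetic_by_class"])
        w.writerow([ts.subject_id, ts.n_real_normal,
                    ";".join(f"{k}={v}" for k, v in sorted(ts.n_synthetic_by_class.items()))])


def load_training_set(directory) -> TrainingSet:
    directory = Path(directory)
    with open(directory / "meta.csv", newline="") as fh:
        rows = list(csv.reader(fh))
    subject_id, n_real = rows[1][0], int(rows[1][1])
    n_by_class = {}
    if rows[1][2]:
        for part in rows[1][2].split(";"):
            k, v = part.split("=")
            n_by_class[k] = int(v)
    items = []
    with open(directory / "items.csv", newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for row in reader:
            label = AAMI[row[0]]
            synth = bool(int(row[1]))
            s = np.array([float(x) for x in row[2:130]])
            t = np.array([float(x) for x in row[130:258]])
            items.append(
                TrainingItem(
                    single=BeatVector(s, "single", label, subject_id,
                                      is_synthetic=synth),
                    trio=BeatVector(t, "trio", label, subject_id,
                                    is_synthetic=synth),
                    label=label,
                )
            )
    return TrainingSet(items=items, subject_id=subject_id, n_real_normal=n_real,
                       n_synthetic_by_class=n_by_class,
                       single_class=(len(n_by_class) == 0))
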