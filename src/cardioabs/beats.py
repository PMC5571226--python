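"""ECG beat segmentation and representation.

Beats are located by annotated R peaks (beat detection itself is out of
scope — annotations are an input).  Every beat is represented two ways,
each as a fixed 128-sample vector:

* **single** — a window centred on the R peak, resampled to 128 samples.
  Captures the morphology of the P–QRS–T complex.
* **trio** — the span covering the previous, current and next beat,
  resampled to 128 samples.  Because resampling is uniform over the whole
  span, the relative timing of the centre beat against its neighbours is
  preserved; a premature (ectopic) beat shows up as an off-centre peak.

The average normal beat (ANB) of a subject is the *real* N beat closest
to the pointwise mean of the N beats in the first five minutes of the
record; it is the sole input to abnormal-beat-synthesis filter design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

BEAT_LEN = 128
#: index of the R peak inside a single-beat vector
R_CENTER = BEAT_LEN // 2


class AAMI(IntEnum):
    """Five-class AAMI beat taxonomy.

    N: sinus-node origin; S: supraventricular ectopic; V: ventricular
    ectopic; Q: unclassifiable/paced; F: fusion of ventricular and normal.
    """

    N = 0
    S = 1
    V = 2
    Q = 3
    F = 4

    @classmethod
    def from_symbol(cls, sym: str) -> "AAMI":
        try:
            return cls[sym.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown AAMI label {sym!r}") from None


#: MIT-BIH annotation symbol -> AAMI class (AAMI EC57/ECAR grouping).
#: Symbols absent from this table map to Q (unclassifiable).
MITBIH_SYMBOL_TO_AAMI = {
    "N": AAMI.N, "L": AAMI.N, "R": AAMI.N, "e": AAMI.N, "j": AAMI.N, ".": AAMI.N,
    "A": AAMI.S, "a": AAMI.S, "J": AAMI.S, "S": AAMI.S,
    "V": AAMI.V, "E": AAMI.V,
    "F": AAMI.F,
    "/": AAMI.Q, "f": AAMI.Q, "Q": AAMI.Q, "?": AAMI.Q,
}


@dataclass(frozen=True)
class BeatAnnotation:
    """R-peak location (0-based sample index) plus AAMI class label."""

    r_sample: int
    label: AAMI

    def __post_init__(self):
        if self.r_sample < 0:
            raise ValueError(f"r_sample must be >= 0, got {self.r_sample}")


@dataclass
class EcgRecord:
    """A single-lead ECG signal (mV) with per-beat annotations."""

    subject_id: str
    signal: np.ndarray
    fs: float = 360.0
    annotations: list[BeatAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for a in self.annotations:
            if a.r_sample >= len(self.signal):
                raise ValueError(
                    f"annotation at sample {a.r_sample} beyond signal "
                    f"length {len(self.signal)}"
                )
        rs = [a.r_sample for a in self.annotations]
        if any(b <= a for a, b in zip(rs, rs[1:])):
            raise ValueError("annotations must be strictly increasing in r_sample")

    @property
    def duration_s(self) -> float:
        return len(self.signal) / self.fs

    @property
    def n_beats(self) -> int:
        return len(self.annotations)

    def labels(self) -> np.ndarray:
        return np.array([a.label for a in self.annotations], dtype=int)


@dataclass
class BeatVector:
    """A 128-sample beat representation (single-beat or beat-trio)."""

    samples: np.ndarray
    mode: str  # "single" | "trio"
    label: AAMI
    subject_id: str
    is_synthetic: bool = False
    beat_index: int = -1

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (BEAT_LEN,):
            raise ValueError(
                f"BeatVector must have exactly {BEAT_LEN} samples, "
                f"got shape {self.samples.shape}"
            )
        if self.mode not in ("single", "trio"):
            raise ValueError(f"mode must be 'single' or 'trio', got {self.mode!r}")


@dataclass
class AverageNormalBeat:
    """The real N beat closest to the mean of a subject's early N beats.

    ``trio`` is None only when the selected beat sits at a record boundary
    (no neighbouring beats); pipeline code requires the trio form.
    """

    single: BeatVector
    trio: Optional[BeatVector]
    source_beat_index: int


def default_half_window(fs: float) -> int:
    """Half window of the raw single-beat segment: 0.35 s per side.

    Covers the P–QRS–T complex at normal heart rates.
    """
    return int(round(0.35 * fs))


def resample_to_128(segment: Sequence[float], method: str = "linear") -> np.ndarray:
    """Uniformly resample a segment onto 128 points spanning it.

    ``linear`` (default): interpolation with endpoints preserved; a
    128-sample input is returned unchanged.  ``polyphase``: anti-aliased
    polyphase filtering via scipy (preferable for heavily oversampled
    segments, at the cost of edge transients).
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 1 or seg.size < 2:
        raise ValueError("segment must be a 1-D sequence of length >= 2")
    if seg.size == BEAT_LEN:
        return seg.copy()
    if method == "linear":
        x_new = np.linspace(0.0, seg.size - 1.0, BEAT_LEN)
        return np.interp(x_new, np.arange(seg.size), seg)
    if method == "polyphase":
        import scipy.signal

        g = np.gcd(BEAT_LEN, seg.size)
        return scipy.signal.resample_poly(seg, BEAT_LEN // g, seg.size // g)
    raise ValueError(f"unknown resampling method {method!r}")


def _extract_padded(signal: np.ndarray, start: int, stop: int, subject_id: str) -> np.ndarray:
    """signal[start:stop] with zero padding outside the record."""
    n = len(signal)
    if start >= 0 and stop <= n:
        return signal[start:stop].astype(float)
    warnings.warn(
        f"beat window [{start}, {stop}) crosses record boundary of "
        f"subject {subject_id}; zero-padding",
        stacklevel=3,
    )
    out = np.zeros(stop - start, dtype=float)
    lo, hi = max(start, 0), min(stop, n)
    out[lo - start:hi - start] = signal[lo:hi]
    return out


def _finalize(samples: np.ndarray, zscore: bool) -> np.ndarray:
    if not zscore:
        return samples
    sd = samples.std()
    return (samples - samples.mean()) / (sd if sd > 0 else 1.0)


def segment_single_beat(
    record: EcgRecord, beat_index: int, half_window: Optional[int] = None,
    zscore: bool = False,
) -> BeatVector:
    """Cut a symmetric window around the R peak and resample to 128 samples.

    The R peak lands at index 64 of the output.  Windows crossing the
    record boundary are zero-padded (with a warning) rather than dropped.
    ``zscore`` standardizes the beat (off by default: amplitudes carry
    class information).
    """
    if not 0 <= beat_index < record.n_beats:
        raise IndexError(f"beat_index {beat_index} out of range [0, {record.n_beats})")
    if half_window is None:
        half_window = default_half_window(record.fs)
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    ann = record.annotations[beat_index]
    raw = _extract_padded(
        record.signal, ann.r_sample - half_window, ann.r_sample + half_window,
        record.subject_id,
    )
    return BeatVector(
        samples=_finalize(resample_to_128(raw), zscore),
        mode="single",
        label=ann.label,
        subject_id=record.subject_id,
        beat_index=beat_index,
    )


def segment_trio(
    record: EcgRecord, beat_index: int, half_window: Optional[int] = None,
    zscore: bool = False,
) -> BeatVector:
    """Resample the span covering beats i−1, i, i+1 to 128 samples.

    The span runs from the previous beat's window start to the next
    beat's window end; the label is that of the *centre* beat.  First and
    last beats have no trio and raise IndexError (callers drop them).
    """
    if not 0 < beat_index < record.n_beats - 1:
        raise IndexError(
            f"beat_index {beat_index} has no trio (needs both neighbours in "
            f"record of {record.n_beats} beats)"
        )
    if half_window is None:
        half_window = default_half_window(record.fs)
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    prev_r = record.annotations[beat_index - 1].r_sample
    next_r = record.annotations[beat_index + 1].r_sample
    raw = _extract_padded(
        record.signal, prev_r - half_window, next_r + half_window, record.subject_id
    )
    return BeatVector(
        samples=_finalize(resample_to_128(raw), zscore),
        mode="trio",
        label=record.annotations[beat_index].label,
        subject_id=record.subject_id,
        beat_index=beat_index,
    )


def select_anb(
    record: EcgRecord,
    duration_s: float = 300.0,
    half_window: Optional[int] = None,
    require_trio: bool = False,
) -> AverageNormalBeat:
    """Select the average normal beat (ANB) of a subject.

    The pointwise mean of all single-beat N vectors within the first
    ``duration_s`` seconds is computed; the real N beat with the smallest
    Euclidean distance to that mean is returned (ties broken by earliest
    beat index).  With ``require_trio`` the candidates are restricted to
    beats that have both neighbours, so the trio form always exists.
    """
    limit = int(duration_s * record.fs)
    idx = [
        i
        for i, a in enumerate(record.annotations)
        if a.label == AAMI.N and a.r_sample < limit
    ]
    if require_trio:
        idx = [i for i in idx if 0 < i < record.n_beats - 1]
    if not idx:
        raise ValueError(
            f"no eligible N beats in the first {duration_s:g} s of "
            f"subject {record.subject_id}"
        )
    vecs = [segment_single_beat(record, i, half_window) for i in idx]
    mean = np.mean([v.samples for v in vecs], axis=0)
    dists = [float(np.linalg.norm(v.samples - mean)) for v in vecs]
    best = int(np.argmin(dists))  # argmin returns first minimum: earliest beat
    chosen = idx[best]
    trio = None
    if 0 < chosen < record.n_beats - 1:
        trio = segment_trio(record, chosen, half_window)
    return AverageNormalBeat(single=vecs[best], trio=trio, source_beat_index=chosen)


# ---------------------------------------------------------------------------
# CSV interchange.  Signal file: columns (sample_index, mV); annotation
# file: columns (sample_index, aami_label).  0-based sample indices.
# ---------------------------------------------------------------------------

def write_record_csv(record: EcgRecord, signal_path, ann_path) -> None:
    sig = pd.DataFrame(
        {"sample_index": np.arange(len(record.signal)), "mV": record.signal}
    )
    sig.to_csv(signal_path, index=False, float_format="%.17g")
    ann = pd.DataFrame(
        {
            "sample_index": [a.r_sample for a in record.annotations],
            "aami_label": [a.label.name for a in record.annotations],
        }
    )
    ann.to_csv(ann_path, index=False)


def read_record_csv(signal_path, ann_path, subject_id: Optional[str] = None,
                    fs: float = 360.0) -> EcgRecord:
    try:
        sig = pd.read_csv(signal_path)
        sig_vals = sig["mV"].to_numpy(dtype=float)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed signal CSV {signal_path}: {exc}") from exc
    try:
        ann_df = pd.read_csv(ann_path)
        annotations = [
            BeatAnnotation(int(r.sample_index), AAMI.from_symbol(str(r.aami_label)))
            for r in ann_df.itertuples()
        ]
    except (AttributeError, ValueError) as exc:
        raise ValueError(f"malformed annotation CSV {ann_path}: {exc}") from exc
    if subject_id is None:
        subject_id = Path(signal_path).stem
    return EcgRecord(subject_id=subject_id, signal=sig_vals, fs=fs,
                     annotations=annotations)


def read_record(path, format: str = "csv", **kwargs) -> EcgRecord:
    """Read an ECG record in ``csv`` or ``wfdb`` format.

    ``csv``: ``path`` is the signal CSV; the annotation CSV is looked for
    at ``<stem>.ann.csv`` unless ``ann_path`` is given.  ``wfdb``:
    ``path`` is the record name (without extension); WFDB annotation
    symbols are mapped to AAMI classes, unknown symbols to Q.
    """
    if format == "csv":
        path = Path(path)
        ann_path = kwargs.pop("ann_path", path.with_suffix("").with_suffix(".ann.csv"))
        return read_record_csv(path, ann_path, **kwargs)
    if format == "wfdb":
        from . import wfdb_io

        return wfdb_io.read_record(path, **kwargs)
    raise ValueError(f"unknown record format {format!r}")
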