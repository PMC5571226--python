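"""Abnormal-beat-synthesis (ABS) filter design and library curation.

Each normal-to-abnormal degradation is modelled as an M-tap FIR kernel
``h`` fitted by regularized least squares:

    h* = argmin_h ||b - A h||^2 + lambda ||h||^2

where ``A`` is the (128 x M) convolution matrix of the subject's average
normal beat (ANB) ``a`` and ``b`` is the target abnormal beat.  Applying
``h`` to another person's ANB synthesizes a *potential* abnormal beat of
that person.

The library is curated in three steps mirroring the two selection models
plus the variance criterion:

1. *all-pass rejection* — an abnormal beat nearly identical to the ANB
   would yield a do-nothing filter and is skipped;
2. *deduplication* — near-duplicate filters from a subject with many
   similar abnormal beats collapse to the best-fitting representative;
3. *distinctness* — optionally keep only the k filters with the highest
   coefficient variance (the most "active" degradations).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.linalg

from .beats import AAMI, BEAT_LEN, BeatVector


@dataclass
class FilterDesignConfig:
    """Filter length and ridge weight.

    The default M covers 3/4 of the beat vector: the kernel's reach
    (+-M/2 samples) must span the QRS-to-T-wave separation, otherwise a
    degradation that reshapes the T wave (e.g. the discordant T of a
    ventricular beat) is outside the model class.  M = 128 would make
    the fit exactly determined and overfit recording noise.
    """

    M: int = 96
    lam: float = 1e-3
    mode: str = "single"

    def __post_init__(self):
        if not 1 <= self.M <= BEAT_LEN:
            raise ValueError(f"M must be in [1, {BEAT_LEN}], got {self.M}")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class AbsFilter:
    """One FIR degradation kernel with provenance."""

    h: np.ndarray
    source_subject: str
    source_class: AAMI
    mode: str
    fit_residual: float  # RMSE of A h vs the target beat
    filter_id: str = ""
    ill_conditioned: bool = False

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        if self.source_class == AAMI.N:
            raise ValueError("ABS filters model degradations to abnormal classes")

    @property
    def M(self) -> int:
        return len(self.h)

    @property
    def coeff_variance(self) -> float:
        return float(np.var(self.h))


@dataclass
class CurationConfig:
    allpass_threshold: float = 0.15
    sim_threshold: float = 0.95
    k_distinct: Optional[int] = None  # None: keep all post-dedup filters


def convolution_matrix(a: np.ndarray, M: int) -> np.ndarray:
    """128 x M matrix A with A h = centred same-length convolution of a, h.

    ``(A h)[t] = sum_k h[k] a[t - k + M//2]`` with zero-padded borders;
    column k of A is ``a`` shifted by ``k - M//2``.
    """
    a = np.asarray(a, dtype=float)
    if M < 1:
        raise ValueError("M must be >= 1")
    n = len(a)
    A = np.zeros((n, M))
    c = M // 2
    for k in range(M):
        shift = k - c  # output index t draws from a[t - shift]
        if shift >= 0:
            A[shift:, k] = a[: n - shift] if shift else a
        else:
            A[: n + shift, k] = a[-shift:]
    return A


def apply_filter(a: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Centred same-length convolution (equals convolution_matrix(a, M) @ h)."""
    a = np.asarray(a, dtype=float)
    h = np.asarray(h, dtype=float)
    full = np.convolve(a, h, mode="full")
    c = len(h) // 2
    return full[c:c + len(a)]


def design_filter(
    anb: BeatVector, abnormal: BeatVector, cfg: FilterDesignConfig
) -> AbsFilter:
    """Fit the ridge-regularized FIR degradation kernel for one beat pair."""
    if anb.mode != abnormal.mode or anb.mode != cfg.mode:
        raise ValueError(
            f"mode mismatch: anb={anb.mode}, abnormal={abnormal.mode}, "
            f"cfg={cfg.mode}"
        )
    if abnormal.label == AAMI.N:
        raise ValueError("target beat must be abnormal (label != N)")
    A = convolution_matrix(anb.samples, cfg.M)
    b = abnormal.samples
    gram = A.T @ A + cfg.lam * np.eye(cfg.M)
    ill = False
    if cfg.lam == 0:
        # unregularized: fall back to the pseudoinverse if singular
        try:
            h = scipy.linalg.solve(gram, A.T @ b, assume_a="pos")
        except np.linalg.LinAlgError:
            h, *_ = np.linalg.lstsq(A, b, rcond=None)
            ill = True
        if not np.all(np.isfinite(h)):
            h, *_ = np.linalg.lstsq(A, b, rcond=None)
            ill = True
    else:
        h = scipy.linalg.solve(gram, A.T @ b, assume_a="pos")
    resid = float(np.sqrt(np.mean((A @ h - b) ** 2)))
    return AbsFilter(
        h=h,
        source_subject=abnormal.subject_id,
        source_class=abnormal.label,
        mode=cfg.mode,
        fit_residual=resid,
        filter_id=f"{abnormal.subject_id}:{abnormal.beat_index}:{cfg.mode}",
        ill_conditioned=ill,
    )


def is_all_pass(anb: BeatVector, abnormal: BeatVector, threshold: float = 0.15) -> bool:
    """True if the abnormal beat is nearly identical to the ANB.

    Similarity test on the beats themselves (independent of filter
    length): normalized distance ||b - a|| / ||a|| below ``threshold``.
    """
    if anb.mode != abnormal.mode:
        raise ValueError("mode mismatch")
    norm_a = float(np.linalg.norm(anb.samples))
    if norm_a == 0:
        raise ValueError("ANB has zero norm")
    return float(np.linalg.norm(abnormal.samples - anb.samples)) / norm_a < threshold


def _coef_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation, defined for degenerate (constant) vectors."""
    sx, sy = float(np.std(x)), float(np.std(y))
    if sx == 0 or sy == 0:
        return 1.0 if np.allclose(x, y) else 0.0
    return float(np.corrcoef(x, y)[0, 1])


def dedup_similar(filters: list[AbsFilter], sim_threshold: float = 0.95) -> list[AbsFilter]:
    """Collapse near-duplicate filters, keeping the best fit of each cluster.

    Greedy leader clustering on Pearson correlation of coefficient
    vectors, processed in (fit_residual, subject, id) order so the
    result is independent of input order: a filter joins the first kept
    cluster whose leader correlates above ``sim_threshold``, otherwise
    becomes a new leader.  Leaders have minimal residual in their cluster
    by construction.
    """
    modes = {f.mode for f in filters}
    lens = {f.M for f in filters}
    if len(modes) > 1 or len(lens) > 1:
        raise ValueError("dedup_similar requires filters of one mode and length")
    ordered = sorted(filters, key=lambda f: (f.fit_residual, f.source_subject, f.filter_id))
    kept: list[AbsFilter] = []
    for f in ordered:
        if all(_coef_corr(f.h, g.h) <= sim_threshold for g in kept):
            kept.append(f)
    return kept


def select_distinct(filters: list[AbsFilter], k: Optional[int] = None) -> list[AbsFilter]:
    """Keep the k filters with highest coefficient variance.

    Sorted by variance descending (ties by subject then id); ``k=None``
    returns all, sorted.
    """
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(
        filters, key=lambda f: (-f.coeff_variance, f.source_subject, f.filter_id)
    )
    return ordered if k is None else ordered[:k]


@dataclass
class FilterLibrary:
    """Curated ABS filter collection over both beat representations."""

    filters: list[AbsFilter]
    design_config: FilterDesignConfig
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def by_mode(self, mode: str) -> list[AbsFilter]:
        return [f for f in self.filters if f.mode == mode]

    def __len__(self) -> int:
        return len(self.filters)


def exclude_subject(library: FilterLibrary, subject_id: str) -> FilterLibrary:
    """Library view without the filters a subject's own beats produced.

    Leave-subject-out: the monitored person's real abnormal beats must
    not leak into their own synthetic training data.
    """
    kept = [f for f in library.filters if f.source_subject != subject_id]
    prov = {s: ids for s, ids in library.provenance.items() if s != subject_id}
    return FilterLibrary(filters=kept, design_config=library.design_config,
                         provenance=prov)


def build_library(
    records,
    cfg: Optional[FilterDesignConfig] = None,
    curation: Optional[CurationConfig] = None,
    half_window: Optional[int] = None,
    window_s: Optional[float] = None,
) -> FilterLibrary:
    """Design and curate the ABS filter library over a training cohort.

    Per record and per beat representation: select the ANB; design one
    filter per abnormal beat not rejected as all-pass; deduplicate within
    the subject; finally pool subjects and apply the distinctness
    selection per mode.  Fully deterministic.  ``window_s`` optionally
    restricts the abnormal beats used to the first so many seconds of
    each record (default: whole record).

    Returns the library together with per-subject provenance and stashes
    per-record curation attrition counts on ``library.attrition``.
    """
    from .beats import segment_single_beat, segment_trio, select_anb

    cfg = cfg or FilterDesignConfig()
    curation = curation or CurationConfig()
    pooled: dict[str, list[AbsFilter]] = {"single": [], "trio": []}
    provenance: dict[str, list[str]] = {}
    attrition: dict[str, dict[str, int]] = {}

    for record in records:
        anb = select_anb(record, half_window=half_window, require_trio=True)
        anb_by_mode = {"single": anb.single, "trio": anb.trio}
        limit = None if window_s is None else int(window_s * record.fs)
        counts = {"designed": 0, "all_pass_skipped": 0, "dedup_removed": 0}
        sub_filters: dict[str, list[AbsFilter]] = {"single": [], "trio": []}
        for i, ann in enumerate(record.annotations):
            if ann.label == AAMI.N:
                continue
            if limit is not None and ann.r_sample >= limit:
                continue
            if not 0 < i < record.n_beats - 1:
                continue  # no trio representation at the record boundary
            beats = {
                "single": segment_single_beat(record, i, half_window),
                "trio": segment_trio(record, i, half_window),
            }
            for mode in ("single", "trio"):
                if is_all_pass(anb_by_mode[mode], beats[mode],
                               curation.allpass_threshold):
                    counts["all_pass_skipped"] += 1
                    continue
                f = design_filter(anb_by_mode[mode], beats[mode],
                                  replace(cfg, mode=mode))
                sub_filters[mode].append(f)
                counts["designed"] += 1
        for mode in ("single", "trio"):
            kept = dedup_similar(sub_filters[mode], curation.sim_threshold)
            counts["dedup_removed"] += len(sub_filters[mode]) - len(kept)
            pooled[mode].extend(kept)
        if counts["designed"] or counts["all_pass_skipped"]:
            attrition[record.subject_id] = counts

    final: list[AbsFilter] = []
    for mode in ("single", "trio"):
        final.extend(select_distinct(pooled[mode], curation.k_distinct))
    for f in final:
        provenance.setdefault(f.source_subject, []).append(f.filter_id)
    lib = FilterLibrary(filters=final, design_config=cfg, provenance=provenance)
    lib.attrition = attrition
    return lib


# ---------------------------------------------------------------------------
# Serialization: JSON manifest + CSV coefficient matrix (filters x taps),
# floats written with repr so the round-trip is bit-exact.
# ---------------------------------------------------------------------------

def save_library(library: FilterLibrary, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "design_config": {
            "M": library.design_config.M,
            "lam": library.design_config.lam,
            "mode": library.design_config.mode,
        },
        "provenance": library.provenance,
        "filters": [
            {
                "filter_id": f.filter_id,
                "source_subject": f.source_subject,
                "source_class": f.source_class.name,
                "mode": f.mode,
                "fit_residual": f.fit_residual,
                "coeff_variance": f.coeff_variance,
                "ill_conditioned": f.ill_conditioned,
            }
            for f in library.filters
        ],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    with open(directory / "coefficients.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filter_id"] + [f"h{k}" for k in range(library.design_config.M)])
        for f in library.filters:
            writer.writerow([f.filter_id] + [repr(x) for x in f.h.tolist()])


def load_library(directory) -> FilterLibrary:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    coeffs: dict[str, np.ndarray] = {}
    with open(directory / "coefficients.csv", newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for row in reader:
            coeffs[row[0]] = np.array([float(x) for x in row[1:]])
    dc = manifest["design_config"]
    filters = [
        AbsFilter(
            h=coeffs[m["filter_id"]],
            source_subject=m["source_subject"],
            source_class=AAMI[m["source_class"]],
            mode=m["mode"],
            fit_residual=m["fit_residual"],
            filter_id=m["filter_id"],
            ill_conditioned=m.get("ill_conditioned", False),
        )
        for m in manifest["filters"]
    ]
    return FilterLibrary(
        filters=filters,
        design_config=FilterDesignConfig(M=dc["M"], lam=dc["lam"], mode=dc["mode"]),
        provenance=manifest["provenance"],
    )
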