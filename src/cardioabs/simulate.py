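"""Synthetic MIT-BIH-like ECG record generator.

Beat morphology is a sum of five Gaussian bumps (P, Q, R, S, T waves),
which is analytic, seedable and sufficient to produce the inter-class
contrasts the pipeline needs.  Each synthetic subject draws its own
morphology parameters once (inter-patient variation); every beat then
receives small per-beat jitter and additive Gaussian noise.

Class phenomenology follows the standard AAMI picture:

* **V** (ventricular ectopic): widened QRS (wave widths x >= 2), taller
  main deflection, suppressed P wave, discordant (inverted, enlarged)
  T wave, premature with a full compensatory pause.
* **S** (supraventricular ectopic): clearly premature (short preceding
  RR) with a compensatory pause — visible in the beat-trio
  representation — and an ectopic P' wave (inverted, shifted toward the
  QRS) while the QRS-T complex stays normal, so the single-beat
  representation is only subtly different from an N beat.
* **F** (fusion): convex blend of the subject's N and V shapes.
* **Q** (unclassifiable): randomized morphology, normal timing.

Premature beats conserve the two-beat span: the RR interval after the
ectopic beat is lengthened so that the sum of the two intervals equals
two normal intervals (classic compensatory pause), which keeps trio
spans comparable and the trio channel informative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .beats import AAMI, BeatAnnotation, EcgRecord

WAVES = ("P", "Q", "R", "S", "T")

#: canonical modified-lead-II morphology: amplitude (mV), centre relative
#: to the R peak (s), width sigma (s)
_BASE_AMPL = {"P": 0.15, "Q": -0.10, "R": 1.00, "S": -0.18, "T": 0.30}
_BASE_MU = {"P": -0.16, "Q": -0.026, "R": 0.0, "S": 0.026, "T": 0.22}
_BASE_SIGMA = {"P": 0.025, "Q": 0.010, "R": 0.012, "S": 0.010, "T": 0.055}


@dataclass
class MorphologyParams:
    """Per-subject beat morphology: one Gaussian bump per wave."""

    ampl: dict[str, float]
    mu: dict[str, float]
    sigma: dict[str, float]
    heart_rate_bpm: float = 70.0
    noise_sd: float = 0.02
    subject_jitter_sd: float = 0.04  # fractional per-beat jitter

    def __post_init__(self):
        if any(self.sigma[w] <= 0 for w in WAVES):
            raise ValueError("wave widths must be positive")

    @property
    def rr_s(self) -> float:
        return 60.0 / self.heart_rate_bpm

    def jittered(self, rng: np.random.Generator) -> "MorphologyParams":
        """Per-beat copy with fractional jitter on amplitudes and widths."""
        j = self.subject_jitter_sd
        return replace(
            self,
            ampl={w: a * (1 + j * rng.standard_normal()) for w, a in self.ampl.items()},
            sigma={w: s * max(1 + j * rng.standard_normal(), 0.3)
                   for w, s in self.sigma.items()},
            noise_sd=0.0,
        )


@dataclass
class ClassDegradation:
    """Morphology/timing transform turning an N beat into an abnormal one."""

    aami: AAMI
    qrs_width_factor: float = 1.0
    suppress_p: bool = False
    r_amp_factor: float = 1.0
    invert_r: bool = False
    p_amp_factor: float = 1.0   # ectopic P' morphology (negative: inverted)
    p_shift_s: float = 0.0      # P' displacement toward the QRS (s)
    t_amp_factor: float = 1.0   # discordant T when negative (PVC hallmark)
    blend_weight: float = 0.0  # convex weight of the V shape (fusion)
    rr_premature_factor: float = 1.0  # fraction of the normal RR interval

    def apply(self, p: MorphologyParams) -> MorphologyParams:
        ampl = dict(p.ampl)
        mu = dict(p.mu)
        sigma = dict(p.sigma)
        for w in ("Q", "R", "S"):
            sigma[w] *= self.qrs_width_factor
        if self.suppress_p:
            ampl["P"] = 0.0
        ampl["P"] *= self.p_amp_factor
        mu["P"] += self.p_shift_s
        ampl["R"] *= self.r_amp_factor * (-1 if self.invert_r else 1)
        # discordant T follows the main deflection's polarity flip
        ampl["T"] *= self.t_amp_factor * (-1 if self.invert_r else 1)
        return replace(p, ampl=ampl, mu=mu, sigma=sigma)


def default_degradations(
    rng: np.random.Generator, n_variants: int = 2
) -> dict[AAMI, list[ClassDegradation]]:
    """Draw per-subject class degradations with realistic variation.

    Each subject carries ``n_variants`` independent morphology families
    per abnormal class (real patients commonly show more than one
    ectopic focus, hence more than one abnormal-beat shape); each
    abnormal beat uses one family at random.
    """
    return {
        cls: [_draw_degradation(cls, rng) for _ in range(n_variants)]
        for cls in (AAMI.V, AAMI.S, AAMI.F, AAMI.Q)
    }


def _draw_degradation(cls: AAMI, rng: np.random.Generator) -> ClassDegradation:
    if cls == AAMI.V:
        return ClassDegradation(
            aami=AAMI.V,
            qrs_width_factor=float(rng.uniform(2.5, 3.5)),
            suppress_p=True,
            r_amp_factor=float(rng.uniform(1.2, 1.7)),
            invert_r=bool(rng.random() < 0.3),
            t_amp_factor=float(rng.uniform(-1.5, -0.8)),
            rr_premature_factor=float(rng.uniform(0.75, 0.85)),
        )
    if cls == AAMI.S:
        return ClassDegradation(
            aami=AAMI.S,
            p_amp_factor=float(rng.uniform(-0.9, -0.3)),
            p_shift_s=float(rng.uniform(0.02, 0.05)),
            rr_premature_factor=float(rng.uniform(0.60, 0.75)),
        )
    if cls == AAMI.F:
        return ClassDegradation(
            aami=AAMI.F,
            qrs_width_factor=float(rng.uniform(2.5, 3.5)),
            suppress_p=True,
            r_amp_factor=float(rng.uniform(1.2, 1.7)),
            invert_r=bool(rng.random() < 0.3),
            t_amp_factor=float(rng.uniform(-1.5, -0.8)),
            blend_weight=float(rng.uniform(0.4, 0.6)),
            rr_premature_factor=float(rng.uniform(0.85, 0.95)),
        )
    if cls == AAMI.Q:
        return ClassDegradation(
            aami=AAMI.Q,
            qrs_width_factor=float(rng.uniform(0.5, 4.0)),
            suppress_p=bool(rng.random() < 0.5),
            r_amp_factor=float(rng.uniform(0.3, 1.5)),
            invert_r=bool(rng.random() < 0.5),
        )
    raise ValueError(f"no degradation defined for class {cls!r}")


def draw_subject_morphology(rng: np.random.Generator) -> MorphologyParams:
    """Sample a subject's normal-beat morphology around the canonical shape."""
    ampl = {w: a * float(rng.uniform(0.75, 1.25)) for w, a in _BASE_AMPL.items()}
    mu = {w: m + float(rng.normal(0, 0.006)) if w != "R" else 0.0
          for w, m in _BASE_MU.items()}
    sigma = {w: s * float(rng.uniform(0.85, 1.15)) for w, s in _BASE_SIGMA.items()}
    return MorphologyParams(
        ampl=ampl, mu=mu, sigma=sigma,
        heart_rate_bpm=float(rng.uniform(60.0, 85.0)),
    )


def gen_beat_waveform(
    p: MorphologyParams,
    fs: float,
    rng: Optional[np.random.Generator] = None,
    t: Optional[np.ndarray] = None,
    window_s: float = 0.40,
) -> np.ndarray:
    """Evaluate the sum-of-Gaussians beat waveform.

    ``waveform(t) = sum_w a_w * exp(-(t - mu_w)^2 / (2 sigma_w^2)) + noise``
    with t relative to the R peak.  Deterministic given the rng state.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if t is None:
        t = np.arange(-window_s, window_s, 1.0 / fs)
    wave = np.zeros_like(t, dtype=float)
    for w in WAVES:
        wave += p.ampl[w] * np.exp(-((t - p.mu[w]) ** 2) / (2 * p.sigma[w] ** 2))
    if p.noise_sd > 0 and rng is not None:
        wave = wave + rng.normal(0.0, p.noise_sd, size=wave.shape)
    return wave


def _beat_shape(
    label: AAMI,
    base: MorphologyParams,
    deg: Optional[ClassDegradation],
    rng: np.random.Generator,
    t: np.ndarray,
) -> np.ndarray:
    """Noise-free per-beat waveform on grid ``t`` (per-beat jitter applied)."""
    jittered = base.jittered(rng)
    if label == AAMI.N or deg is None:
        return gen_beat_waveform(jittered, fs=1.0, t=t)
    if label == AAMI.F:
        v_shape = gen_beat_waveform(deg.apply(jittered), fs=1.0, t=t)
        n_shape = gen_beat_waveform(jittered, fs=1.0, t=t)
        w = deg.blend_weight
        return w * v_shape + (1 - w) * n_shape
    return gen_beat_waveform(deg.apply(jittered), fs=1.0, t=t)


def gen_record(
    subject_seed: int,
    n_beats: int,
    class_mix: dict[AAMI, float],
    fs: float = 360.0,
    subject_id: Optional[str] = None,
    normal_prefix_s: float = 0.0,
    morphology: Optional[MorphologyParams] = None,
) -> EcgRecord:
    """Generate a labelled single-lead record for one synthetic subject.

    Beats are laid on an RR grid (small Gaussian jitter around the
    subject's heart rate); premature classes shorten the preceding RR by
    their ``rr_premature_factor`` and receive a compensatory pause.
    Beats whose R peak falls within ``normal_prefix_s`` seconds of the
    start are forced to class N (the monitoring scenario: a clean
    personal-training prefix).  Deterministic per seed.
    """
    probs = np.array([class_mix.get(c, 0.0) for c in AAMI], dtype=float)
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix probabilities must be >= 0 and sum to 1")
    rng = np.random.default_rng(subject_seed)
    base = morphology or draw_subject_morphology(rng)
    degradations = default_degradations(rng)
    if subject_id is None:
        subject_id = f"syn{subject_seed}"

    if n_beats == 0:
        return EcgRecord(subject_id=subject_id, signal=np.zeros(int(fs)), fs=fs)

    drawn = [AAMI(i) for i in rng.choice(5, size=n_beats, p=probs)]

    rr0 = base.rr_s
    r_times = np.empty(n_beats)
    labels: list[AAMI] = []
    beat_degs: list[Optional[ClassDegradation]] = []
    pause = 0.0
    for i, lab in enumerate(drawn):
        rr_base = rr0 * (1 + 0.03 * rng.standard_normal())
        deg = None
        if lab != AAMI.N:
            variants = degradations[lab]
            deg = variants[int(rng.integers(len(variants)))]
        factor = deg.rr_premature_factor if deg is not None else 1.0
        t = (1.0 if i == 0 else r_times[i - 1]) + rr_base * factor + pause
        if i == 0:
            t = 1.0  # leave room before the first beat
        if t < normal_prefix_s and lab != AAMI.N:
            # clean personal-training prefix: force N, restore normal timing
            lab = AAMI.N
            deg = None
            factor = 1.0
            t = (1.0 if i == 0 else r_times[i - 1]) + rr_base + pause
            if i == 0:
                t = 1.0
        r_times[i] = t
        labels.append(lab)
        beat_degs.append(deg)
        # compensatory pause: conserve the 2-beat span after a premature beat
        pause = rr0 * (1.0 - factor)

    total_s = r_times[-1] + 1.0
    n_samples = int(np.ceil(total_s * fs))
    signal = np.zeros(n_samples)
    half = 0.45  # seconds of beat support on each side of R
    for i, lab in enumerate(labels):
        r_samp = int(round(r_times[i] * fs))
        lo = max(r_samp - int(half * fs), 0)
        hi = min(r_samp + int(half * fs), n_samples)
        t = (np.arange(lo, hi) - r_times[i] * fs) / fs
        signal[lo:hi] += _beat_shape(lab, base, beat_degs[i], rng, t)
    if base.noise_sd > 0:
        signal += rng.normal(0.0, base.noise_sd, size=n_samples)

    annotations = [
        BeatAnnotation(int(round(r_times[i] * fs)), labels[i])
        for i in range(n_beats)
    ]
    return EcgRecord(subject_id=subject_id, signal=signal, fs=fs,
                     annotations=annotations)


# -- cohort profiles ---------------------------------------------------------

#: training-partition profile: abnormal beats throughout the record
TRAIN_MIX = {AAMI.N: 0.84, AAMI.S: 0.05, AAMI.V: 0.07, AAMI.F: 0.04, AAMI.Q: 0.0}
#: test-partition profile: clean 5-minute prefix, then sparse abnormal beats
TEST_MIX = {AAMI.N: 0.86, AAMI.S: 0.05, AAMI.V: 0.06, AAMI.F: 0.03, AAMI.Q: 0.0}


def gen_cohort(
    n_train: int = 5,
    n_test: int = 3,
    master_seed: int = 0,
    n_beats_train: int = 420,
    n_beats_test: int = 680,
    train_mix: Optional[dict[AAMI, float]] = None,
    test_mix: Optional[dict[AAMI, float]] = None,
    fs: float = 360.0,
    normal_prefix_s: float = 300.0,
) -> tuple[list[EcgRecord], list[EcgRecord]]:
    """Generate a (training, test) cohort of distinct synthetic subjects.

    Training subjects carry abnormal beats throughout (they donate
    degradation filters); test subjects have an all-N first 5 minutes
    (the personal training prefix) followed by sparse abnormal beats
    (the monitoring scenario).  Subject seeds derive from ``master_seed``
    so the cohort is byte-reproducible.
    """
    train_mix = train_mix or TRAIN_MIX
    test_mix = test_mix or TEST_MIX
    train = [
        gen_record(
            subject_seed=master_seed * 1000 + i,
            n_beats=n_beats_train,
            class_mix=train_mix,
            fs=fs,
            subject_id=f"train{i:02d}",
        )
        for i in range(n_train)
    ]
    test = [
        gen_record(
            subject_seed=master_seed * 1000 + 500 + i,
            n_beats=n_beats_test,
            class_mix=test_mix,
            fs=fs,
            subject_id=f"test{i:02d}",
            normal_prefix_s=normal_prefix_s,
        )
        for i in range(n_test)
    ]
    return train, test
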