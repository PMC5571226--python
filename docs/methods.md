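# Methods

This note records the model, the parameter choices that matter, what
the synthetic-data generator does and does not emulate, and the design
decisions taken where the design was genuinely open. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Beat representations

Beats are located by annotated R peaks; beat detection is outside the
package's scope. Two fixed 128-sample representations feed every
downstream stage:

* **single-beat** — a symmetric window of ±0.35 s around the R peak
  (±126 samples at 360 Hz), linearly resampled to 128 points. 0.35 s
  per side covers the P–QRS–T complex at normal rates; the R peak lands
  at index 64. Windows crossing the record boundary are zero-padded
  with a warning rather than dropped, keeping beat counts stable.
* **beat-trio** — the span from the previous beat's window start to the
  next beat's window end, resampled to 128 points. Uniform resampling
  over the whole span preserves the relative timing of the centre beat,
  so prematurity (a supraventricular hallmark) is visible as an
  off-centre peak. First/last beats have no trio and are excluded from
  trio-based datasets.

Resampling is linear interpolation onto 128 uniform points (endpoints
preserved; a 128-sample input passes through unchanged). It is
deterministic and checkable against a brute-force interpolation oracle,
which the test suite does to 1e−9. No per-beat amplitude normalization
is applied; an optional z-score flag exists but is off by default.

The **average normal beat** (ANB) of a subject is the real N beat whose
single-beat vector is closest (Euclidean) to the pointwise mean of all
N beats in the first five minutes of the record; ties break to the
earliest beat. Pipeline callers restrict candidates to beats with both
neighbours so the trio form always exists.

## Degradation filters

Each normal→abnormal degradation is an M-tap FIR kernel fitted by ridge
regression: h\* = argmin‖b − A h‖² + λ‖h‖², with A the 128×M
convolution matrix of the ANB (same-length, centre-tap aligned,
zero-padded borders) and b the 128-sample abnormal beat. The solution
is the closed-form regularized normal equations; with λ = 0 a singular
system falls back to the pseudoinverse and is flagged.

**Filter length M = 96 (default).** The kernel's reach is ±M/2 samples.
A degradation that moves energy between the QRS and the T wave — the
discordant T of a ventricular beat is the canonical example — needs a
reach of roughly the QRS→T separation, ≈ 40–48 samples at the
128-sample beat scale, hence M ≈ 96. Shorter kernels (e.g. M = 32)
leave such degradations outside the model class: the self-fit residual
stays large and synthesized beats remain closer to the normal cluster
than to real abnormal beats. M = 128 makes the system exactly
determined and overfits recording noise (cross-subject transfer
degrades). λ defaults to 1e−3; synthesis quality is insensitive over
1e−3…1e−1, and the ridge term mainly stabilizes the solve.

**Curation.** Three rules, in order: (1) *all-pass rejection* — an
abnormal beat with ‖b − a‖/‖a‖ < 0.15 would yield a do-nothing kernel
and is skipped (the test operates on beats, not designed kernels: it is
cheaper and is what the rule means); (2) *deduplication* — greedy
leader clustering on Pearson correlation of coefficient vectors
(threshold 0.95), processed in (fit-residual, subject, id) order so the
result is order-independent and each cluster keeps its best-fitting
member; (3) *distinctness* — optionally keep the k kernels with the
highest coefficient variance (default: keep all).

Single-beat and trio kernels are designed and curated independently per
representation. When assembling a training set, per-class single/trio
synthetic beats are paired by zipping the two curated pools (cycling
the shorter); a class with an empty pool in one representation uses the
ANB itself for that channel, which is exactly the all-pass semantics
(the degradation is invisible in that representation).

Abnormal beats for filter design are taken from the whole donor record
by default (a window option exists). Leave-subject-out exclusion
removes a subject's own kernels before synthesizing their training set,
so no information from a person's real abnormal beats ever reaches
their own classifier.

Class balance is untouched by default (all real N beats, all surviving
synthetic beats). `build_training_set` offers optional, deterministic
thinning caps per synthetic class and for the real-N pool, and can
merge real N beats from donor records (representative common training
data); all off by default.

## The personal classifier

A two-channel 1D CNN: input 2×128 → conv(32 neurons, kernel 7, valid)
→ tanh → average-pool 3 → conv(16) → tanh → pool 3 → conv(16) → tanh →
global average pool → FC(32, tanh) → FC(5, tanh). The global average at
the last convolutional stage makes the fully-connected input
independent of the input length (the "adaptive" property of this CNN
family). Layer arithmetic (128→40→11→5→1) is asserted at construction.

Targets are +1 for the true class and −1 elsewhere; the loss is MSE.
Average pooling and tanh are the classical choices of this lineage;
average pooling is also everywhere differentiable, which keeps the
gradient check clean, and is the only pooling implemented.  Weights
initialize uniformly in [−0.1, 0.1] from a seeded generator.

**Training** is shallow: at most 50 iterations, early stop at 3 %
training classification error, ε₀ = 0.001 with the global adaptation
ε ← ε×1.05 after an iteration whose mean train MSE decreased, ×0.70
otherwise. One *iteration* sweeps the training set once in fixed order,
applying an update after every 32 items with the per-pattern error
summed over the five output units — classical incremental
back-propagation. A single whole-set update per iteration was tried
first and cannot reach the error floor within the 50-iteration budget
at ε₀ = 0.001; incremental updates routinely reach it in 30–50
iterations. The schedule, stopping rules and ε₀ are unchanged; the
recorded ε trace obeys the ×1.05/×0.70 rule against the MSE trace
exactly and is audited by the tests.

Two numerical choices: (a) each input channel is standardized with
mean/std fitted on the training set and stored in the model — with raw
millivolt inputs the 50-iteration budget is spent fitting the class
prior; (b) training arithmetic runs in float32 (twice the throughput on
one CPU; gradient-descent on a network this size does not benefit from
float64). `loss_and_gradients` itself is exact in the dtype of its
inputs, and the analytic gradients are verified against central
differences at 1e−5 relative tolerance in float64.

An ensemble is 10 runs with seeds s, s+1, …, s+9. Evaluation cumulates
the ensemble's confusion matrices (each beat counted once per member).

## Evaluation

The 5×5 confusion matrix (rows ground truth N,S,V,F,Q; columns
predicted) collapses to Normal-vs-Abnormal: tn = [N,N], fp = rest of
the N row, fn = rest of the N column, tp = remainder. Metrics:
Sen = tp/(tp+fn), Spe = tn/(tn+fp), Ppr = tp/(tp+fp),
Acc = (tp+tn)/total, FAR = fp/(tn+fp) = 100 − Spe (same division, so
the identity is exact). Undefined ratios (a subject with no abnormal
beats has no Sen) are reported as not-available, never as 0.

The advance-warning statistic assumes independence across consecutive
abnormal beats: p_miss1 = fn/(tp+fn), p_miss3 = p_miss1³,
p_detect_within3 = 1 − p_miss3. p_miss1 is computed from the *pooled*
2×2 matrix; the machine-readable report carries both the rounded and
the 3-decimal-truncated variant of p_miss1. Pooling across subjects
sums matrices first and divides once — never averages per-subject
percentages.

## Synthetic data generator

Each synthetic subject draws a morphology once (inter-patient
variation): five Gaussian bumps (P, Q, R, S, T) with subject-scaled
amplitudes/widths/centres, heart rate uniform in 60–85 bpm. Every beat
gets 4 % fractional jitter on amplitudes and widths plus 0.02 mV white
noise. Records lay beats on an RR grid with 3 % jitter; premature
classes shorten the preceding RR and receive a full compensatory pause
(the two-beat span is conserved), which keeps trio spans comparable and
the trio channel informative.

Class phenomenology (drawn per subject, two independent variants per
class — real patients commonly show more than one ectopic morphology):

* **V** — QRS widths ×2.5–3.5, P suppressed, main deflection ×1.2–1.7
  (inverted in 30 % of subjects), discordant T (×−0.8…−1.5, polarity
  tracking the QRS), preceding RR ×0.75–0.85.
* **S** — ectopic P′: amplitude ×−0.9…−0.3 (inverted), shifted
  0.02–0.05 s toward the QRS; QRS-T unchanged; preceding RR ×0.60–0.75.
* **F** — convex blend (weight 0.4–0.6) of the subject's N shape and a
  V-like shape; mildly premature.
* **Q** — randomized morphology, normal timing.

Cohorts: donor ("training") subjects carry abnormal beats throughout;
monitored ("test") subjects have an all-N first 5 minutes followed by
sparse abnormal beats. Default problem sizes are 5 donors × 420 beats
and 3 monitored subjects × 680 beats — large enough that each donor
contributes tens of kernels per class and each monitored subject has
well over 20 abnormal beats to detect, small enough that the full
leave-subject-out evaluation (library + 30 ensemble trainings +
monitoring) completes in a few minutes on one CPU.

**What the generator does not emulate**, and hence what passing tests
do not show about real data: baseline wander, electrode motion and
other noise artifacts; beat-to-beat morphology drift beyond i.i.d.
jitter; the long-tailed diversity of real ectopic morphologies;
annotation error. The sum-of-Gaussians beat is a caricature —
sufficient to express the class contrasts the method exploits, not a
physiologically validated simulation. Results on MIT-BIH-scale real
data will be worse than the synthetic-cohort numbers, as the published
benchmark figures (Sen ≈ 82.5 %) themselves indicate.

## Known limitations

* **Timing-only anomalies transfer poorly through LTI kernels.** A
  convolution cannot shift the centre beat of a trio without moving its
  neighbours, and trio peak spacing depends on the subject's heart
  rate, so trio-mode kernels fitted on one subject synthesize smeared
  timing patterns on another. Synthetic S beats are therefore carried
  mostly by the single-beat P′ morphology; the nearest-neighbour
  fidelity audit (synthetic beat closer to real same-class beats than
  to real N beats) holds for the morphology-dominant V class in the
  single-beat channel and is asserted there, not for trio-mode
  transfers.
* The miss-probability cube assumes independent per-beat detection;
  consecutive abnormal beats of one morphology are correlated, so
  p_miss3 is optimistic in that regime.
* The false-alarm rate varies across cohorts (N beats with high
  morphological or timing variation attract occasional alarms); single
  subjects can exceed the pooled rate severalfold.
* WFDB support is a deliberate subset: header + format-16 signal +
  standard beat-annotation codes, enough to round-trip the generator's
  records and read MIT-BIH-style single-channel data.
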