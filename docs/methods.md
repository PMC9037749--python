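# Methods

`weakbeat` trains a beat-by-beat ECG arrhythmia detector for the AAMI
classes N (normal and bundle-branch-block beats), S (supraventricular
ectopic beats, SVEB) and V (ventricular ectopic beats, VEB) using only
record-level label sets — the weak-supervision setting in which large
coarsely annotated ECG corpora can be exploited without per-beat
annotations.

## Model

The signal is conditioned by (1) subtracting a 1-second centered moving
average (baseline wander estimate; shrinking windows at the record edges
avoid phase shift), (2) a zero-phase 2nd-order Butterworth band-pass
0.1–30 Hz applied forward–backward (zero phase matters: the masked
aggregation below indexes predictions at R-peak sample positions),
(3) polyphase resampling to 125 Hz — skipped when the native rate is
within 3 Hz of the target, which generalizes the usual exemption for
128 Hz recordings — and (4) standardization to zero mean, unit variance.
Records entering batched training are zero-padded or truncated to 20 s;
padded samples carry no beats and are excluded from every aggregation by
a validity mask.

A 1-D residual network extracts morphology features: a channel-lifting
convolution, then residual blocks of Conv–BatchNorm–ReLU–Dropout–Conv–
BatchNorm with identity shortcut, ReLU and max-pool(2). The reference
configuration is 4 blocks × 32 kernels of length 8 with dropout 0.25 and
He initialization. Pooling uses floor lengths; the feature maps are
brought back to signal length by nearest-neighbour repetition (right
edge extended), keeping them piecewise constant like the knowledge maps.

Two knowledge-based channels are concatenated with the upsampled network
features before a time-distributed dense softmax head over {N, S, V}:

* **Relative RR interval** `I_R = s · (I_N − I_A) / I_N`, with `I_A` the
  RR interval ending at the beat's R peak, `I_N` the mean of a context
  window of up to 60 RR intervals centered on the current one (clamped
  at the record bounds, all intervals when fewer than 60 exist), and
  `s = 10`. Positive values mark premature beats — the sign convention
  deliberately feeds ReLU-friendly positive activations for the
  clinically salient direction. Each beat's value is painted over its
  region: the span between the midpoints of its flanking RR intervals.
  The first beat has no preceding interval and inherits the second
  beat's value, avoiding an artificial spike at the record start.
* **RR entropy**: sample entropy (`m = 1`, match threshold `r = 0.05`,
  Chebyshev distance) of the median-normalized RR series in sliding
  windows of 60 intervals, each window's value painted on its central
  (30th) heartbeat, remaining samples filled from the nearest painted
  neighbour. SampEn uses the standard template count (the first `n − m`
  start positions at both lengths), so constant series score exactly 0.
  When no template pairs match, the value is capped at
  `ln(#template pairs + 1)` to keep the map finite.

Record-level scores per class come from an aggregation mechanism over
the per-sample probabilities: GAP (mean), GMP (max),
LSE `(1/b)·log((1/n)·Σ exp(b·ŷ))` with default `b = 5`, and MGMP — the
max restricted to R-peak samples. MGMP is the default: it evaluates one
representative sample per beat, shrinks the hypothesis space of the
ill-posed weak problem, and guarantees that gradients vanish at every
non-R-peak sample. Note `|LSE_b − GMP| ≤ ln(n)/b` exactly (the `1/n`
term), so LSE approaches GMP only once `b ≫ ln n`.

## Training

The weak objective is the per-class binary cross-entropy between the
aggregated scores (clamped to `[1e−7, 1−1e−7]`; GMP-type aggregations
can emit exact 0/1) and indicators of the record label set, averaged
over the three classes and weighted per record: 4 when both S and V are
in the label set, 2 when exactly one is, 0.1 otherwise. Labels of
coarsely annotated records are first complemented: a record containing S
or V but neither supraventricular tachyarrhythmia nor idioventricular
rhythm almost surely also contains N beats, so N is added.

Optimization is Adam (β₁ = 0.9, β₂ = 0.999, learning rate 0.001 by
default) with early stopping on the mean beat-level F1 over {N, S, V} on
a finely annotated validation set (argmax of the local probabilities at
the R peaks), patience 10 epochs, best-epoch parameters restored.
Beat-level validation is the default because validation corpora are
beat-annotated; a record-level alternative is a config switch.

Supervised pre-training minimizes categorical cross-entropy at the
R peaks of a small finely annotated corpus for a fixed 10 epochs (no
early stopping), initializing the weak stage away from the degenerate
solutions that make pure weak training unstable. F and Q beats are kept
in the annotations (they shape RR features) but never contribute to
losses or metrics.

All randomness (initialization, shuffling, dropout) flows from explicit
integer seeds through `numpy.random.Generator`; identical seeds give
bit-identical runs.

The network and its gradients run on a small reverse-mode tape engine
over numpy (`weakbeat.autodiff`) implementing exactly the required ops;
convolutions are evaluated as K shifted BLAS matmuls. The engine
computes in float32 by default and can be switched to float64
(`autodiff.set_dtype`), which the finite-difference gradient tests use.

## Synthetic data

The generator (`weakbeat.synthetic_ecg`) emulates the statistical
structure the detector relies on, not a biophysical ECG. Beat templates
are sums of Gaussian bumps: N has P–QRS–T with a narrow (< 100 ms) QRS;
S shares the sinus QRS and T but lacks the P wave, so S and N overlap in
morphology and the RR context must carry the distinction, as it does
clinically; V has a wide (≥ 140 ms), high-amplitude QRS with discordant
T and no P. Rhythm grammars: sinus RR ~ 0.8 s ± 0.03 s jitter; SVEB
events shorten the preceding RR to U(0.55, 0.8)·base with a
non-compensatory (roughly normal) following cycle; VEB events shorten
likewise but are followed by a compensatory pause (flanking RRs sum to
two cycles); `af_like` draws i.i.d. U(0.6, 1.1)·base RRs with all-N
beats — the hard negative that punishes a pure "short RR ⇒ ectopic"
rule; atrial/ventricular bigeminy alternates sinus and ectopic beats.
Baseline wander (0.1 mV at 0.3 Hz) and white noise (0.03 mV) are added;
per-beat amplitude varies ±10%. Default ectopic-event probability when a
class is enabled is 0.12 per beat, giving the 2–4 ectopics per 20 s
record typical of low-burden ectopy.

What the generator does not emulate: real QRS morphology variation
across patients and leads, muscle/electrode artifacts, P-wave variants
(flutter waves, retrograde P), fusion beats, and rate-dependent
template changes. Passing the recovery benchmark therefore shows that
the weak-supervision machinery (masked aggregation, RR features,
pre-training) identifies beats whose separability is of the kind the
framework assumes — it does not certify clinical performance.

## Recovery benchmark

`weakbeat.benchmark` fixes the end-to-end experiment: corpora with
record mix 0.2 S-only / 0.2 V-only / 0.1 both / 0.5 neither; two-stage
training (10 pre-training epochs on 20 finely annotated records, then
weak training with MGMP). Corpus sizes and the optimization budget are
chosen for single-CPU runtimes: 320 training / 40 validation / 80 test
records, batch size 4, learning rate 0.005, a fixed budget of 40 weak
epochs with best-validation-epoch restore (no early stopping: the rare
S class learns in a late, non-monotonic phase that patience-based
stopping truncates). The raised learning rate and fixed budget stand in
for the reference protocol (0.001, patience 10), whose convergence on
this benchmark is several times slower at unchanged asymptotic accuracy;
a fully supervised model on the same corpora reaches S F1 ≈ 0.99,
confirming the benchmark is learnable and weak-training results are not
feature-limited. The stability comparison (repeated seeds with and
without pre-training) and the aggregation ablation run the same
conditions at reduced corpus/epoch scale so that a 10-seed × 2-setting
sweep stays tractable; the compared quantities (F1 dispersion, S-class
average precision) are computed identically in both arms of each
comparison.

## Evaluation

Per-beat decisions take the argmax of the local probabilities at the
R peak, exact ties resolving to N (the majority class — conservative
against false ectopy alarms). One-vs-rest counts give Sen, Spe, Ppr,
Acc and F1; 0/0 ratios are reported as 0 so early stopping never sees
NaN. The precision–recall curve thresholds at the distinct score values
in descending order and `AP = Σ_n (Sen_n − Sen_{n−1})·Ppr_n`; with no
positive beats AP is undefined (NaN). Stability across repeated
training runs is summarized as mean ± sample standard deviation. When
beats come from a detector instead of annotations, predicted peaks are
matched to reference beats within 150 ms.

## Known limitations

* The numpy engine is single-threaded and ~1–2 orders of magnitude
  slower than a GPU framework; the default backbone (4 × 32) is
  practical for inference and small corpora, while the recovery
  benchmark trains a 2-block × 16-kernel variant.
* The R-peak detector is a classical energy detector intended for
  synthetic or clean signals; annotated peaks should be preferred.
* WFDB support covers text headers, signal formats 16 and 212, and MIT
  annotation files — enough for the common arrhythmia databases, not
  the full format family.
* `af_like` rhythm approximates atrial fibrillation only through RR
  irregularity; it retains P waves, so real AF is harder than its
  synthetic stand-in.
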