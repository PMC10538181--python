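# Methods

## The transform

The delineator works on the continuous wavelet transform of the ECG at a
single integer scale. The mother wavelet is the first derivative of a cubic
B-spline expanded by a factor of two; because it is the derivative of a
smoothing kernel, every monophasic wave in the ECG maps to a pair of
opposite-polarity lobes in the transform, and the zero-crossing between the
lobes marks the wave's peak. At 1 kHz, scale m = 8 spans roughly 80 ms and
is a workable compromise that enhances both the QRS complex and the much
slower T wave, so a single filter chain serves both detectors.

The transform at scale m factors into three streaming stages:

1. **Spline prefilter** — a 5-tap symmetric FIR with weights
   (1, 26, 66, 26, 1)/120, the sampled quintic B-spline, implemented in
   transposed form (4 delay registers, one multiply-accumulate per tap per
   sample).
2. **Moving-sum cascade** — four cascaded running sums of width m, each
   updated recursively with two additions per sample,
   `r_i(k) = r_i(k-1) + r_{i-1}(k+m) - r_{i-1}(k)`. The `k+m` lookahead is
   realized with an m-deep input buffer per stage; a cascade of four
   width-m boxes is the discrete B-spline of degree 3 dilated by m.
3. **Upsampled wavelet FIR** — the 7 taps (−1, −4, −5, 0, 5, 4, 1) spread
   apart by m−1 zeros (length 6m+1), again in transposed form, so only
   seven of the 6m delay registers are tap-weighted.

The composed impulse response has length 10m+1, sums to zero and is
antisymmetric about its center at lag 5m. Two consequences follow
directly and are enforced by tests:

* **Streaming equals batch.** The per-sample pipeline output is exactly
  the causal convolution of the input with the composed kernel
  (tolerance 1e−9 over random signals at m ∈ {2, 4, 8, 16}).
* **The constant detection delay is 5m.** A causal linear-phase chain
  delays every feature by its phase center; at m = 8 and 1 kHz the
  measured offset between true and detected R peaks is exactly 40 samples,
  identical for every beat. The delay is compensated by subtraction when
  beat tables are reported; it cancels exactly in RR and RT intervals.

### Fixed-point mode

The reference design runs on divider-free integer hardware: prefilter
coefficients are pre-scaled by 2^16 and rounded to (543, 14201, 36044,
14201, 543), all arithmetic is integer, and the output is rescaled by one
division by 2^16. This package reproduces that arithmetic with unbounded
Python integers plus range checks standing in for the hardware register
widths: 40-bit signed for the prefilter accumulators (at coefficient
scale), 31-bit for the moving-sum registers and 28-bit for the FIR
registers (both at the post-rescale scale implied by each submodule's
24-bit output port). Exceeding a budget raises `FixedPointOverflowError`
rather than wrapping — surfacing overflow is strictly safer than emulating
it. A full-scale 24-bit constant input does overflow by design; a
physiologic ECG mapped through the documented unity-gain 24-bit ADC
convention (±2.4 V reference, so 1 mV ≈ 3495 counts) stays inside all
budgets, and fixed-mode output then deviates from float mode by about
3×10⁻⁵ of the dynamic range — well below the 2⁻¹⁰ design bound. The
deviation is dominated by the printed coefficient roundings themselves
(543 differs from the exact (1/120)·2^16 = 546.1 by 0.6 %).

## The detectors

One ten-stage machine per lead consumes the CWT stream sample by sample;
stages 1–5 find the QRS, stages 6–10 the T-wave end.

**QRS (stages 1–5).** Two threshold memories track 0.75× the most extreme
lobe values seen. Stage 1 waits for either memory to be exceeded; which
lobe arrives first sets the polarity flag, so inverted leads need no
separate logic (detections on −x occur at identical indices to x). Stage 2
follows the first lobe with the 0.75 rule and fires the R event at the
zero-crossing, capturing and resetting the RR counter and starting the RT
counter. Stages 3–4 do the same for the opposite lobe; stage 5 idles 40 ms
and hands over to the Te search. Both memories start at zero: the first
60 s (configurable) are a learning window whose events are flagged
unreliable. If a lobe search stalls more than 3 s — a noise spike inflated
the memories, or the electrode gel is drying — both memories are halved
once per further second until detection resumes.

**T end (stages 6–10).** The Te search opens after stage 5's 40 ms delay,
with a first-lobe search window of 140 ms when the preceding RR exceeded
700 ms and 100 ms otherwise (the 700 ms boundary takes the short window).
The fiducial is not the crossing between the T lobes (that is the T peak,
Tp, reported as well) but the *second* crossing, where the descending limb
flattens into the baseline. Stages 6–9 mirror the QRS structure with twin
memories; stage 10 halves any T memory that has outgrown its QRS
counterpart, which is what keeps the T thresholds from ever capturing QRS
lobes. Three behaviors the reference description leaves open are fixed
here as follows:

* the window bounds the first-lobe search only; the remaining stages are
  bounded by an overall RT search timeout (default 500 ms after R, far
  beyond any physiologic RT at the supported rates) — a beat whose search
  times out is recorded with a missing RT rather than aborting the stream;
* stage-10 rebalancing runs at every beat conclusion, timeouts included;
* the T memories get the same 3 s stall protection as the QRS memories.
  The latter two close the only gap by which a transient could push the T
  thresholds above T-lobe amplitude with no path back down, which would
  otherwise silence Te detection permanently.

The Te search is armed only once the learning window has passed. During
learning the QRS machine keeps the whole stream, which lets its thresholds
ratchet up to true QRS amplitude within a beat or two; arming the
zero-initialized Te machine from the first, unreliable R anchors instead
makes it consume QRS complexes as "T lobes" and can lock the coupled
machines into stable wrong-phase cycles on perfectly periodic records.

**Discrete conventions.** A zero-crossing is the first index k with
sign(w[k−1]) ≠ sign(w[k]) and w[k−1] ≠ 0; a sample that is exactly zero
counts as the crossing itself. Because the detectors' Te criterion relies
on decayed lobes genuinely reaching zero — which 24-bit integer hardware
guarantees but float arithmetic does not — the detection path flushes
magnitudes below 2⁻²⁴ of the running dynamic range (sub-LSB in the
reference design) to exact zero. The transform itself is never flushed, so
the streaming/batch oracle equivalence is unaffected.

## Beat metrics and storage encoding

Heart rate is 60000/RR with RR in ms; RR is taken between consecutive
compensated R indices (the first beat of a record has no RR). RT is the Te
machine's counter, which runs from the R crossing. For storage, RT rides
inside the heart-rate record: the stream holds the current HR at every
sample and a 0 at each R and Te index, so event positions and RT spacings
are recoverable offline from a single channel; the decoder also recovers
the first R marker as the last sample of the leading zero run. Across
simultaneously delineated leads, RT dispersion is max − min of the per-lead
RT values, ignoring leads with a missing RT.

## Synthetic records

The generator places per-beat waves on a global time axis: Gaussian bumps
for P (0.15 mV, σ 25 ms, −160 ms), Q (−0.1, σ 8, −40), R (1.0, σ 10, 0)
and S (−0.15, σ 8, +40) — textbook surface-ECG values — and a
raised-cosine T wave of amplitude 0.3×R and width parameter σ_T = 55 ms.
The T wave is compact-support deliberately: a real T wave ends, and the
end is the fiducial under test, so the generator's T returns to baseline
exactly at the declared truth Te = center + 2σ_T (a Gaussian never returns
to baseline and leaves Te undefined on noise-free data). Biphasic T is an
opposite-polarity lobe pair whose joint support ends at the same Te. The T
position adapts to rate by a Bazett-type rule RT = 340 ms · √(RR in s).
RR schedules may be fixed, ramped or jittered; optional additive noise,
sinusoidal baseline wander and a linear amplitude decay (electrode drying)
complete the signal model. All randomness flows through one seeded
generator; identical seeds give bit-identical records.

What the generator does *not* model: asymmetric T waves, ectopic beats,
muscle/mains artifact, respiration modulation, or pathological morphology
changes. Recovery results on it show that the state machines track this
signal class; they are not field validation, which requires expert-annotated
databases through the `evaluate` pathway.

## Problem sizes and measured behavior

Test and acceptance runs use records of 30–90 beats at RR 600–1200 ms with
a 10 s learning window (the constant is configurable; the 60 s default is
kept for field-like reliability flagging, but would leave nothing to score
on records of the sizes used here). On noise-free records, five of the six
polarity × T-morphology combinations recover 100 % of post-warm-up beats
with exact RR and a beat-constant Te offset (jitter ≤ 0.4 ms). The sixth —
positive QRS with a biphasic T — settles into a stable constant-offset
anchor on a T-lobe crossing, a trap reachable by the algorithm as
published: its threshold-learning is ratchet-like, and on a perfectly
periodic signal a phase-locked cycle can keep the big QRS lobes forever
inside the machine's blind intervals. RR intervals remain exact there, but
absolute R positions and Te are wrong; real recordings, whose variability
breaks such cycles, are the algorithm's intended regime.

## Known limitations

* Latency measurement requires fixed-RR records; under RR jitter the
  truth-index rounding makes the offset alternate between adjacent
  integers and the constancy assertion (deliberately) fails.
* The marker-stream encoding cannot represent two events on the same
  sample; the degenerate beat is stored with one zero and flagged invalid.
* The WFDB reader covers headers, signal formats 16 and 212 and basic
  annotation decoding — enough for QTDB-style evaluation — not the full
  format family.
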