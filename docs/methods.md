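# Methods

This note documents the models and procedures implemented in `pigsound`,
the parameters that matter, the numerical choices made where the underlying
method leaves room, and what the synthetic protocols do and do not show.

## Signal front end

**Activity gate.** A clip is processed only if its total energy
`E = Σ x(n)²` reaches 40 (default; `preprocess.energy_threshold`). The
threshold separates quiet-pen background (energy below ~40 for 1 s at
8 kHz on the [−1, 1] PCM scale) from vocalisations (energy above ~200).
Energy exactly at the threshold passes.

**Framing.** Hamming-windowed frames of 256 samples (32 ms at 8 kHz) with a
128-sample shift. The power-of-two length keeps the FFT exact and 50%
overlap makes weighted overlap-add resynthesis an identity for an
unmodified spectrum (verified to 1e-6 on interior samples). A trailing
partial frame is dropped; resynthesis pads it with silence so clip length
is preserved.

**Noise tracking (IMCRA-style).** The noise power per bin is recursively
averaged with a time-varying smoothing factor
`α̂(l,k) = α_d + (1−α_d) p(l,k)`, `α_d = 0.85`, so the update freezes
wherever sound is probably present. The presence probability `p` is
computed by a two-stage minima-tracking scheme: 3-bin frequency smoothing,
first-order time smoothing (factor 0.9), a causal running minimum over 40
frames as the local noise floor, a ratio test (threshold 5) giving a binary
presence flag, and asymmetric recursive smoothing of that flag —
instantaneous rise, slow (0.9) release. The asymmetric smoothing matters:
with a symmetric smoother the probability needs ~10 frames to saturate
after a burst onset, during which the recursion absorbs a large fraction of
the vocalisation's power into the noise estimate and the subtraction then
removes the vocalisation itself (measured: the full chain gains under 1 dB
instead of ~14 dB on a 0 dB mixture). Fast-engage/slow-release is the
standard hangover behaviour of speech-presence estimators. The recursion is
seeded with the mean power of the first five frames and bias-compensated by
ε = 1.47.

Convergence is measured on 200 frames of stationary noise as the per-bin
time average of the estimate over the final 100 frames (the recursion's
time constant is ≈ 7 frames, so this window is fully in steady state). A
single-frame read-out of an exponentially smoothed estimator has relative
standard deviation `√((1−α_d)/(1+α_d)) ≈ 0.28` and is not a meaningful
measure of the converged level; the tail average is.

**Spectral subtraction.** Over-subtraction factor α = 2.0 and floor
β = 0.01 (conventional values; configurable). The branch condition uses the
noisy power `|Y|²`. Noisy phase is reused at resynthesis.

**Endpoint detection.** The double-threshold state machine: the vocalisation
is the earliest run of ≥ 3 frames whose energy reaches 0.25× the maximum
frame energy, extended outward while energy stays above 0.05× the maximum
or the zero-crossing rate stays above 1.5× the mean ZCR of the first five
frames. All four constants are config keys. On synthetic bursts at
10–20 dB SNR the detector localises both endpoints within ±2 frames in
≥ 95 of 100 clips.

## Features

12 cepstral coefficients (n = 1..12; the 0th, which carries overall gain,
is excluded) from M = 24 triangular mel filters spanning 0–4000 Hz, via an
unnormalised DCT-II of the log filterbank energies. Filterbank energies are
clamped at 1e-10 before the log so silent frames stay finite. ΔMFCC is the
plain first-order frame difference (first frame zero); a ±2-frame
regression delta is available behind `features.delta_mode`. No liftering or
cepstral mean normalisation is applied; instead each SVDD z-scores its
training data (stored in the model, applied at decision time), because RBF
distances across raw cepstral dimensions are scale-incoherent.

## Confidence-weighted SVDD

Densities use the neighbouring radius `r_a = ½ min_j max_i ‖x_i − x_j‖`
(half the 1-centre radius of the set; the alternative max-min reading is
available as `density.radius_mode`). Confidences are computed on the
z-scored instances so the density metric matches the kernel metric. The
confidence function maps the density centre to 1 and an infinitely isolated
point to ½ — the suppression leverage is therefore at most a factor 2 on
the dual box, which shapes what the weighting can and cannot absorb (see
the robustness protocol below).

The dual — maximise `Σ α_i K_ii − α'Kα` subject to `Σ α_i = 1`,
`0 ≤ α_i ≤ C·w_i` — is solved by a deterministic most-violating-pair SMO:
select the feasible coordinate pair with the largest KKT gap, take the
exact analytic step clipped to the box, update the gradient, stop when the
gap falls below 1e-10 (200k-iteration safety cap). Ties in pair selection
resolve to the lowest index, so training is bit-reproducible. On 50-point
problems the solution agrees with an independent SLSQP solution of the same
QP to ~1e-7 in α and ~1e-9 in r².

The squared radius is the mean of `K(x_k,x_k) − 2Σ_i α_i K(x_i,x_k) + α'Kα`
over support vectors strictly inside their box (tolerance 1e-6·C); if none
are strictly interior, over all support vectors. Individual interior
radii agree to < 1e-6 and are asserted separately. The decision function
`sign(r² − K(z,z) + 2Σ α_i K(z,x_i) − α'Kα)` treats values within 1e-9 of
zero as inside: unbounded support vectors sit numerically on the boundary
and the tie-breaks-inside convention must survive rounding.

Feasibility requires `Σ C·w_i ≥ 1`; violating C raises an explicit error.
`sigma=None` selects the median-pairwise-distance heuristic on the z-scored
training set.

## Multi-sphere recognition

Frame decisions from the cough and scream spheres are fused by lookup
(+1/−1 → cough; −1/+1 → scream; −1/−1 → other; +1/+1 → unknown). In the
clip-level majority vote, "unknown" frames are excluded unless unanimous,
and ties resolve cough > scream > other > unknown — the system's purpose is
flagging sick animals, so ties favour reporting an abnormality. Metrics are
one-vs-rest accuracy/precision/recall in percent; 0/0 ratios are reported
as undefined (None), never NaN.

PSO defaults to swarm 60, 200 iterations (accelerations
1.5/2.0, inertia 1.0 — kept despite being undamped; a decay option exists
but defaults off) over C ∈ [0.01, 10], σ ∈ [0.1, 20], velocities clamped to
20% of each range. Fitness is the negative mean 10-fold cross-validated
own-class acceptance; folds are deterministic and can be grouped so frames
of one clip never straddle folds. Tests and examples run reduced swarms on
toy data; the full budget is a dataset-scale setting.

## Synthetic data: what it emulates, and what it does not

`gen_clip` produces 1 s, 8 kHz clips: a band-limited noise burst (4th-order
Butterworth band, linear attack/decay envelope, random placement) over
stationary background (white, pink, or harmonic fan hum) scaled to a target
SNR. Class presets: cough-like 300–800 Hz centres with fast attack;
scream-like 1500–3500 Hz, longer sustain; distractors are either near-flat
broadband or tonal/harmonic events. Burst RMS 0.3 puts clip energy above
200 (matching field vocalisation levels); burst-free ambient clips at RMS
0.05 stay under the energy gate. These clips reproduce the premises the
method relies on — spectrally discriminable classes, stationary additive
noise, bounded burst support — and nothing else: no formant structure, no
overlapping calls, no reverberation, no animal-to-animal variability.
Passing tests show the machinery is correct under those premises, not that
field accuracy would match.

`gen_feature_set` produces Gaussian class clouds in 24-D whose
per-dimension standard deviations decay geometrically (factor 0.7 per two
dimensions), emulating the energy concentration of cepstral features in the
leading coefficients; class means sit a configurable distance apart along
random orthogonal directions, with per-class spread multipliers.

## The tag-error robustness protocol

Conditions: target class of 200 training vectors (compact cloud, spread 1);
the mislabeled entries and the "other" test pool are drawn from a broad
cloud 2.5× as spread out at mean distance 6 — deliberately heterogeneous,
as a pen's non-target sounds (voices, machinery, other pig noises) are.
Test set: 100 held-out target + 200 other, 20 replicates; C = 0.08,
σ = 1.25× the median heuristic recomputed on each (contaminated) training
set. Contaminated points must demand more dual weight than their
confidence-scaled box allows for the weighting to bite; since confidences
are bounded below by ½, the suppression window spans roughly a factor 2 in
per-point demand. A broad contaminant cloud keeps per-point demand high
across the whole 5–20% range, which is why heterogeneity is part of the
protocol rather than a nuisance. The observed pattern: both variants
degrade as contamination grows; the weighted sphere's advantage appears at
5%, grows to ~8 accuracy points by 10%, and stays above its 5% onset value
through 20%. The advantage peaks mid-range and eases slightly at the
heaviest contamination — as contaminants multiply, each needs less dual
weight and partially re-enters its shrunken box — which is intrinsic to
box-based suppression.

## End-to-end benchmark

100 cough-like + 100 scream-like training clips, 50/50/50 test clips
(distractors alternate broadband and tonal), SNR 15 dB. Spheres use
C = 0.02 and σ = 0.35× the median heuristic: the median pairwise distance
reflects the class's own diversity, and a one-class boundary must be
tighter than that to reject distractor spectra it never saw; the 0.35
fraction was fixed as part of the benchmark protocol. Clip accuracy is
90–96% across seeds (93.7% mean over ten seeds), with errors almost
entirely broadband distractors voted as scream.

## Known limitations

- The confidence floor of ½ bounds the weighting's leverage; gross
  contamination (> ~25%) overwhelms it.
- IMCRA here is a documented simplification (binary presence flag with
  hangover) rather than the full likelihood-ratio estimator; it is
  validated by its convergence and end-to-end gain properties, not by
  matching a reference implementation bit for bit.
- Single-channel, single-call processing only: mixtures of overlapping
  calls, non-stationary noise, and resampling are out of scope.
- All accuracy figures in this repository are computed on synthetic data;
  they characterise the implementation, not field performance.
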