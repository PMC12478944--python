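# pigsound

Automatic recognition of porcine abnormal sounds — coughs (early sign of
respiratory disease) and screams (acute stress) — from short mono recordings
made in a pig pen. The package is aimed at precision-livestock-farming work
where continuously collected audio must be screened for signs of sick or
hurt animals, and where hand-labelled training data inevitably contains
tagging mistakes.

The pipeline has three stages:

1. **Preprocessing.** An absolute energy gate (`Σ x(n)² ≥ 40` for a 1 s clip
   at 8 kHz) discards quiet background. Surviving clips are denoised by
   spectral subtraction whose noise spectrum is tracked per frequency bin by
   minima-controlled recursive averaging (IMCRA):
   `λ̄(l+1,k) = α̂(l,k) λ̄(l,k) + (1−α̂(l,k)) |Y(l,k)|²` with
   `α̂ = α_d + (1−α_d) p(l,k)` and bias compensation `λ̂ = 1.47 λ̄`, where
   `p(l,k)` is a sound-presence probability from two-stage minima tracking.
   Over-subtraction with a spectral floor
   (`|X̂|² = |Y|² − α λ̂` if `|Y|² ≥ α λ̂`, else `β λ̂`) suppresses musical
   noise. A double-threshold detector on short-time energy and zero-crossing
   rate locates the vocalisation's endpoints.
2. **Features.** Per frame (Hamming window, 256 samples, 50% overlap):
   12 mel-frequency cepstral coefficients
   (`mfcc(i,n) = Σ_m C(i,m) cos(πn(2m+1)/2M)`, coefficients n = 1..12 over
   M = 24 triangular mel filters) plus their first-order differences —
   a 24-dimensional vector per frame.
3. **Recognition.** One confidence-weighted Support Vector Data Description
   (SVDD) hypersphere per abnormal class. Subtractive-clustering densities
   `P_i = Σ_j exp(−‖x_i−x_j‖²/(r_a/2)²)` give per-sample confidences
   `w_i = 1/(1 + ((P_max−P_i)/P_max)²) ∈ (½, 1]` that scale the slack
   penalty, so the dual box constraint becomes `0 ≤ α_i ≤ C·w_i`: isolated
   (likely mislabeled) points cannot inflate the sphere. A frame inside
   exactly one sphere names its class; inside neither is "other"; clip
   labels come from majority voting over frames. Hyperparameters (C, σ) can
   be tuned by particle-swarm optimisation of the negative 10-fold
   cross-validated acceptance.

Because no public pig-sound corpus exists, the package ships a synthetic
generator (`pigsound.synthetic`) that reproduces the statistical premises of
the method — band-limited bursts with class-distinct spectral envelopes,
stationary pen noise, and seeded tag-error injection — so every stage is
testable end to end.

## Worked example

```bash
python examples/04_label_noise_robustness.py
```

```
tag errors   weighted   classical   gap
      0%     96.15%      96.18%   -0.03
      5%     96.77%      95.57%   +1.20
     10%     92.02%      83.82%   +8.20
     15%     81.87%      75.40%   +6.47
     20%     72.83%      66.33%   +6.50
```

Each row trains a sphere on 200 target-class feature vectors in which the
stated fraction of entries is actually mislabeled "other" sounds, then
scores 100 held-out target and 200 other-pool vectors (20 replicates,
mean accuracy). Both variants lose accuracy as tagging errors grow, but the
confidence weighting slows the decay: at 10% contamination the weighted
sphere is 8 points better than classical SVDD.

The other examples cover denoising (`01`, prints the ~14 dB SNR gain on a
0 dB mixture), feature extraction (`02`), training and recognising clips
end to end (`03`), and PSO tuning (`05`).

There is also a CLI for shell use:

```bash
pigsound synth --class cough_like -n 50 -o data/cough --seed 7
pigsound synth --class scream_like -n 50 -o data/scream --seed 8
pigsound train --cough data/cough --scream data/scream -o model.json
pigsound recognize model.json data/cough/cough_like_7_0001.wav
```

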