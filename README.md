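# songlat

Latent population dynamics of songbird vocal-motor nuclei: neural-manifold
inference from simultaneously recorded spike trains, manifold statistics,
prediction of probabilistic vocal transitions, and continuous song
synthesis from either spikes or latent trajectories.

## The problem

During singing, zebra finches produce stereotyped motifs — sequences of
3–10 short syllables — driven by the premotor nucleus HVC and the motor
nucleus RA. Modern probes record dozens to hundreds of neurons in these
nuclei at once, and the question shifts from single-neuron tuning to
population structure: is the collective activity confined to a
low-dimensional *neural manifold*, how variable are single-trial
trajectories on it, do latent states predict upcoming syllable choices at
probabilistic "branch points", and can continuous vocal output be
synthesized from latent trajectories as well as from raw spike trains —
including when the recorded population turns over?

`songlat` implements this analysis pipeline end to end, together with a
synthetic-session generator whose full ground truth (grammar, latents,
loadings, audio rules) makes every stage testable by recovery.

## The model

Spike counts are binned, square-root transformed, and modelled by
Gaussian-process factor analysis (GPFA). For `q` clusters and a
`p`-dimensional manifold,

    y_t | x_t ~ N(C x_t + d, R),        R diagonal,
    cov(x_j(t1), x_j(t2)) = (1 − σ_n²) exp(−(t1−t2)² / 2τ_j²) + σ_n² δ,

fit by EM (closed-form `C, d, R`; timescales `τ_j` by bounded numerical
maximization; the data log-likelihood is non-decreasing across
iterations). Latents are orthonormalized through the SVD `C = UΣVᵀ`
(`x̃ = ΣVᵀx`), ordering dimensions by explained covariance. On top of the
model sit:

- **latent dispersion** `σ_n = (1/T) Σ_t ‖x_{n,t} − μ_t‖ / ‖μ_t − μ̄‖`,
  the normalized spread of single-trial trajectories around the
  trial-mean trajectory, compared across populations by bootstrap refits
  plus ANOVA / Tukey HSD;
- **shared vs private variance**, `tr(CCᵀ)` against `tr(R)`;
- **syllable-state distances**: same-syllable vs dissimilar-syllable
  distance distributions at syllable onsets, z-scored against the
  same-syllable reference, with Welch (within-manifold) and paired
  Wilcoxon (between-manifold) tests;
- **branch-point decoding**: per-time-bin Fisher LDA with uniform priors
  `1/C`, bootstrapped 80/20 splits, mean correct-class posterior with 95%
  CIs;
- **continuous decoding**: a feed-forward network (`N × 3` history bins →
  64 → 64 → 128, ELU, AdamW, dropout, jitter/noise augmentation) from
  smoothed spike trains or latents at 150 Hz onto frame embeddings of an
  invertible toy codec, evaluated by normalized-spectrogram MSE against
  temporal-shuffle controls;
- **turnover stability**: decoders trained on one half of a population
  and tested on the CCA-aligned other half.

## Worked example

```python
import numpy as np
from songlat import (GPFA, simulate_session, bin_spikes, segment_trials,
                     sqrt_transform, variance_explained, latent_dispersion,
                     syllable_onset_states, distance_analysis)

session, annotations, audio, truth = simulate_session(seed=42, n_bouts=12)
counts = bin_spikes(session, bin_width_s=0.001)
trials = segment_trials(counts, session, annotations,
                        ("S1", "S2", "S3", "S4", "S5"), rebin_width_s=0.015)
print(f"{trials.n_trials} motif renditions, {trials.n_clusters} clusters, "
      f"{trials.n_bins} bins of 15 ms")

for region in ("HVC", "RA"):
    ids = [c.cluster_id for c in session.clusters if c.region == region]
    sub = sqrt_transform(trials.subset_clusters(ids))
    model = GPFA(n_factors=12, max_iter=40, tol=1e-6).fit(sub)
    latents = model.transform(sub)
    disp = latent_dispersion(latents)
    ve = variance_explained(model)
    print(f"{region}: dispersion {disp.mean:.3f} +/- {disp.sd:.3f}, "
          f"shared variance {ve['shared_fraction']:.2f}")
```

prints

```
19 motif renditions, 170 clusters, 25 bins of 15 ms
HVC: dispersion 0.573 +/- 0.113, shared variance 0.70
RA: dispersion 0.255 +/- 0.022, shared variance 0.68
```

The HVC-like population (high trial-to-trial latent variability, half
sparse-firing units) shows more than twice the latent dispersion of the
RA-like population — single-trial trajectories wander further from the
mean trajectory, relative to the manifold's extent. Adding the
syllable-state analysis on the RA manifold:

```python
states, labels, rends = syllable_onset_states(
    latents, trials.trial_t0_s, annotations, {"S1", "S2", "S3", "S4", "S5"})
dd = distance_analysis(states, labels, rends)
print(f"RA syllable separability: mean Z_DSD {dd.z_dsd.mean():.2f}, "
      f"Welch p = {dd.welch_p:.2e}")
# RA syllable separability: mean Z_DSD 3.42, Welch p = 0.00e+00
```

states at the onsets of different syllables sit several same-syllable
standard deviations apart on the manifold: nearby manifold regions
correspond to similar vocal output.

A `songlat` command-line tool mirrors the pipeline stages
(`simulate`, `preprocess`, `fit-gpfa`, `metrics`, `branch`,
`train-decoder`, `decode`, `stability`), each taking
`--config <yaml> --seed <int> --out <dir>` and writing a run manifest
with seeds and checksums.

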