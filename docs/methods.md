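# Methods

This note documents the models and procedures implemented in `songlat`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real recordings.

## Data model and conventions

Times are seconds (float64) from session start; intervals are half-open
`[onset, offset)`; a spike or syllable onset exactly on a bin edge belongs
to the later bin. Tabular data (spike times, cluster metadata, annotation
intervals) are plain CSV; arrays (trial tensors, latents, model parameters)
are HDF5. Audio is mono WAV. Every randomized stage draws from an
explicitly seeded `numpy` generator recorded in a JSON run manifest
together with input/output checksums, so any stage is reproducible
bit-for-bit from (config, seed).

## Preprocessing

Spikes are binned at 1 ms. Cross-channel motion artifacts are detected on
the summed-across-clusters count series: bins exceeding the mean by more
than 5 standard deviations are zeroed in **all** clusters. Zeroing rather
than excision keeps trial time axes uniform (the choice is ours; flagged
bins are reported so rate statistics can exclude them). The operation is
idempotent in practice because removed mass no longer drives the
threshold.

HVC single units are labelled putative projection neurons (HVCpn) when
their mean rate over annotated song periods is below 5 Hz **and** they
produce at least one within-song burst at ≥ 100 Hz instantaneous rate.
The burst detector — a run of ≥ 2 spikes with consecutive inter-spike
intervals ≤ 10 ms — is our choice; only the rate threshold is given by the
phenotype definition. Everything else is HVCint. Two named subpopulation
criteria are built in: `hs-SUA` (single units with song-period rate
> 10 Hz, which excludes nearly all sparse-firing HVCpn) and
`all-clusters`.

Motif renditions are cut at the first syllable's onset and rebinned by
summation to the analysis width (15 ms for manifold analyses, 5 ms for
decoding). Unequal rendition durations are handled by cropping every trial
to the shortest rendition's bin count — no time warping — and the cropping
is logged.

## Gaussian-process factor analysis

Square-root-transformed counts `y_t ∈ R^q` relate to latents
`x_t ∈ R^p` by `y_t | x_t ~ N(C x_t + d, R)` with `R` diagonal; each
latent dimension carries an independent unit-variance GP prior over time
with squared-exponential kernel
`K_j(t1,t2) = (1−σ_n²) exp(−Δt²/2τ_j²) + σ_n² δ`. Parameters are fit by
EM: closed-form joint updates for `(C, d)` and the diagonal of `R`;
timescales by bounded scalar maximization of the expected complete-data
objective per dimension, accepted only when the objective improves, which
keeps the data log-likelihood non-decreasing to the EM tolerance. The
E-step exploits the Kronecker structure of the joint posterior precision
`(K̄⁻¹ + I_T ⊗ CᵀR⁻¹C)`; one Cholesky factorization per unique trial
length serves all trials of that length, which is what makes 10-fit
bootstrap loops affordable. The marginal likelihood is evaluated through
the same factorization (matrix-determinant lemma), and in the white-noise
limit (τ → 0) it reduces exactly to factor analysis — a unit test checks
agreement with the closed-form Gaussian likelihood to 1e-6 relative.

Defaults: initialization from factor analysis on pooled bins (LAPACK SVD
for determinism), τ₀ = 100 ms, GP noise floor σ_n² = 1e-3 (fixed),
convergence at 1e-8 relative log-likelihood change, ≤ 500 iterations. The
stopping rule, τ initialization and noise floor are conventional choices,
all configurable. Bootstrap refits use a reduced budget (25–40 iterations,
1e-6 tolerance, timescale updates every other iteration); parameter
estimates are already stable at that depth while full-precision fits are
reserved for single-model analyses.

Orthonormalization uses the SVD `C = UΣVᵀ`: latents map to `x̃ = ΣVᵀx`,
ordered by singular value; each basis column's sign is fixed so its
largest-magnitude loading is positive (platform determinism). Variance is
decomposed as shared `tr(CCᵀ)` versus private `tr(R)`; the two fractions
sum to one exactly by construction.

## Manifold metrics

**Latent dispersion.** For trials of equal length, with `μ_t` the
trial-average state and `μ̄` its time average, a trial's dispersion is the
time average of per-bin normalized deviations
`σ_n = (1/T) Σ_t ‖x_{n,t} − μ_t‖ / ‖μ_t − μ̄‖`. The typographic grouping
of this ratio is ambiguous in the field; we default to the per-bin ratio
averaged over bins (consistent with "mean deviation over time steps") and
expose the un-averaged sum and the ratio-of-sums variants behind a flag.
Bins whose denominator is below 1e-9 of the manifold scale are excluded
and counted. The statistic is invariant under rigid isometries and global
rescaling of the latent space (property-tested).

**Bootstrap population contrast.** For each named cluster population, 10
random 90% cluster subsamples are refit at p = 12 and summarized by mean
dispersion and shared-variance fraction; populations are compared by
one-way ANOVA followed by Tukey's HSD on each metric. The negative control
("identical settings") is implemented as two populations drawing from the
same cluster pool, so bootstrap subsampling is the only source of
variation: with only 10 correlated samples per group the test cannot
absorb a fixed cluster-identity offset, and even exchangeable disjoint
halves of one region produce spurious significance; overlapping
subpopulations of one recording (hs-SUA versus all-clusters) are precisely
the comparisons that are expected to be null.

**Syllable-distance analysis.** Latent states are read at the bin
containing each syllable onset. Same-syllable pairwise distances (SSD)
form the reference; SSD and dissimilar-syllable distances (DSD) are
z-scored against it (`mean(Z_SSD) = 0`, `sd(Z_SSD) = 1` by construction);
Welch's t-test compares Z_DSD with Z_SSD within a manifold. Between two
manifolds computed on the same behavior, each DSD entry carries a pairing
key (syllable pair + rendition pair) and a Wilcoxon signed-rank test is
applied to the paired differences; unmatched pairs are an error, never
silently dropped. Distance analyses run on orthonormalized latents at the
same dimensionality as the dispersion analysis (12 unless configured) —
the dimensionality for this analysis is not externally constrained, so we
reuse the bootstrap one.

## Branch-point transition decoding

Syllables with ≥ 2 successors each observed at least twice are branch
points ('silence' is a successor when no interval starts within 150 ms).
Latent segments aligned to the end of the branch syllable are labelled by
the following transition. At each time bin an LDA with shared,
Ledoit-Wolf-shrunk covariance and uniform priors `1/C` yields the
correct-class posterior for held-out renditions; per bootstrap run a
random 80/20 split is drawn under the constraint that every class keeps a
training example (a strict leave-one-out mode is available behind
`mode='loo'`; the hybrid phrasing of the published procedure is internally
tensioned, and the constrained random split is our resolution). Means and
2.5/97.5-percentile CIs are aggregated across runs. The permutation null
re-shuffles labels independently in every run — a single fixed shuffle
would bake chance-level class structure into all runs and bias the null
away from `1/C`. The instantaneous latent state (no history window) feeds
each per-bin classifier.

## Song decoding

A pluggable codec maps waveforms to 128-dimensional frame embeddings at
150 frames/s. The provided toy codec is exactly invertible: 128-sample
frames at 19,200 Hz (so one frame is exactly 1/150 s) through a fixed
seeded orthonormal transform. An adapter class for a pre-trained
residual-vector-quantization codec exposes the same interface but is
optional and untested here.

Neural features are either (a) 1 ms spike counts smoothed with a
normalized Gaussian kernel of σ = 30 samples (30 ms — the unit of the
smoothing width is a convention we fix as samples of the 1 ms signal) and
window-averaged down to 150 Hz, or (b) 12-dimensional latents at 5 ms
resolution linearly interpolated to 150 Hz. The decoder network is a
feed-forward net (input `N × 3` history bins → 64 → 64 → 128, ELU on the
hidden layers), trained with AdamW on frame-wise MSE with 30% dropout,
probabilistic (p = 0.5 each) temporal jitter of up to ±2 frames (≈10 ms)
and additive Gaussian noise (σ = 0.25), early-stopped on a 10% validation
split of the training motifs (patience 20, with learning-rate halving on
plateau), one motif per batch. The network, including AdamW and
backpropagation, is implemented in NumPy and is deterministic given its
seed.

Feature normalization: spike features are z-scored per feature with a
robust variance floor (per-unit sd floored at 25% of the median sd) —
without the floor, near-silent sparse units are amplified into dominant
shot noise and the decoder degenerates. Latent features use a single
pooled scale ("global" normalization): orthonormalized modes are ordered
by variance, and per-dimension z-scoring would inflate trailing near-noise
modes.

Reconstruction error is the pixel-wise MSE between magnitude spectrograms
(256-sample Hann window, 50% overlap, dB relative to peak clipped at
−80 dB, then min-max normalized per spectrogram); the parameters are
conventions we fix and log. The chance control permutes feature frames in
time (identity permutation excluded) and compares MSE distributions by
two-sample t-test.

## Population-turnover stability

A region's clusters are split into random disjoint halves Z1/Z2. A decoder
is trained on Z1 features; Z2 features (computed independently — for
latents, a separate state-space fit on Z2 alone) are aligned to Z1's
feature space by regularized CCA (ridge 1e-6 on both covariance blocks;
whitening + SVD) fit on training-motif frames only, so test frames never
influence the alignment. Components: the latent dimensionality (12) for
latent features; min(|Z1|, |Z2|) capped at 32 for spike features. The
cross-half decode is compared with the within-half baseline and the
temporal-shuffle control. When Z2's features are an exact orthogonal
transform of Z1's, the aligned cross-half decode equals the within-half
decode to numerical tolerance (tested).

## The synthetic generator

The generator emulates: a Markov song grammar over syllables with an
absorbing silence state (the default grammar has an introductory note, a
5-syllable motif, and one branch point whose successors are S1/S6/silence
with probabilities 0.4/0.4/0.2); per-syllable latent template curves drawn
from a smooth seeded GP (draws, not hand-authored shapes, to avoid
favorable geometry) plus a per-trial GP perturbation with the region's
timescales scaled by `trial_variability_scale` — the knob that creates the
premotor/motor dispersion contrast; spikes from either a Gaussian
square-root-count regime matched to the analysis model (sqrt-counts
`~ N(Cx+d, R)`, squared and rounded; negatives clamped at zero) or a
Poisson regime (`counts ~ Poisson(100·softplus(Cx+d)·Δt)`); and audio.
SE-kernel GP noise is generated exactly by Gaussian-filtering white noise
(filter width τ/√2), verified against the closed-form autocorrelation.

Sparse ("projection-neuron-like") units get a strongly negative offset and
a high-gain random preferred direction; their offsets are calibrated
per-unit so only the top ≈0.04% of their drive crosses the firing
threshold — brief ≥100 Hz bursts at the preferred direction's maxima,
mean song rates in the low Hz, analogous to thresholds adapted to inputs.
Default region scales are an HVC-like population of 60 clusters (half
sparse, high trial variability) and an RA-like population of 110 tonic
clusters (low variability), mirroring typical relative yields of the two
nuclei at desk scale.

Audio synthesis is locked to the codec frame grid: a frame whose center
falls in a syllable is a Hann-windowed harmonic stack at the syllable's
fixed fundamental whose per-harmonic amplitudes are affine in two
designated latent dimensions (dimension 0 tilts the spectrum, dimension 1
scales loudness); silence is exactly zero. Each voiced frame is therefore
an affine function of the instantaneous latent state given the syllable,
so an exact frame-level decoder exists by construction. An earlier design
modulated the fundamental frequency itself; because the oscillator phase
then integrates the entire pitch history, codec frames cease to be a
function of the instantaneous latent and the regression target becomes
rapidly oscillatory in the latent — empirically unlearnable even from
ground-truth latents — so pitch-as-frequency was replaced by
pitch-as-spectral-tilt. Motif spans are snapped inward to the codec frame
grid for the same reason: embeddings of identical latent states must be
comparable across renditions.

**What the synthetic data does not show.** Real recordings have
non-Poisson, history-dependent spiking, nonstationary drift, imperfect
sorting, richer acoustics (frequency modulation, noise, amplitude
envelopes not affine in anything), and behavioral variability in syllable
durations that we crop rather than warp. Passing tests establish that each
procedure recovers what it claims under its own assumptions and fails its
negative controls — not that the scientific conclusions transfer to any
particular dataset.

## Problem sizes

Analyses run at desk scale by choice: sessions of 12–18 bouts,
populations of 24–50 clusters per region, 12-dimensional manifolds for
bootstrap/dispersion/decoding analyses, 10 bootstrap fits per group, 200
bootstrap runs for branch-prediction nulls, 20 temporal shuffles per
control, four region × session configurations for the stability
experiment. `scripts/acceptance.py --seed <s> --out <json>` recomputes all
headline quantities from scratch at these sizes.

## Known limitations

- The EM timescale step is a bounded scalar search per dimension, not a
  joint gradient step; it is robust but slightly slower to converge.
- Dispersion requires equal-length trials (cropping upstream); trials of
  differing length are supported by the model fit and inference only.
- The toy codec is linear and invertible; conclusions about decoding
  through a learned residual-quantization codec are out of scope.
- The bootstrap ANOVA treats the 10 subsample fits as independent
  samples; they share trials, so its null is only approximately
  calibrated (hence the same-pool negative control above).
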