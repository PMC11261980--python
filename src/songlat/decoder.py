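"""Continuous song synthesis from neural activity.

A small feed-forward network maps neural features — Gaussian-smoothed spike
trains or state-space latent trajectories, resampled to the codec frame
rate of 150 Hz — onto 128-dimensional frame embeddings of the concurrent
audio; a codec's decoder then renders the predicted embeddings back into a
waveform.  The network sees ``history_bins`` frames of causal neural
context per output frame (frame k uses features k-2..k), is trained with
AdamW on a frame-wise MSE loss with 30% dropout, probabilistic temporal
jitter (up to 10 ms) and additive Gaussian noise augmentation, and early
stops on a held-back validation split of the training motifs.

Reconstruction quality is the pixel-wise MSE between min-max-normalized
magnitude spectrograms; temporal shuffling of the neural input provides
the chance-level control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np
from scipy import signal, stats
from scipy.ndimage import gaussian_filter1d
from sklearn.base import BaseEstimator

from .nn import MLP

logger = logging.getLogger("songlat")


# ---------------------------------------------------------------------------
# Feature preparation


def _window_average(x: np.ndarray, in_rate: float, out_rate: float) -> np.ndarray:
    """Anti-aliased downsampling by averaging non-overlapping output windows.

    ``x`` is (n_in, d); output frame k averages the input samples whose
    centers fall in [k/out_rate, (k+1)/out_rate).
    """
    n_out = int(np.floor(x.shape[0] * out_rate / in_rate))
    edges = np.floor(np.arange(n_out + 1) * in_rate / out_rate).astype(int)
    out = np.empty((n_out, x.shape[1]))
    for k in range(n_out):
        out[k] = x[edges[k] : max(edges[k + 1], edges[k] + 1)].mean(axis=0)
    return out


def prepare_spike_features(
    counts_1ms: np.ndarray,
    smoothing_sigma_samples: float = 30.0,
    frame_rate: int = 150,
    base_bin_s: float = 0.001,
) -> np.ndarray:
    """Smoothed, downsampled spike-train features, (n_frames, n_clusters).

    Counts at 1 ms are smoothed with a normalized 1-d Gaussian kernel of
    ``smoothing_sigma_samples`` samples (30 samples = 30 ms by default) and
    averaged down to the codec frame rate.
    """
    sm = gaussian_filter1d(counts_1ms.astype(float), smoothing_sigma_samples,
                           axis=1, mode="constant")
    return _window_average(sm.T, 1.0 / base_bin_s, frame_rate)


def prepare_latent_features(
    latents: np.ndarray,
    latent_bin_s: float = 0.005,
    frame_rate: int = 150,
) -> np.ndarray:
    """Latent trajectories resampled to the frame rate by linear interpolation.

    ``latents`` is (p, T) at ``latent_bin_s`` resolution (5 ms by default);
    output is (n_frames, p) at frame centers.
    """
    p, T = latents.shape
    t_in = (np.arange(T) + 0.5) * latent_bin_s
    n_out = int(np.floor(T * latent_bin_s * frame_rate))
    t_out = (np.arange(n_out) + 0.5) / frame_rate
    return np.stack([np.interp(t_out, t_in, latents[j]) for j in range(p)], axis=1)


def prepare_features(source: np.ndarray, kind: str = "spikes", **kwargs) -> np.ndarray:
    if kind == "spikes":
        return prepare_spike_features(source, **kwargs)
    if kind == "latents":
        return prepare_latent_features(source, **kwargs)
    raise ValueError(f"unknown feature source {kind!r}")


def stack_history(features: np.ndarray, history_bins: int = 3) -> np.ndarray:
    """Causal history stacking: output row k is [f_{k-H+1}, ..., f_k],
    zero-padded at the sequence start."""
    n, d = features.shape
    out = np.zeros((n, d * history_bins))
    for h in range(history_bins):
        lag = history_bins - 1 - h
        out[lag:, h * d : (h + 1) * d] = features[: n - lag]
    return out


# ---------------------------------------------------------------------------
# The decoder network


class SongDecoder(BaseEstimator):
    """Feed-forward neural-to-embedding decoder (fit on per-motif lists).

    Parameters mirror the training procedure: 80/20 motif-level train/test
    splitting is done by the caller; ``fit`` reserves ``val_frac`` of its
    training motifs for early stopping.  Features are z-scored with
    training-set statistics.  ``jitter_frames`` (<= 2 frames ~ 10 ms at
    150 Hz) and ``noise_sd`` augmentations are each applied with
    probability ``augment_p`` per motif per epoch.
    """

    def __init__(
        self,
        hidden: tuple[int, ...] = (64, 64),
        history_bins: int = 3,
        dropout: float = 0.3,
        lr: float = 1e-3,
        weight_decay: float = 1e-4,
        max_epochs: int = 400,
        patience: int = 20,
        lr_decay: float = 0.5,
        lr_patience: int = 8,
        min_lr: float = 2e-5,
        val_frac: float = 0.1,
        jitter_frames: int = 2,
        noise_sd: float = 0.25,
        augment_p: float = 0.5,
        augment: bool = True,
        normalization: str = "zscore",
        random_state: int = 0,
    ) -> None:
        self.hidden = hidden
        self.history_bins = history_bins
        self.dropout = dropout
        self.lr = lr
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.patience = patience
        self.lr_decay = lr_decay
        self.lr_patience = lr_patience
        self.min_lr = min_lr
        self.val_frac = val_frac
        self.jitter_frames = jitter_frames
        self.noise_sd = noise_sd
        self.augment_p = augment_p
        self.augment = augment
        self.normalization = normalization
        self.random_state = random_state

    def fit(self, features: list[np.ndarray], embeddings: list[np.ndarray]) -> "SongDecoder":
        if len(features) < 3:
            raise ValueError("need >= 3 motifs to train (train + validation)")
        for f, e in zip(features, embeddings):
            if f.shape[0] != e.shape[0]:
                raise ValueError("features and embeddings misaligned in length")
        rng = np.random.default_rng(self.random_state)
        n = len(features)
        n_val = max(1, int(round(self.val_frac * n)))
        order = rng.permutation(n)
        val_idx, train_idx = order[:n_val], order[n_val:]

        train_feats = [np.asarray(features[i], dtype=float) for i in train_idx]
        pooled = np.concatenate(train_feats, axis=0)
        self.feat_mean_ = pooled.mean(axis=0)
        if self.normalization == "zscore":
            # per-feature z-scoring with a robust variance floor: near-silent
            # sparse units would otherwise be amplified into dominant shot
            # noise (their sd is tiny), drowning the informative channels
            sd = pooled.std(axis=0)
            floor = 0.25 * np.median(sd)
            self.feat_sd_ = np.maximum(sd, floor if floor > 0 else 1e-12)
            self.feat_sd_[self.feat_sd_ < 1e-12] = 1.0
        elif self.normalization == "global":
            # scale-preserving: one pooled scale for all features, so
            # low-variance dimensions (e.g. trailing orthonormalized latent
            # modes) are not inflated to unit variance
            sd = float(pooled.std())
            self.feat_sd_ = np.full(pooled.shape[1], sd if sd > 1e-12 else 1.0)
        else:
            raise ValueError(f"unknown normalization {self.normalization!r}")

        d_in = features[0].shape[1] * self.history_bins
        d_out = embeddings[0].shape[1]
        self.embed_dim_ = d_out
        net = MLP([d_in, *self.hidden, d_out], seed=int(rng.integers(2**31)))

        def xy(i: int, feats: np.ndarray | None = None):
            f = feats if feats is not None else features[i]
            fz = (np.asarray(f, dtype=float) - self.feat_mean_) / self.feat_sd_
            return stack_history(fz, self.history_bins), np.asarray(embeddings[i])

        val_sets = [xy(i) for i in val_idx]

        best_val, best_w, since_best = np.inf, None, 0
        lr, since_decay = self.lr, 0
        curve = []
        for epoch in range(self.max_epochs):
            for i in rng.permutation(train_idx):
                f = np.asarray(features[i], dtype=float)
                if self.augment and self.jitter_frames > 0 and rng.random() < self.augment_p:
                    s = int(rng.integers(-self.jitter_frames, self.jitter_frames + 1))
                    if s:
                        f = np.roll(f, s, axis=0)
                if self.augment and self.noise_sd > 0 and rng.random() < self.augment_p:
                    f = f + self.noise_sd * rng.standard_normal(f.shape)
                X, Y = xy(i, feats=f)
                out, cache = net.forward(X, dropout=self.dropout, rng=rng)
                dY = 2.0 * (out - Y) / out.size
                gW, gb = net.backward(cache, dY)
                net.adamw_step(gW, gb, lr=lr, weight_decay=self.weight_decay)
            val = float(
                np.mean([np.mean((net.predict(X) - Y) ** 2) for X, Y in val_sets])
            )
            if not np.isfinite(val):
                raise RuntimeError(f"validation loss became non-finite at epoch {epoch}")
            curve.append(val)
            if val < best_val - 1e-12:
                best_val, best_w, since_best, since_decay = val, net.get_weights(), 0, 0
            else:
                since_best += 1
                since_decay += 1
                if since_best >= self.patience:
                    break
                if since_decay >= self.lr_patience and lr > self.min_lr:
                    lr = max(lr * self.lr_decay, self.min_lr)
                    since_decay = 0
        net.set_weights(*best_w)
        self.net_ = net
        self.val_loss_ = best_val
        self.train_curve_ = np.asarray(curve)
        return self

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Predicted embedding frames for one motif's features (n_frames, d)."""
        fz = (np.asarray(features, dtype=float) - self.feat_mean_) / self.feat_sd_
        return self.net_.predict(stack_history(fz, self.history_bins))

    def score(self, features: list[np.ndarray], embeddings: list[np.ndarray]) -> float:
        """Negative mean frame MSE across motifs (higher is better)."""
        return -float(
            np.mean(
                [np.mean((self.predict(f) - e) ** 2) for f, e in zip(features, embeddings)]
            )
        )


def train_ensongdec(
    features: list[np.ndarray], embeddings: list[np.ndarray], rng_seed: int = 0, **cfg
) -> SongDecoder:
    return SongDecoder(random_state=rng_seed, **cfg).fit(features, embeddings)


def decode_song(decoder: SongDecoder, features: np.ndarray, codec) -> np.ndarray:
    """Features -> predicted embedding frames -> codec decode -> waveform."""
    return codec.decode(decoder.predict(features))


# ---------------------------------------------------------------------------
# Evaluation


def evaluate_reconstruction(
    original: np.ndarray,
    reconstructed: np.ndarray,
    sample_rate: int = 19200,
    nperseg: int = 256,
    db_floor: float = -80.0,
) -> float:
    """Pixel-wise MSE between min-max-normalized magnitude spectrograms.

    Spectrograms use a 256-sample Hann window at 50% overlap; magnitudes in
    dB (relative to each spectrogram's peak) are clipped at ``db_floor``
    before per-spectrogram min-max normalization to [0, 1].  Inputs are
    trimmed to the shorter duration; the measure is symmetric.
    """
    n = min(len(original), len(reconstructed))
    specs = []
    for w in (original, reconstructed):
        _, _, S = signal.spectrogram(
            np.asarray(w[:n], dtype=float), fs=sample_rate, window="hann",
            nperseg=nperseg, noverlap=nperseg // 2, mode="magnitude",
        )
        peak = S.max()
        if peak <= 0:
            logger.warning("all-zero signal in spectrogram comparison")
            specs.append(np.zeros_like(S))
            continue
        db = 20.0 * np.log10(np.maximum(S / peak, 10 ** (db_floor / 20.0)))
        specs.append((db - db_floor) / (-db_floor))
    return float(np.mean((specs[0] - specs[1]) ** 2))


@dataclass
class ShuffleControlResult:
    true_mse: np.ndarray  # per held-out motif
    shuffle_mse: np.ndarray  # n_shuffles per motif, flattened
    t_stat: float
    p_value: float


def shuffle_control(
    decoder: SongDecoder,
    features: list[np.ndarray],
    originals: list[np.ndarray],
    codec,
    n_shuffles: int = 20,
    rng: np.random.Generator | int = 0,
) -> ShuffleControlResult:
    """Chance-level control: permute neural feature frames in time.

    For each held-out motif the decoder is evaluated on the true features
    and on ``n_shuffles`` random temporal permutations (identity excluded);
    a two-sample t-test compares the two spectrogram-MSE distributions.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    true_mse, shuf_mse = [], []
    for f, orig in zip(features, originals):
        wave = decode_song(decoder, f, codec)
        true_mse.append(evaluate_reconstruction(orig, wave, codec.sample_rate))
        n = f.shape[0]
        for _ in range(n_shuffles):
            perm = rng.permutation(n)
            while np.array_equal(perm, np.arange(n)):
                perm = rng.permutation(n)
            wave_s = decode_song(decoder, f[perm], codec)
            shuf_mse.append(evaluate_reconstruction(orig, wave_s, codec.sample_rate))
    t, p = stats.ttest_ind(true_mse, shuf_mse, equal_var=False)
    return ShuffleControlResult(
        true_mse=np.asarray(true_mse),
        shuffle_mse=np.asarray(shuf_mse),
        t_stat=float(t),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# Serialization


def save_decoder(decoder: SongDecoder, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("decoder")
        for k, w in enumerate(decoder.net_.W):
            g.create_dataset(f"W{k}", data=w)
            g.create_dataset(f"b{k}", data=decoder.net_.b[k])
        g.create_dataset("feat_mean", data=decoder.feat_mean_)
        g.create_dataset("feat_sd", data=decoder.feat_sd_)
        g.attrs["history_bins"] = decoder.history_bins
        g.attrs["hidden"] = list(decoder.hidden)
        g.attrs["n_layers"] = len(decoder.net_.W)


def load_decoder(path) -> SongDecoder:
    with h5py.File(path, "r") as f:
        g = f["decoder"]
        n_layers = int(g.attrs["n_layers"])
        W = [g[f"W{k}"][...] for k in range(n_layers)]
        b = [g[f"b{k}"][...] for k in range(n_layers)]
        dec = SongDecoder(hidden=tuple(int(h) for h in g.attrs["hidden"]),
                          history_bins=int(g.attrs["history_bins"]))
        sizes = [W[0].shape[0]] + [w.shape[1] for w in W]
        dec.net_ = MLP(sizes)
        dec.net_.set_weights(W, b)
        dec.feat_mean_ = g["feat_mean"][...]
        dec.feat_sd_ = g["feat_sd"][...]
        dec.embed_dim_ = W[-1].shape[1]
    return dec
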