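"""Population-turnover stability of song decoders.

The experiment: split a region's clusters into disjoint halves Z1 and Z2,
train a decoder on Z1's features (smoothed spike trains, or latent
trajectories from a state-space model fit on Z1 alone), then decode
held-out motifs from Z2's features after aligning them to Z1's feature
space with canonical correlation analysis fit on the training-period
frames only.  If population activity is confined to a region-level latent
manifold, latent-feature decoders should survive this complete neuron
turnover much better than spike-feature decoders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, svd
from sklearn.base import BaseEstimator

from .codec import ToyCodec
from .decoder import (
    SongDecoder,
    decode_song,
    evaluate_reconstruction,
    prepare_latent_features,
    prepare_spike_features,
)
from .gpfa import GPFA
from .io import AnnotationTrack, SpikeSession
from .preprocess import bin_spikes, find_motifs

logger = logging.getLogger("songlat")


@dataclass
class SplitPlan:
    z1: list[int]
    z2: list[int]
    seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.z1) & set(self.z2):
            raise ValueError("Z1 and Z2 overlap")
        if abs(len(self.z1) - len(self.z2)) > 1:
            raise ValueError("halves must be equal size (+-1)")


def split_population(
    session: SpikeSession,
    region: str,
    rng: np.random.Generator,
    min_clusters: int = 4,
) -> SplitPlan:
    """Uniform random disjoint halves of a region's clusters (|Z1|>=|Z2|)."""
    ids = [c.cluster_id for c in session.clusters if c.region == region]
    if len(ids) < min_clusters:
        raise ValueError(
            f"region {region!r} has {len(ids)} clusters; need >= {min_clusters}"
        )
    perm = rng.permutation(ids)
    half = (len(ids) + 1) // 2
    return SplitPlan(z1=sorted(int(i) for i in perm[:half]),
                     z2=sorted(int(i) for i in perm[half:]))


class CCAAligner(BaseEstimator):
    """Regularized canonical correlation alignment between feature spaces.

    Fit on time-aligned frame matrices X1 (n, d1) and X2 (n, d2): canonical
    directions A, B maximize successive correlations between X1 A and X2 B
    (ridge 1e-6 on both covariance blocks).  ``transform`` sends new X2
    frames through the canonical space into X1's space via the
    pseudo-inverse of A.  ``correlations_`` are non-increasing.
    """

    def __init__(self, n_components: int = 12, ridge: float = 1e-6) -> None:
        self.n_components = n_components
        self.ridge = ridge

    def fit(self, X1: np.ndarray, X2: np.ndarray) -> "CCAAligner":
        X1, X2 = np.asarray(X1, float), np.asarray(X2, float)
        if X1.shape[0] != X2.shape[0]:
            raise ValueError("X1 and X2 must have the same frame count")
        k = min(self.n_components, X1.shape[1], X2.shape[1])
        n = X1.shape[0]
        self.mean1_, self.mean2_ = X1.mean(axis=0), X2.mean(axis=0)
        X1c, X2c = X1 - self.mean1_, X2 - self.mean2_
        C11 = X1c.T @ X1c / n + self.ridge * np.eye(X1.shape[1])
        C22 = X2c.T @ X2c / n + self.ridge * np.eye(X2.shape[1])
        C12 = X1c.T @ X2c / n
        W1 = _inv_sqrt(C11)
        W2 = _inv_sqrt(C22)
        U, s, Vt = svd(W1 @ C12 @ W2)
        self.A_ = W1 @ U[:, :k]
        self.B_ = W2 @ Vt.T[:, :k]
        self.correlations_ = np.clip(s[:k], 0.0, 1.0)
        self.A_pinv_ = np.linalg.pinv(self.A_)
        return self

    def transform(self, X2: np.ndarray) -> np.ndarray:
        """Map X2 frames into X1's feature space."""
        v = (np.asarray(X2, float) - self.mean2_) @ self.B_
        return v @ self.A_pinv_ + self.mean1_


def _inv_sqrt(C: np.ndarray) -> np.ndarray:
    w, V = eigh(C)
    w = np.maximum(w, 1e-12)
    return V @ np.diag(w**-0.5) @ V.T


def cca_align(X1: np.ndarray, X2: np.ndarray, k: int, ridge: float = 1e-6) -> CCAAligner:
    return CCAAligner(n_components=k, ridge=ridge).fit(X1, X2)


# ---------------------------------------------------------------------------
# Per-motif feature construction for each half


def snap_spans_to_frames(
    spans: list[tuple[float, float]], frame_rate: int = 150
) -> list[tuple[float, float]]:
    """Snap motif spans to the codec frame grid (inward), so codec frames
    tile each motif exactly and embeddings are comparable across motifs."""
    out = []
    for a, b in spans:
        k0 = int(np.ceil(a * frame_rate - 1e-9))
        k1 = int(np.floor(b * frame_rate + 1e-9))
        if k1 <= k0:
            raise ValueError(f"span ({a}, {b}) shorter than one codec frame")
        out.append((k0 / frame_rate, k1 / frame_rate))
    return out


def _cut(counts_1ms: np.ndarray, span: tuple[float, float], base_bin_s: float = 0.001):
    b0 = int(round(span[0] / base_bin_s))
    b1 = int(round(span[1] / base_bin_s))
    return counts_1ms[:, b0:b1]


def spike_motif_features(
    counts_1ms: np.ndarray,
    spans: list[tuple[float, float]],
    frame_rate: int = 150,
    smoothing_sigma_samples: float = 30.0,
) -> list[np.ndarray]:
    return [
        prepare_spike_features(
            _cut(counts_1ms, sp), smoothing_sigma_samples, frame_rate
        )
        for sp in spans
    ]


def latent_motif_features(
    counts_1ms: np.ndarray,
    spans: list[tuple[float, float]],
    train_span_idx: list[int],
    n_factors: int = 12,
    latent_bin_s: float = 0.005,
    frame_rate: int = 150,
    gpfa_kwargs: dict | None = None,
) -> tuple[list[np.ndarray], GPFA]:
    """State-space latents per motif, model fit on training motifs only."""
    factor = int(round(latent_bin_s / 0.001))
    segs = []
    for sp in spans:
        seg = _cut(counts_1ms, sp)
        T = seg.shape[1] // factor
        segs.append(np.sqrt(seg[:, : T * factor].reshape(seg.shape[0], T, factor).sum(axis=2)))
    gpfa_kwargs = dict(gpfa_kwargs or {})
    gpfa_kwargs.setdefault("max_iter", 25)
    gpfa_kwargs.setdefault("tol", 1e-6)
    model = GPFA(n_factors=n_factors, bin_width_s=latent_bin_s, **gpfa_kwargs).fit(
        [segs[i] for i in train_span_idx]
    )
    lat = model.transform(segs)
    src = lat.orthonormalized or lat.trajectories
    feats = [prepare_latent_features(x, latent_bin_s, frame_rate) for x in src]
    return feats, model


def motif_embeddings(
    wave: np.ndarray, spans: list[tuple[float, float]], codec
) -> list[np.ndarray]:
    sr = codec.sample_rate
    out = []
    for a, b in spans:
        out.append(codec.encode(wave[int(round(a * sr)) : int(round(b * sr))]))
    return out


def _align_lengths(feats: list[np.ndarray], embs: list[np.ndarray]):
    fa, ea = [], []
    for f, e in zip(feats, embs):
        n = min(f.shape[0], e.shape[0])
        fa.append(f[:n])
        ea.append(e[:n])
    return fa, ea


# ---------------------------------------------------------------------------
# The experiment


@dataclass
class StabilityResult:
    feature_source: str
    region: str
    mse_within: np.ndarray  # per held-out motif, Z1 input
    mse_cross: np.ndarray  # per held-out motif, CCA-aligned Z2 input
    mse_shuffle: np.ndarray  # per held-out motif, shuffled aligned input
    cca_correlations: np.ndarray
    split: SplitPlan


def stability_experiment(
    session: SpikeSession,
    annotations: AnnotationTrack,
    wave: np.ndarray,
    region: str,
    feature_source: str,
    rng: np.random.Generator,
    motif_labels: tuple[str, ...] = ("S1", "S2", "S3", "S4", "S5"),
    codec: ToyCodec | None = None,
    n_factors: int = 12,
    test_frac: float = 0.2,
    spike_cca_cap: int = 32,
    decoder_kwargs: dict | None = None,
    split: SplitPlan | None = None,
) -> StabilityResult:
    """Train on Z1, decode held-out motifs from CCA-aligned Z2 features.

    CCA components: the latent dimensionality (12) for latent features, or
    min(|Z1|, |Z2|) capped at ``spike_cca_cap`` for spike features.  The
    alignment is fit on training-motif frames only, so test frames never
    influence it.
    """
    codec = codec or ToyCodec()
    split = split or split_population(session, region, rng)
    spans = snap_spans_to_frames(find_motifs(annotations, motif_labels), codec.frame_rate)
    if len(spans) < 5:
        raise ValueError(f"only {len(spans)} motif renditions; need >= 5")
    n_test = max(1, int(round(test_frac * len(spans))))
    order = rng.permutation(len(spans))
    test_idx = sorted(int(i) for i in order[:n_test])
    train_idx = sorted(int(i) for i in order[n_test:])

    halves = {}
    for name, ids in (("z1", split.z1), ("z2", split.z2)):
        sub = session.subset(ids)
        counts = bin_spikes(sub, 0.001)
        if feature_source == "spikes":
            feats = spike_motif_features(counts, spans)
        elif feature_source == "latents":
            feats, _ = latent_motif_features(counts, spans, train_idx, n_factors)
        else:
            raise ValueError(f"unknown feature_source {feature_source!r}")
        halves[name] = feats
    embs = motif_embeddings(wave, spans, codec)
    f1, e1 = _align_lengths(halves["z1"], embs)
    f2, _ = _align_lengths(halves["z2"], embs)

    dk = dict(decoder_kwargs or {})
    dk.setdefault("normalization", "global" if feature_source == "latents" else "zscore")
    dec = SongDecoder(
        random_state=int(rng.integers(2**31)), **dk
    ).fit([f1[i] for i in train_idx], [e1[i] for i in train_idx])

    k = n_factors if feature_source == "latents" else min(
        len(split.z1), len(split.z2), spike_cca_cap
    )
    aligner = cca_align(
        np.concatenate([f1[i] for i in train_idx], axis=0),
        np.concatenate([f2[i] for i in train_idx], axis=0),
        k=k,
    )

    originals = []
    sr = codec.sample_rate
    for i in test_idx:
        a, b = spans[i]
        originals.append(wave[int(round(a * sr)) : int(round(b * sr))])

    mse_within, mse_cross, mse_shuffle = [], [], []
    for j, i in enumerate(test_idx):
        w_hat = decode_song(dec, f1[i], codec)
        mse_within.append(evaluate_reconstruction(originals[j], w_hat, sr))
        f2_aligned = aligner.transform(f2[i])
        w_cross = decode_song(dec, f2_aligned, codec)
        mse_cross.append(evaluate_reconstruction(originals[j], w_cross, sr))
        perm = rng.permutation(f2_aligned.shape[0])
        while np.array_equal(perm, np.arange(len(perm))):
            perm = rng.permutation(f2_aligned.shape[0])
        w_shuf = decode_song(dec, f2_aligned[perm], codec)
        mse_shuffle.append(evaluate_reconstruction(originals[j], w_shuf, sr))
    return StabilityResult(
        feature_source=feature_source,
        region=region,
        mse_within=np.asarray(mse_within),
        mse_cross=np.asarray(mse_cross),
        mse_shuffle=np.asarray(mse_shuffle),
        cca_correlations=aligner.correlations_,
        split=split,
    )
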