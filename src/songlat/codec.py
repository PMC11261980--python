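"""Audio codecs mapping waveforms to frame-level embeddings and back.

The decoder pipeline is codec-agnostic: anything exposing ``encode``,
``decode``, ``sample_rate``, ``embed_dim`` and ``frame_rate`` works.  The
provided :class:`ToyCodec` is an exactly invertible stand-in: it chops the
waveform into 128-sample frames at 19,200 Hz (so one frame = 1/150 s and
the embedding rate is 150 frames/s) and applies a fixed, seeded orthonormal
transform per frame.  An adapter for a pre-trained residual-vector-
quantization codec can be plugged in through the same interface when its
weights are available.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np


@runtime_checkable
class Codec(Protocol):
    sample_rate: int
    embed_dim: int
    frame_rate: int

    def encode(self, waveform: np.ndarray) -> np.ndarray: ...

    def decode(self, frames: np.ndarray) -> np.ndarray: ...


class ToyCodec:
    """Invertible frame codec: orthonormal transform of 128-sample frames.

    encode(w) returns (n_frames, 128); a trailing partial frame is
    zero-padded.  decode(encode(w)) reproduces w exactly (up to that
    padding), and the transform preserves energy.
    """

    def __init__(self, sample_rate: int = 19200, frame_size: int = 128, seed: int = 1234):
        if sample_rate % frame_size != 0:
            raise ValueError("sample_rate must be a multiple of frame_size")
        self.sample_rate = int(sample_rate)
        self.frame_size = int(frame_size)
        self.embed_dim = int(frame_size)
        self.frame_rate = sample_rate // frame_size
        rng = np.random.default_rng(seed)
        Q, _ = np.linalg.qr(rng.standard_normal((frame_size, frame_size)))
        self._Q = Q

    def encode(self, waveform: np.ndarray) -> np.ndarray:
        w = np.asarray(waveform, dtype=float).ravel()
        pad = (-len(w)) % self.frame_size
        if pad:
            w = np.concatenate([w, np.zeros(pad)])
        frames = w.reshape(-1, self.frame_size)
        return frames @ self._Q

    def decode(self, frames: np.ndarray) -> np.ndarray:
        frames = np.atleast_2d(np.asarray(frames, dtype=float))
        if frames.shape[1] != self.embed_dim:
            raise ValueError(f"frames must have {self.embed_dim} columns")
        return (frames @ self._Q.T).ravel()


def toy_codec(seed: int = 1234) -> ToyCodec:
    return ToyCodec(seed=seed)


class EncodecAdapter:
    """Adapter exposing a pre-trained EnCodec model through the Codec
    interface (24 kbps at 48 kHz, 16 residual codebooks of 1024 entries).

    Requires the optional ``encodec``/``torch`` packages and downloaded
    weights; nothing in this package depends on it.
    """

    def __init__(self, bandwidth_kbps: float = 24.0):
        try:
            import torch  # noqa: F401
            from encodec import EncodecModel
        except ImportError as e:  # pragma: no cover - optional dependency
            raise ImportError(
                "EncodecAdapter requires the optional 'encodec' and 'torch' packages"
            ) from e
        self._model = EncodecModel.encodec_model_48khz()
        self._model.set_target_bandwidth(bandwidth_kbps)
        self.sample_rate = self._model.sample_rate
        self.embed_dim = 128
        self.frame_rate = 150

    def encode(self, waveform: np.ndarray) -> np.ndarray:  # pragma: no cover
        import torch

        x = torch.tensor(waveform, dtype=torch.float32)[None, None, :].repeat(1, 2, 1)
        with torch.no_grad():
            emb = self._model.encoder(x)
        return emb[0].T.numpy()

    def decode(self, frames: np.ndarray) -> np.ndarray:  # pragma: no cover
        import torch

        z = torch.tensor(frames.T[None], dtype=torch.float32)
        with torch.no_grad():
            wav = self._model.decoder(z)
        return wav[0].mean(dim=0).numpy()
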