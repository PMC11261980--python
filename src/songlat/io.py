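"""Data model and on-disk formats for the song-latents pipeline.

The raw observational unit is a :class:`SpikeSession` — spike-sorted cluster
times for one recording session — together with an :class:`AnnotationTrack`
of syllable/bout intervals and a mono WAV of the concurrent audio.  Aligned,
binned spike counts live in a :class:`TrialSet`.

On disk, tabular data (spikes, cluster metadata, annotations) are plain CSV;
array-valued objects (trial tensors, latent trajectories, model parameters)
are stored in HDF5.  Times are seconds (float64) from session start and all
intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import subprocess
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("songlat")

REGIONS = ("HVC", "RA", "UNKNOWN")
QUALITIES = ("SUA", "MUA")
PUTATIVE_TYPES = ("HVCpn", "HVCint", "RA", "UNLABELED")


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


class FormatError(ValueError):
    """A file is missing required columns or is otherwise malformed."""


@dataclass
class ClusterRecord:
    """One spike-sorted cluster: identity, anatomical region, sort quality."""

    cluster_id: int
    region: str = "UNKNOWN"
    quality: str = "SUA"
    putative_type: str = "UNLABELED"
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}")
        if self.quality not in QUALITIES:
            raise ValidationError(f"unknown quality {self.quality!r}")
        if self.putative_type not in PUTATIVE_TYPES:
            raise ValidationError(f"unknown putative_type {self.putative_type!r}")
        if self.putative_type in ("HVCpn", "HVCint") and self.region != "HVC":
            raise ValidationError(
                f"cluster {self.cluster_id}: putative type {self.putative_type} "
                f"requires region HVC, got {self.region}"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def mean_rate(self, intervals: Sequence[tuple[float, float]]) -> float:
        """Mean firing rate (Hz) restricted to the union of intervals."""
        total_t = sum(b - a for a, b in intervals)
        if total_t <= 0:
            return np.nan
        n = sum(
            int(np.searchsorted(self.spike_times, b) - np.searchsorted(self.spike_times, a))
            for a, b in intervals
        )
        return n / total_t


@dataclass
class SpikeSession:
    """A session's worth of sorted clusters with their spike times."""

    clusters: list[ClusterRecord]
    duration_s: float
    sample_rate_hint: float = 30000.0

    def __post_init__(self) -> None:
        ids = [c.cluster_id for c in self.clusters]
        if len(ids) != len(set(ids)):
            raise ValidationError("cluster ids are not unique")
        for c in self.clusters:
            t = c.spike_times
            if t.size and t.min() < 0:
                raise ValidationError(f"cluster {c.cluster_id}: negative spike time")
            if t.size and t.max() > self.duration_s:
                raise ValidationError(
                    f"cluster {c.cluster_id}: spike time {t.max():g} beyond "
                    f"session duration {self.duration_s:g}"
                )
            if np.any(np.diff(t) < 0):
                raise ValidationError(f"cluster {c.cluster_id}: spike times not sorted")

    @property
    def cluster_ids(self) -> list[int]:
        return [c.cluster_id for c in self.clusters]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def subset(self, cluster_ids: Iterable[int]) -> "SpikeSession":
        keep = set(cluster_ids)
        return SpikeSession(
            clusters=[replace(c) for c in self.clusters if c.cluster_id in keep],
            duration_s=self.duration_s,
            sample_rate_hint=self.sample_rate_hint,
        )

    def by_region(self, region: str) -> "SpikeSession":
        return self.subset(c.cluster_id for c in self.clusters if c.region == region)


@dataclass
class AnnotationTrack:
    """Sorted, non-overlapping labelled intervals (syllables, notes, bouts)."""

    intervals: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        self.intervals = sorted(
            [(float(a), float(b), str(lab)) for a, b, lab in self.intervals],
            key=lambda iv: iv[0],
        )
        for a, b, lab in self.intervals:
            if not b > a:
                raise ValidationError(f"interval ({a}, {b}, {lab!r}): offset <= onset")
        for prev, cur in zip(self.intervals, self.intervals[1:]):
            if cur[0] < prev[1]:
                raise ValidationError(
                    f"overlapping intervals {prev} and {cur}"
                )

    @property
    def labels(self) -> list[str]:
        return [lab for _, _, lab in self.intervals]

    @property
    def label_set(self) -> set[str]:
        return set(self.labels)

    def with_label(self, label: str) -> list[tuple[float, float]]:
        return [(a, b) for a, b, lab in self.intervals if lab == label]

    def span(self) -> tuple[float, float]:
        return self.intervals[0][0], self.intervals[-1][1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["onset_s", "offset_s", "label"])


@dataclass
class TrialSet:
    """Time-aligned binned spike counts, ``counts[trial, cluster, bin]``.

    ``sqrt_transformed`` guards against accidentally applying the square-root
    variance-stabilising transform twice.
    """

    counts: np.ndarray
    bin_width_s: float
    cluster_ids: list[int]
    trial_t0_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    alignment_event: str = ""
    sqrt_transformed: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValidationError("counts must be trial x cluster x bin")
        if self.bin_width_s <= 0:
            raise ValidationError("bin_width_s must be positive")
        if self.counts.shape[1] != len(self.cluster_ids):
            raise ValidationError("cluster_ids length must match counts axis 1")
        if np.any(self.counts < 0):
            raise ValidationError("negative counts")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    def subset_clusters(self, cluster_ids: Sequence[int]) -> "TrialSet":
        idx = [self.cluster_ids.index(cid) for cid in cluster_ids]
        return TrialSet(
            counts=self.counts[:, idx, :].copy(),
            bin_width_s=self.bin_width_s,
            cluster_ids=list(cluster_ids),
            trial_t0_s=self.trial_t0_s,
            alignment_event=self.alignment_event,
            sqrt_transformed=self.sqrt_transformed,
        )


# ---------------------------------------------------------------------------
# CSV readers / writers


def read_spike_session(path: str | Path) -> SpikeSession:
    """Read a session directory containing ``spikes.csv`` and ``clusters.csv``.

    Spike times are auto-sorted (with a warning) if out of order; negative
    times and metadata invariant violations raise :class:`ValidationError`
    with offending rows identified.
    """
    path = Path(path)
    spikes_f, clusters_f = path / "spikes.csv", path / "clusters.csv"
    if not clusters_f.exists():
        raise FormatError(f"missing {clusters_f}")
    meta = pd.read_csv(clusters_f)
    for col in ("cluster_id", "region", "quality"):
        if col not in meta.columns:
            raise FormatError(f"{clusters_f}: missing column {col!r}")
    if "putative_type" not in meta.columns:
        meta["putative_type"] = "UNLABELED"

    if spikes_f.exists():
        spk = pd.read_csv(spikes_f)
        for col in ("cluster_id", "spike_time_s"):
            if col not in spk.columns:
                raise FormatError(f"{spikes_f}: missing column {col!r}")
    else:
        spk = pd.DataFrame({"cluster_id": [], "spike_time_s": []})

    neg = spk.index[spk["spike_time_s"] < 0]
    if len(neg):
        raise ValidationError(f"negative spike times at rows {list(neg[:10])}")

    by_cluster = {cid: g["spike_time_s"].to_numpy() for cid, g in spk.groupby("cluster_id")}
    clusters = []
    for row in meta.itertuples(index=True):
        times = by_cluster.get(row.cluster_id, np.empty(0))
        if np.any(np.diff(times) < 0):
            logger.warning(
                "cluster %s: spike times out of order, sorting", row.cluster_id
            )
            times = np.sort(times)
        try:
            clusters.append(
                ClusterRecord(
                    cluster_id=int(row.cluster_id),
                    region=str(row.region),
                    quality=str(row.quality),
                    putative_type=str(row.putative_type),
                    spike_times=times,
                )
            )
        except ValidationError as e:
            raise ValidationError(f"clusters.csv row {row.Index}: {e}") from e

    duration = _read_session_meta(path).get(
        "duration_s",
        float(spk["spike_time_s"].max()) if len(spk) else 0.0,
    )
    rate = _read_session_meta(path).get("sample_rate_hint", 30000.0)
    return SpikeSession(clusters=clusters, duration_s=float(duration), sample_rate_hint=rate)


def _read_session_meta(path: Path) -> dict:
    f = path / "session.json"
    if f.exists():
        return json.loads(f.read_text())
    return {}


def write_spike_session(session: SpikeSession, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = [
        (c.cluster_id, t)
        for c in session.clusters
        for t in np.round(c.spike_times, 6)
    ]
    pd.DataFrame(rows, columns=["cluster_id", "spike_time_s"]).to_csv(
        path / "spikes.csv", index=False
    )
    pd.DataFrame(
        [(c.cluster_id, c.region, c.quality, c.putative_type) for c in session.clusters],
        columns=["cluster_id", "region", "quality", "putative_type"],
    ).to_csv(path / "clusters.csv", index=False)
    (path / "session.json").write_text(
        json.dumps(
            {"duration_s": session.duration_s, "sample_rate_hint": session.sample_rate_hint}
        )
    )
    return path


def read_annotations(path: str | Path) -> AnnotationTrack:
    """Read a CSV of (onset_s, offset_s, label) intervals, sorted on return."""
    df = pd.read_csv(path)
    for col in ("onset_s", "offset_s", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return AnnotationTrack(
        intervals=list(zip(df["onset_s"], df["offset_s"], df["label"].astype(str)))
    )


def write_annotations(track: AnnotationTrack, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = track.to_frame()
    df["onset_s"] = df["onset_s"].round(6)
    df["offset_s"] = df["offset_s"].round(6)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# WAV audio

def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=float), int(rate)


def write_wav(waveform: np.ndarray, sample_rate: int, path: str | Path) -> Path:
    from scipy.io import wavfile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wavfile.write(path, int(sample_rate), np.asarray(waveform, dtype=np.float32))
    return path


# ---------------------------------------------------------------------------
# HDF5 containers


def save_trial_set(trials: TrialSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        g = f.create_group("trial_set")
        g.create_dataset("counts", data=trials.counts)
        g.create_dataset("cluster_ids", data=np.asarray(trials.cluster_ids))
        g.create_dataset("trial_t0_s", data=np.asarray(trials.trial_t0_s))
        g.attrs["bin_width_s"] = trials.bin_width_s
        g.attrs["alignment_event"] = trials.alignment_event
        g.attrs["sqrt_transformed"] = trials.sqrt_transformed
    return path


def load_trial_set(path: str | Path) -> TrialSet:
    with h5py.File(path, "r") as f:
        g = f["trial_set"]
        return TrialSet(
            counts=g["counts"][...],
            bin_width_s=float(g.attrs["bin_width_s"]),
            cluster_ids=[int(i) for i in g["cluster_ids"][...]],
            trial_t0_s=g["trial_t0_s"][...],
            alignment_event=str(g.attrs["alignment_event"]),
            sqrt_transformed=bool(g.attrs["sqrt_transformed"]),
        )


def save_arrays(path: str | Path, **arrays: np.ndarray) -> Path:
    """Save named arrays (or lists of equal-meaning arrays) to one HDF5 file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for name, arr in arrays.items():
            if isinstance(arr, (list, tuple)):
                g = f.create_group(name)
                for i, a in enumerate(arr):
                    g.create_dataset(str(i), data=np.asarray(a))
            else:
                f.create_dataset(name, data=np.asarray(arr))
    return path


def load_arrays(path: str | Path) -> dict:
    out: dict = {}
    with h5py.File(path, "r") as f:
        for name, obj in f.items():
            if isinstance(obj, h5py.Group):
                out[name] = [obj[str(i)][...] for i in range(len(obj))]
            else:
                out[name] = obj[...]
    return out


# ---------------------------------------------------------------------------
# Run manifests


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _code_version() -> str:
    try:
        return (
            subprocess.run(
                ["git", "rev-parse", "HEAD"],
                capture_output=True,
                text=True,
                cwd=Path(__file__).parent,
                timeout=5,
            ).stdout.strip()
            or "unknown"
        )
    except Exception:
        return "unknown"


def write_run_manifest(
    config: dict,
    outputs: Iterable[str | Path],
    out_dir: str | Path,
    inputs: Iterable[str | Path] = (),
) -> Path:
    """Record config, seeds, code version and file checksums for a stage.

    Re-running a stage with the manifest's config and seed reproduces its
    outputs bit-for-bit (all randomized stages draw from explicitly seeded
    generators).
    """
    out_dir = Path(out_dir)
    if not out_dir.exists():
        logger.warning("creating missing output directory %s", out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "code_version": _code_version(),
        "inputs": {str(p): _checksum(Path(p)) for p in inputs if Path(p).is_file()},
        "outputs": {str(p): _checksum(Path(p)) for p in outputs if Path(p).is_file()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


def load_config(path: str | Path) -> dict:
    """Load a declarative YAML (or JSON) key-value pipeline configuration."""
    import yaml

    text = Path(path).read_text()
    return yaml.safe_load(text) or {}
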