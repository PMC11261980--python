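"""From raw spike sessions to clean, aligned trial tensors.

Steps: 1 ms binning, cross-channel artifact rejection (summed-count > 5 s.d.
rule), putative cell-type labelling for HVC single units (sparse bursty
projection neurons vs tonic interneurons), sub-population selection, and
segmentation of song bouts into motif-aligned trials at the analysis bin
width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .io import AnnotationTrack, SpikeSession, TrialSet

logger = logging.getLogger("songlat")


@dataclass
class SubpopulationCriterion:
    """Named cluster-selection rule.

    ``hs-SUA`` keeps well-isolated single units with mean song-period rate
    above 10 Hz (which excludes most sparse-firing projection neurons);
    ``all-clusters`` keeps every SUA and MUA cluster.
    """

    name: str = "hs-SUA"
    min_quality: str = "SUA"
    min_mean_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.name == "hs-SUA":
            self.min_quality = "SUA"
            self.min_mean_rate_hz = 10.0
        elif self.name == "all-clusters":
            self.min_quality = "MUA"
            self.min_mean_rate_hz = 0.0
        elif self.name != "custom":
            raise ValueError(f"unknown criterion {self.name!r}")


def bin_spikes(
    session: SpikeSession,
    bin_width_s: float = 0.001,
    t_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Bin spike times into a (cluster x bin) count matrix.

    Bins are half-open ``[t0 + b*w, t0 + (b+1)*w)``; a spike exactly on an
    edge lands in the later bin.  Total spikes inside ``t_range`` are
    conserved.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    t0, t1 = t_range if t_range is not None else (0.0, session.duration_s)
    if t1 <= t0:
        raise ValueError(f"empty range ({t0}, {t1})")
    n_bins = int(np.ceil((t1 - t0) / bin_width_s - 1e-9))
    counts = np.zeros((session.n_clusters, n_bins), dtype=int)
    edges = t0 + bin_width_s * np.arange(n_bins + 1)
    for i, c in enumerate(session.clusters):
        t = c.spike_times
        t = t[(t >= t0) & (t < edges[-1])]
        if t.size:
            counts[i] = np.histogram(t, bins=edges)[0]
    return counts


def remove_artifacts(
    counts: np.ndarray, threshold_sd: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Zero out near-simultaneous cross-channel spiking events.

    Bins whose summed-across-clusters count exceeds the mean by more than
    ``threshold_sd`` standard deviations are zeroed in *all* clusters.
    Returns (cleaned counts, flagged bin indices).  Zeroing (rather than
    excising) keeps trial time axes uniform; flagged bins should be excluded
    from firing-rate statistics.
    """
    s = counts.sum(axis=0)
    sd = s.std()
    if sd == 0:
        logger.warning("summed counts constant; no artifact bins flagged")
        return counts.copy(), np.empty(0, dtype=int)
    flagged = np.nonzero(s > s.mean() + threshold_sd * sd)[0]
    cleaned = counts.copy()
    cleaned[:, flagged] = 0
    return cleaned, flagged


def classify_hvc_units(
    session: SpikeSession,
    annotations: AnnotationTrack,
    song_labels: set[str] | None = None,
    rate_threshold_hz: float = 5.0,
    burst_isi_s: float = 0.010,
) -> SpikeSession:
    """Label HVC single units as putative projection neurons or interneurons.

    A cluster is labelled HVCpn iff its mean rate during song periods is
    below ``rate_threshold_hz`` AND it produces at least one within-song
    burst at >= 100 Hz instantaneous rate — detected as a run of >= 2 spikes
    with consecutive inter-spike intervals <= 10 ms.  Otherwise HVCint.
    Non-HVC or MUA clusters are left untouched.
    """
    song_iv = _song_intervals(annotations, song_labels)
    if not song_iv:
        logger.warning("no song periods annotated; leaving HVC units UNLABELED")
        return session
    clusters = []
    for c in session.clusters:
        if c.region != "HVC" or c.quality != "SUA":
            clusters.append(replace(c))
            continue
        rate = c.mean_rate(song_iv)
        bursty = _has_burst(c.spike_times, song_iv, burst_isi_s)
        ptype = "HVCpn" if (rate < rate_threshold_hz and bursty) else "HVCint"
        clusters.append(replace(c, putative_type=ptype))
    return SpikeSession(
        clusters=clusters, duration_s=session.duration_s,
        sample_rate_hint=session.sample_rate_hint,
    )


def _song_intervals(
    annotations: AnnotationTrack, song_labels: set[str] | None
) -> list[tuple[float, float]]:
    ivs = [
        (a, b)
        for a, b, lab in annotations.intervals
        if song_labels is None or lab in song_labels
    ]
    # merge adjacent/nearby vocal intervals into bout-like song periods
    merged: list[list[float]] = []
    for a, b in ivs:
        if merged and a - merged[-1][1] < 0.2:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _has_burst(
    spike_times: np.ndarray, song_iv: list[tuple[float, float]], burst_isi_s: float
) -> bool:
    for a, b in song_iv:
        t = spike_times[(spike_times >= a) & (spike_times < b)]
        if t.size >= 2 and np.any(np.diff(t) <= burst_isi_s):
            return True
    return False


def select_subpopulation(
    session: SpikeSession,
    criterion: SubpopulationCriterion,
    annotations: AnnotationTrack,
    song_labels: set[str] | None = None,
) -> list[int]:
    """Cluster ids passing the criterion (rates over annotated song periods)."""
    song_iv = _song_intervals(annotations, song_labels)
    selected = []
    for c in session.clusters:
        if criterion.min_quality == "SUA" and c.quality != "SUA":
            continue
        if criterion.min_mean_rate_hz > 0:
            if not song_iv or not (c.mean_rate(song_iv) > criterion.min_mean_rate_hz):
                continue
        selected.append(c.cluster_id)
    if not selected:
        raise ValueError(f"criterion {criterion.name!r} selects no clusters")
    return selected


def find_motifs(
    annotations: AnnotationTrack, motif_labels: tuple[str, ...]
) -> list[tuple[float, float]]:
    """Spans of complete motif renditions (the full ordered label sequence)."""
    ivs = annotations.intervals
    k = len(motif_labels)
    spans = []
    i = 0
    while i + k <= len(ivs):
        if tuple(lab for _, _, lab in ivs[i : i + k]) == tuple(motif_labels):
            spans.append((ivs[i][0], ivs[i + k - 1][1]))
            i += k
        else:
            i += 1
    return spans


def segment_trials(
    counts_1ms: np.ndarray,
    session: SpikeSession,
    annotations: AnnotationTrack,
    motif_labels: tuple[str, ...],
    rebin_width_s: float = 0.015,
    base_bin_s: float = 0.001,
) -> TrialSet:
    """Cut motif renditions out of the session counts and rebin by summation.

    One trial per rendition, aligned to the first-syllable onset.  Trials are
    equalized by cropping to the shortest rendition's bin count (no
    time-warping); rebinning conserves spike counts within the cropped span.
    """
    spans = find_motifs(annotations, motif_labels)
    if not spans:
        raise ValueError(f"no motif renditions of {motif_labels} found")
    factor = int(round(rebin_width_s / base_bin_s))
    if abs(factor * base_bin_s - rebin_width_s) > 1e-9:
        raise ValueError("rebin width must be an integer multiple of the base bin")
    n_rebins = [int((b - a) / rebin_width_s) for a, b in spans]
    t_bins = min(n_rebins)
    if t_bins < 1:
        raise ValueError("motif shorter than one analysis bin")
    if max(n_rebins) > t_bins:
        logger.info(
            "cropping %d trials to %d bins (max was %d)",
            len(spans), t_bins, max(n_rebins),
        )
    trials = np.empty((len(spans), counts_1ms.shape[0], t_bins), dtype=int)
    for n, (a, _) in enumerate(spans):
        b0 = int(round(a / base_bin_s))
        seg = counts_1ms[:, b0 : b0 + t_bins * factor]
        trials[n] = seg.reshape(seg.shape[0], t_bins, factor).sum(axis=2)
    return TrialSet(
        counts=trials,
        bin_width_s=rebin_width_s,
        cluster_ids=session.cluster_ids,
        trial_t0_s=np.array([a for a, _ in spans]),
        alignment_event=f"motif_onset:{motif_labels[0]}",
    )
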