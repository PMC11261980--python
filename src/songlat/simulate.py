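"""Synthetic sessions with known ground truth.

The generator emulates the structure of awake-singing songbird recordings:
a Markov song grammar with deterministic and probabilistic ("branch point")
syllable transitions, per-region low-dimensional latent trajectories built
from smooth per-syllable template curves plus trial-to-trial Gaussian-process
perturbations, spike trains driven linearly by the latents (either a Gaussian
square-root-count regime, matching the state-space model downstream, or a
Poisson-count regime), and audio whose pitch and amplitude are affine in two
designated latent dimensions so that a linear readout of the latents can in
principle reconstruct the song exactly.

Everything needed to score recovery (true latents, loadings, grammar,
templates, audio rules) is retained in :class:`GroundTruth`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import AnnotationTrack, ClusterRecord, SpikeSession

logger = logging.getLogger("songlat")

SILENCE = "silence"


class GrammarError(ValueError):
    pass


@dataclass
class SongGrammar:
    """Markov grammar over syllables with an absorbing silence state."""

    syllables: list[str]
    durations: dict[str, tuple[float, float]]  # label -> (mean_s, jitter_sd_s)
    transitions: dict[str, dict[str, float]]  # row label -> {successor: prob}
    start: str
    gap_s: float = 0.010
    bout_gap_s: float = 0.8

    def __post_init__(self) -> None:
        for syl in self.syllables:
            row = self.transitions.get(syl)
            if row is None:
                raise GrammarError(f"no transition row for {syl!r}")
            s = sum(row.values())
            if abs(s - 1.0) > 1e-12:
                raise GrammarError(f"transition row {syl!r} sums to {s!r}, not 1")
            succ = {k for k, v in row.items() if v > 0}
            if succ == {syl}:
                raise GrammarError(f"absorbing non-silence state {syl!r}")
        for syl in self.syllables:
            if syl not in self.durations:
                raise GrammarError(f"no duration for {syl!r}")

    @property
    def branch_points(self) -> list[str]:
        return [
            s
            for s in self.syllables
            if sum(1 for v in self.transitions[s].values() if v > 0) >= 2
        ]


def default_grammar() -> SongGrammar:
    """A zebra-finch-like grammar: intro note, 5-syllable motif, one branch.

    The branch syllable S5 may be followed by S1 (motif restart), S6, or
    silence — the probabilistic sequencing that branch-point analyses target.
    """
    syls = ["i", "S1", "S2", "S3", "S4", "S5", "S6"]
    durations = {
        "i": (0.040, 0.002),
        "S1": (0.070, 0.002),
        "S2": (0.060, 0.002),
        "S3": (0.080, 0.002),
        "S4": (0.065, 0.002),
        "S5": (0.075, 0.002),
        "S6": (0.060, 0.002),
    }
    transitions = {
        "i": {"S1": 1.0},
        "S1": {"S2": 1.0},
        "S2": {"S3": 1.0},
        "S3": {"S4": 1.0},
        "S4": {"S5": 1.0},
        "S5": {"S1": 0.4, "S6": 0.4, SILENCE: 0.2},
        "S6": {SILENCE: 1.0},
    }
    return SongGrammar(syls, durations, transitions, start="i")


MOTIF_LABELS = ("S1", "S2", "S3", "S4", "S5")


def sample_song_sequence(
    grammar: SongGrammar,
    n_bouts: int,
    rng: np.random.Generator,
    t0: float = 0.5,
    max_syllables_per_bout: int = 200,
) -> AnnotationTrack:
    """Realize a Markov walk over the grammar as annotation intervals."""
    intervals: list[tuple[float, float, str]] = []
    t = t0
    for _ in range(n_bouts):
        label = grammar.start
        for _ in range(max_syllables_per_bout):
            mean, jitter = grammar.durations[label]
            dur = max(mean + jitter * rng.standard_normal(), 0.25 * mean)
            intervals.append((t, t + dur, label))
            t += dur + grammar.gap_s
            row = grammar.transitions[label]
            succ = list(row.keys())
            probs = np.array([row[s] for s in succ])
            label = succ[rng.choice(len(succ), p=probs / probs.sum())]
            if label == SILENCE:
                break
        t += grammar.bout_gap_s
    return AnnotationTrack(intervals=intervals)


@dataclass
class RegionSpec:
    """Ground-truth generative parameters for one simulated region."""

    label: str
    n_clusters: int
    p_true: int
    C_true: np.ndarray  # (n_clusters, p_true)
    d_true: np.ndarray  # (n_clusters,)
    R_true: np.ndarray  # (n_clusters,) diagonal variances
    timescales_s: np.ndarray  # (p_true,)
    trial_variability_scale: float = 0.2
    sparse_fraction: float = 0.0
    sparse_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    regime: str = "gaussian"  # or "poisson"

    def __post_init__(self) -> None:
        self.C_true = np.atleast_2d(np.asarray(self.C_true, dtype=float))
        self.d_true = np.asarray(self.d_true, dtype=float)
        self.R_true = np.asarray(self.R_true, dtype=float)
        if np.any(self.R_true <= 0):
            raise ValueError("R_true must be positive (diagonal variances)")
        if self.trial_variability_scale < 0:
            raise ValueError("trial_variability_scale must be >= 0")
        if self.regime not in ("gaussian", "poisson"):
            raise ValueError(f"unknown regime {self.regime!r}")


def make_region_spec(
    label: str,
    n_clusters: int,
    p_true: int,
    rng: np.random.Generator,
    trial_variability_scale: float = 0.2,
    sparse_fraction: float = 0.0,
    regime: str = "gaussian",
    timescale_s: float = 0.05,
    noise_scale: float = 0.1,
) -> RegionSpec:
    """Draw a random but well-conditioned region specification.

    The offset scale targets 1 ms generation bins: tonic units sit at a
    square-root count of ~0.2/bin (tens of Hz after squaring/rounding);
    ``sparse_fraction`` of units get a strongly negative offset and a
    burst-like gain so they are silent except when their preferred latent
    direction peaks (the projection-neuron phenotype: mean song rate in the
    low Hz with >= 100 Hz instantaneous bursts).
    """
    C = 0.08 * rng.standard_normal((n_clusters, p_true))
    d = 0.20 + 0.04 * rng.standard_normal(n_clusters)  # tonic sqrt-count baseline
    n_sparse = int(round(sparse_fraction * n_clusters))
    sparse_ids = rng.choice(n_clusters, size=n_sparse, replace=False)
    if n_sparse:
        d[sparse_ids] = -3.0 + 0.2 * rng.standard_normal(n_sparse)
        rows = rng.standard_normal((n_sparse, p_true))
        rows /= np.linalg.norm(rows, axis=1, keepdims=True)
        C[sparse_ids] = 1.3 * rows  # burst gain: strong drive, low baseline
    R = noise_scale * (0.5 + rng.random(n_clusters))
    tau = timescale_s * (0.8 + 0.4 * rng.random(p_true))
    return RegionSpec(
        label=label,
        n_clusters=n_clusters,
        p_true=p_true,
        C_true=C,
        d_true=d,
        R_true=R,
        timescales_s=tau,
        trial_variability_scale=trial_variability_scale,
        sparse_fraction=sparse_fraction,
        sparse_ids=sparse_ids,
        regime=regime,
    )


# ---------------------------------------------------------------------------
# Latent trajectories


def _se_gp_noise(
    n_bins: int, p: int, timescales_s: np.ndarray, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance GP noise with squared-exponential autocovariance.

    A Gaussian filter of width sigma = tau/(sqrt(2) dt) applied to white noise
    yields exactly the SE kernel exp(-h^2 / (2 tau^2)); the output is rescaled
    to unit marginal variance using the l2 norm of the discrete kernel.
    """
    out = np.empty((p, n_bins))
    for j in range(p):
        sigma = timescales_s[j] / (np.sqrt(2.0) * dt)
        w = rng.standard_normal(n_bins + int(12 * sigma) + 2)
        f = gaussian_filter1d(w, sigma, mode="constant")
        # norm of the implicit kernel -> std of filtered unit white noise
        k = gaussian_filter1d(
            (np.arange(w.size) == w.size // 2).astype(float), sigma, mode="constant"
        )
        f /= np.linalg.norm(k)
        out[j] = f[: n_bins]
    return out


def sample_syllable_templates(
    grammar: SongGrammar,
    p_true: int,
    rng: np.random.Generator,
    separation: float = 2.0,
    n_points: int = 24,
    within_timescale_s: float = 0.02,
) -> dict[str, np.ndarray]:
    """Fixed per-syllable latent template curves, drawn from a smooth GP.

    Each syllable gets a random offset of magnitude ``separation`` (keeping
    syllables apart on the manifold) plus a smooth within-syllable curve.
    Templates are draws, not hand-authored shapes, to avoid favorable
    geometry.
    """
    templates: dict[str, np.ndarray] = {}
    for syl in grammar.syllables:
        offset = separation * rng.standard_normal(p_true) / np.sqrt(p_true)
        dur = grammar.durations[syl][0]
        dt = dur / n_points
        curve = _se_gp_noise(n_points, p_true, np.full(p_true, within_timescale_s), dt, rng)
        templates[syl] = offset[:, None] + curve
    return templates


def generate_latents(
    annotations: AnnotationTrack,
    spec: RegionSpec,
    templates: dict[str, np.ndarray],
    rng: np.random.Generator,
    dt: float = 0.001,
    duration_s: float | None = None,
) -> np.ndarray:
    """True latent trajectory (p_true x n_bins) on the session timeline.

    Within each annotated interval the template curve is resampled to the
    realized syllable duration; outside vocalization the latent relaxes to 0.
    A smooth per-trial GP perturbation with the region's timescales, scaled
    by ``trial_variability_scale``, is added over the whole timeline.
    """
    if duration_s is None:
        duration_s = annotations.span()[1] + 0.2
    n_bins = int(np.ceil(duration_s / dt))
    x = np.zeros((spec.p_true, n_bins))
    for onset, offset, label in annotations.intervals:
        tmpl = templates.get(label)
        if tmpl is None:
            continue
        if tmpl.shape[0] != spec.p_true:
            raise ValueError(
                f"template for {label!r} has {tmpl.shape[0]} dims, "
                f"expected {spec.p_true}"
            )
        b0, b1 = int(round(onset / dt)), int(round(offset / dt))
        b1 = min(b1, n_bins)
        if b1 <= b0:
            continue
        src = np.linspace(0.0, 1.0, tmpl.shape[1])
        dst = np.linspace(0.0, 1.0, b1 - b0)
        for j in range(spec.p_true):
            x[j, b0:b1] = np.interp(dst, src, tmpl[j])
    # light smoothing for continuity at syllable edges (5 ms)
    x = gaussian_filter1d(x, 0.005 / dt, axis=1, mode="constant")
    if spec.trial_variability_scale > 0:
        x = x + spec.trial_variability_scale * _se_gp_noise(
            n_bins, spec.p_true, spec.timescales_s, dt, rng
        )
    return x


# ---------------------------------------------------------------------------
# Spikes


def calibrate_sparse_offsets(
    spec: RegionSpec,
    latents: np.ndarray,
    peak: float = 0.8,
    quantile: float = 0.9996,
) -> None:
    """Set sparse-unit offsets relative to each unit's own drive distribution.

    Each sparse unit's offset is chosen so only the top ``1 - quantile`` of
    its latent drive crosses the firing threshold, with the drive peak near
    ``peak`` on the square-root-count scale: brief >=100 Hz bursts at the
    preferred latent direction's maxima and near-silence elsewhere — the
    projection-neuron phenotype with a threshold adapted to the input, as
    for real sparse-firing units.
    """
    ids = np.atleast_1d(spec.sparse_ids).astype(int)
    if ids.size == 0:
        return
    proj = spec.C_true[ids] @ latents
    spec.d_true[ids] = peak - np.quantile(proj, quantile, axis=1)


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def generate_spikes(
    latents: np.ndarray,
    spec: RegionSpec,
    rng: np.random.Generator,
    bin_width_s: float = 0.001,
    cluster_id_offset: int = 0,
) -> SpikeSession:
    """Emit a SpikeSession whose counts are driven linearly by the latents.

    Gaussian regime: sqrt-counts ~ N(C x + d, R), squared and rounded to
    non-negative integers (negatives clamped at zero, clamp rate logged).
    Poisson regime: counts ~ Poisson(softplus(C x + d) * bin_width * rate_scale).
    Spike times are placed uniformly within their bin.
    """
    p, n_bins = latents.shape
    if p != spec.p_true:
        raise ValueError(f"latents have {p} dims, spec expects {spec.p_true}")
    drive = spec.C_true @ latents + spec.d_true[:, None]  # (q, n_bins)
    if spec.regime == "gaussian":
        sqrtc = drive + np.sqrt(spec.R_true)[:, None] * rng.standard_normal(drive.shape)
        clamped = np.mean(sqrtc < 0)
        if clamped > 0:
            logger.debug("gaussian regime: clamped %.3f%% of bins at 0", 100 * clamped)
        counts = np.rint(np.clip(sqrtc, 0.0, None) ** 2).astype(int)
    else:
        # softplus drive interpreted as a rate in units of ~100 Hz so tonic
        # units land in the tens-of-Hz range at d ~ 1
        rate_hz = 100.0 * _softplus(drive)
        counts = rng.poisson(rate_hz * bin_width_s)
    clusters = []
    region = "HVC" if spec.label.upper().startswith("HVC") else (
        "RA" if spec.label.upper().startswith("RA") else "UNKNOWN"
    )
    duration = n_bins * bin_width_s
    sparse = set(int(i) for i in np.atleast_1d(spec.sparse_ids))
    for i in range(spec.n_clusters):
        bins = np.nonzero(counts[i])[0]
        times = np.concatenate(
            [
                (b + rng.random(counts[i, b])) * bin_width_s
                for b in bins
            ]
        ) if bins.size else np.empty(0)
        times = np.sort(times)
        times = times[times < duration]
        clusters.append(
            ClusterRecord(
                cluster_id=cluster_id_offset + i,
                region=region,
                quality="SUA",
                putative_type="UNLABELED",
                spike_times=times,
            )
        )
    return SpikeSession(clusters=clusters, duration_s=duration)


def sample_gpfa_trials(
    spec: RegionSpec,
    n_trials: int,
    n_bins: int,
    bin_width_s: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw trials exactly from the latent linear-Gaussian state-space model.

    Latents follow independent unit-variance SE-kernel GPs with the spec's
    timescales; observations are y = C x + d + N(0, R).  Returns
    ``(observations (n_trials, q, T), latents (n_trials, p, T))`` — the
    matched regime for testing parameter recovery.
    """
    p, q = spec.p_true, spec.n_clusters
    t = np.arange(n_bins) * bin_width_s
    dt2 = (t[:, None] - t[None, :]) ** 2
    ys = np.empty((n_trials, q, n_bins))
    xs = np.empty((n_trials, p, n_bins))
    chols = []
    for j in range(p):
        K = np.exp(-dt2 / (2.0 * spec.timescales_s[j] ** 2)) + 1e-9 * np.eye(n_bins)
        chols.append(np.linalg.cholesky(K))
    for n in range(n_trials):
        for j in range(p):
            xs[n, j] = chols[j] @ rng.standard_normal(n_bins)
        noise = np.sqrt(spec.R_true)[:, None] * rng.standard_normal((q, n_bins))
        ys[n] = spec.C_true @ xs[n] + spec.d_true[:, None] + noise
    return ys, xs


# ---------------------------------------------------------------------------
# Audio


@dataclass
class SyllableVoice:
    """Harmonic-stack rule mapping latents to audio, affine per frame.

    Each syllable has a fixed fundamental; the amplitudes of its harmonics
    are affine in two designated latent dimensions (dim 0 tilts the
    spectrum — a brightness/pitch-centroid cue — and dim 1 scales overall
    loudness), so within a syllable the audio frame is an affine function
    of the latent state.
    """

    f0_hz: float
    amps: np.ndarray  # base amplitude per harmonic
    tilt_gain: np.ndarray  # per-harmonic gain on latent dim 0
    loud_gain: np.ndarray  # per-harmonic gain on latent dim 1

    @property
    def n_harmonics(self) -> int:
        return len(self.amps)


def default_voices(grammar: SongGrammar, rng: np.random.Generator) -> dict[str, SyllableVoice]:
    voices = {}
    h = np.arange(1, 4)
    for k, syl in enumerate(grammar.syllables):
        voices[syl] = SyllableVoice(
            f0_hz=700.0 + 450.0 * k + 50.0 * rng.random(),
            amps=0.5 / h,
            tilt_gain=0.08 * (h - 2.0),
            loud_gain=0.10 / h,
        )
    return voices


def generate_audio(
    annotations: AnnotationTrack,
    latents: np.ndarray,
    voices: dict[str, SyllableVoice],
    sample_rate: int = 19200,
    codec_frame_rate: int = 150,
    latent_dt: float = 0.001,
    duration_s: float | None = None,
) -> np.ndarray:
    """Synthesize a waveform whose spectral content is affine in latents 0/1.

    Synthesis is frame-locked: the signal is built from consecutive
    ``sample_rate / codec_frame_rate``-sample frames, and a frame whose
    center falls inside an annotated syllable is a Hann-windowed harmonic
    stack at the syllable's fundamental, with per-harmonic amplitudes
    affine in the latent state at the frame center (phase restarts each
    frame).  Each voiced frame is therefore an affine function of the
    instantaneous latent given the syllable, so a frame-level decoder can
    in principle reconstruct the song exactly.  Silence between intervals
    is exactly zero.
    """
    if sample_rate % codec_frame_rate != 0:
        raise ValueError(
            f"sample rate {sample_rate} not divisible by frame rate {codec_frame_rate}"
        )
    frame = sample_rate // codec_frame_rate
    if duration_s is None:
        duration_s = latents.shape[1] * latent_dt
    n_frames = int(round(duration_s * codec_frame_rate))
    wave = np.zeros(n_frames * frame)
    t_lat = np.arange(latents.shape[1]) * latent_dt
    n_local = np.arange(frame) / sample_rate
    window = np.hanning(frame)
    for onset, offset, label in annotations.intervals:
        voice = voices.get(label)
        if voice is None:
            continue
        k0 = int(np.ceil(onset * codec_frame_rate - 0.5))
        k1 = int(np.floor(offset * codec_frame_rate - 0.5)) + 1
        harmonics = np.stack(
            [
                np.sin(2.0 * np.pi * h * voice.f0_hz * n_local)
                for h in range(1, voice.n_harmonics + 1)
            ]
        )
        for k in range(max(k0, 0), min(k1, n_frames)):
            tc = (k + 0.5) / codec_frame_rate
            if not (onset <= tc < offset):
                continue
            x0 = np.interp(tc, t_lat, latents[0])
            x1 = np.interp(tc, t_lat, latents[1]) if latents.shape[0] > 1 else 0.0
            amps = voice.amps + voice.tilt_gain * x0 + voice.loud_gain * x1
            wave[k * frame : (k + 1) * frame] = (amps @ harmonics) * window
    peak = np.abs(wave).max()
    if peak > 1.0:
        wave /= peak
    return wave


# ---------------------------------------------------------------------------
# Artifacts


def inject_artifacts(
    session: SpikeSession,
    n_events: int,
    magnitude: int,
    rng: np.random.Generator,
    bin_width_s: float = 0.001,
) -> tuple[SpikeSession, np.ndarray]:
    """Add cross-channel motion-artifact events: at ``n_events`` random 1 ms
    bins every cluster receives ``magnitude`` extra spikes.  Returns the
    contaminated session and the artifact bin indices (for recovery scoring).
    """
    n_bins = int(session.duration_s / bin_width_s)
    if n_events > n_bins:
        raise ValueError(f"n_events {n_events} exceeds session bins {n_bins}")
    if n_events == 0:
        return session, np.empty(0, dtype=int)
    event_bins = np.sort(rng.choice(n_bins, size=n_events, replace=False))
    clusters = []
    for c in session.clusters:
        extra = np.concatenate(
            [(b + rng.random(magnitude)) * bin_width_s for b in event_bins]
        )
        times = np.sort(np.concatenate([c.spike_times, extra]))
        clusters.append(
            ClusterRecord(
                cluster_id=c.cluster_id,
                region=c.region,
                quality=c.quality,
                putative_type=c.putative_type,
                spike_times=times,
            )
        )
    return (
        SpikeSession(clusters=clusters, duration_s=session.duration_s,
                     sample_rate_hint=session.sample_rate_hint),
        event_bins,
    )


# ---------------------------------------------------------------------------
# Full sessions


@dataclass
class GroundTruth:
    """Everything needed to score recovery of a simulated session."""

    grammar: SongGrammar
    annotations: AnnotationTrack
    specs: dict[str, RegionSpec]
    templates: dict[str, dict[str, np.ndarray]]
    latents: dict[str, np.ndarray]  # region label -> (p_true, n_bins) at latent_dt
    latent_dt: float
    voices: dict[str, SyllableVoice] | None = None
    audio_sample_rate: int = 19200


def simulate_session(
    seed: int,
    n_bouts: int = 12,
    grammar: SongGrammar | None = None,
    region_configs: dict | None = None,
    regime: str = "gaussian",
    latent_dt: float = 0.001,
    with_audio: bool = True,
    sample_rate: int = 19200,
    template_separation: float = 2.0,
) -> tuple[SpikeSession, AnnotationTrack, np.ndarray | None, GroundTruth]:
    """Generate a complete synthetic session (spikes, annotations, audio).

    Default region scales mirror typical premotor/motor yields (an HVC-like
    population of 60 clusters with a large sparse-firing fraction and larger
    trial-to-trial latent variability, and an RA-like population of 110
    tonic clusters with tighter trajectories).
    """
    rng = np.random.default_rng(seed)
    grammar = grammar or default_grammar()
    if region_configs is None:
        region_configs = {
            "HVC": dict(n_clusters=60, p_true=4, trial_variability_scale=0.45,
                        sparse_fraction=0.5),
            "RA": dict(n_clusters=110, p_true=4, trial_variability_scale=0.15,
                       sparse_fraction=0.0),
        }
    annotations = sample_song_sequence(grammar, n_bouts, rng)
    # snap to the latent grid so spike times cannot exceed the duration
    duration = int(np.ceil((annotations.span()[1] + 0.5) / latent_dt)) * latent_dt

    specs: dict[str, RegionSpec] = {}
    templates: dict[str, dict[str, np.ndarray]] = {}
    latents: dict[str, np.ndarray] = {}
    all_clusters: list[ClusterRecord] = []
    offset = 0
    for label, cfg in region_configs.items():
        cfg = dict(cfg)
        spec = make_region_spec(
            label=label,
            n_clusters=cfg.pop("n_clusters"),
            p_true=cfg.pop("p_true", 4),
            rng=rng,
            regime=regime,
            **cfg,
        )
        specs[label] = spec
        templates[label] = sample_syllable_templates(
            grammar, spec.p_true, rng, separation=template_separation
        )
        latents[label] = generate_latents(
            annotations, spec, templates[label], rng, dt=latent_dt, duration_s=duration
        )
        calibrate_sparse_offsets(spec, latents[label])
        region_session = generate_spikes(
            latents[label], spec, rng, bin_width_s=latent_dt, cluster_id_offset=offset
        )
        all_clusters.extend(region_session.clusters)
        offset += spec.n_clusters

    session = SpikeSession(clusters=all_clusters, duration_s=duration)
    voices = default_voices(grammar, rng) if with_audio else None
    wave = None
    if with_audio:
        first = next(iter(latents))
        wave = generate_audio(
            annotations, latents[first], voices, sample_rate=sample_rate,
            latent_dt=latent_dt, duration_s=duration,
        )
    gt = GroundTruth(
        grammar=grammar,
        annotations=annotations,
        specs=specs,
        templates=templates,
        latents=latents,
        latent_dt=latent_dt,
        voices=voices,
        audio_sample_rate=sample_rate,
    )
    return session, annotations, wave, gt
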