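"""Ground-truth generator: grammar walks, latents, spikes, audio, artifacts."""

import numpy as np
import pytest

from songlat.io import AnnotationTrack
from songlat.metrics import latent_dispersion
from songlat.simulate import (
    GrammarError,
    SongGrammar,
    default_voices,
    generate_audio,
    generate_latents,
    generate_spikes,
    inject_artifacts,
    make_region_spec,
    sample_song_sequence,
    sample_syllable_templates,
    simulate_session,
)

SILENCE = "silence"


def chain_grammar():
    return SongGrammar(
        syllables=["S1", "S2", "S3"],
        durations={s: (0.05, 0.0) for s in ["S1", "S2", "S3"]},
        transitions={
            "S1": {"S2": 1.0},
            "S2": {"S3": 1.0},
            "S3": {SILENCE: 1.0},
        },
        start="S1",
    )


class TestGrammar:
    def test_deterministic_chain_one_bout(self, rng):
        track = sample_song_sequence(chain_grammar(), 1, rng)
        assert track.labels == ["S1", "S2", "S3"]

    def test_row_not_summing_to_one_rejected(self):
        with pytest.raises(GrammarError, match="sums to"):
            SongGrammar(
                syllables=["A"],
                durations={"A": (0.05, 0.0)},
                transitions={"A": {SILENCE: 0.9}},
                start="A",
            )

    def test_absorbing_non_silence_state_rejected(self):
        with pytest.raises(GrammarError, match="absorbing"):
            SongGrammar(
                syllables=["A"],
                durations={"A": (0.05, 0.0)},
                transitions={"A": {"A": 1.0}},
                start="A",
            )

    def test_branch_frequencies_converge_to_matrix(self, rng):
        # P(S1->A)=0.5, P(S1->B)=0.5; binomial SE over ~10^4 transitions
        g = SongGrammar(
            syllables=["S1", "A", "B"],
            durations={s: (0.01, 0.0) for s in ["S1", "A", "B"]},
            transitions={
                "S1": {"A": 0.5, "B": 0.5},
                "A": {SILENCE: 1.0},
                "B": {SILENCE: 1.0},
            },
            start="S1",
        )
        assert g.branch_points == ["S1"]
        track = sample_song_sequence(g, 10_000, rng)
        labels = track.labels
        succ = [labels[i + 1] for i in range(len(labels) - 1) if labels[i] == "S1"]
        p_a = succ.count("A") / len(succ)
        assert abs(p_a - 0.5) < 0.015  # ~3 binomial SEs at n=10^4


class TestLatents:
    def test_zero_variability_reproduces_template_exactly_across_trials(self, rng):
        g = chain_grammar()
        spec = make_region_spec("RA", 10, 3, rng, trial_variability_scale=0.0)
        templates = sample_syllable_templates(g, 3, rng)
        ann = sample_song_sequence(g, 4, rng)
        x = generate_latents(ann, spec, templates, rng)
        # every rendition of S2 has an identical latent segment
        segs = []
        for a, b, lab in ann.intervals:
            if lab == "S2":
                b0, b1 = int(round(a / 0.001)), int(round(b / 0.001))
                segs.append(x[:, b0:b1])
        assert len(segs) >= 2
        for s in segs[1:]:
            assert np.allclose(s, segs[0], atol=1e-12)

    def test_dispersion_grows_with_variability_scale(self, rng):
        g = chain_grammar()
        templates = sample_syllable_templates(g, 3, rng)
        disps = {}
        for scale in (0.1, 0.5):
            spec = make_region_spec(
                "RA", 10, 3, rng, trial_variability_scale=scale
            )
            trials = []
            for _ in range(20):
                ann = AnnotationTrack([(0.05, 0.10, "S1"), (0.11, 0.16, "S2"),
                                       (0.17, 0.22, "S3")])
                x = generate_latents(ann, spec, templates, rng, duration_s=0.25)
                trials.append(x)
            disps[scale] = latent_dispersion(np.stack(trials)).mean
        assert disps[0.5] > disps[0.1]

    def test_perturbation_autocorrelation_decays_on_stated_timescale(self, rng):
        from songlat.simulate import _se_gp_noise

        tau, dt, n = 0.05, 0.001, 200_000
        x = _se_gp_noise(n, 1, np.array([tau]), dt, rng)[0]
        assert abs(x.std() - 1.0) < 0.05
        for lag_s in (0.025, 0.05, 0.1):
            lag = int(lag_s / dt)
            emp = np.corrcoef(x[:-lag], x[lag:])[0, 1]
            expected = np.exp(-(lag_s**2) / (2 * tau**2))
            assert abs(emp - expected) < 0.05

    def test_template_dimension_mismatch_raises(self, rng):
        g = chain_grammar()
        spec = make_region_spec("RA", 10, 3, rng)
        bad = sample_syllable_templates(g, 2, rng)
        ann = sample_song_sequence(g, 1, rng)
        with pytest.raises(ValueError, match="dims"):
            generate_latents(ann, spec, bad, rng)


class TestSpikes:
    def test_poisson_regime_mean_matches_softplus_rate(self, rng):
        # C = 0: count mean per bin is 100*softplus(d)*bin_width
        spec = make_region_spec("RA", 1, 2, rng, regime="poisson", noise_scale=0.05)
        spec.C_true = np.zeros_like(spec.C_true)
        spec.d_true = np.array([0.3])
        n_bins = 100_000
        latents = np.zeros((2, n_bins))
        session = generate_spikes(latents, spec, rng)
        rate = 100.0 * np.logaddexp(0.0, 0.3) * 0.001
        observed = session.clusters[0].n_spikes / n_bins
        se = np.sqrt(rate / n_bins)
        assert abs(observed - rate) < 3 * se

    def test_gaussian_regime_deterministic_when_noise_vanishes(self, rng):
        spec = make_region_spec("RA", 5, 2, rng)
        spec.R_true = np.full(5, 1e-12)
        latents = np.tile(np.array([[1.0], [0.5]]), (1, 50))
        s1 = generate_spikes(latents, spec, np.random.default_rng(1))
        s2 = generate_spikes(latents, spec, np.random.default_rng(2))
        c1 = [c.n_spikes for c in s1.clusters]
        c2 = [c.n_spikes for c in s2.clusters]
        assert c1 == c2  # counts fixed by the latents; only within-bin jitter differs

    def test_sparse_unit_is_classified_as_projection_neuron(self, rng):
        from songlat.preprocess import classify_hvc_units

        # long motif (0.6 s vocal time) so a single per-motif burst keeps the
        # mean song-period rate in the low Hz, as for projection neurons
        syls = [f"S{k}" for k in range(1, 7)]
        g = SongGrammar(
            syllables=syls,
            durations={s: (0.1, 0.0) for s in syls},
            transitions={
                **{f"S{k}": {f"S{k + 1}": 1.0} for k in range(1, 6)},
                "S6": {SILENCE: 1.0},
            },
            start="S1",
        )
        templates = sample_syllable_templates(g, 3, rng)
        spec = make_region_spec("HVC", 1, 3, rng, sparse_fraction=1.0,
                                trial_variability_scale=0.1)
        # drive aligned with the S2 template; offset chosen so only the top
        # ~0.1% of drive bins emit spikes: brief bursts at the template
        # maximum, near-silence elsewhere
        ann = sample_song_sequence(g, 20, rng)
        x = generate_latents(ann, spec, templates, rng)
        tdir = templates["S2"].mean(axis=1)
        spec.C_true = (2.5 * tdir / np.linalg.norm(tdir))[None, :]
        proj = (spec.C_true @ x)[0]
        spec.d_true = np.array([0.72 - np.quantile(proj, 0.999)])
        session = generate_spikes(x, spec, rng)
        labeled = classify_hvc_units(session, ann)
        from songlat.preprocess import _song_intervals

        rate = labeled.clusters[0].mean_rate(_song_intervals(ann, None))
        assert rate < 5.0
        assert labeled.clusters[0].putative_type == "HVCpn"


class TestAudio:
    def test_silence_is_exactly_zero(self, rng):
        g = chain_grammar()
        voices = default_voices(g, rng)
        ann = AnnotationTrack([(0.1, 0.2, "S1")])
        lat = np.zeros((2, 400))
        wave = generate_audio(ann, voices=voices, latents=lat, duration_s=0.4)
        sr = 19200
        assert np.all(wave[: int(0.095 * sr)] == 0)
        assert np.all(wave[int(0.21 * sr):] == 0)
        assert np.abs(wave[int(0.12 * sr): int(0.18 * sr)]).max() > 0

    def test_fixed_latents_give_fft_peak_at_fundamental(self, rng):
        g = chain_grammar()
        voices = default_voices(g, rng)
        ann = AnnotationTrack([(0.0, 0.512, "S1")])
        lat = np.zeros((2, 600))
        wave = generate_audio(ann, voices=voices, latents=lat, duration_s=0.512)
        sr = 19200
        spec = np.abs(np.fft.rfft(wave))
        freqs = np.fft.rfftfreq(len(wave), 1 / sr)
        peak = freqs[np.argmax(spec)]
        assert abs(peak - voices["S1"].f0_hz) < 160  # within one frame-rate sideband

    def test_different_syllables_have_distinct_band_energy(self, rng):
        g = chain_grammar()
        voices = default_voices(g, rng)
        lat = np.zeros((2, 600))
        sr = 19200
        waves = {}
        for syl in ("S1", "S3"):
            ann = AnnotationTrack([(0.0, 0.4, syl)])
            waves[syl] = generate_audio(ann, voices=voices, latents=lat, duration_s=0.4)
        for syl in ("S1", "S3"):
            spec = np.abs(np.fft.rfft(waves[syl]))
            freqs = np.fft.rfftfreq(len(waves[syl]), 1 / sr)
            f_own, f_other = voices[syl].f0_hz, voices["S3" if syl == "S1" else "S1"].f0_hz
            e_own = spec[np.abs(freqs - f_own) < 200].sum()
            e_other = spec[np.abs(freqs - f_other) < 200].sum()
            assert e_own > 3 * e_other

    def test_incompatible_frame_rate_rejected(self, rng):
        g = chain_grammar()
        with pytest.raises(ValueError, match="divisible"):
            generate_audio(
                AnnotationTrack([(0.0, 0.1, "S1")]),
                latents=np.zeros((2, 100)),
                voices=default_voices(g, rng),
                sample_rate=19000,
            )


class TestArtifacts:
    def test_zero_events_leaves_session_unchanged(self, small_session, rng):
        session = small_session[0]
        out, bins = inject_artifacts(session, 0, 3, rng)
        assert bins.size == 0
        assert out is session

    def test_injected_counts_arithmetic(self, rng):
        spec = make_region_spec("RA", 50, 2, rng)
        session = generate_spikes(np.zeros((2, 2000)), spec, rng)
        from songlat.preprocess import bin_spikes

        base = bin_spikes(session, 0.001).sum(axis=0)
        out, bins = inject_artifacts(session, 10, 3, rng)
        contaminated = bin_spikes(out, 0.001).sum(axis=0)
        assert len(bins) == 10
        assert np.all(contaminated[bins] - base[bins] == 150)

    def test_too_many_events_rejected(self, small_session, rng):
        session = small_session[0]
        with pytest.raises(ValueError, match="exceeds"):
            inject_artifacts(session, 10**9, 1, rng)


class TestReproducibility:
    def test_simulation_deterministic_given_seed(self):
        a = simulate_session(seed=3, n_bouts=2, with_audio=True,
                             region_configs={"RA": dict(n_clusters=8, p_true=2)})
        b = simulate_session(seed=3, n_bouts=2, with_audio=True,
                             region_configs={"RA": dict(n_clusters=8, p_true=2)})
        assert a[1].intervals == b[1].intervals
        assert np.array_equal(a[2], b[2])
        for ca, cb in zip(a[0].clusters, b[0].clusters):
            assert np.array_equal(ca.spike_times, cb.spike_times)
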