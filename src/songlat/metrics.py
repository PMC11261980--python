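"""Manifold-level statistics.

Latent dispersion quantifies trial-to-trial spread of latent trajectories
around the trial-mean trajectory, normalized by the overall extent of the
manifold so the number is comparable across manifolds:

    sigma_n = (1/T) sum_t ||x_{n,t} - mu_t|| / ||mu_t - mu_bar||

with mu_t the trial-average state and mu_bar its time average (per-bin
ratio averaged over bins; the un-averaged sum and ratio-of-sums groupings
are available behind ``mode``).

The distance analysis collects pairwise Euclidean distances between latent
states at syllable onsets: the same-syllable distribution (SSD) is the
reference, both SSD and the dissimilar-syllable distribution (DSD) are
z-scored against it, separability is tested with Welch's t-test within a
manifold, and a paired Wilcoxon signed-rank test compares normalized DSDs
between two manifolds.

The bootstrap contrast refits the state-space model on random 90%
sub-samples of each named population and compares dispersion and shared
variance across populations with a one-way ANOVA followed by Tukey's HSD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gpfa import GPFA, LatentTrajectorySet, sqrt_transform, variance_explained
from .io import AnnotationTrack, TrialSet

logger = logging.getLogger("songlat")


@dataclass
class DispersionResult:
    per_trial: np.ndarray  # sigma_n, one per trial
    n_factors: int
    population: str = ""
    n_degenerate_bins: int = 0

    @property
    def mean(self) -> float:
        return float(self.per_trial.mean())

    @property
    def sd(self) -> float:
        return float(self.per_trial.std(ddof=1)) if self.per_trial.size > 1 else 0.0


def latent_dispersion(
    latents: LatentTrajectorySet | np.ndarray,
    mode: str = "per-bin-mean",
    population: str = "",
    eps_rel: float = 1e-9,
) -> DispersionResult:
    """Normalized latent dispersion per trial (requires equal trial lengths).

    ``mode``: 'per-bin-mean' (time-average of per-bin normalized deviations,
    the default), 'per-bin-sum' (same without the 1/T), or 'ratio-of-sums'
    (sum of deviations over sum of denominators).
    """
    if isinstance(latents, LatentTrajectorySet):
        X = latents.stacked(orthonormalized=True)
    else:
        X = np.asarray(latents, dtype=float)
    if X.ndim != 3:
        raise ValueError("latents must be (n_trials, p, T)")
    n, p, T = X.shape
    if n < 2:
        raise ValueError("dispersion requires >= 2 trials")
    mu_t = X.mean(axis=0)  # (p, T)
    mu_bar = mu_t.mean(axis=1, keepdims=True)  # (p, 1)
    dev = np.linalg.norm(X - mu_t[None], axis=1)  # (n, T)
    denom = np.linalg.norm(mu_t - mu_bar, axis=0)  # (T,)
    scale = np.linalg.norm(mu_t, axis=0).max()
    ok = denom > eps_rel * max(scale, 1.0)
    n_degenerate = int(T - ok.sum())
    if not ok.any():
        raise ValueError("all bins have degenerate mean-trajectory denominators")
    if mode == "ratio-of-sums":
        sigma = dev[:, ok].sum(axis=1) / denom[ok].sum()
    elif mode == "per-bin-sum":
        sigma = (dev[:, ok] / denom[None, ok]).sum(axis=1)
    elif mode == "per-bin-mean":
        sigma = (dev[:, ok] / denom[None, ok]).mean(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DispersionResult(
        per_trial=sigma, n_factors=p, population=population,
        n_degenerate_bins=n_degenerate,
    )


# ---------------------------------------------------------------------------
# Bootstrap + ANOVA/Tukey population contrast


@dataclass
class BootstrapContrast:
    samples: pd.DataFrame  # columns: population, boot, dispersion, shared_fraction
    anova: dict[str, tuple[float, float]]  # metric -> (F, p)
    tukey: dict[str, pd.DataFrame]  # metric -> pairwise table

    def tukey_p(self, metric: str, pop_a: str, pop_b: str) -> float:
        t = self.tukey[metric]
        row = t[
            ((t.group_a == pop_a) & (t.group_b == pop_b))
            | ((t.group_a == pop_b) & (t.group_b == pop_a))
        ]
        return float(row.p_value.iloc[0])


def bootstrap_contrast(
    trials: TrialSet,
    populations: dict[str, list[int]],
    rng: np.random.Generator,
    n_factors: int = 12,
    n_boot: int = 10,
    frac: float = 0.9,
    gpfa_kwargs: dict | None = None,
) -> BootstrapContrast:
    """Refit the state-space model on cluster sub-samples and compare groups.

    For each named population, draws ``n_boot`` random subsets of ``frac`` of
    its clusters, refits a ``n_factors``-dimensional model on each, and
    computes mean latent dispersion and the shared-variance fraction.
    Metrics are compared across populations with one-way ANOVA and Tukey's
    HSD (studentized-range distribution).
    """
    gpfa_kwargs = dict(gpfa_kwargs or {})
    gpfa_kwargs.setdefault("max_iter", 40)
    gpfa_kwargs.setdefault("tol", 1e-6)
    rows = []
    for name, ids in populations.items():
        n_keep = int(round(frac * len(ids)))
        if n_keep < n_factors + 1:
            raise ValueError(
                f"population {name!r}: {frac:.0%} subsample ({n_keep}) smaller "
                f"than n_factors+1 ({n_factors + 1})"
            )
        for b in range(n_boot):
            keep = list(rng.choice(ids, size=n_keep, replace=False))
            sub = sqrt_transform(trials.subset_clusters(keep))
            model = GPFA(n_factors=n_factors, **gpfa_kwargs).fit(sub)
            lat = model.transform(sub)
            disp = latent_dispersion(lat, population=name)
            ve = variance_explained(model)
            rows.append(
                {
                    "population": name,
                    "boot": b,
                    "dispersion": disp.mean,
                    "shared_fraction": ve["shared_fraction"],
                }
            )
    samples = pd.DataFrame(rows)
    anova: dict[str, tuple[float, float]] = {}
    tukey: dict[str, pd.DataFrame] = {}
    names = list(populations)
    for metric in ("dispersion", "shared_fraction"):
        groups = [samples.loc[samples.population == nm, metric].to_numpy() for nm in names]
        F, p = stats.f_oneway(*groups)
        anova[metric] = (float(F), float(p))
        res = stats.tukey_hsd(*groups)
        pairs = []
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                pairs.append(
                    {
                        "group_a": names[a],
                        "group_b": names[b],
                        "mean_diff": float(groups[a].mean() - groups[b].mean()),
                        "p_value": float(res.pvalue[a, b]),
                    }
                )
        tukey[metric] = pd.DataFrame(pairs)
    return BootstrapContrast(samples=samples, anova=anova, tukey=tukey)


# ---------------------------------------------------------------------------
# Syllable-onset state distances


def syllable_onset_states(
    latents: LatentTrajectorySet,
    trial_t0_s: np.ndarray,
    annotations: AnnotationTrack,
    syllable_labels: set[str] | None = None,
) -> tuple[np.ndarray, list[str], list[int]]:
    """Latent state at the bin containing each syllable onset, per rendition.

    Returns (states (n, p), syllable labels, rendition indices).  Onsets on a
    bin edge land in the later bin (half-open convention); onsets outside a
    trial's span are skipped and logged.
    """
    w = latents.bin_width_s
    src = latents.orthonormalized or latents.trajectories
    states, labels, rends = [], [], []
    for n, t0 in enumerate(np.asarray(trial_t0_s, dtype=float)):
        X = src[n]
        T = X.shape[1]
        for onset, _, lab in annotations.intervals:
            if syllable_labels is not None and lab not in syllable_labels:
                continue
            b = int(np.floor((onset - t0) / w + 1e-9))
            if onset < t0 - 1e-9 or b >= T:
                continue
            states.append(X[:, b])
            labels.append(lab)
            rends.append(n)
    expected = len(trial_t0_s) * (
        len(syllable_labels) if syllable_labels is not None else 0
    )
    if expected and len(states) < expected:
        logger.info("collected %d onset states (expected up to %d)", len(states), expected)
    return np.asarray(states), labels, rends


@dataclass
class DistanceDistributions:
    """Same-/dissimilar-syllable distance distributions for one manifold."""

    ssd: np.ndarray
    dsd: np.ndarray
    z_ssd: np.ndarray
    z_dsd: np.ndarray
    dsd_keys: list = field(default_factory=list)  # pairing index for matching
    welch_stat: float = np.nan
    welch_p: float = np.nan


def distance_analysis(
    states: np.ndarray,
    labels: list[str],
    renditions: list[int] | None = None,
) -> DistanceDistributions:
    """Pairwise-distance separability of syllable states within a manifold.

    SSD collects distances between states of the same syllable across
    renditions, DSD between different syllables; both are z-scored against
    SSD (so mean(Z_SSD)=0, sd(Z_SSD)=1 by construction) and compared with
    Welch's t-test.  Each DSD entry carries a pairing key (syllable pair +
    rendition pair) so distributions from two manifolds computed on the same
    behavior can be matched one-to-one.
    """
    states = np.asarray(states, dtype=float)
    n = states.shape[0]
    if renditions is None:
        renditions = list(range(n))
    labs = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("need >= 2 distinct syllables")
    ssd, dsd, dsd_keys = [], [], []
    singleton = {
        lab for lab in set(labels) if int((labs == lab).sum()) < 2
    }
    for lab in singleton:
        logger.info("syllable %r has a single rendition; contributes nothing to SSD", lab)
    for i in range(n):
        for j in range(i + 1, n):
            dist = float(np.linalg.norm(states[i] - states[j]))
            if labs[i] == labs[j]:
                ssd.append(dist)
            else:
                dsd.append(dist)
                key = tuple(
                    sorted([(str(labs[i]), renditions[i]), (str(labs[j]), renditions[j])])
                )
                dsd_keys.append(key)
    ssd, dsd = np.asarray(ssd), np.asarray(dsd)
    if ssd.size < 2:
        raise ValueError("need >= 2 same-syllable distances to form the reference")
    mu, sd = ssd.mean(), ssd.std(ddof=0)
    z_ssd = (ssd - mu) / sd
    z_dsd = (dsd - mu) / sd
    stat, p = stats.ttest_ind(z_dsd, z_ssd, equal_var=False)
    return DistanceDistributions(
        ssd=ssd, dsd=dsd, z_ssd=z_ssd, z_dsd=z_dsd, dsd_keys=dsd_keys,
        welch_stat=float(stat), welch_p=float(p),
    )


@dataclass
class PairedWilcoxonResult:
    statistic: float
    p_value: float
    median_diff: float  # median of (A - B) paired normalized distances
    n_pairs: int


def between_manifold_test(
    dist_a: DistanceDistributions, dist_b: DistanceDistributions
) -> PairedWilcoxonResult:
    """Wilcoxon signed-rank test on paired normalized dissimilar-syllable
    distances of two manifolds (matched one-to-one via the pairing index)."""
    keys_a = {k: i for i, k in enumerate(dist_a.dsd_keys)}
    keys_b = {k: i for i, k in enumerate(dist_b.dsd_keys)}
    missing = set(keys_a).symmetric_difference(keys_b)
    if missing:
        raise ValueError(
            f"{len(missing)} unmatched distance pairs, e.g. {list(missing)[:3]}"
        )
    order = sorted(keys_a)
    a = dist_a.z_dsd[[keys_a[k] for k in order]]
    b = dist_b.z_dsd[[keys_b[k] for k in order]]
    diff = a - b
    if np.allclose(diff, 0.0):
        return PairedWilcoxonResult(0.0, 1.0, 0.0, len(diff))
    stat, p = stats.wilcoxon(a, b)
    return PairedWilcoxonResult(
        float(stat), float(p), float(np.median(diff)), len(diff)
    )
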