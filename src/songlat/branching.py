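"""Predicting probabilistic syllable transitions from latent states.

At a "branch point" — a syllable whose successor is probabilistic — the
identity of the upcoming transition is decoded from the latent state at
each time bin around the end of the branch syllable, using Fisher linear
discriminant analysis with uniform class priors (1/C) and a shared,
shrinkage-regularized covariance.  A bootstrap over random train/test
splits yields the time course of the mean correct-class posterior with
percentile confidence intervals; under label shuffling the posterior sits
at the 1/C prior at every bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .io import AnnotationTrack

logger = logging.getLogger("songlat")

SILENCE = "silence"


def identify_branch_points(
    annotations: AnnotationTrack,
    min_count: int = 2,
    gap_tol_s: float = 0.15,
) -> tuple[list[str], dict[str, dict[str, int]]]:
    """Empirical successor counts per syllable and the branch-point list.

    The successor of an interval is the label of the next interval if it
    starts within ``gap_tol_s``, else 'silence'.  A syllable is a branch
    point when >= 2 successors each occur at least ``min_count`` times.
    """
    succ: dict[str, dict[str, int]] = {}
    ivs = annotations.intervals
    for k, (a, b, lab) in enumerate(ivs):
        nxt = SILENCE
        if k + 1 < len(ivs) and ivs[k + 1][0] - b <= gap_tol_s:
            nxt = ivs[k + 1][2]
        succ.setdefault(lab, {})
        succ[lab][nxt] = succ[lab].get(nxt, 0) + 1
    branch = [
        lab
        for lab, row in succ.items()
        if sum(1 for c in row.values() if c >= min_count) >= 2
    ]
    if not branch:
        logger.info("no branch points found")
    return sorted(branch), succ


@dataclass
class BranchDataset:
    """Latent segments aligned to the end of the branch syllable.

    ``segments[n]`` is (p, T); ``labels[n]`` names the transition that
    followed; ``time_s`` is the time axis relative to the alignment point.
    """

    segments: np.ndarray  # (N, p, T)
    labels: list[str]
    time_s: np.ndarray
    branch_syllable: str = ""

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        if len(self.labels) != self.segments.shape[0]:
            raise ValueError("one label per rendition required")
        if len(set(self.labels)) < 2:
            raise ValueError("branch dataset needs >= 2 transition classes")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def build_branch_dataset(
    model,
    counts_1ms: np.ndarray,
    annotations: AnnotationTrack,
    branch_syllable: str,
    window_s: tuple[float, float] = (-0.1, 0.1),
    rebin_width_s: float = 0.015,
    base_bin_s: float = 0.001,
    gap_tol_s: float = 0.15,
) -> BranchDataset:
    """Cut latent segments around each branch-syllable ending.

    Segments of session counts in ``window_s`` relative to each rendition's
    branch-syllable offset are rebinned, square-rooted and passed through
    the fitted state-space model; the transition class is the label that
    follows (or 'silence').
    """
    from .gpfa import GPFA  # noqa: F401  (type only)

    factor = int(round(rebin_width_s / base_bin_s))
    t_bins = int(round((window_s[1] - window_s[0]) / rebin_width_s))
    segs, labels = [], []
    ivs = annotations.intervals
    n_total = counts_1ms.shape[1]
    for k, (a, b, lab) in enumerate(ivs):
        if lab != branch_syllable:
            continue
        nxt = SILENCE
        if k + 1 < len(ivs) and ivs[k + 1][0] - b <= gap_tol_s:
            nxt = ivs[k + 1][2]
        b0 = int(round((b + window_s[0]) / base_bin_s))
        b1 = b0 + t_bins * factor
        if b0 < 0 or b1 > n_total:
            logger.info("branch rendition at %.3f s outside session; skipped", b)
            continue
        seg = counts_1ms[:, b0:b1]
        seg = seg.reshape(seg.shape[0], t_bins, factor).sum(axis=2)
        segs.append(np.sqrt(seg))
        labels.append(nxt)
    if not segs:
        raise ValueError(f"no renditions of branch syllable {branch_syllable!r}")
    lat = model.transform([np.asarray(s, dtype=float) for s in segs])
    src = lat.orthonormalized or lat.trajectories
    time_s = window_s[0] + (np.arange(t_bins) + 0.5) * rebin_width_s
    return BranchDataset(
        segments=np.stack(src, axis=0),
        labels=labels,
        time_s=time_s,
        branch_syllable=branch_syllable,
    )


def fit_lda_posterior(
    train_states: np.ndarray,
    train_labels: list[str],
    query_states: np.ndarray,
    shrinkage: str | float = "auto",
) -> tuple[np.ndarray, list[str]]:
    """Class posteriors at query states under a uniform-prior Gaussian LDA.

    Shared covariance with Ledoit-Wolf analytic shrinkage (per-bin sample
    sizes are small); rows of the returned posterior matrix sum to 1.
    """
    classes = sorted(set(train_labels))
    priors = np.full(len(classes), 1.0 / len(classes))
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage, priors=priors)
    lda.fit(np.asarray(train_states, dtype=float), train_labels)
    post = lda.predict_proba(np.atleast_2d(np.asarray(query_states, dtype=float)))
    order = [list(lda.classes_).index(c) for c in classes]
    return post[:, order], classes


@dataclass
class BranchResult:
    time_s: np.ndarray
    mean_posterior: np.ndarray  # per bin, mean correct-class posterior
    ci_low: np.ndarray
    ci_high: np.ndarray
    prior: float  # 1 / n_classes
    n_boot: int
    per_run: np.ndarray  # (n_boot, T)


class BranchTransitionLDA(BaseEstimator):
    """Bootstrap, time-resolved LDA decoder of branch-point transitions.

    Per bootstrap run, a random train/test split constrained to keep at
    least one example of each class in training is drawn (``mode='split'``,
    default 80/20); each held-out rendition's correct-class posterior is
    read out per time bin from an LDA fit at that bin.  ``mode='loo'``
    instead holds out every rendition once per run.  The mean posterior and
    2.5/97.5 percentile CI across runs are reported next to the 1/C prior.
    """

    def __init__(
        self,
        n_boot: int = 1000,
        test_frac: float = 0.2,
        mode: str = "split",
        shrinkage: str | float = "auto",
        shuffle_labels: bool = False,
        random_state: int | None = 0,
    ) -> None:
        self.n_boot = n_boot
        self.test_frac = test_frac
        self.mode = mode
        self.shrinkage = shrinkage
        # permutation null: re-shuffle labels independently in every run
        self.shuffle_labels = shuffle_labels
        self.random_state = random_state

    def fit(self, dataset: BranchDataset, y=None) -> "BranchTransitionLDA":
        rng = np.random.default_rng(self.random_state)
        X = dataset.segments  # (N, p, T)
        base_labels = np.asarray(dataset.labels)
        classes = dataset.classes
        N, _, T = X.shape
        n_test = max(1, int(round(self.test_frac * N)))
        if N - n_test < len(classes):
            raise ValueError(
                f"{N} renditions cannot give a {1 - self.test_frac:.0%} training "
                f"split covering {len(classes)} classes"
            )
        per_run = np.empty((self.n_boot, T))
        for run in range(self.n_boot):
            labels = rng.permutation(base_labels) if self.shuffle_labels else base_labels
            cls_idx = {c: np.nonzero(labels == c)[0] for c in classes}
            if self.mode == "loo":
                test_idx = np.arange(N)
                train_mask = ~np.eye(N, dtype=bool)
            else:
                test_idx = self._constrained_split(rng, labels, cls_idx, n_test, N)
                train_mask = np.ones((len(test_idx), N), dtype=bool)
                train_mask[:, test_idx] = False
            post_correct = np.empty((len(test_idx), T))
            for t in range(T):
                if self.mode == "loo":
                    for k, i in enumerate(test_idx):
                        tr = train_mask[i]
                        post, cl = fit_lda_posterior(
                            X[tr, :, t], list(labels[tr]), X[i, :, t], self.shrinkage
                        )
                        ci = cl.index(labels[i]) if labels[i] in cl else None
                        post_correct[k, t] = post[0, ci] if ci is not None else 0.0
                else:
                    tr = train_mask[0]
                    post, cl = fit_lda_posterior(
                        X[tr, :, t], list(labels[tr]), X[test_idx, :, t], self.shrinkage
                    )
                    for k, i in enumerate(test_idx):
                        post_correct[k, t] = post[k, cl.index(labels[i])]
            per_run[run] = post_correct.mean(axis=0)
        self.result_ = BranchResult(
            time_s=dataset.time_s,
            mean_posterior=per_run.mean(axis=0),
            ci_low=np.percentile(per_run, 2.5, axis=0),
            ci_high=np.percentile(per_run, 97.5, axis=0),
            prior=1.0 / len(classes),
            n_boot=self.n_boot,
            per_run=per_run,
        )
        return self

    @staticmethod
    def _constrained_split(rng, labels, cls_idx, n_test, N):
        """Random test subset leaving >= 1 member of every class in training."""
        for _ in range(1000):
            test = rng.choice(N, size=n_test, replace=False)
            mask = np.ones(N, dtype=bool)
            mask[test] = False
            if all(mask[idx].any() for idx in cls_idx.values()):
                return np.sort(test)
        raise ValueError("could not draw a class-covering train/test split")


def branch_predict(
    dataset: BranchDataset,
    n_boot: int = 1000,
    test_frac: float = 0.2,
    rng: np.random.Generator | int | None = 0,
    mode: str = "split",
    shuffle_labels: bool = False,
) -> BranchResult:
    seed = rng if isinstance(rng, (int, type(None))) else int(rng.integers(2**31))
    est = BranchTransitionLDA(
        n_boot=n_boot, test_frac=test_frac, mode=mode,
        shuffle_labels=shuffle_labels, random_state=seed,
    ).fit(dataset)
    return est.result_
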