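"""Gaussian-Process Factor Analysis (GPFA).

Model: for a trial of T bins, observations y_t in R^q (square-root-
transformed spike counts) relate to latent states x_t in R^p through

    y_t | x_t ~ N(C x_t + d, R),    R diagonal,

with an independent unit-variance Gaussian-process prior per latent
dimension j over time,

    K_j(t1, t2) = (1 - s2) exp(-(t1-t2)^2 / (2 tau_j^2)) + s2 * delta,

where s2 is a small GP noise floor.  C, d, R are estimated by EM with
closed-form M-steps; the timescales tau are updated by bounded numerical
maximization of the expected complete-data log-likelihood (accepted only if
they improve it, so the data log-likelihood is non-decreasing across EM
iterations).  The E-step exploits the Kronecker structure of the joint
posterior: its precision is (Kbar^-1 + I_T kron C' R^-1 C), with Kbar
block-diagonal per latent dimension, so one Cholesky per unique trial
length serves every trial of that length.

Latents are reported as posterior means; the orthonormalized variant
applies the SVD of C (C = U S V'), mapping x to xt = S V' x so that
dimensions are ordered by explained covariance and U gives an orthonormal
basis in observation space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, svd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator
from sklearn.decomposition import FactorAnalysis

from .io import TrialSet, ValidationError

logger = logging.getLogger("songlat")


def sqrt_transform(trials: TrialSet) -> TrialSet:
    """Square-root variance-stabilizing transform of spike counts.

    Guarded by ``sqrt_transformed`` so it cannot be applied twice.
    """
    if trials.sqrt_transformed:
        raise ValidationError("TrialSet already sqrt-transformed")
    if np.any(trials.counts < 0):
        raise ValidationError("negative counts")
    return TrialSet(
        counts=np.sqrt(trials.counts),
        bin_width_s=trials.bin_width_s,
        cluster_ids=list(trials.cluster_ids),
        trial_t0_s=trials.trial_t0_s,
        alignment_event=trials.alignment_event,
        sqrt_transformed=True,
    )


@dataclass
class LatentTrajectorySet:
    """Per-trial posterior latent trajectories.

    ``trajectories[n]`` is (p, T_n); ``orthonormalized[n]`` the same states
    in the SVD-ordered basis (dimensions sorted by decreasing explained
    covariance); ``basis`` the orthonormal observation-space basis U.
    """

    trajectories: list[np.ndarray]
    bin_width_s: float
    orthonormalized: list[np.ndarray] = field(default_factory=list)
    basis: np.ndarray | None = None
    singular_values: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trajectories)

    @property
    def n_factors(self) -> int:
        return self.trajectories[0].shape[0]

    def stacked(self, orthonormalized: bool = True) -> np.ndarray:
        """(n_trials, p, T) array; requires equal trial lengths."""
        src = self.orthonormalized if orthonormalized and self.orthonormalized else self.trajectories
        return np.stack(src, axis=0)


def _as_trial_list(trials) -> tuple[list[np.ndarray], float]:
    if isinstance(trials, TrialSet):
        return [trials.counts[n] for n in range(trials.n_trials)], trials.bin_width_s
    if isinstance(trials, np.ndarray) and trials.ndim == 3:
        return [trials[n] for n in range(trials.shape[0])], 1.0
    return [np.asarray(t, dtype=float) for t in trials], 1.0


class GPFA(BaseEstimator):
    """Gaussian-process factor analysis estimator.

    Parameters
    ----------
    n_factors : int
        Latent dimensionality p (must be < number of clusters q).
    bin_width_s : float
        Time step between bins; only used if the input does not carry one.
    tau_init_s : float
        Initial GP timescale for every latent dimension (default 100 ms).
    gp_noise_variance : float
        GP noise floor s2 (fixed, not learned).
    tol : float
        Relative log-likelihood change for EM convergence.
    max_iter : int
        EM iteration cap.
    learn_timescales : bool
        If False, timescales stay at ``tau_init_s`` (useful for the
        white-noise limit, where GPFA reduces to factor analysis).

    Attributes (after ``fit``)
    --------------------------
    C_ : (q, p) loading matrix;  d_ : (q,) offset;  R_ : (q,) diagonal
    observation noise variances;  timescales_ : (p,) GP timescales in
    seconds;  loglik_trace_ : per-iteration data log-likelihood.
    """

    def __init__(
        self,
        n_factors: int = 12,
        bin_width_s: float = 0.015,
        tau_init_s: float = 0.1,
        gp_noise_variance: float = 1e-3,
        tol: float = 1e-8,
        max_iter: int = 500,
        learn_timescales: bool = True,
        tau_update_every: int = 1,
        min_noise: float = 1e-6,
        random_state: int | None = 0,
        verbose: bool = False,
    ) -> None:
        self.n_factors = n_factors
        self.bin_width_s = bin_width_s
        self.tau_init_s = tau_init_s
        self.gp_noise_variance = gp_noise_variance
        self.tol = tol
        self.max_iter = max_iter
        self.learn_timescales = learn_timescales
        self.tau_update_every = tau_update_every
        self.min_noise = min_noise
        self.random_state = random_state
        self.verbose = verbose

    # -- kernel -----------------------------------------------------------

    def _kernel(self, T: int, tau: float) -> np.ndarray:
        t = np.arange(T) * self.bin_width_s_
        dt2 = (t[:, None] - t[None, :]) ** 2
        s2 = self.gp_noise_variance
        return (1.0 - s2) * np.exp(-dt2 / (2.0 * tau**2)) + s2 * np.eye(T)

    # -- fitting ----------------------------------------------------------

    def fit(self, trials, y=None) -> "GPFA":
        ys, bw = _as_trial_list(trials)
        self.bin_width_s_ = bw if isinstance(trials, TrialSet) else self.bin_width_s
        q = ys[0].shape[0]
        p = self.n_factors
        if p >= q:
            raise ValueError(f"n_factors={p} must be < number of clusters q={q}")
        if isinstance(trials, TrialSet) and not trials.sqrt_transformed:
            logger.debug("fitting GPFA on a TrialSet without sqrt transform")

        # --- initialization: factor analysis on pooled bins
        pooled = np.concatenate([y.T for y in ys], axis=0)  # (sum_T, q)
        fa = FactorAnalysis(
            n_components=p, svd_method="lapack", random_state=self.random_state
        ).fit(pooled)
        C = fa.components_.T.copy()  # (q, p)
        d = fa.mean_.copy()
        R = np.maximum(fa.noise_variance_.copy(), self.min_noise)
        tau = np.full(p, self.tau_init_s, dtype=float)

        groups = self._group_by_length(ys)
        trace: list[float] = []
        ll_prev = -np.inf
        for it in range(self.max_iter):
            E = self._estep(groups, C, d, R, tau)
            trace.append(E["loglik"])
            if self.verbose:
                logger.info("EM iter %d: loglik %.6f", it, E["loglik"])
            if it > 0:
                rel = (E["loglik"] - ll_prev) / max(abs(ll_prev), 1.0)
                if rel < self.tol:
                    break
            ll_prev = E["loglik"]
            C, d, R = self._mstep_obs(E, q, p)
            if self.learn_timescales and (it % self.tau_update_every == 0):
                tau = self._mstep_tau(E, tau)

        self.C_, self.d_, self.R_, self.timescales_ = C, d, R, tau
        self.loglik_trace_ = np.asarray(trace)
        self.n_clusters_ = q
        return self

    @staticmethod
    def _group_by_length(ys: list[np.ndarray]) -> dict[int, np.ndarray]:
        groups: dict[int, list[np.ndarray]] = {}
        for y in ys:
            groups.setdefault(y.shape[1], []).append(y)
        return {T: np.stack(g, axis=0) for T, g in groups.items()}

    def _estep(self, groups, C, d, R, tau):
        """Joint posterior over each trial's latent path + data log-likelihood.

        Returns sufficient statistics for the M-steps, accumulated over
        trials, plus per-group posterior quantities for timescale updates.
        """
        p = C.shape[1]
        Rinv = 1.0 / R
        CtRinv = C.T * Rinv[None, :]  # (p, q)
        CtRinvC = CtRinv @ C  # (p, p)
        loglik = 0.0
        S_xx = np.zeros((p, p))
        S_x = np.zeros(p)
        S_yx = None
        S_y = None
        n_bins_total = 0
        group_stats = []
        means_by_T: dict[int, np.ndarray] = {}
        for T, Y in groups.items():
            N = Y.shape[0]
            q = Y.shape[1]
            Kinvs, Klogdets = [], []
            for j in range(p):
                K = self._kernel(T, tau[j])
                cK = cho_factor(K + 1e-10 * np.eye(T), lower=True)
                Kinvs.append(cho_solve(cK, np.eye(T)))
                Klogdets.append(2.0 * np.log(np.diag(cK[0])).sum())
            # posterior precision A (time-major stacking: index t*p + j)
            A = np.zeros((T * p, T * p))
            Ar = A.reshape(T, p, T, p)
            idx = np.arange(T)
            Ar[idx, :, idx, :] += CtRinvC[None, :, :]
            for j in range(p):
                Ar[:, j, :, j] += Kinvs[j]
            cA = cho_factor(A, lower=True)
            logdetA = 2.0 * np.log(np.diag(cA[0])).sum()
            Sigma = cho_solve(cA, np.eye(T * p))

            Yd = Y - d[None, :, None]  # (N, q, T)
            B = np.einsum("pq,nqt->ntp", CtRinv, Yd).reshape(N, T * p).T
            M = cho_solve(cA, B)  # posterior means, (T*p, N)

            # log-likelihood via the matrix determinant lemma / Woodbury
            quad_R = np.einsum("nqt,q,nqt->n", Yd, Rinv, Yd)
            quad_corr = np.einsum("in,in->n", B, M)
            logdet_y = T * np.log(R).sum() + sum(Klogdets) + logdetA
            loglik += float(
                -0.5 * np.sum(quad_R - quad_corr)
                - 0.5 * N * (q * T * np.log(2 * np.pi) + logdet_y)
            )

            m = M.reshape(T, p, N)
            Sig_r = Sigma.reshape(T, p, T, p)
            Sig_tt = Sig_r[idx, :, idx, :].sum(axis=0)  # sum over t of p x p blocks
            S_xx += N * Sig_tt + np.einsum("tpn,tqn->pq", m, m)
            S_x += m.sum(axis=(0, 2))
            Syx_g = np.einsum("nqt,tpn->qp", Y, m)
            S_yx = Syx_g if S_yx is None else S_yx + Syx_g
            Sy_g = Y.sum(axis=(0, 2))
            S_y = Sy_g if S_y is None else S_y + Sy_g
            n_bins_total += N * T
            group_stats.append(
                {
                    "T": T,
                    "N": N,
                    "Sigma_jj": [N * Sigma[j::p, j::p] for j in range(p)],
                    "mm_jj": [
                        np.einsum("tn,sn->ts", m[:, j, :], m[:, j, :]) for j in range(p)
                    ],
                }
            )
            means_by_T[T] = m
        # second moment of y for R update
        S_yy = np.zeros(C.shape[0])
        for T, Y in groups.items():
            S_yy += np.einsum("nqt,nqt->q", Y, Y)
        return {
            "loglik": loglik,
            "S_xx": S_xx,
            "S_x": S_x,
            "S_yx": S_yx,
            "S_y": S_y,
            "S_yy": S_yy,
            "n_bins": n_bins_total,
            "groups": group_stats,
            "means": means_by_T,
        }

    def _mstep_obs(self, E, q, p):
        """Closed-form joint update of C, d and diagonal R."""
        n = E["n_bins"]
        G = np.empty((p + 1, p + 1))
        G[:p, :p] = E["S_xx"]
        G[:p, p] = E["S_x"]
        G[p, :p] = E["S_x"]
        G[p, p] = n
        H = np.concatenate([E["S_yx"], E["S_y"][:, None]], axis=1)  # (q, p+1)
        Cd = np.linalg.solve(G + 1e-10 * np.eye(p + 1), H.T).T  # (q, p+1)
        C, d = Cd[:, :p], Cd[:, p]
        R = (E["S_yy"] - np.einsum("qk,qk->q", Cd, H)) / n
        R = np.maximum(R, self.min_noise)
        return C, d, R

    def _mstep_tau(self, E, tau):
        """Per-dimension timescale update by bounded scalar maximization.

        The expected complete-data objective for dimension j is
        -(1/2) sum_groups [N log|K_j| + tr(K_j^-1 S_j)]; a candidate tau is
        accepted only when it improves this objective, which keeps the EM
        likelihood trace monotone.
        """
        p = tau.size
        new = tau.copy()
        for j in range(p):
            stats = [
                (g["T"], g["N"], g["Sigma_jj"][j] + g["mm_jj"][j]) for g in E["groups"]
            ]

            def neg_obj(log_tau: float) -> float:
                tj = float(np.exp(log_tau))
                val = 0.0
                for T, N, S in stats:
                    K = self._kernel(T, tj)
                    try:
                        cK = cho_factor(K + 1e-10 * np.eye(T), lower=True)
                    except np.linalg.LinAlgError:
                        return 1e12
                    val += N * 2.0 * np.log(np.diag(cK[0])).sum()
                    val += np.trace(cho_solve(cK, S))
                return 0.5 * val

            cur = neg_obj(np.log(tau[j]))
            res = minimize_scalar(
                neg_obj,
                bounds=(np.log(2e-4), np.log(2.0)),
                method="bounded",
                options={"xatol": 1e-3},
            )
            if res.fun < cur:
                new[j] = float(np.exp(res.x))
        return new

    # -- inference --------------------------------------------------------

    def transform(self, trials, orthonormalize: bool = True) -> LatentTrajectorySet:
        """Posterior-mean latent trajectories for each trial."""
        ys, bw = _as_trial_list(trials)
        bw = bw if isinstance(trials, TrialSet) else self.bin_width_s_
        q = ys[0].shape[0]
        if q != self.n_clusters_:
            raise ValueError(f"trials have q={q}, model expects {self.n_clusters_}")
        p = self.n_factors
        Rinv = 1.0 / self.R_
        CtRinv = self.C_.T * Rinv[None, :]
        CtRinvC = CtRinv @ self.C_
        out: list[np.ndarray] = [None] * len(ys)
        order: dict[int, list[int]] = {}
        for i, y in enumerate(ys):
            order.setdefault(y.shape[1], []).append(i)
        for T, idxs in order.items():
            A = np.zeros((T * p, T * p))
            Ar = A.reshape(T, p, T, p)
            tid = np.arange(T)
            Ar[tid, :, tid, :] += CtRinvC[None, :, :]
            for j in range(p):
                K = self._kernel(T, self.timescales_[j])
                cK = cho_factor(K + 1e-10 * np.eye(T), lower=True)
                Ar[:, j, :, j] += cho_solve(cK, np.eye(T))
            cA = cho_factor(A, lower=True)
            Y = np.stack([ys[i] for i in idxs], axis=0)
            Yd = Y - self.d_[None, :, None]
            B = np.einsum("pq,nqt->ntp", CtRinv, Yd).reshape(len(idxs), T * p).T
            M = cho_solve(cA, B).reshape(T, p, len(idxs))
            for k, i in enumerate(idxs):
                out[i] = M[:, :, k].T  # (p, T)
        latents = LatentTrajectorySet(trajectories=out, bin_width_s=bw)
        if orthonormalize:
            latents = orthonormalize_latents(self, latents)
        return latents

    def fit_transform(self, trials, y=None) -> LatentTrajectorySet:
        return self.fit(trials).transform(trials)

    def score(self, trials, y=None) -> float:
        """Total data log-likelihood of trials under the fitted model."""
        ys, _ = _as_trial_list(trials)
        groups = self._group_by_length(ys)
        E = self._estep(groups, self.C_, self.d_, self.R_, self.timescales_)
        return E["loglik"]


def fit_gpfa(trials, n_factors: int, **em_config) -> GPFA:
    return GPFA(n_factors=n_factors, **em_config).fit(trials)


def infer_latents(model: GPFA, trials) -> LatentTrajectorySet:
    return model.transform(trials)


def orthonormalize_latents(model: GPFA, latents: LatentTrajectorySet) -> LatentTrajectorySet:
    """Map latents through the SVD of C: with C = U S V', xt = S V' x.

    U's columns are orthonormal and ordered by decreasing singular value
    (explained covariance); each is sign-fixed so its largest-magnitude
    loading is positive.  The reconstruction identity C x = U xt holds
    exactly.
    """
    U, s, Vt = svd(model.C_, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if rank < s.size:
        logger.info("loading matrix rank-deficient: effective dimension %d", rank)
    signs = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs[None, :]
    Vt = Vt * signs[:, None]
    W = s[:, None] * Vt  # (p, p): x -> xt
    orth = [W @ x for x in latents.trajectories]
    return LatentTrajectorySet(
        trajectories=latents.trajectories,
        bin_width_s=latents.bin_width_s,
        orthonormalized=orth,
        basis=U,
        singular_values=s,
    )


def variance_explained(model: GPFA) -> dict[str, float]:
    """Shared/private variance decomposition of the fitted model.

    total = tr(C C' + R); shared = tr(C C')/total; private = tr(R)/total;
    the two fractions sum to one exactly.
    """
    shared = float(np.sum(model.C_**2))
    private = float(np.sum(model.R_))
    total = shared + private
    return {
        "total": total,
        "shared_fraction": shared / total,
        "private_fraction": private / total,
    }
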