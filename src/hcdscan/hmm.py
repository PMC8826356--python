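"""Diagonal-covariance Gaussian HMM with Baum-Welch EM and Viterbi decoding.

Written for the two-state, two-response segmentation at the core of the HCD
caller, but generic in the number of states and responses. Supports multiple
independent observation sequences (one per chromosome-arm run). Forward and
backward passes use per-step scaling, so the per-iteration log-likelihood is
exact and the EM monotonicity guarantee can be asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

__all__ = ["DiagGaussianHMM"]

_VAR_FLOOR = 1e-6


def _log_gauss_diag(X: np.ndarray, means: np.ndarray, variances: np.ndarray
                    ) -> np.ndarray:
    """(T, K) log density of each frame under each state's diagonal Gaussian."""
    T, D = X.shape
    out = np.empty((T, means.shape[0]))
    for k in range(means.shape[0]):
        diff2 = (X - means[k]) ** 2 / variances[k]
        out[:, k] = -0.5 * (D * np.log(2 * np.pi)
                            + np.log(variances[k]).sum()
                            + diff2.sum(axis=1))
    return out


@dataclass
class DiagGaussianHMM:
    """K-state HMM with independent Gaussian responses per state."""

    n_states: int = 2
    tol: float = 1e-6
    max_iter: int = 500
    n_restarts: int = 5
    seed: int = 0

    means_: np.ndarray = field(default=None, repr=False)       # (K, D)
    variances_: np.ndarray = field(default=None, repr=False)   # (K, D)
    transition_: np.ndarray = field(default=None, repr=False)  # (K, K)
    initial_: np.ndarray = field(default=None, repr=False)     # (K,)
    log_likelihood_: float = float("-inf")
    loglik_history_: list = field(default_factory=list, repr=False)
    n_iter_: int = 0
    converged_: bool = False

    # ------------------------------------------------------------------ fit

    def fit(self, sequences: list[np.ndarray]) -> "DiagGaussianHMM":
        seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences
                if len(s) > 0]
        if not seqs:
            raise ValueError("no observation sequences")
        X = np.vstack(seqs)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite observations")
        if np.any(X.var(axis=0) <= 0):
            raise ValueError("a response has zero variance overall; "
                             "add jitter or drop the response")

        best = None
        for r in range(self.n_restarts):
            params = self._init_params(X, restart=r)
            params = self._em(seqs, *params)
            if best is None or params[-2][-1] > best[-2][-1]:
                best = params
        (self.means_, self.variances_, self.transition_, self.initial_,
         self.loglik_history_, self.converged_) = best
        self.log_likelihood_ = float(self.loglik_history_[-1])
        self.n_iter_ = len(self.loglik_history_)
        return self

    def _init_params(self, X: np.ndarray, restart: int):
        km = KMeans(n_clusters=self.n_states, n_init=1,
                    random_state=(int(self.seed) + 1009 * restart) % (2**31))
        labels = km.fit_predict(X)
        means = km.cluster_centers_.copy()
        variances = np.empty_like(means)
        for k in range(self.n_states):
            pts = X[labels == k]
            v = pts.var(axis=0) if len(pts) > 1 else X.var(axis=0)
            variances[k] = np.maximum(v, _VAR_FLOOR)
        if restart > 0:  # jitter the means on later restarts
            rng = np.random.default_rng((int(self.seed) + restart) % (2**31))
            means = means + rng.normal(0, 0.25, means.shape) * X.std(axis=0)
        K = self.n_states
        transition = np.full((K, K), 0.1 / max(K - 1, 1))
        np.fill_diagonal(transition, 0.9)
        initial = np.full(K, 1.0 / K)
        return means, variances, transition, initial

    def _em(self, seqs, means, variances, transition, initial):
        history: list[float] = []
        converged = False
        for _it in range(self.max_iter):
            loglik = 0.0
            K, D = means.shape
            g_sum = np.zeros(K)
            g_first = np.zeros(K)
            xi_sum = np.zeros((K, K))
            mx = np.zeros((K, D))
            mx2 = np.zeros((K, D))
            for X in seqs:
                logb = _log_gauss_diag(X, means, variances)
                b = np.exp(logb - logb.max(axis=1, keepdims=True))
                alpha, beta, scale = self._forward_backward(b, transition, initial)
                loglik += float(np.log(scale).sum()
                                + logb.max(axis=1).sum())
                gamma = alpha * beta
                gamma /= gamma.sum(axis=1, keepdims=True)
                # xi_t(i,j) proportional to alpha_t(i) A(i,j) b_{t+1}(j) beta_{t+1}(j)
                for t in range(len(X) - 1):
                    xi = (alpha[t][:, None] * transition * b[t + 1][None, :]
                          * beta[t + 1][None, :])
                    xi_sum += xi / xi.sum()
                g_first += gamma[0]
                g_sum += gamma.sum(axis=0)
                mx += gamma.T @ X
                mx2 += gamma.T @ (X**2)
            history.append(loglik)
            if len(history) > 1 and abs(history[-1] - history[-2]) < self.tol:
                converged = True
                break
            initial = g_first / g_first.sum()
            transition = xi_sum / xi_sum.sum(axis=1, keepdims=True)
            means = mx / g_sum[:, None]
            variances = np.maximum(mx2 / g_sum[:, None] - means**2, _VAR_FLOOR)
        return means, variances, transition, initial, history, converged

    @staticmethod
    def _forward_backward(b: np.ndarray, A: np.ndarray, pi: np.ndarray):
        """Scaled forward/backward. ``b`` holds (scaled) state likelihoods."""
        T, K = b.shape
        alpha = np.empty((T, K))
        scale = np.empty(T)
        alpha[0] = pi * b[0]
        scale[0] = alpha[0].sum()
        alpha[0] /= scale[0]
        for t in range(1, T):
            alpha[t] = (alpha[t - 1] @ A) * b[t]
            scale[t] = alpha[t].sum()
            alpha[t] /= scale[t]
        beta = np.empty((T, K))
        beta[-1] = 1.0
        for t in range(T - 2, -1, -1):
            beta[t] = (A @ (b[t + 1] * beta[t + 1])) / scale[t + 1]
        return alpha, beta, scale

    # ------------------------------------------------------------- decoding

    def _check_fitted(self) -> None:
        if self.means_ is None:
            raise ValueError("model is not fitted")

    def score(self, sequences: list[np.ndarray]) -> float:
        """Total log-likelihood of the sequences under the fitted model."""
        self._check_fitted()
        total = 0.0
        for X in sequences:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            logb = _log_gauss_diag(X, self.means_, self.variances_)
            b = np.exp(logb - logb.max(axis=1, keepdims=True))
            _, _, scale = self._forward_backward(b, self.transition_,
                                                 self.initial_)
            total += float(np.log(scale).sum() + logb.max(axis=1).sum())
        return total

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the fitted transition matrix.

        Used as the start-state prior when decoding: a chromosome arm is an
        arbitrary window of the genome, so its first bin should not be
        penalized just because the training sequences happened to start in
        one particular state.
        """
        self._check_fitted()
        w, v = np.linalg.eig(self.transition_.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.abs(np.real(v[:, i]))
        return pi / pi.sum()

    def viterbi(self, X: np.ndarray) -> np.ndarray:
        """Most probable state path for one sequence (stationary start prior)."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        logb = _log_gauss_diag(X, self.means_, self.variances_)
        logA = np.log(np.maximum(self.transition_, 1e-300))
        T, K = logb.shape
        delta = np.empty((T, K))
        psi = np.zeros((T, K), dtype=int)
        delta[0] = np.log(np.maximum(self.stationary(), 1e-300)) + logb[0]
        for t in range(1, T):
            cand = delta[t - 1][:, None] + logA
            psi[t] = cand.argmax(axis=0)
            delta[t] = cand.max(axis=0) + logb[t]
        path = np.empty(T, dtype=int)
        path[-1] = int(delta[-1].argmax())
        for t in range(T - 2, -1, -1):
            path[t] = psi[t + 1, path[t + 1]]
        return path

    def path_logprob(self, X: np.ndarray, path: np.ndarray) -> float:
        """Joint log-probability of a given state path and the observations."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        logb = _log_gauss_diag(X, self.means_, self.variances_)
        logA = np.log(np.maximum(self.transition_, 1e-300))
        lp = float(np.log(max(self.stationary()[path[0]], 1e-300))
                   + logb[0, path[0]])
        for t in range(1, len(path)):
            lp += float(logA[path[t - 1], path[t]] + logb[t, path[t]])
        return lp

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """Per-frame state posterior probabilities (gamma)."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        logb = _log_gauss_diag(X, self.means_, self.variances_)
        b = np.exp(logb - logb.max(axis=1, keepdims=True))
        alpha, beta, _ = self._forward_backward(b, self.transition_,
                                                self.stationary())
        gamma = alpha * beta
        return gamma / gamma.sum(axis=1, keepdims=True)
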