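"""Explicit-duration hidden semi-Markov model for activity-count segmentation.

The model partitions an accelerometer count trace into ``K`` latent activity
states (default six, labelled 0–5 in ascending order of emission mean). Each
state ``k`` emits per-epoch count magnitudes from a Gaussian ``N(mu_k,
sigma_k^2)`` and persists for an explicitly modelled dwell of ``1 +
Poisson(lambda_k)`` epochs, truncated and renormalized at ``max_duration``
for inference. Self-transitions are disallowed: the transition matrix governs
which state follows when a dwell ends.

The last dwell of every observation segment is treated as right-censored
(the device record ends while the state is still ongoing), so its
contribution to the likelihood is the dwell survival function rather than
the exact dwell probability.

All recursions run in log space; the O(T*K^2 + T*K*D) inner loops are
numba-compiled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import poisson

NON_WEAR_LABEL = -1  # state code for epochs outside wear time

_NEG_INF = -np.inf


class DegenerateStateWarning(UserWarning):
    """A state lost essentially all responsibility mass during EM."""


class HSMMError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class HSMMParams:
    """Parameters of a K-state explicit-duration hidden semi-Markov model.

    Attributes
    ----------
    initial : (K,) probability vector over the first state of a segment.
    transition : (K, K) row-stochastic matrix with a zero diagonal
        (no self-transitions; dwell length is modelled separately).
    means, sds : (K,) Gaussian emission mean / SD in counts per epoch.
    rates : (K,) Poisson dwell rates; a dwell lasts ``1 + Poisson(rate)``
        epochs.
    max_duration : dwell truncation used by the inference recursions; the
        dwell pmf is renormalized on ``{1, ..., max_duration}``.
    log1p : whether emissions are modelled on ``log1p``-transformed counts.
    """

    initial: np.ndarray
    transition: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    rates: np.ndarray
    max_duration: int = 600
    log1p: bool = False

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        k = self.n_states
        if self.transition.shape != (k, k):
            raise HSMMError(f"transition must be {(k, k)}, got {self.transition.shape}")
        if not np.isclose(self.initial.sum(), 1.0):
            raise HSMMError("initial probabilities must sum to 1")
        if k > 1:
            if not np.allclose(self.transition.sum(axis=1), 1.0):
                raise HSMMError("transition rows must sum to 1")
        if np.any(np.abs(np.diag(self.transition)) > 1e-12):
            raise HSMMError("transition diagonal must be zero (no self-transitions)")
        if np.any(self.sds <= 0):
            raise HSMMError("emission SDs must be positive")
        if np.any(self.rates <= 0):
            raise HSMMError("dwell rates must be positive")
        if self.max_duration < 1:
            raise HSMMError("max_duration must be >= 1")

    @property
    def n_states(self) -> int:
        return len(self.means)

    def duration_logpmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (logdur, logsurv), both (K, D).

        ``logdur[k, d-1]`` is the log probability of an exact dwell of ``d``
        epochs under the truncated, renormalized shifted-Poisson law;
        ``logsurv[k, d-1]`` is the log probability of a dwell of at least
        ``d`` epochs (so ``logsurv[:, 0] == 0``).
        """
        return _duration_tables(self.rates, self.max_duration)

    def emission_logpdf(self, x: np.ndarray) -> np.ndarray:
        """(T, K) per-epoch Gaussian log-densities (after any transform)."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise HSMMError("magnitudes must be finite")
        if self.log1p:
            x = np.log1p(x)
        z = (x[:, None] - self.means[None, :]) / self.sds[None, :]
        return -0.5 * z * z - np.log(self.sds)[None, :] - 0.5 * np.log(2 * np.pi)

    def ordered(self) -> "HSMMParams":
        """Return a copy with states relabelled ascending by emission mean."""
        order = np.argsort(self.means, kind="stable")
        return replace(
            self,
            initial=self.initial[order],
            transition=self.transition[np.ix_(order, order)],
            means=self.means[order],
            sds=self.sds[order],
            rates=self.rates[order],
        )

    # -- serialization (versioned text schema) ------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": "actikid-hsmm/1",
            "n_states": self.n_states,
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "rates": self.rates.tolist(),
            "max_duration": int(self.max_duration),
            "log1p": bool(self.log1p),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HSMMParams":
        if d.get("schema") != "actikid-hsmm/1":
            raise HSMMError(f"unknown model schema: {d.get('schema')!r}")
        return cls(
            initial=np.array(d["initial"]),
            transition=np.array(d["transition"]),
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            rates=np.array(d["rates"]),
            max_duration=int(d["max_duration"]),
            log1p=bool(d["log1p"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "HSMMParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _duration_tables(rates: np.ndarray, max_duration: int):
    d = np.arange(max_duration)  # dwell-1 = 0..D-1
    logpmf = poisson.logpmf(d[None, :], rates[:, None])
    logpmf = logpmf - logsumexp(logpmf, axis=1, keepdims=True)
    # survival S(d) = sum_{d' >= d} p(d'): reversed log-cumsum-exp
    logsurv = np.logaddexp.accumulate(logpmf[:, ::-1], axis=1)[:, ::-1]
    logsurv[:, 0] = 0.0
    return logpmf, logsurv


def _log_transition(params: HSMMParams) -> np.ndarray:
    with np.errstate(divide="ignore"):
        la = np.log(params.transition)
    np.fill_diagonal(la, _NEG_INF)
    return la


def _log_initial(params: HSMMParams) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(params.initial)


# ---------------------------------------------------------------------------
# Numba recursions
# ---------------------------------------------------------------------------


@njit(cache=False)
def _forward(cumb, logdur, logsurv, logA, logpi):
    """Right-censored explicit-duration forward pass.

    Returns (loglik, entry, alpha) where entry[t, k] is the log probability
    of the data before t joint with state k starting at epoch t, and
    alpha[t, k] is the analogue for a completed dwell of k ending at t.
    """
    T = cumb.shape[0] - 1
    K = logpi.shape[0]
    D = logdur.shape[1]
    entry = np.full((T, K), -np.inf)
    alpha = np.full((T, K), -np.inf)
    for t in range(T):
        for k in range(K):
            if t == 0:
                entry[t, k] = logpi[k]
            else:
                m = -np.inf
                for j in range(K):
                    v = alpha[t - 1, j] + logA[j, k]
                    if v > m:
                        m = v
                if m > -np.inf:
                    s = 0.0
                    for j in range(K):
                        v = alpha[t - 1, j] + logA[j, k]
                        if v > -np.inf:
                            s += np.exp(v - m)
                    entry[t, k] = m + np.log(s)
        for k in range(K):
            dmax = min(D, t + 1)
            m = -np.inf
            for d in range(1, dmax + 1):
                v = entry[t + 1 - d, k] + (cumb[t + 1, k] - cumb[t + 1 - d, k]) + logdur[k, d - 1]
                if v > m:
                    m = v
            if m > -np.inf:
                s = 0.0
                for d in range(1, dmax + 1):
                    v = entry[t + 1 - d, k] + (cumb[t + 1, k] - cumb[t + 1 - d, k]) + logdur[k, d - 1]
                    if v > -np.inf:
                        s += np.exp(v - m)
                alpha[t, k] = m + np.log(s)
    # censored tail: the last dwell covers a..T-1 with observed length T-a
    m = -np.inf
    for k in range(K):
        for a in range(max(0, T - D), T):
            v = entry[a, k] + (cumb[T, k] - cumb[a, k]) + logsurv[k, T - a - 1]
            if v > m:
                m = v
    ll = -np.inf
    if m > -np.inf:
        s = 0.0
        for k in range(K):
            for a in range(max(0, T - D), T):
                v = entry[a, k] + (cumb[T, k] - cumb[a, k]) + logsurv[k, T - a - 1]
                if v > -np.inf:
                    s += np.exp(v - m)
        ll = m + np.log(s)
    return ll, entry, alpha


@njit(cache=False)
def _backward(cumb, logdur, logsurv, logA):
    """Return (betaE, betaT).

    betaE[t, k] = log P(x_t..x_{T-1} | state k starts at t);
    betaT[t, k] = log P(x_{t+1}..x_{T-1} | a dwell of k completed at t),
    defined for t <= T-2.
    """
    T = cumb.shape[0] - 1
    K = logA.shape[0]
    D = logdur.shape[1]
    betaE = np.full((T, K), -np.inf)
    betaT = np.full((max(T - 1, 0), K), -np.inf)
    for t in range(T - 1, -1, -1):
        if t <= T - 2:
            for k in range(K):
                m = -np.inf
                for j in range(K):
                    v = logA[k, j] + betaE[t + 1, j]
                    if v > m:
                        m = v
                if m > -np.inf:
                    s = 0.0
                    for j in range(K):
                        v = logA[k, j] + betaE[t + 1, j]
                        if v > -np.inf:
                            s += np.exp(v - m)
                    betaT[t, k] = m + np.log(s)
        for k in range(K):
            rem = T - t
            m = -np.inf
            # censored dwell reaching the end of the segment
            if rem <= D:
                m = (cumb[T, k] - cumb[t, k]) + logsurv[k, rem - 1]
            dmax = min(D, rem - 1)
            for d in range(1, dmax + 1):
                v = (cumb[t + d, k] - cumb[t, k]) + logdur[k, d - 1] + betaT[t + d - 1, k]
                if v > m:
                    m = v
            if m > -np.inf:
                s = 0.0
                if rem <= D:
                    s += np.exp((cumb[T, k] - cumb[t, k]) + logsurv[k, rem - 1] - m)
                for d in range(1, dmax + 1):
                    v = (cumb[t + d, k] - cumb[t, k]) + logdur[k, d - 1] + betaT[t + d - 1, k]
                    if v > -np.inf:
                        s += np.exp(v - m)
                betaE[t, k] = m + np.log(s)
    return betaE, betaT


@njit(cache=False)
def _estep(cumb, logdur, logsurv, logA, logpi):
    """One E-step over a segment.

    Returns (ll, gamma, eta, eta_cens, xi, start) where gamma[t, k] are
    per-epoch state posteriors, eta[k, d-1] expected counts of completed
    dwells of length d, eta_cens[k, d-1] the censored analogue, xi[j, k]
    expected transition counts and start[k] the posterior of the first state.
    """
    T = cumb.shape[0] - 1
    K = logpi.shape[0]
    D = logdur.shape[1]
    ll, entry, alpha = _forward(cumb, logdur, logsurv, logA, logpi)
    gamma = np.zeros((T, K))
    eta = np.zeros((K, D))
    eta_c = np.zeros((K, D))
    xi = np.zeros((K, K))
    start = np.zeros(K)
    if ll == -np.inf:
        return ll, gamma, eta, eta_c, xi, start
    betaE, betaT = _backward(cumb, logdur, logsurv, logA)
    gd = np.zeros((T + 1, K))  # difference array for gamma
    for a in range(T):
        for k in range(K):
            base = entry[a, k]
            if base == -np.inf:
                continue
            rem = T - a
            if rem <= D:
                w = np.exp(base + (cumb[T, k] - cumb[a, k]) + logsurv[k, rem - 1] - ll)
                eta_c[k, rem - 1] += w
                gd[a, k] += w
            dmax = min(D, rem - 1)
            for d in range(1, dmax + 1):
                v = base + (cumb[a + d, k] - cumb[a, k]) + logdur[k, d - 1] + betaT[a + d - 1, k]
                if v > -np.inf:
                    w = np.exp(v - ll)
                    eta[k, d - 1] += w
                    gd[a, k] += w
                    gd[a + d, k] -= w
    for k in range(K):
        acc = 0.0
        for t in range(T):
            acc += gd[t, k]
            gamma[t, k] = acc
    for t in range(T - 1):
        for j in range(K):
            if alpha[t, j] == -np.inf:
                continue
            for k in range(K):
                v = alpha[t, j] + logA[j, k] + betaE[t + 1, k]
                if v > -np.inf:
                    xi[j, k] += np.exp(v - ll)
    for k in range(K):
        v = logpi[k] + betaE[0, k]
        if v > -np.inf:
            start[k] = np.exp(v - ll)
    return ll, gamma, eta, eta_c, xi, start


@njit(cache=False)
def _viterbi(cumb, logdur, logsurv, logA, logpi):
    """Maximum-probability state/dwell segmentation (censored last dwell).

    Returns (score, labels).
    """
    T = cumb.shape[0] - 1
    K = logpi.shape[0]
    D = logdur.shape[1]
    entry = np.full((T, K), -np.inf)
    V = np.full((T, K), -np.inf)
    bp = np.zeros((T, K), dtype=np.int64)  # argmax previous state for entry
    bd = np.zeros((T, K), dtype=np.int64)  # argmax dwell for V
    for t in range(T):
        for k in range(K):
            if t == 0:
                entry[t, k] = logpi[k]
            else:
                m = -np.inf
                arg = 0
                for j in range(K):
                    v = V[t - 1, j] + logA[j, k]
                    if v > m:
                        m = v
                        arg = j
                entry[t, k] = m
                bp[t, k] = arg
        for k in range(K):
            dmax = min(D, t + 1)
            m = -np.inf
            arg = 1
            for d in range(1, dmax + 1):
                v = entry[t + 1 - d, k] + (cumb[t + 1, k] - cumb[t + 1 - d, k]) + logdur[k, d - 1]
                if v > m:
                    m = v
                    arg = d
            V[t, k] = m
            bd[t, k] = arg
    best = -np.inf
    best_k = 0
    best_a = 0
    for k in range(K):
        for a in range(max(0, T - D), T):
            v = entry[a, k] + (cumb[T, k] - cumb[a, k]) + logsurv[k, T - a - 1]
            if v > best:
                best = v
                best_k = k
                best_a = a
    labels = np.zeros(T, dtype=np.int64)
    if best == -np.inf:
        return best, labels
    for t in range(best_a, T):
        labels[t] = best_k
    pos = best_a  # epochs before pos remain to be labelled
    k = best_k
    while pos > 0:
        j = bp[pos, k]
        d = bd[pos - 1, j]
        for t in range(pos - d, pos):
            labels[t] = j
        pos -= d
        k = j
    return best, labels


# ---------------------------------------------------------------------------
# Public inference API
# ---------------------------------------------------------------------------


def _tables(params: HSMMParams, x: np.ndarray):
    logb = params.emission_logpdf(x)
    cumb = np.vstack([np.zeros(params.n_states), np.cumsum(logb, axis=0)])
    logdur, logsurv = params.duration_logpmf()
    return cumb, logdur, logsurv, _log_transition(params), _log_initial(params)


def hsmm_loglik(segment: np.ndarray, params: HSMMParams) -> float:
    """Log-likelihood of one wear-time magnitude segment under the model."""
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1 or len(segment) < 1:
        raise HSMMError("segment must be a non-empty 1-D array")
    ll, _, _ = _forward(*_tables(params, segment))
    if not np.isfinite(ll):
        raise HSMMError(
            "segment has zero likelihood under the model "
            "(check max_duration against segment length)"
        )
    return float(ll)


def hsmm_decode(segment: np.ndarray, params: HSMMParams) -> np.ndarray:
    """Most probable state sequence for one wear-time segment (Viterbi)."""
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1 or len(segment) < 1:
        raise HSMMError("segment must be a non-empty 1-D array")
    score, labels = _viterbi(*_tables(params, segment))
    if not np.isfinite(score):
        raise HSMMError("no feasible state path (check max_duration)")
    return labels


@dataclass
class FitDiagnostics:
    loglik_path: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    restart: int = 0
    restart_logliks: list = field(default_factory=list)
    n_epochs: int = 0


def _init_params(
    segments, n_states, max_duration, rng, perturb: bool, log1p: bool
) -> HSMMParams:
    """Quantile-spread deterministic start, optionally jittered for restarts."""
    pooled = np.concatenate(segments)
    if log1p:
        pooled = np.log1p(pooled)
    qs = (2 * np.arange(n_states) + 1) / (2 * n_states)
    means = np.quantile(pooled, qs)
    sd = max(float(np.std(pooled)), 1e-6)
    sds = np.full(n_states, sd / max(n_states, 2))
    rates = np.full(n_states, 10.0)
    if perturb:
        means = means + rng.normal(0.0, sd / (2 * n_states), n_states)
        rates = rates * np.exp(rng.normal(0.0, 0.3, n_states))
    means = np.sort(means)
    # break exact ties so states are distinguishable
    for k in range(1, n_states):
        if means[k] <= means[k - 1]:
            means[k] = means[k - 1] + 1e-6 * (1 + abs(means[k - 1]))
    if n_states > 1:
        trans = np.full((n_states, n_states), 1.0 / (n_states - 1))
        np.fill_diagonal(trans, 0.0)
    else:
        trans = np.zeros((1, 1))
    return HSMMParams(
        initial=np.full(n_states, 1.0 / n_states),
        transition=trans,
        means=means,
        sds=sds,
        rates=np.clip(rates, 0.1, max_duration),
        max_duration=max_duration,
        log1p=log1p,
    )


def _dwell_q(lam: float, eta: np.ndarray, eta_c: np.ndarray, max_duration: int) -> float:
    """Expected complete-data dwell log-likelihood for one state."""
    logdur, logsurv = _duration_tables(np.array([lam]), max_duration)
    return float(eta @ logdur[0] + eta_c @ logsurv[0])


def _update_rate(lam_old, eta, eta_c, max_duration):
    """Generalized M-step for the dwell rate: bounded 1-D maximization,
    falling back to the previous value if no improvement is found."""
    total = eta.sum() + eta_c.sum()
    if total <= 0:
        return lam_old
    res = minimize_scalar(
        lambda lam: -_dwell_q(lam, eta, eta_c, max_duration),
        bounds=(1e-4, 5.0 * max_duration),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam_new = float(res.x)
    if _dwell_q(lam_new, eta, eta_c, max_duration) >= _dwell_q(
        lam_old, eta, eta_c, max_duration
    ):
        return lam_new
    return lam_old


def hsmm_fit(
    segments,
    n_states: int = 6,
    max_duration: int = 600,
    tol: float = 1e-6,
    max_iter: int = 100,
    n_restarts: int = 1,
    seed: int | None = None,
    max_epochs: int | None = None,
    log1p: bool = False,
) -> tuple[HSMMParams, FitDiagnostics]:
    """Fit the explicit-duration HSMM by EM on pooled wear segments.

    Each element of ``segments`` is one maximal wear-time magnitude sequence;
    segments are treated as independent observation sequences (state dwells
    are never bridged across non-wear gaps). When ``max_epochs`` is set,
    whole segments are subsampled (seeded) until the epoch budget is met.

    The M-step for the dwell rates performs a bounded one-dimensional
    maximization of the expected complete-data dwell log-likelihood
    (a generalized M-step), so the marginal log-likelihood is non-decreasing
    across iterations; this is asserted every iteration.

    Returns the best-of-restarts parameters, states relabelled ascending by
    emission mean, together with fit diagnostics.
    """
    segs = [np.asarray(s, dtype=float).ravel() for s in segments if len(s) > 0]
    if not segs:
        raise HSMMError("no non-empty segments to fit")
    rng = np.random.default_rng(seed)
    if max_epochs is not None and sum(len(s) for s in segs) > max_epochs:
        order = rng.permutation(len(segs))
        kept, total = [], 0
        for i in order:
            kept.append(segs[i])
            total += len(segs[i])
            if total >= max_epochs:
                break
        segs = kept
    n_epochs = sum(len(s) for s in segs)
    n_params = n_states * (n_states + 3)
    if n_epochs < 10 * n_params:
        raise HSMMError(
            f"need at least {10 * n_params} epochs to fit {n_states} states, got {n_epochs}"
        )
    pooled_sd = max(float(np.std(np.log1p(np.concatenate(segs)) if log1p else np.concatenate(segs))), 1e-9)
    sd_floor = 1e-3 * pooled_sd

    best: tuple[float, HSMMParams, FitDiagnostics] | None = None
    restart_lls = []
    for r in range(n_restarts):
        params = _init_params(segs, n_states, max_duration, rng, perturb=(r > 0), log1p=log1p)
        diag = FitDiagnostics(restart=r, n_epochs=n_epochs)
        prev_ll = -np.inf
        degenerate = False
        for it in range(max_iter):
            ll_tot = 0.0
            sw = np.zeros(n_states)
            swx = np.zeros(n_states)
            swx2 = np.zeros(n_states)
            eta = np.zeros((n_states, max_duration))
            eta_c = np.zeros((n_states, max_duration))
            xi = np.zeros((n_states, n_states))
            start = np.zeros(n_states)
            ok = True
            for seg in segs:
                tabs = _tables(params, seg)
                ll, gamma, e, ec, x_, st = _estep(*tabs)
                if not np.isfinite(ll):
                    ok = False
                    break
                ll_tot += ll
                xseg = np.log1p(seg) if log1p else seg
                sw += gamma.sum(axis=0)
                swx += gamma.T @ xseg
                swx2 += gamma.T @ (xseg * xseg)
                eta += e
                eta_c += ec
                xi += x_
                start += st
            if not ok:
                degenerate = True
                break
            diag.loglik_path.append(ll_tot)
            if ll_tot < prev_ll - 1e-6 * (1.0 + abs(prev_ll)):
                raise AssertionError(
                    f"EM log-likelihood decreased: {prev_ll} -> {ll_tot}"
                )
            if np.any(sw < 1e-8 * n_epochs / n_states**2):
                warnings.warn(
                    f"restart {r}: state responsibility mass collapsed",
                    DegenerateStateWarning,
                )
                degenerate = True
                break
            # M-step
            means = swx / sw
            variances = np.maximum(swx2 / sw - means**2, sd_floor**2)
            sds = np.sqrt(variances)
            rates = np.array(
                [
                    _update_rate(params.rates[k], eta[k], eta_c[k], max_duration)
                    for k in range(n_states)
                ]
            )
            if n_states > 1:
                trans = params.transition.copy()
                rowsum = xi.sum(axis=1)
                for k in range(n_states):
                    if rowsum[k] > 1e-12:
                        trans[k] = xi[k] / rowsum[k]
                np.fill_diagonal(trans, 0.0)
                rs = trans.sum(axis=1, keepdims=True)
                trans = np.where(rs > 0, trans / np.where(rs > 0, rs, 1.0), params.transition)
            else:
                trans = np.zeros((1, 1))
            initial = start / start.sum() if start.sum() > 0 else params.initial
            params = HSMMParams(
                initial=initial,
                transition=trans,
                means=means,
                sds=sds,
                rates=np.clip(rates, 1e-4, None),
                max_duration=max_duration,
                log1p=log1p,
            )
            diag.n_iter = it + 1
            if prev_ll > -np.inf and abs(ll_tot - prev_ll) < tol * (1.0 + abs(ll_tot)):
                diag.converged = True
                prev_ll = ll_tot
                break
            prev_ll = ll_tot
        if degenerate or not diag.loglik_path:
            restart_lls.append(-np.inf)
            continue
        final_ll = diag.loglik_path[-1]
        restart_lls.append(final_ll)
        if best is None or final_ll > best[0]:
            best = (final_ll, params, diag)
    if best is None:
        raise HSMMError("all restarts degenerated; try fewer states or more data")
    _, params, diag = best
    diag.restart_logliks = restart_lls
    return params.ordered(), diag


def decode_epoch_series(magnitudes: np.ndarray, wear: np.ndarray, params: HSMMParams) -> np.ndarray:
    """Decode a full epoch series given its wear mask.

    Each maximal wear run is decoded independently; non-wear epochs receive
    ``NON_WEAR_LABEL`` (-1). Returns a full-length int array of labels.
    """
    magnitudes = np.asarray(magnitudes, dtype=float)
    wear = np.asarray(wear, dtype=bool)
    if magnitudes.shape != wear.shape:
        raise HSMMError("magnitudes and wear mask must be aligned")
    labels = np.full(len(magnitudes), NON_WEAR_LABEL, dtype=np.int64)
    if not wear.any():
        return labels
    boundaries = np.flatnonzero(np.diff(wear.astype(np.int8)) != 0) + 1
    edges = np.concatenate([[0], boundaries, [len(wear)]])
    for a, b in zip(edges[:-1], edges[1:]):
        if wear[a]:
            labels[a:b] = hsmm_decode(magnitudes[a:b], params)
    return labels


# ---------------------------------------------------------------------------
# Intensity grouping
# ---------------------------------------------------------------------------

INACTIVE, ACTIVE, INTENSE, NON_WEAR_CAT = 0, 1, 2, 3
CATEGORY_NAMES = {INACTIVE: "inactive", ACTIVE: "active", INTENSE: "intense", NON_WEAR_CAT: "non_wear"}

_STATE_TO_CATEGORY = {
    0: INACTIVE, 1: INACTIVE,   # lowest-amplitude states: inactivity
    2: ACTIVE, 3: ACTIVE,       # mid states: activity
    4: INTENSE, 5: INTENSE,     # highest states: intense activity
    NON_WEAR_LABEL: NON_WEAR_CAT,
}


def order_and_group(states: np.ndarray) -> np.ndarray:
    """Map mean-ordered state labels 0-5 (and -1 non-wear) to intensity
    categories: states 0-1 inactive, 2-3 active, 4-5 intense."""
    states = np.asarray(states, dtype=np.int64)
    bad = set(np.unique(states)) - set(_STATE_TO_CATEGORY)
    if bad:
        raise HSMMError(f"unknown state labels: {sorted(bad)}")
    lut = np.full(8, -1, dtype=np.int64)  # index = state + 1 (non-wear at 0)
    for s, c in _STATE_TO_CATEGORY.items():
        lut[s + 1] = c
    return lut[states + 1]
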