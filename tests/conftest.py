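"""Shared fixtures and independent brute-force oracles for the test suite."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from actikid.hsmm import HSMMParams

# ---------------------------------------------------------------------------
# Enumeration oracles for the explicit-duration semi-Markov model
# ---------------------------------------------------------------------------


def random_hsmm_params(K, D, rng):
    if K == 1:
        trans = np.zeros((1, 1))
    else:
        trans = rng.random((K, K))
        np.fill_diagonal(trans, 0.0)
        trans /= trans.sum(axis=1, keepdims=True)
    pi = rng.random(K)
    pi /= pi.sum()
    return HSMMParams(
        initial=pi,
        transition=trans,
        means=np.sort(rng.normal(0, 3, K)),
        sds=rng.uniform(0.5, 2.0, K),
        rates=rng.uniform(0.5, 4.0, K),
        max_duration=D,
    )


def joint_logprob(labels, x, params):
    """Joint log-probability of one complete labelling: emissions, initial
    state, transitions at run boundaries, exact dwell pmf for completed runs
    and the dwell survival function for the final (right-censored) run."""
    labels = np.asarray(labels)
    logdur, logsurv = params.duration_logpmf()
    with np.errstate(divide="ignore"):
        logA = (
            np.log(params.transition)
            if params.n_states > 1
            else np.full((1, 1), -np.inf)
        )
        logpi = np.log(params.initial)
    lb = params.emission_logpdf(x)
    lp = lb[np.arange(len(x)), labels].sum()
    runs = []
    state, start = labels[0], 0
    for i in range(1, len(labels)):
        if labels[i] != labels[i - 1]:
            runs.append((state, i - start))
            state, start = labels[i], i
    runs.append((state, len(labels) - start))
    lp += logpi[runs[0][0]]
    for (a, _), (b, _) in zip(runs[:-1], runs[1:]):
        lp += logA[a, b]
    D = params.max_duration
    for k, d in runs[:-1]:
        lp += logdur[k, d - 1] if d <= D else -np.inf
    k, d = runs[-1]
    lp += logsurv[k, d - 1] if d <= D else -np.inf
    return lp


def enumerate_loglik(x, params):
    """Total log-likelihood by exhaustive enumeration of all K^T labellings."""
    K, T = params.n_states, len(x)
    lps = [
        joint_logprob(np.array(lab), x, params)
        for lab in itertools.product(range(K), repeat=T)
    ]
    return logsumexp(np.array(lps))


def enumerate_best(x, params):
    """Maximal joint log-probability over all labellings."""
    K, T = params.n_states, len(x)
    return max(
        joint_logprob(np.array(lab), x, params)
        for lab in itertools.product(range(K), repeat=T)
    )


# ---------------------------------------------------------------------------
# Brute-force preprocessing oracles
# ---------------------------------------------------------------------------


def naive_non_wear(mags, threshold, min_epochs):
    """Per-epoch non-wear labels by a direct full scan: an epoch is non-wear
    iff it sits in a maximal sub-threshold run strictly longer than
    ``min_epochs`` epochs."""
    n = len(mags)
    wear = np.ones(n, dtype=bool)
    i = 0
    while i < n:
        if mags[i] < threshold:
            j = i
            while j < n and mags[j] < threshold:
                j += 1
            if (j - i) > min_epochs:
                wear[i:j] = False
            i = j
        else:
            i += 1
    return wear


def naive_best_window(wear_hours, max_window):
    """(start, length, total) of the best window by full enumeration; ties
    resolved toward the earliest start then the shortest window."""
    best = None
    n = len(wear_hours)
    for start in range(n):
        for length in range(1, min(max_window, n - start) + 1):
            total = float(np.sum(wear_hours[start : start + length]))
            key = (-total, start, length)
            if best is None or key < best[0]:
                best = (key, start, length, total)
    return best[1], best[2], best[3]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
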