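"""Unit tests for the explicit-duration semi-Markov model."""

import numpy as np
import pytest
from scipy.stats import norm

from actikid.hsmm import (
    NON_WEAR_LABEL,
    HSMMParams,
    HSMMError,
    decode_epoch_series,
    hsmm_decode,
    hsmm_fit,
    hsmm_loglik,
    order_and_group,
)
from conftest import enumerate_best, enumerate_loglik, joint_logprob, random_hsmm_params


def _one_state(D=10, mu=0.0, sd=1.0, lam=2.0):
    return HSMMParams(
        initial=np.array([1.0]),
        transition=np.zeros((1, 1)),
        means=np.array([mu]),
        sds=np.array([sd]),
        rates=np.array([lam]),
        max_duration=D,
    )


class TestLoglik:
    def test_single_state_closed_form(self):
        """With one state the likelihood is the emission product times the
        truncated probability of a single dwell of at least T epochs."""
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 6)
        p = _one_state(D=10)
        _, logsurv = p.duration_logpmf()
        expected = norm.logpdf(x).sum() + logsurv[0, len(x) - 1]
        assert hsmm_loglik(x, p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(1, 4))
        D = int(rng.integers(1, 5))
        T = int(rng.integers(1, 8))
        p = random_hsmm_params(K, D, rng)
        x = rng.normal(0, 3, T)
        expected = enumerate_loglik(x, p)
        if np.isfinite(expected):
            assert hsmm_loglik(x, p) == pytest.approx(expected, abs=1e-9)

    def test_label_permutation_symmetry(self):
        """Permuting state labels together with all parameter rows leaves
        the likelihood unchanged."""
        rng = np.random.default_rng(7)
        p = random_hsmm_params(3, 4, rng)
        x = rng.normal(0, 3, 7)
        perm = np.array([2, 0, 1])
        q = HSMMParams(
            initial=p.initial[perm],
            transition=p.transition[np.ix_(perm, perm)],
            means=p.means[perm],
            sds=p.sds[perm],
            rates=p.rates[perm],
            max_duration=p.max_duration,
        )
        assert hsmm_loglik(x, p) == pytest.approx(hsmm_loglik(x, q), abs=1e-10)

    def test_nonfinite_magnitudes_rejected(self):
        p = _one_state()
        with pytest.raises(HSMMError):
            hsmm_loglik(np.array([1.0, np.nan]), p)


class TestDecode:
    def test_separable_emissions_recover_labels(self):
        rng = np.random.default_rng(0)
        p = HSMMParams(
            initial=np.array([0.5, 0.5]),
            transition=np.array([[0.0, 1.0], [1.0, 0.0]]),
            means=np.array([0.0, 50.0]),
            sds=np.array([1.0, 1.0]),
            rates=np.array([4.0, 4.0]),
            max_duration=40,
        )
        truth = np.repeat([0, 1, 0, 1, 0], [5, 4, 6, 3, 5])
        x = rng.normal(p.means[truth], 1.0)
        assert np.array_equal(hsmm_decode(x, p), truth)

    @pytest.mark.parametrize("seed", range(8))
    def test_attains_enumerated_maximum(self, seed):
        rng = np.random.default_rng(100 + seed)
        K = int(rng.integers(1, 4))
        D = int(rng.integers(2, 5))
        T = int(rng.integers(1, 8))
        p = random_hsmm_params(K, D, rng)
        x = rng.normal(0, 3, T)
        best = enumerate_best(x, p)
        if np.isfinite(best):
            path = hsmm_decode(x, p)
            assert joint_logprob(path, x, p) == pytest.approx(best, abs=1e-9)

    def test_single_state_labels_all_zero(self):
        x = np.random.default_rng(1).normal(0, 1, 5)
        assert np.array_equal(hsmm_decode(x, _one_state()), np.zeros(5, dtype=int))

    def test_runs_never_exceed_max_duration(self):
        rng = np.random.default_rng(5)
        p = random_hsmm_params(2, 3, rng)
        x = rng.normal(0, 1, 30)
        path = hsmm_decode(x, p)
        run_lengths = np.diff(
            np.concatenate([[0], np.flatnonzero(np.diff(path) != 0) + 1, [len(path)]])
        )
        assert run_lengths.max() <= p.max_duration

    def test_full_series_decode_respects_wear_mask(self):
        rng = np.random.default_rng(2)
        p = random_hsmm_params(2, 10, rng)
        mags = rng.normal(0, 2, 50)
        wear = np.ones(50, dtype=bool)
        wear[10:25] = False
        labels = decode_epoch_series(np.abs(mags), wear, p)
        assert np.all(labels[~wear] == NON_WEAR_LABEL)
        assert np.all(labels[wear] >= 0)


class TestFit:
    def _sim(self, params, n_segments, seg_len, rng):
        from actikid.synthetic import _simulate_chain, _truncated_gaussian_counts

        segs = []
        for _ in range(n_segments):
            st = _simulate_chain(params, seg_len, rng)
            segs.append(_truncated_gaussian_counts(params.means[st], params.sds[st], rng))
        return segs

    def test_loglik_monotone_and_recovery(self):
        rng = np.random.default_rng(42)
        true = HSMMParams(
            initial=np.full(2, 0.5),
            transition=np.array([[0.0, 1.0], [1.0, 0.0]]),
            means=np.array([20.0, 100.0]),
            sds=np.array([8.0, 15.0]),
            rates=np.array([5.0, 9.0]),
            max_duration=40,
        )
        segs = self._sim(true, 8, 1500, rng)
        params, diag = hsmm_fit(segs, n_states=2, max_duration=40, seed=0)
        deltas = np.diff(diag.loglik_path)
        assert np.all(deltas >= -1e-6 * np.abs(diag.loglik_path[:-1]))
        assert params.means == pytest.approx(true.means, rel=0.10)
        assert params.rates == pytest.approx(true.rates, rel=0.20)

    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        segs = [np.abs(rng.normal(20, 10, 800)) for _ in range(3)]
        a, _ = hsmm_fit(segs, n_states=2, max_duration=20, n_restarts=3, seed=5, max_iter=10)
        b, _ = hsmm_fit(segs, n_states=2, max_duration=20, n_restarts=3, seed=5, max_iter=10)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.rates, b.rates)
        assert np.array_equal(a.transition, b.transition)

    def test_states_ordered_by_mean(self):
        rng = np.random.default_rng(10)
        segs = self._sim(
            HSMMParams(
                initial=np.full(2, 0.5),
                transition=np.array([[0.0, 1.0], [1.0, 0.0]]),
                means=np.array([10.0, 80.0]),
                sds=np.array([5.0, 10.0]),
                rates=np.array([4.0, 4.0]),
                max_duration=30,
            ),
            5,
            1000,
            rng,
        )
        params, _ = hsmm_fit(segs, n_states=2, max_duration=30, seed=1)
        assert np.all(np.diff(params.means) >= 0)

    def test_too_few_epochs_rejected(self):
        with pytest.raises(HSMMError):
            hsmm_fit([np.ones(20)], n_states=6)


class TestParams:
    def test_validation_errors(self):
        good = dict(
            initial=np.array([0.5, 0.5]),
            transition=np.array([[0.0, 1.0], [1.0, 0.0]]),
            means=np.array([0.0, 1.0]),
            sds=np.array([1.0, 1.0]),
            rates=np.array([1.0, 1.0]),
        )
        HSMMParams(**good)
        for key, bad in [
            ("initial", np.array([0.7, 0.7])),
            ("transition", np.array([[0.5, 0.5], [1.0, 0.0]])),
            ("sds", np.array([1.0, -1.0])),
            ("rates", np.array([0.0, 1.0])),
        ]:
            with pytest.raises(HSMMError):
                HSMMParams(**{**good, key: bad})

    def test_json_round_trip(self, tmp_path):
        p = random_hsmm_params(3, 12, np.random.default_rng(0))
        path = tmp_path / "model.json"
        p.save(path)
        q = HSMMParams.load(path)
        assert np.allclose(p.means, q.means)
        assert np.allclose(p.transition, q.transition)
        assert p.max_duration == q.max_duration


class TestGrouping:
    def test_state_to_category_mapping(self):
        cats = order_and_group(np.array([0, 1, 2, 3, 4, 5]))
        assert cats.tolist() == [0, 0, 1, 1, 2, 2]  # inactive x2, active x2, intense x2

    def test_non_wear_preserved(self):
        cats = order_and_group(np.array([NON_WEAR_LABEL] * 4))
        assert np.all(cats == 3)

    def test_unknown_label_rejected(self):
        with pytest.raises(HSMMError):
            order_and_group(np.array([0, 6]))

    def test_group_then_count_commutes(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            states = rng.integers(-1, 6, 50)
            cats = order_and_group(states)
            n_active_via_states = np.isin(states, [2, 3, 4, 5]).sum()
            assert (cats >= 1).sum() - (cats == 3).sum() == n_active_via_states
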