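"""HMM coarse-graining: PCCA+ init, Baum-Welch recovery, sampling."""

import numpy as np
import pytest
from sklearn.metrics import rand_score

from confland import hmm_coarse, msm, synthgen
from conftest import permuted_max_error


def block_T(eps, sizes=(2, 2)):
    """Block 2x2-metastable chain with inter-block coupling eps."""
    n = sum(sizes)
    T = np.full((n, n), eps / n)
    start = 0
    for s in sizes:
        T[start : start + s, start : start + s] = (1 - eps) / s
        start += s
    return T / T.sum(axis=1, keepdims=True)


class TestPccaInit:
    def test_block_diagonal_gives_indicators(self):
        T = block_T(0.0)
        # make irreducible within blocks only; pad pi by hand
        model = msm.MarkovModel(
            lag=1, counts=T * 100, T=T, pi=np.full(4, 0.25), active_set=np.arange(4)
        )
        chi = hmm_coarse.pcca_init(model, 2)
        labels = chi.argmax(axis=1)
        assert len(set(labels[:2])) == 1 and len(set(labels[2:])) == 1
        assert labels[0] != labels[2]
        np.testing.assert_allclose(chi.max(axis=1), 1.0, atol=1e-8)

    def test_single_macrostate_all_ones(self, micro_model):
        chi = hmm_coarse.pcca_init(micro_model, 1)
        np.testing.assert_array_equal(chi, np.ones((micro_model.n_states, 1)))

    def test_weakly_coupled_three_blocks_recovered(self):
        rng = np.random.default_rng(0)
        T = block_T(0.02, sizes=(3, 3, 3))
        d = [0]
        cum = np.cumsum(T, axis=1)
        for _ in range(100_000):
            d.append(int(np.searchsorted(cum[d[-1]], rng.random())))
        model = msm.estimate_msm_from_dtrajs([np.array(d)], 1)
        chi = hmm_coarse.pcca_init(model, 3)
        labels = chi.argmax(axis=1)
        blocks = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])[model.active_set]
        # constructed-chain oracle: argmax partition equals the blocks
        assert rand_score(blocks, labels) == 1.0

    def test_rows_are_memberships(self, micro_model):
        chi = hmm_coarse.pcca_init(micro_model, 3)
        assert np.all(chi >= 0)
        np.testing.assert_allclose(chi.sum(axis=1), 1.0, atol=1e-10)


@pytest.fixture(scope="module")
def micro_model(traj_set, generator):
    return msm.estimate_msm_from_dtrajs(traj_set.true_micro_paths, 1)


@pytest.fixture(scope="module")
def fitted_hmm(traj_set, generator):
    return hmm_coarse.fit_hmm(traj_set.true_micro_paths, generator.n_macro, lag=1)


class TestFitHmm:
    def test_recovers_generator(self, fitted_hmm, traj_set, generator):
        err = permuted_max_error(fitted_hmm.macro_T, generator.macro_T)
        assert err < 0.05
        # macrostate path recovery via argmax membership of observed microstates
        labels = hmm_coarse.assign_macrostates(fitted_hmm)
        pred = np.concatenate([labels[d] for d in traj_set.true_micro_paths])
        truth = np.concatenate(traj_set.true_macro_paths)
        assert rand_score(truth, pred) >= 0.95

    def test_loglik_nondecreasing(self, fitted_hmm):
        diffs = np.diff(fitted_hmm.loglik_trace)
        assert np.all(diffs > -1e-6 * np.abs(fitted_hmm.loglik_trace[:-1]).max())

    def test_single_macrostate_reduces_to_frequencies(self, traj_set):
        h = hmm_coarse.fit_hmm(traj_set.true_micro_paths, 1, lag=1)
        np.testing.assert_allclose(h.macro_T, [[1.0]])
        all_frames = np.concatenate(traj_set.true_micro_paths)
        freqs = np.bincount(all_frames, minlength=h.n_micro) / len(all_frames)
        np.testing.assert_allclose(h.obs[0], freqs, atol=1e-6)

    def test_row_sums_and_membership_normalization(self, fitted_hmm):
        np.testing.assert_allclose(fitted_hmm.macro_T.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(fitted_hmm.obs.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(fitted_hmm.memberships.sum(axis=1), 1.0, atol=1e-10)

    def test_too_many_macrostates_rejected(self):
        with pytest.raises(ValueError):
            hmm_coarse.fit_hmm([np.array([0, 1, 0, 1])], n_macro=3, lag=1)

    def test_recovery_improves_with_data(self, generator):
        errs = []
        for n_frames in (5_000, 50_000):
            meds = []
            for seed in range(3):
                ts = synthgen.sample_trajectories(
                    generator, 20, n_frames // 20, 4, seed=100 * seed + n_frames
                )
                h = hmm_coarse.fit_hmm(ts.true_micro_paths, generator.n_macro, lag=1)
                meds.append(permuted_max_error(h.macro_T, generator.macro_T))
            errs.append(np.median(meds))
        assert errs[1] < errs[0]

    def test_fixed_point_of_hmmlearn_em(self, traj_set, generator):
        """Independent cross-check: our optimum is a fixed point of hmmlearn's EM.

        hmmlearn's CategoricalHMM is initialized at our fitted parameters; if
        Baum-Welch converged, further EM sweeps by the reference
        implementation must not move the transition matrix materially.
        """
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        seqs = [d[:500] for d in traj_set.true_micro_paths[:20]]
        ours = hmm_coarse.fit_hmm(seqs, generator.n_macro, lag=1, tol=1e-10)
        X = np.concatenate(seqs)[:, None]
        lengths = [len(s) for s in seqs]
        ref = hmmlearn.CategoricalHMM(
            n_components=generator.n_macro, n_iter=20, tol=1e-12,
            random_state=0, init_params="", params="ste",
        )
        ref.startprob_ = ours.macro_pi
        ref.transmat_ = ours.macro_T
        ref.emissionprob_ = ours.obs
        ref.fit(X, lengths)
        assert np.max(np.abs(ref.transmat_ - ours.macro_T)) < 0.02


class TestAssignMacrostates:
    def test_argmax_and_tie_rule(self):
        h = hmm_coarse.HiddenMarkovModel(
            lag=1,
            macro_T=np.array([[0.9, 0.1], [0.1, 0.9]]),
            obs=np.array([[0.60, 0.25, 0.15], [0.15, 0.25, 0.60]]),
            macro_pi=np.array([0.5, 0.5]),
        )
        labels = hmm_coarse.assign_macrostates(h)
        assert labels[0] == 0
        assert labels[1] == 0  # 0.5/0.5 tie broken toward the lower index
        assert labels[2] == 1

    def test_matches_bruteforce_argmax(self, fitted_hmm):
        labels = hmm_coarse.assign_macrostates(fitted_hmm)
        oracle = np.array(
            [int(np.argmax(fitted_hmm.memberships[m])) for m in range(fitted_hmm.n_micro)]
        )
        np.testing.assert_array_equal(labels, oracle)

    def test_permutation_equivariance(self, fitted_hmm):
        perm = np.array([2, 0, 1])[: fitted_hmm.n_macro]
        h2 = hmm_coarse.HiddenMarkovModel(
            lag=fitted_hmm.lag,
            macro_T=fitted_hmm.macro_T[np.ix_(perm, perm)],
            obs=fitted_hmm.obs[perm],
            macro_pi=fitted_hmm.macro_pi[perm],
        )
        l1 = hmm_coarse.assign_macrostates(fitted_hmm)
        l2 = hmm_coarse.assign_macrostates(h2)
        inv = np.argsort(perm)
        np.testing.assert_array_equal(l2, inv[l1])


class TestSampleLongTrajectory:
    def test_single_step_from_stationary(self, fitted_hmm):
        counts = np.bincount(
            [int(hmm_coarse.sample_long_trajectory(fitted_hmm, 1, seed=s)[0]) for s in range(300)],
            minlength=fitted_hmm.n_macro,
        )
        freq = counts / 300
        se = np.sqrt(fitted_hmm.macro_pi * (1 - fitted_hmm.macro_pi) / 300)
        assert np.all(np.abs(freq - fitted_hmm.macro_pi) < 4 * se + 0.02)

    def test_long_sample_matches_stationary(self, fitted_hmm):
        path = hmm_coarse.sample_long_trajectory(fitted_hmm, 100_000, seed=4)
        freq = np.bincount(path, minlength=fitted_hmm.n_macro) / len(path)
        n_eff = len(path) / 80.0  # decorrelate by the slowest timescale
        se = np.sqrt(fitted_hmm.macro_pi * (1 - fitted_hmm.macro_pi) / n_eff)
        assert np.all(np.abs(freq - fitted_hmm.macro_pi) < 3 * se + 1e-3)

    def test_two_ms_at_fifty_ns_steps_visits_everything(self, fitted_hmm):
        # 2 ms of dynamics at a 50 ns step is 40,000 steps
        n_steps = int(2e-3 / 50e-9)
        assert n_steps == 40_000
        path = hmm_coarse.sample_long_trajectory(fitted_hmm, n_steps, seed=9)
        assert set(path.tolist()) == set(range(fitted_hmm.n_macro))

    def test_micro_emission_and_determinism(self, fitted_hmm):
        a = hmm_coarse.sample_long_trajectory(fitted_hmm, 500, seed=3, emit="micro")
        b = hmm_coarse.sample_long_trajectory(fitted_hmm, 500, seed=3, emit="micro")
        np.testing.assert_array_equal(a, b)
        assert a.max() < fitted_hmm.n_micro


def test_macrostate_sweep_reports(traj_set):
    table = hmm_coarse.macrostate_sweep(traj_set.true_micro_paths[:10], [1, 2, 3], lag=1)
    assert list(table["n_macro"]) == [1, 2, 3]
    assert table["loglik"].notna().all()
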