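"""MSM estimation, scoring and validation against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import beta as beta_dist

from confland import msm, synthgen
from confland._types import DiscreteTrajectorySet, FeatureTrajectory


@pytest.fixture(scope="module")
def micro_dts(traj_set, generator):
    return DiscreteTrajectorySet(
        traj_set.true_micro_paths, generator.n_micro, group_ids=traj_set.group_ids
    )


class TestCountMatrix:
    def test_hand_count(self):
        C = msm.count_matrix([[0, 1, 0, 1]], lag=1)
        np.testing.assert_array_equal(C, [[0, 2], [1, 0]])

    def test_lag_equals_length_minus_one(self):
        C = msm.count_matrix([[0, 1, 1, 2]], lag=3)
        assert C.sum() == 1
        assert C[0, 2] == 1

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        dtrajs = [rng.integers(0, 4, size=n) for n in (20, 35, 50)]
        for lag in (1, 3, 7):
            C = msm.count_matrix(dtrajs, lag)
            assert C.sum() == sum(n - lag for n in (20, 35, 50))

    def test_lag_too_long_rejected(self):
        with pytest.raises(ValueError):
            msm.count_matrix([[0, 1]], lag=5)


class TestEstimateMsm:
    def test_symmetric_counts_give_row_normalized(self):
        C = np.array([[8.0, 2.0, 1.0], [2.0, 6.0, 3.0], [1.0, 3.0, 9.0]])
        m = msm.estimate_msm(C)
        np.testing.assert_allclose(m.T, C / C.sum(axis=1, keepdims=True), atol=1e-10)

    def test_detailed_balance_and_direct_likelihood_oracle(self):
        C = np.array([[90.0, 10.0, 3.0], [20.0, 80.0, 6.0], [2.0, 9.0, 70.0]])
        m = msm.estimate_msm(C)
        # detailed balance
        db = m.pi[:, None] * m.T
        np.testing.assert_allclose(db, db.T, atol=1e-10)
        # independent oracle: direct likelihood maximization over the
        # symmetric-weight parameterization x_ij (reversible by construction)
        iu = np.triu_indices(3)

        def negloglik(logx):
            x = np.zeros((3, 3))
            x[iu] = np.exp(logx)
            x = x + np.triu(x, 1).T
            T = x / x.sum(axis=1, keepdims=True)
            return -np.sum(C * np.log(T))

        x0 = np.log((C + C.T)[iu] / C.sum())
        res = minimize(negloglik, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        x = np.zeros((3, 3))
        x[iu] = np.exp(res.x)
        x = x + np.triu(x, 1).T
        T_oracle = x / x.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(m.T, T_oracle, atol=1e-6)

    def test_isolated_state_excluded(self):
        C = np.zeros((3, 3))
        C[:2, :2] = [[5, 3], [2, 4]]
        C[2, 2] = 7.0  # self-loop only, unreachable
        m = msm.estimate_msm(C)
        np.testing.assert_array_equal(m.active_set, [0, 1])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            msm.estimate_msm(np.array([[1.0, -1.0], [1.0, 1.0]]))


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        # exact chain: lambda2 = 1 - p - q; t2 = -lag / ln(lambda2)
        p, q = 0.05, 0.1
        rng = np.random.default_rng(3)
        T = np.array([[1 - p, p], [q, 1 - q]])
        d = [0]
        cum = np.cumsum(T, axis=1)
        for _ in range(200_000):
            d.append(int(np.searchsorted(cum[d[-1]], rng.random())))
        table = msm.implied_timescales([np.array(d)], lags=[1, 2], n_its=1)
        lam2 = 1 - p - q
        assert table.loc[1, "t2"] == pytest.approx(-1 / np.log(lam2), rel=0.1)

    def test_flat_in_lag_for_markovian_data(self, micro_dts, generator):
        table = msm.implied_timescales(micro_dts, lags=[1, 2, 5, 10], n_its=2)
        t2 = table["t2"].to_numpy()
        assert np.all(np.abs(t2 - 80.0) / 80.0 < 0.15)

    def test_nonpositive_eigenvalues_undefined(self):
        # period-2 alternation: lambda2 = -1 -> timescale undefined, not negative
        table = msm.implied_timescales([np.array([0, 1] * 50)], lags=[1], n_its=1)
        assert np.isnan(table.loc[1, "t2"])


class TestShuffleSplit:
    def test_two_groups(self):
        (tr, te), *_ = msm.shuffle_split([0, 0, 1, 1], n_splits=1, seed=0)
        assert len(tr) == 1 and len(te) == 1 and set(tr) != set(te)

    def test_nine_groups_partition(self):
        splits = msm.shuffle_split(list(range(9)), ratio=0.5, n_splits=5, seed=1)
        for tr, te in splits:
            assert len(tr) in (4, 5)
            assert len(te) == 9 - len(tr)
            assert set(tr) & set(te) == set()
            assert set(tr) | set(te) == set(range(9))

    def test_deterministic(self):
        a = msm.shuffle_split(list(range(7)), n_splits=3, seed=5)
        b = msm.shuffle_split(list(range(7)), n_splits=3, seed=5)
        for (t1, s1), (t2, s2) in zip(a, b):
            np.testing.assert_array_equal(t1, t2)
            np.testing.assert_array_equal(s1, s2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            msm.shuffle_split([0, 0, 0])


class TestVamp2Score:
    def test_identity_model_scores_rank(self):
        m = msm.MarkovModel(
            lag=1, counts=np.eye(10) * 100, T=np.eye(10),
            pi=np.full(10, 0.1), active_set=np.arange(10),
        )
        assert msm.vamp2_score(m, None, rank=10) == pytest.approx(10.0)

    def test_train_equals_test_equality(self, micro_dts):
        model = msm.estimate_msm_from_dtrajs(micro_dts.dtrajs, lag=1)
        lam = model.eigenvalues()[:10]
        in_sample = float(np.sum(lam**2))
        out = msm.vamp2_score(model, micro_dts.dtrajs, rank=10)
        assert out == pytest.approx(in_sample, abs=1e-8)

    def test_true_discretization_beats_lumping(self, micro_dts, generator):
        # mis-lumped model: microstates folded onto 2 labels, merging macrostates
        lump = np.arange(generator.n_micro) % 2
        lumped = [lump[d] for d in micro_dts.dtrajs]
        splits = msm.shuffle_split(micro_dts.group_ids, n_splits=5, seed=2)
        wins = 0
        for tr_g, te_g in splits:
            tr = [d for d, g in zip(micro_dts.dtrajs, micro_dts.group_ids) if g in tr_g]
            te = [d for d, g in zip(micro_dts.dtrajs, micro_dts.group_ids) if g in te_g]
            tr_l = [lump[d] for d in tr]
            te_l = [lump[d] for d in te]
            s_full = msm.vamp2_score(msm.estimate_msm_from_dtrajs(tr, 1), te, rank=10)
            s_lump = msm.vamp2_score(msm.estimate_msm_from_dtrajs(tr_l, 1), te_l, rank=10)
            wins += s_full > s_lump
        assert wins >= 4

    def test_in_sample_monotone_under_refinement_lumping(self, micro_dts, generator):
        # lumping a perfect partition cannot increase the VAMP-2 score
        model_full = msm.estimate_msm_from_dtrajs(micro_dts.dtrajs, 1)
        block = np.array(
            [int(np.nonzero(generator.emission[:, m])[0][0]) for m in range(generator.n_micro)]
        )
        lumped = [block[d] for d in micro_dts.dtrajs]
        model_lump = msm.estimate_msm_from_dtrajs(lumped, 1)
        assert msm.vamp2_score(model_full, None, 10) >= msm.vamp2_score(model_lump, None, 10) - 1e-9


class TestCkTest:
    def test_factor_one_is_exact(self, micro_dts):
        model = msm.estimate_msm_from_dtrajs(micro_dts.dtrajs, 1)
        table = msm.ck_test(model, micro_dts.dtrajs, factors=[1])
        one = table[table["factor"] == 1]
        np.testing.assert_allclose(one["predicted"], one["estimated"], atol=1e-8)

    def test_markovian_data_pass(self, micro_dts, generator):
        from confland import hmm_coarse

        model = msm.estimate_msm_from_dtrajs(micro_dts.dtrajs, 1)
        chi = hmm_coarse.pcca_init(model, generator.n_macro)
        table = msm.ck_test(model, micro_dts.dtrajs, memberships=chi, factors=[2, 3, 4, 5])
        assert msm.ck_within_bars(table) >= 0.8

    def test_non_markovian_counterexample_fails(self):
        # hidden 3-state chain whose lumped pair mixes short dwells (state 1)
        # with near-absorbing dwells (state 2): observing {0} vs {1, 2} hides a
        # slow process, so dwell times are a mixture and the lumped chain is
        # strongly non-Markovian
        T = np.array(
            [
                [0.90, 0.10, 0.00],
                [0.10, 0.895, 0.005],
                [0.00, 0.001, 0.999],
            ]
        )
        rng = np.random.default_rng(6)
        from confland.synthgen import _sample_markov_paths

        start = rng.integers(0, 3, size=50)
        paths = _sample_markov_paths(T, start, 2000, rng)
        lump = np.array([0, 1, 1])
        obs = [lump[p] for p in paths]
        model = msm.estimate_msm_from_dtrajs(obs, 1)
        table = msm.ck_test(model, obs, factors=[2, 3, 4, 5])
        assert msm.ck_within_bars(table) < 0.5


class TestEscapeProbability:
    def test_all_self_transitions(self):
        est = msm.escape_probability([np.zeros(100, dtype=int)], lags=[1], n_boot=0)[0]
        assert est.f == 1.0 and est.ci_high == 1.0

    def test_beta_interval_oracle(self):
        # M = 50 of N = 100 at lag 1: CI is the Beta(50, 50) central interval
        d = np.array([0, 0] * 25 + [0, 1] * 25)  # 50 self, 50 out of state 0
        # construct explicitly: state 0 appears with 50 self-transitions of 100
        est = msm.escape_probability([d], lags=[1], states=[0], n_boot=0)[0]
        assert est.N >= 50  # sanity on the fixture
        lo, hi = beta_dist.ppf([0.025, 0.975], est.Neff * est.f, est.Neff * (1 - est.f))
        assert est.ci_low == pytest.approx(lo, abs=1e-12)
        assert est.ci_high == pytest.approx(hi, abs=1e-12)
        assert beta_dist.ppf(0.025, 50, 50) == pytest.approx(0.402, abs=5e-3)
        assert beta_dist.ppf(0.975, 50, 50) == pytest.approx(0.598, abs=5e-3)

    def test_ci_width_shrinks_with_more_data(self, generator):
        widths = []
        for n in (500, 5_000, 50_000):
            ts = synthgen.sample_trajectories(generator, 10, n // 10, 2, seed=8)
            est = msm.escape_probability(ts.true_macro_paths, lags=[1], states=[0], n_boot=0)[0]
            widths.append(est.ci_high - est.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_bootstrap_interval_brackets_truth(self, generator, traj_set):
        est = msm.escape_probability(
            traj_set.true_macro_paths, lags=[1], states=[0], n_boot=40, seed=1
        )[0]
        assert est.ci_low <= generator.macro_T[0, 0] <= est.ci_high


class TestHyperparameterSearch:
    def test_single_point_table(self, traj_set):
        table = msm.hyperparameter_search(
            traj_set, [{"tica_lag": 5, "n_clusters": 12}], seed=0, n_splits=3
        )
        assert len(table) == 1
        assert table.loc[0, "sd_score"] >= 0

    def test_sufficient_clusters_outrank_two_state_lumping(self, traj_set, generator):
        grid = [
            {"tica_lag": 5, "n_clusters": 2},
            {"tica_lag": 5, "n_clusters": generator.n_micro},
        ]
        table = msm.hyperparameter_search(traj_set, grid, seed=1, n_splits=3)
        assert table.loc[0, "n_clusters"] == generator.n_micro

    def test_reproducible_under_seed(self, traj_set):
        grid = [{"tica_lag": 5, "n_clusters": 6}]
        a = msm.hyperparameter_search(traj_set, grid, seed=4, n_splits=2)
        b = msm.hyperparameter_search(traj_set, grid, seed=4, n_splits=2)
        assert a.loc[0, "mean_score"] == b.loc[0, "mean_score"]


class TestReversibleRecovery:
    def test_estimator_converges_with_data(self, generator):
        Tm = synthgen.micro_transition_matrix(generator)
        errs = []
        for n in (2_000, 20_000, 100_000):
            ts = synthgen.sample_trajectories(
                generator, 20, n // 20, 4, seed=n, start_by_group=False
            )
            m = msm.estimate_msm_from_dtrajs(ts.true_micro_paths, 1)
            T_full = np.zeros_like(Tm)
            T_full[np.ix_(m.active_set, m.active_set)] = m.T
            errs.append(np.max(np.abs(T_full[np.ix_(m.active_set, m.active_set)] -
                                      Tm[np.ix_(m.active_set, m.active_set)])))
        assert errs[2] < errs[0]

    def test_stationary_distribution_recovery(self, generator):
        pim = synthgen.micro_stationary_distribution(generator)
        ts = synthgen.sample_trajectories(generator, 100, 10_000, 10, seed=42,
                                          start_by_group=False)
        m = msm.estimate_msm_from_dtrajs(ts.true_micro_paths, 1)
        pi_full = np.zeros(generator.n_micro)
        pi_full[m.active_set] = m.pi
        assert 0.5 * np.abs(pi_full - pim).sum() < 0.02
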