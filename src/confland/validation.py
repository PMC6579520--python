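"""Synthetic self-validation experiments for the full pipeline.

Each function sets up a ground-truth generator, runs one stage of the
analysis on data sampled from it, and reports recovery metrics against the
known truth.  These experiments double as an executable record of the
package's statistical behavior under its reference study conditions:

* MSM estimation on a 3-macrostate / 12-microstate metastable generator with
  relaxation timescales of 80 and 15 steps, sampled as 200 trajectories of
  5,000 steps in 10 seed groups;
* HMM coarse-graining on the same data;
* group-wise cross-validated VAMP-2 model discrimination;
* tICA slow-direction recovery on a linearly mixed two-timescale process;
* Chapman-Kolmogorov behavior on Markovian data and on a lumped
  mixture-dwell counterexample;
* frequentist coverage of the Beta escape-probability intervals;
* two-step binding-kinetics parameter recovery at the stopped-flow design
  (1 µM enzyme, 16–2000 µM ligand in 8 doubling steps) and the
  induced-fit vs conformational-selection model comparison.

All randomness flows from the single ``seed`` argument.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

from . import hmm_coarse, kinetics, msm, synthgen, tica
from ._types import DiscreteTrajectorySet

# reference study conditions ------------------------------------------------
N_MACRO, N_MICRO = 3, 12
TIMESCALES = (80.0, 15.0)  # steps
N_TRAJ, TRAJ_LEN, N_GROUPS = 200, 5000, 10

RATES_TRUE = kinetics.TwoStepRates(0.3, 92.7, 0.2, 6.0)  # Kd1=309 uM, Keq=30
OBSERVABLE_TRUE = kinetics.ObservableModel(1.0, 0.45, 0.25, 0.1)
CONCENTRATIONS = (16.0, 31.0, 63.0, 125.0, 250.0, 500.0, 1000.0, 2000.0)  # uM
T_GRID = np.linspace(0.0, 1.0, 1000)  # s


def _permuted_max_error(A: np.ndarray, B: np.ndarray) -> float:
    n = A.shape[0]
    return min(float(np.max(np.abs(A[np.ix_(p, p)] - B))) for p in permutations(range(n)))


def _rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Rand index between two labelings (pair-counting, contingency form)."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    C = np.zeros((int(a.max()) + 1, int(b.max()) + 1))
    np.add.at(C, (a, b), 1.0)
    same = np.sum(C * (C - 1)) / 2
    sa = np.sum(np.bincount(a) * (np.bincount(a) - 1)) / 2
    sb = np.sum(np.bincount(b) * (np.bincount(b) - 1)) / 2
    total = n * (n - 1) / 2
    return float((total + 2 * same - sa - sb) / total)


def reference_generator(seed: int) -> synthgen.GeneratorModel:
    return synthgen.make_generator(N_MACRO, N_MICRO, list(TIMESCALES), seed=seed)


def msm_recovery_experiment(seed: int, n_seeds: int = 10) -> dict:
    """Stationary-distribution and timescale recovery of the reversible MSM.

    Returns medians over sampling seeds of the total-variation distance to
    the true microstate stationary distribution and of the relative errors
    of the two slowest implied timescales.
    """
    gen = reference_generator(seed)
    pi_true = synthgen.micro_stationary_distribution(gen)
    tvs, errs = [], []
    for k in range(n_seeds):
        ts = synthgen.sample_trajectories(
            gen, N_TRAJ, TRAJ_LEN, N_GROUPS, seed=seed + 1000 * (k + 1)
        )
        m = msm.estimate_msm_from_dtrajs(ts.true_micro_paths, 1)
        pi_full = np.zeros(N_MICRO)
        pi_full[m.active_set] = m.pi
        tvs.append(0.5 * float(np.abs(pi_full - pi_true).sum()))
        t_est = m.timescales()[:2]
        errs.append(np.abs(t_est - np.array(TIMESCALES)) / np.array(TIMESCALES))
    return {
        "tv_median": float(np.median(tvs)),
        "timescale_rel_err_median": float(np.median(np.max(errs, axis=1))),
        "per_timescale_rel_err_median": np.median(np.array(errs), axis=0),
        "n_frames": N_TRAJ * TRAJ_LEN,
        "n_seeds": n_seeds,
    }


def hmm_recovery_experiment(seed: int) -> dict:
    """Baum-Welch recovery of the macrostate transition matrix and paths."""
    gen = reference_generator(seed)
    ts = synthgen.sample_trajectories(gen, N_TRAJ, TRAJ_LEN, N_GROUPS, seed=seed + 500)
    h = hmm_coarse.fit_hmm(ts.true_micro_paths, N_MACRO, lag=1, max_iter=50, tol=1e-3)
    err = _permuted_max_error(h.macro_T, gen.macro_T)
    labels = hmm_coarse.assign_macrostates(h)
    pred = np.concatenate([labels[d] for d in ts.true_micro_paths])
    truth = np.concatenate(ts.true_macro_paths)
    return {
        "macro_T_max_error": err,
        "rand_index": _rand_index(truth, pred),
        "n_frames": N_TRAJ * TRAJ_LEN,
    }


def vamp2_discrimination_experiment(seed: int, n_splits: int = 5) -> dict:
    """Cross-validated VAMP-2: true-resolution vs 2-state-lumped discretization.

    Also verifies that scoring a model on its own training data reproduces
    the in-sample eigenvalue formula.
    """
    gen = reference_generator(seed)
    ts = synthgen.sample_trajectories(gen, N_TRAJ, TRAJ_LEN, N_GROUPS, seed=seed + 700)
    dtrajs = ts.true_micro_paths
    lump = np.arange(N_MICRO) % 2
    splits = msm.shuffle_split(ts.group_ids, n_splits=n_splits, seed=seed + 3)
    wins = 0
    for tr_g, te_g in splits:
        tr = [d for d, g in zip(dtrajs, ts.group_ids) if g in tr_g]
        te = [d for d, g in zip(dtrajs, ts.group_ids) if g in te_g]
        s_full = msm.vamp2_score(msm.estimate_msm_from_dtrajs(tr, 1), te, rank=10)
        s_lump = msm.vamp2_score(
            msm.estimate_msm_from_dtrajs([lump[d] for d in tr], 1),
            [lump[d] for d in te],
            rank=10,
        )
        wins += int(s_full > s_lump)
    model = msm.estimate_msm_from_dtrajs(dtrajs, 1)
    in_sample = float(np.sum(model.eigenvalues()[:10] ** 2))
    out = msm.vamp2_score(model, dtrajs, rank=10)
    return {
        "wins": wins,
        "n_splits": n_splits,
        "train_test_identity_gap": abs(out - in_sample),
    }


def tica_recovery_experiment(seed: int, n_frames: int = 100_000) -> dict:
    """Slow-direction recovery on a linearly mixed two-timescale process."""
    tset, slow_series, v_true = synthgen.sample_two_timescale_process(
        100.0, 10.0, n_frames, seed=seed + 17
    )
    model = tica.fit_tica(tset.trajectories, lag=5)
    proj = tica.transform(model, tset.trajectories, n_components=1)[0].features[:, 0]
    corr = float(abs(np.corrcoef(proj, slow_series)[0, 1]))
    v = model.components[:, 0]
    cos = float(abs(v_true @ v) / np.linalg.norm(v_true) / np.linalg.norm(v))
    return {"series_correlation": corr, "direction_cosine": cos, "n_frames": n_frames}


def ck_consistency_experiment(seed: int) -> dict:
    """Chapman-Kolmogorov on Markovian data vs a lumped non-Markovian chain."""
    gen = reference_generator(seed)
    ts = synthgen.sample_trajectories(gen, 100, 2000, N_GROUPS, seed=seed + 29)
    model = msm.estimate_msm_from_dtrajs(ts.true_micro_paths, 1)
    chi = hmm_coarse.pcca_init(model, N_MACRO)
    table = msm.ck_test(model, ts.true_micro_paths, memberships=chi, factors=[2, 3, 4, 5])
    frac_markov = msm.ck_within_bars(table)

    # counterexample: lumping a fast-exchanging and a near-absorbing state
    T_bad = np.array(
        [
            [0.90, 0.10, 0.00],
            [0.10, 0.895, 0.005],
            [0.00, 0.001, 0.999],
        ]
    )
    rng = np.random.default_rng(seed + 31)
    start = rng.integers(0, 3, size=50)
    paths = synthgen._sample_markov_paths(T_bad, start, 2000, rng)
    lumped = [np.array([0, 1, 1])[p] for p in paths]
    bad_model = msm.estimate_msm_from_dtrajs(lumped, 1)
    bad_table = msm.ck_test(bad_model, lumped, factors=[2, 3, 4, 5])
    frac_bad = msm.ck_within_bars(bad_table)
    return {"markov_within_bars": frac_markov, "lumped_within_bars": frac_bad}


def escape_ci_coverage_experiment(
    seed: int, n_replicates: int = 500, n_traj: int = 25, length: int = 200
) -> dict:
    """Empirical coverage of the Beta escape-probability 95% intervals.

    Each replicate samples fresh macrostate trajectories, builds the interval
    for the persistence probability of state 0 at lag 1, and checks whether
    the generator's true self-transition probability lies inside.
    """
    gen = reference_generator(seed)
    truth = float(gen.macro_T[0, 0])
    rng = np.random.default_rng(seed + 41)
    hits = 0
    for _ in range(n_replicates):
        start = rng.integers(0, N_MACRO, size=n_traj)
        paths = synthgen._sample_markov_paths(gen.macro_T, start, length, rng)
        est = msm.escape_probability(list(paths), lags=[1], states=[0], n_boot=0)[0]
        hits += int(est.ci_low <= truth <= est.ci_high)
    return {"coverage_pct": 100.0 * hits / n_replicates, "n_replicates": n_replicates}


def _clean_dataset() -> kinetics.StoppedFlowDataset:
    return kinetics.simulate_traces(
        RATES_TRUE, OBSERVABLE_TRUE, list(CONCENTRATIONS), T_GRID, noise_sd=0.0
    )


def kinetics_recovery_experiment(seed: int, n_noise_seeds: int = 20) -> dict:
    """Two-step global-fit recovery and the rejected-alternative comparison.

    Noiseless traces must return the true rate constants; with Gaussian noise
    at 1% of the dynamic range the first-step dissociation constant
    Kd1 = k-1/k1 must be recovered; and the conformational-selection model
    must fit the induced-fit data strictly worse.
    """
    ds = _clean_dataset()
    fit = kinetics.global_fit(ds, n_starts=8, seed=seed)
    rel = np.abs(fit.rates.as_array() - RATES_TRUE.as_array()) / RATES_TRUE.as_array()

    f_all = np.concatenate(ds.intensities)
    noise_sd = 0.01 * (f_all.max() - f_all.min())
    kd1_true = RATES_TRUE.k_1 / RATES_TRUE.k1
    kd1_errs = []
    for k in range(n_noise_seeds):
        noisy = kinetics.simulate_traces(
            RATES_TRUE, OBSERVABLE_TRUE, list(CONCENTRATIONS), T_GRID,
            noise_sd=noise_sd, seed=seed + 100 * (k + 1),
        )
        nf = kinetics.global_fit(noisy, n_starts=4, seed=seed + k)
        kd1 = nf.rates.k_1 / nf.rates.k1
        kd1_errs.append(abs(kd1 - kd1_true) / kd1_true)

    cs = kinetics.global_fit(ds, model="conformational_selection", n_starts=8, seed=seed)
    return {
        "noiseless_max_rel_err": float(np.max(rel)),
        "kd1_rel_err_median": float(np.median(kd1_errs)),
        "conf_sel_residual_ratio": cs.residual_norm / max(fit.residual_norm, 1e-300),
        "two_step_residual": fit.residual_norm,
        "conf_sel_residual": cs.residual_norm,
        "n_noise_seeds": n_noise_seeds,
    }


def equilibrium_algebra_experiment(seed: int, n_mc: int = 100_000) -> dict:
    """Equilibrium-constant algebra and error-propagation cross-check.

    Kd from the reference rate constants (Kd1 = 309 µM, Keq = 30) and the
    agreement of delta-method standard errors with Monte-Carlo propagation.
    """
    se = np.array([0.006, 1.9, 0.01, 0.5])  # plausible fit standard errors
    cov = np.diag(se**2)
    eq = kinetics.equilibrium_constants(RATES_TRUE, cov)
    rng = np.random.default_rng(seed + 77)
    draws = RATES_TRUE.as_array() + rng.standard_normal((n_mc, 4)) * se
    draws = np.clip(draws, 1e-9, None)
    kd1 = draws[:, 1] / draws[:, 0]
    keq = draws[:, 3] / draws[:, 2]
    kd = kd1 * keq / (1 + keq)
    return {
        "Kd1_uM": eq.Kd1,
        "Keq": eq.Keq,
        "Kd_uM": eq.Kd,
        "se_rel_gap_Kd": abs(eq.se_Kd - kd.std()) / kd.std(),
        "se_rel_gap_Kd1": abs(eq.se_Kd1 - kd1.std()) / kd1.std(),
        "n_mc": n_mc,
    }


def combinatorics_exactness_experiment(seed: int) -> dict:
    """Bit-exact checks of the counting machinery against brute force.

    Covers Venn-region set algebra, the coverage-grid corner consistency,
    differential-contact threshold selection, candidate-frame striding (with
    the wide-stride rule), and RMSD cluster expansion.  Each check reports 1
    on exact agreement with its independent brute-force oracle.
    """
    from . import ensemble, featurize, landscape

    rng = np.random.default_rng(seed + 53)
    checks = {}

    # Venn regions over three random visited-state sets
    raw = {lab: [rng.integers(0, 12, size=30) for _ in range(3)] for lab in "ABC"}
    sets = {lab: DiscreteTrajectorySet(v, 12) for lab, v in raw.items()}
    py = {lab: set(np.concatenate(v).tolist()) for lab, v in raw.items()}
    regions = ensemble.venn_regions(sets)
    ok = True
    from itertools import combinations

    for r in range(1, 4):
        for combo in combinations("ABC", r):
            want = set.intersection(*(py[c] for c in combo))
            for other in "ABC":
                if other not in combo:
                    want -= py[other]
            ok &= regions[combo] == len(want)
    checks["venn_regions_exact"] = int(ok)

    # coverage-grid corner equals union coverage
    gen = reference_generator(seed)
    ts = synthgen.sample_trajectories(gen, 30, 400, 6, seed=seed + 59)
    pool = DiscreteTrajectorySet(ts.true_micro_paths, N_MICRO, group_ids=ts.group_ids)
    _, _, grid = ensemble.coverage_contour(pool, traj_step=10, length_step=100, n_draws=2, seed=seed)
    union = ensemble.coverage_by_sets({"all": pool}, "all")
    checks["coverage_corner_exact"] = int(grid[-1, -1] == union.n_covered)

    # differential-contact selection at the 0.2 / 3-fold thresholds
    n = 10
    W = np.zeros((n, n))
    M = np.zeros((n, n))
    pairs = [(i, j) for i in range(n) for j in range(i + 3, n)]
    for i, j in pairs:
        W[i, j] = W[j, i] = rng.choice([0.0, 0.05, 0.1, 0.3])
        M[i, j] = M[j, i] = rng.choice([0.0, 0.1, 0.5, 0.9])
    cm = lambda A: featurize.ContactMap(matrix=A, n_frames=5)
    diff = ensemble.differential_contact_map(cm(M), cm(W))
    oracle = [
        (i, j) for i, j in pairs
        if abs(M[i, j] - W[i, j]) > 0.2
        and W[i, j] > 0
        and abs(M[i, j] - W[i, j]) / W[i, j] > 3.0
    ]
    checks["contact_selection_exact"] = int(diff.selected_pairs == oracle)

    # candidate-frame striding incl. the wide-stride rule
    ens_fix = synthgen.make_bead_chain_ensemble(
        12, {(0, 5)}, {(1, 8)}, n_frames_base=40, n_frames_perturbed=60, seed=seed
    )
    A = np.zeros((12, 12))
    A[1, 8] = A[8, 1] = 0.6
    diff2 = ensemble.DiffContactMap(
        absolute=A, relative=np.where(A != 0, 4.0, 0.0),
        selected_pairs=[(1, 8)], abs_thresh=0.2, rel_thresh=3.0,
    )
    got10 = ensemble.extract_candidate_frames([ens_fix], diff2, burn_in=0)
    got20 = ensemble.extract_candidate_frames(
        [ens_fix], diff2, burn_in=0, stride_cap=30, stride_wide=20
    )
    checks["stride_rules_exact"] = int(
        got10 == [(0, f) for f in range(40, 100, 10)]
        and got20 == [(0, f) for f in range(40, 100, 20)]
    )

    # 0.3 nm RMSD cluster expansion vs brute force
    base = rng.standard_normal((6, 3))
    frames = np.stack([base + 0.12 * rng.standard_normal((6, 3)) for _ in range(30)])
    cluster = frames[:3]
    got = ensemble.expand_cluster_by_rmsd(cluster, frames, threshold=0.3, stride=10)
    oracle = [
        k for k in range(0, 30, 10)
        if min(landscape.superpose_rmsd(c, frames[k]) for c in cluster) < 0.3
    ]
    checks["rmsd_expansion_exact"] = int(got == oracle)

    checks["all_exact"] = int(all(checks.values()))
    return checks


def geometry_experiment(seed: int) -> dict:
    """Kabsch superposition: rigid-transform residual and a closed-form case."""
    from . import landscape

    rng = np.random.default_rng(seed + 61)
    X = rng.standard_normal((30, 3))
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    moved = X @ q + rng.standard_normal(3) * 10
    rigid_rmsd = float(landscape.superpose_rmsd(moved, X))

    ref = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    d = 0.3
    frame = ref.copy()
    frame[2, 2] += d
    cfg = landscape.SuperpositionConfig(fit_residues=((0, 1),), rmsd_residues=((2, 2),))
    closed = float(
        landscape.superpose_rmsd(frame, ref, config=cfg, residue_ids=np.arange(3))
    )
    return {
        "rigid_transform_rmsd": rigid_rmsd,
        "three_atom_rmsd": closed,
        "three_atom_expected": d,
    }
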