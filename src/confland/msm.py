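"""Markov state models: discretization, reversible estimation, scoring, validation.

The workflow mirrors standard MSM construction practice: projected features
are discretized with k-means into microstates; a reversible transition matrix
is estimated at a Markovian lag by maximum likelihood on the largest strongly
connected count set; model quality is scored with the rank-10 VAMP-2 score
under a 50:50 shuffle-split over seed groups; validity is checked by implied
timescales, the Chapman-Kolmogorov test and macrostate escape probabilities
with Beta-distribution confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import beta as beta_dist
from sklearn.cluster import KMeans

from ._markov import (
    reversible_eigendecomposition,
    reversible_eigenvalues,
    stationary_distribution,
    timescales_from_eigenvalues,
)
from ._types import DiscreteTrajectorySet, FeatureTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "MarkovModel",
    "ScoreResult",
    "EscapeEstimate",
    "discretize_kmeans",
    "assign_to_centers",
    "count_matrix",
    "estimate_msm",
    "implied_timescales",
    "shuffle_split",
    "vamp2_score",
    "ck_test",
    "escape_probability",
    "hyperparameter_search",
]


@dataclass
class MarkovModel:
    """Reversible MSM on the active (largest strongly connected) state set."""

    lag: int
    counts: np.ndarray
    T: np.ndarray
    pi: np.ndarray
    active_set: np.ndarray

    def __post_init__(self) -> None:
        if np.max(np.abs(self.T.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("transition-matrix rows must sum to 1")
        if np.max(np.abs(self.pi @ self.T - self.pi)) > 1e-8:
            raise ValueError("pi is not stationary for T")

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        vals = reversible_eigenvalues(self.T, self.pi)
        return vals if k is None else vals[:k]

    def timescales(self, k: int | None = None) -> np.ndarray:
        vals = self.eigenvalues()[1:]
        ts = timescales_from_eigenvalues(vals, self.lag)
        return ts if k is None else ts[:k]


@dataclass
class ScoreResult:
    """Cross-validated VAMP-2 scores over shuffle-splits."""

    rank: int
    per_split_scores: list

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_split_scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_split_scores, ddof=1)) if len(self.per_split_scores) > 1 else 0.0


@dataclass
class EscapeEstimate:
    """Self-transition (persistence) probability of one macrostate at one lag.

    f = M / N with M self-transition counts and N all counts out of the
    state; the 95% CI comes from Beta(Neff f, Neff (1-f)) with Neff = N / lag
    correcting sliding-window overcounting.
    """

    state: int
    lag: int
    M: float
    N: float
    f: float
    Neff: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("f must lie in [0, 1]")
        if not (self.ci_low - 1e-12 <= self.f <= self.ci_high + 1e-12):
            raise ValueError("CI must bracket f")


# ---------------------------------------------------------------------------
# discretization


def discretize_kmeans(
    projected, k: int, seed: int = 0, frame_time: float = 1.0
) -> DiscreteTrajectorySet:
    """k-means microstate discretization (k-means++ init, Lloyd iterations).

    Returns a :class:`DiscreteTrajectorySet` with the fitted cluster centers
    attached, so held-out data can be assigned with
    :func:`assign_to_centers`.
    """
    if isinstance(projected, FeatureTrajectory):
        projected = [projected]
    Xs = [t.features if isinstance(t, FeatureTrajectory) else np.asarray(t, float) for t in projected]
    lengths = [x.shape[0] for x in Xs]
    X = np.concatenate(Xs, axis=0)
    if k > X.shape[0]:
        raise ValueError("k must not exceed the total number of frames")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=500, tol=1e-6, random_state=seed)
    labels = km.fit_predict(X)
    dtrajs = np.split(labels, np.cumsum(lengths)[:-1])
    group_ids = np.array(
        [t.group_id if isinstance(t, FeatureTrajectory) else 0 for t in projected]
    )
    return DiscreteTrajectorySet(
        dtrajs=list(dtrajs),
        n_states=k,
        frame_time=frame_time,
        group_ids=group_ids,
        centers=km.cluster_centers_,
    )


def assign_to_centers(projected, centers: np.ndarray, group_ids=None, frame_time: float = 1.0) -> DiscreteTrajectorySet:
    """Nearest-center assignment of (held-out) trajectories to fixed centers."""
    if isinstance(projected, FeatureTrajectory):
        projected = [projected]
    dtrajs = []
    gids = []
    for t in projected:
        x = t.features if isinstance(t, FeatureTrajectory) else np.asarray(t, float)
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        dtrajs.append(np.argmin(d2, axis=1))
        gids.append(t.group_id if isinstance(t, FeatureTrajectory) else 0)
    if group_ids is None:
        group_ids = np.array(gids)
    return DiscreteTrajectorySet(
        dtrajs=dtrajs,
        n_states=centers.shape[0],
        frame_time=frame_time,
        group_ids=group_ids,
        centers=centers,
    )


# ---------------------------------------------------------------------------
# counting and estimation


def count_matrix(dtrajs, lag: int, n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts at integer lag, per trajectory.

    C[i, j] = #{t : s_t = i, s_{t+lag} = j}, never counting across
    trajectory boundaries.
    """
    if isinstance(dtrajs, DiscreteTrajectorySet):
        if n_states is None:
            n_states = dtrajs.n_states
        dtrajs = dtrajs.dtrajs
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    if n_states is None:
        n_states = int(max(d.max() for d in dtrajs)) + 1
    C = np.zeros((n_states, n_states))
    counted = False
    for d in dtrajs:
        if len(d) <= lag:
            continue
        np.add.at(C, (d[:-lag], d[lag:]), 1.0)
        counted = True
    if not counted:
        raise ValueError("lag is not shorter than any trajectory")
    return C


def _largest_scc(C: np.ndarray) -> np.ndarray:
    """States of the largest strongly connected component of the count graph."""
    A = csr_matrix((C > 0).astype(np.int8))
    n, labels = connected_components(A, directed=True, connection="strong")
    sizes = np.bincount(labels)
    # tie-break: among equally large components prefer most counts
    best, best_key = None, None
    for comp in np.nonzero(sizes == sizes.max())[0]:
        idx = np.nonzero(labels == comp)[0]
        key = C[np.ix_(idx, idx)].sum()
        if best_key is None or key > best_key:
            best, best_key = idx, key
    return best


def _reversible_mle(C: np.ndarray, tol: float = 1e-12, max_iter: int = 1_000_000) -> tuple[np.ndarray, np.ndarray]:
    """Reversible maximum-likelihood transition matrix.

    Standard self-consistent fixed-point iteration on the symmetric variables
    x_ij: x_ij <- (c_ij + c_ji) / (c_i / x_i + c_j / x_j), iterated until the
    largest elementwise change of the (normalized) x falls below ``tol``.
    """
    C = np.asarray(C, dtype=float)
    c_row = C.sum(axis=1)
    Csym = C + C.T
    x = Csym / Csym.sum()
    mask = Csym > 0
    for _ in range(max_iter):
        xi = x.sum(axis=1)
        q = c_row / xi
        denom = q[:, None] + q[None, :]
        x_new = np.where(mask, Csym / np.where(denom > 0, denom, 1.0), 0.0)
        x_new /= x_new.sum()
        delta = np.max(np.abs(x_new - x))
        x = x_new
        if delta < tol:
            break
    xi = x.sum(axis=1)
    T = x / xi[:, None]
    pi = xi / xi.sum()
    return T, pi


def estimate_msm(counts, lag: int = 1, reversible: bool = True) -> MarkovModel:
    """Estimate an MSM from a count matrix (restricted to the largest SCC)."""
    C = np.asarray(counts, dtype=float)
    if np.any(C < 0):
        raise ValueError("counts must be nonnegative")
    active = _largest_scc(C)
    if active is None or len(active) == 0:
        raise ValueError("empty connected set")
    Ca = C[np.ix_(active, active)]
    if reversible:
        T, pi = _reversible_mle(Ca)
    else:
        T = Ca / Ca.sum(axis=1, keepdims=True)
        pi = stationary_distribution(T)
    return MarkovModel(lag=int(lag), counts=Ca, T=T, pi=pi, active_set=np.asarray(active))


def estimate_msm_from_dtrajs(dtrajs, lag: int, reversible: bool = True) -> MarkovModel:
    """Convenience: counts at ``lag`` then :func:`estimate_msm`."""
    return estimate_msm(count_matrix(dtrajs, lag), lag=lag, reversible=reversible)


def implied_timescales(dtrajs, lags, n_its: int = 5) -> pd.DataFrame:
    """Implied timescales t_i(tau) = -tau / ln lambda_i(tau) per lag.

    Nonpositive eigenvalues yield NaN (undefined), never a negative time.
    """
    rows = []
    for lag in lags:
        m = estimate_msm_from_dtrajs(dtrajs, int(lag))
        ts = m.timescales()[:n_its]
        row = {"lag": int(lag)}
        for i in range(n_its):
            row[f"t{i + 2}"] = ts[i] if i < len(ts) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("lag")


# ---------------------------------------------------------------------------
# cross-validation and scoring


def shuffle_split(groups, ratio: float = 0.5, n_splits: int = 5, seed: int = 0) -> list:
    """Random 50:50 (by default) partitions of seed GROUPS into train/test.

    Groups — not individual trajectories — are the unit of splitting, so
    trajectories started from the same conformation never leak across the
    train/test boundary.  Returns ``[(train_groups, test_groups), ...]``.
    """
    uniq = np.unique(np.asarray(groups))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups to split")
    n_train = int(round(len(uniq) * ratio))
    n_train = min(max(n_train, 1), len(uniq) - 1)
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        perm = rng.permutation(uniq)
        splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return splits


def vamp2_score(train_model: MarkovModel, test_dtrajs=None, rank: int = 10) -> float:
    """Rank-capped VAMP-2 score of a trained MSM.

    Without test data this is the in-sample score 1 + sum of the top
    ``rank - 1`` non-unit squared eigenvalues of T.  With test data the test
    correlation operator is expressed in the train model's top-``rank``
    eigenfunction basis: a reversible MSM is re-estimated from the test
    counts (restricted to states shared with the train active set; unseen
    states are dropped with a logged count) and the score is
    ||C00^{-1/2} C0t Ctt^{-1/2}||_F^2 with C00 = Psi' diag(pi_test) Psi,
    C0t = Psi' diag(pi_test) T_test Psi, Ctt = C00, capped at ``rank``.
    When the test set is the training set this reduces exactly to the
    in-sample formula.
    """
    lam_train = train_model.eigenvalues()
    r = min(rank, len(lam_train))
    if test_dtrajs is None:
        return float(np.sum(lam_train[:r] ** 2))

    if isinstance(test_dtrajs, DiscreteTrajectorySet):
        test_list = test_dtrajs.dtrajs
    else:
        test_list = [np.asarray(d, dtype=np.int64) for d in test_dtrajs]

    # map test states onto the train active set
    active = train_model.active_set
    remap = -np.ones(int(max(active.max(), max(d.max() for d in test_list))) + 1, dtype=np.int64)
    remap[active] = np.arange(len(active))
    mapped, dropped, total = [], 0, 0
    for d in test_list:
        m = remap[d]
        keep = m >= 0
        dropped += int((~keep).sum())
        total += len(d)
        # split at dropped frames so fake transitions are not created
        if keep.all():
            mapped.append(m)
        else:
            idx = np.nonzero(~keep)[0]
            for seg in np.split(m, idx):
                seg = seg[seg >= 0]
                if len(seg) > train_model.lag:
                    mapped.append(seg)
    if dropped:
        logger.info("vamp2_score: dropped %d/%d test frames outside the train active set", dropped, total)
    if not mapped:
        raise ValueError("no mappable test transitions")

    C_test = count_matrix(mapped, train_model.lag, n_states=len(active))
    test_active = _largest_scc(C_test)
    Ct = C_test[np.ix_(test_active, test_active)]
    T_test, pi_test = _reversible_mle(Ct)

    _, psi = reversible_eigendecomposition(train_model.T, train_model.pi)
    Psi = psi[:, :r][test_active]  # train eigenfunctions on the common states

    D = pi_test[:, None]
    C00 = Psi.T @ (D * Psi)
    C0t = Psi.T @ (D * (T_test @ Psi))
    # symmetric inverse square root of C00
    w, U = np.linalg.eigh(C00)
    keep = w > 1e-12 * w.max()
    C00_inv_half = U[:, keep] / np.sqrt(w[keep])
    Kt = C00_inv_half.T @ C0t @ C00_inv_half
    score = float(np.sum(Kt * Kt))
    return min(score, float(rank))


def score_cv(
    dtrajs: DiscreteTrajectorySet,
    lag: int,
    rank: int = 10,
    ratio: float = 0.5,
    n_splits: int = 5,
    seed: int = 0,
    splits=None,
) -> ScoreResult:
    """Shuffle-split cross-validated VAMP-2 score of a discretization."""
    if splits is None:
        splits = shuffle_split(dtrajs.group_ids, ratio=ratio, n_splits=n_splits, seed=seed)
    scores = []
    for train_groups, test_groups in splits:
        tr = [d for d, g in zip(dtrajs.dtrajs, dtrajs.group_ids) if g in train_groups]
        te = [d for d, g in zip(dtrajs.dtrajs, dtrajs.group_ids) if g in test_groups]
        model = estimate_msm_from_dtrajs(tr, lag)
        scores.append(vamp2_score(model, te, rank=rank))
    return ScoreResult(rank=rank, per_split_scores=scores)


# ---------------------------------------------------------------------------
# validation


def ck_test(
    model: MarkovModel,
    dtrajs,
    memberships: np.ndarray | None = None,
    n_sets: int | None = None,
    factors=(2, 3, 4, 5),
) -> pd.DataFrame:
    """Chapman-Kolmogorov test on metastable sets.

    Compares the set-persistence probability predicted by T(tau)^k against
    the one re-estimated from the data at lag k*tau, with count-based
    standard errors on the estimate.  Sets are the argmax-membership lumps of
    ``memberships`` (micro -> macro, e.g. from the HMM coarse-graining);
    identity memberships test each microstate separately.
    """
    if min(factors) < 1:
        raise ValueError("factors must be >= 1")
    if memberships is None:
        if n_sets is not None and n_sets != model.n_states:
            raise ValueError("provide memberships to aggregate into n_sets")
        assign_full = np.arange(model.n_states)
    else:
        assign_full = np.argmax(memberships, axis=1)
    n_sets = int(assign_full.max()) + 1

    if isinstance(dtrajs, DiscreteTrajectorySet):
        dtrajs = dtrajs.dtrajs

    rows = []
    for k in sorted(set(int(f) for f in factors) | {1}):
        Tk = np.linalg.matrix_power(model.T, k)
        lag_k = model.lag * k
        C = count_matrix(dtrajs, lag_k)
        # restrict to the model's active set
        Ca = C[np.ix_(model.active_set, model.active_set)]
        if Ca.sum() == 0:
            raise ValueError(f"insufficient counts at lag factor {k}")
        m_est = estimate_msm(Ca, lag=lag_k)
        # map back onto the (possibly smaller) estimation active set
        sub = m_est.active_set
        for a in range(n_sets):
            in_set = np.nonzero(assign_full == a)[0]
            w = model.pi[in_set]
            if w.sum() == 0:
                continue
            w = w / w.sum()
            pred = float(w @ Tk[np.ix_(in_set, in_set)].sum(axis=1))
            # estimated persistence from the re-estimated model
            sub_mask = np.isin(sub, in_set)
            if not sub_mask.any():
                continue
            wi = m_est.pi[sub_mask]
            wi = wi / wi.sum()
            est = float(wi @ m_est.T[np.ix_(np.nonzero(sub_mask)[0], np.nonzero(sub_mask)[0])].sum(axis=1))
            n_obs = float(Ca[in_set].sum())
            se = np.sqrt(max(est * (1 - est), 1e-12) / max(n_obs / lag_k, 1.0))
            rows.append(
                {"set": a, "factor": k, "predicted": pred, "estimated": est, "se_estimated": se}
            )
    return pd.DataFrame(rows)


def ck_within_bars(table: pd.DataFrame, z: float = 1.96) -> float:
    """Fraction of (set, factor>1) points with |predicted - estimated| <= z*se."""
    t = table[table["factor"] > 1]
    ok = np.abs(t["predicted"] - t["estimated"]) <= z * t["se_estimated"]
    return float(ok.mean())


def _beta_ci(f: float, Neff: float, level: float = 0.95) -> tuple[float, float]:
    a = Neff * f
    b = Neff * (1.0 - f)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    if a <= 0:
        return 0.0, float(beta_dist.ppf(hi_q, 1.0, max(b, 1e-12)))
    if b <= 0:
        return float(beta_dist.ppf(lo_q, max(a, 1e-12), 1.0)), 1.0
    return float(beta_dist.ppf(lo_q, a, b)), float(beta_dist.ppf(hi_q, a, b))


def escape_probability(
    macro_dtrajs,
    lags,
    states=None,
    n_boot: int = 40,
    seed: int = 0,
) -> list:
    """Macrostate persistence probability f = M/N with Beta CIs per lag.

    For every state and lag, sliding-window counts give M (self) and N
    (total); f = M/N and its 95% CI is the Beta(Neff f, Neff (1-f)) interval
    with Neff = N/lag effectively uncorrelated counts.  With ``n_boot > 0``
    whole trajectories are bootstrapped, the f estimates averaged and the CI
    bounds taken as the 2.5th/97.5th percentiles of the per-replicate CI
    bounds; ``n_boot=0`` returns the direct single-sample interval.
    """
    if isinstance(macro_dtrajs, DiscreteTrajectorySet):
        macro_dtrajs = macro_dtrajs.dtrajs
    macro_dtrajs = [np.asarray(d, dtype=np.int64) for d in macro_dtrajs]
    n_states = int(max(d.max() for d in macro_dtrajs)) + 1
    if states is None:
        states = list(range(n_states))
    rng = np.random.default_rng(seed)

    def counts_for(trajs, lag):
        C = count_matrix(trajs, lag, n_states=n_states)
        M = np.diag(C)
        N = C.sum(axis=1)
        return M, N

    out = []
    for lag in lags:
        lag = int(lag)
        M0, N0 = counts_for(macro_dtrajs, lag)
        for s in states:
            if N0[s] == 0:
                raise ValueError(f"no counts for state {s} at lag {lag}")
            if n_boot == 0:
                f = M0[s] / N0[s]
                Neff = N0[s] / lag
                lo, hi = _beta_ci(f, Neff)
                out.append(EscapeEstimate(s, lag, float(M0[s]), float(N0[s]), float(f), float(Neff), lo, hi))
            else:
                fs, los, his = [], [], []
                for _ in range(n_boot):
                    idx = rng.integers(0, len(macro_dtrajs), size=len(macro_dtrajs))
                    Mb, Nb = counts_for([macro_dtrajs[i] for i in idx], lag)
                    if Nb[s] == 0:
                        continue
                    fb = Mb[s] / Nb[s]
                    lo, hi = _beta_ci(fb, Nb[s] / lag)
                    fs.append(fb)
                    los.append(lo)
                    his.append(hi)
                if not fs:
                    raise ValueError(f"no counts for state {s} at lag {lag} in any replicate")
                f = float(np.mean(fs))
                lo = float(np.percentile(los, 2.5))
                hi = float(np.percentile(his, 97.5))
                lo, hi = min(lo, f), max(hi, f)
                out.append(
                    EscapeEstimate(s, lag, float(M0[s]), float(N0[s]), f, float(N0[s] / lag), lo, hi)
                )
    return out


# ---------------------------------------------------------------------------
# hyperparameter search


def hyperparameter_search(
    dataset,
    grid,
    seed: int = 0,
    msm_lag: int = 1,
    rank: int = 10,
    n_splits: int = 5,
    ratio: float = 0.5,
) -> pd.DataFrame:
    """Grid search over tICA/discretization hyperparameters with group CV.

    ``dataset`` is a :class:`~confland._types.TrajectorySet` of (already
    featurized) trajectories; each grid entry is a dict with keys among
    ``tica_lag``, ``mapping``, ``kinetic_content``, ``n_clusters``.  For each
    grid point and each shuffle-split, tICA and k-means are fitted on the
    train groups only, the test groups are transformed and assigned to the
    train centers, an MSM is estimated on the train discretization and scored
    on the test set.  Failing grid points are logged and skipped.  The table
    is ranked by mean score, descending.
    """
    from . import tica as tica_mod

    if not grid:
        raise ValueError("empty hyperparameter grid")
    splits = shuffle_split(dataset.group_ids, ratio=ratio, n_splits=n_splits, seed=seed)
    rows = []
    for gi, params in enumerate(grid):
        tica_lag = params.get("tica_lag", 1)
        mapping = params.get("mapping", "commute")
        content = params.get("kinetic_content", 0.95)
        k = params.get("n_clusters", 100)
        try:
            scores = []
            for si, (train_groups, test_groups) in enumerate(splits):
                tr = [t for t in dataset.trajectories if t.group_id in train_groups]
                te = [t for t in dataset.trajectories if t.group_id in test_groups]
                model = tica_mod.fit_tica(tr, lag=tica_lag, mapping=mapping)
                tr_p = tica_mod.transform(model, tr, kinetic_content=content)
                te_p = tica_mod.transform(model, te, kinetic_content=content)
                dts = discretize_kmeans(tr_p, k=k, seed=seed * 1000 + si)
                dte = assign_to_centers(te_p, dts.centers)
                msm_model = estimate_msm_from_dtrajs(dts.dtrajs, msm_lag)
                scores.append(vamp2_score(msm_model, dte.dtrajs, rank=rank))
            rows.append(
                {
                    "grid_index": gi,
                    "tica_lag": tica_lag,
                    "mapping": mapping,
                    "kinetic_content": content,
                    "n_clusters": k,
                    "mean_score": float(np.mean(scores)),
                    "sd_score": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
                }
            )
        except Exception as err:  # noqa: BLE001 - individual failures are not fatal
            logger.warning("grid point %d (%r) failed: %s", gi, params, err)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("mean_score", ascending=False).reset_index(drop=True)
    return table
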