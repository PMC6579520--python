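"""Synthetic inputs with the statistical structure the downstream analysis assumes.

Three generators are provided:

* a metastable hidden-Markov trajectory generator (:func:`make_generator`,
  :func:`sample_trajectories`) whose macrostate transition matrix is reversible
  with prescribed relaxation timescales and whose microstate/feature emissions
  are known, organized into seed groups (the analogue of parallel MD "RUNs"
  started from the same conformation);
* a bead-chain structural ensemble (:func:`make_bead_chain_ensemble`) with
  controllable residue contacts, for contact-map and RMSD machinery;
* noisy biphasic fluorescence traces, delegated to :mod:`confland.kinetics`
  (:func:`confland.kinetics.simulate_traces`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._markov import (
    reversible_eigenvalues,
    stationary_distribution,
    timescales_from_eigenvalues,
)
from ._types import FeatureTrajectory, TrajectorySet

__all__ = [
    "GeneratorModel",
    "BeadChainEnsemble",
    "make_generator",
    "sample_trajectories",
    "make_bead_chain_ensemble",
    "micro_transition_matrix",
    "micro_stationary_distribution",
]

_ROW_SUM_TOL = 1e-12


@dataclass
class GeneratorModel:
    """Ground-truth hidden-Markov generator.

    ``macro_T`` is the per-step row-stochastic macrostate transition matrix,
    ``emission`` the macrostate -> microstate categorical probabilities,
    ``micro_centers`` the feature-space centers of each microstate, and
    ``emission_sd`` the isotropic Gaussian feature noise around them.
    """

    macro_T: np.ndarray
    emission: np.ndarray
    micro_centers: np.ndarray
    emission_sd: float
    step_time: float = 1.0
    timescales: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.macro_T = np.asarray(self.macro_T, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        self.micro_centers = np.asarray(self.micro_centers, dtype=float)
        if self.macro_T.shape[0] > self.emission.shape[1]:
            raise ValueError("need n_macro <= n_micro")
        for name, M in (("macro_T", self.macro_T), ("emission", self.emission)):
            if np.max(np.abs(M.sum(axis=1) - 1.0)) > _ROW_SUM_TOL:
                raise ValueError(f"rows of {name} must sum to 1 within {_ROW_SUM_TOL}")
        if self.timescales is None:
            vals = reversible_eigenvalues(self.macro_T)
            self.timescales = timescales_from_eigenvalues(vals[1:], self.step_time)

    @property
    def n_macro(self) -> int:
        return self.macro_T.shape[0]

    @property
    def n_micro(self) -> int:
        return self.emission.shape[1]

    @property
    def n_features(self) -> int:
        return self.micro_centers.shape[1]

    @property
    def macro_pi(self) -> np.ndarray:
        return stationary_distribution(self.macro_T)


@dataclass
class BeadChainEnsemble:
    """Toy bead-chain structural ensemble with a known contact truth table.

    ``frames`` holds (n_residue, 3) coordinate arrays in nm; ``frame_labels``
    marks each frame "base" or "perturbed"; ``contact_spec`` records which
    residue pairs are in contact in which frame subset.
    """

    frames: list
    residue_ids: np.ndarray
    contact_spec: dict
    frame_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for f in self.frames:
            if not np.all(np.isfinite(f)):
                raise ValueError("non-finite coordinates")

    @property
    def xyz(self) -> np.ndarray:
        return np.stack(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


def _random_reversible_metastable(
    n: int, rng: np.random.Generator, mean_eigenvalue: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized symmetric count-like matrix with a tuned diagonal.

    The diagonal weight is chosen so the base spectrum sits near the target
    eigenvalues, keeping the subsequent eigenvalue rescaling a small
    perturbation.  Returns (T0, pi0); T0 is reversible w.r.t. pi0.
    """
    C = rng.uniform(0.2, 1.0, size=(n, n))
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 0.0)
    off_rows = C.sum(axis=1)
    s = float(np.clip(mean_eigenvalue, 0.05, 0.995))
    diag = off_rows * s / (1.0 - s) * rng.uniform(0.8, 1.25, size=n)
    C[np.diag_indices(n)] = diag
    rows = C.sum(axis=1)
    return C / rows[:, None], rows / rows.sum()


def make_generator(
    n_macro: int,
    n_micro: int,
    slow_timescales,
    seed: int,
    *,
    n_features: int | None = None,
    emission_sd: float = 0.05,
    step_time: float = 1.0,
    max_attempts: int = 100,
) -> GeneratorModel:
    """Build a reversible metastable generator with prescribed timescales.

    The macrostate matrix is constructed by symmetrizing a random count-like
    matrix, row-normalizing (which fixes a stationary distribution and an
    eigenvector basis) and then rescaling the non-unit eigenvalues so the
    implied timescales equal ``slow_timescales`` exactly.  Draws producing
    negative transition probabilities are rejected and retried.

    Emission rows have disjoint microstate support (a contiguous block per
    macrostate) so macrostates are identifiable from the observed microstates.
    ``n_features`` defaults to ``n_micro``: with at least as many generic
    feature dimensions as microstates, every state function (in particular
    the slow eigenfunctions) is linearly observable, which downstream
    tICA/k-means recovery relies on.
    """
    if n_macro < 2:
        raise ValueError("need n_macro >= 2")
    if n_macro > n_micro:
        raise ValueError("need n_macro <= n_micro")
    ts = np.asarray(slow_timescales, dtype=float)
    if ts.shape != (n_macro - 1,):
        raise ValueError("slow_timescales must have length n_macro - 1")
    if np.any(ts <= 0):
        raise ValueError("timescales must be positive")
    if np.any(ts < step_time):
        raise ValueError(
            "requested timescale shorter than step_time is not realizable"
        )
    if n_features is None:
        n_features = max(n_micro, 2)
    target = np.sort(np.exp(-step_time / ts))[::-1]  # descending eigenvalues

    rng = np.random.default_rng(seed)
    T = None
    new_vals = np.concatenate([[1.0], target])
    for _ in range(max_attempts):
        T0, pi0 = _random_reversible_metastable(n_macro, rng, float(np.mean(target)))
        # alternating projections: exact spectrum <-> nonnegative reversible
        cand = T0
        pi = pi0
        for _ in range(200):
            s = np.sqrt(pi)
            S = (s[:, None] * cand) / s[None, :]
            vals, U = np.linalg.eigh(0.5 * (S + S.T))
            order = np.argsort(vals)[::-1]
            U = U[:, order]
            S = (U * new_vals) @ U.T
            cand = (S / s[:, None]) * s[None, :]
            if cand.min() >= -1e-14:
                cand = np.clip(cand, 0.0, None)
                cand /= cand.sum(axis=1, keepdims=True)
                break
            cand = np.clip(cand, 0.0, None)
            cand /= cand.sum(axis=1, keepdims=True)
            pi = stationary_distribution(cand)
            cand = 0.5 * (cand + (pi[None, :] * cand.T / pi[:, None]))
            cand /= cand.sum(axis=1, keepdims=True)
        got = reversible_eigenvalues(cand)[1:]
        if cand.min() >= 0 and np.all(np.abs(got - target) <= 5e-3 * (1 - target) + 1e-9):
            T = cand
            break
    if T is None:
        raise RuntimeError(
            "could not realize the requested timescales with nonnegative "
            "transition probabilities; try longer timescales"
        )

    # disjoint emission blocks: contiguous microstate ranges per macrostate
    bounds = np.linspace(0, n_micro, n_macro + 1).astype(int)
    emission = np.zeros((n_macro, n_micro))
    for a in range(n_macro):
        lo, hi = bounds[a], bounds[a + 1]
        w = rng.dirichlet(np.full(hi - lo, 5.0))
        emission[a, lo:hi] = w

    # well-separated feature centers: rejection-sample in a hypercube
    min_sep = 6.0 * emission_sd
    edge = 2.0 * min_sep * max(2.0, n_micro ** (1.0 / n_features))
    centers = np.empty((n_micro, n_features))
    placed = 0
    for _ in range(20000):
        c = rng.uniform(0.0, edge, size=n_features)
        if placed == 0 or np.min(
            np.linalg.norm(centers[:placed] - c, axis=1)
        ) >= min_sep:
            centers[placed] = c
            placed += 1
            if placed == n_micro:
                break
    if placed < n_micro:
        raise RuntimeError("could not place separated microstate centers")

    return GeneratorModel(
        macro_T=T,
        emission=emission,
        micro_centers=centers,
        emission_sd=emission_sd,
        step_time=step_time,
        timescales=ts.copy(),
    )


def micro_transition_matrix(model: GeneratorModel) -> np.ndarray:
    """Exact microstate transition matrix implied by a disjoint-emission model.

    With disjoint emission blocks the observed microstate chain is itself
    Markov: T_micro[m, m'] = macro_T[b(m), b(m')] * emission[b(m'), m'].
    """
    block = np.array(
        [int(np.nonzero(model.emission[:, m])[0][0]) for m in range(model.n_micro)]
    )
    e_col = model.emission[block, np.arange(model.n_micro)]
    return model.macro_T[np.ix_(block, block)] * e_col[None, :]


def micro_stationary_distribution(model: GeneratorModel) -> np.ndarray:
    """pi_micro[m] = macro_pi[b(m)] * emission[b(m), m] (disjoint emissions)."""
    pi = model.macro_pi
    out = np.zeros(model.n_micro)
    for m in range(model.n_micro):
        a = int(np.nonzero(model.emission[:, m])[0][0])
        out[m] = pi[a] * model.emission[a, m]
    return out


def _sample_markov_paths(
    T: np.ndarray,
    start: np.ndarray,
    length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized sampling of many Markov chains; start is a state per chain."""
    n_chains = len(start)
    cum = np.cumsum(T, axis=1)
    paths = np.empty((n_chains, length), dtype=np.int64)
    paths[:, 0] = start
    for t in range(1, length):
        u = rng.random(n_chains)
        paths[:, t] = (u[:, None] > cum[paths[:, t - 1]]).sum(axis=1)
    return paths


def sample_trajectories(
    model: GeneratorModel,
    n_traj: int,
    length: int,
    n_groups: int = 1,
    seed: int = 0,
    *,
    start_by_group: bool = True,
) -> TrajectorySet:
    """Sample feature trajectories with ground-truth macro/micro label paths.

    Trajectories are assigned round-robin to ``n_groups`` seed groups.  By
    default every trajectory of group g starts in macrostate ``g % n_macro``,
    emulating swarms of simulations launched from a common seed conformation;
    with ``start_by_group=False`` all chains start from the stationary
    distribution.
    """
    if length < 2:
        raise ValueError("need length >= 2")
    rng = np.random.default_rng(seed)
    group_ids = np.arange(n_traj) % n_groups

    if start_by_group:
        start = group_ids % model.n_macro
    else:
        cum = np.cumsum(model.macro_pi)
        start = np.searchsorted(cum, rng.random(n_traj))

    macro = _sample_markov_paths(model.macro_T, start, length, rng)

    # microstate emission, vectorized over all frames
    cum_e = np.cumsum(model.emission, axis=1)
    u = rng.random(macro.shape)
    micro = (u[..., None] > cum_e[macro]).sum(axis=-1)

    feats = model.micro_centers[micro] + model.emission_sd * rng.standard_normal(
        (n_traj, length, model.n_features)
    )

    trajectories = [
        FeatureTrajectory(feats[i], group_id=int(group_ids[i])) for i in range(n_traj)
    ]
    return TrajectorySet(
        trajectories=trajectories,
        group_ids=group_ids,
        true_macro_paths=[macro[i] for i in range(n_traj)],
        true_micro_paths=[micro[i] for i in range(n_traj)],
    )


def sample_two_timescale_process(
    t_slow: float,
    t_fast: float,
    n_frames: int,
    mixing: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[TrajectorySet, np.ndarray, np.ndarray]:
    """Linearly mixed pair of stationary AR(1) processes with known timescales.

    The latent coordinates relax with timescales ``t_slow`` and ``t_fast``
    (steps); observed features are an invertible linear mixture.  This is the
    linear-Gaussian setting in which tICA provably recovers the slow
    direction.  Returns (trajectories, slow_series, slow_direction) where
    ``slow_direction`` is the feature-space vector whose projection equals
    the latent slow coordinate.
    """
    if not (t_slow > t_fast > 0):
        raise ValueError("need t_slow > t_fast > 0")
    rng = np.random.default_rng(seed)

    def ar1(rho):
        x = np.empty(n_frames)
        x[0] = rng.standard_normal()
        eps = np.sqrt(1 - rho**2) * rng.standard_normal(n_frames)
        for t in range(1, n_frames):
            x[t] = rho * x[t - 1] + eps[t]
        return x

    s = ar1(np.exp(-1.0 / t_slow))
    f = ar1(np.exp(-1.0 / t_fast))
    if mixing is None:
        mixing = np.array([[2.0, 1.0], [0.5, -1.5]])
    mixing = np.asarray(mixing, dtype=float)
    X = np.column_stack([s, f]) @ mixing.T
    slow_direction = np.linalg.inv(mixing).T[:, 0]
    tset = TrajectorySet(trajectories=[FeatureTrajectory(X)])
    return tset, s, slow_direction


_BOND_LENGTH = 0.38  # nm, Calpha-like virtual bond
_CONTACT_TARGET = 0.32  # nm, where specified contacts are placed
_NONCONTACT_MIN = 0.55  # nm, clearance for everything else
_CONTACT_CUTOFF = 0.4  # nm, the contact rule the truth table is checked under


def _build_chain_geometry(
    n_residue: int,
    contacts: set,
    rng: np.random.Generator,
) -> np.ndarray:
    """Optimize bead coordinates to satisfy a contact specification."""
    # initial loose helix so the chain starts self-avoiding
    t = np.arange(n_residue) * 1.0
    x0 = np.stack(
        [0.45 * np.cos(t), 0.45 * np.sin(t), 0.20 * t], axis=1
    ) + 0.01 * rng.standard_normal((n_residue, 3))

    pairs_all = [
        (i, j) for i in range(n_residue) for j in range(i + 3, n_residue)
    ]
    contact_list = sorted(contacts)
    noncontact = [p for p in pairs_all if p not in contacts]

    def energy(flat):
        X = flat.reshape(n_residue, 3)
        e = 0.0
        d_bond = np.linalg.norm(np.diff(X, axis=0), axis=1)
        e += 100.0 * np.sum((d_bond - _BOND_LENGTH) ** 2)
        # keep immediate neighbors-of-neighbors from collapsing
        d2 = np.linalg.norm(X[2:] - X[:-2], axis=1)
        e += 20.0 * np.sum(np.clip(0.45 - d2, 0, None) ** 2)
        for i, j in contact_list:
            d = np.linalg.norm(X[i] - X[j])
            e += 50.0 * (d - _CONTACT_TARGET) ** 2
        for i, j in noncontact:
            d = np.linalg.norm(X[i] - X[j])
            e += 50.0 * np.clip(_NONCONTACT_MIN - d, 0, None) ** 2
        return e

    res = minimize(energy, x0.ravel(), method="L-BFGS-B", options={"maxiter": 2000})
    X = res.x.reshape(n_residue, 3)

    # verify the truth table under the 0.4 nm rule
    for i, j in contact_list:
        if np.linalg.norm(X[i] - X[j]) >= _CONTACT_CUTOFF:
            raise ValueError(
                f"contact specification geometrically unsatisfiable: pair {(i, j)}"
            )
    for i, j in noncontact:
        if np.linalg.norm(X[i] - X[j]) < _CONTACT_CUTOFF:
            raise ValueError(
                f"contact specification geometrically unsatisfiable: pair {(i, j)} "
                "cannot be kept apart"
            )
    return X


def make_bead_chain_ensemble(
    n_residue: int,
    base_contacts,
    perturbed_contacts,
    n_frames_base: int,
    n_frames_perturbed: int = 0,
    seed: int = 0,
    *,
    jitter_sd: float = 0.005,
) -> BeadChainEnsemble:
    """Bead-chain ensemble realizing a requested contact truth table.

    In "base" frames every pair of ``base_contacts`` sits below the 0.4 nm
    contact cutoff and every ``perturbed_contacts`` pair does not; "perturbed"
    frames reverse the roles.  All other eligible pairs (sequence separation
    >= 3) stay above the cutoff in every frame.  Per-frame Gaussian jitter
    (``jitter_sd`` nm) is small enough not to flip the truth table.
    """
    base_contacts = {tuple(sorted(p)) for p in base_contacts}
    perturbed_contacts = {tuple(sorted(p)) for p in perturbed_contacts}
    for i, j in base_contacts | perturbed_contacts:
        if abs(i - j) < 3:
            raise ValueError("contact pairs must be separated in sequence by >= 3")
        if not (0 <= i < n_residue and 0 <= j < n_residue):
            raise ValueError("contact pair out of range")

    rng = np.random.default_rng(seed)
    frames: list = []
    labels: list = []
    if n_frames_base > 0:
        Xb = _build_chain_geometry(n_residue, base_contacts, rng)
        for _ in range(n_frames_base):
            frames.append(Xb + jitter_sd * rng.standard_normal(Xb.shape))
            labels.append("base")
    if n_frames_perturbed > 0:
        Xp = _build_chain_geometry(n_residue, perturbed_contacts, rng)
        for _ in range(n_frames_perturbed):
            frames.append(Xp + jitter_sd * rng.standard_normal(Xp.shape))
            labels.append("perturbed")

    return BeadChainEnsemble(
        frames=frames,
        residue_ids=np.arange(n_residue),
        contact_spec={"base": base_contacts, "perturbed": perturbed_contacts},
        frame_labels=labels,
    )
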