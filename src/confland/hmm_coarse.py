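"""Coarse-graining of microstate dynamics into kinetically metastable macrostates.

A discrete-emission hidden Markov model (HMM) is estimated at the Markovian
lag: the hidden chain moves between a small number of macrostates and each
macrostate emits microstates from its own categorical observation
distribution.  Estimation is Baum-Welch EM on lag-strided discrete
trajectories, initialized from a PCCA+-style fuzzy spectral partition of a
microstate MSM.  The fitted model provides the macrostate transition matrix,
the observation probabilities, and the fractional membership of each
microstate to each macrostate — the quantities the landscape analysis
consumes.  Long synthetic trajectories can be sampled from the fitted model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._markov import reversible_eigendecomposition, stationary_distribution
from ._types import DiscreteTrajectorySet
from .msm import MarkovModel, count_matrix, estimate_msm

logger = logging.getLogger(__name__)

__all__ = [
    "HiddenMarkovModel",
    "pcca_init",
    "fit_hmm",
    "assign_macrostates",
    "sample_long_trajectory",
    "macrostate_sweep",
]

_OBS_FLOOR = 1e-12  # observation-probability floor before renormalization


@dataclass
class HiddenMarkovModel:
    """Discrete-emission HMM over macrostates.

    ``obs[a, m]`` is the probability that macrostate a emits microstate m;
    ``memberships[m, a]`` the posterior probability that microstate m belongs
    to macrostate a (rows sum to 1).  ``lag`` is in frames of the original
    discretization; ``frame_time`` converts it to physical time.
    """

    lag: int
    macro_T: np.ndarray
    obs: np.ndarray
    macro_pi: np.ndarray = None
    memberships: np.ndarray = None
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    frame_time: float = 1.0

    def __post_init__(self) -> None:
        self.macro_T = np.asarray(self.macro_T, dtype=float)
        self.obs = np.asarray(self.obs, dtype=float)
        for name, M in (("macro_T", self.macro_T), ("obs", self.obs)):
            if np.max(np.abs(M.sum(axis=1) - 1.0)) > 1e-10:
                raise ValueError(f"rows of {name} must sum to 1")
        if self.macro_pi is None:
            self.macro_pi = stationary_distribution(self.macro_T)
        if self.memberships is None:
            joint = self.obs * self.macro_pi[:, None]  # (a, m)
            tot = joint.sum(axis=0)
            with np.errstate(invalid="ignore"):
                memb = (joint / np.where(tot > 0, tot, 1.0)).T
            memb[tot == 0] = 1.0 / self.n_macro
            self.memberships = memb

    @property
    def n_macro(self) -> int:
        return self.macro_T.shape[0]

    @property
    def n_micro(self) -> int:
        return self.obs.shape[1]

    @property
    def lag_time(self) -> float:
        return self.lag * self.frame_time


def pcca_init(msm: MarkovModel, n_macro: int) -> np.ndarray:
    """PCCA+-style fuzzy memberships from the top right eigenvectors of T.

    Simplex vertices are found by successive farthest-point search in the
    space of the top ``n_macro`` eigenvectors; memberships are the linear
    transform mapping each microstate onto those vertices, with negative
    entries clipped and rows renormalized.
    """
    vals, psi = reversible_eigendecomposition(msm.T, msm.pi)
    if n_macro > int(np.sum(vals > 0)):
        raise ValueError("n_macro exceeds the number of positive eigenvalues")
    if n_macro < len(vals) and abs(vals[n_macro - 1] - vals[n_macro]) < 1e-8:
        warnings.warn(
            "degenerate spectrum at the macrostate cut; PCCA+ memberships may be "
            "ill-conditioned",
            RuntimeWarning,
        )
    if n_macro == 1:
        return np.ones((msm.n_states, 1))

    X = psi[:, :n_macro]
    # successive farthest-point vertex search
    vertices = [int(np.argmax(np.linalg.norm(X - X.mean(axis=0), axis=1)))]
    Y = X - X[vertices[0]]
    for _ in range(n_macro - 1):
        # project out the directions already spanned by chosen vertices
        B = Y[vertices[1:]] if len(vertices) > 1 else np.empty((0, X.shape[1]))
        P = Y.copy()
        if len(B):
            Q, _ = np.linalg.qr(B.T)
            P = Y - Y @ Q @ Q.T
        cand = int(np.argmax(np.linalg.norm(P, axis=1)))
        vertices.append(cand)
    V = X[vertices]
    chi, *_ = np.linalg.lstsq(V.T, X.T, rcond=None)
    chi = chi.T
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    return chi


def _coarse_grain_T(msm: MarkovModel, chi: np.ndarray) -> np.ndarray:
    """Membership-projected macrostate transition matrix (rows renormalized)."""
    D = msm.pi[:, None] * chi  # (micro, macro) joint weights
    A = chi.T @ (msm.pi[:, None] * msm.T) @ chi
    norm = D.sum(axis=0)
    Tm = A / norm[:, None]
    Tm = np.clip(Tm, 0.0, None)
    return Tm / Tm.sum(axis=1, keepdims=True)


def _stride_dtrajs(dtrajs, lag: int) -> list:
    return [np.asarray(d, dtype=np.int64)[::lag] for d in dtrajs if len(d) >= lag + 1]


def fit_hmm(
    dtrajs,
    n_macro: int,
    lag: int = 1,
    init: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    frame_time: float | None = None,
) -> HiddenMarkovModel:
    """Baum-Welch EM for a discrete-emission HMM on lag-strided trajectories.

    Frames at multiples of ``lag`` form the EM sequences, so the hidden chain
    is modeled at the Markovian lag rather than at sub-lag resolution.  EM
    stops when the log-likelihood improves by less than ``tol`` or after
    ``max_iter`` iterations; the trace is recorded and is nondecreasing.
    Initialization defaults to :func:`pcca_init` on an MSM estimated from the
    same data.
    """
    if isinstance(dtrajs, DiscreteTrajectorySet):
        if frame_time is None:
            frame_time = dtrajs.frame_time
        dtrajs = dtrajs.dtrajs
    frame_time = 1.0 if frame_time is None else frame_time
    seqs = _stride_dtrajs(dtrajs, lag)
    if not seqs:
        raise ValueError("no trajectory long enough for the requested lag")
    n_micro = int(max(s.max() for s in seqs)) + 1
    observed = np.unique(np.concatenate(seqs))
    if n_macro > len(observed):
        raise ValueError("n_macro exceeds the number of observed microstates")

    # --- initialization ------------------------------------------------
    msm0 = estimate_msm(count_matrix(seqs, 1, n_states=n_micro), lag=1)
    if init is None:
        chi0_active = pcca_init(msm0, n_macro)
        chi0 = np.full((n_micro, n_macro), 1.0 / n_macro)
        chi0[msm0.active_set] = chi0_active
    else:
        chi0 = np.asarray(init, dtype=float)
        if chi0.shape != (n_micro, n_macro):
            # allow init defined on the MSM active set
            full = np.full((n_micro, n_macro), 1.0 / n_macro)
            full[msm0.active_set] = chi0
            chi0 = full
    pi_micro = np.zeros(n_micro)
    pi_micro[msm0.active_set] = msm0.pi
    pi_micro = np.clip(pi_micro, 1e-12, None)
    pi_micro /= pi_micro.sum()

    obs = (chi0 * pi_micro[:, None]).T  # (macro, micro)
    obs = np.clip(obs, _OBS_FLOOR, None)
    obs /= obs.sum(axis=1, keepdims=True)
    Tm = _coarse_grain_T(msm0, chi0[msm0.active_set]) if init is None else _coarse_grain_T(msm0, chi0[msm0.active_set])
    Tm = 0.9 * Tm + 0.1 / n_macro  # soften, keeps EM off the boundary
    Tm /= Tm.sum(axis=1, keepdims=True)
    start = stationary_distribution(Tm)

    # pad sequences into a (n_seq, T_max) masked array for vectorized EM
    n_seq = len(seqs)
    T_max = max(len(s) for s in seqs)
    O = np.zeros((n_seq, T_max), dtype=np.int64)
    mask = np.zeros((n_seq, T_max), dtype=bool)
    for i, s in enumerate(seqs):
        O[i, : len(s)] = s
        mask[i, : len(s)] = True
    lengths = mask.sum(axis=1)

    loglik_trace = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        B = obs.T[O]  # (n_seq, T_max, n_macro) emission likelihoods
        alpha = np.zeros((n_seq, T_max, n_macro))
        c = np.ones((n_seq, T_max))
        a0 = start[None, :] * B[:, 0]
        c[:, 0] = a0.sum(axis=1)
        alpha[:, 0] = a0 / c[:, 0][:, None]
        for t in range(1, T_max):
            act = mask[:, t]
            a = (alpha[:, t - 1] @ Tm) * B[:, t]
            s_t = a.sum(axis=1)
            s_t = np.where(act & (s_t > 0), s_t, 1.0)
            alpha[:, t] = a / s_t[:, None]
            c[:, t] = np.where(act, s_t, 1.0)

        ll = float(np.sum(np.log(c[mask])))
        loglik_trace.append(ll)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite likelihood in Baum-Welch")

        beta = np.zeros((n_seq, T_max, n_macro))
        for i in range(n_seq):
            beta[i, lengths[i] - 1] = 1.0
        xi_sum = np.zeros((n_macro, n_macro))
        gamma_obs = np.zeros((n_macro, n_micro))
        gamma_start = np.zeros(n_macro)
        for t in range(T_max - 1, 0, -1):
            act = mask[:, t]
            bb = B[:, t] * beta[:, t]
            # xi accumulation for active sequences at step t
            w = alpha[:, t - 1][act]  # (na, m)
            bbw = bb[act] / c[:, t][act][:, None]
            xi_sum += (w.T @ bbw) * Tm
            beta_prev = (bb / c[:, t][:, None]) @ Tm.T
            beta[:, t - 1] = np.where(act[:, None], beta_prev, beta[:, t - 1])
            # sequences ending exactly at t-1 keep beta=1 set above
            ended = (~act) & mask[:, t - 1] & (lengths - 1 == t - 1)
            beta[ended, t - 1] = 1.0

        gamma = alpha * beta  # (n_seq, T_max, n_macro), normalized per frame
        gamma /= np.clip(gamma.sum(axis=2, keepdims=True), 1e-300, None)
        gamma = np.where(mask[:, :, None], gamma, 0.0)
        gamma_start = gamma[:, 0].sum(axis=0)
        flat_g = gamma.reshape(-1, n_macro)
        flat_o = O.reshape(-1)
        np.add.at(gamma_obs.T, flat_o, flat_g)

        Tm = xi_sum / np.clip(xi_sum.sum(axis=1, keepdims=True), 1e-300, None)
        obs = np.clip(gamma_obs, _OBS_FLOOR, None)
        obs[:, ~np.isin(np.arange(n_micro), observed)] = 0.0
        obs = np.clip(obs, 0.0, None)
        obs[:, observed] = np.clip(obs[:, observed], _OBS_FLOOR, None)
        obs /= obs.sum(axis=1, keepdims=True)
        start = gamma_start / gamma_start.sum()

        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll

    macro_pi = stationary_distribution(Tm)
    return HiddenMarkovModel(
        lag=int(lag),
        macro_T=Tm,
        obs=obs,
        macro_pi=macro_pi,
        loglik_trace=np.asarray(loglik_trace),
        frame_time=frame_time,
    )


def assign_macrostates(hmm: HiddenMarkovModel, frames_per_micro=None):
    """Hard macrostate label per microstate by largest fractional membership.

    Ties are broken toward the lower macrostate index and logged.  If
    ``frames_per_micro`` maps microstates to representative frames, the same
    labels are propagated to the frames and a frame table is returned too.
    """
    memb = hmm.memberships
    labels = np.argmax(memb, axis=1)
    best = memb[np.arange(len(labels)), labels]
    ties = np.sum(np.isclose(memb, best[:, None]), axis=1) > 1
    for m in np.nonzero(ties)[0]:
        logger.info(
            "microstate %d: membership tie broken toward macrostate %d", m, labels[m]
        )
    if frames_per_micro is None:
        return labels
    frame_table = {
        micro: (int(labels[micro]), frames) for micro, frames in frames_per_micro.items()
    }
    return labels, frame_table


def sample_long_trajectory(
    hmm: HiddenMarkovModel, n_steps: int, seed: int = 0, emit: str = "macro"
) -> np.ndarray:
    """Sample a long synthetic trajectory from the fitted HMM.

    The macrostate path starts from the stationary distribution; with
    ``emit='micro'`` each step additionally emits a microstate from the
    observation distribution.  One step spans one model lag (``lag_time`` of
    physical time), so millisecond-scale synthetic trajectories are cheap.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if emit not in ("macro", "micro"):
        raise ValueError("emit must be 'macro' or 'micro'")
    rng = np.random.default_rng(seed)
    cum_T = np.cumsum(hmm.macro_T, axis=1)
    path = np.empty(n_steps, dtype=np.int64)
    path[0] = np.searchsorted(np.cumsum(hmm.macro_pi), rng.random())
    for t in range(1, n_steps):
        path[t] = np.searchsorted(cum_T[path[t - 1]], rng.random())
    if emit == "macro":
        return path
    cum_obs = np.cumsum(hmm.obs, axis=1)
    u = rng.random(n_steps)
    micro = np.array([np.searchsorted(cum_obs[a], x) for a, x in zip(path, u)])
    return micro


def macrostate_sweep(dtrajs, n_macro_values, lag: int = 1, **fit_kwargs):
    """Fit HMMs over a range of macrostate counts; report loglik and timescales.

    The macrostate count itself is a modeling decision made by inspecting
    structural separation; this sweep only reports the quantitative evidence
    (final log-likelihood and relaxation timescales per candidate count).
    """
    import pandas as pd

    from ._markov import reversible_eigenvalues, timescales_from_eigenvalues

    rows = []
    for n in n_macro_values:
        h = fit_hmm(dtrajs, n_macro=int(n), lag=lag, **fit_kwargs)
        vals = reversible_eigenvalues(h.macro_T, h.macro_pi)
        ts = timescales_from_eigenvalues(vals[1:], h.lag)
        rows.append(
            {
                "n_macro": int(n),
                "loglik": float(h.loglik_trace[-1]),
                "n_iter": len(h.loglik_trace),
                "timescales": ts,
            }
        )
    return pd.DataFrame(rows)
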