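"""Landscape artifacts derived from a coarse-grained HMM.

From a macrostate HMM this module computes equilibrium flux matrices (using a
power of the transition matrix to eliminate sparsity), thresholds them into
flux networks, embeds log-inverse fluxes in two dimensions with restarted
metric MDS, converts stationary populations into relative free energies, and
annotates states structurally via Kabsch-superposed C-alpha RMSDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import smacof

from .hmm_coarse import HiddenMarkovModel

__all__ = [
    "EmbeddingResult",
    "SuperpositionConfig",
    "flux_matrix",
    "embed_mds",
    "free_energies",
    "flux_network",
    "superpose_rmsd",
    "state_rmsd_summary",
    "structural_diversity",
    "sample_macrostate_frames",
]


@dataclass
class EmbeddingResult:
    """Minimum-stress 2-D MDS embedding of log-inverse fluxes."""

    coords: np.ndarray
    dissimilarity: np.ndarray
    stress: float
    n_restarts: int
    seed: int
    restart_stresses: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class SuperpositionConfig:
    """Atom selections for rigid superposition and RMSD evaluation.

    ``fit_residues`` are inclusive residue-id ranges of the conformationally
    homogeneous core used for the superposition fit (defaults to the SET
    motifs, residues 257–290 and 327–376); the RMSD itself is evaluated over
    ``rmsd_residues`` (default: all residues).  Residue ids are matched
    against the structure's residue labels.
    """

    fit_residues: tuple = ((257, 290), (327, 376))
    rmsd_residues: tuple | None = None

    def resolve(self, residue_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        residue_ids = np.asarray(residue_ids)

        def pick(ranges):
            m = np.zeros(len(residue_ids), dtype=bool)
            for lo, hi in ranges:
                m |= (residue_ids >= lo) & (residue_ids <= hi)
            return np.nonzero(m)[0]

        fit = pick(self.fit_residues)
        if len(fit) == 0:
            raise ValueError("fit_residues select no atoms in this structure")
        rmsd = (
            np.arange(len(residue_ids))
            if self.rmsd_residues is None
            else pick(self.rmsd_residues)
        )
        if len(rmsd) == 0:
            raise ValueError("rmsd_residues select no atoms in this structure")
        return fit, rmsd


def flux_matrix(
    hmm: HiddenMarkovModel, power: int = 3, lag_time: float | None = None
) -> np.ndarray:
    """Equilibrium flux between macrostate pairs, per unit time.

    F_ij = pi_i (T^power)_ij / (power * lag_time) for i != j; the matrix
    power removes sparsity so every off-diagonal flux is positive, and the
    normalization reports probability flux per unit physical time (s^-1 when
    ``lag_time`` is in seconds).  Under detailed balance F is symmetric.
    """
    if lag_time is None:
        lag_time = hmm.lag_time
    Tp = np.linalg.matrix_power(hmm.macro_T, power)
    F = hmm.macro_pi[:, None] * Tp / (power * lag_time)
    np.fill_diagonal(F, 0.0)
    return F


def embed_mds(
    flux: np.ndarray, n_restarts: int = 50, seed: int = 0
) -> EmbeddingResult:
    """2-D metric MDS of log-inverse fluxes, best of ``n_restarts`` restarts.

    Dissimilarities D_ij = log(1 / F_ij), shifted so the smallest
    off-diagonal entry is zero (metric MDS needs nonnegative input), zero
    diagonal.  Each restart runs SMACOF stress majorization from a random
    configuration; the minimum-stress embedding is returned along with every
    restart's final stress so a different projection can be re-selected.
    """
    F = np.asarray(flux, dtype=float)
    n = F.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(F[off] <= 0):
        raise ValueError("all off-diagonal fluxes must be positive")
    D = np.zeros_like(F)
    D[off] = np.log(1.0 / F[off])
    shift = max(0.0, -float(D[off].min()))  # only shift when log-inverse goes negative
    D[off] += shift
    D = 0.5 * (D + D.T)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite dissimilarity")

    rng = np.random.default_rng(seed)
    best_coords, best_stress, stresses = None, np.inf, []
    for _ in range(n_restarts):
        rs = int(rng.integers(0, 2**31 - 1))
        coords, stress = smacof(
            D, n_components=2, n_init=1, random_state=rs, metric=True,
            normalized_stress=False,
        )
        stresses.append(stress)
        if stress < best_stress:
            best_coords, best_stress = coords, stress
    return EmbeddingResult(
        coords=best_coords,
        dissimilarity=D,
        stress=float(best_stress),
        n_restarts=n_restarts,
        seed=seed,
        restart_stresses=np.asarray(stresses),
    )


def free_energies(pi, kT: float = 1.0) -> np.ndarray:
    """Free energy of each state relative to the most populated one.

    dG_i = -kT ln(pi_i / max_j pi_j); the minimum is exactly 0 and the
    result is invariant to rescaling pi by a constant.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("populations must be positive")
    return -kT * np.log(pi / pi.max())


def flux_network(flux: np.ndarray, threshold: float) -> list:
    """Edges (i, j, F_ij) with i < j and flux at or above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    F = np.asarray(flux, dtype=float)
    n = F.shape[0]
    return [
        (i, j, float(F[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if F[i, j] >= threshold
    ]


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing ||(P R + t) - Q||."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    S = np.diag([1.0, 1.0, d])
    R = U @ S @ Vt
    t = qc - pc @ R
    return R, t


def superpose_rmsd(
    frames,
    reference: np.ndarray,
    config: SuperpositionConfig | None = None,
    residue_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD to a reference after Kabsch superposition on a core.

    The rigid-body fit uses only the ``fit_residues`` selection; the RMSD is
    evaluated over the ``rmsd_residues`` selection (all atoms by default).
    Input frames are (n_atoms, 3) arrays (nm) or a (T, n_atoms, 3) stack.
    """
    reference = np.asarray(reference, dtype=float)
    frames = np.asarray(frames, dtype=float)
    single = frames.ndim == 2
    if single:
        frames = frames[None]
    if frames.shape[1:] != reference.shape:
        raise ValueError("frame/reference atom selections do not match")
    n_atoms = reference.shape[0]
    if residue_ids is None:
        residue_ids = np.arange(n_atoms)
    if config is None:
        fit_idx = np.arange(n_atoms)
        rmsd_idx = np.arange(n_atoms)
    else:
        fit_idx, rmsd_idx = config.resolve(residue_ids)

    out = np.empty(frames.shape[0])
    for k, X in enumerate(frames):
        R, t = _kabsch(X[fit_idx], reference[fit_idx])
        moved = X @ R + t
        diff = moved[rmsd_idx] - reference[rmsd_idx]
        out[k] = np.sqrt(np.mean(np.sum(diff * diff, axis=1)))
    return out[0] if single else out


def state_rmsd_summary(micro_rmsds, hmm: HiddenMarkovModel) -> np.ndarray:
    """Observation-probability-weighted mean microstate RMSD per macrostate.

    macro_rmsd[a] = sum_m obs[a, m] * micro_rmsd[m].
    """
    micro_rmsds = np.asarray(micro_rmsds, dtype=float)
    if micro_rmsds.shape[0] != hmm.n_micro:
        raise ValueError("micro_rmsds must cover every microstate")
    return hmm.obs @ micro_rmsds


def sample_macrostate_frames(
    hmm: HiddenMarkovModel,
    frame_micro_labels: np.ndarray,
    macrostate: int,
    n: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Sample frame indices for one macrostate, weighted by observation prob.

    Each frame's weight is the observation probability of its microstate from
    the macrostate, divided by the number of frames in that microstate, so
    microstates contribute in proportion to obs and frames within a
    microstate uniformly.
    """
    labels = np.asarray(frame_micro_labels)
    counts = np.bincount(labels, minlength=hmm.n_micro).astype(float)
    w = hmm.obs[macrostate][labels] / counts[labels]
    tot = w.sum()
    if tot <= 0:
        raise ValueError("macrostate has no observable frames")
    rng = np.random.default_rng(seed)
    return rng.choice(len(labels), size=n, replace=False, p=w / tot)


def structural_diversity(
    frames,
    config: SuperpositionConfig | None = None,
    residue_ids: np.ndarray | None = None,
) -> float:
    """Minimum mean pairwise RMSD over reference frames of a sample.

    For each frame the mean RMSD (after core superposition) to every other
    frame is computed; the minimum over reference frames is returned.  Zero
    for an ensemble of identical structures.
    """
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames")
    D = np.zeros((n, n))
    for i in range(n):
        D[i] = superpose_rmsd(frames, frames[i], config=config, residue_ids=residue_ids)
    mean_to_others = (D.sum(axis=1)) / (n - 1)
    return float(mean_to_others.min())
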