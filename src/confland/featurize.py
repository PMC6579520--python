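"""Trajectory featurization and contact maps.

Three feature sets are supported, mirroring common MSM practice for a folded
protein domain:

* residue–residue minimum heavy-atom distances for pairs separated in
  sequence by at least two intervening residues (``|i - j| >= 3``), optionally
  restricted to pairs that actually cross the contact cutoff at least once;
* a logistic transform of those distances that emphasizes near-contact
  geometry, ``1 / (1 + exp(steepness * (d - center)))`` with steepness
  5 nm^-1 and center 0.5 nm;
* backbone (phi, psi) and side-chain (chi1) dihedral angles, each featurized
  as its sine and cosine.

Inputs may be ``mdtraj.Trajectory`` objects (heavy-atom aware) or
:class:`~confland.synthgen.BeadChainEnsemble` fixtures (one bead per residue).
All distances are in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._types import FeatureTrajectory
from .synthgen import BeadChainEnsemble

__all__ = [
    "FeaturizationConfig",
    "ContactMap",
    "eligible_pairs",
    "pairwise_min_distances",
    "select_dynamic_pairs",
    "logistic_transform",
    "dihedral_features",
    "mean_contact_map",
]


@dataclass
class FeaturizationConfig:
    """Featurization thresholds and the sequence-separation rule.

    ``min_seq_sep = 3`` encodes "separated in sequence by at least two
    neighboring residues": two residues strictly between the pair.
    """

    mode: str = "distances"  # distances | logistic_distances | dihedrals
    contact_select_cutoff: float = 0.4  # nm, dynamic-pair selection threshold
    steepness: float = 5.0  # nm^-1
    center: float = 0.5  # nm
    min_seq_sep: int = 3
    contact_map_cutoff: float = 0.4  # nm

    def __post_init__(self) -> None:
        if self.mode not in ("distances", "logistic_distances", "dihedrals"):
            raise ValueError(f"unknown featurization mode {self.mode!r}")
        for name in ("contact_select_cutoff", "steepness", "center", "contact_map_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_seq_sep < 1:
            raise ValueError("min_seq_sep must be >= 1")


@dataclass
class ContactMap:
    """Mean residue x residue contact-fraction matrix over an ensemble."""

    matrix: np.ndarray
    n_frames: int
    residue_index: np.ndarray = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("contact map must be square")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("contact map must be symmetric")
        if self.matrix.min() < 0 or self.matrix.max() > 1:
            raise ValueError("contact fractions must lie in [0, 1]")
        if self.residue_index is None:
            self.residue_index = np.arange(n)
        self.residue_index = np.asarray(self.residue_index)

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]


def eligible_pairs(n_residues: int, min_seq_sep: int = 3) -> list:
    """All residue pairs (i, j), i < j, with j - i >= min_seq_sep."""
    return [
        (i, j)
        for i in range(n_residues)
        for j in range(i + min_seq_sep, n_residues)
    ]


def _is_mdtraj(traj) -> bool:
    return hasattr(traj, "topology") and hasattr(traj, "xyz")


def _bead_pair_distances(ens: BeadChainEnsemble, pairs) -> np.ndarray:
    X = ens.xyz  # (T, n, 3)
    idx = np.asarray(pairs)
    return np.linalg.norm(X[:, idx[:, 0]] - X[:, idx[:, 1]], axis=-1)


def pairwise_min_distances(traj, config: FeaturizationConfig | None = None) -> FeatureTrajectory:
    """Per-frame minimum heavy-atom distance for every eligible residue pair.

    For mdtraj input the closest-heavy-atom scheme is used; for bead chains
    each residue is its single bead.  One column per pair, ordered by the
    lexicographic pair enumeration of :func:`eligible_pairs`.
    """
    config = config or FeaturizationConfig()
    if _is_mdtraj(traj):
        import mdtraj as md

        n_res = traj.topology.n_residues
        for r in traj.topology.residues:
            if not any(a.element.symbol != "H" for a in r.atoms):
                raise ValueError(f"residue {r} has no heavy atoms")
        pairs = eligible_pairs(n_res, config.min_seq_sep)
        d, _ = md.compute_contacts(traj, contacts=pairs, scheme="closest-heavy")
    elif isinstance(traj, BeadChainEnsemble):
        n_res = len(traj.residue_ids)
        pairs = eligible_pairs(n_res, config.min_seq_sep)
        d = _bead_pair_distances(traj, pairs)
    else:
        raise TypeError("expected an mdtraj.Trajectory or a BeadChainEnsemble")
    return FeatureTrajectory(d, column_labels=pairs)


def select_dynamic_pairs(distances, cutoff: float = 0.4) -> list:
    """Indices of columns whose distance crosses ``cutoff`` at least once.

    A pair is kept iff, pooled over the whole dataset, its distance takes
    values both below and at-or-above the cutoff.
    """
    if isinstance(distances, FeatureTrajectory):
        distances = [distances]
    if not distances:
        raise ValueError("empty distance dataset")
    mins = np.min(np.stack([t.features.min(axis=0) for t in distances]), axis=0)
    maxs = np.max(np.stack([t.features.max(axis=0) for t in distances]), axis=0)
    return [int(i) for i in np.nonzero((mins < cutoff) & (maxs >= cutoff))[0]]


def logistic_transform(d, config: FeaturizationConfig | None = None):
    """Logistic contact emphasis 1 / (1 + exp(steepness * (d - center))).

    Strictly decreasing in d; equals exactly 0.5 at d = center.
    """
    config = config or FeaturizationConfig(mode="logistic_distances")
    d = np.asarray(d, dtype=float)
    from scipy.special import expit

    out = expit(-config.steepness * (d - config.center))
    return float(out) if out.ndim == 0 else out


def _bead_torsions(ens: BeadChainEnsemble) -> tuple[np.ndarray, list]:
    """Torsion angles of every consecutive bead quadruplet, in radians."""
    X = ens.xyz
    n = X.shape[1]
    if n < 4:
        raise ValueError("need at least 4 beads to define a torsion")
    quads = [(i, i + 1, i + 2, i + 3) for i in range(n - 3)]
    b1 = X[:, 1:-2] - X[:, 0:-3]
    b2 = X[:, 2:-1] - X[:, 1:-2]
    b3 = X[:, 3:] - X[:, 2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.arctan2(y, x), quads


def dihedral_features(traj) -> FeatureTrajectory:
    """(sin, cos) of every defined phi, psi and chi1 angle.

    Angles undefined for a residue (e.g. chi1 for glycine/alanine, phi at the
    N-terminus) are omitted, not imputed.  For a bead-chain stand-in the angle
    set is the torsions of consecutive bead quadruplets.
    """
    if _is_mdtraj(traj):
        import mdtraj as md

        blocks, labels = [], []
        for name, fn in (("phi", md.compute_phi), ("psi", md.compute_psi), ("chi1", md.compute_chi1)):
            idx, ang = fn(traj)
            if ang.shape[1]:
                blocks.append(ang)
                labels += [(name, k) for k in range(ang.shape[1])]
        if not blocks:
            raise ValueError("no dihedral angles defined for this topology")
        angles = np.concatenate(blocks, axis=1)
    elif isinstance(traj, BeadChainEnsemble):
        angles, quads = _bead_torsions(traj)
        labels = [("torsion", q) for q in quads]
    else:
        raise TypeError("expected an mdtraj.Trajectory or a BeadChainEnsemble")
    feats = np.empty((angles.shape[0], 2 * angles.shape[1]))
    feats[:, 0::2] = np.sin(angles)
    feats[:, 1::2] = np.cos(angles)
    cols = []
    for lab in labels:
        cols += [("sin", lab), ("cos", lab)]
    return FeatureTrajectory(feats, column_labels=cols)


def mean_contact_map(trajs, config: FeaturizationConfig | None = None) -> ContactMap:
    """Fraction of frames in which each eligible pair is in contact.

    A pair counts as a contact in a frame when its minimum heavy-atom distance
    is below ``config.contact_map_cutoff``.  Pairs inside the sequence-
    separation band are identically zero.  The result is symmetric.
    """
    config = config or FeaturizationConfig()
    if not isinstance(trajs, (list, tuple)):
        trajs = [trajs]
    n_res = None
    total = 0
    acc = None
    pairs = None
    for traj in trajs:
        ft = (
            traj
            if isinstance(traj, FeatureTrajectory)
            else pairwise_min_distances(traj, config)
        )
        if pairs is None:
            pairs = ft.column_labels
            n_res = max(max(p) for p in pairs) + 1
            acc = np.zeros(len(pairs))
        contact = ft.features < config.contact_map_cutoff
        acc += contact.sum(axis=0)
        total += ft.features.shape[0]
    if total < 1:
        raise ValueError("need at least one frame")
    frac = acc / total
    M = np.zeros((n_res, n_res))
    for (i, j), f in zip(pairs, frac):
        M[i, j] = M[j, i] = f
    return ContactMap(matrix=M, n_frames=total)
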