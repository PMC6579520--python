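"""Small shared linear-algebra helpers for row-stochastic matrices."""

from __future__ import annotations

import numpy as np


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic, irreducible matrix."""
    T = np.asarray(T, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def reversible_eigenvalues(T: np.ndarray, pi: np.ndarray | None = None) -> np.ndarray:
    """Real, descending eigenvalues of a reversible transition matrix.

    Uses the symmetric similarity D^{1/2} T D^{-1/2} so the spectrum comes out
    exactly real.
    """
    T = np.asarray(T, dtype=float)
    if pi is None:
        pi = stationary_distribution(T)
    s = np.sqrt(pi)
    S = (s[:, None] * T) / s[None, :]
    vals = np.linalg.eigvalsh(0.5 * (S + S.T))
    return np.sort(vals)[::-1]


def reversible_eigendecomposition(
    T: np.ndarray, pi: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and right eigenvectors of a reversible T.

    Right eigenvectors are normalized to unit pi-weighted norm
    (sum_i pi_i psi_k(i)^2 = 1); the first is the constant vector.
    """
    T = np.asarray(T, dtype=float)
    if pi is None:
        pi = stationary_distribution(T)
    s = np.sqrt(pi)
    S = (s[:, None] * T) / s[None, :]
    vals, U = np.linalg.eigh(0.5 * (S + S.T))
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    U = U[:, order]
    psi = U / s[:, None]  # right eigenvectors of T, pi-orthonormal
    # fix sign convention: first nonzero entry positive
    for k in range(psi.shape[1]):
        j = np.argmax(np.abs(psi[:, k]))
        if psi[j, k] < 0:
            psi[:, k] = -psi[:, k]
    return vals, psi


def timescales_from_eigenvalues(vals: np.ndarray, lag: float) -> np.ndarray:
    """Implied timescales t_i = -lag / ln(lambda_i) for non-unit eigenvalues.

    Eigenvalues <= 0 or >= 1 map to NaN (undefined) and +inf respectively.
    """
    vals = np.asarray(vals, dtype=float)
    out = np.full(vals.shape, np.nan)
    pos = (vals > 0) & (vals < 1)
    out[pos] = -lag / np.log(vals[pos])
    out[vals >= 1] = np.inf
    return out
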