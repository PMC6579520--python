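"""Time-lagged independent component analysis (tICA).

Solves the symmetrized generalized eigenproblem C(tau) v = lambda C(0) v on
mean-free data pooled over trajectories.  Lagged pairs never span trajectory
boundaries.  Components can be scaled by the *kinetic* map (multiply tIC i by
its eigenvalue) or the *commute* map (multiply by sqrt(t_i / 2), where
t_i = -tau / ln lambda_i is the implied relaxation timescale), and truncated
to the smallest set of components explaining a requested fraction of the
total kinetic content.

Kinetic content of component i is defined here as t_i / 2 (the commute-map
variance), normalized over components with a positive timescale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._types import FeatureTrajectory

__all__ = ["TicaModel", "fit_tica", "transform", "kinetic_content_profile"]

_EPS_RANK = 1e-10  # relative covariance-eigenvalue cutoff for whitening


@dataclass
class TicaModel:
    """Fitted tICA model.

    ``components`` holds one eigenvector per column, orthonormal with respect
    to the instantaneous covariance C(0); ``eigenvalues`` are sorted
    descending and clipped to (-1, 1].
    """

    lag: int
    mean: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray
    mapping: str = "commute"
    timescales: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.mapping not in ("kinetic", "commute"):
            raise ValueError("mapping must be 'kinetic' or 'commute'")
        if self.timescales is None:
            lam = np.abs(self.eigenvalues)
            with np.errstate(divide="ignore"):
                self.timescales = np.where(
                    lam > 0, -self.lag / np.log(np.clip(lam, None, 1 - 1e-16)), np.nan
                )
            self.timescales[self.eigenvalues >= 1.0] = np.inf

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def _as_feature_list(features) -> list:
    if isinstance(features, FeatureTrajectory):
        features = [features]
    out = []
    for f in features:
        arr = f.features if isinstance(f, FeatureTrajectory) else np.asarray(f, float)
        if arr.ndim == 1:
            arr = arr[:, None]
        out.append(arr)
    return out


def fit_tica(features, lag: int, mapping: str = "commute") -> TicaModel:
    """Fit tICA at integer lag (in frames) on a list of feature trajectories.

    Covariances are the symmetrized estimates over all in-trajectory lagged
    pairs: C0 averages both time windows, Ct is symmetrized.  A spectral
    regularization discards covariance eigenpairs below 1e-10 of the largest
    before whitening; all-constant feature sets are rejected.
    """
    Xs = _as_feature_list(features)
    if any(x.shape[0] <= lag for x in Xs):
        raise ValueError("every trajectory must be longer than the lag")
    n_feat = Xs[0].shape[1]

    n_pairs = sum(x.shape[0] - lag for x in Xs)
    # mean over both lagged windows
    s = np.zeros(n_feat)
    for x in Xs:
        s += x[:-lag].sum(axis=0) + x[lag:].sum(axis=0)
    mean = s / (2 * n_pairs)

    C0 = np.zeros((n_feat, n_feat))
    Ct = np.zeros((n_feat, n_feat))
    for x in Xs:
        a = x[:-lag] - mean
        b = x[lag:] - mean
        C0 += a.T @ a + b.T @ b
        Ct += a.T @ b
    C0 /= 2 * n_pairs
    Ct = (Ct + Ct.T) / (2 * n_pairs)

    evals, evecs = np.linalg.eigh(C0)
    keep = evals > _EPS_RANK * evals.max()
    if not np.any(keep):
        raise ValueError("all features are constant; tICA undefined")
    L = evecs[:, keep] / np.sqrt(evals[keep])  # whitening transform
    M = L.T @ Ct @ L
    lam, W = np.linalg.eigh(0.5 * (M + M.T))
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], -1.0 + 1e-15, 1.0)
    V = L @ W[:, order]  # C0-orthonormal eigenvectors in feature space

    return TicaModel(
        lag=int(lag), mean=mean, eigenvalues=lam, components=V, mapping=mapping
    )


def _content_weights(model: TicaModel) -> np.ndarray:
    """Unnormalized kinetic content t_i/2 per component; 0 where undefined."""
    w = np.zeros(model.n_components)
    ok = (model.eigenvalues > 0) & np.isfinite(model.timescales)
    w[ok] = model.timescales[ok] / 2.0
    return w


def kinetic_content_profile(model: TicaModel) -> np.ndarray:
    """Cumulative normalized kinetic content per component (ends at 1)."""
    w = _content_weights(model)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("model has no component with positive timescale")
    return np.cumsum(w) / tot


def transform(
    model: TicaModel,
    features,
    kinetic_content: float | None = None,
    n_components: int | None = None,
) -> list:
    """Project feature trajectories onto (scaled) tICs.

    Kinetic mapping scales component i by its eigenvalue; commute mapping by
    sqrt(t_i / 2).  Components with nonpositive eigenvalue carry no
    resolvable kinetics and are dropped under the commute map.  With
    ``kinetic_content=q`` the smallest leading set whose cumulative content
    reaches q is kept.
    """
    if kinetic_content is not None and n_components is not None:
        raise ValueError("give either kinetic_content or n_components, not both")

    lam = model.eigenvalues
    if model.mapping == "commute":
        valid = lam > 0
        scales = np.sqrt(_content_weights(model)[valid])
        comps = model.components[:, valid]
        lam_v = lam[valid]
    else:
        valid = np.ones(len(lam), dtype=bool)
        scales = lam.copy()
        comps = model.components
        lam_v = lam

    if n_components is not None:
        if n_components > comps.shape[1]:
            raise ValueError(
                f"requested {n_components} components, only {comps.shape[1]} available"
            )
        k = n_components
    elif kinetic_content is not None:
        w = _content_weights(model)[valid]
        if w.sum() <= 0:
            raise ValueError("no components with positive kinetic content")
        profile = np.cumsum(w) / w.sum()
        k = int(np.searchsorted(profile, kinetic_content - 1e-12) + 1)
        k = min(k, comps.shape[1])
    else:
        k = comps.shape[1]

    src = [features] if isinstance(features, FeatureTrajectory) else list(features)
    res = []
    for f, x in zip(src, _as_feature_list(src)):
        if x.shape[1] != model.components.shape[0]:
            raise ValueError("feature dimensionality does not match the model")
        y = (x - model.mean) @ comps[:, :k] * scales[:k]
        gid = f.group_id if isinstance(f, FeatureTrajectory) else 0
        res.append(FeatureTrajectory(y, group_id=gid))
    return res
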