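"""Stopped-flow two-step ligand-binding kinetics.

The induced-fit (two-step) binding scheme

    E + S  <-> ES  <-> E'S
          k1,k-1  k2,k-2

produces biphasic fluorescence relaxations.  This module simulates noisy
stopped-flow traces from known rate constants, fits them globally (all ligand
concentrations simultaneously, shared rates and fluorescence coefficients),
fits the conformational-selection alternative (E <-> E', E' + S <-> E'S) for
model comparison, performs conventional double-exponential and dilution
fits, and derives equilibrium constants with delta-method error propagation:

    Kd1 = k-1 / k1,   Keq = k-2 / k2,   Kd = Kd1 * Keq / (1 + Keq).

Observed-rate predictions follow the standard pseudo-first-order relations
    kobs_fast = k1 [S] + k-1 + k2 + k-2
    kobs_slow ~ k1 [S] + (k-2 + k2) + k-1 k-2 / (k1 [S] + k-1 + k2 + k-2)
with the S-independent plateau k-2 + k2.

Units: concentrations in µM, time in s, k1 in µM^-1 s^-1, other rates s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "TwoStepRates",
    "ObservableModel",
    "DoubleExpFit",
    "EquilibriumConstants",
    "StoppedFlowDataset",
    "simulate_traces",
    "species_trajectories",
    "global_fit",
    "GlobalFitResult",
    "double_exp_fit",
    "kobs_predictions",
    "dilution_fit",
    "equilibrium_constants",
]


@dataclass
class TwoStepRates:
    """Rate constants of the induced-fit scheme (k1 in µM^-1 s^-1, rest s^-1)."""

    k1: float
    k_1: float
    k2: float
    k_2: float

    def __post_init__(self) -> None:
        if min(self.k1, self.k_1, self.k2, self.k_2) < 0:
            raise ValueError("rate constants must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k_1, self.k2, self.k_2])


@dataclass
class ObservableModel:
    """Fluorescence coefficients: F = a[E] + b[ES] + c[E'S] + bkg."""

    a: float
    b: float
    c: float
    bkg: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.bkg])


@dataclass
class DoubleExpFit:
    """F(t) = A1 exp(-kobs_fast t) + A2 exp(-kobs_slow t) + C."""

    A1: float
    A2: float
    kobs_fast: float
    kobs_slow: float
    C: float
    residual_norm: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.kobs_slow <= 0 or self.kobs_fast < self.kobs_slow:
            raise ValueError("need kobs_fast >= kobs_slow > 0")


@dataclass
class EquilibriumConstants:
    """Derived equilibrium constants with propagated standard errors."""

    Kd1: float
    Keq: float
    Kd: float
    se_Kd1: float
    se_Keq: float
    se_Kd: float
    dG_kT: float


@dataclass
class StoppedFlowDataset:
    """Per-concentration fluorescence traces (time in s, intensity a.u.)."""

    times: list
    intensities: list
    concentrations: np.ndarray
    enzyme_conc: float = 1.0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("ligand concentrations must be positive")
        for t in self.times:
            if np.any(np.diff(t) <= 0):
                raise ValueError("times must be strictly increasing per trace")

    def __len__(self) -> int:
        return len(self.concentrations)


# ---------------------------------------------------------------------------
# forward model


def _two_step_matrix(rates: np.ndarray, S: float) -> np.ndarray:
    k1, k_1, k2, k_2 = rates
    return np.array(
        [
            [-k1 * S, k_1, 0.0],
            [k1 * S, -(k_1 + k2), k_2],
            [0.0, k2, -k_2],
        ]
    )


def _conf_sel_matrix(rates: np.ndarray, S: float) -> np.ndarray:
    # species (E, E', E'S); E <-> E' (kf, kb), E' + S <-> E'S (kon, koff)
    kf, kb, kon, koff = rates
    return np.array(
        [
            [-kf, kb, 0.0],
            [kf, -(kb + kon * S), koff],
            [0.0, kon * S, -koff],
        ]
    )


def _conf_sel_x0(rates: np.ndarray) -> np.ndarray:
    kf, kb = rates[0], rates[1]
    tot = kf + kb
    if tot == 0:
        return np.array([1.0, 0.0, 0.0])
    # apo enzyme pre-equilibrated between E and E' before mixing
    return np.array([kb / tot, kf / tot, 0.0])


def _linear_species(A: np.ndarray, x0: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Solve x' = A x by eigendecomposition (A is a small rate matrix)."""
    w, V = np.linalg.eig(A)
    coef = np.linalg.solve(V, x0)
    X = np.real((V[None, :, :] * np.exp(np.outer(t, w))[:, None, :]) @ coef)
    return X  # (len(t), 3)


def species_trajectories(
    rates: TwoStepRates | np.ndarray,
    S: float,
    t: np.ndarray,
    enzyme_conc: float = 1.0,
    model: str = "two_step",
    pseudo_first_order: bool | None = None,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Species concentrations over time for one ligand concentration.

    In the pseudo-first-order regime ([S] >= 10x enzyme, the stopped-flow
    design) the ligand is held constant and the linear system is solved
    exactly by eigendecomposition; otherwise the full bimolecular system with
    ligand depletion is integrated with a stiff implicit method (BDF,
    atol 1e-12).  ``x0`` overrides the initial species vector (e.g. a
    pre-equilibrated mixture for a dilution experiment); the default is all
    enzyme free/apo at mixing.
    """
    r = rates.as_array() if isinstance(rates, TwoStepRates) else np.asarray(rates, float)
    if np.any(r < 0):
        raise ValueError("rate constants must be nonnegative")
    matrix = _two_step_matrix if model == "two_step" else _conf_sel_matrix
    if x0 is not None:
        x0 = np.asarray(x0, dtype=float)
    elif model == "two_step":
        x0 = np.array([1.0, 0.0, 0.0]) * enzyme_conc
    else:
        x0 = _conf_sel_x0(r) * enzyme_conc
    if pseudo_first_order is None:
        pseudo_first_order = S >= 10.0 * enzyme_conc
    if pseudo_first_order:
        return _linear_species(matrix(r, S), x0, t)

    def rhs(_, y):
        s_free = y[3]
        A = matrix(r, s_free)
        dy = A @ y[:3]
        # ligand depletion: binding consumes free S
        if model == "two_step":
            ds = -r[0] * s_free * y[0] + r[1] * y[1]
        else:
            ds = -r[2] * s_free * y[1] + r[3] * y[2]
        return np.append(dy, ds)

    sol = solve_ivp(
        rhs, (t[0], t[-1]), np.append(x0, S), t_eval=t, method="BDF",
        atol=1e-12, rtol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[:3].T


def _fluorescence(X: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    return X @ coeffs[:3] + coeffs[3]


def simulate_traces(
    rates: TwoStepRates,
    observable: ObservableModel,
    concentrations,
    t_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    enzyme_conc: float = 1.0,
    model: str = "two_step",
) -> StoppedFlowDataset:
    """Simulate stopped-flow fluorescence traces at several concentrations."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0:
        raise ValueError("t_grid must start at 0 (mixing time)")
    rng = np.random.default_rng(seed)
    times, intens = [], []
    for S in np.atleast_1d(concentrations):
        X = species_trajectories(rates, float(S), t_grid, enzyme_conc, model=model)
        F = _fluorescence(X, observable.as_array())
        if noise_sd > 0:
            F = F + noise_sd * rng.standard_normal(F.shape)
        times.append(t_grid.copy())
        intens.append(F)
    return StoppedFlowDataset(
        times=times,
        intensities=intens,
        concentrations=np.atleast_1d(concentrations),
        enzyme_conc=enzyme_conc,
    )


# ---------------------------------------------------------------------------
# global fitting


@dataclass
class GlobalFitResult:
    """Jointly fitted rates, fluorescence coefficients and standard errors."""

    model: str
    rates: TwoStepRates | np.ndarray
    observable: ObservableModel
    se_rates: np.ndarray
    covariance_rates: np.ndarray
    residual_norm: float
    n_starts_used: int
    at_bound: bool = False


def _predict_all(log_rates: np.ndarray, dataset: StoppedFlowDataset, model: str):
    """Species matrices per concentration for given log rates."""
    r = np.exp(log_rates)
    blocks = []
    for S, t in zip(dataset.concentrations, dataset.times):
        X = species_trajectories(r, float(S), np.asarray(t), dataset.enzyme_conc, model=model)
        blocks.append(X)
    return blocks


def _solve_coefficients(blocks, dataset, model: str = "two_step") -> np.ndarray:
    """Linear least squares for the fluorescence coefficients.

    Two-step: free (a, b, c, bkg) per species.  Conformational selection:
    the two apo conformers E and E' share one coefficient (the fluorescence
    change is ligand-mediated), giving (a, a, c, bkg); this constraint also
    removes the algebraic degeneracy by which an unconstrained three-species
    conformational-selection model can exactly mimic induced-fit data.
    """
    Xall = np.concatenate(blocks, axis=0)
    y = np.concatenate([np.asarray(f) for f in dataset.intensities])
    if model == "conformational_selection":
        D = np.column_stack([Xall[:, 0] + Xall[:, 1], Xall[:, 2], np.ones(Xall.shape[0])])
        a, c, bkg = np.linalg.lstsq(D, y, rcond=None)[0]
        return np.array([a, a, c, bkg])
    D = np.column_stack([Xall, np.ones(Xall.shape[0])])
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    return coef


def _residuals(log_rates, dataset, model):
    blocks = _predict_all(log_rates, dataset, model)
    coef = _solve_coefficients(blocks, dataset, model)
    res = []
    for X, f in zip(blocks, dataset.intensities):
        res.append(_fluorescence(X, coef) - np.asarray(f))
    return np.concatenate(res)


def _heuristic_start(dataset: StoppedFlowDataset) -> np.ndarray | None:
    """Initial rate guess from conventional double-exponential fits.

    kobs_fast is linear in [S] with slope k1 and intercept k-1 + k2 + k-2;
    kobs_slow plateaus near k2 + k-2.  The intercept is split assuming the
    dissociation step dominates it.
    """
    try:
        fast, slow = [], []
        for t, f in zip(dataset.times, dataset.intensities):
            fit = double_exp_fit(np.asarray(t), np.asarray(f))
            fast.append(fit.kobs_fast)
            slow.append(fit.kobs_slow)
        S = dataset.concentrations
        k1 = max(np.polyfit(S, fast, 1)[0], 1e-4)
        intercept = max(np.polyfit(S, fast, 1)[1], 1e-3)
        plateau = max(np.median(slow), 1e-3)
        k2 = 0.5 * plateau
        k_2 = 0.5 * plateau
        k_1 = max(intercept - plateau, 0.1 * intercept)
        return np.log([k1, k_1, k2, k_2])
    except Exception:  # noqa: BLE001 - heuristic only
        return None


def global_fit(
    dataset: StoppedFlowDataset,
    model: str = "two_step",
    init: TwoStepRates | np.ndarray | None = None,
    bounds: tuple = ((1e-4, 1e-2, 1e-3, 1e-3), (1e2, 1e4, 1e3, 1e3)),
    n_starts: int = 20,
    seed: int = 0,
) -> GlobalFitResult:
    """Global nonlinear least squares over all traces simultaneously.

    Rates are optimized in log space; for any candidate rate set the
    fluorescence coefficients (a, b, c, bkg) are profiled out by linear
    least squares, so only the four rate constants are nonlinear parameters.
    Besides ``n_starts`` log-uniform random starts within ``bounds``, one
    data-driven start from conventional double-exponential fits is used.
    Standard errors come from the Jacobian at the optimum.
    """
    if len(dataset) < 2:
        raise ValueError("global fit needs at least 2 concentrations")
    if model not in ("two_step", "conformational_selection"):
        raise ValueError(f"unknown model {model!r}")
    lo = np.log(np.asarray(bounds[0], float))
    hi = np.log(np.asarray(bounds[1], float))
    rng = np.random.default_rng(seed)

    starts = []
    if init is not None:
        arr = init.as_array() if isinstance(init, TwoStepRates) else np.asarray(init, float)
        starts.append(np.clip(np.log(arr), lo, hi))
    h = _heuristic_start(dataset)
    if h is not None:
        starts.append(np.clip(h, lo, hi))
    for _ in range(n_starts):
        starts.append(lo + (hi - lo) * rng.random(4))

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                _residuals, x0, args=(dataset, model), bounds=(lo, hi),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:  # noqa: BLE001 - individual starts may diverge
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("global fit did not converge from any start")

    log_opt = best.x
    at_bound = bool(np.any(np.isclose(log_opt, lo, atol=1e-6)) or np.any(np.isclose(log_opt, hi, atol=1e-6)))
    blocks = _predict_all(log_opt, dataset, model)
    coef = _solve_coefficients(blocks, dataset, model)
    resid = best.fun
    n_obs = len(resid)
    n_par = 4 + 4
    dof = max(n_obs - n_par, 1)
    sigma2 = float(resid @ resid) / dof
    J = best.jac  # d resid / d log-rate
    JTJ = J.T @ J
    try:
        cov_log = sigma2 * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        cov_log = sigma2 * np.linalg.pinv(JTJ)
    r_opt = np.exp(log_opt)
    # delta method from log to linear scale
    cov_rates = cov_log * np.outer(r_opt, r_opt)
    se_rates = np.sqrt(np.clip(np.diag(cov_rates), 0, None))

    rates_out = (
        TwoStepRates(*r_opt) if model == "two_step" else r_opt
    )
    return GlobalFitResult(
        model=model,
        rates=rates_out,
        observable=ObservableModel(*coef),
        se_rates=se_rates,
        covariance_rates=cov_rates,
        residual_norm=float(np.linalg.norm(resid)),
        n_starts_used=len(starts),
        at_bound=at_bound,
    )


# ---------------------------------------------------------------------------
# conventional fits


def _exp_design(t: np.ndarray, ks) -> np.ndarray:
    return np.column_stack([np.exp(-k * t) for k in ks] + [np.ones_like(t)])


def double_exp_fit(t: np.ndarray, f: np.ndarray, n_starts: int = 10, seed: int = 0) -> DoubleExpFit:
    """Fit F = A1 exp(-kfast t) + A2 exp(-kslow t) + C.

    Amplitudes and offset are profiled out linearly; the two rates are
    optimized in log space from several starts and reported sorted
    (kobs_fast >= kobs_slow).  An amplitude ratio below 1e-3 flags the fit
    as effectively single-exponential.
    """
    t = np.asarray(t, float)
    f = np.asarray(f, float)
    if len(t) < 6:
        raise ValueError("need at least 6 points")
    span = t[-1] - t[0]

    def resid(logk):
        D = _exp_design(t, np.exp(logk))
        coef, *_ = np.linalg.lstsq(D, f, rcond=None)
        return D @ coef - f

    rng = np.random.default_rng(seed)
    k_lo, k_hi = np.log(0.01 / span), np.log(1000.0 / span)
    starts = [np.array([np.log(50.0 / span), np.log(5.0 / span)])]
    for _ in range(n_starts - 1):
        starts.append(k_lo + (k_hi - k_lo) * rng.random(2))
    best = None
    for x0 in starts:
        sol = least_squares(resid, x0, bounds=(k_lo, k_hi), method="trf", xtol=1e-15, ftol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    ks = np.exp(best.x)
    order = np.argsort(ks)[::-1]
    ks = ks[order]
    D = _exp_design(t, ks)
    coef, *_ = np.linalg.lstsq(D, f, rcond=None)
    A1, A2, C = coef
    amps = np.abs([A1, A2])
    degenerate = amps.min() < 1e-3 * max(amps.max(), 1e-300)
    return DoubleExpFit(
        A1=float(A1),
        A2=float(A2),
        kobs_fast=float(ks[0]),
        kobs_slow=float(ks[1]),
        C=float(C),
        residual_norm=float(np.linalg.norm(best.fun)),
        degenerate=bool(degenerate),
    )


def kobs_predictions(rates: TwoStepRates, S) -> tuple:
    """Predicted (kobs_fast, kobs_slow, plateau) at ligand concentration S.

    The plateau constant k-2 + k2 is the S-independent bracket of the slow
    phase; the full slow-phase expression retains its additive k1[S] term.
    Both are exposed; see the module docstring for the tension between them.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("concentration must be >= 0")
    k1, k_1, k2, k_2 = rates.as_array()
    fast = k1 * S + k_1 + k2 + k_2
    slow = k1 * S + (k_2 + k2) + k_1 * k_2 / (k1 * S + k_1 + k2 + k_2)
    plateau = k_2 + k2
    if S.ndim == 0:
        return float(fast), float(slow), float(plateau)
    return fast, slow, plateau


def dilution_fit(t: np.ndarray, f: np.ndarray) -> float:
    """Dissociation rate from a single-exponential dilution trace.

    Fits F = A exp(-k t) + C; in the dissociation-dominated regime after
    rapid dilution the fitted rate estimates k-1.  Raises on a flat
    (non-decaying) trace.
    """
    t = np.asarray(t, float)
    f = np.asarray(f, float)
    span = t[-1] - t[0]
    dynamic = f.max() - f.min()
    if dynamic <= 1e-12 * max(abs(f).max(), 1.0):
        raise ValueError("trace shows no decay")

    def resid(logk):
        D = _exp_design(t, [np.exp(logk[0])])
        coef, *_ = np.linalg.lstsq(D, f, rcond=None)
        return D @ coef - f

    grid = np.log(np.geomspace(0.01 / span, 1000.0 / span, 40))
    costs = [float(0.5 * resid([g]) @ resid([g])) for g in grid]
    x0 = np.array([grid[int(np.argmin(costs))]])
    sol = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15)
    k = float(np.exp(sol.x[0]))
    D = _exp_design(t, [k])
    coef, *_ = np.linalg.lstsq(D, f, rcond=None)
    if abs(coef[0]) <= 1e-9 * dynamic:
        raise ValueError("trace is not a relaxing exponential")
    return k


def dilution_fit_average(traces) -> float:
    """Average k-1 over separately fitted per-concentration dilution traces."""
    return float(np.mean([dilution_fit(t, f) for t, f in traces]))


# ---------------------------------------------------------------------------
# equilibrium constants


def equilibrium_constants(
    rates: TwoStepRates,
    covariance: np.ndarray | None = None,
    kT_kJ: float | None = None,
) -> EquilibriumConstants:
    """Equilibrium constants and delta-method standard errors.

    Kd1 = k-1/k1 (µM), Keq = k-2/k2 (unitless), Kd = Kd1 Keq / (1 + Keq).
    Standard errors propagate the fit covariance of (k1, k-1, k2, k-2) to
    first order.  The binding free energy is reported in kT units,
    dG = ln(Kd[M]).
    """
    k1, k_1, k2, k_2 = rates.as_array()
    if k1 <= 0 or k2 <= 0:
        raise ValueError("k1 and k2 must be positive")
    Kd1 = k_1 / k1
    Keq = k_2 / k2
    Kd = Kd1 * Keq / (1.0 + Keq)

    # gradients wrt (k1, k_1, k2, k_2)
    g_Kd1 = np.array([-k_1 / k1**2, 1.0 / k1, 0.0, 0.0])
    g_Keq = np.array([0.0, 0.0, -k_2 / k2**2, 1.0 / k2])
    dKd_dKd1 = Keq / (1.0 + Keq)
    dKd_dKeq = Kd1 / (1.0 + Keq) ** 2
    g_Kd = dKd_dKd1 * g_Kd1 + dKd_dKeq * g_Keq

    if covariance is None:
        cov = np.zeros((4, 4))
    else:
        cov = np.asarray(covariance, dtype=float)
    se_Kd1 = float(np.sqrt(g_Kd1 @ cov @ g_Kd1))
    se_Keq = float(np.sqrt(g_Keq @ cov @ g_Keq))
    se_Kd = float(np.sqrt(g_Kd @ cov @ g_Kd))
    dG_kT = float(np.log(Kd * 1e-6))  # Kd is in µM; free energy in kT
    return EquilibriumConstants(
        Kd1=float(Kd1), Keq=float(Keq), Kd=float(Kd),
        se_Kd1=se_Kd1, se_Keq=se_Keq, se_Kd=se_Kd, dG_kT=dG_kT,
    )
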