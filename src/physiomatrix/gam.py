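"""Periodic functional-ANOVA decomposition of the physio-matrix.

The bin-averaged flow surface is modelled as

    P_ij = Q + R_i + E_j + I_ij + noise

with Q a constant offset equal to the net flow level, R and E periodic main
effects of respiratory and cardiac phase (each constrained to zero sum over
its phase grid), and I a doubly-centered periodic tensor-product interaction
(every row and column sum over the grid is zero).  All smooth terms use
cyclic cubic B-spline bases on the unit phase interval with cyclic
second-order difference penalties (periodic P-splines); the identifiability
constraints are imposed by null-space reparameterization, so the constrained
fit remains an ordinary penalized least-squares problem.

Smoothing parameters (one per term) are selected by generalized
cross-validation; a fixed common smoothing parameter may be requested
instead.  Per-component significance uses a Wald-type test: the quadratic
form of the component's coefficients in the pseudo-inverse of their Bayesian
posterior covariance, truncated at a rank given by the component's rounded
effective degrees of freedom, referred to the chi-square distribution of
that rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, null_space
from scipy.stats import chi2

from .config import AnalysisConfig
from .errors import (
    CoverageError,
    FittingError,
    InferenceError,
    ParameterError,
    UndefinedMetricError,
)
from .matrix import PhysioMatrix
from .signals import FlowSampleSeries, PhaseAssignments

COMPONENTS = ("R", "E", "I")


# ---------------------------------------------------------------------------
# cyclic spline machinery
# ---------------------------------------------------------------------------

def cyclic_basis(x: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    """Evaluate a period-1 cyclic B-spline basis at phases ``x`` in [0, 1).

    Built from uniform B-splines on an extended knot vector with coefficient
    indices folded modulo ``n_basis``, which makes every basis function (and
    any spline in its span) exactly periodic: the basis at phase 0 and
    phase 1 coincides.
    """
    if n_basis < 3:
        raise ParameterError("cyclic basis needs at least 3 functions")
    x = np.atleast_1d(np.asarray(x, dtype=float)) % 1.0
    step = 1.0 / n_basis
    knots = np.arange(-degree, n_basis + degree + 1) * step
    n_ext = n_basis + degree
    B = np.zeros((len(x), n_basis))
    coeffs = np.eye(n_ext)
    for m in range(n_ext):
        spl = BSpline(knots, coeffs[m], degree, extrapolate=False)
        vals = np.nan_to_num(spl(x))
        B[:, m % n_basis] += vals
    return B


def cyclic_penalty(n_basis: int) -> np.ndarray:
    """Cyclic second-order difference penalty matrix D'D."""
    D = np.zeros((n_basis, n_basis))
    for k in range(n_basis):
        D[k, k] = 1.0
        D[k, (k + 1) % n_basis] = -2.0
        D[k, (k + 2) % n_basis] = 1.0
    return D.T @ D


@dataclass
class _Term:
    """One smooth term: constrained design columns, penalty, grid evaluator."""

    name: str
    design: np.ndarray  # observation-level columns (already constrained)
    penalty: np.ndarray  # penalty in constrained coordinates
    grid_design: np.ndarray  # native phase-grid columns (constrained)
    Z: np.ndarray = None  # constraint null-space (basis -> constrained coords)
    dims: tuple = None  # basis dimension(s)
    sl: slice = field(default=None)  # column slice in the full design


def _main_effect_term(
    name: str,
    obs_phase: np.ndarray,
    grid_phase: np.ndarray,
    n_basis: int,
) -> _Term:
    B_grid = cyclic_basis(grid_phase, n_basis)
    constraint = B_grid.sum(axis=0, keepdims=True)  # sum over grid = 0
    Z = null_space(constraint)
    S = cyclic_penalty(n_basis)
    return _Term(
        name=name,
        design=cyclic_basis(obs_phase, n_basis) @ Z,
        penalty=Z.T @ S @ Z,
        grid_design=B_grid @ Z,
        Z=Z,
        dims=(n_basis,),
    )


def _interaction_term(
    obs_r: np.ndarray,
    obs_c: np.ndarray,
    grid_r: np.ndarray,
    grid_c: np.ndarray,
    dims: Tuple[int, int],
) -> _Term:
    kr, kc = dims
    Br_g = cyclic_basis(grid_r, kr)
    Bc_g = cyclic_basis(grid_c, kc)
    sr = Br_g.sum(axis=0)
    sc = Bc_g.sum(axis=0)
    # marginal centering: every grid row sum and column sum of I vanishes
    C = np.vstack(
        [np.kron(np.eye(kr), sc[None, :]).reshape(kr, kr * kc),
         np.kron(sr[None, :], np.eye(kc)).reshape(kc, kr * kc)]
    )
    Z = null_space(C)
    S = np.kron(cyclic_penalty(kr), np.eye(kc)) + np.kron(
        np.eye(kr), cyclic_penalty(kc)
    )
    Br_o = cyclic_basis(obs_r, kr)
    Bc_o = cyclic_basis(obs_c, kc)
    design = (Br_o[:, :, None] * Bc_o[:, None, :]).reshape(len(obs_r), kr * kc)
    grid = (Br_g[:, None, :, None] * Bc_g[None, :, None, :]).reshape(
        len(grid_r) * len(grid_c), kr * kc
    )
    return _Term(
        name="I",
        design=design @ Z,
        penalty=Z.T @ S @ Z,
        grid_design=grid @ Z,
        Z=Z,
        dims=(kr, kc),
    )


# ---------------------------------------------------------------------------
# decomposition result
# ---------------------------------------------------------------------------

@dataclass
class GAMDecomposition:
    """Fitted functional-ANOVA components on the native phase grid.

    ``Q`` is the constant net-flow level (ml/s); ``R`` and ``E`` the
    respiratory and cardiac main components at the n_i / n_j grid points;
    ``I`` the doubly-centered interaction surface.  ``p_values``, ``edf``
    and ``lambdas`` are keyed by component name.
    """

    Q: float
    R: np.ndarray
    E: np.ndarray
    I: np.ndarray
    p_values: Dict[str, float]
    edf: Dict[str, float]
    lambdas: Dict[str, float]
    sigma2: float
    # internals needed for the Wald test, refits and continuous evaluation
    coefficients: np.ndarray = field(repr=False, default=None)
    covariance: np.ndarray = field(repr=False, default=None)
    slices: Dict[str, slice] = field(repr=False, default_factory=dict)
    evaluators: Dict[str, object] = field(repr=False, default_factory=dict)

    @property
    def surface(self) -> np.ndarray:
        """Fitted flow surface Q + R_i + E_j + I_ij on the native grid."""
        return self.Q + self.R[:, None] + self.E[None, :] + self.I

    def R_at(self, phase) -> np.ndarray:
        """Fitted respiratory component at arbitrary phase fractions."""
        return self.evaluators["R"](np.asarray(phase, dtype=float))

    def E_at(self, phase) -> np.ndarray:
        """Fitted cardiac component at arbitrary phase fractions."""
        return self.evaluators["E"](np.asarray(phase, dtype=float))

    def I_at(self, resp_phase, cardiac_phase) -> np.ndarray:
        """Fitted interaction surface at arbitrary phase-fraction grids."""
        return self.evaluators["I"](
            np.asarray(resp_phase, dtype=float),
            np.asarray(cardiac_phase, dtype=float),
        )

    def to_dict(self) -> dict:
        return {
            "Q": self.Q,
            "R": self.R.tolist(),
            "E": self.E.tolist(),
            "I": self.I.tolist(),
            "p_values": self.p_values,
            "edf": self.edf,
            "lambda": self.lambdas,
            "sigma2": self.sigma2,
        }


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _assemble(
    obs_r, obs_c, grid_r, grid_c, config: AnalysisConfig
):
    terms = [
        _main_effect_term("R", obs_r, grid_r, config.basis_dim_resp),
        _main_effect_term("E", obs_c, grid_c, config.basis_dim_cardiac),
        _interaction_term(obs_r, obs_c, grid_r, grid_c,
                          tuple(config.basis_dim_interaction)),
    ]
    n = len(obs_r)
    X = np.hstack([np.ones((n, 1))] + [t.design for t in terms])
    col = 1
    for t in terms:
        t.sl = slice(col, col + t.design.shape[1])
        col += t.design.shape[1]
    return X, terms


def _penalty_matrix(p, terms, lambdas):
    S = np.zeros((p, p))
    for t, lam in zip(terms, lambdas):
        S[t.sl, t.sl] = lam * t.penalty
    return S


def _solve(XtWX, XtWy, S):
    try:
        c, low = cho_factor(XtWX + S)
    except np.linalg.LinAlgError as exc:
        raise FittingError("penalized normal equations not positive definite") from exc
    beta = cho_solve((c, low), XtWy)
    H = cho_solve((c, low), XtWX)  # 'hat' map on coefficients
    Ainv = cho_solve((c, low), np.eye(len(XtWy)))
    return beta, H, Ainv


def _gcv_score(log10_lam, X, y, w, terms, XtWX, XtWy):
    log10_lam = np.clip(np.asarray(log10_lam, dtype=float), -8.0, 8.0)
    S = _penalty_matrix(X.shape[1], terms, 10.0**log10_lam)
    try:
        beta, H, _ = _solve(XtWX, XtWy, S)
    except FittingError:
        return np.inf
    fitted = X @ beta
    rss = float(np.sum(w * (y - fitted) ** 2))
    n = len(y)
    edf = float(np.trace(H))
    if n - edf < 1.0:
        return np.inf
    return n * rss / (n - edf) ** 2


def _select_lambdas(X, y, w, terms, XtWX, XtWy):
    """Coarse log-grid search refined by Nelder-Mead on the GCV score."""
    grid = np.array([-4.0, -2.0, 0.0, 2.0, 4.0])
    best, best_score = None, np.inf
    for lr in grid:
        for lc in grid:
            for li in grid:
                s = _gcv_score((lr, lc, li), X, y, w, terms, XtWX, XtWy)
                if s < best_score:
                    best, best_score = np.array([lr, lc, li]), s
    res = optimize.minimize(
        _gcv_score,
        best,
        args=(X, y, w, terms, XtWX, XtWy),
        method="Nelder-Mead",
        options={"xatol": 0.05, "fatol": 1e-10, "maxiter": 400},
    )
    sol = res.x if res.fun <= best_score else best
    return 10.0 ** np.clip(sol, -8.0, 8.0)


def fit_gam(
    M: Optional[PhysioMatrix] = None,
    config: Optional[AnalysisConfig] = None,
    samples: Optional[FlowSampleSeries] = None,
    assignments: Optional[PhaseAssignments] = None,
) -> GAMDecomposition:
    """Fit the periodic functional-ANOVA decomposition.

    By default the fit uses one observation per occupied physio-matrix bin
    (phase-grid midpoints as covariates), optionally weighted by bin counts.
    With ``config.fit_level == 'samples'`` the raw samples and their
    continuous phase fractions are fitted instead.
    """
    config = config or AnalysisConfig()
    if M is None:
        raise ParameterError("a physio-matrix is required")
    n_i, n_j = M.n_i, M.n_j
    if n_i < 4 or n_j < 4:
        raise ParameterError("need at least 4 phases on each axis to fit")
    if M.occupancy < 0.8:
        raise CoverageError(
            f"bin occupancy {M.occupancy:.1%} below the 80% required for fitting"
        )
    grid_r = (np.arange(n_i) + 0.5) / n_i
    grid_c = (np.arange(n_j) + 0.5) / n_j

    if config.fit_level == "samples":
        if samples is None or assignments is None:
            raise ParameterError("sample-level fit needs samples and assignments")
        valid = assignments.valid
        obs_r = assignments.resp_frac[valid]
        obs_c = assignments.cardiac_frac[valid]
        y = samples.flows[valid]
        w = np.ones_like(y)
    else:
        occ = ~M.empty_mask
        ii, jj = np.nonzero(occ)
        obs_r = grid_r[ii]
        obs_c = grid_c[jj]
        y = M.values[occ]
        w = M.counts[occ].astype(float) if config.weight_by_counts else np.ones(len(y))

    X, terms = _assemble(obs_r, obs_c, grid_r, grid_c, config)
    p = X.shape[1]
    if len(y) <= p:
        raise FittingError(
            f"only {len(y)} observations for {p} coefficients; reduce basis dims"
        )
    XtWX = (X * w[:, None]).T @ X
    XtWy = (X * w[:, None]).T @ y

    fixed = config.fixed_lambda()
    if fixed is not None:
        lambdas = np.full(3, fixed)
    else:
        lambdas = _select_lambdas(X, y, w, terms, XtWX, XtWy)

    S = _penalty_matrix(p, terms, lambdas)
    beta, H, Ainv = _solve(XtWX, XtWy, S)
    fitted = X @ beta
    rss = float(np.sum(w * (y - fitted) ** 2))
    edf_total = float(np.trace(H))
    dof = max(len(y) - edf_total, 1.0)
    sigma2 = rss / dof
    # frequentist (sandwich) covariance of the penalized coefficients: for a
    # given smoothing parameter the Wald quadratic form against this matrix
    # is exactly chi-square under the component's null, unlike the wider
    # Bayesian posterior covariance which makes the test conservative
    Vb = sigma2 * (Ainv @ XtWX @ Ainv)

    edf = {t.name: float(np.trace(H[t.sl, t.sl])) for t in terms}
    slices = {t.name: t.sl for t in terms}

    def _main_eval(term):
        coef = term.Z @ beta[term.sl]
        k = term.dims[0]
        return lambda phi: cyclic_basis(phi, k) @ coef

    def _inter_eval(term):
        coef = (term.Z @ beta[term.sl]).reshape(term.dims)
        kr, kc = term.dims
        return lambda pr, pc: cyclic_basis(pr, kr) @ coef @ cyclic_basis(pc, kc).T

    evaluators = {
        "R": _main_eval(terms[0]),
        "E": _main_eval(terms[1]),
        "I": _inter_eval(terms[2]),
    }
    fit = GAMDecomposition(
        Q=float(beta[0]),
        R=terms[0].grid_design @ beta[terms[0].sl],
        E=terms[1].grid_design @ beta[terms[1].sl],
        I=(terms[2].grid_design @ beta[terms[2].sl]).reshape(n_i, n_j),
        p_values={},
        edf=edf,
        lambdas={t.name: float(lam) for t, lam in zip(terms, lambdas)},
        sigma2=sigma2,
        coefficients=beta,
        covariance=Vb,
        slices=slices,
        evaluators=evaluators,
    )
    fit.p_values = {name: wald_test(fit, name) for name in COMPONENTS}
    return fit


def wald_test(fit: GAMDecomposition, component: str, rank_policy: str = "full") -> float:
    """Wald test of the null hypothesis that a smooth component is zero.

    Computes ``b' V+ b`` where b are the component's coefficients and V+ is
    the eigenvalue pseudo-inverse of their frequentist covariance, referred
    to chi-square at the retained rank.  With the default ``rank_policy =
    'full'`` every numerically non-null eigen-direction is kept: for a given
    smoothing parameter the statistic is then an exact chi-square projection
    of the noise under the component's null, which keeps the realized test
    size close to nominal even though the smoothing parameter is selected
    from the data.  ``rank_policy = 'edf'`` truncates at the component's
    rounded effective degrees of freedom instead (more powerful against very
    smooth alternatives, but anticonservative after GCV selection).
    """
    if component not in COMPONENTS:
        raise ParameterError(f"component must be one of {COMPONENTS}")
    if fit.covariance is None:
        raise InferenceError("fit does not carry a coefficient covariance")
    sl = fit.slices[component]
    b = fit.coefficients[sl]
    V = fit.covariance[sl, sl]
    evals, evecs = np.linalg.eigh(V)
    tol = len(b) * np.finfo(float).eps * max(evals.max(), 0.0)
    if np.all(evals <= tol):
        # perfect fit (zero residual variance): no sampling variability, so
        # the test degenerates to whether the component is literally zero
        if fit.sigma2 == 0.0:
            return 1.0 if np.max(np.abs(b)) <= 1e-10 else 0.0
        raise InferenceError(f"covariance of component {component} is singular")
    if rank_policy == "full":
        rank = int(np.sum(evals > max(tol, evals.max() * 1e-10)))
    else:
        rank = int(min(len(b), max(1, round(fit.edf[component]))))
    # keep the 'rank' largest eigen-directions
    order = np.argsort(evals)[::-1][:rank]
    if np.any(evals[order] <= tol):
        raise InferenceError(
            f"covariance of component {component} singular beyond rank tolerance"
        )
    z = evecs[:, order].T @ b
    stat = float(np.sum(z**2 / evals[order]))
    return float(chi2.sf(stat, rank))


# ---------------------------------------------------------------------------
# amplitudes and pulsatility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulsatilityMetrics:
    """Component amplitudes (ml/s) and derived pulsatility indices.

    The pulsatility index of a component is its amplitude divided by the
    constant flow term Q; the respiratory-to-cardiac amplitude ratio equals
    the ratio of the two pulsatility indices by construction.
    """

    cardiac_amplitude: float
    respiratory_amplitude: float
    interaction_amplitude: float
    cardiac_PI: Optional[float]
    respiratory_PI: Optional[float]
    resp_to_cardiac_ratio: float
    pi_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "cardiac_amplitude_ml_s": self.cardiac_amplitude,
            "respiratory_amplitude_ml_s": self.respiratory_amplitude,
            "interaction_amplitude_ml_s": self.interaction_amplitude,
            "cardiac_PI": self.cardiac_PI,
            "respiratory_PI": self.respiratory_PI,
            "resp_to_cardiac_ratio": self.resp_to_cardiac_ratio,
            "pi_defined": self.pi_defined,
        }


def component_amplitude(values: np.ndarray) -> float:
    """Flow amplitude: difference between maximal and minimal values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("cannot take the amplitude of an empty component")
    return float(values.max() - values.min())


_AMPLITUDE_OVERSAMPLE = 10  # phase points per native bin when reading amplitudes


def pulsatility_metrics(fit: GAMDecomposition) -> PulsatilityMetrics:
    """Amplitudes, pulsatility indices and the respiratory-to-cardiac ratio.

    Amplitudes are read off the fitted continuous components on a grid
    oversampled 10x relative to the native phase bins, so narrow waveform
    features whose extremum falls between bin midpoints are not missed.
    """
    if fit.evaluators:
        fr = (np.arange(len(fit.R) * _AMPLITUDE_OVERSAMPLE) + 0.5) / (
            len(fit.R) * _AMPLITUDE_OVERSAMPLE
        )
        fc = (np.arange(len(fit.E) * _AMPLITUDE_OVERSAMPLE) + 0.5) / (
            len(fit.E) * _AMPLITUDE_OVERSAMPLE
        )
        a_r = component_amplitude(fit.R_at(fr))
        a_c = component_amplitude(fit.E_at(fc))
        a_i = component_amplitude(fit.I_at(fr[::2], fc[::2]))
    else:
        a_c = component_amplitude(fit.E)
        a_r = component_amplitude(fit.R)
        a_i = component_amplitude(fit.I)
    if a_c == 0:
        raise UndefinedMetricError(
            "respiratory-to-cardiac ratio undefined: zero cardiac amplitude"
        )
    if fit.Q != 0:
        pi_c, pi_r, defined = a_c / fit.Q, a_r / fit.Q, True
    else:
        pi_c, pi_r, defined = None, None, False
    return PulsatilityMetrics(
        cardiac_amplitude=a_c,
        respiratory_amplitude=a_r,
        interaction_amplitude=a_i,
        cardiac_PI=pi_c,
        respiratory_PI=pi_r,
        resp_to_cardiac_ratio=a_r / a_c,
        pi_defined=defined,
    )
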