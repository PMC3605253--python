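"""Parameter identification for one sub-model.

The parameters of an active sub-model (input coefficients b, state
coefficients a, ordered ``[b_1..b_Mi, a_1..a_Ni]``) are estimated in two
stages:

1. *Weighted linear regression* on numeric derivatives of the target series:
   theta = ([U X]' W [U X])^-1 [U X]' W dx/dt, with experiments concatenated
   row-wise (dynamic independence of data points).
2. *Bounded quasi-Newton refinement* (L-BFGS-B) of the simulation-based
   weighted least-squares objective, optionally penalised by flexible prior
   knowledge.

During sub-model fitting the incoming signals are known time courses:
stimulus step profiles, simulated trajectories of already-included genes and
the measured+interpolated data of not-yet-included genes.  The sub-model is
therefore a driven integrator chain; for the linear (non-sigmoid) case it is
propagated *exactly* over each grid interval, treating the driver as
piecewise linear, which is both faster and more accurate than a generic ODE
solver in the inner loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import minimize

from .errors import IntegrationFailureError, UnidentifiableStructureError

__all__ = [
    "SubmodelStructure",
    "SubmodelFit",
    "RegressionDesign",
    "numeric_derivative",
    "regress_init",
    "objective_output",
    "objective_total",
    "higher_order_init",
    "simulate_chain",
    "SubmodelProblem",
    "fit_submodel",
]


# --------------------------------------------------------------------------
# structure bookkeeping
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubmodelStructure:
    """Active index sets of one sub-model.

    ``inputs`` (M_i) and ``states`` (N_i, always containing ``gene`` itself)
    are sorted tuples of column indices; ``order`` is the integrator-chain
    order r.
    """

    gene: int
    inputs: tuple
    states: tuple
    order: int = 1

    def __post_init__(self):
        object.__setattr__(self, "inputs", tuple(sorted(self.inputs)))
        object.__setattr__(self, "states", tuple(sorted(set(self.states) | {self.gene})))

    @property
    def n_params(self) -> int:
        return len(self.inputs) + len(self.states)

    @property
    def self_pos(self) -> int:
        """Position of the self coefficient within the state block of theta."""
        return self.states.index(self.gene)

    @property
    def self_index(self) -> int:
        """Position of the self coefficient within the full theta vector."""
        return len(self.inputs) + self.self_pos

    @property
    def n_connections(self) -> int:
        """Incoming connections beyond the mandatory self-regulation."""
        return len(self.inputs) + len(self.states) - 1

    def with_input(self, m: int) -> "SubmodelStructure":
        return SubmodelStructure(self.gene, self.inputs + (m,), self.states, self.order)

    def with_state(self, j: int) -> "SubmodelStructure":
        return SubmodelStructure(self.gene, self.inputs, self.states + (j,), self.order)

    def without(self, kind: str, idx: int) -> "SubmodelStructure":
        if kind == "input":
            return SubmodelStructure(
                self.gene, tuple(m for m in self.inputs if m != idx),
                self.states, self.order)
        if idx == self.gene:
            raise ValueError("self-regulation can never be removed")
        return SubmodelStructure(
            self.gene, self.inputs,
            tuple(j for j in self.states if j != idx), self.order)

    def with_order(self, r: int) -> "SubmodelStructure":
        return SubmodelStructure(self.gene, self.inputs, self.states, r)


@dataclass
class SubmodelFit:
    """Fitted parameters and objective values of one sub-model."""

    structure: SubmodelStructure
    theta: np.ndarray
    j_output: float        # Eq.-style raw weighted sum
    j_norm: float          # j_output / sum of weights (per-point error)
    j_total: float         # j_norm + lambda * prior penalty
    converged: bool = True

    def __post_init__(self):
        if len(self.theta) != self.structure.n_params:
            raise ValueError("theta length must equal |M_i| + |N_i|")


@dataclass
class RegressionDesign:
    """Concatenated regression quantities for one sub-model."""

    U: np.ndarray          # T x |M_i|
    X: np.ndarray          # T x |N_i|
    weights: np.ndarray    # diagonal of W, length T
    dxdt: np.ndarray       # numeric derivative of the target series


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def numeric_derivative(series, times) -> np.ndarray:
    """Central differences at interior points, one-sided at the boundaries.

    Applied per experiment; never across experiment boundaries.
    """
    times = np.asarray(times, dtype=float)
    if len(np.unique(times)) != len(times):
        raise ValueError("duplicate time values in derivative grid")
    return np.gradient(np.asarray(series, dtype=float), times)


def regress_init(design: RegressionDesign) -> np.ndarray:
    """Weighted least-squares initial parameters [b..., a...].

    Raises :class:`UnidentifiableStructureError` on a rank-deficient
    weighted design; the caller must reject the candidate structure.
    """
    G = np.hstack([design.U, design.X])
    sw = np.sqrt(design.weights)
    Gw = G * sw[:, None]
    yw = design.dxdt * sw
    if np.linalg.matrix_rank(Gw) < G.shape[1]:
        raise UnidentifiableStructureError(
            f"unidentifiable structure: design rank < {G.shape[1]} columns"
        )
    theta, *_ = np.linalg.lstsq(Gw, yw, rcond=None)
    return theta


def objective_output(dataset, gene: int, simulated) -> float:
    """Weighted squared deviation summed over experiments and time points.

    ``simulated`` holds one series per experiment, sampled on the
    experiment's (measured + interpolated) grid.
    """
    total = 0.0
    for e, sim in zip(dataset.experiments, simulated):
        resid = e.Y[:, gene] - np.asarray(sim, dtype=float)
        total += float(np.sum(e.weights * resid * resid))
    return total


def objective_total(j_output: float, gene: int, gene_coeffs: dict,
                    input_coeffs: dict, prior=None, lam: float = 0.0) -> float:
    """Penalised objective: model error plus lambda-weighted prior distance."""
    if prior is None or lam == 0.0:
        return float(j_output)
    return float(j_output) + lam * prior.penalty_row(gene, gene_coeffs, input_coeffs)


def higher_order_init(theta: np.ndarray, structure: SubmodelStructure,
                      r: int) -> np.ndarray:
    """Adapt first-order parameters to chain order r.

    The diagonal coefficient becomes a_r = r * a_1 (total time constant
    r/(-a_r) = 1/(-a_1) preserved) and all other coefficients are rescaled by
    (-a_r)^r / (-a_1) so that the static gain of the observed chain state is
    unchanged.
    """
    theta = np.asarray(theta, dtype=float)
    if r == 1:
        return theta.copy()
    if r < 1:
        raise ValueError("order must be >= 1")
    k = structure.self_index
    a1 = theta[k]
    if a1 >= 0:
        raise ValueError("higher-order adaptation requires a stable sub-model")
    a_r = r * a1
    scale = (-a_r) ** r / (-a1)
    out = theta * scale
    out[k] = a_r
    return out


# --------------------------------------------------------------------------
# driven-chain simulation
# --------------------------------------------------------------------------

def simulate_chain(a: float, r: int, times, d, *, sigmoid: bool = False,
                   gain: float = 1.0, rtol: float = 1e-6,
                   atol: float = 1e-8) -> np.ndarray:
    """Observed trajectory of an order-r chain driven by signal ``d``.

    ``d`` is sampled on ``times`` and treated as piecewise linear.  The chain
    starts at zero.  The linear case is propagated exactly per interval; the
    sigmoid case (driven row wrapped by tanh(g z)/g) falls back to LSODA.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(d, dtype=float)
    n = len(t)
    if n == 0:
        return np.empty(0)
    if sigmoid:
        return _simulate_chain_sigmoid(a, r, t, d, gain, rtol, atol)
    out = np.empty(n)
    out[0] = 0.0
    if n == 1:
        return out
    h = np.diff(t)
    slope = np.diff(d) / h
    if r == 1:
        E = np.exp(a * h)
        phi1 = (E - 1.0) / a
        phi2 = (E - 1.0 - a * h) / (a * a)
        x = 0.0
        for k in range(n - 1):
            x = E[k] * x + d[k] * phi1[k] + slope[k] * phi2[k]
            out[k + 1] = x
        return out
    # order-r chain: exact discretisation via an augmented matrix exponential
    # (two extra states carry the affine-in-time driver).
    G = np.zeros((r + 2, r + 2))
    G[np.arange(r), np.arange(r)] = a
    G[np.arange(1, r), np.arange(r - 1)] = 1.0
    G[0, r] = 1.0
    G[r, r + 1] = 1.0
    cache: dict = {}
    z = np.zeros(r)
    for k in range(n - 1):
        key = round(float(h[k]), 12)
        step = cache.get(key)
        if step is None:
            M = expm(G * h[k])
            step = (M[:r, :r], M[:r, r], M[:r, r + 1])
            cache[key] = step
        Ad, b1, b2 = step
        z = Ad @ z + b1 * d[k] + b2 * slope[k]
        out[k + 1] = z[r - 1]
    return out


def _simulate_chain_sigmoid(a, r, t, d, gain, rtol, atol):
    def drive(tt):
        return np.interp(tt, t, d)

    def rhs(tt, z):
        dz = a * z
        dz[0] = np.tanh(gain * (a * z[0] + drive(tt))) / gain
        if r > 1:
            dz[1:] += z[:-1]
        return dz

    sol = solve_ivp(rhs, (t[0], t[-1]), np.zeros(r), method="LSODA",
                    t_eval=t, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationFailureError(
            f"integration failure in sub-model (a={a}, r={r}): {sol.message}"
        )
    return sol.y[r - 1]


# --------------------------------------------------------------------------
# the fitting problem
# --------------------------------------------------------------------------

class SubmodelProblem:
    """One sub-model's data, drivers, bounds and objectives.

    ``driver_lookup(j, e)`` returns the series of gene ``j`` in experiment
    ``e`` acting as an incoming signal: its simulated trajectory if the gene
    is already part of the model, its measured+interpolated data otherwise.
    """

    def __init__(self, structure: SubmodelStructure, dataset, driver_lookup,
                 config, prior=None, lam: float = 0.0):
        self.structure = structure
        self.dataset = dataset
        self.config = config
        self.prior = prior
        self.lam = lam
        g = structure.gene
        self.times = [e.times for e in dataset.experiments]
        self.ys = [e.Y[:, g] for e in dataset.experiments]
        self.w = [e.weights for e in dataset.experiments]
        self.w_total = float(sum(np.sum(w) for w in self.w))
        self._off_states = tuple(j for j in structure.states if j != g)
        # driver columns per experiment: inputs first, then non-self states
        self.drive_cols = []
        for e_idx, e in enumerate(dataset.experiments):
            cols = [e.U[:, m] for m in structure.inputs]
            cols += [np.asarray(driver_lookup(j, e_idx), dtype=float)
                     for j in self._off_states]
            self.drive_cols.append(
                np.column_stack(cols) if cols else np.zeros((e.n_points, 0))
            )
        self._driver_lookup = driver_lookup

    # ------------------------------------------------------------ plumbing
    def _split(self, theta):
        """(a_self, drive coefficients aligned with drive_cols columns)."""
        theta = np.asarray(theta, dtype=float)
        k = self.structure.self_index
        drive = np.delete(theta, k)
        return theta[k], drive

    def coefficient_maps(self, theta):
        """Dicts source-index -> coefficient for the prior penalty."""
        nb = len(self.structure.inputs)
        input_coeffs = {m: float(theta[i]) for i, m in enumerate(self.structure.inputs)}
        gene_coeffs = {j: float(theta[nb + i]) for i, j in enumerate(self.structure.states)}
        return gene_coeffs, input_coeffs

    def bounds(self):
        cfg = self.config
        lo, hi = -cfg.coeff_bound, cfg.coeff_bound
        bounds = []
        for m in self.structure.inputs:
            interval = (lo, hi)
            if self.prior is not None:
                code = self.prior.B_fix[self.structure.gene, m]
                if not np.isnan(code):
                    interval = self.prior.sign_interval(code, cfg.coeff_bound)
            bounds.append(interval)
        for j in self.structure.states:
            if j == self.structure.gene:
                bounds.append((lo, cfg.diag_upper))
            else:
                interval = (lo, hi)
                if self.prior is not None:
                    code = self.prior.A_fix[self.structure.gene, j]
                    if not np.isnan(code):
                        interval = self.prior.sign_interval(code, cfg.coeff_bound)
                bounds.append(interval)
        return bounds

    # ---------------------------------------------------------- regression
    def regression_design(self) -> RegressionDesign:
        g = self.structure.gene
        U_blocks, X_blocks, w_blocks, dx_blocks = [], [], [], []
        for e_idx, e in enumerate(self.dataset.experiments):
            U_blocks.append(e.U[:, list(self.structure.inputs)])
            xcols = []
            for j in self.structure.states:
                if j == g:
                    xcols.append(e.Y[:, g])
                else:
                    xcols.append(np.asarray(self._driver_lookup(j, e_idx), dtype=float))
            X_blocks.append(np.column_stack(xcols))
            w_blocks.append(e.weights)
            dx_blocks.append(numeric_derivative(e.Y[:, g], e.times))
        return RegressionDesign(
            U=np.vstack(U_blocks), X=np.vstack(X_blocks),
            weights=np.concatenate(w_blocks), dxdt=np.concatenate(dx_blocks),
        )

    def initial_theta(self) -> np.ndarray:
        """Regression initialiser, adapted to the structure's order."""
        theta1 = regress_init(self.regression_design())
        theta1 = self.clip(theta1, order_one=True)
        if self.structure.order > 1:
            return higher_order_init(theta1, self.structure, self.structure.order)
        return theta1

    def clip(self, theta, order_one: bool = False):
        theta = np.asarray(theta, dtype=float).copy()
        for i, (lo, hi) in enumerate(self.bounds()):
            theta[i] = min(max(theta[i], lo), hi)
        return theta

    # ---------------------------------------------------------- objectives
    def simulate(self, theta):
        a, drive = self._split(theta)
        cfg = self.config
        sims = []
        for t, D in zip(self.times, self.drive_cols):
            d = D @ drive if D.shape[1] else np.zeros(len(t))
            sims.append(simulate_chain(
                a, self.structure.order, t, d,
                sigmoid=cfg.sigmoid, gain=cfg.sigmoid_gain,
                rtol=cfg.rtol, atol=cfg.atol,
            ))
        return sims

    def j_output(self, theta) -> float:
        return objective_output(self.dataset, self.structure.gene,
                                self.simulate(theta))

    def penalty(self, theta) -> float:
        if self.prior is None or self.lam == 0.0:
            return 0.0
        gene_coeffs, input_coeffs = self.coefficient_maps(theta)
        return self.lam * self.prior.penalty_row(
            self.structure.gene, gene_coeffs, input_coeffs)

    def j_total(self, theta) -> float:
        """Per-point (weight-normalised) error plus prior penalty."""
        return self.j_output(theta) / self.w_total + self.penalty(theta)

    def evaluate(self, theta, converged: bool = True) -> SubmodelFit:
        jo = self.j_output(theta)
        jn = jo / self.w_total
        return SubmodelFit(
            structure=self.structure, theta=np.asarray(theta, dtype=float),
            j_output=jo, j_norm=jn, j_total=jn + self.penalty(theta),
            converged=converged,
        )


def fit_submodel(problem: SubmodelProblem, theta0=None) -> SubmodelFit:
    """Bounded quasi-Newton refinement from the regression initialiser.

    Guarantees J_total(theta*) <= J_total(theta0) + 1e-12: if the optimiser
    fails or ends worse, the initial parameters are returned with
    ``converged=False``.
    """
    if theta0 is None:
        theta0 = problem.initial_theta()
    theta0 = problem.clip(theta0)
    cfg = problem.config
    try:
        res = minimize(
            problem.j_total, theta0, method="L-BFGS-B",
            bounds=problem.bounds(),
            options={"maxiter": cfg.max_iter, "gtol": cfg.gtol, "ftol": 1e-14},
        )
        theta, ok = res.x, bool(res.success)
    except (IntegrationFailureError, FloatingPointError):
        theta, ok = theta0, False
    if problem.j_total(theta) > problem.j_total(theta0) + 1e-12:
        theta, ok = theta0, False
    return problem.evaluate(theta, converged=ok)
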