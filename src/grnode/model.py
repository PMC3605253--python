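"""Sparse linear state-space models of gene-regulatory networks.

A network of N observed genes driven by M external stimuli is modelled as

    dx/dt = A x + B u,      x(t0) = x0

where each gene i owns a *sub-model*: an integrator chain of order r_i >= 1
sharing one diagonal coefficient a_ii.  Incoming connections (state and
input terms) enter the first chain state; the last chain state is the one
compared with the gene's time series.  Chains reproduce S-shaped responses
without extra parameters.  Diagonal elements model self-regulation and mRNA
degradation and are kept strictly negative, so every sub-model is stable.

The optional saturating non-linearity wraps each sub-model's driven-row
linear combination with an odd sigmoid f(z) = tanh(g z)/g; f'(0) = 1, so the
linear model is recovered for small signals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationFailureError, UnstableSubmodelError

__all__ = [
    "GRNModel",
    "simulate",
    "static_gain",
    "total_time_constant",
    "sigmoid_transform",
]


@dataclass
class GRNModel:
    """LTI interaction model with per-gene integrator-chain sub-models.

    ``A`` is N_s x N_s and ``B`` is N_s x M with N_s = sum of orders.  State
    blocks follow ``gene_names`` order; within a block the first state is the
    driven one (incoming connections), the last the observed one.
    """

    A: np.ndarray
    B: np.ndarray
    gene_names: list[str]
    input_names: list[str]
    orders: list[int] = None  # type: ignore[assignment]
    x0: np.ndarray = None  # type: ignore[assignment]
    t0: float = 0.0
    sigmoid: bool = False
    sigmoid_gain: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim == 1:
            self.B = self.B.reshape(-1, max(1, len(self.input_names)))
        if self.orders is None:
            self.orders = [1] * len(self.gene_names)
        self.orders = [int(r) for r in self.orders]
        ns = sum(self.orders)
        if self.A.shape != (ns, ns):
            raise ValueError(f"A must be {ns}x{ns} for orders {self.orders}")
        if self.B.shape != (ns, len(self.input_names)):
            raise ValueError("B shape inconsistent with orders / input names")
        if self.x0 is None:
            self.x0 = np.zeros(ns)
        self.x0 = np.asarray(self.x0, dtype=float)

    # ------------------------------------------------------------- indexing
    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    def driven_index(self, gene: int) -> int:
        """State index receiving gene ``gene``'s incoming connections."""
        return sum(self.orders[:gene])

    def obs_index(self, gene: int) -> int:
        """State index compared with gene ``gene``'s time series."""
        return sum(self.orders[:gene]) + self.orders[gene] - 1

    def gene_index(self, name: str) -> int:
        return self.gene_names.index(name)

    def self_coefficient(self, gene: int) -> float:
        d = self.driven_index(gene)
        return self.A[d, d]

    def edge_coefficient(self, source, target) -> float:
        """Coefficient of the gene/input -> gene connection (0 if absent).

        ``source`` is a gene or stimulus name, ``target`` a gene name.
        """
        i = self.gene_index(target)
        if source in self.input_names:
            return self.B[self.driven_index(i), self.input_names.index(source)]
        j = self.gene_index(source)
        if i == j:
            return self.self_coefficient(i)
        return self.A[self.driven_index(i), self.obs_index(j)]

    # ------------------------------------------------------------ validator
    def validate(self) -> None:
        """Check the integrator-chain row pattern of every sub-model.

        For a chain of order r the r-1 intermediate rows must carry exactly
        the shared diagonal element and a unit coupling to the predecessor
        state; all structurally inactive entries must be exactly zero.
        """
        ns = self.n_states
        chain_rows = np.zeros(ns, dtype=bool)
        for g, r in enumerate(self.orders):
            d = self.driven_index(g)
            a_ii = self.A[d, d]
            for k in range(1, r):
                row = d + k
                chain_rows[row] = True
                expected = np.zeros(ns)
                expected[row] = a_ii
                expected[row - 1] = 1.0
                if not np.array_equal(self.A[row], expected):
                    raise ValueError(
                        f"chain row {row} of gene {self.gene_names[g]!r} "
                        "violates the integrator-chain pattern"
                    )
                if np.any(self.B[row] != 0):
                    raise ValueError(
                        f"chain row {row} must have no input connections"
                    )
        # incoming connections may only target driven states
        for g in range(self.n_genes):
            d, o = self.driven_index(g), self.obs_index(g)
            for col in range(d + 1, o):
                # intermediate states must not feed other sub-models
                for g2 in range(self.n_genes):
                    if g2 != g and self.A[self.driven_index(g2), col] != 0:
                        raise ValueError(
                            "connections must originate from observed states"
                        )

    # ---------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        return {
            "gene_names": self.gene_names,
            "input_names": self.input_names,
            "orders": self.orders,
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "x0": self.x0.tolist(),
            "t0": self.t0,
            "sigmoid": self.sigmoid,
            "sigmoid_gain": self.sigmoid_gain,
            "meta": self.meta,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "GRNModel":
        return cls(
            A=np.array(d["A"], dtype=float),
            B=np.array(d["B"], dtype=float),
            gene_names=list(d["gene_names"]),
            input_names=list(d["input_names"]),
            orders=list(d["orders"]),
            x0=np.array(d["x0"], dtype=float),
            t0=float(d.get("t0", 0.0)),
            sigmoid=bool(d.get("sigmoid", False)),
            sigmoid_gain=float(d.get("sigmoid_gain", 1.0)),
            meta=d.get("meta", {}),
        )

    @classmethod
    def load(cls, path) -> "GRNModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# simulation and sub-model characteristics
# --------------------------------------------------------------------------

def _input_function(stimuli, times, n_inputs):
    """Normalise a step-input spec into a callable u(t) -> (M,) vector."""
    if callable(stimuli):
        return lambda t: np.asarray(stimuli(t), dtype=float)
    arr = np.asarray(stimuli, dtype=float)
    if arr.ndim == 1:
        if len(arr) != n_inputs:
            raise ValueError("constant input vector must have length M")
        return lambda t: arr
    if arr.shape != (len(times), n_inputs):
        raise ValueError("input matrix must be T x M over the given times")
    t_grid = np.asarray(times, dtype=float)

    def u(t):
        k = np.clip(np.searchsorted(t_grid, t, side="right") - 1, 0, len(t_grid) - 1)
        return arr[k]

    return u


def simulate(model: GRNModel, stimuli, times) -> np.ndarray:
    """Integrate the model as an initial value problem.

    ``stimuli`` may be a length-M vector of constant step levels, a T x M
    matrix sampled on ``times`` (held piecewise constant), or a callable
    ``u(t)``.  Returns the trajectory of the *observed* states only, as a
    (len(times), N) array.  Integration uses LSODA, an implicit
    stiffness-tolerant multistep method.
    """
    times = np.asarray(times, dtype=float)
    if times[0] < model.t0 - 1e-12:
        raise ValueError("times must start at or after the model's t0")
    u = _input_function(stimuli, times, model.n_inputs)
    A, B = model.A, model.B
    driven = np.array([model.driven_index(g) for g in range(model.n_genes)])

    if model.sigmoid:
        g = model.sigmoid_gain

        def rhs(t, x):
            lin = A @ x + B @ u(t)
            lin[driven] = np.tanh(g * lin[driven]) / g
            return lin
    else:
        def rhs(t, x):
            return A @ x + B @ u(t)

    if len(times) == 1:
        return model.x0[[model.obs_index(g) for g in range(model.n_genes)]][None, :]
    sol = solve_ivp(
        rhs, (times[0], times[-1]), model.x0, method="LSODA",
        t_eval=times, rtol=1e-6, atol=1e-8,
    )
    if not sol.success:
        raise IntegrationFailureError(
            f"integration failure: {sol.message}; A={A.tolist()}, B={B.tolist()}"
        )
    obs = [model.obs_index(g) for g in range(model.n_genes)]
    return sol.y[obs, :].T


def static_gain(model: GRNModel, gene: int, input_index: int) -> float:
    """Steady-state response of gene's observed state to a unit step input.

    Only the direct input coefficient of the sub-model is considered:
    b/(-a) for first order, times (1/(-a))^(r-1) along the chain.
    """
    a = model.self_coefficient(gene)
    if a >= 0:
        raise UnstableSubmodelError(
            f"unstable sub-model for gene {model.gene_names[gene]!r}: a_ii={a}"
        )
    b = model.B[model.driven_index(gene), input_index]
    r = model.orders[gene]
    return b / (-a) * (1.0 / (-a)) ** (r - 1)


def total_time_constant(model: GRNModel, gene: int) -> float:
    """Summed characteristic time r * 1/(-a_ii) of the integrator chain."""
    a = model.self_coefficient(gene)
    if a >= 0:
        raise UnstableSubmodelError(
            f"unstable sub-model for gene {model.gene_names[gene]!r}: a_ii={a}"
        )
    return model.orders[gene] / (-a)


def sigmoid_transform(z, gain: float = 1.0):
    """Odd, monotone, saturating map with unit slope at the origin."""
    return np.tanh(gain * np.asarray(z, dtype=float)) / gain
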