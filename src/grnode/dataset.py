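"""Multi-experiment time-series containers and pre-processing.

Expression time courses from ``E`` separate stimulation experiments are held
in one :class:`Dataset`.  Each experiment carries an expression matrix
``Y`` (time points x genes), a stimulus matrix ``U`` (time points x stimuli,
typically 0/1 step profiles), a per-point measured/interpolated flag and a
per-point weight.

Pre-processing follows the standard recipe for sparse expression time
courses:

* :func:`standardise` - per gene and experiment, subtract the initial value
  (every series starts at 0); then divide the gene's series in *all*
  experiments by one common scalar, the maximum absolute centred value across
  experiments.  Standardised data lie in [-1, 1].
* :func:`interpolate` - insert equally spaced artificial points per measured
  interval using a natural cubic spline, flagged ``interpolated`` and
  down-weighted to curb over-fitting of the regression initialiser.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import ConfigError, DegenerateSeriesError

__all__ = [
    "ExperimentData",
    "Dataset",
    "standardise",
    "interpolate",
    "build_step_inputs",
    "read_wide_csv",
    "write_wide_csv",
]

log = logging.getLogger(__name__)

#: value of ``ExperimentData.measured`` entries
MEASURED, INTERPOLATED = True, False


@dataclass
class ExperimentData:
    """Time series and stimulus profiles of one experiment.

    ``times`` must be strictly increasing; ``Y`` is T x N, ``U`` is T x M.
    ``measured`` flags genuine data points (inserted spline points are
    ``False``); ``weights`` holds the non-negative per-point weights w(t_k).
    """

    times: np.ndarray
    Y: np.ndarray
    U: np.ndarray
    gene_names: list[str]
    stimulus_names: list[str]
    measured: np.ndarray = None  # type: ignore[assignment]
    weights: np.ndarray = None  # type: ignore[assignment]
    name: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.U = np.atleast_2d(np.asarray(self.U, dtype=float))
        T = len(self.times)
        if self.Y.shape[0] != T or self.U.shape[0] != T:
            raise ValueError("Y and U must have one row per time point")
        if self.Y.shape[1] != len(self.gene_names):
            raise ValueError("Y column count must match gene_names")
        if self.U.shape[1] != len(self.stimulus_names):
            raise ValueError("U column count must match stimulus_names")
        if T >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.measured is None:
            self.measured = np.ones(T, dtype=bool)
        else:
            self.measured = np.asarray(self.measured, dtype=bool)
        if self.weights is None:
            self.weights = np.ones(T, dtype=float)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    @property
    def n_points(self) -> int:
        return len(self.times)


@dataclass
class Dataset:
    """Ordered collection of experiments sharing genes and stimuli."""

    experiments: list[ExperimentData] = field(default_factory=list)

    def __post_init__(self):
        if self.experiments:
            ref = self.experiments[0]
            for e in self.experiments[1:]:
                if e.gene_names != ref.gene_names:
                    raise ValueError("all experiments must share gene_names")
                if e.stimulus_names != ref.stimulus_names:
                    raise ValueError("all experiments must share stimulus_names")

    @property
    def gene_names(self) -> list[str]:
        return self.experiments[0].gene_names if self.experiments else []

    @property
    def stimulus_names(self) -> list[str]:
        return self.experiments[0].stimulus_names if self.experiments else []

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_inputs(self) -> int:
        return len(self.stimulus_names)

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    @property
    def total_points(self) -> int:
        """Concatenated length T = sum_e T_e used by the regression."""
        return sum(e.n_points for e in self.experiments)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_files(cls, expression_paths, stimulus_paths) -> "Dataset":
        """Build a dataset from wide CSV files, one pair per experiment."""
        if len(expression_paths) != len(stimulus_paths):
            raise ConfigError("need one stimulus file per expression file")
        exps = []
        for ep, sp in zip(expression_paths, stimulus_paths):
            genes, t_y, Y = read_wide_csv(ep)
            stims, t_u, U = read_wide_csv(sp)
            if not np.allclose(t_y, t_u):
                raise ConfigError(f"time grids of {ep} and {sp} differ")
            exps.append(
                ExperimentData(t_y, Y, U, genes, stims, name=Path(ep).stem)
            )
        return cls(exps)

    def to_files(self, out_dir, prefix: str = "experiment") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, e in enumerate(self.experiments, 1):
            write_wide_csv(out / f"{prefix}{i}_expression.csv",
                           e.gene_names, e.times, e.Y)
            write_wide_csv(out / f"{prefix}{i}_stimuli.csv",
                           e.stimulus_names, e.times, e.U)


def read_wide_csv(path):
    """Read a wide matrix CSV: first column names, header row = time points.

    Returns ``(row_names, times, values)`` with ``values`` of shape
    (time points, rows), i.e. transposed into the T x N orientation.
    """
    df = pd.read_csv(path, index_col=0)
    times = np.array([float(c) for c in df.columns])
    return list(df.index.astype(str)), times, df.to_numpy(dtype=float).T


def write_wide_csv(path, row_names, times, values) -> None:
    df = pd.DataFrame(
        np.asarray(values).T, index=row_names,
        columns=[repr(float(t)) for t in times],
    )
    df.index.name = "name"
    df.to_csv(path)


# --------------------------------------------------------------------------
# pre-processing
# --------------------------------------------------------------------------

def standardise(data: Dataset, *, tol: float = 1e-12) -> Dataset:
    """Centre and scale every gene series; idempotent.

    Centering subtracts each experiment's initial value from that
    experiment's series; scaling divides the gene's series in all experiments
    by one common scalar, the maximum absolute centred value over all
    experiments.  Raises :class:`DegenerateSeriesError` for a gene that is
    constant after centering in every experiment.
    """
    if not data.experiments:
        return Dataset([])
    for e in data.experiments:
        if e.n_points < 2:
            raise ValueError("standardisation needs >= 2 time points per experiment")
    centred = [e.Y - e.Y[0:1, :] for e in data.experiments]
    scale = np.max(
        np.stack([np.max(np.abs(c), axis=0) for c in centred]), axis=0
    )
    for j, s in enumerate(scale):
        if s <= tol:
            raise DegenerateSeriesError(data.gene_names[j])
    new = [
        replace(e, Y=c / scale[np.newaxis, :])
        for e, c in zip(data.experiments, centred)
    ]
    return Dataset(new)


def interpolate(
    data: Dataset,
    k_per_interval: int = 3,
    *,
    interpolated_weight: float = 0.25,
    measured_weight: float = 1.0,
) -> Dataset:
    """Insert ``k_per_interval`` spline points per measured interval.

    Measured points are preserved bit-exactly and keep ``measured_weight``;
    inserted points are flagged interpolated and carry
    ``interpolated_weight``.  Natural cubic splines are fitted per gene and
    experiment; with fewer than 4 measured points the fit falls back to
    piecewise-linear interpolation (logged).
    """
    if k_per_interval < 0:
        raise ConfigError("k_per_interval must be >= 0")
    if k_per_interval == 0:
        return data
    new_exps = []
    for e in data.experiments:
        t = e.times
        T = len(t)
        # new grid: original points plus k interior points per interval
        pieces, src_index = [], []
        for k in range(T - 1):
            pieces.append(t[k:k + 1])
            src_index.append([k])
            inner = np.linspace(t[k], t[k + 1], k_per_interval + 2)[1:-1]
            pieces.append(inner)
            src_index.append([-1] * len(inner))
        pieces.append(t[-1:])
        src_index.append([T - 1])
        grid = np.concatenate(pieces)
        src = np.concatenate([np.asarray(s) for s in src_index])
        measured_mask = src >= 0

        Y_new = np.empty((len(grid), e.Y.shape[1]))
        if T >= 4:
            for j in range(e.Y.shape[1]):
                Y_new[:, j] = CubicSpline(t, e.Y[:, j], bc_type="natural")(grid)
        else:
            log.info(
                "experiment %r: only %d measured points, using piecewise-linear "
                "interpolation", e.name, T,
            )
            for j in range(e.Y.shape[1]):
                Y_new[:, j] = np.interp(grid, t, e.Y[:, j])
        # measured values exactly preserved
        Y_new[measured_mask] = e.Y[src[measured_mask]]
        # stimuli are step profiles: hold the previous measured value
        idx_prev = np.clip(np.searchsorted(t, grid, side="right") - 1, 0, T - 1)
        U_new = e.U[idx_prev]
        U_new[measured_mask] = e.U[src[measured_mask]]

        weights = np.where(measured_mask, measured_weight, interpolated_weight)
        new_exps.append(
            ExperimentData(
                grid, Y_new, U_new, e.gene_names, e.stimulus_names,
                measured=measured_mask, weights=weights, name=e.name,
            )
        )
    return Dataset(new_exps)


def build_step_inputs(applied, times, stimulus_names) -> np.ndarray:
    """Constant 0/1 stimulus columns for one experiment.

    ``applied`` maps stimulus name to level (or is an iterable of names
    switched on at level 1).  Unknown names raise :class:`ConfigError`.
    """
    if not isinstance(applied, dict):
        applied = {name: 1.0 for name in applied}
    unknown = set(applied) - set(stimulus_names)
    if unknown:
        raise ConfigError(f"unknown stimulus name(s): {sorted(unknown)}")
    U = np.zeros((len(times), len(stimulus_names)))
    for name, level in applied.items():
        U[:, stimulus_names.index(name)] = float(level)
    return U
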