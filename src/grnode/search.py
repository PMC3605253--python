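"""Heuristic structure search.

Starting from empty interaction and input matrices, the outer loop picks one
time series per step and adds it to the model as a sub-model:

1. For every remaining gene, *basic* candidate structures are fitted:
   self-regulation plus one input term each, plus any fix prior connections.
2. The gene whose best basic sub-model reproduces its series best (lowest
   penalised error) is selected and improved:
   *growing* (add incoming connections), *higher order* (integrator chain),
   *pruning* (remove connections that do not carry signal).
3. The improved sub-model is frozen and its simulated trajectory becomes an
   incoming signal for later sub-models.

Growing is not restricted to already-included genes: data of not-yet-included
genes act as proxy inputs; once those genes are included the proxy edges are
rewired to their states and become global feedbacks (above-diagonal entries
of the final interaction matrix).

Growing and order raising run only while the sub-model error exceeds
``allowed_error`` (per time series, weight-normalised); each structural
acceptance requires a relative improvement beyond ``growing_threshold``, and
pruning keeps a removal only if it worsens the error by at most
``pruning_threshold``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import InferenceConfig
from .dataset import Dataset, interpolate, standardise
from .errors import IntegrationFailureError, UnidentifiableStructureError
from .identify import (
    SubmodelFit,
    SubmodelProblem,
    SubmodelStructure,
    fit_submodel,
    higher_order_init,
)
from .model import GRNModel, simulate
from .prior import PriorKnowledge

__all__ = [
    "SearchState",
    "InferenceResult",
    "infer",
    "basic_candidates",
    "select_best",
    "grow",
    "raise_order",
    "prune",
    "finalize_global_feedbacks",
]

log = logging.getLogger(__name__)


@dataclass
class SearchState:
    """Bookkeeping of the outer loop."""

    dataset: Dataset
    config: InferenceConfig
    prior: PriorKnowledge
    lam: float
    included: list = field(default_factory=list)       # gene indices in order
    remaining: list = field(default_factory=list)
    fits: dict = field(default_factory=dict)           # gene -> SubmodelFit
    trajectories: dict = field(default_factory=dict)   # gene -> [series per exp]

    def driver_lookup(self, j: int, e_idx: int):
        traj = self.trajectories.get(j)
        if traj is not None:
            return traj[e_idx]
        return self.dataset.experiments[e_idx].Y[:, j]

    def problem(self, structure: SubmodelStructure) -> SubmodelProblem:
        return SubmodelProblem(
            structure, self.dataset, self.driver_lookup,
            self.config, self.prior, self.lam,
        )

    def include(self, gene: int, fit: SubmodelFit) -> None:
        self.included.append(gene)
        self.remaining.remove(gene)
        self.fits[gene] = fit
        self.trajectories[gene] = self.problem(fit.structure).simulate(fit.theta)


# --------------------------------------------------------------------------
# inner-loop building blocks
# --------------------------------------------------------------------------

def basic_candidates(gene: int, n_inputs: int,
                     prior: PriorKnowledge) -> list[SubmodelStructure]:
    """One candidate per admissible input, each carrying the fix edges."""
    fix_inputs = tuple(prior.fix_input_sources(gene))
    fix_genes = tuple(prior.fix_gene_sources(gene))
    excluded = prior.excluded_input_sources(gene)
    cands, seen = [], set()
    for m in range(n_inputs):
        if m in excluded:
            continue
        s = SubmodelStructure(gene, (m,) + fix_inputs, (gene,) + fix_genes)
        if s not in seen:
            seen.add(s)
            cands.append(s)
    if not cands:  # no admissible input: self-regulation (+ fix) only
        cands.append(SubmodelStructure(gene, fix_inputs, (gene,) + fix_genes))
    return cands


def select_best(fits: dict) -> int:
    """Gene with minimal J_total; ties: fewer parameters, then gene order."""
    return min(fits, key=lambda g: (fits[g].j_total,
                                    fits[g].structure.n_params, g))


def _fit_structure(state: SearchState, structure: SubmodelStructure,
                   theta0=None) -> SubmodelFit:
    return fit_submodel(state.problem(structure), theta0)


def _best_basic(state: SearchState, gene: int, audit: list) -> SubmodelFit | None:
    best = None
    for structure in basic_candidates(gene, state.dataset.n_inputs, state.prior):
        try:
            fit = _fit_structure(state, structure)
        except UnidentifiableStructureError as exc:
            audit.append({"gene": gene, "structure": _describe(structure, state),
                          "rejected": str(exc)})
            continue
        audit.append({"gene": gene, "structure": _describe(structure, state),
                      "J": fit.j_total})
        if best is None or (fit.j_total, fit.structure.n_params) < (
                best.j_total, best.structure.n_params):
            best = fit
    return best


def _candidate_sources(state: SearchState, structure: SubmodelStructure):
    """Admissible new incoming connections: inputs first, then genes."""
    g = structure.gene
    prior = state.prior
    for m in range(state.dataset.n_inputs):
        if m not in structure.inputs and m not in prior.excluded_input_sources(g):
            yield ("input", m)
    for j in range(state.dataset.n_genes):
        if (j != g and j not in structure.states
                and j not in prior.excluded_gene_sources(g)):
            yield ("gene", j)


def grow(fit: SubmodelFit, state: SearchState, audit: list) -> SubmodelFit:
    """Greedily add the best new incoming connection while worthwhile."""
    cfg = state.config
    while (fit.j_norm > cfg.allowed_error
           and fit.structure.n_connections < cfg.max_connections):
        best = None
        for kind, idx in _candidate_sources(state, fit.structure):
            structure = (fit.structure.with_input(idx) if kind == "input"
                         else fit.structure.with_state(idx))
            try:
                cand = _fit_structure(state, structure)
            except UnidentifiableStructureError:
                continue
            if best is None or cand.j_total < best.j_total:
                best = cand
        if best is None or best.j_total > (1 - cfg.growing_threshold) * fit.j_total:
            break
        audit.append({"step": "grow", "gene": fit.structure.gene,
                      "structure": _describe(best.structure, state),
                      "J_before": fit.j_total, "J_after": best.j_total})
        fit = best
    return fit


def raise_order(fit: SubmodelFit, state: SearchState, audit: list) -> SubmodelFit:
    """Try chain orders 2..maxOrder; keep the best significantly-better one."""
    cfg = state.config
    if cfg.max_order == 1 or fit.j_norm <= cfg.allowed_error:
        return fit
    base_theta = fit.theta
    best = None
    for r in range(2, cfg.max_order + 1):
        structure = fit.structure.with_order(r)
        try:
            theta0 = higher_order_init(base_theta, fit.structure, r)
        except ValueError:
            continue
        cand = fit_submodel(state.problem(structure), theta0)
        if best is None or cand.j_total < best.j_total:
            best = cand
    if best is not None and best.j_total <= (1 - cfg.growing_threshold) * fit.j_total:
        audit.append({"step": "raise_order", "gene": fit.structure.gene,
                      "order": best.structure.order,
                      "J_before": fit.j_total, "J_after": best.j_total})
        return best
    return fit


def _removable_edges(structure: SubmodelStructure, prior: PriorKnowledge):
    g = structure.gene
    fix_in = set(prior.fix_input_sources(g))
    fix_gn = set(prior.fix_gene_sources(g))
    for m in structure.inputs:
        if m not in fix_in:
            yield ("input", m)
    for j in structure.states:
        if j != g and j not in fix_gn:
            yield ("gene", j)


def prune(fit: SubmodelFit, state: SearchState, audit: list) -> SubmodelFit:
    """Remove connections whose loss does not worsen the fit significantly.

    Each tentative removal is refitted (warm-started from the current
    parameters); the self-regulation and fix prior edges are never touched.
    A removal is kept when it does not worsen the penalised error beyond the
    pruning tolerance, or when the reduced sub-model still meets the allowed
    per-series error (a connection that is not needed to reach the error
    target carries no signal worth a parameter).  Passes repeat until none
    of the removals is acceptable.
    """
    cfg = state.config
    changed = True
    while changed:
        changed = False
        for kind, idx in list(_removable_edges(fit.structure, state.prior)):
            structure = fit.structure.without(kind, idx)
            pos = (fit.structure.inputs.index(idx) if kind == "input"
                   else len(fit.structure.inputs) + fit.structure.states.index(idx))
            theta0 = np.delete(fit.theta, pos)
            cand = fit_submodel(state.problem(structure), theta0)
            if (cand.j_total <= (1 + cfg.pruning_threshold) * fit.j_total
                    or cand.j_norm <= cfg.allowed_error):
                audit.append({"step": "prune", "gene": fit.structure.gene,
                              "removed": (kind, idx),
                              "J_before": fit.j_total, "J_after": cand.j_total})
                fit = cand
                changed = True
                break
    return fit


# --------------------------------------------------------------------------
# model assembly
# --------------------------------------------------------------------------

def finalize_global_feedbacks(state: SearchState) -> GRNModel:
    """Assemble the final coupled model; rewire proxy edges to states.

    States follow inclusion order, so connections from earlier-included genes
    sit below the diagonal (forward) and rewired proxy connections from
    later-included genes sit above it (global feedbacks).  Proxy-edge
    parameters are kept as fitted; the rewiring is purely topological.
    """
    ds, order = state.dataset, state.included
    pos = {g: k for k, g in enumerate(order)}
    orders = [state.fits[g].structure.order for g in order]
    ns = sum(orders)
    offsets = np.concatenate([[0], np.cumsum(orders)])[:-1]
    A = np.zeros((ns, ns))
    B = np.zeros((ns, ds.n_inputs))
    for g in order:
        fit = state.fits[g]
        k = pos[g]
        d = int(offsets[k])
        r = orders[k]
        a_self = fit.theta[fit.structure.self_index]
        for c in range(r):
            A[d + c, d + c] = a_self
            if c:
                A[d + c, d + c - 1] = 1.0
        nb = len(fit.structure.inputs)
        for i, m in enumerate(fit.structure.inputs):
            B[d, m] = fit.theta[i]
        for i, j in enumerate(fit.structure.states):
            if j == g:
                continue
            kj = pos[j]
            obs_j = int(offsets[kj]) + orders[kj] - 1
            A[d, obs_j] = fit.theta[nb + i]
    model = GRNModel(
        A=A, B=B,
        gene_names=[ds.gene_names[g] for g in order],
        input_names=list(ds.stimulus_names),
        orders=orders,
    )
    model.validate()
    return model


@dataclass
class InferenceResult:
    """Final model plus the audit trail of the search."""

    model: GRNModel
    dataset: Dataset           # standardised + interpolated data actually fitted
    fits: dict                 # original gene index -> SubmodelFit
    report: dict
    J: float                   # mean per-gene weight-normalised model error
    simulated: list = None     # type: ignore[assignment]  # coupled simulation per experiment


# --------------------------------------------------------------------------
# the driver
# --------------------------------------------------------------------------

def infer(data: Dataset, prior: PriorKnowledge | None = None,
          config: InferenceConfig | None = None) -> InferenceResult:
    """Run the full heuristic on a multi-experiment dataset.

    ``data`` may be raw or already standardised/interpolated; pre-processing
    is applied as needed (standardisation is idempotent; interpolation is
    skipped when artificial points are already present).  Deterministic for
    identical data, prior and configuration.
    """
    config = (config or InferenceConfig()).validate()
    if data.n_genes == 0 or not data.experiments:
        model = GRNModel(np.zeros((0, 0)), np.zeros((0, data.n_inputs)),
                         [], list(data.stimulus_names), orders=[])
        return InferenceResult(model, data, {}, {"inclusion_order": []}, 0.0, [])

    ds = standardise(data)
    if all(e.measured.all() for e in ds.experiments):
        ds = interpolate(
            ds, config.k_per_interval,
            interpolated_weight=config.weight_interpolated,
            measured_weight=config.weight_measured,
        )
    if prior is None:
        prior = PriorKnowledge.empty(ds.gene_names, ds.stimulus_names)
    elif (prior.gene_names != ds.gene_names
          or prior.input_names != ds.stimulus_names):
        raise ValueError("prior knowledge names must match the dataset")
    lam = prior.lam if prior.lam is not None else config.prior_lambda

    state = SearchState(ds, config, prior, lam,
                        remaining=list(range(ds.n_genes)))
    report = {"inclusion_order": [], "candidates": [], "improvements": [],
              "warnings": [], "config": config.to_text()}

    while state.remaining:
        best_fits = {}
        for g in state.remaining:
            fit = _best_basic(state, g, report["candidates"])
            if fit is not None:
                best_fits[g] = fit
        if not best_fits:
            g = state.remaining[0]
            fit = _fallback_fit(state, g)
            report["warnings"].append(
                f"no identifiable basic structure for gene "
                f"{ds.gene_names[g]!r}; best-effort sub-model included"
            )
        else:
            g = select_best(best_fits)
            fit = best_fits[g]
            fit = grow(fit, state, report["improvements"])
            fit = raise_order(fit, state, report["improvements"])
            fit = prune(fit, state, report["improvements"])
        state.include(g, fit)
        report["inclusion_order"].append(ds.gene_names[g])
        log.debug("included %s: J=%.3g order=%d", ds.gene_names[g],
                  fit.j_total, fit.structure.order)

    model = finalize_global_feedbacks(state)
    j_mean = float(np.mean([state.fits[g].j_norm for g in state.included]))
    report["per_gene"] = {
        ds.gene_names[g]: {
            "J_output": state.fits[g].j_output,
            "J_per_point": state.fits[g].j_norm,
            "J_total": state.fits[g].j_total,
            "order": state.fits[g].structure.order,
            "converged": state.fits[g].converged,
        }
        for g in state.included
    }
    report["J"] = j_mean

    simulated = []
    for e in ds.experiments:
        try:
            simulated.append(simulate(model, e.U, e.times))
        except IntegrationFailureError as exc:
            report["warnings"].append(f"coupled simulation failed: {exc}")
            simulated.append(None)
    return InferenceResult(model, ds, dict(state.fits), report, j_mean, simulated)


def _fallback_fit(state: SearchState, gene: int) -> SubmodelFit:
    """Best-effort basic sub-model when no candidate is identifiable."""
    structure = basic_candidates(gene, state.dataset.n_inputs, state.prior)[0]
    problem = state.problem(structure)
    theta0 = np.zeros(structure.n_params)
    theta0[structure.self_index] = -1.0
    return fit_submodel(problem, theta0)


def _describe(structure: SubmodelStructure, state: SearchState) -> str:
    ds = state.dataset
    parts = [f"u:{ds.stimulus_names[m]}" for m in structure.inputs]
    parts += [f"g:{ds.gene_names[j]}" for j in structure.states]
    return f"{ds.gene_names[structure.gene]} <- {{{', '.join(parts)}}} (r={structure.order})"
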