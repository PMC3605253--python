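"""Cross-talk benchmark systems, artificial data and structure evaluation.

Benchmark systems are sparse stable LTI networks driven by two (or more)
step stimuli, classified by their degree of cross-talk:

* **FCT** (full cross-talk): every gene is reachable from every input,
* **LCT** (limited cross-talk): some but not all genes are reachable from
  more than one input (cross-talk of downstream components),
* **NCT** (no cross-talk): the inputs drive disjoint sub-networks.

Artificial data mimic sparse expression time courses: six time points with
exponentially increasing intervals (t = 0, 1, 2, 4, 8, 16 by default) and
additive Gaussian noise N(0, 0.05^2), standardised afterwards.

Inferred structures are scored against the generating structure position by
position over all N^2 + M*N candidate connections (self-loops included) as
edge-confusion counts; false positives are split into wrong-sign (FPs) and
non-existent (FPn) connections:

    SE = TP/(TP+FN+FPs)   SP = TN/(TN+FPn)
    PR = TP/(TP+FPn+FPs)  FM = 2*PR*SE/(PR+SE)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .config import InferenceConfig
from .dataset import Dataset, ExperimentData, standardise
from .model import GRNModel, simulate
from .prior import PriorKnowledge, encode_edge
from .search import InferenceResult, infer

__all__ = [
    "BenchmarkSystem",
    "StructureEvaluation",
    "EdgeFrequencyTable",
    "generate_benchmark",
    "generate_data",
    "evaluate_structure",
    "evaluation_from_counts",
    "sweep_allowed_error",
    "resample_validate",
    "DEFAULT_TIMES",
    "DEFAULT_SWEEP",
]

#: six sampling times with exponentially increasing intervals
DEFAULT_TIMES = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0)

#: the canonical allowedError sweep 0.001, 0.002, ..., 0.01
DEFAULT_SWEEP = tuple(round(0.001 * k, 3) for k in range(1, 11))

_DEFAULT_GENES = {"FCT": 5, "LCT": 4, "NCT": 7}


@dataclass
class BenchmarkSystem:
    """Ground-truth model plus generation metadata."""

    truth: GRNModel
    kind: str
    seed: int


@dataclass
class StructureEvaluation:
    """Edge-confusion counts and derived measures."""

    TP: int
    TN: int
    FPn: int
    FPs: int
    FN: int
    SE: float = field(init=False)
    SP: float = field(init=False)
    PR: float = field(init=False)
    FM: float = field(init=False)

    def __post_init__(self):
        self.SE = _ratio(self.TP, self.TP + self.FN + self.FPs)
        self.SP = _ratio(self.TN, self.TN + self.FPn)
        self.PR = _ratio(self.TP, self.TP + self.FPn + self.FPs)
        self.FM = (2 * self.PR * self.SE / (self.PR + self.SE)
                   if (self.PR + self.SE) > 0 else 0.0)

    @property
    def n_positions(self) -> int:
        return self.TP + self.TN + self.FPn + self.FPs + self.FN

    def as_dict(self) -> dict:
        return {k: getattr(self, k)
                for k in ("TP", "TN", "FPn", "FPs", "FN", "SE", "SP", "PR", "FM")}


def _ratio(num, den) -> float:
    return float(num) / float(den) if den else 0.0


def evaluation_from_counts(TP, TN, FPn, FPs, FN) -> StructureEvaluation:
    """Derived measures straight from given confusion counts."""
    return StructureEvaluation(TP, TN, FPn, FPs, FN)


@dataclass
class EdgeFrequencyTable:
    """Relative frequency of each nominal-model connection over resampling."""

    table: pd.DataFrame      # columns: source, target, kind, code, frequency
    n_runs: int


# --------------------------------------------------------------------------
# benchmark generation
# --------------------------------------------------------------------------

def _topology(kind: str, n: int, m: int):
    """Fixed adjacency per kind: sets of (target, source) for A and B.

    Cross-talk targets are placed at leaf positions and fan-out is preferred
    over deep chains; together with the depth-graded time constants (slow
    roots, faster downstream genes) this keeps the systems identifiable from
    step-response data: a fast upstream gene saturates like the stimulus
    step itself, making its outgoing connections indistinguishable from
    direct stimulus effects.
    """
    a_edges, b_edges = set(), set()
    if kind == "NCT":
        if n < m:
            raise ValueError("NCT needs at least one gene per input")
        sizes = [n // m + (1 if g < n % m else 0) for g in range(m)]
        start = 0
        for g, size in enumerate(sizes):
            genes = list(range(start, start + size))
            start += size
            b_edges.add((genes[0], g))
            # root fans out; one second-level edge when the group is large
            for child in genes[1:3]:
                a_edges.add((child, genes[0]))
            for child in genes[3:]:
                a_edges.add((child, genes[1]))
    elif kind == "LCT":
        # roots 0..m-1 driven by one stimulus each; gene m a single-lineage
        # leaf; the remaining genes are downstream cross-talk leaves that
        # combine one gene lineage with one further direct stimulus.
        if n < m + 2:
            raise ValueError("LCT needs at least m + 2 genes")
        for i in range(m):
            b_edges.add((i, i))
        a_edges.add((m, 0))
        for g in range(m + 1, n):
            a_edges.add((g, 0))
            b_edges.add((g, 1 + (g - m - 1) % max(1, m - 1)))
    elif kind == "FCT":
        # every root sees every stimulus; downstream genes inherit full
        # cross-talk from their root lineage
        if n < m + 1:
            raise ValueError("FCT needs at least m + 1 genes")
        roots = list(range(m))
        for i in roots:
            for j in range(m):
                b_edges.add((i, j))
        for g in range(m, n):
            a_edges.add((g, roots[g % m]))
    else:
        raise ValueError(f"unknown benchmark kind {kind!r}")
    return a_edges, b_edges


def _depths(n: int, a_edges, b_edges):
    """Shortest stimulus-to-gene distance through the interaction graph."""
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    src = "stimulus"
    for (i, _m) in b_edges:
        g.add_edge(src, i)
    for (i, j) in a_edges:
        g.add_edge(j, i)
    lengths = nx.single_source_shortest_path_length(g, src)
    return [lengths.get(i, 1) - 1 for i in range(n)]


def _reachable_from_input(A, B, m):
    """Genes reachable from input ``m`` through the interaction graph."""
    n = A.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(n + 1))
    src = n  # virtual input node
    for i in range(n):
        if B[i, m] != 0:
            g.add_edge(src, i)
        for j in range(n):
            if i != j and A[i, j] != 0:
                g.add_edge(j, i)
    return set(nx.descendants(g, src))


def generate_benchmark(kind: str, n_genes: int | None = None,
                       n_inputs: int = 2, seed: int = 0) -> BenchmarkSystem:
    """Seeded stable sparse LTI benchmark with the kind's cross-talk pattern.

    The adjacency is fixed per kind; coefficients are random but drawn away
    from zero (off-diagonal magnitudes in [0.3, 1.5], diagonals within
    [-2, -0.2]).  Diagonal time constants are graded by network depth (genes
    further from the stimuli respond more slowly) and jittered to stay
    distinct; without this grading a downstream gene can collapse into a
    quasi-static follower of its parent, which is unidentifiable from
    step-response data.
    """
    kind = kind.upper()
    if n_genes is None:
        n_genes = _DEFAULT_GENES.get(kind)
        if n_genes is None:
            raise ValueError(f"unknown benchmark kind {kind!r}")
    rng = np.random.default_rng(seed)
    a_edges, b_edges = _topology(kind, n_genes, n_inputs)
    A = np.zeros((n_genes, n_genes))
    B = np.zeros((n_genes, n_inputs))
    depths = _depths(n_genes, a_edges, b_edges)
    diag = np.array([
        -np.clip(0.25 * 2.2 ** d * rng.uniform(0.85, 1.18), 0.2, 2.0)
        for d in depths
    ])
    A[np.diag_indices(n_genes)] = diag
    for (i, j) in sorted(a_edges):
        sign = -1.0 if rng.random() < 0.25 else 1.0
        A[i, j] = sign * rng.uniform(0.3, 1.5)
    for (i, m) in sorted(b_edges):
        B[i, m] = rng.uniform(0.3, 1.5)

    reach = [_reachable_from_input(A, B, m) for m in range(n_inputs)]
    all_genes = set(range(n_genes))
    if kind == "FCT":
        assert all(r == all_genes for r in reach)
    elif kind == "NCT":
        assert all(not (reach[i] & reach[j])
                   for i in range(n_inputs) for j in range(i + 1, n_inputs))
    else:
        multi = set.intersection(*reach) if reach else set()
        assert multi and multi != all_genes

    truth = GRNModel(
        A=A, B=B,
        gene_names=[f"G{i + 1}" for i in range(n_genes)],
        input_names=[f"Input{m + 1}" for m in range(n_inputs)],
        orders=[1] * n_genes,
        meta={"kind": kind, "seed": int(seed)},
    )
    return BenchmarkSystem(truth, kind, int(seed))


def scenario_experiments(n_inputs: int, scenario: str) -> list[int]:
    """Input index applied in each experiment of a scenario.

    ``S1``/``S2``/... apply a single stimulus; ``M`` integrates one
    experiment per stimulus.
    """
    scenario = scenario.upper()
    if scenario == "M":
        return list(range(n_inputs))
    if scenario.startswith("S"):
        k = int(scenario[1:]) - 1
        if not 0 <= k < n_inputs:
            raise ValueError(f"scenario {scenario!r} exceeds {n_inputs} inputs")
        return [k]
    raise ValueError(f"unknown scenario {scenario!r}")


def generate_data(system: BenchmarkSystem, scenario: str = "M",
                  noise_sd: float = 0.05, seed: int = 0,
                  times=DEFAULT_TIMES) -> Dataset:
    """Simulate the truth per scenario, add noise, standardise.

    Noise streams are keyed by (seed, applied input), so the single-stimulus
    experiments of scenario ``M`` carry exactly the noise realisations of the
    corresponding ``S`` scenarios.
    """
    truth = system.truth
    times = np.asarray(times, dtype=float)
    experiments = []
    for input_idx in scenario_experiments(truth.n_inputs, scenario):
        u = np.zeros(truth.n_inputs)
        u[input_idx] = 1.0
        traj = simulate(truth, u, times)
        if noise_sd > 0:
            rng = np.random.default_rng([int(seed), int(input_idx)])
            traj = traj + rng.normal(0.0, noise_sd, traj.shape)
        U = np.tile(u, (len(times), 1))
        experiments.append(ExperimentData(
            times, traj, U, list(truth.gene_names), list(truth.input_names),
            name=f"{scenario}-{truth.input_names[input_idx]}",
        ))
    return standardise(Dataset(experiments))


# --------------------------------------------------------------------------
# structure evaluation
# --------------------------------------------------------------------------

def _gene_codes(model: GRNModel, gene_order: list[str], input_order: list[str],
                tol: float = 1e-6):
    """Gene-level sign codes of A and B in the given name orders."""
    n, m = len(gene_order), len(input_order)
    a_codes = np.zeros((n, n), dtype=int)
    b_codes = np.zeros((n, m), dtype=int)
    for i, tgt in enumerate(gene_order):
        for j, src in enumerate(gene_order):
            a_codes[i, j] = encode_edge(model.edge_coefficient(src, tgt), tol)
        for k, src in enumerate(input_order):
            b_codes[i, k] = encode_edge(model.edge_coefficient(src, tgt), tol)
    return a_codes, b_codes


def evaluate_structure(inferred: GRNModel, truth: GRNModel,
                       tol: float = 1e-6) -> StructureEvaluation:
    """Classify every candidate position of A and B against the truth.

    TP: present in both with matching sign; FPs: present in both with wrong
    sign; FPn: inferred only; FN: truth only; TN: absent in both.  The counts
    partition all N^2 + M*N positions.
    """
    if (sorted(inferred.gene_names) != sorted(truth.gene_names)
            or sorted(inferred.input_names) != sorted(truth.input_names)):
        raise ValueError("inferred and truth models must share gene/input sets")
    genes, inputs = list(truth.gene_names), list(truth.input_names)
    mi = _gene_codes(inferred, genes, inputs, tol)
    mt = _gene_codes(truth, genes, inputs, tol)
    counts = dict(TP=0, TN=0, FPn=0, FPs=0, FN=0)
    for infc, truc in zip(mi, mt):
        for c_inf, c_tru in zip(infc.ravel(), truc.ravel()):
            if c_tru == 0 and c_inf == 0:
                counts["TN"] += 1
            elif c_tru == 0:
                counts["FPn"] += 1
            elif c_inf == 0:
                counts["FN"] += 1
            elif c_inf == c_tru:
                counts["TP"] += 1
            else:
                counts["FPs"] += 1
    return StructureEvaluation(**counts)


# --------------------------------------------------------------------------
# sweeps and resampling
# --------------------------------------------------------------------------

def sweep_allowed_error(system: BenchmarkSystem,
                        scenarios=("M", "S1", "S2"),
                        values=DEFAULT_SWEEP,
                        noise_sd: float = 0.05, seed: int = 0,
                        config: InferenceConfig | None = None,
                        prior: PriorKnowledge | None = None) -> pd.DataFrame:
    """Infer one model per (scenario, allowedError) and tabulate the scores."""
    config = config or InferenceConfig()
    rows = []
    for scenario in scenarios:
        data = generate_data(system, scenario, noise_sd, seed)
        for value in values:
            cfg = config.replace(allowed_error=float(value), seed=int(seed))
            result = infer(data, prior, cfg)
            ev = evaluate_structure(result.model, system.truth)
            rows.append({"scenario": scenario, "allowed_error": float(value),
                         "J": result.J, **ev.as_dict()})
    return pd.DataFrame(rows)


def _present_edges(model: GRNModel, include_self: bool = False,
                   tol: float = 1e-6):
    """(kind, source, target) -> sign code of the present connections."""
    edges = {}
    for i, tgt in enumerate(model.gene_names):
        for src in model.input_names:
            code = encode_edge(model.edge_coefficient(src, tgt), tol)
            if code:
                edges[("input", src, tgt)] = code
        for src in model.gene_names:
            if src == tgt and not include_self:
                continue
            code = encode_edge(model.edge_coefficient(src, tgt), tol)
            if code:
                edges[("gene", src, tgt)] = code
    return edges


def resample_validate(data: Dataset, prior: PriorKnowledge | None = None,
                      config: InferenceConfig | None = None,
                      n_runs: int = 100, noise_sd: float = 0.05,
                      seed: int = 0,
                      nominal: InferenceResult | None = None) -> EdgeFrequencyTable:
    """Perturb-and-infer validation of an inferred (nominal) model.

    Gaussian noise N(0, noise_sd^2) is added to the standardised time series,
    the data are re-standardised and inference repeated; each nominal
    connection's relative frequency is the fraction of runs containing it
    with matching sign.  Self-loops (always present) are not tabulated.
    """
    config = config or InferenceConfig()
    base = standardise(data)
    if nominal is None:
        nominal = infer(base, prior, config)
    edges = _present_edges(nominal.model)
    hits = {edge: 0 for edge in edges}
    for run in range(n_runs):
        if noise_sd > 0:
            rng = np.random.default_rng([int(seed), run])
            perturbed = Dataset([
                replace(e, Y=e.Y + rng.normal(0.0, noise_sd, e.Y.shape))
                for e in base.experiments
            ])
            perturbed = standardise(perturbed)
        else:
            perturbed = base
        result = infer(perturbed, prior, config)
        found = _present_edges(result.model)
        for edge, code in edges.items():
            if found.get(edge) == code:
                hits[edge] += 1
    table = pd.DataFrame(
        [{"kind": k, "source": s, "target": t, "code": c,
          "frequency": hits[(k, s, t)] / n_runs if n_runs else np.nan}
         for (k, s, t), c in sorted(edges.items())]
    )
    return EdgeFrequencyTable(table, n_runs)
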