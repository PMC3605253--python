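"""Graph and trajectory export.

DOT output follows the colour convention: black inferred connection without
knowledge, green agreement with prior knowledge, red contradiction, blue
agreement backed by a predicted binding site, grey dashed prior knowledge
not reproduced.  Optional resampling frequencies drive edge width and a
percentage label.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import GRNModel, simulate
from .prior import PriorKnowledge, classify_edges

__all__ = ["export_dot", "export_timecourses", "read_timecourses", "write_report"]


def _q(name: str) -> str:
    return '"' + str(name).replace('"', r'\"') + '"'


def export_dot(model: GRNModel, prior: PriorKnowledge | None = None,
               frequencies=None) -> str:
    """Render the network as DOT text (Graphviz-compatible)."""
    freq = {}
    if frequencies is not None:
        table = getattr(frequencies, "table", frequencies)
        for _, row in table.iterrows():
            freq[(row["source"], row["target"])] = float(row["frequency"])
    lines = ["digraph grn {", "  rankdir=LR;"]
    for name in model.input_names:
        lines.append(f"  {_q(name)} [shape=box];")
    for name in model.gene_names:
        lines.append(f"  {_q(name)} [shape=ellipse];")
    for rec in classify_edges(model, prior):
        if rec["source"] == rec["target"]:
            continue  # self-regulation models degradation; not drawn
        attrs = [f'color={rec["colour"]}']
        if rec["style"] != "solid":
            attrs.append(f'style={rec["style"]}')
        if rec["code"] == -10:
            attrs.append("arrowhead=tee")
        f = freq.get((rec["source"], rec["target"]))
        if f is not None:
            attrs.append(f'label="{round(100 * f)}%"')
            attrs.append(f"penwidth={0.5 + 2.5 * f:.2f}")
        lines.append(
            f'  {_q(rec["source"])} -> {_q(rec["target"])} [{", ".join(attrs)}];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_timecourses(model: GRNModel, dataset, path=None) -> pd.DataFrame:
    """Measured, interpolated and simulated values per gene and experiment.

    One block per experiment: data rows (kind measured/interpolated) followed
    by the model's coupled simulation sampled on the same grid.
    """
    frames = []
    for e_idx, e in enumerate(dataset.experiments, 1):
        kinds = np.where(e.measured, "measured", "interpolated")
        data = pd.DataFrame(e.Y, columns=dataset.gene_names)
        data.insert(0, "kind", kinds)
        data.insert(0, "time", e.times)
        data.insert(0, "experiment", e_idx)
        sim = simulate(model, e.U, e.times)
        # model gene order may differ from the dataset's
        cols = {name: sim[:, model.gene_names.index(name)]
                for name in dataset.gene_names}
        simdf = pd.DataFrame(cols)
        simdf.insert(0, "kind", "simulated")
        simdf.insert(0, "time", e.times)
        simdf.insert(0, "experiment", e_idx)
        frames.append(pd.concat([data, simdf], ignore_index=True))
    out = pd.concat(frames, ignore_index=True)
    if path is not None:
        out.to_csv(path, index=False)
    return out


def read_timecourses(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(report: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(report, indent=1, default=default))
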