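"""File-based workflow: CSV time series in, model + DOT + trajectories out.

Writes a small two-experiment dataset to wide CSV files (genes x time
points), reads it back, infers a model and exports every artefact the
command-line interface would produce.  The same steps are available from a
shell as `grnode infer --data ... --inputs ... --out-dir ...`.
"""

import tempfile
from pathlib import Path

from grnode import (
    Dataset,
    GRNModel,
    InferenceConfig,
    export_dot,
    export_timecourses,
    generate_benchmark,
    generate_data,
    infer,
)

workdir = Path(tempfile.mkdtemp(prefix="grnode_example_"))

# stand-in for real measurements: noisy benchmark data written as CSV
system = generate_benchmark("LCT", seed=5)
generate_data(system, scenario="M", noise_sd=0.05, seed=5).to_files(workdir)
print("input files:", *sorted(p.name for p in workdir.iterdir()), sep="\n  ")

data = Dataset.from_files(
    [workdir / "experiment1_expression.csv", workdir / "experiment2_expression.csv"],
    [workdir / "experiment1_stimuli.csv", workdir / "experiment2_stimuli.csv"],
)
result = infer(data, config=InferenceConfig(allowed_error=0.001))

result.model.save(workdir / "model.json")
(workdir / "network.dot").write_text(export_dot(result.model))
export_timecourses(result.model, result.dataset, workdir / "timecourses.csv")

reloaded = GRNModel.load(workdir / "model.json")
print(f"\ninferred {reloaded.n_genes} sub-models, orders {reloaded.orders}, "
      f"J = {result.J:.2g}")
print(f"outputs in {workdir}: model.json (state-space matrices), "
      "network.dot (render with Graphviz), timecourses.csv "
      "(measured/interpolated/simulated per gene and experiment)")
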