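import numpy as np
import pytest

from grnode import Dataset, ExperimentData, GRNModel, simulate

TIMES6 = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 16.0])


def single_gene_dataset(a=-1.0, b=1.0, times=TIMES6, noise_sd=0.0, seed=0):
    """Noise-free (or noisy) data generated from dx = a x + b u, unit step."""
    model = GRNModel(A=[[a]], B=[[b]], gene_names=["G1"], input_names=["u1"])
    traj = simulate(model, [1.0], times)
    if noise_sd:
        rng = np.random.default_rng(seed)
        traj = traj + rng.normal(0, noise_sd, traj.shape)
    exp = ExperimentData(times, traj, np.ones((len(times), 1)),
                         ["G1"], ["u1"])
    return Dataset([exp]), model


def random_stable_model(rng, n_states, n_inputs=1):
    A = rng.uniform(-0.5, 0.5, (n_states, n_states))
    A[np.diag_indices(n_states)] = rng.uniform(-2.0, -0.5, n_states)
    B = rng.uniform(-1.0, 1.0, (n_states, n_inputs))
    return GRNModel(A=A, B=B,
                    gene_names=[f"G{i+1}" for i in range(n_states)],
                    input_names=[f"u{m+1}" for m in range(n_inputs)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
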