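"""Quantify the benefit of integrating multiple stimulation experiments.

On a full-cross-talk system (every gene responds to both stimuli) the same
noisy data are modelled three ways: from each single-stimulus experiment
alone (S1, S2) and jointly from both (M), sweeping the allowedError setting
over 0.001..0.01.  The mean F-measure shows that joint inference recovers
the structure better than either experiment alone.
"""

from grnode import generate_benchmark, sweep_allowed_error

system = generate_benchmark("FCT", seed=1)
table = sweep_allowed_error(system, scenarios=("M", "S1", "S2"),
                            noise_sd=0.05, seed=1)

summary = table.groupby("scenario")[["SE", "SP", "FM", "J"]].mean()
print(summary.round(3))
print()
print("Each row averages 10 models (allowedError = 0.001 .. 0.01).")
print("The integrated scenario M dominates in F-measure because the second "
      "stimulus disentangles input attributions that a single experiment "
      "cannot resolve.")
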