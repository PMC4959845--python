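"""The u-shaped relationship between membrane noise and coding error.

Too little noise lets delayed inhibition synchronize the whole population
(large rhythmic reconstruction errors); too much noise decouples the
neurons (Poisson-like errors).  At an intermediate level — with the L2
spike costs re-calibrated at each noise level so the estimation bias stays
zero — the error is minimal and excitation/inhibition balance is tightest.
Runs a coarse three-point sweep (a couple of minutes).
"""

import gammanet as gn

spec = gn.SweepSpec(
    "noise_sweep", grid=[2.0, 17.0, 60.0], seeds=[1, 2], duration=6.0, calibrate=True
)
table = gn.run_sweep(spec, gn.EINetworkConfig())
summary = table.groupby("value")[["error", "ei_mismatch", "poisson_error", "cv", "rate_e"]].mean()

print(summary.round(3))
print(
    "\nThe middle noise level minimizes both the reconstruction error and the\n"
    "E/I mismatch, and beats the rate-matched Poisson baseline; firing rates\n"
    "stay constant across the sweep because the costs are re-calibrated."
)
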