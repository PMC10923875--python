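"""Simulate coupled FitzHugh-Nagumo activity and convert it to BOLD.

A 20-node modular network is driven by the 60 s square-wave task input on
6 mid-strength nodes; the fast activator dynamics (milliseconds-to-seconds
scale oscillations) are z-scored and passed through the Balloon-Windkessel
model, producing slow BOLD-like signals sampled every TR = 2 s.
"""

import numpy as np

import brainflex as bf

G = bf.generate_synthetic_connectome(20, 2, seed=3)
targets = bf.select_nodes(G, "mid", count=6)
protocol = bf.StimulusProtocol(amplitude_c=3.0, period_T=60.0, targets=targets)

u0, w0 = bf.random_initial_conditions(20, seed=0)
traj = bf.integrate(G, bf.FHNParams(), protocol, duration=128.0, dt=0.01, u0=u0, w0=w0)
print(f"neural trajectory: {traj.u.shape[1]} steps, u in [{traj.u.min():.2f}, {traj.u.max():.2f}]")

bold = bf.transform(traj, bf.BalloonParams(), TR=2.0)
print(f"BOLD series: {bold.n_vol} volumes at TR={bold.TR:.0f} s")
print("first target node, volumes 0..9:", np.round(bold.y[targets.zero_based()[0], :10], 4))
# The BOLD values are fractional signal changes around 0 (the hemodynamic
# resting point); they vary on a time scale of seconds even though the
# underlying oscillators are much faster.
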