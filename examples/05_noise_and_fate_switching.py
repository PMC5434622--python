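"""Stochastic dynamics: multiplicative noise can switch fates.

Simulates the two-seeding protocol with state-proportional noise
(Euler-Maruyama, a single shared Wiener process).  At an intermediate
second-seeding stiffness where myogenic and osteogenic attractors coexist,
noise occasionally kicks a cell from one program to the other.
"""

from mscfate import (DosingSchedule, SDEConfig, detect_fate_switch,
                     simulate_sde)

schedule = DosingSchedule(first_S_kpa=12.0, first_duration=20.0,
                          second_S_kpa=12.0, total_time=200.0)
config = SDEConfig(seed=0, n_replicates=8)   # eta defaults to sqrt(0.05)

ensemble = simulate_sde(schedule, config=config)
print(f"{config.n_replicates} replicates, eta = {config.eta:.4f}, "
      f"dt = {config.dt}, clipped fraction = {ensemble.clip_fraction:.2e}\n")

def marker_path(report):
    """Episode sequence with consecutive repeats collapsed."""
    path = []
    for episode in report["episodes"]:
        if not path or path[-1] != episode.marker:
            path.append(episode.marker)
    return " -> ".join(path) or "(none)"


for i in range(config.n_replicates):
    report = detect_fate_switch(ensemble.replicate(i))
    print(f"replicate {i}: {report['n_switches']:2d} switches   "
          f"{marker_path(report)}")

# The zero-noise limit recovers the deterministic trajectory: a transient
# passage through the soft-substrate programs, then a single settled fate.
quiet = simulate_sde(schedule, config=SDEConfig(eta=0.0, seed=0))
report = detect_fate_switch(quiet.replicate(0))
print(f"\neta = 0: {report['n_switches']} switches, path "
      f"{marker_path(report)}")
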