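"""Ionic currents and conductance from a drift-diffusion ion trajectory.

Simulates Na+ and Cl- ions in a periodic box under a 200-mV bias with
drift velocities tuned so the analytic mean currents match the per-species
means of the fully pore-lining channel (Na+ 13.6 pA, Cl- 1.2 pA; Cl-
drifting against z carries positive current), then recovers them with the
displacement-sum estimator and 4-block standard errors.
"""

from oligoring import synthgen as sg
from oligoring.iontransport import conductance, ionic_current, local_concentration
from oligoring.units import E_PER_PS_TO_PA

LZ = 26.0
target = {"NA": (300, 1.0, 13.6), "CL": (360, -1.0, 1.2)}
spec = {name: (n, q, i_pa * LZ / (n * q * E_PER_PS_TO_PA))
        for name, (n, q, i_pa) in target.items()}

# 20,001 frames -> 20,000 displacement samples, an exact multiple of 4 blocks
traj = sg.simulate_ion_trajectory(spec, box=(14.0, 14.0, LZ), frames=20_001,
                                  diffusion=1e-7, voltage=200.0, seed=7)
est = ionic_current(traj)
for name, (mean, se) in est.per_species.items():
    print(f"{name:3s} current: {mean:6.2f} +/- {se:.2f} pA "
          f"(analytic {traj.metadata['analytic_current_pa'][name]:.2f} pA)")
print(f"total current: {est.total:.2f} pA at {traj.voltage:.0f} mV")
print(f"conductance:   {est.conductance:.1f} pS")

cmap = local_concentration(traj, bins=13)
print("mean Na+ molarity per 2-nm slab:",
      [round(float(c), 3) for c in cmap.concentration["NA"]][:5], "...")
print("-> the estimator reproduces the tuned per-species currents, and their"
      "\n   sum over the 200-mV bias gives the channel conductance in pS.")
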