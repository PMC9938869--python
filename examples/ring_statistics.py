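"""Subunit-state statistics on a synthetic hexamer-ring dataset.

Simulates a channel population whose 12 protomers independently adopt one
of three N-terminal-helix conformations at the equilibrium fractions
observed for Cx43 in phospholipid nanodiscs (GCN 37.3%, FIN 22%, PLN
40.7%), then asks the analysis to prove the independence back to us:
composition histograms against Binomial predictions, arrangement classes
against pure ring combinatorics, and a nearest-neighbour coupling fit
whose J should be indistinguishable from zero.
"""

import numpy as np
from scipy import stats

from oligoring import ringstats as rs
from oligoring import synthgen as sg

t = sg.simulate_state_table(n_particles=20_000, seed=42)
fractions = rs.state_fractions(t)
print("state fractions:", {k: round(v, 4) for k, v in fractions.items()})

hist = rs.composition_histogram(t, "PLN", level="channel")
print(f"PLN-per-channel histogram mode: {hist.mode} (Binomial(12, 0.407) mode: "
      f"{int(np.argmax(stats.binom.pmf(np.arange(13), 12, 0.407)))})")

print("\narrangement classes for k = 2 PLN protomers per hemichannel")
obs = rs.observed_arrangements(t, "PLN", k=2)
for cls in rs.enumerate_arrangements(2):
    total = sum(obs.values())
    print(f"  pattern {cls}: predicted {cls.conditional_probability:.3f}, "
          f"observed {obs[cls.pattern] / total:.3f}  (multiplicity {cls.multiplicity})")
counts = [obs[c.pattern] for c in rs.enumerate_arrangements(2)]
probs = [c.conditional_probability for c in rs.enumerate_arrangements(2)]
gof = rs.gof_test(counts, probs)
print(f"  goodness of fit: chi2 = {gof.statistic:.2f}, p = {gof.p_value:.3f}")

fit = rs.fit_ring_model(t, "PLN")
print(f"\nring coupling fit: J = {fit.J:.4f}, 95% CI [{fit.J_ci[0]:.4f}, {fit.J_ci[1]:.4f}]")
print(f"likelihood-ratio test of independence (J = 0): p = {fit.lrt_p_value:.3f}")
print("-> the CI straddles 0 and the LRT is non-significant: protomer states"
      "\n   on these rings behave independently, as generated.")
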