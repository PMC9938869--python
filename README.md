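# oligoring

Statistics and biophysics of ring-oligomeric membrane channels whose
subunits switch between conformations — the situation revealed by cryo-EM
for connexin-43 gap-junction channels, where each of the twelve protomers of
a dodecameric channel (two stacked hexameric hemichannels) independently
adopts a gate-covering (GCN), flexible-intermediate (FIN), or pore-lining
(PLN) N-terminal-helix conformation.

The package is a library with three pillars:

* **`ringstats`** — are per-protomer states independent on the 6-ring?
  Composition histograms against Binomial(n, p) predictions; arrangement
  classes of occupied ring positions under rotational symmetry, whose
  conditional probabilities given k occupied sites are pure combinatorics
  (multiplicity / C(6, k)); Pearson and exact-multinomial goodness of fit;
  and a nearest-neighbour Ising model
  P(x) ∝ exp(h Σxᵢ + J Σxᵢxᵢ₊₁) fit by exact enumeration of the 64 ring
  configurations, with profile-likelihood CIs and a likelihood-ratio test of
  independence (J = 0).
* **`structmodel` + `porepath`** — Kabsch superposition and mean-Cα-deviation
  comparison of conformations; assembly of hybrid hemichannels from two
  template conformations by anchor-region superposition with clash checking;
  and a HOLE-style pore profiler (per-slice maximal inscribed sphere,
  r(p) = minᵢ(‖p − xᵢ‖ − vdwᵢ)) reporting the constriction diameter 2·min r.
* **`iontransport`** — ionic currents from ion trajectories via the
  displacement-sum estimator I = (1/Lz) Σᵢ qᵢ⟨Δzᵢ/Δt⟩ with block-average
  standard errors (default 4 blocks), conductance G = I/V in pS,
  position-dependent molar concentration maps, and trajectory RMSD/RMSF.

`synthgen` generates every input with known ground truth (state tables with
controllable coupling, toy channels with closed-form pore profiles,
drift-diffusion trajectories with analytic currents), and a thin `oligoring`
CLI wraps the common pipelines. See `docs/methods.md` for the models and
conventions, and `examples/` for narrative walk-throughs.

## Worked example

```sh
python examples/ion_currents.py
```

```
NA  current:  13.48 +/- 0.12 pA (analytic 13.60 pA)
CL  current:   1.34 +/- 0.08 pA (analytic 1.20 pA)
total current: 14.82 pA at 200 mV
conductance:   74.1 pS
```

A 20,000-step drift-diffusion trajectory of 300 Na⁺ and 360 Cl⁻ ions in a
14 × 14 × 26 nm periodic box is tuned so the analytic mean currents match the
per-species means of the fully pore-lining channel; the displacement-sum
estimator recovers them within its 4-block standard errors, and their sum
over the 200-mV bias gives the 74-pS conductance.

```sh
python examples/ring_statistics.py
```

```
state fractions: {'GCN': 0.3724, 'FIN': 0.2197, 'PLN': 0.4079}
PLN-per-channel histogram mode: 5 (Binomial(12, 0.407) mode: 5)
...
ring coupling fit: J = 0.0013, 95% CI [-0.0153, 0.0179]
likelihood-ratio test of independence (J = 0): p = 0.878
```

20,000 synthetic channels at the three-state equilibrium fractions
(37.3 / 22 / 40.7%) show the expected peak at five PLN protomers per channel,
arrangement-class frequencies matching the combinatorial prediction
(0.4 / 0.4 / 0.2 at k = 2), and a coupling estimate indistinguishable from
zero — the analyses recover the independence they were generated under.

`examples/hybrid_pore_profile.py` assembles a 3:3 hybrid hemichannel from
open and closed toy templates, verifies zero inter-chain clashes, and shows
the constriction widening monotonically from the all-closed to the all-open
ring.

## Command line

```sh
oligoring synth states --seed 17 --n-particles 20000 --out states.tsv
oligoring ringstats --table states.tsv --focal PLN --out report.json
oligoring pore --structure channel.cif --axis principal --step 0.25 --out pore.json
oligoring hybrid --gcn gcn.cif --pln pln.cif --pattern PPPGGG --out hybrid.cif
oligoring ioncurrent --traj traj.tsv --out current.json
```

Reports are JSON with embedded provenance (package version, config hash,
seed); the same config and seed give byte-identical numeric content.

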