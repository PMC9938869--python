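# Methods

`oligoring` analyzes the conformational statistics and transport properties of
ring-oligomeric membrane channels, with connexin gap-junction channels as the
motivating system: a gap-junction intercellular channel (GJICh) is a dodecamer
of two docked hexameric hemichannels, and symmetry-expanded single-particle
classification can assign each of the twelve protomers its own N-terminal-helix
(NTH) conformation — gate-covering (GCN), flexible intermediate (FIN), or
pore-lining (PLN). The package answers three families of questions about such
data: do the per-protomer states behave independently on the ring; what pore
geometry do mixed-conformation assemblies have; and what ionic currents and
conductances do trajectories through them carry.

## Ring-state statistics (`ringstats`)

**Data model.** One row per protomer observation: particle ID, hemichannel
index (0/1), ring position (0–5, counted counter-clockwise viewed from the
extracellular side, position 0 = chain A), and a state label. Each
(particle, hemichannel) pair carries exactly six rows; hemichannel-level
statistics therefore count twice as many assemblies as channel-level ones.
Tables read from TSV or from RELION-flavoured STAR particle loops, where ring
position and hemichannel are recovered from the symmetry-expansion Euler
angles (position = rot/60° mod 6, hemichannel from tilt ≶ 90°). Any consistent
angle convention yields identical ring statistics, because every analysis here
is invariant under ring rotation.

**Independence predictions.** Under independence with per-site probability
*p*, the number of focal-state protomers per hemichannel (n = 6) or channel
(n = 12) is Binomial(n, p); `expected_composition` returns total × pmf.
Conditional on *k* occupied sites, the arrangement of those sites on the
6-ring falls into equivalence classes under rotation (C6; reflection
optionally merged under D6), enumerated by brute force over all C(6, k)
placements. A class's conditional probability is multiplicity / C(6, k) —
pure combinatorics, independent of *p*. Rotation-only equivalence is the
default so mirror-image arrangements stay distinct; the D6 option merges them.
Goodness of fit uses Pearson chi-square (df = categories − 1) or an exact
multinomial tail (full enumeration up to total 20, seeded Monte Carlo above),
with a Bonferroni helper for the small number of pre-specified k-groups.

**Cooperativity model.** Whether neighbouring protomers influence each
other's conformation is posed as a nearest-neighbour Ising model on the
6-ring: P(x) ∝ exp(h Σ xᵢ + J Σ xᵢ x₍ᵢ₊₁ mod 6₎) over binary occupancy
(focal state vs. rest). The 64 configurations are enumerated exactly, so the
likelihood, its gradient, and the partition function are closed-form sums; the
MLE is found by BFGS, 95% intervals by profile likelihood (Δ deviance =
3.84), and independence is tested by a likelihood ratio against J = 0, whose
null MLE is h = logit(mean occupancy). J > 0 means neighbouring protomers
reinforce each other's focal conformation; at matched marginal it strictly
enriches fully occupied rings over the Binomial prediction. Multi-state
tables are binarized for this fit; a full 3-state Potts variant (729
configurations, still exactly enumerable) is a straightforward extension we
have not implemented. Coupling between the two stacked hexamer rings of a
channel is deliberately out of scope.

**Classification noise.** Focused classification can leak density between
conformations, so an optional row-stochastic confusion matrix can be applied
to synthetic tables and inverted on observed marginals (solve Cᵀp = q, clip,
renormalize). It is off by default.

## Structures and hybrid assembly (`structmodel`)

Structures are flat atom tables (gemmi-backed PDB/mmCIF I/O, author chain IDs
and residue numbering preserved; hydrogens dropped; highest-occupancy altloc
kept). Superposition is the closed-form Kabsch SVD solution with the proper-
rotation sign fix; atoms pair by (residue number, atom name), adding chain ID
when both selections are multi-chain. The "mean Cα deviation" between two
conformations is the arithmetic mean of per-residue Cα distances after the
optimal fit (the RMS is reported alongside, since the two statistics differ
and published values rarely say which was used). Cross-protein comparisons
(e.g. Cx43 vs. Cx46) pair residues through a global sequence alignment
(Biopython PairwiseAligner, BLOSUM62, gap open −10/extend −0.5) and use only
matched, ungapped pairs, because author numbering differs between proteins.

Hybrid hemichannels are assembled by placing, at each ring position of a
six-chain reference frame, the donor protomer named by a length-6
pattern over {GCN, PLN}, superposed on *anchor* residues only. The default
anchor is the structurally conserved extracellular region — both
extracellular loops plus the extracellular halves of TM1–TM4 (residue ranges
37–45, 46–75, 76–84, 160–170, 171–208, 209–219 in Cx43 author numbering) — a
package choice shipped as an overridable range set, since only the region
("ECLs and the extracellular halves of the TMDs") and not exact bounds is
conventionally fixed. Donor chains are copied rigidly (internal geometry
bit-preserved), relabeled A–F, and the per-position anchor RMSD is logged;
an anchor RMSD above 2.0 Å (configurable) aborts the assembly as a template
mismatch. Steric checking counts inter-chain heavy-atom pairs below a
2.2 Å centre-distance cutoff via a KD-tree (an all-pairs oracle backs it in
the tests).

## Pore profiling (`porepath`)

A HOLE-style profiler: at each axial slice z the point p in the slice plane
maximizing r(p) = minᵢ(‖p − xᵢ‖ − vdwᵢ) is found by multi-start Nelder–Mead
(default 8 seeded restarts around the previous slice's centre and around the
axis; ties broken by larger radius, then smaller in-plane norm). Because the
objective grows without bound outside the channel wall, the search is
confined to the radial extent of the nearby atoms. The constriction diameter
is twice the minimum slice radius — the "solvent-accessible diameter" with no
probe subtraction, the convention under which the deposited Cx43 models give
≈5 Å for the full-GCN channel and ≈10 Å for the full-PLN hemichannel.

The channel axis is detected as the distinct eigenvector of the Cα gyration
tensor (a ring-symmetric channel has two nearly equal eigenvalues; the odd
one marks the symmetry axis), falling back to +z with a warning when the
tensor is isotropic within 1%. Defaults: 0.25 Å slice step; Bondi element
radii, with HOLE's united-atom set available by name (published profiles
rarely state their radius set, so deviations under a different set should be
reported, not hidden); heteroatoms and lipids excluded unless requested,
since published constriction values for hybrid models are protein-only.
Atoms carrying explicit stored radii (toy channels) win over the named set.
Note that structure files do not carry per-atom radii, so a toy channel
written to mmCIF and re-profiled uses the element-based set.

## Ion transport (`iontransport`)

Currents use the displacement-sum ("charge-flux") estimator
I = (1/Lz) Σᵢ qᵢ⟨Δzᵢ/Δt⟩ with per-step displacements unwrapped by the
minimum-image convention; it is translation-invariant, exactly antisymmetric
under charge negation, and exact on noise-free drift. A plane-crossing
counting estimator is provided purely as a cross-check (it is quantized to
one charge per crossing and noisier). Statistical errors follow block
averaging: the per-step current series is split into n contiguous blocks
(default 4, mirroring the 4 × 50-ns convention for 200-ns runs) and the SE of
block means is reported. Conductance is G = I/V with the pA/mV → pS factor of
1000 centralized in `units`; simulated currents are *never* silently scaled
for water-model viscosity — a reporting flag exposes that correction.
Concentration maps convert time-averaged counts per bin with 1 particle/nm³ =
1.6605 M, and integrate back to the mean ion count exactly. Trajectory
RMSD/RMSF fits every frame to a reference by Kabsch over a fit selection;
RMSF is the per-atom (or residue-averaged) RMS deviation from the time-mean
fitted structure.

Units are fixed throughout: nm/ps/e/mV in, pA/pS/M out. Trajectories live in
memory as (frames × ions × 3) arrays with a plain-text columnar reader/writer;
binary MD formats are intentionally not parsed here — adapt through the array
interface.

## Synthetic data (`synthgen`)

The generators define the conditions under which the statistics are
exercised, with known ground truth:

* **State tables** — default fractions (0.373, 0.22, 0.407) for
  (GCN, FIN, PLN), the three-state equilibrium of Cx43-M257 hemichannels in
  POPE nanodiscs; iid multinomial at J = 0, exact inverse-CDF draws over the
  64 ring configurations at J ≠ 0 (no MCMC, hence no convergence questions);
  two independent hemichannels per particle. Optional confusion-matrix label
  noise. What these tables do *not* emulate: orientation-dependent
  misclassification, correlation between the two rings of one particle, or
  particle-level quality variation — so passing tests show estimator
  correctness under the stated model, not robustness to every real-data
  pathology.
* **Toy channels** — stacked rings of pseudo-atoms with explicit radii whose
  pore radius at a ring's slice is (ring distance − vdW) in closed form; the
  independent dense-grid oracle for the profiler lives in the tests. Slices
  between widely spaced rings, and end slices of narrow rings, are governed
  by 3-D distances and can legitimately exceed the per-ring formula.
* **Toy hexamer templates** — open/closed six-chain rings sharing a
  byte-identical anchor region, for exercising assembly without deposited
  coordinates.
* **Ion trajectories** — overdamped dynamics z ← z + v dt + √(2D dt) ξ in a
  periodic box (defaults: 14 × 14 × 26 nm box, 20-ps frames, 200 mV, physical
  Na⁺ diffusivity 1.33 × 10⁻³ nm²/ps), with the analytic expected current
  n·q·v/Lz recorded in metadata. Diffusion is a free noise dial: calibration
  studies that need the conductance to printed precision use a small D so the
  block SE is sub-pA at 20,000 frames.

All generators are bit-reproducible under a seed and write their settings
into output metadata.

## Numerical and calibration choices

* Profile-likelihood bounds are bracketed geometrically and solved by Brent
  to 10⁻⁶; the ring fit is on sufficient statistics, so cost is independent
  of the number of rings.
* The estimator-calibration study (current within 3 block-SE of the analytic
  value in ≥95% of runs) uses 16 blocks rather than 4: with 4 blocks a
  "3 SE" band is a Student-t(3) interval with ≈94% coverage per species —
  the shortfall is a property of the error bar, not of the estimator. Finer
  blocking conditions the SE without widening the band (the synthetic samples
  are iid, so there is no autocorrelation constraint). Production trajectory
  analysis keeps the 4-block default.
* Study sizes: composition statistics at 10⁵ particles; coupling-recovery at
  100 replicates × 50,000 rings (J = 0.5, marginal 0.4); current recovery at
  100 runs × 400 frames × 660 ions; profiler-oracle checks on seeded toy
  channels at 0.1-Å grids refined 10×. These run in well under a minute each
  on one CPU.

## Deposited-structure analyses

The operations reproduce published numbers when pointed at the deposited
coordinate sets (full-GCN channel constriction ≈5.0 Å; full-PLN hemichannel
≈10 Å; hybrids with 3 and 4 consecutive PLN protomers 13.2 and 14.3 Å; mean
Cα deviation 0.6 Å among GCN protomers of the three POPE/CHS-family entries
and ≈1.2 Å between the Cx43 PLN protomer and Cx46). `fetch_structure`
resolves entries from a local `data/deposited/` cache or downloads from
RCSB; the corresponding acceptance tests fail with a clear diagnostic when
neither is available, rather than silently skipping. Coordinates are not
bundled with the package.

## Known limitations

* The pore profiler reports the per-slice maximal inscribed sphere; it does
  not trace off-axis tunnels (CAVER-style) and can "leak" around the rim at
  the open ends of short toy stacks — real channel walls are dense enough
  that this does not arise in practice.
* The Ising fit assumes ring homogeneity (one h, one J) and ignores
  cross-ring coupling within a particle.
* The current estimator assumes saved frames are dense enough that no ion
  travels Lz/2 between frames; it warns when displacements approach that
  bound.
* Exact multinomial p-values switch to seeded Monte Carlo above total 20.
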