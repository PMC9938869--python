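"""Synthetic fixtures with known ground truth for every analysis module.

Three generator families:

* protomer-state tables drawn from the exact ring model (iid multinomial at
  J = 0, nearest-neighbour-coupled binary rings at J != 0), with optional
  misclassification noise -- emulating symmetry-expanded classification
  output whose three-state fractions default to the (0.373, 0.22, 0.407)
  equilibrium observed for Cx43 hemichannels in phospholipid nanodiscs;
* toy channel structures (stacked rings of pseudo-atoms) whose pore radius
  profile is known in closed form: radius at a ring's z equals the ring
  distance minus the atom vdW radius;
* overdamped drift-diffusion ion trajectories in a periodic box whose mean
  current is analytic (n q v_z / Lz), sized after the simulated systems
  (hundreds of ions, 200 mV, 20-ps frames).

All generators are deterministic under a seed and write their settings into
the output metadata so any fixture is regenerable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import units
from .iontransport import IonTrajectory
from .ringstats import (
    ProtomerStateTable,
    ring_config_log_probs,
    solve_field_for_marginal,
)
from .structmodel import Structure

__all__ = [
    "DEFAULT_STATE_PROBS",
    "sample_ring_configs",
    "simulate_state_table",
    "add_misclassification",
    "toy_channel_structure",
    "toy_hexamer_template",
    "simulate_ion_trajectory",
]

#: Conformational-state fractions of the three-state equilibrium condition
#: (GCN / FIN / PLN protomers in POPE nanodiscs).
DEFAULT_STATE_PROBS: dict[str, float] = {"GCN": 0.373, "FIN": 0.22, "PLN": 0.407}

RING_N = 6


def sample_ring_configs(n_rings: int, p_focal: float, J: float,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Exact (n_rings, 6) binary ring draws from the nearest-neighbour model.

    Inverse-CDF sampling over the 64 enumerated configurations; the field h
    is solved so the per-site marginal equals ``p_focal``. No MCMC, so there
    are no convergence questions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h = solve_field_for_marginal(p_focal, J)
    config_p = np.exp(ring_config_log_probs(h, J))
    configs = rng.choice(64, size=n_rings, p=config_p)
    return (configs[:, None] >> np.arange(RING_N)[None, :]) & 1


def simulate_state_table(
    n_particles: int,
    probs: dict[str, float] | None = None,
    seed: int = 0,
    J: float = 0.0,
    focal_state: str | None = None,
    label: str = "synthetic",
) -> ProtomerStateTable:
    """Draw a protomer-state table of ``n_particles`` 12-protomer channels.

    At J = 0 every protomer state is iid multinomial with the given
    probabilities. At J != 0 the occupancy of ``focal_state`` on each
    hexamer ring is drawn exactly from the nearest-neighbour ring model
    (inverse-CDF over the 64 enumerated configurations, with the field h
    solved so the per-site marginal equals probs[focal_state]); non-focal
    sites are filled iid from the remaining states' renormalized
    probabilities. The two hemichannel rings of a particle are independent.
    """
    if probs is None:
        probs = dict(DEFAULT_STATE_PROBS)
    states = list(probs)
    p = np.array([probs[s] for s in states], dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("state probabilities must be non-negative and sum to 1")
    if n_particles < 1:
        raise ValueError("need at least one particle")
    rng = np.random.default_rng(seed)
    n_rings = 2 * n_particles

    if J == 0.0:
        flat = rng.choice(len(states), size=n_rings * RING_N, p=p)
        state_col = np.array(states, dtype=object)[flat]
    else:
        if focal_state is None or focal_state not in probs:
            raise ValueError("J != 0 requires focal_state present in probs")
        bits = sample_ring_configs(n_rings, probs[focal_state], J, rng)
        others = [s for s in states if s != focal_state]
        q = np.array([probs[s] for s in others], dtype=float)
        q = q / q.sum() if q.sum() > 0 else np.full(len(others), 1.0 / max(len(others), 1))
        state_col = np.empty(n_rings * RING_N, dtype=object)
        flat_bits = bits.reshape(-1).astype(bool)
        state_col[flat_bits] = focal_state
        n_other = int((~flat_bits).sum())
        if n_other and others:
            state_col[~flat_bits] = np.array(others, dtype=object)[
                rng.choice(len(others), size=n_other, p=q)
            ]

    particle_ids = np.repeat(
        np.array([f"ptcl{i:07d}" for i in range(n_particles)], dtype=object), 12
    )
    hemis = np.tile(np.repeat([0, 1], RING_N), n_particles)
    positions = np.tile(np.arange(RING_N), n_rings)
    df = pd.DataFrame({
        "particle_id": particle_ids,
        "hemichannel": hemis,
        "position": positions,
        "state": state_col,
    })
    t = ProtomerStateTable(df, tuple(states), label=label)
    t.validate()
    return t


def add_misclassification(
    t: ProtomerStateTable, confusion: np.ndarray, seed: int = 0
) -> ProtomerStateTable:
    """Resample each state label through a row-stochastic confusion matrix.

    ``confusion[i, j]`` = P(observed state j | true state i), rows/columns
    ordered as ``t.states``. Deterministic under the seed.
    """
    confusion = np.asarray(confusion, dtype=float)
    k = len(t.states)
    if confusion.shape != (k, k) or not np.allclose(confusion.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("confusion must be row-stochastic over the table's states")
    rng = np.random.default_rng(seed)
    index = {s: i for i, s in enumerate(t.states)}
    true_idx = np.array([index[s] for s in t.df["state"]])
    u = rng.random(len(true_idx))
    cdf = np.cumsum(confusion, axis=1)
    new_idx = (u[:, None] > cdf[true_idx]).sum(axis=1)
    df = t.df.copy()
    df["state"] = np.array(t.states, dtype=object)[new_idx]
    return ProtomerStateTable(df, t.states, label=f"{t.label}+noise")


def toy_channel_structure(
    rings: list[tuple[float, float, int, float]],
    label: str = "toy_channel",
) -> Structure:
    """Stacked rings of pseudo-atoms about the z axis with analytic pore radii.

    Each entry of ``rings`` is (z in A, ring distance from the axis in A,
    atoms per ring, vdW radius in A); the analytic pore radius at that slice
    is ring distance minus vdW. Atoms are labelled as alanine CA pseudo-atoms
    and carry their vdW radius explicitly; chains cycle A-F by azimuthal
    sector so axis detection has multiple chains to work with.
    """
    chains = "ABCDEF"
    serial, names, elements, resnames, resids, chain_ids, coords, vdw = \
        [], [], [], [], [], [], [], []
    counter = 0
    for z, dist, n_atoms, r_vdw in rings:
        if dist <= r_vdw:
            raise ValueError("ring distance must exceed the vdW radius")
        for j in range(n_atoms):
            theta = 2 * np.pi * j / n_atoms
            counter += 1
            serial.append(counter)
            names.append("CA")
            elements.append("C")
            resnames.append("ALA")
            resids.append(counter)
            chain_ids.append(chains[int(theta // (np.pi / 3)) % 6])
            coords.append((dist * np.cos(theta), dist * np.sin(theta), z))
            vdw.append(r_vdw)
    s = Structure(
        serial=np.array(serial),
        atom_name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        res_name=np.array(resnames, dtype=object),
        res_id=np.array(resids),
        chain_id=np.array(chain_ids, dtype=object),
        coords=np.array(coords),
        vdw=np.array(vdw),
        name=label,
    )
    s.validate()
    return s


def toy_hexamer_template(
    conformation: str = "open",
    n_res: int = 30,
    anchor_last: int = 15,
    ring_distance: float = 12.0,
    gate_pitch: float = 0.5,
    seed: int = 0,
) -> Structure:
    """Hexameric toy hemichannel for exercising assembly and profiling.

    Six single-chain "protomers" (chains A-F) of ``n_res`` CA pseudo-atoms
    each are placed by 60-degree rotations about the z axis. Residues 1 to
    ``anchor_last`` (the mock extracellular half) sit at ``ring_distance``
    from the axis and are byte-identical between conformations -- they are
    the anchor region for hybrid assembly. The remaining residues form the
    mock gate: in the ``open`` conformation they stay at ``ring_distance``;
    in ``closed`` they step inward by ``gate_pitch`` A per residue. A small
    seeded jitter (identical across conformations per residue) keeps the
    geometry from being pathologically symmetric.
    """
    if conformation not in ("open", "closed"):
        raise ValueError("conformation must be 'open' or 'closed'")
    rng = np.random.default_rng(seed)
    jitter = rng.normal(scale=0.05, size=(n_res, 3))
    protomer = []
    for j in range(1, n_res + 1):
        z = 1.5 * j
        if conformation == "closed" and j > anchor_last:
            rho = max(ring_distance - gate_pitch * (j - anchor_last), 3.0)
        else:
            rho = ring_distance
        protomer.append(np.array([rho, 0.15 * j, z]) + jitter[j - 1])
    protomer = np.array(protomer)

    chains = "ABCDEF"
    serial, names, elements, resnames, resids, chain_ids, coords = \
        [], [], [], [], [], [], []
    aa_cycle = ["ALA", "GLY", "SER", "LEU", "VAL", "THR"]
    counter = 0
    for i, cname in enumerate(chains):
        angle = np.pi / 3 * i
        rot = np.array([
            [np.cos(angle), -np.sin(angle), 0.0],
            [np.sin(angle), np.cos(angle), 0.0],
            [0.0, 0.0, 1.0],
        ])
        placed = protomer @ rot.T
        for j in range(n_res):
            counter += 1
            serial.append(counter)
            names.append("CA")
            elements.append("C")
            resnames.append(aa_cycle[j % len(aa_cycle)])
            resids.append(j + 1)
            chain_ids.append(cname)
            coords.append(placed[j])
    s = Structure(
        serial=np.array(serial),
        atom_name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        res_name=np.array(resnames, dtype=object),
        res_id=np.array(resids),
        chain_id=np.array(chain_ids, dtype=object),
        coords=np.array(coords),
        name=f"toy_hexamer_{conformation}",
    )
    s.validate()
    return s


def simulate_ion_trajectory(
    n_per_species: dict[str, tuple[int, float, float]],
    box: tuple[float, float, float] = (14.0, 14.0, 26.0),
    frames: int = 500,
    dt: float = 20.0,
    diffusion: float = 1.33e-3,
    voltage: float = 200.0,
    seed: int = 0,
) -> IonTrajectory:
    """Overdamped drift-diffusion ion trajectory with analytic mean current.

    ``n_per_species`` maps a species name to (count, charge in e, drift
    v_z in nm/ps). Each ion follows z_{t+1} = z_t + v_z dt + sqrt(2 D dt) xi
    with periodic wrap along z and pure diffusion in x, y. The analytic
    expected current per species, n q v_z / Lz (in pA), is recorded in the
    metadata. Defaults mirror the simulated channel systems: a ~14 x 14 x
    26 nm box, 20-ps saved frames, 200 mV along z.
    """
    if diffusion < 0:
        raise ValueError("diffusion must be non-negative")
    Lx, Ly, Lz = box
    rng = np.random.default_rng(seed)
    names: list[str] = []
    charges: list[float] = []
    drifts: list[float] = []
    for sp, (count, q, vz) in n_per_species.items():
        step = abs(vz) * dt + 4.0 * np.sqrt(2.0 * diffusion * dt)
        if step > Lz / 2:
            raise ValueError(
                f"per-frame step ~{step:.2f} nm exceeds Lz/2; unwrapping unsafe "
                "(reduce dt, drift, or diffusion)"
            )
        names.extend([sp] * count)
        charges.extend([q] * count)
        drifts.extend([vz] * count)
    n_ions = len(names)
    if n_ions == 0:
        raise ValueError("no ions requested")
    charges_a = np.array(charges)
    drifts_a = np.array(drifts)

    pos = np.empty((frames, n_ions, 3))
    pos[0, :, 0] = rng.uniform(0, Lx, n_ions)
    pos[0, :, 1] = rng.uniform(0, Ly, n_ions)
    pos[0, :, 2] = rng.uniform(0, Lz, n_ions)
    sigma = np.sqrt(2.0 * diffusion * dt)
    for f in range(1, frames):
        noise = rng.normal(scale=sigma, size=(n_ions, 3))
        pos[f, :, 0] = np.mod(pos[f - 1, :, 0] + noise[:, 0], Lx)
        pos[f, :, 1] = np.mod(pos[f - 1, :, 1] + noise[:, 1], Ly)
        pos[f, :, 2] = np.mod(pos[f - 1, :, 2] + drifts_a * dt + noise[:, 2], Lz)

    analytic = {
        sp: units.current_pa(count * q * vz / Lz)
        for sp, (count, q, vz) in n_per_species.items()
    }
    meta = {
        "generator": "simulate_ion_trajectory",
        "seed": seed,
        "diffusion_nm2_per_ps": diffusion,
        "spec": {sp: list(v) for sp, v in n_per_species.items()},
        "analytic_current_pa": analytic,
        "analytic_total_pa": float(sum(analytic.values())),
    }
    return IonTrajectory(
        positions=pos, dt=dt, box=box,
        species=np.array(names, dtype=object),
        charges=charges_a, voltage=voltage, metadata=meta,
    )
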