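"""Statistics of subunit conformational states on hexameric rings.

A gap-junction channel is a dodecamer of two stacked hexameric hemichannels;
symmetry-expanded classification assigns each of the 12 protomers one of a
small set of N-terminal-helix conformations (e.g. GCN, FIN, PLN). This
module asks whether those per-protomer states behave independently:

* composition histograms (how many focal-state protomers per hemichannel or
  per channel) against the Binomial(n, p) independence prediction;
* arrangement classes of the occupied ring positions under rotational
  symmetry, whose conditional probabilities given k occupied sites are pure
  combinatorics (multiplicity / C(6, k));
* goodness-of-fit tests (Pearson chi-square or exact multinomial);
* a nearest-neighbour Ising-type ring model
      P(x) proportional to exp(h * sum x_i + J * sum x_i x_{i+1 mod 6})
  fit by maximum likelihood over the 64 exactly enumerated binary ring
  configurations, with profile-likelihood confidence intervals and a
  likelihood-ratio test of J = 0 (independence).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

__all__ = [
    "ProtomerStateTable",
    "CompositionHistogram",
    "ArrangementClass",
    "RingModelParams",
    "GoFResult",
    "read_table_tsv",
    "read_table_star",
    "write_table_star",
    "state_fractions",
    "composition_histogram",
    "expected_composition",
    "canonical_arrangement",
    "enumerate_arrangements",
    "observed_arrangements",
    "gof_test",
    "fit_ring_model",
    "fit_ring_model_from_rings",
    "ring_config_stats",
    "ring_config_log_probs",
    "ring_marginal_probability",
    "solve_field_for_marginal",
    "invert_confusion",
    "bonferroni",
]

RING_N = 6
N_CONFIGS = 64


# ---------------------------------------------------------------------------
# State table container and I/O

REQUIRED_COLUMNS = ("particle_id", "hemichannel", "position", "state")


@dataclass
class ProtomerStateTable:
    """One row per protomer observation on symmetry-expanded particles.

    Columns: particle_id (text), hemichannel (0/1), position (0-5, counted
    counter-clockwise from the extracellular side), state (label from the
    declared state set). Each (particle, hemichannel) must contribute
    exactly 6 rows covering positions 0..5.
    """

    df: pd.DataFrame
    states: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        self.states = tuple(self.states)

    def validate(self) -> None:
        if len(self.df) == 0:
            raise ValueError("empty table")
        bad = set(self.df["state"]) - set(self.states)
        if bad:
            raise ValueError(f"states outside the declared set: {sorted(bad)}")
        if not self.df["hemichannel"].isin([0, 1]).all():
            raise ValueError("hemichannel must be 0 or 1")
        sizes = self.df.groupby(["particle_id", "hemichannel"])["position"].agg(
            ["count", "nunique", "min", "max"]
        )
        ok = (sizes["count"] == 6) & (sizes["nunique"] == 6) & (sizes["min"] == 0) & (sizes["max"] == 5)
        if not ok.all():
            raise ValueError("each (particle, hemichannel) needs exactly positions 0..5")

    @property
    def n_particles(self) -> int:
        return self.df["particle_id"].nunique()

    def rings(self, focal_state: str) -> np.ndarray:
        """(n_rings, 6) binary occupancy array, one row per hemichannel ring."""
        df = self.df.sort_values(["particle_id", "hemichannel", "position"])
        occ = (df["state"] == focal_state).to_numpy(dtype=int)
        return occ.reshape(-1, RING_N)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_table_tsv(path: str | Path, states: tuple[str, ...] | None = None,
                   label: str = "") -> ProtomerStateTable:
    df = pd.read_csv(path, sep="\t")
    if states is None:
        states = tuple(sorted(df["state"].unique()))
    t = ProtomerStateTable(df, states, label or Path(path).stem)
    t.validate()
    return t


def write_table_star(t: ProtomerStateTable, path: str | Path,
                     state_to_class: dict[str, int] | None = None) -> None:
    """Write the table as a RELION-flavoured STAR particle loop.

    Ring position and hemichannel are encoded in the symmetry-expansion
    Euler angles (rot = 60 deg * position, tilt = 0/180 for the two
    hemichannels); the conformation is encoded as a class number.
    """
    if state_to_class is None:
        state_to_class = {s: i + 1 for i, s in enumerate(t.states)}
    lines = [
        "data_particles", "", "loop_",
        "_rlnImageOriginalName #1", "_rlnClassNumber #2",
        "_rlnAngleRot #3", "_rlnAngleTilt #4", "_rlnAnglePsi #5",
    ]
    for row in t.df.itertuples(index=False):
        rot = 60.0 * int(row.position)
        tilt = 0.0 if int(row.hemichannel) == 0 else 180.0
        lines.append(
            f"{row.particle_id} {state_to_class[row.state]} {rot:.2f} {tilt:.2f} 0.00"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_table_star(path: str | Path, class_to_state: dict[int, str],
                    label: str = "") -> ProtomerStateTable:
    """Read a STAR-subset particle table (gemmi CIF/STAR reader underneath).

    Hemichannel and ring position indices are derived from the
    symmetry-expansion Euler angles: position = round(rot / 60) mod 6 and
    hemichannel 0/1 for tilt below/above 90 degrees. Any consistent
    convention yields identical ring statistics.
    """
    import gemmi

    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    names = list(block.find_loop("_rlnImageOriginalName"))
    classes = [int(x) for x in block.find_loop("_rlnClassNumber")]
    rots = [float(x) for x in block.find_loop("_rlnAngleRot")]
    tilts = [float(x) for x in block.find_loop("_rlnAngleTilt")]
    if not names:
        raise ValueError(f"{path}: no particle loop found")
    df = pd.DataFrame({
        "particle_id": names,
        "hemichannel": [0 if tt < 90.0 else 1 for tt in tilts],
        "position": [int(round((r % 360.0) / 60.0)) % 6 for r in rots],
        "state": [class_to_state[c] for c in classes],
    })
    t = ProtomerStateTable(df, tuple(sorted(set(df["state"]))), label or Path(path).stem)
    t.validate()
    return t


# ---------------------------------------------------------------------------
# Composition statistics


def state_fractions(t: ProtomerStateTable) -> dict[str, float]:
    """Fraction of protomer observations in each state (sums to 1)."""
    t.validate()
    counts = t.df["state"].value_counts()
    total = int(counts.sum())
    return {s: float(counts.get(s, 0)) / total for s in t.states}


@dataclass
class CompositionHistogram:
    level: str                 # "hemichannel" (n=6) or "channel" (n=12)
    focal_state: str
    counts: np.ndarray         # indexed 0..n
    total: int

    @property
    def n(self) -> int:
        return len(self.counts) - 1

    @property
    def mode(self) -> int:
        return int(np.argmax(self.counts))


def composition_histogram(t: ProtomerStateTable, focal_state: str,
                          level: str = "channel") -> CompositionHistogram:
    """Histogram of focal-state counts per assembly.

    ``channel`` counts focal protomers among the 12 per particle;
    ``hemichannel`` treats each of the two hexamer rings per particle as a
    separate assembly (so hemichannel totals are twice the particle total).
    """
    t.validate()
    is_focal = t.df["state"] == focal_state
    if level == "channel":
        per = is_focal.groupby(t.df["particle_id"]).sum()
        n = 12
    elif level == "hemichannel":
        per = is_focal.groupby([t.df["particle_id"], t.df["hemichannel"]]).sum()
        n = 6
    else:
        raise ValueError("level must be 'channel' or 'hemichannel'")
    counts = np.bincount(per.to_numpy(dtype=int), minlength=n + 1)
    return CompositionHistogram(level, focal_state, counts, int(counts.sum()))


def expected_composition(n: int, p: float, total: float) -> np.ndarray:
    """Independence prediction: total x Binomial(n, p) pmf over 0..n."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return total * stats.binom.pmf(np.arange(n + 1), n, p)


# ---------------------------------------------------------------------------
# Arrangement classes under ring symmetry


def _rotations(word: tuple[int, ...]):
    for s in range(RING_N):
        yield word[s:] + word[:s]


def canonical_arrangement(occupancy, symmetry: str = "C6") -> tuple[int, ...]:
    """Lexicographically minimal rotation (and reflection for D6) of a ring word."""
    word = tuple(int(x) for x in occupancy)
    if len(word) != RING_N:
        raise ValueError("occupancy word must have length 6")
    candidates = list(_rotations(word))
    if symmetry == "D6":
        candidates += list(_rotations(word[::-1]))
    elif symmetry != "C6":
        raise ValueError("symmetry must be 'C6' or 'D6'")
    return min(candidates)


@dataclass(frozen=True)
class ArrangementClass:
    pattern: tuple[int, ...]   # canonical occupancy word
    multiplicity: int          # labeled placements in the class
    k: int                     # occupied sites

    @property
    def conditional_probability(self) -> float:
        """P(class | k occupied) under independence: multiplicity / C(6, k)."""
        return self.multiplicity / math.comb(RING_N, self.k)

    def __str__(self) -> str:
        return "".join(map(str, self.pattern))


def enumerate_arrangements(k: int, symmetry: str = "C6") -> list[ArrangementClass]:
    """Distinct classes of k occupied ring positions under C6 (or D6) symmetry.

    Brute-force orbit counting over all C(6, k) labeled placements; the
    multiplicities therefore sum to C(6, k) exactly and the conditional
    class probabilities to 1.
    """
    if not 0 <= k <= RING_N:
        raise ValueError("k must be in 0..6")
    groups: dict[tuple[int, ...], int] = {}
    for occupied in itertools.combinations(range(RING_N), k):
        word = tuple(1 if i in occupied else 0 for i in range(RING_N))
        canon = canonical_arrangement(word, symmetry)
        groups[canon] = groups.get(canon, 0) + 1
    return [ArrangementClass(pat, mult, k) for pat, mult in sorted(groups.items())]


def observed_arrangements(t: ProtomerStateTable, focal_state: str, k: int,
                          symmetry: str = "C6") -> dict[tuple[int, ...], int]:
    """Counts of hemichannels with exactly k focal protomers per arrangement class."""
    if not 1 <= k <= 5:
        raise ValueError("k must be in 1..5 (k = 0 and 6 have a single trivial class)")
    rings = t.rings(focal_state)
    counts: dict[tuple[int, ...], int] = {
        cls.pattern: 0 for cls in enumerate_arrangements(k, symmetry)
    }
    for ring in rings[rings.sum(axis=1) == k]:
        counts[canonical_arrangement(ring, symmetry)] += 1
    return counts


# ---------------------------------------------------------------------------
# Goodness of fit


@dataclass
class GoFResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    method: str


def _log_multinomial_pmf(counts: np.ndarray, probs: np.ndarray) -> float:
    n = counts.sum()
    with np.errstate(divide="ignore"):
        logp = np.where(counts > 0, counts * np.log(probs), 0.0)
    return float(math.lgamma(n + 1) - sum(math.lgamma(c + 1) for c in counts) + logp.sum())


def gof_test(observed, expected_probs, method: str = "pearson_chi2",
             n_mc: int = 10_000, seed: int = 0) -> GoFResult:
    """Test observed category counts against given probabilities.

    ``pearson_chi2`` uses the chi-square statistic with df = categories - 1
    (warning when any expected count is below 5). ``exact_multinomial``
    computes the exact tail probability (sum of outcome probabilities not
    exceeding the observed one) by full enumeration when the total is at
    most 20, otherwise by seeded Monte Carlo.
    """
    observed = np.asarray(observed, dtype=float)
    probs = np.asarray(expected_probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("expected probabilities must sum to 1")
    total = observed.sum()
    if total <= 0:
        raise ValueError("observed total must be positive")
    expected = total * probs
    if method == "pearson_chi2":
        if (expected < 5).any():
            warnings.warn(
                "expected count below 5 in some category; consider exact_multinomial",
                stacklevel=2,
            )
        keep = probs > 0
        stat, _ = stats.chisquare(observed[keep], expected[keep])
        dof = int(keep.sum() - 1)
        p = float(stats.chi2.sf(stat, dof))
        return GoFResult(float(stat), dof, p, expected, method)
    if method != "exact_multinomial":
        raise ValueError("method must be 'pearson_chi2' or 'exact_multinomial'")
    k = len(observed)
    obs_counts = observed.astype(int)
    log_p_obs = _log_multinomial_pmf(obs_counts, probs)
    tol = 1e-9
    if total <= 20:
        p = 0.0
        for combo in itertools.combinations_with_replacement(range(k), int(total)):
            counts = np.bincount(combo, minlength=k)
            lp = _log_multinomial_pmf(counts, probs)
            if lp <= log_p_obs + tol:
                p += math.exp(lp)
        p = min(p, 1.0)
    else:
        rng = np.random.default_rng(seed)
        draws = rng.multinomial(int(total), probs, size=n_mc)
        lps = np.array([_log_multinomial_pmf(d, probs) for d in draws])
        p = float((np.sum(lps <= log_p_obs + tol) + 1) / (n_mc + 1))
    return GoFResult(float("nan"), k - 1, float(p), expected, method)


def bonferroni(p_values) -> list[float]:
    """Bonferroni-adjusted p-values for a small set of pre-specified tests."""
    m = len(p_values)
    return [min(1.0, m * p) for p in p_values]


# ---------------------------------------------------------------------------
# Exact ring (Ising) model on 6 sites


def ring_config_stats() -> tuple[np.ndarray, np.ndarray]:
    """Sufficient statistics (n_occupied, n_adjacent_pairs) for all 64 configs."""
    n1 = np.zeros(N_CONFIGS, dtype=int)
    n2 = np.zeros(N_CONFIGS, dtype=int)
    for c in range(N_CONFIGS):
        bits = [(c >> i) & 1 for i in range(RING_N)]
        n1[c] = sum(bits)
        n2[c] = sum(bits[i] * bits[(i + 1) % RING_N] for i in range(RING_N))
    return n1, n2


_N1, _N2 = ring_config_stats()


def ring_config_log_probs(h: float, J: float) -> np.ndarray:
    """Log-probabilities of the 64 binary ring configurations."""
    e = h * _N1 + J * _N2
    return e - logsumexp(e)


def ring_marginal_probability(h: float, J: float) -> float:
    """Per-site occupancy probability implied by (h, J)."""
    p = np.exp(ring_config_log_probs(h, J))
    return float(np.dot(p, _N1) / RING_N)


def solve_field_for_marginal(p: float, J: float) -> float:
    """Field h such that the ring model's per-site marginal equals p."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be strictly between 0 and 1")
    f = lambda h: ring_marginal_probability(h, J) - p
    lo, hi = -30.0, 30.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def _nll(h: float, J: float, config_counts: np.ndarray) -> float:
    logp = ring_config_log_probs(h, J)
    return float(-np.dot(config_counts, logp))


def _configs_from_rings(rings: np.ndarray) -> np.ndarray:
    weights = 1 << np.arange(RING_N)
    return rings @ weights


@dataclass
class RingModelParams:
    """Fitted ring-model parameters (natural-log units).

    ``h`` is the per-site field, ``J`` the adjacent-pair coupling; J > 0
    means the focal conformation of neighbouring protomers is mutually
    reinforcing (cooperativity), J = 0 independence. ``p`` is the implied
    per-site marginal and ``log_z`` the log-partition function over the 64
    ring configurations.
    """

    h: float
    J: float
    p: float
    log_z: float
    h_ci: tuple[float, float]
    J_ci: tuple[float, float]
    log_likelihood: float
    n_rings: int
    lrt_statistic: float
    lrt_p_value: float
    converged: bool = True


def _profile_ci(param: str, mle: tuple[float, float], nll_min: float,
                config_counts: np.ndarray, level_delta: float = 1.9207) -> tuple[float, float]:
    """Profile-likelihood CI bounds where the profiled NLL rises by 1.92 (95%)."""
    h_mle, J_mle = mle

    def profiled(value: float) -> float:
        if param == "J":
            res = optimize.minimize_scalar(
                lambda h: _nll(h, value, config_counts), bracket=(h_mle - 1, h_mle + 1)
            )
        else:
            res = optimize.minimize_scalar(
                lambda J: _nll(value, J, config_counts), bracket=(J_mle - 1, J_mle + 1)
            )
        return res.fun

    center = h_mle if param == "h" else J_mle
    target = nll_min + level_delta

    def bound(direction: float) -> float:
        step = 0.1
        lo, hi = center, center + direction * step
        for _ in range(60):
            if profiled(hi) >= target:
                break
            step *= 1.8
            lo, hi = hi, hi + direction * step
        else:
            return float(direction * np.inf)
        a, b = (lo, hi) if direction > 0 else (hi, lo)
        return float(optimize.brentq(lambda v: profiled(v) - target, a, b, xtol=1e-6))

    return (bound(-1.0), bound(+1.0))


def fit_ring_model(t: ProtomerStateTable, focal_state: str,
                   compute_ci: bool = True) -> RingModelParams:
    """Maximum-likelihood fit of the nearest-neighbour ring model.

    The table is binarized as focal-state vs. rest; each hemichannel ring
    contributes one 6-bit configuration. The likelihood is exact (64
    enumerated configurations), maximized over (h, J) by BFGS with analytic
    gradients. Profile-likelihood 95% CIs and the likelihood-ratio test of
    J = 0 (independence) are reported.
    """
    t.validate()
    return fit_ring_model_from_rings(t.rings(focal_state), compute_ci=compute_ci)


def fit_ring_model_from_rings(rings: np.ndarray,
                              compute_ci: bool = True) -> RingModelParams:
    """Array-level ring-model fit: rings is an (n, 6) binary occupancy array."""
    rings = np.asarray(rings, dtype=int)
    n_rings = len(rings)
    if n_rings < 100:
        warnings.warn(f"only {n_rings} hemichannel rings; >= 100 recommended", stacklevel=2)
    occ = rings.sum()
    if occ == 0 or occ == rings.size:
        raise ValueError("separation: every site identical, ring model unidentifiable")
    config_counts = np.bincount(_configs_from_rings(rings), minlength=N_CONFIGS).astype(float)

    def f_and_g(theta):
        h, J = theta
        logp = ring_config_log_probs(h, J)
        p = np.exp(logp)
        nll = -float(np.dot(config_counts, logp))
        n = config_counts.sum()
        g_h = -(float(np.dot(config_counts, _N1)) - n * float(np.dot(p, _N1)))
        g_J = -(float(np.dot(config_counts, _N2)) - n * float(np.dot(p, _N2)))
        return nll, np.array([g_h, g_J])

    p_hat = occ / rings.size
    x0 = np.array([np.log(p_hat / (1 - p_hat)), 0.0])
    res = optimize.minimize(f_and_g, x0, jac=True, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    if not res.success and np.linalg.norm(res.jac) > 1e-3 * max(1.0, n_rings):
        raise RuntimeError(f"ring-model fit did not converge: {res.message}; last iterate {res.x}")
    h, J = map(float, res.x)
    nll_min = float(res.fun)

    # LRT of J = 0: under independence the MLE field is the logit of mean occupancy
    h0 = float(np.log(p_hat / (1 - p_hat)))
    nll0 = _nll(h0, 0.0, config_counts)
    lrt = max(0.0, 2.0 * (nll0 - nll_min))
    lrt_p = float(stats.chi2.sf(lrt, 1))

    if compute_ci:
        h_ci = _profile_ci("h", (h, J), nll_min, config_counts)
        J_ci = _profile_ci("J", (h, J), nll_min, config_counts)
    else:
        h_ci = J_ci = (float("nan"), float("nan"))
    log_z = float(logsumexp(h * _N1 + J * _N2))
    return RingModelParams(
        h=h, J=J, p=ring_marginal_probability(h, J), log_z=log_z,
        h_ci=h_ci, J_ci=J_ci, log_likelihood=-nll_min, n_rings=n_rings,
        lrt_statistic=lrt, lrt_p_value=lrt_p, converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# Classification-noise correction


def invert_confusion(observed_fractions: np.ndarray, confusion: np.ndarray) -> np.ndarray:
    """Correct observed state fractions for known misclassification.

    ``confusion[i, j]`` is P(observed state j | true state i) (rows sum to
    1). Observed marginals are q = C^T p, so the corrected (true) fractions
    are obtained by solving C^T p = q; small negative components from noise
    are clipped and the result renormalized.
    """
    confusion = np.asarray(confusion, dtype=float)
    if not np.allclose(confusion.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("confusion rows must sum to 1")
    q = np.asarray(observed_fractions, dtype=float)
    p = np.linalg.solve(confusion.T, q)
    p = np.clip(p, 0.0, None)
    return p / p.sum()
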