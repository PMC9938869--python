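"""Atomic structures, rigid superposition, and hybrid hemichannel assembly.

This module handles the structural side of the analysis: reading and writing
PDB/mmCIF coordinate files, Kabsch least-squares superposition of protomers,
mean C-alpha deviation between conformations, assembly of hybrid hexameric
hemichannels from two template conformations (gate-covering "GCN" and
pore-lining "PLN" subunits placed on a common frame), and steric clash
counting.

Coordinates are in Angstrom throughout. Author chain IDs and residue
numbers are preserved; hydrogens are dropped on input and, where alternate
locations exist, the highest-occupancy altloc is kept.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import gemmi
from scipy.spatial import cKDTree

__all__ = [
    "Structure",
    "RigidTransform",
    "SuperpositionResult",
    "AssemblyPattern",
    "DEFAULT_ANCHOR_RANGES",
    "read_structure",
    "write_structure",
    "fetch_structure",
    "kabsch",
    "superpose",
    "mean_ca_deviation",
    "build_hybrid_hemichannel",
    "clash_count",
]

PDB_MAX_SERIAL = 99_999

#: Default anchor for assembly superposition of Cx43 protomers: the two
#: extracellular loops plus the extracellular halves of the four TM helices
#: (author numbering of the deposited Cx43 models). The exact ranges are a
#: package choice and can be overridden per call.
DEFAULT_ANCHOR_RANGES: tuple[tuple[int, int], ...] = (
    (37, 45),    # extracellular half of TM1
    (46, 75),    # ECL1
    (76, 84),    # extracellular half of TM2 (outer leaflet)
    (160, 170),  # extracellular half of TM3
    (171, 208),  # ECL2
    (209, 219),  # extracellular half of TM4
)


# ---------------------------------------------------------------------------
# Core containers


@dataclass
class Structure:
    """A flat atom table for one model of an atomic structure.

    Parallel numpy arrays, one entry per atom. ``vdw`` holds optional
    per-atom van der Waals radii (NaN where unset); synthetic toy channels
    use it to carry their analytic radii.
    """

    serial: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    coords: np.ndarray
    vdw: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        self.serial = np.asarray(self.serial, dtype=int)
        for attr in ("atom_name", "element", "res_name", "chain_id"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=object))
        self.res_id = np.asarray(self.res_id, dtype=int)
        for attr in ("serial", "atom_name", "element", "res_name", "res_id", "chain_id"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"field {attr!r} length != number of atoms")
        if self.vdw is not None:
            self.vdw = np.asarray(self.vdw, dtype=float)
            if len(self.vdw) != n:
                raise ValueError("vdw length != number of atoms")

    def __len__(self) -> int:
        return len(self.coords)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if any(len(e) == 0 for e in self.element):
            raise ValueError("empty element symbol")
        keys = list(zip(self.chain_id, self.res_id, self.atom_name))
        if len(set(keys)) != len(keys):
            raise ValueError("(chain, residue, atom name) not unique")

    def chains(self) -> list[str]:
        """Chain IDs in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(c, None)
        return list(seen)

    def select(
        self,
        chain: str | None = None,
        residues: Iterable[tuple[int, int]] | None = None,
        atom_names: Iterable[str] | None = None,
        heavy_only: bool = False,
    ) -> "Structure":
        """Subset of atoms, returned as a new Structure (copied arrays)."""
        mask = np.ones(len(self), dtype=bool)
        if chain is not None:
            mask &= self.chain_id == chain
        if residues is not None:
            mask &= residue_mask(self.res_id, residues)
        if atom_names is not None:
            names = set(atom_names)
            mask &= np.array([a in names for a in self.atom_name])
        if heavy_only:
            mask &= np.array([e.upper() not in ("H", "D") for e in self.element])
        return self._subset(mask)

    def _subset(self, mask: np.ndarray) -> "Structure":
        return Structure(
            serial=self.serial[mask].copy(),
            atom_name=self.atom_name[mask].copy(),
            element=self.element[mask].copy(),
            res_name=self.res_name[mask].copy(),
            res_id=self.res_id[mask].copy(),
            chain_id=self.chain_id[mask].copy(),
            coords=self.coords[mask].copy(),
            vdw=None if self.vdw is None else self.vdw[mask].copy(),
            name=self.name,
        )

    def copy(self) -> "Structure":
        return self._subset(np.ones(len(self), dtype=bool))

    def transformed(self, transform: "RigidTransform") -> "Structure":
        out = self.copy()
        out.coords = transform.apply(out.coords)
        return out

    @staticmethod
    def concat(parts: Sequence["Structure"], name: str = "") -> "Structure":
        have_vdw = all(p.vdw is not None for p in parts)
        return Structure(
            serial=np.concatenate([p.serial for p in parts]),
            atom_name=np.concatenate([p.atom_name for p in parts]),
            element=np.concatenate([p.element for p in parts]),
            res_name=np.concatenate([p.res_name for p in parts]),
            res_id=np.concatenate([p.res_id for p in parts]),
            chain_id=np.concatenate([p.chain_id for p in parts]),
            coords=np.concatenate([p.coords for p in parts]),
            vdw=np.concatenate([p.vdw for p in parts]) if have_vdw else None,
            name=name,
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or abs(np.linalg.det(R) - 1) > 1e-8:
            raise ValueError("rotation must be orthonormal with determinant +1")

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_pairs: int
    per_residue_deviation: list[tuple[int, float]] = field(default_factory=list)


@dataclass(frozen=True)
class AssemblyPattern:
    """Length-6 conformation pattern over ring positions 0-5.

    Positions are counted counter-clockwise viewed from the extracellular
    side, position 0 = chain A of the template. States are 'GCN' or 'PLN'.
    """

    states: tuple[str, ...]

    def __post_init__(self) -> None:
        states = tuple(self.states)
        object.__setattr__(self, "states", states)
        if len(states) != 6:
            raise ValueError("assembly pattern must have exactly 6 positions")
        bad = set(states) - {"GCN", "PLN"}
        if bad:
            raise ValueError(f"unknown states in pattern: {sorted(bad)}")

    @staticmethod
    def from_string(word: str) -> "AssemblyPattern":
        """Parse a 6-character pattern over {G, P}, e.g. 'PPPGGG'."""
        mapping = {"G": "GCN", "P": "PLN"}
        try:
            return AssemblyPattern(tuple(mapping[c] for c in word.upper()))
        except KeyError as exc:
            raise ValueError(f"pattern characters must be G or P, got {word!r}") from exc

    def __str__(self) -> str:
        return "".join(s[0] for s in self.states)


def residue_mask(res_id: np.ndarray, ranges: Iterable[tuple[int, int]]) -> np.ndarray:
    """Boolean mask of residues falling in any inclusive (start, end) range."""
    mask = np.zeros(len(res_id), dtype=bool)
    for lo, hi in ranges:
        mask |= (res_id >= lo) & (res_id <= hi)
    return mask


# ---------------------------------------------------------------------------
# File I/O (gemmi-backed)


def _structure_from_gemmi(st: gemmi.Structure, path: str) -> Structure:
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    if len(st) > 1:
        warnings.warn(f"{path}: {len(st)} models present, using the first", stacklevel=3)
    model = st[0]
    rows: dict[tuple[str, int, str], tuple[float, tuple]] = {}
    order: list[tuple[str, int, str]] = []
    for chain in model:
        for res in chain:
            for atom in res:
                if atom.is_hydrogen():
                    continue
                key = (chain.name, res.seqid.num, atom.name)
                rec = (
                    atom.serial,
                    atom.name,
                    atom.element.name,
                    res.name,
                    res.seqid.num,
                    chain.name,
                    (atom.pos.x, atom.pos.y, atom.pos.z),
                )
                if key not in rows:
                    order.append(key)
                    rows[key] = (atom.occ, rec)
                elif atom.occ > rows[key][0]:
                    # keep the highest-occupancy altloc
                    rows[key] = (atom.occ, rec)
    if not order:
        raise ValueError(f"{path}: no heavy atoms found")
    recs = [rows[k][1] for k in order]
    serial, atom_name, element, res_name, res_id, chain_id, xyz = zip(*recs)
    return Structure(
        serial=np.array(serial),
        atom_name=np.array(atom_name, dtype=object),
        element=np.array(element, dtype=object),
        res_name=np.array(res_name, dtype=object),
        res_id=np.array(res_id),
        chain_id=np.array(chain_id, dtype=object),
        coords=np.array(xyz, dtype=float),
        name=Path(path).stem,
    )


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read the first model of a PDB or mmCIF file into a Structure.

    Hydrogens are dropped; for alternate locations the highest-occupancy
    copy of each atom is kept. Author chain IDs and residue numbers are
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        elif format == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    st.setup_entities()
    return _structure_from_gemmi(st, str(path))


def write_structure(s: Structure, path: str | Path, format: str = "auto") -> None:
    """Write a Structure as PDB or mmCIF; re-readable by :func:`read_structure`.

    PDB coordinates carry 3 decimals; structures with more than 99,999 atoms
    cannot be expressed in the PDB dialect and raise, suggesting mmCIF.
    """
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    s.validate()
    if format == "pdb" and len(s) > PDB_MAX_SERIAL:
        raise ValueError(
            f"{len(s)} atoms exceed the PDB serial limit ({PDB_MAX_SERIAL}); write mmCIF instead"
        )
    st = gemmi.Structure()
    st.name = s.name or path.stem
    model = gemmi.Model("1")
    serial = 0
    for cname in s.chains():
        chain = gemmi.Chain(cname)
        idx = np.nonzero(s.chain_id == cname)[0]
        cur_res = None
        res = None
        for i in idx:
            if cur_res != s.res_id[i]:
                if res is not None:
                    chain.add_residue(res)
                res = gemmi.Residue()
                res.name = str(s.res_name[i])
                res.seqid = gemmi.SeqId(int(s.res_id[i]), " ")
                cur_res = s.res_id[i]
            atom = gemmi.Atom()
            atom.name = str(s.atom_name[i])
            atom.element = gemmi.Element(str(s.element[i]))
            atom.pos = gemmi.Position(*s.coords[i])
            serial += 1
            atom.serial = serial
            atom.occ = 1.0
            res.add_atom(atom)
        if res is not None:
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    elif format == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def fetch_structure(code: str, cache_dir: str | Path = "data/deposited") -> Structure:
    """Resolve a deposited PDB entry from a local cache, else download.

    Looks for ``<cache_dir>/<code>.{cif,pdb}``; if absent, attempts a
    download from RCSB (requires network). Raises FileNotFoundError with a
    clear diagnostic when neither route is available.
    """
    code = code.lower()
    cache = Path(cache_dir)
    for suffix in (".cif", ".pdb"):
        p = cache / f"{code}{suffix}"
        if p.exists():
            return read_structure(p)
    url = f"https://files.rcsb.org/download/{code.upper()}.cif"
    try:
        import urllib.request

        cache.mkdir(parents=True, exist_ok=True)
        target = cache / f"{code}.cif"
        with urllib.request.urlopen(url, timeout=30) as resp:
            target.write_bytes(resp.read())
        return read_structure(target)
    except Exception as exc:
        raise FileNotFoundError(
            f"deposited entry {code.upper()} not found in {cache}/ and could not be "
            f"downloaded ({exc}); place {code}.cif there to run deposited-model analyses"
        ) from exc


# ---------------------------------------------------------------------------
# Superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping mobile points onto reference.

    Standard SVD solution with the determinant sign fix so the returned
    rotation is always proper.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("need >= 3 paired points of identical shape")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    return RigidTransform(R, t)


def _pair_atoms(
    mobile: Structure, reference: Structure
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices of atoms paired by (chain, residue number, atom name).

    Chain ID is part of the key only when both structures are multi-chain;
    single-chain selections pair purely by residue number and atom name so
    protomers from different chains can be compared directly.
    """
    use_chain = len(mobile.chains()) > 1 and len(reference.chains()) > 1

    def keys(s: Structure):
        if use_chain:
            return list(zip(s.chain_id, s.res_id, s.atom_name))
        return list(zip(s.res_id, s.atom_name))

    km, kr = keys(mobile), keys(reference)
    lookup = {k: i for i, k in enumerate(kr)}
    mi, ri, res_ids = [], [], []
    for i, k in enumerate(km):
        j = lookup.get(k)
        if j is not None:
            mi.append(i)
            ri.append(j)
            res_ids.append(mobile.res_id[i])
    return np.array(mi, dtype=int), np.array(ri, dtype=int), np.array(res_ids, dtype=int)


_ATOM_FILTERS = {
    "CA": lambda s: s.select(atom_names=["CA"]),
    "backbone": lambda s: s.select(atom_names=["N", "CA", "C", "O"]),
    "all": lambda s: s.select(heavy_only=True),
}


def superpose(
    mobile: Structure,
    reference: Structure,
    selection: Iterable[tuple[int, int]] | None = None,
    atom_filter: str = "CA",
) -> SuperpositionResult:
    """Kabsch superposition of mobile onto reference over paired atoms.

    Atoms are paired by (residue number, atom name) within ``selection``
    (inclusive residue ranges; None = all residues). Returns the optimal
    transform, the RMSD over the paired atoms after applying it, and
    per-residue mean deviations.
    """
    if atom_filter not in _ATOM_FILTERS:
        raise ValueError(f"atom_filter must be one of {sorted(_ATOM_FILTERS)}")
    mob = _ATOM_FILTERS[atom_filter](mobile)
    ref = _ATOM_FILTERS[atom_filter](reference)
    if selection is not None:
        selection = list(selection)
        mob = mob.select(residues=selection)
        ref = ref.select(residues=selection)
    mi, ri, res_ids = _pair_atoms(mob, ref)
    if len(mi) < 3:
        raise ValueError(
            f"only {len(mi)} atom pairs matched by residue number and atom name; "
            "need >= 3 (consider alignment-based pairing for different proteins)"
        )
    transform = kabsch(mob.coords[mi], ref.coords[ri])
    moved = transform.apply(mob.coords[mi])
    dists = np.linalg.norm(moved - ref.coords[ri], axis=1)
    rmsd = float(np.sqrt(np.mean(dists**2)))
    per_res: dict[int, list[float]] = {}
    for rid, d in zip(res_ids, dists):
        per_res.setdefault(int(rid), []).append(float(d))
    per_residue = [(rid, float(np.mean(v))) for rid, v in sorted(per_res.items())]
    return SuperpositionResult(transform, rmsd, int(len(mi)), per_residue)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "SEC": "U",
}


def _ca_table(s: Structure) -> tuple[np.ndarray, np.ndarray, str]:
    """CA coordinates, residue ids, and one-letter sequence of the first chain."""
    ca = s.select(atom_names=["CA"])
    if len(ca.chains()) > 1:
        ca = ca.select(chain=ca.chains()[0])
    order = np.argsort(ca.res_id, kind="stable")
    seq = "".join(_THREE_TO_ONE.get(str(r), "X") for r in ca.res_name[order])
    return ca.coords[order], ca.res_id[order], seq


def _aligned_pairs(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Ungapped CA pairs from a global sequence alignment (Biopython)."""
    from Bio import Align

    ca_a, _, seq_a = _ca_table(a)
    ca_b, _, seq_b = _ca_table(b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aln = aligner.align(seq_a, seq_b)[0]
    ia, ib = [], []
    for (sa, ea), (sb, eb) in zip(aln.aligned[0], aln.aligned[1]):
        ia.extend(range(sa, ea))
        ib.extend(range(sb, eb))
    return ca_a[np.array(ia, dtype=int)], ca_b[np.array(ib, dtype=int)]


def mean_ca_deviation(
    a: Structure, b: Structure, pairing: str = "by_number"
) -> dict[str, float]:
    """Mean (and RMS) C-alpha deviation between two structures after fitting.

    ``by_number`` pairs CA atoms by residue number; ``by_alignment`` pairs
    by a global sequence alignment and uses only matched, ungapped pairs --
    the right mode when comparing different connexin isoforms whose author
    numbering differs. The headline statistic is the arithmetic mean of
    per-residue distances after the optimal superposition; the RMS is
    reported alongside.
    """
    if pairing == "by_number":
        res = superpose(a, b, atom_filter="CA")
        dists = np.array([d for _, d in res.per_residue_deviation])
    elif pairing == "by_alignment":
        pa, pb = _aligned_pairs(a, b)
        if len(pa) < 3:
            raise ValueError("alignment produced fewer than 3 matched CA pairs")
        tr = kabsch(pa, pb)
        dists = np.linalg.norm(tr.apply(pa) - pb, axis=1)
    else:
        raise ValueError("pairing must be 'by_number' or 'by_alignment'")
    if len(dists) == 0:
        raise ValueError("no matched CA pairs")
    return {
        "mean": float(np.mean(dists)),
        "rms": float(np.sqrt(np.mean(dists**2))),
        "n_pairs": int(len(dists)),
    }


# ---------------------------------------------------------------------------
# Hybrid assembly and clash checking


def build_hybrid_hemichannel(
    gcn_template: Structure,
    pln_template: Structure,
    pattern: AssemblyPattern,
    anchor: Iterable[tuple[int, int]] = DEFAULT_ANCHOR_RANGES,
    anchor_rmsd_ceiling: float = 2.0,
) -> tuple[Structure, dict]:
    """Assemble a hybrid hexameric hemichannel from two template conformations.

    For each ring position i the donor protomer (GCN or PLN chain per the
    pattern) is rigidly superposed onto chain i of the GCN template using
    only the anchor residues (the extracellular region, which is nearly
    identical between the conformations), then copied in unchanged. Output
    chains are relabeled A-F in ring order. Returns the model together with
    an assembly record of per-position anchor RMSDs.
    """
    anchor = list(anchor)
    gcn_chains = gcn_template.chains()
    pln_chains = pln_template.chains()
    if len(gcn_chains) != 6 or len(pln_chains) != 6:
        raise ValueError("templates must be hexameric (6 chains each)")
    parts: list[Structure] = []
    record: dict = {"pattern": str(pattern), "anchor_rmsd": {}}
    for i, state in enumerate(pattern.states):
        target = gcn_template.select(chain=gcn_chains[i])
        donor_template = gcn_template if state == "GCN" else pln_template
        donor_chain = (gcn_chains if state == "GCN" else pln_chains)[i]
        donor = donor_template.select(chain=donor_chain)
        fit = superpose(donor, target, selection=anchor, atom_filter="CA")
        if fit.rmsd > anchor_rmsd_ceiling:
            raise ValueError(
                f"anchor RMSD {fit.rmsd:.2f} A at position {i} exceeds ceiling "
                f"{anchor_rmsd_ceiling} A; templates are incompatible"
            )
        placed = donor.transformed(fit.transform)
        placed.chain_id = np.full(len(placed), string.ascii_uppercase[i], dtype=object)
        parts.append(placed)
        record["anchor_rmsd"][i] = fit.rmsd
    out = Structure.concat(parts, name=f"hybrid_{pattern}")
    out.serial = np.arange(1, len(out) + 1)
    return out, record


def clash_count(
    s: Structure,
    cutoff: float = 2.2,
    interface_only: bool = True,
) -> tuple[int, list[tuple[int, int]]]:
    """Count heavy-atom pairs closer than ``cutoff`` Angstrom.

    With ``interface_only`` (default) only inter-chain pairs are counted --
    the relevant check for assembled hybrid models. Otherwise intra-chain
    pairs are also counted, excluding same-residue and sequence-adjacent
    residue pairs (a crude bonded-pair exclusion). Returns the count and the
    atom-index pair list. Uses a KD-tree; a brute-force oracle lives in the
    test suite.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    heavy = np.array([e.upper() not in ("H", "D") for e in s.element])
    idx = np.nonzero(heavy)[0]
    coords = s.coords[idx]
    tree = cKDTree(coords)
    pairs = []
    for a, b in tree.query_pairs(cutoff):
        ia, ib = int(idx[a]), int(idx[b])
        same_chain = s.chain_id[ia] == s.chain_id[ib]
        if interface_only:
            if same_chain:
                continue
        elif same_chain and abs(int(s.res_id[ia]) - int(s.res_id[ib])) <= 1:
            continue
        pairs.append((min(ia, ib), max(ia, ib)))
    pairs.sort()
    return len(pairs), pairs
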