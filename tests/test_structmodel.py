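"""Structure I/O, superposition, hybrid assembly, and clash counting."""

import numpy as np
import pytest

from conftest import random_chain_structure, random_rotation
from oligoring.structmodel import (
    AssemblyPattern,
    RigidTransform,
    Structure,
    build_hybrid_hemichannel,
    clash_count,
    kabsch,
    mean_ca_deviation,
    read_structure,
    superpose,
    write_structure,
)

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.674   6.693  -4.139  1.00  0.00           C
END
"""


class TestReadWrite:
    def test_read_minimal_pdb_copies_fields(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(THREE_ATOM_PDB)
        s = read_structure(p)
        assert len(s) == 3
        assert list(s.atom_name) == ["N", "CA", "C"]
        assert list(s.element) == ["N", "C", "C"]
        np.testing.assert_allclose(s.coords[0], [11.104, 6.134, -6.504])
        assert s.chain_id[0] == "A" and s.res_id[0] == 1

    @pytest.mark.parametrize("fmt", ["pdb", "mmcif"])
    def test_round_trip_identity(self, tmp_path, rng, fmt):
        s = random_chain_structure(rng)
        suffix = ".pdb" if fmt == "pdb" else ".cif"
        p = tmp_path / f"rt{suffix}"
        write_structure(s, p, format=fmt)
        s2 = read_structure(p)
        assert list(s2.atom_name) == list(s.atom_name)
        assert list(s2.res_id) == list(s.res_id)
        # PDB coordinates carry 3 decimals
        np.testing.assert_allclose(s2.coords, s.coords, atol=5e-4)
        # second round-trip is exact
        p3 = tmp_path / f"rt2{suffix}"
        write_structure(s2, p3, format=fmt)
        s3 = read_structure(p3)
        np.testing.assert_array_equal(s3.coords, s2.coords)

    def test_unparseable_file_raises(self, tmp_path):
        p = tmp_path / "junk.cif"
        p.write_text("this is not a structure\n")
        with pytest.raises((ValueError, FileNotFoundError)):
            read_structure(p, format="mmcif")

    def test_pdb_serial_overflow_suggests_mmcif(self, tmp_path):
        n = 100_001
        s = Structure(
            serial=np.arange(1, n + 1),
            atom_name=np.array([f"C{i%100}" for i in range(n)], dtype=object),
            element=np.array(["C"] * n, dtype=object),
            res_name=np.array(["ALA"] * n, dtype=object),
            res_id=np.repeat(np.arange(n // 100 + 1), 100)[:n] + 1,
            chain_id=np.array(["A"] * n, dtype=object),
            coords=np.zeros((n, 3)),
        )
        with pytest.raises(ValueError, match="mmCIF"):
            write_structure(s, tmp_path / "big.pdb", format="pdb")

    def test_hybrid_model_round_trips(self, tmp_path, hexamer_closed, hexamer_open):
        model, _ = build_hybrid_hemichannel(
            hexamer_closed, hexamer_open,
            AssemblyPattern.from_string("PPPGGG"), anchor=[(1, 15)],
        )
        p = tmp_path / "hybrid.cif"
        write_structure(model, p)
        s2 = read_structure(p)
        assert s2.chains() == list("ABCDEF")
        np.testing.assert_allclose(s2.coords, model.coords, atol=1e-5)


class TestSuperpose:
    def test_self_superposition_is_identity(self, rng):
        s = random_chain_structure(rng)
        res = superpose(s, s)
        assert res.rmsd < 1e-10
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-8)

    def test_recovers_known_rigid_transform(self, rng):
        s = random_chain_structure(rng)
        R = random_rotation(rng)
        t = rng.normal(scale=10.0, size=3)
        moved = s.copy()
        moved.coords = s.coords @ R.T + t
        res = superpose(moved, s)
        assert res.rmsd < 1e-8
        # recovered transform inverts the applied one
        comp = res.transform.compose(RigidTransform(R, t))
        np.testing.assert_allclose(comp.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(comp.translation, 0.0, atol=1e-6)

    def test_rmsd_invariant_under_rigid_pre_transform(self, rng):
        a = random_chain_structure(rng)
        b = random_chain_structure(rng)
        base = superpose(a, b).rmsd
        for seed in range(5):
            r2 = np.random.default_rng(seed)
            pre = RigidTransform(random_rotation(r2), r2.normal(size=3))
            assert abs(superpose(a.transformed(pre), b).rmsd - base) < 1e-8

    def test_too_few_pairs_raises(self, rng):
        a = random_chain_structure(rng, n_res=5)
        b = random_chain_structure(rng, n_res=5)
        b.res_id = b.res_id + 100  # disjoint numbering
        with pytest.raises(ValueError, match="pair"):
            superpose(a, b)


class TestMeanCaDeviation:
    def test_identical_structures_give_zero(self, rng):
        s = random_chain_structure(rng)
        out = mean_ca_deviation(s, s)
        assert out["mean"] < 1e-10 and out["rms"] < 1e-10

    def test_single_displaced_residue_matches_direct_oracle(self, rng):
        """One CA moved 2 A out of 100: mean deviation is the direct distance
        sum after the optimal fit (~2/100 A before the refit spreads it)."""
        a = random_chain_structure(rng, n_res=100)
        b = a.copy()
        b.coords[50] = b.coords[50] + np.array([2.0, 0.0, 0.0])
        out = mean_ca_deviation(a, b)
        # independent oracle: Kabsch on the raw coordinate arrays
        tr = kabsch(a.coords, b.coords)
        dists = np.linalg.norm(tr.apply(a.coords) - b.coords, axis=1)
        assert out["mean"] == pytest.approx(float(dists.mean()), abs=1e-9)
        # without the refit the mean would be exactly 2/100; the refit can
        # only redistribute, keeping the same order of magnitude
        assert 0.01 < out["mean"] < 0.06
        assert out["n_pairs"] == 100

    def test_symmetric_in_arguments_by_number(self, rng):
        a = random_chain_structure(rng)
        b = a.copy()
        b.coords = b.coords + rng.normal(scale=0.5, size=b.coords.shape)
        d_ab = mean_ca_deviation(a, b)["mean"]
        d_ba = mean_ca_deviation(b, a)["mean"]
        assert abs(d_ab - d_ba) < 1e-8

    def test_alignment_pairing_handles_offset_numbering(self, rng):
        a = random_chain_structure(rng, n_res=60)
        b = a.copy()
        b.res_id = b.res_id + 500  # different author numbering, same protein
        out = mean_ca_deviation(a, b, pairing="by_alignment")
        assert out["mean"] < 1e-6
        assert out["n_pairs"] == 60


class TestHybridAssembly:
    def test_all_gcn_pattern_reproduces_template(self, hexamer_closed, hexamer_open):
        model, record = build_hybrid_hemichannel(
            hexamer_closed, hexamer_open,
            AssemblyPattern.from_string("GGGGGG"), anchor=[(1, 15)],
        )
        rmsd = np.sqrt(np.mean(np.sum((model.coords - hexamer_closed.coords) ** 2, axis=1)))
        assert rmsd < 0.05
        assert all(v < 0.05 for v in record["anchor_rmsd"].values())

    def test_rigid_placement_preserves_internal_distances(self, hexamer_closed, hexamer_open):
        model, _ = build_hybrid_hemichannel(
            hexamer_closed, hexamer_open,
            AssemblyPattern.from_string("PPPPPP"), anchor=[(1, 15)],
        )
        donor = hexamer_open.select(chain="C")
        placed = model.select(chain="C")
        d_donor = np.linalg.norm(donor.coords[:, None] - donor.coords[None, :], axis=2)
        d_placed = np.linalg.norm(placed.coords[:, None] - placed.coords[None, :], axis=2)
        np.testing.assert_allclose(d_placed, d_donor, atol=1e-8)

    def test_mixed_pattern_takes_each_donor(self, hexamer_closed, hexamer_open):
        pat = AssemblyPattern.from_string("PPPGGG")
        model, _ = build_hybrid_hemichannel(
            hexamer_closed, hexamer_open, pat, anchor=[(1, 15)]
        )
        assert model.chains() == list("ABCDEF")
        # gate residues (beyond the anchor) sit closer to the axis for GCN donors
        for chain, state in zip("ABCDEF", pat.states):
            gate = model.select(chain=chain, residues=[(30, 30)])
            rho = np.hypot(gate.coords[0, 0], gate.coords[0, 1])
            if state == "GCN":
                assert rho < 8.0
            else:
                assert rho > 10.0

    def test_incompatible_anchor_raises(self, hexamer_closed, hexamer_open, rng):
        warped = hexamer_open.copy()
        warped.coords = warped.coords + rng.normal(scale=3.0, size=warped.coords.shape)
        with pytest.raises(ValueError, match="incompatible"):
            build_hybrid_hemichannel(
                hexamer_closed, warped,
                AssemblyPattern.from_string("PPPPPP"), anchor=[(1, 15)],
            )

    def test_pattern_string_validation(self):
        with pytest.raises(ValueError):
            AssemblyPattern.from_string("PPXGGG")
        with pytest.raises(ValueError):
            AssemblyPattern(("GCN",) * 5)


class TestClashCount:
    @staticmethod
    def brute_force(s, cutoff, interface_only=True):
        pairs = []
        for i in range(len(s)):
            for j in range(i + 1, len(s)):
                same_chain = s.chain_id[i] == s.chain_id[j]
                if interface_only and same_chain:
                    continue
                if not interface_only and same_chain and abs(int(s.res_id[i]) - int(s.res_id[j])) <= 1:
                    continue
                if np.linalg.norm(s.coords[i] - s.coords[j]) <= cutoff:
                    pairs.append((i, j))
        return len(pairs), pairs

    def test_distant_atoms_do_not_clash(self):
        s = Structure(
            serial=[1, 2], atom_name=["CA", "CA"], element=["C", "C"],
            res_name=["ALA", "ALA"], res_id=[1, 1], chain_id=["A", "B"],
            coords=[[0, 0, 0], [5, 0, 0]],
        )
        assert clash_count(s, cutoff=2.2)[0] == 0

    def test_close_pair_identified(self):
        s = Structure(
            serial=[1, 2], atom_name=["CA", "CA"], element=["C", "C"],
            res_name=["ALA", "ALA"], res_id=[1, 1], chain_id=["A", "B"],
            coords=[[0, 0, 0], [1.0, 0, 0]],
        )
        n, pairs = clash_count(s, cutoff=2.2)
        assert n == 1 and pairs == [(0, 1)]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("interface_only", [True, False])
    def test_kdtree_matches_all_pairs_oracle(self, seed, interface_only):
        r = np.random.default_rng(seed)
        n = 120
        s = Structure(
            serial=np.arange(n),
            atom_name=np.array([f"C{i}" for i in range(n)], dtype=object),
            element=np.array(["C"] * n, dtype=object),
            res_name=np.array(["ALA"] * n, dtype=object),
            res_id=np.repeat(np.arange(n // 4) + 1, 4),
            chain_id=np.array(["AB"[i % 2] for i in range(n)], dtype=object),
            coords=r.uniform(0, 12, size=(n, 3)),
        )
        n_fast, pairs_fast = clash_count(s, cutoff=2.2, interface_only=interface_only)
        n_slow, pairs_slow = self.brute_force(s, 2.2, interface_only)
        assert n_fast == n_slow
        assert pairs_fast == pairs_slow

    def test_hybrid_model_has_no_interface_clashes(self, hexamer_closed, hexamer_open):
        model, _ = build_hybrid_hemichannel(
            hexamer_closed, hexamer_open,
            AssemblyPattern.from_string("PGPGPG"), anchor=[(1, 15)],
        )
        n, _ = clash_count(model, cutoff=2.2)
        assert n == self.brute_force(model, 2.2)[0]
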