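"""PDB parsing, PA-CCS, SASA, contacts, compactness and gromos clustering."""

import numpy as np
import pytest

from oligoccs import structure_analysis as sa
from oligoccs import synthetic_data as syn
from oligoccs.structure_analysis import AtomRecord, StructureModel


def _pdb_atom(serial, name, resname, chain, resid, x, y, z, element):
    return (
        f"ATOM  {serial:5d} {name:<4s}{resname:>4s} {chain}{resid:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
    )


MINIMAL_PDB = _pdb_atom(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C") + "\nEND\n"

TWO_MODEL_PDB = "\n".join(
    [
        "MODEL        1",
        _pdb_atom(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, "C"),
        "ENDMDL",
        "MODEL        2",
        _pdb_atom(1, "CA", "GLY", "A", 1, 5.0, 0.0, 0.0, "C"),
        "ENDMDL",
        "END",
    ]
) + "\n"


class TestReadStructure:
    def test_minimal_single_atom(self):
        model = sa.read_structure(MINIMAL_PDB)
        assert len(model.atoms) == 1
        assert model.atoms[0].element == "C"
        assert model.atoms[0].radius == sa.BONDI_RADII["C"]

    def test_second_model_selected_by_frame(self):
        model = sa.read_structure(TWO_MODEL_PDB, frame=2)
        assert model.atoms[0].coordinates == pytest.approx((5.0, 0.0, 0.0))

    def test_three_chain_partition(self):
        lines = []
        serial = 1
        for chain in "ABC":
            for resid in (1, 2):
                lines.append(_pdb_atom(serial, "CA", "ALA", chain, resid,
                                       float(serial), 0.0, 0.0, "C"))
                serial += 1
        model = sa.read_structure("\n".join(lines) + "\nEND\n")
        assert model.chain_ids == ["A", "B", "C"]
        assert len(model.chain_atoms("B")) == 2

    def test_unknown_element_falls_back_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="oligoccs"):
            radius = sa.element_radius("Xx")
        assert radius == sa.FALLBACK_RADIUS
        assert "fallback" in caplog.text

    def test_no_atoms_raises(self):
        with pytest.raises(ValueError):
            sa.read_structure("END\n")

    def test_write_read_round_trip(self):
        structure = syn.generate_sphere_cluster(3, arrangement="chain")
        text = sa.write_structure_pdb(structure)
        back = sa.read_structure(text)
        np.testing.assert_allclose(back.coordinates, structure.coordinates, atol=1e-3)


class TestPaCcs:
    def test_single_sphere_matches_disk_area(self, single_sphere):
        ccs = sa.pa_ccs(single_sphere, n_orientations=2000, seed=1)
        assert ccs == pytest.approx(np.pi * 100.0, rel=0.01)

    def test_coincident_atoms_idempotent(self, single_sphere):
        doubled = StructureModel(single_sphere.atoms * 2)
        a = sa.pa_ccs(single_sphere, 1000, seed=2)
        b = sa.pa_ccs(doubled, 1000, seed=2)
        assert b == pytest.approx(a, rel=1e-12)

    def test_reproducible_for_fixed_seed(self, sphere_pair):
        assert sa.pa_ccs(sphere_pair, 500, seed=3) == sa.pa_ccs(sphere_pair, 500, seed=3)

    def test_probe_radius_inflates_area(self, single_sphere):
        bare = sa.pa_ccs(single_sphere, 1000, probe_radius=0.0, seed=4)
        inflated = sa.pa_ccs(single_sphere, 1000, probe_radius=2.0, seed=4)
        assert inflated == pytest.approx(bare * (12.0 / 10.0) ** 2, rel=0.02)

    def test_rigid_motion_invariance(self, sphere_pair, rng):
        from scipy.spatial.transform import Rotation

        matrix = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        moved = sphere_pair.rotated(matrix).translated([12.0, -5.0, 3.0])
        a = sa.pa_ccs(sphere_pair, 4000, seed=5)
        b = sa.pa_ccs(moved, 4000, seed=6)
        assert b == pytest.approx(a, rel=0.02)

    def test_empty_orientations_raise(self, single_sphere):
        with pytest.raises(ValueError):
            sa.pa_ccs(single_sphere, 0)


class TestShrakeRupley:
    def test_isolated_atom_analytic(self):
        model = StructureModel([AtomRecord("C", (0.0, 0.0, 0.0), 1.7)])
        area = sa.shrake_rupley_sasa(model, 1.4, 960).sum()
        assert area == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=0.02)

    def test_buried_atom_has_zero_area(self):
        import itertools

        shell = [
            AtomRecord("C", tuple(3.0 * np.array(v) / np.linalg.norm(v)), 1.7)
            for v in itertools.product([-1, 0, 1], repeat=3)
            if any(v)
        ]
        model = StructureModel([AtomRecord("C", (0.0, 0.0, 0.0), 1.7)] + shell)
        areas = sa.shrake_rupley_sasa(model, 1.4, 960)
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_atoms_additive(self):
        a = StructureModel([AtomRecord("C", (0.0, 0.0, 0.0), 1.7)])
        b = StructureModel([AtomRecord("O", (50.0, 0.0, 0.0), 1.52)])
        both = StructureModel(a.atoms + b.atoms)
        assert sa.shrake_rupley_sasa(both, 1.4, 960).sum() == pytest.approx(
            sa.shrake_rupley_sasa(a, 1.4, 960).sum() + sa.shrake_rupley_sasa(b, 1.4, 960).sum(),
            rel=1e-12,
        )

    def test_matches_biotite_reference(self, rng):
        """Independent cross-check against the biotite Shrake-Rupley implementation."""
        import biotite.structure as struc

        pts = rng.normal(scale=3.0, size=(25, 3))
        model = StructureModel([AtomRecord("C", tuple(p), 1.7) for p in pts])
        mine = sa.shrake_rupley_sasa(model, 1.4, 960).sum()
        arr = struc.AtomArray(25)
        arr.coord = pts.astype(np.float32)
        arr.element = np.array(["C"] * 25)
        arr.res_id = np.arange(1, 26)
        arr.res_name = np.array(["ALA"] * 25)
        arr.atom_name = np.array(["CA"] * 25)
        arr.chain_id = np.array(["A"] * 25)
        ref = struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii=np.full(25, 1.7)).sum()
        assert mine == pytest.approx(ref, rel=1e-3)

    def test_too_few_points_raise(self, single_sphere):
        with pytest.raises(ValueError):
            sa.shrake_rupley_sasa(single_sphere, 1.4, 16)


class TestHydrophobicRatio:
    @staticmethod
    def _residue(resname, center, n_atoms=3):
        return [
            AtomRecord("C", (center + 0.8 * i, 0.0, 0.0), 1.7,
                       residue_index=int(center), residue_name=resname)
            for i in range(n_atoms)
        ]

    def test_all_hydrophobic_is_one(self):
        model = StructureModel(self._residue("LEU", 0.0) + self._residue("VAL", 10.0))
        assert sa.hydrophobic_sasa_ratio(model) == 1.0

    def test_no_hydrophobic_is_zero(self):
        model = StructureModel(self._residue("SER", 0.0) + self._residue("ASP", 10.0))
        assert sa.hydrophobic_sasa_ratio(model) == 0.0

    def test_alternating_ala_ser_matches_bookkeeping(self):
        atoms = []
        for i, resname in enumerate(["ALA", "SER"] * 3):
            atoms.extend(
                [AtomRecord("C", (4.0 * i, 0.0, 0.0), 1.7,
                            residue_index=i + 1, residue_name=resname)]
            )
        model = StructureModel(atoms)
        areas = sa.shrake_rupley_sasa(model)
        # independent per-residue bookkeeping
        expected = sum(
            areas[i] for i, a in enumerate(model.atoms) if a.residue_name == "ALA"
        ) / areas.sum()
        assert sa.hydrophobic_sasa_ratio(model, areas) == pytest.approx(expected, rel=1e-12)

    def test_one_letter_codes_accepted(self):
        model = StructureModel(self._residue("LEU", 0.0))
        assert sa.hydrophobic_sasa_ratio(model, hydrophobic_residue_set={"L"}) == 1.0


class TestContactMap:
    @staticmethod
    def _toy_structure():
        # 4 residues: two per chain, one heavy atom each at known positions
        coords = {("A", 1): (0.0, 0.0, 0.0), ("A", 2): (10.0, 0.0, 0.0),
                  ("B", 1): (0.0, 7.0, 0.0), ("B", 2): (10.0, 7.0, 0.0)}
        atoms = [
            AtomRecord("C", xyz, 1.7, chain_id=c, residue_index=r, residue_name="GLY")
            for (c, r), xyz in coords.items()
        ]
        return StructureModel(atoms)

    def test_self_distance_is_zero(self):
        matrix, rows, _ = sa.contact_map(self._toy_structure(), "A")
        assert matrix[0, 0] == 0.0

    def test_intra_chain_map_symmetric(self):
        matrix, _, _ = sa.contact_map(self._toy_structure(), "A")
        np.testing.assert_array_equal(matrix, matrix.T)

    def test_matches_brute_force_in_nm(self):
        model = self._toy_structure()
        matrix, rows, cols = sa.contact_map(model, "A", "B")
        coords = model.coordinates
        for i, ri in enumerate(rows):
            for j, rj in enumerate(cols):
                ai = [k for k, a in enumerate(model.atoms) if a.chain_id == "A" and a.residue_index == ri]
                aj = [k for k, a in enumerate(model.atoms) if a.chain_id == "B" and a.residue_index == rj]
                brute = min(
                    np.linalg.norm(coords[p] - coords[q]) for p in ai for q in aj
                ) / 10.0
                assert matrix[i, j] == pytest.approx(brute, rel=1e-12)

    def test_hydrogens_excluded(self):
        atoms = [
            AtomRecord("C", (0.0, 0.0, 0.0), 1.7, residue_index=1, residue_name="GLY"),
            AtomRecord("H", (0.0, 1.0, 0.0), 1.2, residue_index=1, residue_name="GLY"),
            AtomRecord("C", (0.0, 5.0, 0.0), 1.7, residue_index=2, residue_name="GLY"),
        ]
        matrix, _, _ = sa.contact_map(StructureModel(atoms), "A")
        assert matrix[0, 1] == pytest.approx(0.5)  # C-C distance, not the closer H

    def test_unknown_chain_raises(self):
        with pytest.raises(ValueError):
            sa.contact_map(self._toy_structure(), "Z")


class TestCompactness:
    @staticmethod
    def _packed_ball():
        atoms = [
            AtomRecord("C", (float(x), float(y), float(z)), 1.7)
            for x in range(-4, 5, 2) for y in range(-4, 5, 2) for z in range(-4, 5, 2)
            if x * x + y * y + z * z <= 25
        ]
        return StructureModel(atoms)

    def test_packed_sphere_scores_high(self):
        assert sa.compactness(self._packed_ball(), seed=1) >= 0.9

    def test_elongation_lowers_score(self):
        ball = self._packed_ball()
        line = StructureModel(
            [AtomRecord("C", (3.0 * i, 0.0, 0.0), 1.7) for i in range(len(ball.atoms))]
        )
        assert sa.compactness(line, seed=1) < sa.compactness(ball, seed=1)

    def test_bounded_on_random_structures(self, rng):
        for _ in range(20):
            pts = rng.normal(scale=4.0, size=(6, 3))
            model = StructureModel([AtomRecord("C", tuple(p), 1.7) for p in pts])
            score = sa.compactness(model, points_per_atom=194, n_volume_samples=20_000, seed=2)
            assert 0.0 <= score <= 1.0


class TestDauraCluster:
    @staticmethod
    def _two_conformers(rng, n_frames_a=4, n_frames_b=3):
        line = np.column_stack([np.arange(8) * 3.0, np.zeros(8), np.zeros(8)])
        angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        ring = np.column_stack([4.0 * np.cos(angles), 4.0 * np.sin(angles), np.zeros(8)])
        frames = [line + rng.normal(scale=0.05, size=(8, 3)) for _ in range(n_frames_a)]
        frames += [ring + rng.normal(scale=0.05, size=(8, 3)) for _ in range(n_frames_b)]
        return frames

    def test_rmsd_matches_mdanalysis_reference(self, rng):
        from MDAnalysis.analysis import rms

        a = rng.normal(size=(12, 3))
        b = rng.normal(size=(12, 3))
        ref = rms.rmsd(a, b, center=True, superposition=True)
        assert sa.superposed_rmsd(a, b) == pytest.approx(ref, rel=1e-6)

    def test_identical_frames_one_cluster(self):
        frame = np.arange(24, dtype=float).reshape(8, 3)
        result = sa.daura_cluster([frame.copy() for _ in range(5)], cutoff=0.4)
        assert result.sizes == [5]
        assert np.all(result.assignments == 0)

    def test_two_separated_conformer_groups(self, rng):
        frames = self._two_conformers(rng)
        result = sa.daura_cluster(frames, cutoff=0.4)
        assert result.sizes == [4, 3]
        assert len(set(result.assignments[:4])) == 1
        assert len(set(result.assignments[4:])) == 1

    def test_matches_brute_force_oracle(self, rng):
        """Independent re-implementation of the algorithm on 6 frames."""
        frames = [rng.normal(scale=2.0, size=(5, 3)) for _ in range(6)]
        rmsd_nm = sa.pairwise_rmsd_matrix(frames) / 10.0
        cutoff = float(np.median(rmsd_nm[np.triu_indices(6, 1)]))

        # brute force: literal restatement of the published procedure
        remaining = set(range(6))
        expected_clusters = []
        while remaining:
            best, best_count = None, -1
            for i in sorted(remaining):
                count = sum(1 for j in remaining if rmsd_nm[i, j] <= cutoff)
                if count > best_count:
                    best, best_count = i, count
            members = sorted(j for j in remaining if rmsd_nm[best, j] <= cutoff)
            expected_clusters.append((best, members))
            remaining -= set(members)

        result = sa.daura_cluster(frames, cutoff=cutoff)
        got = sorted(zip(result.centers, result.sizes))
        exp = sorted((c, len(m)) for c, m in expected_clusters)
        assert got == exp

    def test_frame_order_invariance_up_to_tiebreak(self, rng):
        frames = self._two_conformers(rng)
        reordered = frames[::-1]
        a = sa.daura_cluster(frames, cutoff=0.4)
        b = sa.daura_cluster(reordered, cutoff=0.4)
        assert sorted(a.sizes) == sorted(b.sizes)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            sa.daura_cluster([])

    def test_mismatched_atom_counts_raise(self):
        with pytest.raises(ValueError):
            sa.daura_cluster([np.zeros((3, 3)), np.zeros((4, 3))])
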