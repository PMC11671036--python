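from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from confland.errors import ArgumentError, FormatError, SelectionError
from confland.fixtures import TwoStateStructureSpec, make_two_state_structures
from confland.structure import (
    AtomRecord,
    Chain,
    Residue,
    ResidueSelection,
    StateCall,
    StructureModel,
    classify_state,
    kabsch_rmsd,
    landscape_summary,
    landscape_table,
    rank_top_fraction,
    read_structure,
    reference_gap_rmsd,
    rmsd_to_references,
    superposed_rmsd,
    write_structure,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 80.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00 82.00           C
ATOM      3  CA  GLY A   2       3.000   1.000   0.000  1.00 70.00           C
ATOM      4  CA  SER A   3       4.500   2.000   1.000  1.00 60.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 50.00           C
ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.60 55.00           C
END
"""


class TestPdbIO:
    def test_minimal_parse(self, tmp_path):
        path = tmp_path / "m.pdb"
        path.write_text(MINIMAL_PDB)
        model = read_structure(path)
        chain = model.chain("A")
        assert [r.resseq for r in chain.residues] == [1, 2, 3]
        assert chain.residues[0].plddt == pytest.approx(81.0)  # mean of N and CA
        assert chain.residues[2].plddt == pytest.approx(60.0)

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        model = read_structure(path)
        (res,) = model.chain("A").residues
        assert len(res.atoms) == 1
        assert res.atoms[0].xyz == (9.0, 9.0, 9.0)

    def test_no_atoms_is_format_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(FormatError):
            read_structure(path)

    def test_round_trip_pdb_precision(self, tmp_path, reference_pair):
        path = tmp_path / "ref.pdb"
        write_structure(reference_pair.ref_active, path)
        back = read_structure(path)
        a = reference_pair.selection.resolve(reference_pair.ref_active)
        b = reference_pair.selection.resolve(back)
        assert np.abs(a - b).max() < 1.5e-3  # PDB stores 3 decimals
        assert back.chain("A").residues[0].plddt == pytest.approx(100.0)


def _random_cloud(seed, n=10):
    return np.random.default_rng(seed).normal(size=(n, 3))


class TestKabsch:
    def test_identity_zero(self):
        p = _random_cloud(0)
        assert kabsch_rmsd(p, p)[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_invariance(self, seed):
        p = _random_cloud(seed)
        rot = Rotation.random(random_state=seed).as_matrix()
        q = p @ rot.T + np.array([5.0, -3.0, 2.0])
        assert kabsch_rmsd(p, q)[0] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry(self, seed):
        p, q = _random_cloud(seed), _random_cloud(seed + 100)
        assert kabsch_rmsd(p, q)[0] == pytest.approx(kabsch_rmsd(q, p)[0], abs=1e-9)

    def test_rotation_is_proper(self):
        # mirror-image cloud: the reflection must NOT be used
        p = _random_cloud(3)
        q = p.copy()
        q[:, 0] *= -1
        rmsd, R, _t = kabsch_rmsd(p, q)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert rmsd > 0.1

    def test_transform_maps_p_onto_q(self):
        p = _random_cloud(4)
        rot = Rotation.random(random_state=4).as_matrix()
        q = p @ rot.T + 1.0
        _rmsd, R, t = kabsch_rmsd(p, q)
        assert np.allclose(p @ R.T + t, q, atol=1e-9)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ArgumentError):
            kabsch_rmsd(_random_cloud(0, 10), _random_cloud(0, 9))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_align_vectors(self, seed):
        p, q = _random_cloud(seed), _random_cloud(seed + 50)
        rot, rssd = Rotation.align_vectors(
            q - q.mean(0), p - p.mean(0)
        )
        expected = rssd / np.sqrt(len(p))
        assert kabsch_rmsd(p, q)[0] == pytest.approx(expected, abs=1e-9)


class TestSelections:
    def test_missing_residue_names_chain_and_resseq(self, reference_pair):
        sel = ResidueSelection((("A", 79, 99),), "CA")
        with pytest.raises(SelectionError, match="chain A residue 81"):
            sel.resolve(reference_pair.ref_active)

    def test_missing_chain(self, reference_pair):
        with pytest.raises(SelectionError, match="chain"):
            ResidueSelection((("B", 1, 5),)).resolve(reference_pair.ref_active)

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ArgumentError, match="overlap"):
            ResidueSelection((("A", 1, 10), ("A", 5, 12)))

    def test_start_after_end_rejected(self):
        with pytest.raises(ArgumentError):
            ResidueSelection((("A", 9, 3),))

    def test_atom_subsets(self):
        res = Residue(
            1,
            "ALA",
            (
                AtomRecord("N", "N", (0.0, 0.0, 0.0)),
                AtomRecord("CA", "C", (1.0, 0.0, 0.0)),
                AtomRecord("C", "C", (2.0, 0.0, 0.0)),
                AtomRecord("O", "O", (3.0, 0.0, 0.0)),
                AtomRecord("CB", "C", (4.0, 0.0, 0.0)),
                AtomRecord("H", "H", (5.0, 0.0, 0.0)),
            ),
        )
        model = StructureModel((Chain("A", (res,)),))
        assert len(ResidueSelection((("A", 1, 1),), "CA").resolve(model)) == 1
        assert len(ResidueSelection((("A", 1, 1),), "backbone").resolve(model)) == 4
        assert len(ResidueSelection((("A", 1, 1),), "all-heavy").resolve(model)) == 5


class TestRmsdToReferences:
    def test_model_equals_active_reference(self, reference_pair):
        gap = reference_pair.gap()
        ra, ri = rmsd_to_references(
            reference_pair.ref_active,
            reference_pair.ref_active,
            reference_pair.ref_inactive,
            reference_pair.selection,
        )
        assert ra == pytest.approx(0.0, abs=1e-9)
        assert ri == pytest.approx(gap, abs=1e-9)

    def test_model_equals_inactive_reference(self, reference_pair):
        gap = reference_pair.gap()
        ra, ri = rmsd_to_references(
            reference_pair.ref_inactive,
            reference_pair.ref_active,
            reference_pair.ref_inactive,
            reference_pair.selection,
        )
        assert ra == pytest.approx(gap, abs=1e-9)
        assert ri == pytest.approx(0.0, abs=1e-9)

    def test_midpoint_structure_equidistant(self, reference_pair):
        # the coordinate average of the references is exactly equidistant
        # in a shared frame; an independent refit onto each reference may
        # break the tie, so the symmetry is asserted without refitting
        a = reference_pair.template_coords("active")
        i = reference_pair.template_coords("inactive")
        mid = (a + i) / 2.0
        rmsd_a = superposed_rmsd(mid, a, fit_P=a, fit_Q=a)
        rmsd_i = superposed_rmsd(mid, i, fit_P=a, fit_Q=a)
        assert rmsd_a == pytest.approx(rmsd_i, abs=1e-9)
        assert rmsd_a > 1.0  # the midpoint is genuinely between the states

    def test_fit_on_whole_differs_from_selection_fit(self, reference_pair):
        # fitting on the whole chain, the displaced-segment RMSD must not
        # shrink below the selection-fitted value for the displaced tail
        n = reference_pair.spec.n_residues
        seg = ResidueSelection((("A", reference_pair.segment_start + 1, n),), "CA")
        ra_sel, _ = rmsd_to_references(
            reference_pair.ref_inactive,
            reference_pair.ref_active,
            reference_pair.ref_inactive,
            seg,
            fit_on="selection",
        )
        ra_whole, _ = rmsd_to_references(
            reference_pair.ref_inactive,
            reference_pair.ref_active,
            reference_pair.ref_inactive,
            seg,
            fit_on="whole",
        )
        assert ra_whole > ra_sel  # rigid translation is invisible to a local fit


class TestReferenceGap:
    def test_identical_references_zero(self, reference_pair):
        assert reference_gap_rmsd(
            reference_pair.ref_active,
            reference_pair.ref_active,
            reference_pair.selection,
        ) == pytest.approx(0.0, abs=1e-12)

    def test_calibrated_gap(self, reference_pair):
        gap = reference_gap_rmsd(
            reference_pair.ref_active,
            reference_pair.ref_inactive,
            reference_pair.selection,
        )
        assert gap == pytest.approx(5.0, abs=1e-6)


class TestRanking:
    def _calls(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return [
            StateCall(
                f"m{i:04d}",
                1.0,
                2.0,
                float(rng.uniform(50, 95)),
                float(rng.uniform(0, 1)),
                "active",
                "argmin_excl3",
            )
            for i in range(n)
        ]

    def test_ceil_arithmetic_230(self):
        assert len(rank_top_fraction(self._calls(230), "iptm", 0.10)) == 23

    def test_full_fraction_sorted(self):
        top = rank_top_fraction(self._calls(20), "plddt", 1.0)
        assert len(top) == 20
        values = [c.mean_plddt for c in top]
        assert values == sorted(values, reverse=True)

    def test_order_invariance(self):
        calls = self._calls(50)
        rng = np.random.default_rng(1)
        shuffled = [calls[i] for i in rng.permutation(50)]
        assert rank_top_fraction(calls, "iptm", 0.1) == rank_top_fraction(
            shuffled, "iptm", 0.1
        )

    def test_subset_of_input(self):
        calls = self._calls(37)
        top = rank_top_fraction(calls, "plddt", 0.25)
        assert len(top) == int(np.ceil(0.25 * 37))
        assert set(c.model_id for c in top) <= set(c.model_id for c in calls)

    def test_missing_iptm_rejected(self):
        calls = self._calls(5)
        calls[2] = StateCall("x", 1.0, 2.0, 80.0, None, "active", "argmin_excl3")
        with pytest.raises(ArgumentError):
            rank_top_fraction(calls, "iptm", 0.5)


class TestLandscapeSummary:
    def _mixed(self):
        mk = lambda i, s: StateCall(f"m{i}", 1.0, 2.0, 80.0, None, s, "argmin_excl3")
        calls = [mk(i, "active") for i in range(75)]
        calls += [mk(75 + i, "inactive") for i in range(18)]
        calls += [mk(93 + i, "excluded") for i in range(7)]
        return calls

    def test_percentages_mirror_counts(self):
        summary = landscape_summary(self._mixed())
        assert summary.loc["active", "percent"] == 75.0
        assert summary.loc["inactive", "percent"] == 18.0
        assert summary.loc["excluded", "percent"] == 7.0
        assert summary["percent"].sum() == pytest.approx(100.0)

    def test_permutation_invariant(self):
        calls = self._mixed()
        rng = np.random.default_rng(0)
        shuffled = [calls[i] for i in rng.permutation(len(calls))]
        assert landscape_summary(calls).equals(landscape_summary(shuffled))

    def test_table_one_row_per_model(self):
        table = landscape_table(self._mixed())
        assert len(table) == 100
        assert set(table.columns) == {
            "model",
            "rmsd_active",
            "rmsd_inactive",
            "plddt",
            "iptm",
            "state",
        }
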