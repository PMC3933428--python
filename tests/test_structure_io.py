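import io

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bivalens.errors import (EmptySelectionError, FormatError, PDBParseError,
                             RadiusAssignmentError, TopologyError)
from bivalens.structure_io import (DEFAULT_RADII, Ensemble, Selection,
                                   Structure, assign_radii,
                                   read_radius_table, read_pdb,
                                   resolve_selection, write_pdb)

ATOM_BLOCK = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   2      12.759   7.113  -4.973  1.00  0.00           C
"""


def make_structure(n=5, chain="A", seed=0):
    rng = np.random.default_rng(seed)
    return Structure(
        serial=np.arange(1, n + 1),
        atom_name=np.array(["CA"] * n),
        res_name=np.array(["GLY"] * n),
        chain_id=np.array([chain] * n),
        res_id=np.arange(1, n + 1),
        icode=np.array([""] * n),
        element=np.array(["C"] * n),
        coord=rng.uniform(-50, 50, size=(n, 3)),
    )


class TestReadPdb:
    def test_atom_block_echoes_coordinates(self):
        st_ = read_pdb(io.StringIO(ATOM_BLOCK))
        assert isinstance(st_, Structure)
        assert len(st_) == 3
        np.testing.assert_allclose(
            st_.coord[0], [11.104, 6.134, -6.504], atol=1e-3)
        assert st_.atom_name.tolist() == ["N", "CA", "C"]
        assert st_.res_id.tolist() == [1, 1, 2]
        assert st_.chain_id.tolist() == ["A", "A", "A"]

    def test_duplicated_model_gives_two_identical_frames(self):
        text = (f"MODEL        1\n{ATOM_BLOCK}ENDMDL\n"
                f"MODEL        2\n{ATOM_BLOCK}ENDMDL\n")
        ens = read_pdb(io.StringIO(text), model_policy="all")
        assert isinstance(ens, Ensemble)
        assert len(ens) == 2
        np.testing.assert_array_equal(ens.frames[0].coord,
                                      ens.frames[1].coord)

    def test_permuted_atom_order_between_models_is_topology_error(self):
        lines = ATOM_BLOCK.splitlines(keepends=True)
        permuted = "".join([lines[1], lines[0], lines[2]])
        text = (f"MODEL        1\n{ATOM_BLOCK}ENDMDL\n"
                f"MODEL        2\n{permuted}ENDMDL\n")
        with pytest.raises(TopologyError):
            read_pdb(io.StringIO(text), model_policy="all")

    def test_malformed_coordinate_names_line_number(self):
        bad = ATOM_BLOCK.replace("11.639", "11.6x9")
        with pytest.raises(PDBParseError, match="line 2"):
            read_pdb(io.StringIO(bad))

    def test_hetatm_and_water_excluded_by_default(self):
        text = ATOM_BLOCK + (
            "HETATM    4 ZN    ZN A 101      10.000  10.000  10.000"
            "  1.00  0.00          ZN\n"
            "ATOM      5  O   HOH A 201       1.000   2.000   3.000"
            "  1.00  0.00           O\n")
        st_ = read_pdb(io.StringIO(text))
        assert len(st_) == 3
        st_with = read_pdb(io.StringIO(text), include_hetero=True)
        assert "ZN" in st_with.res_name.tolist()
        assert "HOH" not in st_with.res_name.tolist()

    def test_altloc_resolved_to_highest_occupancy_tie_first(self):
        text = (
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000"
            "  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       2.000   0.000   0.000"
            "  0.60  0.00           C\n"
            "ATOM      3  CB AALA A   1       3.000   0.000   0.000"
            "  0.50  0.00           C\n"
            "ATOM      4  CB BALA A   1       4.000   0.000   0.000"
            "  0.50  0.00           C\n")
        st_ = read_pdb(io.StringIO(text))
        assert len(st_) == 2
        assert st_.coord[st_.atom_name == "CA"][0][0] == pytest.approx(2.0)
        assert st_.coord[st_.atom_name == "CB"][0][0] == pytest.approx(3.0)


class TestWritePdb:
    @given(st.integers(min_value=1, max_value=40),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_round_trip_identity(self, n, seed):
        original = make_structure(n=n, seed=seed)
        buf = io.StringIO()
        write_pdb(original, buf)
        again = read_pdb(io.StringIO(buf.getvalue()))
        np.testing.assert_allclose(again.coord, original.coord, atol=1e-3)
        assert again.identity() == original.identity()
        assert again.res_name.tolist() == original.res_name.tolist()
        assert again.element.tolist() == original.element.tolist()

    def test_ensemble_writes_model_blocks(self):
        frames = [make_structure(seed=0) for _ in range(3)]
        ens = Ensemble(frames=frames)
        buf = io.StringIO()
        write_pdb(ens, buf)
        text = buf.getvalue()
        assert text.count("MODEL") - text.count("ENDMDL") == 0
        assert text.count("ENDMDL") == 3
        again = read_pdb(io.StringIO(text), model_policy="all")
        assert len(again) == 3

    def test_coordinate_overflow_is_format_error(self):
        st_ = make_structure()
        st_.coord[0, 0] = 10000.0
        with pytest.raises(FormatError):
            write_pdb(st_, io.StringIO())

    def test_long_chain_id_is_format_error(self):
        st_ = make_structure()
        st_.chain_id = np.array(["AB"] * len(st_), dtype="U4")
        with pytest.raises(FormatError):
            write_pdb(st_, io.StringIO())


class TestSelections:
    @pytest.fixture
    def two_chain(self):
        rng = np.random.default_rng(7)
        n = 20
        return Structure(
            serial=np.arange(1, n + 1),
            atom_name=np.array(["CA", "CB"] * (n // 2)),
            res_name=np.array(["GLY"] * n),
            chain_id=np.array(["A"] * 10 + ["B"] * 10),
            res_id=np.array(list(range(1, 11)) + list(range(1, 11))),
            icode=np.array([""] * n),
            element=np.array(["C"] * n),
            coord=rng.normal(size=(n, 3)),
        )

    def test_chain_only(self, two_chain):
        idx = resolve_selection(two_chain, Selection.make(chains=["A"]))
        assert idx.tolist() == list(range(10))

    def test_residue_range_is_stalk_exclusion_pattern(self, two_chain):
        idx = resolve_selection(
            two_chain, Selection.make(chains=["A"], residues=[(1, 6)]))
        assert np.all(two_chain.res_id[idx] <= 6)
        assert np.all(two_chain.chain_id[idx] == "A")

    def test_atom_names(self, two_chain):
        idx = resolve_selection(two_chain, Selection.make(atoms=["CA"]))
        assert np.all(two_chain.atom_name[idx] == "CA")
        assert len(idx) == 10

    def test_intersection_semantics(self, two_chain):
        idx = resolve_selection(two_chain, Selection.make(
            chains=["B"], residues=[(2, 4)], atoms=["CA"]))
        assert np.all(two_chain.chain_id[idx] == "B")
        assert np.all((two_chain.res_id[idx] >= 2)
                      & (two_chain.res_id[idx] <= 4))
        assert np.all(two_chain.atom_name[idx] == "CA")

    def test_empty_selection_raises(self, two_chain):
        with pytest.raises(EmptySelectionError):
            resolve_selection(two_chain, Selection.make(chains=["Z"]))

    def test_indices_strictly_increasing_and_idempotent(self, two_chain):
        sel = Selection.make(residues=[(3, 8)])
        idx = resolve_selection(two_chain, sel)
        assert np.all(np.diff(idx) > 0)
        np.testing.assert_array_equal(
            idx, resolve_selection(two_chain, sel))

    @given(split=st.integers(min_value=1, max_value=9))
    def test_partition_union_equals_full_chain(self, two_chain, split):
        full = resolve_selection(two_chain, Selection.make(chains=["A"]))
        lo = resolve_selection(two_chain, Selection.make(
            chains=["A"], residues=[(1, split)]))
        hi = resolve_selection(two_chain, Selection.make(
            chains=["A"], residues=[(split + 1, 10)]))
        assert sorted(set(lo) | set(hi)) == full.tolist()
        assert not set(lo) & set(hi)


class TestRadii:
    def test_table_assignment(self):
        st_ = make_structure()
        out = assign_radii(st_, {"C": 1.70})
        assert np.all(out.radius == 1.70)
        np.testing.assert_array_equal(out.coord, st_.coord)
        assert st_.radius is None  # original untouched

    def test_unknown_element_without_default_raises(self):
        st_ = make_structure()
        st_.element = np.array(["X"] * len(st_), dtype="U2")
        with pytest.raises(RadiusAssignmentError):
            assign_radii(st_, {"C": 1.70})

    def test_unknown_element_with_default_warns_and_assigns(self, caplog):
        st_ = make_structure()
        st_.element = np.array(["X"] * len(st_), dtype="U2")
        with caplog.at_level("WARNING"):
            out = assign_radii(st_, {"C": 1.70}, default=1.50)
        assert np.all(out.radius == 1.50)
        assert "default" in caplog.text

    def test_radius_table_io(self, tmp_path):
        path = tmp_path / "radii.txt"
        path.write_text("# element radius\nC 1.70\nN 1.55\n")
        table = read_radius_table(path)
        assert table == {"C": 1.70, "N": 1.55}

    def test_default_table_has_standard_values(self):
        assert DEFAULT_RADII["C"] == 1.70
        assert DEFAULT_RADII["H"] == 1.20


class TestEnsembleInvariants:
    def test_mismatched_topology_rejected(self):
        a = make_structure(n=5)
        b = make_structure(n=5)
        b.atom_name = np.array(["CB"] * 5)
        with pytest.raises(TopologyError):
            Ensemble(frames=[a, b])

    def test_frame_times_length_checked(self):
        frames = [make_structure(), make_structure()]
        with pytest.raises(ValueError):
            Ensemble(frames=frames, frame_times=np.array([0.0]))
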