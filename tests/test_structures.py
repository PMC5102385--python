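import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gagfold.structures import (
    ChainBreakWarning,
    StructureModel,
    assign_ss,
    load_ca_model,
    segment_list,
    ss_composition,
    write_ca_pdb,
)
from gagfold.synthetic_data import build_ideal_helix

from conftest import random_rigid_transform


PDB_THREE_CA = """\
ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00  0.00           C
ATOM      2  CA  GLY A   2      12.560   8.100  -4.200  1.00  0.00           C
ATOM      3  CA  SER A   3      14.000  10.000  -2.000  1.00  0.00           C
END
"""

PDB_TWO_MODELS = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1      99.000  99.000  99.000  1.00  0.00           C
ATOM      2  CA  GLY A   2      95.000  99.000  99.000  1.00  0.00           C
ENDMDL
END
"""

PDB_HETATM_ONLY = """\
HETATM    1  CA  CA  A 101      10.000  10.000  10.000  1.00  0.00          CA
END
"""


class TestLoadCaModel:
    def test_parses_ca_records_in_order(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(PDB_THREE_CA)
        model = load_ca_model(p)
        assert len(model) == 3
        np.testing.assert_allclose(model.ca_coords[0], [11.104, 6.134, -6.504])
        np.testing.assert_allclose(model.ca_coords[2], [14.0, 10.0, -2.0])

    def test_first_model_only(self, tmp_path):
        p = tmp_path / "two_models.pdb"
        p.write_text(PDB_TWO_MODELS)
        model = load_ca_model(p)
        assert len(model) == 2
        np.testing.assert_allclose(model.ca_coords[0], [0.0, 0.0, 0.0])

    def test_hetatm_only_is_empty(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(PDB_HETATM_ONLY)
        with pytest.raises(ValueError, match="empty structure"):
            load_ca_model(p)

    def test_unknown_chain(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(PDB_THREE_CA)
        with pytest.raises(ValueError, match="unknown chain"):
            load_ca_model(p, chain="Z")

    def test_chain_break_warns_not_errors(self, tmp_path):
        p = tmp_path / "broken.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2      10.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        with pytest.warns(ChainBreakWarning):
            model = load_ca_model(p)
        assert len(model) == 2

    def test_roundtrip_through_writer(self, tmp_path, n_bundle):
        out = tmp_path / "bundle.pdb"
        write_ca_pdb(n_bundle, out)
        back = load_ca_model(out)
        np.testing.assert_allclose(back.ca_coords, n_bundle.ca_coords, atol=1.5e-3)


class TestAssignSS:
    def test_ideal_helix_interior_is_helical(self):
        model = build_ideal_helix(12)
        assert model.ss[2:-2].count("H") >= 8 - 2  # well inside the windows
        assert model.ss.count("H") >= 8

    def test_straight_chain_has_no_helix(self):
        coords = np.column_stack([np.arange(12) * 3.8, np.zeros(12), np.zeros(12)])
        model = assign_ss(StructureModel("line", [str(i) for i in range(12)], coords))
        assert "H" not in model.ss  # d(i,i+2) = 7.6 Å fits neither window

    def test_short_chain_all_coil(self):
        coords = np.column_stack([np.arange(4) * 3.8, np.zeros(4), np.zeros(4)])
        model = assign_ss(StructureModel("tiny", list("abcd"), coords))
        assert model.ss == "CCCC"

    def test_rigid_motion_invariance(self, n_bundle, rng):
        rot, trans = random_rigid_transform(rng)
        moved = dataclasses.replace(n_bundle, ca_coords=n_bundle.ca_coords @ rot.T + trans)
        assert assign_ss(moved).ss == assign_ss(n_bundle).ss


class TestSSComposition:
    @pytest.mark.parametrize(
        "ss,counts",
        [("HHHHCCC", {"H": 4, "C": 3, "E": 0}), ("HHHH", {"H": 4, "C": 0, "E": 0})],
    )
    def test_counts_and_fractions(self, ss, counts):
        comp = ss_composition(ss)
        assert comp.counts == counts
        assert not comp.undefined
        assert sum(comp.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert comp.fractions["H"] == pytest.approx(counts["H"] / len(ss))

    def test_empty_string_flagged_undefined(self):
        comp = ss_composition("")
        assert comp.undefined
        assert sum(comp.counts.values()) == 0

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet="HEC", min_size=1, max_size=200))
    def test_counts_fractions_consistent_for_any_string(self, ss):
        comp = ss_composition(ss)
        assert sum(comp.counts.values()) == len(ss)
        assert sum(comp.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert "".join(c * n for c, n in segment_list(ss)) == ss

    def test_segment_list_roundtrip(self):
        ss = "HHHHCCEEEC"
        segs = segment_list(ss)
        assert segs == [("H", 4), ("C", 2), ("E", 3), ("C", 1)]
        assert "".join(c * n for c, n in segs) == ss
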