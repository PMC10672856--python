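"""Structure and sequence I/O: trace extraction, gap handling, round-trips."""

import numpy as np
import pytest

import knotaudit as ka
from knotaudit.structure_io import EmptyChainError, StructureFormatError
from knotaudit.types import CATrace

ALTLOC_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 81.30           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00 79.00           C
ATOM      3  CA AALA A   3       7.600   0.000   0.000  0.30 75.00           C
ATOM      4  CA BALA A   3       7.600   0.500   0.000  0.70 76.00           C
ATOM      5  CA  ALA A   4      11.400   0.000   0.000  1.00 74.00           C
ATOM      6  CA  ALA A   5      15.200   0.000   0.000  1.00 72.50           C
END
"""


def test_read_minimal_pdb_and_plddt(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(ALTLOC_PDB)
    traces = ka.read_structure(str(path))
    assert len(traces) == 1
    tr = traces[0]
    assert len(tr) == 5
    assert list(tr.residue_numbers) == [1, 2, 3, 4, 5]
    # altloc resolved to highest occupancy (B, occ 0.70, b=76.0)
    assert tr.plddt is not None
    assert tr.plddt[2] == pytest.approx(76.0)
    assert tr.plddt[0] == pytest.approx(81.3)
    assert not tr.broken


def test_bfactor_outside_plddt_range_disables_confidence(tmp_path):
    text = ALTLOC_PDB.replace(" 81.30", "181.3")
    path = tmp_path / "bfac.pdb"
    path.write_text(text)
    tr = ka.read_structure(str(path))[0]
    assert tr.plddt is None


def test_missing_chain_raises(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(ALTLOC_PDB)
    with pytest.raises(EmptyChainError):
        ka.read_structure(str(path), chain="Z")


def test_unreadable_file_raises():
    with pytest.raises(StructureFormatError):
        ka.read_structure("/nonexistent/file.pdb")


def test_chain_selection_order_independent(two_chain_pdb):
    all_traces = {t.chain_id: t for t in ka.read_structure(str(two_chain_pdb))}
    a = ka.read_structure(str(two_chain_pdb), chain="A")[0]
    b = ka.read_structure(str(two_chain_pdb), chain="B")[0]
    np.testing.assert_allclose(all_traces["A"].coords, a.coords)
    np.testing.assert_allclose(all_traces["B"].coords, b.coords)


def test_pdb_write_read_roundtrip(tmp_path, trefoil_trace):
    path = tmp_path / "synthetic.pdb"
    ka.write_trace_pdb(trefoil_trace, str(path))
    back = ka.read_structure(str(path))[0]
    np.testing.assert_allclose(
        back.coords, trefoil_trace.coords, atol=1e-3
    )


def test_mmcif_read(tmp_path, trefoil_trace):
    import gemmi

    pdb_path = tmp_path / "t.pdb"
    ka.write_trace_pdb(trefoil_trace, str(pdb_path))
    st = gemmi.read_structure(str(pdb_path))
    st.setup_entities()
    cif_path = tmp_path / "t.cif"
    st.make_mmcif_document().write_file(str(cif_path))
    back = ka.read_structure(str(cif_path))[0]
    np.testing.assert_allclose(back.coords, trefoil_trace.coords, atol=1e-3)


class TestBridgeGaps:
    def _trace(self, resnums):
        coords = np.column_stack(
            [3.8 * np.asarray(resnums, float), np.zeros(len(resnums)),
             np.zeros(len(resnums))]
        )
        return CATrace("A", np.array(resnums), coords)

    def test_short_gap_interpolated(self):
        tr = self._trace([7, 8, 9, 12, 13])  # residues 10-11 missing
        out = ka.bridge_gaps(tr, max_bridge=3)
        assert list(out.residue_numbers) == [7, 8, 9, 10, 11, 12, 13]
        assert not out.broken
        # interpolation is linear
        np.testing.assert_allclose(out.coords[3], [3.8 * 10, 0, 0])

    def test_long_gap_flags_broken(self):
        tr = self._trace([1, 2, 3, 34, 35])
        out = ka.bridge_gaps(tr, max_bridge=3)
        assert out.broken

    def test_gap_free_unchanged(self):
        tr = self._trace([1, 2, 3, 4])
        out = ka.bridge_gaps(tr, max_bridge=3)
        assert out is tr or np.allclose(out.coords, tr.coords)

    def test_broken_trace_refused_by_topology(self):
        tr = self._trace([1, 2, 3, 34, 35])
        out = ka.bridge_gaps(tr, max_bridge=3)
        from knotaudit.topology import BrokenTraceError

        with pytest.raises(BrokenTraceError):
            ka.classify_knot(out, n_closures=5, seed=1)


class TestFasta:
    def test_roundtrip(self, tmp_path):
        recs = [
            ka.SequenceRecord("a", "MKVLA"),
            ka.SequenceRecord("b", "GGGGS"),
            ka.SequenceRecord("c", "WYFHK"),
        ]
        path = tmp_path / "x.fasta"
        ka.write_fasta(recs, str(path))
        back = ka.read_fasta(str(path))
        assert [r.id for r in back] == ["a", "b", "c"]
        assert [r.sequence for r in back] == [r.sequence for r in recs]

    def test_noncanonical_letter_rejected(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">x\nMKXVA\n")
        with pytest.raises(ValueError, match="non-canonical"):
            ka.read_fasta(str(path))

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError):
            ka.read_fasta(str(path))


def test_span_parsing_and_length():
    assert ka.parse_span("Arg74-Phe99") == (74, 99)
    assert ka.parse_span("74-99") == (74, 99)
    assert ka.residue_span_length(74, 99) == 26
    with pytest.raises(ValueError):
        ka.parse_span("Xyz74-Phe99")
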