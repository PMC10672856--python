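"""Reading and writing structures and sequences.

PDB and mmCIF parsing is delegated to gemmi; FASTA to Biopython.  Only
polymer C-alpha atoms are used for traces: hetero compounds and waters are
dropped, alternate locations are resolved to the highest-occupancy conformer
(first on ties).  The B-factor column is interpreted as pLDDT only when every
value lies in [0, 100], the convention AlphaFold-style predictors use;
otherwise confidence annotations are disabled for that trace rather than
risking a misread of crystallographic B-factors.
"""

from __future__ import annotations

import os
from typing import List, Optional, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .types import CA_DIST_MAX, CA_DIST_MIN, CATrace, SequenceRecord

DEFAULT_MAX_BRIDGE = 3


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


class EmptyChainError(ValueError):
    """Raised when a requested chain has no polymer C-alpha atoms."""


def _pick_ca(residue: gemmi.Residue) -> Optional[gemmi.Atom]:
    """Highest-occupancy CA in a residue; first one on ties; None if absent."""
    best = None
    for atom in residue:
        if atom.name != "CA" or atom.element == gemmi.Element("H"):
            continue
        if best is None or atom.occ > best.occ + 1e-9:
            best = atom
    return best


def read_structure(
    path: str,
    chain: Optional[str] = None,
    max_bridge: int = DEFAULT_MAX_BRIDGE,
) -> List[CATrace]:
    """Extract one C-alpha trace per (selected) chain of a PDB/mmCIF file.

    Gaps of up to ``max_bridge`` missing residues are bridged by linear
    interpolation; longer gaps, or non-physical consecutive C-alpha
    distances, mark the trace ``broken`` (topology operations then refuse
    it, but the trace is still returned for inspection).
    """
    if not os.path.exists(path):
        raise StructureFormatError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    st.remove_waters()

    model = st[0]
    traces: List[CATrace] = []
    names = [ch.name for ch in model]
    if chain is not None and chain not in names:
        raise EmptyChainError(f"chain {chain!r} not found in {path}")
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        resnums: list[int] = []
        coords: list[list[float]] = []
        bvals: list[float] = []
        for res in ch:
            if res.is_water():
                continue
            ca = _pick_ca(res)
            if ca is None:
                continue
            num = res.seqid.num
            if resnums and num <= resnums[-1]:
                # insertion codes / duplicated numbers: keep first occurrence
                continue
            resnums.append(num)
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            bvals.append(ca.b_iso)
        if not resnums:
            if chain is not None:
                raise EmptyChainError(f"chain {chain!r} in {path} has no CA atoms")
            continue
        b = np.array(bvals)
        plddt = b if (np.all(b >= 0.0) and np.all(b <= 100.0)) else None
        trace = CATrace(
            chain_id=ch.name,
            residue_numbers=np.array(resnums, dtype=int),
            coords=np.array(coords, dtype=float),
            plddt=plddt,
            source=str(path),
        )
        traces.append(bridge_gaps(trace, max_bridge=max_bridge))
    if chain is None and not traces:
        raise EmptyChainError(f"no polymer CA atoms found in {path}")
    return traces


def bridge_gaps(trace: CATrace, max_bridge: int = DEFAULT_MAX_BRIDGE) -> CATrace:
    """Fill short numbering gaps by linear interpolation of coordinates.

    Gaps longer than ``max_bridge`` residues are left open and flag the
    trace as broken: interpolating across long gaps can silently change the
    chain topology, which is exactly the failure mode this package audits.
    A trace is also flagged broken when any consecutive C-alpha distance
    falls outside the physical 2.0-4.5 angstrom window.
    """
    if max_bridge < 0:
        raise ValueError("max_bridge must be >= 0")
    gaps = trace.gap_lengths()
    if len(trace) == 0:
        return trace
    if not np.any(gaps > 0):
        broken = not trace.check_continuity()
        if broken != trace.broken:
            return CATrace(
                trace.chain_id, trace.residue_numbers, trace.coords,
                trace.plddt, trace.source, broken, dict(trace.meta),
            )
        return trace

    resnums: list[int] = [int(trace.residue_numbers[0])]
    coords: list[np.ndarray] = [trace.coords[0]]
    plddt: Optional[list[float]] = (
        [float(trace.plddt[0])] if trace.has_plddt else None
    )
    broken = False
    for k in range(1, len(trace)):
        gap = int(trace.residue_numbers[k] - trace.residue_numbers[k - 1] - 1)
        if 0 < gap <= max_bridge:
            a, b = trace.coords[k - 1], trace.coords[k]
            for j in range(1, gap + 1):
                f = j / (gap + 1)
                resnums.append(int(trace.residue_numbers[k - 1]) + j)
                coords.append(a + f * (b - a))
                if plddt is not None:
                    pa = float(trace.plddt[k - 1])
                    pb = float(trace.plddt[k])
                    plddt.append(pa + f * (pb - pa))
        elif gap > max_bridge:
            broken = True
        resnums.append(int(trace.residue_numbers[k]))
        coords.append(trace.coords[k])
        if plddt is not None:
            plddt.append(float(trace.plddt[k]))

    out = CATrace(
        chain_id=trace.chain_id,
        residue_numbers=np.array(resnums, dtype=int),
        coords=np.array(coords, dtype=float),
        plddt=np.array(plddt) if plddt is not None else None,
        source=trace.source,
        broken=broken,
        meta=dict(trace.meta),
    )
    if not out.broken and not out.check_continuity():
        out.broken = True
    return out


def write_trace_pdb(trace: CATrace, path: str) -> None:
    """Write a trace as a poly-alanine C-alpha-only PDB file."""
    st = gemmi.Structure()
    st.name = "knotaudit"
    model = gemmi.Model("1")
    ch = gemmi.Chain(trace.chain_id or "A")
    for k in range(len(trace)):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(int(trace.residue_numbers[k]), " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        x, y, z = trace.coords[k]
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.occ = 1.0
        atom.b_iso = float(trace.plddt[k]) if trace.has_plddt else 0.0
        res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    doc_path = str(path)
    st.write_pdb(doc_path)


def read_fasta(path: str) -> List[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"malformed FASTA header in {path}")
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_xyz(path: str) -> np.ndarray:
    """Read a plain-text polyline: one 'x y z' triple per line."""
    pts = np.loadtxt(str(path), ndmin=2)
    if pts.shape[1] != 3:
        raise ValueError("xyz file must have three columns")
    return pts


def write_xyz(points: np.ndarray, path: str) -> None:
    np.savetxt(str(path), np.asarray(points, dtype=float), fmt="%.4f")
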