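"""Core containers shared across the toolkit.

A :class:`CATrace` is the minimal representation this package works on: the
ordered alpha-carbon polyline of one protein chain, optionally carrying the
per-residue pLDDT confidence that structure predictors store in the B-factor
column.  Topology operations act on the polyline only; confidence and
reporting operations use the annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

# Calpha-Calpha virtual bond limits in angstrom.  Anything outside after gap
# bridging means the polyline does not represent a continuous backbone.
CA_DIST_MIN = 2.0
CA_DIST_MAX = 4.5


@dataclass
class CATrace:
    """Ordered C-alpha trace of a single chain.

    Parameters
    ----------
    chain_id : str
        Chain identifier from the source file, or ``"A"`` for synthetic data.
    residue_numbers : ndarray of int
        Strictly increasing residue numbers (1-based, as in the source file).
    coords : ndarray, shape (n, 3)
        C-alpha coordinates in angstrom.
    plddt : ndarray or None
        Per-residue confidence in [0, 100]; ``None`` when the B-factor column
        did not follow the pLDDT convention.
    source : str
        File path the trace came from, or ``"synthetic"``.
    broken : bool
        True when the trace contains an unbridged gap or a non-physical
        consecutive C-alpha distance; topology operations refuse such traces.
    """

    chain_id: str
    residue_numbers: np.ndarray
    coords: np.ndarray
    plddt: Optional[np.ndarray] = None
    source: str = "synthetic"
    broken: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.plddt is not None:
            self.plddt = np.asarray(self.plddt, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if len(self.residue_numbers) != len(self.coords):
            raise ValueError("residue_numbers and coords length mismatch")
        if self.plddt is not None and len(self.plddt) != len(self.coords):
            raise ValueError("plddt and coords length mismatch")
        if len(self.residue_numbers) > 1 and np.any(
            np.diff(self.residue_numbers) <= 0
        ):
            raise ValueError("residue_numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def has_plddt(self) -> bool:
        return self.plddt is not None

    def gap_lengths(self) -> np.ndarray:
        """Number of missing residues between consecutive trace positions."""
        if len(self) < 2:
            return np.zeros(0, dtype=int)
        return np.diff(self.residue_numbers) - 1

    def consecutive_distances(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    def check_continuity(self) -> bool:
        """True when all consecutive C-alpha distances look physical."""
        if len(self) < 2:
            return True
        d = self.consecutive_distances()
        return bool(np.all((d >= CA_DIST_MIN) & (d <= CA_DIST_MAX)))


# canonical 20-letter amino-acid alphabet
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SequenceRecord:
    """A named amino-acid sequence restricted to the 20 canonical letters."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-canonical letters: "
                f"{sorted(bad)}"
            )
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


def residue_span_length(start: int, end: int) -> int:
    """Inclusive length of a residue span, e.g. 74..99 -> 26 residues."""
    if end < start:
        raise ValueError("span end before start")
    return end - start + 1


_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def parse_span(text: str) -> tuple[int, int]:
    """Parse a residue span written like ``"Arg74-Phe99"`` or ``"74-99"``."""
    import re

    m = re.fullmatch(
        r"([A-Za-z]{3})?(\d+)\s*[-–]\s*([A-Za-z]{3})?(\d+)", text.strip()
    )
    if not m:
        raise ValueError(f"cannot parse residue span {text!r}")
    for code in (m.group(1), m.group(3)):
        if code and code.upper() not in _AA3:
            raise ValueError(f"unknown residue code {code!r} in span {text!r}")
    return int(m.group(2)), int(m.group(4))
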