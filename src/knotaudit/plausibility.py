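"""Folding-mechanism plausibility rules and auxiliary red-flag detectors.

The known mechanisms of knot formation in proteins constrain what a
predicted structure may look like: direct tail threading can produce at
most two (most probably shallow) knots, on-ribosome folding or domain
swapping a single deep knot, and their combination at most three
consecutive knots — two shallow ones at the termini around one central
deep knot.  A geometry that violates these bounds (e.g. ten consecutive
trefoils in a tandem-repeat model) is mechanistically implausible no
matter how confident the predictor's local quality scores are.

The rules are encoded as deterministic hard checks over a factor
decomposition rather than probabilities: the tool's job is red-flagging,
and every threshold is explicit and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fingerprint import KnotFactor
from .types import CATrace

__all__ = [
    "RuleConfig",
    "PlausibilityVerdict",
    "OcclusionReport",
    "assess_feasibility",
    "loop_occlusion",
    "domain_overlap",
    "confidence_profile",
    "PiercingError",
]

#: van der Waals radii (angstrom) for clearance computations
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
_VDW_DEFAULT = 1.7

#: occlusion verdict thresholds: a water molecule is ~2.8 A across; below
#: 1.0 A nothing can move through without hard clashes
OCCLUSION_OPEN = 2.8
OCCLUSION_BLOCKED = 1.0


@dataclass
class RuleConfig:
    """Tunable thresholds of the feasibility rule engine.

    ``max_consecutive`` — more factors than this is implausible (the
    mechanism combination argument allows at most three).
    ``max_deep`` — at most this many deep factors (one central deep knot).
    ``terminal_margin`` — a factor whose outer core boundary lies within
    this many residues of a chain end counts as terminal.
    Rules can be disabled individually via ``enabled``.
    """

    max_consecutive: int = 3
    max_deep: int = 1
    terminal_margin: int = 40
    enabled: Dict[str, bool] = field(
        default_factory=lambda: {"R1": True, "R2": True, "R3": True,
                                 "R4": True}
    )


@dataclass
class PlausibilityVerdict:
    verdict: str  # "plausible" | "implausible" | "ambiguous"
    triggered_rules: List[Tuple[str, str]]
    factors: List[KnotFactor]
    red_flags: List[str]

    @property
    def is_implausible(self) -> bool:
        return self.verdict == "implausible"


def assess_feasibility(
    factors: Sequence[KnotFactor],
    chain_length: Optional[int] = None,
    config: Optional[RuleConfig] = None,
) -> PlausibilityVerdict:
    """Rule the factor decomposition of one chain, ordered N to C.

    Hard rules (any one triggers "implausible"):

    R1  more than ``max_consecutive`` (3) consecutive knot factors;
    R2  more than ``max_deep`` (1) deep factors;
    R3  with exactly three factors, a deep factor must be the central one;
    R4  more than one internal (non-terminal) deep factor.

    Soft rule S1 flags the exactly-at-the-limit case (three factors with a
    central deep knot) as plausible but at the mechanism limit.  Zero or
    one factor is plausible.  Unresolved factors yield "ambiguous".
    """
    cfg = config or RuleConfig()
    factors = list(factors)
    if any(not f.resolved for f in factors):
        return PlausibilityVerdict(
            verdict="ambiguous",
            triggered_rules=[("U1", "factor decomposition unresolved")],
            factors=factors,
            red_flags=["unresolved_factors"],
        )
    k = len(factors)
    deep_idx = [i for i, f in enumerate(factors) if f.depth_class == "deep"]

    def is_terminal(i: int) -> bool:
        if chain_length is not None:
            f = factors[i]
            if i == 0 and f.core_start - 1 <= cfg.terminal_margin:
                return True
            if (
                i == k - 1
                and chain_length - f.core_end <= cfg.terminal_margin
            ):
                return True
            return False
        return i in (0, k - 1)

    rules: List[Tuple[str, str]] = []
    flags: List[str] = []
    if cfg.enabled.get("R1", True) and k > cfg.max_consecutive:
        rules.append(
            ("R1",
             f"{k} consecutive knot factors exceed the mechanism maximum "
             f"of {cfg.max_consecutive}")
        )
        flags.append("slipknot_expected")
    if cfg.enabled.get("R2", True) and len(deep_idx) > cfg.max_deep:
        rules.append(
            ("R2",
             f"{len(deep_idx)} deep factors; known mechanisms provide at "
             f"most {cfg.max_deep}")
        )
    if (
        cfg.enabled.get("R3", True)
        and k == 3
        and any(i != 1 for i in deep_idx)
    ):
        rules.append(
            ("R3",
             "with three consecutive factors the deep knot must be the "
             "central one")
        )
    internal_deep = [i for i in deep_idx if not is_terminal(i)]
    if cfg.enabled.get("R4", True) and len(internal_deep) > 1:
        rules.append(
            ("R4",
             f"{len(internal_deep)} internal deep factors; at most one "
             f"deep knot can form internally")
        )
    if rules:
        return PlausibilityVerdict(
            verdict="implausible", triggered_rules=rules, factors=factors,
            red_flags=flags,
        )
    soft: List[Tuple[str, str]] = []
    if k == 3 and deep_idx == [1]:
        soft.append(
            ("S1",
             "three consecutive factors with a central deep knot: at the "
             "limit of known folding mechanisms")
        )
        flags.append("mechanism_limit")
    return PlausibilityVerdict(
        verdict="plausible", triggered_rules=soft, factors=factors,
        red_flags=flags,
    )


# ---------------------------------------------------------------------------
# loop occlusion
# ---------------------------------------------------------------------------

class PiercingError(ValueError):
    """The thread does not pierce the loop."""


@dataclass
class OcclusionReport:
    loop_span: Tuple[int, int]
    piercing_residue: int
    clearance: float
    verdict: str  # "open" | "tight" | "blocked"


def _occlusion_verdict(clearance: float) -> str:
    if clearance > OCCLUSION_OPEN:
        return "open"
    if clearance >= OCCLUSION_BLOCKED:
        return "tight"
    return "blocked"


def loop_occlusion(
    full_atom_path: str,
    loop_span: Tuple[int, int],
    thread_span: Tuple[int, int],
    chain: Optional[str] = None,
) -> OcclusionReport:
    """Measure how occluded a twisted loop is around its threading segment.

    The loop residues' C-alpha ring is fitted with a plane; the thread's
    C-alpha polyline must cross that plane inside the loop polygon.  The
    clearance is the smallest distance from the thread axis (the piercing
    segment's line) to any loop heavy atom minus that atom's van der Waals
    radius.  Verdicts: open (> 2.8 A, a water fits through), tight
    (1.0-2.8 A), blocked (< 1.0 A: no movement needed for threading is
    possible without clashes).
    """
    import gemmi
    from shapely.geometry import Point, Polygon

    st = gemmi.read_structure(str(full_atom_path))
    st.setup_entities()
    model = st[0]
    loop_ca: List[Tuple[int, np.ndarray]] = []
    loop_atoms: List[Tuple[str, np.ndarray]] = []
    thread_ca: List[Tuple[int, np.ndarray]] = []
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            num = res.seqid.num
            for atom in res:
                if atom.element.name == "H":
                    continue
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if loop_span[0] <= num <= loop_span[1]:
                    loop_atoms.append((atom.element.name, pos))
                    if atom.name == "CA":
                        loop_ca.append((num, pos))
                if (
                    thread_span[0] <= num <= thread_span[1]
                    and atom.name == "CA"
                ):
                    thread_ca.append((num, pos))
    if len(loop_ca) < 3:
        raise ValueError("loop span has fewer than 3 CA atoms")
    if len(thread_ca) < 2:
        raise ValueError("thread span has fewer than 2 CA atoms")
    loop_ca.sort()
    thread_ca.sort()
    ring = np.array([p for _, p in loop_ca])

    centroid = ring.mean(axis=0)
    _, _, vt = np.linalg.svd(ring - centroid)
    normal = vt[2]
    e1, e2 = vt[0], vt[1]
    poly = Polygon([((p - centroid) @ e1, (p - centroid) @ e2) for p in ring])

    pierce = None
    for (num_a, pa), (num_b, pb) in zip(thread_ca, thread_ca[1:]):
        if num_b != num_a + 1:
            continue
        sa = (pa - centroid) @ normal
        sb = (pb - centroid) @ normal
        if sa * sb > 0 or (sa == 0 and sb == 0):
            continue
        t = sa / (sa - sb) if sa != sb else 0.0
        x = pa + t * (pb - pa)
        pt = Point(((x - centroid) @ e1, (x - centroid) @ e2))
        if poly.contains(pt):
            pierce = (num_a, pa, pb, x)
            break
    if pierce is None:
        raise PiercingError("thread does not pierce loop")
    res_num, pa, pb, x = pierce
    axis = pb - pa
    axis = axis / np.linalg.norm(axis)

    clearance = np.inf
    for elem, pos in loop_atoms:
        v = pos - x
        perp = v - (v @ axis) * axis
        d = float(np.linalg.norm(perp)) - VDW_RADII.get(elem, _VDW_DEFAULT)
        clearance = min(clearance, d)
    clearance = max(0.0, clearance)
    return OcclusionReport(
        loop_span=tuple(loop_span),
        piercing_residue=int(res_num),
        clearance=float(clearance),
        verdict=_occlusion_verdict(clearance),
    )


# ---------------------------------------------------------------------------
# domain overlap
# ---------------------------------------------------------------------------

@dataclass
class DomainOverlap:
    pair: Tuple[Tuple[int, int], Tuple[int, int]]
    overlap_score: float
    clash_count: int
    flagged: bool


def domain_overlap(
    trace: CATrace,
    domain_spans: Sequence[Tuple[int, int]],
    clash_cutoff: float = 4.0,
    score_cutoff: float = 0.5,
    clash_fraction: float = 0.1,
) -> List[DomainOverlap]:
    """Detect pairs of sequence domains predicted on top of each other.

    For each pair of (sequence-disjoint) domain spans the overlap score is
    the centroid distance divided by the sum of the two radii of gyration;
    the clash count is the number of inter-domain C-alpha pairs closer
    than ``clash_cutoff``.  A pair is flagged overlaid when the score
    falls below ``score_cutoff`` and the clash count exceeds
    ``clash_fraction`` times the smaller domain length — the signature of
    two copies of one domain predicted in the same place.
    """
    from scipy.spatial import cKDTree

    if len(domain_spans) < 2:
        raise ValueError("need at least 2 domain spans")
    spans = sorted(tuple(s) for s in domain_spans)
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 <= b1:
            raise ValueError("domain spans overlap in sequence")
    n = len(trace)
    coords = {}
    for (a, b) in spans:
        if a < 1 or b > n:
            raise IndexError(f"span ({a}, {b}) outside trace [1, {n}]")
        coords[(a, b)] = trace.coords[a - 1 : b]

    out: List[DomainOverlap] = []
    for i, s1 in enumerate(spans):
        for s2 in spans[i + 1 :]:
            c1, c2 = coords[s1], coords[s2]
            cen1, cen2 = c1.mean(axis=0), c2.mean(axis=0)
            rg1 = float(np.sqrt(((c1 - cen1) ** 2).sum(axis=1).mean()))
            rg2 = float(np.sqrt(((c2 - cen2) ** 2).sum(axis=1).mean()))
            score = float(
                np.linalg.norm(cen1 - cen2) / max(rg1 + rg2, 1e-9)
            )
            tree = cKDTree(c2)
            clashes = int(
                sum(len(hits) for hits in tree.query_ball_point(
                    c1, clash_cutoff))
            )
            flagged = (
                score < score_cutoff
                and clashes > clash_fraction * min(len(c1), len(c2))
            )
            out.append(DomainOverlap((s1, s2), score, clashes, flagged))
    return out


# ---------------------------------------------------------------------------
# confidence profiling
# ---------------------------------------------------------------------------

def _plddt_class(mean: float) -> str:
    if mean >= 90.0:
        return "high"
    if mean >= 70.0:
        return "good"
    return "low"


def confidence_profile(
    trace: CATrace,
    segments: Sequence[Tuple[str, int, int]] = (),
    verdict: Optional[PlausibilityVerdict] = None,
) -> dict:
    """Per-segment and global pLDDT summary, with the masking warning.

    Predictors' per-residue confidence is commonly averaged over the whole
    chain; a mean above 70 reads as "a generally good backbone prediction"
    (above 90: "modeled to high accuracy") even when the global topology
    is impossible, because the mutual placement of loop and thread is
    invisible to a local, averaged metric.  When the global mean is >= 70
    but the feasibility verdict is implausible, the ``masking`` flag is
    set.
    """
    if not trace.has_plddt:
        raise ValueError("trace carries no pLDDT values")
    rows = []
    for (label, a, b) in segments:
        if a < 1 or b > len(trace) or a > b:
            raise IndexError(f"segment ({a}, {b}) outside trace")
        seg = trace.plddt[a - 1 : b]
        rows.append(
            {
                "segment": label,
                "start": a,
                "end": b,
                "mean_plddt": float(seg.mean()),
                "min_plddt": float(seg.min()),
                "class": _plddt_class(float(seg.mean())),
            }
        )
    gmean = float(trace.plddt.mean())
    masking = bool(
        gmean >= 70.0 and verdict is not None and verdict.is_implausible
    )
    return {
        "segments": rows,
        "global_mean": gmean,
        "global_min": float(trace.plddt.min()),
        "global_class": _plddt_class(gmean),
        "masking": masking,
    }
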