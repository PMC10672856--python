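"""Subchain knot fingerprints, knotted-core location, and composite
decomposition.

A knot fingerprint classifies subchains (i, j) of a trace on a step grid.
The knotted core of a factor is the minimal subchain that stays knotted
when trimmed from either side; its distance to the chain termini (or, for
internal factors of a composite, to the neighbouring core) defines the
knot depth.  Knots whose core lies within ~20 residues of the nearest
terminus are shallow; deeper knots require threading long chain segments
and are mechanistically expensive, which is what the plausibility rules
act on.

The fingerprint is evaluated lazily: entries are classified on demand and
memoized, so the greedy core search only pays for the intervals it visits;
``compute_full()`` fills the whole grid for heat-map-style inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .topology import BrokenTraceError, KnotLabel, classify_knot
from .types import CATrace

__all__ = [
    "KnotFingerprint",
    "KnotFactor",
    "find_cores",
    "detect_slipknots",
    "DEEP_THRESHOLD",
]

#: residues from the nearest terminus beyond which a knot counts as deep
DEEP_THRESHOLD = 20

#: minimal consensus for accepting a prime core
CORE_PROB_MIN = 0.5

#: intervals shorter than this cannot hold a knot worth classifying
_MIN_KNOT_SPAN = 20


@dataclass
class KnotFactor:
    """One consecutive prime-knot factor of a (possibly composite) chain.

    ``depth_n``/``depth_c`` measure, in residues, how far the knotted core
    lies from the N-/C-terminus (terminal factors) or from the neighbouring
    factor's core boundary (internal factors).
    """

    label: KnotLabel
    core_start: int
    core_end: int
    depth_n: int
    depth_c: int
    depth_class: str  # "shallow" | "deep"
    resolved: bool = True

    def __post_init__(self) -> None:
        if self.resolved and self.core_start >= self.core_end:
            raise ValueError("core_start must be < core_end")
        if self.depth_n < 0 or self.depth_c < 0:
            raise ValueError("depths must be >= 0")


def _depth_class(depth_n: int, depth_c: int, threshold: int) -> str:
    return "deep" if min(depth_n, depth_c) > threshold else "shallow"


class KnotFingerprint:
    """Memoizing subchain classifier over a step grid.

    Intervals are closed 1-based ``[i, j]`` ranges of trace positions.
    Each interval gets its own deterministic closure seed derived from the
    base seed and the interval, so results do not depend on evaluation
    order.
    """

    def __init__(
        self,
        trace: Union[CATrace, np.ndarray],
        step: int = 5,
        n_closures: int = 100,
        seed: int = 42,
        early_stop: Optional[int] = 25,
    ) -> None:
        if step < 1:
            raise ValueError("step must be >= 1")
        if isinstance(trace, CATrace):
            if trace.broken:
                raise BrokenTraceError("cannot fingerprint a broken trace")
            self.points = trace.coords
        else:
            self.points = np.asarray(trace, dtype=float)
        self.n = len(self.points)
        self.step = step
        self.n_closures = n_closures
        self.seed = seed
        self.early_stop = early_stop
        self.labels: Dict[Tuple[int, int], KnotLabel] = {}

    # -- grid ---------------------------------------------------------------
    def grid_positions(self) -> List[int]:
        """Step-grid positions plus the exact chain ends."""
        pos = list(range(1, self.n + 1, self.step))
        if pos[-1] != self.n:
            pos.append(self.n)
        return pos

    # -- classification -----------------------------------------------------
    def _interval_seed(self, i: int, j: int) -> int:
        ss = np.random.SeedSequence([self.seed, i, j])
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def at(self, i: int, j: int) -> KnotLabel:
        """Knot label of the subchain [i, j] (1-based, inclusive)."""
        if not (1 <= i < j <= self.n):
            raise IndexError(f"interval ({i}, {j}) outside [1, {self.n}]")
        key = (i, j)
        if key not in self.labels:
            if j - i + 1 < _MIN_KNOT_SPAN:
                self.labels[key] = KnotLabel("0_1", 1.0)
            else:
                self.labels[key] = classify_knot(
                    self.points[i - 1 : j],
                    n_closures=self.n_closures,
                    seed=self._interval_seed(i, j),
                    early_stop=self.early_stop,
                )
        return self.labels[key]

    @property
    def intervals(self) -> List[Tuple[int, int]]:
        return sorted(self.labels)

    def whole(self) -> KnotLabel:
        return self.at(1, self.n)

    def compute_full(self) -> None:
        """Classify every grid interval (quadratic; for heat maps)."""
        pos = self.grid_positions()
        for a_idx, i in enumerate(pos):
            for j in pos[a_idx + 1 :]:
                self.at(i, j)

    def to_tsv(self, path: str) -> None:
        with open(str(path), "w") as fh:
            fh.write("start\tend\tlabel\tprobability\n")
            for (i, j) in self.intervals:
                lab = self.labels[(i, j)]
                fh.write(f"{i}\t{j}\t{lab.notation}\t{lab.probability:.3f}\n")


# ---------------------------------------------------------------------------
# knotted-core decomposition
# ---------------------------------------------------------------------------

def _is_prime(label: KnotLabel, min_prob: float) -> bool:
    return (
        label.is_knotted
        and "#" not in label.notation
        and label.probability >= min_prob
    )


def _bisect_last_true(lo_idx: int, hi_idx: int, pred) -> int:
    """Largest index in [lo_idx, hi_idx] for which pred holds; assumes pred
    is True at lo_idx and monotone (True ... True False ... False)."""
    lo, hi = lo_idx, hi_idx
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if pred(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def find_cores(
    fp: KnotFingerprint,
    core_prob_min: float = CORE_PROB_MIN,
    deep_threshold: int = DEEP_THRESHOLD,
) -> List[KnotFactor]:
    """Decompose a chain into consecutive prime-knot factors.

    Greedy left-to-right scan: the next factor is the shortest prefix (from
    the running left boundary, grid-quantised) that classifies as a prime
    knot and whose removal leaves a remainder with exactly one factor
    fewer; the core is then tightened from both sides by bisection using
    the monotone trimming property, with a final +/-step refinement at
    single-residue resolution.  Returns an empty list for unknotted
    chains, and a single unresolved factor when the full-chain label is
    composite/knotted but no consistent core assignment exists.
    """
    n = fp.n
    full = fp.whole()
    if full.notation == "0_1":
        return []
    unresolved = [
        KnotFactor(
            label=full, core_start=1, core_end=n, depth_n=0, depth_c=0,
            depth_class="shallow", resolved=False,
        )
    ]
    total = full.n_factors
    if total is None:
        return unresolved

    pos = fp.grid_positions()
    cores: List[Tuple[KnotLabel, int, int]] = []
    left = 1
    for fidx in range(total):
        remaining_after = total - fidx - 1
        found = None
        # shortest prime prefix whose removal drops the factor count by one
        for j in pos:
            if j - left + 1 < _MIN_KNOT_SPAN:
                continue
            if j < left:
                continue
            lab = fp.at(left, j)
            if not _is_prime(lab, core_prob_min):
                continue
            if remaining_after == 0:
                rem_ok = (
                    j >= n - fp.step
                    or not fp.at(min(j + 1, n - 1), n).is_knotted
                )
            else:
                rem = fp.at(min(j + 1, n - 1), n)
                rem_ok = rem.n_factors == remaining_after
            if rem_ok:
                found = (j, lab)
                break
        if found is None:
            return cores_to_factors(cores, n, deep_threshold) + unresolved
        j_end, lab = found
        prime = lab.notation

        def still_prime_from(i: int) -> bool:
            if j_end - i + 1 < _MIN_KNOT_SPAN:
                return False
            la = fp.at(i, j_end)
            return la.notation == prime and la.probability >= core_prob_min

        # tighten the left boundary upward (monotone trimming)
        grid_left = [p for p in pos if left <= p <= j_end]
        k = _bisect_last_true(
            0, len(grid_left) - 1, lambda t: still_prime_from(grid_left[t])
        )
        i_core = grid_left[k]
        # refine at single-residue resolution within one step
        while i_core + 1 < j_end and still_prime_from(i_core + 1):
            i_core += 1

        def still_prime_to(j: int) -> bool:
            if j - i_core + 1 < _MIN_KNOT_SPAN:
                return False
            la = fp.at(i_core, j)
            return la.notation == prime and la.probability >= core_prob_min

        grid_right = [p for p in pos if i_core <= p <= j_end]
        k2 = _bisect_last_true(
            0,
            len(grid_right) - 1,
            lambda t: still_prime_to(grid_right[len(grid_right) - 1 - t]),
        )
        j_core = grid_right[len(grid_right) - 1 - k2]
        while j_core - 1 > i_core and still_prime_to(j_core - 1):
            j_core -= 1

        cores.append((lab, i_core, j_core))
        left = j_core + 1

    # relabel each factor from its full territory (between the neighbouring
    # cores, or the chain ends): classification at the minimal core interval
    # is noisy at the boundaries, while the territory window holds exactly
    # this factor and gives the reliable consensus
    relabeled: List[Tuple[KnotLabel, int, int]] = []
    for idx, (lab, s, e) in enumerate(cores):
        lo = 1 if idx == 0 else cores[idx - 1][2] + 1
        hi = n if idx == len(cores) - 1 else cores[idx + 1][1] - 1
        terr = fp.at(min(lo, s), max(hi, e))
        if terr.notation == lab.notation:
            lab = terr
        relabeled.append((lab, s, e))
    return cores_to_factors(relabeled, n, deep_threshold)


def cores_to_factors(
    cores: Sequence[Tuple[KnotLabel, int, int]],
    n: int,
    deep_threshold: int = DEEP_THRESHOLD,
) -> List[KnotFactor]:
    """Assign depths and depth classes to located cores.

    Terminal factors measure depth to the chain ends; internal factors to
    the neighbouring cores' boundaries.
    """
    factors: List[KnotFactor] = []
    for k, (lab, s, e) in enumerate(cores):
        left_bound = 1 if k == 0 else cores[k - 1][2]
        right_bound = n if k == len(cores) - 1 else cores[k + 1][1]
        depth_n = s - left_bound if k > 0 else s - 1
        depth_c = right_bound - e if k < len(cores) - 1 else n - e
        factors.append(
            KnotFactor(
                label=lab,
                core_start=s,
                core_end=e,
                depth_n=int(depth_n),
                depth_c=int(depth_c),
                depth_class=_depth_class(depth_n, depth_c, deep_threshold),
            )
        )
    return factors


def detect_slipknots(
    fp: KnotFingerprint,
    min_prob: float = CORE_PROB_MIN,
) -> List[Tuple[Tuple[int, int], KnotLabel]]:
    """Maximal knotted subchains of a chain whose full length is unknotted.

    A slipknot threads a loop and backs out again: some subchain closes to
    a knot although the complete chain does not.  Returns an empty list
    when the whole chain is knotted (then the knot is real, not a
    slipknot).  Intervals are scanned longest-first on the fingerprint
    grid; intervals nested inside an already-reported knotted interval are
    skipped, so the result is the set of maximal knotted intervals.
    """
    if fp.whole().is_knotted:
        return []
    pos = fp.grid_positions()
    pairs = [
        (i, j)
        for ai, i in enumerate(pos)
        for j in pos[ai + 1 :]
        if j - i + 1 >= _MIN_KNOT_SPAN and (i, j) != (1, fp.n)
    ]
    pairs.sort(key=lambda p: p[0] - p[1])  # longest first
    found: List[Tuple[Tuple[int, int], KnotLabel]] = []
    for (i, j) in pairs:
        if any(s <= i and j <= e for (s, e), _ in found):
            continue
        lab = fp.at(i, j)
        if lab.is_knotted and lab.probability >= min_prob:
            found.append(((i, j), lab))
    return found
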