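# Methods

## Problem

A structure predictor can emit a backbone whose local geometry and local
confidence look excellent while its global topology is unreachable by any
known protein-folding mechanism. `knotaudit` treats topology as a
first-class validation axis: it assigns knot types to open chains,
localises and decomposes composite knots, and checks the result against
mechanism-derived feasibility rules.

## Open-chain knot assignment

A linear chain has no knot type until it is closed. We use the standard
stochastic-closure convention: both termini are joined to a single point
drawn uniformly on a sphere centred on the chain's bounding box, with
radius 10× the bounding-box diagonal (far enough that the closure arcs
are effectively rays to infinity). The consensus over `n_closures`
(default 100) independent closures defines the label, and the vote
fraction doubles as a confidence. A direct closure (one segment joining
the termini) is available but misclassifies chains whose termini sit
inside the globule.

Per closure, the loop is simplified by KMT vertex deletion: vertex v_i is
removed when the triangle (v_{i−1}, v_i, v_{i+1}) is crossed by no other
segment of the loop. Our implementation is conservative: coplanar or
boundary-touching configurations block deletion, so a vertex is only
removed when the isotopy is unambiguous.

**Reduce-then-close correctness.** Reducing the *open* chain once and
reusing it for every closure is the only way to keep the cost of 100
closures per interval tractable, but a triangle move may sweep the region
a later closure arc passes through, silently changing that closure's knot.
We therefore draw all closure points *first* and pass the closure arcs to
the reduction as obstacles: the isotopy then takes place in the complement
of every planned closure arc, and each closure's knot type is preserved
exactly. This is the single most important correctness detail in the
pipeline; without it, nearly closed chains lose their knot
deterministically for some cut geometries.

## Invariant and classification table

Each reduced loop is projected along a random direction (redrawn on any
degeneracy: over/under ambiguity, a crossing through a projected vertex,
overlapping parallel segments, coincident crossing parameters within 1e−9
of arc length). From the crossing diagram we build the Alexander matrix
via the abelianised Wirtinger relations — for a crossing with incoming
under-arc a, outgoing under-arc b and over-arc c, the row is
(t, −1, 1−t) at columns (a, b, c) for one sign and (1, −t, t−1) for the
other — strike one row and one column, and evaluate the determinant
exactly over the integers (fraction-free Bareiss elimination; Python
integers, no overflow).

The determinant equals ±t^m·Δ(t), so |Δ(−1)| is exact but the value at
t = −2 is defined only up to a power of two. Classification therefore
keys on the projection-invariant pair **(|Δ(−1)|, odd part of |Δ(−2)|)**:

| knot | pair | knot | pair |
|------|------|------|------|
| 0₁ | (1, 1) | 5₂ | (7, 1) |
| 3₁ | (3, 7) | 6₁ | (9, 5) |
| 4₁ | (5, 11) | 6₂ | (11, 59) |
| 5₁ | (5, 31) | 6₃ | (13, 67) |
| 7₁ | (7, 127) | | |

t = −2 resolves the classic t = −1 collisions (4₁/5₁ at 5, 5₂/7₁ at 7,
granny knot/6₁ at 9). The table also contains all pairwise connected sums
of these primes, k-fold trefoil sums to k = 12, and trefoil-dominated
mixed sums; uniqueness of all keys is asserted when the table is built.
Alexander polynomials are blind to chirality, so labels are achiral; 
invariants beyond seven crossings may alias rare knots to "unknown".

`alexander_value(loop, t)` exposes the raw invariant with all factors of
|t| stripped, which makes it projection-independent and preserves
multiplicativity over connected sums (3ᵏ at t = −1 for k trefoils).

## Fingerprint, cores, slipknots

The fingerprint classifies subchains [i, j] with i, j on a step grid
(default step 5) plus the exact ends, each interval with its own closure
seed derived from (base seed, i, j) so results are independent of
evaluation order. Entries are evaluated lazily and memoized: the greedy
core search only pays for the intervals it visits (a dense matrix would
cost ~24 000 interval classifications on a 1081-residue decamer);
`compute_full()` fills the grid when a heat map is wanted.

`find_cores` decomposes a composite chain left to right: the next factor
is the shortest grid prefix from the running left boundary that
classifies as a prime knot (consensus ≥ 0.5) and whose removal leaves a
remainder with exactly one factor fewer; the core is then tightened from
both sides by bisection (using the monotone trimming property) and
refined at single-residue resolution. Factors are finally *relabelled
from their territory* — the window between the neighbouring cores (or
chain ends) — because classification at the minimal core interval is
noisy at the boundaries while the territory holds exactly one factor.
Depths are measured to the chain ends for terminal factors and to the
neighbouring core boundaries for internal ones; a factor is **deep** when
min(depth_n, depth_c) > 20 residues (configurable). The core-boundary
convention (last residue whose removal keeps the subchain knotted)
differs by ±1 residue between published tools.

`detect_slipknots` applies only when the full chain is unknotted: grid
intervals are scanned longest-first, intervals nested in an
already-reported knotted interval are skipped, and the maximal knotted
intervals are returned.

## Feasibility rules

Encoded as deterministic hard checks, ordered and configurable
(`RuleConfig`): R1 — more than 3 consecutive factors; R2 — more than one
deep factor; R3 — with exactly three factors the deep one must be
central; R4 — more than one *internal* deep factor (redundant with R2 at
defaults, but it fires independently when R2 is toggled off). Soft rule
S1 flags the exactly-at-the-limit pattern (three factors, central deep)
as plausible but at the mechanism limit. "Terminal" means the outer core
boundary lies within `terminal_margin` (default 40 residues, the main
free parameter of the rule engine) of a chain end. Unresolved
decompositions yield `ambiguous`, never a hard verdict.

## Red-flag detectors

**Loop occlusion.** The loop residues' C-alpha ring is fitted with a
plane (SVD); the threading segment must cross the plane inside the ring
polygon (shapely point-in-polygon). Clearance is the minimum over loop
heavy atoms of (distance from the thread axis − van der Waals radius;
C 1.7, N 1.55, O 1.52, S 1.8 Å). Verdicts: open > 2.8 Å (a water fits
through), tight 1.0–2.8 Å, blocked < 1.0 Å. The thresholds are anchored
to the water diameter and the hard-clash scale; the underlying
observation they operationalise is qualitative.

**Domain overlap.** For each pair of sequence-disjoint spans:
overlap_score = centroid distance / (Rg₁ + Rg₂); clash count = number of
inter-domain C-alpha pairs under 4.0 Å (cKDTree). Flagged when score
< 0.5 and clashes > 0.1 × the smaller domain length — two copies of a
domain predicted in the same place.

**Confidence masking.** Per-segment and global pLDDT means with classes
high ≥ 90, good ≥ 70, low < 70. The masking flag is set when the global
mean is ≥ 70 while the feasibility verdict is implausible: averaging a
local metric hides global topology errors.

## Synthetic generators

The generators stand in for predicted models so the whole pipeline is
testable without a predictor run. Closed parametric curves — torus knots
T(2,3), T(2,5), T(2,7) for 3₁/5₁/7₁, the Fourier figure-eight curve for
4₁, and the published Lissajous parametrizations (3,2,7; phases 0.7/0.2)
for 5₂ and (3,2,5; 1.5/0.2) for 6₁ — are resampled at 3.8 Å spacing
(C-alpha virtual-bond length), cut open, given short terminal leads, and
jittered with Gaussian noise. 6₃ has no convenient low-harmonic
parametrization and is not generated, though the table recognises it.

Three construction details keep the generator's ground-truth contract
(requested knot recovered with high consensus at noise ≤ 0.5 Å):

1. **Cut placement** — opening the curve inside a threading region
   changes the open chain's knot, so the seeded cut is restricted to the
   top clearance tercile of the curve (distance to non-neighbouring
   strand parts).
2. **Terminal leads** — five points per terminus directed outward, like
   the exposed tails of real deeply knotted proteins, so stochastic
   closures rarely re-thread the knot. Candidate directions are ranked by
   geometric clearance, but clearance cannot tell a clean escape from an
   escape through a knot loop, so candidates are verified topologically
   against the direct-closure label of the nearly closed chain (which is
   faithful to the parametric curve) and the first pair preserving the
   label at consensus ≥ 0.9 wins.
3. **Cut retry** — if no lead pair verifies, the next seeded cut site is
   tried (up to six).

`concat_knots` places units along x with disjoint bounding boxes and
joins them with straight tip-to-tip linkers (default 9 vertices; the
spacing stretches beyond 3.8 Å when unit bodies force a longer gap, which
does not affect topology). A straight linker can, in unlucky
orientations, thread a neighbouring unit's loop, so every unit span and
every junction window is re-classified after assembly and an offending
unit is deterministically re-oriented (up to 8 attempts). The slipknot
generator walks 92% of a closed trefoil, retraces 40% of that walk
backwards along an offset parallel path (the threaded end backs out),
then escapes radially; the full chain closes to 0₁ while the forward
prefix closes to 3₁. The ring-and-thread generator writes a full-atom
PDB ring of pseudo-residues (extra inward carbons emulate bulky side
chains when the requested pseudo-atom radius exceeds carbon's 1.7 Å)
pierced — or deliberately missed — by a straight strand.

What the generators do *not* emulate: real secondary structure, sequence–
structure consistency, side-chain packing, or predictor-specific error
modes. Passing tests demonstrate that the pipeline measures topology
correctly on C-alpha-like polylines; they do not validate any claim about
how often real predicted models are implausible.

## Numerical choices and problem sizes

- Closure sphere factor 10× the bounding-box diagonal; closure and
  projection randomness from `numpy` PCG64 streams seeded explicitly —
  identical seeds give identical outputs bit for bit.
- Consensus short-circuits once 25 initial closures agree unanimously
  (the remaining votes cannot realistically change the label); pass
  `early_stop=None` to force every closure.
- Intervals shorter than 20 residues are trivially unknotted (a knot
  needs ~20+ C-alpha steps at 3.8 Å spacing).
- Degenerate chains (< 3 non-collinear points) classify as 0₁.
- The remainder-count check in `find_cores` uses the full remaining
  suffix; prefix scans use the step grid with ±step refinement.
- Default problem sizes (100-point units, 100 closures, step 5) keep a
  full decamer decomposition at about a minute on one core and the
  accuracy sweeps at a few minutes; they are the package's defaults, not
  hard limits.

## Known limitations

- Chirality is not resolved (Alexander-based); 3₁ covers both trefoil
  handednesses.
- Knots outside the table (8 crossings and up, exotic sums) report
  "unknown".
- The rule engine judges geometry only; it neither simulates folding
  pathways nor estimates free energies, and a "plausible" verdict is not
  a claim that the protein folds.
- B-factors are read as pLDDT only when every value is in [0, 100];
  crystallographic B-factor files silently disable confidence analysis.
- Gap bridging interpolates at most `max_bridge` (default 3) missing
  residues; longer gaps flag the trace broken and topology operations
  refuse it, since interpolation across long gaps can change topology.
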