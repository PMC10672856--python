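# knotaudit

Topology validation for predicted protein structures.

Structure predictors such as AlphaFold optimise local geometry and local
confidence metrics; nothing in that objective prevents them from emitting
backbones whose *global* topology no known folding mechanism can reach —
for example ten consecutive trefoil knots in a tandem-repeat construct,
each reported with high per-residue confidence. `knotaudit` detects knots
on open polypeptide backbones, decomposes composite knots into consecutive
prime factors, classifies each factor's depth, and applies
folding-mechanism rules to flag topologically implausible models, together
with loop-occlusion, domain-overlap and per-segment confidence red-flag
detectors.

## The method

**Open-chain knot detection.** A C-alpha trace is simplified by KMT vertex
deletion (a vertex is removed whenever the triangle it spans with its
neighbours is pierced by no other chain segment — an ambient isotopy), then
closed stochastically: both termini are joined to a point drawn uniformly
on a sphere of radius 10× the chain's bounding-box diagonal. Each closed
loop is projected along a random direction, its crossing diagram built, and
the Alexander polynomial Δ(t) evaluated at t = −1 and t = −2 as an exact
integer determinant of the reduced Alexander matrix. The pair
(|Δ(−1)|, odd part of |Δ(−2)|) indexes a table covering the prime knots
0₁, 3₁, 4₁, 5₁, 5₂, 6₁, 6₂, 6₃, 7₁ and their connected sums (Alexander is
multiplicative over sums: a k-fold trefoil sum gives |Δ(−1)| = 3ᵏ). The
majority label over (by default) 100 closures is reported with its vote
fraction as a probability. Alexander invariants are chirality-blind, so
labels are achiral.

**Fingerprints, cores and depth.** Subchains [i, j] on a step grid are
classified the same way; the knotted core of a factor is the minimal
subchain that stays knotted under trimming from both sides. A knot whose
core lies within ~20 residues of the nearest terminus is *shallow*; deeper
knots require threading long chain segments through a twisted loop and are
mechanistically expensive.

**Plausibility rules.** Known mechanisms bound what a real protein can do:
tail threading yields at most two (most probably shallow) knots,
on-ribosome folding or domain swapping one deep knot, and their
combination at most **three consecutive knots** — two shallow terminal
ones around a central deep knot. The rule engine rules a factor
decomposition `implausible` when it exceeds these bounds (R1: > 3 factors;
R2: > 1 deep factor; R3: a non-central deep factor among exactly three;
R4: > 1 internal deep factor), and flags the exactly-at-the-limit pattern.
A high mean pLDDT (≥ 70) combined with an implausible topology raises the
*masking* flag: averaged local confidence cannot see global topology.

## Worked example

```python
import knotaudit as ka
from knotaudit.fingerprint import KnotFingerprint

# a synthetic tandem of three open trefoils, the analogue of a
# triple-repeat construct of the smallest knotted protein
units = [ka.KnotRecipe(knot="3_1", n_points=100, noise_sigma=0.2, seed=s)
         for s in (1, 2, 3)]
trace = ka.concat_knots(units, linker_points=9)

fp = KnotFingerprint(trace, step=5, n_closures=100, seed=1)
print(fp.whole())                 # full-chain label
factors = ka.find_cores(fp)
for f in factors:
    print(f.label.notation, f.label.probability,
          (f.core_start, f.core_end), f.depth_class)
verdict = ka.assess_feasibility(factors, chain_length=len(trace))
print(verdict.verdict, [r[0] for r in verdict.triggered_rules])
```

Output:

```
KnotLabel(notation='3_1#3_1#3_1', probability=0.96)
3_1 0.91 (20, 86) shallow
3_1 1.0 (126, 195) deep
3_1 0.95 (235, 301) shallow
plausible ['S1']
```

The full chain closes to a granny-knot-like triple trefoil sum; the three
cores are recovered with the central one deep — exactly the
at-the-mechanism-limit pattern, plausible but flagged. With ten units the
same pipeline returns ten factors and the verdict `implausible` (rule R1).

The same pipeline is exposed on the command line:

```
knotaudit synth --knot 3_1 --repeats 3 --out tandem3.pdb
knotaudit classify tandem3.pdb --seed 1 --out-dir reports/
```

`classify` exits 0 when all models are plausible and 3 otherwise, so it
can gate model-selection pipelines. See `examples/` for short scripts
covering each capability (classification, decomposition, rules, loop
occlusion, confidence masking, construct building).

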