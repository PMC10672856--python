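"""Classify synthetic open chains of every supported knot type.

Builds one noisy C-alpha-like chain per knot, runs stochastic-closure
classification, and prints the consensus label with its vote fraction.
A probability near 1 means almost every random closure produced the same
Alexander invariant pair.
"""

import knotaudit as ka
from knotaudit.synthetic import SUPPORTED_KNOTS

for name in SUPPORTED_KNOTS:
    n = 140 if name == "7_1" else 100
    trace = ka.generate_knot(
        ka.KnotRecipe(knot=name, n_points=n, noise_sigma=0.3, seed=1)
    )
    label = ka.classify_knot(trace, n_closures=60, seed=7)
    print(
        f"requested {name:>4}  ->  detected {label.notation:>4} "
        f"(consensus {label.probability:.2f}, {len(trace)} residues)"
    )

print(
    "\nEach line should match: the generator's ground truth is recovered\n"
    "by KMT reduction + random closure + Alexander invariants."
)
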