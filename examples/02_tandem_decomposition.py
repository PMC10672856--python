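"""Decompose a tandem-repeat composite knot into consecutive factors.

Concatenates three open trefoil units with straight 9-point linkers (the
synthetic analogue of a triple repeat of the smallest knotted protein),
fingerprints the chain, and extracts the knotted cores with their depths.
"""

import knotaudit as ka
from knotaudit.fingerprint import KnotFingerprint

units = [
    ka.KnotRecipe(knot="3_1", n_points=100, noise_sigma=0.2, seed=s)
    for s in (1, 2, 3)
]
trace = ka.concat_knots(units, linker_points=9)
print(f"chain of {len(trace)} residues, units at {trace.meta['unit_spans']}")

fp = KnotFingerprint(trace, step=5, n_closures=100, seed=1)
full = fp.whole()
print(f"full chain: {full.notation} (consensus {full.probability:.2f})")

for k, f in enumerate(ka.find_cores(fp), 1):
    print(
        f"factor {k}: {f.label.notation} p={f.label.probability:.2f} "
        f"core [{f.core_start}, {f.core_end}] "
        f"depths N:{f.depth_n} C:{f.depth_c} -> {f.depth_class}"
    )

print(
    "\nThe full chain closes to a triple trefoil connected sum; each unit\n"
    "contributes one core, and only the central factor is deep."
)
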