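"""The folding-mechanism rule engine on three factor patterns.

Known mechanisms allow at most three consecutive knots (two shallow
terminal ones around a central deep one); anything beyond is
mechanistically implausible regardless of predictor confidence.
"""

import knotaudit as ka
from knotaudit.fingerprint import KnotFactor
from knotaudit.topology import KnotLabel


def factor(depth, start, end):
    d = 5 if depth == "shallow" else 25
    return KnotFactor(
        label=KnotLabel("3_1", 0.95), core_start=start, core_end=end,
        depth_n=d, depth_c=d, depth_class=depth,
    )


cases = {
    "single shallow trefoil": [factor("shallow", 10, 90)],
    "three, central deep": [
        factor("shallow", 10, 90),
        factor("deep", 140, 220),
        factor("shallow", 270, 350),
    ],
    "ten consecutive trefoils": [
        factor("shallow", 10 + 100 * i, 90 + 100 * i) for i in range(10)
    ],
}

for name, factors in cases.items():
    v = ka.assess_feasibility(factors, chain_length=1100)
    rules = [r[0] for r in v.triggered_rules]
    print(f"{name:28s} -> {v.verdict:12s} rules={rules} flags={v.red_flags}")

print(
    "\nThe decamer trips R1 (max three consecutive knots); the triple with\n"
    "a central deep knot is plausible but flagged at the mechanism limit."
)
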