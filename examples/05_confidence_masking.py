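"""Mean pLDDT can mask an impossible topology.

Builds a trace whose knotted cores carry high confidence and whose
linkers are low, so the global mean reads 'generally good' (>= 70) — yet
the topology (ten consecutive knots) is mechanistically implausible.
The masking flag captures exactly this failure mode of averaged local
metrics.
"""

import numpy as np

import knotaudit as ka
from knotaudit.fingerprint import KnotFactor
from knotaudit.topology import KnotLabel

# 10 units of 90 residues at pLDDT 88 joined by 9-residue linkers at 45
plddt = []
segments = []
pos = 1
for k in range(10):
    plddt += [88.0] * 90
    segments.append((f"unit_{k + 1}", pos, pos + 89))
    pos += 90
    if k < 9:
        plddt += [45.0] * 9
        segments.append((f"linker_{k + 1}", pos, pos + 8))
        pos += 9
plddt = np.array(plddt)
n = len(plddt)
coords = np.column_stack([np.arange(n) * 3.8, np.zeros(n), np.zeros(n)])
trace = ka.CATrace("A", np.arange(1, n + 1), coords, plddt=plddt)

factors = [
    KnotFactor(KnotLabel("3_1", 0.95), 10 + 99 * i, 80 + 99 * i, 5, 5,
               "shallow")
    for i in range(10)
]
verdict = ka.assess_feasibility(factors, chain_length=n)
prof = ka.confidence_profile(trace, segments, verdict=verdict)

print(f"verdict: {verdict.verdict} "
      f"(rules {[r[0] for r in verdict.triggered_rules]})")
print(f"global mean pLDDT: {prof['global_mean']:.1f} "
      f"({prof['global_class']})")
lows = [s for s in prof["segments"] if s["class"] == "low"]
print(f"low-confidence segments: {[s['segment'] for s in lows]}")
print(f"masking flag: {prof['masking']}")

print(
    "\nA mean above 70 reads as a good model, but the masking flag warns\n"
    "that the averaged metric is hiding an implausible global topology."
)
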