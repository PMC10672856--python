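"""End-to-end structure auditing and batch reporting.

``audit_trace`` runs the full pipeline on one C-alpha trace: fingerprint,
core decomposition, slipknot scan, feasibility rules, and (when pLDDT is
available) confidence profiling with the masking warning.  The result is
a plain JSON-serialisable dict; ``batch_summary_tsv`` condenses a batch
of reports to one TSV row per structure.
"""

from __future__ import annotations

import json
from typing import List, Optional, Sequence, Tuple

from .fingerprint import (
    DEEP_THRESHOLD,
    KnotFingerprint,
    detect_slipknots,
    find_cores,
)
from .plausibility import RuleConfig, assess_feasibility, confidence_profile
from .types import CATrace

__all__ = ["audit_trace", "batch_summary_tsv"]


def audit_trace(
    trace: CATrace,
    step: int = 5,
    n_closures: int = 100,
    seed: int = 42,
    deep_threshold: int = DEEP_THRESHOLD,
    rule_config: Optional[RuleConfig] = None,
    segments: Sequence[Tuple[str, int, int]] = (),
    scan_slipknots: bool = True,
) -> dict:
    """Audit one chain and return the full verdict report."""
    report: dict = {
        "file": trace.source,
        "chain": trace.chain_id,
        "n_residues": len(trace),
        "config": {
            "step": step,
            "n_closures": n_closures,
            "seed": seed,
            "deep_threshold": deep_threshold,
        },
        "red_flags": [],
    }
    if trace.broken:
        report.update(
            {
                "knot_label": None,
                "probability": None,
                "factors": [],
                "verdict": "ambiguous",
                "triggered_rules": [],
                "red_flags": ["broken_chain"],
            }
        )
        return report

    fp = KnotFingerprint(
        trace, step=step, n_closures=n_closures, seed=seed
    )
    full = fp.whole()
    factors = find_cores(fp, deep_threshold=deep_threshold)
    verdict = assess_feasibility(
        factors, chain_length=len(trace), config=rule_config
    )
    flags = list(verdict.red_flags)
    slipknots: list = []
    if scan_slipknots and not full.is_knotted:
        slipknots = detect_slipknots(fp)
        if slipknots:
            flags.append("slipknot")
    report.update(
        {
            "knot_label": full.notation,
            "probability": full.probability,
            "factors": [
                {
                    "label": f.label.notation,
                    "probability": f.label.probability,
                    "core_start": f.core_start,
                    "core_end": f.core_end,
                    "depth_n": f.depth_n,
                    "depth_c": f.depth_c,
                    "depth_class": f.depth_class,
                    "resolved": f.resolved,
                }
                for f in factors
            ],
            "slipknots": [
                {"start": i, "end": j, "label": lab.notation,
                 "probability": lab.probability}
                for (i, j), lab in slipknots
            ],
            "verdict": verdict.verdict,
            "triggered_rules": [
                {"id": rid, "text": text}
                for rid, text in verdict.triggered_rules
            ],
            "red_flags": flags,
        }
    )
    if trace.has_plddt:
        report["confidence"] = confidence_profile(
            trace, segments=segments, verdict=verdict
        )
        if report["confidence"]["masking"]:
            report["red_flags"].append("plddt_masking")
    return report


_SUMMARY_COLS = [
    "file", "chain", "n_residues", "knot_label", "probability",
    "n_factors", "verdict", "rules", "red_flags",
]


def batch_summary_tsv(reports: Sequence[dict], path: str) -> None:
    """One TSV row per audited structure."""
    with open(str(path), "w") as fh:
        fh.write("\t".join(_SUMMARY_COLS) + "\n")
        for rep in reports:
            row = [
                str(rep.get("file", "")),
                str(rep.get("chain", "")),
                str(rep.get("n_residues", "")),
                str(rep.get("knot_label", "")),
                (
                    f"{rep['probability']:.3f}"
                    if rep.get("probability") is not None
                    else ""
                ),
                str(len(rep.get("factors", []))),
                str(rep.get("verdict", "")),
                ",".join(r["id"] for r in rep.get("triggered_rules", [])),
                ",".join(rep.get("red_flags", [])),
            ]
            fh.write("\t".join(row) + "\n")


def write_report_json(report: dict, path: str) -> None:
    with open(str(path), "w") as fh:
        json.dump(report, fh, indent=1)
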