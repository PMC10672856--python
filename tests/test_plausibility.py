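"""Feasibility rule engine and red-flag detectors."""

import numpy as np
import pytest

import knotaudit as ka
from knotaudit.fingerprint import KnotFactor
from knotaudit.plausibility import RuleConfig
from knotaudit.topology import KnotLabel


def factor(depth="shallow", start=10, end=90, notation="3_1",
           resolved=True):
    return KnotFactor(
        label=KnotLabel(notation, 0.95),
        core_start=start,
        core_end=end,
        depth_n=5 if depth == "shallow" else 30,
        depth_c=30,
        depth_class=depth,
        resolved=resolved,
    )


class TestRules:
    def test_single_shallow_trefoil_plausible(self):
        v = ka.assess_feasibility([factor("shallow")])
        assert v.verdict == "plausible"
        assert v.triggered_rules == []

    def test_no_factors_plausible(self):
        assert ka.assess_feasibility([]).verdict == "plausible"

    def test_ten_factors_implausible_by_count(self):
        v = ka.assess_feasibility([factor("shallow") for _ in range(10)])
        assert v.verdict == "implausible"
        assert v.triggered_rules[0][0] == "R1"
        assert "slipknot_expected" in v.red_flags

    def test_three_with_central_deep_at_mechanism_limit(self):
        v = ka.assess_feasibility(
            [factor("shallow"), factor("deep"), factor("shallow")]
        )
        assert v.verdict == "plausible"
        assert [r[0] for r in v.triggered_rules] == ["S1"]
        assert "mechanism_limit" in v.red_flags

    def test_two_deep_factors_implausible(self):
        v = ka.assess_feasibility([factor("deep"), factor("deep")])
        assert v.verdict == "implausible"
        assert "R2" in [r[0] for r in v.triggered_rules]

    def test_three_with_terminal_deep_implausible(self):
        v = ka.assess_feasibility(
            [factor("deep"), factor("shallow"), factor("shallow")]
        )
        assert v.verdict == "implausible"
        assert "R3" in [r[0] for r in v.triggered_rules]

    def test_unresolved_factors_give_ambiguous(self):
        bad = KnotFactor(
            label=KnotLabel("unknown", 0.0), core_start=1, core_end=100,
            depth_n=0, depth_c=0, depth_class="shallow", resolved=False,
        )
        assert ka.assess_feasibility([bad]).verdict == "ambiguous"

    def test_rule_toggles(self):
        cfg = RuleConfig(enabled={"R1": False, "R2": True, "R3": True,
                                  "R4": True})
        v = ka.assess_feasibility(
            [factor("shallow") for _ in range(5)], config=cfg
        )
        assert v.verdict == "plausible"

    def test_monotonicity_appending_never_rescues(self):
        """Once implausible, appending more factors cannot make the list
        plausible again."""
        base = [factor("deep"), factor("deep")]
        assert ka.assess_feasibility(base).is_implausible
        grown = list(base)
        for _ in range(5):
            grown = grown + [factor("shallow")]
            assert ka.assess_feasibility(grown).is_implausible

    def test_rule_order_deterministic(self):
        factors = [factor("deep") for _ in range(5)]
        a = ka.assess_feasibility(factors).triggered_rules
        b = ka.assess_feasibility(factors).triggered_rules
        assert a == b
        assert [r[0] for r in a] == sorted(r[0] for r in a)


class TestOcclusion:
    def test_wide_ring_open(self, tmp_path):
        p = tmp_path / "wide.pdb"
        ka.generate_ring_and_thread(p, ring_radius=12.0, pierce=True)
        rep = ka.loop_occlusion(str(p), (1, 19), (21, 31))
        assert rep.verdict == "open"
        assert rep.clearance == pytest.approx(12.0 - 1.7, abs=0.2)

    def test_small_bulky_ring_blocked(self, tmp_path):
        p = tmp_path / "bulky.pdb"
        ka.generate_ring_and_thread(
            p, ring_radius=4.5, ring_atom_radius=4.0, pierce=True
        )
        import json

        side = json.load(open(str(p) + ".json"))
        rep = ka.loop_occlusion(
            str(p), tuple(side["ring_span"]), tuple(side["thread_span"])
        )
        assert rep.verdict == "blocked"

    def test_unpierced_ring_raises(self, tmp_path):
        from knotaudit.plausibility import PiercingError

        p = tmp_path / "miss.pdb"
        ka.generate_ring_and_thread(p, ring_radius=12.0, pierce=False)
        import json

        side = json.load(open(str(p) + ".json"))
        with pytest.raises(PiercingError):
            ka.loop_occlusion(
                str(p), tuple(side["ring_span"]), tuple(side["thread_span"])
            )

    def test_clearance_monotone_in_atom_radius(self, tmp_path):
        import json

        clearances = []
        for k, r_atom in enumerate([1.7, 3.0, 4.5, 6.0]):
            p = tmp_path / f"ring{k}.pdb"
            ka.generate_ring_and_thread(
                p, ring_radius=9.0, ring_atom_radius=r_atom, pierce=True
            )
            side = json.load(open(str(p) + ".json"))
            rep = ka.loop_occlusion(
                str(p), tuple(side["ring_span"]), tuple(side["thread_span"])
            )
            clearances.append(rep.clearance)
        assert all(a > b for a, b in zip(clearances, clearances[1:]))


class TestDomainOverlap:
    @staticmethod
    def _blob(seed, n=40):
        rng = np.random.default_rng(seed)
        return rng.normal(scale=4.0, size=(n, 3))

    def _trace(self, c1, c2):
        coords = np.vstack([c1, c2])
        return ka.CATrace("A", np.arange(1, len(coords) + 1), coords)

    def test_separated_copies_not_flagged(self):
        blob = self._blob(1)
        tr = self._trace(blob, blob + np.array([50.0, 0, 0]))
        res = ka.domain_overlap(tr, [(1, 40), (41, 80)])
        assert res[0].overlap_score > 2
        assert not res[0].flagged

    def test_superimposed_copies_flagged(self):
        blob = self._blob(1)
        jitter = self._blob(2) * 0.25
        tr = self._trace(blob, blob + jitter)
        res = ka.domain_overlap(tr, [(1, 40), (41, 80)])
        assert res[0].overlap_score < 0.5
        assert res[0].flagged

    def test_score_invariant_under_rigid_motion(self):
        blob = self._blob(3)
        tr = self._trace(blob, blob + np.array([10.0, 0, 0]))
        res0 = ka.domain_overlap(tr, [(1, 40), (41, 80)])
        rng = np.random.default_rng(0)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        moved = self._trace(
            blob @ q.T + 30, (blob + np.array([10.0, 0, 0])) @ q.T + 30
        )
        res1 = ka.domain_overlap(moved, [(1, 40), (41, 80)])
        assert res0[0].overlap_score == pytest.approx(
            res1[0].overlap_score, abs=1e-9
        )
        assert res0[0].clash_count == res1[0].clash_count

    def test_sequence_overlapping_spans_rejected(self):
        tr = self._trace(self._blob(1), self._blob(2))
        with pytest.raises(ValueError):
            ka.domain_overlap(tr, [(1, 50), (40, 80)])


class TestConfidence:
    def _trace_with_plddt(self, plddt):
        n = len(plddt)
        coords = np.column_stack(
            [np.arange(n) * 3.8, np.zeros(n), np.zeros(n)]
        )
        return ka.CATrace(
            "A", np.arange(1, n + 1), coords, plddt=np.asarray(plddt)
        )

    def test_uniform_segment_mean(self):
        tr = self._trace_with_plddt([80.0] * 30)
        prof = ka.confidence_profile(tr, [("seg", 1, 30)])
        assert prof["segments"][0]["mean_plddt"] == pytest.approx(80.0)
        assert prof["segments"][0]["class"] == "good"

    def test_masking_flag_requires_implausible_verdict(self):
        plddt = [92.0] * 60 + [65.0] * 60
        tr = self._trace_with_plddt(plddt)
        bad = ka.assess_feasibility(
            [factor("shallow") for _ in range(10)]
        )
        prof = ka.confidence_profile(tr, verdict=bad)
        assert prof["global_mean"] == pytest.approx(78.5)
        assert prof["masking"]
        ok = ka.assess_feasibility([factor("shallow")])
        prof2 = ka.confidence_profile(tr, verdict=ok)
        assert not prof2["masking"]

    def test_empty_segments_global_row_only(self):
        tr = self._trace_with_plddt([95.0] * 20)
        prof = ka.confidence_profile(tr)
        assert prof["segments"] == []
        assert prof["global_class"] == "high"

    def test_missing_plddt_refused(self):
        tr = ka.CATrace(
            "A", np.arange(1, 4),
            np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]]),
        )
        with pytest.raises(ValueError):
            ka.confidence_profile(tr)
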