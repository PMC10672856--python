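"""Fingerprints, knotted-core decomposition, slipknot detection."""

import numpy as np
import pytest

import knotaudit as ka
from knotaudit.fingerprint import KnotFingerprint, cores_to_factors
from knotaudit.topology import KnotLabel


def test_full_chain_entry_matches_classify(trefoil_trace):
    fp = KnotFingerprint(trefoil_trace, step=5, n_closures=30, seed=2)
    whole = fp.whole()
    direct = ka.classify_knot(
        trefoil_trace,
        n_closures=30,
        seed=fp._interval_seed(1, fp.n),
        early_stop=25,
    )
    assert whole == direct
    assert (1, fp.n) in fp.labels


def test_unknotted_chain_all_entries_trivial(unknot_trace):
    fp = KnotFingerprint(unknot_trace, step=20, n_closures=20, seed=2)
    fp.compute_full()
    assert all(lab.notation == "0_1" for lab in fp.labels.values())
    assert ka.find_cores(fp) == []


def test_single_trefoil_yields_one_shallow_factor(trefoil_trace):
    fp = KnotFingerprint(trefoil_trace, step=5, n_closures=50, seed=3)
    factors = ka.find_cores(fp)
    assert len(factors) == 1
    f = factors[0]
    assert f.label.notation == "3_1"
    assert f.core_start < f.core_end
    # generated units are cut shallowly: the core reaches near both ends
    assert f.depth_class == "shallow"


def test_core_localisation_excludes_tails():
    """Trimming past the core boundary unties the subchain."""
    tr = ka.generate_knot(
        ka.KnotRecipe(knot="3_1", n_points=100, noise_sigma=0.2, seed=11)
    )
    fp = KnotFingerprint(tr, step=5, n_closures=50, seed=3)
    f = ka.find_cores(fp)[0]
    # the interval strictly inside the core is no longer the full knot
    inner = fp.at(min(f.core_start + 10, fp.n - 21), fp.n)
    assert not (
        inner.notation == "3_1" and inner.probability >= 0.9
    ) or f.core_start + 10 > f.core_end


def test_unknot_plus_trefoil_gives_single_factor():
    tr = ka.concat_knots(
        [
            ka.KnotRecipe(knot="0_1", n_points=60, noise_sigma=0.2, seed=1),
            ka.KnotRecipe(knot="3_1", n_points=90, noise_sigma=0.2, seed=2),
            ka.KnotRecipe(knot="0_1", n_points=60, noise_sigma=0.2, seed=3),
        ]
    )
    assert tr.meta["ground_truth_factors"] == ["3_1"]
    fp = KnotFingerprint(tr, step=5, n_closures=50, seed=4)
    factors = ka.find_cores(fp)
    assert [f.label.notation for f in factors] == ["3_1"]


def test_slipknot_has_no_factors_but_is_detected(slipknot_trace):
    fp = KnotFingerprint(slipknot_trace, step=10, n_closures=36, seed=5)
    assert ka.find_cores(fp) == []
    hits = ka.detect_slipknots(fp)
    assert len(hits) >= 1
    (i, j), lab = hits[0]
    assert lab.notation == "3_1"
    # the knotted subchain sits in the prefix of the chain
    assert i <= 11
    assert j <= slipknot_trace.meta["knotted_prefix_end"] + 10


def test_plain_trefoil_is_not_a_slipknot(trefoil_trace):
    fp = KnotFingerprint(trefoil_trace, step=10, n_closures=30, seed=6)
    assert ka.detect_slipknots(fp) == []


def test_interval_bounds_checked(trefoil_trace):
    fp = KnotFingerprint(trefoil_trace, step=5, n_closures=10, seed=1)
    with pytest.raises(IndexError):
        fp.at(0, 50)
    with pytest.raises(IndexError):
        fp.at(10, fp.n + 1)


def test_depth_classification_threshold():
    """Cores exactly at the configured depth threshold stay shallow; one
    residue beyond becomes deep."""
    lab = KnotLabel("3_1", 1.0)
    n = 200
    shallow = cores_to_factors([(lab, 21, 180)], n, deep_threshold=20)[0]
    assert shallow.depth_n == 20
    assert shallow.depth_class == "shallow"
    deep = cores_to_factors([(lab, 22, 179)], n, deep_threshold=20)[0]
    assert deep.depth_n == 21 and deep.depth_c == 21
    assert deep.depth_class == "deep"
    # internal factors measure depth to the neighbouring cores
    fs = cores_to_factors(
        [(lab, 10, 80), (lab, 120, 190), (lab, 230, 290)], 300,
        deep_threshold=20,
    )
    assert fs[1].depth_n == 120 - 80
    assert fs[1].depth_c == 230 - 190
    assert fs[1].depth_class == "deep"


def test_fingerprint_tsv_roundtrip(tmp_path, unknot_trace):
    fp = KnotFingerprint(unknot_trace, step=40, n_closures=10, seed=1)
    fp.compute_full()
    out = tmp_path / "fp.tsv"
    fp.to_tsv(str(out))
    lines = out.read_text().strip().splitlines()
    assert lines[0].split("\t") == ["start", "end", "label", "probability"]
    assert len(lines) == len(fp.labels) + 1
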