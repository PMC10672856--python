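import numpy as np
import pytest

import knotaudit as ka


@pytest.fixture(scope="session")
def trefoil_trace():
    """Open noisy trefoil chain, reused by read-only tests."""
    return ka.generate_knot(
        ka.KnotRecipe(knot="3_1", n_points=100, noise_sigma=0.2, seed=11)
    )


@pytest.fixture(scope="session")
def unknot_trace():
    return ka.generate_knot(
        ka.KnotRecipe(knot="0_1", n_points=80, noise_sigma=0.2, seed=11)
    )


@pytest.fixture(scope="session")
def slipknot_trace():
    return ka.generate_slipknot(seed=2, noise_sigma=0.2)


@pytest.fixture(scope="session")
def closed_trefoil():
    """Closed parametric trefoil polygon (400 vertices)."""
    from knotaudit.synthetic import _CURVES, _resample_closed

    return _resample_closed(_CURVES["3_1"], 400) * 12.0


@pytest.fixture()
def two_chain_pdb(tmp_path):
    """Minimal two-chain poly-ALA PDB written through gemmi."""
    import gemmi

    st = gemmi.Structure()
    model = gemmi.Model("1")
    rng = np.random.default_rng(3)
    for cname, n in (("A", 6), ("B", 5)):
        ch = gemmi.Chain(cname)
        x = rng.normal(scale=0.2, size=(n, 2))
        for i in range(n):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(3.8 * i + x[i, 0], x[i, 1], 0.0)
            atom.occ = 1.0
            atom.b_iso = 80.0 + i
            res.add_atom(atom)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    path = tmp_path / "two_chain.pdb"
    st.write_pdb(str(path))
    return path
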