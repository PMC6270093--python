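"""Peptide chemistry and the internal-coordinate conformer builder."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppii_ensemble.peptide import (
    ChemFormula,
    Conformer,
    DihedralSet,
    SequenceSpec,
    build_conformer,
    chirality_volumes,
    clash_count,
    get_plan,
    mass,
    peptide_formula,
    wrap_angle,
)

from conftest import circular_diff


# ---------------------------------------------------------------------------
# formulas and masses
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text,expected", [
    ("Ac-YPHNPG-NH2", "C33H44N10O9"),           # capped hexapeptide
    ("G", "C2H5NO2"),                           # free glycine
    ("Ac-(PHNPGY)2-NH2", "C64H83N19O17"),       # capped double hexarepeat
])
def test_peptide_formula(text, expected):
    assert peptide_formula(SequenceSpec.from_string(text)).hill() == expected


def test_unknown_residue_rejected():
    with pytest.raises(ValueError, match="XXX"):
        SequenceSpec(("XXX",))
    with pytest.raises(ValueError, match="'Z'"):
        SequenceSpec.from_string("AZA")


@pytest.mark.parametrize("kind,expected", [
    ("monoisotopic", 724.33),
    ("average", 724.78),
])
def test_capped_hexapeptide_mass(kind, expected):
    f = peptide_formula(SequenceSpec.from_string("Ac-YPHNPG-NH2"))
    assert mass(f, kind) == pytest.approx(expected, abs=0.01)


def test_empty_formula_mass_is_zero():
    assert mass(ChemFormula({}), "monoisotopic") == 0.0
    assert mass(ChemFormula({}), "average") == 0.0


def test_unknown_element_rejected():
    with pytest.raises(ValueError, match="Xx"):
        mass({"Xx": 1})


@settings(deadline=None, derandomize=True)
@given(st.lists(st.sampled_from(["GLY", "PRO", "HIS", "ASN", "TYR"]),
                min_size=1, max_size=8))
def test_formula_arithmetic_order_independent(residues):
    """Residue-formula summation commutes; mass is additive over formulas."""
    import random
    shuffled = list(residues)
    random.Random(0).shuffle(shuffled)
    a = peptide_formula(SequenceSpec(tuple(residues)))
    b = peptide_formula(SequenceSpec(tuple(shuffled)))
    assert a == b
    for kind in ("monoisotopic", "average"):
        assert mass(a + b, kind) == pytest.approx(
            mass(a, kind) + mass(b, kind), rel=1e-12)


# ---------------------------------------------------------------------------
# conformer building
# ---------------------------------------------------------------------------

def test_builder_deterministic(two_hexapy):
    d = DihedralSet.uniform(12, -75.0, 145.0)
    c1 = build_conformer(two_hexapy, d)
    c2 = build_conformer(two_hexapy, d)
    assert np.array_equal(c1.coords, c2.coords)


def test_dihedral_count_mismatch(two_hexapy):
    with pytest.raises(ValueError, match="12"):
        build_conformer(two_hexapy, DihedralSet.uniform(6, -75.0, 145.0))


def test_trans_chain_calpha_spacing(beta_conformer):
    """omega = 180 fixes consecutive CA-CA distances at 3.80 A."""
    cas = np.array([beta_conformer.position(i, "CA") for i in range(1, 13)])
    d = np.linalg.norm(np.diff(cas, axis=0), axis=1)
    assert np.all(np.abs(d - 3.80) < 0.05)


@pytest.mark.parametrize("phi,psi", [(-139.0, 135.0), (-75.0, 145.0),
                                     (-65.0, -40.0), (55.0, 45.0)])
def test_dihedral_round_trip(two_hexapy, phi, psi):
    """Recomputing dihedrals from built coordinates reproduces the inputs."""
    d = DihedralSet.uniform(12, phi, psi)
    back = build_conformer(two_hexapy, d).dihedrals()
    ok = np.isfinite(back.phi)
    assert circular_diff(back.phi[ok], d.phi[ok]).max() < 0.5
    ok = np.isfinite(back.psi)
    assert circular_diff(back.psi[ok], d.psi[ok]).max() < 0.5
    ok = np.isfinite(back.omega)
    assert circular_diff(back.omega[ok], 180.0).max() < 0.5


def test_beta_strand_sequential_proton_distances(beta_conformer):
    """Ideal beta geometry reproduces the standard NOE distance table."""
    d_an = np.linalg.norm(beta_conformer.position(2, "HA")
                          - beta_conformer.position(3, "H"))
    d_nn = np.linalg.norm(beta_conformer.position(2, "H")
                          - beta_conformer.position(3, "H"))
    assert d_an == pytest.approx(2.2, abs=0.15)
    assert d_nn == pytest.approx(4.3, abs=0.2)


def test_bonded_heavy_atom_distances(ppii_conformer):
    plan = get_plan(ppii_conformer.seq)
    for a, b in plan.bonds:
        if plan.elements[a] == "H" or plan.elements[b] == "H":
            continue
        d = np.linalg.norm(ppii_conformer.coords[a] - ppii_conformer.coords[b])
        assert 1.2 < d < 1.9, (plan.names[a], plan.names[b], d)


def test_chirality_all_L(ppii_conformer, beta_conformer):
    """Signed volume about CA has one constant sign for all non-Gly residues."""
    for conf in (ppii_conformer, beta_conformer):
        vols = list(chirality_volumes(conf).values())
        assert all(v > 0 for v in vols) or all(v < 0 for v in vols)
        assert np.std(vols) < 1e-6 * max(1.0, abs(vols[0]))


def test_chirality_sign_matches_rdkit_l_alanine(ppii_conformer):
    """Independent oracle: L-alanine embedded by RDKit has the same sign of
    det[N-CA, C-CA, CB-CA] as the builder's residues."""
    rdkit = pytest.importorskip("rdkit")
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles("N[C@@H](C)C(=O)O"))
    params = AllChem.ETKDGv3()
    params.randomSeed = 7
    assert AllChem.EmbedMolecule(mol, params) == 0
    conf = mol.GetConformer()
    pos = {a.GetIdx(): np.array(conf.GetAtomPosition(a.GetIdx()))
           for a in mol.GetAtoms()}
    # SMILES atom order: 0 N, 1 CA, 2 CB, 3 C(=O)
    ca = pos[1]
    vol = np.linalg.det(np.stack([pos[0] - ca, pos[3] - ca, pos[2] - ca]))
    ours = next(iter(chirality_volumes(ppii_conformer).values()))
    assert np.sign(vol) == np.sign(ours)


# ---------------------------------------------------------------------------
# clash detection
# ---------------------------------------------------------------------------

def test_extended_chain_has_no_clashes(beta_conformer):
    assert clash_count(beta_conformer) == 0


def test_superposed_atoms_clash(two_hexapy):
    c = build_conformer(two_hexapy, DihedralSet.uniform(12, -139.0, 135.0))
    bad = c.coords.copy()
    i = c.atom_index(2, "CA")
    j = c.atom_index(9, "CA")
    bad[j] = bad[i] + 0.1
    assert clash_count(Conformer(two_hexapy, bad)) >= 1


def test_clash_count_matches_brute_force():
    """O(N^2) oracle with an independent bond-graph distance (networkx)."""
    import itertools

    import networkx as nx

    seq = SequenceSpec(("TYR", "PRO", "HIS", "ASN", "GLY"))
    conf = build_conformer(seq, DihedralSet.uniform(5, -65.0, -40.0))
    plan = get_plan(seq)
    g = nx.Graph(plan.bonds)
    threshold = 3.0   # large enough to exercise non-trivial counting
    expected = 0
    heavy = [i for i, el in enumerate(plan.elements) if el != "H"]
    for a, b in itertools.combinations(heavy, 2):
        try:
            hops = nx.shortest_path_length(g, a, b)
        except nx.NetworkXNoPath:
            hops = 99
        if hops >= 3 and np.linalg.norm(conf.coords[a] - conf.coords[b]) < threshold:
            expected += 1
    assert clash_count(conf, threshold=threshold) == expected


def test_clash_threshold_must_be_positive(beta_conformer):
    with pytest.raises(ValueError):
        clash_count(beta_conformer, threshold=0.0)


def test_wrap_angle_domain():
    vals = wrap_angle(np.array([-180.0, 180.0, 540.0, -190.0, 0.0]))
    assert np.all(vals > -180.0) and np.all(vals <= 180.0)
    assert vals[0] == 180.0 and vals[1] == 180.0 and vals[2] == 180.0
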