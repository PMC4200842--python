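"""Structure I/O, activity transform, PEOE charges and atom typing."""

import math

import numpy as np
import pytest

from fieldqsar._tables import PEOE_H_CATION_CHI, PEOE_PARAMS
from fieldqsar.chem_io import (
    Atom,
    Molecule,
    PropertyRuleset,
    assign_peoe_charges,
    assign_property_weights,
    attach_activities,
    read_activities,
    read_structures,
    to_pIC50,
    write_structures,
)


def _methane():
    atoms = [Atom("C", np.zeros(3))]
    # tetrahedral-ish hydrogens; exact geometry is irrelevant to PEOE
    for i, v in enumerate(
        [(1.09, 0, 0), (-0.36, 1.03, 0), (-0.36, -0.51, 0.89), (-0.36, -0.51, -0.89)]
    ):
        atoms.append(Atom("H", np.array(v, dtype=float)))
    return Molecule("methane", atoms, bonds=[(0, i, 1.0) for i in range(1, 5)])


def _ethanol():
    coords = {
        "C1": (0, 0, 0), "C2": (1.5, 0, 0), "O": (2.2, 1.2, 0),
        "H1": (-0.5, 0.9, 0.2), "H2": (-0.5, -0.9, 0.2), "H3": (-0.3, 0, -1.0),
        "H4": (1.9, -0.5, 0.9), "H5": (1.9, -0.5, -0.9), "HO": (3.1, 1.0, 0.2),
    }
    els = ["C", "C", "O", "H", "H", "H", "H", "H", "H"]
    atoms = [Atom(e, np.array(c, dtype=float)) for e, c in zip(els, coords.values())]
    bonds = [(0, 1, 1.0), (1, 2, 1.0), (0, 3, 1.0), (0, 4, 1.0), (0, 5, 1.0),
             (1, 6, 1.0), (1, 7, 1.0), (2, 8, 1.0)]
    return Molecule("ethanol", atoms, bonds=bonds)


# --------------------------------------------------------------------- SDF

def test_sdf_read_counts_and_elements(embedded_sdf):
    mols = read_structures(embedded_sdf, format="sdf")
    assert [m.id for m in mols] == ["ethanol", "benzamide"]
    assert mols[0].n_atoms == 9  # CCO + 6 H
    assert sum(a.element == "C" for a in mols[1].atoms) == 7


def test_sdf_round_trip_preserves_coordinates(embedded_sdf, tmp_path):
    mols = read_structures(embedded_sdf, format="sdf")
    out = tmp_path / "out.sdf"
    write_structures(mols, str(out))
    back = read_structures(out, format="sdf")
    for a, b in zip(mols, back):
        assert a.id == b.id
        assert [x.element for x in a.atoms] == [x.element for x in b.atoms]
        # SDF V2000 stores 4 decimal places
        np.testing.assert_allclose(a.coords(), b.coords(), atol=5e-5)


def test_flat_2d_record_rejected(tmp_path):
    from rdkit import Chem

    mol = Chem.AddHs(Chem.MolFromSmiles("CCO"))
    Chem.rdDepictor.Compute2DCoords(mol)
    path = tmp_path / "flat.sdf"
    w = Chem.SDWriter(str(path))
    w.write(mol)
    w.close()
    with pytest.raises(ValueError, match="3D coordinates required"):
        read_structures(path, format="sdf")


def test_mol2_reader_keeps_external_charges(tmp_path):
    mol2 = """\
@<TRIPOS>MOLECULE
charged_water
3 2 1
SMALL
USER_CHARGES
@<TRIPOS>ATOM
1 O1 0.0000 0.0000 0.1173 O.3 1 WAT -0.8340
2 H1 0.0000 0.7572 -0.4692 H 1 WAT 0.4170
3 H2 0.0000 -0.7572 -0.4692 H 1 WAT 0.4170
@<TRIPOS>BOND
1 1 2 1
2 1 3 1
"""
    path = tmp_path / "w.mol2"
    path.write_text(mol2)
    (mol,) = read_structures(path, format="mol2")
    assert mol.id == "charged_water"
    assert mol.atoms[0].element == "O"
    np.testing.assert_allclose(mol.atom_array("partial_charge"), [-0.834, 0.417, 0.417])


# ------------------------------------------------------------------ pIC50

@pytest.mark.parametrize(
    "ic50, expected", [(1.0, 9.0), (1000.0, 6.0), (3.47, 8.46)]
)
def test_pic50_transform(ic50, expected):
    assert to_pIC50(ic50) == pytest.approx(expected, abs=5e-3)


def test_pic50_rejects_nonpositive():
    with pytest.raises(ValueError):
        to_pIC50(0.0)
    with pytest.raises(ValueError):
        to_pIC50(-2.0)


def test_activity_csv_roundtrip(tmp_path):
    path = tmp_path / "act.csv"
    path.write_text("id,ic50_nM,split\nm1,1.0,train\nm2,1000.0,test\n")
    table = read_activities(path)
    assert list(table["pIC50"]) == pytest.approx([9.0, 6.0])
    mol = Molecule("m2", [Atom("C", np.zeros(3))])
    attach_activities([mol], table)
    assert mol.activity_pIC50 == pytest.approx(6.0)
    assert mol.split_label == "test"


def test_activity_csv_duplicate_id_rejected(tmp_path):
    path = tmp_path / "dup.csv"
    path.write_text("id,pIC50\nm1,7.0\nm1,8.0\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_activities(path)


# ------------------------------------------------------------------- PEOE

def _peoe_oracle(mol, iterations=6, damping=0.5):
    """Literal transcription of the PEOE recurrence, atom by atom."""
    def params(i):
        el = mol.atoms[i].element
        if el == "H":
            return PEOE_PARAMS[("H", "s")]
        orders = [o for _, o in mol.neighbors(i)]
        if any(o == 3.0 for o in orders) or sum(o == 2.0 for o in orders) >= 2:
            hyb = "sp"
        elif any(o in (2.0, 1.5) for o in orders):
            hyb = "sp2"
        else:
            hyb = "sp3"
        return PEOE_PARAMS[(el, hyb)]

    q = [float(a.formal_charge) for a in mol.atoms]
    for k in range(1, iterations + 1):
        chi = []
        for i in range(mol.n_atoms):
            a, b, c = params(i)
            chi.append(a + b * q[i] + c * q[i] ** 2)
        moves = []
        for i, j, _ in mol.bonds:
            lo, hi = (i, j) if chi[j] > chi[i] else (j, i)
            if mol.atoms[lo].element == "H":
                denom = PEOE_H_CATION_CHI
            else:
                a, b, c = params(lo)
                denom = a + b + c
            moves.append((lo, hi, (chi[hi] - chi[lo]) / denom * damping**k))
        for lo, hi, dq in moves:
            q[lo] += dq
            q[hi] -= dq
    return q


def test_peoe_h2_is_chargeless():
    mol = Molecule(
        "h2",
        [Atom("H", np.zeros(3)), Atom("H", np.array([0.74, 0, 0]))],
        bonds=[(0, 1, 1.0)],
    )
    out = assign_peoe_charges(mol)
    assert out.atom_array("partial_charge") == pytest.approx([0.0, 0.0], abs=1e-12)


@pytest.mark.parametrize("builder", [_methane, _ethanol])
def test_peoe_conserves_charge_and_matches_oracle(builder):
    mol = builder()
    out = assign_peoe_charges(mol)
    q = out.atom_array("partial_charge")
    assert abs(q.sum() - sum(a.formal_charge for a in mol.atoms)) < 1e-6
    np.testing.assert_allclose(q, _peoe_oracle(mol), atol=1e-4)


def test_peoe_methane_symmetry_and_polarity():
    out = assign_peoe_charges(_methane())
    q = out.atom_array("partial_charge")
    assert q[0] < 0  # carbon pulls density from hydrogen
    assert np.ptp(q[1:]) < 1e-6  # equivalent hydrogens


def test_peoe_agrees_with_rdkit_gasteiger():
    """Independent implementation check: RDKit's Gasteiger charges on the
    same sp3 molecule use the same 1980 parameter set."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rd = Chem.AddHs(Chem.MolFromSmiles("CCO"))
    AllChem.ComputeGasteigerCharges(rd, nIter=6)
    ref = [a.GetDoubleProp("_GasteigerCharge") for a in rd.GetAtoms()]
    ours = assign_peoe_charges(_ethanol()).atom_array("partial_charge")
    np.testing.assert_allclose(sorted(ours), sorted(ref), atol=5e-3)


def test_peoe_errors():
    noble = Molecule("xe", [Atom("Xe", np.zeros(3))])
    with pytest.raises(ValueError, match="Xe"):
        assign_peoe_charges(noble)
    bare = Molecule(
        "c2", [Atom("C", np.zeros(3)), Atom("C", np.array([1.5, 0, 0]))],
        bonds=[(0, 1, 1.0)],
    )
    with pytest.raises(ValueError, match="hydrogens"):
        assign_peoe_charges(bare)


# --------------------------------------------------------------- weights

def _benzamide_like():
    # C6H5-C(=O)-NH2 without ring hydrogens (enough for the typing rules)
    atoms = [Atom("C", np.array([float(i), 0.0, 0.0])) for i in range(6)]
    atoms += [
        Atom("C", np.array([6.0, 0, 0])),   # carbonyl C
        Atom("O", np.array([6.5, 1.0, 0])),  # carbonyl O
        Atom("N", np.array([6.8, -1.0, 0])),
        Atom("H", np.array([7.6, -1.2, 0])),
        Atom("H", np.array([6.4, -1.9, 0])),
    ]
    ring = [(i, (i + 1) % 6, 1.5) for i in range(6)]
    bonds = ring + [(5, 6, 1.0), (6, 7, 2.0), (6, 8, 1.0), (8, 9, 1.0), (8, 10, 1.0)]
    return Molecule("benzamide", atoms, bonds=bonds)


def test_property_weight_rules():
    mol = assign_property_weights(_benzamide_like())
    carbonyl_o, amide_n = mol.atoms[7], mol.atoms[8]
    assert carbonyl_o.acceptor_weight == 1.0 and carbonyl_o.donor_weight == 0.0
    assert amide_n.donor_weight == 1.0
    assert amide_n.acceptor_weight == 0.0  # amide exclusion
    benzene_c = mol.atoms[0]
    assert benzene_c.hydrophobic_weight > 0
    assert benzene_c.steric_weight == pytest.approx(1.70**3)


def test_typing_is_deterministic():
    a = assign_property_weights(_benzamide_like())
    b = assign_property_weights(_benzamide_like())
    for attr in ("hydrophobic_weight", "donor_weight", "acceptor_weight", "steric_weight"):
        np.testing.assert_array_equal(a.atom_array(attr), b.atom_array(attr))


def test_weights_require_bonds():
    mol = Molecule("pair", [Atom("C", np.zeros(3)), Atom("O", np.ones(3))])
    with pytest.raises(ValueError, match="bond"):
        assign_property_weights(mol)


def test_custom_hydrophobic_table():
    rules = PropertyRuleset()
    rules.hydrophobic_table["C_apolar"] = 2.5
    mol = assign_property_weights(_benzamide_like(), rules)
    assert mol.atoms[0].hydrophobic_weight == 2.5
    assert rules.hash() != PropertyRuleset().hash()
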