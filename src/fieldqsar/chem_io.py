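"""Molecular structure I/O, activities, partial charges and CoMSIA atom weights.

The unit record is :class:`Molecule` — an ordered list of atoms with 3D
coordinates, bonds, per-atom physicochemical weights, and an optional
activity (pIC50) plus train/test split label.  SDF (V2000) is the primary
interchange format, read and written through RDKit; MOL2 is supported as a
carrier for externally assigned partial charges.

Partial charges are assigned by PEOE (partial equalization of orbital
electronegativities), the iterative sigma-charge scheme behind Gasteiger
charges.  CoMSIA property weights (steric, electrostatic, hydrophobic,
H-bond donor/acceptor) are assigned by a configurable rule set; donor and
acceptor weights sit on the heavy atoms themselves rather than on projected
lone-pair sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._tables import (
    BONDI_VDW_RADII,
    HYDROPHOBIC_TABLE,
    PEOE_H_CATION_CHI,
    PEOE_PARAMS,
    table_hash,
)

SPLIT_LABELS = ("train", "test", "unassigned")


@dataclass
class Atom:
    """One atom: element, position (Å) and the per-property CoMSIA weights."""

    element: str
    coords: np.ndarray  # shape (3,), Å
    formal_charge: int = 0
    partial_charge: float = 0.0
    vdw_radius: float = 0.0
    steric_weight: float = 0.0      # r_vdw**3 by convention
    hydrophobic_weight: float = 0.0
    donor_weight: float = 0.0       # 0 or 1
    acceptor_weight: float = 0.0    # 0 or 1

    def copy(self) -> "Atom":
        return replace(self, coords=np.array(self.coords, dtype=float))


@dataclass
class Molecule:
    """An ordered atom list with bonds, activity and split membership.

    ``bonds`` are (i, j, order) triples with order 1.0, 1.5 (aromatic),
    2.0 or 3.0; indices refer to positions in ``atoms``.
    """

    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    activity_pIC50: float | None = None
    split_label: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        if self.split_label not in SPLIT_LABELS:
            raise ValueError(f"invalid split label {self.split_label!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, row in zip(self.atoms, xyz):
            atom.coords = row.copy()

    def atom_array(self, attr: str) -> np.ndarray:
        return np.array([getattr(a, attr) for a in self.atoms], dtype=float)

    def copy(self) -> "Molecule":
        return Molecule(
            id=self.id,
            atoms=[a.copy() for a in self.atoms],
            bonds=list(self.bonds),
            activity_pIC50=self.activity_pIC50,
            split_label=self.split_label,
        )

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        """Bonded neighbour indices of atom i with bond orders."""
        out = []
        for a, b, order in self.bonds:
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out


# ---------------------------------------------------------------------------
# structure reading / writing
# ---------------------------------------------------------------------------

_BOND_ORDER_FROM_RDKIT = {"SINGLE": 1.0, "DOUBLE": 2.0, "TRIPLE": 3.0, "AROMATIC": 1.5}


def _check_3d(coords: np.ndarray, label: str) -> None:
    # a record whose z column is identically zero is a 2D depiction
    if coords.shape[0] >= 3 and np.allclose(coords[:, 2], 0.0, atol=1e-8):
        raise ValueError(f"record {label}: 3D coordinates required")


def _from_rdkit(rdmol, mol_id: str) -> Molecule:
    conf = rdmol.GetConformer()
    atoms = []
    for idx, at in enumerate(rdmol.GetAtoms()):
        pos = conf.GetAtomPosition(idx)
        sym = at.GetSymbol()
        atoms.append(
            Atom(
                element=sym,
                coords=np.array([pos.x, pos.y, pos.z], dtype=float),
                formal_charge=at.GetFormalCharge(),
                vdw_radius=BONDI_VDW_RADII.get(sym, 1.70),
            )
        )
    bonds = [
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            _BOND_ORDER_FROM_RDKIT.get(str(b.GetBondType()), 1.0),
        )
        for b in rdmol.GetBonds()
    ]
    return Molecule(id=mol_id, atoms=atoms, bonds=bonds)


def read_structures(path: str, format: str = "sdf") -> list[Molecule]:
    """Read a multi-molecule structure file into Molecules.

    SDF is parsed with RDKit (hydrogens retained, atom order preserved);
    MOL2 with a TRIPOS section reader that keeps externally assigned
    partial charges.  Records with all-zero z coordinates are rejected as
    2D depictions.
    """
    if format == "sdf":
        return _read_sdf(path)
    if format == "mol2":
        return _read_mol2(path)
    raise ValueError(f"unknown structure format {format!r}")


def _read_sdf(path: str) -> list[Molecule]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    molecules: list[Molecule] = []
    for rec_idx, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ValueError(f"unparseable SDF record at index {rec_idx}")
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
        mol_id = name.strip() or f"mol_{rec_idx}"
        mol = _from_rdkit(rdmol, mol_id)
        _check_3d(mol.coords(), f"{rec_idx} ({mol_id})")
        molecules.append(mol)
    return molecules


def _read_mol2(path: str) -> list[Molecule]:
    # TRIPOS MOL2: @<TRIPOS>MOLECULE / ATOM / BOND sections.  Atom records
    # carry SYBYL atom types (e.g. C.3) and, in column 9, partial charges.
    with open(path) as fh:
        lines = fh.read().splitlines()
    molecules: list[Molecule] = []
    i = 0
    rec_idx = -1
    while i < len(lines):
        if lines[i].strip() != "@<TRIPOS>MOLECULE":
            i += 1
            continue
        rec_idx += 1
        try:
            mol_id = lines[i + 1].strip() or f"mol_{rec_idx}"
            section = None
            atoms: list[Atom] = []
            bonds: list[tuple[int, int, float]] = []
            i += 2
            while i < len(lines) and lines[i].strip() != "@<TRIPOS>MOLECULE":
                line = lines[i].strip()
                if line.startswith("@<TRIPOS>"):
                    section = line[9:]
                elif line and section == "ATOM":
                    parts = line.split()
                    sym = parts[5].split(".")[0].capitalize()
                    charge = float(parts[8]) if len(parts) > 8 else 0.0
                    atoms.append(
                        Atom(
                            element=sym,
                            coords=np.array(
                                [float(parts[2]), float(parts[3]), float(parts[4])]
                            ),
                            partial_charge=charge,
                            vdw_radius=BONDI_VDW_RADII.get(sym, 1.70),
                        )
                    )
                elif line and section == "BOND":
                    parts = line.split()
                    order = {"1": 1.0, "2": 2.0, "3": 3.0, "ar": 1.5, "am": 1.0}.get(
                        parts[3], 1.0
                    )
                    bonds.append((int(parts[1]) - 1, int(parts[2]) - 1, order))
                i += 1
            if not atoms:
                raise ValueError("no atoms")
            mol = Molecule(id=mol_id, atoms=atoms, bonds=bonds)
            _check_3d(mol.coords(), f"{rec_idx} ({mol_id})")
            molecules.append(mol)
        except (IndexError, ValueError) as exc:
            if "3D coordinates" in str(exc):
                raise
            raise ValueError(f"unparseable MOL2 record at index {rec_idx}: {exc}")
    if rec_idx < 0:
        raise ValueError("no MOL2 records found")
    return molecules


def write_structures(molecules: list[Molecule], path: str) -> None:
    """Write Molecules to an SDF file (V2000), preserving atom order."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    order_to_rdkit = {
        1.0: Chem.BondType.SINGLE,
        1.5: Chem.BondType.AROMATIC,
        2.0: Chem.BondType.DOUBLE,
        3.0: Chem.BondType.TRIPLE,
    }
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for mol in molecules:
            rw = Chem.RWMol()
            for atom in mol.atoms:
                a = Chem.Atom(atom.element)
                a.SetFormalCharge(atom.formal_charge)
                a.SetNoImplicit(True)
                rw.AddAtom(a)
            for i, j, order in mol.bonds:
                rw.AddBond(i, j, order_to_rdkit.get(order, Chem.BondType.SINGLE))
            conf = Chem.Conformer(mol.n_atoms)
            for idx, atom in enumerate(mol.atoms):
                conf.SetAtomPosition(idx, Point3D(*map(float, atom.coords)))
            rw.AddConformer(conf)
            out = rw.GetMol()
            out.SetProp("_Name", mol.id)
            Chem.SanitizeMol(
                out, Chem.SanitizeFlags.SANITIZE_FINDRADICALS, catchErrors=True
            )
            out.UpdatePropertyCache(strict=False)
            writer.write(out)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# activities
# ---------------------------------------------------------------------------

def to_pIC50(ic50_nM: float) -> float:
    """Convert an IC50 in nM to pIC50 = −log10(IC50 in mol/L) = 9 − log10(nM)."""
    if not ic50_nM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return 9.0 - math.log10(ic50_nM)


def read_activities(path: str) -> pd.DataFrame:
    """Read an activity table CSV.

    Header must contain ``id`` and one of ``ic50_nM`` / ``pIC50``; an
    optional ``split`` column holds train/test labels.  Returns a frame
    with columns ``id``, ``pIC50``, ``split`` (one row per molecule id).
    """
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError("activity table must have an 'id' column")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate molecule id in activity table: {dup!r}")
    if "pIC50" in df.columns:
        p = df["pIC50"].astype(float)
    elif "ic50_nM" in df.columns:
        if (df["ic50_nM"] <= 0).any():
            raise ValueError("IC50 values must be positive")
        p = df["ic50_nM"].astype(float).map(to_pIC50)
    else:
        raise ValueError("activity table needs an 'ic50_nM' or 'pIC50' column")
    split = df["split"] if "split" in df.columns else "unassigned"
    out = pd.DataFrame({"id": df["id"].astype(str), "pIC50": p, "split": split})
    bad = set(out["split"]) - set(SPLIT_LABELS)
    if bad:
        raise ValueError(f"invalid split labels: {sorted(bad)}")
    return out


def attach_activities(molecules: list[Molecule], table: pd.DataFrame) -> None:
    """Set activity and split label on molecules from an activity frame."""
    by_id = table.set_index("id")
    for mol in molecules:
        if mol.id in by_id.index:
            mol.activity_pIC50 = float(by_id.loc[mol.id, "pIC50"])
            mol.split_label = str(by_id.loc[mol.id, "split"])


# ---------------------------------------------------------------------------
# PEOE (Gasteiger) partial charges
# ---------------------------------------------------------------------------

def _hybridization(mol: Molecule, i: int) -> str:
    if mol.atoms[i].element == "H":
        return "s"
    orders = [o for _, o in mol.neighbors(i)]
    if any(o == 3.0 for o in orders) or sum(1 for o in orders if o == 2.0) >= 2:
        return "sp"
    if any(o in (2.0, 1.5) for o in orders):
        return "sp2"
    return "sp3"


def _peoe_params_for(mol: Molecule) -> list[tuple[float, float, float]]:
    params = []
    missing = set()
    for i, atom in enumerate(mol.atoms):
        hyb = _hybridization(mol, i)
        key = (atom.element, hyb)
        if key not in PEOE_PARAMS:
            # fall back across hybridizations before giving up
            alts = [k for k in PEOE_PARAMS if k[0] == atom.element]
            if alts:
                key = alts[0]
            else:
                missing.add(atom.element)
                continue
        params.append(PEOE_PARAMS[key])
    if missing:
        raise ValueError(
            f"no PEOE parameters for element(s): {sorted(missing)}"
        )
    return params


def assign_peoe_charges(
    mol: Molecule, iterations: int = 6, damping: float = 0.5
) -> Molecule:
    """Assign sigma partial charges by partial equalization of orbital
    electronegativities.

    Each iteration k transfers charge across every bond from the less to the
    more electronegative atom, scaled by ``damping**k``; electronegativity
    chi(q) = a + b·q + c·q² is re-evaluated from the running charges.  Total
    charge is conserved exactly and symmetry-equivalent atoms end up with
    identical charges.
    """
    if mol.n_atoms > 1 and not mol.bonds:
        raise ValueError(f"molecule {mol.id!r}: bond information required for PEOE")
    heavy_with_h = any(a.element == "H" for a in mol.atoms)
    needs_h = any(a.element in ("C", "N", "O") for a in mol.atoms)
    if needs_h and not heavy_with_h:
        raise ValueError(
            f"molecule {mol.id!r}: explicit hydrogens required for PEOE charges"
        )
    params = _peoe_params_for(mol)
    a = np.array([p[0] for p in params])
    b = np.array([p[1] for p in params])
    c = np.array([p[2] for p in params])
    # cation electronegativity chi(+1); hydrogen uses the fixed 20.02 eV
    chi_plus = a + b + c
    for i, atom in enumerate(mol.atoms):
        if atom.element == "H":
            chi_plus[i] = PEOE_H_CATION_CHI

    q = np.array([float(at.formal_charge) for at in mol.atoms])
    for k in range(1, iterations + 1):
        chi = a + b * q + c * q * q
        damp = damping**k
        dq = np.zeros_like(q)
        for i, j, _ in mol.bonds:
            if chi[j] > chi[i]:
                lo, hi = i, j
            else:
                lo, hi = j, i
            transfer = (chi[hi] - chi[lo]) / chi_plus[lo] * damp
            dq[lo] += transfer
            dq[hi] -= transfer
        q += dq

    out = mol.copy()
    for atom, charge in zip(out.atoms, q):
        atom.partial_charge = float(charge)
    return out


# ---------------------------------------------------------------------------
# CoMSIA property weights
# ---------------------------------------------------------------------------

@dataclass
class PropertyRuleset:
    """Configurable atom-typing rules behind the CoMSIA weights.

    ``acceptor_exclusions`` may contain ``"amide"`` (N single-bonded to a
    carbonyl carbon) and ``"aniline"`` (N single-bonded to an aromatic
    atom); such nitrogens are not counted as acceptors.
    """

    hydrophobic_table: dict[str, float] = field(
        default_factory=lambda: dict(HYDROPHOBIC_TABLE)
    )
    acceptor_exclusions: tuple[str, ...] = ("amide", "aniline")
    vdw_radii: dict[str, float] = field(
        default_factory=lambda: dict(BONDI_VDW_RADII)
    )

    def hash(self) -> str:
        return table_hash(
            self.hydrophobic_table,
            {"excl": ",".join(self.acceptor_exclusions)},
            self.vdw_radii,
        )


_HALOGENS = {"F", "Cl", "Br", "I"}


def _is_acceptor_nitrogen(mol: Molecule, i: int, rules: PropertyRuleset) -> bool:
    atom = mol.atoms[i]
    if atom.formal_charge > 0:
        return False
    for j, order in mol.neighbors(i):
        nb = mol.atoms[j]
        if "amide" in rules.acceptor_exclusions and nb.element == "C" and order == 1.0:
            # carbonyl carbon neighbour -> amide-type conjugation
            if any(
                mol.atoms[k].element in ("O", "S") and o == 2.0
                for k, o in mol.neighbors(j)
            ):
                return False
        if "aniline" in rules.acceptor_exclusions and order == 1.0:
            if any(o == 1.5 for _, o in mol.neighbors(j)):
                return False
    return True


def _hydrophobic_weight(mol: Molecule, i: int, table: dict[str, float]) -> float:
    atom = mol.atoms[i]
    el = atom.element
    nb_elements = [mol.atoms[j].element for j, _ in mol.neighbors(i)]
    if el == "C":
        key = "C_polar" if any(e in ("N", "O", "S") for e in nb_elements) else "C_apolar"
    elif el in _HALOGENS:
        key = "halogen"
    elif el == "H":
        key = "H_on_polar" if any(e in ("N", "O") for e in nb_elements) else "H_on_apolar"
    elif el in table:
        key = el
    else:
        return 0.0
    return table[key]


def assign_property_weights(
    mol: Molecule, rules: PropertyRuleset | None = None
) -> Molecule:
    """Assign steric, hydrophobic and donor/acceptor weights to every atom.

    Donor: N or O bearing at least one hydrogen.  Acceptor: every O, and N
    unless excluded by the ruleset.  Steric weight is vdw_radius cubed.
    """
    if mol.n_atoms > 1 and not mol.bonds:
        raise ValueError(f"molecule {mol.id!r}: bond information required")
    rules = rules or PropertyRuleset()
    out = mol.copy()
    for i, atom in enumerate(out.atoms):
        atom.vdw_radius = rules.vdw_radii.get(atom.element, atom.vdw_radius or 1.70)
        atom.steric_weight = atom.vdw_radius**3
        atom.hydrophobic_weight = _hydrophobic_weight(out, i, rules.hydrophobic_table)
        has_h = any(out.atoms[j].element == "H" for j, _ in out.neighbors(i))
        atom.donor_weight = 1.0 if atom.element in ("N", "O") and has_h else 0.0
        if atom.element == "O":
            atom.acceptor_weight = 1.0
        elif atom.element == "N":
            atom.acceptor_weight = (
                1.0 if _is_acceptor_nitrogen(out, i, rules) else 0.0
            )
        else:
            atom.acceptor_weight = 0.0
    return out
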