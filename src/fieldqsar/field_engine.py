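"""CoMFA and CoMSIA molecular interaction fields on a shared lattice.

CoMFA samples probe–molecule interaction energies on a rectangular grid:
steric energies from a Lennard-Jones potential (truncated at +30 kcal/mol)
and electrostatic energies from a Coulomb potential with a
distance-dependent dielectric, eps(r) = r.  CoMSIA instead evaluates
Gaussian-attenuated similarity indices

    A_k(q) = - sum_i  w_probe,k * w_ik * exp(-alpha * r_iq^2)

for five physicochemical properties k: steric (S), electrostatic (E),
hydrophobic (H), H-bond donor (D) and H-bond acceptor (A), with attenuation
factor alpha = 0.3 by default.  The Gaussian needs no cutoff and yields
smooth fields, which is the practical advantage of similarity indices over
the hard-walled CoMFA potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._tables import LJ_EPSILON, lj_sigma
from .alignment import AlignedSet
from .chem_io import Molecule

COULOMB_CONSTANT = 332.17  # kcal·Å/(mol·e²)

COMFA_KINDS = ("CoMFA_steric", "CoMFA_electrostatic")
COMSIA_KINDS = ("CoMSIA_S", "CoMSIA_E", "CoMSIA_H", "CoMSIA_D", "CoMSIA_A")
ALL_KINDS = COMFA_KINDS + COMSIA_KINDS

_COMSIA_WEIGHT_ATTR = {
    "CoMSIA_S": "steric_weight",
    "CoMSIA_E": "partial_charge",
    "CoMSIA_H": "hydrophobic_weight",
    "CoMSIA_D": "donor_weight",
    "CoMSIA_A": "acceptor_weight",
}


@dataclass(frozen=True)
class Lattice:
    """Axis-aligned rectangular grid: origin (Å), spacing (Å), dims counts.

    Grid point (ix, iy, iz) sits at origin + spacing * (ix, iy, iz); the
    flattened point order runs z fastest (C order over dims), matching the
    OpenDX regular-grid convention.
    """

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("lattice spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("lattice dims must each be >= 1")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """(n_points, 3) coordinates of every grid point, z fastest."""
        nx, ny, nz = self.dims
        o = np.asarray(self.origin)
        ax = [o[k] + self.spacing * np.arange(n) for k, n in enumerate(self.dims)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def header(self) -> dict:
        return {
            "origin": list(self.origin),
            "spacing": self.spacing,
            "dims": list(self.dims),
        }

    @classmethod
    def from_header(cls, h: dict) -> "Lattice":
        return cls(tuple(h["origin"]), float(h["spacing"]), tuple(h["dims"]))


@dataclass(frozen=True)
class Probe:
    """The probe atom placed at each grid point.

    CoMFA default: sp3 carbon, vdW radius 1.52 Å, charge +1.
    CoMSIA default: sp3 atom, radius 1.00 Å, charge +1, donor/acceptor +1;
    hydrophobic and steric probe weights are +1 (radius³ = 1).
    """

    kind: str
    vdw_radius: float
    charge: float = 1.0
    donor: float = 1.0
    acceptor: float = 1.0
    hydrophobic: float = 1.0
    steric: float = 1.0

    @classmethod
    def comfa_default(cls) -> "Probe":
        return cls(kind="comfa", vdw_radius=1.52, charge=1.0)

    @classmethod
    def comsia_default(cls) -> "Probe":
        return cls(kind="comsia", vdw_radius=1.00, charge=1.0)

    def comsia_weight(self, field_kind: str) -> float:
        return {
            "CoMSIA_S": self.steric,
            "CoMSIA_E": self.charge,
            "CoMSIA_H": self.hydrophobic,
            "CoMSIA_D": self.donor,
            "CoMSIA_A": self.acceptor,
        }[field_kind]


@dataclass
class FieldBlock:
    """Per-molecule, per-grid-point descriptor values for one field kind.

    ``values`` is (n_molecules, n_gridpoints); kcal/mol for CoMFA,
    dimensionless similarity index for CoMSIA.  For the CoMFA electrostatic
    field, ``flags`` marks entries inside the steric cap region, where the
    Coulomb value is unreliable and is replaced by the training-set column
    mean at matrix-assembly time.
    """

    field_kind: str
    values: np.ndarray
    lattice: Lattice
    mol_ids: list[str]
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.field_kind not in ALL_KINDS:
            raise ValueError(f"unknown field kind {self.field_kind!r}")
        if self.values.shape[0] != len(self.mol_ids):
            raise ValueError("row count does not match molecule ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in {self.field_kind} block")


def build_lattice(
    aligned: AlignedSet, spacing: float = 2.0, margin: float = 4.0
) -> Lattice:
    """Rectangular lattice covering the aligned set plus a margin.

    The box is the union bounding box of all atoms expanded by ``margin`` on
    every side, discretized at ``spacing`` with the origin at the box
    minimum; dims = floor(extent/spacing) + 1 per axis.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if not aligned.molecules:
        raise ValueError("empty aligned set")
    all_xyz = np.vstack([m.coords() for m in aligned.molecules])
    lo = all_xyz.min(axis=0) - margin
    hi = all_xyz.max(axis=0) + margin
    extent = hi - lo
    dims = tuple(int(np.floor(e / spacing + 1e-9)) + 1 for e in extent)
    return Lattice(origin=tuple(lo), spacing=spacing, dims=dims)


def comfa_fields(
    mol: Molecule,
    lattice: Lattice,
    probe: Probe | None = None,
    cutoff: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Steric (LJ) and electrostatic (Coulomb) probe energies on the lattice.

    Steric: E(q) = sum_i 4 eps_ip [(sigma_ip/r)^12 − (sigma_ip/r)^6], with
    Lorentz–Berthelot combination of per-element parameters, truncated at
    +cutoff.  Electrostatic: E(q) = 332.17 · q_i · q_probe / r², i.e. a
    distance-dependent dielectric eps(r) = r, clamped to ±cutoff.

    Returns (steric, electrostatic, capped) rows; ``capped`` flags grid
    points where the steric energy sits at the truncation value.
    """
    probe = probe or Probe.comfa_default()
    pts = lattice.points()
    xyz = mol.coords()
    r = cdist(pts, xyz)  # (n_points, n_atoms)

    eps_i = np.array([LJ_EPSILON.get(a.element, 0.1) for a in mol.atoms])
    sigma_i = np.array(
        [lj_sigma_for_radius(a.vdw_radius) for a in mol.atoms]
    )
    eps_p = LJ_EPSILON["C"]
    sigma_p = lj_sigma_for_radius(probe.vdw_radius)
    eps_ip = np.sqrt(eps_i * eps_p)
    sigma_ip = 0.5 * (sigma_i + sigma_p)

    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        sr6 = (sigma_ip[None, :] / r) ** 6
        lj = 4.0 * eps_ip[None, :] * (sr6 * sr6 - sr6)
    lj[~np.isfinite(lj)] = cutoff  # atom-coincident grid points
    steric = np.minimum(lj.sum(axis=1), cutoff)
    capped = steric >= cutoff

    w = mol.atom_array("partial_charge")
    with np.errstate(divide="ignore", invalid="ignore"):
        coul = COULOMB_CONSTANT * probe.charge * w[None, :] / (r * r)
    coul[~np.isfinite(coul)] = 0.0  # flagged via the steric cap
    electrostatic = np.clip(coul.sum(axis=1), -cutoff, cutoff)
    return steric, electrostatic, capped


def lj_sigma_for_radius(vdw_radius: float) -> float:
    """Zero-crossing sigma whose pair minimum sits at twice the radius."""
    return 2.0 * vdw_radius * 2.0 ** (-1.0 / 6.0)


def comsia_field(
    mol: Molecule,
    lattice: Lattice,
    field_kind: str,
    probe: Probe | None = None,
    alpha: float = 0.3,
) -> np.ndarray:
    """Gaussian similarity index row: A(q) = −Σ_i w_probe·w_i·exp(−α r²)."""
    if field_kind not in COMSIA_KINDS:
        raise ValueError(f"unknown CoMSIA property kind {field_kind!r}")
    probe = probe or Probe.comsia_default()
    w_attr = _COMSIA_WEIGHT_ATTR[field_kind]
    w = mol.atom_array(w_attr) * probe.comsia_weight(field_kind)
    pts = lattice.points()
    r2 = cdist(pts, mol.coords(), metric="sqeuclidean")
    return -(np.exp(-alpha * r2) @ w)


def compute_all_fields(
    aligned: AlignedSet,
    lattice: Lattice,
    kinds: list[str] | tuple[str, ...] = COMSIA_KINDS,
    comfa_probe: Probe | None = None,
    comsia_probe: Probe | None = None,
    alpha: float = 0.3,
    cutoff: float = 30.0,
) -> list[FieldBlock]:
    """One FieldBlock per requested kind, rows in aligned-set order."""
    mols = aligned.molecules
    ids = [m.id for m in mols]
    blocks: list[FieldBlock] = []
    comfa_cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def comfa_rows(mol: Molecule):
        if mol.id not in comfa_cache:
            try:
                comfa_cache[mol.id] = comfa_fields(mol, lattice, comfa_probe, cutoff)
            except Exception as exc:
                raise RuntimeError(f"CoMFA field failed for {mol.id!r}: {exc}")
        return comfa_cache[mol.id]

    for kind in kinds:
        if kind in COMFA_KINDS:
            steric = np.vstack([comfa_rows(m)[0] for m in mols])
            elec = np.vstack([comfa_rows(m)[1] for m in mols])
            capped = np.vstack([comfa_rows(m)[2] for m in mols])
            if kind == "CoMFA_steric":
                blocks.append(FieldBlock(kind, steric, lattice, ids))
            else:
                blocks.append(FieldBlock(kind, elec, lattice, ids, flags=capped))
        elif kind in COMSIA_KINDS:
            try:
                rows = np.vstack(
                    [comsia_field(m, lattice, kind, comsia_probe, alpha) for m in mols]
                )
            except Exception as exc:
                raise RuntimeError(f"CoMSIA field {kind} failed: {exc}")
            blocks.append(FieldBlock(kind, rows, lattice, ids))
        else:
            raise ValueError(f"unknown field kind {kind!r}")
    return blocks


# ---------------------------------------------------------------------------
# persistence: NPZ container + CSV manifest
# ---------------------------------------------------------------------------

def save_field_blocks(blocks: list[FieldBlock], path: str) -> None:
    """Persist blocks to an NPZ container with a CSV manifest alongside.

    The manifest (<path>.manifest.csv) lists molecule ids, field kinds and
    the lattice header so a reload is bit-exact and self-describing.
    """
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    rows = []
    for blk in blocks:
        arrays[f"values_{blk.field_kind}"] = blk.values
        if blk.flags is not None:
            arrays[f"flags_{blk.field_kind}"] = blk.flags
        rows.append(
            {
                "field_kind": blk.field_kind,
                "n_molecules": blk.values.shape[0],
                "n_gridpoints": blk.values.shape[1],
                "mol_ids": ";".join(blk.mol_ids),
                "origin": ";".join(repr(float(v)) for v in blk.lattice.origin),
                "spacing": repr(float(blk.lattice.spacing)),
                "dims": ";".join(map(str, blk.lattice.dims)),
            }
        )
    np.savez_compressed(path, **arrays)
    pd.DataFrame(rows).to_csv(str(path) + ".manifest.csv", index=False)


def load_field_blocks(path: str) -> list[FieldBlock]:
    data = np.load(path)
    manifest = pd.read_csv(str(path) + ".manifest.csv")
    blocks = []
    for _, row in manifest.iterrows():
        lattice = Lattice(
            origin=tuple(float(x) for x in row["origin"].split(";")),
            spacing=float(row["spacing"]),
            dims=tuple(int(x) for x in row["dims"].split(";")),
        )
        kind = row["field_kind"]
        flags_key = f"flags_{kind}"
        blocks.append(
            FieldBlock(
                field_kind=kind,
                values=data[f"values_{kind}"],
                lattice=lattice,
                mol_ids=row["mol_ids"].split(";"),
                flags=data[flags_key] if flags_key in data else None,
            )
        )
    return blocks
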