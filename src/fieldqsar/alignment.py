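"""Rigid scaffold superposition onto a template molecule.

Every compound in a congeneric series shares a common scaffold; the series
is aligned by least-squares superposition (Kabsch) of each molecule's
scaffold atoms onto the template's, applying the resulting rigid transform
to the whole molecule.  Conformations are otherwise untouched — no flexible
fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem_io import Molecule


@dataclass
class AtomMap:
    """Scaffold correspondence: (template atom index, molecule atom index)."""

    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.pairs) < 3:
            raise ValueError("an atom map needs at least 3 pairs")
        t_idx = [p[0] for p in self.pairs]
        m_idx = [p[1] for p in self.pairs]
        if len(set(t_idx)) != len(t_idx) or len(set(m_idx)) != len(m_idx):
            raise ValueError("atom map indices must be unique on each side")


@dataclass
class AlignedSet:
    """Aligned molecules plus per-molecule scaffold RMSD (Å)."""

    template_id: str
    molecules: list[Molecule]
    rmsds: dict[str, float] = field(default_factory=dict)


def kabsch_superpose(
    ref_coords: np.ndarray, mov_coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mov`` onto ``ref``.

    Returns (rotation, translation, rmsd) with ``aligned = mov @ R.T + t``.
    The rotation is reflection-corrected (det = +1).
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("at least 3 points required")
    ref_mean = ref.mean(axis=0)
    mov_mean = mov.mean(axis=0)
    ref_c = ref - ref_mean
    mov_c = mov - mov_mean
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) reference geometry")
    h = mov_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = ref_mean - rotation @ mov_mean
    aligned = mov @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


def _maps_from_query(
    template: Molecule, molecules: list[Molecule], scaffold_query: str
) -> dict[str, AtomMap]:
    """Derive atom maps by SMARTS substructure match (RDKit connectivity).

    The lexicographically smallest match is taken on each side, which makes
    the mapping deterministic when the scaffold is symmetric.
    """
    from rdkit import Chem

    query = Chem.MolFromSmarts(scaffold_query)
    if query is None:
        raise ValueError(f"invalid scaffold query: {scaffold_query!r}")

    def match(mol: Molecule) -> tuple[int, ...] | None:
        rd = _to_rdkit_graph(mol)
        hits = rd.GetSubstructMatches(query, uniquify=True, maxMatches=256)
        return min(hits) if hits else None

    t_match = match(template)
    if t_match is None:
        raise ValueError(f"template {template.id!r} does not match the scaffold query")
    missing = []
    maps: dict[str, AtomMap] = {}
    for mol in molecules:
        m_match = match(mol)
        if m_match is None:
            missing.append(mol.id)
            continue
        maps[mol.id] = AtomMap(list(zip(t_match, m_match)))
    if missing:
        raise ValueError(f"no scaffold match for molecule(s): {missing}")
    return maps


def _to_rdkit_graph(mol: Molecule):
    """Connectivity-only RDKit graph (no valence model) for SMARTS matching."""
    from rdkit import Chem

    order_map = {
        1.0: Chem.BondType.SINGLE,
        1.5: Chem.BondType.AROMATIC,
        2.0: Chem.BondType.DOUBLE,
        3.0: Chem.BondType.TRIPLE,
    }
    aromatic_atoms = {i for i, j, o in mol.bonds if o == 1.5} | {
        j for i, j, o in mol.bonds if o == 1.5
    }
    rw = Chem.RWMol()
    for idx, atom in enumerate(mol.atoms):
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.formal_charge)
        a.SetNoImplicit(True)
        a.SetIsAromatic(idx in aromatic_atoms)
        rw.AddAtom(a)
    for i, j, order in mol.bonds:
        n = rw.AddBond(i, j, order_map.get(order, Chem.BondType.SINGLE))
        if order == 1.5:
            rw.GetBondWithIdx(n - 1).SetIsAromatic(True)
    g = rw.GetMol()
    g.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(g)
    return g


def align_database(
    template: Molecule,
    molecules: list[Molecule],
    maps: dict[str, AtomMap] | None = None,
    scaffold_query: str | None = None,
) -> AlignedSet:
    """Superpose each molecule onto the template via its scaffold atoms.

    Scaffold correspondences come either from explicit ``maps`` (keyed by
    molecule id) or from a SMARTS ``scaffold_query`` matched against both
    sides.  Transforms are rigid; the template itself is never moved.
    """
    if maps is None:
        if scaffold_query is None:
            raise ValueError("either maps or scaffold_query must be given")
        maps = _maps_from_query(template, molecules, scaffold_query)

    t_coords = template.coords()
    aligned: list[Molecule] = []
    rmsds: dict[str, float] = {}
    for mol in molecules:
        if mol.id == template.id:
            out = mol.copy()
            aligned.append(out)
            rmsds[mol.id] = 0.0
            continue
        if mol.id not in maps:
            raise ValueError(f"no atom map for molecule {mol.id!r}")
        amap = maps[mol.id]
        ref = t_coords[[p[0] for p in amap.pairs]]
        mov = mol.coords()[[p[1] for p in amap.pairs]]
        rotation, translation, rmsd = kabsch_superpose(ref, mov)
        out = mol.copy()
        out.set_coords(mol.coords() @ rotation.T + translation)
        aligned.append(out)
        rmsds[mol.id] = rmsd
    if any(not np.isfinite(r) for r in rmsds.values()):
        warnings.warn("non-finite scaffold RMSD encountered")
    return AlignedSet(template_id=template.id, molecules=aligned, rmsds=rmsds)
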