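"""Synthetic congeneric series with a planted field→activity relationship.

The generator emulates the shape of a ligand-based 3D-QSAR dataset: a rigid
common scaffold shared (atom-for-atom, coordinate-for-coordinate) by every
molecule — so the series is pre-aligned by construction — plus a small
number of variable substituent sites.  Mirroring how congeneric series are
actually assembled, each site draws its substituent from a finite R-group
palette (randomized atom clouds with randomized physicochemical weights,
sampled once per seed), with small per-molecule geometric jitter on top.
Activities are a known sparse linear
functional of the molecules' own grid-field values,

    pIC50_i = offset + Σ_q c_q · field_i(q) + N(0, noise_sd),

computed with the very field engine the analysis pipeline uses, so
parameter-recovery tests have an exact ground truth.  Substituents are
random atom clouds, not chemically valid structures: the statistics under
test are geometry- and weight-driven, not valence-driven.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._tables import BONDI_VDW_RADII
from .alignment import AlignedSet
from .chem_io import Atom, Molecule, write_structures
from .field_engine import COMSIA_KINDS, Lattice, build_lattice, compute_all_fields

DEFAULT_SEED = 20140915
ACTIVITY_RANGE = (5.02, 8.46)  # observed pIC50 span the generator emulates


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic series.

    Defaults describe the benchmark scenario used throughout the test
    suite: 60 molecules, a 12-atom scaffold with two substituent sites of
    1–4 atoms, activity planted on the hydrophobic field at 8 grid points,
    Gaussian noise at 10% of the signal standard deviation.
    """

    n_molecules: int = 60
    scaffold_size: int = 12
    n_sites: int = 2
    substituent_atoms: tuple[int, int] = (1, 4)
    substituent_library: int = 8   # distinct R-groups available per site
    geometry_jitter: float = 0.05  # Å, per-molecule conformational scatter
    charge_sd: float = 0.15          # e
    hydrophobic_range: tuple[float, float] = (-1.0, 1.0)
    donor_p: float = 0.3
    acceptor_p: float = 0.3
    planted_field: str = "CoMSIA_H"
    n_planted_points: int = 8
    planted_min_separation: int = 2  # grid cells between planted hotspots
    planted_coefficients: dict[int, float] | None = None
    noise_sd: float | None = None    # None → 10% of signal sd, pIC50 units
    activity_offset: float = 6.5
    spacing: float = 2.0
    margin: float = 4.0
    alpha: float = 0.3
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_molecules < 6:
            raise ValueError("need at least 6 molecules")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.planted_field not in COMSIA_KINDS:
            raise ValueError(f"unknown planted field {self.planted_field!r}")
        if self.planted_coefficients is not None and not self.planted_coefficients:
            raise ValueError("planted_coefficients must be non-empty when given")


_SUB_ELEMENTS = ["C", "C", "C", "N", "O", "F", "H"]
_CHAIN_ELEMENTS = ["C", "C", "C", "N"]  # valence-safe for mid-chain positions


def _scaffold_positions(n: int) -> np.ndarray:
    """Compact fused-bicyclic layout (two hexagons sharing an edge), plus a
    short exocyclic tail for any atoms beyond the tenth.  A slight ring
    pucker keeps the geometry genuinely three-dimensional."""
    ring = 1.40 * np.column_stack(
        [np.cos(np.pi / 3 * np.arange(6)), np.sin(np.pi / 3 * np.arange(6)),
         np.zeros(6)]
    )
    second = ring + np.array([2.10, 1.21, 0.0])  # fused across one edge
    fused = np.vstack([ring, [p for p in second
                              if min(np.linalg.norm(p - q) for q in ring) > 0.5]])
    tail = [fused[2] + np.array([0.0, -1.4 * (k + 1), 0.3 * (k + 1)])
            for k in range(max(0, n - len(fused)))]
    pos = np.vstack([fused] + ([tail] if tail else []))[:n]
    pos[:, 2] += 0.15 * np.sin(np.arange(len(pos)))
    return pos


def _build_scaffold(spec: SyntheticSpec, rng: np.random.Generator) -> Molecule:
    """A rigid fused-ring scaffold with fixed coordinates and weights."""
    n = spec.scaffold_size
    pos = _scaffold_positions(n)
    atoms = []
    for i in range(n):
        el = "N" if i == n // 2 else ("O" if i == n - 3 else "C")
        r = BONDI_VDW_RADII[el]
        atoms.append(
            Atom(
                element=el,
                coords=pos[i].copy(),
                partial_charge=float(rng.normal(0.0, spec.charge_sd / 2)),
                vdw_radius=r,
                steric_weight=r**3,
                hydrophobic_weight=float(rng.uniform(*spec.hydrophobic_range)),
                donor_weight=float(rng.random() < spec.donor_p),
                acceptor_weight=float(rng.random() < spec.acceptor_p),
            )
        )
    bonds = [(i, i + 1, 1.0) for i in range(n - 1)]
    if n >= 6:
        bonds.append((0, 5, 1.0))  # close the first ring
    return Molecule(id="scaffold", atoms=atoms, bonds=bonds)


def _site_anchors(spec: SyntheticSpec) -> list[int]:
    n = spec.scaffold_size
    step = max(1, (n - 2) // max(1, spec.n_sites))
    return [min(1 + k * step, n - 1) for k in range(spec.n_sites)]


def _random_substituent(
    anchor_xyz: np.ndarray, direction: np.ndarray, count: int,
    spec: SyntheticSpec, rng: np.random.Generator,
) -> list[Atom]:
    atoms = []
    for j in range(count):
        pool = _SUB_ELEMENTS if j == count - 1 else _CHAIN_ELEMENTS
        el = pool[int(rng.integers(0, len(pool)))]
        r = BONDI_VDW_RADII[el]
        xyz = anchor_xyz + direction * 1.5 * (j + 1) + rng.normal(0.0, 0.4, 3)
        atoms.append(
            Atom(
                element=el,
                coords=xyz,
                partial_charge=float(rng.normal(0.0, spec.charge_sd)),
                vdw_radius=r,
                steric_weight=r**3,
                hydrophobic_weight=float(rng.uniform(*spec.hydrophobic_range)),
                donor_weight=float(rng.random() < spec.donor_p),
                acceptor_weight=float(rng.random() < spec.acceptor_p),
            )
        )
    return atoms


def generate_series(
    spec: SyntheticSpec | None = None,
) -> tuple[AlignedSet, np.ndarray, dict]:
    """Generate the aligned series, activities and the ground-truth record.

    Returns ``(aligned, activities, truth)`` where ``truth`` holds the
    lattice, the planted field kind, the planted {grid index: coefficient}
    map, the noise-free signal and the realized noise standard deviation.
    Fully reproducible from ``spec.seed``.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    scaffold = _build_scaffold(spec, rng)
    anchors = _site_anchors(spec)
    directions = [
        np.array([0.0, 1.0 if k % 2 == 0 else -1.0, 0.4 * (1 if k % 2 else -1)])
        / np.linalg.norm([0.0, 1.0, 0.4])
        for k in range(spec.n_sites)
    ]

    # one fixed R-group palette per site, sampled once per seed
    lo, hi = spec.substituent_atoms
    palette: list[list[list[Atom]]] = []
    for k, anchor in enumerate(anchors):
        groups = []
        for _t in range(spec.substituent_library):
            count = int(rng.integers(lo, hi + 1))
            groups.append(
                _random_substituent(
                    scaffold.atoms[anchor].coords, directions[k], count, spec, rng
                )
            )
        palette.append(groups)

    molecules: list[Molecule] = []
    for m in range(spec.n_molecules):
        atoms = [a.copy() for a in scaffold.atoms]
        bonds = list(scaffold.bonds)
        for k, anchor in enumerate(anchors):
            group = palette[k][int(rng.integers(0, spec.substituent_library))]
            start = len(atoms)
            prev = anchor
            for j, tmpl in enumerate(group):
                atom = tmpl.copy()
                atom.coords = atom.coords + rng.normal(0.0, spec.geometry_jitter, 3)
                atoms.append(atom)
                bonds.append((prev, start + j, 1.0))
                prev = start + j
        molecules.append(Molecule(id=f"syn_{m:03d}", atoms=atoms, bonds=bonds))

    aligned = AlignedSet(
        template_id=molecules[0].id,
        molecules=molecules,
        rmsds={m.id: 0.0 for m in molecules},
    )
    lattice = build_lattice(aligned, spacing=spec.spacing, margin=spec.margin)
    block = compute_all_fields(
        aligned, lattice, kinds=[spec.planted_field], alpha=spec.alpha
    )[0]

    if spec.planted_coefficients is None:
        # distinct hotspots: greedy top-variance points, kept at least
        # planted_min_separation grid cells apart so the planted functional
        # is well conditioned (adjacent columns are nearly collinear)
        variances = block.values.var(axis=0)
        order = np.argsort(-variances, kind="stable")
        nx, ny, nz = lattice.dims
        chosen: list[int] = []
        for q in order:
            cell = np.array([q // (ny * nz), (q // nz) % ny, q % nz])
            ok = all(
                np.abs(cell - np.array([p // (ny * nz), (p // nz) % ny, p % nz])).max()
                >= spec.planted_min_separation
                for p in chosen
            )
            if ok:
                chosen.append(int(q))
            if len(chosen) == spec.n_planted_points:
                break
        points = np.array(chosen)
        signs = rng.choice([-1.0, 1.0], size=points.size)
        mags = rng.uniform(0.5, 1.5, size=points.size)
        coeffs = {int(q): float(s * m) for q, s, m in zip(points, signs, mags)}
    else:
        coeffs = dict(spec.planted_coefficients)
        bad = [q for q in coeffs if not (0 <= q < lattice.n_points)]
        if bad:
            raise ValueError(f"planted coefficients outside the lattice: {bad}")

    idx = np.array(sorted(coeffs))
    c = np.array([coeffs[q] for q in idx])
    signal = block.values[:, idx] @ c
    sig_sd = float(signal.std(ddof=1))
    noise_sd = 0.1 * sig_sd if spec.noise_sd is None else spec.noise_sd
    noise = rng.normal(0.0, noise_sd, spec.n_molecules) if noise_sd > 0 else 0.0
    activities = spec.activity_offset + signal + noise

    for mol, act in zip(molecules, activities):
        mol.activity_pIC50 = float(act)

    truth = {
        "lattice": lattice,
        "planted_field": spec.planted_field,
        "planted_coefficients": coeffs,
        "signal": signal,
        "signal_sd": sig_sd,
        "noise_sd": noise_sd,
        "seed": spec.seed,
    }
    return aligned, np.asarray(activities, dtype=float), truth


def scale_activities(
    activities: np.ndarray, target_range: tuple[float, float] = ACTIVITY_RANGE
) -> np.ndarray:
    """Affine rescale so min/max hit the target range exactly (rank-preserving)."""
    a = np.asarray(activities, dtype=float)
    lo, hi = float(a.min()), float(a.max())
    if hi - lo <= 0:
        raise ValueError("cannot rescale constant activities")
    t_lo, t_hi = target_range
    return t_lo + (a - lo) * (t_hi - t_lo) / (hi - lo)


def write_series(
    aligned: AlignedSet, activities: np.ndarray, out_dir: str,
    split_labels: list[str] | None = None,
) -> tuple[Path, Path]:
    """Emit the series as standard SDF + activity CSV pipeline inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sdf = out / "molecules.sdf"
    csv = out / "activities.csv"
    write_structures(aligned.molecules, str(sdf))
    ids = [m.id for m in aligned.molecules]
    split = split_labels or [m.split_label for m in aligned.molecules]
    pd.DataFrame({"id": ids, "pIC50": activities, "split": split}).to_csv(
        csv, index=False
    )
    return sdf, csv
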