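import numpy as np
import pytest

from fieldqsar import field_engine, qsar_stats
from fieldqsar.synthetic_data import SyntheticSpec, generate_series


@pytest.fixture(scope="session")
def default_scenario():
    """The benchmark synthetic scenario: 60 molecules, 10% noise, fixed seed."""
    aligned, y, truth = generate_series(SyntheticSpec())
    labeled = qsar_stats.split_dataset(aligned.molecules, seed=1)
    split = np.array([m.split_label for m in labeled])
    blocks = field_engine.compute_all_fields(aligned, truth["lattice"])
    return {"aligned": aligned, "y": y, "truth": truth,
            "split": split, "blocks": blocks}


@pytest.fixture(scope="session")
def default_search(default_scenario):
    """All-31-subsets CoMSIA search on the benchmark scenario."""
    sc = default_scenario
    table, fitted = qsar_stats.model_search(
        sc["blocks"], sc["y"], split_labels=sc["split"], max_components=8
    )
    return table, fitted


@pytest.fixture(scope="session")
def small_series():
    """A faster 20-molecule series for unit-level pipeline tests."""
    spec = SyntheticSpec(n_molecules=20, seed=7, n_planted_points=5)
    aligned, y, truth = generate_series(spec)
    blocks = field_engine.compute_all_fields(aligned, truth["lattice"])
    return {"aligned": aligned, "y": y, "truth": truth, "blocks": blocks}


@pytest.fixture(scope="session")
def small_matrix(small_series):
    """Single-field descriptor matrix over the 20-molecule series."""
    blk = [b for b in small_series["blocks"] if b.field_kind == "CoMSIA_H"]
    return qsar_stats.assemble_matrix(blk, small_series["y"])


@pytest.fixture()
def embedded_sdf(tmp_path):
    """A 2-record 3D SDF built from real SMILES via RDKit embedding."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    path = tmp_path / "mols.sdf"
    writer = Chem.SDWriter(str(path))
    for name, smi in [("ethanol", "CCO"), ("benzamide", "c1ccccc1C(=O)N")]:
        mol = Chem.AddHs(Chem.MolFromSmiles(smi))
        AllChem.EmbedMolecule(mol, randomSeed=11)
        mol.SetProp("_Name", name)
        writer.write(mol)
    writer.close()
    return path
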