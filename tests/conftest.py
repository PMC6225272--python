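import numpy as np
import pytest

from aconiqstr.molecules import AlignedMolecule


def point_molecule(coords, charges=None, props=None, mol_id="pt", radius=1.7, eps=0.107):
    """Bare point-atom molecule for field closed-form tests."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    charges = np.zeros(n) if charges is None else np.asarray(charges, dtype=float)
    zeros = np.zeros(n)
    base = {"hydrophobic": zeros, "donor": zeros, "acceptor": zeros}
    if props:
        base.update({k: np.asarray(v, dtype=float) for k, v in props.items()})
    return AlignedMolecule(
        id=mol_id, elements=tuple("C" for _ in range(n)), coords=coords,
        charges=charges, vdw_radius=np.full(n, radius), vdw_epsilon=np.full(n, eps),
        props=base,
    )


@pytest.fixture
def rdkit_mol():
    def make(smiles, seed=7):
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
        AllChem.EmbedMolecule(mol, randomSeed=seed)
        return mol

    return make
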