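"""Aligned small-molecule container, file readers and PEOE charge assignment.

Molecules enter the field engine already aligned on a common scaffold; this
module only represents them, reads them from SDF/MOL2 (via RDKit), types their
atoms for the similarity fields, and assigns Gasteiger (PEOE) partial charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .params import (
    PEOE_DAMPING,
    PEOE_H_CATION,
    PEOE_ITERATIONS,
    VDW_PARAMS,
    peoe_coefficients,
)

COMSIA_PROPERTIES = ("hydrophobic", "donor", "acceptor")


@dataclass(frozen=True)
class AlignedMolecule:
    """A rigid, pre-aligned molecule with per-atom field parameters.

    Attributes
    ----------
    id : molecule identifier.
    elements : element symbol per atom.
    coords : (n_atoms, 3) Cartesian coordinates in Angstrom, in the shared
        alignment frame of the dataset.
    charges : per-atom partial charges (e); populated by
        :func:`assign_gasteiger_charges` if the input file carries none.
    vdw_radius, vdw_epsilon : Lennard-Jones parameters (Angstrom, kcal/mol).
    props : per-atom weights for the similarity fields, keyed by property
        name ("hydrophobic", "donor", "acceptor").
    bonds : (i, j) atom-index pairs; required for charge assignment.
    hybridizations : "sp3" / "sp2" / "sp" / "" per atom.
    formal_charges : integer formal charge per atom.
    """

    id: str
    elements: tuple[str, ...]
    coords: np.ndarray
    charges: np.ndarray
    vdw_radius: np.ndarray
    vdw_epsilon: np.ndarray
    props: dict[str, np.ndarray] = field(default_factory=dict)
    bonds: tuple[tuple[int, int], ...] = ()
    hybridizations: tuple[str, ...] = ()
    formal_charges: tuple[int, ...] = ()

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"{self.id}: coords must be (n_atoms, 3)")
        if coords.shape[0] < 3:
            raise ValueError(f"{self.id}: need at least 3 atoms")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"{self.id}: non-finite coordinates")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "charges", np.asarray(self.charges, dtype=float))
        object.__setattr__(self, "vdw_radius", np.asarray(self.vdw_radius, dtype=float))
        object.__setattr__(self, "vdw_epsilon", np.asarray(self.vdw_epsilon, dtype=float))

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def formal_charge(self) -> int:
        return int(sum(self.formal_charges)) if self.formal_charges else 0

    def translated(self, vector) -> "AlignedMolecule":
        return replace(self, coords=self.coords + np.asarray(vector, dtype=float))


def _hybridization_label(atom) -> str:
    from rdkit.Chem import rdchem

    table = {
        rdchem.HybridizationType.SP3: "sp3",
        rdchem.HybridizationType.SP2: "sp2",
        rdchem.HybridizationType.SP: "sp",
    }
    return table.get(atom.GetHybridization(), "")


def comsia_atom_properties(mol) -> dict[str, np.ndarray]:
    """Rule-based hydrophobic / H-bond donor / H-bond acceptor atom weights.

    Hydrophobic: carbons with no polar neighbour weight 1, halogens 0.5.
    Donor: N/O bearing at least one hydrogen. Acceptor: O, and neutral N
    that is not a donor-only amide-type nitrogen with full valence of C.
    Weights are binary/half and dimensionless, as the similarity fields only
    need relative magnitudes.
    """
    n = mol.GetNumAtoms()
    hydrophobic = np.zeros(n)
    donor = np.zeros(n)
    acceptor = np.zeros(n)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        if sym == "C":
            polar_nbr = any(a.GetSymbol() in ("N", "O", "S", "P") for a in atom.GetNeighbors())
            hydrophobic[i] = 0.0 if polar_nbr else 1.0
        elif sym in ("Cl", "Br", "I", "F"):
            hydrophobic[i] = 0.5
        if sym in ("N", "O"):
            if atom.GetTotalNumHs(includeNeighbors=True) > 0:
                donor[i] = 1.0
            if sym == "O":
                acceptor[i] = 1.0
            elif atom.GetFormalCharge() <= 0 and atom.GetTotalValence() <= 3:
                acceptor[i] = 1.0
    return {"hydrophobic": hydrophobic, "donor": donor, "acceptor": acceptor}


def from_rdkit(mol, mol_id: str | None = None) -> AlignedMolecule:
    """Build an :class:`AlignedMolecule` from an RDKit mol with a conformer."""
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D conformer")
    conf = mol.GetConformer()
    coords = np.array(conf.GetPositions(), dtype=float)
    elements, radii, eps, hybs, formal = [], [], [], [], []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in VDW_PARAMS:
            raise ValueError(f"unparameterized element {sym!r} at atom {atom.GetIdx()}")
        elements.append(sym)
        r, e = VDW_PARAMS[sym]
        radii.append(r)
        eps.append(e)
        hybs.append(_hybridization_label(atom))
        formal.append(atom.GetFormalCharge())
    bonds = tuple((b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds())
    name = mol_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else "mol")
    return AlignedMolecule(
        id=name,
        elements=tuple(elements),
        coords=coords,
        charges=np.zeros(len(elements)),
        vdw_radius=np.array(radii),
        vdw_epsilon=np.array(eps),
        props=comsia_atom_properties(mol),
        bonds=bonds,
        hybridizations=tuple(hybs),
        formal_charges=tuple(formal),
    )


def read_sdf(path) -> list[AlignedMolecule]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    out = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unparsable record {i} in {path}")
        out.append(from_rdkit(mol, mol_id=mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"))
    if not out:
        raise ValueError(f"no molecules in {path}")
    return out


def read_mol2(path) -> list[AlignedMolecule]:
    from rdkit import Chem

    mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=True)
    if mol is None:
        raise ValueError(f"unparsable MOL2 file {path}")
    return [from_rdkit(mol)]


def assign_gasteiger_charges(molecule: AlignedMolecule) -> AlignedMolecule:
    """Assign partial charges by partial equalization of orbital
    electronegativity (PEOE).

    Charge flows along each bond from the less to the more electronegative
    atom, proportional to the electronegativity difference normalized by the
    donor's cation electronegativity, with geometric damping per iteration.
    Six iterations with damping 0.5; total charge is conserved exactly.
    The aromatic (Hueckel) pi-charge correction is not applied.
    """
    if not molecule.bonds:
        raise ValueError(f"{molecule.id}: connectivity required for charge assignment")
    n = molecule.n_atoms
    coeffs = []
    for i, (el, hyb) in enumerate(zip(molecule.elements, molecule.hybridizations or [""] * n)):
        try:
            coeffs.append(peoe_coefficients(el, hyb))
        except KeyError:
            raise ValueError(f"{molecule.id}: unparameterized element {el!r} at atom {i}")
    a = np.array([c[0] for c in coeffs])
    b = np.array([c[1] for c in coeffs])
    c = np.array([c[2] for c in coeffs])
    chi_cation = a + b + c
    chi_cation[np.array(molecule.elements) == "H"] = PEOE_H_CATION

    q = np.array(molecule.formal_charges, dtype=float) if molecule.formal_charges else np.zeros(n)
    for it in range(1, PEOE_ITERATIONS + 1):
        chi = a + b * q + c * q * q
        damp = PEOE_DAMPING**it
        dq = np.zeros(n)
        for i, j in molecule.bonds:
            if chi[j] > chi[i]:
                donor_idx = i
                transfer = (chi[j] - chi[i]) / chi_cation[i] * damp
                dq[i] += transfer
                dq[j] -= transfer
            elif chi[i] > chi[j]:
                transfer = (chi[i] - chi[j]) / chi_cation[j] * damp
                dq[j] += transfer
                dq[i] -= transfer
        q = q + dq
    return replace(molecule, charges=q)
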