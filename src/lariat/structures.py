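"""Lightweight multi-model structure container and PDB I/O.

The analyses in this package operate on small peptides at coarse (Cα/Sγ) or
backbone resolution, so structures are held as flat numpy arrays rather than a
full macromolecular hierarchy.  PDB reading/writing goes through :mod:`gemmi`;
multi-model files (MODEL/ENDMDL) map onto the leading axis of ``coords``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StructureEnsemble", "read_pdb", "write_pdb"]

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class StructureEnsemble:
    """One or more models of the same set of named atoms.

    Attributes
    ----------
    res_num : (n_atoms,) int array, 1-based residue numbers.
    res_name : (n_atoms,) array of three-letter residue names.
    atom_name : (n_atoms,) array of atom names (``CA``, ``SG``, ...).
    coords : (n_models, n_atoms, 3) float array, Å.
    """

    res_num: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    coords: np.ndarray
    chain: str = "A"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.res_num = np.asarray(self.res_num, dtype=int)
        self.res_name = np.asarray(self.res_name, dtype="U3")
        self.atom_name = np.asarray(self.atom_name, dtype="U4")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.shape[1:] != (len(self.res_num), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{len(self.res_num)} atoms"
            )

    # -- basic introspection -------------------------------------------------
    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residues(self) -> np.ndarray:
        """Sorted unique residue numbers."""
        return np.unique(self.res_num)

    def model(self, index: int = 0) -> np.ndarray:
        """Coordinates of one model, shape (n_atoms, 3)."""
        return self.coords[index]

    # -- selection -----------------------------------------------------------
    def atom_index(self, res: int, atom: str) -> int:
        hits = np.flatnonzero((self.res_num == res) & (self.atom_name == atom))
        if hits.size == 0:
            raise KeyError(f"atom {atom} of residue {res} not in structure")
        return int(hits[0])

    def select(self, residues=None, atoms=None) -> np.ndarray:
        """Indices of atoms matching a residue set and/or atom-name set.

        ``residues`` may be an iterable of residue numbers or ``None`` (all);
        ``atoms`` an iterable of atom names or ``None`` (all).  Order follows
        the structure's own atom order.
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        if residues is not None:
            mask &= np.isin(self.res_num, np.asarray(list(residues), dtype=int))
        if atoms is not None:
            mask &= np.isin(self.atom_name, np.asarray(list(atoms), dtype="U4"))
        return np.flatnonzero(mask)

    def subset(self, indices) -> "StructureEnsemble":
        indices = np.asarray(indices, dtype=int)
        return StructureEnsemble(
            res_num=self.res_num[indices],
            res_name=self.res_name[indices],
            atom_name=self.atom_name[indices],
            coords=self.coords[:, indices],
            chain=self.chain,
            meta=dict(self.meta),
        )

    def with_coords(self, coords: np.ndarray) -> "StructureEnsemble":
        return StructureEnsemble(
            res_num=self.res_num.copy(),
            res_name=self.res_name.copy(),
            atom_name=self.atom_name.copy(),
            coords=np.asarray(coords, dtype=float),
            chain=self.chain,
            meta=dict(self.meta),
        )

    def ca_trace(self, model: int = 0) -> np.ndarray:
        """Cα coordinates ordered by residue number, shape (n_res, 3)."""
        idx = self.select(atoms=["CA"])
        order = np.argsort(self.res_num[idx], kind="stable")
        return self.coords[model, idx[order]]


def residue_name(one_letter: str) -> str:
    """Three-letter residue name for a one-letter code (``X`` → ``UNK``)."""
    return _AA3.get(one_letter.upper(), "UNK")


def read_pdb(path) -> StructureEnsemble:
    """Read a (multi-model) PDB file into a :class:`StructureEnsemble`.

    All models must contain the same atoms in the same order, the usual
    convention for NMR ensembles and MD snapshots written as MODEL blocks.
    Only the first chain is read.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    models = []
    names = None
    chain_name = "A"
    for mod in st:
        chain = mod[0]
        chain_name = chain.name
        rn, rname, aname, xyz = [], [], [], []
        for res in chain:
            for atom in res:
                rn.append(res.seqid.num)
                rname.append(res.name)
                aname.append(atom.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        key = (tuple(rn), tuple(aname))
        if names is None:
            names = key
            first = (rn, rname, aname)
        elif key != names:
            raise ValueError("models differ in atom content; cannot stack")
        models.append(np.asarray(xyz))
    if not models:
        raise ValueError(f"no models found in {path}")
    rn, rname, aname = first
    return StructureEnsemble(
        res_num=np.asarray(rn),
        res_name=np.asarray(rname),
        atom_name=np.asarray(aname),
        coords=np.stack(models),
        chain=chain_name,
    )


def write_pdb(structure: StructureEnsemble, path) -> None:
    """Write a :class:`StructureEnsemble` as a multi-model PDB file."""
    import gemmi

    st = gemmi.Structure()
    st.name = "lariat"
    for m in range(structure.n_models):
        model = gemmi.Model(m + 1)
        chain = gemmi.Chain(structure.chain)
        current = None
        res = None
        for i in range(structure.n_atoms):
            num = int(structure.res_num[i])
            if num != current:
                res = gemmi.Residue()
                res.name = str(structure.res_name[i])
                res.seqid = gemmi.SeqId(num, " ")
                chain.add_residue(res)
                current = num
                res = chain[-1]
            atom = gemmi.Atom()
            atom.name = str(structure.atom_name[i])
            x, y, z = structure.coords[m, i]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            atom.element = gemmi.Element(
                "S" if structure.atom_name[i].startswith("S") else "C"
            )
            res.add_atom(atom)
        model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))
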