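"""Molecular structures as flat atom tables, with PDB input/output.

A :class:`MolecularStructure` holds one atom per row: serial, atom name,
residue name, residue index, chain id, Cartesian coordinates in Å, and a
per-atom biopolymer class (``protein``, ``RNA``, ``ion`` or ``other``)
derived from the residue name.  PDB files are read and written through
Biopython; hydrogens are dropped on input because the models built here
represent non-hydrogen atoms only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
RNA_RESNAMES = {"A", "U", "G", "C", "RA", "RU", "RG", "RC", "ADE", "URA", "GUA", "CYT"}
ION_RESNAMES = {"MG", "NA", "K", "CL", "ZN", "CA", "MN"}

#: Names used for the toy RNA backbone; everything else in an RNA residue is "base".
RNA_BACKBONE_NAMES = {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'", "O4'", "C2'", "C1'", "O2'"}


def classify_residue(resname: str) -> str:
    """Assign a biopolymer class from a residue name."""
    rn = resname.strip().upper()
    if rn in PROTEIN_RESNAMES:
        return "protein"
    if rn in RNA_RESNAMES:
        return "RNA"
    if rn in ION_RESNAMES:
        return "ion"
    return "other"


@dataclass
class MolecularStructure:
    """All-atom structure: parallel arrays, one entry per atom."""

    serial: np.ndarray          # int
    name: np.ndarray            # str, PDB atom names (e.g. "P", "O3'")
    resname: np.ndarray         # str
    resid: np.ndarray           # int, 1-based as in PDB
    chain: np.ndarray           # str, single-character chain ids
    coords: np.ndarray          # (N, 3) float, Å
    residue_class: np.ndarray = field(default=None)  # per atom

    def __post_init__(self) -> None:
        self.serial = np.asarray(self.serial, dtype=int)
        self.name = np.asarray(self.name, dtype=object)
        self.resname = np.asarray(self.resname, dtype=object)
        self.resid = np.asarray(self.resid, dtype=int)
        self.chain = np.asarray(self.chain, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.residue_class is None:
            self.residue_class = np.array(
                [classify_residue(r) for r in self.resname], dtype=object
            )
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def validate(self) -> None:
        n = self.n_atoms
        for arr_name in ("name", "resname", "resid", "chain", "residue_class"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"field {arr_name!r} length mismatch")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must be ({n}, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        triples = list(zip(self.chain, self.resid, self.name))
        if len(set(triples)) != n:
            seen: set = set()
            for t in triples:
                if t in seen:
                    raise ValueError(f"duplicate (chain, resid, name) triple: {t}")
                seen.add(t)

    def atom_index(self, chain: str, resid: int, name: str) -> int:
        """Index of a single atom; raises KeyError if absent."""
        mask = (self.chain == chain) & (self.resid == resid) & (self.name == name)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise KeyError(f"no atom ({chain}, {resid}, {name})")
        return int(idx[0])

    def select(self, *, chain=None, resname=None, name=None) -> np.ndarray:
        """Indices of atoms matching all given criteria (each a str or set)."""
        mask = np.ones(self.n_atoms, dtype=bool)

        def _match(values, crit):
            crit = {crit} if isinstance(crit, str) else set(crit)
            return np.array([v in crit for v in values])

        if chain is not None:
            mask &= _match(self.chain, chain)
        if resname is not None:
            mask &= _match(self.resname, resname)
        if name is not None:
            mask &= _match(self.name, name)
        return np.flatnonzero(mask)

    def residues(self):
        """Iterate (chain, resid, atom index array) over residues in file order."""
        seen = {}
        for i in range(self.n_atoms):
            key = (self.chain[i], self.resid[i])
            seen.setdefault(key, []).append(i)
        for key, idx in seen.items():
            yield key[0], key[1], np.array(idx, dtype=int)

    def copy(self) -> "MolecularStructure":
        return MolecularStructure(
            serial=self.serial.copy(),
            name=self.name.copy(),
            resname=self.resname.copy(),
            resid=self.resid.copy(),
            chain=self.chain.copy(),
            coords=self.coords.copy(),
            residue_class=self.residue_class.copy(),
        )

    def subset(self, indices: np.ndarray) -> "MolecularStructure":
        """New structure containing the given atoms (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return MolecularStructure(
            serial=self.serial[idx],
            name=self.name[idx],
            resname=self.resname[idx],
            chain=self.chain[idx],
            resid=self.resid[idx],
            coords=self.coords[idx],
            residue_class=self.residue_class[idx],
        )


def _is_hydrogen(atom_name: str, element: str) -> bool:
    if element and element.strip().upper() == "H":
        return True
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped.startswith("H")


def read_pdb(path) -> MolecularStructure:
    """Parse ATOM/HETATM records into a :class:`MolecularStructure`.

    Hydrogens are dropped; chain ids and 1-based residue numbering are
    preserved.  Raises ``ValueError`` naming the line for malformed records
    and for files containing no atoms.
    """
    serials, names, resnames, resids, chains, xyz = [], [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21].strip() or "A"
                resid = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed PDB record at line {lineno}") from exc
            element = line[76:78] if len(line) >= 78 else ""
            if _is_hydrogen(name, element):
                continue
            serials.append(serial)
            names.append(name)
            resnames.append(resname)
            resids.append(resid)
            chains.append(chain)
            xyz.append((x, y, z))
    if not serials:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return MolecularStructure(
        serial=np.array(serials),
        name=np.array(names, dtype=object),
        resname=np.array(resnames, dtype=object),
        resid=np.array(resids),
        chain=np.array(chains, dtype=object),
        coords=np.array(xyz, dtype=float),
    )


def write_pdb(structure: MolecularStructure, path) -> None:
    """Write the structure as PDB ATOM records (coordinates to 0.001 Å)."""
    from Bio.PDB import PDBIO, StructureBuilder

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("toy")
    builder.init_model(0)
    current_chain = None
    current_res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Biopython warns on non-standard names
        for i in range(structure.n_atoms):
            ch = structure.chain[i]
            if ch != current_chain:
                builder.init_chain(ch)
                builder.init_seg("    ")
                current_chain = ch
                current_res = None
            key = (structure.resid[i], structure.resname[i])
            if key != current_res:
                hetfield = "H_ION" if structure.residue_class[i] == "ion" else " "
                builder.init_residue(structure.resname[i], hetfield, int(structure.resid[i]), " ")
                current_res = key
            name = structure.name[i]
            builder.init_atom(
                name,
                structure.coords[i].astype(np.float32),
                0.0,
                1.0,
                " ",
                name if len(name) >= 4 else f" {name}",
                int(structure.serial[i]),
                element=name[0],
            )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        io.save(str(path))
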