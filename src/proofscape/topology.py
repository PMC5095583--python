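"""Bonded topology (bonds, angles, dihedrals) from residue templates.

The structure-based potentials built here operate on small synthetic
polymers with a fixed per-residue atom inventory, so connectivity is
declared by residue templates rather than inferred from chemistry:

* toy RNA residue (resname ``U``): backbone ``P``-``C4'``-``O3'`` with an
  inter-residue ``O3'``-``P`` link, and a three-atom base ring
  ``N1``/``C2``/``C4`` hanging off ``C4'``;
* toy peptide residues (standard amino-acid resnames): backbone
  ``N``-``CA``-``C``(=``O``) with an inter-residue ``C``-``N`` link and an
  optional ``CB``(-``CG``) side chain;
* ``LIG`` (mobile ligand bead chain): linear ``L1``-``L2``-``L3``;
* obstacle bodies (``REC``, ``GAT``, ``CAP``, ``WAL``): no bonded terms.

Angles are every connected triple, proper dihedrals every connected
quadruple along bonds.  A dihedral is backbone (``BB``) when all four atoms
carry backbone names for their biopolymer class, otherwise side-chain
(``SC``).  Impropers/planars are small per-template lists keeping branch
geometry and base planarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import MolecularStructure

PROTEIN_BACKBONE_NAMES = {"N", "CA", "C", "O"}
RNA_BACKBONE_TOY = {"P", "C4'", "O3'"}

# intra-residue bonds, inter-residue link (this_atom, next_atom),
# impropers and planars as 4-tuples of atom names ("+X" = atom X of the
# next residue)
_TEMPLATES = {
    "RNA_TOY": {
        "bonds": [("P", "C4'"), ("C4'", "O3'"), ("C4'", "N1"),
                  ("N1", "C2"), ("C2", "C4"), ("C4", "N1")],
        "link": ("O3'", "P"),
        "impropers": [("P", "C4'", "O3'", "N1")],
        "planars": [("N1", "C2", "C4", "C4'")],
    },
    "PROTEIN_TOY": {
        "bonds": [("N", "CA"), ("CA", "C"), ("C", "O"),
                  ("CA", "CB"), ("CB", "CG")],
        "link": ("C", "N"),
        "impropers": [("CA", "C", "O", "+N")],
        "planars": [],
    },
    "LIG": {
        "bonds": [("L1", "L2"), ("L2", "L3")],
        "link": None,
        "impropers": [],
        "planars": [],
    },
}


def _template_for(resname: str, residue_class: str):
    if resname == "LIG":
        return _TEMPLATES["LIG"]
    if residue_class == "RNA":
        return _TEMPLATES["RNA_TOY"]
    if residue_class == "protein":
        return _TEMPLATES["PROTEIN_TOY"]
    return None  # ions, obstacles: no bonded terms


@dataclass
class Topology:
    """Connectivity of a structure; native values are filled in later."""

    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    angles: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))
    dihedrals: np.ndarray = field(default_factory=lambda: np.empty((0, 4), dtype=int))
    dihedral_class: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    impropers: np.ndarray = field(default_factory=lambda: np.empty((0, 4), dtype=int))
    planars: np.ndarray = field(default_factory=lambda: np.empty((0, 4), dtype=int))

    def bonded_pairs(self) -> set:
        """All atom pairs appearing together in any bonded term (1-2/1-3/1-4)."""
        pairs = set()
        for arr in (self.bonds, self.angles, self.dihedrals, self.impropers, self.planars):
            for term in arr:
                for a in range(len(term)):
                    for b in range(a + 1, len(term)):
                        i, j = int(term[a]), int(term[b])
                        pairs.add((min(i, j), max(i, j)))
        return pairs


def build_topology(structure: MolecularStructure) -> Topology:
    """Derive bonds from templates, then angles/dihedrals from the bond graph."""
    bonds: list[tuple[int, int]] = []
    impropers: list[tuple[int, int, int, int]] = []
    planars: list[tuple[int, int, int, int]] = []

    residues = list(structure.residues())
    atom_lookup = [
        {structure.name[i]: int(i) for i in idx} for _, _, idx in residues
    ]

    for ri, (chain, resid, idx) in enumerate(residues):
        tpl = _template_for(structure.resname[idx[0]], structure.residue_class[idx[0]])
        if tpl is None:
            continue
        here = atom_lookup[ri]
        nxt = None
        if ri + 1 < len(residues):
            nchain, nresid, nidx = residues[ri + 1]
            same_polymer = (
                nchain == chain
                and nresid == resid + 1
                and structure.residue_class[nidx[0]] == structure.residue_class[idx[0]]
            )
            if same_polymer:
                nxt = atom_lookup[ri + 1]

        def resolve(name, *, _here=here, _nxt=nxt):
            if name.startswith("+"):
                return None if _nxt is None else _nxt.get(name[1:])
            return _here.get(name)

        for a, b in tpl["bonds"]:
            ia, ib = resolve(a), resolve(b)
            if ia is not None and ib is not None:
                bonds.append((ia, ib))
        if tpl["link"] is not None and nxt is not None:
            ia, ib = here.get(tpl["link"][0]), nxt.get(tpl["link"][1])
            if ia is not None and ib is not None:
                bonds.append((ia, ib))
        for quad_names, target in ((tpl["impropers"], impropers), (tpl["planars"], planars)):
            for quad in quad_names:
                idx4 = [resolve(nm) for nm in quad]
                if all(i is not None for i in idx4):
                    target.append(tuple(idx4))

    adjacency: dict[int, set] = {}
    for i, j in bonds:
        adjacency.setdefault(i, set()).add(j)
        adjacency.setdefault(j, set()).add(i)

    angles = []
    for j, nbrs in adjacency.items():
        nb = sorted(nbrs)
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))

    dihedrals = []
    seen = set()
    for j, k in bonds:
        for jj, kk in ((j, k), (k, j)):
            for i in adjacency.get(jj, ()):  # i-jj-kk-l paths
                if i == kk:
                    continue
                for l in adjacency.get(kk, ()):
                    if l == jj or l == i:
                        continue
                    canon = min((i, jj, kk, l), (l, kk, jj, i))
                    if canon in seen:
                        continue
                    seen.add(canon)
                    dihedrals.append((i, jj, kk, l))

    def _is_backbone(i: int) -> bool:
        cls = structure.residue_class[i]
        if cls == "protein":
            return structure.name[i] in PROTEIN_BACKBONE_NAMES
        if cls == "RNA":
            return structure.name[i] in RNA_BACKBONE_TOY
        return True

    dih_class = np.array(
        ["BB" if all(_is_backbone(i) for i in quad) else "SC" for quad in dihedrals],
        dtype=object,
    )

    return Topology(
        bonds=np.array(bonds, dtype=int).reshape(-1, 2),
        angles=np.array(angles, dtype=int).reshape(-1, 3),
        dihedrals=np.array(dihedrals, dtype=int).reshape(-1, 4),
        dihedral_class=dih_class,
        impropers=np.array(impropers, dtype=int).reshape(-1, 4),
        planars=np.array(planars, dtype=int).reshape(-1, 4),
    )
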