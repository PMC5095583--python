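"""Plain-text topology files for the structure-based potential.

Sections (``[atoms]``, ``[params]``, ``[bonds]``, ``[angles]``,
``[impropers]``, ``[planars]``, ``[dihedrals]``, ``[contacts]``,
``[repulsion]``, ``[charges]``, ``[restraints]``, ``[electrostatics]``)
hold whitespace-separated columns; ``#`` starts a comment.  Indices are
0-based atom indices into the ``[atoms]`` section.  The format is
versioned via the ``format`` header line.
"""

from __future__ import annotations

import ast

import numpy as np

from .forcefield import (ContactList, ElectrostaticParams, EnergyParams,
                         ForceFieldTerms)

FORMAT_VERSION = 1


def write_forcefield(ff: ForceFieldTerms, path) -> None:
    with open(path, "w") as fh:
        w = fh.write
        w(f"# proofscape topology\nformat\t{FORMAT_VERSION}\nn_atoms\t{ff.n_atoms}\n")
        w("[params]\n")
        for k, v in ff.params.__dict__.items():
            w(f"{k}\t{v!r}\n")
        if ff.electrostatics is not None:
            w("[electrostatics]\n")
            for k, v in ff.electrostatics.__dict__.items():
                w(f"{k}\t{v!r}\n")
        w("[bonds]\n# i j r0\n")
        for (i, j), r0 in zip(ff.bonds, ff.bond_r0):
            w(f"{i}\t{j}\t{r0:.17g}\n")
        w("[angles]\n# i j k theta0\n")
        for (i, j, k), t0 in zip(ff.angles, ff.angle_t0):
            w(f"{i}\t{j}\t{k}\t{t0:.17g}\n")
        for section, quads, p0s in (("impropers", ff.impropers, ff.improper_p0),
                                    ("planars", ff.planars, ff.planar_p0)):
            w(f"[{section}]\n# i j k l phi0\n")
            for quad, p0 in zip(quads, p0s):
                w("\t".join(str(int(q)) for q in quad) + f"\t{p0:.17g}\n")
        w("[dihedrals]\n# i j k l phi0 K class\n")
        for quad, p0, K, cl in zip(ff.dihedrals, ff.dihedral_p0,
                                   ff.dihedral_k, ff.dihedral_class):
            w("\t".join(str(int(q)) for q in quad) + f"\t{p0:.17g}\t{K:.17g}\t{cl}\n")
        w("[contacts]\n# i j sigma eps class\n")
        c = ff.contacts
        for i, j, s, e, cl in zip(c.i, c.j, c.sigma, c.eps, c.weight_class):
            w(f"{i}\t{j}\t{s:.17g}\t{e:.17g}\t{cl}\n")
        w("[repulsion]\n# i j\n")
        for i, j in ff.rep_pairs:
            w(f"{i}\t{j}\n")
        w("[charges]\n# atom q\n")
        for i in np.flatnonzero(ff.charges != 0):
            w(f"{i}\t{ff.charges[i]:.17g}\n")
        w("[restraints]\n# atom cx cy cz kx ky kz\n")
        for a, ctr, k in zip(ff.restraint_atoms, ff.restraint_centers, ff.restraint_k):
            w(f"{a}\t" + "\t".join(f"{v:.17g}" for v in ctr)
              + "\t" + "\t".join(f"{v:.17g}" for v in k) + "\n")


def read_forcefield(path) -> ForceFieldTerms:
    sections: dict[str, list[list[str]]] = {}
    header: dict[str, str] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                sections[current] = []
                continue
            if current is None:
                key, _, val = line.partition("\t")
                header[key] = val
            else:
                sections[current].append(line.split("\t"))

    if int(header.get("format", -1)) != FORMAT_VERSION:
        raise ValueError(f"unsupported topology format {header.get('format')}")
    n_atoms = int(header["n_atoms"])

    def _parse_params(cls, name):
        if name not in sections:
            return None
        kwargs = {}
        for key, val in (row[:2] for row in sections[name]):
            kwargs[key] = ast.literal_eval(val)
        return cls(**kwargs)

    params = _parse_params(EnergyParams, "params") or EnergyParams()
    elec = _parse_params(ElectrostaticParams, "electrostatics")

    def _ints(name, ncol):
        rows = sections.get(name, [])
        arr = np.array([[int(v) for v in row[:ncol]] for row in rows], dtype=int)
        return arr.reshape(-1, ncol)

    def _col(name, col, dtype=float):
        return np.array([dtype(row[col]) for row in sections.get(name, [])])

    bonds = _ints("bonds", 2)
    angles = _ints("angles", 3)
    impropers = _ints("impropers", 4)
    planars = _ints("planars", 4)
    dihedrals = _ints("dihedrals", 4)
    contacts = ContactList(
        i=_col("contacts", 0, int), j=_col("contacts", 1, int),
        sigma=_col("contacts", 2), eps=_col("contacts", 3),
        weight_class=np.array([row[4] for row in sections.get("contacts", [])],
                              dtype=object),
    )
    charges = np.zeros(n_atoms)
    for row in sections.get("charges", []):
        charges[int(row[0])] = float(row[1])
    restr = sections.get("restraints", [])
    bonded = set(map(tuple, np.sort(bonds, axis=1).tolist())) if len(bonds) else set()
    for arr in (angles, dihedrals, impropers, planars):
        for term in arr:
            for a in range(len(term)):
                for b in range(a + 1, len(term)):
                    bonded.add((min(term[a], term[b]), max(term[a], term[b])))
    qi = np.flatnonzero(charges != 0)
    es_pairs = np.array(
        [(a, b) for ai, a in enumerate(qi) for b in qi[ai + 1:]
         if (min(a, b), max(a, b)) not in bonded],
        dtype=int).reshape(-1, 2)
    return ForceFieldTerms(
        n_atoms=n_atoms,
        bonds=bonds, bond_r0=_col("bonds", 2),
        angles=angles, angle_t0=_col("angles", 3),
        impropers=impropers, improper_p0=_col("impropers", 4),
        planars=planars, planar_p0=_col("planars", 4),
        dihedrals=dihedrals, dihedral_p0=_col("dihedrals", 4),
        dihedral_k=_col("dihedrals", 5),
        dihedral_class=np.array([row[6] for row in sections.get("dihedrals", [])],
                                dtype=object),
        contacts=contacts,
        rep_pairs=_ints("repulsion", 2),
        charges=charges,
        params=params,
        electrostatics=elec,
        restraint_atoms=_col("restraints", 0, int).astype(int),
        restraint_centers=np.array([[float(v) for v in row[1:4]] for row in restr]).reshape(-1, 3),
        restraint_k=np.array([[float(v) for v in row[4:7]] for row in restr]).reshape(-1, 3),
        es_pairs=es_pairs,
    )
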