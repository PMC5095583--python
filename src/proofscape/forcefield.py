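"""All-atom structure-based potential with screened electrostatics.

The potential's global minimum is a preassigned ("native") structure.
Bond lengths, angles, improper and planar dihedrals are harmonic about
their native values; proper dihedrals use the standard
``K[(1 - cos(φ-φ0)) + 1/2 (1 - cos 3(φ-φ0))]`` form; atom pairs in contact
in the native structure attract through a 6-12 well with minimum at the
native separation; every other pair repels as ``ε_NC (r_NC/r)^12``; and an
optional Debye-Hückel term screens charge-charge interactions.

Energies are in reduced units (k_BT = 1 at the simulation temperature),
lengths in Å, masses 1.  The stabilising weights are normalised so that

1. within each biopolymer class, backbone dihedrals are ``R_BB/SC`` times
   stronger than side-chain dihedrals (2 for protein, 1 for RNA);
2. total contact energy over total dihedral energy equals ``R_C/D`` (= 2);
3. total contact + dihedral energy equals ``N_atoms·ε`` with ε the reduced
   energy unit (default 1).

Contacts are native pairs within a 4 Å cutoff; stacked RNA base pairs
(sequence-adjacent residues) are scaled by 1/3; user-declared interface
pairs are scaled (default 0.5) and declared exclusions removed, mirroring
the down-weighting of transient intermolecular contacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import constants
from scipy.spatial import cKDTree

from .structure import MolecularStructure, RNA_BACKBONE_NAMES
from .topology import Topology, build_topology

logger = logging.getLogger(__name__)

__all__ = [
    "EnergyParams",
    "ElectrostaticParams",
    "ContactList",
    "ForceFieldTerms",
    "EnergyBreakdown",
    "detect_contacts",
    "classify_and_scale_contacts",
    "assign_charges",
    "build_forcefield",
    "energy",
    "forces",
    "energy_and_forces",
]


@dataclass
class EnergyParams:
    """Scaling rules and constants of the structure-based potential."""

    r_bbsc_protein: float = 2.0   # backbone/side-chain dihedral ratio, protein
    r_bbsc_rna: float = 1.0       # same, RNA
    r_cd: float = 2.0             # total contact / total dihedral energy
    epsilon: float = 1.0          # reduced energy unit
    r_nc: float = 2.5             # Å, excluded-volume radius
    eps_nc: float = 1.0           # strength of the r^-12 repulsion
    rep_cutoff: float = 4.0       # Å; repulsion truncated+shifted to 0 here
    stacked_scale: float = 1.0 / 3.0
    interface_scale: float = 0.5
    k_bond: float = 100.0         # ε/Å², harmonic bonds
    k_angle: float = 20.0         # ε/rad²
    k_improper: float = 10.0      # ε/rad²
    k_planar: float = 10.0        # ε/rad²

    def __post_init__(self):
        for name in ("r_bbsc_protein", "r_bbsc_rna", "r_cd", "epsilon", "r_nc",
                     "eps_nc", "stacked_scale", "interface_scale",
                     "k_bond", "k_angle", "k_improper", "k_planar"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"EnergyParams.{name} must be finite and > 0, got {v}")


def bjerrum_length(temperature_K: float = 298.15, dielectric: float = 80.0) -> float:
    """Bjerrum length in Å at the given temperature and relative dielectric."""
    e = constants.elementary_charge
    lb_m = e ** 2 / (4 * np.pi * constants.epsilon_0 * dielectric
                     * constants.Boltzmann * temperature_K)
    return lb_m * 1e10


@dataclass
class ElectrostaticParams:
    """Debye-Hückel screening: V = B·l_B·q_i q_j exp(-κr)/r in k_BT.

    ``screening_length_nm`` is the Debye length κ⁻¹ (default 1.4 nm,
    i.e. 0.05 M monovalent salt); the dielectric (default 80) enters the
    Bjerrum length, which carries the energy scale in reduced (k_BT) units.
    The interaction is truncated at ``cutoff_factor``·κ⁻¹ and shifted to
    zero there.
    """

    screening_length_nm: float = 1.4
    dielectric: float = 80.0
    prefactor_B: float = 1.0
    cutoff_factor: float = 4.0
    temperature_K: float = 298.15
    enabled: bool = True

    def __post_init__(self):
        if self.screening_length_nm <= 0:
            raise ValueError("screening length must be > 0")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be > 0")

    @property
    def kappa(self) -> float:
        """Inverse screening length in Å⁻¹."""
        return 1.0 / (self.screening_length_nm * 10.0)

    @property
    def amplitude(self) -> float:
        """Energy prefactor B·l_B in k_BT·Å."""
        return self.prefactor_B * bjerrum_length(self.temperature_K, self.dielectric)

    @property
    def cutoff(self) -> float:
        return self.cutoff_factor / self.kappa


@dataclass
class ContactList:
    """Native contact pairs with well positions σ and depths ε."""

    i: np.ndarray
    j: np.ndarray
    sigma: np.ndarray          # Å, native separations
    eps: np.ndarray            # well depths, reduced units
    weight_class: np.ndarray   # normal | stacked | interface_scaled

    def __post_init__(self):
        self.i = np.asarray(self.i, dtype=int)
        self.j = np.asarray(self.j, dtype=int)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        self.weight_class = np.asarray(self.weight_class, dtype=object)
        if np.any(self.i >= self.j):
            raise ValueError("contacts must have i < j")

    def __len__(self) -> int:
        return len(self.i)

    def pairs(self) -> set:
        return set(zip(self.i.tolist(), self.j.tolist()))

    def copy(self) -> "ContactList":
        return ContactList(self.i.copy(), self.j.copy(), self.sigma.copy(),
                           self.eps.copy(), self.weight_class.copy())


@dataclass
class ForceFieldTerms:
    """The complete potential: term arrays plus native parameters."""

    n_atoms: int
    bonds: np.ndarray            # (nb, 2) int
    bond_r0: np.ndarray
    angles: np.ndarray           # (na, 3) int
    angle_t0: np.ndarray
    impropers: np.ndarray        # (ni, 4) int
    improper_p0: np.ndarray
    planars: np.ndarray
    planar_p0: np.ndarray
    dihedrals: np.ndarray        # (nd, 4) int
    dihedral_p0: np.ndarray
    dihedral_k: np.ndarray
    dihedral_class: np.ndarray
    contacts: ContactList
    rep_pairs: np.ndarray        # (nr, 2) int, excluded-volume pairs
    charges: np.ndarray          # per atom
    params: EnergyParams
    electrostatics: ElectrostaticParams | None = None
    restraint_atoms: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    restraint_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    restraint_k: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    es_pairs: np.ndarray | None = None   # restrict electrostatics to these pairs

    def with_restraints(self, atoms, centers, k) -> "ForceFieldTerms":
        atoms = np.asarray(atoms, dtype=int)
        centers = np.asarray(centers, dtype=float).reshape(len(atoms), 3)
        k = np.asarray(k, dtype=float)
        if k.ndim == 1:
            k = np.repeat(k[:, None], 3, axis=1) if len(k) == len(atoms) else k
        return replace(self, restraint_atoms=atoms, restraint_centers=centers,
                       restraint_k=k.reshape(len(atoms), 3))

    @property
    def total_contact_energy(self) -> float:
        return float(self.contacts.eps.sum())

    @property
    def total_dihedral_energy(self) -> float:
        return float(self.dihedral_k.sum())


@dataclass
class EnergyBreakdown:
    """Per-term energies in reduced units; ``total`` is their sum."""

    bonds: float = 0.0
    angles: float = 0.0
    impropers: float = 0.0
    planars: float = 0.0
    dihedrals: float = 0.0
    contacts: float = 0.0
    repulsion: float = 0.0
    electrostatics: float = 0.0
    restraints: float = 0.0

    @property
    def total(self) -> float:
        return (self.bonds + self.angles + self.impropers + self.planars
                + self.dihedrals + self.contacts + self.repulsion
                + self.electrostatics + self.restraints)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("bonds", "angles", "impropers", "planars", "dihedrals",
              "contacts", "repulsion", "electrostatics", "restraints")}
        d["total"] = self.total
        return d


# ---------------------------------------------------------------- contacts

def detect_contacts(structure: MolecularStructure, cutoff: float = 4.0,
                    topology: Topology | None = None) -> ContactList:
    """Native contacts: non-bonded pairs of distinct residues within cutoff.

    Pairs already connected through a bond, angle or dihedral term and
    intra-residue pairs are excluded; σ is set to the native distance.
    """
    if structure.n_atoms == 0:
        raise ValueError("cannot detect contacts in an empty structure")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if topology is None:
        topology = build_topology(structure)
    bonded = topology.bonded_pairs()
    tree = cKDTree(structure.coords)
    raw = sorted(tree.query_pairs(cutoff))
    res_key = list(zip(structure.chain, structure.resid))
    ii, jj, sig = [], [], []
    for i, j in raw:
        if res_key[i] == res_key[j]:
            continue
        if (i, j) in bonded:
            continue
        ii.append(i)
        jj.append(j)
        sig.append(float(np.linalg.norm(structure.coords[i] - structure.coords[j])))
    n = len(ii)
    return ContactList(
        i=np.array(ii, dtype=int), j=np.array(jj, dtype=int),
        sigma=np.array(sig), eps=np.ones(n),
        weight_class=np.array(["normal"] * n, dtype=object),
    )


def _is_rna_base_atom(structure: MolecularStructure, i: int) -> bool:
    return (structure.residue_class[i] == "RNA"
            and structure.name[i] not in RNA_BACKBONE_NAMES)


def classify_and_scale_contacts(
    contacts: ContactList,
    structure: MolecularStructure,
    params: EnergyParams,
    interface_pairs=None,
    exclude_pairs=None,
    exclude_resnames=None,
) -> ContactList:
    """Apply the contact weighting rules.

    Stacked RNA base-base contacts (sequence-adjacent residues, same chain)
    are scaled by 1/3.  ``interface_pairs`` / ``exclude_pairs`` are
    residue-pair lists ``((chain, resid), (chain, resid))``: interface
    contacts are scaled by ``params.interface_scale``, excluded ones are
    removed (as are all contacts touching ``exclude_resnames`` residues,
    used for purely steric bodies).
    """
    res_keys = {(c, int(r)) for c, r in zip(structure.chain, structure.resid)}

    def _norm_pairs(pairs, label):
        out = set()
        for a, b in pairs or ():
            a, b = (a[0], int(a[1])), (b[0], int(b[1]))
            for key in (a, b):
                if key not in res_keys:
                    raise ValueError(f"{label} names unknown residue {key}")
            out.add(frozenset((a, b)))
        return out

    iface = _norm_pairs(interface_pairs, "interface list")
    excl = _norm_pairs(exclude_pairs, "exclusion list")
    excl_rn = set(exclude_resnames or ())

    out = contacts.copy()
    keep = np.ones(len(out), dtype=bool)
    for n, (i, j) in enumerate(zip(out.i, out.j)):
        ri = (structure.chain[i], int(structure.resid[i]))
        rj = (structure.chain[j], int(structure.resid[j]))
        pair = frozenset((ri, rj))
        if pair in excl or structure.resname[i] in excl_rn or structure.resname[j] in excl_rn:
            keep[n] = False
            continue
        stacked = (
            _is_rna_base_atom(structure, i) and _is_rna_base_atom(structure, j)
            and structure.chain[i] == structure.chain[j]
            and abs(int(structure.resid[i]) - int(structure.resid[j])) == 1
        )
        if stacked:
            out.eps[n] *= params.stacked_scale
            out.weight_class[n] = "stacked"
        elif pair in iface:
            out.eps[n] *= params.interface_scale
            out.weight_class[n] = "interface_scaled"
    return ContactList(out.i[keep], out.j[keep], out.sigma[keep],
                       out.eps[keep], out.weight_class[keep])


# ---------------------------------------------------------------- charges

#: preferred side-chain charge carrier per residue type, first present wins
_CHARGE_SITES = {
    "ARG": (+1, ["CZ", "NH1", "CG", "CB"]),
    "LYS": (+1, ["NZ", "CE", "CG", "CB"]),
    "ASP": (-1, ["CG", "CB"]),
    "GLU": (-1, ["CD", "CG", "CB"]),
}


def assign_charges(structure: MolecularStructure) -> np.ndarray:
    """Charge map: P atoms -1, Mg²⁺ +2, Arg/Lys +1, Asp/Glu -1, His 0.

    The ±1 protein charge sits on a single designated side-chain atom
    (CZ/NZ/CG/CD, falling back to the outermost side-chain atom present).
    Unknown residues get charge 0 and are logged.
    """
    q = np.zeros(structure.n_atoms)
    unknown = set()
    for chain, resid, idx in structure.residues():
        cls = structure.residue_class[idx[0]]
        resname = str(structure.resname[idx[0]]).upper()
        names = {structure.name[i]: i for i in idx}
        if cls == "RNA":
            if "P" in names:
                q[names["P"]] = -1.0
        elif cls == "ion":
            if resname == "MG":
                q[idx[0]] = +2.0
        elif cls == "protein":
            if resname in _CHARGE_SITES:
                charge, prefs = _CHARGE_SITES[resname]
                for nm in prefs:
                    if nm in names:
                        q[names[nm]] = charge
                        logger.debug("charge %+d on %s %s%d atom %s",
                                     charge, resname, chain, resid, nm)
                        break
        elif resname not in ("LIG", "REC", "GAT", "CAP", "WAL"):
            unknown.add(resname)
    if unknown:
        logger.info("uncharged unknown residues: %s", sorted(unknown))
    return q


# ---------------------------------------------------------------- build

def build_forcefield(
    structure: MolecularStructure,
    params: EnergyParams | None = None,
    electrostatics: ElectrostaticParams | None = None,
    *,
    contacts: ContactList | None = None,
    interface_pairs=None,
    exclude_pairs=None,
    exclude_resnames=None,
    topology: Topology | None = None,
) -> ForceFieldTerms:
    """Assemble the full potential and enforce the three normalisation ratios.

    Raises ``ValueError`` for structures with zero contacts (the contact /
    dihedral normalisation is then undefined).
    """
    params = params or EnergyParams()
    if topology is None:
        topology = build_topology(structure)
    coords = structure.coords
    if contacts is None:
        contacts = detect_contacts(structure, topology=topology)
        contacts = classify_and_scale_contacts(
            contacts, structure, params,
            interface_pairs=interface_pairs,
            exclude_pairs=exclude_pairs,
            exclude_resnames=exclude_resnames,
        )
    if len(contacts) == 0:
        raise ValueError("structure has zero native contacts; "
                         "the stabilising-energy normalisation is undefined")

    bond_r0 = _distances(coords, topology.bonds)
    angle_t0 = _angles(coords, topology.angles)
    improper_p0 = _dihedral_angles(coords, topology.impropers)
    planar_p0 = _dihedral_angles(coords, topology.planars)
    dihedral_p0 = _dihedral_angles(coords, topology.dihedrals)

    # raw dihedral weights: R_BB/SC within each biopolymer class
    n_dih = len(topology.dihedrals)
    raw_w = np.ones(n_dih)
    for n in range(n_dih):
        j = topology.dihedrals[n, 1]
        cls = structure.residue_class[j]
        r = params.r_bbsc_protein if cls == "protein" else params.r_bbsc_rna
        if topology.dihedral_class[n] == "BB":
            raw_w[n] = r

    # purely steric bodies (contact-excluded resnames) carry no stabilising
    # energy and do not count toward the N_atoms·ε budget
    n_atoms = structure.n_atoms
    excl_rn = set(exclude_resnames or ())
    n_stabilised = int(np.sum(~np.isin(structure.resname.astype(str), list(excl_rn)))) \
        if excl_rn else n_atoms
    total = n_stabilised * params.epsilon
    sum_c_raw = contacts.eps.sum()
    sum_d_raw = raw_w.sum()
    if n_dih > 0:
        target_d = total / (1.0 + params.r_cd)
        target_c = total - target_d
        dihedral_k = raw_w * (target_d / sum_d_raw)
    else:
        logger.info("no dihedrals: full stabilising budget assigned to contacts")
        target_c = total
        dihedral_k = raw_w
    eps_scaled = contacts.eps * (target_c / sum_c_raw)
    contacts = ContactList(contacts.i, contacts.j, contacts.sigma,
                           eps_scaled, contacts.weight_class)

    # excluded-volume pairs: inter-residue, not bonded, not a contact
    # (intra-residue geometry is carried by the bonded terms)
    bonded = topology.bonded_pairs()
    contact_set = contacts.pairs()
    res_key = list(zip(structure.chain, structure.resid))
    rep = [
        (i, j)
        for i in range(n_atoms)
        for j in range(i + 1, n_atoms)
        if res_key[i] != res_key[j]
        and (i, j) not in bonded and (i, j) not in contact_set
    ]

    charges = assign_charges(structure)
    qi = np.flatnonzero(charges != 0)
    es_pairs = np.array(
        [(a, b) for ai, a in enumerate(qi) for b in qi[ai + 1:]
         if (min(a, b), max(a, b)) not in bonded],
        dtype=int,
    ).reshape(-1, 2)

    return ForceFieldTerms(
        n_atoms=n_atoms,
        bonds=topology.bonds, bond_r0=bond_r0,
        angles=topology.angles, angle_t0=angle_t0,
        impropers=topology.impropers, improper_p0=improper_p0,
        planars=topology.planars, planar_p0=planar_p0,
        dihedrals=topology.dihedrals, dihedral_p0=dihedral_p0,
        dihedral_k=dihedral_k, dihedral_class=topology.dihedral_class,
        contacts=contacts,
        rep_pairs=np.array(rep, dtype=int).reshape(-1, 2),
        charges=charges,
        params=params,
        electrostatics=electrostatics,
        es_pairs=es_pairs,
    )


# ---------------------------------------------------------------- geometry

def _distances(coords, pairs):
    if len(pairs) == 0:
        return np.empty(0)
    d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    return np.linalg.norm(d, axis=1)


def _angles(coords, triples):
    if len(triples) == 0:
        return np.empty(0)
    u = coords[triples[:, 0]] - coords[triples[:, 1]]
    v = coords[triples[:, 2]] - coords[triples[:, 1]]
    cos = np.sum(u * v, axis=1) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    return np.arccos(np.clip(cos, -1.0, 1.0))


def _dihedral_angles(coords, quads):
    if len(quads) == 0:
        return np.empty(0)
    b1 = coords[quads[:, 1]] - coords[quads[:, 0]]
    b2 = coords[quads[:, 2]] - coords[quads[:, 1]]
    b3 = coords[quads[:, 3]] - coords[quads[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(np.cross(n1, n2) * (b2 / b2n[:, None]), axis=1)
    return np.arctan2(y, x)


def _wrap(dphi):
    return (dphi + np.pi) % (2 * np.pi) - np.pi


# ---------------------------------------------------------------- energy

def energy_and_forces(coords: np.ndarray, ff: ForceFieldTerms):
    """Evaluate every term and its analytic gradient (force = -∇V)."""
    coords = np.asarray(coords, dtype=float).reshape(ff.n_atoms, 3)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    br = EnergyBreakdown()
    F = np.zeros_like(coords)
    p = ff.params

    # bonds
    if len(ff.bonds):
        d = coords[ff.bonds[:, 0]] - coords[ff.bonds[:, 1]]
        r = np.linalg.norm(d, axis=1)
        dr = r - ff.bond_r0
        br.bonds = float(np.sum(0.5 * p.k_bond * dr ** 2))
        fpair = (-p.k_bond * dr / r)[:, None] * d
        np.add.at(F, ff.bonds[:, 0], fpair)
        np.add.at(F, ff.bonds[:, 1], -fpair)

    # angles
    if len(ff.angles):
        i, j, k = ff.angles[:, 0], ff.angles[:, 1], ff.angles[:, 2]
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cos)
        dth = theta - ff.angle_t0
        br.angles = float(np.sum(0.5 * p.k_angle * dth ** 2))
        sin = np.sqrt(np.clip(1.0 - cos ** 2, 1e-12, None))
        dV = p.k_angle * dth
        # dθ/dri and dθ/drk
        dthi = (u * (cos / nu)[:, None] - v / nv[:, None]) / (nu * sin)[:, None]
        dthk = (v * (cos / nv)[:, None] - u / nu[:, None]) / (nv * sin)[:, None]
        np.add.at(F, i, -dV[:, None] * dthi)
        np.add.at(F, k, -dV[:, None] * dthk)
        np.add.at(F, j, dV[:, None] * (dthi + dthk))

    # dihedral-type terms
    def _dihedral_term(quads, dVdphi_fn, phi0, energy_fn):
        if len(quads) == 0:
            return 0.0
        i, j, k, l = quads[:, 0], quads[:, 1], quads[:, 2], quads[:, 3]
        b1 = coords[j] - coords[i]
        b2 = coords[k] - coords[j]
        b3 = coords[l] - coords[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2n = np.linalg.norm(b2, axis=1)
        x = np.sum(n1 * n2, axis=1)
        y = np.sum(np.cross(n1, n2) * (b2 / b2n[:, None]), axis=1)
        phi = np.arctan2(y, x)
        dphi = _wrap(phi - phi0)
        E = energy_fn(dphi)
        dV = dVdphi_fn(dphi)
        n1sq = np.sum(n1 * n1, axis=1)
        n2sq = np.sum(n2 * n2, axis=1)
        dphi_dri = -(b2n / n1sq)[:, None] * n1
        dphi_drl = (b2n / n2sq)[:, None] * n2
        c1 = (np.sum(b1 * b2, axis=1) / b2n ** 2)
        c2 = (np.sum(b3 * b2, axis=1) / b2n ** 2)
        dphi_drj = (-c1 - 1.0)[:, None] * dphi_dri + c2[:, None] * dphi_drl
        dphi_drk = -dphi_dri - dphi_drj - dphi_drl
        np.add.at(F, i, -dV[:, None] * dphi_dri)
        np.add.at(F, j, -dV[:, None] * dphi_drj)
        np.add.at(F, k, -dV[:, None] * dphi_drk)
        np.add.at(F, l, -dV[:, None] * dphi_drl)
        return float(np.sum(E))

    br.impropers = _dihedral_term(
        ff.impropers, lambda d: p.k_improper * d, ff.improper_p0,
        lambda d: 0.5 * p.k_improper * d ** 2)
    br.planars = _dihedral_term(
        ff.planars, lambda d: p.k_planar * d, ff.planar_p0,
        lambda d: 0.5 * p.k_planar * d ** 2)
    K = ff.dihedral_k
    br.dihedrals = _dihedral_term(
        ff.dihedrals,
        lambda d: K * (np.sin(d) + 1.5 * np.sin(3 * d)),
        ff.dihedral_p0,
        lambda d: K * ((1 - np.cos(d)) + 0.5 * (1 - np.cos(3 * d))))

    # contacts: ε[(σ/r)^12 - 2(σ/r)^6]
    c = ff.contacts
    if len(c):
        d = coords[c.i] - coords[c.j]
        r = np.linalg.norm(d, axis=1)
        sr6 = (c.sigma / r) ** 6
        br.contacts = float(np.sum(c.eps * (sr6 ** 2 - 2 * sr6)))
        dVdr = c.eps * (-12.0 / r) * (sr6 ** 2 - sr6)
        fpair = (-dVdr / r)[:, None] * d
        np.add.at(F, c.i, fpair)
        np.add.at(F, c.j, -fpair)

    # excluded volume: ε_NC (r_NC/r)^12, truncated and shifted to 0 at rep_cutoff
    if len(ff.rep_pairs):
        i, j = ff.rep_pairs[:, 0], ff.rep_pairs[:, 1]
        d = coords[i] - coords[j]
        r = np.linalg.norm(d, axis=1)
        inside = r < p.rep_cutoff
        sr12 = (p.r_nc / r) ** 12
        shift = (p.r_nc / p.rep_cutoff) ** 12
        br.repulsion = float(np.sum(np.where(inside, p.eps_nc * (sr12 - shift), 0.0)))
        dVdr = np.where(inside, -12.0 * p.eps_nc * sr12 / r, 0.0)
        fpair = (-dVdr / r)[:, None] * d
        np.add.at(F, i, fpair)
        np.add.at(F, j, -fpair)

    # Debye-Hückel electrostatics, truncated and shifted
    es = ff.electrostatics
    if es is not None and es.enabled and np.any(ff.charges != 0):
        pairs = ff.es_pairs
        if pairs is None:
            qi = np.flatnonzero(ff.charges != 0)
            pairs = np.array([(a, b) for ai, a in enumerate(qi) for b in qi[ai + 1:]],
                             dtype=int).reshape(-1, 2)
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            d = coords[i] - coords[j]
            r = np.linalg.norm(d, axis=1)
            kap = es.kappa
            rc = es.cutoff
            qq = ff.charges[i] * ff.charges[j]
            amp = es.amplitude
            inside = r < rc
            shift = np.exp(-kap * rc) / rc
            V = amp * qq * (np.exp(-kap * r) / r - shift)
            V = np.where(inside, V, 0.0)
            br.electrostatics = float(np.sum(V))
            dVdr = amp * qq * np.exp(-kap * r) * (-kap / r - 1.0 / r ** 2)
            dVdr = np.where(inside, dVdr, 0.0)
            fpair = (-dVdr / r)[:, None] * d
            np.add.at(F, i, fpair)
            np.add.at(F, j, -fpair)

    # position restraints, per-axis harmonic
    if len(ff.restraint_atoms):
        dx = coords[ff.restraint_atoms] - ff.restraint_centers
        br.restraints = float(np.sum(0.5 * ff.restraint_k * dx ** 2))
        np.add.at(F, ff.restraint_atoms, -ff.restraint_k * dx)

    return br, F


def energy(coords: np.ndarray, ff: ForceFieldTerms) -> EnergyBreakdown:
    """Per-term energies of a configuration."""
    return energy_and_forces(coords, ff)[0]


def forces(coords: np.ndarray, ff: ForceFieldTerms) -> np.ndarray:
    """Per-atom forces (-∇V) of a configuration."""
    return energy_and_forces(coords, ff)[1]
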