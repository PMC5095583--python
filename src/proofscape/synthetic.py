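"""Synthetic inputs: analytic landscapes, toy structures, steric fixtures.

Everything the pipeline consumes can be generated here without downloads:

* :func:`make_double_well` — an analytic two-basin free-energy curve with
  exact control of the forward barrier and basin offset, the ground truth
  for the histogram-reweighting and rate machinery;
* :func:`make_toy_hairpin` — a minimal double-stranded RNA-like polymer
  (backbone P/C4'/O3' plus three base pseudo-atoms per residue) on which
  the contact, stacking and charge rules of the structure-based model all
  fire;
* :func:`make_toy_peptide` — a two-strand peptide analogue exercising the
  protein backbone/side-chain dihedral rules;
* :func:`make_gated_system` — a mobile ligand that must squeeze past a
  fixed steric ring (the analogue of the rRNA helix blocking the tRNA
  elbow) to move between a contact-stabilised bound site and an extended
  corridor region;
* :func:`add_confinement_wall` — a purely repulsive body truncating the
  extended region (the analogue of the elongation factor occluding
  extended tRNA conformations);
* :func:`sample_biased_1d` — overdamped Brownian sampling of an analytic
  potential under a harmonic umbrella bias.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .sampler import CoordinateSpec
from .structure import MolecularStructure

#: resnames of purely steric bodies; they never receive stabilising contacts
STERIC_RESNAMES = ("GAT", "CAP", "WAL", "REC_X")


# ------------------------------------------------------------ analytic

@dataclass
class AnalyticPotential:
    """F(x) in k_BT over a 1D domain with labelled basins and barrier.

    The curve is a cubic Hermite spline through (basin, barrier) anchor
    points with zero slope there, so declared basin/barrier values are
    exact stationary points, flanked by steep confining walls.
    """

    spline: CubicHermiteSpline
    bounds: tuple[float, float]
    basins: tuple[float, ...]
    barrier: float | None
    length_unit: str = "Å"

    def __call__(self, x):
        return self.spline(np.asarray(x, dtype=float))

    def grad(self, x):
        if not hasattr(self, "_deriv"):
            self._deriv = self.spline.derivative()
        return self._deriv(np.asarray(x, dtype=float))

    def to_tsv(self, path, n: int = 400) -> None:
        xs = np.linspace(*self.bounds, n)
        with open(path, "w") as fh:
            fh.write(f"# position({self.length_unit})\tF(kBT)\n")
            for x, f in zip(xs, self(xs)):
                fh.write(f"{x:.8g}\t{f:.8g}\n")


def make_double_well(
    basin1_pos: float,
    basin2_pos: float,
    barrier_height_fwd: float,
    basin_offset: float = 0.0,
    barrier_pos: float | None = None,
    wall_height: float | None = None,
) -> AnalyticPotential:
    """Two-basin landscape: F(basin1)=0, forward barrier exactly
    ``barrier_height_fwd`` k_BT, F(basin2) = -``basin_offset``.

    A positive offset stabilises basin 2; a negative one destabilises it.
    """
    vals = [basin1_pos, basin2_pos, barrier_height_fwd, basin_offset]
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("double-well parameters must be finite")
    if basin1_pos >= basin2_pos:
        raise ValueError("basin1_pos must be < basin2_pos")
    if barrier_height_fwd <= 0:
        raise ValueError("forward barrier must be > 0")
    if barrier_height_fwd <= -basin_offset:
        raise ValueError("barrier must exceed F(basin2) to be a maximum")
    span = basin2_pos - basin1_pos
    xb = barrier_pos if barrier_pos is not None else 0.5 * (basin1_pos + basin2_pos)
    if not (basin1_pos < xb < basin2_pos):
        raise ValueError("barrier position must lie between the basins")
    top = max(barrier_height_fwd, -basin_offset, 0.0)
    wall = wall_height if wall_height is not None else top + 12.0
    lo = basin1_pos - 0.25 * span
    hi = basin2_pos + 0.25 * span
    xs = np.array([lo, basin1_pos, xb, basin2_pos, hi])
    fs = np.array([wall, 0.0, barrier_height_fwd, -basin_offset, wall])
    ds = np.array([-(wall) / (0.25 * span) * 1.0, 0.0, 0.0, 0.0,
                   (wall) / (0.25 * span) * 1.0])
    spline = CubicHermiteSpline(xs, fs, ds)
    return AnalyticPotential(spline=spline, bounds=(lo, hi),
                             basins=(basin1_pos, basin2_pos), barrier=xb)


def destabilize_segment(centers, F, delta: float, split: float,
                        width: float = 1.0) -> np.ndarray:
    """Raise the low-ρ side of a profile by ``delta`` k_BT.

    Returns ``F + delta·s(ρ)`` with a smooth switch s = ½(1 - tanh((ρ -
    split)/width)): the profile is identical beyond ``split`` (the switch
    decays fast against the barrier scale) while the starting basin is
    uniformly shifted up — the minimal model of a basin destabilised by a
    steric body.
    """
    centers = np.asarray(centers, dtype=float)
    return np.asarray(F, dtype=float) + delta * 0.5 * (1.0 - np.tanh((centers - split) / width))


def potential_from_profile(centers, F, length_unit="Å") -> AnalyticPotential:
    """Wrap a tabulated profile as an AnalyticPotential (cubic interpolation)."""
    from scipy.interpolate import CubicSpline

    centers = np.asarray(centers, dtype=float)
    F = np.asarray(F, dtype=float)
    cs = CubicSpline(centers, F)
    basins = centers[[np.argmin(F)]]
    return AnalyticPotential(spline=cs, bounds=(centers[0], centers[-1]),
                             basins=tuple(basins), barrier=None,
                             length_unit=length_unit)


# ------------------------------------------------------------ structures

def _jitter(rng: np.random.Generator, shape, scale=0.05):
    return rng.uniform(-scale, scale, size=shape)


def make_toy_hairpin(n_residues: int, seed: int = 0) -> MolecularStructure:
    """Minimal double-stranded RNA-like polymer.

    Residues 1..n/2 run up one strand, the rest back down a parallel
    strand, with base pseudo-atoms reaching across the strand gap so
    cross-strand contacts (< 4 Å) and intra-strand stacking contacts both
    exist.  Atom names are RNA-style (P, C4', O3', N1, C2, C4); every
    residue carries one P atom, so the charge rule yields one -1 per
    residue.  Deterministic for a fixed seed (coordinates jittered by at
    most ±0.05 Å).
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues for a hairpin")
    rng = np.random.default_rng(seed)
    n_a = (n_residues + 1) // 2
    rise = 3.5
    x_b = 10.0
    serial, names, resids, xyz = [], [], [], []
    for r in range(1, n_residues + 1):
        on_a = r <= n_a
        k = r - 1 if on_a else n_residues - r      # position index along strand
        z = k * rise
        x0 = 0.0 if on_a else x_b
        s = 1.0 if on_a else -1.0                  # base points toward other strand
        template = [
            ("P", (0.0, 0.0, 0.0)),
            ("C4'", (0.8, 0.6, 1.0)),
            ("O3'", (0.2, 0.3, 2.2)),
            ("N1", (2.0, 0.6, 1.0)),
            ("C2", (3.3, 0.6, 0.4)),
            ("C4", (3.3, 0.6, 1.6)),
        ]
        for name, (dx, dy, dz) in template:
            serial.append(len(serial) + 1)
            names.append(name)
            resids.append(r)
            xyz.append((x0 + s * dx, dy, z + dz))
    coords = np.array(xyz) + _jitter(rng, (len(xyz), 3))
    n_at = len(serial)
    return MolecularStructure(
        serial=np.array(serial),
        name=np.array(names, dtype=object),
        resname=np.array(["U"] * n_at, dtype=object),
        resid=np.array(resids),
        chain=np.array(["A"] * n_at, dtype=object),
        coords=coords,
    )


def make_toy_peptide(n_residues: int, seed: int = 0,
                     resnames: list[str] | None = None) -> MolecularStructure:
    """Two-strand peptide analogue with N/CA/C/O backbone and CB/CG side chains."""
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    rng = np.random.default_rng(seed)
    if resnames is None:
        cycle = ["ALA", "ARG", "LYS", "ASP", "GLU", "HIS", "SER", "LEU"]
        resnames = [cycle[i % len(cycle)] for i in range(n_residues)]
    n_a = (n_residues + 1) // 2
    rise = 3.4
    x_b = 9.0
    serial, names, rnames, resids, xyz = [], [], [], [], []
    for r in range(1, n_residues + 1):
        on_a = r <= n_a
        k = r - 1 if on_a else n_residues - r
        z = k * rise
        x0 = 0.0 if on_a else x_b
        s = 1.0 if on_a else -1.0
        template = [
            ("N", (0.0, 0.0, 0.0)),
            ("CA", (0.9, 0.9, 0.9)),
            ("C", (0.2, 0.5, 2.2)),
            ("O", (-1.0, 0.9, 2.5)),
            ("CB", (2.2, 0.3, 0.9)),
            ("CG", (3.4, 1.0, 0.9)),
        ]
        for name, (dx, dy, dz) in template:
            serial.append(len(serial) + 1)
            names.append(name)
            rnames.append(resnames[r - 1])
            resids.append(r)
            xyz.append((x0 + s * dx, dy, z + dz))
    coords = np.array(xyz) + _jitter(rng, (len(xyz), 3))
    return MolecularStructure(
        serial=np.array(serial),
        name=np.array(names, dtype=object),
        resname=np.array(rnames, dtype=object),
        resid=np.array(resids),
        chain=np.array(["A"] * len(serial), dtype=object),
        coords=np.array(coords),
    )


# ------------------------------------------------------------ fixtures

@dataclass
class ToyFixture:
    """A structure plus the plumbing a sampling experiment needs.

    ``coordinate`` defines the reaction coordinate; ``fixed_atoms`` are
    frozen during dynamics; ``wall_atoms``/steric residues interact only
    through excluded volume (they are excluded from the contact map);
    ``restraints`` confine the mobile group to the corridor axis.
    """

    structure: MolecularStructure
    coordinate: CoordinateSpec
    fixed_atoms: np.ndarray
    seed: int
    wall_atoms: np.ndarray | None = None
    gate_atoms: np.ndarray | None = None
    restraints: list = field(default_factory=list)  # (atom, center(3), k(3))
    phantom_atoms: np.ndarray | None = None   # atoms with all nonbonded terms removed
    bound_basin: float = 4.3       # native coordinate value, Å
    extended_basin: float = 20.0   # representative extended coordinate, Å
    corridor_end: float = 26.0     # x of the end cap
    wall_position: float | None = None
    gate_x: float | None = None    # position of the steric ring, if active

    @property
    def max_coordinate(self) -> float:
        """Largest usefully sampleable coordinate (inside wall/end cap)."""
        edge = self.corridor_end if self.wall_position is None else self.wall_position
        return edge - 2.5

    def umbrella_centers(self, n_uniform: int = 24, lo: float = 3.2,
                         gate_spacing: float = 0.4) -> np.ndarray:
        """Umbrella centres: a uniform grid over the sampleable range,
        refined around the steric ring where the barrier makes adjacent
        histograms hardest to overlap."""
        hi = self.max_coordinate
        centers = np.linspace(lo, hi, n_uniform)
        if self.gate_x is not None:
            extra = np.arange(self.gate_x - 1.2, self.gate_x + 1.21, gate_spacing)
            centers = np.union1d(centers, extra[(extra > lo) & (extra < hi)])
        return centers

    def __post_init__(self):
        n = self.structure.n_atoms
        for grp in (self.coordinate.group1, self.coordinate.group2):
            if np.any(grp < 0) or np.any(grp >= n):
                raise ValueError("coordinate spec references atoms outside the structure")

    def restraint_arrays(self):
        if not self.restraints:
            return (np.empty(0, dtype=int), np.empty((0, 3)), np.empty((0, 3)))
        atoms = np.array([r[0] for r in self.restraints], dtype=int)
        centers = np.array([r[1] for r in self.restraints], dtype=float)
        ks = np.array([r[2] for r in self.restraints], dtype=float)
        return atoms, centers, ks

    def build_forcefield(self, params=None, electrostatics=None):
        """Forcefield with steric residues contact-excluded and corridor
        restraints attached."""
        from .forcefield import build_forcefield

        ff = build_forcefield(
            self.structure, params, electrostatics,
            exclude_resnames=STERIC_RESNAMES,
        )
        if self.phantom_atoms is not None and len(self.phantom_atoms):
            # "virtual deletion": drop all nonbonded interactions of these
            # atoms while keeping them in the structure, so energies of the
            # two systems coincide configuration-by-configuration elsewhere
            ph = set(int(a) for a in self.phantom_atoms)
            keep = np.array([i not in ph and j not in ph for i, j in ff.rep_pairs])
            ff = replace(ff, rep_pairs=ff.rep_pairs[keep].reshape(-1, 2))
        atoms, centers, ks = self.restraint_arrays()
        if len(atoms):
            ff = ff.with_restraints(atoms, centers, ks)
        return ff

    def seed_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": int(self.seed),
                       "n_atoms": int(self.structure.n_atoms)}, fh)


def _ring(x: float, radius: float, n: int = 6):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([np.full(n, x), radius * np.cos(ang), radius * np.sin(ang)])


def _disc(x: float, radius: float = 2.4):
    return np.array([
        (x, 0.0, 0.0),
        (x, radius, 0.0), (x, -radius, 0.0),
        (x, 0.0, radius), (x, 0.0, -radius),
    ])


def _append_atoms(structure: MolecularStructure, resname: str, resid: int,
                  prefix: str, coords: np.ndarray) -> MolecularStructure:
    n_new = len(coords)
    start = structure.n_atoms
    return MolecularStructure(
        serial=np.concatenate([structure.serial, np.arange(start + 1, start + n_new + 1)]),
        name=np.concatenate([structure.name,
                             np.array([f"{prefix}{k+1}" for k in range(n_new)], dtype=object)]),
        resname=np.concatenate([structure.resname, np.array([resname] * n_new, dtype=object)]),
        resid=np.concatenate([structure.resid, np.full(n_new, resid)]),
        chain=np.concatenate([structure.chain, np.array(["A"] * n_new, dtype=object)]),
        coords=np.vstack([structure.coords, coords]),
    )


GATE_X = 12.0          # Å, position of the steric ring along the corridor
GATE_RADIUS = 2.7      # Å, aperture radius
CORRIDOR_END = 26.0    # Å, end cap of the extended region


def make_gated_system(seed: int = 0, gate: bool = True) -> ToyFixture:
    """Bound site, steric gate, and extended corridor along the x axis.

    A three-bead ligand is natively bound to a four-atom receptor at the
    origin (stabilising contacts at the native geometry).  To reach the
    extended region it must pass a six-atom purely repulsive ring at
    x = 12 Å; the corridor is closed by a repulsive end cap at x = 26 Å,
    and the ligand is harmonically confined to the axis in y/z.  The
    coordinate is the receptor-centre to ligand-centre distance.  With
    ``gate=False`` the ring is omitted (the "virtual deletion" control);
    all other atoms and energies coincide.
    """
    rng = np.random.default_rng(seed)
    rec = np.array([(0.0, 1.8, 0.0), (0.0, -1.8, 0.0),
                    (0.0, 0.0, 1.8), (0.0, 0.0, -1.8)])
    lig = np.array([(2.8, 0.0, 0.0), (4.3, 0.0, 0.0), (5.8, 0.0, 0.0)])
    lig = lig + _jitter(rng, lig.shape, 0.02)

    s = MolecularStructure(
        serial=np.arange(1, 5),
        name=np.array(["R1", "R2", "R3", "R4"], dtype=object),
        resname=np.array(["REC"] * 4, dtype=object),
        resid=np.ones(4, dtype=int),
        chain=np.array(["A"] * 4, dtype=object),
        coords=rec,
    )
    s = _append_atoms(s, "LIG", 2, "L", lig)
    s = _append_atoms(s, "GAT", 3, "G", _ring(GATE_X, GATE_RADIUS))
    gate_atoms = np.arange(7, 13)
    s = _append_atoms(s, "CAP", 4, "E", _disc(CORRIDOR_END))

    lig_idx = s.select(resname="LIG")
    rec_idx = s.select(resname="REC")
    fixed = np.setdiff1d(np.arange(s.n_atoms), lig_idx)
    coord = CoordinateSpec(group1=rec_idx, group2=lig_idx, mode="center")
    restraints = [(int(i), (0.0, 0.0, 0.0), (0.0, 2.0, 2.0)) for i in lig_idx]
    return ToyFixture(
        structure=s, coordinate=coord, fixed_atoms=fixed, seed=seed,
        gate_atoms=gate_atoms, restraints=restraints,
        corridor_end=CORRIDOR_END,
        phantom_atoms=None if gate else gate_atoms,
        gate_x=GATE_X if gate else None,
    )


def add_confinement_wall(fixture: ToyFixture, wall_position: float = 18.0) -> ToyFixture:
    """Add a purely repulsive disc truncating the extended region.

    The wall must sit beyond the bound basin with enough clearance that
    it exerts zero force there (its r⁻¹² reach is ~4 Å); positions that
    would overlap the bound complex are rejected.
    """
    min_pos = fixture.bound_basin + 4.0 + 4.0   # ligand extent + repulsion reach
    if wall_position < min_pos:
        raise ValueError(
            f"wall at {wall_position} Å would overlap the bound basin "
            f"(minimum allowed {min_pos} Å)")
    s = _append_atoms(fixture.structure.copy(), "WAL",
                      int(fixture.structure.resid.max()) + 1, "W",
                      _disc(wall_position))
    n_old = fixture.structure.n_atoms
    wall_atoms = np.arange(n_old, s.n_atoms)
    lig_idx = s.select(resname="LIG")
    fixed = np.setdiff1d(np.arange(s.n_atoms), lig_idx)
    return ToyFixture(
        structure=s,
        coordinate=CoordinateSpec(group1=s.select(resname="REC"),
                                  group2=lig_idx, mode="center"),
        fixed_atoms=fixed,
        seed=fixture.seed,
        wall_atoms=wall_atoms,
        gate_atoms=fixture.gate_atoms,
        restraints=fixture.restraints,
        phantom_atoms=fixture.phantom_atoms,
        bound_basin=fixture.bound_basin,
        extended_basin=min(fixture.extended_basin, wall_position - 4.0),
        corridor_end=fixture.corridor_end,
        wall_position=wall_position,
        gate_x=fixture.gate_x,
    )


# ------------------------------------------------------------ 1D sampling

def sample_biased_1d(
    potential: AnalyticPotential,
    window_center: float,
    window_k: float,
    n_samples: int,
    temperature: float = 1.0,
    seed: int = 0,
    n_walkers: int = 64,
    burn_in: int | None = None,
    thin: int | None = None,
) -> np.ndarray:
    """Overdamped Brownian samples of exp(-[F(x)+½k(x-c)²]/k_BT).

    Euler-Maruyama dynamics (γ = 1, so D = k_BT) over a population of
    independent walkers initialised from the exact biased density (a 1D
    inverse-CDF draw — analytic potentials make the target computable),
    so the chain starts in its stationary state and the dynamics only has
    to preserve it.  The time step keeps the drift below ~0.1 k_BT of
    energy per step over the thermally accessible region, and the default
    thinning interval is about half the local relaxation time.  Walkers
    reflect at the domain bounds.  Deterministic under a fixed seed.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if window_k < 0:
        raise ValueError("window spring constant must be >= 0")
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    rng = np.random.default_rng(seed)
    lo, hi = potential.bounds

    def biased_F(x):
        F = potential(x)
        if window_k > 0:
            F = F + 0.5 * window_k * (x - window_center) ** 2
        return F

    def force(x):
        f = -potential.grad(x)
        if window_k > 0:
            f = f - window_k * (x - window_center)
        return f

    grid = np.linspace(lo, hi, 2048)
    Fb = biased_F(grid)
    accessible = Fb < Fb.min() + 12.0 * temperature
    gmax = np.max(np.abs(force(grid[accessible]))) + 1e-9
    dt = min(0.1 * temperature / gmax ** 2, 0.05)

    # local stiffness sets the relaxation time 1/κ (overdamped, γ=1)
    d2 = np.gradient(np.gradient(Fb, grid), grid)
    kappa = max(float(np.median(np.abs(d2[accessible]))), window_k, 0.2)
    if thin is None:
        thin = max(1, int(np.ceil(0.5 / (kappa * dt))))
    if burn_in is None:
        burn_in = max(200, int(np.ceil(5.0 / (kappa * dt))))

    # stationary start: inverse-CDF draw from the biased Boltzmann density
    w = np.exp(-(Fb - Fb.min()) / temperature)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    x = np.interp(rng.random(n_walkers), cdf, grid)

    n_per = int(np.ceil(n_samples / n_walkers))
    out = np.empty((n_per, n_walkers))
    sigma = np.sqrt(2.0 * temperature * dt)
    n_steps = burn_in + n_per * thin
    isave = 0
    for step in range(n_steps):
        x = x + dt * force(x) + sigma * rng.normal(size=n_walkers)
        # reflect at the domain bounds
        x = np.where(x < lo, 2 * lo - x, x)
        x = np.where(x > hi, 2 * hi - x, x)
        if step >= burn_in and (step - burn_in) % thin == 0 and isave < n_per:
            out[isave] = x
            isave += 1
    return out.reshape(-1)[:n_samples]
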