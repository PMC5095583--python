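"""Langevin dynamics with umbrella restraints on a distance coordinate.

The integrator is BAOAB splitting with unit masses: it reduces to velocity
Verlet at zero friction and samples the canonical distribution at the set
temperature otherwise.  The default friction is high, putting the dynamics
in the overdamped regime assumed by the diffusive rate picture downstream.

Umbrella restraints act on either an atom-atom distance or the distance
between the geometric centres of two atom groups; the restraint force is
distributed over the group atoms by the chain rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .forcefield import ForceFieldTerms, energy_and_forces


@dataclass
class CoordinateSpec:
    """A distance reaction coordinate between two atom selections."""

    group1: np.ndarray
    group2: np.ndarray
    mode: str = "center"   # "center": group-centre distance; "atom": single atoms

    def __post_init__(self):
        self.group1 = np.atleast_1d(np.asarray(self.group1, dtype=int))
        self.group2 = np.atleast_1d(np.asarray(self.group2, dtype=int))
        if len(self.group1) == 0 or len(self.group2) == 0:
            raise ValueError("coordinate groups must be non-empty")
        if set(self.group1.tolist()) & set(self.group2.tolist()):
            raise ValueError("coordinate groups must be disjoint")
        if self.mode not in ("center", "atom"):
            raise ValueError(f"unknown coordinate mode {self.mode!r}")
        if self.mode == "atom" and (len(self.group1) != 1 or len(self.group2) != 1):
            raise ValueError("atom mode requires single-atom groups")

    def value(self, coords: np.ndarray) -> float:
        c1 = coords[self.group1].mean(axis=0)
        c2 = coords[self.group2].mean(axis=0)
        return float(np.linalg.norm(c1 - c2))

    def value_and_gradient(self, coords: np.ndarray):
        """Distance and its gradient w.r.t. the member atoms.

        Returns ``(d, unit)`` where ``unit`` is the normalised centre
        separation; the gradient on each atom of group1 is ``unit/n1`` and
        on each atom of group2 ``-unit/n2``.
        """
        c1 = coords[self.group1].mean(axis=0)
        c2 = coords[self.group2].mean(axis=0)
        diff = c1 - c2
        d = float(np.linalg.norm(diff))
        unit = diff / d if d > 1e-12 else np.zeros(3)
        return d, unit


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias ½k(ρ-c)² and its coordinate samples."""

    center: float
    spring_k: float
    samples: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")
        n_steps = self.metadata.get("n_steps")
        stride = self.metadata.get("stride")
        if n_steps is not None and stride is not None and n_steps % stride:
            raise ValueError("recorded stride must divide n_steps")


@dataclass
class Trajectory:
    """Result of a Langevin run."""

    final_coords: np.ndarray
    coord_samples: np.ndarray | None
    frames: np.ndarray | None
    energies: np.ndarray            # potential (incl. bias)
    kinetic: np.ndarray
    metadata: dict


def run_langevin(
    ff: ForceFieldTerms,
    coords0: np.ndarray,
    temperature: float = 1.0,
    friction: float = 5.0,
    dt: float = 0.005,
    n_steps: int = 10000,
    seed: int = 0,
    umbrella: tuple[float, float] | None = None,
    coord_spec: CoordinateSpec | None = None,
    stride: int = 10,
    fixed: np.ndarray | None = None,
    save_frames: bool = False,
    energy_cap: float = 1e8,
) -> Trajectory:
    """Integrate Langevin dynamics under the forcefield (+ optional umbrella).

    ``umbrella`` is ``(center, k)`` acting on ``coord_spec``.  Atoms listed
    in ``fixed`` are frozen.  Identical seeds give identical outputs.
    Raises ``RuntimeError`` with a diagnostic if the energy diverges.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if len(ff.bonds):
        omega_max = np.sqrt(ff.params.k_bond)  # unit masses
        if dt * omega_max > 0.25:
            raise ValueError(
                f"dt={dt} exceeds the stability bound {0.25 / omega_max:.4g} "
                f"for bond stiffness {ff.params.k_bond}")
    if umbrella is not None and coord_spec is None:
        raise ValueError("umbrella requires a coordinate spec")

    rng = np.random.default_rng(seed)
    x = np.array(coords0, dtype=float).reshape(ff.n_atoms, 3)
    v = rng.normal(0.0, np.sqrt(temperature), size=x.shape)
    mobile = np.ones(ff.n_atoms, dtype=bool)
    if fixed is not None and len(fixed):
        mobile[np.asarray(fixed, dtype=int)] = False
    v[~mobile] = 0.0

    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(temperature * (1.0 - c1 ** 2))

    def total_force(coords):
        br, F = energy_and_forces(coords, ff)
        if umbrella is not None:
            center, k = umbrella
            d, unit = coord_spec.value_and_gradient(coords)
            pre = -k * (d - center)
            F[coord_spec.group1] += pre * unit / len(coord_spec.group1)
            F[coord_spec.group2] -= pre * unit / len(coord_spec.group2)
            bias = 0.5 * k * (d - center) ** 2
        else:
            bias = 0.0
        return br.total + bias, F

    V, F = total_force(x)
    n_saved = n_steps // stride
    coord_samples = np.empty(n_saved) if coord_spec is not None else None
    frames = np.empty((n_saved, ff.n_atoms, 3)) if save_frames else None
    energies = np.empty(n_saved)
    kinetic = np.empty(n_saved)
    isave = 0

    for step in range(1, n_steps + 1):
        v[mobile] += 0.5 * dt * F[mobile]
        x[mobile] += 0.5 * dt * v[mobile]
        noise = rng.normal(size=x.shape)   # drawn every step for determinism
        if friction > 0:
            v[mobile] = c1 * v[mobile] + c2 * noise[mobile]
        x[mobile] += 0.5 * dt * v[mobile]
        V, F = total_force(x)
        v[mobile] += 0.5 * dt * F[mobile]
        if step % stride == 0:
            if not np.isfinite(V) or abs(V) > energy_cap:
                raise RuntimeError(
                    f"energy diverged at step {step}: V={V:.3g} "
                    f"(dt={dt}, friction={friction}); reduce dt or check the model")
            energies[isave] = V
            kinetic[isave] = 0.5 * np.sum(v[mobile] ** 2)
            if coord_samples is not None:
                coord_samples[isave] = coord_spec.value(x)
            if frames is not None:
                frames[isave] = x
            isave += 1

    meta = {
        "temperature": temperature, "friction": friction, "dt": dt,
        "n_steps": n_steps, "stride": stride, "seed": seed,
        "umbrella": umbrella,
    }
    return Trajectory(final_coords=x, coord_samples=coord_samples,
                      frames=frames, energies=energies, kinetic=kinetic,
                      metadata=meta)


def run_umbrella_series(
    ff: ForceFieldTerms,
    coords0: np.ndarray,
    coord_spec: CoordinateSpec,
    centers,
    spring_k: float,
    n_steps: int = 5000,
    equil_steps: int = 1000,
    temperature: float = 1.0,
    friction: float = 5.0,
    dt: float = 0.005,
    seed: int = 0,
    stride: int = 10,
    fixed: np.ndarray | None = None,
    reverse: bool = False,
) -> list[UmbrellaWindow]:
    """One Langevin window per umbrella centre, chained sequentially.

    Each window starts from the previous window's final configuration
    (a forward sweep over sorted centres, or the reverse sweep with
    ``reverse=True``), equilibrates for ``equil_steps`` and then records
    the coordinate for ``n_steps``.  Adjacent-histogram overlap is checked
    post hoc and gaps are reported as warnings.
    """
    centers = np.sort(np.asarray(centers, dtype=float))
    order = centers[::-1] if reverse else centers
    x = np.array(coords0, dtype=float)
    windows: list[UmbrellaWindow] = []
    for wi, c in enumerate(order):
        wseed = int(seed) + 1000 * wi
        eq = run_langevin(ff, x, temperature, friction, dt, equil_steps,
                          seed=wseed, umbrella=(c, spring_k),
                          coord_spec=coord_spec, stride=max(equil_steps, 1),
                          fixed=fixed)
        tr = run_langevin(ff, eq.final_coords, temperature, friction, dt,
                          n_steps, seed=wseed + 1, umbrella=(c, spring_k),
                          coord_spec=coord_spec, stride=stride, fixed=fixed)
        x = tr.final_coords
        meta = dict(tr.metadata)
        meta.update({"window_index": wi, "equil_steps": equil_steps})
        windows.append(UmbrellaWindow(center=float(c), spring_k=float(spring_k),
                                      samples=tr.coord_samples, metadata=meta))
    windows.sort(key=lambda w: w.center)
    validate_overlap(windows)
    return windows


def validate_overlap(windows: list[UmbrellaWindow], min_overlap: float = 0.0) -> list:
    """Warn about adjacent windows whose sampled ranges do not overlap."""
    gaps = []
    for a, b in zip(windows, windows[1:]):
        hi_a = np.max(a.samples)
        lo_b = np.min(b.samples)
        if hi_a - lo_b < min_overlap:
            gaps.append((a.center, b.center))
            warnings.warn(
                f"umbrella histogram gap between centers {a.center:.3g} and "
                f"{b.center:.3g}: [{hi_a:.3g}, {lo_b:.3g}] unsampled",
                stacklevel=2)
    return gaps


def write_window_tsv(window: UmbrellaWindow, path) -> None:
    """Window samples as TSV (step, coordinate), metadata in comment lines."""
    stride = window.metadata.get("stride", 1)
    with open(path, "w") as fh:
        fh.write(f"# center\t{window.center}\n# spring_k\t{window.spring_k}\n")
        for key in ("temperature", "dt", "seed", "n_steps", "stride"):
            if key in window.metadata:
                fh.write(f"# {key}\t{window.metadata[key]}\n")
        fh.write("step\tcoordinate\n")
        for n, s in enumerate(window.samples):
            fh.write(f"{(n + 1) * stride}\t{s:.8g}\n")


def read_window_tsv(path) -> UmbrellaWindow:
    meta: dict = {}
    samples = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("\t")
                meta[key] = float(val) if "." in val or "e" in val else int(float(val))
            elif not line.startswith("step"):
                samples.append(float(line.split("\t")[1]))
    center = meta.pop("center")
    spring_k = meta.pop("spring_k")
    return UmbrellaWindow(center=center, spring_k=spring_k,
                          samples=np.array(samples), metadata=meta)
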