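"""Iterative fluctuation matching of boundary position restraints.

When a large assembly is truncated to a corridor, boundary atoms lose
interactions; harmonic position restraints stand in for them.  Their
strengths are calibrated so the restrained atoms' root-mean-square
fluctuations (RMSF) match prescribed targets: after a short sampling run,
each spring constant is rescaled by (observed RMSF / target RMSF)², which
is a fixed point exactly when the fluctuations match (for an isolated
harmonic atom, RMSF² = 3 k_BT / k).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .forcefield import ForceFieldTerms
from .sampler import run_langevin


@dataclass
class FluctMatchResult:
    strengths: np.ndarray       # per boundary atom, isotropic k
    observed_rmsf: np.ndarray
    target_rmsf: np.ndarray
    correlation: float          # Pearson r of observed vs target
    converged: bool
    n_iters: int


def observed_rmsf(frames: np.ndarray, atoms: np.ndarray) -> np.ndarray:
    """Per-atom RMSF over trajectory frames (no alignment; restrained atoms)."""
    sub = frames[:, atoms, :]
    mean = sub.mean(axis=0)
    return np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))


def fluctuation_match_restraints(
    ff: ForceFieldTerms,
    coords0: np.ndarray,
    boundary_atoms,
    target_rmsf,
    n_iters: int = 10,
    seed: int = 0,
    n_steps: int = 4000,
    temperature: float = 1.0,
    friction: float = 2.0,
    dt: float = 0.01,
    rtol: float = 0.05,
) -> tuple[ForceFieldTerms, FluctMatchResult]:
    """Calibrate boundary restraint strengths against target RMSF values.

    Returns the forcefield with updated restraints and a result record.
    If the per-atom RMSF has not matched within ``rtol`` after ``n_iters``
    rounds, the best-so-far strengths are returned with ``converged=False``
    and a warning.
    """
    boundary_atoms = np.asarray(boundary_atoms, dtype=int)
    target = np.asarray(target_rmsf, dtype=float)
    if np.any(target <= 0):
        raise ValueError("target RMSF must be > 0 for every atom")
    if np.any(boundary_atoms >= ff.n_atoms):
        raise ValueError("boundary atoms outside the structure")

    coords0 = np.asarray(coords0, dtype=float)
    # seed restraints from equipartition if none are present for these atoms
    k = np.full(len(boundary_atoms), np.nan)
    existing = {int(a): i for i, a in enumerate(ff.restraint_atoms)}
    for n, a in enumerate(boundary_atoms):
        if int(a) in existing:
            k[n] = ff.restraint_k[existing[int(a)]].mean()
        else:
            k[n] = 3.0 * temperature / target[n] ** 2
    centers = coords0[boundary_atoms]

    best = None
    converged = False
    it = 0
    for it in range(1, n_iters + 1):
        trial = ff.with_restraints(
            boundary_atoms, centers, np.repeat(k[:, None], 3, axis=1))
        traj = run_langevin(trial, coords0, temperature=temperature,
                            friction=friction, dt=dt, n_steps=n_steps,
                            seed=seed + it, stride=5, save_frames=True)
        obs = observed_rmsf(traj.frames, boundary_atoms)
        err = np.max(np.abs(obs - target) / target)
        if best is None or err < best[0]:
            best = (err, k.copy(), obs.copy())
        if err < rtol:
            converged = True
            break
        k = k * (obs / target) ** 2

    err, k_best, obs_best = best
    if not converged:
        import warnings
        warnings.warn(f"fluctuation matching not converged after {it} rounds "
                      f"(max relative RMSF error {err:.2g}); returning best so far",
                      stacklevel=2)
    if len(target) > 1 and np.std(target) > 0 and np.std(obs_best) > 0:
        corr = float(np.corrcoef(obs_best, target)[0, 1])
    else:
        corr = 1.0 if err < rtol else 0.0
    final = ff.with_restraints(boundary_atoms, centers,
                               np.repeat(k_best[:, None], 3, axis=1))
    return final, FluctMatchResult(
        strengths=k_best, observed_rmsf=obs_best, target_rmsf=target,
        correlation=corr, converged=converged, n_iters=it)
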