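"""Diffusive rates from 1D free-energy profiles, and electrostatic helpers.

Transition rates are the inverse mean first-passage time of 1D diffusion
on the profile F(ρ) with a position-independent diffusion coefficient D:

    τ = (1/D) ∫_a^b dρ e^{F(ρ)/k_BT} ∫_r^ρ dρ' e^{-F(ρ')/k_BT}

with a reflecting boundary r behind the starting basin and an absorbing
boundary b at the destination.  On a flat profile of length L this reduces
to τ = L²/2D.  The Kramers high-barrier approximation is provided for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .wham import FreeEnergyProfile


@dataclass
class RateConfig:
    """Boundaries and diffusion coefficient for the MFPT integral."""

    D: float = 1.0                    # Å²/time, position-independent
    reflecting: float | None = None   # defaults to the starting basin minimum
    absorbing: float | None = None    # defaults to the destination basin minimum
    temperature: float = 1.0          # k_BT in reduced units

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("diffusion coefficient must be > 0")


@dataclass
class RateEstimate:
    rate: float
    mfpt: float
    barrier: float          # ΔF‡ in k_BT from the starting basin
    start_basin: float
    end_basin: float
    barrier_pos: float | None

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.barrier < -1e-9:
            raise ValueError("barrier must be >= 0")


def locate_extrema(profile: FreeEnergyProfile, prominence: float = 0.5):
    """(basin positions, barrier positions) from profile extrema.

    A minimum-prominence filter (default 0.5 k_BT) ignores noise wiggles.
    """
    F = profile.F
    minima, _ = find_peaks(-F, prominence=prominence)
    maxima, _ = find_peaks(F, prominence=prominence)
    # end bins can be genuine basins but are never found by find_peaks
    if len(minima) == 0 or F[0] < F.min() + 1e-9:
        minima = np.unique(np.append(minima, 0))
    if F[-1] < F.min() + 1e-9:
        minima = np.unique(np.append(minima, len(F) - 1))
    return profile.centers[minima], profile.centers[maxima]


def mfpt_rate(
    profile: FreeEnergyProfile,
    config: RateConfig,
    direction: str = "forward",
    n_grid: int = 4001,
    _check_convergence: bool = True,
) -> RateEstimate:
    """Rate = 1/MFPT for diffusion from one basin of the profile to the other.

    ``direction='forward'`` runs from the lower-ρ basin to the higher-ρ
    one, ``'reverse'`` the other way.  The profile is cubic-interpolated
    onto a fine grid; convergence is verified by grid doubling.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    basins, barriers = locate_extrema(profile)
    if len(basins) == 0:
        raise ValueError("no basin found in profile")
    lo_basin, hi_basin = float(basins[0]), float(basins[-1])
    if direction == "forward":
        start, end = lo_basin, hi_basin
    else:
        start, end = hi_basin, lo_basin
    reflect = config.reflecting if config.reflecting is not None else start
    absorb = config.absorbing if config.absorbing is not None else end
    dom_lo, dom_hi = profile.centers[0], profile.centers[-1]
    for b in (reflect, absorb):
        if not (dom_lo - 1e-9 <= b <= dom_hi + 1e-9):
            raise ValueError(f"boundary {b} outside profile domain [{dom_lo}, {dom_hi}]")

    spline = CubicSpline(profile.centers, profile.F)
    beta = 1.0 / config.temperature

    def tau_on_grid(n):
        # integrate from the reflecting to the absorbing boundary
        xs = np.linspace(reflect, absorb, n)
        F = spline(xs)
        F = F - F.min()                     # stabilise the exponentials
        inner = cumulative_trapezoid(np.exp(-beta * F), xs, initial=0.0)
        outer = np.exp(beta * F) * inner
        tau = np.trapezoid(outer, xs) / config.D
        return abs(tau)

    tau = tau_on_grid(n_grid)
    if _check_convergence:
        tau2 = tau_on_grid(2 * n_grid - 1)
        if not np.isclose(tau, tau2, rtol=5e-3):
            tau = tau2
    between = barriers[(barriers > min(start, end)) & (barriers < max(start, end))]
    barrier_pos = float(between[0]) if len(between) else None
    dF = profile.barrier_from(start, end)
    return RateEstimate(rate=1.0 / tau, mfpt=tau, barrier=max(dF, 0.0),
                        start_basin=start, end_basin=end, barrier_pos=barrier_pos)


def kramers_rate(profile: FreeEnergyProfile, config: RateConfig,
                 direction: str = "forward") -> float:
    """High-barrier approximation k = (D β √(F''_min |F''_max|) / 2π) e^{-βΔF‡}."""
    est = mfpt_rate(profile, config, direction, _check_convergence=False)
    if est.barrier_pos is None:
        raise ValueError("no barrier between basins")
    spline = CubicSpline(profile.centers, profile.F)
    d2 = spline.derivative(2)
    curv_min = float(d2(est.start_basin))
    curv_max = float(d2(est.barrier_pos))
    beta = 1.0 / config.temperature
    return (config.D * beta * np.sqrt(abs(curv_min) * abs(curv_max)) / (2 * np.pi)
            * np.exp(-beta * est.barrier))


def acceleration_factor(
    profile_without: FreeEnergyProfile,
    profile_with: FreeEnergyProfile,
    config: RateConfig,
    direction: str = "forward",
) -> float:
    """Fold change of the MFPT rate when the perturbation is present.

    Ratio = rate(with) / rate(without); the two profiles must share the
    direction and (optionally configured) boundaries.
    """
    r_with = mfpt_rate(profile_with, config, direction)
    r_without = mfpt_rate(profile_without, config, direction)
    return r_with.rate / r_without.rate


# ------------------------------------------------------------ helpers

def debye_length(conc_molar: float, temperature_K: float = 298.15,
                 dielectric: float = 80.0) -> float:
    """Debye screening length κ⁻¹ in nm for a 1:1 monovalent salt.

    λ_D = (8π l_B N_A I)^{-1/2} with l_B the Bjerrum length.
    """
    if conc_molar <= 0:
        raise ValueError("concentration must be > 0")
    e = constants.elementary_charge
    lb_nm = e ** 2 / (4 * np.pi * constants.epsilon_0 * dielectric
                      * constants.Boltzmann * temperature_K) * 1e9
    number_density = conc_molar * constants.Avogadro / 1e24  # per nm³
    return 1.0 / np.sqrt(8 * np.pi * lb_nm * number_density)


def kBT_to_kcal(n_kBT: float, temperature_K: float = 300.0) -> float:
    """Convert an energy in k_BT units to kcal/mol at the given temperature."""
    joule_per_mol = n_kBT * constants.Boltzmann * temperature_K * constants.Avogadro
    return joule_per_mol / 4184.0
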