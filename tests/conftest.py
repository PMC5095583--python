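"""Shared fixtures: toy structures, forcefields, and (session-scoped)
umbrella-sampling profiles of the gate/wall steric experiments."""

import warnings

import numpy as np
import pytest

import proofscape as ps
from proofscape import rates, wham


@pytest.fixture(scope="session")
def hairpin():
    return ps.make_toy_hairpin(10, seed=3)


@pytest.fixture(scope="session")
def hairpin_ff(hairpin):
    return ps.build_forcefield(hairpin)


@pytest.fixture(scope="session")
def peptide():
    return ps.make_toy_peptide(8, seed=5)


def _profile_for(fixture, seed, n_windows=20, spring_k=15.0,
                 n_steps=2500, equil_steps=1200):
    ff = fixture.build_forcefield()
    centers = fixture.umbrella_centers(n_windows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # tiny histogram-edge gap warnings
        windows = ps.run_umbrella_series(
            ff, fixture.structure.coords, fixture.coordinate, centers,
            spring_k, n_steps=n_steps, equil_steps=equil_steps,
            temperature=1.0, friction=2.0, dt=0.005, seed=seed, stride=5,
            fixed=fixture.fixed_atoms)
        return wham.wham_1d(windows)


@pytest.fixture(scope="session")
def steric_profiles():
    """WHAM profiles of the gated system, its gate-deleted control, and the
    wall-confined variant, plus accommodation (extended → bound) rates."""
    gated = ps.make_gated_system(1)
    nogate = ps.make_gated_system(1, gate=False)
    walled = ps.add_confinement_wall(gated, 18.0)
    profiles = {
        "gated": _profile_for(gated, 11),
        "no_gate": _profile_for(nogate, 12),
        "walled": _profile_for(walled, 13),
    }
    rcfg = rates.RateConfig(D=1.0)
    estimates = {name: rates.mfpt_rate(p, rcfg, direction="reverse")
                 for name, p in profiles.items()}
    return {"fixtures": {"gated": gated, "no_gate": nogate, "walled": walled},
            "profiles": profiles, "rates": estimates, "config": rcfg}
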