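"""Proofreading factor and efficiency versus the factor dissociation rate.

Scans the six-state kinetic model in both discrimination scenarios:
induced fit (near-cognate forward elbow rates 50-fold slower) and EA
destabilisation (near-cognate reverse elbow rates e^8 faster, one curve
per relative 3'-CCA accommodation rate).  Cross-checks one grid point
against the Gillespie stochastic simulator.  Writes both scan tables.
"""

from pathlib import Path

import numpy as np

from proofscape.kinetics import (ScenarioSpec, absorption_probabilities,
                                 build_scheme, gillespie, scan)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 5


def main():
    RESULTS.mkdir(exist_ok=True)
    grid = np.logspace(-4, 4, 81)

    induced = scan(ScenarioSpec(mode="induced_fit", f_nc=50.0,
                                k_minusTu_grid=grid))
    induced.to_csv(RESULTS / "pf_induced_fit.tsv", sep="\t", index=False)

    ea = scan(ScenarioSpec(mode="EA_destabilized", ddF_nc=8.0,
                           cca_ratios=(0.1, 1.0, 10.0), k_minusTu_grid=grid))
    ea.to_csv(RESULTS / "pf_ea_destabilized.tsv", sep="\t", index=False)

    # stochastic cross-check at one representative grid point
    scen = ScenarioSpec(mode="induced_fit", f_nc=50.0)
    scheme = build_scheme(scen.cognate_rates(1.0))
    exact = absorption_probabilities(scheme)["A"]
    sim = gillespie(scheme, n_traj=100000, seed=SEED)

    print("Induced fit (f_NC = 50, k_reject/k_acc = 10):")
    print(f"  P_f at k_-Tu -> 0 : {induced['P_f'].iloc[0]:.4f}")
    print(f"  max P_f over scan : {induced['P_f'].max():.2f} (bound: 50)")
    print(f"  efficiency E>0.9 up to k_-Tu = "
          f"{induced.loc[induced['efficient'], 'k_minusTu'].max():.3g}")
    print("EA destabilised (ddF_NC = 8 kBT), max P_f per k_CCA:")
    for cca, block in ea.groupby("k_CCA"):
        print(f"  k_CCA = {cca:>4}: {block['P_f'].max():.1f}")
    print(f"Gillespie cross-check at k_-Tu = 1: "
          f"exact P(A) = {exact:.4f}, simulated {sim['A']:.4f} "
          f"± {sim['se_A']:.4f}")
    print("-> P_f rises monotonically with factor dissociation while the")
    print("   efficiency falls: dissociation must be slow enough to assist")
    print("   accommodation yet fast enough to permit rejection.")


if __name__ == "__main__":
    main()
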