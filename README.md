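# proofscape

From structure-based energy landscapes to kinetic proofreading of
aminoacyl-tRNA selection.

During each elongation cycle the ribosome must distinguish correct
(cognate) from incorrect (near-cognate) aa-tRNA, and it does so twice:
once during initial selection and once during accommodation — the
proofreading step — after the elongation factor EF-Tu has hydrolysed GTP.
Accommodation begins with the tRNA *elbow* swinging from the extended
A/T conformation into the A site (the elbow-accommodated, EA, state),
over a free-energy barrier created by a steric obstacle (a 23S rRNA
helix), before the 3′-CCA end reaches the peptidyl-transferase centre.
Because EF-Tu occludes extended tRNA conformations while it remains
bound, its mere steric presence destabilises the A/T state and can
accelerate elbow accommodation by orders of magnitude — which couples
the *timing of EF-Tu dissociation* to both the speed and the accuracy of
proofreading.

`proofscape` implements that whole chain of reasoning as a tested,
desk-scale pipeline on synthetic systems:

* **`forcefield`/ `topology`** — an all-atom structure-based (Gō-type)
  potential: harmonic bonded terms, `K[(1−cos Δφ)+½(1−cos 3Δφ)]`
  dihedrals, 6–12 native contacts from a 4 Å cutoff, r⁻¹² excluded
  volume, Debye–Hückel electrostatics (κ⁻¹ = 1.4 nm at 0.05 M salt),
  stacked-base (1/3) and interface (0.5) contact scaling, and the
  normalisation rules ε_BB/ε_SC = 2 (protein) or 1 (RNA),
  Σε_contacts/Σε_dihedrals = 2, Σε_contacts + Σε_dihedrals = N_atoms·ε.
* **`sampler`** — BAOAB Langevin dynamics with umbrella restraints on a
  distance coordinate; **`wham`** — the Weighted Histogram Analysis
  Method with block-bootstrap uncertainties.
* **`rates`** — diffusive rates from 1D profiles via the
  mean-first-passage-time integral
  τ = (1/D)∫dρ e^{F(ρ)/k_BT} ∫dρ′ e^{−F(ρ′)/k_BT}, plus Debye-length and
  k_BT→kcal/mol helpers.
* **`kinetics`** — the extended six-state proofreading model
  (A/T and EA states with and without EF-Tu, absorbing accommodated/
  rejected states), exact absorption probabilities, proofreading factor
  P_f = P(A|cognate)/P(A|near-cognate), efficiency E = P(A|cognate),
  scenario scans over the EF-Tu dissociation rate k₋Tu, and a Gillespie
  simulator as an independent stochastic check.
* **`synthetic`** — every input generated in-process: analytic double
  wells with exact barrier control, toy RNA/peptide polymers on which all
  forcefield rules fire, and a gated-corridor fixture with a steric ring
  (the rRNA-helix analogue) and a confining wall (the EF-Tu analogue).
* **`pipeline` / `cli`** — an end-to-end demo
  (fixtures → forcefield → umbrella sampling → WHAM → rates → kinetics)
  and the `proofscape` command with `build-ff`, `sample`, `wham`, `rate`,
  `proofread`, `demo` subcommands.

The numbered scripts under `analysis/` run the study: landscape-recovery
validation, forcefield bookkeeping, the gate/wall steric experiments,
acceleration versus basin destabilisation, and the proofreading scans.
Each writes its tables under `results/`.

## Worked example

```python
import numpy as np
import proofscape as ps

# landscape -> rate: destabilising the starting basin of a 12 kBT
# accommodation profile by 8 kBT (the steric effect of bound EF-Tu)
pot = ps.make_double_well(0.0, 20.0, barrier_height_fwd=12.0)
c = np.linspace(*pot.bounds, 2401)
F = pot(c) - pot(c).min()
from proofscape.synthetic import destabilize_segment
from proofscape.wham import FreeEnergyProfile
from proofscape.rates import RateConfig, mfpt_rate

cfg = RateConfig(D=1.0, reflecting=0.0, absorbing=20.0)
k_ref = mfpt_rate(FreeEnergyProfile(centers=c, F=F), cfg).rate
F8 = destabilize_segment(c, F, 8.0, split=5.0)
k_tu = mfpt_rate(FreeEnergyProfile(centers=c, F=F8 - F8.min()), cfg).rate
print(f"acceleration: {k_tu / k_ref:.0f}-fold")   # acceleration: 1550-fold

# kinetics: proofreading factor vs EF-Tu dissociation rate (induced fit)
scen = ps.ScenarioSpec(mode="induced_fit", f_nc=50.0,
                       k_minusTu_grid=np.logspace(-4, 6, 101))
df = ps.scan(scen)
print(f"P_f at slow dissociation: {df['P_f'].iloc[0]:.4f}")  # 1.0000
print(f"max P_f over the scan:    {df['P_f'].max():.2f}")    # 47.67
```

The first number says that raising the extended basin by 8 k_BT — without
touching the barrier top or the accommodated basin — speeds accommodation
by ~1.5·10³ (the high-barrier limit is e⁸ ≈ 3·10³): a purely steric body
can accelerate a conformational transition a thousandfold.  The second
pair says the six-state model loses all discrimination when EF-Tu never
leaves (P_f → 1) and approaches, but cannot exceed, the 50-fold
forward-rate penalty as dissociation becomes fast — while the efficiency
falls, so dissociation timing trades accuracy against yield.

The sampled counterpart of the first result (`analysis/03`): deleting the
steric gate's interactions lowers the sampled accommodation barrier by
several k_BT, and adding the confining wall truncates the extended basin
and *increases* the accommodation rate, reproducing the sign of both
steric effects end to end from a forcefield rather than from an analytic
curve.

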