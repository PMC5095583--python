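# Methods

This note documents the models and numerical procedures behind
`proofscape`: a desk-scale pipeline that connects structure-based
(Gō-type) energy landscapes of aminoacyl-tRNA elbow accommodation to the
kinetics of ribosomal proofreading.  The pipeline is exercised on
synthetic toy systems; nothing here requires downloads or cluster
computing.

## 1. The structure-based potential

All heavy atoms are beads of unit mass.  The potential's global minimum
is a preassigned native structure: bond lengths, angles, improper and
planar dihedrals are harmonic about their native values, proper dihedrals
use

    V_dih = K [ (1 − cos(φ−φ₀)) + ½ (1 − cos 3(φ−φ₀)) ],

native contacts (non-bonded heavy-atom pairs within 4 Å of each other in
the native structure, different residues, not sharing a bonded term)
attract through a 6–12 well `ε[(σ/r)¹² − 2(σ/r)⁶]` with σ the native
separation, and every other inter-residue pair repels as
`ε_NC (r_NC/r)¹²` with `r_NC = 2.5 Å` (truncated and shifted to zero at
4 Å, so the native structure sits exactly at −Σε).  Units are reduced:
lengths in Å, energies in k_BT (temperature 1), friction and time in the
matching Langevin units.

Three normalisation rules fix the stabilising weights:

1. backbone dihedrals are `R_BB/SC` times stronger than side-chain
   dihedrals within each biopolymer class — 2 for protein, 1 for RNA;
2. total contact energy over total dihedral energy is `R_C/D = 2`;
3. total contact + dihedral energy equals `N_atoms·ε` with ε = 1 (the
   reduced energy unit), counting only atoms of stabilised molecules —
   purely steric bodies (gate, wall, end cap) are excluded from the
   budget, so adding an obstacle never re-scales the rest of the model.

Contacts between stacked RNA bases (base atoms of sequence-adjacent
residues) are scaled by 1/3; user-declared interface residue pairs are
scaled by 0.5 (the down-weighting applied to transiently formed
intermolecular contacts); declared exclusion lists remove contacts
entirely.  A structure with zero dihedrals puts the whole stabilising
budget into contacts (the minimal toys have no dihedrals); a structure
with zero contacts is rejected because rule 2 is then undefined.

Electrostatics is a Debye–Hückel term between charged atoms,

    V_ES = B(κ) · l_B · q_i q_j · exp(−κ r)/r      [k_BT],

with `B(κ) = 1`, the Bjerrum length l_B evaluated at the configured
temperature and dielectric (ε_r = 80 → l_B ≈ 7.0 Å at 298 K), and the
default screening length κ⁻¹ = 1.4 nm (0.05 M monovalent salt).  The
interaction is truncated at 4 κ⁻¹ and shifted to zero there.  Charges:
P atoms −1, crystallographic Mg²⁺ +2, Arg/Lys +1 and Asp/Glu −1 on a
single designated side-chain atom (CZ, NZ, CG, CD, falling back to the
outermost side-chain atom present in reduced toy residues), His and
everything else 0.  Which atom carries the protein charge is a modelling
choice; it is logged per residue.

Bonded topology comes from residue templates (toy RNA: P–C4′–O3′ backbone
with a three-atom base ring; toy peptide: N–CA–C(=O) with CB–CG side
chain; a three-bead ligand), with angles and proper dihedrals enumerated
from the bond graph.  Forces are analytic for every term and are verified
against central finite differences to 10⁻⁵ relative error.

### Boundary restraints and fluctuation matching

Truncating a large assembly to a corridor removes interactions from
boundary atoms; harmonic position restraints stand in for them.  Their
spring constants are calibrated by iterative fluctuation matching: after
a short Langevin run, each k is multiplied by (observed RMSF / target
RMSF)², whose fixed point is the matched spectrum (for an isolated atom,
RMSF² = 3 k_BT/k).  The toys converge in a few rounds; the result records
the observed-vs-target RMSF correlation.

## 2. Sampling and WHAM

Dynamics is BAOAB Langevin with unit masses; at zero friction it reduces
to velocity Verlet (energy drift < 10⁻⁴ over 10⁴ steps), at the default
friction (γ = 2/time, overdamped regime) it samples the canonical
ensemble.  Umbrella restraints act on an atom–atom or group-centre
distance; the group-centre force is distributed over member atoms by the
chain rule.  Windows are chained (each starts from the previous window's
final frame) in a forward sweep over sorted centres or the reverse sweep,
and adjacent-histogram overlap is validated after the fact.

WHAM iterates the standard self-consistency equations on binned window
histograms (Freedman–Diaconis bin count on the pooled samples unless
overridden) until the window offsets move by less than 10⁻⁷ k_BT.
Adjacent windows whose occupied bins are separated by more than two bin
widths make the offsets unidentifiable and raise an error naming the
windows; a gap of an empty bin or two is tolerated because the bias
Boltzmann factors still couple the windows.  Uncertainties come from a
block bootstrap (blocks of one statistical-inefficiency length, at least
10 samples) re-running WHAM per replica.  An independently coded route to
the same estimate — quasi-Newton maximisation of the binned WHAM
likelihood — is kept in the test suite and agrees with the fixed-point
iteration to 10⁻⁶ k_BT.

The 1D overdamped sampler used for analytic landscapes draws its initial
walker population from the exact biased Boltzmann density (computable in
1D by inverse CDF), chooses the Euler–Maruyama time step so the drift
moves less than 0.1 k_BT per step over the thermally accessible region
(12 k_BT above the minimum; the steep confining walls would otherwise
dictate an absurdly small step), and thins at about half the local
relaxation time.  Long-run histograms pass a Kolmogorov–Smirnov test
against the analytic density at α = 0.01 on 2·10⁵ samples.

## 3. Rates from profiles

Transition rates are inverse mean first-passage times for diffusion on
the profile with constant D:

    τ = (1/D) ∫_a^b dρ e^{F(ρ)} ∫_r^ρ dρ′ e^{−F(ρ′)},

reflecting boundary r behind the starting basin, absorbing boundary b at
the destination; on a flat profile this is exactly L²/2D.  Basins and the
barrier are profile extrema with a 0.5 k_BT prominence filter; the
integral is evaluated on a cubic-spline refinement of the WHAM grid and
checked by grid doubling.  The Kramers high-barrier approximation
`k = (Dβ√(κ_min|κ_max|)/2π)·e^{−βΔF‡}` is exposed for comparison; on the
spline landscapes its prefactor is only order-of-magnitude accurate
because the anchor construction leaves a curvature discontinuity at the
basin, and the tests treat it accordingly.  D is an input parameter
throughout (default 1 in reduced units); absolute rates are therefore
only meaningful relative to one another, which is all the analysis needs.

Two helpers back the printed physical-chemistry numbers: the Debye length
λ_D = (8π l_B N_A I)^{−1/2} (0.05 M, 298 K, ε_r 80 → 1.37 nm, printing as
1.4 nm) and the k_BT → kcal/mol conversion (10 k_BT at 300 K → 5.96 ≈ 6).

## 4. The synthetic study systems

**Analytic double wells** are cubic Hermite splines through
(basin, barrier) anchors with zero slope there, so the declared barrier
height and basin offset are exact, flanked by steep confining walls.
`destabilize_segment` raises the low-ρ side by δ k_BT through a smooth
tanh switch (width 1 Å) placed between the starting basin and the
barrier: the minimal model of "same landscape, starting basin
destabilised", used for the e^δ acceleration analyses.

**The toy hairpin / peptide** are two-strand ladders whose base (or
side-chain) pseudo-atoms reach across the strand gap, giving cross-strand
contacts, intra-strand stacking contacts, one P (charge −1) per RNA
residue, and both backbone and side-chain dihedrals — the smallest
structures on which every forcefield rule fires.  Coordinates carry a
±0.05 Å seeded jitter so no two fixtures are accidentally degenerate.

**The gated corridor** emulates the steric situation of elbow
accommodation.  A three-bead ligand is natively bound to a four-atom
receptor at the origin (the analogue of the elbow-accommodated state); to
reach an extended region it must pass a six-atom purely repulsive ring at
x = 12 Å (the analogue of the 23S rRNA helix that obstructs the incoming
elbow); a repulsive end cap closes the corridor at 26 Å and harmonic y/z
restraints (2 k_BT/Å²) keep the ligand near the axis.  The reaction
coordinate is the receptor-centre–ligand-centre distance.  "Virtual
deletion" of the gate removes the ring's nonbonded interactions while
keeping its atoms, so the two systems' energies coincide configuration by
configuration away from the ring.  The confining wall — the analogue of
the bound elongation factor occluding extended tRNA conformations — is a
repulsive disc placed at 18 Å by default; placements that would reach
into the bound complex (closer than the ligand extent plus the repulsion
range) are rejected.  Steric bodies never receive contacts or charges.

Umbrella centres for these systems are a uniform grid refined with extra
windows (0.4 Å spacing) around the gate, where the barrier makes adjacent
histograms hardest to overlap.  Default production sizes — 24 + 7 windows,
spring 15 k_BT/Å², 3 500 sampling + 1 500 equilibration steps per window,
dt 0.005 — resolve the barriers to a few tenths of k_BT in about half a
minute per system; the test suite runs scaled-down versions of the same
chain.  These fixtures reproduce the *signs* and rough magnitudes of the
steric effects (gate raises the accommodation barrier by several k_BT;
the wall truncates the extended basin and accelerates accommodation);
they make no attempt at tRNA or ribosome geometric realism, sequence
content, or absolute energetics, so quantitative agreement with
ribosome-scale simulations is out of reach by design.

## 5. The six-state proofreading model

After initial selection, an aa-tRNA starts in A/T⁺ᵀᵘ and is absorbed in
A (accommodated) or R (rejected), moving through EA (elbow-accommodated)
and factor-free states:

    A/T⁺ᵀᵘ ⇄ EA⁺ᵀᵘ  (k_acc⁺, k_rev⁺)       EA⁺ᵀᵘ → A  (k_CCA)
       ↓ k_-Tu        ↓ k_-Tu
    A/T⁻ᵀᵘ ⇄ EA⁻ᵀᵘ  (k_acc⁻, k_rev⁻)       EA⁻ᵀᵘ → A  (k_CCA)
       ↓ k_reject → R

Factor dissociation is irreversible (re-association is kinetically
equivalent to lowering k_-Tu); rejection requires the factor to have
left; 3′-CCA accommodation is irreversible.  k_CCA operates from both EA
states by default — the slow-dissociation limit P_f → 1 requires that
accommodation can complete while the factor is bound; a flag restricts it
to EA⁻ᵀᵘ for comparison (in that variant the k_-Tu → 0 limit traps the
system instead).  Absorption probabilities are an exact first-step linear
solve, verified on every call against the steady-state flux formulation
(unit source into A/T⁺ᵀᵘ) and, in the tests, against a Gillespie
simulator to three Monte-Carlo standard errors at 10⁵ trajectories.

The proofreading factor is P_f = P(A | cognate)/P(A | near-cognate) and
the efficiency E = P(A | cognate).  Two discrimination scenarios:
*induced fit* divides both forward elbow rates by f_NC = 50 for
near-cognate tRNA; *EA destabilisation* multiplies both reverse elbow
rates by e^{ΔΔF_NC} with ΔΔF_NC = 8 k_BT.  Default base rates are all 1
in relative units with k_reject = 10 (the rejection-to-forward ratio the
scans are shown at; only ratios matter — the model is invariant to a
common rescaling of all rates).  Scans cover k_-Tu from 10⁻⁴ to 10⁴
(10⁶ where a wider range is informative) times k_acc⁺ᵀᵘ; the E > 0.9
region is flagged on every curve.  Under induced fit P_f is capped by
f_NC (only forward rates discriminate) and approaches
f_NC·(k_reject+k_eff^NC)/(k_reject+k_eff^C) ≈ 47.7 at fast dissociation;
under EA destabilisation P_f grows as k_CCA shrinks because near-cognate
molecules revisit the rejectable A/T⁻ᵀᵘ state more often.

## 6. Numerical and design notes

* Determinism: every stochastic component (generators, Langevin,
  Gillespie, bootstrap) is seeded; identical seeds give bit-identical
  outputs, and the demo report carries the seeds plus a hash of its
  configuration.
* The Langevin step is validated against the bond stiffness
  (dt·√k_bond ≤ 0.25 raises); energy divergence aborts with a
  diagnostic rather than producing NaN samples.
* Degenerate inputs: empty structures, zero-contact structures,
  non-finite coordinates and parameters, negative rates, overlapping
  wall placements and empty scan grids are rejected with messages; WHAM
  warns (with the residual) when the iteration cap is hit.
* Problem sizes in the tests (window counts, steps, trajectory counts,
  walker counts, barrier heights for the brute-force first-passage
  oracle) are chosen so each check resolves its target quantity with
  comfortable margin at desk scale; the brute-force oracle runs at a
  5 k_BT barrier where its Monte-Carlo error is ~2 % of the mean
  first-passage time.
* Known limitations: 1D umbrella coordinates only (no 2D surfaces); no
  explicit solvent, hydrogens, or GPU engine; D is never estimated, only
  supplied; the toys do not attempt geometric realism, so only signs and
  scalings — not absolute barrier heights — transfer to the biological
  system; initial selection is not modelled, so total selectivity
  (initial selectivity × P_f) is outside the package's scope.
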