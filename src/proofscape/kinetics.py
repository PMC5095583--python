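"""Extended six-state kinetic model of aa-tRNA proofreading.

After passing initial selection, an aa-tRNA starts in the A/T conformation
with the elongation factor still bound (A/T⁺ᵀᵘ) and ends absorbed in one
of two states: fully accommodated (A) or rejected (R).  The transient
states are the A/T and elbow-accommodated (EA) conformations with (⁺ᵀᵘ)
and without (⁻ᵀᵘ) the factor:

    A/T⁺ᵀᵘ ⇄ EA⁺ᵀᵘ   (k_acc⁺, k_rev⁺)      EA⁺ᵀᵘ → A  (k_CCA)
      ↓ k_-Tu   ↓ k_-Tu
    A/T⁻ᵀᵘ ⇄ EA⁻ᵀᵘ   (k_acc⁻, k_rev⁻)      EA⁻ᵀᵘ → A  (k_CCA)
      ↓ k_reject → R

Factor dissociation is irreversible; rejection is only possible after the
factor has left; 3'-CCA accommodation (k_CCA) is irreversible.  The
proofreading factor P_f is the ratio of cognate to near-cognate absorption
probability at A, and the efficiency E is the cognate absorption
probability itself.  Near-cognate molecules are penalised either by
slowing both forward elbow rates ("induced fit", default 50-fold) or by
destabilising the EA ensemble, multiplying both reverse elbow rates by
exp(ΔΔF_NC) (default ΔΔF_NC = 8 k_BT).

Absorption probabilities come from an exact first-step linear solve and,
equivalently, a steady-state flux balance with a unit source in A/T⁺ᵀᵘ;
a Gillespie simulator provides an independent stochastic check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STATES = ("AT_plusTu", "EA_plusTu", "AT_minusTu", "EA_minusTu", "A", "R")
TRANSIENT = STATES[:4]
ABSORBING = STATES[4:]
START = "AT_plusTu"


@dataclass
class RateSet:
    """Elementary rates (time⁻¹; any common unit — only ratios matter)."""

    k_acc_plusTu: float = 1.0
    k_rev_plusTu: float = 1.0
    k_acc_minusTu: float = 1.0
    k_rev_minusTu: float = 1.0
    k_minusTu: float = 1.0
    k_CCA: float = 1.0
    k_reject: float = 10.0

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")

    def scaled(self, factor: float) -> "RateSet":
        return RateSet(**{k: v * factor for k, v in self.__dict__.items()})


@dataclass
class KineticScheme:
    """Labelled states, generator matrix, absorbing set {A, R}."""

    rates: RateSet
    Q: np.ndarray                      # 6x6 generator, rows sum to 0
    states: tuple = STATES
    start: str = START
    cca_while_tu_bound: bool = True

    @property
    def n_transitions(self) -> int:
        off = self.Q.copy()
        np.fill_diagonal(off, 0.0)
        return int(np.count_nonzero(off))


def build_scheme(rates: RateSet, cca_while_tu_bound: bool = True) -> KineticScheme:
    """Generator matrix with exactly the nine transitions of the model.

    ``cca_while_tu_bound=False`` drops the EA⁺ᵀᵘ → A step (a variant in
    which 3'-CCA accommodation requires prior factor dissociation; note
    the k_-Tu → 0 limit then sends every molecule nowhere rather than
    to A).
    """
    r = rates
    idx = {s: i for i, s in enumerate(STATES)}
    Q = np.zeros((6, 6))

    def add(a, b, k):
        Q[idx[a], idx[b]] += k

    add("AT_plusTu", "EA_plusTu", r.k_acc_plusTu)
    add("EA_plusTu", "AT_plusTu", r.k_rev_plusTu)
    add("AT_plusTu", "AT_minusTu", r.k_minusTu)
    add("EA_plusTu", "EA_minusTu", r.k_minusTu)
    if cca_while_tu_bound:
        add("EA_plusTu", "A", r.k_CCA)
    add("AT_minusTu", "EA_minusTu", r.k_acc_minusTu)
    add("EA_minusTu", "AT_minusTu", r.k_rev_minusTu)
    add("EA_minusTu", "A", r.k_CCA)
    add("AT_minusTu", "R", r.k_reject)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return KineticScheme(rates=rates, Q=Q, cca_while_tu_bound=cca_while_tu_bound)


def absorption_probabilities(scheme: KineticScheme) -> dict:
    """P(absorb at A) and P(absorb at R) from the start state.

    Solves the first-step equations B = (-Q_TT)⁻¹ Q_TA exactly, verifies
    the equivalent steady-state flux formulation (unit source into the
    start state), and asserts their agreement and P(A)+P(R)=1.
    """
    Q = scheme.Q
    nt = len(TRANSIENT)
    Qtt = Q[:nt, :nt]
    Qta = Q[:nt, nt:]
    start = TRANSIENT.index(scheme.start)
    try:
        B = np.linalg.solve(-Qtt, Qta)
    except np.linalg.LinAlgError as exc:
        raise ValueError("no absorption possible from the start state "
                         "(singular transient generator)") from exc
    pA, pR = float(B[start, 0]), float(B[start, 1])
    if not np.isfinite(pA) or pA < -1e-9:
        raise ValueError("no absorption possible from the start state")

    # steady-state flux check: π solves πᵀ Q_TT = -e_startᵀ
    pi = np.linalg.solve(Qtt.T, -np.eye(nt)[start])
    flux = pi @ Qta
    if not np.allclose(flux, [pA, pR], rtol=1e-9, atol=1e-12):
        raise AssertionError("first-step solve and steady-state flux disagree")
    if not np.isclose(pA + pR, 1.0, atol=1e-9):
        raise AssertionError("absorption probabilities do not sum to 1")
    return {"A": pA, "R": pR}


def gillespie(scheme: KineticScheme, n_traj: int = 100000, seed: int = 0,
              max_steps: int = 100000) -> dict:
    """Exact stochastic simulation to absorption; empirical fractions + SE.

    Trajectories exceeding ``max_steps`` are counted separately under
    ``"capped"`` (they are excluded from the fractions).
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    rng = np.random.default_rng(seed)
    Q = scheme.Q
    n = len(STATES)
    # embedded jump chain: probabilities out of each transient state
    jump = np.zeros((n, n))
    for i in range(len(TRANSIENT)):
        out = -Q[i, i]
        if out > 0:
            jump[i] = Q[i] / out
            jump[i, i] = 0.0
    cum = np.cumsum(jump, axis=1)

    state = np.full(n_traj, STATES.index(scheme.start))
    active = np.ones(n_traj, dtype=bool)
    steps = 0
    while np.any(active) and steps < max_steps:
        u = rng.random(np.count_nonzero(active))
        cur = state[active]
        nxt = (cum[cur] < u[:, None]).sum(axis=1)
        state[active] = nxt
        active = state < len(TRANSIENT)
        steps += 1
    n_capped = int(np.count_nonzero(active))
    done = ~active
    n_done = int(np.count_nonzero(done))
    fracs = {}
    for name in ABSORBING:
        k = int(np.count_nonzero(state[done] == STATES.index(name)))
        p = k / n_done if n_done else np.nan
        se = np.sqrt(p * (1 - p) / n_done) if n_done else np.nan
        fracs[name] = (p, se)
    return {"A": fracs["A"][0], "R": fracs["R"][0],
            "se_A": fracs["A"][1], "se_R": fracs["R"][1],
            "n_done": n_done, "capped": n_capped}


# ------------------------------------------------------------ scenarios

@dataclass
class ScenarioSpec:
    """Cognate vs near-cognate parameterisation and the k_-Tu scan grid.

    ``mode='induced_fit'``: near-cognate forward elbow rates are divided
    by ``f_nc`` (default 50).  ``mode='EA_destabilized'``: near-cognate
    reverse elbow rates are multiplied by exp(``ddF_nc``) (default 8 k_BT);
    forward rates are shared.  ``k_minusTu_grid`` is in units of the
    cognate k_acc⁺ᵀᵘ.
    """

    mode: str = "induced_fit"
    f_nc: float = 50.0
    ddF_nc: float = 8.0
    base: RateSet = field(default_factory=RateSet)
    k_minusTu_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-4, 4, 81))
    cca_ratios: tuple = (1.0,)        # k_CCA values for EA-destabilised curves
    cca_while_tu_bound: bool = True
    efficiency_threshold: float = 0.9

    def __post_init__(self):
        if self.mode not in ("induced_fit", "EA_destabilized"):
            raise ValueError(f"unknown scenario mode {self.mode!r}")
        if self.f_nc <= 0 or self.ddF_nc <= 0:
            raise ValueError("near-cognate modifiers must be > 0")
        self.k_minusTu_grid = np.asarray(self.k_minusTu_grid, dtype=float)

    def cognate_rates(self, k_minusTu: float, k_CCA: float | None = None) -> RateSet:
        return replace(self.base, k_minusTu=k_minusTu,
                       k_CCA=self.base.k_CCA if k_CCA is None else k_CCA)

    def near_cognate_rates(self, k_minusTu: float, k_CCA: float | None = None) -> RateSet:
        r = self.cognate_rates(k_minusTu, k_CCA)
        if self.mode == "induced_fit":
            return replace(r, k_acc_plusTu=r.k_acc_plusTu / self.f_nc,
                           k_acc_minusTu=r.k_acc_minusTu / self.f_nc)
        boost = np.exp(self.ddF_nc)
        return replace(r, k_rev_plusTu=r.k_rev_plusTu * boost,
                       k_rev_minusTu=r.k_rev_minusTu * boost)


def _p_accept(rates: RateSet, cca_while_tu_bound: bool) -> float:
    scheme = build_scheme(rates, cca_while_tu_bound)
    return absorption_probabilities(scheme)["A"]


def proofreading_factor(scenario: ScenarioSpec, k_minusTu: float,
                        k_CCA: float | None = None) -> float:
    """P_f = P(A | cognate) / P(A | near-cognate); +inf when the
    near-cognate acceptance probability is zero."""
    pc = _p_accept(scenario.cognate_rates(k_minusTu, k_CCA),
                   scenario.cca_while_tu_bound)
    pnc = _p_accept(scenario.near_cognate_rates(k_minusTu, k_CCA),
                    scenario.cca_while_tu_bound)
    if pnc == 0.0:
        return np.inf
    return pc / pnc


def efficiency(scenario: ScenarioSpec, k_minusTu: float,
               k_CCA: float | None = None) -> float:
    """E = P(A | cognate): fraction of cognate molecules accommodated."""
    return _p_accept(scenario.cognate_rates(k_minusTu, k_CCA),
                     scenario.cca_while_tu_bound)


def scan(scenario: ScenarioSpec) -> pd.DataFrame:
    """P_f, E and the absorption probabilities over the k_-Tu grid.

    For the EA-destabilised mode one curve per ``cca_ratios`` entry is
    produced (column ``k_CCA``); the ``efficient`` flag marks E > 0.9.
    """
    if scenario.k_minusTu_grid.size == 0:
        raise ValueError("empty k_minusTu grid")
    cca_values = scenario.cca_ratios if scenario.mode == "EA_destabilized" else (None,)
    rows = []
    for cca in cca_values:
        for km in scenario.k_minusTu_grid:
            pc = _p_accept(scenario.cognate_rates(km, cca),
                           scenario.cca_while_tu_bound)
            pnc = _p_accept(scenario.near_cognate_rates(km, cca),
                            scenario.cca_while_tu_bound)
            rows.append({
                "k_minusTu": km,
                "k_CCA": scenario.base.k_CCA if cca is None else cca,
                "P_A_cognate": pc,
                "P_A_near_cognate": pnc,
                "P_f": np.inf if pnc == 0 else pc / pnc,
                "E": pc,
                "efficient": pc > scenario.efficiency_threshold,
            })
    return pd.DataFrame(rows)


def classic_parallel_model(k_acc: float, k_minusTu: float,
                           k_reject_after_Tu_loss: float) -> float:
    """P(A) in the prevailing (non-extended) scheme.

    Accommodation and factor dissociation compete from the factor-bound
    state; after dissociation, accommodation competes with rejection:
    P(A) = k_acc/(k_acc+k_-Tu) + k_-Tu/(k_acc+k_-Tu)·k_acc/(k_acc+k_rej).
    """
    for v in (k_acc, k_minusTu, k_reject_after_Tu_loss):
        if v < 0:
            raise ValueError("rates must be >= 0")
    tot1 = k_acc + k_minusTu
    if tot1 == 0:
        raise ValueError("no exit from the initial state")
    p_direct = k_acc / tot1
    tot2 = k_acc + k_reject_after_Tu_loss
    p_after = (k_acc / tot2) if tot2 > 0 else 0.0
    return p_direct + (k_minusTu / tot1) * p_after
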