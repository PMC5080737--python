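"""Individual-based, discretized SIS coevolution dynamics.

Each time step applies, in order and using start-of-step counts S, I, N:

1. births: ``b N (1 - N/K)`` viable offspring candidates (stable expression,
   >= N_ER expressed receptors) are generated from uniformly drawn parent
   pairs; each survives with probability 1, (k_I+1)/2, or k_I according to
   its parents' infection status, and survivors join the susceptible pool.
2. contacts: ``(r/N) S I`` contact events pair a uniform susceptible with a
   uniform infected host; the carried virus is copied, mutated at rate
   ``mu_vp``, and infects the susceptible iff it binds at least one of its
   expressed receptors.
3. recoveries: ``gamma I`` infected hosts return to the susceptible pool,
   dropping their virus.
4. deaths: ``lambda_N S`` and ``lambda_N I`` natural deaths plus
   ``lambda_D I`` disease deaths, drawn without replacement.

The transmissibility ``xi = infections / contacts`` and offspring survival
``eta = survivors / candidates`` are emergent, recorded per step in a ledger
together with every event count.  Continuous rate terms are converted to
integer event counts by stochastic rounding (floor plus a Bernoulli trial on
the fractional part), which is unbiased in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import binds_many, mutate_sequence
from .grn import GRN
from .individuals import Host, offspring_survival_probability, spawn_candidates

__all__ = [
    "EpidemicParams",
    "PopulationState",
    "StepLedger",
    "SteadyState",
    "stochastic_round",
    "attempt_infection",
    "step_epidemic",
    "analytic_steady_state",
    "simulate_frozen_sis",
    "ledgers_to_frame",
]


@dataclass(frozen=True)
class EpidemicParams:
    """Population-dynamics rates of the SIS difference equations."""

    b: float = 0.15
    K: int = 1000
    r: float = 2.0
    lambda_N: float = 0.09
    lambda_D: float = 0.06
    gamma: float = 0.2
    k_I: float = 0.8
    mu_vp: float = 0.1

    @classmethod
    def from_config(cls, cfg) -> "EpidemicParams":
        return cls(cfg.b, cfg.K, cfg.r, cfg.lambda_N, cfg.lambda_D,
                   cfg.gamma, cfg.k_I, cfg.mu_vp)


@dataclass
class PopulationState:
    """Susceptible and infected host pools."""

    susceptible: list[Host]
    infected: list[Host]

    @property
    def N(self) -> int:
        return len(self.susceptible) + len(self.infected)


@dataclass
class StepLedger:
    """Per-step bookkeeping of every demographic and epidemic event."""

    t: int
    S: int                      # start-of-step susceptible count
    I: int                      # start-of-step infected count
    offspring_candidates: int
    offspring_survived: int
    contacts: int
    infections: int
    recoveries: int
    natural_deaths_S: int
    natural_deaths_I: int
    disease_deaths: int
    xi: float                   # infections / contacts (0 when contacts == 0)
    eta: float                  # survived / candidates (1 when candidates == 0)
    S_end: int
    I_end: int
    per_receptor_infections: np.ndarray  # (N_R,) matches among newly infected
    resist_classified: int = 0  # resisters classifiable vs the step's top receptor
    rewire_weight: float = 0.0  # of those, weight not expressing the top receptor

    def check_conservation(self) -> None:
        """Integer accounting identities; raise if bookkeeping is broken."""
        s = (self.S + self.offspring_survived - self.infections
             - self.natural_deaths_S + self.recoveries)
        i = (self.I + self.infections - self.recoveries
             - self.natural_deaths_I - self.disease_deaths)
        if s != self.S_end or i != self.I_end:
            raise AssertionError(
                f"ledger conservation violated at t={self.t}: "
                f"S {s} != {self.S_end} or I {i} != {self.I_end}"
            )


def ledgers_to_frame(ledgers: list[StepLedger]) -> pd.DataFrame:
    rows = []
    for led in ledgers:
        d = {
            k: getattr(led, k)
            for k in (
                "t", "S", "I", "offspring_candidates", "offspring_survived",
                "contacts", "infections", "recoveries", "natural_deaths_S",
                "natural_deaths_I", "disease_deaths", "xi", "eta",
                "S_end", "I_end", "resist_classified", "rewire_weight",
            )
        }
        for k, v in enumerate(led.per_receptor_infections):
            d[f"matches_receptor_{k}"] = int(v)
        rows.append(d)
    return pd.DataFrame(rows)


def stochastic_round(x: float, rng: np.random.Generator, mode: str = "stochastic") -> int:
    """Convert a continuous rate term to an integer event count.

    ``stochastic``: floor(x) plus a Bernoulli trial on the fractional part
    (unbiased).  ``round``: nearest integer.  Non-positive x gives 0.
    """
    if x <= 0:
        return 0
    if mode == "round":
        return int(np.rint(x))
    base = int(np.floor(x))
    frac = x - base
    return base + int(rng.random() < frac)


def attempt_infection(
    susceptible: Host,
    infected: Host,
    policy,
    mu_vp: float,
    rng: np.random.Generator,
    mutate: bool = True,
):
    """One contact event: copy + mutate the carried virus and test binding.

    Returns ``(success, virus_copy, matched_receptor_indices)`` where the
    matched indices list *every* expressed receptor the (mutated) virus
    binds, for the multi-receptor targeting metric.
    """
    if infected.virus is None:
        raise ValueError("infecting host carries no virus")
    if mutate:
        virus = mutate_sequence(infected.virus, mu_vp, rng)
    else:
        virus = infected.virus.copy()
    er = susceptible.expressed_receptor_indices
    bound = binds_many(virus, susceptible.receptors[er], policy)
    matched = er[bound]
    return matched.size > 0, virus, matched


def _pop_random(pool: list, rng: np.random.Generator):
    """Remove and return a uniformly chosen element (order not preserved)."""
    i = int(rng.integers(len(pool)))
    pool[i], pool[-1] = pool[-1], pool[i]
    return pool.pop()


def _remove_random(pool: list, k: int, rng: np.random.Generator) -> int:
    k = min(k, len(pool))
    for _ in range(k):
        _pop_random(pool, rng)
    return k


def step_epidemic(
    state: PopulationState,
    cfg,
    rng: np.random.Generator,
    s0: np.ndarray,
    t: int = 0,
) -> StepLedger:
    """Advance the population by one SIS step (mutating ``state`` in place).

    ``s0`` is the run-wide initial expression state used to evaluate
    offspring phenotypes.  Event counts use start-of-step S, I, N, mirroring
    the synchronous difference-equation form.
    """
    S0, I0 = len(state.susceptible), len(state.infected)
    N0 = S0 + I0
    if N0 == 0:
        return StepLedger(t, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0.0, 1.0, 0, 0,
                          np.zeros(cfg.N_R, dtype=np.int64))
    policy = cfg.binding_policy

    # --- 1. births ---------------------------------------------------------
    growth = cfg.b * N0 * (1.0 - N0 / cfg.K)
    n_candidates = stochastic_round(growth, rng, cfg.rounding)
    pool = state.susceptible + state.infected
    survived = 0
    produced = 0
    newborns: list[Host] = []
    if n_candidates > 0:
        Ws = np.stack([h.grn.W for h in pool])
        Rs = np.stack([h.receptors for h in pool])
        statuses = np.array([h.infected for h in pool], dtype=bool)
        attempts = 0
        max_attempts = 200 * n_candidates + 1000
        while produced < n_candidates and attempts < max_attempts:
            batch = max(int((n_candidates - produced) * 1.6) + 4, 8)
            out = spawn_candidates(Ws, Rs, batch, cfg, rng, s0)
            viable = out["converged"] & (
                out["phenotype"][:, cfg.N_TF :].sum(axis=1) >= cfg.N_ER
            )
            for i in np.flatnonzero(viable):
                if produced >= n_candidates:
                    break
                produced += 1
                pa, pb = out["parents"][i]
                if cfg.reproduction == "sexual":
                    p = offspring_survival_probability(
                        bool(statuses[pa]), bool(statuses[pb]), cfg.k_I
                    )
                else:
                    p = offspring_survival_probability(
                        bool(statuses[pa]), None, cfg.k_I
                    )
                if rng.random() < p:
                    survived += 1
                    newborns.append(Host(
                        GRN(out["W"][i], cfg.N_TF, cfg.N_R),
                        out["receptors"][i],
                        out["phenotype"][i],
                    ))
            attempts += batch
    eta = survived / produced if produced > 0 else 1.0
    state.susceptible.extend(newborns)

    # --- 2. contacts -------------------------------------------------------
    n_contacts = stochastic_round(cfg.r / N0 * S0 * I0, rng, cfg.rounding)
    infectors = list(state.infected)  # start-of-step snapshot
    per_receptor = np.zeros(cfg.N_R, dtype=np.int64)
    infections = 0
    contacts_done = 0
    resister_expr: list[np.ndarray] = []
    for _ in range(n_contacts):
        if not state.susceptible or not infectors:
            break
        contacts_done += 1
        si = int(rng.integers(len(state.susceptible)))
        sus = state.susceptible[si]
        inf = infectors[int(rng.integers(len(infectors)))]
        success, virus, matched = attempt_infection(
            sus, inf, policy, cfg.mu_vp, rng
        )
        if success:
            # newly infected hosts are immediately ineligible as susceptibles
            state.susceptible[si] = state.susceptible[-1]
            state.susceptible.pop()
            sus.virus = virus
            state.infected.append(sus)
            per_receptor[matched] += 1
            infections += 1
        else:
            resister_expr.append(sus.phenotype[cfg.N_TF :])
    xi = infections / contacts_done if contacts_done > 0 else 0.0

    # resistance-strategy classification against this step's most-targeted
    # receptor(s); ties contribute the mean over co-leading receptors
    resist_classified = 0
    rewire_weight = 0.0
    if resister_expr and per_receptor.sum() > 0:
        top = per_receptor.max()
        leaders = np.flatnonzero(per_receptor == top)
        for expr in resister_expr:
            resist_classified += 1
            rewire_weight += float(np.mean(expr[leaders] == 0))

    # --- 3. recoveries -----------------------------------------------------
    n_rec = min(stochastic_round(cfg.gamma * I0, rng, cfg.rounding),
                len(state.infected))
    for _ in range(n_rec):
        h = _pop_random(state.infected, rng)
        h.virus = None
        state.susceptible.append(h)

    # --- 4. deaths ---------------------------------------------------------
    nd_S = _remove_random(
        state.susceptible, stochastic_round(cfg.lambda_N * S0, rng, cfg.rounding), rng
    )
    nd_I = _remove_random(
        state.infected, stochastic_round(cfg.lambda_N * I0, rng, cfg.rounding), rng
    )
    dd_I = _remove_random(
        state.infected, stochastic_round(cfg.lambda_D * I0, rng, cfg.rounding), rng
    )

    led = StepLedger(
        t=t, S=S0, I=I0,
        offspring_candidates=produced, offspring_survived=survived,
        contacts=contacts_done, infections=infections, recoveries=n_rec,
        natural_deaths_S=nd_S, natural_deaths_I=nd_I, disease_deaths=dd_I,
        xi=xi, eta=eta,
        S_end=len(state.susceptible), I_end=len(state.infected),
        per_receptor_infections=per_receptor,
        resist_classified=resist_classified, rewire_weight=rewire_weight,
    )
    led.check_conservation()
    return led


# -- analytic steady state ---------------------------------------------------


@dataclass(frozen=True)
class SteadyState:
    """Closed-form SIS steady state for fixed transmissibility and survival."""

    S_tilde: float
    I_tilde: float
    delta_I: float
    feasible: bool


def analytic_steady_state(p: EpidemicParams, xi: float, eta: float) -> SteadyState:
    """Steady-state (S, I) of the difference equations at fixed xi and eta.

    Requires ``r * xi != 0``.  ``feasible`` records the existence condition
    ``(b eta - lambda_N) / lambda_D > 1 - delta_I / (r xi) > 0``.
    """
    rxi = p.r * xi
    if rxi == 0:
        raise ValueError("analytic steady state undefined when r * xi == 0")
    delta_I = p.lambda_N + p.lambda_D + p.gamma
    frac = delta_I / rxi
    brace = 1.0 - (p.lambda_N + p.lambda_D * (1.0 - frac)) / (p.b * eta)
    S_tilde = frac * p.K * brace
    I_tilde = (1.0 - frac) * p.K * brace
    lhs = (p.b * eta - p.lambda_N) / p.lambda_D if p.lambda_D > 0 else np.inf
    feasible = bool(lhs > (1.0 - frac) > 0.0)
    return SteadyState(S_tilde, I_tilde, delta_I, feasible)


def simulate_frozen_sis(
    p: EpidemicParams,
    xi: float,
    eta: float,
    steps: int,
    s_init: int,
    i_init: int,
    rng: np.random.Generator,
    rounding: str = "stochastic",
) -> np.ndarray:
    """SIS skeleton with the genotype layer replaced by fixed probabilities.

    Event counts are produced exactly as in :func:`step_epidemic`, but each
    contact infects with fixed probability ``xi`` and each offspring
    candidate survives with fixed probability ``eta``.  Used to validate the
    discretization against :func:`analytic_steady_state`.

    Returns an array of shape (steps + 1, 2) with the (S, I) trajectory.
    """
    S, I = int(s_init), int(i_init)
    traj = np.zeros((steps + 1, 2), dtype=np.int64)
    traj[0] = (S, I)
    for t in range(1, steps + 1):
        S0, I0 = S, I  # start-of-step counts drive every event term
        N = S0 + I0
        if N <= 0:
            break
        n_cand = stochastic_round(p.b * N * (1.0 - N / p.K), rng, rounding)
        survived = int(rng.binomial(n_cand, eta)) if n_cand else 0
        S += survived
        n_contacts = stochastic_round(p.r / N * S0 * I0, rng, rounding)
        infections = min(int(rng.binomial(n_contacts, xi)) if n_contacts else 0, S)
        S -= infections
        I += infections
        n_rec = min(stochastic_round(p.gamma * I0, rng, rounding), I)
        I -= n_rec
        S += n_rec
        S -= min(stochastic_round(p.lambda_N * S0, rng, rounding), S)
        I -= min(stochastic_round(p.lambda_N * I0, rng, rounding), I)
        I -= min(stochastic_round(p.lambda_D * I0, rng, rounding), I)
        traj[t] = (S, I)
    return traj
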