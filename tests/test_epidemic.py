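"""SIS step mechanics, ledger accounting, and the analytic steady state."""

import copy
import math

import numpy as np
import pytest

from coevosis import RunConfig
from coevosis.epidemic import (
    EpidemicParams,
    PopulationState,
    analytic_steady_state,
    attempt_infection,
    simulate_frozen_sis,
    step_epidemic,
    stochastic_round,
)
from coevosis.individuals import make_founder_host, stabilizing_burn_in


def _population(cfg, rng, steps=5):
    founder = make_founder_host(cfg, rng)
    hosts = stabilizing_burn_in(founder, cfg, rng, steps=steps)
    return founder, hosts


def test_stochastic_round_properties(rng):
    assert stochastic_round(-1.3, rng) == 0
    assert stochastic_round(0.0, rng) == 0
    assert stochastic_round(7.0, rng) == 7
    draws = [stochastic_round(2.3, rng) for _ in range(20_000)]
    assert set(draws) <= {2, 3}
    se = math.sqrt(0.3 * 0.7 / len(draws))
    assert abs(np.mean(draws) - 2.3) < 3 * se
    assert stochastic_round(2.5, rng, mode="round") in (2, 3)  # np.rint ties-to-even
    assert stochastic_round(2.4, rng, mode="round") == 2


def test_attempt_infection_exact_copy_succeeds(rng, small_config):
    cfg = small_config()
    founder, hosts = _population(cfg, rng)
    sus = hosts[0]
    ridx = int(sus.expressed_receptor_indices[0])
    inf = hosts[1]
    inf.virus = sus.receptors[ridx].copy()
    ok, virus, matched = attempt_infection(
        sus, inf, cfg.binding_policy, mu_vp=0.0, rng=rng
    )
    assert ok and ridx in matched.tolist()
    inf.virus = 1 - sus.receptors[ridx]  # complement: matches nothing
    ok2, _, matched2 = attempt_infection(
        sus, inf, cfg.binding_policy, mu_vp=0.0, rng=rng
    )
    assert not ok2 and matched2.size == 0
    inf.virus = None
    with pytest.raises(ValueError):
        attempt_infection(sus, inf, cfg.binding_policy, 0.0, rng)


def test_step_without_contacts_when_contact_rate_zero(rng, small_config):
    cfg = small_config(r=0.0)
    founder, hosts = _population(cfg, rng)
    hosts[0].virus = hosts[0].receptors[0].copy()
    state = PopulationState(hosts[1:], [hosts[0]])
    led = step_epidemic(state, cfg, rng, founder.s0)
    assert led.contacts == 0 and led.infections == 0 and led.xi == 0.0


def test_step_full_recovery_at_unit_rate(rng, small_config):
    cfg = small_config(gamma=1.0, lambda_N=0.0, lambda_D=0.0, b=0.0, r=0.0)
    founder, hosts = _population(cfg, rng)
    infected = hosts[:10]
    for h in infected:
        h.virus = h.receptors[0].copy()
    state = PopulationState(hosts[10:], infected)
    led = step_epidemic(state, cfg, rng, founder.s0)
    assert led.recoveries == 10
    assert led.I_end == 0
    assert all(h.virus is None for h in hosts)


def test_step_perfect_transmission(rng, small_config):
    """Identical receptors and no virus mutation: every contact infects."""
    cfg = small_config(mu_vp=0.0, b=0.0, lambda_N=0.0, lambda_D=0.0, gamma=0.0)
    founder, hosts = _population(cfg, rng, steps=0)
    hosts[0].virus = hosts[0].receptors[
        int(hosts[0].expressed_receptor_indices[0])
    ].copy()
    state = PopulationState(hosts[1:], [hosts[0]])
    led = step_epidemic(state, cfg, rng, founder.s0)
    assert led.contacts > 0
    assert led.infections == led.contacts
    assert led.xi == 1.0


def test_ledger_conservation_across_consecutive_steps(rng, small_config):
    cfg = small_config()
    founder, hosts = _population(cfg, rng)
    hosts[0].virus = hosts[0].receptors[0].copy()
    state = PopulationState(hosts[1:], [hosts[0]])
    prev = None
    for t in range(40):
        led = step_epidemic(state, cfg, rng, founder.s0, t=t)
        led.check_conservation()
        if prev is not None:
            assert led.S == prev.S_end and led.I == prev.I_end
        prev = led
        assert 0.0 <= led.xi <= 1.0 and 0.0 <= led.eta <= 1.0


def test_infections_monotone_in_matching_threshold(rng, small_config):
    """With a shared RNG stream, a stricter threshold never gains infections."""
    cfg_lo = small_config(eps_seqM=60.0)
    founder, hosts = _population(cfg_lo, rng, steps=20)
    infected = hosts[0]
    infected.virus = infected.receptors[0].copy()
    outcomes = {}
    for eps in (60.0, 95.0):
        cfg = small_config(eps_seqM=eps)
        n = 0
        pair_rng = np.random.default_rng(99)
        for h in hosts[1:]:
            ok, _, _ = attempt_infection(
                h, infected, cfg.binding_policy, cfg.mu_vp, pair_rng
            )
            n += ok
        outcomes[eps] = n
    assert outcomes[95.0] <= outcomes[60.0]


def test_contacts_are_frequency_dependent(rng, small_config):
    """Doubling N at fixed S/N, I/N doubles contacts (per-capita constant)."""
    p = RunConfig()
    S, I = 60, 40
    c1 = p.r / (S + I) * S * I
    c2 = p.r / (2 * (S + I)) * (2 * S) * (2 * I)
    assert c2 == pytest.approx(2 * c1)
    assert c2 / (2 * (S + I)) == pytest.approx(c1 / (S + I))


def test_analytic_steady_state_closed_form():
    p = EpidemicParams()
    ss = analytic_steady_state(p, xi=0.5, eta=1.0)
    assert ss.delta_I == pytest.approx(0.35)
    assert ss.S_tilde == pytest.approx(49.0, abs=1e-9)
    assert ss.I_tilde == pytest.approx(91.0, abs=1e-9)
    assert ss.feasible


def test_analytic_steady_state_boundary_and_errors():
    p = EpidemicParams()
    # r*xi == delta_I puts the infected fraction exactly at zero
    ss = analytic_steady_state(p, xi=0.35 / p.r, eta=1.0)
    assert ss.I_tilde == pytest.approx(0.0, abs=1e-12)
    assert not ss.feasible
    with pytest.raises(ValueError):
        analytic_steady_state(p, xi=0.0, eta=1.0)


@pytest.mark.parametrize("xi,eta", [(0.5, 1.0), (0.3, 0.9), (0.8, 0.7)])
def test_steady_state_is_fixed_point_of_difference_equations(xi, eta):
    """Substituting (S~, I~) into the update equations gives dS = dI = 0."""
    p = EpidemicParams()
    ss = analytic_steady_state(p, xi, eta)
    S, I = ss.S_tilde, ss.I_tilde
    N = S + I
    dS = (eta * p.b * N * (1 - N / p.K) - xi * p.r / N * S * I
          - p.lambda_N * S + p.gamma * I)
    dI = xi * p.r / N * S * I - (p.lambda_N + p.lambda_D + p.gamma) * I
    assert dS == pytest.approx(0.0, abs=1e-9)
    assert dI == pytest.approx(0.0, abs=1e-9)


def test_frozen_sis_tracks_analytic_steady_state():
    p = EpidemicParams()
    ss = analytic_steady_state(p, 0.5, 1.0)
    traj = simulate_frozen_sis(p, 0.5, 1.0, 1000, 135, 15,
                               np.random.default_rng(5))
    tail = traj[-100:].mean(axis=0)
    assert abs(tail[0] - ss.S_tilde) / ss.S_tilde < 0.05
    assert abs(tail[1] - ss.I_tilde) / ss.I_tilde < 0.05
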