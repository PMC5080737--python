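"""Gini, Margalef, targeting statistics, and the perturbation assays."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevosis import RunConfig
from coevosis.epidemic import StepLedger
from coevosis.grn import GRN
from coevosis.individuals import Host
from coevosis.metrics import (
    count_grn_variants,
    count_phenotype_variants,
    count_sequence_variants,
    eligible_pairs,
    gini,
    grn_resistance_potential,
    margalef,
    multi_receptor_frequency,
    multi_switch_ability,
    protein_resistance_potential,
    rewiring_preference,
    steady_state_transmissibility,
    targeting_vector,
)


def mk_ledger(t, per_receptor, xi=0.0, contacts=0, resist=0, rewire=0.0):
    per_receptor = np.asarray(per_receptor, dtype=np.int64)
    infections = int(per_receptor.sum())
    return StepLedger(
        t=t, S=100, I=10, offspring_candidates=0, offspring_survived=0,
        contacts=contacts, infections=infections, recoveries=0,
        natural_deaths_S=0, natural_deaths_I=0, disease_deaths=0,
        xi=xi, eta=1.0, S_end=100 - infections, I_end=10 + infections,
        per_receptor_infections=per_receptor,
        resist_classified=resist, rewire_weight=rewire,
    )


# -- gini --------------------------------------------------------------------


def gini_mad_oracle(y):
    """Mean-absolute-difference form: sum |y_i - y_j| / (2 n^2 ybar)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    return float(np.abs(y[:, None] - y[None, :]).sum() / (2 * n * n * y.mean()))


def test_gini_evenness_and_onehot():
    assert gini([1, 1, 1, 1, 1]) == 0.0
    assert gini([7, 7, 7]) == 0.0
    assert gini([0, 0, 0, 0, 1]) == pytest.approx(0.8, abs=1e-12)
    assert gini([0, 0, 0, 0, 1]) == pytest.approx(
        gini_mad_oracle([0, 0, 0, 0, 1]), abs=1e-12
    )


def test_gini_undefined_cases():
    assert math.isnan(gini([0.0, 0.0, 0.0]))
    with pytest.raises(ValueError):
        gini([])
    with pytest.raises(ValueError):
        gini([1.0, -0.5])


@settings(deadline=None, derandomize=True, max_examples=80)
@given(
    y=st.lists(st.floats(0.0, 1e6), min_size=2, max_size=25).filter(
        lambda v: sum(v) > 0
    ),
    scale=st.floats(1e-3, 1e3),
)
def test_gini_matches_oracle_and_is_scale_invariant(y, scale):
    g = gini(y)
    assert g == pytest.approx(gini_mad_oracle(y), abs=1e-9)
    assert gini([scale * v for v in y]) == pytest.approx(g, abs=1e-9)
    n = len(y)
    assert -1e-12 <= g <= (n - 1) / n + 1e-12


# -- margalef ----------------------------------------------------------------


def test_margalef_examples():
    assert margalef(1, 50) == 0.0
    assert margalef(5, 100) == pytest.approx(4 / math.log(100))
    assert margalef(10, 10) == pytest.approx(9 / math.log(10))
    assert math.isnan(margalef(3, 1))
    with pytest.raises(ValueError):
        margalef(0, 10)


def test_margalef_monotone_in_variants():
    vals = [margalef(v, 200) for v in range(1, 30)]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_variant_counting_levels():
    W1 = np.zeros((10, 5)); W1[0, 0] = 0.8
    W2 = np.zeros((10, 5)); W2[0, 0] = 2.5   # same sign pattern as W1
    W3 = np.zeros((10, 5)); W3[0, 0] = -0.8
    r = np.zeros((5, 10), dtype=np.uint8)
    p = np.zeros(10, dtype=np.uint8)
    hosts = [
        Host(GRN(W, 5, 5), r.copy(), p.copy()) for W in (W1, W2, W3)
    ]
    assert count_grn_variants(hosts) == 2  # sign-simplification merges W1, W2
    hosts[2].phenotype = np.ones(10, dtype=np.uint8)
    assert count_phenotype_variants(hosts) == 2
    hosts[0].receptors = np.ones((5, 10), dtype=np.uint8)
    assert count_sequence_variants(hosts) == 2


# -- run-level targeting metrics ---------------------------------------------


def test_steady_state_transmissibility_averaging():
    ledgers = [mk_ledger(t, [0] * 5, xi=0.3, contacts=4) for t in range(300)]
    assert steady_state_transmissibility(ledgers, window=250) == pytest.approx(0.3)
    alt = [
        mk_ledger(t, [0] * 5, xi=(0.2 if t % 2 else 0.4), contacts=3)
        for t in range(250)
    ]
    assert steady_state_transmissibility(alt, window=250) == pytest.approx(0.3)
    # zero-contact steps are excluded, not averaged as zeros
    mixed = [mk_ledger(t, [0] * 5, xi=0.6, contacts=2) for t in range(100)]
    mixed += [mk_ledger(t, [0] * 5, xi=0.0, contacts=0) for t in range(100)]
    assert steady_state_transmissibility(mixed, window=200) == pytest.approx(0.6)
    none_valid = [mk_ledger(t, [0] * 5, contacts=0) for t in range(50)]
    assert math.isnan(steady_state_transmissibility(none_valid, window=50))


def test_multi_receptor_frequency_sampled_and_windowed():
    # infections on two receptors mid-window, single receptor at the
    # measurement steps themselves
    ledgers = [mk_ledger(t, [0, 0, 0, 0, 0]) for t in range(200)]
    ledgers[10] = mk_ledger(10, [3, 0, 0, 0, 0])
    ledgers[20] = mk_ledger(20, [0, 2, 0, 0, 0])
    ledgers[49] = mk_ledger(49, [1, 0, 0, 0, 0])
    ledgers[99] = mk_ledger(99, [0, 2, 1, 0, 0])
    assert multi_receptor_frequency(ledgers, 50, mode="sample") == pytest.approx(0.25)
    assert multi_receptor_frequency(ledgers, 50, mode="window") == pytest.approx(0.5)
    assert math.isnan(multi_receptor_frequency(ledgers[:30], 50))
    with pytest.raises(ValueError):
        multi_receptor_frequency(ledgers, 50, mode="bogus")


def test_targeting_vector_averages_measurement_points():
    ledgers = [mk_ledger(t, [0] * 5) for t in range(100)]
    ledgers[49] = mk_ledger(49, [4, 0, 0, 0, 0])
    ledgers[99] = mk_ledger(99, [0, 2, 0, 0, 0])
    y = targeting_vector(ledgers, 50)
    assert y.tolist() == [2.0, 1.0, 0.0, 0.0, 0.0]


def test_rewiring_preference_accumulation():
    ledgers = [
        mk_ledger(0, [5, 0, 0, 0, 0], resist=6, rewire=4.0),
        mk_ledger(1, [2, 0, 0, 0, 0], resist=4, rewire=2.0),
    ]
    res = rewiring_preference(ledgers)
    assert res.n_events == 10
    assert res.rewiring_fraction == pytest.approx(0.6)
    assert res.prefers_rewiring is True
    protein_led = [mk_ledger(0, [5, 0, 0, 0, 0], resist=10, rewire=0.0)]
    assert rewiring_preference(protein_led).prefers_rewiring is False
    empty = rewiring_preference([mk_ledger(0, [0] * 5)])
    assert empty.prefers_rewiring is None and math.isnan(empty.rewiring_fraction)


# -- perturbation assays -----------------------------------------------------


def _toy_cfg(**kw):
    base = dict(N_TF=1, N_R=2, N_ER=1, L=10)
    base.update(kw)
    return RunConfig(**base)


def _toy_host(rng):
    """One self-activating TF driving receptor 0 (+1.0) and receptor 1 (+1.5)."""
    W = np.array([[2.0], [1.0], [1.5]])
    receptors = np.stack([
        np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=np.uint8),
        np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1], dtype=np.uint8),
    ])
    phenotype = np.array([1, 1, 1], dtype=np.uint8)
    return Host(GRN(W, 1, 2), receptors, phenotype)


def test_eligible_pairs_require_binding_an_expressed_receptor(rng):
    cfg = _toy_cfg()
    host = _toy_host(rng)
    virus = host.receptors[0].copy()
    pairs = eligible_pairs([host], [virus, virus], cfg.binding_policy)
    assert len(pairs) == 1  # duplicate viruses collapse
    stranger = 1 - virus
    assert eligible_pairs([host], [stranger], cfg.binding_policy) == []


def test_grn_resistance_potential_toy_value(rng):
    """Only the bound receptor's own interaction can rescue the host.

    Redrawing receptor 0's regulation goes negative half the time, shutting
    the targeted receptor off while receptor 1 keeps the host viable: that
    interaction scores ~0.5.  The TF self-loop and receptor 1's interaction
    score 0 (perturbing them either keeps the bound receptor on or breaks
    viability/stability).  Mean over the 3 interactions: ~1/6.
    """
    cfg = _toy_cfg()
    host = _toy_host(rng)
    virus = host.receptors[0].copy()
    s0 = np.array([1.0, 0.0, 0.0])
    pot = grn_resistance_potential([host], [virus], cfg, s0, rng, trials=1200)
    assert pot == pytest.approx(1 / 6, abs=0.02)


def test_grn_resistance_potential_no_eligible_pairs_is_nan(rng):
    cfg = _toy_cfg()
    host = _toy_host(rng)
    pot = grn_resistance_potential(
        [host], [1 - host.receptors[0]], cfg, np.ones(3), rng
    )
    assert math.isnan(pot)


def test_protein_resistance_potential_boundary_match(rng):
    """Virus one mismatch above failure: exact probability by enumeration.

    Each site of the matched receptor flips independently with rate mu_hp;
    binding survives iff (matches after flips) stays above the threshold.
    The expected escape fraction is computed by exact enumeration over flip
    counts on matching/mismatching sites and compared at 3 sigma.
    """
    cfg = _toy_cfg(eps_seqM=85.0)
    host = _toy_host(rng)
    virus = host.receptors[0].copy()
    virus[0] ^= 1  # 9/10 match; 90 > 85 binds, 80 does not
    mu_hp = 0.1
    # oracle: receptor 1 never binds this virus, so escape = bound receptor
    # falling to <= 85%: matches' = 9 - X + Y with X~Bin(9,p), Y~Bin(1,p)
    p = mu_hp
    p_bind = 0.0
    for X in range(10):
        for Y in range(2):
            if 9 - X + Y >= 9:
                p_bind += (
                    math.comb(9, X) * p**X * (1 - p) ** (9 - X)
                    * math.comb(1, Y) * p**Y * (1 - p) ** (1 - Y)
                )
    expected = 1.0 - p_bind
    trials = 4000
    pot = protein_resistance_potential(
        [host], [virus], mu_hp, cfg, rng, trials=trials
    )
    se = math.sqrt(expected * (1 - expected) / trials)
    assert abs(pot - expected) < 3 * se


def test_protein_resistance_potential_double_match_is_zero(rng):
    """A virus bound to two receptors cannot be escaped by perturbing one."""
    cfg = _toy_cfg(L=20, eps_seqM=75.0)
    receptors = np.zeros((2, 20), dtype=np.uint8)
    receptors[1, 0] = 1  # 19/20 = 95% match to the all-zero virus
    host = Host(GRN(np.array([[2.0], [1.0], [1.5]]), 1, 2), receptors,
                np.array([1, 1, 1], dtype=np.uint8))
    virus = np.zeros(20, dtype=np.uint8)
    pot = protein_resistance_potential([host], [virus], 0.1, cfg, rng, trials=300)
    assert pot == 0.0


def test_multi_switch_ability_hub_and_empty(rng):
    """A TF hub can flip several receptors at once; an empty GRN cannot."""
    cfg = RunConfig(N_TF=2, N_R=3, N_ER=1, L=10)
    W = np.zeros((5, 2))
    W[0, 0] = 2.0    # TF0 self-activates
    W[1, 0] = 2.0    # TF0 activates TF1
    W[2:, 1] = 2.0   # TF1 activates all three receptors ...
    W[2:, 0] = -1.0  # ... against a repressive TF0 baseline
    pheno = np.ones(5, dtype=np.uint8)
    hub = Host(GRN(W, 2, 3), np.zeros((3, 10), dtype=np.uint8), pheno)
    s0 = np.ones(5)
    # redrawing the TF0->TF1 hub interaction negative silences TF1 and with
    # it all three receptors (4 genes flip); every other interaction moves
    # at most one gene, so the average over 8 interactions is ~0.5/8
    score = multi_switch_ability([hub], cfg, s0, rng, trials=400)
    assert 0.02 < score < 0.15
    empty = Host(GRN(np.zeros((5, 2)), 2, 3), np.zeros((3, 10), dtype=np.uint8),
                 np.zeros(5, dtype=np.uint8))
    assert math.isnan(multi_switch_ability([empty], cfg, s0, rng))
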