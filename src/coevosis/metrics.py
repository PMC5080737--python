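"""Measurements over simulation runs.

Covers the emergent transmissibility, multi-receptor targeting, the Gini
coefficient of per-receptor infection counts, the network-rewiring vs
protein-mutation resistance preference, perturbation-based resistance
potentials, the multi-receptor switch ability, and Margalef richness of
genotypes, phenotypes and receptor sequences.

Quantities that are undefined for a given input (no infections, no
resistance events, fewer than two individuals, ...) return ``nan`` rather
than a misleading zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import binds_many
from .grn import binarize_vector, iterate_expression_batch
from .individuals import Host

__all__ = [
    "gini",
    "margalef",
    "count_grn_variants",
    "count_phenotype_variants",
    "count_sequence_variants",
    "diversity_record",
    "steady_state_transmissibility",
    "targeting_vector",
    "multi_receptor_frequency",
    "rewiring_preference",
    "RewiringResult",
    "eligible_pairs",
    "grn_resistance_potential",
    "protein_resistance_potential",
    "multi_switch_ability",
]


# -- scalar statistics -------------------------------------------------------


def gini(y) -> float:
    """Unevenness of a nonnegative vector, 0 (even) to (n-1)/n (one-hot).

    Sorted-ascending form: ``(n + 1 - 2 * sum_i y'_i (n + 1 - i) / sum_i
    y'_i) / n``.  Returns nan for an empty or all-zero vector (undefined).
    """
    y = np.sort(np.asarray(y, dtype=float))
    n = y.size
    if n == 0 or (y < 0).any():
        raise ValueError("gini requires a nonempty, nonnegative vector")
    total = y.sum()
    if total <= 0:
        return float("nan")
    i = np.arange(1, n + 1)
    return float((n + 1 - 2.0 * np.sum(y * (n + 1 - i)) / total) / n)


def margalef(variant_count: int, individual_count: int) -> float:
    """Richness corrected for sample size: (variants - 1) / ln(individuals).

    Undefined (nan) for fewer than two individuals.
    """
    if variant_count < 1:
        raise ValueError("variant_count must be >= 1")
    if individual_count < 2:
        return float("nan")
    return (variant_count - 1) / np.log(individual_count)


# -- variant counting --------------------------------------------------------


def count_grn_variants(hosts: list[Host]) -> int:
    """Distinct GRNs after sign simplification of every interaction."""
    return len({
        np.sign(h.grn.W).astype(np.int8).tobytes() for h in hosts
    })


def count_phenotype_variants(hosts: list[Host]) -> int:
    return len({h.phenotype.tobytes() for h in hosts})


def count_sequence_variants(hosts: list[Host]) -> int:
    """Distinct concatenated receptor sequence sets."""
    return len({h.receptors.tobytes() for h in hosts})


def diversity_record(hosts: list[Host]) -> dict:
    """Margalef indices of a host group at the three description levels."""
    n = len(hosts)
    if n < 2:
        nan = float("nan")
        return {"grn_div": nan, "phenotype_div": nan, "sequence_div": nan}
    return {
        "grn_div": margalef(count_grn_variants(hosts), n),
        "phenotype_div": margalef(count_phenotype_variants(hosts), n),
        "sequence_div": margalef(count_sequence_variants(hosts), n),
    }


# -- run-level measurements ---------------------------------------------------


def steady_state_transmissibility(ledgers, window: int = 250) -> float:
    """Mean per-step xi over the last ``window`` steps, excluding steps with
    zero contacts (where the ratio is undefined)."""
    tail = ledgers[-window:]
    vals = [led.xi for led in tail if led.contacts > 0]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def _measurement_counts(ledgers, interval: int, mode: str) -> np.ndarray:
    """Per-measurement-point matched-receptor counts of the newly infected.

    ``sample`` (default): the newly infected at every ``interval``-th step
    (the measurement cadence samples single time points).  ``window``: sums
    over each consecutive ``interval``-step block instead.
    """
    if mode == "sample":
        pts = ledgers[interval - 1 :: interval]
        return np.array([led.per_receptor_infections for led in pts])
    if mode == "window":
        n_windows = len(ledgers) // interval
        return np.array([
            np.sum(
                [led.per_receptor_infections
                 for led in ledgers[w * interval : (w + 1) * interval]],
                axis=0,
            )
            for w in range(n_windows)
        ])
    raise ValueError(f"unknown measurement mode {mode!r}")


def targeting_vector(ledgers, interval: int = 50, mode: str = "sample") -> np.ndarray:
    """Mean number of newly infected hosts matched to each receptor, averaged
    over the measurement points (every ``interval`` steps)."""
    counts = _measurement_counts(ledgers, interval, mode)
    if counts.size == 0:
        raise ValueError("run shorter than one measurement interval")
    return counts.mean(axis=0)


def multi_receptor_frequency(
    ledgers, interval: int = 50, mode: str = "sample"
) -> float:
    """Fraction of measurement points at which the newly infected hosts'
    matched receptors cover >= 2 distinct receptor indices."""
    counts = _measurement_counts(ledgers, interval, mode)
    if counts.size == 0:
        return float("nan")
    return float(np.mean((counts > 0).sum(axis=1) >= 2))


@dataclass(frozen=True)
class RewiringResult:
    """Accumulated resistance-strategy tally over a run."""

    prefers_rewiring: bool | None
    rewiring_fraction: float
    n_events: int


def rewiring_preference(ledgers) -> RewiringResult:
    """Does network-level resistance outweigh protein-level resistance?

    Per step, hosts that resisted a contact are split by whether they express
    the step's most frequently targeted receptor (ties contribute the mean
    across co-leaders): not expressing it counts as network rewiring,
    expressing it as protein-level (binding mismatch) resistance.  Events are
    accumulated over all steps; with no classifiable events the result is
    undefined.
    """
    total = sum(led.resist_classified for led in ledgers)
    rewire = sum(led.rewire_weight for led in ledgers)
    if total == 0:
        return RewiringResult(None, float("nan"), 0)
    frac = rewire / total
    return RewiringResult(rewire > total - rewire, float(frac), total)


# -- perturbation assays -------------------------------------------------------


def eligible_pairs(susceptibles: list[Host], viruses: list[np.ndarray], policy):
    """(host, virus) pairs where the virus binds >= 1 expressed receptor
    (the host 'can be potentially infected').  Duplicate virus sequences are
    collapsed."""
    unique = {np.asarray(v).tobytes(): np.asarray(v) for v in viruses}
    pairs = []
    for v in unique.values():
        for h in susceptibles:
            er = h.expressed_receptor_indices
            if er.size and binds_many(v, h.receptors[er], policy).any():
                pairs.append((h, v))
    return pairs


def _perturbed_phenotypes(host: Host, trials: int, cfg, rng, s0):
    """Redraw each nonzero interaction ``trials`` times and recompute the
    phenotype for every perturbed network.

    Returns (positions (k, 2), phenotypes (k, trials, N), converged
    (k, trials)); k = number of nonzero interactions (0 for an empty GRN).
    """
    W = host.grn.W
    pos = np.argwhere(W != 0.0)
    k = pos.shape[0]
    if k == 0:
        return pos, None, None
    Wp = np.repeat(W[None], k * trials, axis=0)
    vals = rng.standard_normal(k * trials)
    vals[vals == 0.0] = 1e-12  # probability-zero guard
    rows = np.repeat(pos[:, 0], trials)
    cols = np.repeat(pos[:, 1], trials)
    Wp[np.arange(k * trials), rows, cols] = vals
    S, conv, _ = iterate_expression_batch(
        Wp, np.asarray(s0, dtype=float), a=cfg.a, tol=cfg.stability_tol,
        window=cfg.stability_window, max_steps=cfg.max_expression_steps,
    )
    pheno = binarize_vector(S).reshape(k, trials, -1)
    return pos, pheno, conv.reshape(k, trials)


def grn_resistance_potential(
    susceptibles: list[Host],
    viruses: list[np.ndarray],
    cfg,
    s0: np.ndarray,
    rng: np.random.Generator,
    trials: int = 50,
    max_pairs: int | None = None,
) -> float:
    """How often a single regulatory-interaction redraw makes a potentially
    infectable host resistant.

    For each (host, virus) pair where the virus binds an expressed receptor,
    every nonzero interaction is redrawn ``trials`` times; a perturbation
    counts as resistance iff the perturbed phenotype is stable, still
    expresses >= N_ER receptors (the escape must be viable), and the virus
    binds none of the newly expressed receptors.  Fractions are averaged
    over interactions, then over pairs.  nan if no pair is eligible.
    """
    policy = cfg.binding_policy
    pairs = eligible_pairs(susceptibles, viruses, policy)
    if not pairs:
        return float("nan")
    if max_pairs is not None and len(pairs) > max_pairs:
        pairs = [pairs[i] for i in rng.choice(len(pairs), max_pairs, replace=False)]
    scores = []
    for host, virus in pairs:
        pos, pheno, conv = _perturbed_phenotypes(host, trials, cfg, rng, s0)
        if pheno is None:
            continue
        k = pos.shape[0]
        per_interaction = np.zeros(k)
        for ki in range(k):
            resist = 0
            for tr in range(trials):
                if not conv[ki, tr]:
                    continue
                expr = np.flatnonzero(pheno[ki, tr, cfg.N_TF :])
                if expr.size < cfg.N_ER:
                    continue
                if not binds_many(virus, host.receptors[expr], policy).any():
                    resist += 1
            per_interaction[ki] = resist / trials
        scores.append(per_interaction.mean())
    if not scores:
        return float("nan")
    return float(np.mean(scores))


def protein_resistance_potential(
    susceptibles: list[Host],
    viruses: list[np.ndarray],
    mu_hp: float,
    cfg,
    rng: np.random.Generator,
    trials: int = 50,
    max_pairs: int | None = None,
) -> float:
    """How often mutating a matched receptor at the in-simulation host
    protein mutation rate (independently at each site) breaks all binding.

    For each matched receptor of each potentially infectable host, the
    receptor is perturbed ``trials`` times by flipping each site with
    probability ``mu_hp``; a perturbation counts as resistance iff the virus
    then binds none of the host's expressed receptors.  Averaged over
    matched receptors, then over pairs.  nan if no pair is eligible.
    """
    policy = cfg.binding_policy
    pairs = eligible_pairs(susceptibles, viruses, policy)
    if not pairs:
        return float("nan")
    if max_pairs is not None and len(pairs) > max_pairs:
        pairs = [pairs[i] for i in rng.choice(len(pairs), max_pairs, replace=False)]
    scores = []
    for host, virus in pairs:
        er = host.expressed_receptor_indices
        bound = binds_many(virus, host.receptors[er], policy)
        matched = er[bound]
        per_receptor = []
        for ridx in matched:
            resist = 0
            for _ in range(trials):
                seqs = host.receptors[er].copy()
                row = int(np.flatnonzero(er == ridx)[0])
                flips = rng.random(host.receptors.shape[1]) < mu_hp
                seqs[row, flips] ^= 1
                if not binds_many(virus, seqs, policy).any():
                    resist += 1
            per_receptor.append(resist / trials)
        scores.append(float(np.mean(per_receptor)))
    return float(np.mean(scores))


def multi_switch_ability(
    susceptibles: list[Host],
    cfg,
    s0: np.ndarray,
    rng: np.random.Generator,
    trials: int = 50,
    max_hosts: int | None = None,
) -> float:
    """How often a single regulatory-interaction redraw flips the expression
    of more than one gene.

    Every nonzero interaction of every susceptible host is redrawn
    ``trials`` times; the fraction of perturbations changing > 1 entry of
    the binarized phenotype is averaged over interactions, then over hosts.
    Hosts with no interactions contribute nothing; non-converging
    perturbations do not count as switches.
    """
    hosts = susceptibles
    if max_hosts is not None and len(hosts) > max_hosts:
        hosts = [hosts[i] for i in rng.choice(len(hosts), max_hosts, replace=False)]
    scores = []
    for host in hosts:
        pos, pheno, conv = _perturbed_phenotypes(host, trials, cfg, rng, s0)
        if pheno is None:
            continue
        base = host.phenotype.astype(np.int16)
        flips = np.abs(pheno.astype(np.int16) - base).sum(axis=2)  # (k, trials)
        multi = (flips > 1) & conv
        scores.append(float(multi.mean()))
    if not scores:
        return float("nan")
    return float(np.mean(scores))
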