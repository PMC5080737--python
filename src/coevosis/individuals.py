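"""Hosts, viruses, reproduction, and the pre-coevolution burn-in.

A host is a GRN plus one binding-site sequence per receptor gene, with its
binarized steady-state phenotype cached against a fixed initial expression
state ``S(0)`` drawn once for the founder.  A virus is a single binding
protein sequence, carried by exactly one infected host.

Before viruses are introduced, the population evolves for a fixed number of
steps at constant size under stabilizing selection: offspring survive only if
their expression dynamics converge, they express at least ``N_ER`` receptors,
their phenotype differs from the founder's in at most one gene, and they pass
a Bernoulli trial with probability ``exp(-D / sigma)`` on the receptor-
sequence distance from the founder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import mutate_sequence, random_sequence
from .grn import GRN, apply_mutation_event, binarize_vector, iterate_expression_batch

__all__ = [
    "Host",
    "Candidate",
    "Founder",
    "make_founder_host",
    "make_null_founder",
    "reproduce",
    "offspring_survival_probability",
    "stabilizing_burn_in",
    "make_founder_viruses",
]


@dataclass
class Host:
    """One host individual.  ``virus`` is present iff the host is infected."""

    grn: GRN
    receptors: np.ndarray  # (N_R, L) uint8
    phenotype: np.ndarray  # (N,) uint8, binarized steady state under S(0)
    virus: np.ndarray | None = None

    @property
    def infected(self) -> bool:
        return self.virus is not None

    @property
    def expressed_receptor_indices(self) -> np.ndarray:
        return np.flatnonzero(self.phenotype[self.grn.N_TF :])

    @property
    def expressed_receptor_sequences(self) -> np.ndarray:
        return self.receptors[self.expressed_receptor_indices]


@dataclass
class Candidate:
    """Offspring candidate prior to selection filters."""

    grn: GRN
    receptors: np.ndarray
    phenotype: np.ndarray | None
    converged: bool | None

    def to_host(self) -> Host:
        if self.phenotype is None or not self.converged:
            raise ValueError("cannot realize a non-evaluated or unstable candidate")
        return Host(self.grn, self.receptors, self.phenotype)


@dataclass
class Founder:
    """The founder host together with the run-wide initial expression state."""

    host: Host
    s0: np.ndarray  # (N,) binary initial expression, shared by all descendants


# -- founder construction ----------------------------------------------------


def make_founder_host(cfg, rng: np.random.Generator, max_redraws: int = 10_000) -> Founder:
    """Draw founders until one is stable and expresses >= N_ER receptors.

    The founder's W has exactly ``round(c * N * N_TF)`` nonzero Normal(0,1)
    entries; each receptor gets an independent uniform random binding
    sequence, redrawn if any two receptors coincide (a homogeneous receptor
    set makes infection trivially easy).
    """
    for _ in range(max_redraws):
        grn = GRN.random(cfg.N_TF, cfg.N_R, cfg.c, rng)
        s0 = rng.integers(0, 2, size=cfg.N).astype(float)
        S, conv, _ = iterate_expression_batch(
            grn.W[None], s0, a=cfg.a, tol=cfg.stability_tol,
            window=cfg.stability_window, max_steps=cfg.max_expression_steps,
        )
        if not conv[0]:
            continue
        pheno = binarize_vector(S[0])
        if int(pheno[cfg.N_TF :].sum()) < cfg.N_ER:
            continue
        receptors = _distinct_receptor_set(cfg.N_R, cfg.L, rng)
        return Founder(Host(grn, receptors, pheno), s0)
    raise RuntimeError(
        f"no viable founder found in {max_redraws} draws "
        f"(c={cfg.c}, N_ER={cfg.N_ER}): configuration may be pathological"
    )


def make_null_founder(cfg, rng: np.random.Generator, max_redraws: int = 10_000) -> Founder:
    """No-regulation null founder: identity TF block, receptor rows with a
    single diagonal entry present with probability
    ``diagonal_receptor_density`` (redrawn until >= N_ER receptors)."""
    n_diag = min(cfg.N_R, cfg.N_TF)
    for _ in range(max_redraws):
        W = np.zeros((cfg.N, cfg.N_TF))
        W[np.arange(cfg.N_TF), np.arange(cfg.N_TF)] = 1.0
        present = rng.random(n_diag) < cfg.diagonal_receptor_density
        W[cfg.N_TF + np.arange(n_diag), np.arange(n_diag)] = present.astype(float)
        grn = GRN(W, cfg.N_TF, cfg.N_R)
        s0 = rng.integers(0, 2, size=cfg.N).astype(float)
        S, conv, _ = iterate_expression_batch(
            grn.W[None], s0, a=cfg.a, tol=cfg.stability_tol,
            window=cfg.stability_window, max_steps=cfg.max_expression_steps,
        )
        if not conv[0]:
            continue
        pheno = binarize_vector(S[0])
        if int(pheno[cfg.N_TF :].sum()) < cfg.N_ER:
            continue
        receptors = _distinct_receptor_set(cfg.N_R, cfg.L, rng)
        return Founder(Host(grn, receptors, pheno), s0)
    raise RuntimeError(
        f"no viable null-model founder found in {max_redraws} draws"
    )


def _distinct_receptor_set(n_r: int, L: int, rng: np.random.Generator) -> np.ndarray:
    while True:
        receptors = np.stack([random_sequence(L, rng) for _ in range(n_r)])
        if len({seq.tobytes() for seq in receptors}) == n_r:
            return receptors


# -- reproduction ------------------------------------------------------------


def spawn_candidates(
    Ws: np.ndarray,
    Rs: np.ndarray,
    n: int,
    cfg,
    rng: np.random.Generator,
    s0: np.ndarray,
    parent_pairs: np.ndarray | None = None,
):
    """Vectorized offspring generation from stacked parent genotypes.

    Parameters
    ----------
    Ws : ndarray (M, N, N_TF); Rs : ndarray (M, N_R, L)
        Parent pool genotypes.
    n : number of candidates to generate.
    parent_pairs : optional (n, 2) indices into the pool; drawn uniformly
        with replacement if omitted.  Under asexual reproduction only the
        first column is used.

    Returns
    -------
    dict with candidate arrays: ``W`` (n, N, N_TF), ``receptors`` (n, N_R, L),
    ``phenotype`` (n, N) uint8, ``converged`` (n,) bool, ``parents`` (n, 2).
    """
    M = Ws.shape[0]
    N, K = Ws.shape[1], Ws.shape[2]
    if parent_pairs is None:
        parent_pairs = rng.integers(0, M, size=(n, 2))
    pa, pb = parent_pairs[:, 0], parent_pairs[:, 1]
    if cfg.reproduction == "sexual":
        # free recombination: each gene's cis-row (and, for receptor genes,
        # its protein sequence) comes from a uniformly chosen parent
        from_a = rng.integers(0, 2, size=(n, N)).astype(bool)
        Wc = np.where(from_a[:, :, None], Ws[pa], Ws[pb])
        Rc = np.where(from_a[:, cfg.N_TF :, None], Rs[pa], Rs[pb])
    else:
        Wc = Ws[pa].copy()
        Rc = Rs[pa].copy()
    Rc = np.ascontiguousarray(Rc)

    # GRN mutation: one Bernoulli(mu) candidate event per offspring matrix
    rates = cfg.mutation_rates
    positions = cfg.mutation_positions
    hits = np.flatnonzero(rng.random(n) < rates.mu)
    for i in hits:
        apply_mutation_event(Wc[i], rates, rng, positions)

    # host protein mutation: one Bernoulli(mu_hp) event per receptor set,
    # flipping a single uniformly chosen (receptor, site) pair
    if cfg.per_site_protein_mutation:
        flips = rng.random(Rc.shape) < cfg.mu_hp
        Rc[flips] ^= 1
    else:
        hp_hits = np.flatnonzero(rng.random(n) < cfg.mu_hp)
        for i in hp_hits:
            r = int(rng.integers(cfg.N_R))
            site = int(rng.integers(cfg.L))
            Rc[i, r, site] ^= 1

    S, conv, _ = iterate_expression_batch(
        Wc, s0, a=cfg.a, tol=cfg.stability_tol,
        window=cfg.stability_window, max_steps=cfg.max_expression_steps,
    )
    return {
        "W": Wc,
        "receptors": Rc,
        "phenotype": binarize_vector(S),
        "converged": conv,
        "parents": parent_pairs,
    }


def reproduce(
    parentA: Host,
    parentB: Host | None,
    cfg,
    rng: np.random.Generator,
    s0: np.ndarray,
    compute_phenotype: bool = True,
) -> Candidate:
    """Produce one offspring candidate (sexual or asexual) with mutation.

    Sexual mode requires two parents and recombines freely gene-by-gene;
    asexual mode clones ``parentA``.  The phenotype is recomputed from the
    shared initial state ``s0`` unless ``compute_phenotype`` is False.
    """
    if cfg.reproduction == "sexual" and parentB is None:
        raise ValueError("sexual reproduction requires two parents")
    if parentB is None:
        parentB = parentA
    Ws = np.stack([parentA.grn.W, parentB.grn.W])
    Rs = np.stack([parentA.receptors, parentB.receptors])
    if compute_phenotype:
        out = spawn_candidates(
            Ws, Rs, 1, cfg, rng, s0, parent_pairs=np.array([[0, 1]])
        )
        return Candidate(
            GRN(out["W"][0], cfg.N_TF, cfg.N_R),
            out["receptors"][0],
            out["phenotype"][0],
            bool(out["converged"][0]),
        )
    # genotype only (no expression dynamics) -- used for recombination and
    # mutation statistics where the phenotype is irrelevant
    n, N = 1, cfg.N
    if cfg.reproduction == "sexual":
        from_a = rng.integers(0, 2, size=(n, N)).astype(bool)
        Wc = np.where(from_a[:, :, None], Ws[[0]], Ws[[1]])
        Rc = np.ascontiguousarray(np.where(from_a[:, cfg.N_TF :, None], Rs[[0]], Rs[[1]]))
    else:
        Wc, Rc = Ws[[0]].copy(), Rs[[0]].copy()
    rates = cfg.mutation_rates
    if rates.mu > 0 and rng.random() < rates.mu:
        apply_mutation_event(Wc[0], rates, rng, cfg.mutation_positions)
    if cfg.mu_hp > 0 and rng.random() < cfg.mu_hp:
        r = int(rng.integers(cfg.N_R))
        site = int(rng.integers(cfg.L))
        Rc[0, r, site] ^= 1
    return Candidate(GRN(Wc[0], cfg.N_TF, cfg.N_R), Rc[0], None, None)


def offspring_survival_probability(
    parentA_infected: bool, parentB_infected: bool | None, k_I: float
) -> float:
    """1 if both parents susceptible, k_I if both infected, (k_I + 1)/2 for
    one infected parent; asexual offspring use the single parent's status."""
    if not (0.0 < k_I <= 1.0):
        raise ValueError(f"k_I must be in (0, 1]; got {k_I}")
    if parentB_infected is None:
        return k_I if parentA_infected else 1.0
    n_inf = int(parentA_infected) + int(parentB_infected)
    return (1.0, (k_I + 1.0) / 2.0, k_I)[n_inf]


# -- burn-in -----------------------------------------------------------------


def stabilizing_burn_in(
    founder: Founder,
    cfg,
    rng: np.random.Generator,
    steps: int | None = None,
) -> list[Host]:
    """Evolve M_init clones of the founder at fixed size under stabilizing
    selection, generating within-population genetic diversity before any
    virus is introduced.

    Each step replaces the population with ``M_init`` accepted offspring.
    A candidate is accepted iff its expression dynamics converge, it
    expresses >= N_ER receptors, its phenotype is within Hamming distance 1
    of the founder phenotype, and it survives a Bernoulli trial with
    probability ``exp(-D / sigma)`` on receptor distance from the founder.
    """
    if steps is None:
        steps = cfg.burn_in_steps
    M = cfg.M_init
    founder_pheno = founder.host.phenotype.astype(np.int16)
    founder_R = founder.host.receptors.astype(np.int16)
    Ws = np.repeat(founder.host.grn.W[None], M, axis=0).copy()
    Rs = np.repeat(founder.host.receptors[None], M, axis=0).copy()
    phenos = np.repeat(founder.host.phenotype[None], M, axis=0).copy()
    max_attempts_per_step = 2000 * M
    for _ in range(steps):
        acc_W, acc_R, acc_P = [], [], []
        need = M
        attempts = 0
        while need > 0:
            batch = min(max(int(need * 1.7) + 8, 16), 4096)
            out = spawn_candidates(Ws, Rs, batch, cfg, rng, founder.s0)
            pheno = out["phenotype"]
            ok = out["converged"].copy()
            expr_R = pheno[:, cfg.N_TF :].astype(bool)
            ok &= expr_R.sum(axis=1) >= cfg.N_ER
            ok &= (
                np.abs(pheno.astype(np.int16) - founder_pheno).sum(axis=1) <= 1
            )
            if ok.any():
                idx = np.flatnonzero(ok)
                # receptor-sequence stabilizing selection, Bernoulli(exp(-D/sigma))
                diffs = np.abs(
                    out["receptors"][idx].astype(np.int16) - founder_R
                ).sum(axis=2)
                n_expr = expr_R[idx].sum(axis=1)
                D = (diffs * expr_R[idx]).sum(axis=1) / (n_expr * cfg.L)
                keep = rng.random(idx.size) < np.exp(-D / cfg.sigma)
                idx = idx[keep][:need]
                if idx.size:
                    acc_W.append(out["W"][idx])
                    acc_R.append(out["receptors"][idx])
                    acc_P.append(pheno[idx])
                    need -= idx.size
            attempts += batch
            if attempts > max_attempts_per_step and need > 0:
                raise RuntimeError(
                    "burn-in stalled: could not produce enough viable "
                    f"offspring in {attempts} attempts (need {need} more); "
                    "the configuration may be pathological"
                )
        Ws = np.concatenate(acc_W)
        Rs = np.concatenate(acc_R)
        phenos = np.concatenate(acc_P)
    return [
        Host(GRN(Ws[i], cfg.N_TF, cfg.N_R), Rs[i], phenos[i])
        for i in range(M)
    ]


# -- founder viruses ---------------------------------------------------------


def make_founder_viruses(
    hosts: list[Host],
    mu_vp: float,
    rng: np.random.Generator,
    count: int = 2,
    per_receptor: int | None = None,
) -> list[np.ndarray]:
    """Seed viruses copied from host receptor sequences, then mutated.

    Default: ``count`` viruses, each copied from a uniformly chosen host's
    uniformly chosen *expressed* receptor.  With ``per_receptor=k``, create
    ``k`` viruses per receptor index instead (each copied from a random host
    expressing that receptor), guaranteeing all receptors start targeted.
    """
    viruses: list[np.ndarray] = []
    if per_receptor is not None:
        n_r = hosts[0].receptors.shape[0]
        for ridx in range(n_r):
            expressing = [h for h in hosts if ridx in h.expressed_receptor_indices]
            pool = expressing if expressing else hosts
            for _ in range(per_receptor):
                h = pool[int(rng.integers(len(pool)))]
                viruses.append(mutate_sequence(h.receptors[ridx], mu_vp, rng))
        return viruses
    for _ in range(count):
        h = hosts[int(rng.integers(len(hosts)))]
        er = h.expressed_receptor_indices
        ridx = int(er[int(rng.integers(er.size))])
        viruses.append(mutate_sequence(h.receptors[ridx], mu_vp, rng))
    return viruses
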