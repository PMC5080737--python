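"""Receptor / virus binding-site sequences and the binding decision.

Binding sites are binary vectors of length ``L`` (0 = polar amino acid,
1 = hydrophobic).  A virus entry protein binds a host receptor when the
percentage of one-to-one matching positions exceeds the matching threshold
``eps_seqM``.  The same representation carries the stabilizing-selection
fitness used before coevolution: hosts whose expressed receptors drift away
from the founder sequences survive with probability ``exp(-D / sigma)``,
where ``D`` is the mean per-site L1 distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BindingPolicy",
    "ReceptorFitness",
    "random_sequence",
    "match_fraction",
    "binds",
    "binds_many",
    "mutate_sequence",
    "receptor_distance",
]


@dataclass(frozen=True)
class BindingPolicy:
    """Matching threshold, as a percentage.

    ``strict=True`` (default) requires the match percentage to strictly
    exceed ``eps_seqM``; the inclusive variant (``>=``) is provided because
    at short sequences the distinction is material (e.g. at L=10 and
    eps_seqM=90 the strict rule demands a perfect match).
    """

    eps_seqM: float = 90.0
    strict: bool = True

    def __post_init__(self):
        if not (0.0 < self.eps_seqM <= 100.0):
            raise ValueError(f"eps_seqM must be in (0, 100]; got {self.eps_seqM}")


def random_sequence(L: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 2, size=L, dtype=np.uint8)


def match_fraction(u: np.ndarray, v: np.ndarray) -> float:
    """Fraction of positions with identical bits."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError(f"sequence length mismatch: {u.shape} vs {v.shape}")
    return float(np.mean(u == v))


def binds(virus: np.ndarray, receptor: np.ndarray, policy: BindingPolicy) -> bool:
    pct = 100.0 * match_fraction(virus, receptor)
    return pct > policy.eps_seqM if policy.strict else pct >= policy.eps_seqM


def binds_many(
    virus: np.ndarray, receptors: np.ndarray, policy: BindingPolicy
) -> np.ndarray:
    """Vectorized :func:`binds` of one virus against rows of ``receptors``.

    Returns a boolean array of length ``receptors.shape[0]``.
    """
    receptors = np.asarray(receptors)
    if receptors.size == 0:
        return np.zeros(0, dtype=bool)
    pct = 100.0 * np.mean(receptors == np.asarray(virus), axis=1)
    return pct > policy.eps_seqM if policy.strict else pct >= policy.eps_seqM


def mutate_sequence(
    seq: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    per_site: bool = False,
) -> np.ndarray:
    """Return a (possibly) mutated copy of a binding sequence.

    Default (event model): with probability ``rate`` exactly one uniformly
    chosen position flips 0 <-> 1.  With ``per_site=True`` each position
    flips independently with probability ``rate`` instead.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must be in [0, 1]; got {rate}")
    out = np.asarray(seq).copy()
    if per_site:
        flips = rng.random(out.shape[0]) < rate
        out[flips] ^= 1
    elif rate > 0 and rng.random() < rate:
        i = int(rng.integers(out.shape[0]))
        out[i] ^= 1
    return out


def sequences_to_tsv(seqs: dict, path) -> None:
    """Write binding sequences as a two-column TSV (id, '0'/'1' string)."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f"{name}\t{''.join(str(int(b)) for b in np.asarray(seq))}\n")


def sequences_from_tsv(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, s = line.partition("\t")
            out[name] = np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")
    return out


@dataclass(frozen=True)
class ReceptorFitness:
    """Stabilizing-selection fitness from receptor-sequence divergence."""

    D: float
    sigma: float
    f: float


def receptor_distance(
    expressed: np.ndarray,
    founder: np.ndarray,
    sigma: float = 0.1,
) -> ReceptorFitness:
    """Mean per-site L1 distance of expressed receptors from the founder.

    Parameters
    ----------
    expressed : ndarray (m, L)
        Sequences of the host's *expressed* receptors.
    founder : ndarray (m, L)
        The founder sequences of the same receptors, row-aligned.

    Returns
    -------
    ReceptorFitness with ``D = sum |a - a_f| / (m * L)`` and
    ``f = exp(-D / sigma)``.
    """
    expressed = np.atleast_2d(np.asarray(expressed))
    founder = np.atleast_2d(np.asarray(founder))
    if expressed.shape != founder.shape:
        raise ValueError(
            f"shape mismatch: {expressed.shape} vs {founder.shape}"
        )
    if expressed.shape[0] == 0:
        raise ValueError("no expressed receptors: fitness undefined (nonviable)")
    D = float(
        np.abs(expressed.astype(np.int8) - founder.astype(np.int8)).sum()
        / expressed.size
    )
    return ReceptorFitness(D=D, sigma=sigma, f=float(np.exp(-D / sigma)))
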