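"""Gene regulatory network core.

A host's regulatory genotype is a real-valued interaction matrix ``W`` of
shape ``N x N_TF``: row *i* holds the cis-regulatory region of gene *i*, and
only transcription-factor (TF) gene products act as regulators.  The first
``N_TF`` rows are TF genes, the remaining ``N_R`` rows are receptor genes
(``N = N_TF + N_R``).  Expression dynamics follow the discrete map

    S(t+1) = Sig(W . S_TF(t)),    Sig(x) = 1 / (1 + exp(-a x))

iterated from a binary initial state until a steady state is reached, after
which expression is binarized (``phi(x) = 1`` iff ``x > 0.5``) to give the
phenotype ``S_hat``.  Mutations add, delete, or redraw single interactions at
rates chosen so the expected network density stays at the founder value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRN",
    "ExpressionState",
    "Phenotype",
    "GRNMutationRates",
    "addition_rate_for_balance",
    "sigmoid",
    "iterate_expression",
    "iterate_expression_batch",
    "binarize",
    "binarize_vector",
    "mutate_network",
    "density",
]

#: sigmoid steepness; large values make expression nearly switch-like
DEFAULT_STEEPNESS = 100.0

#: steady-state declaration: max |S(t+1) - S(t)| below this ...
STABILITY_TOL = 1e-4
#: ... for this many consecutive updates ...
STABILITY_WINDOW = 10
#: ... within this many updates overall
MAX_EXPRESSION_STEPS = 100


def sigmoid(x, a: float = DEFAULT_STEEPNESS):
    """Map regulatory input to an expression level in (0, 1).

    Computed in the numerically stable branch form so that extreme inputs
    saturate to 0/1 without overflow.  ``sigmoid(0) == 0.5`` exactly (basal,
    unregulated expression).
    """
    ax = np.asarray(x, dtype=float) * a
    out = np.empty_like(ax)
    pos = ax >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-ax[pos]))
    ez = np.exp(ax[~pos])
    out[~pos] = ez / (1.0 + ez)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class GRN:
    """Regulatory interaction matrix with its gene-block structure.

    Parameters
    ----------
    W : ndarray of shape (N, N_TF)
        Regulatory weights; ``W[i, j]`` is regulation of gene *i* by TF *j*
        (positive = activation, negative = inhibition, zero = none).
    N_TF, N_R : int
        Number of transcription-factor and receptor genes.
    """

    W: np.ndarray
    N_TF: int
    N_R: int

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        if W.ndim != 2 or W.shape != (self.N_TF + self.N_R, self.N_TF):
            raise ValueError(
                f"W must have shape (N, N_TF) = ({self.N_TF + self.N_R}, "
                f"{self.N_TF}); got {W.shape}"
            )

    @property
    def N(self) -> int:
        return self.N_TF + self.N_R

    @property
    def density(self) -> float:
        return float(np.count_nonzero(self.W) / self.W.size)

    def copy(self) -> "GRN":
        return GRN(self.W.copy(), self.N_TF, self.N_R)

    @classmethod
    def random(cls, N_TF: int, N_R: int, c: float, rng: np.random.Generator) -> "GRN":
        """Founder network: exactly ``round(c * N * N_TF)`` entries nonzero,
        placed uniformly at random, each drawn from Normal(0, 1)."""
        N = N_TF + N_R
        n_cells = N * N_TF
        k = int(round(c * n_cells))
        W = np.zeros(n_cells)
        pos = rng.choice(n_cells, size=k, replace=False)
        W[pos] = _nonzero_normal(rng, size=k)
        return cls(W.reshape(N, N_TF), N_TF, N_R)

    # -- plain-text serialization ------------------------------------------

    def to_tsv(self, path) -> None:
        header = (
            f"# N={self.N}\tN_TF={self.N_TF}\tN_R={self.N_R}"
            f"\tc={self.density:.6g}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for row in self.W:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "GRN":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if "=" in tok:
                            k, v = tok.split("=", 1)
                            meta[k] = v
                    continue
                rows.append([float(v) for v in line.split("\t")])
        W = np.array(rows, dtype=float)
        n_tf = int(meta.get("N_TF", W.shape[1]))
        n_r = int(meta.get("N_R", W.shape[0] - n_tf))
        return cls(W, n_tf, n_r)


def density(grn: GRN) -> float:
    """Fraction of nonzero entries of W."""
    return grn.density


@dataclass
class ExpressionState:
    """Outcome of iterating the expression map from an initial state."""

    S: np.ndarray
    N_TF: int
    converged: bool
    steps_taken: int

    @property
    def S_TF(self) -> np.ndarray:
        return self.S[: self.N_TF]

    @property
    def S_R(self) -> np.ndarray:
        return self.S[self.N_TF :]


@dataclass(frozen=True)
class Phenotype:
    """Binarized steady-state expression; 1 = gene on."""

    expr: np.ndarray
    N_TF: int

    @property
    def expressed_receptors(self) -> np.ndarray:
        """Receptor indices (0-based within the receptor block) that are on."""
        return np.flatnonzero(self.expr[self.N_TF :])


@dataclass(frozen=True)
class GRNMutationRates:
    """Per-offspring network mutation model.

    One candidate mutation event occurs per offspring matrix with probability
    ``mu``; a uniformly random entry is picked.  Zero entries become a fresh
    Normal(0,1) draw with probability ``rho`` (addition); nonzero entries are
    zeroed with probability ``phi`` (deletion) or redrawn otherwise
    (``delta = 1 - phi``, modification).  Choosing ``rho (1 - c) = phi c``
    makes the expected density drift vanish at founder density ``c``.
    """

    mu: float = 0.1
    rho: float = 0.028
    phi: float = 0.042
    delta: float = 0.958

    def __post_init__(self):
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mu must be in [0, 1]; got {self.mu}")
        for name in ("rho", "phi", "delta"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]; got {v}")
        if abs(self.phi + self.delta - 1.0) > 1e-9:
            raise ValueError(
                f"phi + delta must equal 1; got {self.phi} + {self.delta}"
            )

    def density_drift(self, c: float) -> float:
        """Expected per-event change in nonzero count, up to the mu/(N*N_TF)
        prefactor: rho (1 - c) - phi c."""
        return self.rho * (1.0 - c) - self.phi * c

    @classmethod
    def balanced(cls, c: float, phi: float, mu: float = 0.1) -> "GRNMutationRates":
        rho = addition_rate_for_balance(c, phi)
        return cls(mu=mu, rho=rho, phi=phi, delta=1.0 - phi)


def addition_rate_for_balance(c: float, phi: float) -> float:
    """Solve ``rho (1 - c) - phi c = 0`` for the conditional addition rate."""
    if not (0.0 < c < 1.0):
        raise ValueError("density must be strictly between 0 and 1")
    return phi * c / (1.0 - c)


# -- expression dynamics ---------------------------------------------------


def iterate_expression_batch(
    W: np.ndarray,
    s0: np.ndarray,
    a: float = DEFAULT_STEEPNESS,
    tol: float = STABILITY_TOL,
    window: int = STABILITY_WINDOW,
    max_steps: int = MAX_EXPRESSION_STEPS,
):
    """Vectorized expression dynamics for a batch of networks.

    Parameters
    ----------
    W : ndarray (B, N, N_TF)
    s0 : ndarray (N,) or (B, N)
        Initial expression state(s), shared or per-individual.

    Returns
    -------
    S : ndarray (B, N) final expression levels
    converged : ndarray (B,) bool
    steps : ndarray (B,) updates applied per individual
    """
    W = np.asarray(W, dtype=float)
    B, N, K = W.shape
    S = np.array(np.broadcast_to(np.asarray(s0, dtype=float), (B, N)))
    stable = np.zeros(B, dtype=np.int64)
    steps = np.zeros(B, dtype=np.int64)
    active = np.ones(B, dtype=bool)
    for _ in range(max_steps):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Sa = S[idx]
        new = sigmoid(np.einsum("bnk,bk->bn", W[idx], Sa[:, :K]), a)
        delta = np.max(np.abs(new - Sa), axis=1)
        S[idx] = new
        steps[idx] += 1
        stable[idx] = np.where(delta < tol, stable[idx] + 1, 0)
        done = stable[idx] >= window
        if done.any():
            active[idx[done]] = False
    return S, stable >= window, steps


def iterate_expression(
    grn: GRN,
    s0: np.ndarray,
    max_steps: int = MAX_EXPRESSION_STEPS,
    a: float = DEFAULT_STEEPNESS,
    tol: float = STABILITY_TOL,
    window: int = STABILITY_WINDOW,
) -> ExpressionState:
    """Run the expression map to steady state for a single network.

    Convergence is declared when the maximum absolute elementwise change
    between consecutive states stays below ``tol`` for ``window`` consecutive
    updates; otherwise ``converged`` is False after ``max_steps``.
    """
    s0 = np.asarray(s0, dtype=float)
    if s0.shape != (grn.N,):
        raise ValueError(f"s0 must have length N={grn.N}; got shape {s0.shape}")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    S, conv, steps = iterate_expression_batch(
        grn.W[None], s0, a=a, tol=tol, window=window, max_steps=max_steps
    )
    return ExpressionState(S[0], grn.N_TF, bool(conv[0]), int(steps[0]))


def binarize_vector(S: np.ndarray) -> np.ndarray:
    """phi(x): 0 if x <= 0.5, 1 if x > 0.5, elementwise."""
    return (np.asarray(S) > 0.5).astype(np.uint8)


def binarize(state: ExpressionState) -> Phenotype:
    """Binarize a *converged* expression state into the phenotype S_hat."""
    if not state.converged:
        raise ValueError("cannot binarize a non-converged expression state")
    return Phenotype(binarize_vector(state.S), state.N_TF)


# -- mutation --------------------------------------------------------------


def _nonzero_normal(rng: np.random.Generator, size=None, exclude: float = 0.0):
    """Normal(0,1) draw conditioned on being != 0 and != ``exclude``
    (probability-zero rejections, kept for formal compliance)."""
    while True:
        v = rng.standard_normal(size)
        if size is None:
            if v != 0.0 and v != exclude:
                return float(v)
        else:
            bad = (v == 0.0) | (v == exclude)
            if not bad.any():
                return v
            v[bad] = rng.standard_normal(int(bad.sum()))
            if not ((v == 0.0) | (v == exclude)).any():
                return v


def apply_mutation_event(
    W: np.ndarray,
    rates: GRNMutationRates,
    rng: np.random.Generator,
    positions: np.ndarray | None = None,
) -> None:
    """In-place single candidate mutation event on ``W`` (already Bernoulli-
    gated by the caller on ``rates.mu``).

    ``positions`` optionally restricts the candidate entries to an array of
    ``(row, col)`` pairs (used by the no-regulation null model, where only
    the receptor-diagonal entries may mutate).
    """
    if positions is None:
        n, k = W.shape
        i = int(rng.integers(n))
        j = int(rng.integers(k))
    else:
        i, j = positions[int(rng.integers(len(positions)))]
    w = W[i, j]
    if w == 0.0:
        if rng.random() < rates.rho:
            W[i, j] = _nonzero_normal(rng)
    else:
        if rng.random() < rates.phi:
            W[i, j] = 0.0
        else:
            W[i, j] = _nonzero_normal(rng, exclude=w)


def mutate_network(
    grn: GRN,
    rates: GRNMutationRates,
    rng: np.random.Generator,
    positions: np.ndarray | None = None,
) -> GRN:
    """Return a copy of ``grn`` with at most one mutation event applied.

    With probability ``rates.mu`` a uniformly random entry is selected and
    mutated (addition / deletion / modification, see
    :class:`GRNMutationRates`); the input network is never modified.
    """
    W = grn.W.copy()
    if rates.mu > 0 and rng.random() < rates.mu:
        apply_mutation_event(W, rates, rng, positions)
    return GRN(W, grn.N_TF, grn.N_R)
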