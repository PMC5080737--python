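"""Run configuration: every model parameter in one validated record."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .binding import BindingPolicy
from .grn import GRNMutationRates

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All parameters of a simulation run.

    Individual-level parameters
    ---------------------------
    L : binding-site length (receptor binding complexity)
    mu_hp : host protein mutation rate, per set of receptors per offspring
    mu_vp : virus protein mutation rate, per protein per contact
    N_TF, N_R : transcription-factor and receptor gene counts (N = N_TF + N_R)
    N_ER : minimum number of expressed receptors for viability
    eps_seqM : matching threshold for receptor binding, in percent
    c : founder network density; mu, rho, phi, delta : GRN mutation rates
    sigma : stabilizing-selection strength on receptor sequences
    a : sigmoid steepness of the expression map

    Population-level parameters
    ---------------------------
    k_I : offspring survival probability when both parents are infected
    K : carrying capacity; M_init : initial (burn-in) population size
    b : growth rate; lambda_N / lambda_D : natural / disease death rates
    gamma : recovery rate; r : contact rate

    Run structure
    -------------
    burn_in_steps / coevolution_steps : phase lengths
    founder_virus_count : number of founder viruses introduced
    founder_viruses_per_receptor : if set, instead create this many founder
        viruses per receptor index (e.g. 3 per receptor -> 15 total)
    measurement_interval : cadence of targeting / diversity measurements
    potential_assays : also run the (expensive) resistance-potential
        perturbation assays at each measurement point
    null_model : replace the founder GRN by the no-regulation diagonal
        network and restrict GRN mutations to the receptor diagonal
    """

    # individual level
    L: int = 10
    mu_hp: float = 0.01
    mu_vp: float = 0.1
    N_TF: int = 5
    N_R: int = 5
    N_ER: int = 1
    eps_seqM: float = 90.0
    strict_binding: bool = True
    c: float = 0.4
    mu: float = 0.1
    rho: float = 0.028
    phi: float = 0.042
    delta: float = 0.958
    sigma: float = 0.1
    a: float = 100.0
    per_site_protein_mutation: bool = False

    # population level
    k_I: float = 0.8
    K: int = 1000
    M_init: int = 150
    b: float = 0.15
    lambda_N: float = 0.09
    lambda_D: float = 0.06
    gamma: float = 0.2
    r: float = 2.0

    # run structure
    burn_in_steps: int = 500
    coevolution_steps: int = 500
    founder_virus_count: int = 2
    founder_viruses_per_receptor: int | None = None
    reproduction: str = "sexual"
    rounding: str = "stochastic"
    measurement_interval: int = 50
    steady_state_window: int = 250
    potential_assays: bool = False
    assay_trials: int = 50
    null_model: bool = False
    diagonal_receptor_density: float = 0.7

    # numerics of the expression map
    stability_tol: float = 1e-4
    stability_window: int = 10
    max_expression_steps: int = 100

    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- derived views ------------------------------------------------------

    @property
    def N(self) -> int:
        return self.N_TF + self.N_R

    @property
    def mutation_rates(self) -> GRNMutationRates:
        return GRNMutationRates(self.mu, self.rho, self.phi, self.delta)

    @property
    def binding_policy(self) -> BindingPolicy:
        return BindingPolicy(self.eps_seqM, self.strict_binding)

    @property
    def mutation_positions(self) -> np.ndarray | None:
        """Entries eligible for GRN mutation (receptor diagonal only under
        the null model; everything otherwise)."""
        if not self.null_model:
            return None
        return np.array(
            [(self.N_TF + k, k) for k in range(min(self.N_R, self.N_TF))],
            dtype=np.int64,
        )

    def validate(self) -> None:
        errors = []
        positive_int = [
            "L", "N_TF", "N_R", "K", "M_init", "burn_in_steps",
            "measurement_interval", "stability_window", "max_expression_steps",
        ]
        for name in positive_int:
            if getattr(self, name) < 1:
                errors.append(f"{name} must be >= 1")
        if self.coevolution_steps < 0:
            errors.append("coevolution_steps must be >= 0")
        if not (1 <= self.N_ER <= self.N_R):
            errors.append(f"N_ER must be in [1, N_R={self.N_R}]")
        rates01 = [
            "mu_hp", "mu_vp", "mu", "rho", "phi", "delta",
            "b", "lambda_N", "lambda_D", "gamma",
        ]
        for name in rates01:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errors.append(f"{name} must be in [0, 1]; got {v}")
        if not (0.0 < self.k_I <= 1.0):
            errors.append(f"k_I must be in (0, 1]; got {self.k_I}")
        if not (0.0 < self.eps_seqM <= 100.0):
            errors.append(f"eps_seqM must be in (0, 100]; got {self.eps_seqM}")
        if not (0.0 < self.c < 1.0):
            errors.append(f"c must be in (0, 1); got {self.c}")
        if self.r < 0:
            errors.append("r must be >= 0")
        if self.sigma <= 0:
            errors.append("sigma must be > 0")
        if self.a <= 0:
            errors.append("a must be > 0")
        if abs(self.phi + self.delta - 1.0) > 1e-9:
            errors.append(
                f"phi + delta must equal 1; got {self.phi} + {self.delta}"
            )
        if abs(self.rho * (1.0 - self.c) - self.phi * self.c) > 1e-9:
            errors.append(
                "rho(1-c) - phi*c must be 0 (zero expected density drift); "
                f"got rho={self.rho}, phi={self.phi}, c={self.c}"
            )
        if self.reproduction not in ("sexual", "asexual"):
            errors.append("reproduction must be 'sexual' or 'asexual'")
        if self.rounding not in ("stochastic", "round"):
            errors.append("rounding must be 'stochastic' or 'round'")
        if not (0.0 <= self.diagonal_receptor_density <= 1.0):
            errors.append("diagonal_receptor_density must be in [0, 1]")
        if self.founder_viruses_per_receptor is not None:
            if self.founder_viruses_per_receptor < 1:
                errors.append("founder_viruses_per_receptor must be >= 1")
        elif self.founder_virus_count < 1:
            errors.append("founder_virus_count must be >= 1")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    # -- flat key = value round trip ----------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.to_dict().items():
                fh.write(f"{k} = {v}\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        raw = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                raw[k.strip()] = v.strip()
        return cls.from_strings(raw)

    @classmethod
    def from_strings(cls, raw: dict) -> "RunConfig":
        """Build a config from string values (CLI flags / config file)."""
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(fields)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for name, val in raw.items():
            if isinstance(val, str):
                val = _parse_value(val)
            kwargs[name] = val
        return cls(**kwargs)


def _parse_value(s: str):
    low = s.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("none", ""):
        return None
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        return s
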