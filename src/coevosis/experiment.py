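"""Run orchestration: burn-in, virus introduction, coevolution, metrics.

A run is fully determined by a :class:`~coevosis.config.RunConfig`
(including its seed): the founder host is drawn, the population burns in
under stabilizing selection, founder viruses are copied from host receptors
and seeded into the population, and the SIS coevolution loop runs for a
fixed number of steps with targeting/diversity measurements on a fixed
cadence.  Sweeps run independently seeded replicates over a parameter grid.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics
from .config import RunConfig
from .epidemic import PopulationState, StepLedger, ledgers_to_frame, step_epidemic
from .individuals import (
    Founder,
    make_founder_host,
    make_founder_viruses,
    make_null_founder,
)
from .individuals import stabilizing_burn_in

__all__ = ["RunResult", "run_simulation", "run_null_model", "run_sweep",
           "founder_virus_experiment", "seed_infections"]


@dataclass
class RunResult:
    """Everything a single run produced."""

    config: RunConfig
    ledgers: list[StepLedger]
    records: list[dict]          # cadence measurements (diversity, assays)
    summary: dict
    state: PopulationState
    founder: Founder
    extinct: bool
    excluded: bool               # mean population size <= M_init

    def ledger_frame(self) -> pd.DataFrame:
        return ledgers_to_frame(self.ledgers)

    def metrics_frame(self) -> pd.DataFrame:
        """Tidy (step, metric, value) table of cadence measurements."""
        rows = []
        for rec in self.records:
            step = rec["step"]
            for k, v in rec.items():
                if k != "step":
                    rows.append({"step": step, "metric": k, "value": v})
        return pd.DataFrame(rows, columns=["step", "metric", "value"])

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.config.save(outdir / "config.txt")
        self.ledger_frame().to_csv(outdir / "ledger.csv", index=False)
        self.metrics_frame().to_csv(outdir / "metrics.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, default=float)
        snapshot_to_tsv(self.state, outdir / "population.tsv")


def snapshot_to_tsv(state: PopulationState, path) -> None:
    """One row per host: id, status, phenotype bits, receptors, flattened W."""
    with open(path, "w") as fh:
        fh.write("id\tstatus\tphenotype\treceptors\tW\n")
        hosts = [("S", h) for h in state.susceptible] + [
            ("I", h) for h in state.infected
        ]
        for i, (status, h) in enumerate(hosts):
            pheno = "".join(map(str, h.phenotype))
            recs = ";".join("".join(map(str, r)) for r in h.receptors)
            w = ";".join(repr(float(v)) for v in h.grn.W.ravel())
            fh.write(f"{i}\t{status}\t{pheno}\t{recs}\t{w}\n")


def seed_infections(
    state: PopulationState,
    viruses: list[np.ndarray],
    cfg,
    rng: np.random.Generator,
) -> int:
    """Place each founder virus into one susceptible host by contact.

    Each virus attempts contacts with uniformly random susceptibles (without
    the on-contact mutation, so the founder sequence is placed as created)
    until it binds one of the host's expressed receptors, capped at
    ``10 * M_init`` attempts.  Returns the number of viruses placed.
    """
    policy = cfg.binding_policy
    placed = 0
    from .binding import binds_many

    for virus in viruses:
        cap = 10 * cfg.M_init
        for _ in range(cap):
            if not state.susceptible:
                break
            si = int(rng.integers(len(state.susceptible)))
            host = state.susceptible[si]
            er = host.expressed_receptor_indices
            if er.size and binds_many(virus, host.receptors[er], policy).any():
                state.susceptible[si] = state.susceptible[-1]
                state.susceptible.pop()
                host.virus = virus.copy()
                state.infected.append(host)
                placed += 1
                break
    return placed


def run_simulation(cfg: RunConfig) -> RunResult:
    """Full pipeline: founder -> burn-in -> founder viruses -> coevolution.

    Deterministic given the config (seed included): the seed is split into
    independent sub-streams for the burn-in, the epidemic, and the
    measurement assays so that optional assays never perturb the simulated
    trajectory.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_burn, rng_epi, rng_assay = (np.random.default_rng(s) for s in ss.spawn(3))

    founder = (make_null_founder if cfg.null_model else make_founder_host)(
        cfg, rng_burn
    )
    hosts = stabilizing_burn_in(founder, cfg, rng_burn)

    if cfg.founder_viruses_per_receptor is not None:
        viruses = make_founder_viruses(
            hosts, cfg.mu_vp, rng_epi,
            per_receptor=cfg.founder_viruses_per_receptor,
        )
    else:
        viruses = make_founder_viruses(
            hosts, cfg.mu_vp, rng_epi, count=cfg.founder_virus_count
        )
    state = PopulationState(susceptible=hosts, infected=[])
    seed_infections(state, viruses, cfg, rng_epi)

    ledgers: list[StepLedger] = []
    records: list[dict] = []
    extinct = False
    for t in range(cfg.coevolution_steps):
        if state.N == 0:
            extinct = True
            break
        led = step_epidemic(state, cfg, rng_epi, founder.s0, t=t)
        ledgers.append(led)
        if (t + 1) % cfg.measurement_interval == 0:
            rec = {"step": t + 1}
            rec.update(metrics.diversity_record(state.susceptible))
            inf_div = metrics.diversity_record(state.infected)
            rec.update({f"infected_{k}": v for k, v in inf_div.items()})
            if cfg.potential_assays:
                carried = [h.virus for h in state.infected if h.virus is not None]
                rec["grn_resistance_potential"] = metrics.grn_resistance_potential(
                    state.susceptible, carried, cfg, founder.s0, rng_assay,
                    trials=cfg.assay_trials,
                )
                rec["protein_resistance_potential"] = (
                    metrics.protein_resistance_potential(
                        state.susceptible, carried, cfg.mu_hp, cfg, rng_assay,
                        trials=cfg.assay_trials,
                    )
                )
                rec["multi_switch_ability"] = metrics.multi_switch_ability(
                    state.susceptible, cfg, founder.s0, rng_assay,
                    trials=cfg.assay_trials,
                )
            records.append(rec)

    summary = summarize(cfg, ledgers, records, state, extinct)
    return RunResult(
        config=cfg, ledgers=ledgers, records=records, summary=summary,
        state=state, founder=founder, extinct=extinct,
        excluded=bool(summary["excluded"]),
    )


def summarize(cfg, ledgers, records, state, extinct) -> dict:
    """Run-level metrics and the analysis-exclusion flag."""
    if ledgers:
        mean_N = float(np.mean([led.S_end + led.I_end for led in ledgers]))
        if len(ledgers) >= cfg.measurement_interval:
            y = metrics.targeting_vector(ledgers, cfg.measurement_interval)
            gini_val = metrics.gini(y) if y.sum() > 0 else float("nan")
        else:
            gini_val = float("nan")
        multi = metrics.multi_receptor_frequency(ledgers, cfg.measurement_interval)
        xi_bar = metrics.steady_state_transmissibility(
            ledgers, cfg.steady_state_window
        )
        rew = metrics.rewiring_preference(ledgers)
        total_inf = int(sum(led.infections for led in ledgers))
    else:
        mean_N = 0.0
        gini_val = multi = xi_bar = float("nan")
        rew = metrics.RewiringResult(None, float("nan"), 0)
        total_inf = 0
    return {
        "seed": cfg.seed,
        "mean_population": mean_N,
        "excluded": bool(mean_N <= cfg.M_init),
        "extinct": bool(extinct),
        "disease_free": bool(len(state.infected) == 0),
        "total_infections": total_inf,
        "steady_state_xi": xi_bar,
        "targeting_gini": gini_val,
        "multi_receptor_frequency": multi,
        "rewiring_fraction": rew.rewiring_fraction,
        "prefers_rewiring": rew.prefers_rewiring,
        "resistance_events": rew.n_events,
        "final_S": len(state.susceptible),
        "final_I": len(state.infected),
    }


def run_null_model(cfg: RunConfig) -> RunResult:
    """Run with the no-regulation diagonal network in place of the GRN."""
    return run_simulation(cfg.replace(null_model=True))


def _child_seeds(base_seed: int, n: int) -> list[int]:
    """Independent sub-seeds (< 2**31) for replicate isolation."""
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def run_sweep(
    base_cfg: RunConfig,
    grid: dict[str, list],
    replicates: int,
    base_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Independent seeded replicates over a parameter grid.

    Returns (per-run table, per-cell aggregate of means and standard
    deviations over non-excluded runs).  Failures are recorded per cell and
    the sweep continues.
    """
    keys = list(grid)
    rows = []
    cells = list(itertools.product(*(grid[k] for k in keys))) or [()]
    for ci, cell in enumerate(cells):
        overrides = dict(zip(keys, cell))
        seeds = _child_seeds(base_seed + ci, replicates)
        for rep, seed in enumerate(seeds):
            row = {**overrides, "replicate": rep, "seed": seed}
            try:
                res = run_simulation(base_cfg.replace(seed=seed, **overrides))
                row.update(res.summary)
                row["failed"] = False
            except Exception as exc:  # pragma: no cover - defensive
                row["failed"] = True
                row["error"] = str(exc)
            rows.append(row)
    runs = pd.DataFrame(rows)
    ok = runs[~runs["failed"]]
    included = ok[~ok["excluded"].astype(bool)] if len(ok) else ok
    if len(included) == 0:
        included = ok
    metric_cols = [
        c for c in (
            "steady_state_xi", "targeting_gini", "multi_receptor_frequency",
            "rewiring_fraction", "mean_population",
        ) if c in included.columns
    ]
    if keys and len(included):
        agg = included.groupby(keys)[metric_cols].agg(["mean", "std"])
        agg.columns = ["_".join(c) for c in agg.columns]
        agg = agg.reset_index()
        counts = runs.groupby(keys).agg(
            n_runs=("failed", "size"),
            n_excluded=("excluded", lambda s: int(pd.Series(s).fillna(True).sum())),
        ).reset_index()
        agg = agg.merge(counts, on=keys)
    else:
        agg = included[metric_cols].agg(["mean", "std"]).T.reset_index()
    return runs, agg


def founder_virus_experiment(
    L: int,
    mu_hp: float = 0.002,
    replicates: int = 10,
    base_seed: int = 0,
    viruses_per_receptor: int = 3,
    **overrides,
) -> pd.DataFrame:
    """Diverse-founder-virus experiment: one founder virus triple per receptor.

    Runs ``replicates`` independently seeded simulations with
    ``viruses_per_receptor`` founder viruses per receptor (15 in total for
    the default 5 receptors), at the given binding complexity ``L`` and host
    protein mutation rate.  Returns the per-run summary table; the headline
    quantities are the multi-receptor targeting window frequency and the
    Gini coefficient of per-receptor newly-infected counts.
    """
    rows = []
    for seed in _child_seeds(base_seed, replicates):
        cfg = RunConfig(
            L=L, mu_hp=mu_hp, seed=seed,
            founder_viruses_per_receptor=viruses_per_receptor,
            **overrides,
        )
        res = run_simulation(cfg)
        rows.append(res.summary)
    return pd.DataFrame(rows)


def founder_virus_summary(df: pd.DataFrame) -> dict:
    """Aggregate a founder-virus experiment table across replicates.

    Runs failing the analysis-inclusion rule (mean population size <= M_init)
    are dropped before averaging, falling back to all runs when fewer than
    two pass it.
    """
    included = df[~df["excluded"].astype(bool)]
    if len(included) < 2:
        included = df
    multi = included["multi_receptor_frequency"].astype(float)
    gini_vals = included["targeting_gini"].astype(float)
    return {
        "multi_receptor_frequency": float(np.nanmean(multi)),
        "multi_receptor_frequency_sd": float(np.nanstd(multi, ddof=1)),
        "targeting_gini": float(np.nanmean(gini_vals)),
        "targeting_gini_sd": float(np.nanstd(gini_vals, ddof=1)),
        "n_included": int(len(included)),
        "n_runs": int(len(df)),
    }
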