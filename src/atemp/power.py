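"""Monte-Carlo harness: rejection rates over scenario grids.

A "cell" is one simulation scenario evaluated with one or more test
methods: ``reps`` cohorts are simulated, each method's statistic is
computed on the same cohorts (pairing the comparison), and the proportion
of asymptotic p-values below ``alpha`` is the estimated power (or type-I
error when the scenario is null).  Simulation and testing are vectorized
across replicates and processed in chunks to bound memory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import SimulationScenario, simulate_batch
from .stats import batch_score_statistics
from .transforms import METHODS, apply_method_batch

__all__ = ["HarnessSummary", "run_power_cell", "run_methods_cell", "run_grid",
           "plot_power_curves"]

logger = logging.getLogger("atemp")

#: target number of scalar phenotype values simulated per chunk
_CHUNK_BUDGET = 2e7


@dataclass(frozen=True)
class HarnessSummary:
    """Rejection proportion with Monte-Carlo standard error for one cell."""

    scenario: SimulationScenario
    method: str
    reps: int
    alpha: float
    rejections: int
    rejection_rate: float
    mc_se: float


def _chunk_sizes(reps: int, n: int, k: int) -> list[int]:
    chunk = max(1, min(reps, int(_CHUNK_BUDGET / (n * k))))
    sizes = [chunk] * (reps // chunk)
    if reps % chunk:
        sizes.append(reps % chunk)
    return sizes


def run_methods_cell(scenario: SimulationScenario, methods: Sequence[str],
                     reps: int = 1000, alpha: float = 5e-4,
                     seed: int = 0) -> list[HarnessSummary]:
    """Estimate rejection rates of several methods on shared simulated data.

    All methods are evaluated on the same ``reps`` simulated cohorts, so
    between-method power differences are not diluted by simulation noise.
    Deterministic for fixed ``seed``.  The rejection rule is strict:
    p < alpha.
    """
    if reps < 50:
        raise ValueError("use at least 50 replicates per cell")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    rng = np.random.default_rng(seed)
    counts = {m: 0 for m in methods}
    k = scenario.k
    for chunk in _chunk_sizes(reps, scenario.n, k):
        g, y = simulate_batch(scenario, chunk, rng)
        for m in methods:
            stat = batch_score_statistics(apply_method_batch(y, m), g)
            pvals = sps.chi2.sf(stat, k)
            counts[m] += int(np.count_nonzero(pvals < alpha))
    out = []
    for m in methods:
        rate = counts[m] / reps
        out.append(HarnessSummary(
            scenario=scenario, method=m, reps=reps, alpha=alpha,
            rejections=counts[m], rejection_rate=rate,
            mc_se=float(np.sqrt(rate * (1.0 - rate) / reps)),
        ))
    return out


def run_power_cell(scenario: SimulationScenario, method: str = "multiphen",
                   reps: int = 1000, alpha: float = 5e-4,
                   seed: int = 0) -> HarnessSummary:
    """Single-method convenience wrapper around :func:`run_methods_cell`."""
    return run_methods_cell(scenario, [method], reps=reps, alpha=alpha,
                            seed=seed)[0]


_SCENARIO_KEYS = {"kind", "n", "maf", "error_dist", "beta_g1", "beta_g2", "r",
                  "n_phenotypes", "a", "h2", "ar_rho"}


def _parse_scenario(entry, path: str) -> SimulationScenario:
    if not isinstance(entry, dict):
        raise ValueError(f"{path}: expected a mapping of scenario fields")
    unknown = set(entry) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown field(s) {sorted(unknown)}; "
                         f"allowed: {sorted(_SCENARIO_KEYS)}")
    try:
        return SimulationScenario(**entry)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def run_grid(config: dict) -> pd.DataFrame:
    """Run every scenario x method cell of a grid configuration.

    ``config`` is a mapping (typically loaded from YAML) with keys:

    * ``scenarios`` — list of scenario field mappings (required);
    * ``methods`` — list of method labels (default: all three);
    * ``reps`` (default 1000), ``alpha`` (default 5e-4), ``seed`` (default 0).

    Returns a tidy DataFrame with one row per scenario x method.
    """
    if not isinstance(config, dict):
        raise ValueError("config: expected a mapping")
    if "scenarios" not in config or not isinstance(config["scenarios"], list):
        raise ValueError("config.scenarios: required and must be a list")
    methods = config.get("methods", list(METHODS))
    if not isinstance(methods, list):
        raise ValueError("config.methods: must be a list of method labels")
    reps = int(config.get("reps", 1000))
    alpha = float(config.get("alpha", 5e-4))
    seed = int(config.get("seed", 0))

    if not methods:
        warnings.warn("config.methods is empty: returning an empty table")
        return pd.DataFrame()

    scenarios = [_parse_scenario(s, f"config.scenarios[{i}]")
                 for i, s in enumerate(config["scenarios"])]
    seeds = np.random.SeedSequence(seed).generate_state(len(scenarios)) % (2 ** 31)

    rows = []
    for i, (scenario, cell_seed) in enumerate(zip(scenarios, seeds)):
        logger.info("cell %d/%d: %s x %d methods, %d reps",
                    i + 1, len(scenarios), scenario.kind, len(methods), reps)
        for s in run_methods_cell(scenario, methods, reps=reps, alpha=alpha,
                                  seed=int(cell_seed)):
            sc = s.scenario
            rows.append({
                "kind": sc.kind, "n": sc.n, "K": sc.k, "maf": sc.maf,
                "error_dist": sc.error_dist, "r": sc.r,
                "beta_g1": sc.beta_g1, "beta_g2": sc.beta_g2,
                "a": sc.a, "h2": sc.h2, "method": s.method,
                "reps": s.reps, "alpha": s.alpha,
                "rejections": s.rejections,
                "rejection_rate": s.rejection_rate, "mc_se": s.mc_se,
            })
    return pd.DataFrame(rows)


def plot_power_curves(table: pd.DataFrame, x: str, out_file,
                      title: Optional[str] = None) -> None:
    """Plot rejection rate against ``x``, one line per method."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for method, sub in table.groupby("method"):
        sub = sub.sort_values(x)
        ax.plot(sub[x], sub["rejection_rate"], marker="o", label=method)
    ax.set_xlabel(x)
    ax.set_ylabel("rejection rate")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_file, dpi=150)
    plt.close(fig)
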