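"""Monte Carlo study harness: performance rates over the design grid.

For every cell of the {trajectory model} x {true K} x {N} grid the harness
repeatedly simulates a dataset, runs the residual-based class enumeration,
and records whether the selected number of classes equals the generating
one.  The cell's performance rate is the percentage of replications with a
correct selection; its standard error is the binomial proportion SE
sqrt(p(1-p)/R), reported on the proportion scale.

Replication seeds derive deterministically from a single master seed via
``numpy.random.SeedSequence``, so cells and replications are independent,
order-invariant, and bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .class_enumerator import EnumerationConfig, select_num_classes
from .simulator import SimulationDesign, simulate

__all__ = [
    "StudyConfig",
    "CellResult",
    "StudyResult",
    "rep_seed",
    "run_replication",
    "run_condition",
    "run_study",
    "default_grid",
]

log = logging.getLogger("gmmresid")

_MODELS = (1, 2)
_KS = (2, 3, 4)
_NS = (180, 540, 1080)


def default_grid(models=_MODELS, ks=_KS, ns=_NS, **kwargs) -> list[SimulationDesign]:
    """The full 2 x 3 x 3 design grid (trajectory model, true K, N)."""
    return [SimulationDesign(k=k, n=n, model=m, **kwargs)
            for m in models for k in ks for n in ns]


@dataclass
class StudyConfig:
    """Replication count, K scan bound and seeding for a Monte Carlo study."""

    replications: int = 100
    k_max: int = 5
    master_seed: int = 0
    enumeration: EnumerationConfig = field(default_factory=EnumerationConfig)

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")


def rep_seed(master_seed: int, design: SimulationDesign, rep: int) -> int:
    """Deterministic per-replication seed < 2**31."""
    ss = np.random.SeedSequence(
        [int(master_seed), design.model, design.k, design.n, rep]
    )
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class CellResult:
    """Performance summary of one design cell."""

    model: int
    k_true: int
    n: int
    n_reps: int
    n_correct: int
    n_under: int
    n_over: int
    n_failed: int
    k_hat: list[int] = field(default_factory=list)

    @property
    def percent_correct(self) -> float:
        return 100.0 * self.n_correct / self.n_reps

    @property
    def se(self) -> float:
        p = self.n_correct / self.n_reps
        return float(np.sqrt(p * (1.0 - p) / self.n_reps))

    def to_row(self) -> dict:
        return {
            "model": self.model, "K_true": self.k_true, "N": self.n,
            "reps": self.n_reps, "percent_correct": self.percent_correct,
            "se": self.se,
            "pct_under": 100.0 * self.n_under / self.n_reps,
            "pct_over": 100.0 * self.n_over / self.n_reps,
            "failures": self.n_failed,
        }


@dataclass
class StudyResult:
    cells: list[CellResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_row() for c in self.cells])

    def to_table(self) -> pd.DataFrame:
        """Wide layout: one row per (model, K), one column per N."""
        df = self.to_frame()
        return df.pivot_table(index=["model", "K_true"], columns="N",
                              values="percent_correct")

    def write(self, csv_path: str | Path | None = None,
              json_path: str | Path | None = None) -> None:
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            payload = [c.to_row() | {"k_hat": c.k_hat} for c in self.cells]
            Path(json_path).write_text(json.dumps(payload, indent=2))


def run_replication(design: SimulationDesign, config: StudyConfig, rep: int) -> int:
    """Simulate one dataset and return the selected number of classes."""
    seed = rep_seed(config.master_seed, design, rep)
    sim = simulate(design, seed=seed)
    enum_cfg = config.enumeration
    if enum_cfg.k_max != config.k_max:
        enum_cfg = replace(enum_cfg, k_max=config.k_max)
    result = select_num_classes(sim.data, design.spec(), k_max=config.k_max,
                                config=enum_cfg)
    return result.k_hat


def run_condition(design: SimulationDesign, config: StudyConfig) -> CellResult:
    """Run all replications of one cell; failures are recorded, not raised."""
    k_hats: list[int] = []
    n_failed = 0
    for rep in range(config.replications):
        try:
            k_hats.append(run_replication(design, config, rep))
        except Exception:  # noqa: BLE001 - a bad replication must not kill the study
            log.exception("replication %d of cell (model=%d, K=%d, N=%d) failed",
                          rep, design.model, design.k, design.n)
            n_failed += 1
    arr = np.array(k_hats, dtype=int)
    cell = CellResult(
        model=design.model, k_true=design.k, n=design.n,
        n_reps=config.replications,
        n_correct=int(np.sum(arr == design.k)),
        n_under=int(np.sum(arr < design.k)),
        n_over=int(np.sum(arr > design.k)),
        n_failed=n_failed, k_hat=arr.tolist(),
    )
    log.info("cell model=%d K=%d N=%d: %.1f%% correct (se %.3f)",
             design.model, design.k, design.n, cell.percent_correct, cell.se)
    return cell


def run_study(config: StudyConfig,
              designs: list[SimulationDesign] | None = None) -> StudyResult:
    """Run every cell of the grid; deterministic given the master seed."""
    designs = designs if designs is not None else default_grid()
    return StudyResult(cells=[run_condition(d, config) for d in designs])
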