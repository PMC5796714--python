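"""Seeded RSBM sweep experiments: sample, minimise, compare, tabulate.

One master seed drives the whole sweep; each (s value, replicate) cell
gets an independent child stream derived deterministically from it, so a
sweep is bit-reproducible and cells are independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .graph import PenaltySpec
from .metrics import adjusted_rand_index, contingency_counts, rank_alignment
from .rsbm import RSBMParams, sample
from .solvers import SolverError, minimize_agony
from .theory import optimal_candidate, planted_estimate

__all__ = ["SweepConfig", "run_sweep"]

log = logging.getLogger("agony")


@dataclass(frozen=True)
class SweepConfig:
    """Declarative description of an RSBM sweep.

    ``s_grid`` lists the backward-link probabilities to scan; each is
    replicated ``replicates`` times with independent seeds spawned from
    ``master_seed``.  ``theory`` adds first-order planted/optimal
    estimates as columns; ``heatmaps`` writes one planted-vs-inferred
    contingency CSV per cell into ``heatmap_dir``.
    """

    p: float
    q: float
    R: int
    n: int
    s_grid: Sequence[float]
    d: float = 1.0
    replicates: int = 1
    master_seed: int = 0
    method: str = "auto"
    theory: bool = True
    heatmaps: bool = False
    heatmap_dir: Optional[str] = None
    time_limit: Optional[float] = None


def _cell_seed(master: int, i_s: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master), spawn_key=(i_s, rep))


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """Run the sweep and return one tidy row per (s, replicate) cell.

    Columns: ``s, replicate, N, m, agony, h_opt, R_inferred, ari,
    alignment`` plus (with ``theory=True``) ``h_planted_est, h_opt_est,
    R_opt_est`` and an ``error`` column which is empty unless the solver
    failed for that cell (the sweep continues).
    """
    import warnings

    spec = PenaltySpec(config.d)
    rows: List[dict] = []
    heat_dir = Path(config.heatmap_dir) if config.heatmap_dir else None
    if config.heatmaps and heat_dir:
        heat_dir.mkdir(parents=True, exist_ok=True)
    for i_s, s in enumerate(config.s_grid):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sweeps may scan s past s_max
            params = RSBMParams(p=config.p, q=config.q, s=float(s),
                                R=config.R, n=config.n)
        theory_cols = {}
        if config.theory:
            est = planted_estimate(params, config.d)
            cand, best = optimal_candidate(params, config.d)
            theory_cols = {"h_planted_est": est.value, "h_opt_est": best.value,
                           "R_opt_est": cand.n_classes(params.R),
                           "opt_inverted_est": cand.inverted}
        for rep in range(config.replicates):
            seed = _cell_seed(config.master_seed, i_s, rep)
            G, planted = sample(params, seed)
            row = {"s": float(s), "replicate": rep, "N": G.n_nodes,
                   "m": G.n_edges, **theory_cols, "error": ""}
            try:
                res = minimize_agony(G, spec, method=config.method,
                                     time_limit=config.time_limit)
                inferred = res.ranking
                row.update(agony=res.agony, h_opt=res.hierarchy,
                           R_inferred=inferred.n_classes,
                           ari=adjusted_rand_index(planted, inferred),
                           alignment=rank_alignment(planted, inferred))
                if config.heatmaps and heat_dir is not None:
                    table = contingency_counts(planted, inferred)
                    pd.DataFrame(table).to_csv(
                        heat_dir / f"heatmap_s{i_s}_rep{rep}.csv", index=False)
            except SolverError as err:
                log.warning("cell (s=%s, rep=%d) failed: %s", s, rep, err)
                row.update(agony=np.nan, h_opt=np.nan, R_inferred=np.nan,
                           ari=np.nan, alignment=np.nan, error=str(err))
            rows.append(row)
    return pd.DataFrame(rows)
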