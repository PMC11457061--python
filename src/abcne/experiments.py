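"""Parameter-recovery experiments on simulator-generated targets.

These helpers run the validation protocol used to characterize the
estimator: simulate replicate target datasets at a known true Ne over a
grid of sample sizes and locus counts, estimate Ne for each with a uniform
prior bracketing the truth, and summarize medians, interval widths and
bias.

Protocol notes (see docs/methods.md): target datasets come straight from
the Wright–Fisher simulator with the same initialization floor as the
reference table and carry no genotyping artifacts, so the estimator runs
with sample filters disabled; the reference table for a grid cell depends
only on (prior, S, L, seed) and is shared across that cell's replicates.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimator import NeEstimator
from .simulate import PriorConfig, build_reference_table, simulate_sample

DEFAULT_MAF_FLOOR = 0.05
DEFAULT_MU = 1.2e-8


def run_recovery_grid(
    true_ne: int,
    prior: tuple[int, int],
    s_values: Sequence[int],
    l_values: Sequence[int],
    replicates: int,
    trials_j: int,
    seed: int,
    acceptance_fraction: float = 0.02,
    maf_floor: float = DEFAULT_MAF_FLOOR,
    mu: float = DEFAULT_MU,
    workers: int = 1,
    t_bounds: tuple[int, int] = (2, 8),
) -> pd.DataFrame:
    """One row per estimator run over the (S, L, replicate) grid.

    Columns: ``s, l, replicate, true_ne, t, median, ci_low, ci_high,
    width, pct_error``.  Fully deterministic given ``seed``.
    """
    root = np.random.SeedSequence(seed)
    rows = []
    for s in s_values:
        for n_loci in l_values:
            cell = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(true_ne, s, n_loci)
            )
            table_ss, targets_ss = cell.spawn(2)
            cfg = PriorConfig(
                ne_low=prior[0], ne_high=prior[1], mu=mu, trials_j=trials_j
            )
            table = build_reference_table(
                cfg, s, n_loci, maf_floor=maf_floor, seed=table_ss, workers=workers
            )
            estimator = NeEstimator(
                ne_low=prior[0],
                ne_high=prior[1],
                mu=mu,
                n_trials=trials_j,
                min_maf=0.0,
                max_missing_individual=1.0,
                max_missing_locus=1.0,
                maf_floor=maf_floor,
                acceptance_fraction=acceptance_fraction,
                random_state=0,
            )
            for rep, rep_ss in enumerate(targets_ss.spawn(replicates)):
                rng = np.random.default_rng(rep_ss)
                t = int(rng.integers(t_bounds[0], t_bounds[1] + 1))
                target = simulate_sample(
                    true_ne, t, 4.8e-4, s, n_loci, mu, maf_floor, rng
                )
                fit = estimator.fit(target, reference_table=table)
                rows.append(
                    {
                        "s": s,
                        "l": n_loci,
                        "replicate": rep,
                        "true_ne": true_ne,
                        "t": t,
                        "median": fit.median_,
                        "ci_low": fit.ci_low_,
                        "ci_high": fit.ci_high_,
                        "width": fit.ci_high_ - fit.ci_low_,
                        "pct_error": 100.0 * (fit.median_ - true_ne) / true_ne,
                    }
                )
    return pd.DataFrame(rows)


def grand_mean_median(runs: pd.DataFrame, s: Optional[int] = None) -> float:
    """Mean of median estimates, optionally restricted to one sample size."""
    sub = runs if s is None else runs[runs["s"] == s]
    return float(sub["median"].mean())


def mean_interval_width(runs: pd.DataFrame, s: Optional[int] = None) -> float:
    sub = runs if s is None else runs[runs["s"] == s]
    return float(sub["width"].mean())


def mean_absolute_pct_error(runs: pd.DataFrame, s: Optional[int] = None) -> float:
    sub = runs if s is None else runs[runs["s"] == s]
    return float(sub["pct_error"].abs().mean())


def signed_bias_pct(runs: pd.DataFrame) -> float:
    return float(runs["pct_error"].mean())


def width_narrowing_pct(runs: pd.DataFrame, s: int, l_wide: int, l_narrow: int) -> float:
    """Relative decrease (%) in mean interval width from l_wide to l_narrow loci."""
    sub = runs[runs["s"] == s]
    w_wide = sub[sub["l"] == l_wide]["width"].mean()
    w_narrow = sub[sub["l"] == l_narrow]["width"].mean()
    return float(100.0 * (w_wide - w_narrow) / w_wide)
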