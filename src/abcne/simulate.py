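"""Two-sex Wright–Fisher forward simulation and the ABC reference table.

The simulator creates a diploid population of census size ``ne`` split into
equal numbers of males and females, initializes each locus from the neutral
folded site-frequency spectrum (density proportional to 1/x, symmetrized)
conditioned on a minor-allele-frequency floor, then mates it at random for
``t`` non-overlapping generations.  Every offspring draws a uniform-random
father and mother and inherits one uniformly chosen allele from each (free
recombination: loci segregate independently); transmitted alleles mutate
(state flip) with probability ``mu``.  With two sexes of equal size the
effective size slightly exceeds the census size; the drawn census value is
recorded as the trial's ``ne`` without correction.

A reference table is ``trials_j`` independent draws of (ne, t, theta) from
the prior, each run through the simulator at the input sample's (S, L) and
summarized by the five statistics.  Each trial owns a counter-derived RNG
substream, so tables are bit-for-bit reproducible and independent of the
worker count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .genotypes import GenotypeMatrix
from .stats import SummaryStatVector, _stats_from_dosage

logger = logging.getLogger(__name__)

SeedLike = Union[int, np.random.SeedSequence]

# dense mutation masks only pay off at high rates; below this the expected
# flip count is resolved by a binomial draw over flat indices
_SPARSE_MU_CUTOFF = 0.01


@dataclass
class PriorConfig:
    """Uniform prior bounds and simulation budget for the ABC estimator.

    ``ne`` and ``t`` are discrete-uniform on their closed bounds; ``theta``
    (the population mutation rate, only recorded as a nuisance draw) is
    log-uniform by default since its default range spans two orders of
    magnitude, with ``theta_prior="linear"`` available.
    """

    ne_low: int = 50
    ne_high: int = 150
    t_low: int = 2
    t_high: int = 8
    theta_low: float = 4.8e-5
    theta_high: float = 4.8e-3
    mu: float = 1.2e-8
    trials_j: int = 20_000
    theta_prior: str = "log-uniform"

    def __post_init__(self) -> None:
        if not 4 <= self.ne_low <= self.ne_high:
            raise ValueError("need 4 <= ne_low <= ne_high")
        if not 2 <= self.t_low <= self.t_high:
            raise ValueError("need 2 <= t_low <= t_high")
        if not 0 < self.theta_low <= self.theta_high:
            raise ValueError("need 0 < theta_low <= theta_high")
        if not 0.0 <= self.mu <= 0.5:
            raise ValueError("mu must lie in [0, 0.5]")
        if self.trials_j < 1:
            raise ValueError("trials_j must be >= 1")
        if self.theta_prior not in ("log-uniform", "linear"):
            raise ValueError("theta_prior must be 'log-uniform' or 'linear'")


@dataclass
class Population:
    """Allele state of one generation: ``alleles[ind, locus, copy]`` is True
    for allele 1.  The first ``n_males`` individuals are male."""

    alleles: np.ndarray
    n_males: int
    initial_freqs: Optional[np.ndarray] = None

    @property
    def size(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def allele1_frequency(self) -> np.ndarray:
        return self.alleles.mean(axis=(0, 2))


@dataclass(frozen=True)
class SimRecord:
    """One reference-table row."""

    ne: int
    t: int
    theta: float
    stats: SummaryStatVector


@dataclass
class ReferenceTable:
    """``trials_j`` simulated records sharing the input sample's (S, L)."""

    ne: np.ndarray
    t: np.ndarray
    theta: np.ndarray
    stats: np.ndarray  # (J, 5) columns he, fis, h_mean, h_var, r2
    n_individuals: int
    n_loci: int
    seed: Optional[int] = None
    n_redrawn: int = 0

    def __len__(self) -> int:
        return self.ne.size

    def record(self, k: int) -> SimRecord:
        return SimRecord(
            int(self.ne[k]),
            int(self.t[k]),
            float(self.theta[k]),
            SummaryStatVector.from_array(self.stats[k]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame({"ne": self.ne, "t": self.t, "theta": self.theta})
        for col, name in enumerate(SummaryStatVector.names):
            frame[name] = self.stats[:, col]
        return frame

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# prior


def draw_prior(cfg: PriorConfig, rng: np.random.Generator) -> tuple[int, int, float]:
    """One (ne, t, theta) draw from the uniform prior."""
    ne = int(rng.integers(cfg.ne_low, cfg.ne_high + 1))
    t = int(rng.integers(cfg.t_low, cfg.t_high + 1))
    if cfg.theta_prior == "log-uniform":
        theta = float(np.exp(rng.uniform(np.log(cfg.theta_low), np.log(cfg.theta_high))))
    else:
        theta = float(rng.uniform(cfg.theta_low, cfg.theta_high))
    return ne, t, theta


# ---------------------------------------------------------------------------
# forward simulation


def _conditioned_sfs_grid(ne: int, maf_floor: float) -> tuple[np.ndarray, np.ndarray]:
    """Folded neutral spectrum on the 1/(2ne) grid, restricted to the MAF floor."""
    k = np.arange(1, 2 * ne)
    x = k / (2.0 * ne)
    w = 1.0 / k + 1.0 / (2.0 * ne - k)
    keep = np.minimum(x, 1.0 - x) >= maf_floor - 1e-12
    if not keep.any():
        raise ValueError(
            f"maf_floor={maf_floor} leaves no admissible initial frequency "
            f"for ne={ne}"
        )
    x, w = x[keep], w[keep]
    return x, w / w.sum()


def init_population(
    ne: int,
    theta: float,
    n_loci: int,
    maf_floor: float,
    rng: np.random.Generator,
) -> Population:
    """Found a population at mutation–drift-equilibrium-like polymorphism.

    Initial allele-1 frequencies come from the folded 1/x spectrum
    conditioned on minor frequency >= ``maf_floor`` (every locus starts
    polymorphic, matching a MAF-filtered input panel); genotypes are then
    Hardy–Weinberg binomial draws.  ``theta`` scales the polymorphism of the
    unconditioned process and is carried in the record; conditioning on the
    fixed number of polymorphic loci removes its influence on the draw.
    """
    if ne < 4:
        raise ValueError("ne must be >= 4")
    if ne % 2:
        # constant message so the default warning filter reports it once
        warnings.warn(
            "odd census size rounded up to the next even value (equal sexes)",
            stacklevel=2,
        )
        ne += 1
    if n_loci < 1:
        raise ValueError("need at least one locus")
    x, w = _conditioned_sfs_grid(ne, maf_floor)
    freqs = rng.choice(x, size=n_loci, p=w)
    alleles = rng.random((ne, n_loci, 2)) < freqs[None, :, None]
    return Population(alleles, n_males=ne // 2, initial_freqs=freqs)


def _mutate(alleles: np.ndarray, mu: float, rng: np.random.Generator) -> None:
    if mu <= 0.0:
        return
    if mu >= _SPARSE_MU_CUTOFF:
        flips = rng.random(alleles.shape) < mu
        alleles ^= flips
        return
    n_flip = rng.binomial(alleles.size, mu)
    if n_flip:
        flat = rng.integers(0, alleles.size, size=n_flip)
        alleles.reshape(-1)[flat] ^= True


def advance_generation(
    pop: Population,
    mu: float,
    rng: np.random.Generator,
    offspring_n: Optional[int] = None,
) -> Population:
    """Produce the next non-overlapping generation by random mating.

    ``offspring_n`` overrides the cohort size (defaults to the parent census
    size); offspring sexes are assigned to keep the counts as equal as
    possible.
    """
    n_m = pop.n_males
    n_f = pop.size - n_m
    if n_m < 1 or n_f < 1:
        raise ValueError("population needs at least one male and one female")
    n_off = pop.size if offspring_n is None else int(offspring_n)
    fathers = rng.integers(0, n_m, size=n_off)
    mothers = n_m + rng.integers(0, n_f, size=n_off)
    n_loci = pop.n_loci

    pat_src = pop.alleles[fathers]  # (n_off, L, 2)
    mat_src = pop.alleles[mothers]
    which_p = rng.random((n_off, n_loci)) < 0.5
    which_m = rng.random((n_off, n_loci)) < 0.5
    paternal = np.where(which_p, pat_src[:, :, 0], pat_src[:, :, 1])
    maternal = np.where(which_m, mat_src[:, :, 0], mat_src[:, :, 1])
    offspring = np.stack([paternal, maternal], axis=2)
    _mutate(offspring, mu, rng)
    return Population(offspring, n_males=n_off // 2)


def _simulate_dosage(
    ne: int,
    t: int,
    theta: float,
    n_ind: int,
    n_loci: int,
    mu: float,
    maf_floor: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Forward-simulate and return the sampled cohort's allele-1 dosages (S, L)."""
    if t < 1:
        raise ValueError("t must be >= 1")
    pop = init_population(ne, theta, n_loci, maf_floor, rng)
    for _ in range(t):
        pop = advance_generation(pop, mu, rng)
    cohort_n = max(pop.size, n_ind)
    cohort = advance_generation(pop, mu, rng, offspring_n=cohort_n)
    pick = rng.permutation(cohort_n)[:n_ind]
    return cohort.alleles[pick].sum(axis=2).astype(np.int8)


def simulate_sample(
    ne: int,
    t: int,
    theta: float,
    n_individuals: int,
    n_loci: int,
    mu: float,
    maf_floor: float,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Simulate one population and sample ``n_individuals`` fresh progeny.

    The terminal progeny cohort produced by the generation-``t`` adults has
    size ``max(ne, n_individuals)`` — progeny counts are not bounded by the
    parental census size — and the sample is drawn from it without
    replacement.
    """
    dosage = _simulate_dosage(ne, t, theta, n_individuals, n_loci, mu, maf_floor, rng)
    calls = np.where(
        (np.arange(2)[None, None, :] < dosage[:, :, None]), np.int8(1), np.int8(2)
    )
    return GenotypeMatrix(
        calls,
        [f"sim_{k + 1}" for k in range(n_individuals)],
        [f"locus_{k + 1}" for k in range(n_loci)],
        population_label=f"wf_ne{ne}_t{t}",
    )


# ---------------------------------------------------------------------------
# reference table


def _run_trial(
    cfg: PriorConfig,
    n_ind: int,
    n_loci: int,
    maf_floor: float,
    seedseq: np.random.SeedSequence,
) -> tuple[int, int, float, np.ndarray, int]:
    """One reference-table row; redraws until the LD statistic is defined."""
    redraws = 0
    stream = seedseq
    while True:
        rng = np.random.default_rng(stream)
        ne, t, theta = draw_prior(cfg, rng)
        dosage = _simulate_dosage(ne, t, theta, n_ind, n_loci, cfg.mu, maf_floor, rng)
        row = _stats_from_dosage(dosage)
        if np.isfinite(row).all():
            return ne, t, theta, row, redraws
        redraws += 1
        stream = stream.spawn(1)[0]


def _trial_batch(cfg, n_ind, n_loci, maf_floor, seedseqs):
    return [_run_trial(cfg, n_ind, n_loci, maf_floor, ss) for ss in seedseqs]


def build_reference_table(
    cfg: PriorConfig,
    n_individuals: int,
    n_loci: int,
    maf_floor: float = 0.05,
    seed: Optional[SeedLike] = None,
    workers: int = 1,
) -> ReferenceTable:
    """Simulate ``cfg.trials_j`` samples at the input's (S, L) and summarize them.

    Bit-for-bit reproducible given ``seed`` and independent of ``workers``:
    trial k always consumes the k-th spawned substream.  Trials whose sample
    has no usable LD pair (or is fully monomorphic) are redrawn; a warning is
    emitted when more than 1% of trials needed redrawing.
    """
    if isinstance(seed, np.random.SeedSequence):
        root = seed
        seed_int = None
    else:
        root = np.random.SeedSequence(seed)
        seed_int = seed
    children = root.spawn(cfg.trials_j)

    if workers > 1 and cfg.trials_j > 8:
        chunks = np.array_split(np.arange(cfg.trials_j), workers * 4)
        results_nested = Parallel(n_jobs=workers)(
            delayed(_trial_batch)(
                cfg, n_individuals, n_loci, maf_floor, [children[k] for k in chunk]
            )
            for chunk in chunks
            if chunk.size
        )
        results = [row for batch in results_nested for row in batch]
    else:
        results = _trial_batch(cfg, n_individuals, n_loci, maf_floor, children)

    ne = np.array([r[0] for r in results], dtype=np.int64)
    t = np.array([r[1] for r in results], dtype=np.int64)
    theta = np.array([r[2] for r in results], dtype=np.float64)
    stats = np.stack([r[3] for r in results])
    n_redrawn = int(sum(r[4] for r in results))
    if n_redrawn > 0.01 * cfg.trials_j:
        warnings.warn(
            f"{n_redrawn} of {cfg.trials_j} trials were redrawn for lacking a "
            "usable LD pair; the prior may reach very small Ne for this panel",
            stacklevel=2,
        )
    return ReferenceTable(
        ne, t, theta, stats, n_individuals, n_loci, seed=seed_int, n_redrawn=n_redrawn
    )
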