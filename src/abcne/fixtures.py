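"""Deterministic synthetic GENEPOP datasets for testing and benchmarking.

Datasets are produced by the package's own Wright–Fisher simulator at known
(Ne, t, S, L), optionally degraded with uniform-at-random missingness, and
serialized through the GENEPOP writer, so every other module is testable
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .genepop import write_genepop
from .simulate import simulate_sample


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    ne: int = 100
    t: int = 5
    n_individuals: int = 50
    n_loci: int = 40
    mu: float = 1.2e-8
    maf_floor: float = 0.05
    missing_rate_individuals: float = 0.0
    missing_rate_loci: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate_individuals", "missing_rate_loci"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_individuals < 1 or self.n_loci < 1:
            raise ValueError("dimensions must be positive")


def make_matrix(spec: FixtureSpec) -> GenotypeMatrix:
    """Simulate the sample and inject missingness; deterministic per seed."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    matrix = simulate_sample(
        spec.ne,
        spec.t,
        theta=4.8e-4,
        n_individuals=spec.n_individuals,
        n_loci=spec.n_loci,
        mu=spec.mu,
        maf_floor=spec.maf_floor,
        rng=rng,
    )
    # the two rates act as independent per-cell masking processes
    p_miss = 1.0 - (1.0 - spec.missing_rate_individuals) * (1.0 - spec.missing_rate_loci)
    if p_miss > 0.0:
        mask = rng.random((spec.n_individuals, spec.n_loci)) < p_miss
        calls = matrix.calls.copy()
        calls[mask] = MISSING
        matrix = GenotypeMatrix(
            calls, matrix.individual_ids, matrix.locus_ids, matrix.population_label
        )
    return matrix


def make_dataset(spec: FixtureSpec, allele_width: int = 2) -> str:
    """GENEPOP text for one synthetic dataset."""
    return write_genepop(make_matrix(spec), allele_width)


def make_grid(
    ne_values: Sequence[int],
    s_values: Sequence[int],
    l_values: Sequence[int],
    replicates: int,
    seed: int,
    out_dir: str | Path,
    t_bounds: tuple[int, int] = (2, 8),
    maf_floor: float = 0.05,
) -> pd.DataFrame:
    """Cartesian grid of GENEPOP fixtures plus a TSV manifest of true parameters.

    Every cell/replicate gets its own derived seed, so no two emitted files
    are identical; the manifest lists one row per file with the generating
    parameters.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    counter = 0
    for ne in ne_values:
        for s in s_values:
            for n_loci in l_values:
                for rep in range(replicates):
                    child = np.random.SeedSequence(entropy=seed, spawn_key=(counter,))
                    sub_seed = int(child.generate_state(1)[0] % (2**31))
                    t = int(
                        np.random.default_rng(child).integers(
                            t_bounds[0], t_bounds[1] + 1
                        )
                    )
                    spec = FixtureSpec(
                        ne=ne,
                        t=t,
                        n_individuals=s,
                        n_loci=n_loci,
                        maf_floor=maf_floor,
                        seed=sub_seed,
                    )
                    name = f"ne{ne}_s{s}_l{n_loci}_rep{rep}.gen"
                    (out_dir / name).write_text(make_dataset(spec), encoding="utf-8")
                    rows.append(
                        {
                            "filename": name,
                            "ne": ne,
                            "t": t,
                            "n_individuals": s,
                            "n_loci": n_loci,
                            "replicate": rep,
                            "seed": sub_seed,
                        }
                    )
                    counter += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
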